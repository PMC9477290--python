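"""K-fold splitting, weighted percentiles, transition matrices, ROC/AUROC,
cross-validated simulation, and report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ticsim.errors import DomainError
from ticsim.microsim_engine import SimulationConfig, simulate
from ticsim.validation import (
    cross_validated_simulate,
    evaluate,
    full_followup_ids,
    kfold_split,
    roc_auc,
    transition_matrix,
    weighted_percentiles,
)


class TestKFold:
    def test_small_even_split(self):
        folds = kfold_split(np.arange(10), 5, seed=1)
        sizes = folds.value_counts()
        assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_reproducible(self):
        a = kfold_split(np.arange(100), 5, seed=3)
        b = kfold_split(np.arange(100), 5, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_survey_sized_split(self):
        folds = kfold_split(np.arange(13_106), 5, seed=0)
        sizes = sorted(folds.value_counts())
        assert set(sizes) == {2621, 2622}
        assert sum(sizes) == 13_106

    def test_invalid_k(self):
        with pytest.raises(DomainError):
            kfold_split(np.arange(10), 1, seed=0)
        with pytest.raises(DomainError):
            kfold_split(np.arange(10), 11, seed=0)


class TestWeightedPercentiles:
    def test_hand_computed_cdf(self):
        d = weighted_percentiles([10, 20, 30], [1, 1, 2], probs=(0.5,))
        assert d.percentiles[0.5] == 20

    def test_uniform_weights_match_type1_quantiles(self):
        rng = np.random.default_rng(4)
        v = rng.integers(0, 28, 57).astype(float)
        d = weighted_percentiles(v, np.ones(57))
        for p, got in d.percentiles.items():
            assert got == np.quantile(v, p, method="inverted_cdf")

    def test_point_mass(self):
        d = weighted_percentiles([5.0, 9.0], [1e-12, 1.0])
        assert (d.percentiles == 9.0).all()

    def test_empty_is_domain_error(self):
        with pytest.raises(DomainError):
            weighted_percentiles([], [])

    def test_percentiles_non_decreasing_property(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            v = rng.normal(size=30)
            w = rng.uniform(0.1, 2.0, size=30)
            d = weighted_percentiles(v, w)
            assert (np.diff(d.percentiles.to_numpy()) >= 0).all()


class TestTransitionMatrix:
    def test_everyone_stays_normal(self):
        m = transition_matrix([0, 0, 0], [0, 0, 0], [1, 1, 1])
        assert m.loc["normal", "normal"] == 100
        assert m.to_numpy().sum() == pytest.approx(100)

    def test_hand_built_quarters(self):
        b = [0, 0, 1, 2]
        f = [1, 3, 3, 2]
        m = transition_matrix(b, f, [1, 1, 1, 1])
        assert m.loc["normal", "mci"] == 25
        assert m.loc["normal", "dead_without_dementia"] == 25
        assert m.loc["mci", "dead_without_dementia"] == 25
        assert m.loc["dementia", "dementia"] == 25

    def test_baseline_dementia_death_goes_to_dead_with_dementia(self):
        m = transition_matrix([2], [4], [1.0])
        assert m.loc["dementia", "dead_with_dementia"] == 100
        assert m.drop(columns="dead_with_dementia").to_numpy().sum() == 0

    def test_structural_zero_violation_raises(self):
        with pytest.raises(DomainError):
            transition_matrix([1], [0], [1.0])
        with pytest.raises(DomainError):
            transition_matrix([2], [3], [1.0])


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.1], [1, 0]).auroc == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.3, 0.3, 0.3, 0.3], [1, 0, 1, 0]).auroc == 0.5

    def test_hand_counted_pairs(self):
        assert roc_auc([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0]).auroc == 0.75

    def test_degenerate_outcomes_raise(self):
        with pytest.raises(DomainError):
            roc_auc([0.1, 0.2], [1, 1])
        with pytest.raises(DomainError):
            roc_auc([0.1, 0.2], [0, 0])

    def test_matches_brute_force_concordance_including_ties(self):
        rng = np.random.default_rng(11)
        for trial in range(25):
            n = int(rng.integers(10, 200))
            risks = np.round(rng.random(n), 2)  # rounding forces ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            res = roc_auc(risks, y)
            cases = risks[y == 1]
            controls = risks[y == 0]
            conc = (cases[:, None] > controls[None, :]).sum()
            ties = (cases[:, None] == controls[None, :]).sum()
            brute = (conc + 0.5 * ties) / (len(cases) * len(controls))
            assert res.auroc == pytest.approx(brute, abs=1e-12)

    def test_curve_monotone_and_area_consistent(self):
        rng = np.random.default_rng(12)
        risks = np.round(rng.random(300), 1)
        y = (rng.random(300) < risks).astype(int)
        res = roc_auc(risks, y)
        assert res.fpr[0] == 0 and res.tpr[0] == 0
        assert res.fpr[-1] == 1 and res.tpr[-1] == 1
        assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()
        assert res.auroc == pytest.approx(np.trapezoid(res.tpr, res.fpr), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(0, 1, allow_nan=False).map(lambda x: round(x, 4)),
            min_size=4,
            max_size=40,
        ),
        st.data(),
    )
    def test_invariant_under_monotone_transform(self, risks, data):
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=len(risks), max_size=len(risks))
        )
        if sum(y) in (0, len(y)):
            return
        risks = np.asarray(risks)
        base = roc_auc(risks, y).auroc
        assert roc_auc(3 * risks + 2, y).auroc == pytest.approx(base, abs=1e-12)
        assert roc_auc(np.exp(risks), y).auroc == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# Cross-validated simulation and evaluation
# ---------------------------------------------------------------------------


def test_cross_validation_contract(tiny_panel, reduced_spec):
    """k=2 on a 100-person panel runs end-to-end and returns both fold fits.

    At this scale several rare indicators are constant within a fold, so
    the smoke contract uses the reduced design a practitioner would fit on
    a tiny sample; the full design keeps its rank-deficiency error.
    """
    ids = tiny_panel["person_id"].unique()[:100]
    panel = tiny_panel[tiny_panel["person_id"].isin(ids)]
    cfg = SimulationConfig(horizon_waves=2, replicates=3, base_seed=4)
    outcomes, fits = cross_validated_simulate(panel, 2, cfg, spec=reduced_spec, seed=9)
    assert len(fits) == 2
    assert all(t.converged and m.converged for t, m in fits)
    # every person simulated exactly once
    assert np.array_equal(
        np.sort(outcomes.person_id), np.sort(panel["person_id"].unique())
    )
    assert len(np.unique(outcomes.person_id)) == len(outcomes.person_id)


def test_fold_exclusion_changes_risks(small_panel, true_models):
    """Held-out risks must differ from train-on-all risks for some persons."""
    from ticsim.microsim_engine import risk_fraction
    from ticsim.transition_models import fit_mortality_model, fit_tics_model

    sub_ids = small_panel["person_id"].unique()[:1000]
    panel = small_panel[small_panel["person_id"].isin(sub_ids)]
    cfg = SimulationConfig(horizon_waves=2, replicates=5, base_seed=1)
    pooled, _ = cross_validated_simulate(panel, 2, cfg, seed=2)
    tics_fit = fit_tics_model(panel, compute_se=False)
    mort_fit = fit_mortality_model(panel, compute_se=False)
    waves = sorted(panel["wave"].unique())[:2]
    non_cv = simulate(
        panel[panel["wave"].isin(waves)], tics_fit.params, mort_fit.params, cfg
    )
    r_cv = risk_fraction(pooled, "dementia_or_dead_with_dementia", 2)
    r_all = risk_fraction(non_cv, "dementia_or_dead_with_dementia", 2)
    assert not np.allclose(r_cv, r_all)


def test_full_followup_filter_excludes_mid_panel_nonrespondent():
    rows = []
    for pid, waves in ((1, [-1, 0, 1, 2]), (2, [-1, 0, 2]), (3, [-1, 0, 1])):
        for w in waves:
            rows.append({"person_id": pid, "wave": w, "alive": 1, "tics27": 15.0})
    panel = pd.DataFrame(rows)
    # person 3 dies at wave 1: death row then nothing (complete follow-up)
    panel.loc[(panel.person_id == 3) & (panel.wave == 1), "alive"] = 0
    ids = full_followup_ids(panel, horizon_wave=2)
    assert 1 in ids and 3 in ids and 2 not in ids


def test_evaluate_full_sample_duplicated_by_everyone_subgroup(tiny_panel, true_models):
    tics, mort = true_models
    waves = sorted(tiny_panel["wave"].unique())[:2]
    out = simulate(
        tiny_panel[tiny_panel["wave"].isin(waves)],
        tics,
        mort,
        SimulationConfig(horizon_waves=3, replicates=10, base_seed=6),
    )
    n = len(out.person_id)
    rep = evaluate(
        tiny_panel,
        out,
        horizons=[3],
        predicates=["dementia_or_dead_with_dementia"],
        subgroups={"full_sample": np.ones(n, bool), "everyone": np.ones(n, bool)},
    )
    a = rep.auroc.set_index("subgroup")
    assert a.loc["full_sample", "auroc"] == a.loc["everyone", "auroc"]
    with pytest.raises(DomainError):
        evaluate(tiny_panel, out, horizons=[9])


def test_transition_matrix_cells_sum_to_100(small_panel, true_models):
    tics, mort = true_models
    waves = sorted(small_panel["wave"].unique())[:2]
    out = simulate(
        small_panel[small_panel["wave"].isin(waves)],
        tics,
        mort,
        SimulationConfig(horizon_waves=5, replicates=10, base_seed=14),
    )
    rep = evaluate(small_panel, out, horizons=[5], predicates=["dementia_or_dead_with_dementia"])
    for m in (rep.transition_truth, rep.transition_sim):
        assert m.to_numpy().sum() == pytest.approx(100, abs=0.1)
        assert m.loc["mci", "normal"] == 0
        assert m.loc["dementia", "normal"] == 0
        assert m.loc["dementia", "mci"] == 0
        assert m.loc["dementia", "dead_without_dementia"] == 0
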