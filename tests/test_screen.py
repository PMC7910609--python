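"""Group contrasts, candidate selection criteria and permutation FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meltscreen import (
    ExperimentConfig,
    PermutationFdrResult,
    Thresholds,
    compare_groups,
    estimate_fdr_permutation,
    replicate_variation_summary,
    select_candidates,
    summarize_shifts,
)
from .conftest import eight_sample_columns, make_tm_table

CFG = ExperimentConfig()


class TestCompareGroups:
    def test_hand_computed_pooled_t(self):
        """{50, 51} vs {47, 48}: ΔTm = 3, t = 4.2426 (df 2), p = 0.0513."""
        table = make_tm_table(
            {
                ("cosubstrate", 1): [50.0],
                ("cosubstrate", 2): [51.0],
                ("vehicle", 1): [47.0],
                ("vehicle", 2): [48.0],
            }
        )
        res = compare_groups(table, "cosubstrate", "vehicle").iloc[0]
        assert res["delta_tm"] == pytest.approx(3.0)
        assert res["t"] == pytest.approx(4.2426, abs=1e-4)
        assert res["p_value"] == pytest.approx(0.0513, abs=1e-4)
        assert res["variance_mode"] == "student"
        assert res["df"] == 2

    def test_identical_groups_give_p_one(self):
        table = make_tm_table(
            {
                ("both", 1): [50.0, 48.0],
                ("both", 2): [51.0, 49.0],
                ("enzyme", 1): [50.0, 48.0],
                ("enzyme", 2): [51.0, 49.0],
            }
        )
        res = compare_groups(table, "both", "enzyme")
        assert (res["delta_tm"] == 0).all()
        assert (res["p_value"] == 1.0).all()

    def test_matches_scipy_ttest(self):
        """Vectorized test agrees with scipy's reference implementation."""
        rng = np.random.default_rng(4)
        vals = rng.normal(50, 2, (60, 3 * 2))
        cols = [("both", r) for r in (1, 2, 3)] + [("enzyme", r) for r in (1, 2, 3)]
        table = make_tm_table(vals, columns=cols)
        res = compare_groups(table, "both", "enzyme")
        for i in range(60):
            a, b = vals[i, :3], vals[i, 3:]
            f = a.var(ddof=1) / b.var(ddof=1)
            pf = 2 * min(stats.f.cdf(f, 2, 2), stats.f.sf(f, 2, 2))
            ref = stats.ttest_ind(a, b, equal_var=pf >= 0.05)
            assert res["p_value"].iloc[i] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_null_p_values_are_uniform(self):
        """With no effects the p-value distribution is approximately uniform."""
        rng = np.random.default_rng(8)
        vals = rng.normal(52, 0.5, (4000, 8))
        table = make_tm_table(vals, columns=eight_sample_columns())
        res = compare_groups(table, "both", "enzyme")
        frac = (res["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_incomplete_proteins_skipped(self):
        table = make_tm_table(
            {
                ("both", 1): [50.0, np.nan],
                ("both", 2): [51.0, 50.0],
                ("enzyme", 1): [47.0, 47.0],
                ("enzyme", 2): [48.0, 48.0],
            }
        )
        res = compare_groups(table, "both", "enzyme")
        assert np.isnan(res["delta_tm"].iloc[1])


def substrate_table(both, enzyme, cosub, vehicle=(50.0, 50.0)):
    return make_tm_table(
        {
            ("both", 1): [both[0]],
            ("both", 2): [both[1]],
            ("enzyme", 1): [enzyme[0]],
            ("enzyme", 2): [enzyme[1]],
            ("cosubstrate", 1): [cosub[0]],
            ("cosubstrate", 2): [cosub[1]],
            ("vehicle", 1): [vehicle[0]],
            ("vehicle", 2): [vehicle[1]],
        }
    )


class TestSelection:
    def test_clear_substrate_is_selected(self):
        """+3 °C against both single arms with small p → stabilized substrate."""
        table = substrate_table(
            both=(53.0, 53.1), enzyme=(50.0, 50.1), cosub=(50.0, 50.3)
        )
        cand = select_candidates(table, CFG, "substrate").iloc[0]
        assert cand["selected"] and cand["direction"] == "stabilized"
        assert cand["delta_tm"] == pytest.approx(2.95, abs=0.01)

    def test_small_shift_in_one_contrast_rejected(self):
        """ΔTm must exceed 1 °C in *both* substrate contrasts."""
        table = substrate_table(
            both=(50.4, 50.5), enzyme=(50.0, 50.1), cosub=(47.4, 47.5)
        )
        cand = select_candidates(table, CFG, "substrate").iloc[0]
        assert not cand["dtm_pass"] and not cand["selected"]

    def test_discordant_signs_rejected(self):
        """A Tm between the two single arms is not a specific combination shift."""
        table = substrate_table(
            both=(50.5, 50.6), enzyme=(48.0, 48.1), cosub=(53.0, 53.1)
        )
        cand = select_candidates(table, CFG, "substrate").iloc[0]
        assert cand["dtm_pass"] and not cand["sign_concordant"]
        assert not cand["selected"]

    def test_binder_uses_cosubstrate_vs_vehicle(self):
        table = substrate_table(
            both=(50.0, 50.1), enzyme=(50.0, 50.1),
            cosub=(53.0, 53.1), vehicle=(50.0, 50.1),
        )
        binder = select_candidates(table, CFG, "cosubstrate_binder").iloc[0]
        substrate = select_candidates(table, CFG, "substrate").iloc[0]
        assert binder["selected"]
        # shifted with cosubstrate alone: the specificity contrast filters it
        assert not substrate["selected"]

    def test_binder_shared_shift_never_substrate(self):
        """Equal shift in cosubstrate-alone and both arms → binder, not substrate."""
        table = substrate_table(
            both=(53.0, 53.1), enzyme=(50.0, 50.1),
            cosub=(53.0, 53.1), vehicle=(50.0, 50.1),
        )
        assert select_candidates(table, CFG, "cosubstrate_binder").iloc[0]["selected"]
        assert not select_candidates(table, CFG, "substrate").iloc[0]["selected"]

    def test_interactor_uses_enzyme_vs_vehicle(self):
        table = substrate_table(
            both=(47.0, 47.1), enzyme=(46.9, 47.2),
            cosub=(50.0, 50.1), vehicle=(50.0, 50.1),
        )
        inter = select_candidates(table, CFG, "enzyme_interactor").iloc[0]
        assert inter["selected"] and inter["direction"] == "destabilized"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_selection_is_threshold_monotone(self, seed):
        """Stricter thresholds can only shrink the candidate set."""
        rng = np.random.default_rng(seed)
        vals = rng.normal(52, 1.0, (300, 8))
        vals[:30, 6:] += rng.normal(2.5, 0.5, (30, 2))  # shift the both arm
        table = make_tm_table(
            vals,
            columns=[
                (t, r)
                for t in ("vehicle", "cosubstrate", "enzyme", "both")
                for r in (1, 2)
            ],
        )
        loose = select_candidates(table, CFG, "substrate")
        strict_cfg = ExperimentConfig(
            thresholds=Thresholds(p_primary=0.01, p_secondary=0.05, dtm_min=1.5)
        )
        strict = select_candidates(table, strict_cfg, "substrate")
        loose_set = set(loose.index[loose["selected"]])
        strict_set = set(strict.index[strict["selected"]])
        assert strict_set <= loose_set


class TestPermutationFdr:
    def test_constant_tm_has_no_permuted_hits(self):
        """Identical Tm everywhere: nothing to find, shuffled or not."""
        vals = np.full((50, 8), 52.0)
        table = make_tm_table(vals, columns=eight_sample_columns())
        with pytest.warns(RuntimeWarning, match="undefined"):
            res = estimate_fdr_permutation(table, CFG, "substrate", n_perm=10, seed=0)
        assert res.observed_hits == 0
        assert res.mean_permuted_hits == 0
        assert np.isnan(res.fdr)

    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(52, 0.8, (200, 8))
        vals[:10, 6:] += 3.0
        table = make_tm_table(vals, columns=eight_sample_columns())
        r1 = estimate_fdr_permutation(table, CFG, "substrate", n_perm=20, seed=5)
        r2 = estimate_fdr_permutation(table, CFG, "substrate", n_perm=20, seed=5)
        assert r1.per_round_hits == r2.per_round_hits
        assert r1.fdr == r2.fdr
        assert r1.observed_hits == 10

    def test_column_granularity_mode(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(52, 0.8, (200, 8))
        vals[:10, 6:] += 3.0
        table = make_tm_table(vals, columns=eight_sample_columns())
        res = estimate_fdr_permutation(
            table, CFG, "substrate", n_perm=10, seed=5, granularity="column"
        )
        assert res.n_permutations == 10 and res.observed_hits == 10

    def test_fdr_arithmetic(self):
        assert PermutationFdrResult.fdr_from_counts(78, 12.0) == pytest.approx(
            0.1538, abs=1e-4
        )
        assert np.isnan(PermutationFdrResult.fdr_from_counts(0, 3.0))


class TestSummaries:
    def test_replicate_variation_identical_replicates(self):
        vals = np.tile(np.linspace(48, 55, 20)[:, None], (1, 8))
        table = make_tm_table(vals, columns=eight_sample_columns())
        summary = replicate_variation_summary(table)
        assert (summary["median_sd"] == 0).all()

    def test_replicate_variation_median_arithmetic(self):
        """Per-protein replicate SDs {0.2, 0.8} → median 0.5."""
        sd_to_diff = lambda sd: sd * np.sqrt(2)  # |x1-x2| giving that SD
        table = make_tm_table(
            {
                ("vehicle", 1): [50.0, 50.0],
                ("vehicle", 2): [50.0 + sd_to_diff(0.2), 50.0 + sd_to_diff(0.8)],
            }
        )
        summary = replicate_variation_summary(table)
        assert summary.loc["vehicle", "median_sd"] == pytest.approx(0.5)

    def test_shift_summary_arithmetic(self):
        cand = pd.DataFrame(
            {
                "selected": [True, True, True],
                "delta_tm": [2.0, -3.0, -1.5],
                "direction": ["stabilized", "destabilized", "destabilized"],
            }
        )
        s = summarize_shifts(cand)
        assert (s["n_stabilized"], s["n_destabilized"]) == (1, 2)
        assert s["mean_abs_dtm"] == pytest.approx(2.1667, abs=1e-3)
        assert s["median_abs_dtm"] == pytest.approx(2.0)

    def test_empty_summary(self):
        s = summarize_shifts(pd.DataFrame(columns=["selected", "delta_tm", "direction"]))
        assert s["n_candidates"] == 0 and np.isnan(s["mean_abs_dtm"])
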