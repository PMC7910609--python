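"""OPLS-DA model structure, VIP identities and candidate ranking."""

import warnings

import numpy as np
import pandas as pd
import pytest

from meltscreen import ModelError, compute_vip, fit_oplsda, rank_candidates


def random_matrix(n_samples=6, n_proteins=50, seed=0, effect=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(52, 1.0, (n_samples, n_proteins))
    half = n_samples // 2
    if effect is not None:
        for j, size in effect.items():
            X[:half, j] += size
    samples = [f"s{i}" for i in range(n_samples)]
    df = pd.DataFrame(X, index=samples, columns=[f"P{j:03d}" for j in range(n_proteins)])
    return df, samples[:half], samples[half:]


class TestModelStructure:
    def test_predictive_orthogonal_scores_are_orthogonal(self):
        X, a, b = random_matrix(seed=1)
        model = fit_oplsda(X, a, b, n_ortho=1)
        assert abs(model.t_pred @ model.t_ortho[0]) < 1e-8

    def test_zero_ortho_matches_pls_oracle(self):
        """n_ortho = 0 reduces to one-component PLS-DA (sklearn NIPALS oracle)."""
        from sklearn.cross_decomposition import PLSRegression

        X, a, b = random_matrix(seed=2, n_proteins=30)
        model = fit_oplsda(X, a, b, n_ortho=0)
        y = np.array([1.0] * 3 + [-1.0] * 3)
        oracle = PLSRegression(n_components=1, scale=True).fit(X.to_numpy(), y)
        got = model.predict(X.to_numpy()) + y.mean()
        want = oracle.predict(X.to_numpy()).ravel()
        assert np.allclose(got, want, atol=1e-8)

    def test_orthogonal_removal_then_pls_is_identity(self):
        """Deflating the orthogonal component and fitting plain PLS reproduces
        the OPLS predictive component — the defining property."""
        X, a, b = random_matrix(seed=3)
        m1 = fit_oplsda(X, a, b, n_ortho=1)
        Xs = (X.to_numpy() - m1.x_mean) / m1.x_scale
        Xd = Xs - np.outer(m1.t_ortho[0], m1.p_ortho[0])
        df = pd.DataFrame(Xd, index=X.index, columns=X.columns)
        m0 = fit_oplsda(df, a, b, n_ortho=0, scale="center")
        assert np.allclose(m0.t_pred, m1.t_pred, atol=1e-10)
        assert np.allclose(
            m0.t_pred * m0.c_pred, m1.t_pred * m1.c_pred, atol=1e-10
        )

    def test_perfect_separator_dominates_loadings(self):
        sep = np.array([53.0, 53.1, 52.9, 50.0, 49.9, 50.1])  # separates classes
        # identical pattern in both classes: zero class covariance
        noise = np.array([50.1, 49.95, 50.05, 50.1, 49.95, 50.05])
        X = pd.DataFrame(
            {"SEP": sep, "NOISE": noise}, index=[f"s{i}" for i in range(6)]
        )
        model = fit_oplsda(X, ["s0", "s1", "s2"], ["s3", "s4", "s5"], n_ortho=0)
        w = pd.Series(np.abs(model.w_pred), index=model.proteins)
        assert w["SEP"] > 5 * w["NOISE"]
        # the separator loads on the same side as the positive-class star
        load = pd.Series(model.p_pred, index=model.proteins)
        ref = model.reference_points.loc["class_a", "p_pred"]
        assert np.sign(load["SEP"]) == np.sign(ref)

    def test_too_many_orthogonal_components_rejected(self):
        X, a, b = random_matrix(n_samples=4, seed=5)
        with pytest.raises(ModelError):
            fit_oplsda(X, a, b, n_ortho=3)

    def test_zero_variance_protein_dropped(self):
        X, a, b = random_matrix(seed=6, n_proteins=10)
        X["P000"] = 52.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_oplsda(X, a, b, n_ortho=1)
        assert "P000" not in model.proteins
        assert model.dropped_proteins == ["P000"]


class TestVip:
    def test_sum_of_squares_identity(self):
        """ΣVIP² equals the number of proteins on any fitted model."""
        for seed in (0, 1):
            X, a, b = random_matrix(seed=seed)
            model = fit_oplsda(X, a, b, n_ortho=1)
            for variant in ("predictive", "total"):
                vip = compute_vip(model, variant=variant, confidence=False)
                assert np.sum(vip["vip"] ** 2) == pytest.approx(
                    len(model.proteins), abs=1e-6
                )

    def test_identical_variables_have_unit_vip(self):
        base = np.array([1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
        X = pd.DataFrame(
            {f"P{j}": base for j in range(5)}, index=[f"s{i}" for i in range(6)]
        )
        model = fit_oplsda(
            X, ["s0", "s1", "s2"], ["s3", "s4", "s5"], n_ortho=0
        )
        vip = compute_vip(model, confidence=False)
        assert np.allclose(vip["vip"], 1.0)

    def test_planted_discriminators_rank_top_and_match_direct_formula(self):
        X, a, b = random_matrix(
            n_proteins=10, seed=7, effect={2: 4.0, 7: 4.0}
        )
        model = fit_oplsda(X, a, b, n_ortho=0)
        vip = compute_vip(model, confidence=False)
        top2 = set(vip["vip"].nlargest(2).index)
        assert top2 == {"P002", "P007"}
        # independent direct formula: VIP_j = sqrt(K)|w_j| with w ∝ X_scaledᵀ y
        Xs = (X.to_numpy() - X.to_numpy().mean(0)) / X.to_numpy().std(0, ddof=1)
        y = np.array([1.0] * 3 + [-1.0] * 3)
        w = Xs.T @ (y - y.mean())
        w = np.abs(w) / np.linalg.norm(w)
        want = np.sqrt(10) * w
        assert np.allclose(vip["vip"].to_numpy(), want, atol=1e-8)

    def test_jackknife_bounds_bracket_the_point(self):
        X, a, b = random_matrix(seed=8)
        model = fit_oplsda(X, a, b, n_ortho=1)
        vip = compute_vip(model)
        assert (vip["vip_lo"] <= vip["vip"] + 1e-12).all()
        assert (vip["vip"] <= vip["vip_hi"] + 1e-12).all()

    def test_vip_invariant_to_column_order_and_scaling(self):
        X, a, b = random_matrix(seed=9)
        v1 = compute_vip(fit_oplsda(X, a, b, n_ortho=1), confidence=False)
        shuffled = X[list(X.columns[::-1])]
        v2 = compute_vip(fit_oplsda(shuffled, a, b, n_ortho=1), confidence=False)
        assert np.allclose(v1["vip"].sort_index(), v2["vip"].sort_index())
        v3 = compute_vip(fit_oplsda(X * 10.0, a, b, n_ortho=1), confidence=False)
        assert np.allclose(v1["vip"], v3["vip"], atol=1e-8)


class TestRanking:
    def make_candidates(self, vips, dtms):
        idx = pd.Index([f"P{i}" for i in range(len(dtms))], name="protein_id")
        cand = pd.DataFrame({"delta_tm": dtms, "selected": True}, index=idx)
        vip = pd.DataFrame({"vip": vips}, index=idx)
        return cand, vip

    def test_descending_vip_order(self):
        cand, vip = self.make_candidates([2.1, 1.3, 0.9], [1.0, 2.0, 3.0])
        ranked = rank_candidates(cand, vip)
        assert list(ranked.index) == ["P0", "P1", "P2"]
        assert list(ranked["rank_vip"]) == [1, 2, 3]

    def test_tie_broken_by_abs_shift(self):
        cand, vip = self.make_candidates([1.5, 1.5], [2.0, 3.0])
        ranked = rank_candidates(cand, vip)
        assert list(ranked.index) == ["P1", "P0"]

    def test_missing_vip_is_flagged_and_ranked_by_shift(self):
        cand, vip = self.make_candidates([2.0, 1.0], [1.0, 3.0])
        vip = vip.drop(index="P1")
        ranked = rank_candidates(cand, vip)
        assert bool(ranked.loc["P1", "vip_missing"])
        assert ranked.loc["P1", "rank_abs_dtm"] == 1
        assert pd.isna(ranked.loc["P1", "rank_vip"])

    def test_strong_effects_agree_between_rankings(self, small_planted_run):
        """For strong planted shifts the VIP and |ΔTm| top lists overlap."""
        _, result, _ = small_planted_run
        ranked = result.ranked_substrates
        if ranked is None or len(ranked) < 5:
            pytest.skip("too few substrate candidates in the small run")
        top_vip = set(ranked.sort_values("vip", ascending=False).head(5).index)
        top_dtm = set(ranked.sort_values("abs_dtm", ascending=False).head(5).index)
        jaccard = len(top_vip & top_dtm) / len(top_vip | top_dtm)
        assert jaccard >= 0.6
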