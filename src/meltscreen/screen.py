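"""Candidate screening on the melting-temperature matrix.

Three candidate classes come out of the four-arm design:

* cosubstrate binders — Tm shift in cosubstrate vs vehicle;
* enzyme interactors — Tm shift in enzyme vs vehicle;
* substrates — Tm shift in the enzyme+cosubstrate arm relative to *both*
  single-treatment arms (shifts that also appear with cosubstrate or enzyme
  alone are explained by binding and filtered away).

Per protein and contrast, the mean Tm difference is tested with a two-sided
t-test, pooled or Welch variance chosen by an F-test of variance equality at
α = 0.05.  No multiple-testing adjustment is applied; instead a global false
discovery rate is estimated by permuting each protein's Tm values across the
sample labels and re-running the full selection on the shuffled matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ExperimentConfig
from .meltfit import TmTable

_P_FLOOR = 1e-300  # p-values live in (0, 1]

#: Contrasts (group A minus group B) per candidate class.
CLASS_CONTRASTS = {
    "cosubstrate_binder": [("cosubstrate", "vehicle")],
    "enzyme_interactor": [("enzyme", "vehicle")],
    "substrate": [("both", "enzyme"), ("both", "cosubstrate")],
}


def _group_values(tm: pd.DataFrame, treatment: str) -> np.ndarray:
    cols = [c for c in tm.columns if c[0] == treatment]
    if not cols:
        raise KeyError(f"no samples for treatment {treatment!r}")
    return tm[cols].to_numpy(dtype=float)


def _welch_student_t(A: np.ndarray, B: np.ndarray, f_alpha: float = 0.05):
    """Vectorized two-sided t-test per row, F-test gated.

    Rows with any missing value are returned as NaN.  Identical groups give
    t = 0, p = 1; zero within-group variance with a nonzero difference gives
    the p floor.  Returns (delta, p, welch_mask, t, df)."""
    na, nb = A.shape[1], B.shape[1]
    complete = np.isfinite(A).all(axis=1) & np.isfinite(B).all(axis=1)
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    delta = ma - mb

    with np.errstate(divide="ignore", invalid="ignore"):
        F = va / vb
        p_f = 2.0 * np.minimum(
            stats.f.cdf(F, na - 1, nb - 1), stats.f.sf(F, na - 1, nb - 1)
        )
    # zero/undefined variance ratio: fall back to the pooled test
    welch = np.isfinite(p_f) & (p_f < f_alpha)

    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_student = delta / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df_student = np.full_like(delta, float(na + nb - 2))
        se_w2 = va / na + vb / nb
        t_welch = delta / np.sqrt(se_w2)
        df_welch = se_w2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = np.where(welch, t_welch, t_student)
    df = np.where(welch, df_welch, df_student)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate rows: both variances zero
    degen = ~np.isfinite(t)
    p = np.where(degen & (delta == 0.0), 1.0, p)
    p = np.where(degen & (delta != 0.0), _P_FLOOR, p)
    with np.errstate(invalid="ignore"):
        t = np.where(
            degen, np.where(delta == 0.0, 0.0, np.inf * np.sign(delta)), t
        )
    p = np.clip(p, _P_FLOOR, 1.0)

    delta = np.where(complete, delta, np.nan)
    p = np.where(complete, p, np.nan)
    return delta, p, welch, np.where(complete, t, np.nan), df


def compare_groups(
    tm_table: TmTable, group_a: str, group_b: str, *, f_alpha: float = 0.05
) -> pd.DataFrame:
    """Per-protein mean ΔTm (A − B) and two-sided t-test p-value.

    Complete cases only: a protein is tested when it has at least two Tm
    values in each group and none missing.  The variance model (pooled
    Student vs Welch) follows a two-sided F-test at ``f_alpha``.
    """
    A = _group_values(tm_table.tm, group_a)
    B = _group_values(tm_table.tm, group_b)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("each group needs at least 2 replicates")
    delta, p, welch, t, df = _welch_student_t(A, B, f_alpha)
    out = pd.DataFrame(
        {
            "contrast": f"{group_a}-{group_b}",
            "delta_tm": delta,
            "p_value": p,
            "variance_mode": np.where(welch, "welch", "student"),
            "t": t,
            "df": df,
        },
        index=tm_table.tm.index,
    )
    out.loc[out["delta_tm"].isna(), "variance_mode"] = pd.NA
    return out


def _qc_masks(
    tm_table: TmTable, treatments: list[str], config: ExperimentConfig
) -> tuple[pd.Series, pd.Series]:
    """(r2_pass, sd_pass) over the treatments relevant to a contrast set."""
    thr = config.thresholds
    cols = [c for c in tm_table.tm.columns if c[0] in treatments]
    r2_rel = tm_table.r2[cols]
    r2_pass = (r2_rel > thr.r2_min).all(axis=1) & r2_rel.notna().all(axis=1)
    sd = tm_table.treatment_sd()[treatments]
    sd_pass = (sd < thr.sd_max).all(axis=1) & sd.notna().all(axis=1)
    return r2_pass, sd_pass


def select_candidates(
    tm_table: TmTable,
    config: ExperimentConfig,
    mode: str,
    contrasts: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Apply the class-specific selection criteria.

    Returns one row per evaluable protein with per-criterion booleans
    (``r2_pass``, ``sd_pass``, ``p_pass``, ``dtm_pass``, for substrates also
    ``sign_concordant``) and the final ``selected`` flag.  ``delta_tm`` is the
    class-defining effect size (single contrast, or the mean of the two
    substrate contrasts); ``direction`` is stabilized/destabilized by its sign.

    Criteria (defaults from the published screen): fit quality R² > 0.7 in
    every relevant sample; replicate SD of Tm < 2.5 °C per relevant treatment;
    t-test p < 0.05 (for substrates: < 0.05 in one contrast and < 0.1 in the
    other); |ΔTm| > 1 °C (for substrates in both contrasts, with concordant
    signs).
    """
    if mode not in CLASS_CONTRASTS:
        raise ValueError(f"unknown mode {mode!r}")
    thr = config.thresholds
    pairs = CLASS_CONTRASTS[mode]
    if contrasts is None:
        contrasts = {}
    cons = [
        contrasts.get(f"{a}-{b}")
        if contrasts.get(f"{a}-{b}") is not None
        else compare_groups(tm_table, a, b)
        for a, b in pairs
    ]

    treatments = sorted({t for pair in pairs for t in pair})
    r2_pass, sd_pass = _qc_masks(tm_table, treatments, config)

    idx = tm_table.tm.index
    out = pd.DataFrame(index=idx)
    out["class"] = mode
    deltas = []
    for (a, b), con in zip(pairs, cons):
        out[f"delta_tm_{a}-{b}"] = con["delta_tm"]
        out[f"p_{a}-{b}"] = con["p_value"]
        deltas.append(con["delta_tm"])
    D = pd.concat(deltas, axis=1)
    P = pd.concat([c["p_value"] for c in cons], axis=1)

    complete = D.notna().all(axis=1)
    out["r2_pass"] = r2_pass.reindex(idx, fill_value=False)
    out["sd_pass"] = sd_pass.reindex(idx, fill_value=False)
    if len(pairs) == 1:
        out["p_pass"] = P.iloc[:, 0] < thr.p_primary
        out["dtm_pass"] = D.iloc[:, 0].abs() > thr.dtm_min
        out["sign_concordant"] = True
    else:
        out["p_pass"] = (P.min(axis=1) < thr.p_primary) & (
            P.max(axis=1) < thr.p_secondary
        )
        out["dtm_pass"] = (D.abs() > thr.dtm_min).all(axis=1)
        concordant = (np.sign(D) > 0).all(axis=1) | (np.sign(D) < 0).all(axis=1)
        out["sign_concordant"] = (
            concordant if config.require_sign_concordance
            else pd.Series(True, index=idx)
        )
    out["delta_tm"] = D.mean(axis=1)
    out["direction"] = np.where(out["delta_tm"] > 0, "stabilized", "destabilized")
    out["p_pass"] = out["p_pass"].fillna(False) & complete
    out["dtm_pass"] = out["dtm_pass"].fillna(False) & complete
    out["sign_concordant"] = out["sign_concordant"] & complete
    out.loc[~complete, "direction"] = pd.NA
    out["selected"] = (
        complete
        & out["r2_pass"]
        & out["sd_pass"]
        & out["p_pass"]
        & out["dtm_pass"]
        & out["sign_concordant"]
    )
    out.index.name = "protein_id"
    return out


@dataclass
class PermutationFdrResult:
    """Permutation-based global FDR estimate for one candidate class."""

    observed_hits: int
    mean_permuted_hits: float
    fdr: float  # NaN when observed_hits == 0
    n_permutations: int
    seed: int | None
    per_round_hits: list[int]

    @staticmethod
    def fdr_from_counts(observed_hits: int, mean_permuted_hits: float) -> float:
        if observed_hits <= 0:
            return float("nan")
        return mean_permuted_hits / observed_hits


def _permute_tm_table(tm_table: TmTable, rng: np.random.Generator) -> TmTable:
    """Shuffle each protein's observed (Tm, R²) pairs across its sample slots.

    The missingness pattern and each protein's Tm multiset are preserved;
    treatment structure is destroyed."""
    tm = tm_table.tm.to_numpy().copy()
    r2 = tm_table.r2.to_numpy().copy()
    for i in range(tm.shape[0]):
        obs = np.flatnonzero(np.isfinite(tm[i]))
        if obs.size > 1:
            perm = rng.permutation(obs.size)
            tm[i, obs] = tm[i, obs][perm]
            r2[i, obs] = r2[i, obs][perm]
    return TmTable(
        tm=pd.DataFrame(tm, index=tm_table.tm.index, columns=tm_table.tm.columns),
        r2=pd.DataFrame(r2, index=tm_table.r2.index, columns=tm_table.r2.columns),
        flags=tm_table.flags,
    )


def _permute_columns(tm_table: TmTable, rng: np.random.Generator) -> TmTable:
    """Alternative granularity: one sample-label permutation for all proteins."""
    perm = rng.permutation(tm_table.tm.shape[1])
    tm = tm_table.tm.iloc[:, perm]
    r2 = tm_table.r2.iloc[:, perm]
    tm.columns = tm_table.tm.columns
    r2.columns = tm_table.r2.columns
    return TmTable(tm=tm, r2=r2, flags=tm_table.flags)


def estimate_fdr_permutation(
    tm_table: TmTable,
    config: ExperimentConfig,
    mode: str,
    n_perm: int | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    granularity: str = "protein",
) -> PermutationFdrResult:
    """Estimate the FDR of a selection by Tm-value permutation.

    Each round reassigns every protein's observed Tm values across its sample
    labels (``granularity='protein'``; ``'column'`` permutes whole sample
    columns instead), re-runs the complete selection — including the QC gates
    that depend on the shuffled values when
    ``config.reapply_qc_in_permutation`` — and counts hits.  The estimate is
    mean permuted hits / observed hits; with zero observed hits the FDR is
    undefined (NaN, with a warning).
    """
    n_perm = n_perm if n_perm is not None else config.n_permutations
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    permute = {"protein": _permute_tm_table, "column": _permute_columns}[granularity]

    observed = int(select_candidates(tm_table, config, mode)["selected"].sum())

    frozen_qc = None
    if not config.reapply_qc_in_permutation:
        treatments = sorted(
            {t for pair in CLASS_CONTRASTS[mode] for t in pair}
        )
        frozen_qc = _qc_masks(tm_table, treatments, config)

    hits = []
    for _ in range(n_perm):
        shuffled = permute(tm_table, rng)
        sel = select_candidates(shuffled, config, mode)
        if frozen_qc is not None:
            r2_pass, sd_pass = frozen_qc
            sel["selected"] = (
                sel["p_pass"]
                & sel["dtm_pass"]
                & sel["sign_concordant"]
                & r2_pass.reindex(sel.index, fill_value=False)
                & sd_pass.reindex(sel.index, fill_value=False)
                & sel["delta_tm"].notna()
            )
        hits.append(int(sel["selected"].sum()))

    mean_hits = float(np.mean(hits)) if hits else 0.0
    fdr = PermutationFdrResult.fdr_from_counts(observed, mean_hits)
    if observed == 0:
        warnings.warn(
            "no observed hits: permutation FDR is undefined", RuntimeWarning
        )
    return PermutationFdrResult(
        observed_hits=observed,
        mean_permuted_hits=mean_hits,
        fdr=fdr,
        n_permutations=n_perm,
        seed=seed,
        per_round_hits=hits,
    )


def replicate_variation_summary(tm_table: TmTable) -> pd.DataFrame:
    """Median and mean of the per-protein replicate SD of Tm, per treatment.

    This is the quantity that motivates the 1 °C shift cutoff: the cutoff
    should sit well above the typical between-replicate Tm variation.
    Treatments with a single replicate yield NA.
    """
    sd = tm_table.treatment_sd()
    return pd.DataFrame(
        {
            "median_sd": sd.median(axis=0),
            "mean_sd": sd.mean(axis=0),
            "n_proteins": sd.notna().sum(axis=0),
        }
    ).rename_axis("treatment")


def summarize_shifts(candidates: pd.DataFrame) -> dict:
    """Counts by direction and mean/median |ΔTm| of the selected candidates."""
    sel = candidates[candidates["selected"]] if "selected" in candidates else candidates
    if len(sel) == 0:
        return {
            "n_candidates": 0,
            "n_stabilized": 0,
            "n_destabilized": 0,
            "mean_abs_dtm": float("nan"),
            "median_abs_dtm": float("nan"),
        }
    abs_dtm = sel["delta_tm"].abs()
    return {
        "n_candidates": int(len(sel)),
        "n_stabilized": int((sel["direction"] == "stabilized").sum()),
        "n_destabilized": int((sel["direction"] == "destabilized").sum()),
        "mean_abs_dtm": float(abs_dtm.mean()),
        "median_abs_dtm": float(abs_dtm.median()),
    }
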