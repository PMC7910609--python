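"""Orthogonal-validation helpers for peptide-level and label-free tables.

These mirror the downstream checks typically run alongside the thermal
screen: quality filtering of enriched phosphopeptides, normalization and
missing-value imputation of label-free (LFQ) pulldown matrices, and
fold-change-based enrichment calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import InputError


def filter_phosphopeptides(
    records: pd.DataFrame,
    abundance_cols: list[str],
    *,
    loc_prob_col: str = "localization_probability",
    score_col: str = "score",
    delta_score_col: str = "delta_score",
    loc_prob_min: float = 0.75,
    score_min: float = 40.0,
    delta_score_min: float = 8.0,
) -> pd.DataFrame:
    """Quality-filter phosphopeptides, then channel-normalize and log2.

    Gates (all strict ``>``): site localization probability > 0.75, search
    score > 40, delta score > 8.  Surviving abundances are divided by the
    per-channel totals computed over the *unfiltered* table, then
    log2-transformed.  An empty input returns an empty output.
    """
    if len(records) == 0:
        return records.copy()
    totals = records[abundance_cols].sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise InputError(f"zero total abundance in channels: {bad}")
    keep = (
        (records[loc_prob_col] > loc_prob_min)
        & (records[score_col] > score_min)
        & (records[delta_score_col] > delta_score_min)
    )
    out = records.loc[keep].copy()
    out[abundance_cols] = np.log2(out[abundance_cols] / totals)
    return out


def normalize_and_impute_lfq(
    matrix: pd.DataFrame,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    max_missing: int | None = None,
    downshift: float = 1.8,
    width: float = 0.25,
    log_input: bool = False,
) -> pd.DataFrame:
    """Total-normalize an LFQ matrix, exclude sparse proteins, impute the rest.

    Proteins (rows) with more than ``max_missing`` missing values (default:
    half the samples, i.e. 4 of 8) are excluded.  Remaining missing cells are
    drawn from a down-shifted normal per sample:
    Normal(mean − ``downshift``·SD, (``width``·SD)²) of that sample's
    observed log2 distribution — the standard proxy for below-detection
    intensities.  Observed cells are never altered, and exclusion precedes
    imputation.  ``width`` multiplies the sample SD; pass the SD itself and
    ``width=1`` for an absolute width.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if max_missing is None:
        max_missing = matrix.shape[1] // 2
    if matrix.isna().all(axis=0).any():
        bad = list(matrix.columns[matrix.isna().all(axis=0)])
        raise InputError(f"all-missing samples: {bad}")

    if log_input:
        logm = matrix.astype(float)
    else:
        totals = matrix.sum(axis=0, skipna=True)
        if (totals <= 0).any():
            raise InputError("non-positive sample totals")
        logm = np.log2(matrix / totals)

    n_missing = logm.isna().sum(axis=1)
    out = logm.loc[n_missing <= max_missing].copy()

    for col in out.columns:
        obs = out[col].dropna()
        mu, sd = obs.mean(), obs.std(ddof=1)
        mask = out[col].isna()
        if mask.any():
            out.loc[mask, col] = rng.normal(
                mu - downshift * sd, width * sd, int(mask.sum())
            )
    return out


def select_enriched_pulldown(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    *,
    lfc_min: float = 0.5,
    p_max: float = 0.05,
    peptide_counts: pd.Series | None = None,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Proteins enriched in pulldown (group A) over control (group B).

    Requires mean log2 fold change ≥ ``lfc_min`` (a hard floor) and a
    two-sided t-test p < ``p_max`` on the log2 values.  Rows quantified with
    fewer than ``min_peptides`` peptides are excluded when counts are given.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InputError("each group needs at least 2 samples")
    m = matrix
    if peptide_counts is not None:
        m = m.loc[peptide_counts.reindex(m.index) >= min_peptides]
    A = m[group_a].to_numpy(dtype=float)
    B = m[group_b].to_numpy(dtype=float)
    lfc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1)
    p = np.where(
        np.isnan(p), np.where(lfc == 0.0, 1.0, np.nan), p
    )
    out = pd.DataFrame(
        {"log2_fc": lfc, "p_value": p, "t": t}, index=m.index
    )
    enriched = out[(out["log2_fc"] >= lfc_min) & (out["p_value"] < p_max)]
    return enriched.sort_values("log2_fc", ascending=False)
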