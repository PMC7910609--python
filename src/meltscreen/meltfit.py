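"""Melting-curve construction and sigmoid fitting.

Each protein/sample pair yields a relative-solubility curve: reporter
abundance at every gradient temperature divided by the abundance at the
lowest (reference) temperature.  Curves are normalized to the bulk-proteome
melting behavior, then a three-parameter sigmoid

    I(T) = (1 - Pl) / (1 + exp((T - Tm) / (b*T))) + Pl

is fitted per curve by bounded nonlinear least squares, where Tm is the
melting temperature (the model value at T = Tm is (1 + Pl)/2), b the slope
parameter and Pl the high-temperature plateau.  Proteins whose fitted
plateau is large are non-melters: their Tm is not measurable and they are
excluded from downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .config import ExperimentConfig, TemperatureGrid
from .io import AbundanceData


class NormalizationError(RuntimeError):
    """Too few shared well-behaved proteins to normalize; consider skipping
    normalization for very small panels."""


def melt_model(T, tm, slope, plateau, slope_times_t: bool = True):
    """Sigmoid relative solubility at temperature ``T`` (°C).

    With ``slope_times_t`` the exponent is (T-Tm)/(b*T) — the re-centered form of the
    classical a/T-parameterized melting sigmoid; otherwise (T-Tm)/b with b in °C.
    """
    T = np.asarray(T, dtype=float)
    denom = slope * T if slope_times_t else slope
    z = np.clip((T - tm) / denom, -700.0, 700.0)
    return (1.0 - plateau) / (1.0 + np.exp(z)) + plateau


@dataclass(frozen=True)
class MeltFit:
    """Fitted sigmoid parameters for one curve."""

    tm: float
    slope: float
    plateau: float
    r2: float
    converged: bool
    n_points: int
    message: str = ""


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    if sst == 0.0:
        return np.nan  # constant observations: R2 undefined, fails any gate
    return 1.0 - sse / sst


def _melt_jac(T, tm, slope, plateau, slope_times_t):
    """Analytic Jacobian of :func:`melt_model` w.r.t. (tm, slope, plateau)."""
    denom = slope * T if slope_times_t else np.full_like(T, slope)
    z = np.clip((T - tm) / denom, -350.0, 350.0)
    ez = np.exp(z)
    sig = 0.25 / np.cosh(0.5 * z) ** 2  # = e^z / (1+e^z)^2, overflow-safe
    d_tm = (1.0 - plateau) * sig / denom
    d_slope = (1.0 - plateau) * sig * z / slope
    d_pl = 1.0 - 1.0 / (1.0 + ez)
    return np.column_stack([d_tm, d_slope, d_pl])


def _tm_guess(T: np.ndarray, y: np.ndarray) -> float:
    """Data-driven Tm start: temperature of the half-melt crossing.

    Linear interpolation of the first crossing of (min+max)/2; the curve
    midpoint is robust to plateaus.  Falls back to the median temperature."""
    half = 0.5 * (np.max(y) + np.min(y))
    below = np.flatnonzero(y <= half)
    if below.size == 0 or below[0] == 0:
        return float(np.median(T))
    j = below[0]
    y0, y1 = y[j - 1], y[j]
    if y0 == y1:
        return float(T[j])
    frac = (y0 - half) / (y0 - y1)
    return float(T[j - 1] + frac * (T[j] - T[j - 1]))


def fit_melting_curve(
    temperatures,
    fractions,
    *,
    slope_times_t: bool = True,
    tm_pad: float = 15.0,
    min_points: int = 5,
    early_stop_r2: float = 0.95,
) -> MeltFit:
    """Fit the melting sigmoid to one curve.

    Deterministic multi-start schedule: first a data-driven Tm start (the
    interpolated half-melt temperature), then the grid minimum, median and
    maximum; a start whose fit reaches ``early_stop_r2`` ends the schedule
    (the fit clearly succeeded and further starts cannot displace a global
    optimum by more than noise).  The best fit by lowest SSE wins, ties
    broken by lower Tm.  Optimizer failure
    returns ``converged=False``, never an exception.
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(fractions, dtype=float)
    ok = np.isfinite(T) & np.isfinite(y)
    T, y = T[ok], y[ok]
    n = len(y)
    if n < min_points:
        return MeltFit(np.nan, np.nan, np.nan, np.nan, False, n, "too_few_points")

    lo_tm, hi_tm = T.min() - tm_pad, T.max() + tm_pad
    if slope_times_t:
        slope_bounds, slope0 = (1e-4, 5.0), 0.05
    else:
        slope_bounds, slope0 = (1e-3, 100.0), 3.0
    bounds = ([lo_tm, slope_bounds[0], 0.0], [hi_tm, slope_bounds[1], 1.0 - 1e-9])
    pl0 = float(np.clip(np.min(y), 0.0, 0.5))

    def f(T, tm, slope, plateau):
        return melt_model(T, tm, slope, plateau, slope_times_t=slope_times_t)

    def jac(T, tm, slope, plateau):
        return _melt_jac(T, tm, slope, plateau, slope_times_t)

    starts = [_tm_guess(T, y), float(T.min()), float(np.median(T)), float(T.max())]
    best: tuple[float, float] | None = None  # (sse, tm)
    best_fit: MeltFit | None = None
    for tm0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    f,
                    T,
                    y,
                    p0=[float(np.clip(tm0, lo_tm, hi_tm)), slope0, pl0],
                    bounds=bounds,
                    jac=jac,
                    xtol=1e-9,
                    ftol=1e-12,
                    maxfev=2000,
                )
        except (RuntimeError, ValueError):
            continue
        yhat = f(T, *popt)
        sse = float(np.sum((y - yhat) ** 2))
        r2 = _r_squared(y, yhat)
        cand = (sse, float(popt[0]))
        if best is None or cand < best:
            best = cand
            best_fit = MeltFit(
                float(popt[0]), float(popt[1]), float(popt[2]), r2, True, n
            )
        if np.isfinite(r2) and r2 >= early_stop_r2:
            break
    if best_fit is None:
        return MeltFit(np.nan, np.nan, np.nan, np.nan, False, n, "optimizer_failed")
    return best_fit


def scale_fold_changes(abund: AbundanceData) -> tuple[pd.DataFrame, AbundanceData]:
    """Convert abundances to relative solubility: abundance(T)/abundance(T_ref).

    Protein/sample pairs with a missing or non-positive reference abundance
    are dropped from the curve table and recorded in
    ``AbundanceData.sample_exclusions`` with reason ``reference_missing``.
    Proteins already flagged excluded (contaminant, <2 peptides) are skipped.
    """
    ref_temp = abund.grid.reference
    data = abund.data[abund.data["protein_id"].isin(abund.included_ids())]

    ref = (
        data[data["temperature"] == ref_temp]
        .set_index(["protein_id", "treatment", "replicate"])["abundance"]
        .rename("ref_abundance")
    )
    merged = data.join(
        ref, on=["protein_id", "treatment", "replicate"], how="left"
    )
    bad_ref = ~(merged["ref_abundance"] > 0)
    excl = (
        merged.loc[bad_ref, ["protein_id", "treatment", "replicate"]]
        .drop_duplicates()
        .assign(reason="reference_missing")
    )
    curves = merged.loc[~bad_ref].copy()
    curves["fraction"] = curves["abundance"] / curves["ref_abundance"]
    curves = curves[
        ["protein_id", "treatment", "replicate", "temperature", "fraction"]
    ].reset_index(drop=True)

    out = AbundanceData(
        data=abund.data,
        proteins=abund.proteins,
        grid=abund.grid,
        sample_exclusions=pd.concat(
            [abund.sample_exclusions, excl], ignore_index=True
        ),
    )
    return curves, out


@dataclass
class NormalizationResult:
    """Per-sample multiplicative correction factors and the reference curve."""

    factors: pd.DataFrame  # treatment, replicate, temperature, factor
    median_curves: pd.DataFrame  # per-sample median fraction of the norm set
    fitted_reference: pd.DataFrame  # temperature, fraction (fitted median curve)
    n_proteins: int
    fit: MeltFit


def _spearman_vs_temperature(wide: pd.DataFrame) -> pd.Series:
    """Spearman correlation of each row (curve) against the temperature order.

    Temperatures are strictly increasing, so this is the Pearson correlation
    of the within-row ranks with 1..k."""
    ranks = wide.rank(axis=1)
    k = wide.shape[1]
    tr = np.arange(1, k + 1, dtype=float)
    rc = ranks.to_numpy() - ranks.to_numpy().mean(axis=1, keepdims=True)
    tc = tr - tr.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ tc) / denom
    return pd.Series(rho, index=wide.index)


def normalize_to_reference(
    curves: pd.DataFrame,
    grid: TemperatureGrid,
    *,
    min_shared: int = 20,
    spearman_max: float = -0.8,
    top_fraction_max: float = 0.3,
    slope_times_t: bool = True,
) -> tuple[pd.DataFrame, NormalizationResult]:
    """Normalize every sample to the bulk-proteome melting curve.

    A well-behaved reference set — proteins quantified at all temperatures in
    all samples whose raw curves decrease with temperature (Spearman ≤
    ``spearman_max``) and melt out (top-temperature fraction <
    ``top_fraction_max``) in every sample — defines each sample's median
    melting curve.  The across-sample median of those medians is the target
    (samples that already agree are a fixed point); each sample's curves are
    multiplied, at every temperature above the reference temperature, by
    ``target(T) / sample_median(T)``.  The reference temperature is never
    touched (factor 1 by construction).  A sigmoid fit of the target curve
    is reported for QC.
    """
    temps = list(grid)
    wide = curves.pivot_table(
        index=["protein_id", "treatment", "replicate"],
        columns="temperature",
        values="fraction",
    ).reindex(columns=temps)

    complete = wide.dropna()
    # protein must be present (complete) in every sample
    n_samples = curves[["treatment", "replicate"]].drop_duplicates().shape[0]
    counts = complete.groupby(level="protein_id").size()
    shared_ids = counts[counts == n_samples].index

    cand = complete[complete.index.get_level_values("protein_id").isin(shared_ids)]
    rho = _spearman_vs_temperature(cand)
    top_ok = cand[temps[-1]] < top_fraction_max
    good = (rho <= spearman_max) & top_ok
    per_protein_ok = good.groupby(level="protein_id").all()
    norm_ids = per_protein_ok[per_protein_ok].index
    if len(norm_ids) < min_shared:
        raise NormalizationError(
            f"only {len(norm_ids)} shared well-behaved proteins "
            f"(need >= {min_shared}); skip normalization for small panels"
        )

    norm_set = cand[cand.index.get_level_values("protein_id").isin(norm_ids)]
    sample_median = norm_set.groupby(level=["treatment", "replicate"]).median()
    target = sample_median.median(axis=0)
    # sigmoid fit of the target curve is reported for QC; the raw median is
    # the normalization target so that identical samples are a fixed point
    fit = fit_melting_curve(temps, target.to_numpy(), slope_times_t=slope_times_t)
    fitted = (
        melt_model(np.array(temps), fit.tm, fit.slope, fit.plateau,
                   slope_times_t=slope_times_t)
        if fit.converged
        else target.to_numpy()
    )

    factors = target / sample_median
    factors[temps[0]] = 1.0  # reference temperature untouched
    factors_long = (
        factors.reset_index()
        .melt(id_vars=["treatment", "replicate"], var_name="temperature",
              value_name="factor")
        .astype({"temperature": float})
    )

    out = curves.merge(factors_long, on=["treatment", "replicate", "temperature"])
    out["fraction"] = out["fraction"] * out["factor"]
    out = out.drop(columns="factor").sort_values(
        ["protein_id", "treatment", "replicate", "temperature"], kind="stable"
    ).reset_index(drop=True)

    result = NormalizationResult(
        factors=factors_long,
        median_curves=sample_median.reset_index(),
        fitted_reference=pd.DataFrame(
            {"temperature": temps, "fraction": fitted}
        ),
        n_proteins=len(norm_ids),
        fit=fit,
    )
    return out, result


def fit_all_curves(
    curves: pd.DataFrame,
    *,
    slope_times_t: bool = True,
    min_points: int = 5,
) -> pd.DataFrame:
    """Fit the melting sigmoid for every (protein, sample) curve.

    Returns one row per curve: protein_id, treatment, replicate, tm, slope,
    plateau, r2, converged, n_points, message.
    """
    rows = []
    for (pid, trt, rep), grp in curves.groupby(
        ["protein_id", "treatment", "replicate"], sort=True
    ):
        fit = fit_melting_curve(
            grp["temperature"].to_numpy(),
            grp["fraction"].to_numpy(),
            slope_times_t=slope_times_t,
            min_points=min_points,
        )
        rows.append(
            {
                "protein_id": pid,
                "treatment": trt,
                "replicate": rep,
                "tm": fit.tm,
                "slope": fit.slope,
                "plateau": fit.plateau,
                "r2": fit.r2,
                "converged": fit.converged,
                "n_points": fit.n_points,
                "message": fit.message,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TmTable:
    """Protein × sample melting-temperature matrix with QC annotations.

    ``tm`` and ``r2`` are wide frames indexed by protein_id with
    (treatment, replicate) MultiIndex columns; Tm is present only for
    converged, melting (plateau below the non-melter threshold) fits.
    ``flags`` carries per-protein annotations: ``no_melting`` (no usable fit
    anywhere) and ``fit_quality_pass`` (every usable fit has r2 above the
    gate).
    """

    tm: pd.DataFrame
    r2: pd.DataFrame
    flags: pd.DataFrame

    def treatment_sd(self) -> pd.DataFrame:
        """Per-protein replicate SD of Tm for each treatment (ddof=1)."""
        return self.tm.T.groupby(level="treatment").std(ddof=1).T


def qc_fits(fits: pd.DataFrame, config: ExperimentConfig) -> TmTable:
    """Assemble the Tm matrix and QC flags from per-curve fits.

    A fit is *usable* iff it converged and its plateau is below
    ``config.plateau_max`` — a high plateau means the protein never melts out
    (e.g. still >50% soluble at the top temperature) and its Tm is not
    measurable.  Proteins with no usable fit carry the ``no_melting`` flag.
    """
    fits = fits.copy()
    usable = fits["converged"] & (fits["plateau"] < config.plateau_max)
    fits["tm_usable"] = fits["tm"].where(usable)

    tm = fits.pivot_table(
        index="protein_id", columns=["treatment", "replicate"],
        values="tm_usable", dropna=False,
    )
    r2 = fits.pivot_table(
        index="protein_id", columns=["treatment", "replicate"],
        values="r2", dropna=False,
    )
    r2 = r2.where(tm.notna())

    any_usable = usable.groupby(fits["protein_id"]).any()
    min_r2 = r2.min(axis=1)
    flags = pd.DataFrame(
        {
            "no_melting": ~any_usable.reindex(tm.index, fill_value=True),
            "fit_quality_pass": min_r2 > config.thresholds.r2_min,
        }
    )
    flags.index.name = "protein_id"
    return TmTable(tm=tm, r2=r2, flags=flags)
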