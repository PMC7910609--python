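"""Synthetic four-arm thermal-profiling experiments with planted ground truth.

The generator emulates the measured data end to end: per-protein sigmoid
melting (protein-specific Tm, slope and plateau), treatment-specific planted
Tm shifts per candidate class, replicate-level Tm jitter, per-sample
per-temperature multiplicative distortions (what proteome normalization must
undo), multiplicative reporter noise on every cell, and whole-protein
missingness per sample.  Classes follow the four-arm logic:

* null        — identical true Tm in all arms;
* binder      — shift in the cosubstrate and combination arms;
* interactor  — shift in the enzyme and combination arms;
* substrate   — shift in the combination arm only.

Default noise scales reflect typical replicate Tm variation of ~0.5 °C in
this assay, and default effect magnitudes (|ΔTm| ~ N(2.5, 0.5²)) the typical
absolute shifts of confirmed substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    ConfigurationError,
    ExperimentConfig,
    SampleKey,
    TemperatureGrid,
    TREATMENTS,
    default_sample_map,
)
from .io import AbundanceData, mark_excluded
from .meltfit import melt_model

CLASSES = ("null", "cosubstrate_binder", "substrate", "enzyme_interactor")

#: Which treatment arms a planted effect of each class acts on.
CLASS_ARMS = {
    "null": (),
    "cosubstrate_binder": ("cosubstrate", "both"),
    "substrate": ("both",),
    "enzyme_interactor": ("enzyme", "both"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults are the reference study conditions."""

    n_proteins: int = 1000
    grid: TemperatureGrid = field(default_factory=TemperatureGrid)
    n_replicates: int = 2
    # baseline curve-parameter distributions
    tm_mean: float = 52.0
    tm_sd: float = 4.0
    slope_mean: float = 0.035
    slope_sd: float = 0.008
    plateau_low: float = 0.0
    plateau_high: float = 0.15
    # planted class composition
    frac_binders: float = 0.05
    frac_substrates: float = 0.03
    frac_interactors: float = 0.02
    # planted effect magnitude |ΔTm| ~ N(effect_mean, effect_sd²), clipped > 0
    effect_mean: float = 2.5
    effect_sd: float = 0.5
    destabilization_prob: float = 0.5  # P(negative shift); raise for e.g. reductases
    # noise model
    tm_noise_sd: float = 0.5  # replicate-level Tm jitter, °C
    abundance_noise_sd: float = 0.05  # log-normal sigma per reporter cell
    distortion_sd: float = 0.05  # per-sample per-temperature log-normal sigma
    missing_rate: float = 0.01  # P(protein absent from a sample entirely)
    # table realism
    reference_intensity_log10_mean: float = 6.0
    reference_intensity_log10_sd: float = 0.5
    contaminant_rate: float = 0.005
    single_peptide_rate: float = 0.02
    # plateau-shift mode: planted effects raise the plateau instead of Tm
    plateau_shift: bool = False
    plateau_shift_value: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_binders + self.frac_substrates + self.frac_interactors
        if total > 1.0:
            raise ConfigurationError("class fractions must sum to <= 1")
        for name in ("tm_sd", "slope_sd", "effect_sd", "tm_noise_sd",
                     "abundance_noise_sd", "distortion_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")

    def experiment_config(self, **overrides) -> ExperimentConfig:
        """Matching analysis configuration (grid + default sample map)."""
        return ExperimentConfig(
            grid=self.grid,
            sample_map=default_sample_map(self.grid, self.n_replicates),
            seed=self.seed,
            **overrides,
        )


def simulate_experiment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[AbundanceData, pd.DataFrame]:
    """Generate one experiment; returns (abundances, truth table).

    The truth table has one row per protein: class, true curve parameters,
    the planted signed ΔTm and the true Tm per treatment arm.  Identical
    seed (and no external rng) → identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    temps = np.array(list(config.grid))
    ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    n_b = int(round(config.frac_binders * n))
    n_s = int(round(config.frac_substrates * n))
    n_i = int(round(config.frac_interactors * n))
    classes = np.array(
        ["cosubstrate_binder"] * n_b
        + ["substrate"] * n_s
        + ["enzyme_interactor"] * n_i
        + ["null"] * (n - n_b - n_s - n_i)
    )
    rng.shuffle(classes)

    base_tm = rng.normal(config.tm_mean, config.tm_sd, n)
    slope = np.clip(rng.normal(config.slope_mean, config.slope_sd, n), 0.01, None)
    plateau = rng.uniform(config.plateau_low, config.plateau_high, n)

    magnitude = np.abs(rng.normal(config.effect_mean, config.effect_sd, n))
    sign = np.where(rng.random(n) < config.destabilization_prob, -1.0, 1.0)
    effect = np.where(classes == "null", 0.0, magnitude * sign)

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "class": classes,
            "true_tm": base_tm,
            "true_slope": slope,
            "true_plateau": plateau,
            "planted_dtm": effect,
        }
    )
    for arm in TREATMENTS:
        shifted = np.array(
            [arm in CLASS_ARMS[c] for c in classes], dtype=float
        )
        truth[f"tm_{arm}"] = base_tm + effect * shifted

    samples = [
        SampleKey(trt, rep)
        for trt in TREATMENTS
        for rep in range(1, config.n_replicates + 1)
    ]
    # per-sample per-temperature distortion, shared across proteins
    distortion = {
        s.label: np.exp(rng.normal(0.0, config.distortion_sd, len(temps)))
        for s in samples
    }
    ref_intensity = 10.0 ** rng.normal(
        config.reference_intensity_log10_mean,
        config.reference_intensity_log10_sd,
        n,
    )

    frames = []
    for s in samples:
        tm_true = truth[f"tm_{s.treatment}"].to_numpy()
        tm_rep = tm_true + rng.normal(0.0, config.tm_noise_sd, n)
        if config.plateau_shift:
            pl_s = np.where(
                (effect != 0)
                & np.array([s.treatment in CLASS_ARMS[c] for c in classes]),
                config.plateau_shift_value,
                plateau,
            )
            tm_rep = truth["true_tm"].to_numpy() + rng.normal(
                0.0, config.tm_noise_sd, n
            )
        else:
            pl_s = plateau
        curve = melt_model(
            temps[None, :], tm_rep[:, None], slope[:, None], pl_s[:, None]
        )
        noise = np.exp(
            rng.normal(0.0, config.abundance_noise_sd, (n, len(temps)))
        )
        intensity = ref_intensity[:, None] * curve * distortion[s.label][None, :] * noise
        missing = rng.random(n) < config.missing_rate
        intensity[missing] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": np.repeat(ids, len(temps)),
                    "treatment": s.treatment,
                    "replicate": s.replicate,
                    "temperature": np.tile(temps, n),
                    "abundance": intensity.ravel(),
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    data = data.sort_values(
        ["protein_id", "treatment", "replicate", "temperature"], kind="stable"
    ).reset_index(drop=True)

    contaminant = rng.random(n) < config.contaminant_rate
    single_pep = rng.random(n) < config.single_peptide_rate
    peptide_count = np.where(single_pep, 1, rng.poisson(8, n) + 2)
    proteins = pd.DataFrame(
        {
            "protein_id": ids,
            "peptide_count": peptide_count,
            "contaminant": contaminant,
            "excluded": False,
            "exclude_reasons": "",
        }
    ).sort_values("protein_id", kind="stable", ignore_index=True)
    proteins = mark_excluded(proteins, proteins["contaminant"], "contaminant")
    proteins = mark_excluded(
        proteins, proteins["peptide_count"] < 2, "min_peptides"
    )

    abund = AbundanceData(data=data, proteins=proteins, grid=config.grid)
    truth = truth.sort_values("protein_id", kind="stable", ignore_index=True)
    return abund, truth


def write_simulated_quant(
    abund: AbundanceData, truth: pd.DataFrame, quant_path, truth_path=None
) -> None:
    """Write the simulated experiment in the wide-TSV dialect the reader expects."""
    wide = abund.data.copy()
    wide["column"] = [
        f"{t}_r{r}_T{temp:g}"
        for t, r, temp in zip(
            wide["treatment"], wide["replicate"], wide["temperature"]
        )
    ]
    table = wide.pivot_table(
        index="protein_id", columns="column", values="abundance", dropna=False
    )
    meta = abund.proteins.set_index("protein_id")[["peptide_count", "contaminant"]]
    out = meta.join(table).reset_index()
    out.to_csv(quant_path, sep="\t", index=False, na_rep="")
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)


def evaluate_against_truth(
    candidates: pd.DataFrame, truth: pd.DataFrame, mode: str
) -> dict:
    """Confusion summary of a candidate list against the planted truth.

    Returns true/false positive counts, sensitivity over the planted class
    and the empirical FDR of the selection.  The candidate index must be a
    subset of the truth's protein universe.
    """
    truth_idx = pd.Index(truth["protein_id"])
    cand_ids = candidates.index
    if not cand_ids.isin(truth_idx).all():
        raise ValueError("candidate proteins not present in the truth table")
    sel = candidates[candidates["selected"]] if "selected" in candidates else candidates
    truth_class = truth.set_index("protein_id")["class"]
    planted = truth_class[truth_class == mode].index
    hits = pd.Index(sel.index)
    tp = int(hits.isin(planted).sum())
    fp = int(len(hits) - tp)
    sens = tp / len(planted) if len(planted) else float("nan")
    fdr = fp / len(hits) if len(hits) else float("nan")
    return {
        "n_planted": int(len(planted)),
        "n_selected": int(len(hits)),
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": int(len(planted) - tp),
        "sensitivity": sens,
        "empirical_fdr": fdr,
    }
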