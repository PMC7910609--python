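"""End-to-end pipeline: scale → normalize → fit → QC → contrasts →
selection (three classes) → permutation FDR → multivariate ranking.

A run is a pure function of (input table, configuration, seed); the manifest
written alongside the result tables records everything needed to reproduce
it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig, SampleKey
from .io import AbundanceData, read_protein_quant, write_results, write_table
from .meltfit import (
    NormalizationError,
    NormalizationResult,
    TmTable,
    fit_all_curves,
    normalize_to_reference,
    qc_fits,
    scale_fold_changes,
)
from .oplsda import ModelError, compute_vip, fit_oplsda, rank_candidates
from .screen import (
    CLASS_CONTRASTS,
    compare_groups,
    estimate_fdr_permutation,
    replicate_variation_summary,
    select_candidates,
    summarize_shifts,
)
from .simulate import SimulationConfig, simulate_experiment

MODES = ("cosubstrate_binder", "substrate", "enzyme_interactor")


@dataclass
class PipelineResult:
    """Everything a run computes, stage by stage."""

    curves: pd.DataFrame
    normalization: NormalizationResult | None
    fits: pd.DataFrame
    tm_table: TmTable
    contrasts: dict[str, pd.DataFrame]
    candidates: dict[str, pd.DataFrame]
    fdr: dict[str, object]
    replicate_variation: pd.DataFrame
    shift_summaries: dict[str, dict]
    vip: pd.DataFrame | None
    ranked_substrates: pd.DataFrame | None
    opls_model: object | None
    manifest: dict = field(default_factory=dict)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: ExperimentConfig,
    quant_path=None,
    *,
    abundances: AbundanceData | None = None,
    sim_config: SimulationConfig | None = None,
    seed: int | None = None,
    outdir=None,
    n_perm: int | None = None,
    normalize: bool = True,
) -> PipelineResult:
    """Execute the full screen and optionally write the results bundle.

    Input is exactly one of ``quant_path`` (wide TSV), ``abundances``
    (in-memory) or ``sim_config`` (generate synthetically).  ``seed``
    overrides ``config.seed`` for permutations and simulation.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    manifest: dict = {
        "tool": "meltscreen",
        "version": __version__,
        "seed": int(seed),
        "stages": {},
    }
    if sum(x is not None for x in (quant_path, abundances, sim_config)) != 1:
        raise ValueError("provide exactly one of quant_path/abundances/sim_config")
    if quant_path is not None:
        abundances = read_protein_quant(quant_path, config)
        manifest["input"] = {"path": str(quant_path), "sha256": _digest(quant_path)}
    elif sim_config is not None:
        abundances, truth = simulate_experiment(sim_config, rng=rng)
        manifest["input"] = {"simulated": True, "n_proteins": sim_config.n_proteins}
    manifest["stages"]["input_proteins"] = int(len(abundances.proteins))
    manifest["stages"]["excluded_proteins"] = int(
        abundances.proteins["excluded"].sum()
    )

    curves, abundances = scale_fold_changes(abundances)
    manifest["stages"]["curves"] = int(
        curves[["protein_id", "treatment", "replicate"]].drop_duplicates().shape[0]
    )

    norm_result = None
    if normalize:
        try:
            curves, norm_result = normalize_to_reference(
                curves,
                config.grid,
                min_shared=config.norm_min_shared,
                spearman_max=config.norm_spearman_max,
                top_fraction_max=config.norm_top_fraction_max,
                slope_times_t=config.slope_times_t,
            )
            manifest["stages"]["normalization_proteins"] = norm_result.n_proteins
        except NormalizationError:
            manifest["stages"]["normalization_proteins"] = 0

    fits = fit_all_curves(
        curves, slope_times_t=config.slope_times_t
    )
    manifest["stages"]["fits"] = int(len(fits))
    manifest["stages"]["converged_fits"] = int(fits["converged"].sum())

    tm_table = qc_fits(fits, config)
    manifest["stages"]["proteins_with_tm"] = int(
        tm_table.tm.notna().any(axis=1).sum()
    )

    contrast_pairs = sorted({p for pairs in CLASS_CONTRASTS.values() for p in pairs})
    contrasts = {
        f"{a}-{b}": compare_groups(tm_table, a, b) for a, b in contrast_pairs
    }

    candidates, fdr, summaries = {}, {}, {}
    for mode in MODES:
        cand = select_candidates(tm_table, config, mode, contrasts)
        candidates[mode] = cand
        manifest["stages"][f"candidates_{mode}"] = int(cand["selected"].sum())
        summaries[mode] = summarize_shifts(cand)
        fdr[mode] = estimate_fdr_permutation(
            tm_table,
            config,
            mode,
            n_perm=n_perm,
            rng=np.random.default_rng(rng.integers(0, 2**31 - 1)),
        )

    rep_var = replicate_variation_summary(tm_table)

    vip_df, ranked, model = None, None, None
    n_rep = max((k.replicate for k in config.samples), default=2)
    class_a = [SampleKey("both", r) for r in range(1, n_rep + 1)]
    class_b = [
        SampleKey(t, r)
        for t in ("enzyme", "cosubstrate")
        for r in range(1, n_rep + 1)
    ]
    try:
        model = fit_oplsda(tm_table, class_a, class_b, n_ortho=1)
        vip_df = compute_vip(model)
        ranked = rank_candidates(
            candidates["substrate"][candidates["substrate"]["selected"]],
            vip_df,
        )
    except ModelError:
        pass
    manifest["stages"]["opls_proteins"] = (
        int(len(model.proteins)) if model is not None else 0
    )

    result = PipelineResult(
        curves=curves,
        normalization=norm_result,
        fits=fits,
        tm_table=tm_table,
        contrasts=contrasts,
        candidates=candidates,
        fdr=fdr,
        replicate_variation=rep_var,
        shift_summaries=summaries,
        vip=vip_df,
        ranked_substrates=ranked,
        opls_model=model,
        manifest=manifest,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def write_bundle(result: PipelineResult, outdir) -> None:
    """Write all result tables plus the run manifest into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(result.fits, outdir / "fits.tsv")
    if result.normalization is not None:
        write_table(result.normalization.factors, outdir / "normalization.tsv")
    tm_flat = result.tm_table.tm.copy()
    tm_flat.columns = [f"tm_{t}_r{r}" for t, r in tm_flat.columns]
    write_table(tm_flat.reset_index(), outdir / "tm_table.tsv")
    for name, con in result.contrasts.items():
        write_table(con.reset_index(), outdir / f"contrast_{name}.tsv")
    for mode, cand in result.candidates.items():
        write_results(cand.reset_index(), outdir / f"candidates_{mode}.tsv")
    fdr_rows = [
        {
            "mode": mode,
            "observed_hits": r.observed_hits,
            "mean_permuted_hits": r.mean_permuted_hits,
            "fdr": r.fdr,
            "n_permutations": r.n_permutations,
        }
        for mode, r in result.fdr.items()
    ]
    write_table(pd.DataFrame(fdr_rows), outdir / "fdr_report.tsv")
    write_table(
        result.replicate_variation.reset_index(), outdir / "replicate_variation.tsv"
    )
    if result.vip is not None:
        write_table(
            result.vip.rename_axis("protein_id").reset_index(), outdir / "vip.tsv"
        )
    if result.ranked_substrates is not None:
        write_results(
            result.ranked_substrates.rename_axis("protein_id").reset_index(),
            outdir / "ranked_substrates.tsv",
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
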