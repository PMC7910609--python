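"""Tabular input/output.

The quantification input is a generic wide TSV — one row per protein, one
abundance column per (sample, temperature) — as exported from a search
engine's protein-groups table.  Column semantics come entirely from the
config's sample map, so the reader is engine-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, ExperimentConfig, InputError, TemperatureGrid

#: Candidate fallback column names for protein-groups style exports.
_PEPTIDE_FALLBACKS = ("Peptides", "Razor + unique peptides", "peptides")
_CONTAMINANT_FALLBACKS = ("Potential contaminant", "Contaminant")


@dataclass
class AbundanceData:
    """Long-format reporter abundances plus per-protein metadata.

    ``data`` columns: protein_id, treatment, replicate, temperature, abundance
    (NaN where the cell was empty).  ``proteins`` columns: protein_id,
    peptide_count, contaminant, excluded, exclude_reasons.  Exclusion is a
    flag, never a silent drop; reasons accumulate and are monotone.
    """

    data: pd.DataFrame
    proteins: pd.DataFrame
    grid: TemperatureGrid
    sample_exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["protein_id", "treatment", "replicate", "reason"]
        )
    )

    def included_ids(self) -> pd.Index:
        return pd.Index(
            self.proteins.loc[~self.proteins["excluded"], "protein_id"]
        )


def mark_excluded(proteins: pd.DataFrame, mask, reason: str) -> pd.DataFrame:
    """Flag rows matching ``mask`` as excluded, appending ``reason``.

    Never clears an existing flag (exclusion is monotone)."""
    proteins = proteins.copy()
    mask = np.asarray(mask, dtype=bool)
    proteins.loc[mask, "excluded"] = True
    has = proteins.loc[mask, "exclude_reasons"].astype(str)
    proteins.loc[mask, "exclude_reasons"] = np.where(
        has == "", reason, has + ";" + reason
    )
    return proteins


def read_protein_quant(path, config: ExperimentConfig) -> AbundanceData:
    """Read a wide TSV quant table into the canonical long representation.

    Every column that is not the protein-id / peptide-count / contaminant
    column must be present in the config sample map; an unmapped column is a
    configuration error (named in the message).  Contaminants and proteins
    quantified with fewer than two peptides are flagged excluded, not dropped.
    """
    raw = pd.read_csv(path, sep="\t")
    if config.protein_id_column not in raw.columns:
        raise ConfigurationError(
            f"protein id column {config.protein_id_column!r} not found in {path}"
        )

    pep_col = config.peptide_count_column
    if pep_col not in raw.columns:
        pep_col = next((c for c in _PEPTIDE_FALLBACKS if c in raw.columns), None)
    cont_col = config.contaminant_column
    if cont_col not in raw.columns:
        cont_col = next((c for c in _CONTAMINANT_FALLBACKS if c in raw.columns), None)

    meta_cols = {config.protein_id_column, pep_col, cont_col} - {None}
    unmapped = [
        c for c in raw.columns if c not in meta_cols and c not in config.sample_map
    ]
    if unmapped:
        raise ConfigurationError(
            f"columns not present in the sample map: {unmapped}"
        )
    missing_cols = [c for c in config.sample_map if c not in raw.columns]
    if missing_cols:
        raise ConfigurationError(
            f"sample-map columns absent from {path}: {missing_cols}"
        )

    ids = raw[config.protein_id_column].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise InputError(f"duplicate protein ids in {path}: {dupes}")

    if pep_col is not None:
        peptide_count = pd.to_numeric(raw[pep_col], errors="raise").astype(int)
    else:
        peptide_count = pd.Series(np.full(len(raw), 2), index=raw.index)
    if cont_col is not None:
        cont = raw[cont_col]
        contaminant = (
            cont.astype(str).isin(("+", "True", "true", "1"))
            if cont.dtype == object
            else cont.fillna(False).astype(bool)
        )
    else:
        contaminant = pd.Series(False, index=raw.index)

    proteins = pd.DataFrame(
        {
            "protein_id": ids.to_numpy(),
            "peptide_count": peptide_count.to_numpy(),
            "contaminant": contaminant.to_numpy(),
            "excluded": False,
            "exclude_reasons": "",
        }
    )
    proteins = mark_excluded(proteins, proteins["contaminant"], "contaminant")
    proteins = mark_excluded(proteins, proteins["peptide_count"] < 2, "min_peptides")

    frames = []
    for col, (key, temp) in config.sample_map.items():
        vals = pd.to_numeric(raw[col], errors="coerce")
        if (vals.dropna() < 0).any():
            raise InputError(f"negative abundances in column {col!r}")
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": ids.to_numpy(),
                    "treatment": key.treatment,
                    "replicate": key.replicate,
                    "temperature": temp,
                    "abundance": vals.to_numpy(dtype=float),
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    data = data.sort_values(
        ["protein_id", "treatment", "replicate", "temperature"], kind="stable"
    ).reset_index(drop=True)
    return AbundanceData(data=data, proteins=proteins, grid=config.grid)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV with missing cells left empty (never zero-filled)."""
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# canonical column order of the candidate-results table
RESULT_COLUMNS = [
    "protein_id",
    "class",
    "direction",
    "selected",
    "delta_tm",
    "vip",
    "rank_abs_dtm",
    "rank_vip",
]


def write_results(records: pd.DataFrame, path) -> None:
    """Write the candidate-record table as TSV.

    One row per protein; ΔTm/p per contrast plus class, direction, VIP and
    ranks.  Missing VIP (protein absent from the multivariate model input)
    is written as an empty cell.  Round-trips losslessly through
    :func:`read_results`.
    """
    records = records.copy()
    lead = [c for c in RESULT_COLUMNS if c in records.columns]
    rest = [c for c in records.columns if c not in lead]
    write_table(records[lead + rest], path)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "protein_id" in df.columns:
        df["protein_id"] = df["protein_id"].astype(str)
    return df
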