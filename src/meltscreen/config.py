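"""Experiment configuration: temperature grid, sample map, selection thresholds.

A screen compares four treatment arms of the same lysate — vehicle (control),
cosubstrate alone, enzyme alone, and enzyme + cosubstrate ("both") — each heated
across a temperature gradient and quantified per protein.  Every configurable
constant of the downstream analysis lives here so that a run is a pure function
of (input table, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

#: Canonical treatment arms of the four-arm lysate design.
TREATMENTS = ("vehicle", "cosubstrate", "enzyme", "both")

#: Default 10-point gradient in °C used by the assay.
DEFAULT_TEMPERATURES = (37.0, 41.0, 44.0, 47.0, 50.0, 53.0, 56.0, 59.0, 63.0, 67.0)


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent configuration."""


class InputError(ValueError):
    """Raised for malformed input tables."""


@dataclass(frozen=True)
class TemperatureGrid:
    """Ordered heating temperatures in °C; the first point is the reference."""

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        object.__setattr__(self, "temperatures", temps)
        if len(temps) < 4:
            raise ConfigurationError("temperature grid needs at least 4 points")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ConfigurationError("temperatures must be strictly increasing")

    @property
    def reference(self) -> float:
        return self.temperatures[0]

    def __len__(self) -> int:
        return len(self.temperatures)

    def __iter__(self):
        return iter(self.temperatures)


@dataclass(frozen=True)
class SampleKey:
    """One measured sample: a treatment arm and a replicate number."""

    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ConfigurationError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.replicate < 1:
            raise ConfigurationError("replicate must be a positive integer")

    @property
    def label(self) -> str:
        return f"{self.treatment}_r{self.replicate}"


@dataclass(frozen=True)
class Thresholds:
    """Candidate-selection thresholds.

    r2_min       minimum coefficient of determination of the melt fit
    sd_max       maximum replicate standard deviation of Tm, °C
    p_primary    stricter t-test threshold (must hold for one substrate contrast)
    p_secondary  looser t-test threshold (must hold for the other contrast)
    dtm_min      minimum absolute melting-temperature shift, °C
    """

    r2_min: float = 0.7
    sd_max: float = 2.5
    p_primary: float = 0.05
    p_secondary: float = 0.1
    dtm_min: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r2_min", "sd_max", "p_primary", "p_secondary", "dtm_min"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")
        if self.p_primary > self.p_secondary:
            raise ConfigurationError(
                f"p_primary ({self.p_primary}) must not exceed "
                f"p_secondary ({self.p_secondary})"
            )


@dataclass
class ExperimentConfig:
    """Everything the pipeline needs besides the quantification table itself.

    ``sample_map`` maps an abundance column name to ``(SampleKey, temperature)``.
    """

    grid: TemperatureGrid = field(default_factory=TemperatureGrid)
    sample_map: dict[str, tuple[SampleKey, float]] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_permutations: int = 100
    seed: int = 0
    # model options
    slope_times_t: bool = True  # exponent (T-Tm)/(b*T) if True else (T-Tm)/b
    plateau_max: float = 0.5  # fitted plateau at/above this marks a non-melter
    # normalization reference-set filter (bulk-proteome melting subset)
    norm_min_shared: int = 20
    norm_spearman_max: float = -0.8
    norm_top_fraction_max: float = 0.3
    # screening options
    reapply_qc_in_permutation: bool = True
    require_sign_concordance: bool = True
    # column conventions for the quant reader
    protein_id_column: str = "protein_id"
    peptide_count_column: str = "peptide_count"
    contaminant_column: str = "contaminant"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not 0 < self.plateau_max <= 1:
            raise ConfigurationError("plateau_max must be in (0, 1]")

    @property
    def samples(self) -> list[SampleKey]:
        """Unique samples in the map, ordered by treatment then replicate."""
        keys = {key for key, _ in self.sample_map.values()}
        return sorted(keys, key=lambda k: (TREATMENTS.index(k.treatment), k.replicate))

    def with_sample_map(
        self, sample_map: Mapping[str, tuple[SampleKey, float]]
    ) -> "ExperimentConfig":
        return replace(self, sample_map=dict(sample_map))


def default_sample_map(
    grid: TemperatureGrid | None = None,
    n_replicates: int = 2,
    column_pattern: str = "{treatment}_r{replicate}_T{temperature:g}",
) -> dict[str, tuple[SampleKey, float]]:
    """Generate the column → (sample, temperature) map for the default layout."""
    grid = grid or TemperatureGrid()
    out: dict[str, tuple[SampleKey, float]] = {}
    for treatment in TREATMENTS:
        for rep in range(1, n_replicates + 1):
            key = SampleKey(treatment, rep)
            for temp in grid:
                col = column_pattern.format(
                    treatment=treatment, replicate=rep, temperature=temp
                )
                out[col] = (key, temp)
    return out


def reporter_intensity_sample_map(
    sample_names: Mapping[str, SampleKey], grid: TemperatureGrid | None = None
) -> dict[str, tuple[SampleKey, float]]:
    """Convenience map for the common ``Reporter intensity corrected N <sample>``
    column naming, where channel order follows the temperature gradient."""
    grid = grid or TemperatureGrid()
    out: dict[str, tuple[SampleKey, float]] = {}
    for name, key in sample_names.items():
        for channel, temp in enumerate(grid, start=1):
            out[f"Reporter intensity corrected {channel} {name}"] = (key, temp)
    return out


def infer_sample_map(
    columns, grid: TemperatureGrid | None = None
) -> dict[str, tuple[SampleKey, float]]:
    """Infer the sample map from ``{treatment}_r{replicate}_T{temp}`` columns.

    Only columns matching the canonical pattern are mapped; others are left
    out (the reader treats them as metadata or errors as appropriate).
    """
    import re

    pattern = re.compile(
        rf"^({'|'.join(TREATMENTS)})_r(\d+)_T([0-9.]+)$"
    )
    out: dict[str, tuple[SampleKey, float]] = {}
    for col in columns:
        m = pattern.match(str(col))
        if m:
            key = SampleKey(m.group(1), int(m.group(2)))
            out[col] = (key, float(m.group(3)))
    if grid is not None:
        temps = set(grid)
        bad = {c for c, (_, t) in out.items() if t not in temps}
        if bad:
            raise ConfigurationError(
                f"columns map to temperatures outside the grid: {sorted(bad)}"
            )
    return out


def _parse_sample_map(raw: Mapping) -> dict[str, tuple[SampleKey, float]]:
    out: dict[str, tuple[SampleKey, float]] = {}
    for col, entry in raw.items():
        try:
            key = SampleKey(str(entry["treatment"]), int(entry["replicate"]))
            temp = float(entry["temperature"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(
                f"sample_map entry for column {col!r} is malformed: {exc}"
            ) from exc
        out[str(col)] = (key, temp)
    return out


def load_config(path) -> ExperimentConfig:
    """Load a YAML experiment configuration.

    Absent keys fall back to the package defaults (the published selection
    criteria: r2_min 0.7, sd_max 2.5 °C, p 0.05/0.1, |ΔTm| > 1 °C).  An empty
    file yields the full default configuration.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"config file {path} must contain a mapping")

    kwargs: dict = {}
    if "grid" in raw:
        kwargs["grid"] = TemperatureGrid(tuple(raw["grid"]))
    if "thresholds" in raw:
        try:
            kwargs["thresholds"] = Thresholds(**raw["thresholds"])
        except TypeError as exc:
            raise ConfigurationError(f"unknown threshold key: {exc}") from exc
    if "sample_map" in raw:
        kwargs["sample_map"] = _parse_sample_map(raw["sample_map"])
    for key in (
        "n_permutations",
        "seed",
        "slope_times_t",
        "plateau_max",
        "norm_min_shared",
        "norm_spearman_max",
        "norm_top_fraction_max",
        "reapply_qc_in_permutation",
        "require_sign_concordance",
        "protein_id_column",
        "peptide_count_column",
        "contaminant_column",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    unknown = set(raw) - set(kwargs) - {"grid", "thresholds", "sample_map"}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**kwargs)
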