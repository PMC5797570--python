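"""File input/output and run configuration.

Single source of truth for the CSV dialects the pipeline speaks: soil.csv,
towns.csv, an adjacency edge list, and a nested YAML configuration file.
All CSVs are comma-separated UTF-8 with a mandatory header row and '.' as
the decimal mark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, FormatError, ValidationError
from .tables import SoilSampleTable, TownTable, TransformedTable, ScoreTable

_RESERVED_SOIL = ["sample_id", "x", "y"]
_RESERVED_TOWN = ["town_id", "x", "y", "observed", "expected"]


# ---------------------------------------------------------------------------
# soil table

def read_soil_table(path) -> SoilSampleTable:
    """Read soil.csv: sample_id, x, y, then one column per element (mg/kg)."""
    df = pd.read_csv(path, comment="#")
    for col in _RESERVED_SOIL:
        if col not in df.columns:
            raise FormatError(f"soil table {path}: missing required column {col!r}")
    elements = [c for c in df.columns if c not in _RESERVED_SOIL]
    if len(elements) < 2:
        raise FormatError(f"soil table {path}: found fewer than 2 element columns")
    conc = df[elements].apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.any(~np.isfinite(conc)):
        i = int(np.where(~np.isfinite(conc).all(axis=1))[0][0])
        raise ValidationError(
            f"soil table {path}: non-numeric concentration in row "
            f"{df['sample_id'].iloc[i]!r}"
        )
    return SoilSampleTable(
        sample_id=df["sample_id"].to_numpy(),
        coords=df[["x", "y"]].to_numpy(float),
        concentrations=conc,
        elements=elements,
    )


def write_soil_table(table: SoilSampleTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_transformed_table(table: TransformedTable, path) -> None:
    """Write transformed.csv with the transform tag in a comment header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# transform: {table.transform}\n")
        table.to_frame().to_csv(fh, index=False)


def read_transformed_table(path) -> TransformedTable:
    tag = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#") and "transform:" in first:
        tag = first.split("transform:")[1].strip()
    if tag not in ("log", "clr"):
        raise FormatError(f"{path}: missing '# transform: {{log,clr}}' header line")
    df = pd.read_csv(path, comment="#")
    elements = [c for c in df.columns if c not in _RESERVED_SOIL]
    return TransformedTable(
        sample_id=df["sample_id"].to_numpy(),
        coords=df[["x", "y"]].to_numpy(float),
        values=df[elements].to_numpy(float),
        elements=elements,
        transform=tag,
    )


def write_score_table(table: ScoreTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_score_table(path) -> ScoreTable:
    df = pd.read_csv(path, comment="#")
    factors = [c for c in df.columns if c not in _RESERVED_SOIL]
    return ScoreTable(
        sample_id=df["sample_id"].to_numpy(),
        coords=df[["x", "y"]].to_numpy(float),
        scores=df[factors].to_numpy(float),
        factor_names=factors,
    )


# ---------------------------------------------------------------------------
# town table

def read_town_table(path) -> TownTable:
    """Read towns.csv: town_id, x, y, observed, expected, then covariates."""
    df = pd.read_csv(path, comment="#")
    for col in _RESERVED_TOWN:
        if col not in df.columns:
            raise FormatError(f"town table {path}: missing required column {col!r}")
    covs = [c for c in df.columns if c not in _RESERVED_TOWN]
    return TownTable(
        town_id=df["town_id"].to_numpy(),
        coords=df[["x", "y"]].to_numpy(float),
        observed=df["observed"].to_numpy(),
        expected=df["expected"].to_numpy(float),
        covariates=df[covs].to_numpy(float) if covs else None,
        covariate_names=covs,
    )


def write_town_table(table: TownTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# adjacency

def read_adjacency(path, town_ids):
    """Read a whitespace- or comma-separated edge list into an AdjacencyGraph.

    The graph is undirected and simple: duplicate edges collapse, self-loops
    are rejected, and every endpoint must be one of ``town_ids``.
    """
    from .spatial import AdjacencyGraph  # deferred to avoid a cycle

    ids = [str(t) for t in town_ids]
    known = set(ids)
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two town ids, got {line!r}")
            a, b = parts
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-loop on town {a!r}")
            for t in (a, b):
                if t not in known:
                    raise ValidationError(f"{path}:{lineno}: unknown town id {t!r}")
            edges.append((a, b))
    return AdjacencyGraph(ids, edges)


def write_adjacency(graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in graph.edges:
            fh.write(f"{a} {b}\n")


# ---------------------------------------------------------------------------
# configuration

_ALLOWED_TRANSFORMS = ("log", "clr")


@dataclass
class MeshConfig:
    max_edge: float = 5.0            # km; greatest triangle edge allowed
    extension_factor: float = 3.0    # coarsening of the boundary-extension ring
    extension_width: float | None = None  # km; default scales with the domain
    max_vertices: int = 20000


@dataclass
class InferenceConfig:
    method: str = "laplace"
    chains: int = 1
    iterations: int = 400            # optimiser evaluation budget
    seed: int = 0


@dataclass
class PriorConfig:
    coef_sd: float = 10.0            # Normal sd for alpha, beta, delta
    sd_prior: str = "half_normal"    # family tag for scale hyperpriors
    sd_prior_scale: float = 1.0
    range_prior: str = "log_normal"  # family tag for the Matern range


@dataclass
class PipelineConfig:
    """Fully-specified run configuration with documented defaults."""

    soil: str = "soil.csv"
    towns: str = "towns.csv"
    adjacency: str = "adjacency.txt"
    output_dir: str = "output"
    transform: str = "clr"
    variance_threshold: float = 0.75
    mesh: MeshConfig = field(default_factory=MeshConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    adjusted: bool = True
    naive: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.transform not in _ALLOWED_TRANSFORMS:
            raise ConfigError(
                f"transform: {self.transform!r} is not allowed; "
                f"choose one of {list(_ALLOWED_TRANSFORMS)}"
            )
        if not (0 < self.variance_threshold <= 1):
            raise ConfigError(
                f"variance_threshold: {self.variance_threshold} not in (0, 1]"
            )
        if not self.mesh.max_edge > 0:
            raise ConfigError(f"mesh.max_edge: {self.mesh.max_edge} must be > 0")
        if self.mesh.extension_factor < 1:
            raise ConfigError(
                f"mesh.extension_factor: {self.mesh.extension_factor} must be >= 1"
            )
        if not (isinstance(self.inference.seed, (int, np.integer))
                and self.inference.seed >= 0):
            raise ConfigError(f"inference.seed: {self.inference.seed} must be a "
                              "non-negative integer")

    def to_dict(self) -> dict:
        return asdict(self)


_SECTION_TYPES = {"mesh": MeshConfig, "inference": InferenceConfig,
                  "priors": PriorConfig}


def _build_section(cls, data: dict, prefix: str):
    allowed = set(cls.__dataclass_fields__)
    for key in data:
        if key not in allowed:
            raise ConfigError(f"unknown configuration key {prefix}{key!r}")
    try:
        return cls(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"invalid section {prefix!r}: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load a YAML config; absent keys take documented defaults, unknown keys error."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    top_allowed = set(PipelineConfig.__dataclass_fields__)
    kwargs = {}
    for key, value in data.items():
        if key not in top_allowed:
            raise ConfigError(f"unknown configuration key {key!r}")
        if key in _SECTION_TYPES:
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, f"{key}.")
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
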