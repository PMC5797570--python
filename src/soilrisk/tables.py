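"""In-memory containers for the pipeline's tabular data.

All containers are thin, validated wrappers around numpy arrays plus the
identifier/name metadata needed to keep rows and columns aligned across
pipeline stages.  Coordinates are planar (already projected), in kilometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: the ten elements of the national topsoil survey, in conventional order
DEFAULT_ELEMENTS = ["Al", "As", "Cd", "Cr", "Cu", "Fe", "Mn", "Ni", "Pb", "Zn"]

#: population-size strata used for the categorical socio-demographic covariate
ZONE_LEVELS = ("rural", "semi-urban", "urban")


def _as_2d_float(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class SoilSampleTable:
    """Point-located element concentrations (mg/kg), strictly positive."""

    sample_id: np.ndarray          # (n,) str or int identifiers
    coords: np.ndarray             # (n, 2) planar km
    concentrations: np.ndarray     # (n, D) strictly positive
    elements: list[str]

    def __post_init__(self):
        self.sample_id = np.asarray(self.sample_id)
        self.coords = _as_2d_float(self.coords, "coords")
        self.concentrations = _as_2d_float(self.concentrations, "concentrations")
        n, d = self.concentrations.shape
        if d < 2:
            raise ValidationError("need at least 2 elements for a composition")
        if len(self.elements) != d:
            raise ValidationError("element names do not match concentration columns")
        if self.coords.shape != (n, 2):
            raise ValidationError("coords must be (n_samples, 2)")
        bad = np.where(~(self.concentrations > 0))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"non-positive concentration for element {self.elements[j]!r} "
                f"in row {self.sample_id[i]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_elements(self) -> int:
        return self.concentrations.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=self.elements)
        df.insert(0, "y", self.coords[:, 1])
        df.insert(0, "x", self.coords[:, 0])
        df.insert(0, "sample_id", self.sample_id)
        return df


@dataclass
class TransformedTable:
    """Transformed (opened) element data; ``transform`` is 'log' or 'clr'."""

    sample_id: np.ndarray
    coords: np.ndarray
    values: np.ndarray             # (n, D)
    elements: list[str]
    transform: str

    def __post_init__(self):
        self.sample_id = np.asarray(self.sample_id)
        self.coords = _as_2d_float(self.coords, "coords")
        self.values = _as_2d_float(self.values, "values")
        if self.transform not in ("log", "clr"):
            raise ValidationError(f"unknown transform tag {self.transform!r}")
        if len(self.elements) != self.values.shape[1]:
            raise ValidationError("element names do not match value columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.elements)
        df.insert(0, "y", self.coords[:, 1])
        df.insert(0, "x", self.coords[:, 0])
        df.insert(0, "sample_id", self.sample_id)
        return df


@dataclass
class ScoreTable:
    """Per-sample factor scores at the soil sampling locations."""

    sample_id: np.ndarray
    coords: np.ndarray
    scores: np.ndarray             # (n, k)
    factor_names: list[str]

    def __post_init__(self):
        self.sample_id = np.asarray(self.sample_id)
        self.coords = _as_2d_float(self.coords, "coords")
        self.scores = _as_2d_float(self.scores, "scores")
        if len(self.factor_names) != self.scores.shape[1]:
            raise ValidationError("factor names do not match score columns")

    @property
    def n_factors(self) -> int:
        return self.scores.shape[1]

    def column(self, factor: str) -> np.ndarray:
        if factor not in self.factor_names:
            raise ValidationError(f"unknown factor {factor!r}")
        return self.scores[:, self.factor_names.index(factor)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.factor_names)
        df.insert(0, "y", self.coords[:, 1])
        df.insert(0, "x", self.coords[:, 0])
        df.insert(0, "sample_id", self.sample_id)
        return df


@dataclass
class TownTable:
    """Town-level mortality counts, expected counts and covariates.

    ``observed`` are non-negative integers, ``expected`` strictly positive;
    ``covariates`` is an (n, p) block (possibly p = 0) whose columns are
    already numeric (the population-size category is encoded upstream as two
    dummies against the rural baseline).
    """

    town_id: np.ndarray
    coords: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    covariates: np.ndarray = field(default=None)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.town_id = np.asarray(self.town_id)
        self.coords = _as_2d_float(self.coords, "coords")
        obs = np.asarray(self.observed, dtype=float)
        if np.any(obs < 0) or np.any(obs != np.round(obs)):
            i = int(np.where((obs < 0) | (obs != np.round(obs)))[0][0])
            raise ValidationError(
                f"observed deaths must be non-negative integers; "
                f"offending town {self.town_id[i]!r}"
            )
        self.observed = obs.astype(int)
        self.expected = np.asarray(self.expected, dtype=float)
        if np.any(~(self.expected > 0)):
            i = int(np.where(~(self.expected > 0))[0][0])
            raise ValidationError(
                f"expected deaths must be > 0; offending town {self.town_id[i]!r}"
            )
        if self.covariates is None:
            self.covariates = np.empty((len(self.town_id), 0))
        self.covariates = _as_2d_float(self.covariates, "covariates")
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValidationError("covariate names do not match covariate columns")

    @property
    def n_towns(self) -> int:
        return len(self.town_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "town_id": self.town_id,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "observed": self.observed,
                "expected": self.expected,
            }
        )
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        return df
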