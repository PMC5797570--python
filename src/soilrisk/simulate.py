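"""Synthetic misaligned datasets with known ground truth.

The generator emulates the structure the analysis assumes, at desk scale:

* soil samples scattered uniformly over a square domain, whose positive
  element concentrations carry a planted low-rank log-scale factor
  structure, each latent factor a smooth Matérn field;
* towns on an r × c lattice with queen (8-neighbour) adjacency;
* expected death counts proportional to a lognormal town population
  (classified into the rural / semi-urban / urban strata);
* socio-demographic covariates, optionally correlated with the exposure
  field (the confounding knob);
* Poisson observed deaths generated from the same log-linear relative-risk
  model the estimator fits, with known α, β, δ and BYM effects.

Everything is deterministic given the master seed; per-component child
seeds derive from :class:`numpy.random.SeedSequence` spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .spatial import (
    AdjacencyGraph,
    Mesh,
    build_mesh,
    make_projector,
    sample_gmrf,
    icar_precision,
)
from .spatial import SpdeBasis
from .tables import ScoreTable, SoilSampleTable, TownTable

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "generate_towns",
    "generate_soil_samples",
    "generate_mortality",
    "generate_scenario",
    "generate_endpoint_battery",
]

_DEFAULT_ELEMENTS = ["Al", "Fe", "Mn", "Zn", "Pb", "Cd"]
# typical topsoil geometric means, mg/kg, on the log scale
_DEFAULT_BASE = np.log([50000.0, 30000.0, 700.0, 60.0, 25.0, 0.3])
_DEFAULT_LOADINGS = np.array(
    [
        [0.9, 0.0],
        [0.8, 0.1],
        [0.7, 0.0],
        [0.0, 0.9],
        [0.0, 0.8],
        [0.2, 0.6],
    ]
)


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults give the reference scenario: a 20 km square with a 20 × 20
    town lattice, 600 soil samples, D = 6 elements carrying k* = 2 planted
    factors (range = side/4, unit marginal sd), score measurement sd 0.3,
    a true log relative risk of 0.2 per unit of factor 1 and 0 for
    factor 2, modest BYM heterogeneity and a mean expected count of 30.
    """

    side: float = 20.0                 # km, square domain
    n_rows: int = 20
    n_cols: int = 20
    n_soil_samples: int = 600
    elements: list = field(default_factory=lambda: list(_DEFAULT_ELEMENTS))
    loadings: np.ndarray = field(default_factory=lambda: _DEFAULT_LOADINGS.copy())
    base_log_conc: np.ndarray = field(default_factory=lambda: _DEFAULT_BASE.copy())
    field_range: float | None = None   # km; default side / 4
    field_sigma: float = 1.0
    noise_sd: float = 0.3              # log-concentration residual sd
    measurement_sd: float = 0.3        # score observation error sd
    alpha: float = 0.0
    beta: tuple = (0.2, 0.0)           # effect per planted factor
    covariate_names: list = field(
        default_factory=lambda: ["illiteracy", "farmers", "unemployment"]
    )
    delta: np.ndarray | None = None    # per covariate; default zeros
    confounding: float = 0.0           # corr of covariate 1 with exposure
    sd_u: float = 0.1
    sd_v: float = 0.05
    mean_expected: float = 30.0
    closure: bool = False
    closure_total: float = 1.0e6       # mg/kg row total when closed
    mesh_max_edge: float | None = None  # km; default side / 8
    seed: int = 0

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.base_log_conc = np.asarray(self.base_log_conc, dtype=float)
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValidationError("town lattice must be at least 2 x 2")
        d, k = self.loadings.shape
        if d != len(self.elements) or d != self.base_log_conc.size:
            raise ValidationError("loadings/elements/base dimensions disagree")
        if k > d:
            raise ValidationError("more planted factors than elements")
        if len(self.beta) != k:
            raise ValidationError("one true beta per planted factor required")
        if self.delta is None:
            self.delta = np.zeros(len(self.covariate_names))
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.size != len(self.covariate_names):
            raise ValidationError("delta length must match covariate names")
        for name, val in [("noise_sd", self.noise_sd),
                          ("measurement_sd", self.measurement_sd),
                          ("sd_u", self.sd_u), ("sd_v", self.sd_v)]:
            if val < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.mean_expected <= 0:
            raise ValidationError("mean_expected must be > 0")

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def range_(self) -> float:
        return self.field_range if self.field_range is not None else self.side / 4.0

    @property
    def max_edge(self) -> float:
        return (self.mesh_max_edge if self.mesh_max_edge is not None
                else self.side / 8.0)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated scenario, for recovery tests."""

    config: ScenarioConfig
    mesh: Mesh
    fields_mesh: np.ndarray         # (n_v, k*) latent factor fields
    fields_samples: np.ndarray      # (n_samples, k*)
    fields_centroids: np.ndarray    # (n_towns, k*); column f is expos for f
    u: np.ndarray
    v: np.ndarray
    eta: np.ndarray
    lam: np.ndarray

    def exposure_scores(self, factor: int = 0, seed: int = 0) -> ScoreTable:
        """Direct noisy observations of one latent field at the sample
        points: c_j = x(s_j) + N(0, measurement_sd²)."""
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
        c = (self.fields_samples[:, factor]
             + self.config.measurement_sd * rng.standard_normal(
                 self.fields_samples.shape[0]))
        return ScoreTable(
            sample_id=np.arange(len(c)),
            coords=self._sample_coords,
            scores=c[:, None],
            factor_names=[f"F{factor + 1}"],
        )

    _sample_coords: np.ndarray = None


def _rng(seed, *key):
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _lattice_coords(config: ScenarioConfig) -> np.ndarray:
    r, c = config.n_rows, config.n_cols
    xs = (np.arange(c) + 0.5) * config.side / c
    ys = (np.arange(r) + 0.5) * config.side / r
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _queen_edges(r: int, c: int):
    edges = []
    for i in range(r):
        for j in range(c):
            a = i * c + j
            for di, dj in ((0, 1), (1, -1), (1, 0), (1, 1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < r and 0 <= nj < c:
                    edges.append((str(a), str(ni * c + nj)))
    return edges


def generate_towns(config: ScenarioConfig, seed: int,
                   exposure=None) -> tuple:
    """Town lattice skeleton (observed = 0) and its queen adjacency.

    ``exposure`` (per-town values) lets the first covariate correlate with
    the exposure field at strength ``config.confounding``.
    """
    coords = _lattice_coords(config)
    n = len(coords)
    ids = np.array([str(i) for i in range(n)])
    graph = AdjacencyGraph(ids, _queen_edges(config.n_rows, config.n_cols))

    rng = _rng(seed, 1)
    population = np.exp(rng.normal(np.log(2000.0), 1.2, size=n))
    expected = population / population.mean() * config.mean_expected

    zone_semi = ((population >= 2000) & (population < 10000)).astype(float)
    zone_urban = (population >= 10000).astype(float)

    covs = []
    names = []
    for j, name in enumerate(config.covariate_names):
        noise = rng.standard_normal(n)
        if j == 0 and exposure is not None and config.confounding != 0:
            ex = np.asarray(exposure, dtype=float)
            exs = (ex - ex.mean()) / max(ex.std(), 1e-12)
            rho = config.confounding
            col = rho * exs + np.sqrt(max(1 - rho**2, 0.0)) * noise
        else:
            col = noise
        covs.append(col)
        names.append(name)
    covs.extend([zone_semi, zone_urban])
    names.extend(["zone_semiurban", "zone_urban"])

    towns = TownTable(
        town_id=ids,
        coords=coords,
        observed=np.zeros(n, dtype=int),
        expected=expected,
        covariates=np.column_stack(covs) if covs else None,
        covariate_names=names,
    )
    return towns, graph


def generate_soil_samples(config: ScenarioConfig, sample_coords,
                          fields_samples, seed: int) -> SoilSampleTable:
    """Compositional concentrations with the planted factor structure:
    log x = base + L* f(s) + noise, exponentiated; optional closure
    renormalises each row to a constant total."""
    fields_samples = np.asarray(fields_samples, dtype=float)
    n = fields_samples.shape[0]
    if fields_samples.shape[1] != config.n_factors:
        raise ValidationError("field matrix does not match planted factors")
    rng = _rng(seed, 2)
    logx = (
        config.base_log_conc[None, :]
        + fields_samples @ config.loadings.T
        + config.noise_sd * rng.standard_normal((n, len(config.elements)))
    )
    conc = np.exp(logx)
    if config.closure:
        conc = conc / conc.sum(axis=1, keepdims=True) * config.closure_total
    return SoilSampleTable(
        sample_id=np.arange(n),
        coords=np.asarray(sample_coords, dtype=float),
        concentrations=conc,
        elements=list(config.elements),
    )


def generate_mortality(towns: TownTable, eta, seed: int) -> TownTable:
    """Draw O_i ~ Poisson(E_i exp(η_i)) into a completed town table."""
    eta = np.asarray(eta, dtype=float)
    if np.any(eta > 30):
        raise ValidationError(
            "log relative risk exceeds 30; choose smaller effect sizes"
        )
    rng = _rng(seed, 3)
    observed = rng.poisson(towns.expected * np.exp(eta))
    return TownTable(
        town_id=towns.town_id,
        coords=towns.coords,
        observed=observed,
        expected=towns.expected,
        covariates=towns.covariates.copy(),
        covariate_names=list(towns.covariate_names),
    )


def _draw_bym(config: ScenarioConfig, graph: AdjacencyGraph, seed: int):
    n = graph.n_towns
    if config.sd_u > 0:
        q_u = icar_precision(graph)
        constraint = [np.where(graph.component_labels == comp)[0]
                      for comp in range(graph.n_components)]
        u = config.sd_u * sample_gmrf(
            q_u, seed=_rng(seed, 4).integers(2**31), constraint=constraint
        )
    else:
        u = np.zeros(n)
    v = config.sd_v * _rng(seed, 5).standard_normal(n)
    return u, v


def generate_scenario(config: ScenarioConfig, seed: int | None = None):
    """Full coherent dataset: soil table, completed town table, adjacency
    and the ground truth.  The exposure factor driving mortality is the
    first latent field, evaluated at the town centroid (so score
    measurement error never enters the outcome layer)."""
    if seed is None:
        seed = config.seed
    rng = _rng(seed, 0)
    sample_coords = rng.uniform(0.0, config.side,
                                size=(config.n_soil_samples, 2))

    domain = np.array([[0.0, 0.0], [config.side, 0.0],
                       [0.0, config.side], [config.side, config.side]])
    mesh = build_mesh(domain, max_edge=config.max_edge)
    basis = SpdeBasis(mesh)
    q_f = basis.precision(config.range_, config.field_sigma)
    k = config.n_factors
    field_seeds = _rng(seed, 6).integers(2**31, size=k)
    fields_mesh = np.column_stack(
        [sample_gmrf(q_f, seed=int(s)) for s in field_seeds]
    )
    a_s = make_projector(mesh, sample_coords).matrix

    soil = generate_soil_samples(config, sample_coords,
                                 a_s @ fields_mesh, seed)

    towns_skel, graph = generate_towns(config, seed, exposure=None)
    a_t = make_projector(mesh, towns_skel.coords).matrix
    fields_centroids = a_t @ fields_mesh
    # redraw covariates with the confounding link now the field exists
    towns_skel, graph = generate_towns(config, seed,
                                       exposure=fields_centroids[:, 0])

    u, v = _draw_bym(config, graph, seed)
    beta = np.asarray(config.beta, dtype=float)
    eta = (
        config.alpha
        + fields_centroids @ beta
        + towns_skel.covariates[:, : config.delta.size] @ config.delta
        + u + v
    )
    towns = generate_mortality(towns_skel, eta, seed)

    truth = SyntheticTruth(
        config=config,
        mesh=mesh,
        fields_mesh=fields_mesh,
        fields_samples=np.asarray(a_s @ fields_mesh),
        fields_centroids=np.asarray(fields_centroids),
        u=u,
        v=v,
        eta=eta,
        lam=np.exp(eta),
    )
    truth._sample_coords = sample_coords
    return soil, towns, graph, truth


def generate_endpoint_battery(config: ScenarioConfig, endpoints, sexes,
                              seed: int | None = None):
    """One shared exposure layout plus an independently generated outcome
    table per (endpoint, sex): fresh BYM effects and Poisson draws, same
    truth coefficients.  Returns (soil, towns_by_endpoint, graph, truth)."""
    if seed is None:
        seed = config.seed
    soil, _, graph, truth = generate_scenario(config, seed)
    beta = np.asarray(config.beta, dtype=float)
    towns_by_endpoint = {}
    for i, endpoint in enumerate(endpoints):
        for j, sex in enumerate(sexes):
            sub = int(np.random.SeedSequence(seed, spawn_key=(7, i, j))
                      .generate_state(1)[0] % (2**31))
            skel, _ = generate_towns(config, sub,
                                     exposure=truth.fields_centroids[:, 0])
            u, v = _draw_bym(config, graph, sub)
            eta = (config.alpha + truth.fields_centroids @ beta
                   + skel.covariates[:, : config.delta.size] @ config.delta
                   + u + v)
            towns_by_endpoint[(endpoint, sex)] = generate_mortality(
                skel, eta, sub
            )
    return soil, towns_by_endpoint, graph, truth
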