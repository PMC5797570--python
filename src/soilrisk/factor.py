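"""Principal factor analysis of the transformed element data.

The geochemical signal in topsoil is driven by a few latent element
associations (ore bodies, parent lithology, anthropogenic deposition).
This module reduces the D transformed concentrations to k common factors:

* principal-axis factoring (iterated communalities) on the correlation
  matrix, with squared-multiple-correlation starting communalities;
* factor count chosen as the smallest k whose cumulative explained-variance
  fraction exceeds a threshold (0.75 by default);
* varimax rotation (Kaiser row-normalised) for simple structure;
* sign orientation so each factor's dominant element loads positively;
* regression (Thomson) factor scores at every sampling point, using a
  pseudo-inverse so the singular clr correlation matrix is handled.

The public surface follows the model/results idiom:
``PrincipalFactorAnalysis(table).fit()`` returns a :class:`FactorResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .exceptions import FitError, ValidationError
from .tables import ScoreTable, TransformedTable

__all__ = [
    "correlation_matrix",
    "select_n_factors",
    "principal_factor_analysis",
    "varimax_criterion",
    "varimax_rotate",
    "orient_factors",
    "label_factors",
    "factor_scores",
    "biplot_data",
    "PrincipalFactorAnalysis",
    "FactorResults",
]


def correlation_matrix(table: TransformedTable) -> np.ndarray:
    """Pearson correlation matrix of the transformed element columns."""
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples for a correlation matrix")
    if not np.all(np.isfinite(table.values)):
        raise ValidationError("non-finite transformed values")
    r = np.corrcoef(table.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def select_n_factors(explained_fractions, threshold: float) -> int:
    """Smallest k whose cumulative explained-variance fraction exceeds ``threshold``."""
    frac = np.asarray(explained_fractions, dtype=float)
    if frac.size == 0 or np.any(frac < 0):
        raise ValidationError("explained fractions must be non-negative")
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold {threshold} not in (0, 1]")
    csum = np.cumsum(frac)
    above = np.where(csum > threshold)[0]
    if above.size == 0:
        raise FitError(
            f"cumulative explained variance {csum[-1]:.3f} never exceeds "
            f"threshold {threshold}"
        )
    return int(above[0]) + 1


def _smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlations via pseudo-inverse (clr-safe)."""
    rinv = np.linalg.pinv(corr, hermitian=True)
    d = np.diag(rinv).copy()
    d[d < 1e-12] = 1e-12
    return np.clip(1.0 - 1.0 / d, 0.0, 1.0)


def _reduced_eig(corr: np.ndarray, communalities: np.ndarray):
    red = corr.copy()
    np.fill_diagonal(red, communalities)
    vals, vecs = np.linalg.eigh(red)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def principal_factor_analysis(
    corr: np.ndarray, k: int, max_iter: int = 200, tol: float = 1e-6
):
    """Iterated principal-axis factoring of a correlation matrix.

    Returns ``(loadings, communalities, eigenvalues, n_iter, heywood)``
    where ``eigenvalues`` are those of the final reduced matrix (descending)
    and ``heywood`` flags any communality clamped at 1.

    Raises :class:`FitError` if the communalities have not stabilised
    (max change >= ``tol``) after ``max_iter`` iterations.
    """
    corr = np.asarray(corr, dtype=float)
    d = corr.shape[0]
    if corr.shape != (d, d) or not np.allclose(corr, corr.T, atol=1e-8):
        raise ValidationError("correlation matrix must be square symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-6):
        raise ValidationError("correlation matrix must have unit diagonal")
    if not 1 <= k < d:
        raise ValidationError(f"need 1 <= k < D, got k={k}, D={d}")
    h2 = _smc(corr)
    heywood = False
    loadings = np.zeros((d, k))
    for it in range(1, max_iter + 1):
        vals, vecs = _reduced_eig(corr, h2)
        lam = np.clip(vals[:k], 0.0, None)
        loadings = vecs[:, :k] * np.sqrt(lam)
        new_h2 = np.sum(loadings**2, axis=1)
        if np.any(new_h2 > 1.0):
            heywood = True
            scale = np.sqrt(np.minimum(1.0, 1.0 / np.maximum(new_h2, 1e-300)))
            loadings = loadings * scale[:, None]
            new_h2 = np.minimum(new_h2, 1.0)
        delta = np.max(np.abs(new_h2 - h2))
        h2 = new_h2
        if delta < tol:
            vals, _ = _reduced_eig(corr, h2)
            return loadings, h2, np.clip(vals, 0.0, None), it, heywood
    raise FitError(
        f"principal-axis factoring did not converge in {max_iter} iterations "
        f"(last communality change {delta:.2e})"
    )


# ---------------------------------------------------------------------------
# rotation

def varimax_criterion(loadings: np.ndarray, kaiser: bool = True) -> float:
    """Varimax objective: sum over factors of the variance of squared
    (optionally Kaiser row-normalised) loadings."""
    a = np.asarray(loadings, dtype=float)
    if kaiser:
        w = np.sqrt(np.sum(a**2, axis=1))
        w[w < 1e-12] = 1.0
        a = a / w[:, None]
    a2 = a**2
    return float(np.sum(a2.var(axis=0)))


def varimax_rotate(loadings: np.ndarray, kaiser: bool = True):
    """Varimax rotation with Kaiser row-normalisation.

    Returns ``(rotated, R)`` with ``rotated = loadings @ R`` and R
    orthonormal.  For k = 1 the identity rotation is returned.
    """
    a = np.asarray(loadings, dtype=float)
    if a.ndim != 2:
        raise ValidationError("loadings must be a 2-d array")
    k = a.shape[1]
    if k == 1:
        return a.copy(), np.eye(1)
    w = np.ones(a.shape[0])
    if kaiser:
        w = np.sqrt(np.sum(a**2, axis=1))
        w[w < 1e-12] = 1.0
    a_norm = a / w[:, None]
    with np.errstate(divide="ignore"):  # GPA logs a zero gradient at optima
        rotated_norm, rot = rotate_factors(a_norm, "varimax")
    rotated = rotated_norm * w[:, None]
    # guard against numerical drift in the returned rotation
    if np.linalg.norm(rot.T @ rot - np.eye(k)) > 1e-8:
        u, _, vt = np.linalg.svd(rot)
        rot = u @ vt
        rotated = a @ rot
    return rotated, rot


def orient_factors(loadings: np.ndarray):
    """Flip factors whose dominant element loads negatively.

    The dominant element is the one with the largest absolute loading; exact
    ties resolve to the first tied element in column order.  Returns
    ``(oriented, signs)``; applying twice is a no-op.
    """
    a = np.asarray(loadings, dtype=float).copy()
    signs = np.ones(a.shape[1])
    for j in range(a.shape[1]):
        col = a[:, j]
        idx = int(np.argmax(np.abs(col)))  # argmax takes the first tie
        if col[idx] < 0:
            signs[j] = -1.0
    return a * signs, signs


def label_factors(loadings, elements, threshold: float = 0.4):
    """Signed element lists per factor, e.g. ``'Pb, Zn, -Ni'``.

    Elements with |loading| >= ``threshold`` are listed in decreasing
    |loading| order, negative loadings prefixed with '-'.  An empty string
    means no element passes the threshold.
    """
    a = np.asarray(loadings, dtype=float)
    labels = []
    for j in range(a.shape[1]):
        col = a[:, j]
        idx = np.argsort(-np.abs(col), kind="stable")
        parts = [
            ("-" if col[i] < 0 else "") + str(elements[i])
            for i in idx
            if abs(col[i]) >= threshold
        ]
        labels.append(", ".join(parts))
    return labels


# ---------------------------------------------------------------------------
# scores & biplot

def _standardise_columns(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1.0
    return (values - mu) / sd


def factor_scores(table: TransformedTable, results: "FactorResults") -> ScoreTable:
    """Regression (Thomson) factor scores: c = z . pinv(R) . L.

    ``z`` are the column-standardised transformed values, ``R`` the observed
    correlation matrix (pseudo-inverted, so the singular clr case works) and
    ``L`` the oriented rotated loadings.
    """
    if list(table.elements) != list(results.elements):
        raise ValidationError(
            "element mismatch between transformed table and factor model"
        )
    z = _standardise_columns(table.values)
    weights = np.linalg.pinv(results.corr, hermitian=True) @ results.loadings
    scores = z @ weights
    return ScoreTable(
        sample_id=table.sample_id,
        coords=table.coords,
        scores=scores,
        factor_names=list(results.factor_names),
    )


def biplot_data(table: TransformedTable, n_components: int = 2) -> pd.DataFrame:
    """First two principal-component scores and loading arrows, as one table.

    Output rows: one per sample (kind='score') followed by one per element
    (kind='loading'); the ``explained`` column repeats each PC's share of
    total variance.
    """
    if table.values.shape[1] < 2:
        raise ValidationError("biplot needs at least 2 elements")
    z = _standardise_columns(table.values)
    n = z.shape[0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    shares = s**2 / np.sum(s**2)
    pcs = u[:, :n_components] * s[:n_components]
    loads = vt[:n_components].T * (s[:n_components] / np.sqrt(n - 1))
    rows = []
    for i in range(n):
        rows.append(
            {"kind": "score", "name": str(table.sample_id[i]),
             "PC1": pcs[i, 0], "PC2": pcs[i, 1],
             "explained_PC1": shares[0], "explained_PC2": shares[1]}
        )
    for j, e in enumerate(table.elements):
        rows.append(
            {"kind": "loading", "name": e,
             "PC1": loads[j, 0], "PC2": loads[j, 1],
             "explained_PC1": shares[0], "explained_PC2": shares[1]}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results classes

@dataclass
class FactorResults:
    """Fitted principal factor analysis.

    ``loadings`` are varimax-rotated and sign-oriented; ``explained`` /
    ``explained_rotated`` are per-factor variance fractions (of total
    observed variance D) before and after rotation.
    """

    elements: list[str]
    transform: str
    loadings: np.ndarray            # (D, k), rotated + oriented
    unrotated_loadings: np.ndarray  # (D, k)
    rotation: np.ndarray            # (k, k) orthonormal
    signs: np.ndarray               # (k,) orientation flips applied
    communalities: np.ndarray       # (D,)
    eigenvalues: np.ndarray         # reduced-matrix eigenvalues, descending
    explained: np.ndarray           # pre-rotation fractions (k,)
    explained_rotated: np.ndarray   # post-rotation fractions (k,)
    corr: np.ndarray                # observed correlation matrix
    n_iter: int
    heywood: bool
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.factor_names:
            self.factor_names = [f"F{j + 1}" for j in range(self.loadings.shape[1])]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained)

    def labels(self, threshold: float = 0.4):
        return label_factors(self.loadings, self.elements, threshold)

    def scores(self, table: TransformedTable) -> ScoreTable:
        return factor_scores(table, self)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.elements,
                            columns=self.factor_names)

    def summary(self) -> str:
        lines = [
            f"Principal factor analysis ({self.transform}-transformed, "
            f"D={len(self.elements)}, k={self.n_factors})",
            f"converged in {self.n_iter} iterations"
            + ("; Heywood case clamped" if self.heywood else ""),
            "",
            self.loadings_frame().round(3).to_string(),
            "",
            "explained variance fraction (pre-rotation):  "
            + " ".join(f"{v:.3f}" for v in self.explained)
            + f"  (cumulative {self.cumulative_explained[-1]:.3f})",
            "explained variance fraction (post-rotation): "
            + " ".join(f"{v:.3f}" for v in self.explained_rotated),
            "",
        ]
        for name, lab in zip(self.factor_names, self.labels()):
            lines.append(f"{name}: {lab if lab else '(no loading >= 0.4)'}")
        return "\n".join(lines)


class PrincipalFactorAnalysis:
    """Principal factor analysis model for a transformed element table.

    Parameters
    ----------
    table : TransformedTable
        log- or clr-transformed concentrations.
    n_factors : int, optional
        Fixed factor count; when omitted the count is the smallest k whose
        cumulative explained-variance fraction (eigenvalue shares of the
        SMC-reduced correlation matrix over total variance D) exceeds
        ``variance_threshold``.
    variance_threshold : float
        Cumulative-variance rule, default 0.75.
    """

    def __init__(self, table: TransformedTable, n_factors: int | None = None,
                 variance_threshold: float = 0.75):
        self.table = table
        self.n_factors = n_factors
        self.variance_threshold = variance_threshold
        self.corr = correlation_matrix(table)

    def initial_explained_fractions(self) -> np.ndarray:
        """Eigenvalue shares of the SMC-reduced matrix relative to D."""
        vals, _ = _reduced_eig(self.corr, _smc(self.corr))
        return np.clip(vals, 0.0, None) / self.corr.shape[0]

    def fit(self, max_iter: int = 200, tol: float = 1e-6) -> FactorResults:
        k = self.n_factors
        if k is None:
            k = select_n_factors(
                self.initial_explained_fractions(), self.variance_threshold
            )
        loadings, h2, eigvals, n_iter, heywood = principal_factor_analysis(
            self.corr, k, max_iter=max_iter, tol=tol
        )
        d = self.corr.shape[0]
        rotated, rot = varimax_rotate(loadings)
        oriented, signs = orient_factors(rotated)
        # order rotated factors by explained variance, descending
        ssq = np.sum(oriented**2, axis=0)
        order = np.argsort(-ssq, kind="stable")
        oriented = oriented[:, order]
        rot = rot[:, order]
        signs = signs[order]
        ssq = ssq[order]
        return FactorResults(
            elements=list(self.table.elements),
            transform=self.table.transform,
            loadings=oriented,
            unrotated_loadings=loadings,
            rotation=rot,
            signs=signs,
            communalities=h2,
            eigenvalues=eigvals,
            explained=np.clip(eigvals[:k], 0.0, None) / d,
            explained_rotated=ssq / d,
            corr=self.corr,
            n_iter=n_iter,
            heywood=heywood,
        )
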