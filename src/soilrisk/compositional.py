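"""Opening closed concentration data.

Soil element concentrations are compositional: each sample's parts are tied
to an (approximately) constant total, so raw correlations between elements
are distorted by closure.  Two transforms are offered:

* ``standardised_log_transform`` — the classical option: per element,
  z-score the log concentration, ``y = (log x - mean(log x)) / sd(log x)``.
* ``clr_transform`` — the centred logratio: per sample, log of each part
  over the geometric mean of all the sample's parts, which removes closure
  at the cost of a singular correlation matrix (rows sum to zero).
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .tables import SoilSampleTable, TransformedTable

__all__ = [
    "standardised_log_transform",
    "clr_transform",
    "transform",
    "spurious_correlation_demo",
]


def standardised_log_transform(table: SoilSampleTable) -> TransformedTable:
    """Standardise log concentrations per element (sample sd, ddof=1).

    Raises
    ------
    ValidationError
        If fewer than two samples are given or an element is constant
        across samples (zero log-scale standard deviation).
    """
    if table.n_samples < 2:
        raise ValidationError("standardised log transform needs >= 2 samples")
    logx = np.log(table.concentrations)
    mean = logx.mean(axis=0)
    sd = logx.std(axis=0, ddof=1)
    degenerate = np.where(sd == 0)[0]
    if degenerate.size:
        raise ValidationError(
            f"element {table.elements[degenerate[0]]!r} is constant across samples"
        )
    return TransformedTable(
        sample_id=table.sample_id,
        coords=table.coords,
        values=(logx - mean) / sd,
        elements=list(table.elements),
        transform="log",
    )


def clr_transform(table: SoilSampleTable) -> TransformedTable:
    """Centred logratio: y_i = log(x_i / g(x)) with g the per-sample
    geometric mean, computed as exp(mean(log x)) for stability."""
    logx = np.log(table.concentrations)
    y = logx - logx.mean(axis=1, keepdims=True)
    return TransformedTable(
        sample_id=table.sample_id,
        coords=table.coords,
        values=y,
        elements=list(table.elements),
        transform="clr",
    )


def transform(table: SoilSampleTable, method: str) -> TransformedTable:
    """Dispatch on the transform tag ('log' or 'clr')."""
    if method == "log":
        return standardised_log_transform(table)
    if method == "clr":
        return clr_transform(table)
    raise ValidationError(f"unknown transform {method!r}; allowed: 'log', 'clr'")


def spurious_correlation_demo(
    table: SoilSampleTable, element_a: str, element_b: str
) -> tuple[float, float]:
    """Pearson correlation of two elements under log vs. clr transforms.

    A diagnostic making the closure artefact visible: parts of a closed
    composition can correlate strongly on the raw log scale purely because
    their sum is constrained; the clr correlation reflects the relative
    (subcompositional) association instead.

    Returns ``(r_log, r_clr)``.
    """
    for e in (element_a, element_b):
        if e not in table.elements:
            raise ValidationError(f"unknown element {e!r}")
    if element_a == element_b:
        # degenerate request; correlation of a column with itself
        return 1.0, 1.0
    ia = table.elements.index(element_a)
    ib = table.elements.index(element_b)
    logx = np.log(table.concentrations)
    clr = logx - logx.mean(axis=1, keepdims=True)
    r_log = float(np.corrcoef(logx[:, ia], logx[:, ib])[0, 1])
    r_clr = float(np.corrcoef(clr[:, ia], clr[:, ib])[0, 1])
    return r_log, r_clr
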