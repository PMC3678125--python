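"""Scalar summaries of simulated time series for parameter-space maps,
plus multiscale entropy.

The two variance metrics reduce a 4-D ``[time, svar, space, modes]``
monitor output to a single number: *global variance* zero-centers every
individual time series and takes the variance over all data points of the
array; *variance of node variances* measures how heterogeneous the nodes'
temporal variances are.  Both use the population variance (divide by the
number of points) and are invariant under adding a constant to any series.
"""

from __future__ import annotations

import numpy as np

from .monitors import TimeSeriesResult

__all__ = [
    "global_variance",
    "variance_of_node_variances",
    "sample_entropy",
    "multiscale_entropy",
    "METRIC_REGISTRY",
]


def _as_array(result) -> np.ndarray:
    data = result.data if isinstance(result, TimeSeriesResult) else np.asarray(result)
    if data.size == 0:
        raise ValueError("empty time series")
    return np.asarray(data, dtype=float)


def global_variance(result) -> float:
    """Zero-center each (svar, node, mode) series over time, then take the
    variance over every data point of the 4-D array."""
    data = _as_array(result)
    centered = data - data.mean(axis=0, keepdims=True)
    return float(np.var(centered))


def variance_of_node_variances(result) -> float:
    """Per node: variance over time of the concatenated per-(svar, mode)
    zero-centered series; then the variance of those node variances."""
    data = _as_array(result)
    if data.ndim != 4 or data.shape[2] < 2:
        raise ValueError("need a 4-D result with at least 2 nodes")
    centered = data - data.mean(axis=0, keepdims=True)
    # [time, svar, node, mode] -> per node, all svar/mode samples pooled
    per_node = centered.transpose(2, 0, 1, 3).reshape(data.shape[2], -1)
    node_vars = per_node.var(axis=1)
    return float(np.var(node_vars))


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): −ln(A/B) with B the count of template pairs of length
    ``m`` within Chebyshev tolerance ``r`` and A the count for length
    ``m + 1`` (self-matches excluded).  ``r`` is an absolute tolerance.
    Returns inf when no (m+1)-matches exist."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"series too short for m={m}: need at least {m + 2} points")
    if r is None:
        r = 0.15 * x.std()
    within = np.abs(x[:, None] - x[None, :]) <= r

    # both template lengths range over the same n - m starting indices
    # (Richman & Moorman convention), so a constant series gives exactly 0
    nt = n - m

    def template_matches(length: int) -> int:
        acc = within[:nt, :nt].copy()
        for k in range(1, length):
            acc &= within[k : nt + k, k : nt + k]
        np.fill_diagonal(acc, False)
        return int(acc.sum())  # ordered pairs; the ratio is unaffected

    b = template_matches(m)
    a = template_matches(m + 1)
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def coarse_grain(series: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping window means of width ``scale`` (scale 1 = identity)."""
    x = np.asarray(series, dtype=float)
    n = (x.size // scale) * scale
    return x[:n].reshape(-1, scale).mean(axis=1)


def multiscale_entropy(
    series: np.ndarray,
    scales: int = 5,
    m: int = 2,
    r: float = 0.15,
) -> np.ndarray:
    """Sample entropy of coarse-grained versions of a series.

    The tolerance is ``r`` times the standard deviation of the *original*
    (scale-1) series and is held fixed across scales.  Requires at least
    ``10 * (m + 1)`` points at the largest scale.
    """
    x = np.asarray(series, dtype=float)
    min_len = 10 * (m + 1)
    if x.size // scales < min_len:
        raise ValueError(
            f"series of length {x.size} too short for {scales} scales: "
            f"need at least {min_len * scales} points"
        )
    tol = r * x.std()
    return np.array(
        [sample_entropy(coarse_grain(x, s), m=m, r=tol) for s in range(1, scales + 1)]
    )


METRIC_REGISTRY = {
    "global_variance": global_variance,
    "node_variance": variance_of_node_variances,
}
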