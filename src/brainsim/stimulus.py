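"""Spatiotemporal stimulation patterns.

A stimulus factorises exactly into a spatial weight per node (or vertex)
and a temporal profile: ``pattern(node, t) = spatial_weights[node] *
temporal(t)``.  Region-level models take an explicit per-node weighting
vector; surface models evaluate a finite-support profile (e.g. Gaussian)
as a function of distance from one or more focal vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import DimensionError

__all__ = [
    "pulse_train",
    "PulseTrain",
    "StimulusPattern",
    "region_stimulus",
    "gaussian_profile",
    "spatial_profile",
    "surface_stimulus",
]


def pulse_train(t, onset: float = 0.0, width: float = 5.0, period: float = 1000.0,
                amplitude: float = 1.0):
    """Rectangular pulse train: ``amplitude`` while ``(t - onset) mod period``
    lies in the half-open window ``[0, width)`` and ``t >= onset``, else 0."""
    if period <= 0:
        raise ValueError("period must be positive")
    if width >= period:
        raise ValueError("pulse width must be smaller than the period")
    t = np.asarray(t, dtype=float)
    phase = np.mod(t - onset, period)
    out = np.where((t >= onset) & (phase < width), amplitude, 0.0)
    return out if out.ndim else float(out)


@dataclass
class PulseTrain:
    """Callable rectangular pulse train (picklable temporal equation)."""

    onset: float = 0.0
    width: float = 5.0
    period: float = 1000.0
    amplitude: float = 1.0

    def __post_init__(self):
        pulse_train(0.0, self.onset, self.width, self.period, self.amplitude)

    def __call__(self, t):
        return pulse_train(t, self.onset, self.width, self.period, self.amplitude)


@dataclass
class StimulusPattern:
    """Separable spatiotemporal pattern: spatial weights x temporal profile."""

    spatial_weights: np.ndarray
    temporal: Callable[[float], float]
    focal_points: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.spatial_weights = np.asarray(self.spatial_weights, dtype=float)
        if not np.all(np.isfinite(self.spatial_weights)):
            raise ValueError("spatial weights must be finite")

    @property
    def n_nodes(self) -> int:
        return self.spatial_weights.size

    def __call__(self, t: float) -> np.ndarray:
        """Per-node stimulus amplitude at time ``t`` (ms)."""
        return self.spatial_weights * self.temporal(t)


def region_stimulus(weighting, temporal) -> StimulusPattern:
    """Region-level stimulus: a per-node weighting modulating one temporal
    equation (region nodes have no spatial extent)."""
    w = np.asarray(weighting, dtype=float).ravel()
    return StimulusPattern(spatial_weights=w, temporal=temporal)


@dataclass
class gaussian_profile:
    """Gaussian distance profile with finite support:
    ``amplitude * exp(-d^2 / (2 sigma^2))`` for ``d <= cutoff``, else 0."""

    amplitude: float = 1.0
    sigma: float = 5.0
    cutoff: float = 20.0

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        out = self.amplitude * np.exp(-(d**2) / (2.0 * self.sigma**2))
        return np.where(d <= self.cutoff, out, 0.0)


def spatial_profile(
    vertices: np.ndarray,
    focal_points: Sequence[int],
    equation: Callable[[np.ndarray], np.ndarray],
    combine: str = "max",
) -> np.ndarray:
    """Per-vertex weights from distance-profile equations around focal vertices.

    Distances are Euclidean.  Overlapping kernels from several focal points
    are combined by ``max`` (default, avoids double-counting) or ``sum``.
    """
    vertices = np.asarray(vertices, dtype=float)
    n = vertices.shape[0]
    focal_points = list(focal_points)
    for fp in focal_points:
        if not (0 <= fp < n):
            raise IndexError(f"focal point {fp} out of range for {n} vertices")
    if combine not in ("max", "sum"):
        raise ValueError("combine must be 'max' or 'sum'")
    per_focal = np.empty((len(focal_points), n))
    for k, fp in enumerate(focal_points):
        d = np.linalg.norm(vertices - vertices[fp], axis=1)
        per_focal[k] = equation(d)
    return per_focal.max(axis=0) if combine == "max" else per_focal.sum(axis=0)


def surface_stimulus(
    vertices: np.ndarray,
    focal_points: Sequence[int],
    equation,
    temporal,
    combine: str = "max",
) -> StimulusPattern:
    """Surface stimulus: spatial profile around focal vertices x temporal."""
    weights = spatial_profile(vertices, focal_points, equation, combine)
    return StimulusPattern(
        spatial_weights=weights, temporal=temporal, focal_points=list(focal_points)
    )
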