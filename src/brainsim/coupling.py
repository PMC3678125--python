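"""Long-range coupling functions.

The weighted sum of delayed afferent activity is rescaled by one of these
elementwise transforms before it enters a node's equations.  By default the
transform is applied *after* the weighted summation (post-aggregation); set
``apply_before_sum=True`` to transform each delayed afferent signal first
and then sum (the two orders differ for the sigmoidal transform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LinearCoupling", "SigmoidalCoupling", "COUPLING_REGISTRY"]


@dataclass
class LinearCoupling:
    """Affine rescaling ``a*x + b``; ``a`` is the global coupling strength."""

    a: float = 0.1
    b: float = 0.0
    apply_before_sum: bool = False

    def __call__(self, x):
        return self.a * np.asarray(x) + self.b


@dataclass
class SigmoidalCoupling:
    """Saturating transform ``cmin + (cmax-cmin)/(1 + exp(-steepness*(x-midpoint)))``."""

    cmin: float = 0.0
    cmax: float = 1.0
    midpoint: float = 0.0
    steepness: float = 1.0
    apply_before_sum: bool = False

    def __post_init__(self):
        if self.cmax < self.cmin:
            raise ValueError("cmax must be >= cmin")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def __call__(self, x):
        span = self.cmax - self.cmin
        return self.cmin + span / (1.0 + np.exp(-self.steepness * (np.asarray(x) - self.midpoint)))


COUPLING_REGISTRY = {"linear": LinearCoupling, "sigmoidal": SigmoidalCoupling}
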