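"""Per-reaction standardization of fluxes.

Flux scales and locations differ by orders of magnitude between reactions,
which cripples joint HMC exploration.  Each reaction is therefore rescaled
by ``delta_j`` (from rough variance estimates) and shifted so that its
prior location lands on a common target (default 10):

    V''_{,j} = V_{,j} / delta_j + alpha_j,    alpha_j = target - mu_j / delta_j.

By default ``delta_j = sqrt(sigma2_U_j + sigma2_V_j)`` (standard-deviation
scale, the dimensionally coherent choice); ``mode="literal"`` uses the
plain sum of the two variance estimates instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FluxTable
from .mixedmodel import GeneticParams

__all__ = ["ScalingParams", "compute_scaling", "transform_fluxes"]


@dataclass
class ScalingParams:
    """Per-reaction scale (delta > 0) and offset (alpha)."""

    delta: np.ndarray
    alpha: np.ndarray
    location_target: float = 10.0

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if (self.delta <= 0).any():
            raise ValueError("all scales delta_j must be positive")
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("offsets alpha_j must be finite")


def compute_scaling(
    rough: GeneticParams, location_target: float = 10.0, mode: str = "sqrt"
) -> ScalingParams:
    """Scales/offsets from rough per-reaction estimates.

    mode="sqrt":    delta_j = sqrt(sigma2_U~ + sigma2_V~)   (default)
    mode="literal": delta_j = sigma2_U~ + sigma2_V~
    """
    total = rough.sigma2_u + rough.sigma2_v
    if mode == "sqrt":
        delta = np.sqrt(total)
    elif mode == "literal":
        delta = total.copy()
    else:
        raise ValueError(f"unknown delta mode {mode!r}")
    if (delta <= 0).any():
        bad = np.nonzero(delta <= 0)[0]
        raise ValueError(
            f"zero scale for reaction(s) {[int(j) + 1 for j in bad]}; floor the variances first"
        )
    alpha = location_target - rough.mu / delta
    return ScalingParams(delta=delta, alpha=alpha, location_target=location_target)


def transform_fluxes(
    fluxes: FluxTable, scaling: ScalingParams, direction: str = "forward"
) -> FluxTable:
    """Map fluxes to the standardized scale (``forward``) or back (``inverse``)."""
    if len(scaling.delta) != fluxes.n_reactions:
        raise ValueError("scaling covers a different number of reactions")
    if direction == "forward":
        vals = fluxes.values / scaling.delta + scaling.alpha
    elif direction == "inverse":
        vals = (fluxes.values - scaling.alpha) * scaling.delta
    else:
        raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    return FluxTable(values=vals, genotype_ids=list(fluxes.genotype_ids))
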