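"""Evaluation of the full objective, for monitoring and for tests.

The total objective is F = E + nu * sum_j L(phi_j) + mu * sum_j R(phi_j):
the MAP data energy E (a double window sum over pixel pairs), the contour
length term L, and the signed-distance regulariser R.  The energy is never
needed by the coordinate-descent updates themselves — it exists so that
monotonicity and the closed-form optimality of each update can be verified
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import KernelMask, local_weighted_convolve
from .levelset import (
    GRAD_GUARD,
    LevelSetState,
    _central_gradients,
    compute_memberships,
    smoothed_delta,
)
from .statistics import PRIOR_FLOOR, LogImage

__all__ = ["EnergyBreakdown", "data_energy", "length_term", "distance_regularizer", "total_energy"]

_LOG_ROOT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Objective decomposition: total = data + nu*sum(length) + mu*sum(regularizer)."""

    data: float
    length: tuple[float, ...]
    regularizer: tuple[float, ...]
    nu: float
    mu: float

    @property
    def total(self) -> float:
        return self.data + self.nu * sum(self.length) + self.mu * sum(self.regularizer)


def data_energy(
    log_image: LogImage,
    memberships: np.ndarray,
    constants: np.ndarray,
    stddevs: np.ndarray,
    bias: np.ndarray,
    priors: np.ndarray,
    kernel: KernelMask,
) -> float:
    """Discrete MAP data energy E.

    The double integral over (x, y) pairs with |x - y| <= r is evaluated by
    expanding the squared residual (J~(x) - b~(y) - c_i)^2 in powers of
    b~(y), turning the inner x-sum into three convolutions per region.
    Smoothed memberships are used; masked pixels carry zero weight on both
    the x and y sides; unit pixel area.
    """
    m = log_image.mask_float
    total = 0.0
    for i in range(memberships.shape[0]):
        mm = memberships[i] * m
        u = (log_image.values - constants[i]) * m
        conv_m = local_weighted_convolve(mm, kernel)
        conv_um = local_weighted_convolve(u * memberships[i], kernel)
        conv_u2m = local_weighted_convolve(u * u * memberships[i], kernel)
        s2 = stddevs[i] ** 2
        log_term = -np.log(np.maximum(priors[i], PRIOR_FLOOR)) + _LOG_ROOT_2PI + np.log(stddevs[i])
        residual = conv_u2m - 2.0 * bias * conv_um + bias * bias * conv_m
        total += float(np.sum(m * (log_term * conv_m + residual / (2.0 * s2))))
    if not np.isfinite(total):
        raise FloatingPointError("data energy is non-finite")
    return total


def length_term(phi: np.ndarray, epsilon: float) -> float:
    """Contour length: sum_x delta_eps(phi) |grad phi| (discrete)."""
    gy, gx = _central_gradients(np.asarray(phi, dtype=float))
    return float(np.sum(smoothed_delta(phi, epsilon) * np.sqrt(gy * gy + gx * gx)))


def distance_regularizer(phi: np.ndarray) -> float:
    """Deviation from a signed distance function: sum_x (|grad phi| - 1)^2 / 2."""
    gy, gx = _central_gradients(np.asarray(phi, dtype=float))
    mag = np.sqrt(gy * gy + gx * gx + GRAD_GUARD**2)
    return float(0.5 * np.sum((mag - 1.0) ** 2))


def total_energy(
    log_image: LogImage,
    state: LevelSetState,
    constants: np.ndarray,
    stddevs: np.ndarray,
    bias: np.ndarray,
    priors: np.ndarray,
    kernel: KernelMask,
    nu: float,
    mu: float,
    memberships: np.ndarray | None = None,
) -> EnergyBreakdown:
    """Full objective F with its per-function length and regulariser terms.

    ``memberships`` defaults to the smoothed partition of ``state``; pass
    indicator memberships to evaluate F in the convention the model fits
    with.
    """
    if memberships is None:
        memberships = compute_memberships(state)
    e = data_energy(log_image, memberships, constants, stddevs, bias, priors, kernel)
    lengths = tuple(length_term(phi, state.epsilon) for phi in state.functions)
    regs = tuple(distance_regularizer(phi) for phi in state.functions)
    return EnergyBreakdown(data=e, length=lengths, regularizer=regs, nu=nu, mu=mu)
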