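"""Closed-form statistical updates for the local Gaussian MAP energy.

The segmentation energy models the log-intensity J~(x) inside region i of a
neighbourhood O_y as Gaussian with mean c_i + b~(y) and variance sigma_i^2,
weighted by a spatial prior p_i(y).  With the level-set memberships held
fixed, each of the region constants c_i, the region standard deviations
sigma_i, the log-bias field b~ and the priors p_i has a closed-form
minimiser — a weighted average over the truncated Gaussian window.  All of
them, and the per-pixel evidence fields e_i that drive the contour, are
computed here as quotients of window convolutions.

Pixels excluded by the validity mask (low raw intensity) carry zero weight
in every window sum: x-indexed fields are multiplied by the mask before
convolving, and y-sums are restricted to the mask.  With zero padding this
makes every ratio renormalise itself near boundaries and holes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kernel import KernelMask, local_weighted_convolve

__all__ = [
    "LogImage",
    "RegionModel",
    "SIGMA_FLOOR",
    "PRIOR_FLOOR",
    "update_region_constants",
    "update_region_stddevs",
    "update_bias_field",
    "update_priors",
    "compute_evidence_fields",
]

#: Floor on region standard deviations (log-intensity units); prevents the
#: 1/sigma^2 terms from blowing up on noise-free regions.
SIGMA_FLOOR = 1e-3

#: Floor applied to spatial priors before taking logarithms.
PRIOR_FLOOR = 1e-6

_LOG_ROOT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class LogImage:
    """Log-transformed observed image with a validity mask.

    Attributes
    ----------
    values : ndarray
        J~ = log(J) wherever ``valid_mask`` is true; finite there,
        undefined (zeroed) elsewhere.
    valid_mask : ndarray of bool
        True where the raw intensity was at or above the log-transform
        floor.
    original : ndarray
        The raw intensity image J.
    """

    values: np.ndarray = field(repr=False)
    valid_mask: np.ndarray = field(repr=False)
    original: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("log-image contains non-finite values on the valid mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask_float(self) -> np.ndarray:
        return self.valid_mask.astype(float)


@dataclass
class RegionModel:
    """Per-region Gaussian parameters in the log domain.

    ``constants[i]`` is the tissue log-intensity c_i; ``stddevs[i]`` the
    region standard deviation sigma_i (floored at SIGMA_FLOOR).
    """

    constants: np.ndarray
    stddevs: np.ndarray

    def __post_init__(self) -> None:
        self.constants = np.atleast_1d(np.asarray(self.constants, dtype=float))
        self.stddevs = np.atleast_1d(np.asarray(self.stddevs, dtype=float))
        if self.constants.shape != self.stddevs.shape:
            raise ValueError("constants and stddevs must have equal length")
        if np.any(self.stddevs < SIGMA_FLOOR):
            raise ValueError(f"stddevs must be >= {SIGMA_FLOOR}")

    @property
    def n_regions(self) -> int:
        return self.constants.size


def _masked_memberships(memberships: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.asarray(memberships, dtype=float) * mask
    return out


def update_region_constants(
    log_image: LogImage,
    bias: np.ndarray,
    memberships: np.ndarray,
    kernel: KernelMask,
    prev_constants: np.ndarray | None = None,
) -> np.ndarray:
    """Optimal region constants c_i given everything else.

    c_i is the omega-weighted average of J~(x) - b~(y) over all (x, y)
    pairs with x carrying membership i::

        c_i = [ sum_y conv(J~ M_i)(y) - b~(y) conv(M_i)(y) ]
              / [ sum_y conv(M_i)(y) ]

    A region whose denominator vanishes (no member pixels anywhere) keeps
    its previous constant and a warning is issued.
    """
    m = log_image.mask_float
    jt = log_image.values * m
    n = memberships.shape[0]
    out = np.empty(n)
    for i in range(n):
        mm = _masked_memberships(memberships[i], m)
        conv_m = local_weighted_convolve(mm, kernel)
        conv_jm = local_weighted_convolve(jt * memberships[i], kernel)
        num = float(np.sum((conv_jm - bias * conv_m) * m))
        den = float(np.sum(conv_m * m))
        if den <= 1e-12:
            if prev_constants is None:
                raise ValueError(f"region {i} has no member pixels and no previous constant")
            warnings.warn(f"region {i} collapsed; keeping previous constant", stacklevel=2)
            out[i] = prev_constants[i]
        else:
            out[i] = num / den
    return out


def update_region_stddevs(
    log_image: LogImage,
    bias: np.ndarray,
    constants: np.ndarray,
    memberships: np.ndarray,
    kernel: KernelMask,
    prev_stddevs: np.ndarray | None = None,
    floor: float = SIGMA_FLOOR,
) -> np.ndarray:
    """Optimal region standard deviations given freshly updated constants.

    sigma_i^2 is the omega-weighted mean of (J~(x) - b~(y) - c_i)^2 over
    membership i; the quadratic in b~(y) is expanded so the double sum
    becomes three convolutions.  Result is floored at ``floor``.
    """
    m = log_image.mask_float
    n = memberships.shape[0]
    out = np.empty(n)
    for i in range(n):
        u = (log_image.values - constants[i]) * m
        mm = _masked_memberships(memberships[i], m)
        conv_m = local_weighted_convolve(mm, kernel)
        conv_um = local_weighted_convolve(u * memberships[i], kernel)
        conv_u2m = local_weighted_convolve(u * u * memberships[i], kernel)
        num = float(np.sum((conv_u2m - 2.0 * bias * conv_um + bias * bias * conv_m) * m))
        den = float(np.sum(conv_m * m))
        if den <= 1e-12:
            if prev_stddevs is None:
                raise ValueError(f"region {i} has no member pixels and no previous stddev")
            warnings.warn(f"region {i} collapsed; keeping previous stddev", stacklevel=2)
            out[i] = prev_stddevs[i]
        else:
            out[i] = np.sqrt(max(num / den, 0.0))
    return np.maximum(out, floor)


def update_bias_field(
    log_image: LogImage,
    constants: np.ndarray,
    stddevs: np.ndarray,
    memberships: np.ndarray,
    kernel: KernelMask,
    prev_bias: np.ndarray | None = None,
) -> np.ndarray:
    """Optimal log-bias field b~(y) given region parameters and memberships.

    Pointwise quotient of two window sums over the neighbours x of y::

        b~(y) = sum_i conv((J~ - c_i)/sigma_i^2 * M_i)(y)
                / sum_i conv(M_i / sigma_i^2)(y)

    Pixels where the denominator vanishes keep the previous bias value.
    """
    m = log_image.mask_float
    shape = log_image.shape
    num = np.zeros(shape)
    den = np.zeros(shape)
    for i in range(memberships.shape[0]):
        mm = _masked_memberships(memberships[i], m)
        w = 1.0 / (stddevs[i] ** 2)
        num += local_weighted_convolve((log_image.values - constants[i]) * mm * w, kernel)
        den += local_weighted_convolve(mm * w, kernel)
    bad = den <= 1e-300
    if np.any(bad):
        warnings.warn(
            f"bias denominator vanished at {int(bad.sum())} pixels; keeping previous values",
            stacklevel=2,
        )
    safe_den = np.where(bad, 1.0, den)
    bias = num / safe_den
    if prev_bias is not None:
        bias = np.where(bad, prev_bias, bias)
    else:
        bias = np.where(bad, 0.0, bias)
    return bias


def update_priors(
    memberships: np.ndarray,
    kernel: KernelMask,
    mask: np.ndarray | None = None,
    floor: float = PRIOR_FLOOR,
) -> np.ndarray:
    """Optimal spatial priors p_i(y): the local membership fractions.

    p_i(y) = conv(M_i)(y) / sum_j conv(M_j)(y), then floored at ``floor``
    and renormalised so the simplex constraint sum_i p_i(y) = 1 holds
    exactly at every pixel.
    """
    n = memberships.shape[0]
    if mask is None:
        mask = np.ones(memberships.shape[1:])
    else:
        mask = np.asarray(mask, dtype=float)
    q = np.stack(
        [local_weighted_convolve(_masked_memberships(memberships[i], mask), kernel) for i in range(n)]
    )
    total = q.sum(axis=0)
    empty = total <= 1e-300
    p = np.where(empty[None], 1.0 / n, q / np.where(empty, 1.0, total)[None])
    p = np.maximum(p, floor)
    return p / p.sum(axis=0, keepdims=True)


def compute_evidence_fields(
    log_image: LogImage,
    bias: np.ndarray,
    constants: np.ndarray,
    stddevs: np.ndarray,
    priors: np.ndarray,
    kernel: KernelMask,
) -> np.ndarray:
    """Per-pixel MAP assignment cost e_i(x) for each region.

    e_i(x) integrates, over the window centred at x, the negative log prior
    and the Gaussian negative log likelihood of J~(x) under region i::

        e_i(x) = conv(-log p_i)(x) + log(sqrt(2 pi) sigma_i) W(x)
                 + [ W(x) u^2 - 2 u conv(b~)(x) + conv(b~^2)(x) ] / (2 sigma_i^2)

    with u = J~(x) - c_i and W = conv(mask) the local window weight (1 in
    the interior, < 1 near boundaries or masked pixels).  Expanding the
    y-integral into convolutions of b~ and b~^2 avoids a per-pixel inner
    loop; equivalence with the literal double integral is a tested oracle
    property.  Evidence is zeroed on invalid pixels so they exert no force.
    """
    m = log_image.mask_float
    w_local = local_weighted_convolve(m, kernel)
    conv_b = local_weighted_convolve(bias * m, kernel)
    conv_b2 = local_weighted_convolve(bias * bias * m, kernel)
    n = priors.shape[0]
    e = np.empty((n,) + log_image.shape)
    for i in range(n):
        log_prior = local_weighted_convolve(-np.log(np.maximum(priors[i], PRIOR_FLOOR)) * m, kernel)
        u = (log_image.values - constants[i]) * m
        s2 = stddevs[i] ** 2
        e[i] = (
            log_prior
            + (_LOG_ROOT_2PI + np.log(stddevs[i])) * w_local
            + (w_local * u * u - 2.0 * u * conv_b + conv_b2) / (2.0 * s2)
        )
        e[i] *= m
    if not np.all(np.isfinite(e)):
        idx = np.argwhere(~np.isfinite(e))[0]
        raise FloatingPointError(
            f"non-finite evidence for region {idx[0]} at pixel ({idx[1]}, {idx[2]})"
        )
    return e
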