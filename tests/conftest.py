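"""Shared fixtures: small random instances and brute-force oracles.

The oracles evaluate the defining double sums literally — quadruple loops
over (x, y) pixel pairs — independent of the convolution-based production
code they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mapseg.kernel import KernelMask, build_truncated_gaussian_kernel
from mapseg.statistics import PRIOR_FLOOR, LogImage

_LOG_ROOT_2PI = 0.5 * np.log(2.0 * np.pi)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_kernel():
    return build_truncated_gaussian_kernel(sigma=1.5, radius=3)


@pytest.fixture
def random_instance(rng, small_kernel):
    """16x16 random problem: log-image, bias, 2-region memberships, priors."""
    shape = (16, 16)
    values = rng.normal(4.0, 0.5, shape)
    log_image = LogImage(values=values, valid_mask=np.ones(shape, bool), original=np.exp(values))
    bias = rng.normal(0.0, 0.2, shape)
    m1 = rng.uniform(0.0, 1.0, shape)
    memberships = np.stack([m1, 1.0 - m1])
    p1 = rng.uniform(0.05, 0.95, shape)
    priors = np.stack([p1, 1.0 - p1])
    constants = np.array([3.6, 4.4])
    stddevs = np.array([0.3, 0.5])
    return log_image, bias, memberships, priors, constants, stddevs


# ---------------------------------------------------------------- oracles
def oracle_convolve(field: np.ndarray, kernel: KernelMask) -> np.ndarray:
    """out(y) = sum_x w(x - y) field(x), zero outside the image."""
    r = kernel.radius
    h, w = field.shape
    out = np.zeros_like(field, dtype=float)
    for y0 in range(h):
        for y1 in range(w):
            acc = 0.0
            for x0 in range(max(0, y0 - r), min(h, y0 + r + 1)):
                for x1 in range(max(0, y1 - r), min(w, y1 + r + 1)):
                    acc += kernel.weights[x0 - y0 + r, x1 - y1 + r] * field[x0, x1]
            out[y0, y1] = acc
    return out


def oracle_constant(log_image, bias, membership, kernel) -> float:
    """Literal double sum defining the optimal region constant."""
    r = kernel.radius
    h, w = log_image.shape
    jt = log_image.values
    num = den = 0.0
    for y0 in range(h):
        for y1 in range(w):
            for x0 in range(max(0, y0 - r), min(h, y0 + r + 1)):
                for x1 in range(max(0, y1 - r), min(w, y1 + r + 1)):
                    wgt = kernel.weights[x0 - y0 + r, x1 - y1 + r] * membership[x0, x1]
                    num += wgt * (jt[x0, x1] - bias[y0, y1])
                    den += wgt
    return num / den


def oracle_stddev(log_image, bias, c, membership, kernel) -> float:
    """Literal double sum defining the optimal region standard deviation."""
    r = kernel.radius
    h, w = log_image.shape
    jt = log_image.values
    num = den = 0.0
    for y0 in range(h):
        for y1 in range(w):
            for x0 in range(max(0, y0 - r), min(h, y0 + r + 1)):
                for x1 in range(max(0, y1 - r), min(w, y1 + r + 1)):
                    wgt = kernel.weights[x0 - y0 + r, x1 - y1 + r] * membership[x0, x1]
                    num += wgt * (jt[x0, x1] - bias[y0, y1] - c) ** 2
                    den += wgt
    return np.sqrt(num / den)


def oracle_bias(log_image, constants, stddevs, memberships, kernel) -> np.ndarray:
    """Literal window sums defining the optimal log-bias field."""
    r = kernel.radius
    h, w = log_image.shape
    jt = log_image.values
    out = np.zeros((h, w))
    for y0 in range(h):
        for y1 in range(w):
            num = den = 0.0
            for x0 in range(max(0, y0 - r), min(h, y0 + r + 1)):
                for x1 in range(max(0, y1 - r), min(w, y1 + r + 1)):
                    wgt = kernel.weights[x0 - y0 + r, x1 - y1 + r]
                    for i in range(len(constants)):
                        mi = memberships[i, x0, x1] / stddevs[i] ** 2
                        num += wgt * (jt[x0, x1] - constants[i]) * mi
                        den += wgt * mi
            out[y0, y1] = num / den
    return out


def oracle_priors(memberships, kernel) -> np.ndarray:
    """Literal window sums defining the optimal spatial priors."""
    n = memberships.shape[0]
    q = np.stack([oracle_convolve(memberships[i], kernel) for i in range(n)])
    return q / q.sum(axis=0, keepdims=True)


def oracle_evidence(log_image, bias, constants, stddevs, priors, kernel) -> np.ndarray:
    """Literal y-integral defining the per-pixel evidence e_i(x)."""
    r = kernel.radius
    h, w = log_image.shape
    jt = log_image.values
    n = len(constants)
    out = np.zeros((n, h, w))
    for i in range(n):
        s2 = stddevs[i] ** 2
        for x0 in range(h):
            for x1 in range(w):
                acc = 0.0
                for y0 in range(max(0, x0 - r), min(h, x0 + r + 1)):
                    for y1 in range(max(0, x1 - r), min(w, x1 + r + 1)):
                        wgt = kernel.weights[y0 - x0 + r, y1 - x1 + r]
                        acc += wgt * (
                            -np.log(max(priors[i, y0, y1], PRIOR_FLOOR))
                            + _LOG_ROOT_2PI
                            + np.log(stddevs[i])
                            + (jt[x0, x1] - bias[y0, y1] - constants[i]) ** 2 / (2.0 * s2)
                        )
                out[i, x0, x1] = acc
    return out


def oracle_data_energy(
    log_image, memberships, constants, stddevs, bias, priors, kernel
) -> float:
    """Literal quadruple-loop evaluation of the MAP data energy."""
    r = kernel.radius
    h, w = log_image.shape
    jt = log_image.values
    total = 0.0
    for i in range(len(constants)):
        s2 = stddevs[i] ** 2
        for y0 in range(h):
            for y1 in range(w):
                log_term = (
                    -np.log(max(priors[i, y0, y1], PRIOR_FLOOR))
                    + _LOG_ROOT_2PI
                    + np.log(stddevs[i])
                )
                for x0 in range(max(0, y0 - r), min(h, y0 + r + 1)):
                    for x1 in range(max(0, y1 - r), min(w, y1 + r + 1)):
                        wgt = kernel.weights[x0 - y0 + r, x1 - y1 + r] * memberships[i, x0, x1]
                        total += wgt * (
                            log_term
                            + (jt[x0, x1] - bias[y0, y1] - constants[i]) ** 2 / (2.0 * s2)
                        )
    return total
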