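"""Synthetic phantoms with known ground truth.

A phantom is a piecewise-constant "tissue" image I built from labelled
shapes, multiplied by a smooth positive bias field b (mean 1), and corrupted
with Gaussian noise under one of three image-formation models:

* ``multiplicative``  — J = I * b + n          (scanner noise, bias-independent)
* ``biological``      — J = (I + n) * b        (biological noise, SNR preserved)
* ``log-additive``    — log J = log I + log b + n   (additive in the log domain)

The log-additive model exactly satisfies the additive log-domain assumption
the segmentation core is built on, making parameter recovery a well-posed
test; the other two let tests probe model mismatch.  ``noise_sd`` is in the
units of the domain where the noise enters: raw intensity for the first
two models, log intensity for the third.

All randomness flows from the single integer seed in the spec; regenerating
with an identical spec reproduces the arrays bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "QuadraticBias",
    "BlurredRandomBias",
    "ConstantBias",
    "PhantomSpec",
    "PhantomBundle",
    "make_smooth_bias",
    "generate_phantom",
    "default_two_phase_spec",
    "default_multiphase_spec",
]

FORMATION_MODELS = ("multiplicative", "biological", "log-additive")


@dataclass(frozen=True)
class QuadraticBias:
    """Radial quadratic ramp, brightest at ``center``.

    ``rel_range`` is the fractional drop from peak to trough:
    min = (1 - rel_range) * max, so rel_range = 0.4 gives the "±40%"
    inhomogeneity severity used throughout.
    """

    rel_range: float = 0.4
    center: tuple[float, float] | None = None


@dataclass(frozen=True)
class BlurredRandomBias:
    """Gaussian-blurred white noise rescaled to the requested relative range."""

    rel_range: float = 0.4
    blur_sigma: float = 32.0


@dataclass(frozen=True)
class ConstantBias:
    """No inhomogeneity: the all-ones field."""


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a phantom.

    ``shapes`` are drawn in order over a background that fills the rest;
    shape k gets region label k+2 (background is label 1).  A shape is
    ``("disc", row, col, radius)``, ``("rect", r0, c0, r1, c1)`` or
    ``("annulus", row, col, r_inner, r_outer)``.  ``constants`` lists the
    true intensity of every region, background first, and must have
    ``len(shapes) + 1`` entries.  ``noise_sd`` is a scalar or one value per
    region.
    """

    shape: tuple[int, int] = (128, 128)
    shapes: tuple = ()
    constants: tuple = (100.0,)
    bias: object = field(default_factory=ConstantBias)
    noise_sd: float | tuple = 0.0
    formation_model: str = "log-additive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.formation_model not in FORMATION_MODELS:
            raise ValueError(
                f"formation_model must be one of {FORMATION_MODELS}, got {self.formation_model!r}"
            )
        if len(self.constants) != len(self.shapes) + 1:
            raise ValueError(
                f"need {len(self.shapes) + 1} constants (background + one per shape), "
                f"got {len(self.constants)}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.constants)


@dataclass(frozen=True)
class PhantomBundle:
    """Generated phantom with its ground truth."""

    observed: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    bias: np.ndarray = field(repr=False)
    constants: np.ndarray = field(repr=False)
    spec: PhantomSpec = field(repr=True)


def _shape_mask(shape: tuple[int, int], spec) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    kind = spec[0]
    if kind == "disc":
        _, r, c, rad = spec
        return (rows - r) ** 2 + (cols - c) ** 2 <= rad**2
    if kind == "rect":
        _, r0, c0, r1, c1 = spec
        out = np.zeros(shape, dtype=bool)
        out[r0:r1, c0:c1] = True
        return out
    if kind == "annulus":
        _, r, c, ri, ro = spec
        d2 = (rows - r) ** 2 + (cols - c) ** 2
        return (d2 >= ri**2) & (d2 <= ro**2)
    raise ValueError(f"unknown shape kind {kind!r}")


def make_smooth_bias(shape: tuple[int, int], model_spec, seed: int = 0) -> np.ndarray:
    """Smooth, strictly positive field normalised to mean exactly 1.

    Mean-normalisation fixes the gauge: in the log domain the generated
    bias has (approximately) zero mean, matching how estimated biases are
    normalised for evaluation.
    """
    if isinstance(model_spec, ConstantBias):
        return np.ones(shape)
    if isinstance(model_spec, QuadraticBias):
        r0, c0 = model_spec.center or ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
        rows, cols = np.ogrid[: shape[0], : shape[1]]
        q = (rows - r0) ** 2 + (cols - c0) ** 2
        q = q / q.max()
        raw = 1.0 - model_spec.rel_range * q
    elif isinstance(model_spec, BlurredRandomBias):
        rng = np.random.default_rng(seed)
        raw = ndimage.gaussian_filter(rng.standard_normal(shape), model_spec.blur_sigma)
        lo, hi = raw.min(), raw.max()
        raw = 1.0 - model_spec.rel_range * (hi - raw) / (hi - lo)
    else:
        raise ValueError(f"unknown bias model {model_spec!r}")
    if raw.min() <= 0:
        raise ValueError("bias field must be strictly positive; reduce rel_range")
    return raw / raw.mean()


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Compose I, b and noise per the spec's formation model.

    The observed image is clamped to be strictly positive (the log
    transform downstream requires it); the true label map, bias field and
    constants ride along for recovery tests.
    """
    labels = np.ones(spec.shape, dtype=np.int32)
    for k, shp in enumerate(spec.shapes):
        labels[_shape_mask(spec.shape, shp)] = k + 2

    constants = np.asarray(spec.constants, dtype=float)
    image = constants[labels - 1]

    bias = make_smooth_bias(spec.shape, spec.bias, seed=spec.seed)

    sd = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float), (spec.n_regions,))
    sd_map = sd[labels - 1]
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.shape) * sd_map

    if spec.formation_model == "multiplicative":
        observed = image * bias + noise
    elif spec.formation_model == "biological":
        observed = (image + noise) * bias
    else:  # log-additive: noise lives in the log domain
        observed = np.exp(np.log(image) + np.log(bias) + noise)
    observed = np.maximum(observed, 1e-6)

    return PhantomBundle(
        observed=observed, labels=labels, bias=bias, constants=constants, spec=spec
    )


#: Log-domain noise sd equivalent to sd 10 at 8-bit mid-scale (d log J = dJ/J).
NOISE_SD_LOG_DEFAULT = 10.0 / 127.5


def default_two_phase_spec(
    seed: int = 7, noise_sd: float = NOISE_SD_LOG_DEFAULT
) -> PhantomSpec:
    """One bright disc on a darker background.

    128x128, constants (60, 180), ±40% quadratic bias, log-additive noise
    equivalent to sd 10 on the 8-bit scale.  The disc radius (14 px) is at
    the kernel window scale so that the bias field stays identifiable:
    every window centred inside the disc also sees background.
    """
    return PhantomSpec(
        shape=(128, 128),
        shapes=(("disc", 63.5, 63.5, 14.0),),
        constants=(60.0, 180.0),
        bias=QuadraticBias(rel_range=0.4),
        noise_sd=noise_sd,
        formation_model="log-additive",
        seed=seed,
    )


def default_multiphase_spec(
    seed: int = 7, noise_sd: float = NOISE_SD_LOG_DEFAULT
) -> PhantomSpec:
    """Three discs + background: constants (40, 100, 160, 220), ±40%
    quadratic bias, log-additive noise equivalent to sd 10 at 8-bit scale."""
    return PhantomSpec(
        shape=(128, 128),
        shapes=(
            ("disc", 38.0, 38.0, 13.0),
            ("disc", 38.0, 90.0, 13.0),
            ("disc", 90.0, 64.0, 14.0),
        ),
        constants=(40.0, 100.0, 160.0, 220.0),
        bias=QuadraticBias(rel_range=0.4),
        noise_sd=noise_sd,
        formation_model="log-additive",
        seed=seed,
    )


def _shrunk_seed(shape_spec, margin: float):
    kind = shape_spec[0]
    if kind == "disc":
        _, r, c, rad = shape_spec
        return ("circle", r, c, max(rad - margin, 2.0))
    if kind == "rect":
        _, r0, c0, r1, c1 = shape_spec
        m = int(margin)
        if r1 - r0 > 2 * m + 2 and c1 - c0 > 2 * m + 2:
            return ("rect", r0 + m, c0 + m, r1 - m, c1 - m)
        return ("rect", r0, c0, r1, c1)
    raise ValueError(f"cannot derive a seed from shape {shape_spec!r}")


def suggest_seeds(spec: PhantomSpec, margin: float = 4.0):
    """Binary-step seed regions placed inside each of the spec's objects.

    Mirrors the manual near-object initialisation the method expects: each
    seed is the object shrunk by ``margin`` pixels.  For N = 3 or 4 the two
    level-set functions get unions of seeds chosen so every region has a
    distinct sign combination: with shapes (A, B[, C]),
    phi_1 < 0 on B [∪ C] and phi_2 < 0 on A [∪ C], giving
    background = (+,+), A = (+,-), B = (-,+), C = (-,-).
    """
    n = spec.n_regions
    inner = [_shrunk_seed(s, margin) for s in spec.shapes]
    if n == 2:
        return [inner[0]]
    if n == 3:
        return [[inner[1]], [inner[0]]]
    if n == 4:
        return [[inner[1], inner[2]], [inner[0], inner[2]]]
    raise ValueError("seed suggestion supports 2-4 regions")
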