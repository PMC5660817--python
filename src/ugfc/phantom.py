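"""Seeded synthetic head phantoms with known lesion ground truth.

Emulates the data regime the pipeline targets — contrast-enhanced
T1/FLAIR-like slices with a hyperintense lesion — as flat-intensity
tissue ellipses plus lesion blobs, a smooth multiplicative bias field
(MR coil inhomogeneity) and additive Gaussian or Rician noise.  Identical
spec + seed gives bit-identical output, so every stage of the pipeline is
testable without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SpecError


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-by-default ellipse; angle in radians, counterclockwise."""

    cx: float
    cy: float
    rx: float
    ry: float
    angle: float = 0.0

    def contains(self, x, y):
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        u = (x - self.cx) * ca + (y - self.cy) * sa
        v = -(x - self.cx) * sa + (y - self.cy) * ca
        return (u / self.rx) ** 2 + (v / self.ry) ** 2 <= 1.0


@dataclass(frozen=True)
class LesionBlob:
    cx: float
    cy: float
    r: float
    mean: float = 210.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic head slice.

    ``tissues`` are painted in order onto the background, so later entries
    overwrite earlier ones; ``lesions`` are painted last.  ``bias_amplitude``
    is the peak relative deviation of the multiplicative bias field
    (0.15 = +/-15%); ``noise_model`` is ``gaussian`` or ``rician`` with
    scale ``noise_sigma`` in gray levels.
    """

    size: tuple[int, int] = (128, 128)
    background: float = 10.0
    tissues: tuple = ()
    lesions: tuple = ()
    bias_order: int = 2
    bias_amplitude: float = 0.15
    noise_model: str = "gaussian"
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for t, m in self.tissues:
            if not 0 <= m <= 255:
                raise SpecError("tissue mean outside [0, 255]")
        for b in self.lesions:
            if not 0 <= b.mean <= 255:
                raise SpecError("lesion mean outside [0, 255]")
        if self.noise_model not in ("gaussian", "rician"):
            raise SpecError(f"unknown noise model {self.noise_model!r}")
        if self.tissues and self.lesions:
            brain = self.tissues[0][0]
            for b in self.lesions:
                # conservative containment: blob circle inside the shrunken
                # brain ellipse
                if brain.rx - b.r <= 0 or brain.ry - b.r <= 0 or not Ellipse(
                        brain.cx, brain.cy, brain.rx - b.r, brain.ry - b.r,
                        brain.angle).contains(b.cx, b.cy):
                    raise SpecError(
                        f"lesion at ({b.cx:.0f}, {b.cy:.0f}) r={b.r:.0f} "
                        "extends outside the brain ellipse")


# the default head recipe: background 10, "GM" outer ellipse 90, "WM"
# inner ellipse 140, a dark ventricle blob 40, hyperintense lesion 210
_BRAIN = Ellipse(cx=64, cy=64, rx=48, ry=56)
_WM = Ellipse(cx=64, cy=66, rx=35, ry=42)
_VENTRICLE = Ellipse(cx=64, cy=58, rx=6, ry=13)
DEFAULT_TISSUES = ((_BRAIN, 90.0), (_WM, 140.0), (_VENTRICLE, 40.0))


def default_head_spec(seed: int = 0, n_lesions: int = 1,
                      noise_sigma: float = 8.0,
                      bias_amplitude: float = 0.15,
                      lesion_radius: float = 9.0) -> PhantomSpec:
    """Default head phantom with lesion(s) placed randomly inside the WM.

    The lesion center is drawn uniformly inside the white-matter ellipse
    shrunk by the blob radius plus a 3-pixel margin, avoiding the
    ventricle, so the blob always sits on homogeneous bright tissue.
    """
    rng = np.random.default_rng(seed)
    lesions = []
    placed = []
    margin = lesion_radius + 3.0
    inner = Ellipse(_WM.cx, _WM.cy, _WM.rx - margin, _WM.ry - margin)
    attempts = 0
    while len(lesions) < n_lesions:
        attempts += 1
        if attempts > 5000:
            raise SpecError(
                f"cannot place {n_lesions} non-overlapping lesions")
        x = rng.uniform(_WM.cx - _WM.rx, _WM.cx + _WM.rx)
        y = rng.uniform(_WM.cy - _WM.ry, _WM.cy + _WM.ry)
        if not inner.contains(x, y):
            continue
        if Ellipse(_VENTRICLE.cx, _VENTRICLE.cy,
                   _VENTRICLE.rx + margin, _VENTRICLE.ry + margin).contains(x, y):
            continue
        if any((x - px) ** 2 + (y - py) ** 2 < (2 * lesion_radius + 4) ** 2
               for px, py in placed):
            continue
        placed.append((x, y))
        lesions.append(LesionBlob(cx=x, cy=y, r=lesion_radius))
    return PhantomSpec(tissues=DEFAULT_TISSUES, lesions=tuple(lesions),
                       noise_sigma=noise_sigma,
                       bias_amplitude=bias_amplitude, seed=seed)


def multiple_lesion_spec(k: int, seed: int = 0,
                         lesion_radius: float = 8.0) -> PhantomSpec:
    """Spec with ``k`` disjoint lesion blobs at randomized in-brain spots."""
    if k < 1:
        raise SpecError("need at least one lesion")
    return default_head_spec(seed=seed, n_lesions=k,
                             lesion_radius=lesion_radius)


def three_class_spec(seed: int = 0, noise_sigma: float = 10.0) -> PhantomSpec:
    """Three flat-intensity regions (means 50 / 120 / 200), no bias field.

    Used for centroid-recovery experiments: a background at 50, an outer
    ellipse at 120 and an inner ellipse at 200.
    """
    return PhantomSpec(
        background=50.0,
        tissues=((Ellipse(64, 64, 46, 52), 120.0),
                 (Ellipse(64, 64, 24, 30), 200.0)),
        lesions=(),
        bias_amplitude=0.0,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _bias_field(shape: tuple[int, int], order: int, amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape)
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    xn = 2.0 * x / (w - 1) - 1.0
    yn = 2.0 * y / (h - 1) - 1.0
    poly = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            if i == j == 0:
                continue
            poly += rng.normal() * xn**i * yn**j
    peak = np.abs(poly).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * poly / peak


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a spec into (image, lesion truth mask, tissue label map).

    The image is float on [0, 255]: piecewise-constant tissue means times
    the bias field plus noise, clamped.  The label map codes background 0,
    tissues 1..n in paint order, lesions n+1..  The truth mask is the
    union of the lesion blobs.
    """
    h, w = spec.size
    y, x = np.mgrid[0:h, 0:w]
    label = np.zeros((h, w), dtype=np.int64)
    means = np.full((h, w), float(spec.background))
    for idx, (shape_, mean) in enumerate(spec.tissues, start=1):
        inside = shape_.contains(x, y)
        label[inside] = idx
        means[inside] = mean
    truth = np.zeros((h, w), dtype=bool)
    for idx, blob in enumerate(spec.lesions, start=len(spec.tissues) + 1):
        inside = (x - blob.cx) ** 2 + (y - blob.cy) ** 2 <= blob.r**2
        label[inside] = idx
        means[inside] = blob.mean
        truth |= inside

    rng = np.random.default_rng(spec.seed)
    img = means * _bias_field((h, w), spec.bias_order, spec.bias_amplitude, rng)
    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))
        else:  # rician: magnitude of the complex-valued noisy signal
            re = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))
            im = rng.normal(0.0, spec.noise_sigma, size=(h, w))
            img = np.hypot(re, im)
    return np.clip(img, 0.0, 255.0), truth, label


def sample_mixture_1d(means, sigmas, weights, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` intensities from a Gaussian mixture, clamped to [0, 255]."""
    means = np.asarray(means, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if means.shape != sigmas.shape or means.shape != weights.shape:
        raise SpecError("means, sigmas and weights must have equal length")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise SpecError("mixture weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(means.size, size=n, p=weights)
    draws = rng.normal(means[comp], sigmas[comp])
    return np.clip(draws, 0.0, 255.0)
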