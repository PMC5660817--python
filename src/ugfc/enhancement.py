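"""Fuzzy rule-based contrast enhancement.

Implements a three-rule Mamdani inference system acting pointwise on gray
levels:

    Rule 1: IF a pixel is dark,   THEN make it darker;
    Rule 2: IF a pixel is gray,   THEN keep it gray;
    Rule 3: IF a pixel is bright, THEN make it brighter.

Each rule fires with strength min(mu_antecedent(z), .), the three clipped
output sets are aggregated by max, and the crisp output is the centroid
(center of gravity) of the aggregated response evaluated on a discrete
output grid.  Because the mapping depends only on the input level z, the
whole transform collapses to an L-entry lookup table applied pointwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateOutputError, InputDomainError, ParameterError

logger = logging.getLogger(__name__)

INPUT_KINDS = ("dark", "gray", "bright")
OUTPUT_KINDS = ("darker", "gray_out", "brighter")

# Canonical breakpoints on the 8-bit scale; rescaled for other bit depths.
# Input sets overlap mid-scale; output sets are unit triangles at the
# extremes and mid-gray so that dark inputs are pulled toward the darker
# set's centroid and bright inputs toward the brighter set's centroid.
_DEFAULT_KNOTS = {
    "dark": ((0.0, 1.0), (64.0, 1.0), (128.0, 0.0), (255.0, 0.0)),
    "gray": ((0.0, 0.0), (64.0, 0.0), (127.5, 1.0), (191.0, 0.0), (255.0, 0.0)),
    "bright": ((0.0, 0.0), (127.0, 0.0), (191.0, 1.0), (255.0, 1.0)),
    "darker": ((0.0, 1.0), (64.0, 0.0), (255.0, 0.0)),
    "gray_out": ((0.0, 0.0), (63.5, 0.0), (127.5, 1.0), (191.5, 0.0), (255.0, 0.0)),
    "brighter": ((0.0, 0.0), (191.0, 0.0), (255.0, 1.0)),
}


@dataclass(frozen=True)
class FuzzySet:
    """Piecewise-linear membership curve on the intensity axis.

    Parameters
    ----------
    kind
        One of ``dark, gray, bright, darker, gray_out, brighter``.
    knots
        Ordered ``(intensity, membership)`` pairs with strictly increasing
        intensities; membership is linearly interpolated between knots and
        takes the boundary value outside them.
    """

    kind: str
    knots: tuple[tuple[float, float], ...]

    def __post_init__(self):
        xs = np.asarray([k[0] for k in self.knots], dtype=float)
        mus = np.asarray([k[1] for k in self.knots], dtype=float)
        if xs.size < 2 or np.any(np.diff(xs) <= 0):
            raise ParameterError(
                f"fuzzy set {self.kind!r}: breakpoints must be strictly increasing"
            )
        if np.any((mus < 0) | (mus > 1)):
            raise ParameterError(
                f"fuzzy set {self.kind!r}: memberships must lie in [0, 1]"
            )
        object.__setattr__(self, "_xs", xs)
        object.__setattr__(self, "_mus", mus)

    def __call__(self, z):
        return np.interp(z, self._xs, self._mus)


@dataclass(frozen=True)
class FuzzyRuleBase:
    """The three (antecedent, consequent) pairs plus the output grid.

    ``input_sets`` and ``output_sets`` are ordered (dark, gray, bright) and
    (darker, gray_out, brighter); rule *r* pairs ``input_sets[r]`` with
    ``output_sets[r]``.  ``y_grid`` holds the ``p`` discrete output levels
    used for aggregation and centroid defuzzification.
    """

    input_sets: tuple[FuzzySet, FuzzySet, FuzzySet]
    output_sets: tuple[FuzzySet, FuzzySet, FuzzySet]
    y_grid: np.ndarray
    L: int = 256

    def __post_init__(self):
        if len(self.input_sets) != 3 or len(self.output_sets) != 3:
            raise ParameterError("a rule base holds exactly three rules")
        y = np.asarray(self.y_grid, dtype=float)
        if y.size < 2:
            raise ParameterError("output grid needs p >= 2 points")
        object.__setattr__(self, "y_grid", y)


def default_rule_base(L: int = 256, p: int | None = None) -> FuzzyRuleBase:
    """Rule base with the default set geometry, rescaled to ``L`` levels.

    ``p`` defaults to ``L`` so the output grid matches the image's native
    quantization (capped at 4096 points for very deep images, where a finer
    grid changes the centroid by far less than one output level).
    """
    scale = (L - 1) / 255.0
    sets = {
        kind: FuzzySet(kind, tuple((x * scale, mu) for x, mu in knots))
        for kind, knots in _DEFAULT_KNOTS.items()
    }
    if p is None:
        p = min(L, 4096)
    y_grid = np.linspace(0.0, L - 1.0, p)
    return FuzzyRuleBase(
        input_sets=(sets["dark"], sets["gray"], sets["bright"]),
        output_sets=(sets["darker"], sets["gray_out"], sets["brighter"]),
        y_grid=y_grid,
        L=L,
    )


def rule_base_from_knots(knots: dict, L: int = 256, p: int | None = None) -> FuzzyRuleBase:
    """Build a rule base from a ``{kind: [[x, mu], ...]}`` mapping.

    Kinds missing from the mapping fall back to the defaults for ``L``.
    """
    unknown = set(knots) - set(INPUT_KINDS + OUTPUT_KINDS)
    if unknown:
        raise ParameterError(f"unknown fuzzy set kinds: {sorted(unknown)}")
    scale = (L - 1) / 255.0
    sets = {}
    for kind in INPUT_KINDS + OUTPUT_KINDS:
        if kind in knots:
            sets[kind] = FuzzySet(kind, tuple((float(x), float(mu)) for x, mu in knots[kind]))
        else:
            sets[kind] = FuzzySet(
                kind, tuple((x * scale, mu) for x, mu in _DEFAULT_KNOTS[kind])
            )
    if p is None:
        p = min(L, 4096)
    return FuzzyRuleBase(
        input_sets=tuple(sets[k] for k in INPUT_KINDS),
        output_sets=tuple(sets[k] for k in OUTPUT_KINDS),
        y_grid=np.linspace(0.0, L - 1.0, p),
        L=L,
    )


def membership_eval(z, fset: FuzzySet, L: int = 256):
    """Degree of membership of intensity ``z`` in ``fset``; 0 outside support."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > L - 1):
        raise InputDomainError(f"intensity outside [0, {L - 1}]")
    return fset(z)


def aggregate_response(z0: float, rules: FuzzyRuleBase) -> np.ndarray:
    """Max-min composition of the three rules for the scalar input ``z0``.

    Returns Q(y) on ``rules.y_grid``: each output set is clipped at its
    rule's firing strength (min-implication) and the clipped sets are
    united by the pointwise max (OR-aggregation).
    """
    if not 0 <= z0 <= rules.L - 1:
        raise InputDomainError(f"intensity {z0} outside [0, {rules.L - 1}]")
    q = np.zeros_like(rules.y_grid)
    for in_set, out_set in zip(rules.input_sets, rules.output_sets):
        strength = float(in_set(z0))
        np.maximum(q, np.minimum(strength, out_set(rules.y_grid)), out=q)
    return q


def defuzzify_centroid(q: np.ndarray, y_grid: np.ndarray) -> float:
    """Center of gravity of the aggregated response on the output grid."""
    q = np.asarray(q, dtype=float)
    total = q.sum()
    if total <= 0:
        raise DegenerateOutputError("aggregated fuzzy response is identically zero")
    return float(np.dot(y_grid, q) / total)


def build_lut(rules: FuzzyRuleBase, float_output: bool = False) -> np.ndarray:
    """Crisp transfer function for every input level 0..L-1.

    Vectorized max-min-centroid evaluation over all levels at once (chunked
    so 16-bit depths stay within memory).  With ``float_output`` the raw
    centroids are returned; otherwise values are rounded half-up to the
    nearest integer level.
    """
    L = rules.L
    z = np.arange(L, dtype=float)
    y = rules.y_grid
    out_curves = np.stack([s(y) for s in rules.output_sets])  # (3, p)
    lut = np.empty(L, dtype=float)
    chunk = max(1, int(2**22 // max(y.size, 1)))
    for lo in range(0, L, chunk):
        zc = z[lo : lo + chunk]
        strengths = np.stack([s(zc) for s in rules.input_sets])  # (3, m)
        # (3, m, 1) clip against (3, 1, p), then OR over rules
        q = np.minimum(strengths[:, :, None], out_curves[:, None, :]).max(axis=0)
        totals = q.sum(axis=1)
        degenerate = totals <= 0
        if np.any(degenerate):
            logger.warning(
                "aggregated response vanished for %d levels; identity mapping used",
                int(degenerate.sum()),
            )
        safe = np.where(degenerate, 1.0, totals)
        lut[lo : lo + chunk] = np.where(degenerate, zc, q @ y / safe)
    np.clip(lut, 0.0, L - 1.0, out=lut)
    if float_output:
        return lut
    return np.floor(lut + 0.5).astype(np.int64)


def enhance_image(img: np.ndarray, rules: FuzzyRuleBase | None = None,
                  float_output: bool = False) -> np.ndarray:
    """Apply the fuzzy contrast transform pointwise to a gray image.

    ``img`` holds levels on [0, L-1]; non-integer inputs are mapped through
    the nearest LUT entry.  Output dtype is float when ``float_output``
    (for the clustering stage), else the integer level type.
    """
    img = np.asarray(img)
    if rules is None:
        rules = default_rule_base()
    if img.ndim != 2 or img.size == 0:
        raise InputDomainError("expected a non-empty 2-D gray image")
    if not np.all(np.isfinite(img)):
        raise InputDomainError("image contains non-finite values")
    if img.min() < 0 or img.max() > rules.L - 1:
        raise InputDomainError(f"image values outside [0, {rules.L - 1}]")
    lut = build_lut(rules, float_output=float_output)
    idx = np.floor(np.asarray(img, dtype=float) + 0.5).astype(np.int64)
    return lut[idx]
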