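"""Unified gravitational fuzzy clustering (UGFC).

Combines hard and fuzzy clustering of gray levels: pixels whose cluster
membership is unambiguous are hard-assigned ("core" pixels), pixels in
controversial intensity ranges keep graded fuzzy-c-means memberships, and
a Newtonian gravity rule lets massive, spatially coherent clusters capture
nearby ambiguous pixels.  Centroids are seeded by mode-counting on a kernel
density estimate of the image histogram at the critical bandwidth.

The objective monitored across iterations is the product

    J_GFC = J_GC * J_CM,

where J_GC sums squared intensity distances of hard-assigned pixels to
their centroid and J_CM is the standard fuzzy-c-means objective over the
remaining fuzzy pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InitializationError, InputDomainError, ParameterError

logger = logging.getLogger(__name__)

#: gravity coefficient standing in for Newton's constant
GRAVITY_COEFF = 2.0
#: squared-distance floor (one pixel spacing) preventing singular attraction
D2_FLOOR = 1.0

FUZZY_LABEL = -1


@dataclass
class KDEProfile:
    """Gaussian kernel density estimate of an image histogram.

    ``density`` is p(x) = (1 / (N h)) * sum_j psi((x - x_j) / h) with psi
    the standard normal kernel, evaluated on the integer level grid.
    ``modes`` holds the strict local maxima of the density.
    """

    grid: np.ndarray
    density: np.ndarray
    h: float
    modes: np.ndarray


@dataclass
class ClusterState:
    """Full state of a UGFC run.

    ``hard_labels`` is -1 for fuzzy pixels, else the cluster index; ``masses``
    count hard-assigned pixels per cluster; ``core_centroids_xy`` are the
    (row, col) spatial centroids of each cluster's hard core (NaN when the
    core is empty).  Traces are one entry per completed iteration.
    """

    c: int
    centroids: np.ndarray
    memberships: np.ndarray  # (c, N), fuzzy pixels only carry meaning
    hard_labels: np.ndarray  # (N,), FUZZY_LABEL for fuzzy pixels
    masses: np.ndarray
    core_centroids_xy: np.ndarray
    t: int
    objective_trace: list = field(default_factory=list)  # (J_GC, J_CM, J_GFC)
    centroid_trace: list = field(default_factory=list)
    hard_count_trace: list = field(default_factory=list)
    membership_sum_err_trace: list = field(default_factory=list)
    w: float = 1.7
    rho: float = 0.01
    theta_hard: float = 0.85
    gamma: float = 2.0
    l: float = GRAVITY_COEFF
    converged: bool = False
    shape: tuple = ()


@dataclass
class ROIMask:
    """Binary region-of-interest mask with provenance."""

    mask: np.ndarray
    selected_cluster: int
    empty: bool = False


def _histogram(img: np.ndarray, L: int) -> np.ndarray:
    levels = np.floor(np.asarray(img, dtype=float).ravel() + 0.5).astype(np.int64)
    if levels.min() < 0 or levels.max() > L - 1:
        raise InputDomainError(f"image values outside [0, {L - 1}]")
    return np.bincount(levels, minlength=L).astype(float)


def kde_histogram(img: np.ndarray, h: float, L: int = 256) -> KDEProfile:
    """Gaussian KDE of the gray-level histogram on the L-point level grid.

    Computed from the binned histogram (a weighted kernel sum) rather than
    per pixel; by linearity the result is identical for integer-quantized
    data and O(L^2) instead of O(N L).
    """
    if h <= 0:
        raise ParameterError("bandwidth h must be positive")
    counts = _histogram(img, L)
    n = counts.sum()
    grid = np.arange(L, dtype=float)
    u = (grid[:, None] - grid[None, :]) / h  # (x, x_j)
    kernel = np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)
    density = kernel @ counts / (n * h)
    peaks, _ = find_peaks(density)
    return KDEProfile(grid=grid, density=density, h=float(h), modes=grid[peaks])


def default_bandwidth_grid() -> np.ndarray:
    """Descending scan 50, 49.5, ..., 0.5 over the admissible range (0, 50)."""
    return np.arange(50.0, 0.49, -0.5)


def find_critical_bandwidth(img: np.ndarray, c: int,
                            h_grid: np.ndarray | None = None,
                            L: int = 256) -> tuple[float, np.ndarray]:
    """Critical bandwidth and the c KDE modes used as initial centroids.

    The critical bandwidth is the smallest scanned h whose density shows
    exactly ``c`` strict local maxima; the mode locations seed the
    centroids.  If no scanned h yields exactly c modes, the c most
    prominent modes at the smallest scanned h are used instead (logged).
    """
    if c < 2:
        raise ParameterError("need at least c = 2 clusters")
    img = np.asarray(img)
    if np.unique(np.floor(img + 0.5)).size < c:
        raise InitializationError(
            f"image has fewer than {c} distinct gray levels; cannot seed {c} clusters"
        )
    if h_grid is None:
        h_grid = default_bandwidth_grid()
    h_grid = np.asarray(h_grid, dtype=float)
    if np.any(h_grid <= 0):
        raise ParameterError("bandwidths must be positive")

    counts = _histogram(img, L)
    n = counts.sum()
    grid = np.arange(L, dtype=float)
    matches = []
    smallest_h = h_grid.min()
    density_at_smallest = None
    for h in h_grid:
        u = (grid[:, None] - grid[None, :]) / h
        density = (np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)) @ counts / (n * h)
        peaks, _ = find_peaks(density)
        if peaks.size == c:
            matches.append((h, grid[peaks]))
        if h == smallest_h:
            density_at_smallest = density
    if matches:
        h_crit, modes = min(matches, key=lambda m: m[0])
        return float(h_crit), modes
    logger.warning(
        "no scanned bandwidth yields exactly %d modes; "
        "falling back to the %d most prominent modes at h = %.3g",
        c, c, smallest_h,
    )
    peaks, props = find_peaks(density_at_smallest, prominence=0.0)
    if peaks.size < c:
        raise InitializationError(
            f"density never shows {c} modes; at most {peaks.size} found"
        )
    top = peaks[np.argsort(props["prominences"])[::-1][:c]]
    return float(smallest_h), grid[np.sort(top)]


def fcm_memberships(dist: np.ndarray, w: float) -> np.ndarray:
    """Fuzzy-c-means membership matrix from a (c, N) distance matrix.

    mu_ij = [ sum_k (d_ij / d_kj)^(2/(w-1)) ]^-1, columns summing to 1.
    Zero distances get full membership, split equally on ties.
    """
    if w <= 1:
        raise ParameterError("fuzzifier w must exceed 1")
    dist = np.asarray(dist, dtype=float)
    if np.any(dist < 0):
        raise InputDomainError("distances must be non-negative")
    zero = dist == 0
    any_zero = zero.any(axis=0)
    with np.errstate(divide="ignore"):
        inv = np.where(dist > 0, dist, 1.0) ** (-2.0 / (w - 1.0))
    mu = inv / inv.sum(axis=0, keepdims=True)
    if any_zero.any():
        cols = np.nonzero(any_zero)[0]
        mu[:, cols] = zero[:, cols] / zero[:, cols].sum(axis=0, keepdims=True)
    return mu


def gravity_force(mass, d2, l: float = GRAVITY_COEFF,
                  d2_floor: float = D2_FLOOR):
    """Newtonian attraction F = l * mass / d^2 of a unit-mass pixel.

    ``d2`` below the floor (one pixel spacing squared) is clamped so a
    pixel sitting on a core centroid never yields a singular force.
    """
    mass = np.asarray(mass, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(mass < 0):
        raise InputDomainError("cluster mass must be non-negative")
    clamped = d2 < d2_floor
    if np.any(clamped & (mass > 0)):
        logger.debug("gravity distance clamped to floor for %d entries",
                     int(np.sum(clamped)))
    return l * mass / np.maximum(d2, d2_floor)


def _empty_jgc_convention() -> float:
    # With no hard pixels the product objective would vanish identically;
    # J_GC := 1 keeps J_GFC = J_CM finite and meaningful at startup.
    return 1.0


def ugfc_objective(intensities: np.ndarray, centroids: np.ndarray,
                   memberships: np.ndarray, hard_labels: np.ndarray,
                   w: float) -> tuple[float, float, float]:
    """(J_GC, J_CM, J_GFC) for the given assignment.

    J_GC sums squared intensity distances of hard pixels to their own
    centroid; J_CM is the fuzzy-c-means objective over fuzzy pixels;
    J_GFC is their product.  An empty hard set contributes J_GC = 1 so the
    product reduces to J_CM.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    d2 = (x[None, :] - np.asarray(centroids, dtype=float)[:, None]) ** 2
    hard = hard_labels != FUZZY_LABEL
    if hard.any():
        j_gc = float(d2[hard_labels[hard], np.nonzero(hard)[0]].sum())
    else:
        j_gc = _empty_jgc_convention()
        logger.debug("no hard pixels; J_GC set to 1 so J_GFC = J_CM")
    fuzzy = ~hard
    j_cm = float((memberships[:, fuzzy] ** w * d2[:, fuzzy]).sum())
    return j_gc, j_cm, j_gc * j_cm


def ugfc_cluster(img: np.ndarray, c: int = 4, w: float = 1.7,
                 rho: float = 0.01, theta_hard: float = 0.85,
                 gamma: float = 2.0, max_iter: int = 100,
                 v0: np.ndarray | None = None,
                 h_grid: np.ndarray | None = None,
                 L: int = 256) -> ClusterState:
    """Run unified gravitational fuzzy clustering on a gray image.

    Each iteration: (1) intensity distances to the current centroids;
    (2) FCM memberships; (3) membership hard-core assignment at threshold
    ``theta_hard``; (4) gravity capture of fuzzy pixels whose spatial
    attraction toward one core dominates every other by factor ``gamma``;
    (5) centroid update as the weighted intensity mean (weight 1 for hard
    pixels, mu^w for fuzzy); (6) masses, core spatial centroids and the
    objective.  Stops when every centroid moves less than ``rho`` gray
    levels or at ``max_iter`` (flagged, not raised).

    ``theta_hard`` > 1 disables hard assignment and ``gamma = inf`` disables
    gravity capture; in that limit the loop is exactly fuzzy c-means.
    """
    if c < 2:
        raise ParameterError("need at least c = 2 clusters")
    if w <= 1:
        raise ParameterError("fuzzifier w must exceed 1")
    if rho <= 0:
        raise ParameterError("convergence threshold rho must be positive")
    if theta_hard <= 0.5:
        raise ParameterError("theta_hard must exceed 0.5")

    img = np.asarray(img, dtype=float)
    shape = img.shape
    x = img.ravel()
    n = x.size
    rows, cols = np.unravel_index(np.arange(n), shape) if img.ndim == 2 else (
        np.zeros(n), np.arange(n))
    pos = np.stack([rows, cols]).astype(float)  # (2, N)

    if v0 is None:
        _, v = find_critical_bandwidth(img, c, h_grid=h_grid, L=L)
        if v.size != c:
            raise InitializationError("initialization produced wrong mode count")
    else:
        v = np.asarray(v0, dtype=float).copy()
        if v.size != c:
            raise ParameterError("v0 must hold c initial centroids")
    v = v.astype(float)

    state = ClusterState(
        c=c, centroids=v, memberships=np.zeros((c, n)),
        hard_labels=np.full(n, FUZZY_LABEL, dtype=np.int64),
        masses=np.zeros(c, dtype=np.int64),
        core_centroids_xy=np.full((c, 2), np.nan),
        t=0, w=w, rho=rho, theta_hard=theta_hard, gamma=gamma, shape=shape,
    )

    prev_labels = np.full(n, FUZZY_LABEL, dtype=np.int64)
    for t in range(1, max_iter + 1):
        dist = np.abs(x[None, :] - v[:, None])
        mu = fcm_memberships(dist, w)

        # (3) membership hard core; argmax breaks ties toward lower index.
        # Hard membership accretes: a pixel that has flowed into an object
        # stays hard.  Pixels qualifying by membership track their best
        # cluster; previously gravity-captured pixels keep the label their
        # capture gave them (gravity deliberately overrides intensity).
        mu_max = mu.max(axis=0)
        core_theta = mu_max >= theta_hard
        labels = np.full(n, FUZZY_LABEL, dtype=np.int64)
        sticky = (prev_labels != FUZZY_LABEL) & ~core_theta
        labels[sticky] = prev_labels[sticky]
        labels[core_theta] = mu.argmax(axis=0)[core_theta]
        core = core_theta | sticky

        masses = np.bincount(labels[core], minlength=c)
        core_xy = np.full((c, 2), np.nan)
        for i in range(c):
            sel = labels == i
            if sel.any():
                core_xy[i] = pos[:, sel].mean(axis=1)

        # (4) gravity capture of dominated fuzzy pixels.  The distance is
        # to the nearest core pixel of each cluster (a point-mass at the
        # spatial centroid would misplace annular clusters such as the
        # background surrounding the head), and a cluster only competes
        # for a pixel it could plausibly own (membership at least the
        # uniform level 1/c): gravity arbitrates controversial pixels, it
        # does not override categorical non-membership.
        fuzzy_idx = np.nonzero(~core)[0]
        if fuzzy_idx.size and np.isfinite(gamma) and masses.sum() > 0:
            from scipy.ndimage import distance_transform_edt

            label_img = labels.reshape(shape if img.ndim == 2 else (1, n))
            d2 = np.full((c, fuzzy_idx.size), np.inf)
            for i in range(c):
                if masses[i] > 0:
                    dist_i = distance_transform_edt(label_img != i)
                    d2[i] = dist_i.ravel()[fuzzy_idx] ** 2
            force = np.where(np.isfinite(d2),
                             gravity_force(masses[:, None], d2), 0.0)
            force[mu[:, fuzzy_idx] < 1.0 / c] = 0.0
            order = np.argsort(force, axis=0)
            best = order[-1]
            f_best = force[best, np.arange(fuzzy_idx.size)]
            f_second = force[order[-2], np.arange(fuzzy_idx.size)]
            captured = f_best >= gamma * np.maximum(f_second, np.finfo(float).tiny)
            captured &= f_best > 0
            labels[fuzzy_idx[captured]] = best[captured]

        prev_labels = labels

        # objective of the iterate the update acts on: assignments paired
        # with the centroids that generated them
        j_gc, j_cm, j_gfc = ugfc_objective(x, v, mu, labels, w)

        # (5) centroid update: weight 1 on hard pixels, mu^w on fuzzy
        hard = labels != FUZZY_LABEL
        muw = mu ** w
        v_new = np.empty(c)
        for i in range(c):
            sel = labels == i
            fz = ~hard
            num = x[sel].sum() + (muw[i, fz] * x[fz]).sum()
            den = sel.sum() + muw[i, fz].sum()
            v_new[i] = num / den if den > 0 else v[i]

        # (6) bookkeeping
        masses = np.bincount(labels[hard], minlength=c)
        core_xy = np.full((c, 2), np.nan)
        for i in range(c):
            sel = labels == i
            if sel.any():
                core_xy[i] = pos[:, sel].mean(axis=1)

        state.memberships = mu
        state.hard_labels = labels
        state.masses = masses
        state.core_centroids_xy = core_xy
        state.objective_trace.append((j_gc, j_cm, j_gfc))
        state.centroid_trace.append(v_new.copy())
        state.hard_count_trace.append(int(hard.sum()))
        fz = ~hard
        if fz.any():
            state.membership_sum_err_trace.append(
                float(np.abs(mu[:, fz].sum(axis=0) - 1.0).max()))
        else:
            state.membership_sum_err_trace.append(0.0)
        state.t = t

        shift = np.abs(v_new - v).max()
        v = v_new
        state.centroids = v
        if shift < rho:
            state.converged = True
            break

    if not state.converged:
        logger.warning("UGFC did not converge within %d iterations", max_iter)
    return state


def extract_roi(state: ClusterState, img_shape: tuple | None = None,
                rule: str = "brightest",
                exclude_border: bool = False) -> ROIMask:
    """Binary region of interest from a cluster state.

    ``rule`` is ``"brightest"`` (cluster with the highest centroid — the
    hyperintense lesion under the enhanced-contrast convention) or
    ``"index:K"``.  Pixels belong to the ROI when their hard label, or
    argmax membership if fuzzy, is the selected cluster.  With
    ``exclude_border`` connected components touching the image border are
    removed (skull/scalp suppression).  An empty result sets ``empty``
    rather than raising.
    """
    from scipy import ndimage

    if img_shape is None:
        img_shape = state.shape
    if rule == "brightest":
        k = int(np.argmax(state.centroids))
    elif rule.startswith("index:"):
        k = int(rule.split(":", 1)[1])
        if not 0 <= k < state.c:
            raise ParameterError(f"cluster index {k} outside 0..{state.c - 1}")
    else:
        raise ParameterError(f"unknown ROI rule {rule!r}")

    labels = state.hard_labels.copy()
    fuzzy = labels == FUZZY_LABEL
    if fuzzy.any():
        labels[fuzzy] = state.memberships[:, fuzzy].argmax(axis=0)
    mask = (labels == k).reshape(img_shape)

    if exclude_border and mask.any():
        comp, ncomp = ndimage.label(mask)
        border = np.unique(np.concatenate([
            comp[0, :], comp[-1, :], comp[:, 0], comp[:, -1]]))
        mask = mask & ~np.isin(comp, border[border > 0])

    empty = not mask.any()
    if empty:
        logger.warning("extracted ROI is empty (cluster %d)", k)
    return ROIMask(mask=mask.astype(bool), selected_cluster=k, empty=empty)
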