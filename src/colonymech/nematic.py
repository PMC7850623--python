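"""Orientation fields, coherence, topological defects and the defect-field fit.

The local cell-elongation orientation of a microscopy-like image is
extracted with the structure-tensor method: the nematic angle phi in
[0, pi) points ALONG image structures (the minor-eigenvalue eigenvector of
the smoothed gradient outer product), and the coherence
C = (l1 - l2)/(l1 + l2) in [0, 1] measures how anisotropic the local
texture is.  +-1/2 topological defects are located by the winding number of
phi around grid plaquettes.  A one-constant liquid-crystal ansatz

    phi_fit(x, y) = alpha + sum_i k_i atan2(y - y_i, x - x_i)

reconstructs the field from the defects with a single global angle alpha,
which is fitted in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class SingularPointError(ValueError):
    """Evaluation of the defect field exactly at a defect core."""


@dataclass
class OrientationGrid:
    """Gridded nematic angle and coherence.

    ``x``/``y`` are 1-D pixel coordinates of the grid columns/rows; ``phi``
    (radians, reduced mod pi) and ``coherence`` are (len(y), len(x)) arrays;
    ``mask`` optionally marks valid grid points.
    """

    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    coherence: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.phi = np.mod(self.phi, np.pi)
        if np.any(self.coherence < -1e-9) or np.any(self.coherence > 1 + 1e-9):
            raise ValueError("coherence must lie in [0, 1]")
        self.coherence = np.clip(self.coherence, 0.0, 1.0)

    def points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (x, y, phi, C) over valid grid points."""
        X, Y = np.meshgrid(self.x, self.y)
        sel = np.ones(self.phi.shape, dtype=bool) if self.mask is None else self.mask
        return X[sel], Y[sel], self.phi[sel], self.coherence[sel]


@dataclass
class DefectSet:
    """Half-integer nematic defects: charges (+-1/2) and pixel positions.

    Plaquettes whose winding is a larger multiple of 1/2 are kept apart in
    ``other`` (charge, x, y) rather than silently mixed in.
    """

    charges: np.ndarray
    positions: np.ndarray
    other: list = field(default_factory=list)

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(self.charges) and not np.allclose(np.abs(self.charges), 0.5, atol=1e-6):
            raise ValueError("DefectSet charges must be exactly +-1/2")

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(np.sum(self.charges))


@dataclass
class NematicSummary:
    """Colony-level nematic readouts."""

    theta_nematic: float
    magnitude: float
    alpha: float | None = None
    theta_colony: float | None = None

    @property
    def delta_theta(self) -> float | None:
        """Angle between mean nematic and colony axis, folded to [0, pi/2]."""
        if self.theta_colony is None or not np.isfinite(self.theta_nematic):
            return None
        return fold_nematic_difference(self.theta_nematic, self.theta_colony)


def fold_nematic_difference(a: float, b: float) -> float:
    """|a - b| as a nematic angle difference in [0, pi/2]."""
    d = abs(a - b) % np.pi
    return min(d, np.pi - d)


# ---------------------------------------------------------------------------
# Structure tensor
# ---------------------------------------------------------------------------

def orientation_field(
    image: np.ndarray,
    smoothing_window: float = 20.0,
    grid_spacing: int = 20,
    mask: np.ndarray | None = None,
    gradient_sigma: float = 1.0,
) -> OrientationGrid:
    """Structure-tensor orientation and coherence sampled on a regular grid.

    The structure tensor J = G_w * (grad I grad I^T) is built from Gaussian
    derivatives (sigma ``gradient_sigma``) and smoothed with a Gaussian
    window of sigma ``smoothing_window / 3``.  phi is the direction along
    image structures (minor eigenvector of J) and C = (l1 - l2)/(l1 + l2).
    Flat regions get C = 0 (never NaN angles).  ``mask``, if given, is a
    pixel-level boolean colony mask sampled onto the grid.
    """
    im = np.asarray(image, dtype=float)
    if im.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if min(im.shape) < 3 * smoothing_window:
        raise ValueError("image must span at least 3 smoothing windows")
    gy = ndimage.gaussian_filter(im, gradient_sigma, order=(1, 0))
    gx = ndimage.gaussian_filter(im, gradient_sigma, order=(0, 1))
    sw = smoothing_window / 3.0
    jxx = ndimage.gaussian_filter(gx * gx, sw)
    jyy = ndimage.gaussian_filter(gy * gy, sw)
    jxy = ndimage.gaussian_filter(gx * gy, sw)

    ys = np.arange(grid_spacing // 2, im.shape[0], grid_spacing)
    xs = np.arange(grid_spacing // 2, im.shape[1], grid_spacing)
    jxx, jyy, jxy = (a[np.ix_(ys, xs)] for a in (jxx, jyy, jxy))

    trace = jxx + jyy
    diff = np.sqrt((jxx - jyy) ** 2 + 4 * jxy**2)
    tiny = trace <= 1e-12 * max(float(trace.max(initial=0.0)), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(tiny, 0.0, diff / np.where(trace == 0, 1.0, trace))
    # major eigenvector of J is the gradient direction; structures run 90 deg away
    phi = 0.5 * np.arctan2(2 * jxy, jxx - jyy) + 0.5 * np.pi
    phi = np.mod(phi, np.pi)
    phi = np.where(tiny, 0.0, phi)

    gmask = None
    if mask is not None:
        gmask = np.asarray(mask, dtype=bool)[np.ix_(ys, xs)]
    return OrientationGrid(
        x=xs.astype(float), y=ys.astype(float), phi=phi, coherence=coh, mask=gmask
    )


# ---------------------------------------------------------------------------
# Defect detection
# ---------------------------------------------------------------------------

def _wrap_nematic(d: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-pi/2, pi/2]."""
    return -((np.pi / 2 - d) % np.pi - np.pi / 2)


def detect_defects(grid: OrientationGrid, tol: float = 1e-6) -> DefectSet:
    """Half-integer defects from plaquette winding numbers.

    For each unit cell of the grid the winding is the sum of
    nematic-wrapped successive angle differences around the loop, divided
    by 2 pi; plaquettes with winding +-1/2 yield a defect at the plaquette
    center.  Plaquettes touching masked-out points are skipped; windings of
    larger magnitude are reported in ``other``.
    """
    phi = grid.phi
    p00 = phi[:-1, :-1]
    p01 = phi[:-1, 1:]
    p11 = phi[1:, 1:]
    p10 = phi[1:, :-1]
    wind = (
        _wrap_nematic(p01 - p00)
        + _wrap_nematic(p11 - p01)
        + _wrap_nematic(p10 - p11)
        + _wrap_nematic(p00 - p10)
    ) / (2 * np.pi)
    if grid.mask is not None:
        m = grid.mask
        ok = m[:-1, :-1] & m[:-1, 1:] & m[1:, 1:] & m[1:, :-1]
        wind = np.where(ok, wind, 0.0)
    cx = 0.5 * (grid.x[:-1] + grid.x[1:])
    cy = 0.5 * (grid.y[:-1] + grid.y[1:])
    CX, CY = np.meshgrid(cx, cy)

    charges, positions, other = [], [], []
    hot = np.nonzero(np.abs(wind) > 0.25)
    for i, j in zip(*hot):
        k = wind[i, j]
        if abs(abs(k) - 0.5) <= tol:
            charges.append(0.5 * np.sign(k))
            positions.append((CX[i, j], CY[i, j]))
        else:
            other.append((float(k), float(CX[i, j]), float(CY[i, j])))
    return DefectSet(np.array(charges), np.array(positions).reshape(-1, 2), other)


# ---------------------------------------------------------------------------
# Defect-field ansatz and the one-parameter fit
# ---------------------------------------------------------------------------

def defect_field(
    charges: np.ndarray | list,
    positions: np.ndarray | list,
    alpha: float,
    points: np.ndarray,
) -> np.ndarray:
    """One-constant equilibrium nematic angle of a set of point defects.

    phi(x, y) = alpha + sum_i k_i atan2(y - y_i, x - x_i), returned mod pi.
    The full-plane atan2 branch keeps the field continuous as a nematic for
    half-integer charges (a principal-branch arctan would not).  Pure
    function; raises at an exact defect position.
    """
    charges = np.asarray(charges, dtype=float)
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    phi = np.full(len(pts), float(alpha))
    for k, (xi, yi) in zip(charges, positions):
        dx = pts[:, 0] - xi
        dy = pts[:, 1] - yi
        if np.any((dx == 0) & (dy == 0)):
            raise SingularPointError(f"evaluation at defect ({xi}, {yi})")
        phi += k * np.arctan2(dy, dx)
    return np.mod(phi, np.pi)


def defect_field_grid(
    charges,
    positions,
    alpha: float,
    x: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray | None = None,
) -> OrientationGrid:
    """Forward-generate an OrientationGrid (C = 1) from a defect set."""
    X, Y = np.meshgrid(np.asarray(x, float), np.asarray(y, float))
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    phi = defect_field(charges, positions, alpha, pts).reshape(X.shape)
    return OrientationGrid(
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        phi=phi,
        coherence=np.ones_like(phi),
        mask=mask,
    )


def fit_alpha(grid: OrientationGrid, defects: DefectSet) -> tuple[float, float]:
    """Best global angle of the defect-field ansatz, in closed form.

    Minimizes the coherence-weighted nematic residual
    sum_j C_j (1 - cos 2(phi_j - phi_fit_j)) over alpha; the minimizer is
    the circular mean (at double angle) of psi_j = phi_j - sum_i k_i
    atan2(...).  Returns (alpha in [0, pi), mean residual in [0, 2]).
    """
    xs, ys, phis, ws = grid.points()
    if len(xs) == 0:
        raise ValueError("no usable grid points")
    if np.all(ws == 0):
        raise ValueError("all coherence weights are zero")
    pts = np.stack([xs, ys], axis=1)
    base = defect_field(defects.charges, defects.positions, 0.0, pts)
    psi = phis - base
    S = float(np.sum(ws * np.sin(2 * psi)))
    C = float(np.sum(ws * np.cos(2 * psi)))
    alpha = 0.5 * np.arctan2(S, C) % np.pi
    resid = float(np.sum(ws * (1 - np.cos(2 * (psi - alpha)))) / np.sum(ws))
    return alpha, resid


# ---------------------------------------------------------------------------
# Colony-level summaries
# ---------------------------------------------------------------------------

def mean_nematic_angle(
    grid: OrientationGrid, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Coherence-weighted mean nematic angle and order magnitude.

    Averages the tensor (cos 2 phi, sin 2 phi) weighted by coherence over
    the (optionally masked) grid; returns (theta in [0, pi), magnitude in
    [0, 1]).  A vanishing average yields magnitude 0 and theta = nan.
    """
    sel = np.ones(grid.phi.shape, dtype=bool)
    if grid.mask is not None:
        sel &= grid.mask
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    if not np.any(sel):
        raise ValueError("empty mask")
    w = grid.coherence[sel]
    if np.all(w == 0):
        return float("nan"), 0.0
    c = float(np.sum(w * np.cos(2 * grid.phi[sel])) / np.sum(w))
    s = float(np.sum(w * np.sin(2 * grid.phi[sel])) / np.sum(w))
    mag = float(np.hypot(c, s))
    if mag < 1e-12:
        return float("nan"), mag
    return 0.5 * np.arctan2(s, c) % np.pi, mag


def delta_theta_cdf(values) -> dict:
    """Empirical CDF of nematic angle differences plus the uniform null.

    ``values`` must lie in [0, pi/2].  Returns a dict with the sorted
    values, their empirical CDF, the uniform-null CDF at those points, and
    the Kolmogorov-Smirnov-style sup distance to the null (no p-value).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    if np.any(v < 0) or np.any(v > np.pi / 2 + 1e-12):
        raise ValueError("delta-theta values must lie in [0, pi/2]")
    v = np.sort(v)
    n = len(v)
    ecdf = np.arange(1, n + 1) / n
    null = v / (np.pi / 2)
    ks = float(np.max(np.maximum(np.abs(ecdf - null), np.abs(ecdf - 1 / n - null))))
    return {"values": v, "ecdf": ecdf, "null": null, "ks_distance": ks}
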