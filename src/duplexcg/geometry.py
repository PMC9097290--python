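"""Conformational observables computed from bead coordinates.

Definitions operate on three families of points derived from a frame:

* base-pair centers  Gamma_i = (B_{1,i} + B_{2,i}) / 2,
* sugar centers      xi_i    = (S_{1,i} + S_{2,i}) / 2,
* sugar separations  zeta_i  = S_{2,i} - S_{1,i}.

The helical axis is global: the axis of the cylinder that best fits the
phosphate positions.  h-twist_{i,i+1} is the signed angle between successive
zeta vectors projected onto the plane perpendicular to the axis (sign from
(zeta_i^r x zeta_{i+1}^r) . h); h-rise_{i,i+1} is the projection of
xi_{i+1} - xi_i on the axis.  The crookedness beta = arccos(|end-to-end| / L)
measures the deviation of the base-pair-center line from a straight rod.

Unless a docstring says otherwise, functions return lengths in the unit of
the input coordinates and angles in degrees (radians are used internally).
Groove geometry is the exception: it reports nm, because the van der Waals
corrections it subtracts (0.58 nm for widths, 0.35 nm for depths) are fixed
physical lengths; it expects Angstrom input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .topology import CGStructure


class DegenerateGeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# frame vectors
# ---------------------------------------------------------------------------

def frame_points(structure: CGStructure, coords: np.ndarray | None = None):
    """Return (Gamma, xi, zeta, P1, P2) arrays for one frame (input units)."""
    x = structure.coords if coords is None else np.asarray(coords, dtype=float)
    if x is None:
        raise ValueError("no coordinates")
    s1 = x[structure.sugar_ids(1)]
    s2 = x[structure.sugar_ids(2)]
    b1 = x[structure.base_ids(1)]
    b2 = x[structure.base_ids(2)]
    gamma = 0.5 * (b1 + b2)
    xi = 0.5 * (s1 + s2)
    zeta = s2 - s1
    return gamma, xi, zeta, x[structure.phosphate_ids(1)], x[structure.phosphate_ids(2)]


# ---------------------------------------------------------------------------
# crookedness
# ---------------------------------------------------------------------------

def crookedness(gamma: np.ndarray):
    """Crookedness beta (rad) and contour length L of the base-pair-center line.

    L = sum_i |Gamma_{i+1} - Gamma_i|; beta = arccos(|Gamma_n - Gamma_1| / L).
    """
    gamma = np.asarray(gamma, dtype=float)
    if len(gamma) < 2:
        raise ValueError("need at least 2 base-pair centers")
    seg = np.linalg.norm(np.diff(gamma, axis=0), axis=1)
    if np.any(seg < 1e-10):
        raise DegenerateGeometryError("coincident consecutive base-pair centers")
    L = float(seg.sum())
    ratio = float(np.linalg.norm(gamma[-1] - gamma[0]) / L)
    return float(math.acos(min(1.0, ratio))), L


# ---------------------------------------------------------------------------
# cylinder fit
# ---------------------------------------------------------------------------

@dataclass
class CylinderFit:
    axis: np.ndarray       # unit vector
    point: np.ndarray      # a point on the axis
    radius: float          # input units
    rms_residual: float


def fit_cylinder(points: np.ndarray, orient: np.ndarray | None = None) -> CylinderFit:
    """Least-squares cylinder through ``points``: minimize sum (d_i - r)^2
    where d_i is the distance of point i from the axis.

    The axis is initialized from the principal component of the point cloud
    and refined by Levenberg-Marquardt; the radius is eliminated analytically
    (r = mean distance).  If ``orient`` is given the axis sign is chosen so
    axis . orient > 0.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 6:
        raise DegenerateGeometryError("cylinder fit needs at least 6 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, Vt = np.linalg.svd(centered)
    if svals[1] < 1e-10 * max(1.0, svals[0]):
        raise DegenerateGeometryError("degenerate (collinear) point set")
    d0 = Vt[0]
    # orthonormal basis perpendicular to the initial axis
    e1 = Vt[1]
    e2 = Vt[2]

    def unpack(p):
        a, b, c1, c2 = p
        d = d0 + a * e1 + b * e2
        d = d / np.linalg.norm(d)
        c = centroid + c1 * e1 + c2 * e2
        return d, c

    def residuals(p):
        d, c = unpack(p)
        rel = pts - c
        perp = rel - np.outer(rel @ d, d)
        dist = np.linalg.norm(perp, axis=1)
        return dist - dist.mean()

    sol = least_squares(residuals, x0=np.zeros(4), method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise DegenerateGeometryError(f"cylinder fit did not converge: {sol.message}")
    d, c = unpack(sol.x)
    rel = pts - c
    dist = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
    if orient is not None and float(np.dot(d, orient)) < 0:
        d = -d
    return CylinderFit(axis=d, point=c, radius=float(dist.mean()),
                       rms_residual=float(np.sqrt(np.mean(sol.fun**2))))


def helical_axis(structure: CGStructure, coords: np.ndarray | None = None) -> CylinderFit:
    """Best-fit cylinder through all phosphates, axis oriented along
    increasing base-pair index."""
    gamma, _, _, p1, p2 = frame_points(structure, coords)
    return fit_cylinder(np.vstack([p1, p2]), orient=gamma[-1] - gamma[0])


# ---------------------------------------------------------------------------
# helical parameters
# ---------------------------------------------------------------------------

def _project_perp(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return v - np.outer(v @ axis, axis)


def h_twist(zeta: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Signed per-step twist (degrees) from successive sugar-separation
    vectors projected perpendicular to ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    zr = _project_perp(np.asarray(zeta, dtype=float), axis)
    norms = np.linalg.norm(zr, axis=1)
    if np.any(norms < 1e-10):
        raise DegenerateGeometryError("zeta parallel to the helical axis")
    zr = zr / norms[:, None]
    a, b = zr[:-1], zr[1:]
    ang = np.arctan2(np.cross(a, b) @ axis, np.sum(a * b, axis=1))
    return np.degrees(ang)


def h_rise(xi: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Per-step rise: (xi_{i+1} - xi_i) . axis, in input units."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return np.diff(np.asarray(xi, dtype=float), axis=0) @ axis


def force_axis_twist(zeta: np.ndarray, direction=(0.0, 0.0, 1.0)):
    """Cumulative torsion angle theta (rad) against a fixed lab direction.

    Per-step angles psi are computed exactly like the h-twist but using the
    rejection of zeta from ``direction`` instead of the helical axis.
    Returns (theta_rad, psi_deg).
    """
    psi = h_twist(zeta, np.asarray(direction, dtype=float))
    return float(np.sum(np.radians(psi))), psi


def torsion_angle(p0, p1, p2, p3) -> float:
    """Standard signed torsion angle (rad) of four points."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear triple in torsion")
    return float(math.atan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2)))


def sbbs_dihedral(structure: CGStructure, coords: np.ndarray | None = None) -> np.ndarray:
    """Per-base-pair dihedral S1-B1-B2-S2 (degrees)."""
    x = structure.coords if coords is None else np.asarray(coords, dtype=float)
    s1 = x[structure.sugar_ids(1)]
    b1 = x[structure.base_ids(1)]
    b2 = x[structure.base_ids(2)]
    s2 = x[structure.sugar_ids(2)]
    return np.degrees([torsion_angle(s1[i], b1[i], b2[i], s2[i])
                       for i in range(structure.n)])


def supercoiling_density(delta_theta: float, theta0: float) -> float:
    """sigma = delta_theta / theta0 (both in radians)."""
    if theta0 == 0:
        raise ValueError("theta0 must be nonzero")
    return delta_theta / theta0


def helical_pitch(twist_deg: np.ndarray) -> float:
    """Base pairs per helical turn from per-step twists (degrees).

    ``twist_deg`` is (n_steps,) or (n_frames, n_steps); the cumulated twist is
    averaged over frames and divided by a full turn.
    """
    twist_deg = np.atleast_2d(np.asarray(twist_deg, dtype=float))
    n_steps = twist_deg.shape[1]
    turns = float(np.mean(np.sum(twist_deg, axis=1))) / 360.0
    if turns <= 0:
        raise ValueError("cumulative twist must be positive to define a pitch")
    return n_steps / turns


# ---------------------------------------------------------------------------
# grooves: centripetal Catmull-Rom interpolation of the phosphate backbones
# ---------------------------------------------------------------------------

class CatmullRomSpline:
    """Centripetal Catmull-Rom spline through control points (alpha = 1/2).

    The curve interpolates every control point; the valid parameter range is
    [knot[1], knot[m-2]] (the first and last control points only steer the
    ends).
    """

    def __init__(self, control_points: np.ndarray):
        pts = np.asarray(control_points, dtype=float)
        if len(pts) < 4:
            raise ValueError("need at least 4 control points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise ValueError("coincident control points")
        self.points = pts
        self.knots = np.concatenate([[0.0], np.cumsum(np.sqrt(seg))])

    @property
    def t_min(self) -> float:
        return self.knots[1]

    @property
    def t_max(self) -> float:
        return self.knots[-2]

    def __call__(self, t):
        """Evaluate at parameter values ``t`` (Barry-Goldman pyramid)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < self.t_min - 1e-9) or np.any(t > self.t_max + 1e-9):
            raise ValueError("parameter outside the interpolated range")
        t = np.clip(t, self.t_min, self.t_max)
        seg = np.clip(np.searchsorted(self.knots, t, side="right") - 1,
                      1, len(self.points) - 3)
        P = self.points
        k = self.knots
        i0, i1, i2, i3 = seg - 1, seg, seg + 1, seg + 2
        t0, t1, t2, t3 = k[i0], k[i1], k[i2], k[i3]

        def lerp(pa, pb, ta, tb):
            w = ((t - ta) / (tb - ta))[:, None]
            return (1.0 - w) * pa + w * pb

        A1 = lerp(P[i0], P[i1], t0, t1)
        A2 = lerp(P[i1], P[i2], t1, t2)
        A3 = lerp(P[i2], P[i3], t2, t3)
        B1 = lerp(A1, A2, t0, t2)
        B2 = lerp(A2, A3, t1, t3)
        C = lerp(B1, B2, t1, t2)
        return C

    def arclength_midpoint(self, t_a: float, t_b: float, samples: int = 256) -> float:
        """Parameter of the arc-length midpoint between t_a and t_b."""
        ts = np.linspace(t_a, t_b, samples)
        pts = self(ts)
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        return float(np.interp(s[-1] / 2.0, s, ts))


def _rotate_about_axis(points, axis, origin, angle):
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * K @ K
    return (np.asarray(points) - origin) @ R.T + origin


def _backbone_spline(phos: np.ndarray, axis_fit: CylinderFit,
                     twist_first: float, rise_first: float,
                     twist_last: float, rise_last: float) -> CatmullRomSpline:
    """Spline through one strand's phosphates with virtual terminal control
    points extrapolated using the h-rise and h-twist of the terminal steps."""
    h = axis_fit.axis
    c = axis_fit.point
    pre = _rotate_about_axis(phos[0], h, c, -twist_first) - rise_first * h
    post = _rotate_about_axis(phos[-1], h, c, twist_last) + rise_last * h
    return CatmullRomSpline(np.vstack([pre, phos, post]))


@dataclass
class GrooveProfile:
    """Per-base-pair groove geometry in nm.

    The two walk directions along the complementary backbone are mapped to
    the minor/major labels according to handedness (the sign of the mean
    h-twist): on a right-handed duplex the walk toward increasing base-pair
    index crosses the minor groove.  On a mirror-image frame the labels
    therefore exchange, while the underlying distances are isometry-invariant.
    """

    bp_index: np.ndarray           # base-pair indices covered (1-based)
    minor_width: np.ndarray
    major_width: np.ndarray
    minor_depth: np.ndarray
    major_depth: np.ndarray
    boundary_flags: list = field(default_factory=list)

    WIDTH_OFFSET_NM = 0.58
    DEPTH_OFFSET_NM = 0.35


def _first_local_min(spline: CatmullRomSpline, t_start: float, target: np.ndarray,
                     direction: int, step: float):
    """Walk the spline from t_start; return (t*, d*) at the first local
    minimum of |spline(t) - target|, or None if the boundary is hit first.

    A minimum at the start point itself (distance increasing immediately) is
    accepted.
    """
    def dist(t):
        return float(np.linalg.norm(spline(np.array([t]))[0] - target))

    lo, hi = spline.t_min, spline.t_max
    t_prev, d_prev = t_start, dist(t_start)
    t_cur = t_start + direction * step
    if t_cur < lo or t_cur > hi:
        return t_start, d_prev
    d_cur = dist(t_cur)
    if d_cur >= d_prev:
        return t_start, d_prev  # already at a local minimum along this walk
    while True:
        t_next = t_cur + direction * step
        if t_next < lo or t_next > hi:
            return None
        d_next = dist(t_next)
        if d_next >= d_cur:
            break
        t_prev, d_prev = t_cur, d_cur
        t_cur, d_cur = t_next, d_next
    # golden-section refinement inside the bracket [t_prev, t_next]
    a, b = sorted((t_prev, t_cur + direction * step))
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    c1 = b - phi * (b - a)
    c2 = a + phi * (b - a)
    f1, f2 = dist(c1), dist(c2)
    for _ in range(60):
        if f1 <= f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - phi * (b - a)
            f1 = dist(c1)
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + phi * (b - a)
            f2 = dist(c2)
    t_best = 0.5 * (a + b)
    return t_best, dist(t_best)


def groove_geometry(structure: CGStructure, coords: np.ndarray | None = None,
                    walk_step_fraction: float = 1e-3) -> GrooveProfile:
    """Groove widths and depths per base pair (nm), Angstrom input.

    The phosphates of each strand are interpolated with centripetal
    Catmull-Rom splines (terminal control points extrapolated from the
    h-rise/h-twist of the terminal steps).  For base pair i the midpoint
    M_{1,i} between P_{1,i} and P_{1,i+1} is taken along the strand-1 curve;
    from the analogous midpoint M_{2,i} the strand-2 curve is walked in both
    directions until the distance from M_{1,i} first reaches a local minimum
    (golden-section refined).  Widths are the two minimal distances minus
    0.58 nm (backbone van der Waals radius); depths are the distances of the
    width-vector midpoints from Gamma_i minus 0.35 nm.
    """
    if structure.n < 4:
        raise ValueError("groove geometry needs at least 4 base pairs")
    gamma, xi, zeta, p1, p2 = frame_points(structure, coords)
    fit = fit_cylinder(np.vstack([p1, p2]), orient=gamma[-1] - gamma[0])
    tw = np.radians(h_twist(zeta, fit.axis))
    rise = h_rise(xi, fit.axis)

    splines = [
        _backbone_spline(p, fit, tw[0], rise[0], tw[-1], rise[-1])
        for p in (p1, p2)
    ]
    s1, s2 = splines
    # phosphate i occupies control-point slot i-1 (virtual point at slot 0)
    # so the knot of P_{s,i} is knots[i-1]
    n = structure.n
    rows = []
    flags = []
    step2 = walk_step_fraction * (s2.t_max - s2.t_min) / max(1, n - 2)
    # walk direction -> groove label, by handedness of the duplex
    right_handed = float(np.mean(tw)) >= 0.0
    direction_labels = ((+1, "minor"), (-1, "major")) if right_handed \
        else ((+1, "major"), (-1, "minor"))
    for i in range(2, n):  # base pairs with both P_i and P_{i+1} present
        k1a, k1b = s1.knots[i - 1], s1.knots[i]
        k2a, k2b = s2.knots[i - 1], s2.knots[i]
        m1 = s1(np.array([s1.arclength_midpoint(k1a, k1b)]))[0]
        t2 = s2.arclength_midpoint(k2a, k2b)
        found = {}
        for direction, label in direction_labels:
            res = _first_local_min(s2, t2, m1, direction, step2)
            if res is None:
                flags.append((i, label))
                found[label] = (np.nan, np.full(3, np.nan))
            else:
                t_star, d_star = res
                found[label] = (d_star, s2(np.array([t_star]))[0])
        row = {"bp": i}
        for label in ("minor", "major"):
            d_star, foot = found[label]
            row[f"{label}_width"] = d_star / 10.0 - GrooveProfile.WIDTH_OFFSET_NM
            mid = 0.5 * (m1 + foot)
            row[f"{label}_depth"] = (np.linalg.norm(mid - gamma[i - 1]) / 10.0
                                     - GrooveProfile.DEPTH_OFFSET_NM)
        rows.append(row)

    return GrooveProfile(
        bp_index=np.array([r["bp"] for r in rows]),
        minor_width=np.array([r["minor_width"] for r in rows]),
        major_width=np.array([r["major_width"] for r in rows]),
        minor_depth=np.array([r["minor_depth"] for r in rows]),
        major_depth=np.array([r["major_depth"] for r in rows]),
        boundary_flags=flags,
    )


# ---------------------------------------------------------------------------
# per-frame summary
# ---------------------------------------------------------------------------

@dataclass
class HelicalGeometry:
    """Observables of one frame, in reporting units (nm / degrees / rad)."""

    axis: np.ndarray
    diameter_nm: float
    h_twist_deg: np.ndarray
    h_rise_nm: np.ndarray
    beta: float
    contour_length_nm: float
    sbbs_deg: np.ndarray


def analyze_frame(structure: CGStructure, coords: np.ndarray | None = None,
                  discard_ends: int = 0) -> HelicalGeometry:
    """Full helical analysis of a frame (coordinates in Angstrom).

    ``discard_ends`` base pairs at each end are excluded from the analysis
    (handles and frayed termini are conventionally dropped).
    """
    x = structure.coords if coords is None else np.asarray(coords, dtype=float)
    gamma, xi, zeta, p1, p2 = frame_points(structure, x)
    sl = slice(discard_ends, structure.n - discard_ends or None)
    gamma, xi, zeta = gamma[sl], xi[sl], zeta[sl]
    psl = slice(max(0, discard_ends - 1), len(p1) - discard_ends or None)
    fit = fit_cylinder(np.vstack([p1[psl], p2[psl]]), orient=gamma[-1] - gamma[0])
    beta, L = crookedness(gamma)
    return HelicalGeometry(
        axis=fit.axis,
        diameter_nm=2.0 * fit.radius / 10.0,
        h_twist_deg=h_twist(zeta, fit.axis),
        h_rise_nm=h_rise(xi, fit.axis) / 10.0,
        beta=beta,
        contour_length_nm=L / 10.0,
        sbbs_deg=sbbs_dihedral(structure, x)[sl],
    )
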