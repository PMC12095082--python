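"""Elastic phase distances between BMI trajectories.

Curves are compared in the square-root slope function (SRSF) framework:
a trajectory ``f`` on normalized time ``t in [0, 1]`` is represented by
``q(t) = sign(f'(t)) * sqrt(|f'(t)|)``, under which optimal time warping
becomes a least-squares problem.  Aligning ``f2`` to ``f1`` means finding a
boundary-fixed, monotone warping function ``gamma`` minimizing

    || q1 - (q2 o gamma) * sqrt(gamma') ||^2 ,

solved here by exact dynamic programming over piecewise-linear warps on the
discretization lattice.  The phase distance between two curves is the
arc-length on the unit Hilbert sphere between the SRSF of the optimal warp
and that of the identity warp:

    d_phase = arccos( integral_0^1 sqrt(gamma'(t)) dt )  in  [0, pi/2].

Distances are symmetrized by averaging both alignment directions, since the
dynamic program is directional while k-medoids requires a symmetric
dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np
from numba import njit

__all__ = [
    "Curve",
    "SRSF",
    "WarpingFunction",
    "DistanceMatrix",
    "curve_from_grid",
    "to_srsf",
    "align_pair",
    "phase_distance",
    "elastic_phase_distance",
    "pairwise_distance_matrix",
    "align_to_reference",
]

#: age range (years) of the standard BMI grid, affinely mapped onto [0, 1]
AGE_MIN = 0.25
AGE_MAX = 16.0

#: default uniform mesh resolution for SRSF / dynamic-programming alignment
DEFAULT_N_POINTS = 101

#: default dynamic-programming neighborhood half-width (max lattice step)
DEFAULT_NEIGHBORHOOD = 7


@dataclass(frozen=True)
class Curve:
    """A trajectory on normalized time.

    ``t`` is strictly increasing with ``t[0] == 0`` and ``t[-1] == 1``;
    ``f`` holds the values (kg/m^2 for BMI curves).
    """

    t: np.ndarray
    f: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("t and f must be 1-D arrays of equal length")
        if t.size < 3:
            raise ValueError("a Curve needs at least 3 points")
        if not (np.all(np.diff(t) > 0) and t[0] == 0.0 and t[-1] == 1.0):
            raise ValueError("t must be strictly increasing from 0 to 1")
        if not np.all(np.isfinite(f)):
            raise ValueError("curve values must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "f", f)

    @property
    def n_points(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class SRSF:
    """Square-root slope representation ``q = sign(f') sqrt(|f'|)`` of a curve."""

    t: np.ndarray
    q: np.ndarray


@dataclass(frozen=True)
class WarpingFunction:
    """Discretized boundary-fixed monotone reparameterization of [0, 1]."""

    t: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gamma, dtype=float)
        t = np.asarray(self.t, dtype=float)
        if g.shape != t.shape:
            raise ValueError("t and gamma must have equal length")
        if abs(g[0]) > 1e-12 or abs(g[-1] - 1.0) > 1e-12:
            raise ValueError("gamma must fix the boundary: gamma(0)=0, gamma(1)=1")
        if np.any(np.diff(g) < -1e-12):
            raise ValueError("gamma must be nondecreasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "gamma", g)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise phase-distance matrix (radians, zero diagonal)."""

    ids: list
    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if D.shape != (n, n):
            raise ValueError("D must be square and match ids")
        if not np.allclose(D, D.T):
            raise ValueError("D must be symmetric")
        object.__setattr__(self, "D", D)


def curve_from_grid(ages, values, n_points: int = DEFAULT_N_POINTS) -> Curve:
    """Map a trajectory from age space onto a uniform mesh in [0, 1].

    Ages in ``[AGE_MIN, AGE_MAX]`` years are affinely rescaled to [0, 1] and
    the values linearly resampled to ``n_points`` uniform points, the mesh the
    dynamic-programming aligner operates on.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    s = (ages - AGE_MIN) / (AGE_MAX - AGE_MIN)
    t = np.linspace(0.0, 1.0, n_points)
    f = np.interp(t, s, values)
    return Curve(t=t, f=f)


def to_srsf(curve: Curve) -> SRSF:
    """SRSF transform with derivatives by central differences.

    Interior points use central differences, the endpoints one-sided
    differences (``numpy.gradient``); then ``q = sign(f') sqrt(|f'|)``.
    """
    if curve.n_points < 3:
        raise ValueError("need at least 3 points for finite differences")
    df = np.gradient(curve.f, curve.t)
    q = np.sign(df) * np.sqrt(np.abs(df))
    return SRSF(t=curve.t, q=q)


def _coprime_steps(width: int) -> np.ndarray:
    """Lattice predecessor steps {(a, b): 1 <= a, b <= width, gcd(a, b) = 1}."""
    if width < 1:
        raise ValueError("neighborhood width must be >= 1")
    steps = [(a, b) for a in range(1, width + 1) for b in range(1, width + 1)
             if gcd(a, b) == 1]
    return np.asarray(steps, dtype=np.int64)


@njit(cache=True)
def _dp_tables(q1, q2, steps):  # pragma: no cover - exercised via align_pair
    n = q1.shape[0]
    h = 1.0 / (n - 1)
    big = np.inf
    E = np.full((n, n), big)
    pred = np.full((n, n), -1, dtype=np.int64)
    E[0, 0] = 0.0
    m = steps.shape[0]
    for i in range(1, n):
        for j in range(1, n):
            best = big
            barg = -1
            for s in range(m):
                a = steps[s, 0]
                b = steps[s, 1]
                i0 = i - a
                j0 = j - b
                if i0 < 0 or j0 < 0:
                    continue
                e0 = E[i0, j0]
                if e0 >= big:
                    continue
                slope = b / a
                sq = np.sqrt(slope)
                # trapezoidal cost of the linear warp segment (i0,j0)->(i,j)
                c = 0.0
                for k in range(a + 1):
                    p = j0 + slope * k  # fractional index of gamma(t_{i0+k})
                    lo = int(p)
                    if lo >= n - 1:
                        q2v = q2[n - 1]
                    else:
                        fr = p - lo
                        q2v = q2[lo] * (1.0 - fr) + q2[lo + 1] * fr
                    d = q1[i0 + k] - q2v * sq
                    w = 0.5 if (k == 0 or k == a) else 1.0
                    c += w * d * d
                cand = e0 + c * h
                if cand < best - 1e-15:
                    best = cand
                    barg = s
            E[i, j] = best
            pred[i, j] = barg
    return E, pred


def align_pair(q1: SRSF, q2: SRSF,
               neighborhood_width: int = DEFAULT_NEIGHBORHOOD) -> WarpingFunction:
    """Optimal warp aligning ``q2`` to ``q1`` by exact lattice dynamic programming.

    Minimizes ``||q1 - (q2 o gamma) sqrt(gamma')||^2`` over continuous
    piecewise-linear warps whose breakpoints lie on the mesh lattice, with
    predecessor steps restricted to coprime pairs up to
    ``neighborhood_width``.  Ties are resolved toward the first-enumerated
    (smallest) step, making the result deterministic.
    """
    q1a = np.asarray(q1.q, dtype=float)
    q2a = np.asarray(q2.q, dtype=float)
    if q1a.shape != q2a.shape or not np.array_equal(q1.t, q2.t):
        raise ValueError("SRSFs must share the same mesh")
    n = q1a.size
    steps = _coprime_steps(neighborhood_width)
    _, pred = _dp_tables(q1a, q2a, steps)
    # backtrack the lattice path from (n-1, n-1)
    nodes_i = [n - 1]
    nodes_j = [n - 1]
    i, j = n - 1, n - 1
    while i > 0 or j > 0:
        s = pred[i, j]
        if s < 0:  # unreachable; cannot happen with step (1,1) present
            raise RuntimeError("dynamic program failed to reach the origin")
        i -= int(steps[s, 0])
        j -= int(steps[s, 1])
        nodes_i.append(i)
        nodes_j.append(j)
    nodes_i.reverse()
    nodes_j.reverse()
    t = np.asarray(q1.t, dtype=float)
    gamma = np.interp(t, t[nodes_i], t[nodes_j])
    gamma[0], gamma[-1] = 0.0, 1.0
    return WarpingFunction(t=t, gamma=gamma)


def phase_distance(gamma: WarpingFunction) -> float:
    """Arc-length phase distance of a warp from the identity, in radians.

    ``d = arccos( integral sqrt(gamma') )`` with the derivative by finite
    differences and trapezoidal quadrature; the arccos argument is clipped to
    [0, 1] to guard quadrature overshoot, so the result lies in [0, pi/2].
    Flat (degenerate) segments of gamma contribute zero.
    """
    dg = np.gradient(gamma.gamma, gamma.t)
    integrand = np.sqrt(np.clip(dg, 0.0, None))
    val = np.trapezoid(integrand, gamma.t)
    return float(np.arccos(np.clip(val, 0.0, 1.0)))


def elastic_phase_distance(f1: Curve, f2: Curve,
                           neighborhood_width: int = DEFAULT_NEIGHBORHOOD) -> float:
    """Symmetrized elastic phase distance between two curves, in radians.

    Averages the phase distance of aligning ``f2`` to ``f1`` and of aligning
    ``f1`` to ``f2``; the underlying dynamic program is directional and the
    average bounds its asymmetry, giving an exactly symmetric dissimilarity.
    """
    q1 = to_srsf(f1)
    q2 = to_srsf(f2)
    d12 = phase_distance(align_pair(q1, q2, neighborhood_width))
    d21 = phase_distance(align_pair(q2, q1, neighborhood_width))
    return 0.5 * (d12 + d21)


def pairwise_distance_matrix(grid, n_points: int = DEFAULT_N_POINTS,
                             neighborhood_width: int = DEFAULT_NEIGHBORHOOD,
                             z_normalize: bool = False) -> DistanceMatrix:
    """All pairwise symmetrized phase distances between the rows of a BMI grid.

    ``grid`` is a :class:`~bmiphase.preprocess.BMIGrid` (or any object with
    ``child_ids``, ``grid_ages`` and an ``n x 34`` ``values`` matrix).  The
    caller stratifies by sex; this function treats all rows as one set.
    ``z_normalize`` standardizes each curve to mean 0 / sd 1 first; off by
    default since phase distances are already amplitude-invariant.
    """
    values = np.asarray(grid.values, dtype=float)
    if z_normalize:
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=1, keepdims=True)) / sd
    ids = list(grid.child_ids)
    if values.shape[0] < 2:
        raise ValueError("need at least two trajectories")
    for cid, row in zip(ids, values):
        if not np.all(np.isfinite(row)):
            raise ValueError(f"non-finite BMI values for child {cid!r}")
    srsfs = [to_srsf(curve_from_grid(grid.grid_ages, row, n_points))
             for row in values]
    n = len(srsfs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d12 = phase_distance(align_pair(srsfs[i], srsfs[j], neighborhood_width))
            d21 = phase_distance(align_pair(srsfs[j], srsfs[i], neighborhood_width))
            D[i, j] = D[j, i] = 0.5 * (d12 + d21)
    return DistanceMatrix(ids=ids, D=D)


def align_to_reference(curves, ref: Curve,
                       neighborhood_width: int = DEFAULT_NEIGHBORHOOD):
    """Align each curve to a reference (e.g. a cluster medoid trajectory).

    Returns ``(aligned, warps)`` where ``aligned[k] = f_k o gamma_k*``
    evaluated on the shared mesh and ``gamma_k*`` is the optimal warp making
    ``f_k`` most similar to ``ref`` in the SRSF metric.
    """
    q_ref = to_srsf(ref)
    aligned = []
    warps = []
    for c in curves:
        if not np.array_equal(c.t, ref.t):
            raise ValueError("curves must share the reference mesh")
        g = align_pair(q_ref, to_srsf(c), neighborhood_width)
        f_warp = np.interp(g.gamma, c.t, c.f)
        aligned.append(Curve(t=c.t, f=f_warp))
        warps.append(g)
    return aligned, warps
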