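"""Linear stability of the mean-field fixed points and Hopf boundaries.

Everything here works in the reduced variables (j, delta, tau); see
:mod:`qiffre.fre_models` for the mapping to dimensional parameters.  The
fixed point satisfies

    0 = v*^2 - pi^2 r*^2 - j r* + 1,    v* = -delta / (2 pi r*),  s* = r*,

and perturbations grow as exp(lambda t~) with lambda a root of the
characteristic equation

    -2 j r* = (1 + lambda tau) [ (2 pi r*)^2 + (lambda - 2 v*)^2 ].

Setting lambda = i w and separating real and imaginary parts yields the
marginal-stability (Hopf) set; for fixed heterogeneity delta it is a
closed curve in the (j, tau) plane, parameterised by r*, which shrinks
with delta and vanishes at a critical delta_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "FixedPoint",
    "HopfCurve",
    "qif_fixed_point",
    "hfre_eigenvalues",
    "qif_characteristic_roots",
    "characteristic_residual",
    "qif_jacobian",
    "max_growth_rate",
    "identical_growth_rate",
    "hopf_curve",
    "tau_branches",
    "hopf_j_of_r",
    "delta_star",
    "critical_delta",
]

R_MAX_IDENTICAL = 1.0 / np.pi  # rate fixed point for j = 0, delta = 0


@dataclass(frozen=True)
class FixedPoint:
    """Nondimensional fixed point (r*, v*, s*) with s* = r*."""

    r_star: float
    v_star: float
    s_star: float

    def dimensional(self, tau_m: float, Theta: float):
        """Return (R*, V*, S*) in 1/ms and dimensionless volts."""
        rt = np.sqrt(Theta)
        return (rt * self.r_star / tau_m, rt * self.v_star, rt * self.s_star / tau_m)


def qif_fixed_point(j: float, delta: float) -> FixedPoint:
    """Unique positive-rate fixed point of the reduced mean-field equations.

    The residual of the fixed-point equation is driven below 1e-12.  For
    j = 0, delta = 0 the rate is maximal, r* = 1/pi; it decreases to 0 as
    j grows.
    """
    if j < 0 or delta < 0:
        raise ValueError("j and delta must be nonnegative")
    if delta == 0:
        r = (-j + np.sqrt(j * j + 4.0 * np.pi**2)) / (2.0 * np.pi**2)
        return FixedPoint(r, 0.0, r)

    def g(r):
        v = -delta / (2.0 * np.pi * r)
        return v * v - np.pi**2 * r * r - j * r + 1.0

    # g is strictly decreasing on r > 0 and spans +inf -> -inf
    hi = 1.0
    while g(hi) > 0:
        hi *= 2.0
    r = brentq(g, 1e-15, hi, xtol=1e-16, rtol=8.9e-16)
    v = -delta / (2.0 * np.pi * r)
    return FixedPoint(r, v, r)


# ---------------------------------------------------------------------------
# Heuristic model eigenvalues
# ---------------------------------------------------------------------------

def hfre_eigenvalues(p, phi_prime: float | None = None) -> np.ndarray:
    """Eigenvalue pair of the heuristic rate model at its fixed point.

    lambda = -alpha (1 +/- sqrt(1 - beta)) with
    alpha = (tau_m + tau_d) / (2 tau_m tau_d) and
    beta  = 4 tau_m tau_d (1 + J tau_m Phi') / (tau_m + tau_d)^2.

    Since Phi' > 0 for an increasing f-I curve, both eigenvalues have a
    strictly negative real part: the heuristic model cannot undergo a
    Hopf bifurcation (only damped oscillations, when beta > 1).
    """
    from .fre_models import fi_curve_prime, steady_state_rate

    if p.tau_d <= 0:
        raise ValueError("the heuristic model is first order for tau_d = 0; "
                         "no eigenvalue pair exists")
    if phi_prime is None:
        R = steady_state_rate(p)
        phi_prime = fi_curve_prime(-p.J * p.tau_m * R + p.Theta, p.Delta, p.tau_m)
    if phi_prime <= 0:
        raise ValueError("phi_prime must be positive (increasing f-I curve)")
    alpha = (p.tau_m + p.tau_d) / (2.0 * p.tau_m * p.tau_d)
    beta = 4.0 * p.tau_m * p.tau_d * (1.0 + p.J * p.tau_m * phi_prime) / (p.tau_m + p.tau_d) ** 2
    root = np.sqrt(complex(1.0 - beta))
    return np.array([-alpha * (1.0 + root), -alpha * (1.0 - root)])


# ---------------------------------------------------------------------------
# Characteristic equation of the exact model
# ---------------------------------------------------------------------------

def _char_coeffs(j: float, tau: float, fp: FixedPoint) -> np.ndarray:
    """Polynomial coefficients (highest power first) of the characteristic
    equation expanded in lambda; cubic for tau > 0, quadratic for tau = 0."""
    a = -2.0 * fp.v_star                    # = delta / (pi r*)
    b2 = (2.0 * np.pi * fp.r_star) ** 2
    c0 = a * a + b2 + 2.0 * j * fp.r_star
    if tau == 0:
        return np.array([1.0, 2.0 * a, c0])
    return np.array([tau, 1.0 + 2.0 * a * tau, 2.0 * a + tau * (a * a + b2), c0])


def qif_characteristic_roots(j: float, delta: float, tau: float,
                             fp: FixedPoint | None = None) -> np.ndarray:
    """Roots of the characteristic equation (companion-matrix eigenvalues).

    Three roots for tau > 0; for instantaneous synapses (tau = 0) the
    system is planar and the two roots are returned — they are always a
    complex-conjugate pair for j > 0 (the fixed point is a focus).
    """
    if fp is None:
        fp = qif_fixed_point(j, delta)
    roots = np.roots(_char_coeffs(j, tau, fp))
    return roots[np.argsort(roots.real)]


def characteristic_residual(lam: complex, j: float, tau: float, fp: FixedPoint) -> float:
    """|(1 + lambda tau)[(2 pi r*)^2 + (lambda - 2v*)^2] + 2 j r*|."""
    b2 = (2.0 * np.pi * fp.r_star) ** 2
    val = (1.0 + lam * tau) * (b2 + (lam - 2.0 * fp.v_star) ** 2) + 2.0 * j * fp.r_star
    return abs(val)


def qif_jacobian(j: float, delta: float, tau: float,
                 fp: FixedPoint | None = None) -> np.ndarray:
    """3x3 Jacobian of the reduced mean-field flow at the fixed point."""
    if tau <= 0:
        raise ValueError("the 3x3 Jacobian requires tau > 0")
    if fp is None:
        fp = qif_fixed_point(j, delta)
    r, v = fp.r_star, fp.v_star
    return np.array([
        [2.0 * v, 2.0 * r, 0.0],
        [-2.0 * np.pi**2 * r, 2.0 * v, -j],
        [1.0 / tau, 0.0, -1.0 / tau],
    ])


def max_growth_rate(j: float, delta: float, tau: float) -> float:
    """Largest real part over the characteristic roots; > 0 inside the
    oscillatory (unstable-focus) region, < 0 outside."""
    return float(np.max(qif_characteristic_roots(j, delta, tau).real))


def identical_growth_rate(J: float, tau_d: float, r_star: float, tau_m: float,
                          delta: float = 0.0) -> tuple[float, float]:
    """Near-critical growth rate and frequency for identical neurons.

    For delta = 0 a perturbative expansion of the characteristic equation
    about the neutral pair lambda = +/- 2 pi i R* gives, to first order in
    the coupling,

        nu ~ (J tau_d / tau_m) R* / (1 + (2 pi tau_d R*)^2)   (per ms),

    so the fixed point is unstable whenever J tau_d > 0 and restabilises
    on either axis.  On the J = 0 boundary the frequency is set entirely
    by the intrinsic rate, omega_c = 2 pi R*.  Returns (nu, omega).
    """
    if delta != 0:
        raise ValueError("identical-neuron expansion requires delta = 0")
    if r_star <= 0 or tau_m <= 0:
        raise ValueError("r_star and tau_m must be positive")
    nu = (J * tau_d / tau_m) * r_star / (1.0 + (2.0 * np.pi * tau_d * r_star) ** 2)
    omega = 2.0 * np.pi * r_star
    return nu, omega


# ---------------------------------------------------------------------------
# Hopf boundaries
# ---------------------------------------------------------------------------

def tau_branches(r_star: float, delta: float) -> tuple[float, float] | None:
    """The two marginal-stability values tau-(r*) <= tau+(r*), or None.

    Substituting lambda = i w into the characteristic equation and
    eliminating w yields a quadratic in tau,

        8 v (v^2 + pi^2 r^2) tau^2 + (1 - pi^2 r^2 - 7 v^2) tau + 2 v = 0,

    with v = -delta/(2 pi r).  Real positive roots exist only where the
    discriminant (pi^2 r^2 - 1)^2 - (14 + 50 pi^2 r^2) v^2 - 15 v^4 is
    nonnegative; None is returned otherwise (including the degenerate
    identical-neuron case v = 0, where the boundary collapses onto the
    axes).
    """
    if not 0.0 < r_star < R_MAX_IDENTICAL:
        raise ValueError("r_star must lie in (0, 1/pi)")
    if delta == 0:
        return None
    v = -delta / (2.0 * np.pi * r_star)
    p2r2 = np.pi**2 * r_star**2
    A = 1.0 - p2r2 - 7.0 * v * v
    D = A * A - 64.0 * v * v * (v * v + p2r2)
    if D < 0:
        return None
    den = 16.0 * v * (v * v + p2r2)
    t1 = (-A + np.sqrt(D)) / den
    t2 = (-A - np.sqrt(D)) / den
    lo, hi = (t1, t2) if t1 <= t2 else (t2, t1)
    if hi <= 0:
        return None
    return lo, hi


def hopf_j_of_r(r_star: float, delta: float) -> float:
    """Coupling on the marginal curve at parameter r*: j = (v*^2+1)/r* - pi^2 r*."""
    v = -delta / (2.0 * np.pi * r_star) if delta > 0 else 0.0
    return (v * v + 1.0) / r_star - np.pi**2 * r_star


@dataclass
class HopfCurve:
    """Marginal-stability locus in the (j, tau) plane at fixed delta.

    Sampled parametrically in r*; entries of ``tau_minus``/``tau_plus``
    are NaN where the branches are complex (outside the curve's r* range)
    and ``j`` is NaN where the marginal coupling would be negative.  For
    delta = 0 the curve degenerates onto the coordinate axes and the
    oscillatory region is the full open quadrant.
    """

    delta: float
    r_star: np.ndarray
    j: np.ndarray
    tau_minus: np.ndarray
    tau_plus: np.ndarray

    @property
    def is_empty(self) -> bool:
        """True when no marginal point exists (delta above critical)."""
        if self.delta == 0:
            return False
        return not np.any(np.isfinite(self.tau_plus) & np.isfinite(self.j))

    @property
    def closed(self) -> bool:
        """True when the curve is a closed loop (0 < delta < delta_c)."""
        return self.delta > 0 and not self.is_empty

    def encloses(self, j: float, tau: float) -> bool:
        """Whether (j, tau) lies inside the oscillatory region.

        Uses the marginal-curve construction directly: j(r*) is strictly
        decreasing, so the vertical line at ``j`` meets the curve at a
        unique r*, and the point is inside iff tau-(r*) < tau < tau+(r*).
        """
        if j <= 0 or tau <= 0:
            return False
        if self.delta == 0:
            return True
        if self.is_empty:
            return False
        lo, hi = 1e-12, R_MAX_IDENTICAL - 1e-12
        f = lambda r: hopf_j_of_r(r, self.delta) - j  # noqa: E731
        if f(hi) > 0:       # j below the curve's entire range
            return False
        r = brentq(f, lo, hi, xtol=1e-14)
        br = tau_branches(r, self.delta)
        if br is None:
            return False
        return br[0] < tau < br[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r_star": self.r_star, "j": self.j,
                             "tau_minus": self.tau_minus, "tau_plus": self.tau_plus})


def hopf_curve(delta: float, n: int = 2000) -> HopfCurve:
    """Sample the Hopf boundary at heterogeneity ``delta``.

    r* is sampled log-spaced over (0, 1/pi) with local refinement around
    the points where the square-root argument of the tau branches changes
    sign (the folds of the closed curve).
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    r = np.geomspace(1e-4, R_MAX_IDENTICAL - 1e-4, n)
    if delta > 0:
        # refine near the discriminant sign changes
        ok = np.array([tau_branches(ri, delta) is not None for ri in r])
        flips = np.nonzero(ok[1:] != ok[:-1])[0]
        extra = [np.linspace(r[i], r[i + 1], 50) for i in flips]
        if extra:
            r = np.unique(np.concatenate([r] + extra))
    jv = np.full(r.size, np.nan)
    tlo = np.full(r.size, np.nan)
    thi = np.full(r.size, np.nan)
    for i, ri in enumerate(r):
        jj = hopf_j_of_r(ri, delta)
        if jj < 0:
            continue
        jv[i] = jj
        if delta > 0:
            br = tau_branches(ri, delta)
            if br is not None:
                tlo[i], thi[i] = br
    return HopfCurve(delta, r, jv, tlo, thi)


# ---------------------------------------------------------------------------
# Critical heterogeneity
# ---------------------------------------------------------------------------

def delta_star(r_star: float) -> float:
    """Heterogeneity at which the two tau branches merge, as a function of r*.

    Obtained by setting the tau-branch discriminant to zero and solving
    for v^2 = delta^2/(2 pi r*)^2 (the unique positive real root of the
    resulting quadratic).  Vanishes at both ends of (0, 1/pi) — the
    minimal (j -> inf) and maximal (j = 0) identical-neuron rates — with
    a single interior maximum.
    """
    if not 0.0 < r_star < R_MAX_IDENTICAL:
        raise ValueError("r_star must lie in (0, 1/pi)")
    p2r2 = np.pi**2 * r_star**2
    P = 1.0 - p2r2
    c = 14.0 + 50.0 * p2r2
    u = (-c + np.sqrt(c * c + 60.0 * P * P)) / 30.0  # u = v^2 at merging
    return 2.0 * np.pi * r_star * np.sqrt(max(u, 0.0))


def critical_delta() -> tuple[float, float]:
    """(delta_c, r*_c): largest heterogeneity with any oscillatory region.

    delta_c = max over r* in (0, 1/pi) of delta*(r*); above it the Hopf
    curve is empty for every (j, tau).
    """
    res = minimize_scalar(lambda r: -delta_star(r),
                          bounds=(1e-9, R_MAX_IDENTICAL - 1e-9),
                          method="bounded", options={"xatol": 1e-12})
    return -res.fun, res.x
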