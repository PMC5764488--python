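"""Macroscopic firing-rate models for a recurrently coupled inhibitory population.

Three related descriptions of the same network are implemented:

* the exact mean-field equations for a heterogeneous quadratic
  integrate-and-fire (QIF) population with first-order synaptic kinetics,
  in terms of the population rate ``r``, mean membrane potential ``v``
  and synaptic activation ``s`` (the "QIF-FRE");
* the heuristic Wilson-Cowan-type rate equation driven by a static f-I
  curve (the "H-FRE"), which has no voltage channel;
* the slow-synapse reduction, a scalar flow for ``s`` with an algebraic
  rate readout, to which both models converge when the synaptic decay is
  much slower than the membrane time constant.

Units: time is in ms throughout; rates are carried internally in 1/ms so
that ``tau_m * R`` is dimensionless, and converted to Hz only for reports
and CSV output.  The mean voltage is dimensionless (normalised so that
positive values are suprathreshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "FREParams",
    "DimlessParams",
    "FREState",
    "ForcingSpec",
    "TimeSeries",
    "IntegrationError",
    "fi_curve",
    "fi_curve_prime",
    "qif_fre_rhs",
    "hfre_rhs",
    "slow_reduction_rhs",
    "slow_reduction_rate",
    "nondimensionalize",
    "dimensionalize",
    "dimless_qif_fre_rhs",
    "state_to_dimless",
    "state_from_dimless",
    "intrinsic_period",
    "intrinsic_frequency_hz",
    "forcing_theta",
    "integrate",
    "steady_state_rate",
    "fixed_point_state",
]

HZ_PER_INVMS = 1000.0


class IntegrationError(RuntimeError):
    """Raised when a trajectory leaves the finite domain."""


@dataclass(frozen=True)
class FREParams:
    """Dimensional parameters of the inhibitory population.

    tau_m : membrane time constant (ms), > 0
    tau_d : synaptic decay constant (ms), >= 0 (0 means instantaneous synapses)
    J     : inhibitory coupling strength (dimensionless, >= 0 for inhibition)
    Theta : center of the Lorentzian distribution of input currents
    Delta : half-width of the Lorentzian distribution, >= 0
    """

    tau_m: float
    tau_d: float
    J: float
    Theta: float
    Delta: float

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if self.tau_d < 0:
            raise ValueError(f"tau_d must be nonnegative, got {self.tau_d}")
        if self.Delta < 0:
            raise ValueError(f"Delta must be nonnegative, got {self.Delta}")

    def with_tau_d(self, tau_d: float) -> "FREParams":
        return replace(self, tau_d=tau_d)


@dataclass(frozen=True)
class DimlessParams:
    """Reduced parameter triple (j, delta, tau), valid for Theta > 0.

    j     = J / sqrt(Theta)        reduced coupling
    delta = Delta / Theta          reduced heterogeneity
    tau   = sqrt(Theta) tau_d/tau_m  synaptic constant relative to the
                                     intrinsic period (up to a factor pi)
    """

    j: float
    delta: float
    tau: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be nonnegative, got {self.delta}")
        if self.tau < 0:
            raise ValueError(f"tau must be nonnegative, got {self.tau}")


@dataclass(frozen=True)
class FREState:
    """Macroscopic state triple.

    r : population rate (1/ms internally; see :data:`HZ_PER_INVMS`)
    v : population mean membrane potential (dimensionless)
    s : synaptic activation (same units as r)
    """

    r: float
    v: float
    s: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.v, self.s], dtype=float)

    @staticmethod
    def from_array(y: Sequence[float]) -> "FREState":
        return FREState(float(y[0]), float(y[1]), float(y[2]))

    @staticmethod
    def from_hz(r_hz: float, v: float, s_hz: float) -> "FREState":
        return FREState(r_hz / HZ_PER_INVMS, v, s_hz / HZ_PER_INVMS)


@dataclass(frozen=True)
class ForcingSpec:
    """Time course of the external drive Theta(t).

    kind = "constant"        : Theta(t) = base
    kind = "sinusoid-cubed"  : Theta(t) = base + (1 + sin(2 pi t / period))**3
    """

    kind: str = "constant"
    base: float = 0.0
    period: float | None = None  # T_Theta in ms, required for non-constant

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid-cubed"):
            raise ValueError(f"unknown forcing kind {self.kind!r}")
        if self.kind != "constant":
            if self.period is None or self.period <= 0:
                raise ValueError("non-constant forcing requires period > 0")

    def __call__(self, t):
        return forcing_theta(t, self)


def forcing_theta(t, spec: ForcingSpec):
    """Evaluate the external drive Theta(t) for a forcing specification."""
    if spec.kind == "constant":
        return spec.base if np.isscalar(t) else np.full_like(np.asarray(t, float), spec.base)
    if spec.kind == "sinusoid-cubed":
        return spec.base + (1.0 + np.sin(2.0 * np.pi * np.asarray(t) / spec.period)) ** 3
    raise ValueError(f"unknown forcing kind {spec.kind!r}")


@dataclass
class TimeSeries:
    """Uniformly sampled macroscopic observables with provenance metadata.

    ``channels`` maps channel names (e.g. "r", "v", "s") to arrays of the
    same length as ``t``.  Rates are stored in 1/ms; :meth:`to_frame`
    converts rate-like channels to Hz for output.
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    RATE_CHANNELS = ("r", "s")

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or (self.t.size > 1 and not np.all(np.diff(self.t) > 0)):
            raise ValueError("times must be a strictly increasing 1-d array")
        for name, x in self.channels.items():
            x = np.asarray(x, dtype=float)
            if x.shape != self.t.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            self.channels[name] = x

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def after(self, t0: float) -> "TimeSeries":
        m = self.t >= t0
        return TimeSeries(self.t[m], {k: v[m] for k, v in self.channels.items()},
                          dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_ms": self.t}
        for name, x in self.channels.items():
            if name in self.RATE_CHANNELS:
                cols[f"{name}_hz"] = x * HZ_PER_INVMS
            else:
                cols[name] = x
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        """Write the series as CSV plus a JSON sidecar with full provenance."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(_jsonable(self.metadata), indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


# ---------------------------------------------------------------------------
# f-I curve
# ---------------------------------------------------------------------------

def fi_curve(I, Delta: float, tau_m: float):
    """Steady-state f-I curve of the heterogeneous QIF population (rate in 1/ms).

    Phi(I) = (1 / (pi tau_m)) * sqrt((I + sqrt(I^2 + Delta^2)) / 2)

    For Delta = 0 this reduces to the Class-1 "squashing function"
    sqrt(max(I, 0)) / (pi tau_m), with a hard threshold at I = 0; any
    Delta > 0 smooths the threshold away.
    """
    if tau_m <= 0:
        raise ValueError(f"tau_m must be positive, got {tau_m}")
    if Delta < 0:
        raise ValueError(f"Delta must be nonnegative, got {Delta}")
    I = np.asarray(I, dtype=float)
    if Delta == 0:
        out = np.sqrt(np.maximum(I, 0.0)) / (np.pi * tau_m)
    else:
        out = np.sqrt((I + np.hypot(I, Delta)) / 2.0) / (np.pi * tau_m)
    return out if out.ndim else float(out)


def fi_curve_prime(I, Delta: float, tau_m: float):
    """Derivative of :func:`fi_curve` with respect to the input current."""
    if tau_m <= 0:
        raise ValueError(f"tau_m must be positive, got {tau_m}")
    if Delta < 0:
        raise ValueError(f"Delta must be nonnegative, got {Delta}")
    I = np.asarray(I, dtype=float)
    if Delta == 0:
        with np.errstate(divide="ignore"):
            out = np.where(I > 0, 1.0 / (2.0 * np.pi * tau_m * np.sqrt(np.maximum(I, 1e-300))), 0.0)
    else:
        w = np.hypot(I, Delta)
        u = (I + w) / 2.0
        out = (1.0 + I / w) / (4.0 * np.pi * tau_m * np.sqrt(u))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Right-hand sides (dimensional)
# ---------------------------------------------------------------------------

def qif_fre_rhs(y, p: FREParams, theta: float) -> np.ndarray:
    """Exact mean-field flow (dr, dv, ds) at state y = (r, v, s).

    tau_m dr = Delta/(pi tau_m) + 2 r v
    tau_m dv = v^2 - (pi tau_m r)^2 - J tau_m s + theta
    tau_d ds = -s + r

    For instantaneous synapses (tau_d = 0) the synaptic activation is
    slaved to the rate, s == r, and the planar two-variable system is
    integrated instead (the s channel then just mirrors r).
    """
    r, v, s = float(y[0]), float(y[1]), float(y[2])
    if p.tau_d == 0:
        s = r
    dr = (p.Delta / (np.pi * p.tau_m) + 2.0 * r * v) / p.tau_m
    dv = (v * v - (np.pi * p.tau_m * r) ** 2 - p.J * p.tau_m * s + theta) / p.tau_m
    ds = dr if p.tau_d == 0 else (-s + r) / p.tau_d
    return np.array([dr, dv, ds])


def hfre_rhs(y, p: FREParams, theta: float,
             phi: Callable[[float], float] | None = None) -> np.ndarray:
    """Heuristic Wilson-Cowan-type flow (dR, dS) at state y = (R, S).

    tau_m dR = -R + Phi(-J tau_m S + theta)
    tau_d dS = -S + R

    ``phi`` defaults to the population f-I curve of :func:`fi_curve` with
    the heterogeneity of ``p``, which makes the steady state coincide with
    the exact mean-field fixed point.
    """
    if phi is None:
        phi = lambda I: fi_curve(I, p.Delta, p.tau_m)  # noqa: E731
    R, S = float(y[0]), float(y[1])
    dR = (-R + phi(-p.J * p.tau_m * S + theta)) / p.tau_m
    dS = (-S + R) / p.tau_d if p.tau_d > 0 else dR
    return np.array([dR, dS])


def slow_reduction_rhs(s, p: FREParams, theta: float) -> float:
    """Scalar slow-synapse flow: tau_d ds = -s + Phi(-J tau_m s + theta).

    Valid for tau_d >> tau_m and slowly varying drive; the rate readout is
    given by :func:`slow_reduction_rate`.
    """
    s = float(np.asarray(s).reshape(-1)[0])
    return (-s + fi_curve(-p.J * p.tau_m * s + theta, p.Delta, p.tau_m)) / p.tau_d


def slow_reduction_rate(s, p: FREParams, theta) -> np.ndarray:
    """Algebraic rate readout R*(s) = Phi(-J tau_m s + theta) of the reduction."""
    return fi_curve(-p.J * p.tau_m * np.asarray(s) + theta, p.Delta, p.tau_m)


# ---------------------------------------------------------------------------
# Nondimensionalization (valid for Theta > 0)
# ---------------------------------------------------------------------------

def nondimensionalize(p: FREParams) -> DimlessParams:
    """Map dimensional parameters onto the reduced triple (j, delta, tau).

    The change of variables (fixed by requiring that the reduced system is
    the exact image of the dimensional one) is::

        r = tau_m R / sqrt(Theta)   v = V / sqrt(Theta)   s = tau_m S / sqrt(Theta)
        t~ = sqrt(Theta) t / tau_m
        j = J / sqrt(Theta)         delta = Delta / Theta
        tau = sqrt(Theta) tau_d / tau_m
    """
    if p.Theta <= 0:
        raise ValueError("nondimensionalization is valid only for Theta > 0")
    rt = np.sqrt(p.Theta)
    return DimlessParams(j=p.J / rt, delta=p.Delta / p.Theta, tau=rt * p.tau_d / p.tau_m)


def dimensionalize(dp: DimlessParams, tau_m: float, Theta: float) -> FREParams:
    """Inverse of :func:`nondimensionalize` for a chosen (tau_m, Theta)."""
    if Theta <= 0:
        raise ValueError("Theta must be positive")
    rt = np.sqrt(Theta)
    return FREParams(tau_m=tau_m, tau_d=dp.tau * tau_m / rt, J=dp.j * rt,
                     Theta=Theta, Delta=dp.delta * Theta)


def state_to_dimless(y, p: FREParams) -> np.ndarray:
    """Map a dimensional state (r, v, s) onto the reduced variables."""
    rt = np.sqrt(p.Theta)
    y = np.asarray(y, dtype=float)
    return np.array([p.tau_m * y[..., 0] / rt, y[..., 1] / rt, p.tau_m * y[..., 2] / rt]).T


def state_from_dimless(y, p: FREParams) -> np.ndarray:
    rt = np.sqrt(p.Theta)
    y = np.asarray(y, dtype=float)
    return np.array([rt * y[..., 0] / p.tau_m, rt * y[..., 1], rt * y[..., 2] / p.tau_m]).T


def dimless_qif_fre_rhs(y, dp: DimlessParams) -> np.ndarray:
    """Reduced mean-field flow: dr = delta/pi + 2rv, dv = v^2 - pi^2 r^2 - j s + 1,
    tau ds = -s + r (with s slaved to r when tau = 0)."""
    r, v, s = float(y[0]), float(y[1]), float(y[2])
    if dp.tau == 0:
        s = r
    dr = dp.delta / np.pi + 2.0 * r * v
    dv = v * v - (np.pi * r) ** 2 - dp.j * s + 1.0
    ds = dr if dp.tau == 0 else (-s + r) / dp.tau
    return np.array([dr, dv, ds])


def intrinsic_period(tau_m: float, Theta: float) -> float:
    """Most-likely intrinsic period pi tau_m / sqrt(Theta) (ms), Theta > 0."""
    if Theta <= 0:
        raise ValueError("intrinsic period requires Theta > 0")
    return np.pi * tau_m / np.sqrt(Theta)


def intrinsic_frequency_hz(tau_m: float, Theta: float) -> float:
    """Most-likely intrinsic frequency in Hz."""
    return HZ_PER_INVMS / intrinsic_period(tau_m, Theta)


# ---------------------------------------------------------------------------
# Fixed points (dimensional)
# ---------------------------------------------------------------------------

def steady_state_rate(p: FREParams, theta: float | None = None) -> float:
    """Self-consistent rate R* = Phi(-J tau_m R* + Theta), in 1/ms.

    Unique because Phi is increasing while the recurrent input decreases
    with the rate (J >= 0).
    """
    th = p.Theta if theta is None else theta
    g = lambda R: R - fi_curve(-p.J * p.tau_m * R + th, p.Delta, p.tau_m)  # noqa: E731
    hi = fi_curve(abs(th) + p.Delta + 1.0, p.Delta, p.tau_m) + 1.0
    return brentq(g, 0.0 if p.Delta == 0 else 1e-300, hi, xtol=1e-15)


def fixed_point_state(p: FREParams, theta: float | None = None) -> FREState:
    """Full fixed point (R*, V*, S*) of the exact mean-field equations.

    V* = -Delta / (2 pi tau_m R*) and S* = R*; for Delta = 0 the voltage
    fixed point is V* = 0 when firing, -sqrt(-I) when quiescent.
    """
    th = p.Theta if theta is None else theta
    R = steady_state_rate(p, th)
    if p.Delta == 0 and R == 0:
        V = -np.sqrt(max(-(th), 0.0))
    elif p.Delta == 0:
        V = 0.0
    else:
        V = -p.Delta / (2.0 * np.pi * p.tau_m * R)
    return FREState(R, V, R)


# ---------------------------------------------------------------------------
# Generic fixed-step integrator
# ---------------------------------------------------------------------------

def integrate(rhs: Callable[[float, np.ndarray], np.ndarray],
              y0: Sequence[float],
              t_span: tuple[float, float],
              dt: float,
              channel_names: Sequence[str] = ("r", "v", "s"),
              sample_every: int = 1,
              metadata: dict | None = None) -> TimeSeries:
    """Integrate ``dy/dt = rhs(t, y)`` with the classical 4th-order scheme.

    Fixed step for bit-reproducible trajectories; the step and solver are
    recorded in the metadata.  Raises :class:`IntegrationError` (naming the
    time of failure) if the state leaves the finite domain.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t0, t1 = t_span
    n_steps = int(round((t1 - t0) / dt))
    y = np.asarray(y0, dtype=float).copy()
    if y.shape == ():
        y = y.reshape(1)
    n_out = n_steps // sample_every + 1
    ts = np.empty(n_out)
    ys = np.empty((n_out, y.size))
    ts[0], ys[0] = t0, y
    k = 1
    t = t0
    for step in range(1, n_steps + 1):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t0 + step * dt
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t = {t:.6g} ms")
        if step % sample_every == 0:
            ts[k], ys[k] = t, y
            k += 1
    meta = {"solver": "rk4", "dt": dt, "sample_every": sample_every}
    if metadata:
        meta.update(metadata)
    channels = {name: ys[:k, i].copy() for i, name in enumerate(channel_names[: y.size])}
    return TimeSeries(ts[:k], channels, meta)


def make_qif_fre_rhs(p: FREParams, forcing: ForcingSpec | None = None):
    """Closure ``rhs(t, y)`` for the exact mean-field equations under forcing.

    Time-varying drive enters only the voltage equation, as the center of
    the input-current distribution.
    """
    spec = forcing if forcing is not None else ForcingSpec("constant", p.Theta)
    return lambda t, y: qif_fre_rhs(y, p, forcing_theta(t, spec))


def make_hfre_rhs(p: FREParams, forcing: ForcingSpec | None = None,
                  phi: Callable[[float], float] | None = None):
    spec = forcing if forcing is not None else ForcingSpec("constant", p.Theta)
    return lambda t, y: hfre_rhs(y, p, forcing_theta(t, spec), phi)


def make_slow_reduction_rhs(p: FREParams, forcing: ForcingSpec | None = None):
    spec = forcing if forcing is not None else ForcingSpec("constant", p.Theta)
    return lambda t, y: np.array([slow_reduction_rhs(y[0], p, forcing_theta(t, spec))])


def make_dimless_rhs(dp: DimlessParams):
    return lambda t, y: dimless_qif_fre_rhs(y, dp)
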