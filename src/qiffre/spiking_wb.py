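"""Wang-Buzsaki conductance-based interneuron network.

Single-compartment Hodgkin-Huxley dynamics with spiking Na+/K+ currents
and a leak,

    C_m dV_i/dt = -I_Na,i - I_K,i - I_L,i - I_syn + I_app,i + I_0,

where I_Na = g_Na m_inf^3 h (V - E_Na) (instantaneous activation),
I_K = g_K n^4 (V - E_K), I_L = g_L (V - E_L), and h, n relax with the
voltage-dependent alpha/beta rates scaled by a common factor phi.  The
model is Class 1 excitable: spiking onset is a saddle-node on an
invariant circle (SNIC), so the offset I_0 can be chosen to sit each
neuron exactly at rheobase when I_app = 0.

Coupling is all-to-all through a single first-order gating variable,
tau_d dS/dt = -S + R, injected identically into every neuron as the
inhibitory current I_syn = k C_m S (k in mV; the C_m factor makes the
effect of a spike independent of the passive time constant).  Applied
currents I_app,i are drawn deterministically from a Lorentzian of center
I_bar and half-width sigma, the conductance-based analogue of the
quenched heterogeneity in :mod:`qiffre.spiking_qif`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .fre_models import TimeSeries
from .spiking_qif import Raster, lorentzian_grid

__all__ = [
    "WBParams",
    "WBState",
    "wb_rhs",
    "gating_steady_state",
    "simulate_wb_network",
    "snic_threshold",
    "single_wb_rate",
]


@dataclass(frozen=True)
class WBParams:
    """Conductances in mS/cm^2, potentials in mV, currents in uA/cm^2,
    capacitance in uF/cm^2, times in ms.  E_L = -65 mV gives the passive
    time constant tau_m = C_m/g_L = 10 ms of the original model."""

    C_m: float = 1.0
    g_L: float = 0.1
    E_L: float = -65.0
    g_Na: float = 35.0
    E_Na: float = 55.0
    g_K: float = 9.0
    E_K: float = -90.0
    phi: float = 5.0
    I0: float = 0.1601        # sets an isolated neuron at the SNIC when I_app = 0
    I_bar: float = 0.0        # Lorentzian center of applied currents
    sigma: float = 0.0        # Lorentzian half-width
    k: float = 0.0            # coupling strength (mV)
    tau_d: float = 5.0
    N: int = 1000
    dt: float = 0.001
    tau_s: float = 0.01       # rate-estimator window (ms)

    def __post_init__(self) -> None:
        for name in ("C_m", "g_L", "g_Na", "g_K"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dt <= 0 or self.tau_d < 0 or self.sigma < 0 or self.N < 1:
            raise ValueError("invalid dt, tau_d, sigma or N")

    def with_(self, **kw) -> "WBParams":
        return replace(self, **kw)


@dataclass
class WBState:
    """Per-neuron membrane state plus the shared synaptic activation."""

    V: np.ndarray
    h: np.ndarray
    n: np.ndarray
    S: float = 0.0


# -- voltage-dependent rates (1/ms); removable singularities handled ---------

@njit(cache=True, inline="always")
def _alpha_m(V):  # pragma: no cover
    x = V + 35.0
    if abs(x) < 1e-7:
        return 1.0
    return 0.1 * x / (1.0 - np.exp(-0.1 * x))


@njit(cache=True, inline="always")
def _beta_m(V):  # pragma: no cover
    return 4.0 * np.exp(-(V + 60.0) / 18.0)


@njit(cache=True, inline="always")
def _alpha_h(V):  # pragma: no cover
    return 0.07 * np.exp(-(V + 58.0) / 20.0)


@njit(cache=True, inline="always")
def _beta_h(V):  # pragma: no cover
    return 1.0 / (np.exp(-0.1 * (V + 28.0)) + 1.0)


@njit(cache=True, inline="always")
def _alpha_n(V):  # pragma: no cover
    x = V + 34.0
    if abs(x) < 1e-7:
        return 0.1
    return 0.01 * x / (1.0 - np.exp(-0.1 * x))


@njit(cache=True, inline="always")
def _beta_n(V):  # pragma: no cover
    return 0.125 * np.exp(-(V + 44.0) / 80.0)


@njit(cache=True, inline="always")
def _wb_derivs(V, h, n, I_ext, C_m, g_L, E_L, g_Na, E_Na, g_K, E_K, phi):  # pragma: no cover
    am = _alpha_m(V)
    m_inf = am / (am + _beta_m(V))
    I_Na = g_Na * m_inf * m_inf * m_inf * h * (V - E_Na)
    I_K = g_K * n * n * n * n * (V - E_K)
    I_L = g_L * (V - E_L)
    dV = (-I_Na - I_K - I_L + I_ext) / C_m
    dh = phi * (_alpha_h(V) * (1.0 - h) - _beta_h(V) * h)
    dn = phi * (_alpha_n(V) * (1.0 - n) - _beta_n(V) * n)
    return dV, dh, dn


def wb_rhs(state, p: WBParams, I_app=0.0, I_syn: float = 0.0):
    """Derivatives (dV, dh, dn) for scalars or arrays of V, h, n.

    ``I_app`` may be a scalar or a per-neuron array.  The rate functions
    are finite everywhere, including the removable singularities of
    alpha_m at V = -35 mV (limit 1) and alpha_n at V = -34 mV (limit 0.1).
    """
    V = np.atleast_1d(np.asarray(state.V if isinstance(state, WBState) else state[0], float))
    h = np.atleast_1d(np.asarray(state.h if isinstance(state, WBState) else state[1], float))
    n = np.atleast_1d(np.asarray(state.n if isinstance(state, WBState) else state[2], float))
    Ia = np.broadcast_to(np.asarray(I_app, float), V.shape)
    dV = np.empty_like(V)
    dh = np.empty_like(V)
    dn = np.empty_like(V)
    for i in range(V.size):
        dV[i], dh[i], dn[i] = _wb_derivs(
            V[i], h[i], n[i], Ia[i] + p.I0 - I_syn, p.C_m, p.g_L, p.E_L,
            p.g_Na, p.E_Na, p.g_K, p.E_K, p.phi)
    if np.isscalar(state) or (not isinstance(state, WBState) and np.ndim(state[0]) == 0):
        return float(dV[0]), float(dh[0]), float(dn[0])
    return dV, dh, dn


def gating_steady_state(V) -> tuple[np.ndarray, np.ndarray]:
    """Voltage-dependent steady states (h_inf, n_inf)."""
    V = np.atleast_1d(np.asarray(V, float))
    h = np.empty_like(V)
    n = np.empty_like(V)
    for i, v in enumerate(V):
        ah, bh = _alpha_h(v), _beta_h(v)
        an, bn = _alpha_n(v), _beta_n(v)
        h[i] = ah / (ah + bh)
        n[i] = an / (an + bn)
    return h, n


@njit(cache=True)
def _wb_net_loop(V, h, n, I_app, I0, C_m, g_L, E_L, g_Na, E_Na, g_K, E_K, phi,
                 k, tau_d, dt, n_steps, S0, sp_i, sp_t):  # pragma: no cover
    N = V.size
    counts = np.zeros(n_steps, dtype=np.int64)
    S_hist = np.empty(n_steps)
    Vm_hist = np.empty(n_steps)
    S = S0
    ns = 0
    cap = sp_i.size
    for step in range(n_steps):
        t = step * dt
        I_syn = k * C_m * S
        c = 0
        vsum = 0.0
        for i in range(N):
            Vold = V[i]
            dV, dh, dn = _wb_derivs(Vold, h[i], n[i], I_app[i] + I0 - I_syn,
                                    C_m, g_L, E_L, g_Na, E_Na, g_K, E_K, phi)
            Vn = Vold + dt * dV
            h[i] = h[i] + dt * dh
            n[i] = n[i] + dt * dn
            if Vold < 0.0 <= Vn:
                c += 1
                if ns < cap:
                    # linear interpolation of the upward 0 mV crossing
                    frac = -Vold / (Vn - Vold)
                    sp_i[ns] = i
                    sp_t[ns] = t + frac * dt
                    ns += 1
            V[i] = Vn
            vsum += Vn
        counts[step] = c
        R_inst = c / (N * dt)
        if tau_d > 0.0:
            S += dt * (-S + R_inst) / tau_d
        else:
            S = R_inst
        S_hist[step] = S
        Vm_hist[step] = vsum / N
    return counts, S_hist, Vm_hist, ns


def simulate_wb_network(p: WBParams, duration: float,
                        init: WBState | None = None,
                        init_voltage_center: float = -62.0,
                        init_voltage_halfwidth: float = 5.0,
                        sample_dt: float = 0.1,
                        smoothing_tau_s: float | None = None,
                        max_rate_hz: float = 500.0) -> tuple[TimeSeries, Raster, WBState]:
    """Euler simulation of the coupled network.

    Returns (TimeSeries with channels "v_mean", "r", "s"; Raster of
    interpolated 0 mV upward crossings; final WBState for continuation).
    By default the initial voltages form a deterministic Lorentzian grid
    (half-width 5 mV around -62 mV) and the gating variables start at
    their steady state for the initial voltage.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    I_app = lorentzian_grid(p.N, p.I_bar, p.sigma)
    if init is None:
        # heavy Lorentzian tails are unphysical for a membrane potential;
        # clip the deterministic grid to the reversal-potential range
        V = np.clip(lorentzian_grid(p.N, init_voltage_center, init_voltage_halfwidth),
                    p.E_K, p.E_Na)
        h, n = gating_steady_state(V)
        S0 = 0.0
    else:
        V, h, n, S0 = init.V.copy(), init.h.copy(), init.n.copy(), init.S
        if V.size != p.N:
            raise ValueError("init state size must equal N")

    n_steps = int(round(duration / p.dt))
    cap = max(10_000, int(p.N * duration * max_rate_hz / 1000.0))
    sp_i = np.empty(cap, dtype=np.int64)
    sp_t = np.empty(cap)
    counts, S_hist, Vm_hist, ns = _wb_net_loop(
        V, h, n, I_app, p.I0, p.C_m, p.g_L, p.E_L, p.g_Na, p.E_Na, p.g_K,
        p.E_K, p.phi, p.k, p.tau_d, p.dt, n_steps, S0, sp_i, sp_t)
    if not np.isfinite(Vm_hist[-1]):
        bad = int(np.argmax(~np.isfinite(Vm_hist)))
        raise RuntimeError(f"network diverged at t = {bad * p.dt:.4g} ms; reduce dt")
    truncated = ns >= cap
    raster = Raster(sp_i[:ns].copy(), sp_t[:ns].copy(), duration, p.N, truncated)

    tau_s = p.tau_s if smoothing_tau_s is None else smoothing_tau_s
    w = max(1, int(round(tau_s / p.dt)))
    csum = np.concatenate([[0], np.cumsum(counts)])
    window_counts = csum[w:] - csum[:-w]
    R = np.concatenate([csum[1:w] / (p.N * np.arange(1, w) * p.dt),
                        window_counts / (p.N * w * p.dt)])

    stride = max(1, int(round(sample_dt / p.dt)))
    idx = np.arange(stride - 1, n_steps, stride)
    t = (idx + 1) * p.dt
    ts = TimeSeries(t, {"v_mean": Vm_hist[idx], "r": R[idx], "s": S_hist[idx]},
                    {"model": "wb-network", "params": p, "solver": "euler",
                     "dt": p.dt, "tau_s": tau_s, "n_spikes": int(ns),
                     "truncated": truncated})
    return ts, raster, WBState(V, h, n, float(S_hist[-1]))


# ---------------------------------------------------------------------------
# Single-neuron probes and the SNIC threshold
# ---------------------------------------------------------------------------

@njit(cache=True)
def _wb_single_spike_count(I_const, C_m, g_L, E_L, g_Na, E_Na, g_K, E_K, phi,
                           dt, discard_steps, probe_steps, V0, h0, n0):  # pragma: no cover
    V, h, n = V0, h0, n0
    count = 0
    for step in range(discard_steps + probe_steps):
        dV, dh, dn = _wb_derivs(V, h, n, I_const, C_m, g_L, E_L, g_Na, E_Na,
                                g_K, E_K, phi)
        Vn = V + dt * dV
        h += dt * dh
        n += dt * dn
        if step >= discard_steps and V < 0.0 <= Vn:
            count += 1
        V = Vn
    return count


def _probe_spikes(p: WBParams, I_total: float, probe_ms: float,
                  discard_ms: float) -> int:
    V0 = p.E_L
    h0, n0 = gating_steady_state(V0)
    return _wb_single_spike_count(
        I_total, p.C_m, p.g_L, p.E_L, p.g_Na, p.E_Na, p.g_K, p.E_K, p.phi,
        p.dt, int(round(discard_ms / p.dt)), int(round(probe_ms / p.dt)),
        float(V0), float(h0[0]), float(n0[0]))


def single_wb_rate(p: WBParams, I_const: float, probe_ms: float = 2000.0,
                   discard_ms: float = 500.0) -> float:
    """Mean firing rate (Hz) of one isolated neuron under the constant
    current ``I_const`` (the I0 offset of ``p`` is NOT added)."""
    return 1000.0 * _probe_spikes(p, I_const, probe_ms, discard_ms) / probe_ms


def snic_threshold(p: WBParams | None = None,
                   bracket: tuple[float, float] = (0.0, 1.0),
                   tol: float = 1e-4,
                   probe_ms: float = 2000.0,
                   discard_ms: float = 500.0) -> float:
    """Rheobase of a single neuron by bisection on repetitive firing.

    The probe criterion is at least two spikes in a ``probe_ms`` window
    after an initial ``discard_ms`` discard (a single spike can be an
    onset transient).  The window is long compared to the arbitrarily
    slow firing near a SNIC, so the returned value is tolerance-limited.
    The I0 offset of ``p`` is ignored: the bisection variable is the
    total constant current.
    """
    p = WBParams(N=1) if p is None else p
    lo, hi = bracket
    if lo >= hi:
        raise ValueError("bracket must be an increasing interval")
    fires = lambda I: _probe_spikes(p, I, probe_ms, discard_ms) >= 2  # noqa: E731
    if fires(lo):
        raise ValueError(f"lower bracket endpoint {lo} already fires repetitively")
    if not fires(hi):
        raise ValueError(f"upper bracket endpoint {hi} does not fire")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
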