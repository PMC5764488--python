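"""Microscopic simulator of all-to-all inhibitory QIF networks.

N quadratic integrate-and-fire neurons, tau_m dV_i/dt = V_i^2 + eta_i
- J tau_m S, with quenched input currents eta_i drawn deterministically
from a Lorentzian (Cauchy) distribution of center Theta and half-width
Delta.  When V_i crosses the threshold +V_theta a spike is recorded, the
neuron is held for a refractory period 2 tau_m / V_theta, and re-enters
at the reset value -V_theta (approximating the up-and-down excursion
through infinity of the unbounded model).  All neurons share a single
synaptic gating variable, tau_d dS/dt = -S + R, driven by the
instantaneous population rate; the reported rate channel is a windowed
estimate over a trailing window tau_s.

The mean field of this network is described exactly (as N -> inf) by the
equations in :mod:`qiffre.fre_models`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .fre_models import FREState, TimeSeries

__all__ = [
    "QIFNetParams",
    "Raster",
    "lorentzian_grid",
    "single_qif_period",
    "estimate_rate",
    "simulate_qif_network",
    "initial_voltages_from_state",
]


@dataclass(frozen=True)
class QIFNetParams:
    """Network parameters.  Defaults follow the standard choices
    V_theta = 100, tau_s = 1e-2 tau_m and dt = 1e-3 tau_m."""

    N: int
    tau_m: float
    tau_d: float
    J: float
    Theta: float
    Delta: float
    V_theta: float = 100.0
    tau_s: float | None = None  # rate-estimator window (ms)
    dt: float | None = None     # Euler step (ms)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.tau_m <= 0 or self.Delta < 0 or self.tau_d < 0:
            raise ValueError("invalid time constants or heterogeneity")
        if self.V_theta < 10:
            warnings.warn("V_theta < 10: threshold/reset no longer approximates "
                          "the unbounded QIF spike", stacklevel=2)
        object.__setattr__(self, "tau_s",
                           1e-2 * self.tau_m if self.tau_s is None else self.tau_s)
        object.__setattr__(self, "dt",
                           1e-3 * self.tau_m if self.dt is None else self.dt)
        if not self.dt < self.tau_s:
            raise ValueError("dt must be smaller than the estimator window tau_s")

    @property
    def refractory(self) -> float:
        return 2.0 * self.tau_m / self.V_theta


@dataclass
class Raster:
    """Spike events as parallel arrays (neuron index, spike time in ms)."""

    neuron: np.ndarray
    time: np.ndarray
    duration: float
    N: int
    truncated: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.neuron = np.asarray(self.neuron, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=float)
        if self.time.size and (self.time.min() < 0 or self.time.max() > self.duration):
            raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return self.time.size

    def min_isi(self) -> float:
        """Smallest per-neuron inter-spike interval (inf if no neuron
        spiked twice); by construction >= the refractory period."""
        best = np.inf
        order = np.lexsort((self.time, self.neuron))
        nrn, t = self.neuron[order], self.time[order]
        same = nrn[1:] == nrn[:-1]
        if np.any(same):
            best = float(np.min(np.diff(t)[same]))
        return best

    def to_text(self, path) -> None:
        """Two-column whitespace text (neuron_index, t_ms)."""
        np.savetxt(path, np.column_stack([self.neuron, self.time]),
                   fmt=["%d", "%.6f"], header="neuron_index t_ms")


def lorentzian_grid(N: int, center: float, halfwidth: float) -> np.ndarray:
    """Deterministic quantile grid of a Lorentzian distribution.

    eta_i = center + halfwidth * tan(pi/2 * (2i - N - 1)/(N + 1)),
    i = 1..N: sorted, symmetric about the center, with the tan argument
    strictly inside (-pi/2, pi/2) so there are no poles.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if halfwidth < 0:
        raise ValueError("halfwidth must be nonnegative")
    i = np.arange(1, N + 1, dtype=float)
    return center + halfwidth * np.tan(0.5 * np.pi * (2.0 * i - N - 1.0) / (N + 1.0))


def single_qif_period(eta: float, tau_m: float, V_theta: float | None = None) -> float:
    """Firing period (ms) of an isolated suprathreshold QIF neuron.

    The transit time from -V_theta to +V_theta under tau_m dV = V^2 + eta
    is (2 tau_m / sqrt(eta)) arctan(V_theta / sqrt(eta)); the period adds
    the refractory hold 2 tau_m / V_theta.  With V_theta -> inf this
    converges to pi tau_m / sqrt(eta).
    """
    if eta <= 0:
        raise ValueError("no periodic firing for eta <= 0 (excitable regime)")
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    root = np.sqrt(eta)
    if V_theta is None or np.isinf(V_theta):
        return np.pi * tau_m / root
    return 2.0 * tau_m / root * np.arctan(V_theta / root) + 2.0 * tau_m / V_theta


def estimate_rate(raster: Raster, tau_s: float, t_grid: np.ndarray) -> np.ndarray:
    """Windowed population-rate estimate, in 1/ms.

    At each grid time t the rate is the number of spikes in the trailing
    window (t - tau_s, t] divided by N tau_s — the finite-window version
    of the delta-comb population rate.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    if raster.n_spikes == 0:
        return np.zeros_like(t_grid)
    t = np.sort(raster.time)
    hi = np.searchsorted(t, t_grid, side="right")
    lo = np.searchsorted(t, t_grid - tau_s, side="right")
    return (hi - lo) / (raster.N * tau_s)


def initial_voltages_from_state(p: QIFNetParams, state: FREState) -> np.ndarray:
    """Deterministic voltage grid consistent with a macroscopic state.

    In the mean-field manifold the voltage density is Lorentzian with
    center v and half-width pi tau_m r, so the network is initialised on
    the corresponding quantile grid (clipped to the reset/threshold range).
    """
    width = np.pi * p.tau_m * max(state.r, 0.0)
    v = lorentzian_grid(p.N, state.v, width)
    return np.clip(v, -p.V_theta, p.V_theta)


@njit(cache=True)
def _qif_loop(V, eta, J, tau_m, tau_d, V_th, dt, n_steps, S0, sp_i, sp_t):  # pragma: no cover
    N = V.size
    t_ref = 2.0 * tau_m / V_th
    refr = np.zeros(N)
    counts = np.zeros(n_steps, dtype=np.int64)
    S_hist = np.empty(n_steps)
    Vm_hist = np.empty(n_steps)
    S = S0
    ns = 0
    max_spikes = sp_i.size
    for step in range(n_steps):
        t = step * dt
        Isyn = J * tau_m * S
        c = 0
        vsum = 0.0
        nact = 0
        for i in range(N):
            if refr[i] > 0.0:
                refr[i] -= dt
                if refr[i] <= 0.0:
                    refr[i] = 0.0
                    V[i] = -V_th
            else:
                Vn = V[i] + dt * (V[i] * V[i] + eta[i] - Isyn) / tau_m
                if Vn >= V_th:
                    c += 1
                    if ns < max_spikes:
                        sp_i[ns] = i
                        sp_t[ns] = t + dt
                        ns += 1
                    refr[i] = t_ref
                    V[i] = V_th
                else:
                    V[i] = Vn
                    vsum += Vn
                    nact += 1
        counts[step] = c
        R_inst = c / (N * dt)
        if tau_d > 0.0:
            S += dt * (-S + R_inst) / tau_d
        else:
            S = R_inst
        S_hist[step] = S
        Vm_hist[step] = vsum / nact if nact > 0 else 0.0
    return counts, S_hist, Vm_hist, ns


def simulate_qif_network(p: QIFNetParams, duration: float,
                         init_voltages: np.ndarray | None = None,
                         init_state: FREState | None = None,
                         s0: float | None = None,
                         sample_dt: float | None = None,
                         smoothing_tau_s: float | None = None,
                         record_v: bool = False,
                         spike_time: str = "crossing",
                         return_final_state: bool = False,
                         max_rate_hz: float = 1000.0):
    """Euler simulation of the full network; returns (TimeSeries, Raster).

    Channels: "r" (windowed rate estimate, 1/ms), "s" (shared gating
    variable), and optionally "v_mean" (mean voltage over non-refractory
    neurons — refractory neurons are excluded because their frozen
    +/- V_theta values would dominate the average).

    ``init_voltages`` overrides the default deterministic Lorentzian grid
    built from ``init_state``; ``smoothing_tau_s`` widens the estimator
    window for display-quality rate traces (e.g. 3e-2 tau_m) without
    touching the gating dynamics, which are always driven by the
    instantaneous per-step rate.

    ``spike_time`` selects the raster timestamp convention: "crossing"
    (default) logs the step at which V reaches +V_theta; "peak" adds the
    residual transit time tau_m/V_theta to approximate the passage of
    the unbounded trajectory through infinity.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if spike_time not in ("crossing", "peak"):
        raise ValueError("spike_time must be 'crossing' or 'peak'")
    eta = lorentzian_grid(p.N, p.Theta, p.Delta)
    if init_voltages is None:
        if init_state is None:
            init_state = FREState(0.0, -1.0, 0.0)
        V = initial_voltages_from_state(p, init_state)
        if s0 is None:
            s0 = init_state.s
    else:
        V = np.asarray(init_voltages, dtype=float).copy()
        if V.size != p.N:
            raise ValueError("init_voltages length must equal N")
    s0 = 0.0 if s0 is None else float(s0)

    n_steps = int(round(duration / p.dt))
    cap = max(10_000, int(p.N * duration * max_rate_hz / 1000.0))
    sp_i = np.empty(cap, dtype=np.int64)
    sp_t = np.empty(cap)
    counts, S_hist, Vm_hist, ns = _qif_loop(
        V, eta, p.J, p.tau_m, p.tau_d, p.V_theta, p.dt, n_steps, s0, sp_i, sp_t)
    if not np.isfinite(S_hist[-1]):
        bad = int(np.argmax(~np.isfinite(S_hist)))
        raise RuntimeError(f"network state diverged at t = {bad * p.dt:.4g} ms; "
                           "reduce dt")
    truncated = ns >= cap
    times = sp_t[:ns].copy()
    if spike_time == "peak":
        times = np.minimum(times + p.tau_m / p.V_theta, duration)
    raster = Raster(sp_i[:ns].copy(), times, duration, p.N, truncated)

    # trailing-window rate estimate from per-step spike counts
    tau_s = p.tau_s if smoothing_tau_s is None else smoothing_tau_s
    w = max(1, int(round(tau_s / p.dt)))
    csum = np.concatenate([[0], np.cumsum(counts)])
    window_counts = csum[w:] - csum[:-w]          # counts in (t-w*dt, t]
    R = np.concatenate([csum[1:w] / (p.N * np.arange(1, w) * p.dt),
                        window_counts / (p.N * w * p.dt)])

    stride = max(1, int(round((sample_dt or p.tau_s) / p.dt)))
    idx = np.arange(stride - 1, n_steps, stride)
    t = (idx + 1) * p.dt
    channels = {"r": R[idx], "s": S_hist[idx]}
    if record_v:
        channels["v_mean"] = Vm_hist[idx]
    meta = {"model": "qif-network", "params": p, "solver": "euler", "dt": p.dt,
            "tau_s": tau_s, "n_spikes": int(ns), "truncated": truncated}
    ts = TimeSeries(t, channels, meta)
    if return_final_state:
        # V was advanced in place by the kernel (refractory phase dropped)
        return ts, raster, (V, float(S_hist[-1]))
    return ts, raster
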