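"""Figure-level experiments: amplitude/frequency measurement, phase-diagram
sweeps, and cross-model comparison runs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from . import fre_models as fm
from .fre_models import (FREParams, FREState, ForcingSpec, TimeSeries,
                         fixed_point_state, integrate)

__all__ = [
    "PhaseDiagram",
    "oscillation_amplitude",
    "oscillation_frequency",
    "trailing_mean",
    "phase_diagram_sweep",
    "wb_sweep_simulator",
    "qif_net_sweep_simulator",
    "run_model",
    "compare_models",
    "relative_l2",
]


# ---------------------------------------------------------------------------
# Scalar measurements
# ---------------------------------------------------------------------------

def _pick_channel(series, channel):
    if isinstance(series, TimeSeries):
        return series.t, series.channel(channel)
    t, x = series
    return np.asarray(t, float), np.asarray(x, float)


def trailing_mean(t: np.ndarray, x: np.ndarray, window: float) -> np.ndarray:
    """Causal moving average over a trailing window (ms).

    Mirrors the windowed spike-count rate estimator of the network
    simulators, so that a smooth model trajectory can be compared with a
    network rate estimate through an identical filter.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    dt = t[1] - t[0]
    n = max(1, int(round(window / dt)))
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty_like(x)
    out[n - 1:] = (c[n:] - c[:-n]) / n
    for i in range(min(n - 1, x.size)):
        out[i] = c[i + 1] / (i + 1)
    return out


def oscillation_amplitude(series, channel: str = "v_mean",
                          transient: float = 1000.0, window: float = 200.0,
                          n_windows: int = 5) -> float:
    """Mean over consecutive windows of the in-window max - min.

    The default protocol discards a 1000 ms transient and averages the
    maximal excursion over five 200 ms windows; a constant channel gives
    0 and a fast sinusoid of amplitude a gives 2a.
    """
    t, x = _pick_channel(series, channel)
    needed = transient + n_windows * window
    slack = (t[1] - t[0]) if t.size > 1 else 0.0  # one sample of rounding slack
    if t[-1] - t[0] < needed - slack - 1e-9:
        raise ValueError(f"series of duration {t[-1] - t[0]:.6g} ms too short for "
                         f"transient {transient} + {n_windows} x {window} ms windows")
    t0 = t[0] + transient
    amps = []
    for i in range(n_windows):
        m = (t >= t0 + i * window) & (t < t0 + (i + 1) * window)
        xi = x[m]
        amps.append(float(xi.max() - xi.min()))
    return float(np.mean(amps))


def oscillation_frequency(series, channel: str = "r", transient: float = 0.0,
                          prominence_frac: float = 0.05) -> float:
    """Dominant frequency (Hz) from mean inter-peak intervals.

    Peaks must exceed a prominence floor of ``prominence_frac`` times the
    post-transient range of the channel, which rejects finite-size ripple
    in network rate estimates; returns 0 if fewer than two peaks survive.
    """
    t, x = _pick_channel(series, channel)
    m = t >= t[0] + transient
    t, x = t[m], x[m]
    rng = float(x.max() - x.min())
    if rng <= 0:
        return 0.0
    peaks, _ = find_peaks(x, prominence=prominence_frac * rng)
    if peaks.size < 2:
        return 0.0
    return 1000.0 / float(np.mean(np.diff(t[peaks])))


# ---------------------------------------------------------------------------
# Phase-diagram sweeps
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    """Gridded oscillation amplitude over (tau_d, k), one sweep direction."""

    delta: float
    tau_d_grid: np.ndarray
    k_grid: np.ndarray
    amplitude: np.ndarray          # shape (len(tau_d_grid), len(k_grid))
    direction: str = "increasing"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau_d_grid = np.asarray(self.tau_d_grid, float)
        self.k_grid = np.asarray(self.k_grid, float)
        self.amplitude = np.asarray(self.amplitude, float)
        for g in (self.tau_d_grid, self.k_grid):
            if g.size and np.any(np.diff(g) <= 0):
                raise ValueError("grid axes must be strictly increasing")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be nonnegative")

    def oscillatory_cells(self, threshold: float) -> int:
        return int(np.sum(self.amplitude > threshold))

    def to_csv(self, path) -> None:
        import json
        import pandas as pd
        from pathlib import Path

        path = Path(path)
        pd.DataFrame(self.amplitude, index=self.tau_d_grid,
                     columns=self.k_grid).to_csv(path)
        meta = {"delta": self.delta, "direction": self.direction,
                "tau_d_grid": list(self.tau_d_grid), "k_grid": list(self.k_grid)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def phase_diagram_sweep(simulate: Callable,
                        tau_d_grid: Sequence[float],
                        k_grid: Sequence[float],
                        direction: str = "increasing",
                        delta: float = 0.0,
                        transient: float = 1000.0,
                        window: float = 200.0,
                        n_windows: int = 5,
                        channel: str = "v_mean") -> PhaseDiagram:
    """Amplitude map over a (tau_d, k) grid with continuation in k.

    ``simulate(tau_d, k, init)`` must return ``(TimeSeries, final_state)``;
    within each tau_d row the coupling is swept in the requested
    direction and the final state of one run seeds the next, mimicking a
    slow experimental parameter ramp (this is what exposes hysteresis if
    the network is bistable).
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    tau_d_grid = np.asarray(tau_d_grid, float)
    k_grid = np.asarray(k_grid, float)
    if tau_d_grid.size == 0 or k_grid.size == 0:
        raise ValueError("grids must be nonempty")
    order = range(k_grid.size) if direction == "increasing" else range(k_grid.size - 1, -1, -1)
    amp = np.zeros((tau_d_grid.size, k_grid.size))
    for a, tau_d in enumerate(tau_d_grid):
        state = None
        for b in order:
            try:
                ts, state = simulate(tau_d, k_grid[b], state)
            except Exception as err:  # annotate with the grid cell
                raise RuntimeError(
                    f"simulator failed at tau_d={tau_d}, k={k_grid[b]}") from err
            amp[a, b] = oscillation_amplitude(ts, channel, transient, window, n_windows)
    return PhaseDiagram(delta, tau_d_grid, k_grid, amp, direction)


def wb_sweep_simulator(base, duration: float, sample_dt: float = 0.1,
                       smoothing_tau_s: float | None = 2.0):
    """Adapter: Wang-Buzsaki network as a ``simulate(tau_d, k, init)`` callable."""
    from .spiking_wb import simulate_wb_network

    def simulate(tau_d, k, init):
        p = base.with_(tau_d=float(tau_d), k=float(k))
        ts, _, final = simulate_wb_network(p, duration, init=init,
                                           sample_dt=sample_dt,
                                           smoothing_tau_s=smoothing_tau_s)
        return ts, final
    return simulate


def qif_net_sweep_simulator(base, duration: float, sample_dt: float | None = None,
                            smoothing_tau_s: float = 2.0):
    """Adapter: QIF network swept in (tau_d, J) through the same interface
    (the 'k' axis is the coupling J).  Continuation passes the final
    voltages and gating value on to the next coupling value."""
    from dataclasses import replace

    from .spiking_qif import simulate_qif_network

    def simulate(tau_d, J, init):
        p = replace(base, tau_d=float(tau_d), J=float(J))
        kw = {"init_voltages": init[0], "s0": init[1]} if init is not None else \
             {"init_state": FREState.from_hz(5.0, 0.0, 5.0)}
        ts, _, final = simulate_qif_network(p, duration, sample_dt=sample_dt,
                                            smoothing_tau_s=smoothing_tau_s,
                                            record_v=True,
                                            return_final_state=True, **kw)
        return ts, final
    return simulate


# ---------------------------------------------------------------------------
# Cross-model comparison
# ---------------------------------------------------------------------------

MODEL_NAMES = ("qif-fre", "h-fre", "slow-reduction", "qif-network")


def run_model(name: str, p: FREParams, forcing: ForcingSpec, duration: float,
              dt: float | None = None, init: FREState | None = None,
              network_params=None, sample_dt: float | None = None) -> TimeSeries:
    """Integrate one of the model variants under a common drive.

    All variants report "r" and "s" channels in 1/ms on their own grids;
    by default they start from the fixed point for the drive at t = 0.
    """
    dt = p.tau_m / 100.0 if dt is None else dt
    theta0 = fm.forcing_theta(0.0, forcing)
    if init is None:
        init = fixed_point_state(p, theta0)
    meta = {"model": name, "params": p, "forcing": forcing}
    if name == "qif-fre":
        ts = integrate(fm.make_qif_fre_rhs(p, forcing), init.as_array(),
                       (0.0, duration), dt, ("r", "v", "s"), metadata=meta)
    elif name == "h-fre":
        ts = integrate(fm.make_hfre_rhs(p, forcing), np.array([init.r, init.s]),
                       (0.0, duration), dt, ("r", "s"), metadata=meta)
    elif name == "slow-reduction":
        ts = integrate(fm.make_slow_reduction_rhs(p, forcing), np.array([init.s]),
                       (0.0, duration), dt, ("s",), metadata=meta)
        theta_t = fm.forcing_theta(ts.t, forcing)
        ts.channels["r"] = fm.slow_reduction_rate(ts.channel("s"), p, theta_t)
    elif name == "qif-network":
        from .spiking_qif import QIFNetParams, simulate_qif_network

        if network_params is None:
            network_params = {"N": 5000}
        np_ = QIFNetParams(tau_m=p.tau_m, tau_d=p.tau_d, J=p.J, Theta=p.Theta,
                           Delta=p.Delta, **network_params)
        ts, _ = simulate_qif_network(np_, duration, init_state=init,
                                     sample_dt=sample_dt,
                                     smoothing_tau_s=3e-2 * p.tau_m)
    else:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    return ts


def relative_l2(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric relative L2 distance ||a - b|| / (0.5 (||a|| + ||b||))."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na + nb == 0:
        return 0.0
    return float(np.linalg.norm(a - b) / (0.5 * (na + nb)))


def compare_models(p: FREParams, forcing: ForcingSpec,
                   models: Iterable[str] = ("qif-fre", "h-fre", "slow-reduction"),
                   duration: float = 2000.0, transient: float = 500.0,
                   dt: float | None = None, init: FREState | None = None,
                   network_params=None,
                   channels: Sequence[str] = ("r", "s")) -> dict:
    """Run several model variants under identical drive and compare them.

    Returns ``{"series": {name: TimeSeries}, "distance": {(a, b): {channel:
    rel-L2}}}`` with distances computed on a common post-transient grid
    (all series are linearly interpolated onto the coarsest grid).
    """
    models = list(models)
    series = {name: run_model(name, p, forcing, duration, dt=dt, init=init,
                              network_params=network_params)
              for name in models}
    # common post-transient grid: the coarsest of the model grids
    ref = max(series.values(), key=lambda ts: ts.dt)
    grid = ref.t[ref.t >= transient]
    interp = {
        name: {c: np.interp(grid, ts.t, ts.channel(c)) for c in channels}
        for name, ts in series.items()
    }
    dist = {}
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            dist[(a, b)] = {c: relative_l2(interp[a][c], interp[b][c])
                            for c in channels}
    return {"series": series, "distance": dist, "grid": grid}
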