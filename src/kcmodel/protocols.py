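"""Model-level experiments: passive-property fitting, F-I / rheobase
analysis, model spike detection and the uniform-NaChBac conductance sweep.

The passive fit follows the estimation style of statsmodels: a
:class:`PassiveFit` model object is built from a morphology (or
pre-discretized segments) plus observed hyperpolarizing current-clamp
sweeps, and ``fit()`` returns a :class:`PassiveFitResult` carrying the
estimates, per-sweep errors, convergence diagnostics and a ``summary()``
table.

Baseline handling: the mean of the first 200 ms of every observed sweep
is subtracted (compensating resting-potential variability), which makes
the subtracted response of a linear passive membrane independent of the
reversal potential.  E_rev is therefore estimated directly from the raw
pre-step baseline (the resting potential at zero holding current) while
Cm, g_leak and Ra are found by bound-constrained least squares on the
subtracted traces, all sweeps fitted simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .ephys import AnalysisError, SweepSet, detect_spikes
from .morphology import Morphology, PassiveParams, discretize
from .simulator import (ClampProtocol, CompartmentalModel, ElectrodeSpec,
                        SimTrace)

#: published plausibility bounds for the passive parameters
RA_BOUNDS = (30.0, 400.0)  # Ohm*cm
CM_BOUNDS = (0.6, 2.6)  # uF/cm^2
GLEAK_BOUNDS = (1e-6, 1e-2)  # S/cm^2


# ---------------------------------------------------------------------------
# model spike detection / F-I


def detect_spikes_model(trace: SimTrace, amplitude_threshold: float = 1.0) -> np.ndarray:
    """Spike times from a simulated voltage trace.

    Local maxima whose prominence above the surrounding trace exceeds
    the threshold (default 1 mV) count as spikes; the relative
    (prominence) criterion excludes slow plateau transients such as the
    early NaChBac surge from being scored by absolute height.
    """
    if np.any(~np.isfinite(trace.v)):
        raise AnalysisError("non-finite voltage trace")
    return detect_spikes(trace.v, trace.t, amplitude_threshold)


@dataclass
class FICurve:
    """Spike counts and firing frequencies per current step."""

    currents_pa: np.ndarray
    counts: np.ndarray
    frequencies_hz: np.ndarray
    rheobase_pa: float | None

    def __post_init__(self):
        if np.any(np.diff(self.currents_pa) <= 0):
            raise ValueError("currents must be strictly increasing")

    def total_spikes(self) -> int:
        return int(self.counts.sum())


def fi_curve(
    model: CompartmentalModel, protocol: ClampProtocol,
    amplitude_threshold: float = 1.0,
) -> FICurve:
    """F-I curve: per-step spike count within the step window.

    Firing frequency is spikes during the step divided by the step
    duration; rheobase is the smallest step current eliciting at least
    one spike (searched on the protocol's own grid only).
    """
    if protocol.mode != "current":
        raise AnalysisError("F-I curve needs a current-clamp protocol")
    traces = model.run_current_clamp(protocol)
    currents = np.asarray(protocol.steps, float)
    counts = np.zeros(len(currents), dtype=int)
    for k, tr in enumerate(traces):
        st = detect_spikes_model(tr, amplitude_threshold)
        counts[k] = int(((st >= protocol.onset) & (st < protocol.offset)).sum())
    dur_s = (protocol.offset - protocol.onset) / 1e3
    fired = np.flatnonzero(counts > 0)
    rheo = float(currents[fired[0]]) if len(fired) else None
    return FICurve(currents_pa=currents, counts=counts,
                   frequencies_hz=counts / dur_s, rheobase_pa=rheo)


@dataclass
class NachbacSweepResult:
    """Total spiking vs uniform NaChBac density.

    ``crossing_ms_cm2`` is the smallest grid density at which total
    spikes fall below the zero-NaChBac model's total; ``boosted`` marks
    grid points whose total meets or exceeds the unperturbed total (the
    low-conductance excitability increase).
    """

    conductances_ms_cm2: np.ndarray
    totals: np.ndarray
    baseline_total: int
    fi_curves: list
    crossing_ms_cm2: float | None
    boosted: np.ndarray


def nachbac_sweep(
    model: CompartmentalModel, conductances, protocol: ClampProtocol,
    amplitude_threshold: float = 1.0,
) -> NachbacSweepResult:
    """Apply a uniform NaChBac density over the whole morphology per grid point."""
    conductances = np.asarray(conductances, float)
    if conductances.size == 0:
        raise AnalysisError("empty conductance grid")
    base_model = model.with_uniform_gbar("NaChBac", 0.0)
    base = fi_curve(base_model, protocol, amplitude_threshold)
    fis = []
    totals = np.zeros(len(conductances), dtype=int)
    for k, g in enumerate(conductances):
        fic = fi_curve(model.with_uniform_gbar("NaChBac", float(g)), protocol,
                       amplitude_threshold)
        fis.append(fic)
        totals[k] = fic.total_spikes()
    below = np.flatnonzero(totals < base.total_spikes())
    crossing = float(conductances[below[0]]) if len(below) else None
    return NachbacSweepResult(
        conductances_ms_cm2=conductances, totals=totals,
        baseline_total=base.total_spikes(), fi_curves=fis,
        crossing_ms_cm2=crossing, boosted=totals >= base.total_spikes(),
    )


# ---------------------------------------------------------------------------
# passive fitting


@dataclass
class PassiveFitResult:
    """Estimates and diagnostics from :meth:`PassiveFit.fit`."""

    params: PassiveParams
    sweep_sse: np.ndarray  # summed squared error per sweep (mV^2)
    converged: bool
    bounds: dict
    n_function_evals: int
    message: str = ""
    start_params: tuple = ()

    def summary(self) -> str:
        p = self.params
        lines = [
            "Passive-property fit",
            "=" * 44,
            f"{'Cm':12s} {p.Cm:12.4f}  uF/cm^2   bounds {self.bounds['Cm']}",
            f"{'g_leak':12s} {p.g_leak:12.3e}  S/cm^2    bounds {self.bounds['g_leak']}",
            f"{'Ra':12s} {p.Ra:12.2f}  Ohm*cm    bounds {self.bounds['Ra']}",
            f"{'E_rev':12s} {p.E_rev:12.2f}  mV        (from pre-step baseline)",
            "-" * 44,
            f"{'converged':12s} {self.converged}",
            f"{'total SSE':12s} {self.sweep_sse.sum():12.4f}  mV^2",
            f"{'n evals':12s} {self.n_function_evals}",
        ]
        return "\n".join(lines)


class PassiveFit:
    """Fit Cm, g_leak, Ra (and baseline E_rev) to hyperpolarizing sweeps.

    Parameters
    ----------
    morphology : Morphology
        Cell skeleton; discretized once with reference passive values
        so the segmentation stays fixed across optimizer iterations.
    sweeps : SweepSet
        Observed current-clamp sweeps; every step must be negative.
    electrode : ElectrodeSpec or None
        Electrode section included in the simulated responses.
    baseline_ms : float
        Length of the initial window whose mean is subtracted.
    sim_dt : float
        Integration step used inside the objective (ms).  The default
        matches the simulator's acquisition step; a coarser step biases
        the weakly identified Ra through its tiny systematic shape error.
    """

    def __init__(
        self, morphology: Morphology, sweeps: SweepSet,
        electrode: ElectrodeSpec | None = None, baseline_ms: float = 200.0,
        sim_dt: float = 0.025, max_fraction: float = 0.1,
    ):
        if sweeps.mode != "current":
            raise AnalysisError("passive fitting needs current-clamp sweeps")
        if np.any(sweeps.step_values >= 0):
            raise AnalysisError("all steps must be hyperpolarizing (negative)")
        if sweeps.onset < baseline_ms:
            raise AnalysisError("baseline window must precede the step onset")
        self.sweeps = sweeps
        self.electrode = electrode
        self.baseline_ms = baseline_ms
        self.sim_dt = sim_dt
        self.segments = discretize(morphology, PassiveParams(), max_fraction)
        # E_rev from the raw pre-step baseline; removed from the traces after
        bl = sweeps.data[:, sweeps.window(0.0, baseline_ms)]
        self.e_rev = float(bl.mean())
        self.observed = sweeps.data - bl.mean(axis=1, keepdims=True)

    def _simulate(self, Cm, g_leak, Ra) -> np.ndarray:
        passive = PassiveParams(Cm=Cm, g_leak=g_leak, Ra=Ra, E_rev=self.e_rev)
        model = CompartmentalModel(self.segments, passive, {}, self.electrode)
        proto = ClampProtocol(
            "current", 0.0, tuple(self.sweeps.step_values),
            self.sweeps.onset, self.sweeps.offset,
            float(self.sweeps.t[-1] + self.sweeps.dt), self.sim_dt, self.e_rev,
        )
        out = np.empty_like(self.observed)
        for k, tr in enumerate(model.run_current_clamp(proto)):
            v = np.interp(self.sweeps.t, tr.t, tr.v)
            bl = v[self.sweeps.window(0.0, self.baseline_ms)].mean()
            out[k] = v - bl
        return out

    def fit(self, start: tuple | None = None, max_nfev: int = 200) -> PassiveFitResult:
        """Bound-constrained least squares over (Cm, log10 g_leak, Ra)."""
        x0 = np.array([
            start[0] if start else 1.5,
            math.log10(start[1]) if start else -4.0,
            start[2] if start else 150.0,
        ])
        lo = np.array([CM_BOUNDS[0], math.log10(GLEAK_BOUNDS[0]), RA_BOUNDS[0]])
        hi = np.array([CM_BOUNDS[1], math.log10(GLEAK_BOUNDS[1]), RA_BOUNDS[1]])
        x0 = np.clip(x0, lo, hi)

        def resid(x):
            sim = self._simulate(x[0], 10.0 ** x[1], x[2])
            return (sim - self.observed).ravel()

        res = least_squares(resid, x0, bounds=(lo, hi), max_nfev=max_nfev,
                            xtol=1e-12, ftol=1e-12, gtol=1e-12,
                            x_scale=(1.0, 0.5, 100.0))
        params = PassiveParams(Cm=float(res.x[0]), g_leak=float(10.0 ** res.x[1]),
                               Ra=float(res.x[2]), E_rev=self.e_rev)
        final = self._simulate(params.Cm, params.g_leak, params.Ra)
        sse = ((final - self.observed) ** 2).sum(axis=1)
        return PassiveFitResult(
            params=params, sweep_sse=sse,
            converged=bool(res.success) and res.status != 0,
            bounds={"Cm": CM_BOUNDS, "g_leak": GLEAK_BOUNDS, "Ra": RA_BOUNDS},
            n_function_evals=int(res.nfev), message=str(res.message),
            start_params=tuple(x0),
        )


def fit_passive(
    morphology: Morphology, sweeps: SweepSet,
    electrode: ElectrodeSpec | None = None, **kw,
) -> PassiveFitResult:
    """Convenience wrapper: build a :class:`PassiveFit` and fit it."""
    start = kw.pop("start", None)
    return PassiveFit(morphology, sweeps, electrode, **kw).fit(start=start)
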