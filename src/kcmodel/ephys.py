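"""Patch-clamp sweep analysis: passive properties, spike waveforms,
NaChBac current/potential metrics, fast-inward-event detection and
steady-state current decomposition.

All procedures operate on a :class:`SweepSet` — a uniformly sampled
time x sweep matrix with step metadata — and work identically on
synthetic and real recordings (nominal acquisition: 1 kHz low-pass,
50 kHz sampling).  Smoothing windows are specified in milliseconds and
converted to an odd number of samples from the sweep's rate.

The steady-state decomposition isolates the voltage-gated outward
current from a 1 s voltage-step family by assuming
I_obs = I_leak + I_K + I_NaChBac: the leak is extrapolated from a linear
fit to the steady-state currents between -100 and -70 mV, and the
residual (end-of-step) NaChBac current I_Nr is estimated in the
-60..-40 mV range where the outward current is absent and scaled to
other steps by the ratio of residual to observed peak NaChBac current,
using only inward observed peaks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks


class AnalysisError(ValueError):
    """Protocol violation or unusable input for an analysis procedure."""


@dataclass
class SweepSet:
    """Time-aligned clamp sweeps with step metadata.

    ``data`` is (n_sweeps, n_samples): mV for current clamp, pA for
    voltage clamp.  ``step_values`` gives the per-sweep step amplitude
    (pA or mV) applied between ``onset`` and ``offset`` (ms).
    """

    t: np.ndarray
    data: np.ndarray
    step_values: np.ndarray
    onset: float
    offset: float
    mode: str  # "current" | "voltage"
    sample_rate_khz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.data = np.atleast_2d(np.asarray(self.data, float))
        self.step_values = np.asarray(self.step_values, float)
        if self.data.shape != (len(self.step_values), len(self.t)):
            raise AnalysisError("data shape inconsistent with steps/time grid")
        dt = np.diff(self.t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise AnalysisError("sampling must be uniform")
        if not (0 <= self.onset < self.offset <= self.t[-1] + 1.0 / self.sample_rate_khz):
            raise AnalysisError("step metadata outside trace duration")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_khz

    def window(self, t0: float, t1: float) -> slice:
        i0 = int(np.searchsorted(self.t, t0))
        i1 = int(np.searchsorted(self.t, t1))
        return slice(i0, i1)

    def sweep(self, step_value: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.step_values - step_value)))
        return self.data[idx]

    # -- delimited-text container: one time column + one column per sweep,
    #    metadata in a JSON sidecar
    def save(self, path: str | Path) -> None:
        path = Path(path)
        cols = {"t_ms": self.t}
        for v, row in zip(self.step_values, self.data):
            cols[f"step_{v:g}"] = row
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
        sidecar = {
            "step_values": list(map(float, self.step_values)),
            "onset": self.onset, "offset": self.offset, "mode": self.mode,
            "sample_rate_khz": self.sample_rate_khz, "metadata": self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SweepSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        t = df["t_ms"].to_numpy()
        data = df.drop(columns="t_ms").to_numpy().T
        return cls(
            t=t, data=data, step_values=np.asarray(meta["step_values"]),
            onset=meta["onset"], offset=meta["offset"], mode=meta["mode"],
            sample_rate_khz=meta["sample_rate_khz"], metadata=meta.get("metadata", {}),
        )


def _odd_window(ms: float, rate_khz: float) -> int:
    n = max(1, int(round(ms * rate_khz)))
    return n if n % 2 == 1 else n + 1


def moving_average(x: np.ndarray, ms: float, rate_khz: float) -> np.ndarray:
    w = _odd_window(ms, rate_khz)
    if w <= 1:
        return np.asarray(x, float)
    return pd.Series(x).rolling(w, center=True, min_periods=1).mean().to_numpy()


def moving_median(x: np.ndarray, ms: float, rate_khz: float) -> np.ndarray:
    w = _odd_window(ms, rate_khz)
    if w <= 1:
        return np.asarray(x, float)
    return pd.Series(x).rolling(w, center=True, min_periods=1).median().to_numpy()


# ---------------------------------------------------------------------------
# passive properties from a hyperpolarizing step


@dataclass
class PassiveProperties:
    input_resistance_gohm: float
    capacitance_pf: float
    tau_ms: float
    step_pa: float
    qc_excluded: bool  # input resistance below the 0.8 GOhm inclusion cut
    fit_ok: bool


def passive_from_sweep(sweeps: SweepSet, qc_min_r_gohm: float = 0.8) -> PassiveProperties:
    """Input resistance, capacitance and membrane tau from a negative step.

    Fits V(t) = V0 + dV*(1 - exp(-t/tau)) to the hyperpolarization
    induced by the most negative current step; R is the plateau voltage
    change divided by the step current, C = tau / R.
    """
    if sweeps.mode != "current":
        raise AnalysisError("passive properties need current-clamp sweeps")
    neg = sweeps.step_values[sweeps.step_values < 0]
    if len(neg) == 0:
        raise AnalysisError("no hyperpolarizing step present")
    I = float(neg.min())
    v = sweeps.sweep(I)
    sl = sweeps.window(sweeps.onset, sweeps.offset)
    t = sweeps.t[sl] - sweeps.onset
    vv = v[sl]
    v0 = float(np.mean(v[sweeps.window(max(0.0, sweeps.onset - 50.0), sweeps.onset)]))

    def f(t, dv, tau):
        return v0 + dv * (1 - np.exp(-t / tau))

    fit_ok = True
    try:
        (dv, tau), _ = curve_fit(f, t, vv, p0=(vv[-1] - v0, 20.0), maxfev=5000)
        tau = abs(float(tau))
    except RuntimeError:
        fit_ok = False
        dv, tau = float(np.median(vv[-len(vv) // 5:]) - v0), float("nan")
    R = abs(dv / I)  # mV/pA = GOhm
    C = tau / R if fit_ok else float("nan")  # ms/GOhm = pF
    return PassiveProperties(
        input_resistance_gohm=R, capacitance_pf=C, tau_ms=tau, step_pa=I,
        qc_excluded=R < qc_min_r_gohm, fit_ok=fit_ok,
    )


# ---------------------------------------------------------------------------
# spike detection and waveform features


def detect_spikes(v: np.ndarray, t: np.ndarray, prominence_mv: float = 1.0,
                  wlen_ms: float = 20.0) -> np.ndarray:
    """Spike times by local-maximum prominence (the relative-threshold rule).

    Prominence is evaluated within a +/- wlen_ms/2 neighbourhood of each
    peak, so only fast events count: slow plateau transients (the early
    NaChBac surge, the relaxation at the end of a sustained current
    step) have large global but small local prominence and are excluded.
    """
    v = np.asarray(v, float)
    t = np.asarray(t, float)
    wlen = None
    if wlen_ms is not None and len(t) > 1:
        wlen = max(3, int(round(wlen_ms / (t[1] - t[0]))))
    with warnings.catch_warnings():
        # flat stretches legitimately yield zero-prominence candidates
        warnings.simplefilter("ignore")
        peaks, _ = find_peaks(v, prominence=prominence_mv, wlen=wlen)
    return t[peaks]


@dataclass
class SpikeFeatures:
    """Per-spike features plus per-cell summary.

    ``table`` columns: step_pa, t_peak_ms, t_onset_ms, v_onset_mv,
    v_peak_mv, height_mv, peak_dvdt_mv_ms.  ``min_voltage_to_spike_mv``
    is the minimum onset voltage across all spikes of the cell;
    ``waveforms`` maps step value -> averaged spike waveform (the
    +/-20 ms window around the peak).
    """

    table: pd.DataFrame
    min_voltage_to_spike_mv: float
    waveforms: dict
    n_skipped_edge: int


def spike_features(
    sweeps: SweepSet, spike_times: dict | None = None,
    prominence_mv: float = 1.0, window_ms: float = 20.0,
    onset_search_ms: float = 5.0, onset_smooth_ms: float = 2.0,
    dvdt_smooth_ms: float = 0.6,
) -> SpikeFeatures:
    """Spike waveform features from current-clamp sweeps.

    The spike onset is the peak of the second voltage derivative within
    5 ms before the voltage peak (with 2 ms moving-average smoothing at
    each differentiation step); height is peak minus onset voltage; the
    upstroke speed is the peak dV/dt in the same pre-peak window after
    0.6 ms smoothing.  Spikes closer than the window to a trace edge
    are skipped with a warning.
    """
    if sweeps.mode != "current":
        raise AnalysisError("spike features need current-clamp sweeps")
    rate = sweeps.sample_rate_khz
    rows = []
    waveforms: dict = {}
    n_skip = 0
    nw = int(round(window_ms * rate))
    for I, v in zip(sweeps.step_values, sweeps.data):
        st = (spike_times.get(float(I), []) if spike_times is not None
              else detect_spikes(v, sweeps.t, prominence_mv))
        snips = []
        for t_peak in st:
            ip = int(round(t_peak * rate))
            if ip - nw < 0 or ip + nw >= len(v):
                n_skip += 1
                warnings.warn(f"spike at {t_peak:.1f} ms too close to trace edge; skipped")
                continue
            snip = v[ip - nw: ip + nw + 1]
            snips.append(snip)
            feats = _spike_onset_features(
                snip, rate, onset_search_ms, onset_smooth_ms, dvdt_smooth_ms)
            if feats is None:
                continue
            i_on, v_on, dvdt = feats
            rows.append({
                "step_pa": float(I), "t_peak_ms": float(t_peak),
                "t_onset_ms": float(t_peak - (nw - i_on) / rate),
                "v_onset_mv": v_on, "v_peak_mv": float(v[ip]),
                "height_mv": float(v[ip]) - v_on, "peak_dvdt_mv_ms": dvdt,
            })
        if snips:
            waveforms[float(I)] = np.mean(snips, axis=0)
    table = pd.DataFrame(rows)
    minv = float(table["v_onset_mv"].min()) if len(table) else float("nan")
    return SpikeFeatures(table=table, min_voltage_to_spike_mv=minv,
                         waveforms=waveforms, n_skipped_edge=n_skip)


def _spike_onset_features(snip, rate, search_ms, smooth_ms, dvdt_smooth_ms,
                          min_d2=0.01):
    """Onset index/voltage and peak dV/dt for one +/-window snippet.

    Returns None when no meaningful second-derivative peak (above
    min_d2 mV/ms^2) exists in the pre-peak search window — e.g. a pure
    ramp with no inflection.
    """
    mid = len(snip) // 2
    i0 = mid - int(round(search_ms * rate))
    d1 = np.gradient(moving_average(snip, smooth_ms, rate)) * rate
    d2 = np.gradient(moving_average(d1, smooth_ms, rate)) * rate
    seg = d2[i0:mid]
    peaks, _ = find_peaks(seg, height=min_d2)
    if len(peaks) == 0:
        return None
    i_on = i0 + int(peaks[np.argmax(seg[peaks])])
    d1s = np.gradient(moving_average(snip, dvdt_smooth_ms, rate)) * rate
    dvdt = float(d1s[i0:mid].max())
    return i_on, float(snip[i_on]), dvdt


# ---------------------------------------------------------------------------
# NaChBac current and potential metrics


def nachbac_current(
    sweeps: SweepSet, capacitance_pf: float,
    median_ms: float = 50.0, peak_window_ms: float = 100.0,
    steady_window_ms: float = 100.0,
) -> pd.DataFrame:
    """Peak slow inward (NaChBac) current and density per voltage step.

    Each trace is smoothed by a 50 ms moving median (removing fast
    inward currents from unclamped spikes), the steady-state current
    (median of the last 100 ms of the step) is subtracted, and the peak
    inward current within the first 100 ms of the step is taken;
    density normalizes to membrane capacitance (pA/pF).
    """
    if sweeps.mode != "voltage":
        raise AnalysisError("NaChBac currents need voltage-clamp sweeps")
    if sweeps.offset - sweeps.onset < 200.0:
        raise AnalysisError("voltage step shorter than 200 ms")
    rate = sweeps.sample_rate_khz
    rows = []
    for V, i in zip(sweeps.step_values, sweeps.data):
        sm = moving_median(i, median_ms, rate)
        steady = float(np.median(sm[sweeps.window(sweeps.offset - steady_window_ms,
                                                  sweeps.offset)]))
        early = sm[sweeps.window(sweeps.onset, sweeps.onset + peak_window_ms)] - steady
        peak = float(min(early.min(), 0.0))
        rows.append({
            "step_mv": float(V), "peak_pa": peak,
            "density_pa_pf": peak / capacitance_pf, "steady_pa": steady,
        })
    return pd.DataFrame(rows)


@dataclass
class NachbacPotential:
    avg_depolarization_mv: float
    best_step_pa: float
    plateau_mv: float
    crossed: bool  # False when the normalized voltage never went above zero


def nachbac_potential_metrics(
    sweeps: SweepSet, plateau_window_ms: float = 200.0,
) -> NachbacPotential:
    """Average depolarization of the biggest NaChBac potential.

    Per depolarizing step: the plateau voltage (mean over the 200 ms
    period with the lowest mean during the step) is subtracted, and the
    average is taken from the first positive crossing of the normalized
    voltage to the end of the step — capturing both amplitude and
    duration of the plateau potential.  The step maximizing the metric
    is reported.
    """
    if sweeps.mode != "current":
        raise AnalysisError("NaChBac potentials need current-clamp sweeps")
    rate = sweeps.sample_rate_khz
    nwin = int(round(plateau_window_ms * rate))
    best = NachbacPotential(0.0, float("nan"), float("nan"), False)
    for I, v in zip(sweeps.step_values, sweeps.data):
        if I <= 0:
            continue
        sl = sweeps.window(sweeps.onset, sweeps.offset)
        vv = v[sl]
        if len(vv) <= nwin:
            continue
        means = pd.Series(vv).rolling(nwin).mean().to_numpy()[nwin - 1:]
        plateau = float(np.nanmin(means))
        norm = vv - plateau
        above = np.nonzero(norm > 0)[0]
        if len(above) == 0:
            continue
        avg = float(np.mean(norm[above[0]:]))
        if avg > best.avg_depolarization_mv:
            best = NachbacPotential(avg, float(I), plateau, True)
    return best


@dataclass
class DecayFit:
    tau_ms: float
    best_step_mv: float
    peak_density_pa_pf: float
    excluded: bool  # density below the 2 pA/pF inclusion threshold
    fit_ok: bool


def nachbac_decay_tau(
    sweeps: SweepSet, capacitance_pf: float,
    min_density_pa_pf: float = 2.0, fit_amplitude: bool = True,
) -> DecayFit:
    """Decay time constant of the NaChBac current.

    Selects the step with the biggest inward current density, excludes
    cells whose mean density in the first 100 ms is below 2 pA/pF,
    normalizes the smoothed trace to its peak and fits the decay to
    -a*exp(-t/tau).  With ``fit_amplitude=False`` the amplitude is
    pinned at 1 (the bare normalized form); the free amplitude is the
    default because the median smoothing attenuates the measured peak,
    and pinning the amplitude to it leaks that attenuation into tau —
    the two coincide when the peak normalization is exact.
    """
    dens = nachbac_current(sweeps, capacitance_pf)
    k = int(dens["density_pa_pf"].idxmin())
    best = dens.loc[k]
    if abs(best["density_pa_pf"]) < min_density_pa_pf:
        return DecayFit(float("nan"), float(best["step_mv"]),
                        float(best["density_pa_pf"]), True, False)
    rate = sweeps.sample_rate_khz
    i = moving_median(sweeps.data[k], 50.0, rate)
    sl = sweeps.window(sweeps.onset, sweeps.offset)
    ii = i[sl] - best["steady_pa"]
    first = ii[: int(round(100.0 * rate))]
    ipk = int(np.argmin(first))
    decay = ii[ipk:] / abs(ii[ipk])
    td = np.arange(len(decay)) / rate
    # the centered median window is contaminated within half a window of
    # the peak (and of the step onset); fit the clean part of the decay
    skip = int(round(25.0 * rate))
    decay, td = decay[skip:], td[skip:]

    try:
        if fit_amplitude:
            (a, tau), _ = curve_fit(lambda t, a, tau: -a * np.exp(-t / tau),
                                    td, decay, p0=(1.0, 100.0), maxfev=5000)
        else:
            (tau,), _ = curve_fit(lambda t, tau: -np.exp(-t / tau),
                                  td, decay, p0=(100.0,), maxfev=5000)
        return DecayFit(abs(float(tau)), float(best["step_mv"]),
                        float(best["density_pa_pf"]), False, True)
    except RuntimeError:
        return DecayFit(float("nan"), float(best["step_mv"]),
                        float(best["density_pa_pf"]), False, False)


# ---------------------------------------------------------------------------
# fast inward events


@dataclass
class FastEvents:
    """Detected fast inward events (unclamped-spike currents)."""

    table: pd.DataFrame  # columns: step_mv, t_trough_ms, amplitude_pa
    waveforms: dict  # step value -> averaged (-3 ms .. +6 ms) waveform
    params: dict


def fast_inward_events(
    sweeps: SweepSet, smooth_ms: float = 1.4,
    deriv_threshold_pa_ms: float = 2.5, deriv_prominence_pa_ms: float = 5.0,
    trough_prominence_pa: float = 2.0, pair_window_ms: float = 3.0,
    analysis_window_ms: float = 400.0,
) -> FastEvents:
    """Detect biphasic fast inward currents in the final 400 ms of each step.

    An event requires (1) a trough < -2.5 pA/ms in the smoothed dI/dt
    followed by a peak > +2.5 pA/ms within 3 ms, each with |prominence|
    > 5 pA/ms, and (2) a current trough with prominence > 2 pA between
    them.  The averaged waveform spans 3 ms before to 6 ms after the
    current trough (unsmoothed).
    """
    if sweeps.mode != "voltage":
        raise AnalysisError("fast inward events need voltage-clamp sweeps")
    rate = sweeps.sample_rate_khz
    rows = []
    waveforms: dict = {}
    n_pair = int(round(pair_window_ms * rate))
    for V, i_raw in zip(sweeps.step_values, sweeps.data):
        sl = sweeps.window(sweeps.offset - analysis_window_ms, sweeps.offset)
        seg_raw = i_raw[sl]
        seg = moving_average(seg_raw, smooth_ms, rate)
        didt = moving_average(np.gradient(seg) * rate, smooth_ms, rate)
        troughs, tprops = find_peaks(-didt, height=deriv_threshold_pa_ms,
                                     prominence=deriv_prominence_pa_ms)
        peaks, pprops = find_peaks(didt, height=deriv_threshold_pa_ms,
                                   prominence=deriv_prominence_pa_ms)
        cur_troughs, cprops = find_peaks(-seg, prominence=trough_prominence_pa)
        snips = []
        for tr_i in troughs:
            later = peaks[(peaks > tr_i) & (peaks <= tr_i + n_pair)]
            if len(later) == 0:
                continue
            pk_i = int(later[0])
            between = cur_troughs[(cur_troughs >= tr_i) & (cur_troughs <= pk_i)]
            if len(between) == 0:
                continue
            ct = int(between[np.argmin(seg[between])])
            t_trough = sweeps.t[sl][ct]
            i0 = sl.start + ct - int(round(3.0 * rate))
            i1 = sl.start + ct + int(round(6.0 * rate))
            if i0 < 0 or i1 >= len(i_raw):
                continue
            rows.append({"step_mv": float(V), "t_trough_ms": float(t_trough),
                         "amplitude_pa": float(cprops["prominences"][
                             np.nonzero(cur_troughs == ct)[0][0]])})
            snips.append(i_raw[i0:i1 + 1])
        if snips:
            waveforms[float(V)] = np.mean(snips, axis=0)
    return FastEvents(
        table=pd.DataFrame(rows), waveforms=waveforms,
        params={"smooth_ms": smooth_ms, "deriv_threshold": deriv_threshold_pa_ms,
                "deriv_prominence": deriv_prominence_pa_ms,
                "trough_prominence": trough_prominence_pa},
    )


# ---------------------------------------------------------------------------
# steady-state decomposition


@dataclass
class SteadyStateDecomposition:
    """Per-step decomposition I_obs = I_leak + I_Nr + I_K (pA)."""

    table: pd.DataFrame  # columns: step_mv, i_obs_pa, i_leak_pa, i_nr_pa, i_k_pa
    leak_slope_ns: float
    leak_intercept_pa: float
    ratio_nr_np: float
    reference_step_mv: float
    cell_excluded: bool  # pre/post baselines differed by more than 15 pA
    no_nachbac: bool


def steady_state_decomposition(
    sweeps: SweepSet, leak_range_mv=(-100.0, -70.0), ref_range_mv=(-60.0, -40.0),
    baseline_qc_pa: float = 15.0, steady_window_ms: float = 100.0,
) -> SteadyStateDecomposition:
    """Decompose steady-state currents into leak, residual NaChBac and I_K."""
    if sweeps.mode != "voltage":
        raise AnalysisError("decomposition needs voltage-clamp sweeps")
    rate = sweeps.sample_rate_khz

    pre_sl = sweeps.window(max(0.0, sweeps.onset - 50.0), sweeps.onset)
    post_sl = sweeps.window(sweeps.offset + 5.0, sweeps.t[-1])
    excluded = False
    i_obs = []
    for i in sweeps.data:
        pre = float(np.median(i[pre_sl]))
        post = float(np.median(i[post_sl])) if post_sl.stop > post_sl.start else pre
        if abs(pre - post) > baseline_qc_pa:
            excluded = True
        sm = moving_median(i, 50.0, rate)
        steady = float(np.median(sm[sweeps.window(sweeps.offset - steady_window_ms,
                                                  sweeps.offset)]))
        i_obs.append(steady - pre)
    i_obs = np.asarray(i_obs)
    V = sweeps.step_values

    sel = (V >= leak_range_mv[0]) & (V <= leak_range_mv[1])
    if sel.sum() < 2:
        raise AnalysisError("need at least two steps in the leak-fit range")
    slope, intercept = np.polyfit(V[sel], i_obs[sel], 1)  # pA/mV = nS
    i_leak = slope * V + intercept

    # observed peak NaChBac current per step (I_Np,obs = I_Np - I_Nr)
    cap = sweeps.metadata.get("capacitance_pf", 1.0)
    i_np_obs = nachbac_current(sweeps, cap)["peak_pa"].to_numpy()

    refsel = (V >= ref_range_mv[0]) & (V <= ref_range_mv[1]) & (i_np_obs < 0)
    no_nachbac = not bool(refsel.any())
    if no_nachbac:
        ratio, v_ref = 0.0, float("nan")
        i_nr = np.zeros_like(i_obs)
    else:
        k = int(np.flatnonzero(refsel)[np.argmin(i_np_obs[refsel])])
        v_ref = float(V[k])
        i_nr_ref = i_obs[k] - i_leak[k]  # I_K = 0 in the reference range
        ratio = float(i_nr_ref / i_np_obs[k])
        i_nr = np.where(i_np_obs < 0, ratio * i_np_obs, 0.0)
    i_k = i_obs - i_leak - i_nr
    table = pd.DataFrame({
        "step_mv": V, "i_obs_pa": i_obs, "i_leak_pa": i_leak,
        "i_np_obs_pa": i_np_obs, "i_nr_pa": i_nr, "i_k_pa": i_k,
    })
    return SteadyStateDecomposition(
        table=table, leak_slope_ns=float(slope), leak_intercept_pa=float(intercept),
        ratio_nr_np=ratio, reference_step_mv=v_ref,
        cell_excluded=excluded, no_nachbac=no_nachbac,
    )
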