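"""Synthetic-data generators with known ground truth.

Every pipeline stage in the package can be tested without external
downloads: this module produces (a) gamma-Kenyon-cell-like labelled tree
morphologies, (b) current- and voltage-clamp sweep sets with known
passive parameters, spikes, NaChBac-like slow inward currents and fast
inward events, and (c) pixel activity maps with controlled population
sparseness and inter-odour correlation.  Each generated artifact carries
a :class:`GroundTruth` sidecar; regeneration from (seed, params) is
bit-identical.

The clamp-recording generator has two modes.  "fast" synthesizes traces
from closed-form templates (RC step responses, alpha-shaped spikes,
single-exponential slow inward currents, biphasic fast events) so the
analysis tests run in seconds; "simulate" runs the full compartmental
model and resamples its output to the 50 kHz acquisition rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .morphology import (AXON, DENDRITE, PRE_SIZ, SIZ, SOMA, TETHER,
                         MorphNode, Morphology)

GENERATOR_VERSION = "1.0"


@dataclass
class GroundTruth:
    """Generator parameters + seed, serialized alongside every dataset."""

    kind: str
    seed: int
    params: dict
    version: str = GENERATOR_VERSION

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=float)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


# ---------------------------------------------------------------------------
# morphology


@dataclass(frozen=True)
class MorphConfig:
    """Geometry of the synthetic gamma-KC surrogate (lengths/radii in um).

    The cell is a single-soma tree: soma -- tether -- {dendritic claws,
    pre-SIZ -- SIZ -- axon}.  ``tether_target`` chooses whether the
    tether ends at the dendrite root ("dendrites", default) or at the
    pre-SIZ junction ("pre_siz"); the published labelling scheme does
    not fix this, so it is configurable rather than asserted.
    """

    soma_radius: float = 3.0
    tether_length: float = 30.0
    tether_radius: float = 0.25
    n_claws: int = 5
    claw_length: float = 20.0
    dend_radius: float = 0.2
    pre_siz_length: float = 20.0
    pre_siz_radius: float = 0.2
    siz_length: float = 25.0
    siz_radius: float = 0.3
    axon_length: float = 40.0
    axon_radius: float = 0.2
    axon_branches: int = 1
    node_spacing: float = 5.0
    tether_target: str = "dendrites"

    def __post_init__(self):
        for name in ("soma_radius", "tether_length", "tether_radius", "claw_length",
                     "dend_radius", "pre_siz_length", "pre_siz_radius", "siz_length",
                     "siz_radius", "axon_length", "axon_radius", "node_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tether_target not in ("dendrites", "pre_siz"):
            raise ValueError("tether_target must be 'dendrites' or 'pre_siz'")


def gen_morphology(config: MorphConfig = MorphConfig(), seed: int = 0):
    """Synthetic labelled gamma-KC tree.  Returns (Morphology, GroundTruth)."""
    rng = np.random.default_rng(seed)
    nodes: list[MorphNode] = []
    next_id = [1]

    def add(label, pos, radius, parent):
        nid = next_id[0]
        next_id[0] += 1
        nodes.append(MorphNode(nid, label, *(float(p) for p in pos), float(radius), parent))
        return nid, np.asarray(pos, float)

    def chain(label, start_pos, direction, length, radius, parent):
        """Straight chain of nodes with exact spacing; returns last id/pos."""
        direction = np.asarray(direction, float)
        direction = direction / np.linalg.norm(direction)
        n = max(1, int(round(length / config.node_spacing)))
        step = length / n
        nid, pos = parent, np.asarray(start_pos, float)
        for _ in range(n):
            pos = pos + direction * step
            nid, _ = add(label, pos, radius, nid)
        return nid, pos

    soma_id, soma_pos = add(SOMA, (0.0, 0.0, 0.0), config.soma_radius, None)

    tether_id, tether_pos = chain(
        TETHER, soma_pos, (1.0, 0.0, 0.0), config.tether_length,
        config.tether_radius, soma_id,
    )

    first_presiz_id = next_id[0]
    ps_id, ps_pos = chain(PRE_SIZ, tether_pos, (1.0, 0.0, 0.0),
                          config.pre_siz_length, config.pre_siz_radius, tether_id)
    if config.tether_target == "dendrites":
        # tether ends at the dendrite root: claws attach at the tether tip
        dend_root_id, dend_root_pos = tether_id, tether_pos
    else:
        # tether runs to the pre-SIZ junction; claws hang off its first node
        dend_root_id = first_presiz_id
        dend_root_pos = next(
            np.array([nd.x, nd.y, nd.z]) for nd in nodes if nd.id == first_presiz_id
        )

    for _ in range(config.n_claws):
        direction = rng.normal(size=3)
        direction[0] = abs(direction[0]) * 0.3 + 0.1  # claws fan out forward
        chain(DENDRITE, dend_root_pos, direction, config.claw_length,
              config.dend_radius, dend_root_id)
    siz_id, siz_pos = chain(SIZ, ps_pos, (1.0, 0.0, 0.0),
                            config.siz_length, config.siz_radius, ps_id)
    ax_id, ax_pos = chain(AXON, siz_pos, (1.0, 0.0, 0.0),
                          config.axon_length, config.axon_radius, siz_id)
    for _ in range(max(0, config.axon_branches - 1)):
        direction = rng.normal(size=3)
        direction[0] = abs(direction[0]) + 0.5
        chain(AXON, ax_pos, direction, config.axon_length / 2,
              config.axon_radius, ax_id)

    morph = Morphology(nodes=nodes, metadata=f"synthetic gamma-KC seed={seed}")
    truth = GroundTruth(kind="morphology", seed=seed, params=asdict(config))
    return morph, truth


def default_morphology(seed: int = 0) -> Morphology:
    """The bundled synthetic gamma-KC surrogate used throughout the tests."""
    return gen_morphology(MorphConfig(), seed)[0]


# ---------------------------------------------------------------------------
# clamp recordings (fast template mode)


def _alpha_spike(t_ms: np.ndarray, t0: float, amp: float, tau_rise=0.4, tau_decay=1.2):
    """Small somatic spike template: difference of exponentials, peak = amp."""
    s = np.zeros_like(t_ms)
    mask = t_ms >= t0
    td = t_ms[mask] - t0
    w = np.exp(-td / tau_decay) - np.exp(-td / tau_rise)
    if w.max() > 0:
        w = w / w.max()
    s[mask] = amp * w
    return s


@dataclass(frozen=True)
class FastCellConfig:
    """Template parameters for a fast-mode synthetic recording.

    Passive membrane (R in GOhm, C in pF), spike placement for current
    clamp, and NaChBac-like slow inward current plus biphasic fast
    events for voltage clamp.
    """

    R_gohm: float = 1.5
    C_pf: float = 25.0
    E_mV: float = -60.0
    spike_amp_mV: float = 15.0
    spike_rate_per_pa: float = 0.05  # spikes per pA above rheobase
    rheobase_pa: float = 20.0
    nachbac_peak_pa: float = -120.0  # peak slow inward current at -40 mV
    nachbac_tau_ms: float = 180.0
    nachbac_rise_ms: float = 20.0
    event_amp_pa: float = -12.0
    n_events_per_step: int = 0
    shab_gmax_ns: float = 0.0  # Shab-like steady outward conductance
    shab_v12: float = -20.0
    shab_k: float = 6.0
    noise_sd: float = 0.0
    lowpass_khz: float = 1.0
    sample_khz: float = 50.0


def gen_cc_recording(
    config: FastCellConfig = FastCellConfig(),
    steps_pa=tuple(range(-40, 101, 10)),
    duration_ms: float = 1200.0, onset_ms: float = 100.0, offset_ms: float = 1100.0,
    seed: int = 0,
):
    """Fast-mode current-clamp sweep set.  Returns (SweepSet, GroundTruth).

    RC step responses with alpha-shaped spikes riding on suprathreshold
    steps; optionally 1 kHz low-pass filtered Gaussian noise.
    """
    from .ephys import SweepSet

    rng = np.random.default_rng(seed)
    fs = config.sample_khz  # samples per ms
    n = int(round(duration_ms * fs))
    t = np.arange(n) / fs
    tau = config.R_gohm * config.C_pf  # GOhm*pF = ms
    sweeps = np.zeros((len(steps_pa), n))
    spike_times: dict[float, list[float]] = {}
    in_step = (t >= onset_ms) & (t < offset_ms)
    for si, I in enumerate(steps_pa):
        v = np.full(n, config.E_mV)
        dv = I * config.R_gohm  # pA*GOhm = mV
        td = t[in_step] - onset_ms
        v[in_step] += dv * (1 - np.exp(-td / tau))
        after = t >= offset_ms
        v_off = dv * (1 - np.exp(-(offset_ms - onset_ms) / tau))
        v[after] = config.E_mV + v_off * np.exp(-(t[after] - offset_ms) / tau)
        st = []
        if I >= config.rheobase_pa and config.spike_amp_mV > 0:
            n_spikes = max(1, int(round((I - config.rheobase_pa + 10) * config.spike_rate_per_pa)))
            st = list(np.linspace(onset_ms + 60, offset_ms - 60, n_spikes))
            for t0 in st:
                v += _alpha_spike(t, t0, config.spike_amp_mV)
        spike_times[float(I)] = st
        sweeps[si] = v
    sweeps += _filtered_noise(rng, sweeps.shape, config.noise_sd,
                              config.lowpass_khz, config.sample_khz)
    ss = SweepSet(
        t=t, data=sweeps, step_values=np.asarray(steps_pa, float),
        onset=onset_ms, offset=offset_ms, mode="current",
        sample_rate_khz=config.sample_khz,
    )
    truth = GroundTruth(
        kind="cc_recording", seed=seed,
        params={**asdict(config), "steps_pa": list(steps_pa),
                "spike_times": {str(k): v for k, v in spike_times.items()},
                "tau_ms": tau},
    )
    return ss, truth


def gen_vc_recording(
    config: FastCellConfig = FastCellConfig(),
    steps_mv=tuple(range(-100, 31, 10)), hold_mv: float = -100.0,
    duration_ms: float = 1200.0, onset_ms: float = 100.0, offset_ms: float = 1100.0,
    seed: int = 0,
):
    """Fast-mode voltage-clamp sweep set.  Returns (SweepSet, GroundTruth).

    Ohmic leak, a NaChBac-like slow inward current with single-exponential
    decay (activating above ~-60 mV, peak density scaled by driving
    force), and optional embedded biphasic fast inward events in the
    final 400 ms.
    """
    from .ephys import SweepSet

    rng = np.random.default_rng(seed)
    fs = config.sample_khz
    n = int(round(duration_ms * fs))
    t = np.arange(n) / fs
    g_leak_ns = 1.0 / config.R_gohm  # nS
    sweeps = np.zeros((len(steps_mv), n))
    in_step = (t >= onset_ms) & (t < offset_ms)
    event_times: dict[float, list[float]] = {}
    true_ik: dict[float, float] = {}
    for si, Vcmd in enumerate(steps_mv):
        i_pa = np.full(n, g_leak_ns * (hold_mv - config.E_mV))
        i_pa[in_step] = g_leak_ns * (Vcmd - config.E_mV)
        # NaChBac-like slow inward current: activates above about -60 mV
        act = 1.0 / (1.0 + math.exp((-47.21 - Vcmd) / 8.17))
        drive = (Vcmd - 60.0) / (-40.0 - 60.0)  # 1 at -40 mV, 0 at E_Na
        amp = config.nachbac_peak_pa * act * max(drive, 0.0)
        if Vcmd > -70 and amp < 0:
            # linear rise then exact single-exponential decay, so the
            # decay constant is recoverable without shape bias
            td = t[in_step] - onset_ms
            rise = np.clip(td / config.nachbac_rise_ms, 0.0, 1.0)
            decay = np.exp(-np.maximum(td - config.nachbac_rise_ms, 0.0)
                           / config.nachbac_tau_ms)
            i_pa[in_step] += amp * rise * decay
        if config.shab_gmax_ns > 0:
            # slowly-inactivating outward K current, settled well before
            # the steady-state window
            xinf = 1.0 / (1.0 + math.exp((config.shab_v12 - Vcmd) / config.shab_k))
            i_k = config.shab_gmax_ns * xinf * (Vcmd + 80.0)
            td = t[in_step] - onset_ms
            i_pa[in_step] += i_k * (1 - np.exp(-td / 10.0))
            true_ik[float(Vcmd)] = i_k
        ev = []
        if config.n_events_per_step > 0 and Vcmd >= -60:
            ev = list(np.linspace(offset_ms - 350, offset_ms - 50,
                                  config.n_events_per_step))
            for t0 in ev:
                i_pa += _alpha_spike(t, t0, config.event_amp_pa,
                                     tau_rise=0.3, tau_decay=0.7)
        event_times[float(Vcmd)] = ev
        sweeps[si] = i_pa
    sweeps += _filtered_noise(rng, sweeps.shape, config.noise_sd,
                              config.lowpass_khz, config.sample_khz)
    ss = SweepSet(
        t=t, data=sweeps, step_values=np.asarray(steps_mv, float),
        onset=onset_ms, offset=offset_ms, mode="voltage",
        sample_rate_khz=config.sample_khz,
    )
    truth = GroundTruth(
        kind="vc_recording", seed=seed,
        params={**asdict(config), "steps_mv": list(steps_mv),
                "event_times": {str(k): v for k, v in event_times.items()},
                "i_k_pa": {str(k): v for k, v in true_ik.items()}},
    )
    return ss, truth


def _filtered_noise(rng, shape, sd, lowpass_khz, sample_khz):
    """Additive Gaussian noise, optionally low-pass filtered (Butterworth)."""
    if sd <= 0:
        return np.zeros(shape)
    noise = rng.normal(0.0, sd, size=shape)
    if lowpass_khz and lowpass_khz < sample_khz / 2:
        b, a = sps.butter(4, lowpass_khz / (sample_khz / 2))
        noise = sps.filtfilt(b, a, noise, axis=-1)
        # refilter to the requested sd so analyses see the stated noise level
        s = noise.std()
        if s > 0:
            noise *= sd / s
    return noise


def gen_simulated_recording(model, protocol, noise_sd: float = 0.0,
                            sample_khz: float = 50.0, seed: int = 0):
    """Run the compartmental model and package the output as a SweepSet.

    Simulator output is resampled (linear interpolation) to the
    acquisition rate and Gaussian noise is added.  Ground truth records
    the model's passive parameters and protocol.
    """
    from .ephys import SweepSet

    rng = np.random.default_rng(seed)
    if protocol.mode == "current":
        traces = model.run_current_clamp(protocol)
        get = np.array([tr.v for tr in traces])
    else:
        traces = model.run_voltage_clamp(protocol)
        get = np.array([tr.i for tr in traces])
    t_new = np.arange(0.0, protocol.duration, 1.0 / sample_khz)
    data = np.array([np.interp(t_new, traces[0].t, row) for row in get])
    data += _filtered_noise(rng, data.shape, noise_sd, 1.0, sample_khz)
    ss = SweepSet(
        t=t_new, data=data, step_values=np.asarray(protocol.steps, float),
        onset=protocol.onset, offset=protocol.offset, mode=protocol.mode,
        sample_rate_khz=sample_khz,
    )
    truth = GroundTruth(
        kind=f"simulated_{protocol.mode}_clamp", seed=seed,
        params={"passive": asdict(model.passive), "noise_sd": noise_sd,
                "V0": protocol.V0, "steps": list(protocol.steps)},
    )
    return ss, truth


# ---------------------------------------------------------------------------
# activity maps


def gen_activity_maps(
    n_pixels: int = 10000, n_odours: int = 3, target_sp: float = 0.9,
    shared_weight: float = 0.0, seed: int = 0,
):
    """Pixel response maps with controlled sparseness and correlation.

    Pixel responses are log-normal, r_i = exp(sigma * z_i), where the
    latent z mixes a shared component s (common to all odours) with an
    odour-specific one:  z = sqrt(w)*s + sqrt(1-w)*e.  sigma is
    calibrated per map on the realized latent sample so the empirical
    population sparseness hits ``target_sp``; the implied pairwise
    Pearson correlation of the maps is the log-normal correlation
    (exp(w*sigma^2)-1)/(exp(sigma^2)-1), reported in the ground truth.

    Returns (maps, GroundTruth) with ``maps`` of shape (n_odours, n_pixels).
    """
    from scipy.optimize import brentq

    if not (0.0 <= shared_weight <= 1.0):
        raise ValueError("shared_weight must be in [0, 1]")
    if not (0.0 < target_sp < 1.0):
        raise ValueError("target sparseness must be strictly inside (0, 1)")
    if n_pixels < 10:
        raise ValueError("need at least 10 pixels")
    rng = np.random.default_rng(seed)
    shared = rng.normal(size=n_pixels)
    w = shared_weight
    maps = np.empty((n_odours, n_pixels))
    sigmas = []
    for k in range(n_odours):
        own = rng.normal(size=n_pixels)
        z = math.sqrt(w) * shared + math.sqrt(1 - w) * own

        def sp_of_sigma(sigma, z=z):
            r = np.exp(sigma * (z - z.max()))  # shift for overflow safety
            mean = r.mean()
            meansq = (r**2).mean()
            n = len(r)
            return (1 - mean**2 / meansq) / (1 - 1 / n)

        try:
            sigma = brentq(lambda s: sp_of_sigma(s) - target_sp, 1e-4, 60.0,
                           xtol=1e-10)
        except ValueError as exc:
            raise ValueError(
                f"target sparseness {target_sp} infeasible for this sample"
            ) from exc
        sigmas.append(sigma)
        maps[k] = np.exp(sigma * (z - z.mean()))
    sigma_mean = float(np.mean(sigmas))
    implied_corr = (
        (math.exp(w * sigma_mean**2) - 1.0) / (math.exp(sigma_mean**2) - 1.0)
        if sigma_mean > 0 else 0.0
    )
    truth = GroundTruth(
        kind="activity_maps", seed=seed,
        params={
            "n_pixels": n_pixels, "n_odours": n_odours, "target_sp": target_sp,
            "shared_weight": w, "sigmas": sigmas, "implied_correlation": implied_corr,
        },
    )
    return maps, truth
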