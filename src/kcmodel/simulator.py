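"""Branched-cable simulator: compartmental model, electrode, clamp protocols.

The model couples the discretized morphology (one compartment per
segment) with Hodgkin-Huxley channels at per-region densities, an
optional patch-electrode section attached to the soma, and a current- or
voltage-clamp source.  The voltage update is implicit (Crank-Nicolson by
default, backward Euler via ``order=1``; dt = 0.025 ms) with the
branched linear system solved exactly per step by Hines elimination;
gates advance by the exact exponential update at the current voltage,
which makes the combined scheme the usual staggered second-order one.
Implicit stability matters here because NaChBac kinetics are stiff
(activation time constants range from ~6 ms depolarized to ~10^5 ms at
very hyperpolarized voltages).

Current clamp injects at the soma by default (the electrode, when
present, contributes only its RC load); ``inject_at="electrode"``
injects at the electrode node instead.  Voltage clamp is an ideal source
by default, implemented as a very large series conductance, with an
optional finite series resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _core
from .channels import ChannelSpec
from .morphology import (SIZ, SOMA, Morphology, PassiveParams, Segment,
                         discretize)


class SimulationError(RuntimeError):
    """Solver divergence or invalid numerical state."""


@dataclass(frozen=True)
class ElectrodeSpec:
    """Cylindrical patch-electrode section attached to the soma.

    Defaults reproduce the published electrode: 10 um x 1 um cylinder
    with Ra = 205.513 Ohm*cm, g_leak = 3.978e-4 S/cm^2, Cm = 6.4 uF/cm^2,
    whose lumped equivalents are ~13 MOhm electrode (axial) resistance,
    ~8 GOhm seal resistance and ~2 pF capacitance.
    """

    length: float = 10.0  # um
    diameter: float = 1.0  # um
    Ra: float = 205.513  # Ohm*cm
    g_leak: float = 3.978e-4  # S/cm^2
    Cm: float = 6.4  # uF/cm^2
    E: float | None = None  # seal-leak reversal; None -> cell E_rev

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("electrode geometry must be positive")


def electrode_properties(spec: ElectrodeSpec) -> dict[str, float]:
    """Lumped electrode values from the cylinder geometry.

    Returns axial resistance to the midpoint (MOhm), seal resistance
    (GOhm) and capacitance (pF):

        R_axial = Ra * (L/2) / (pi * (d/2)^2)
        R_seal  = 1 / (g_leak * pi * d * L)
        C       = Cm * pi * d * L
    """
    L_cm = spec.length * 1e-4
    r_cm = spec.diameter / 2 * 1e-4
    area_cm2 = math.pi * spec.diameter * spec.length * 1e-8
    r_axial_ohm = spec.Ra * (L_cm / 2) / (math.pi * r_cm**2)
    return {
        "axial_resistance_mohm": r_axial_ohm * 1e-6,
        "seal_resistance_gohm": 1.0 / (spec.g_leak * area_cm2) * 1e-9,
        "capacitance_pf": spec.Cm * area_cm2 * 1e6,
    }


@dataclass(frozen=True)
class ClampProtocol:
    """One clamp protocol: a family of steps on a common time base.

    ``mode`` is "current" (baseline/steps in pA) or "voltage" (mV).
    The step is applied between onset and offset (ms); the model is
    reinitialized at ``V0`` before every step.
    """

    mode: str
    baseline: float
    steps: tuple
    onset: float
    offset: float
    duration: float
    dt: float = 0.025
    V0: float = -60.0

    def __post_init__(self):
        if self.mode not in ("current", "voltage"):
            raise ValueError(f"bad clamp mode {self.mode!r}")
        if not (0 < self.onset < self.offset <= self.duration):
            raise ValueError("require 0 < onset < offset <= duration")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not math.isfinite(self.V0):
            raise ValueError("V0 must be finite")

    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def time(self) -> np.ndarray:
        return np.arange(self.n_steps() + 1) * self.dt

    def stim_array(self, value: float) -> np.ndarray:
        """Per-sample stimulus (baseline outside [onset, offset))."""
        t = self.time()
        stim = np.full(t.shape, float(self.baseline))
        stim[(t >= self.onset) & (t < self.offset)] = float(value)
        return stim


def current_step_protocol(
    steps=tuple(range(-40, 101, 10)), duration=1200.0, onset=100.0,
    offset=1100.0, dt=0.025, V0=-60.0,
) -> ClampProtocol:
    """The experimental current-clamp family: 1 s steps, -40..+100 pA in 10 pA increments."""
    return ClampProtocol("current", 0.0, tuple(steps), onset, offset, duration, dt, V0)


def voltage_step_protocol(
    steps=tuple(range(-100, 31, 10)), hold=-100.0, duration=1200.0,
    onset=100.0, offset=1100.0, dt=0.025,
) -> ClampProtocol:
    """The experimental voltage-clamp family: hold -100 mV, 1 s steps to -100..+30 mV."""
    return ClampProtocol("voltage", hold, tuple(steps), onset, offset, duration, dt, V0=hold)


@dataclass
class SimTrace:
    """Simulated sweep: voltage at the recording site and source current."""

    t: np.ndarray  # ms
    v: np.ndarray  # mV at the recording site
    i: np.ndarray  # pA delivered by the source (injected or clamp current)
    step_value: float
    mode: str
    dt: float
    method: str = "backward_euler"
    gates: dict = field(default_factory=dict)  # channel -> (m, h) at the gate-record site

    def __post_init__(self):
        if np.any(~np.isfinite(self.v)) or np.any(~np.isfinite(self.i)):
            raise SimulationError(
                f"non-finite values in simulated trace (step {self.step_value})"
            )
        if np.any(np.diff(self.t) <= 0):
            raise SimulationError("time grid must be strictly increasing")


@dataclass
class ModelState:
    V: np.ndarray
    m: np.ndarray  # (n_channels, n_segments)
    h: np.ndarray


class CompartmentalModel:
    """Discretized neuron + channels + electrode, ready to simulate.

    ``channels`` maps channel name to a :class:`ChannelSpec` whose
    ``gbar`` carries per-region densities (mS/cm^2); region labels must
    exist in the morphology (the "all" baseline always applies).
    """

    def __init__(
        self,
        segments: Sequence[Segment],
        passive: PassiveParams,
        channels: dict[str, ChannelSpec] | None = None,
        electrode: ElectrodeSpec | None = None,
        inject_at: str = "soma",
        record_at: str = "soma",
        gate_record_label: int = SIZ,
    ):
        if inject_at not in ("soma", "electrode"):
            raise ValueError("inject_at must be 'soma' or 'electrode'")
        self.segments = list(segments)
        self.passive = passive
        self.channels = dict(channels or {})
        self.electrode = electrode
        self.inject_at = inject_at
        self.record_at = record_at
        self.gate_record_label = gate_record_label
        self._check_regions()
        self._assemble()

    @classmethod
    def from_morphology(
        cls, morph: Morphology, passive: PassiveParams,
        channels: dict[str, ChannelSpec] | None = None,
        electrode: ElectrodeSpec | None = None,
        max_fraction: float = 0.1, **kw,
    ) -> "CompartmentalModel":
        return cls(discretize(morph, passive, max_fraction), passive, channels,
                   electrode, **kw)

    def _check_regions(self) -> None:
        labels = {s.label for s in self.segments}
        for name, spec in self.channels.items():
            for key in spec.gbar:
                if key != "all" and key not in labels:
                    raise ValueError(
                        f"channel {name}: region label {key} absent from morphology"
                    )

    # ------------------------------------------------------------------
    def _assemble(self) -> None:
        segs = self.segments
        n = len(segs)
        p = self.passive
        self.soma_index = next(
            (s.index for s in segs if s.label == SOMA), 0
        )
        parent = np.full(n + (1 if self.electrode else 0), -1, dtype=np.int64)
        area = np.array([s.area_cm2 for s in segs])
        c_nF = p.Cm * area * 1e3
        gpas = p.g_leak * area * 1e6  # uS
        epas = np.full(n, p.E_rev)
        gax = np.zeros(n + (1 if self.electrode else 0))
        r_half = np.array([s.axial_resistance_mohm(p.Ra) / 2 for s in segs])  # MOhm
        for s in segs:
            parent[s.index] = -1 if s.parent is None else s.parent
            if s.parent is not None:
                r_mohm = r_half[s.index] + r_half[s.parent]
                gax[s.index] = 1.0 / r_mohm  # uS (1/MOhm)
        labels = [s.label for s in segs]

        if self.electrode:
            e = self.electrode
            ei = n
            props = electrode_properties(e)
            area_e = math.pi * e.diameter * e.length * 1e-8
            c_nF = np.append(c_nF, e.Cm * area_e * 1e3)
            gpas = np.append(gpas, e.g_leak * area_e * 1e6)
            epas = np.append(epas, p.E_rev if e.E is None else e.E)
            parent[ei] = self.soma_index
            # soma to electrode midpoint: electrode half-resistance in
            # series with the soma segment's half-resistance
            r_mohm = props["axial_resistance_mohm"] + r_half[self.soma_index]
            gax[ei] = 1.0 / r_mohm
            labels.append(-1)  # electrode pseudo-region
            n += 1

        self.n = n
        self.parent = parent
        self.c_nF = c_nF
        self.gpas_uS = gpas
        self.epas = epas
        self.gax_uS = gax
        self.labels = labels
        self.electrode_index = n - 1 if self.electrode else None

        # channel arrays
        names = sorted(self.channels)
        self.channel_names = names
        n_ch = len(names)
        self.gs_uS = np.zeros((n_ch, n))
        self.p_pow = np.ones(n_ch, dtype=np.int64)
        self.Ech = np.zeros(n_ch)
        ga = np.zeros((n_ch, 6))
        gh = np.zeros((n_ch, 6))
        self.has_h = np.zeros(n_ch, dtype=np.int64)
        for ci, name in enumerate(names):
            spec = self.channels[name]
            self.p_pow[ci] = spec.p
            self.Ech[ci] = spec.E
            a = spec.activation
            ga[ci] = (a.V12, abs(a.k), a.tau_spec.base, a.tau_spec.amp,
                      a.tau_spec.mid, a.tau_spec.slope)
            if spec.has_inactivation:
                self.has_h[ci] = 1
                hh = spec.inactivation
                gh[ci] = (hh.V12, abs(hh.k), hh.tau_spec.base, hh.tau_spec.amp,
                          hh.tau_spec.mid, hh.tau_spec.slope)
            else:
                gh[ci] = (0.0, 1.0, 1.0, 0.0, 0.0, 1.0)
            for i, s in enumerate(self.segments):
                self.gs_uS[ci, i] = spec.gbar_for_label(s.label) * s.area_cm2 * 1e3
        self._ga = ga
        self._gh = gh

        self.record_index = (
            self.electrode_index if self.record_at == "electrode" else self.soma_index
        )
        self.inject_index = (
            self.electrode_index if self.inject_at == "electrode" else self.soma_index
        )
        if self.inject_index is None:
            raise ValueError("inject_at='electrode' requires an electrode")
        try:
            self.gate_record_index = next(
                s.index for s in self.segments if s.label == self.gate_record_label
            )
        except StopIteration:
            self.gate_record_index = self.soma_index

    # ------------------------------------------------------------------
    def with_uniform_gbar(self, channel: str, gbar: float) -> "CompartmentalModel":
        """Copy of the model with one channel's density set uniformly everywhere."""
        chans = dict(self.channels)
        base = chans[channel]
        chans[channel] = base.with_gbar({"all": float(gbar)})
        return CompartmentalModel(
            self.segments, self.passive, chans, self.electrode,
            self.inject_at, self.record_at, self.gate_record_label,
        )

    def init_at_voltage(self, V0: float) -> ModelState:
        """All compartments at V0, every gate at its steady state x_inf(V0)."""
        if not math.isfinite(V0):
            raise ValueError("V0 must be finite")
        V = np.full(self.n, float(V0))
        n_ch = len(self.channel_names)
        m = np.zeros((n_ch, self.n))
        h = np.ones((n_ch, self.n))
        for ci, name in enumerate(self.channel_names):
            spec = self.channels[name]
            m[ci, :] = spec.activation.steady_state(V0)
            if spec.has_inactivation:
                h[ci, :] = spec.inactivation.steady_state(V0)
        return ModelState(V=V, m=m, h=h)

    def _run_kernel(self, state: ModelState, stim: np.ndarray, dt: float,
                    mode: int, stim_idx: int, gclamp: float, order: int = 2):
        ga, gh = self._ga, self._gh
        return _core.run_kernel(
            self.parent, self.gax_uS, self.c_nF / dt, self.gpas_uS, self.epas,
            self.gs_uS, self.p_pow, self.Ech,
            ga[:, 0], ga[:, 1], ga[:, 2], ga[:, 3], ga[:, 4], ga[:, 5],
            self.has_h, gh[:, 0], gh[:, 1], gh[:, 2], gh[:, 3], gh[:, 4], gh[:, 5],
            state.m, state.h, state.V, dt, len(stim) - 1,
            mode, stim, stim_idx, gclamp,
            self.record_index, self.gate_record_index, order,
        )

    def run_current_clamp(self, protocol: ClampProtocol, order: int = 2) -> list[SimTrace]:
        """One SimTrace per step; model reinitialized at V0 before each step.

        ``order`` selects the implicit scheme: 2 = Crank-Nicolson
        (default), 1 = backward Euler.
        """
        if protocol.mode != "current":
            raise ValueError("protocol mode must be 'current'")
        traces = []
        for value in protocol.steps:
            state = self.init_at_voltage(protocol.V0)
            stim_nA = protocol.stim_array(value) / 1e3  # pA -> nA
            try:
                vrec, irec, mrec, hrec = self._run_kernel(
                    state, stim_nA, protocol.dt, _core.MODE_CURRENT,
                    self.inject_index, 0.0, order,
                )
            except Exception as exc:  # pragma: no cover
                raise SimulationError(f"current step {value} pA failed: {exc}") from exc
            gates = {
                name: (mrec[ci], hrec[ci]) for ci, name in enumerate(self.channel_names)
            }
            traces.append(SimTrace(
                t=protocol.time(), v=vrec, i=irec * 1e3, step_value=value,
                mode="current", dt=protocol.dt, gates=gates,
                method="crank_nicolson" if order == 2 else "backward_euler",
            ))
        return traces

    def run_voltage_clamp(
        self, protocol: ClampProtocol, series_resistance_mohm: float = 0.0,
        order: int = 2,
    ) -> list[SimTrace]:
        """Clamp at the injection site; records the current delivered (pA).

        An ideal source by default; a positive series resistance puts
        the source behind that resistance instead.
        """
        if protocol.mode != "voltage":
            raise ValueError("protocol mode must be 'voltage'")
        gclamp = 1e6 if series_resistance_mohm <= 0 else 1.0 / series_resistance_mohm
        traces = []
        for value in protocol.steps:
            state = self.init_at_voltage(protocol.V0)
            stim_mV = protocol.stim_array(value)
            vrec, irec, mrec, hrec = self._run_kernel(
                state, stim_mV, protocol.dt, _core.MODE_VOLTAGE,
                self.inject_index, gclamp, order,
            )
            gates = {
                name: (mrec[ci], hrec[ci]) for ci, name in enumerate(self.channel_names)
            }
            traces.append(SimTrace(
                t=protocol.time(), v=vrec, i=irec * 1e3, step_value=value,
                mode="voltage", dt=protocol.dt, gates=gates,
                method="crank_nicolson" if order == 2 else "backward_euler",
            ))
        return traces


def single_compartment(
    passive: PassiveParams, channels: dict[str, ChannelSpec] | None = None,
    diameter_um: float = 10.0, length_um: float = 10.0, label: int = SOMA,
    **kw,
) -> CompartmentalModel:
    """A one-compartment model (cylinder) — handy for clamp tests and oracles."""
    seg = Segment(
        index=0, section_id=1, label=label, length=length_um,
        diameter=diameter_um, r_prox=diameter_um / 2, r_dist=diameter_um / 2,
        area_cm2=math.pi * diameter_um * length_um * 1e-8, parent=None,
    )
    chans = {}
    for name, spec in (channels or {}).items():
        gb = dict(spec.gbar)
        chans[name] = spec.with_gbar(gb if gb else {"all": 0.0})
    return CompartmentalModel([seg], passive, chans, **kw)
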