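"""Hodgkin-Huxley channel formalism with the NaChBac parameterization.

Every channel carries the current density

    I = gbar * m^p * h * (V - E)        [mS/cm^2 * mV = uA/cm^2]

with gates obeying dx/dt = (x_inf(V) - x)/tau_x(V).  Steady states are
Boltzmann sigmoids and time constants are voltage sigmoids

    tau(V) = base + amp / (1 + exp((V - mid)/slope))   [ms].

Sign convention for the Boltzmann: activation curves are evaluated as
1/(1 + exp((V1/2 - V)/|k|)) so they increase with depolarization, and
inactivation as 1/(1 + exp((V - V1/2)/|k|)) so they decrease.  This is
the physiologically monotone reading of the published half-voltage and
slope magnitudes (the raw printed slope signs would invert both curves);
midpoint values are unaffected.

NaChBac (the Bacillus halodurans sodium channel) is fully parameterized
from published HEK293 whole-cell kinetics: activation V1/2 = -47.21 mV,
slope 8.17 mV, p = 3; inactivation V1/2 = -56.68 mV, slope 6.08 mV; very
slow, strongly voltage-dependent time constants that give the channel
its hallmark plateau ("NaChBac potential") behaviour.  The endogenous
transient Na (NaT), persistent Na (NaP) and delayed-rectifier K channels
are loaded from an editable, clearly-labelled synthetic parameter file
(see ``data/endogenous_channels_synthetic.yaml``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

#: reversal potentials (mV): sodium-family channels and delayed-rectifier K
E_NA = 60.0
E_K = -80.0


@dataclass(frozen=True)
class TauSigmoid:
    """Voltage-sigmoid time constant: base + amp/(1+exp((V-mid)/slope)), ms."""

    base: float
    amp: float
    mid: float
    slope: float

    def __call__(self, V):
        return self.base + self.amp / (1.0 + np.exp((np.asarray(V, float) - self.mid) / self.slope))


@dataclass(frozen=True)
class GatingParams:
    """Boltzmann steady state plus sigmoid time constant for one gate."""

    V12: float  # half-activation/inactivation voltage, mV
    k: float  # slope factor magnitude, mV
    direction: str  # "activation" | "inactivation"
    tau_spec: TauSigmoid

    def __post_init__(self):
        if self.direction not in ("activation", "inactivation"):
            raise ValueError(f"bad gate direction {self.direction!r}")

    def steady_state(self, V):
        """x_inf(V) in (0, 1); increasing for activation, decreasing for inactivation."""
        V = np.asarray(V, float)
        kk = abs(self.k)
        if self.direction == "activation":
            return 1.0 / (1.0 + np.exp((self.V12 - V) / kk))
        return 1.0 / (1.0 + np.exp((V - self.V12) / kk))

    def tau(self, V):
        """tau_x(V) in ms, strictly positive."""
        return self.tau_spec(V)


def steady_state(g: GatingParams, V):
    return g.steady_state(V)


def tau(g: GatingParams, V):
    return g.tau(V)


def gate_step(g: GatingParams, x, V, dt: float):
    """Exact exponential update of a gate over dt ms at fixed voltage V."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    xinf = g.steady_state(V)
    t = g.tau(V)
    return x + (xinf - x) * (1.0 - np.exp(-dt / t))


@dataclass
class ChannelSpec:
    """One voltage-gated channel: gates, reversal and per-region densities.

    ``gbar`` maps region labels (the SWC codes) to maximal conductance in
    mS/cm^2; the special key ``"all"`` sets a baseline density for every
    region, which an explicit region entry overrides (not adds to).
    """

    name: str
    p: int
    activation: GatingParams
    inactivation: GatingParams | None
    E: float  # mV
    gbar: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("activation power p must be >= 1")
        for k, v in self.gbar.items():
            if v < 0:
                raise ValueError(f"gbar[{k}] must be >= 0")

    @property
    def has_inactivation(self) -> bool:
        return self.inactivation is not None

    def gbar_for_label(self, label: int) -> float:
        """Density (mS/cm^2) in a region; explicit label overrides 'all'."""
        if label in self.gbar:
            return self.gbar[label]
        return self.gbar.get("all", 0.0)

    def with_gbar(self, gbar: dict) -> "ChannelSpec":
        return ChannelSpec(self.name, self.p, self.activation, self.inactivation, self.E, dict(gbar))


@dataclass
class ChannelState:
    """Per-segment gate values for one channel; m and h stay in [0, 1]."""

    m: np.ndarray
    h: np.ndarray


def hh_current(spec: ChannelSpec, state: ChannelState, V, gbar=None):
    """HH current density I = gbar * m^p * h * (V - E) in uA/cm^2 (positive = outward)."""
    V = np.asarray(V, float)
    g = np.asarray(gbar if gbar is not None else spec.gbar.get("all", 0.0), float)
    h = state.h if spec.has_inactivation else 1.0
    return g * state.m**spec.p * h * (V - spec.E)


def init_state(spec: ChannelSpec, V0: float, n: int = 1) -> ChannelState:
    """Gate state at steady state for voltage V0."""
    m = np.full(n, float(spec.activation.steady_state(V0)))
    if spec.has_inactivation:
        h = np.full(n, float(spec.inactivation.steady_state(V0)))
    else:
        h = np.ones(n)
    return ChannelState(m=m, h=h)


# ---------------------------------------------------------------------------
# bundled parameter files


def _data_path(name: str) -> Path:
    return Path(resources.files("kcmodel") / "data" / name)


def _gate_from_dict(d: dict, direction: str) -> GatingParams:
    t = d["tau"]
    return GatingParams(
        V12=float(d["V12"]), k=float(d["k"]), direction=direction,
        tau_spec=TauSigmoid(float(t["base"]), float(t["amp"]), float(t["mid"]), float(t["slope"])),
    )


def load_channel_file(path: str | Path) -> dict[str, ChannelSpec]:
    """Read channel definitions from a YAML parameter file."""
    raw = yaml.safe_load(Path(path).read_text())
    specs: dict[str, ChannelSpec] = {}
    for name, c in raw["channels"].items():
        act = _gate_from_dict(c["activation"], "activation")
        inact = _gate_from_dict(c["inactivation"], "inactivation") if "inactivation" in c else None
        specs[name] = ChannelSpec(
            name=name, p=int(c["p"]), activation=act, inactivation=inact,
            E=float(c["E"]), gbar={},
        )
    return specs


def load_default_channels() -> dict[str, ChannelSpec]:
    """NaChBac plus the bundled endogenous-channel definitions."""
    specs = load_channel_file(_data_path("nachbac.yaml"))
    specs.update(load_channel_file(_data_path("endogenous_channels_synthetic.yaml")))
    return specs


def load_conductance_presets() -> dict[str, dict]:
    """The published per-region maximal-conductance presets (mS/cm^2).

    Six rows: three wild-type and three NaChBac-expressing parameter
    sets; the starred rows ("WT*", "NaChBac*") are the representative
    models.  Region keys are SWC labels, "all" is a whole-cell baseline
    that explicit soma/SIZ entries override.
    """
    raw = yaml.safe_load(_data_path("conductance_presets.yaml").read_text())
    return raw["presets"]


def presets() -> dict[str, dict[str, ChannelSpec]]:
    """Named, fully-wired channel sets for each conductance preset row.

    Returns a mapping preset-name -> {channel name -> ChannelSpec with
    per-region gbar filled in}.
    """
    base = load_default_channels()
    table = load_conductance_presets()
    out: dict[str, dict[str, ChannelSpec]] = {}
    for preset_name, row in table.items():
        chans: dict[str, ChannelSpec] = {}
        for ch_name, spec in base.items():
            gbar = {}
            for region_key, value in row.get(ch_name, {}).items():
                gbar["all" if region_key == "all" else int(region_key)] = float(value)
            chans[ch_name] = spec.with_gbar(gbar)
        out[preset_name] = chans
    return out
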