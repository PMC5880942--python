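"""Model parameters for the adapting sensory network.

Internal unit system: mV / ms / uA / kOhm (so ``R_m * I`` is in mV).
The two inhibitory coupling strengths that are conventionally quoted in nA
(``J_EI``, ``J_IE``) are stored converted to uA; ``from_nA`` helpers on the
loader keep the config file in those units.

The external white-noise amplitude ``sigma_ext`` is the spectral amplitude of
a delta-correlated current with the delta function normalised per *second*;
in a discrete step of ``dt`` ms the injected current is
``sigma_ext * z * sqrt(1000 / dt)`` with ``z ~ N(0,1)``.  This makes the
stationary membrane-potential fluctuation ``R_m * sigma_ext / sqrt(2 tau_m[s])``
(~6 mV at defaults) independent of the step size.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: jump conventions for the delta-function source terms in the ODEs.
#: "coefficient": a spike increments the variable by the equation's coefficient
#: (standard Tsodyks-Markram bookkeeping); "coefficient-over-tau": strict
#: ODE reading, increment = coefficient / tau.
DELTA_CONVENTIONS = ("jump-equals-coefficient", "jump-equals-coefficient-over-tau")

NA_PER_UA = 1e-3  # 1 nA = 1e-3 uA


@dataclass
class NetworkParams:
    """Full parameter set of the sensory network and read-out neuron."""

    # single-neuron
    V_th_E: float = -55.0     # mV, spiking threshold of excitatory neurons
    V_th_I: float = -57.0     # mV, spiking threshold of inhibitory neurons
    E_L: float = -65.0        # mV, resting / reset potential
    tau_m: float = 20.0       # ms, membrane time constant
    tau_a: float = 250.0      # ms, adaptation time constant
    A_s: float = 1.0          # uA, spike-triggered adaptation increment
    A_p: float = 0.1          # 1/kOhm, subthreshold adaptation gain
    tau_o: float = 20.0       # ms, read-out membrane time constant
    R_m: float = 1.0          # kOhm, membrane resistance

    # synaptic
    J_EE: float = 6.0         # uA, maximal E->E efficacy (scaled by u*x)
    J_EI: float = 5.0 * NA_PER_UA   # uA, E->I efficacy (5 nA)
    J_IE: float = 4.0 * NA_PER_UA   # uA, I->E efficacy (4 nA)
    tau_s: float = 5.0        # ms, synaptic current time constant
    U: float = 0.00525        # facilitation increment of release probability
    tau_f: float = 400.0      # ms, facilitation time constant
    tau_d: float = 1000.0     # ms, depression time constant
    J_s: float = 0.129        # uA, constant E->E efficacy of the static model

    # network
    T: float = 5000.0         # ms, total simulated time per trial
    T_f: float = 100.0        # ms, window for population firing rates
    t_w: float = 5.0          # ms, bin for population-synchrony fractions
    p: float = 0.1            # connection probability
    N_E: int = 2000
    N_I: int = 500
    mu_ext: float = 0.65      # uA, mean stimulus current (E neurons)
    mu_b: float = 0.45        # uA, mean background current
    sigma_ext: float = 1.2    # uA, white-noise amplitude (delta per second)
    J_EO: float = 1.0         # uA, E -> read-out efficacy
    J_IO: float = 2.0         # uA, I -> read-out efficacy

    # integration / recording
    dt: float = 0.1           # ms, Euler step
    record_dt: float = 1.0    # ms, sampling interval of dense traces
    delta_convention: str = "jump-equals-coefficient"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("tau_m", "tau_a", "tau_s", "tau_f", "tau_d", "tau_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"time constant {name} must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("connection probability p must lie in [0, 1]")
        if not 0.0 <= self.U <= 1.0:
            raise ValueError("facilitation increment U must lie in [0, 1]")
        if self.N_E < 0 or self.N_I < 0:
            raise ValueError("population sizes must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > self.tau_s / 10:
            raise ValueError("dt must be small relative to tau_s (dt <= tau_s/10)")
        if self.delta_convention not in DELTA_CONVENTIONS:
            raise ValueError(
                f"delta_convention must be one of {DELTA_CONVENTIONS}, "
                f"got {self.delta_convention!r}"
            )
        # record_dt must be an integer multiple of dt
        ratio = self.record_dt / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("record_dt must be an integer multiple of dt")

    # -- convenience -------------------------------------------------------

    @property
    def n_total(self) -> int:
        return self.N_E + self.N_I

    @property
    def noise_scale(self) -> float:
        """Per-step multiplier of a unit normal giving the noise current (uA)."""
        return self.sigma_ext * (1000.0 / self.dt) ** 0.5

    @property
    def record_stride(self) -> int:
        return round(self.record_dt / self.dt)

    def replace(self, **changes: Any) -> "NetworkParams":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "NetworkParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "NetworkParams":
        """Load parameters from a YAML or JSON config file.

        The file uses the standard symbol names.  The keys ``J_EI_nA`` and
        ``J_IE_nA`` may be used to give those couplings in nA.
        """
        text = Path(path).read_text()
        d = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if d is None:
            d = {}
        for key, target in (("J_EI_nA", "J_EI"), ("J_IE_nA", "J_IE")):
            if key in d:
                d[target] = float(d.pop(key)) * NA_PER_UA
        return cls.from_dict(d)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix in (".yml", ".yaml"):
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            p.write_text(json.dumps(self.to_dict(), indent=2))


#: STP parameter variants (tau_f ms, tau_d ms, U) probed in the robustness
#: experiment; U is lowered as tau_f grows so firing still adapts.
STP_VARIANTS: dict[str, dict[str, float]] = {
    "tf1000": {"tau_f": 1000.0, "tau_d": 400.0, "U": 0.0018},
    "tf400": {"tau_f": 400.0, "tau_d": 400.0, "U": 0.00425},
    "tf50": {"tau_f": 50.0, "tau_d": 400.0, "U": 0.02},
}
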