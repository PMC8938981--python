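"""Model parameters: neuron tables, projection table, and dopamine modulation.

All quantities use a consistent unit system (pF, nS, mV, ms, pA) in which
``C dV/dt`` and ``g (V - E)`` are both in pA without conversion factors.

The dopamine level ``alpha_dop`` ranges from 0 (dopamine-depleted, PD) to 1
(high dopamine); the healthy/normal operating point is ``alpha_dop = 0.8``.
Modulation is linear in ``phi = alpha_dop - 0.8``: selected resting
potentials, the D1-SPN spike threshold, and selected synaptic weights are
scaled by ``(1 + beta * phi)`` with per-parameter sensitivities ``beta``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

logger = logging.getLogger("bgnet")

POPULATIONS = ("D1-SPN", "D2-SPN", "FSI", "STN", "GPe-TA", "GPe-TI", "SNr")

#: population sizes; the whole network has 6539 neurons
POPULATION_SIZES = {
    "D1-SPN": 2000,
    "D2-SPN": 2000,
    "FSI": 80,
    "STN": 388,
    "GPe-TA": 329,
    "GPe-TI": 988,
    "SNr": 754,
}

ALPHA_NORMAL = 0.8

CONDITION_NAMES = ("normal", "PD-biphasic", "PD-triphasic")


class ConfigurationError(ValueError):
    """Raised for unknown population/projection names or inconsistent setups."""


@dataclass
class DopamineState:
    """Tonic dopamine level and its offset from the healthy reference."""

    alpha_dop: float
    alpha_normal: float = ALPHA_NORMAL

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_dop <= 1.0:
            raise ConfigurationError(
                f"dopamine level must lie in [0, 1], got {self.alpha_dop}"
            )

    @property
    def phi(self) -> float:
        return self.alpha_dop - self.alpha_normal


@dataclass
class LIFParams:
    """Leaky integrate-and-fire parameters for one population.

    ``beta_EL``/``beta_Vth`` are the dopamine sensitivities of the leak
    reversal and spike threshold (0 when the population is not modulated).
    """

    C_m: float          # pF
    g_L: float          # nS
    E_L: float          # mV
    V_th: float         # mV
    V_reset: float      # mV
    E_ex: float         # mV
    E_in: float         # mV
    tau_syn_ex: float   # ms
    tau_syn_in: float   # ms
    I_e: float          # pA
    t_ref: float = 2.0  # ms
    beta_EL: float = 0.0
    beta_Vth: float = 0.0

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.g_L <= 0:
            raise ConfigurationError("C_m and g_L must be positive")
        if self.tau_syn_ex <= 0 or self.tau_syn_in <= 0:
            raise ConfigurationError("synaptic time constants must be positive")


@dataclass
class AdExParams(LIFParams):
    """Adaptive exponential integrate-and-fire parameters.

    ``V_th`` holds the spike-initiation threshold V_T of the exponential
    term; an emitted spike is registered when V crosses ``V_peak``.
    """

    a: float = 0.0        # nS, subthreshold adaptation
    b: float = 0.0        # pA, spike-triggered adaptation increment
    Delta_T: float = 1.0  # mV slope factor (printed with ms units; used as mV)
    tau_w: float = 20.0   # ms
    V_peak: float = 0.0   # mV, numerical spike cutoff

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.tau_w <= 0 or self.Delta_T <= 0:
            raise ConfigurationError("tau_w and Delta_T must be positive")
        if self.V_peak <= self.V_th:
            raise ConfigurationError("V_peak must exceed the spike threshold")


@dataclass
class ProjectionSpec:
    """One directed pathway: in-degree K, peak conductance, delay, dopamine beta.

    Negative weights are inhibitory (routed through the E_in channel of the
    target); positive weights excitatory. ``beta`` is 0 for pathways the
    dopamine model leaves untouched.
    """

    source: str
    target: str
    K: int
    weight: float  # nS, signed
    delay: float   # ms
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.source not in POPULATIONS or self.target not in POPULATIONS:
            raise ConfigurationError(
                f"unknown population in projection {self.source}->{self.target}"
            )
        if not 1 <= self.K <= POPULATION_SIZES[self.source]:
            raise ConfigurationError(
                f"in-degree {self.K} invalid for source {self.source}"
            )
        if self.delay <= 0:
            raise ConfigurationError("delay must be positive")

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"


def _lif(**kw) -> LIFParams:
    return LIFParams(**kw)


def _adex(**kw) -> AdExParams:
    return AdExParams(**kw)


#: neuron parameters per population at the healthy reference (phi = 0)
NEURON_PARAMS = {
    "D1-SPN": _lif(C_m=192.0, g_L=8.04, E_L=-87.2, V_th=-45.0, V_reset=-87.2,
                   E_ex=0.0, E_in=-64.0, tau_syn_ex=0.3, tau_syn_in=2.0,
                   I_e=128.0, beta_EL=0.05, beta_Vth=0.205),
    "D2-SPN": _lif(C_m=157.0, g_L=6.46, E_L=-85.4, V_th=-45.0, V_reset=-85.4,
                   E_ex=0.0, E_in=-64.0, tau_syn_ex=0.3, tau_syn_in=2.0,
                   I_e=0.0),
    "FSI": _lif(C_m=700.0, g_L=16.67, E_L=-65.0, V_th=-54.0, V_reset=-65.0,
                E_ex=0.0, E_in=-76.0, tau_syn_ex=0.3, tau_syn_in=2.0,
                I_e=0.0, beta_EL=-0.078),
    # STN E_ex = -10 mV is atypical but is the printed value; it still lies
    # above the STN operating range so excitatory input depolarizes.
    "STN": _lif(C_m=60.0, g_L=10.0, E_L=-80.2, V_th=-64.0, V_reset=-70.0,
                E_ex=-10.0, E_in=-84.0, tau_syn_ex=0.33, tau_syn_in=1.5,
                I_e=1.0),
    "GPe-TA": _adex(C_m=60.0, g_L=1.0, E_L=-55.1, V_th=-54.7, V_reset=-60.0,
                    E_ex=0.0, E_in=-65.0, tau_syn_ex=1.0, tau_syn_in=5.5,
                    I_e=1.0, beta_EL=-0.181, a=2.5, b=105.0, Delta_T=2.55,
                    tau_w=20.0),
    "GPe-TI": _adex(C_m=40.0, g_L=1.0, E_L=-55.1, V_th=-54.7, V_reset=-60.0,
                    E_ex=0.0, E_in=-65.0, tau_syn_ex=4.8, tau_syn_in=1.0,
                    I_e=12.0, beta_EL=-0.181, a=2.5, b=70.0, Delta_T=1.7,
                    tau_w=20.0),
    "SNr": _adex(C_m=80.0, g_L=3.0, E_L=-55.8, V_th=-55.2, V_reset=-65.0,
                 E_ex=0.0, E_in=-80.0, tau_syn_ex=5.7, tau_syn_in=2.04,
                 I_e=0.0, beta_EL=-0.0896, a=3.0, b=200.0, Delta_T=1.6,
                 tau_w=20.0),
}

# (source, target, K, weight nS, delay ms)
_PROJECTION_TABLE = [
    ("D1-SPN", "D1-SPN", 364, -0.15, 1.7),
    ("D1-SPN", "D2-SPN", 84, -0.375, 1.7),
    ("D2-SPN", "D1-SPN", 392, -0.45, 1.7),
    ("D2-SPN", "D2-SPN", 504, -0.35, 1.7),
    ("FSI", "D1-SPN", 16, -2.6, 1.7),
    ("FSI", "D2-SPN", 11, -2.6, 1.7),
    ("GPe-TA", "D1-SPN", 10, -0.02, 7.0),
    ("GPe-TA", "D2-SPN", 10, -0.04, 7.0),
    ("FSI", "FSI", 10, -0.4, 1.7),
    ("GPe-TA", "FSI", 10, -0.25, 7.0),
    ("GPe-TI", "FSI", 10, -1.0, 7.0),
    ("GPe-TI", "SNr", 32, -52.5, 3.0),
    ("D1-SPN", "SNr", 500, -15.0, 7.0),
    ("STN", "SNr", 30, 4.78, 4.0),
    ("D2-SPN", "GPe-TI", 500, -1.08, 7.0),
    ("STN", "GPe-TA", 30, 0.24, 2.0),
    ("STN", "GPe-TI", 30, 0.175, 2.0),
    ("GPe-TA", "GPe-TA", 5, -0.11, 1.0),
    ("GPe-TA", "GPe-TI", 5, -1.3, 1.0),
    ("GPe-TI", "GPe-TA", 25, -0.35, 1.0),
    ("GPe-TI", "GPe-TI", 25, -1.3, 1.0),
    ("GPe-TI", "STN", 30, -0.3, 1.0),
]

#: dopamine sensitivity per projection, default (PD-biphasic) parameter set
_BETA_BIPHASIC = {
    "FSI->FSI": -1.27,
    "GPe-TA->FSI": -0.53,
    "GPe-TI->FSI": -0.53,
    "GPe-TA->GPe-TA": -0.83,
    "GPe-TA->GPe-TI": -0.83,
    "GPe-TI->GPe-TA": -0.83,
    "GPe-TI->GPe-TI": -0.83,
    "D2-SPN->GPe-TI": -1.00,
    "STN->GPe-TA": -0.3,
    "STN->GPe-TI": -0.3,
    "FSI->D2-SPN": -0.90,
    "D1-SPN->D1-SPN": 0.88,
    "D1-SPN->D2-SPN": 0.88,
    "D2-SPN->D1-SPN": 0.88,
    "D2-SPN->D2-SPN": 0.88,
    "GPe-TA->D1-SPN": -1.22,
    "GPe-TA->D2-SPN": -1.15,
    "D1-SPN->SNr": 0.42,
    "GPe-TI->STN": -0.54,
}

#: overrides that turn the PD parameter set from biphasic into triphasic
TRIPHASIC_BETA_OVERRIDES = {
    "D2-SPN->GPe-TI": -0.48,
    "D1-SPN->SNr": 0.56,
    "GPe-TI->STN": -0.24,
}

#: dopamine sensitivity of the cortical (stimulus) pathway weights
CORTEX_BETA = {"D1-SPN": 1.04, "D2-SPN": -0.26, "STN": -1.15}

#: per-population baseline firing-rate target bands (Hz) used for calibration
BACKGROUND_TARGETS = {
    "normal": {
        "D1-SPN": (0.01, 2.0),
        "D2-SPN": (0.01, 2.0),
        "FSI": (10.0, 20.0),
        "STN": (10.0, 13.0),
        "GPe-TA": (10.7, 12.9),   # 11.8 +/- 1.1
        "GPe-TI": (23.5, 24.9),   # 24.2 +/- 0.7
        "SNr": (20.0, 35.0),
    },
    "PD": {
        "D1-SPN": (0.1, 0.5),
        "D2-SPN": (1.0, 2.0),
        "FSI": (10.0, 20.0),
        "STN": (26.0, 29.0),
        "GPe-TA": (12.0, 16.0),
        "GPe-TI": (17.0, 20.0),
        "SNr": (20.0, 35.0),      # unchanged relative to normal
    },
}


def modulate_neuron(params: LIFParams, population: str,
                    dopamine: DopamineState) -> LIFParams:
    """Apply dopamine modulation to one population's neuron parameters.

    E_L is scaled by (1 + beta_EL * phi) for the modulated populations and
    V_th additionally for D1-SPN; every other field is returned unchanged.
    The transform is the identity at phi = 0.
    """
    if population not in POPULATIONS:
        raise ConfigurationError(f"unknown population {population!r}")
    phi = dopamine.phi
    out = replace(params)
    if params.beta_EL != 0.0:
        out = replace(out, E_L=params.E_L * (1.0 + params.beta_EL * phi))
    if params.beta_Vth != 0.0:
        out = replace(out, V_th=params.V_th * (1.0 + params.beta_Vth * phi))
    return out


def modulate_weight(weight: float, beta: float,
                    dopamine: DopamineState) -> float:
    """Scale a synaptic weight by (1 + beta * phi); linear in phi.

    A result whose sign differs from the input would flip the synapse's
    polarity; this never happens for the published parameter values, so it
    is flagged with a warning rather than an error.
    """
    out = weight * (1.0 + beta * dopamine.phi)
    if weight != 0.0 and out * weight < 0.0:
        warnings.warn(
            f"dopamine modulation flipped synapse sign "
            f"({weight} -> {out}, beta={beta}, phi={dopamine.phi})",
            RuntimeWarning,
        )
        logger.warning("sign flip in modulate_weight: %s -> %s", weight, out)
    return out


@dataclass
class ConditionBundle:
    """A complete, internally consistent parameter set for one condition.

    ``neuron_params`` and ``projections`` hold the *effective* (dopamine
    modulated) values; ``projections_base`` keeps the healthy reference
    values so sweeps and restorations can work from the unmodulated table.
    ``background`` maps population -> (rate Hz, weight nS) of the external
    Poisson drive; ``stimulus_weights`` maps the stimulated populations to
    the effective cortical stimulus weight.
    """

    name: str
    dopamine: DopamineState
    neuron_params: dict
    projections: dict               # name -> ProjectionSpec (effective weight)
    projections_base: dict          # name -> ProjectionSpec (healthy weight)
    background: dict = field(default_factory=dict)
    stimulus_weights: dict = field(default_factory=dict)
    background_targets: dict = field(default_factory=dict)
    d2_modulation: bool = False

    def effective_weight(self, proj_name: str) -> float:
        return self.projections[proj_name].weight

    def to_dict(self) -> dict:
        def enc_params(p):
            d = dataclasses.asdict(p)
            d["kind"] = "AdEx" if isinstance(p, AdExParams) else "LIF"
            return d

        return {
            "name": self.name,
            "alpha_dop": self.dopamine.alpha_dop,
            "alpha_normal": self.dopamine.alpha_normal,
            "d2_modulation": self.d2_modulation,
            "neuron_params": {k: enc_params(v)
                              for k, v in self.neuron_params.items()},
            "projections": {k: dataclasses.asdict(v)
                            for k, v in self.projections.items()},
            "projections_base": {k: dataclasses.asdict(v)
                                 for k, v in self.projections_base.items()},
            "background": {k: list(v) for k, v in self.background.items()},
            "stimulus_weights": dict(self.stimulus_weights),
            "background_targets": {k: list(v)
                                   for k, v in self.background_targets.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionBundle":
        def dec_params(pd):
            pd = dict(pd)
            kind = pd.pop("kind")
            return AdExParams(**pd) if kind == "AdEx" else LIFParams(**pd)

        return cls(
            name=d["name"],
            dopamine=DopamineState(d["alpha_dop"], d["alpha_normal"]),
            neuron_params={k: dec_params(v)
                           for k, v in d["neuron_params"].items()},
            projections={k: ProjectionSpec(**v)
                         for k, v in d["projections"].items()},
            projections_base={k: ProjectionSpec(**v)
                              for k, v in d["projections_base"].items()},
            background={k: tuple(v) for k, v in d["background"].items()},
            stimulus_weights=dict(d["stimulus_weights"]),
            background_targets={k: tuple(v)
                                for k, v in d["background_targets"].items()},
            d2_modulation=d.get("d2_modulation", False),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "ConditionBundle":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def projection_table(self) -> "pandas.DataFrame":  # noqa: F821
        """Audit dump: one row per projection with base and effective weight."""
        import pandas as pd

        rows = []
        for name, p in sorted(self.projections.items()):
            rows.append({
                "source": p.source, "target": p.target, "K": p.K,
                "weight_normal": self.projections_base[name].weight,
                "weight_effective": p.weight,
                "delay": p.delay, "beta": p.beta,
            })
        return pd.DataFrame(rows)


def projection_betas(condition: str, d2_modulation: bool = False) -> dict:
    """Per-projection dopamine sensitivities for a condition preset.

    ``d2_modulation`` is a toggle for the control experiment in which
    dopamine is also allowed to act on D2-SPN excitability; by default
    D2-SPNs are left unmodulated.
    """
    betas = dict(_BETA_BIPHASIC)
    if condition == "PD-triphasic":
        betas.update(TRIPHASIC_BETA_OVERRIDES)
    return betas


# Default D2-SPN excitability sensitivities for the optional control toggle
# (mirrors the D1-SPN mechanism; off unless requested).
D2_CONTROL_BETAS = {"beta_EL": 0.05, "beta_Vth": 0.205}


def build_condition(name: str, alpha_dop: Optional[float] = None,
                    d2_modulation: bool = False) -> ConditionBundle:
    """Build the full parameter bundle for a named condition preset.

    normal -> alpha_dop = 0.8 (phi = 0, Tables as printed); both PD presets
    -> alpha_dop = 0; PD-triphasic additionally swaps in the three override
    betas. ``alpha_dop`` may be overridden for dopamine-level sweeps.
    """
    if name not in CONDITION_NAMES:
        raise ConfigurationError(f"unknown condition preset {name!r}")
    if alpha_dop is None:
        alpha_dop = ALPHA_NORMAL if name == "normal" else 0.0
    dop = DopamineState(alpha_dop)
    betas = projection_betas(name, d2_modulation)

    neuron_params = {}
    for pop, p in NEURON_PARAMS.items():
        if pop == "D2-SPN" and d2_modulation:
            p = replace(p, **D2_CONTROL_BETAS)
        neuron_params[pop] = modulate_neuron(p, pop, dop)

    projections, projections_base = {}, {}
    for src, tgt, K, w, delay in _PROJECTION_TABLE:
        base = ProjectionSpec(src, tgt, K, w, delay,
                              beta=betas.get(f"{src}->{tgt}", 0.0))
        eff = replace(base, weight=modulate_weight(w, base.beta, dop))
        projections_base[base.name] = base
        projections[base.name] = eff

    targets = BACKGROUND_TARGETS["normal" if name == "normal" else "PD"]
    return ConditionBundle(
        name=name, dopamine=dop, neuron_params=neuron_params,
        projections=projections, projections_base=projections_base,
        background_targets=dict(targets), d2_modulation=d2_modulation,
    )
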