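"""λ-window schedule and per-window interaction scaling.

A single coupling parameter λ ∈ [0, 1] morphs ligand A (fully coupled at
λ = 0) into ligand B (fully coupled at λ = 1). Only the alchemical regions
scale: van der Waals interactions of disappearing atoms ramp linearly from
1 to 0 over the whole λ range (and appearing atoms mirror them), while
electrostatics are switched on a narrower ramp to avoid overlapping-charge
singularities — disappearing charges decouple linearly over λ ∈ [0, 0.55]
and stay off beyond, appearing charges couple linearly over λ ∈ [0.45, 1]
and are extinguished below. The soft-core radius-shifting coefficient
(default 5) is carried as metadata for engine configuration; the soft-core
energy itself is never evaluated here.

The standard production protocol uses 13 windows
(0, 0.05, 0.1, 0.2, ..., 0.9, 0.95, 1) and an ensemble of 5 replicas of
4 ns each per window, recording ∂U/∂λ every 2 ps.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .errors import ConfigurationError

#: The 13 standard λ values: endpoints, 0.05/0.95 shoulders, interior step 0.1.
STANDARD_LAMBDAS: tuple[float, ...] = (
    0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.0)

ELEC_DIS_OFF = 0.55   # disappearing electrostatics fully off at and beyond this λ
ELEC_APP_ON = 0.45    # appearing electrostatics start coupling at this λ

DISAPPEARING = "disappearing"
APPEARING = "appearing"


@dataclass(frozen=True)
class LambdaWindow:
    """One alchemical state: λ plus the four interaction scaling factors."""

    lam: float
    elec_scale_dis: float
    elec_scale_app: float
    vdw_scale_dis: float
    vdw_scale_app: float


@dataclass
class ProtocolConfig:
    """Tunable parameters of the coupling protocol.

    ``softcore_shift_coeff`` is the radius-shifting coefficient of the
    engine's soft-core van der Waals potential, recorded for config emission
    only. Times are in ns/ps as named.
    """

    window_values: tuple[float, ...] = STANDARD_LAMBDAS
    elec_dis_off: float = ELEC_DIS_OFF
    elec_app_on: float = ELEC_APP_ON
    ensemble_size: int = 5
    production_ns: float = 4.0
    sample_interval_ps: float = 2.0
    softcore_shift_coeff: float = 5.0

    def __post_init__(self):
        w = tuple(float(x) for x in self.window_values)
        if len(w) < 2 or w[0] != 0.0 or w[-1] != 1.0:
            raise ConfigurationError("window values must start at 0 and end at 1")
        if any(x >= y for x, y in zip(w, w[1:])):
            raise ConfigurationError("window values must be strictly increasing")
        if not (0.0 < self.elec_app_on < self.elec_dis_off < 1.0):
            raise ConfigurationError(
                "electrostatic breakpoints must satisfy 0 < app_on < dis_off < 1")
        if self.ensemble_size < 1:
            raise ConfigurationError("ensemble_size must be >= 1")
        self.window_values = w


def elec_scaling(lam: float, role: str,
                 dis_off: float = ELEC_DIS_OFF, app_on: float = ELEC_APP_ON) -> float:
    """Electrostatic coupling factor at λ for one alchemical role.

    Disappearing charges ramp 1 → 0 linearly over [0, ``dis_off``] and are
    fully off beyond; appearing charges ramp 0 → 1 over [``app_on``, 1] and
    are fully off below.
    """
    _check_lambda(lam)
    if role == DISAPPEARING:
        return max(0.0, 1.0 - lam / dis_off)
    if role == APPEARING:
        return min(1.0, max(0.0, (lam - app_on) / (1.0 - app_on)))
    raise ConfigurationError(f"unknown role {role!r}")


def vdw_scaling(lam: float, role: str) -> float:
    """Van der Waals coupling factor: linear over the whole λ range."""
    _check_lambda(lam)
    if role == DISAPPEARING:
        return 1.0 - lam
    if role == APPEARING:
        return lam
    raise ConfigurationError(f"unknown role {role!r}")


def _check_lambda(lam: float) -> None:
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")


def make_window(lam: float, cfg: ProtocolConfig | None = None) -> LambdaWindow:
    cfg = cfg or ProtocolConfig()
    return LambdaWindow(
        lam=lam,
        elec_scale_dis=elec_scaling(lam, DISAPPEARING, cfg.elec_dis_off, cfg.elec_app_on),
        elec_scale_app=elec_scaling(lam, APPEARING, cfg.elec_dis_off, cfg.elec_app_on),
        vdw_scale_dis=vdw_scaling(lam, DISAPPEARING),
        vdw_scale_app=vdw_scaling(lam, APPEARING),
    )


def schedule(cfg: ProtocolConfig | None = None) -> list[LambdaWindow]:
    """All windows of a protocol, with scale factors populated."""
    cfg = cfg or ProtocolConfig()
    return [make_window(lam, cfg) for lam in cfg.window_values]


def standard_schedule() -> list[LambdaWindow]:
    """The 13-window standard schedule."""
    return schedule(ProtocolConfig())


def emit_protocol_config(cfg: ProtocolConfig, format: str = "yaml") -> str:
    """Serialize a protocol as YAML (round-trippable) or a NAMD-style
    config fragment (advisory text, not bit-compatible with any engine
    version)."""
    if format == "yaml":
        doc = {
            "protocol": {
                "window_values": list(cfg.window_values),
                "elec_dis_off": cfg.elec_dis_off,
                "elec_app_on": cfg.elec_app_on,
                "ensemble_size": cfg.ensemble_size,
                "production_ns": cfg.production_ns,
                "sample_interval_ps": cfg.sample_interval_ps,
                "softcore_shift_coeff": cfg.softcore_shift_coeff,
            }
        }
        return yaml.safe_dump(doc, sort_keys=True)
    if format == "namd_fragment":
        lines = [
            "# alchemical TI fragment (advisory)",
            "alch                 on",
            "alchType             ti",
            f"alchVdwShiftCoeff    {cfg.softcore_shift_coeff:g}",
            f"alchElecLambdaStart  {cfg.elec_app_on:g}",
            "alchVdwLambdaEnd     1.0",
            f"alchOutFreq          {int(round(cfg.sample_interval_ps / 0.002)):d}",
            "# lambda windows: " + " ".join(f"{x:g}" for x in cfg.window_values),
        ]
        return "\n".join(lines) + "\n"
    raise ConfigurationError(f"unknown protocol format {format!r}")


def parse_protocol_config(text: str) -> ProtocolConfig:
    """Read back a YAML protocol produced by :func:`emit_protocol_config`."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "protocol" not in doc:
        raise ConfigurationError("not a protocol document (missing 'protocol' key)")
    p = doc["protocol"]
    return ProtocolConfig(
        window_values=tuple(p["window_values"]),
        elec_dis_off=p.get("elec_dis_off", ELEC_DIS_OFF),
        elec_app_on=p.get("elec_app_on", ELEC_APP_ON),
        ensemble_size=p.get("ensemble_size", 5),
        production_ns=p.get("production_ns", 4.0),
        sample_interval_ps=p.get("sample_interval_ps", 2.0),
        softcore_shift_coeff=p.get("softcore_shift_coeff", 5.0),
    )
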