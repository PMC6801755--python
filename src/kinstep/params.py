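"""Motor parameter sets, physical constants and experimental conditions.

A kinesin dimer is characterised by a small set of kinetic constants: the
zero-force stepping ratio ``r0`` (forward steps per backward step), the
stall-force scale ``FS``, the trailing- and leading-head ATPase rates
``k_plus``/``k_minus``, the zero-force escape probability ``P0_zero`` of the
freshly produced ADP-head (1 for wild-type dimers whose neck linkers are
under high internal tension, <1 for extended-neck-linker mutants), and two
nucleotide-kinetics constants ``kb`` (second-order ATP binding) and
``k_off_leading`` (ATP dissociation from the leading head) that only matter
away from saturating ATP.

The module ships a registry of published parameter sets for seven motor
species (three wild-type kinesin-1 dimers, three kinesin-1 neck-linker
mutants, and the kinesin-2 KIF17) plus a tolerant plain-text (YAML) config
reader for user-defined motors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import yaml

__all__ = [
    "KB",
    "SATURATING",
    "MotorParams",
    "Conditions",
    "ThermalScale",
    "make_motor_params",
    "preset",
    "preset_names",
    "thermal_scale",
    "load_motor_config",
    "dump_motor_config",
]

#: Boltzmann constant in pN·nm/K (CODATA 1.380649e-23 J/K).
KB = 0.0138065

#: Sentinel ATP concentration meaning "saturating": nucleotide binding is
#: never rate limiting and the closed-form theory applies.
SATURATING = math.inf


@dataclass(frozen=True)
class ThermalScale:
    """Thermal energy scale at a given temperature."""

    kBT: float  # pN·nm
    beta: float  # (pN·nm)^-1


def thermal_scale(T: float = 298.0) -> ThermalScale:
    """Thermal energy ``kB*T`` in pN·nm (4.114 pN·nm at room temperature)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got T={T}")
    kBT = KB * T
    return ThermalScale(kBT=kBT, beta=1.0 / kBT)


_VALIDATORS = {
    "r0": (lambda v: v > 1, "must exceed 1 (forward bias at zero force)"),
    "FS": (lambda v: v > 0, "must be positive"),
    "k_plus": (lambda v: v > 0, "must be positive"),
    "k_minus": (lambda v: v >= 0, "must be non-negative"),
    "P0_zero": (lambda v: 0 < v <= 1, "must lie in (0, 1]"),
    "kb": (lambda v: v >= 0, "must be non-negative"),
    "k_off_leading": (lambda v: v >= 0, "must be non-negative"),
    "k_off_other": (lambda v: v >= 0, "must be non-negative"),
    "delta": (lambda v: v > 0, "must be positive"),
    "d": (lambda v: v > 0, "must be positive"),
    "T": (lambda v: v > 0, "must be positive"),
}


@dataclass(frozen=True)
class MotorParams:
    """Kinetic constants of one kinesin dimer species.

    Parameters
    ----------
    name : str
        Species label.
    r0 : float
        Stepping ratio (forward/backward steps) at zero external force.
    FS : float
        Stall-force scale in pN; equals the actual stall force for
        wild-type motors (``P0_zero == 1``).
    k_plus, k_minus : float
        ATPase (hydrolysis + Pi release) rate constants of the trailing and
        leading head, s^-1.  Force- and neck-linker-length independent.
    P0_zero : float
        Probability that the ADP-head escapes its weakened binding site
        within the brief low-affinity window at zero force.
    kb : float
        Second-order ATP binding rate, uM^-1 s^-1.
    k_off_leading : float
        ATP dissociation rate from the leading head (backward neck-linker
        orientation), s^-1.
    k_off_other : float
        ATP dissociation rate from a head in the trailing or intermediate
        position, s^-1 (taken as 0).
    delta : float
        Characteristic distance for the force dependence of the escape
        probability, nm (~Debye length, 1 nm).
    d : float
        Step size, nm (microtubule lattice period, 8.2 nm).
    T : float
        Absolute temperature, K.
    errors : mapping, optional
        Published 1-sigma uncertainties keyed by field name.  Stored for
        reporting; not propagated automatically.
    """

    name: str
    r0: float
    FS: float
    k_plus: float
    k_minus: float
    P0_zero: float = 1.0
    kb: float = 3.3
    k_off_leading: float = 30.0
    k_off_other: float = 0.0
    delta: float = 1.0
    d: float = 8.2
    T: float = 298.0
    errors: Mapping[str, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name, (ok, msg) in _VALIDATORS.items():
            value = getattr(self, name)
            if not ok(value):
                raise ValueError(f"MotorParams.{name}={value!r} {msg}")
        if self.errors is not None:
            object.__setattr__(self, "errors", MappingProxyType(dict(self.errors)))

    @property
    def K(self) -> float:
        """Rate-constant ratio k(+)/k(-); infinite if the leading head is inert."""
        return self.k_plus / self.k_minus if self.k_minus > 0 else math.inf

    @property
    def kBT(self) -> float:
        return KB * self.T

    def with_(self, **changes) -> "MotorParams":
        """Return a validated copy with the given fields replaced."""
        return replace(self, **changes)

    def as_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in ("name", "r0", "FS", "k_plus", "k_minus", "P0_zero", "kb",
                      "k_off_leading", "k_off_other", "delta", "d", "T")
        }
        return out


def make_motor_params(**fields) -> MotorParams:
    """Construct a validated :class:`MotorParams`; invalid fields raise
    ``ValueError`` naming the offending field."""
    return MotorParams(**fields)


@dataclass(frozen=True)
class Conditions:
    """External conditions of a run: signed force (positive = backward,
    resisting), ATP concentration in uM (``SATURATING`` for the
    saturating regime) and temperature in K."""

    F: float = 0.0
    atp: float = SATURATING
    T: float = 298.0

    def __post_init__(self) -> None:
        if self.atp < 0:
            raise ValueError(f"Conditions.atp={self.atp!r} must be non-negative")
        if self.T <= 0:
            raise ValueError(f"Conditions.T={self.T!r} must be positive")

    @property
    def saturating(self) -> bool:
        return math.isinf(self.atp)


# Published parameter registry.  kb / k_off_leading were only calibrated for
# the motors simulated at low ATP (HsK-CL-6AA, KIF17); the remaining presets
# carry those same values as an extrapolation so that any preset can be run
# in the stochastic engine.
_PRESETS: dict[str, MotorParams] = {
    "DmK": MotorParams(
        name="DmK", r0=890, FS=8.0, k_plus=95.0, k_minus=3.0,
        errors={"r0": 120, "FS": 0.3, "k_plus": 1.0, "k_minus": 0.4},
    ),
    "Bovine": MotorParams(
        name="Bovine", r0=220, FS=7.6, k_plus=138.0, k_minus=3.0,
        errors={"r0": 68, "FS": 1.1, "k_plus": 20.0, "k_minus": 1.1},
    ),
    "HsK": MotorParams(
        name="HsK", r0=900, FS=7.0, k_plus=90.5, k_minus=4.0,
        errors={"k_plus": 7.1, "k_minus": 0.5},
    ),
    "HsK-6AA": MotorParams(
        name="HsK-6AA", r0=900, FS=7.0, k_plus=90.5, k_minus=4.0, P0_zero=0.33,
        errors={"k_plus": 7.1, "k_minus": 0.5, "P0_zero": 0.02},
    ),
    "HsK-CL": MotorParams(
        name="HsK-CL", r0=600, FS=5.0, k_plus=107.0, k_minus=4.0,
        errors={"r0": 50, "FS": 0.4, "k_plus": 3.0},
    ),
    "HsK-CL-6AA": MotorParams(
        name="HsK-CL-6AA", r0=600, FS=5.0, k_plus=107.0, k_minus=4.0,
        P0_zero=0.33, kb=3.3, k_off_leading=30.0,
        errors={"r0": 50, "FS": 0.4, "k_plus": 3.0},
    ),
    "KIF17": MotorParams(
        name="KIF17", r0=220, FS=8.0, k_plus=307.0, k_minus=9.8,
        P0_zero=0.65, kb=3.3, k_off_leading=30.0,
        errors={"k_plus": 22.0, "k_minus": 1.6, "P0_zero": 0.1},
    ),
}


def preset_names() -> tuple[str, ...]:
    return tuple(_PRESETS)


def preset(name: str) -> MotorParams:
    """Return the published parameter set for a motor species.

    Wild-type presets (DmK, Bovine, HsK, HsK-CL) carry ``P0_zero = 1``: the
    internal neck-linker tension guarantees escape from the weakened site.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown motor preset {name!r}; valid names: {', '.join(_PRESETS)}"
        ) from None


# -- plain-text configuration -------------------------------------------------

_CONFIG_FIELDS = ("r0", "FS", "k_plus", "k_minus", "P0_zero", "kb",
                  "k_off_leading", "k_off_other", "delta", "d", "T")


def load_motor_config(path: str | Path) -> dict[str, MotorParams]:
    """Read motors from a YAML config: one mapping block per motor, one
    ``key: value`` line per parameter; ``#`` comments tolerated.

    Unspecified fields take the :class:`MotorParams` defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping of motor-name -> parameters")
    motors = {}
    for name, block in doc.items():
        if not isinstance(block, dict):
            raise ValueError(f"{path}: motor {name!r} is not a key: value block")
        unknown = set(block) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"{path}: motor {name!r} has unknown fields {sorted(unknown)}")
        motors[str(name)] = MotorParams(name=str(name), **{k: float(v) for k, v in block.items()})
    return motors


def dump_motor_config(motors: Mapping[str, MotorParams], path: str | Path) -> None:
    """Write motors to the YAML config format read by :func:`load_motor_config`."""
    doc = {}
    for name, p in motors.items():
        block = p.as_dict()
        block.pop("name")
        doc[name] = block
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
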