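"""Model parameters, trade-off wiring and trait containers.

The model describes a well-mixed, asexual host population structured into
juveniles and adults, exposed to a directly transmitted pathogen with either
sterility virulence (fecundity reduction ``1 - f``) or mortality virulence
(``alpha``).  Each life stage carries an innate, infection-preventing
resistance trait ``r_J``/``r_A`` in [0, 1]; resistance is costly because it
trades off against exactly one other life-history trait per stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "Params",
    "TradeoffWiring",
    "ResistancePair",
    "JUVENILE_TARGETS",
    "ADULT_TARGETS",
    "load_config",
]

JUVENILE_TARGETS = ("maturation", "reproduction", "juvenile_mortality")
ADULT_TARGETS = ("reproduction", "adult_mortality")


@dataclass(frozen=True)
class Params:
    """Ecological and trade-off constants.

    Attributes
    ----------
    a0 : float
        Baseline adult reproduction rate (per unit time).
    b0 : float
        Baseline natural mortality rate, shared by both stages.
    g0 : float
        Baseline maturation rate of juveniles.
    q : float
        Strength of density-dependent competition on reproduction.
    beta0 : float
        Baseline transmission rate (density-dependent transmission).
    f : float
        Fecundity retained when infected; sterility virulence is ``1 - f``.
    alpha : float
        Additional mortality rate of infected hosts (mortality virulence).
    c1J, c1A : float
        Maximum proportional change of the traded-off trait (trade-off
        strength), in (0, 1]; 0 disables the trade-off.
    c2J, c2A : float
        Trade-off curvature; positive values give accelerating costs.
    """

    a0: float = 5.0
    b0: float = 1.0
    g0: float = 1.0
    q: float = 1.0
    beta0: float = 8.0
    f: float = 1.0
    alpha: float = 0.0
    c1J: float = 0.5
    c1A: float = 0.5
    c2J: float = 3.0
    c2A: float = 3.0

    def __post_init__(self) -> None:
        for name in ("a0", "b0", "g0", "q", "beta0", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        for name in ("c1J", "c1A"):
            c1 = getattr(self, name)
            if not 0.0 <= c1 <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {c1}")

    def replace(self, **kwargs: float) -> "Params":
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class TradeoffWiring:
    """Which life-history trait each resistance trait degrades.

    Juvenile resistance trades off with maturation, reproduction or juvenile
    mortality; adult resistance with reproduction or adult mortality.  When
    both stages target reproduction the two cost factors multiply.
    """

    juvenile_target: str = "juvenile_mortality"
    adult_target: str = "reproduction"

    def __post_init__(self) -> None:
        if self.juvenile_target not in JUVENILE_TARGETS:
            raise ValueError(
                f"juvenile_target must be one of {JUVENILE_TARGETS}, got {self.juvenile_target!r}"
            )
        if self.adult_target not in ADULT_TARGETS:
            raise ValueError(
                f"adult_target must be one of {ADULT_TARGETS}, got {self.adult_target!r}"
            )

    @property
    def label(self) -> str:
        return f"J~{self.juvenile_target}/A~{self.adult_target}"


#: the six trade-off combinations compared in the headline analyses
ALL_WIRINGS: tuple[TradeoffWiring, ...] = tuple(
    TradeoffWiring(j, a) for j in JUVENILE_TARGETS for a in ADULT_TARGETS
)


@dataclass(frozen=True)
class ResistancePair:
    """The evolving traits: juvenile and adult resistance, each in [0, 1].

    ``r = 0`` is full susceptibility, ``r = 1`` full resistance (the stage
    cannot be infected at all).
    """

    rJ: float = 0.0
    rA: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rJ <= 1.0:
            raise ValueError(f"rJ must lie in [0, 1], got {self.rJ}")
        if not 0.0 <= self.rA <= 1.0:
            raise ValueError(f"rA must lie in [0, 1], got {self.rA}")

    def as_tuple(self) -> tuple[float, float]:
        return (self.rJ, self.rA)

    def with_trait(self, stage: str, value: float) -> "ResistancePair":
        """Return a copy with the juvenile or adult trait replaced."""
        if stage == "juvenile":
            return ResistancePair(value, self.rA)
        if stage == "adult":
            return ResistancePair(self.rJ, value)
        raise ValueError(f"stage must be 'juvenile' or 'adult', got {stage!r}")


def load_config(path: str | Path) -> tuple[Params, TradeoffWiring, ResistancePair]:
    """Read a flat key-value config file (YAML or JSON).

    Recognised keys: the :class:`Params` fields (``a0 b0 g0 q beta0 f alpha
    c1J c1A c2J c2A``), wiring keys ``juvenile_target``/``adult_target`` and
    trait keys ``rJ``/``rA``.  Missing keys keep their defaults.
    """
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> tuple[Params, TradeoffWiring, ResistancePair]:
    raw = dict(raw)
    wiring = TradeoffWiring(
        juvenile_target=raw.pop("juvenile_target", "juvenile_mortality"),
        adult_target=raw.pop("adult_target", "reproduction"),
    )
    traits = ResistancePair(float(raw.pop("rJ", 0.0)), float(raw.pop("rA", 0.0)))
    known = set(Params.field_names())
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    params = Params(**{k: float(v) for k, v in raw.items()})
    return params, wiring, traits


def iter_wirings() -> Iterable[TradeoffWiring]:
    return iter(ALL_WIRINGS)
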