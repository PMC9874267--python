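"""Shared fixtures and random-draw helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from stageres import (
    ALL_WIRINGS,
    Params,
    ResistancePair,
    TradeoffWiring,
    basic_reproduction_number,
)


@pytest.fixture
def default_wiring() -> TradeoffWiring:
    return TradeoffWiring("juvenile_mortality", "reproduction")


@pytest.fixture
def css_params() -> Params:
    """The single-CSS showcase: beta0=8, sterility virulence 0.9."""
    return Params(beta0=8.0, f=0.1, alpha=0.0)


@pytest.fixture
def bistable_setup() -> tuple[Params, TradeoffWiring]:
    """High transmissibility with mortality trade-offs at both stages."""
    return (
        Params(beta0=1000.0, f=0.5, alpha=0.0),
        TradeoffWiring("juvenile_mortality", "adult_mortality"),
    )


def draw_params(rng: np.random.Generator) -> Params:
    """A random but biologically sensible parameter set with exactly one
    virulence mechanism active (the regime the analyses use)."""
    sterility = rng.random() < 0.5
    return Params(
        a0=float(rng.uniform(2.5, 10.0)),
        g0=float(rng.uniform(0.5, 2.0)),
        beta0=float(rng.uniform(3.0, 20.0)),
        f=float(rng.uniform(0.0, 0.95)) if sterility else 1.0,
        alpha=0.0 if sterility else float(rng.uniform(0.1, 2.0)),
        c1J=float(rng.uniform(0.05, 1.0)),
        c1A=float(rng.uniform(0.05, 1.0)),
        c2J=float(rng.uniform(0.5, 6.0)),
        c2A=float(rng.uniform(0.5, 6.0)),
    )


def draw_endemic_setup(
    rng: np.random.Generator, margin: float = 1.05
) -> tuple[Params, TradeoffWiring, ResistancePair]:
    """Rejection-sample a (params, wiring, resident) triple whose resident
    population is viable and supports endemic disease (R0 above ``margin``)."""
    while True:
        p = draw_params(rng)
        w = ALL_WIRINGS[int(rng.integers(len(ALL_WIRINGS)))]
        r = ResistancePair(float(rng.uniform(0.0, 0.9)), float(rng.uniform(0.0, 0.9)))
        try:
            if basic_reproduction_number(p, w, r) > margin:
                return p, w, r
        except ValueError:
            continue


def draw_viable_setup(
    rng: np.random.Generator,
) -> tuple[Params, TradeoffWiring, ResistancePair]:
    """Like :func:`draw_endemic_setup` but only requires host viability."""
    while True:
        p = draw_params(rng)
        w = ALL_WIRINGS[int(rng.integers(len(ALL_WIRINGS)))]
        r = ResistancePair(float(rng.uniform(0.0, 1.0)), float(rng.uniform(0.0, 1.0)))
        try:
            basic_reproduction_number(p, w, r)
            return p, w, r
        except ValueError:
            continue
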