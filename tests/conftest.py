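"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from midakit import (
    FRAGMENT_PRESETS,
    ElementalFormula,
    IsotopeTable,
    default_isotope_table,
)


def enumerate_pattern(formula: ElementalFormula, table: IsotopeTable,
                      length: int) -> np.ndarray:
    """Exhaustive-enumeration oracle for the natural isotope pattern.

    Enumerates, per element, every composition of its atom count over its
    isotopes (with the multinomial weight), then takes the Cartesian product
    across elements, summing mass shifts and multiplying probabilities.
    Deliberately avoids convolution so it is independent of the
    implementation it checks.
    """
    per_element: list[list[tuple[int, float]]] = []
    for el, count in sorted(formula.counts.items()):
        isotopes = table[el]
        k = len(isotopes)
        options: list[tuple[int, float]] = []
        # compositions of `count` atoms over k isotopes
        for cuts in itertools.combinations(range(count + k - 1), k - 1):
            comp = []
            prev = -1
            for c in cuts:
                comp.append(c - prev - 1)
                prev = c
            comp.append(count + k - 2 - prev)
            weight = math.factorial(count)
            shift = 0
            prob = 1.0
            for (iso_shift, iso_ab), m in zip(isotopes, comp):
                weight //= math.factorial(m)
                shift += iso_shift * m
                prob *= iso_ab ** m
            options.append((shift, weight * prob))
        per_element.append(options)

    out = np.zeros(length)
    for combo in itertools.product(*per_element):
        shift = sum(s for s, _ in combo)
        if shift < length:
            prob = 1.0
            for _, p in combo:
                prob *= p
            out[shift] += prob
    return out


@pytest.fixture(scope="session")
def table() -> IsotopeTable:
    return default_isotope_table()


@pytest.fixture(scope="session")
def alanine():
    return FRAGMENT_PRESETS["alanine-260"]


@pytest.fixture(scope="session")
def verified_presets():
    return [s for s in FRAGMENT_PRESETS.values() if s.formula_verified]


@pytest.fixture(scope="session")
def pattern_oracle():
    return enumerate_pattern


def random_formula(rng: np.random.Generator, max_atoms: int = 12) -> ElementalFormula:
    """A random small formula over the supported elements."""
    elements = ["C", "H", "N", "O", "S", "Si"]
    n_el = rng.integers(1, 4)
    chosen = rng.choice(elements, size=n_el, replace=False)
    counts = {}
    budget = int(rng.integers(1, max_atoms + 1))
    for el in chosen:
        if budget <= 0:
            break
        c = int(rng.integers(1, budget + 1))
        counts[el] = c
        budget -= c
    if not counts:
        counts = {"C": 1}
    return ElementalFormula(counts)
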