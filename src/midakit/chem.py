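"""Elemental formulas, isotope tables and theoretical natural-isotope patterns.

The mass channels of a GC-MS fragment ion are indexed by integer mass shift
relative to the monoisotopic (all-light) species M0.  Every quantity in this
module lives on that integer grid: an isotope table maps each element to the
mass shifts and fractional abundances of its stable isotopes, and the natural
pattern of a formula is the distribution of the total shift summed over all
its atoms — a discrete convolution of per-atom shift distributions.

TBDMS (tert-butyldimethylsilyl) derivatization replaces an exchangeable H by
a Si(CH3)2C(CH3)3 group, a net addition of C6H14Si (+114 Da) per substitution.
Under electron impact these derivatives characteristically lose the tert-butyl
radical C4H9 (57 Da), giving the [M-57] fragments whose nominal masses label
the amino-acid fragments analysed here (alanine-260, glycine-246, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SUPPORTED_ELEMENTS",
    "NOMINAL_MASSES",
    "ElementalFormula",
    "FormulaError",
    "IsotopeTable",
    "IsotopeTableError",
    "FragmentSpec",
    "FragmentSpecError",
    "parse_formula",
    "nominal_mass",
    "fragment_formula",
    "natural_isotope_pattern",
    "default_isotope_table",
    "load_isotope_table",
    "load_fragment_presets",
    "FRAGMENT_PRESETS",
    "TBDMS_NET",
    "TBU_LOSS",
]

# Nominal mass = mass number of the lightest (and most abundant) stable
# isotope.  Other elements are rejected loudly rather than silently ignored.
NOMINAL_MASSES: dict[str, int] = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "Si": 28}
SUPPORTED_ELEMENTS = frozenset(NOMINAL_MASSES)


class FormulaError(ValueError):
    """Malformed formula string or invalid formula arithmetic."""


class IsotopeTableError(ValueError):
    """Invalid or incomplete isotope abundance data."""


class FragmentSpecError(ValueError):
    """Inconsistent fragment specification."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map for a (fragment) ion.

    Counts are non-negative integers over the supported element set.
    Supports ``+``, ``-`` and integer ``*``; subtraction raises
    :class:`FormulaError` if any count would go negative.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, cnt in self.counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element {el!r} (supported: "
                                   f"{sorted(SUPPORTED_ELEMENTS)})")
            if not isinstance(cnt, (int, np.integer)) or cnt < 0:
                raise FormulaError(f"count for {el} must be a non-negative "
                                   f"integer, got {cnt!r}")
            if cnt > 0:
                clean[el] = int(cnt)
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, cnt in other.counts.items():
            merged[el] = merged.get(el, 0) + cnt
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, cnt in other.counts.items():
            left = merged.get(el, 0) - cnt
            if left < 0:
                raise FormulaError(
                    f"subtraction yields negative count for {el}: "
                    f"{merged.get(el, 0)} - {cnt}")
            merged[el] = left
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, (int, np.integer)) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative "
                               f"integer, got {k!r}")
        return ElementalFormula({el: cnt * int(k) for el, cnt in self.counts.items()})

    __rmul__ = __mul__

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def __str__(self) -> str:
        # Hill order: C, H, then remaining elements alphabetically.
        parts = []
        for el in ["C", "H"] + sorted(set(self.counts) - {"C", "H"}):
            cnt = self.counts.get(el, 0)
            if cnt == 1:
                parts.append(el)
            elif cnt > 1:
                parts.append(f"{el}{cnt}")
        return "".join(parts)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C3H7NO2"``.

    Element symbols may repeat; counts accumulate.  Raises
    :class:`FormulaError` naming the offending token on unknown elements or
    malformed input.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula near {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


def nominal_mass(f: ElementalFormula) -> int:
    """Nominal (integer) mass in Da: sum of count x lightest-isotope mass."""
    return sum(cnt * NOMINAL_MASSES[el] for el, cnt in f.counts.items())


# ---------------------------------------------------------------------------
# Isotope abundance tables
# ---------------------------------------------------------------------------

class IsotopeTable:
    """Per-element stable-isotope shift/abundance data.

    ``data`` maps element symbol -> list of ``(mass_shift, abundance)`` with
    shifts as non-negative, strictly increasing integers (0 = lightest
    isotope) and abundances summing to 1 per element within 1e-9.
    """

    def __init__(self, data: Mapping[str, Iterable[tuple[int, float]]]):
        clean: dict[str, tuple[tuple[int, float], ...]] = {}
        for el, pairs in data.items():
            if el not in SUPPORTED_ELEMENTS:
                raise IsotopeTableError(f"unsupported element {el!r}")
            pairs = tuple((int(s), float(a)) for s, a in pairs)
            if not pairs:
                raise IsotopeTableError(f"no isotopes listed for {el}")
            shifts = [s for s, _ in pairs]
            if any(s < 0 for s in shifts) or any(
                    b <= a for a, b in zip(shifts, shifts[1:])):
                raise IsotopeTableError(
                    f"mass shifts for {el} must be non-negative and strictly "
                    f"increasing, got {shifts}")
            if any(a < 0 for _, a in pairs):
                raise IsotopeTableError(f"negative abundance for {el}")
            total = sum(a for _, a in pairs)
            if abs(total - 1.0) > 1e-9:
                raise IsotopeTableError(
                    f"abundances for {el} sum to {total!r}, expected 1")
            clean[el] = pairs
        self._data = clean

    def __contains__(self, element: str) -> bool:
        return element in self._data

    def __getitem__(self, element: str) -> tuple[tuple[int, float], ...]:
        return self._data[element]

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(self._data)

    def atom_distribution(self, element: str) -> np.ndarray:
        """Shift distribution of a single atom as a dense vector."""
        if element not in self._data:
            raise IsotopeTableError(f"no isotope data for element {element!r}")
        pairs = self._data[element]
        out = np.zeros(pairs[-1][0] + 1)
        for shift, ab in pairs:
            out[shift] = ab
        return out


# Shipped defaults (IUPAC-style representative abundances).  Users can
# override via load_isotope_table().
_DEFAULT_ISOTOPES = """\
# element  mass-shift(Da)  fractional-abundance
C   0  0.9893
C   1  0.0107
H   0  0.999885
H   1  0.000115
N   0  0.99636
N   1  0.00364
O   0  0.99757
O   1  0.00038
O   2  0.00205
S   0  0.9499
S   1  0.0075
S   2  0.0425
S   4  0.0001
Si  0  0.92223
Si  1  0.04685
Si  2  0.03092
"""


def load_isotope_table(source) -> IsotopeTable:
    """Read an isotope table from a path, stream or string.

    Format: whitespace-separated ``element mass_shift abundance`` triples,
    one per line; ``#`` starts a comment.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(source)
    data: dict[str, list[tuple[int, float]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise IsotopeTableError(
                f"line {lineno}: expected 'element shift abundance', got {line!r}")
        el, shift, ab = parts
        try:
            entry = (int(shift), float(ab))
        except ValueError as exc:
            raise IsotopeTableError(f"line {lineno}: {exc}") from exc
        data.setdefault(el, []).append(entry)
    if not data:
        raise IsotopeTableError("isotope table is empty")
    return IsotopeTable(data)


def default_isotope_table() -> IsotopeTable:
    """The shipped natural-abundance table for C, H, N, O, S, Si."""
    return load_isotope_table(_DEFAULT_ISOTOPES)


# ---------------------------------------------------------------------------
# Natural isotope patterns
# ---------------------------------------------------------------------------

def natural_isotope_pattern(f: ElementalFormula, table: IsotopeTable,
                            length: int) -> np.ndarray:
    """Mass-shift distribution of a whole formula at natural abundance.

    Entry ``s`` of the returned vector is the probability that the molecule's
    total mass exceeds the monoisotopic mass by ``s`` Da.  Computed as the
    discrete convolution of one per-atom shift distribution per atom
    (binomial/polynomial expansion), truncated at ``length`` channels.
    The truncated vector sums to <= 1; it sums to 1 (within 1e-9) whenever
    ``length`` exceeds the maximal possible shift.
    """
    if length < 1:
        raise ValueError(f"pattern length must be >= 1, got {length}")
    pattern = np.array([1.0])
    for el, cnt in sorted(f.counts.items()):
        atom = table.atom_distribution(el)  # raises if missing
        for _ in range(cnt):
            pattern = np.convolve(pattern, atom)[:length]
    out = np.zeros(length)
    out[: pattern.size] = pattern
    return out


# ---------------------------------------------------------------------------
# TBDMS fragment chemistry
# ---------------------------------------------------------------------------

#: Net formula change per TBDMS substitution (H replaced by SiMe2-tBu).
TBDMS_NET = ElementalFormula({"C": 6, "H": 14, "Si": 1})
#: tert-butyl radical, the characteristic 57 Da loss of TBDMS derivatives.
TBU_LOSS = ElementalFormula({"C": 4, "H": 9})


@dataclass(frozen=True)
class FragmentSpec:
    """An amino-acid fragment ion from TBDMS derivatization.

    ``n_labelled`` is the number of carbon-skeleton positions of the amino
    acid retained in the fragment, i.e. the positions a 13C tracer can
    occupy.  ``m0`` is the fragment's nominal mass, the number after the
    dash in names like "alanine-260".

    Presets whose exact composition could not be established carry
    ``base=None`` and ``formula_verified=False``; they still identify the
    channel range (via ``m0`` and ``n_labelled``) but cannot produce a
    theoretical pattern.
    """

    name: str
    base: ElementalFormula | None
    derivative_count: int
    n_labelled: int
    m0: int
    derivative: ElementalFormula = TBDMS_NET
    loss: ElementalFormula = field(default_factory=lambda: ElementalFormula({}))
    formula_verified: bool = True

    def __post_init__(self) -> None:
        if self.n_labelled < 1:
            raise FragmentSpecError(f"{self.name}: n_labelled must be >= 1")
        if self.base is not None:
            if self.n_labelled > self.base["C"]:
                raise FragmentSpecError(
                    f"{self.name}: n_labelled={self.n_labelled} exceeds the "
                    f"base carbon count {self.base['C']}")
            got = nominal_mass(self.formula)
            if got != self.m0:
                raise FragmentSpecError(
                    f"{self.name}: assembled fragment mass {got} does not "
                    f"match declared m0={self.m0}")

    @property
    def formula(self) -> ElementalFormula:
        """Assembled fragment formula: base + k x derivative - loss."""
        if self.base is None:
            raise FragmentSpecError(
                f"{self.name}: fragment composition is unverified; no formula")
        try:
            return self.base + self.derivative_count * self.derivative - self.loss
        except FormulaError as exc:
            raise FragmentSpecError(f"{self.name}: {exc}") from exc


def fragment_formula(spec: FragmentSpec) -> ElementalFormula:
    """Assembled elemental formula of the fragment ion."""
    return spec.formula


def _preset(name, base, k, loss, n, m0) -> FragmentSpec:
    return FragmentSpec(name=name, base=parse_formula(base),
                        derivative_count=k, loss=parse_formula(loss),
                        n_labelled=n, m0=m0)


#: The seven amino-acid fragments used in the worked examples.  [M-57] is
#: loss of tert-butyl; proline-184 is the [M-159] ion (loss of tert-butyl
#: plus the TBDMS-ester carboxyl, C7H15O2Si).  Lysine-300 and tyrosine-302
#: compositions are not derivable from the available fragment numbers alone
#: and are shipped formula-unverified.
FRAGMENT_PRESETS: dict[str, FragmentSpec] = {
    "alanine-260": _preset("alanine-260", "C3H7NO2", 2, "C4H9", 3, 260),
    "glycine-246": _preset("glycine-246", "C2H5NO2", 2, "C4H9", 2, 246),
    "aspartic acid-418": _preset("aspartic acid-418", "C4H7NO4", 3, "C4H9", 4, 418),
    "threonine-404": _preset("threonine-404", "C4H9NO3", 3, "C4H9", 4, 404),
    "proline-184": _preset("proline-184", "C5H9NO2", 2, "C7H15O2Si", 4, 184),
    "lysine-300": FragmentSpec(name="lysine-300", base=None, derivative_count=0,
                               n_labelled=6, m0=300, formula_verified=False),
    "tyrosine-302": FragmentSpec(name="tyrosine-302", base=None, derivative_count=0,
                                 n_labelled=9, m0=302, formula_verified=False),
}


def load_fragment_presets() -> dict[str, FragmentSpec]:
    """The shipped fragment presets (copy; safe to mutate)."""
    return dict(FRAGMENT_PRESETS)
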