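"""Readers and writers for the ``.iso``/``.isx`` record formats.

Grammar (the canonical dialect; published here so third parties can
interoperate):

* A file holds one or more records separated by an asterisk ``*`` on its
  own line; a trailing separator is tolerated on read but never written.
* Lines starting with ``#`` are header comments.  ``.isx`` files carry a
  first-line header ``# isx provenance=<text>`` marking how the data were
  produced (e.g. parsed from raw tables); ``.iso`` content without the
  header is accepted with provenance ``"unknown"``.
* A record is nine semicolon-separated fields, in order:
  metabolite name; mass-to-charge ratio values; first, second and third set
  of relative intensity values (three independent measurements); standard
  relative intensity values; atom mass; fragment; fixed value; date and
  time.  Values within a list are comma-separated.  Encoding is UTF-8;
  numbers are written with 6 significant digits.
* The "fixed value" field is opaque: read and written verbatim, never
  interpreted.

The raw-table layout mirrors the three-sheet form GC-MS data commonly
arrive in: an actual-intensity table (metabolite, m/z, three replicate
intensity columns), a standard-intensity table (metabolite, m/z, standard
intensity) and a fragment-metadata table (metabolite, fragment, atoms, mass,
groups).  ``merge_raw_tables`` deterministically joins them into records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import FragmentSpec
from .mida import MassSpectrumRecord

__all__ = [
    "IsoRecord",
    "FormatError",
    "FIELD_NAMES",
    "parse_iso",
    "write_iso",
    "parse_isx",
    "export_isx",
    "merge_raw_tables",
    "iso_to_spectrum",
    "spectrum_to_iso",
]

FIELD_NAMES = (
    "metabolite name",
    "mass-to-charge ratio values",
    "first set of relative intensity values",
    "second set of relative intensity values",
    "third set of relative intensity values",
    "standard relative intensity values",
    "atom mass",
    "fragment",
    "fixed value",
    "date and time",
)

_ISX_HEADER_PREFIX = "# isx provenance="


class FormatError(ValueError):
    """Malformed .iso/.isx content or inconsistent raw tables."""


@dataclass(frozen=True)
class IsoRecord:
    """One semicolon-delimited record of a ``.iso``/``.isx`` file."""

    name: str
    mz: tuple[int, ...]
    intensities_1: tuple[float, ...]
    intensities_2: tuple[float, ...]
    intensities_3: tuple[float, ...]
    standard: tuple[float, ...]
    atom_mass: int
    fragment: int
    fixed_value: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        mz = tuple(int(v) for v in self.mz)
        object.__setattr__(self, "mz", mz)
        for attr in ("intensities_1", "intensities_2", "intensities_3",
                     "standard"):
            vals = tuple(float(v) for v in getattr(self, attr))
            object.__setattr__(self, attr, vals)
            if len(vals) != len(mz):
                raise FormatError(
                    f"{self.name}: intensity list length {len(vals)} does not "
                    f"match {len(mz)} m/z values")
        if len(mz) == 0:
            raise FormatError(f"{self.name}: no m/z values")
        diffs = np.diff(mz)
        if len(mz) > 1 and not np.all(diffs == 1):
            raise FormatError(
                f"{self.name}: m/z values must be strictly increasing and "
                f"contiguous, got {mz}")

    @property
    def replicates(self):
        return (self.intensities_1, self.intensities_2, self.intensities_3)


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    try:
        with open(source, "r", encoding="utf-8") as fh:
            return fh.read()
    except (OSError, ValueError):
        return str(source)


def _parse_int(token: str, field_name: str, block: int) -> int:
    try:
        return int(token.strip())
    except ValueError as exc:
        raise FormatError(
            f"record {block}: non-integer value {token!r} in field "
            f"{field_name!r}") from exc


def _parse_float_list(token: str, field_name: str, block: int) -> tuple[float, ...]:
    out = []
    for part in token.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            out.append(float(part))
        except ValueError as exc:
            raise FormatError(
                f"record {block}: non-numeric value {part!r} in field "
                f"{field_name!r}") from exc
    if not out:
        raise FormatError(f"record {block}: empty list in field {field_name!r}")
    return tuple(out)


def _parse_block(block_text: str, index: int) -> IsoRecord:
    fields = [f.strip() for f in block_text.split(";")]
    if len(fields) != len(FIELD_NAMES):
        raise FormatError(
            f"record {index}: expected {len(FIELD_NAMES)} semicolon-separated "
            f"fields ({'; '.join(FIELD_NAMES)}), got {len(fields)}")
    name = fields[0]
    mz = tuple(_parse_int(t, FIELD_NAMES[1], index)
               for t in fields[1].split(",") if t.strip())
    reps = [_parse_float_list(fields[i], FIELD_NAMES[i], index)
            for i in (2, 3, 4, 5)]
    atom_mass = _parse_int(fields[6], FIELD_NAMES[6], index)
    fragment = _parse_int(fields[7], FIELD_NAMES[7], index)
    return IsoRecord(name=name, mz=mz, intensities_1=reps[0],
                     intensities_2=reps[1], intensities_3=reps[2],
                     standard=reps[3], atom_mass=atom_mass, fragment=fragment,
                     fixed_value=fields[8], timestamp=fields[9])


def _split_blocks(text: str) -> list[str]:
    body_lines = [ln for ln in text.splitlines() if not ln.lstrip().startswith("#")]
    blocks = "\n".join(body_lines).split("*")
    return [b for b in (blk.strip() for blk in blocks) if b]


def parse_iso(source) -> list[IsoRecord]:
    """Parse ``.iso`` content from a path, stream or string."""
    text = _read_text(source)
    if not text.strip():
        raise FormatError("empty .iso content")
    return [_parse_block(b, i) for i, b in enumerate(_split_blocks(text))]


def _fmt(value: float) -> str:
    return format(value, ".6g")


def _serialize_record(rec: IsoRecord) -> str:
    fields = [
        rec.name,
        ",".join(str(v) for v in rec.mz),
        ",".join(_fmt(v) for v in rec.intensities_1),
        ",".join(_fmt(v) for v in rec.intensities_2),
        ",".join(_fmt(v) for v in rec.intensities_3),
        ",".join(_fmt(v) for v in rec.standard),
        str(rec.atom_mass),
        str(rec.fragment),
        rec.fixed_value,
        rec.timestamp,
    ]
    for f in fields:
        if ";" in f or "*" in f:
            raise FormatError(
                f"{rec.name}: field value {f!r} contains a reserved "
                f"delimiter and cannot be serialized")
    return ";".join(fields)


def write_iso(records, destination=None) -> str:
    """Serialize records to the canonical ``.iso`` dialect.

    Returns the text; if ``destination`` (path or stream) is given, also
    writes it there.
    """
    lines: list[str] = []
    for i, rec in enumerate(records):
        if i:
            lines.append("*")
        lines.append(_serialize_record(rec))
    text = "\n".join(lines) + ("\n" if lines else "")
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


def parse_isx(source) -> tuple[list[IsoRecord], str]:
    """Parse ``.isx`` content; returns ``(records, provenance)``.

    Plain ``.iso`` content (no provenance header) is accepted with
    provenance ``"unknown"``.
    """
    text = _read_text(source)
    provenance = "unknown"
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if first.startswith(_ISX_HEADER_PREFIX):
        provenance = first[len(_ISX_HEADER_PREFIX):].strip()
    return parse_iso(text), provenance


def export_isx(records, destination=None, provenance="raw-tables") -> str:
    """Serialize records to ``.isx``: a provenance header plus .iso body."""
    text = _ISX_HEADER_PREFIX + provenance + "\n" + write_iso(records)
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Raw-table merge
# ---------------------------------------------------------------------------

_T1_COLUMNS = ["metabolite", "mz", "intensity_1", "intensity_2", "intensity_3"]
_T2_COLUMNS = ["metabolite", "mz", "standard"]
_T3_COLUMNS = ["metabolite", "fragment", "atoms", "mass", "groups"]


def _read_table(source, expected: list[str], label: str) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(
            f"{label}: missing column(s) {missing}; expected {expected}")
    return df


def merge_raw_tables(t1, t2, t3, timestamp: str = "") -> list[IsoRecord]:
    """Join the three raw tables into complete records.

    ``t1``: actual intensities (metabolite, mz, intensity_1..3);
    ``t2``: standard intensities (metabolite, mz, standard);
    ``t3``: fragment metadata (metabolite, fragment, atoms, mass, groups).
    The merge is a pure function of table contents: row order never matters.
    Metabolites missing from any table, or duplicated keys, raise
    :class:`FormatError` naming the offender.
    """
    df1 = _read_table(t1, _T1_COLUMNS, "actual-intensity table")
    df2 = _read_table(t2, _T2_COLUMNS, "standard-intensity table")
    df3 = _read_table(t3, _T3_COLUMNS, "fragment-metadata table")
    if df1.empty and df2.empty and df3.empty:
        warnings.warn("all raw tables are empty; no records produced",
                      stacklevel=2)
        return []

    if df1.duplicated(["metabolite", "mz"]).any():
        dups = df1[df1.duplicated(["metabolite", "mz"])]["metabolite"].tolist()
        raise FormatError(f"actual-intensity table: duplicate "
                          f"(metabolite, m/z) rows for {sorted(set(dups))}")
    if df2.duplicated(["metabolite", "mz"]).any():
        dups = df2[df2.duplicated(["metabolite", "mz"])]["metabolite"].tolist()
        raise FormatError(f"standard-intensity table: duplicate "
                          f"(metabolite, m/z) rows for {sorted(set(dups))}")
    if df3.duplicated(["metabolite"]).any():
        dups = df3[df3.duplicated(["metabolite"])]["metabolite"].tolist()
        raise FormatError(f"fragment-metadata table: duplicate metabolite "
                          f"rows for {sorted(set(dups))}")

    names1 = set(df1["metabolite"])
    names2 = set(df2["metabolite"])
    names3 = set(df3["metabolite"])
    orphans = sorted((names1 - names2) | (names1 - names3))
    if orphans:
        raise FormatError(
            f"metabolite(s) {orphans} present in the actual-intensity table "
            f"but missing from the standard-intensity or fragment-metadata "
            f"table")

    meta = df3.set_index("metabolite")
    records: list[IsoRecord] = []
    for name in sorted(names1):
        part1 = df1[df1["metabolite"] == name].sort_values("mz")
        part2 = df2[df2["metabolite"] == name].sort_values("mz")
        if list(part1["mz"]) != list(part2["mz"]):
            raise FormatError(
                f"{name}: m/z values differ between the actual- and "
                f"standard-intensity tables")
        row3 = meta.loc[name]
        records.append(IsoRecord(
            name=name,
            mz=tuple(int(v) for v in part1["mz"]),
            intensities_1=tuple(part1["intensity_1"]),
            intensities_2=tuple(part1["intensity_2"]),
            intensities_3=tuple(part1["intensity_3"]),
            standard=tuple(part2["standard"]),
            atom_mass=int(row3["mass"]),
            fragment=int(row3["fragment"]),
            # atoms/groups metadata is carried opaquely in the fixed value
            fixed_value=f"atoms={int(row3['atoms'])},groups={int(row3['groups'])}",
            timestamp=timestamp,
        ))
    return records


# ---------------------------------------------------------------------------
# Bridges to the analysis layer
# ---------------------------------------------------------------------------

def iso_to_spectrum(record: IsoRecord,
                    spec: FragmentSpec | None = None,
                    presets: dict[str, FragmentSpec] | None = None) -> MassSpectrumRecord:
    """Turn a parsed record into an analysable spectrum.

    The fragment specification is taken from ``spec`` if given, otherwise
    looked up in ``presets`` (defaulting to the shipped presets) by
    metabolite name.  The channel range is the record's m/z values minus the
    fragment nominal mass.
    """
    if spec is None:
        if presets is None:
            from .chem import FRAGMENT_PRESETS
            presets = FRAGMENT_PRESETS
        spec = presets.get(record.name)
        if spec is None:
            raise FormatError(
                f"{record.name}: no fragment preset found; pass an explicit "
                f"fragment specification")
    channel_start = record.mz[0] - record.fragment
    return MassSpectrumRecord(
        name=record.name,
        fragment=spec,
        channel_start=int(channel_start),
        replicates=tuple(np.asarray(r) for r in record.replicates),
        standard=np.asarray(record.standard),
        timestamp=record.timestamp,
    )


def spectrum_to_iso(spectrum: MassSpectrumRecord,
                    fixed_value: str = "") -> IsoRecord:
    """Serialize an in-memory spectrum as an ``.iso`` record."""
    return IsoRecord(
        name=spectrum.name,
        mz=tuple(int(v) for v in spectrum.mz_values),
        intensities_1=tuple(spectrum.replicates[0]),
        intensities_2=tuple(spectrum.replicates[1]),
        intensities_3=tuple(spectrum.replicates[2]),
        standard=tuple(spectrum.standard),
        atom_mass=spectrum.fragment.m0,
        fragment=spectrum.fragment.m0,
        fixed_value=fixed_value or f"atoms={spectrum.fragment.n_labelled},groups=1",
        timestamp=spectrum.timestamp,
    )
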