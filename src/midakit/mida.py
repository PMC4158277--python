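"""Natural-abundance correction and isotopomer deconvolution.

The measured spectrum of a 13C-labelled fragment is a mixture: a molecule
with j labelled carbons contributes the natural-isotope pattern of its
remaining atoms, shifted up by j mass channels.  Collecting those theoretical
patterns as columns gives the rectangular abundance (correction) matrix A,
and the observed channel intensities y satisfy y = A x where x is the vector
of fractional molar abundances x0..xn (the mass-isotopomer distribution).

x is recovered by least squares via the Moore-Penrose pseudo-inverse,
followed by an iterative refinement pass: negative fractions are clamped to
zero, the system is re-solved restricted to the surviving isotopomers, and
the result renormalized to sum to 1.  Two passes are the default; an
optional third pass validates convergence.  The absolute 13C enrichment is
the abundance-weighted mean labelled fraction per position, (sum_j j*x_j)/n.

The model assumes one fragmentation pattern per fragment regardless of
isotopic substitution (no differential isotope effect): the same reduced-
formula pattern is used for every isotopomer column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .chem import (
    ElementalFormula,
    FragmentSpec,
    IsotopeTable,
    natural_isotope_pattern,
)

__all__ = [
    "MassSpectrumRecord",
    "CorrectionMatrix",
    "IsotopomerDistribution",
    "EnrichmentResult",
    "RecordOutcome",
    "AnalysisError",
    "relative_intensities",
    "build_correction_matrix",
    "solve_distribution",
    "absolute_enrichment",
    "analyse_record",
    "analyse_dataset",
    "DEFAULT_SEED",
]

#: Default seed for every stochastic component (arbitrary, pinned).
DEFAULT_SEED = 1316

#: Convergence tolerance for the optional validating third pass.
DEFAULT_TOLERANCE = 1e-6


class AnalysisError(ValueError):
    """Degenerate input, shape mismatch or ill-conditioned system."""


@dataclass(frozen=True)
class MassSpectrumRecord:
    """One metabolite fragment's measured channels.

    ``channel_start`` is the first mass shift relative to M0 and must be -1
    (a diagnostic proton-loss channel is recorded) or 0.  Three replicate
    intensity vectors plus one standard (unlabelled reference) vector span
    the contiguous channel range.
    """

    name: str
    fragment: FragmentSpec
    channel_start: int
    replicates: tuple[np.ndarray, np.ndarray, np.ndarray]
    standard: np.ndarray
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.channel_start not in (-1, 0):
            raise AnalysisError(
                f"{self.name}: channel range must start at -1 or 0, "
                f"got {self.channel_start}")
        reps = tuple(np.asarray(r, dtype=float) for r in self.replicates)
        object.__setattr__(self, "replicates", reps)
        object.__setattr__(self, "standard", np.asarray(self.standard, dtype=float))
        n_chan = self.standard.size
        vectors = list(reps) + [self.standard]
        for v in vectors:
            if v.ndim != 1 or v.size != n_chan:
                raise AnalysisError(
                    f"{self.name}: all intensity vectors must be 1-D with the "
                    f"same length")
            if np.any(v < 0):
                raise AnalysisError(f"{self.name}: negative intensity")
            if not np.any(v > 0):
                raise AnalysisError(f"{self.name}: all-zero intensity vector")
        if self.channel_end < self.fragment.n_labelled:
            raise AnalysisError(
                f"{self.name}: channel range ends at {self.channel_end}, "
                f"below n={self.fragment.n_labelled}")

    @property
    def channel_end(self) -> int:
        return self.channel_start + self.standard.size - 1

    @property
    def channels(self) -> np.ndarray:
        """Mass shifts covered, M-1 or M0 up to Mmax."""
        return np.arange(self.channel_start, self.channel_end + 1)

    @property
    def mz_values(self) -> np.ndarray:
        """Nominal m/z per channel (z = 1)."""
        return self.fragment.m0 + self.channels


@dataclass(frozen=True)
class CorrectionMatrix:
    """Abundance matrix A: rows = mass shifts 0..m, columns = label count j."""

    entries: np.ndarray
    fragment: FragmentSpec

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        if a.ndim != 2 or a.shape[0] < a.shape[1]:
            raise AnalysisError(
                f"correction matrix must be rectangular with rows >= columns, "
                f"got shape {a.shape}")
        if np.any(a < 0):
            raise AnalysisError("correction matrix entries must be >= 0")
        if np.any(a.sum(axis=0) > 1 + 1e-9):
            raise AnalysisError("correction matrix columns must sum to <= 1")
        object.__setattr__(self, "entries", a)

    @property
    def n_rows(self) -> int:
        return self.entries.shape[0]

    @property
    def n_labelled(self) -> int:
        return self.entries.shape[1] - 1


@dataclass(frozen=True)
class IsotopomerDistribution:
    """Fractional molar abundances x0..xn with solver diagnostics."""

    fractions: np.ndarray
    residual_norm: float
    iterations: int
    converged: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.fractions, dtype=float)
        if np.any(x < 0):
            raise AnalysisError("fractions must be non-negative")
        if abs(x.sum() - 1.0) > 1e-9:
            raise AnalysisError(f"fractions sum to {x.sum()!r}, expected 1")
        object.__setattr__(self, "fractions", x)


@dataclass(frozen=True)
class EnrichmentResult:
    """Absolute 13C enrichment of one record over three replicates."""

    name: str
    per_replicate: tuple[float, float, float]
    mean: float
    sd: float
    natural_reference: float
    distributions: tuple[IsotopomerDistribution, ...]
    standard_distribution: IsotopomerDistribution
    m_minus_one_fraction: float | None = None


@dataclass(frozen=True)
class RecordOutcome:
    """Per-record result of a batch analysis; exactly one of result/error set."""

    name: str
    index: int
    result: EnrichmentResult | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.result is not None


def relative_intensities(raw) -> np.ndarray:
    """Normalize an intensity vector to sum to 1 (relative intensities)."""
    v = np.asarray(raw, dtype=float)
    if np.any(v < 0):
        raise AnalysisError("intensities must be non-negative")
    total = v.sum()
    if total <= 0:
        raise AnalysisError("cannot normalize an all-zero intensity vector")
    return v / total


def build_correction_matrix(spec: FragmentSpec, table: IsotopeTable,
                            rows: int | None = None) -> CorrectionMatrix:
    """Build the abundance matrix A for a fragment.

    Column j is the natural-isotope pattern of the fragment formula with j
    carbons removed from the natural pool (they are fixed 13C), placed
    starting at row j.  ``rows`` defaults to n + 5, which covers the
    heavy-isotope tails of Si2-bearing fragments to < 1e-6 lost mass.
    """
    n = spec.n_labelled
    if rows is None:
        rows = n + 5
    if rows < n + 1:
        raise AnalysisError(
            f"{spec.name}: need at least n+1={n + 1} rows, got {rows}")
    formula = spec.formula  # raises for unverified presets
    a = np.zeros((rows, n + 1))
    carbon = ElementalFormula({"C": 1})
    for j in range(n + 1):
        reduced = formula - j * carbon
        pattern = natural_isotope_pattern(reduced, table, rows - j)
        a[j:, j] = pattern
    return CorrectionMatrix(entries=a, fragment=spec)


def _restricted_lstsq(a: np.ndarray, y: np.ndarray,
                      support: np.ndarray) -> np.ndarray:
    """Least squares over the columns in ``support``; zeros elsewhere."""
    x = np.zeros(a.shape[1])
    if support.any():
        sol, *_ = np.linalg.lstsq(a[:, support], y, rcond=None)
        x[support] = sol
    return x


def solve_distribution(matrix: CorrectionMatrix, y,
                       passes: int = 2,
                       tolerance: float = DEFAULT_TOLERANCE) -> IsotopomerDistribution:
    """Deconvolve a normalized intensity vector into isotopomer fractions.

    Pass 1 is unconstrained least squares via the pseudo-inverse.  Each
    refinement pass clamps negative fractions to zero, re-solves restricted
    to the non-negative support and renormalizes to sum 1.  ``passes`` is 2
    by default; with ``passes=3`` the third pass validates convergence:
    ``converged`` is True iff no fraction moved by more than ``tolerance``.
    """
    if passes not in (2, 3):
        raise AnalysisError(f"passes must be 2 or 3, got {passes}")
    a = matrix.entries
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != a.shape[0]:
        raise AnalysisError(
            f"intensity vector length {y.size} does not match the "
            f"{a.shape[0]} matrix rows")
    if np.linalg.matrix_rank(a) < a.shape[1]:
        raise AnalysisError(
            f"{matrix.fragment.name}: correction matrix is rank-deficient")

    # Pass 1: unconstrained pseudo-inverse solution.
    x = np.linalg.pinv(a) @ y

    degenerate = False
    converged = True
    iterations = 1
    prev = None
    for _ in range(passes - 1):
        support = x > 0
        if not support.any():
            # All fractions clamped away: fall back to non-negative least
            # squares over the full system and flag the result.
            x, _ = nnls(a, y)
            degenerate = True
            if x.sum() <= 0:
                raise AnalysisError(
                    f"{matrix.fragment.name}: solver collapsed to the zero "
                    f"vector")
        else:
            x = _restricted_lstsq(a, y, support)
        x = np.clip(x, 0.0, None)
        total = x.sum()
        if total <= 0:
            raise AnalysisError(
                f"{matrix.fragment.name}: solver collapsed to the zero vector")
        x = x / total
        iterations += 1
        if prev is not None:
            converged = bool(np.max(np.abs(x - prev)) < tolerance)
        prev = x

    residual = float(np.linalg.norm(y - a @ x))
    return IsotopomerDistribution(
        fractions=x,
        residual_norm=residual,
        iterations=iterations,
        converged=converged if passes == 3 else False,
        degenerate=degenerate,
    )


def absolute_enrichment(dist: IsotopomerDistribution, n: int) -> float:
    """Average labelled fraction per position: (sum_j j*x_j) / n."""
    if n < 1:
        raise AnalysisError(f"n must be >= 1, got {n}")
    x = dist.fractions
    return float(np.dot(np.arange(x.size), x) / n)


def analyse_record(record: MassSpectrumRecord, table: IsotopeTable,
                   passes: int = 2,
                   tolerance: float = DEFAULT_TOLERANCE) -> EnrichmentResult:
    """Full analysis of one record: three replicates plus the standard.

    Each vector is normalized to relative intensities and deconvolved; the
    standard (unlabelled reference) yields the natural-reference enrichment.
    The diagnostic M-1 channel, when present, is excluded from the fitted
    system and reported as its mean relative intensity (a proton-loss /
    overlap indicator).
    """
    try:
        n = record.fragment.n_labelled
        drop = 1 if record.channel_start == -1 else 0
        rows = record.standard.size - drop
        matrix = build_correction_matrix(record.fragment, table, rows=rows)

        m_minus_one = None
        if drop:
            m_minus_one = float(np.mean(
                [relative_intensities(r)[0] for r in record.replicates]))

        dists = []
        enrichments = []
        for rep in record.replicates:
            y = relative_intensities(rep[drop:])
            d = solve_distribution(matrix, y, passes=passes, tolerance=tolerance)
            dists.append(d)
            enrichments.append(absolute_enrichment(d, n))

        y_std = relative_intensities(record.standard[drop:])
        std_dist = solve_distribution(matrix, y_std, passes=passes,
                                      tolerance=tolerance)
        natural_ref = absolute_enrichment(std_dist, n)

        mean = float(np.mean(enrichments))
        sd = float(np.std(enrichments, ddof=1))
        return EnrichmentResult(
            name=record.name,
            per_replicate=tuple(enrichments),
            mean=mean,
            sd=sd,
            natural_reference=natural_ref,
            distributions=tuple(dists),
            standard_distribution=std_dist,
            m_minus_one_fraction=m_minus_one,
        )
    except (AnalysisError, ValueError) as exc:
        raise AnalysisError(f"{record.name}: {exc}") from exc


def analyse_dataset(records, table: IsotopeTable, passes: int = 2,
                    tolerance: float = DEFAULT_TOLERANCE) -> list[RecordOutcome]:
    """Analyse a batch of records; per-record failures do not abort the batch."""
    records = list(records)
    if not records:
        warnings.warn("analyse_dataset called with an empty record list",
                      stacklevel=2)
        return []
    outcomes: list[RecordOutcome] = []
    for i, rec in enumerate(records):
        name = getattr(rec, "name", f"record-{i}")
        try:
            res = analyse_record(rec, table, passes=passes, tolerance=tolerance)
            outcomes.append(RecordOutcome(name=name, index=i, result=res))
        except AnalysisError as exc:
            outcomes.append(RecordOutcome(name=name, index=i, error=str(exc)))
    return outcomes
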