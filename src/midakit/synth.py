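"""Synthetic labelled-fragment spectra with known ground truth.

The forward model is the exact inverse of the deconvolution: given a true
mass-isotopomer distribution x* on the simplex, the noiseless channel means
are A x* (A the fragment's correction matrix).  Replicates add independent
zero-mean Gaussian noise, truncated at zero because detector counts are
non-negative, with standard deviation sigma times the maximum noiseless
channel intensity.  An instrument gain drawn log-uniformly per record
rescales everything, so the analysis layer's normalization invariance is
actually exercised.  The standard vector is the unlabelled (column-0)
pattern under the same noise model.

All randomness flows from an explicit integer seed; the same scenario and
seed reproduce bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import FRAGMENT_PRESETS, FragmentSpec, IsotopeTable
from .mida import DEFAULT_SEED, MassSpectrumRecord, absolute_enrichment, \
    build_correction_matrix

__all__ = ["SimulationScenario", "SimulatedRecord", "simulate_record",
           "simulate_dataset"]

#: Instrument gain range (arbitrary detector units per unit abundance).
_GAIN_RANGE = (1e4, 1e6)


@dataclass(frozen=True)
class SimulationScenario:
    """One synthetic measurement: fragment, truth, noise and size."""

    fragment: FragmentSpec
    truth: np.ndarray
    sigma: float = 0.0
    replicates: int = 3
    seed: int = DEFAULT_SEED
    channels: int | None = None          # default n + 5
    m_minus_one_fraction: float = 0.0    # optional constant artifact channel

    def __post_init__(self) -> None:
        x = np.asarray(self.truth, dtype=float)
        if x.ndim != 1 or x.size != self.fragment.n_labelled + 1:
            raise ValueError(
                f"truth must have n+1={self.fragment.n_labelled + 1} entries")
        if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
            raise ValueError("truth must lie on the simplex")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        object.__setattr__(self, "truth", x)

    @property
    def n_channels(self) -> int:
        return self.channels if self.channels is not None \
            else self.fragment.n_labelled + 5


@dataclass(frozen=True)
class SimulatedRecord:
    """A synthetic spectrum together with its ground truth."""

    record: MassSpectrumRecord
    truth: np.ndarray
    true_enrichment: float
    scenario: SimulationScenario


def _noisy(mean: np.ndarray, sigma_abs: float, rng: np.random.Generator) -> np.ndarray:
    if sigma_abs == 0:
        return mean.copy()
    return np.clip(mean + rng.normal(0.0, sigma_abs, size=mean.size), 0.0, None)


def simulate_record(scenario: SimulationScenario,
                    table: IsotopeTable) -> SimulatedRecord:
    """Generate one record from the forward model; deterministic given seed."""
    spec = scenario.fragment
    rng = np.random.default_rng(scenario.seed)
    matrix = build_correction_matrix(spec, table, rows=scenario.n_channels)
    means = matrix.entries @ scenario.truth
    standard_means = matrix.entries[:, 0].copy()

    lo, hi = _GAIN_RANGE
    gain = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    means = gain * means
    standard_means = gain * standard_means

    channel_start = 0
    if scenario.m_minus_one_fraction > 0:
        artifact = scenario.m_minus_one_fraction * means.max()
        means = np.concatenate([[artifact], means])
        standard_means = np.concatenate(
            [[scenario.m_minus_one_fraction * standard_means.max()],
             standard_means])
        channel_start = -1

    sigma_abs = scenario.sigma * means.max()
    drawn = [_noisy(means, sigma_abs, rng) for _ in range(scenario.replicates)]
    # records always carry three replicate slots; repeat the last draw
    while len(drawn) < 3:
        drawn.append(drawn[-1].copy())
    reps = tuple(drawn[:3])
    standard = _noisy(standard_means, scenario.sigma * standard_means.max(), rng)

    record = MassSpectrumRecord(
        name=spec.name,
        fragment=spec,
        channel_start=channel_start,
        replicates=reps,
        standard=standard,
        timestamp="1970-01-01T00:00:00",
    )
    n = spec.n_labelled
    true_enr = float(np.dot(np.arange(n + 1), scenario.truth) / n)
    return SimulatedRecord(record=record, truth=scenario.truth,
                           true_enrichment=true_enr, scenario=scenario)


def simulate_dataset(specs=None, concentration: float = 1.0,
                     sigma: float = 0.0, seed: int = DEFAULT_SEED,
                     table: IsotopeTable | None = None
                     ) -> tuple[list[SimulatedRecord], pd.DataFrame]:
    """Simulate one record per fragment with Dirichlet-distributed truths.

    ``concentration`` is the symmetric Dirichlet parameter for drawing each
    truth vector (large values concentrate near the uniform distribution).
    Returns the simulated records and a tidy truth table (one row per
    fragment with its true fractions and enrichment).
    """
    if table is None:
        from .chem import default_isotope_table
        table = default_isotope_table()
    if specs is None:
        specs = [s for s in FRAGMENT_PRESETS.values() if s.formula_verified]
    specs = list(specs)
    if not specs:
        raise ValueError("no fragment specifications given")

    rng = np.random.default_rng(seed)
    records: list[SimulatedRecord] = []
    rows = []
    for spec in specs:
        n = spec.n_labelled
        truth = rng.dirichlet(np.full(n + 1, concentration))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        scenario = SimulationScenario(fragment=spec, truth=truth,
                                      sigma=sigma, seed=sub_seed)
        sim = simulate_record(scenario, table)
        records.append(sim)
        row = {"metabolite": spec.name, "n_labelled": n,
               "true_enrichment": sim.true_enrichment}
        row.update({f"x{j}": truth[j] for j in range(n + 1)})
        rows.append(row)
    return records, pd.DataFrame(rows)
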