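"""Tabular and graphical reporting of enrichment results.

The analysis layer works on the [0, 1] scale throughout; this module is the
only place values are formatted as percentages (x100).  Two plot-ready
tables are produced:

* the bar table — one row per metabolite with mean absolute 13C enrichment
  and its replicate standard deviation (the error bar);
* the mountain table — per-channel curves per fragment comparing the
  theoretical natural-abundance pattern with the measured mean relative
  intensities, the labelled/unlabelled contrast at a glance.

Plot files are a thin rendering of these tables: every number shown is
derivable from the CSVs alone.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .chem import IsotopeTable
from .mida import MassSpectrumRecord, RecordOutcome, relative_intensities

__all__ = [
    "enrichment_table", "abundance_table", "channel_table",
    "bar_table", "mountain_table", "results_json", "read_table",
    "render_bar_plot", "render_mountain_plot",
]


def enrichment_table(outcomes: list[RecordOutcome]) -> pd.DataFrame:
    """One row per metabolite: replicate enrichments, mean, SD, reference."""
    rows = []
    for oc in outcomes:
        if not oc.ok:
            continue
        r = oc.result
        rows.append({
            "metabolite": r.name,
            "enrichment_1": r.per_replicate[0],
            "enrichment_2": r.per_replicate[1],
            "enrichment_3": r.per_replicate[2],
            "mean": r.mean,
            "sd": r.sd,
            "natural_reference": r.natural_reference,
            "m_minus_one_fraction": r.m_minus_one_fraction,
            "converged": all(d.converged for d in r.distributions),
        })
    return pd.DataFrame(rows, columns=[
        "metabolite", "enrichment_1", "enrichment_2", "enrichment_3",
        "mean", "sd", "natural_reference", "m_minus_one_fraction",
        "converged"])


def abundance_table(outcomes: list[RecordOutcome]) -> pd.DataFrame:
    """One row per metabolite x replicate x isotopomer: fraction x_j."""
    rows = []
    for oc in outcomes:
        if not oc.ok:
            continue
        r = oc.result
        for rep, dist in enumerate(r.distributions, start=1):
            for j, xj in enumerate(dist.fractions):
                rows.append({"metabolite": r.name, "replicate": rep,
                             "label_count": j, "fraction": xj})
    return pd.DataFrame(rows, columns=["metabolite", "replicate",
                                       "label_count", "fraction"])


def channel_table(spectra: list[MassSpectrumRecord],
                  table: IsotopeTable) -> pd.DataFrame:
    """Per-channel natural vs measured relative intensities per fragment.

    Fragments without a verified composition carry no theoretical pattern
    and are skipped with a warning.
    """
    from .mida import build_correction_matrix

    rows = []
    for spec in spectra:
        frag = spec.fragment
        if not frag.formula_verified:
            warnings.warn(f"{spec.name}: fragment composition unverified; "
                          f"no natural pattern", stacklevel=2)
            continue
        drop = 1 if spec.channel_start == -1 else 0
        n_rows = spec.standard.size - drop
        matrix = build_correction_matrix(frag, table, rows=n_rows)
        natural = matrix.entries[:, 0]
        natural = natural / natural.sum()
        measured = np.mean(
            [relative_intensities(r[drop:]) for r in spec.replicates], axis=0)
        for shift in range(n_rows):
            rows.append({"metabolite": spec.name, "mass_shift": shift,
                         "mz": frag.m0 + shift,
                         "natural": natural[shift],
                         "relative": measured[shift]})
    return pd.DataFrame(rows, columns=["metabolite", "mass_shift", "mz",
                                       "natural", "relative"])


def bar_table(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Bar-plot data in percent: metabolite, mean enrichment, SD."""
    if enrichment.empty:
        warnings.warn("no results to report", stacklevel=2)
        return pd.DataFrame(columns=["metabolite", "enrichment_pct", "sd_pct"])
    return pd.DataFrame({
        "metabolite": enrichment["metabolite"],
        "enrichment_pct": 100.0 * enrichment["mean"],
        "sd_pct": 100.0 * enrichment["sd"],
    })


def mountain_table(channels: pd.DataFrame) -> pd.DataFrame:
    """Mountain-plot data in percent: per-channel natural vs relative."""
    if channels.empty:
        warnings.warn("no channel data to report", stacklevel=2)
        return pd.DataFrame(columns=["metabolite", "mass_shift", "mz",
                                     "natural_pct", "relative_pct"])
    return pd.DataFrame({
        "metabolite": channels["metabolite"],
        "mass_shift": channels["mass_shift"],
        "mz": channels["mz"],
        "natural_pct": 100.0 * channels["natural"],
        "relative_pct": 100.0 * channels["relative"],
    })


def results_json(outcomes: list[RecordOutcome]) -> str:
    """JSON mirror of the tabular results, including per-record failures."""
    payload = []
    for oc in outcomes:
        if oc.ok:
            r = oc.result
            payload.append({
                "metabolite": r.name,
                "enrichment": list(r.per_replicate),
                "mean": r.mean,
                "sd": r.sd,
                "natural_reference": r.natural_reference,
                "m_minus_one_fraction": r.m_minus_one_fraction,
                "distributions": [list(d.fractions) for d in r.distributions],
                "converged": all(d.converged for d in r.distributions),
            })
        else:
            payload.append({"metabolite": oc.name, "error": oc.error})
    return json.dumps(payload, indent=2, sort_keys=True)


def read_table(source) -> pd.DataFrame:
    """Read back any CSV written by this module."""
    return pd.read_csv(source)


def render_bar_plot(bar: pd.DataFrame, path) -> None:
    """Bar chart of mean enrichment per metabolite with SD error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(bar)), 4))
    ax.bar(bar["metabolite"], bar["enrichment_pct"], yerr=bar["sd_pct"],
           capsize=4, color="#4878a8")
    ax.set_ylabel("absolute $^{13}$C enrichment (%)")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_mountain_plot(mountain: pd.DataFrame, path) -> None:
    """Filled per-channel curves: natural vs measured relative abundance."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(mountain.groupby("metabolite"))
    fig, axes = plt.subplots(len(groups), 1, squeeze=False,
                             figsize=(6, 2.2 * max(1, len(groups))))
    for ax, (name, grp) in zip(axes.ravel(), groups):
        ax.fill_between(grp["mz"], grp["natural_pct"], alpha=0.5,
                        label="natural", color="#8ab17d")
        ax.fill_between(grp["mz"], grp["relative_pct"], alpha=0.5,
                        label="measured", color="#4878a8")
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("m/z")
        ax.set_ylabel("relative intensity (%)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
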