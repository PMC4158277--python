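# Methods

## Problem and model

A GC-MS fragment ion of a TBDMS-derivatized amino acid is recorded over a
contiguous window of nominal mass channels M₋₁, M₀, …, M_max (M₀ the
monoisotopic mass, charge z = 1). In a ¹³C-labelling experiment the
measured intensities are the superposition of (i) the biological mass-
isotopomer distribution x = (x₀, …, xₙ) over the n carbon-skeleton
positions retained in the fragment and (ii) the natural abundance of heavy
isotopes in *all* atoms of the fragment — including the silicon of the
derivatization groups, whose ²⁹Si/³⁰Si contributions are far from
negligible.

The forward model is linear. The theoretical pattern of the isotopomer with
j labelled carbons is the natural-isotope shift distribution of the
fragment formula with j carbons removed from the natural pool (they are
fixed ¹³C), shifted up j channels. These patterns form the columns of the
rectangular abundance matrix A (rows = shifts 0…m, columns j = 0…n,
m ≥ n), and the normalized spectrum satisfies y = A x on the simplex.

Assumptions:

* **No differential isotope effect.** One fragmentation pattern per
  fragment: every isotopomer column is built from the same reduced-formula
  chemistry, never per-isotopomer fragmentation.
* Nominal (unit-mass) resolution; isotopic fine structure, mass defects,
  electron mass and charge states other than z = 1 are out of scope.
* Isotope abundances are known. The shipped table (IUPAC-style
  representative values: ¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038,
  ¹⁸O 0.00205, ²⁹Si 0.04685, ³⁰Si 0.03092, plus ³³/³⁴/³⁶S) can be
  overridden by a plain-text file of `element shift abundance` triples.

## Natural patterns

Per-atom shift distributions are convolved (`numpy.convolve`) across all
atoms of the formula, truncated at the requested channel count — the
binomial expansion generalized to multi-isotope elements. The test suite
checks this against an independent exhaustive-enumeration oracle that sums
multinomial weights over per-element isotope compositions, agreeing to
1e-10 per entry.

## Solver and refinement

Pass 1 solves the overdetermined system by the Moore–Penrose pseudo-inverse
(unconstrained least squares). Each refinement pass clamps negative
fractions to zero, re-solves by least squares restricted to the surviving
columns, clamps any residual negatives, and renormalizes to Σx = 1. Two
passes are the default. An optional third pass validates convergence:
`converged` is set iff no fraction moves by more than the tolerance
(default 1e-6, configurable because no universal stopping rule exists for
such data). The restricted re-solve fits at least as well as naively
clamping the unconstrained solution, by optimality of least squares on the
support. If every fraction clamps to zero (pathological input), the solver
falls back to full non-negative least squares (`scipy.optimize.nnls`) and
flags the result `degenerate`. Rank-deficient matrices are rejected with
the fragment named.

**M₋₁ handling.** The correction matrix has no theoretical intensity below
M₀, so including the M₋₁ channel in the fit would force a non-physical
column. M₋₁ is therefore excluded from the fitted system and reported
separately as its mean relative intensity — a diagnostic for proton loss or
peak overlap.

## Enrichment statistics

Absolute ¹³C enrichment is E = (Σⱼ j·xⱼ)/n per replicate; a record reports
the three replicate values, their arithmetic mean and the sample standard
deviation (n−1 = 2 denominator). The unlabelled standard spectrum is
deconvolved identically, yielding a natural-reference enrichment that
should sit near zero; with the shipped table it is below 0.5 % for all
verified fragments.

## Fragment chemistry

TBDMS derivatization replaces an exchangeable H by SiMe₂tBu — net
+C₆H₁₄Si, +114 Da per substitution — and the dominant electron-impact loss
is the tert-butyl radical C₄H₉ (−57 Da). Presets: alanine-260 and
glycine-246 (2 TBDMS, [M−57]), aspartic acid-418 and threonine-404
(3 TBDMS, [M−57]), proline-184 (2 TBDMS, [M−159]: loss of tert-butyl plus
the TBDMS-ester carboxyl C₇H₁₅O₂Si, so the carboxyl carbon is lost and
n = 4). Every preset's declared nominal mass is verified against the
assembled formula at construction. Lysine-300 and tyrosine-302 ship as
name + M₀ + n presets flagged `formula_verified=False`: no composition
consistent with the shipped chemistry reproduces those masses, so they
identify channel ranges but refuse to build a correction matrix rather
than silently using a guessed formula.

## Parameters that matter

| parameter | default | units / range | rationale |
|---|---|---|---|
| pattern length / matrix rows | n + 5 | channels | Si₂/Si₃ heavy tails beyond that carry < 1e-6 mass |
| refinement passes | 2 (optionally 3) | — | third pass is validation only |
| convergence tolerance | 1e-6 | fraction units | max per-fraction change in pass 3 |
| replicate SD | ddof = 1 | — | three independent measurements |
| seed | 1316 | — | arbitrary, pinned; all randomness flows from it |

## Synthetic data

The generator inverts the analysis: channel means are A x★ for a truth x★
on the simplex (drawn symmetric-Dirichlet in dataset mode), scaled by an
instrument gain drawn log-uniformly over 10⁴–10⁶ per record so that the
normalization invariance is genuinely exercised, with independent Gaussian
noise of SD σ × (max channel mean), truncated at zero because detector
counts are non-negative. The standard vector is the column-0 (unlabelled)
pattern under the same noise model. An optional constant-fraction M₋₁
artifact channel exercises the diagnostic path. Default σ for noisy
studies is 0.005 (0.5 % of the strongest channel), a realistic relative
precision for integrated GC-MS peak areas in triplicate work.

What the generator does **not** emulate: chromatographic peak shapes and
integration error, mass-calibration drift, detector saturation, solvent or
column-bleed contamination, and correlated (non-independent) replicate
error. Passing recovery tests therefore demonstrates correctness of the
deconvolution under the stated noise model, not robustness to instrument
artefacts — real data should always be checked via the standard spectrum
and the M₋₁ diagnostic.

Study sizes used by the tests and the acceptance script: 50 random
formulas (≤ 12 atoms) for the pattern oracle; 100 noiseless truths per
fragment for closure; 1000 Monte-Carlo draws at σ = 0.005 for stochastic
recovery; 40 records per σ on the {0.001, 0.005, 0.02} grid for noise
scaling. These sizes give stable estimates (the measured quantities vary
by < 5 % across seeds) while keeping the whole suite in seconds.

## Formats, archive, reporting

The `.iso`/`.isx` grammar is documented in `midakit/formats.py`: nine
semicolon-separated fields per record, comma-separated lists,
`*`-separated records, numbers at 6 significant digits, UTF-8; `.isx` adds
a provenance header line. The "fixed value" field and the raw-table
"groups" column are carried opaquely, never interpreted (the raw-table
merge stores `atoms=…,groups=…` there as plain text). Binary spreadsheet
input is out of scope; the three-table CSV layout stands in for the
spreadsheet sheets. The archive is a single-file embedded SQLite database
(foreign keys on, cascading deletes, ISO-8601 timestamp text) rather than
a networked server: the pipeline must work offline, and the schema is the
portable artifact. Analysis outputs stay on the [0, 1] scale; only the
report layer multiplies by 100, and plots are thin renderings of the
report CSVs with no hidden computation.

## Design choices where the design was open

* "Partial least squares" here means least squares on the rectangular
  system via pseudo-inverse — not latent-variable PLS regression, which
  would be unidentifiable for a single spectrum.
* The refinement is defined as clamp → restricted re-solve → renormalize;
  simple renormalization of the clamped vector was rejected because the
  restricted re-solve provably fits no worse.
* Fragment presets and the isotope table are embedded in the package (with
  file-based overrides) instead of shipping loose data files, so an
  installed package is self-contained.
* The batch analyser records per-record failures and continues; a single
  malformed record must not abort a multi-metabolite run.

## Known limitations

* Only C, H, N, O, S, Si are supported; other elements are rejected loudly.
* Channel windows narrower than n + 1 fitted rows cannot be deconvolved.
* Enrichment of fragments without a verified composition (lysine-300,
  tyrosine-302) cannot be computed until a formula is supplied explicitly.
* The M₋₁ diagnostic is reported, not modelled; strong proton-loss
  artefacts bias the standard-based reference rather than being corrected.
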