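# Methods

## The flexibility model

The central assumption is that positional spread across an ensemble of
plausible models is a usable surrogate for local conformational
flexibility, and that flexibility differences between a variant and a
reference ensemble localise the variant's destabilising effect.  The
per-residue statistic is the Cα deviation from a reference model after
rigid-body superposition.  Two estimators are kept side by side because
"average per-residue RMSD" is genuinely ambiguous between them:

* `rms_deviation` = √(mean of squared deviations) over models — the default
  in exported maps, and the one with the cleanest closed form: for
  isotropic per-axis Gaussian noise of width σ the deviation is
  Maxwell-distributed and rms → σ√3;
* `mean_deviation` = plain mean deviation (→ σ·2√(2/π) ≈ 1.596 σ).

Both columns appear in every profile and difference table; anything that
needs a single statistic names it explicitly.

**Superposition.** Kabsch via SVD with determinant-sign correction (the
exact least-squares optimum over proper rigid motions), equal weights,
Cα only, no outlier rejection.  For multi-domain proteins the default is
per-domain pre-alignment: each named structural domain is fitted
independently and deviations are recorded within it, so a rigid shift of
one domain relative to another — real conformational signal at the global
scale, but not *local* flexibility — does not inflate the profile.  A
global single-fit mode exists for whole-structure RMSD and for callers who
want the inflation.  Fitting a finite set of residues absorbs 6 rigid-body
degrees of freedom, which biases per-residue deviations low by roughly a
factor √(1 − 6/(3N)) for N fitted residues (≈ 1% at N = 100); the
closed-form recovery tests assert the profile mean, where this bias is
within the stated 5% band at the domain sizes used.

**Reference choice** is explicit, never defaulted: either a published
(experimental) model or the lowest-scoring ensemble member, because the two
conventions answer different questions (diversity around the data vs
spread around the ensemble's own optimum).  The pipeline logs which was
used.

**Confidence band.** Student-t interval on the per-residue mean deviation,
with the model count as sample size; a percentile bootstrap is available
(`ci_method="bootstrap"`).  Deviations are skewed, so at very small model
counts the t-band is approximate; empirical coverage at 30 models is ≥90%
for a nominal 95% band in the test suite.

## Residue correspondence across variants

A deletion variant is compared on reference numbering.  The correspondence
maps reference position *i* to *i* below the deleted site, to nothing at
it, and to *i −(number of deletions below i)* above it; substitutions map
identically but are recorded.  The map is strictly increasing and
invertible on its image (property-tested), and variant profiles are
re-indexed through it before subtraction, leaving NaN at positions with no
variant counterpart.  Insertion codes are rejected outright — the target
systems use plain numbering — and undetermined residues are simply absent:
every per-residue output is sparse over determined residues, never imputed.

## Interface energetics

Pair energies between "contacting side chains" are represented by a
truncated-and-shifted 12-6 potential on side-chain representative atoms
(CB, or CA for glycine):

```
V(d) = ε[(r0/d)^12 − 2(r0/d)^6] − V_LJ(rc),   d < rc;   V(d ≥ rc) = 0
```

with ε = 1 (REU-like), r₀ = 5 Å, rc = 8 Å.  The shift makes V continuous at
the cutoff (V(r₀) = −0.88434 ε rather than −ε).  This is a deliberately
transparent stand-in for force-field pair energies: the scientific content
of the interface analysis is the *aggregation and comparison* layer, which
is identical whichever energy model fills the table, and externally
computed per-pair breakdown tables can be ingested in place of the
surrogate.  The 8 Å representative-atom cutoff doubles as the contact
definition.  Only side-chain-representative pairs are counted (no
backbone–backbone term), and the implementation treats residue numbers as
unique within a model (single-chain; the target systems are single-chain).

An interface energy is the sum of pair energies over pairs with one residue
in each of two named domains; sums partition exactly (interfaces + within-
domain sums = table total, property-tested).  Distributions of sums are
summarised as quartiles with 1.5·IQR whiskers and compared with a
two-sided Mann–Whitney U: exact enumeration of all C(n+m, n) splits
(midrank U, ties handled natively) while that count is ≤ 10⁵, and the
tie-corrected normal approximation above.  Labels: p < 0.05 `*`, < 0.01
`**`, < 0.001 `***`, < 0.0001 `****`.

**Select-then-test caveat.**  The comparison protocol tests the
*best-scoring fraction* of each ensemble.  Order statistics of a sample are
mutually dependent — the whole selected tail co-moves with the realised
tail of its parent ensemble — so the rank test's iid assumption is
violated and the test is anti-conservative: simulation with iid Gaussian
scores and no effect gives ≈25–40% rejection at nominal p < 0.05 for
best-100-of-2000 selections (whether the two groups come from independent
runs or from disjoint halves of one run).  Stars on selected-tail
comparisons therefore overstate evidence; the package implements the
protocol as defined and reports the honest null rate in the acceptance
script rather than recalibrating silently.  Comparisons of unselected
ensembles do not have this problem.

## Selection and calibration

Best-subset selection takes the ⌈f·n⌉ lowest scores (never zero models for
positive f), with ties broken by model tag for reproducibility.  The
stability statistic is the mean score of the best 5%.  Calibration
correlates that statistic with experimental ΔTm (°C vs WT) and ΔΔG
(kcal/mol vs WT) across variants per candidate template count and chooses
the count maximising the mean of the two Pearson coefficients (ties to the
smaller, cheaper count).  The tool correlates raw columns and never flips
signs; the orientation of the experimental axes is the table author's
declaration, anchored by a mandatory WT row with zero deltas.

## Refinement tuning

The density-weight objective is `FSC(w) − c·E(w)` with c = 0.04 by default,
maximised over the scan (ties to the smaller weight).  The scan table is an
input: the module never launches refinement, and how E — "per-residue
energy for the ensemble" — was aggregated over models and residues is the
producer's responsibility, recorded with the table.  Fragment-length and
insertion-rms sweeps are judged by ensemble diversity; the module supplies
median/IQR/max of region-restricted RMSD per setting and ranks by median,
imposing no further selection rule.

## The synthetic generator

The generator emulates the *statistical* structure of a modelling ensemble,
not protein physics:

* deterministic ideal-helix Cα traces (rise 1.5 Å, 100°/residue, radius
  2.3 Å → consecutive Cα ≈ 3.8 Å) with pseudo-CB atoms at 1.53 Å, one helix
  per domain, domains on a grid (12 Å spacing, clash-checked);
* per-residue isotropic Gaussian noise, same draw applied to a residue's CA
  and CB (default σ = 0.4 Å per axis, giving rms ≈ 0.7 Å, the scale of a
  well-determined region in a refinement ensemble); named hot regions
  multiply σ (the CFTR-like preset ships an SDR at 526–547 with ×2.5 — one
  flank of that range is quoted a residue narrower in places — and an
  α-helical subdomain at 500–540 at ×1.0, raised in destabilised variants;
  overlapping regions stack multiplicatively); optional per-model rigid
  domain translations exercise the per-domain-alignment rationale;
* scores `baseline + k·Σ‖displacement‖² + N(0, σ_s²)` with baseline −1000,
  k = 1 REU/Å², σ_s = 15 — so scores rank models by realised perturbation
  with realistic scatter, and a destabilised variant scores higher (worse)
  than the reference without any further dial;
* planted interface contacts: for each designated cross-domain pair the two
  pseudo-CBs are re-oriented so their distance equals the inverse of the
  shifted potential at the target energy (two-sphere intersection,
  deterministic branch) — the surrogate recovers the planted energy
  exactly on the scaffold.  Weakening scales targets toward zero, moving
  pairs apart.  Positional noise averages over the convex well and
  *attenuates* planted energy differences in ensemble means, so weakened
  interfaces are detected by sign and rank rather than by exact magnitude;
* deletion variants drop the residue's atoms and renumber downstream
  residues by −1, leaving all other geometry unchanged — the cleanest null
  for "deletion bookkeeping only" comparisons.  Variant conditions draw an
  independent noise stream (seed + 1).

All randomness flows from the single seed in the spec; ground truth
(per-residue σ, planted contacts, score parameters, the full spec) is
exportable and reloadable losslessly.

What passing tests on this generator do **not** show: anything about real
protein energetics (the surrogate is not a force field), correlated or
collective motions (noise is independent across residues and models),
sequence effects, or the behaviour of real refinement ensembles whose noise
is neither isotropic nor Gaussian.  They show that the measurement chain —
superposition, profiling, correspondence, aggregation, testing, selection,
calibration — recovers known inputs at the stated rates.

## Numerical and format choices

* PDB I/O is backed by biotite (fixed-column; coordinates are float32, so
  round-trips are exact to the format's 3 decimals).  Alt-locs: blank or
  `A` kept, others dropped with a warning.  Waters always dropped; HETATM
  kept on request (ligands as named regions).  Malformed fixed-column
  records are reported with their line number.
* B-factor value maps clip to the field width (−99.99..999.99) and
  round-trip to 2 decimals; map exports clip to a declared range
  (0–4 Å for flexibility, symmetric for differences).
* Score tables use the `score.sc` dialect (header `SCORE:` line, tag last);
  duplicate tags are an error; parsing is order-preserving and total.
* Exact vs asymptotic Mann–Whitney switches at 10⁵ arrangements.
* Pearson r is undefined (error) for constant input or n < 3.
* Degenerate superposition inputs (<3 points, collinear sets) are errors,
  not warnings.

## Problem sizes

The test suite and acceptance script use deliberately scaled conditions:
closed-form recovery at 500 models × 90 residues, σ-profile rank recovery
at 200 models, detection/null rates at 50 replicates of best-100-of-2000
score selections on 60-residue scaffolds, interface-weakening detection at
20 replicates, CI coverage at 200 ensembles of 30 models.  These sizes make
the whole suite run in about a minute on one CPU while keeping every rate
estimate's binomial error well inside the asserted margins.

## Known limitations

Single-chain energetics; no insertion codes; no mmCIF or assembly
handling; ideal-helix scaffolds only (no realistic stereochemistry); the
surrogate potential has no electrostatics or solvation; the select-then-
test significance caveat above applies to any best-fraction comparison.
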