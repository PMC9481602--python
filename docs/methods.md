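# Methods

## Chemical-shift perturbation mapping

A backbone amide's weighted CSP between two ¹H–¹⁵N HSQC spectra is
Δω = √(((Δ¹H)² + (Δ¹⁵N)²/25)/2) in ppm; the 1/25 weight rescales the
roughly five-fold wider ¹⁵N dispersion onto the ¹H scale.  Δω is a
magnitude, so it is invariant under swapping reference and variant, and
scales linearly with any common scaling of the underlying shifts.

Prolines carry no backbone amide and unassigned residues carry no peak;
both are simply absent from peak lists — no placeholder rows — and all
statistics run on the intersection of assigned residues.  Residues present
in only one spectrum (typically broadened out) are dropped from the
profile and surface in the pairing report instead.

Significance cutoffs are the mean and the mean plus one standard deviation
of the pooled non-excluded Δω values.  The SD uses the n−1 denominator
(sample SD), the conventional default.  Two exclusion conventions are
built in and caller-configurable: comparisons of acetyl-lysine variants
against the unmodified protein exclude all seven lysines (the modified
residue's own peak is trivially perturbed at each site), while
point-substitution comparisons exclude only the substituted position.
Classes are assigned with strict inequality (Δω > cutoff), so a
zero-variance pool classifies everything as below the cutoff.

Sequence clusters are maximal runs of significant residues allowing at
most `gap_tolerance` (default 1) non-significant positions in between and
requiring at least `min_size` (default 2) significant members.  The
cluster definition is ours: published CSP maps describe clusters visually;
a gap-tolerant run with a minimum size is the smallest formalization that
reproduces that reading and is deterministic.

Peak pairing across conditions is assignment-based by default.  A
nearest-trajectory mode (greedy one-to-one matching in ascending weighted
distance with a `max_jump` cap, ties broken toward the lower residue
number and flagged) is provided as a reproducible surrogate for manually
following peak trajectories; it is a convention, not a reconstruction of
any particular manual assignment.

## Titration analysis and global Kd fitting

A titration series is an ordered list of spectra with per-step total
protein and ligand concentrations; these can be given directly or derived
from a volume scheme by cumulative dilution ([P] = P₀V₀/(V₀+ΣΔV),
[L] = L_stock·ΣΔV/(V₀+ΣΔV)).  Per-step CSPs are computed against the
ligand-free spectrum.

The binding model is the exact 1:1 quadratic (no weak-binding
approximation), evaluated with the discriminant clamped at zero so that
stoichiometric saturation does not produce a negative round-off under the
square root.  Properties relied on by the tests: the response is strictly
increasing in ligand, bounded by Δω_max, and collapses to the piecewise
linear stoichiometric limit min(1, L/P)·Δω_max as Kd → 0.

Attrition screening compares the final step against step 0 ("net endpoint
loss"): remaining fraction < 0.10 — i.e. strictly more than 90 % loss —
flags the residue; exactly 90 % does not.  A residue absent at the final
step has fraction 0.  Fit residues are those significant (above the mean
cutoff) at the endpoint of every experiment and flagged in none.

The global fit minimizes the summed squared CSP residuals over all
(residue, step) observations with one shared Kd and one Δω_max per
residue.  For fixed Kd each Δω_max has the closed-form least-squares
solution Σyf/Σf² (f = fraction bound), so the search is one-dimensional
in log₁₀ Kd, bounded in [10⁻³, 10⁵] µM to enforce positivity, solved with
bounded scalar minimization (tolerance 10⁻¹⁰ on log₁₀ Kd) plus a local
polish around the heuristic start max([L])/2.  A residue that disappears
mid-titration contributes only its observed steps.  Non-convergence or a
boundary solution is flagged on the result, never silently replaced.

Kd uncertainty: the default is the asymptotic standard error from
s²(JᵀJ)⁻¹ over the full parameter vector (Kd plus all amplitudes); an
optional seeded residual bootstrap (percentile interval, resampling the
pooled residuals) is available since reported ± values on dissociation
constants rarely state their estimation method.

Identifiability: with the default design (33 µM protein, endpoint ~3×
molar excess) Kd values well above max([L]) are weakly constrained — the
curve becomes linear in L and Kd trades off against Δω_max.  The oracle
test therefore draws true Kd values from 1–50 µM, where the design is
informative; recovery degrades gracefully outside this range.

## Synthetic-data generators

All generators are pure functions of a spec plus a seed (numpy
`default_rng`).

*HSQC pairs.*  Base peak positions are uniform in 6.5–10.5 ppm (¹H) and
103–133 ppm (¹⁵N); a planted perturbation (residue, Δω, angle θ) displaces
the variant peak by Δ¹H = Δω√2·cosθ, Δ¹⁵N = 5Δω√2·sinθ — an algebraic
inverse of the weighted-CSP formula, so the pipeline recovers the planted
Δω exactly at zero noise for any θ.  Gaussian noise of SD `noise_sd` (ppm)
is added independently to both dimensions of both spectra.  With the
76-residue default the canonical ubiquitin sequence provides residue
types, and prolines (19, 37, 38) are absent.

*Titrations.*  Concentrations follow the cumulative-dilution scheme with
protein start 33 µM in 500 µL and seven additions (4, 6, 8, 10, 10, 12,
12 µL) of an 803 µM ligand stock — start and stock concentrations are the
published design of the low-concentration experiments; the volumes are our
choice, fixed once so the endpoint reaches ≈3.0× molar excess as those
experiments did.  Six interface residues (14, 43, 45, 51, 67, 71) carry
saturation amplitudes 0.05–0.5 ppm; all other residues have Δω = 0.
Per-step CSPs come from the 1:1 quadratic plus optional Gaussian noise,
decomposed into peak positions as above.  Intensities decay as
I = I₀(1 − β·fraction_bound) with a per-residue broadening coefficient
β ∈ [0, 1], so β ≈ 1 residues trip the >90 % attrition rule near
saturation — emulating intermediate-exchange line broadening without
modelling lineshapes.

*LFQ tables.*  Log2 abundances are baseline (per-protein, Normal(27, 1.5²))
plus a per-(protein, bait) enrichment effect plus Normal(0, 0.5²) noise.
Defaults: 300 proteins, 8 baits × 8 replicates, three planted clusters of
20 proteins with effects drawn uniformly from 4–6 log2 units on disjoint
bait subsets — the structure of a bait-specific interactor heat map.
Values below the detection limit (25 on the log2 scale, ≈9 % of baseline
draws) are censored to 0/"missing", making missingness depend on abundance
(MNAR), which is what the downshifted-normal imputation assumes.  Reverse
and contaminant decoy rows are injected for the filter stage.

*Ensembles.*  An extended-chain template (residues collinear along x,
0.5 nm apart, atoms 0.05 nm apart) with per-frame isotropic Gaussian
jitter and an optional systematic per-residue displacement.  The template
is deliberately simple: displacements along the chain change minimum
distances by exactly the displacement length, which makes difference-map
assertions exact.

What the generators do **not** emulate: real chemical-shift dispersion or
degeneracy (peak overlap), exchange-regime lineshapes, correlated
replicate structure or batch effects in LFQ data, compositional sequence
effects, or physically realistic protein geometry.  Passing tests
demonstrate that the statistics and the optimizer are implemented
correctly and are well-calibrated under their own assumptions — not that
those assumptions hold for any particular real data set.

## AE-MS statistics

The pipeline order is fixed: filter → log2 → valid-value filter → impute
→ test; identical seeds give bit-identical outputs.

Filtering removes decoy ("Reverse"), contaminant and — when the column is
present — site-only identifications, then requires at least `min_valid`
(default 6) observed values among the `n_replicates` (default 8) runs of
**at least one** bait group.  This per-group reading is deliberate: an
interactor specific to one bait is fully observed there and largely
missing elsewhere, and a filter across all columns would discard exactly
the proteins of interest.  A strict all-groups mode is available.

Imputation is per sample column: missing entries are drawn from
Normal(μ − 1.2σ, (0.3σ)²) with μ, σ the column's observed mean and SD —
values just below the detection limit.  Observed values are never altered.

The test statistic is d = √MS_between/(√MS_within + s0), a SAM-style
moderation of the one-way ANOVA: at s0 = 0, d = √F and the ranking equals
the classic F ranking; s0 > 0 (default 4) suppresses proteins whose large
F rests on an implausibly small within-group variance.  The exact
statistic of the desktop software that popularized these parameter names
is unpublished; this denominator moderation keeps the same s0 semantics
and is documented as an approximation.  FDR is estimated by permuting the
sample labels (default 250 random permutations; complete enumeration for
two balanced groups when it is cheaper): q(d*) = E_perm[#{d_perm ≥ d*}] /
#{d_obs ≥ d*}, monotonized so q never increases with d, clipped to [0, 1].
Significance: q ≤ 0.002.

Significant proteins are z-scored across all samples (population SD),
summarized as per-bait medians, and clustered hierarchically with
distance 1 − Pearson and average linkage; rows are index-sorted before
linkage so leaf order is deterministic, and the tree is cut by maxclust.
Bait–bait Pearson correlation of the median profiles gives the
bait-similarity matrix; zero-variance columns yield NaN entries rather
than an error.

## Distance descriptors

Minimum distances use all atoms of a residue, including hydrogens when
present (a heavy-atom-only mode exists).  The matrix applies
truncate-then-average: per frame, each pair's minimum distance is capped
at the cutoff (default 1 nm) and the capped values are averaged — matching
mdmat semantics, and implying the cap also bounds the mean.  Entries are
invariant under rigid-body transformations of whole frames, and raising
the cutoff never decreases an entry.  When a study provides several
independent trajectory replicas, frames are concatenated before averaging
and differencing; averaging per replica and then differencing is the
caller's choice by constructing separate ensembles.

Multi-model PDB is the only trajectory format read (Biopython parser,
Å → nm on read); users export other formats to PDB.  Models must agree on
the (residue, atom-name) topology.

## Problem sizes and numerical conventions

Test and acceptance runs use the generators' default sizes — 7-step
titrations with 6 fitted residues, 300-protein × 64-sample LFQ matrices,
≤ 20-residue toy ensembles — which exercise every code path while keeping
the full suite in the seconds range.  Shifts are written with 4 decimal
places (ppm), exceeding instrument precision so file round-trips are
exact at the stated tolerance.  The attrition boundary is strict
(fraction < 0.10); cutoff classification is strict (>).  All randomness
flows through explicit integer seeds recorded in run reports.

## Known limitations

- Published interactome counts and cluster memberships from real AE-MS
  data depend on the raw deposited spectra and the original software's
  exact statistic; this implementation reproduces the stated workflow and
  its parameters, not byte-level outputs of other tools.
- Real per-step titration concentrations cannot be reconstructed without
  the (unpublished) addition volumes; the volume scheme here is an
  explicit, documented stand-in with the correct start/stock/endpoint.
- The Kd fit assumes fast exchange and 1:1 stoichiometry; no lineshape,
  multi-site or cooperative models.
- Endpoint cutoffs for fit-residue selection are computed per experiment
  by default; pooling across experiments is supported by passing the same
  pooled `CutoffPair` for every experiment.
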