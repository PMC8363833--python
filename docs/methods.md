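# Methods

This note documents the models, conventions and numerical choices behind
`hdxflex`, and what the synthetic generators do and do not emulate.

## Exchange model and uptake bookkeeping

Backbone amide hydrogens exchange with solvent deuterium; structure slows
a residue's intrinsic rate `k_int,i` by a protection factor `P_i ≥ 1`.
In the EX2 limit each amide exchanges independently, so the noiseless
uptake of a peptide at exposure `t` is

    D(t) = Σ_i (1 − exp(−(k_int,i / P_i) · t)),

summed over its exchangeable amides. A peptide of length L reports on
`L − 1 − #Pro(2..L)` amides: prolines carry no amide hydrogen, and the
N-terminal residue loses its label to fast back exchange during
quench/LC — a peptide spanning residues 74–85 effectively reports on
75–85. Some ecosystems exclude the first *two* residues; that convention
is available (`n_term_excluded=2`) but the single-residue exclusion is
the default.

Back exchange (BE) is estimated per peptide from a maximally deuterated
control as `BE = 1 − uptake/ExchangeableNH`, and corrected by dividing
observed uptake by the retained fraction `1 − BE`. Note the correction
divides by `1 − BE`, not by BE: dividing a 1.2 Da uptake by a 40% BE
would overshoot the amide count, whereas dividing by the retained 60%
recovers the pre-loss uptake exactly (the generator applies BE
multiplicatively, and the round trip is exact to machine precision).
Corrections are used only for absolute-uptake displays; differential
comparisons use uncorrected uptake because the same multiplicative loss
affects both states and cancels in the sign of the difference.

Cross-run normalization z-scores all observed uptake within a group.
"Same run" is ambiguous between pooling all exposures and grouping per
exposure; the default group is (run label, exposure), the safer reading
when uptake grows strongly with time, and the group key is configurable.
Zero-variance groups are an error rather than silently producing NaN.

## Differential statistics

ΔHDX = mean(bound) − mean(free) per (peptide, exposure); Δ < 0 is
protection. Two rules are applied jointly before a difference counts:

1. a one-tailed two-sample pooled-variance Student t-test at α
   (protection tested as bound < free; the direction is set per
   comparison, two-tailed available),
2. |Δ| must exceed a global confidence threshold

       threshold = t_{1−α, df} × mean_p √(sd²_f/n_f + sd²_b/n_b),

   the average CI half-width over peptides (df averaged across
   peptides). For triplicates with 0.15 Da replicate SD this is
   t(0.95, 4) × 0.1225 ≈ 0.26 Da — the usual "ca. 0.3 Da" scale of
   peptide-level HDX-MS. Whether such a threshold should be computed per
   timepoint or pooled is a judgment call; the pooled average is the
   default with a per-timepoint option. With no replicate information a
   configurable 0.3 Da fallback is used, with a warning.

No multiple-testing correction is applied by default, matching common
practice for peptide-level protection calls where the threshold already
suppresses small differences; Benjamini–Hochberg is available behind a
flag. Calls over an exposure ladder collapse to Protection /
Deprotection / ND; mixed-sign ladders are reported explicitly as Mixed
with the offending exposures listed, never silently collapsed.

Per-residue consolidation averages each peptide's value onto the
residues it actually reports (span minus excluded N-terminus and
prolines); uncovered residues are NaN, and B-factor output writes a
configurable sentinel (default 0.00) for them.

## Envelope model and bimodal fitting

The natural isotope pattern comes from the peptide's exact elemental
composition (via pyteomics) with per-element extra-neutron abundances
convolved by exponentiation-by-squaring — not an averagine estimate.
Isotope peaks and deuteron shifts are placed on a uniform 1.0 Da grid
(rather than 1.00336/1.00628 Da spacings); generator, fit and centroid
arithmetic share the convention, so uptake bookkeeping in Da is exact by
construction and no mass-recalibration step is needed.

A deuterated population is the natural pattern convolved with a Gaussian
of mean `d` (mean retained deuterons) and width `w`; the model grid
extends below the monoisotopic mass so the symmetric kernel is never
truncated and the centroid equals natural + `d` exactly. A bimodal
spectrum is a two-component mixture with one shared width (an
HX-Express-style constraint that suppresses the near-degeneracy of
overlapping modes). Fitting uses bounded trust-region least squares
(shifts in [0, ExchangeableNH], width in [0.3, 6] Da, fraction in
[0, 1]); the amplitude is profiled out linearly. Initialization splits
the envelope at its intensity-weighted median; three restarts with
deterministic jitter guard against local minima. Non-convergence is
flagged on the returned fit, never silently replaced.

Model selection uses corrected AIC with a two-unit margin before the
two-component model is preferred, plus a resolvability guard: the
bimodal verdict additionally requires component separation ≥ 3 shared
widths and a minor-component fraction ≥ 10%. Populations closer than a
few peak widths, or below ~10% abundance, cannot be distinguished from
envelope noise at a signal-to-noise ratio of ~50, and reporting them
would manufacture false bimodality on unimodal data (without the guard,
noise-driven two-component wins occur in roughly 10% of unimodal
envelopes; with it, essentially none, while 20/50/80% mixtures separated
by 5 Da are recovered with ~0.01 mean absolute fraction error).

A time course of fits is classified EX1 when ≥ 2 exposures are bimodal
with component centroids stable over time (drift < 0.5 Da) and a
nondecreasing heavy fraction; EX2 when every exposure is unimodal and
the centroid rises; anything else — including a flat, fully exchanged
series — is ambiguous.

## Trajectory geometry

Coordinates are in Å; literature cutoffs in nm are converted at the
interface. Residue numbering is 1-based with inclusive ranges; the
default domain definition is NTD 1–76, linker 77–79, CTD 80–165.

Superposition is Kabsch via SVD (proper rotations only); collinear
selections are flagged since the in-plane rotation is then arbitrary.
RMSD series superpose each frame onto the reference before measuring.
RMSF aligns all frames to the first frame, forms the mean structure,
re-aligns once to that mean (a single deterministic refinement pass),
and averages atomic RMSF within residues. The superposition itself
absorbs ~1/N of any single atom's motion, so RMSF of very small systems
underestimates localized fluctuations — with hundreds of anchored atoms
the bias is below a percent.

The interdomain distance is the Euclidean distance between the two
domains' mass-weighted COMs; the interdomain angle is the angle at the
linker COM between the vectors to the two domain COMs, in [0°, 180°].
Probability curves are empirical CDFs (monotone, exactly bounded by
[0, 1]); a fitted-normal overlay is deliberately not the default since
the ECDF makes no distributional assumption.

Bond occupancy uses the distance-only criteria: a hydrogen bond is a
donor–acceptor distance ≤ 3.0 Å, a salt bridge a minimum acidic-O to
basic-N distance ≤ 3.2 Å over all Asp/Glu carboxylate oxygens ×
Lys NZ / Arg NH1, NH2, NE combinations (His ND1/NE2 when named
explicitly). No angle term is applied by default; an optional angular
filter would tighten hydrogen-bond counts but the distance-only rule is
the documented criterion here.

Atom pairing between non-identical structures ("aligned" mode) pairs Cα
atoms of residues matched by global sequence alignment (BLOSUM62, gap
open −11 / extend −1), using gap-free columns only. For homologous
complex comparisons both pairing choices — whole complexes superposed on
all common Cα vs. the inhibitor chains superposed alone — are reported,
since either may be meant by a published figure.

## Synthetic generators: what they emulate, and what they do not

The generators exist so that every analysis stage has exact ground
truth. Their defaults are the study conditions used throughout the
tests and the acceptance script:

- intrinsic rates flat at 1.0 /s (a per-residue table can be supplied;
  full sequence-dependent intrinsic-rate chemistry is out of scope),
- 40% back exchange, 0.15 Da replicate noise, triplicates,
- exposure ladder 10 s / 1 min / 10 min / 60 min for uptake tables,
- EX1 as irreversible opening at rate `k_open` with a fully exchanged
  open state — sufficient for bimodal phenomenology without modelling
  refolding,
- SNR-50 envelopes (Gaussian intensity noise, clamped nonnegative,
  re-normalized to max 1),
- trajectories of 1000 frames at 1 ns spacing with interdomain distance
  N(30 Å, 1 Å) and angle N(100°, 2°): two rigid Cα blobs are *placed*
  each frame so the sampled distance and angle are realized exactly
  (both domain COMs at arm length `d / (2 sin(θ/2))` from the linker
  vertex), then jittered at 0.3 Å per atom and given a random global
  rigid motion,
- two-state bonds as a stationary Markov chain with on-probability
  `p_on` and switching intensity `k_switch` (at `k_switch = 1` frames
  are independent and binomial error bars apply exactly).

One root seed feeds per-purpose `SeedSequence` streams (uptake noise,
envelope noise, blob shapes, frame geometry, jitter, bond dynamics), so
datasets are bit-identical across runs and independent across peptides,
states and purposes.

What the generators do **not** emulate: real spectra (chromatography,
ionization, overlapping peptides, charge-state effects), sequence-
dependent intrinsic-rate chemistry, correlated exchange, force-field
dynamics, periodic-boundary artifacts, or solvent. Passing tests
therefore demonstrate that the *statistics and geometry pipelines*
recover known truth under realistic noise — not that the simple kinetic
and geometric models reproduce any particular protein's raw data.

## Problem sizes

Simulation-based checks use 200 differential simulations, 50 mixture
envelopes, 100 classified time courses, 1000-frame ensembles and
2000-frame bond chains — sizes at which binomial and SEM error bars are
a few percent, chosen so each property is measured rather than assumed.

## Known limitations

- The 1.0 Da grid convention means absolute m/z values differ from true
  isotopologue masses by up to a few mDa per extra neutron; uptake
  differences (the quantities of interest) are unaffected.
- The bimodal fitter assumes at most two populations and a shared
  width; three-state systems or strongly width-divergent populations
  will be reported as the closest two-component mixture.
- RMSF of very small selections is biased low by superposition (see
  above).
- Crystal-structure cross-validation (`validate_crystal`) needs local
  PDB files; no fetching is performed.
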