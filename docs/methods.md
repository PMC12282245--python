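# Methods

## The assay being modelled

Multiplex fluorescent PCR followed by capillary-electrophoresis fragment
analysis (mPCR-CEFA) genotypes alpha- and beta-thalassemia in one run.  Every
amplicon in the multiplex occupies a (dye, fragment-size) slot: alpha-side
variant amplicons are VIC-labelled, beta-side FAM, wild-type control amplicons
NED, and the LIZ channel carries the in-lane size standard.  Three kinds of
evidence come out of one electropherogram:

1. **Dosage.** Unequal crossover between the homologous X/Y/Z boxes of the
   alpha-globin cluster produces the -a3.7 and -a4.2 single-gene deletions,
   the aaa_anti3.7 and aaa_anti4.2 triplications, and the HKaa rearrangement.
   Four dosage amplicons (alpha1, alpha2 on NED; Y1, Y2 on VIC) each amplify
   an integer number of template copies per allele, so the alpha1/alpha2 and
   Y1/Y2 peak-height ratios identify the diploid copy-number configuration.
2. **Presence.** Allele-specific (ARMS-type) amplicons evidence point
   variants; breakpoint (gap-PCR-type) amplicons evidence large deletions
   (--SEA, --THAI, the rare alpha deletions, the fusion gene, and the three
   beta-cluster deletions).
3. **Zygosity.** For selected point variants a NED-labelled amplicon specific
   to the wild-type base is included; mutation peak + wild-type peak reads as
   heterozygous, mutation peak without it as "no wild-type allele present".

GAPDH (FAM) and AMEL (VIC) internal controls must amplify in every sample.

## Copy model

Per-allele copies of (alpha1, alpha2, Y1, Y2), chosen as the unique
small-integer table that reproduces all six validated theoretical ratio pairs
when an allele is paired with normal, and that conserves copies across each
reciprocal crossover pair (deletion + triplication = 2 x normal):

| allele | a1 | a2 | Y1 | Y2 |
|---|---|---|---|---|
| aa | 1 | 1 | 1 | 1 |
| -a3.7 | 1 | 0 | 0 | 1 |
| -a4.2 | 1 | 0 | 1 | 0 |
| aaa_anti3.7 | 1 | 2 | 2 | 1 |
| aaa_anti4.2 | 1 | 2 | 1 | 2 |
| HKaa | 1 | 1 | 0 | 2 |
| --SEA, --THAI | 0 | 0 | 0 | 0 |

Diploid ratios are computed in exact rational arithmetic
(`fractions.Fraction`); a ratio is UNDEFINED when its denominator copy sum is
zero, and all-zero sums set a TOTAL_ABSENCE condition (the hydrops
configuration).  The rare deletions -a2.4/-a21.9/-a27.6 and the fusion gene
are carried with a provisional (1,0,1,0) copy row and flagged LOW_CONFIDENCE;
their detection rests on their breakpoint amplicons, not on dosage.  Whether
--THAI removes Y1/Y2 exactly as --SEA does is an assumption (both are
whole-cluster deletions).

## Ratio classes and the copy-number classifier

All diploid copy-number **classes** are enumerated programmatically from the
allele table; a class is the signature (zero-copy pattern, alpha1:alpha2,
Y1:Y2).  The six classes with published cohort statistics are marked
*validated* and keep their empirical means and SDs as metadata; the rest are
*extended*.

Classification runs in log-ratio space.  Peak-height noise is multiplicative,
so each measured log ratio is modelled as Gaussian around the class's log
theoretical ratio with a **common** standard deviation

    sigma = sqrt(2) * expected_cv        (expected_cv default 0.07)

where `expected_cv` is the assumed per-peak height CV of the assay and the
sqrt(2) accounts for the ratio of two independent peaks.  Under this
homoscedastic model, nearest-centroid assignment (combined
z = sqrt(z_a^2 + z_y^2) over the defined dimensions) is maximum likelihood.

We deliberately do **not** use the per-class cohort SDs as class widths: those
spreads mix measurement noise with between-sample amplification-efficiency
variation, differ several-fold between classes, and under an argmin rule a
broad class acts as an attractor that swallows its narrow neighbours.  They
remain available as reported metadata.

Decision rule, with `calling:` defaults in the panel file:

* classes are first filtered to those whose zero-copy pattern equals the
  measurement's absent-peak pattern (absence is strong, discrete evidence);
* among surviving *validated* classes, the nearest centroid wins if its
  combined z is at most `max_z` (default 4.0); otherwise *extended* classes
  are consulted the same way.  Validated-first ordering keeps rare
  model-derived configurations (e.g. a double-triplication compound) from
  competing with the common, empirically confirmed classes at equal footing;
  at zero noise every extended centroid still lies beyond `max_z` of all
  validated centroids, so extended genotypes remain callable;
* the call is refused as a tie (NO_CALL, reason TIE) when the runner-up class
  is within `tie_loglik` log-likelihood units of the winner (default 0.5,
  i.e. the two hypotheses are indistinguishable at the 1-sigma support
  level);
* no surviving class within `max_z` is NO_CALL (reason ABOVE_MAX_Z), and an
  absence pattern matching no class is NO_CALL (ABSENCE_PATTERN_UNMATCHED).

NO_CALL is a quality refusal and re-testable; UNINTERPRETABLE (failed
internal controls or ladder) is terminal for the run.  Classification is
scale-invariant: a shared factor on all four heights cancels in both ratios.

## Evidence and genotype assembly

A peak counts as evidence when bound to its target and at or above the
analytical threshold (`analytical_min_height`, default 200 RFU; the published
description of the assay names the concept but not a value).  Zygosity labels
(HET / HOM / HET_OR_HOM / ABSENT) follow the wild-type-control rule above and
are reported as evidence only: a single mutant allele in trans with a
whole-gene deletion produces the same "HOM" peak pattern as true
homozygosity, so assembly must not take the label literally.

Assembly enumerates every unordered alpha-allele pair and beta-allele pair in
the panel catalogue (predictions are precomputed once per panel; the two
clusters factorize because every evidence target belongs to one cluster).  A
candidate is consistent iff it predicts

* the called copy-number class (alpha pairs),
* exactly the observed breakpoint-marker peaks,
* exactly the observed mutation peaks, and
* exactly the observed wild-type-control presence/absence pattern.

Status is OK for one consistent genotype, AMBIGUOUS for several (all are
reported, ordered most-parsimonious first), NO_CALL for none (the failed
constraint is recorded).  Ambiguity is honest biology here, in two forms:

* **zygosity ambiguity** — a variant without a wild-type control (e.g. beta
  CD37 in the default panel) cannot be resolved het vs hom; such calls are
  flagged ZYGOSITY_UNRESOLVED;
* **dosage-silent compounds** — a trans deletion+triplication pair
  (-a3.7/aaa_anti3.7, -a4.2/aaa_anti4.2) is copy-identical to aa/aa, and
  -a3.7/aa is copy-identical to -a4.2/HKaa, with no distinguishing amplicon
  in the assay.  All consistent interpretations are listed rather than
  silently dropping the complex ones; the parsimonious interpretation comes
  first, which is what a screening lab would report.

Pair display order is variant-first, whole-deletion late, normal allele last
(the conventional "aWSa/--SEA", "-a3.7/aa" style).

## Peak detection, sizing and binding

Detection subtracts a rolling-minimum baseline (window 51 scans) and picks
local maxima with height >= 200 RFU and prominence >= 100 RFU
(`scipy.signal.find_peaks`); the design rule that same-dye amplicons sit at
least 3 bp apart makes anything fancier unnecessary.  Ladder calibration
matches detected LIZ peaks to the known fragment series (the tallest N in
scan order; when fewer are seen, the best-fitting contiguous window of ladder
sizes), checks residuals against a quadratic migration fit (tolerance 1 bp,
at least 8 matched points), and interpolates piecewise-linearly with linear
extrapolation at the ends.  Binding gives each target the tallest peak of its
dye within `size_tolerance` (default 1.4 bp — below half the 3 bp spacing, so
no peak can satisfy two targets); ties break by smaller size error, then
smaller size; each peak binds at most once.  Peak height, not area, is the
quantity used throughout.

## The simulator

`simulate_peak_table` draws, for each target with template copies c > 0,

    height = base_height * efficiency[target] * c * sample_scale
             * exp(noise_cv * Z),     Z ~ N(0, 1)

with `base_height` 2000 RFU, per-target efficiency 1.0, an optional shared
lognormal per-sample scale (`scale_cv`, default 0), size jitter N(0, 0.15 bp)
and dropout of peaks below 50 RFU.  Copies are: summed allele copies for
dosage targets, carrier counts for mutation/marker targets, wild-type-allele
counts for control targets, and 2 for GAPDH/AMEL.  Everything is reproducible
from (params, seed); cohorts use per-sample child seeds of a master seed.

Because the noise is exactly lognormal, the mean simulated ratio carries the
bias factor exp(noise_cv^2) relative to the theoretical ratio; tests compare
against the corrected value.  A `table1_efficiency` preset reproduces the
validated classes' measured mean ratios as cohort means; it is conditional on
the sample's class (a single per-target vector cannot satisfy all six classes
at once, since the required alpha1/alpha2 efficiency ratio differs per
class).  `simulate_trace` renders peaks as Gaussians (sigma 8 scans) on a
constant 40 RFU baseline under an affine bp -> scan map, with the full ladder
in the LIZ channel.

What the simulator does *not* emulate: stutter, pull-up/spectral overlap,
migration nonlinearity, injection variability, inter-capillary differences,
and any sequence-dependent amplification behaviour.  Green tests therefore
demonstrate the calling logic — copy-model correctness, evidence
intersection, QC routing, noise tolerance at the modelled scale — not
instrument-level robustness on clinical material.

## Problem sizes used in tests

The exhaustive round trip covers all 861 unordered genotypes with at most two
variant alleles at zero noise (the full 49,725-pair space passes identically
and runs in under half a minute; the capped set keeps the suite fast).  Noisy
classification uses 500 samples per validated class at per-peak CV 0.07 with
a fixed seed; the mean-ratio calibration check uses 10,000 replicates.

## Known limitations

* Alpha point variants without wild-type controls (aQS, aCD30, aCD74 in the
  default panel) follow the same HET_OR_HOM logic as beta variants; the
  dosage behaviour of the rare alpha deletions and the fusion allele is a
  flagged default, not an assertion.
* Beta-side copy number is not modelled; beta-cluster deletions are called
  purely from breakpoint and wild-type-control patterns.
* No clinical severity interpretation, no sex calling from AMEL, no
  instrument-file (ABIF) ingestion — peak tables are CSV, traces JSON.
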