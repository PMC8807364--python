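# Methods

## The screening model

The package targets a specific experimental design: a parental cancer
cell line and k derivative lines obtained from it (k = 3 by default),
profiled with duplicate methylation arrays per line and a single RNA-seq
sample per line. The biological hypothesis is that some genes acquired
promoter CpG hypermethylation during derivation and were transcriptionally
silenced by it; the screen ranks genes by the joint evidence.

Beta-values are computed as β = M/(M+U+offset) with offset 100. The
offset means observed β underestimates the true methylation proportion by
the factor S/(S+100), where S = M+U is the probe's total intensity
(≈ 0.976 at the default simulated intensity scale of 4000). This
attenuation is a property of the published formula and is deliberately
not corrected; the Δβ gate at 0.1 is far above it.

Promoter windows are the 500 bp immediately 5′ of the TSS, strand-aware,
half-open, excluding the TSS base itself: for a + strand gene at TSS t
the window is [t−500, t); for a − strand gene, [t+1, t+501). Coordinates
are 0-based throughout. A probe may fall in several genes' windows and
then counts for each.

Gene-level Δβ is the arithmetic mean over the gene's promoter probes
(max |Δβ| is also reported so a peak-probe convention can be screened).
Replicate arrays are combined by the arithmetic mean of their β values —
a deliberate, order-invariant choice; no published combination rule
exists for this design.

### Collapsing the derivative lines

The two arms collapse the k derivative lines differently, and this is a
considered choice rather than an inconsistency:

* **Methylation ("mean"):** per-derivative gene-level Δβ is averaged
  across lines. Each line contributes duplicate arrays, so the per-line
  value is already precise, and averaging across lines suppresses null
  fluctuations: under the default noise (β sd 0.05) the null gene-level
  Δβ has sd ≈ 0.017, putting the 0.1 gate at ~6 standard deviations.
* **Expression ("any"):** a gene passes the fold-change gate if *any*
  derivative line shows |log₂ ratio| > 1 against the parental. With one
  RNA-seq sample per line and negative-binomial dispersion 0.1, the
  log-ratio of line averages carries ~0.5 sd of noise dominated by the
  single parental draw, which would mask 5–10% of genuinely 4-fold
  silenced genes; per-line gating reduces that miss rate to 1–2% while
  the Δβ gate keeps the false-discovery proportion near zero.

Both arms accept `mean` or `any` via configuration
(`methylation_summary`, `expression_summary`, or the global
`derivative_summary` override).

### Gates and classification

All thresholds are strict inequalities: RPKM > 3 in parental or
derivative, |log₂ ratio| > 1, |Δβ| > 0.1. RPKM is floored at 0.01 before
ratios so silent genes give bounded fold-changes (log₂ 0.01 ≈ −6.6)
rather than infinities. Genes passing both gates are classified by sign
pair into four quadrants; candidates are the hypermethylated-down
quadrant (Δβ > +0.1 and log₂ ratio < −1), sorted by descending Δβ, then
ascending log₂ ratio, then gene id — a deterministic order with no
pathway-level prioritization.

Expression z-scores (for heatmaps) use the population standard deviation
(denominator n); constant rows are zeroed and flagged. Hierarchical
clustering is average-linkage: Euclidean distance on per-condition β
vectors, computed per chromosome, for methylation; correlation distance
on z-scores for expression. Ties are resolved by input order (lower
index first), making leaf orders reproducible; constant expression rows,
whose correlation distance is undefined, are treated as maximally
distant.

## Bisulfite clone calling

Only the top strand is modeled: the reference amplicon is treated as the
converted-strand template, as PCR of bisulfite-treated DNA is
strand-specific. Clones are globally aligned to the reference with
bisulfite-aware scoring — match +1, mismatch −1, gap open −2, gap extend
−1, and reference-C/clone-T scored +1 because conversion is the expected
outcome. Clones whose alignment identity (match-equivalent columns over
alignment columns, gaps counting against) falls below 0.7, or whose
clone/reference length differ by more than 20%, are rejected with a
reason.

At each CpG only the C base is inspected (standard lollipop practice;
the G at +1 is ignored): C → methylated, T → unmethylated, anything else
or a gap → ambiguous. Conversion efficiency is the fraction of non-CpG
reference cytosines read as T, over positions where the clone base is C
or T; clones below 0.95 (configurable) stay in the call matrix but are
excluded from per-sample methylation fractions, which also exclude
ambiguous calls from their denominators.

## Survival statistics

The median split labels subjects with marker strictly above the median
"high", ties "low" — deterministic and equal-sized for even tie-free
cohorts. The Kaplan–Meier estimator is the product-limit form over
distinct event times, with subjects censored exactly at an event time
still counted at risk there. The log-rank statistic uses the
hypergeometric variance per stratum, skipping single-subject strata, and
a 1-df χ² reference; a label-permutation p-value is available for small
cohorts. The tests cross-check both estimators against lifelines on
random data.

## The synthetic-data generator

The generator emulates the design above with known ground truth and is a
pure function of (inputs, seed); every generator draws from its own
deterministic stream so adding one output never perturbs another.

Defaults (the emulated study conditions):

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | genes across 8 chromosomes, TSS slots 4 kb apart |
| probes_per_promoter | 3 | probes placed uniformly inside each window |
| n_background_probes | 1000 | probes outside every promoter window |
| n_derivative_conditions | 3 | derivative lines |
| n_array_replicates | 2 | arrays per line |
| planted_fraction | 0.05 | genes given the silencing phenotype |
| delta_beta_effect | +0.4 | promoter β shift in all derivatives |
| log2fc_effect | −2 | expression log₂ fold-change (4-fold drop) |
| beta_noise_sd | 0.05 | additive Gaussian noise on the raw-β scale |
| intensity_scale | 4000 | mean total intensity M+U per probe |
| count_library_size | 10⁶ | reads per RNA-seq sample |
| count_dispersion | 0.1 | NB α (variance = μ + αμ²); 0 = Poisson |
| conversion_rate | 0.99 | bisulfite C→T conversion probability |

Baseline promoter-probe β is Beta(0.5, 5) (CpG-island-like, mostly
unmethylated) and background β is Beta(5, 5); no baseline distribution
is published for this design, and these were chosen once to make a +0.4
shift detectable but not trivial. Noise is added on the raw β scale and
clipped to [0, 0.99]; intensities are back-computed as M = βS,
U = (1−β)S with S ~ Normal(4000, 400) floored at 200. Two biases follow
and are accepted: the offset attenuation above, and a small upward bias
of low-β probes from clipping at 0. Baseline expression is
RPKM ~ LogNormal(ln 30, 0.8), chosen so planted genes almost surely
clear the RPKM > 3 gate in the parental line; expected counts are
RPKM·length·library/10⁹.

Survival cohorts are two exponential groups tied to a marker
(high ~ N(2, 0.1), low ~ N(0, 0.1)) so the median split reproduces the
groups; censoring is independent exponential with its rate solved from
the target censored fraction, P(C<T) = c/(h+c).

What the simulator does **not** emulate: probe chemistry (type I/II),
color bias, batch effects, copy-number confounding, cross-hybridization,
sequencing error in clones, and any correlation structure between
neighboring probes or co-regulated genes. Passing tests therefore show
the pipeline's logic is correct under idealized noise, not that the
thresholds are optimal for a particular real dataset.

## Problem sizes and determinism

The packaged evaluation runs 20 simulated designs at full scale
(2000 genes, 7000 probes, 8 samples) for recovery and another 20 for the
null, 1000 log-rank replicates at n = 200 and 200 at n = 500, 50 clones
× 10 CpGs for the bisulfite round trip, and 100 random tables for the
Kaplan–Meier closed-form check — sizes at which the Monte-Carlo error of
each reported rate is well below the margins being checked. Seeds are
taken modulo 2³¹ into per-stream `SeedSequence`s; identical configs give
byte-identical output files, and each run writes a manifest (config
hash, seed, version, row counts) sufficient to reproduce it.

## Known limitations

* The screen has no per-gene test statistic or FDR: with one RNA-seq
  sample per condition the design cannot support one, so gates are fixed
  thresholds, as in the design it reproduces.
* The Δβ attenuation from the +100 offset is intensity-dependent; arrays
  with very dim probes would need the offset reconsidered.
* The bisulfite aligner is global; amplicons with large structural
  differences from the reference are rejected rather than soft-clipped.
* Log-rank p-values rely on the χ² approximation; use
  `method="permutation"` below a few dozen subjects.
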