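# Methods

`nfiomics` implements the computational core of a spectral-count
interactomics analysis with ChIP-seq targetome integration: scoring bait-prey
pairs from peptide-spectrum-match (PSM) counts, calling high-confidence
interactions (HCIs) through a fixed filtering ledger, comparing interactomes
across baits, labeling times and isoforms, and connecting the interactome to
a factor's binding landscape (peak overlaps, nearest-TSS targetomes, motif
content, gene-set enrichment). Everything is exercisable end to end on
synthetic data with planted ground truth.

## Interaction scoring

Each candidate pair is scored within an (assay, labeling-time) stratum. For
replicate counts x₁..x_r and a prey-specific control mean μ₀ (from the GFP
control library, floored at a pseudo-count c₀ = 0.1 PSM so the background
model is never degenerate), each replicate receives a posterior interaction
probability under a two-component Poisson model with equal priors:

    p(x) = f₁(x) / (f₀(x) + f₁(x)),
    f₀ = Poisson(max(μ₀, c₀)),  f₁ = Poisson(max(x̄, μ₀, c₀))

The signal rate is clamped from below by the background rate: the test is
one-sided, because a prey *depleted* relative to controls is not evidence of
interaction — it scores an uninformative 0.5. `avg_p` is the mean of the
replicate probabilities; `avg_spec` the mean count.

The Bayesian FDR of a pair is the running mean of (1 − avg_p) down the
avg_p-descending ranking, made monotone by a cumulative maximum. Ties are
broken by higher avg_spec, then prey and bait identifiers, so the ranking —
and hence every BFDR — is fully reproducible. BFDR is computed per
(assay, time) stratum across baits; AP-MS runs collapse into a single time
stratum because a labeling window is meaningless for a stable pulldown.

This scorer is a transparent, oracle-testable stand-in for published
spectral-count scorers: probability rises with count excess over controls,
and the downstream filtering ledger is agnostic to the scorer's internals.
It does not model protein length, topology options, or replicate-specific
background rates.

A note on monotonicity: raising a *single* replicate count, or all counts of
a homogeneous vector, never lowers `avg_p` (d/dc [c·ln(c/μ₀) − c + μ₀] =
ln(c/μ₀) ≥ 0 once c ≥ μ₀). Raising counts non-uniformly can lower it: a
large outlier replicate raises the fitted signal rate μ₁ enough that the
remaining low replicates become evidence *against* the signal component.
This is a real property of the two-component model, and the property tests
assert exactly the monotone restrictions.

## The HCI ledger

Filtering applies four rules in a fixed order; each record ends in exactly
one terminal state (kept, or removed as `bfdr` / `contaminant` /
`min_count`), recorded in an audit table:

1. **Primary BFDR cut** — BFDR ≤ 0.01 for proximity labeling (BioID /
   UltraID), ≤ 0.05 for AP-MS. Both cuts are inclusive.
2. **Cross-bait rescue** (BioID strata only) — a pair failing the cut is
   kept when the same prey passed the primary cut for a different bait in
   the same (assay, time) stratum *and* the failing bait actually detected
   the prey (avg_spec > 0). Detection is required because rescuing an
   undetected prey would create an interaction out of nothing. Rescue does
   not cross time-points.
3. **Contaminant filter** — a prey detected in more than 20% of the
   negative-control library is removed unless its average spectral count
   exceeds 3× the library's mean count for that prey. Both comparisons are
   strict: a frequency of exactly 0.20 survives, an abundance of exactly 3×
   does not override. The library mean averages over *all* control runs,
   zeros included.
4. **Minimum abundance** — average spectral count strictly below 3 PSM is
   removed; exactly 3 survives. This applies after rescue, so a rescued but
   barely-detected pair is still dropped.

Rescue precedes the abundance filters; contaminant and minimum-count
filtering commute on the surviving set (both depend only on per-record
quantities), though the recorded removal reason naturally depends on order.

## Synthetic data

The interactome simulator emulates the statistical structure the analysis
assumes, not chromatograms or spectra. Counts are negative binomial —
spectral counts are overdispersed; Poisson is the size → ∞ limit — with the
size (dispersion) parameter defaulting to 2, a deliberately heavy-tailed
choice flagged as tunable since real PSM dispersion varies by experiment.

Defaults describe a four-bait design in biological triplicate with six
GFP-style control runs and two biotinylation windows (3 h and 16 h):

- 100 preys; 10 planted true interactors per bait at mean 50 PSM
  (`signal_mean`), of which 25% are shared by all baits
  (`frac_shared_true`) — the family-sharing fraction a paralogous TF family
  plausibly exhibits;
- background at mean 0.5 PSM over every (run, prey) cell;
- 10% of preys are contaminants appearing in *any* run, control or test,
  with probability 0.5 (`contaminant_frequency`) at mean 10 PSM —
  frequency-structured background the contaminant filter is designed for;
- the bait recovers itself at 150 PSM; at the long labeling window the bait
  self-signal shrinks (`time_effect_bait` = 0.6) while the background pool
  broadens (`time_effect_breadth` = 1.5 on the background mean), mimicking
  how longer labeling dilutes bait-proximal signal into a wider
  biotinylated proteome.

A single scalar cannot simultaneously act as a <1 multiplier on bait PSM
and a >1 multiplier on background breadth, so the two effects are separate
fields. Ground truth records every planted structure: true (bait, prey,
time) triples, contaminant preys, differential preys, planted motif sites.

The peak simulator places mutually non-overlapping fixed-width peaks on a
slot grid (shared peaks at identical coordinates in every bait's set), plants
exactly one TTGGC-N{k}-GCCAA site at each peak center with k drawn from a
spacer distribution (canonical k = 5 at 0.6 by default), and fills the rest
of the genome with i.i.d. uniform ACGT — so chance motif hits exist, as in
real genomes, but every planted site is recorded. The isoform simulator
gives two baits a common prey pool and multiplies/divides the planted
differential preys' means by 2^effect in the short isoform.

What passing tests on this generator do **not** show about real data:
batch effects, prey-specific detectability (protein length, tryptic
peptides), correlated replicates, non-uniform genomic background, and
dispersion heterogeneity are all absent. Recovery results are statements
about the model's self-consistency, not field performance.

### Expected recovery under the defaults

With dispersion 2, roughly 4–5% of replicate counts for a mean-50 pair fall
below the Poisson crossing point (~10 PSM against a sub-1 control mean), so
~14% of true pairs carry at least one near-zero-probability replicate and
cap at avg_p = 2/3; the cumulative-mean BFDR then cannot reach 0.01 for
them, and only the shared 25% can be rescued cross-bait. The ledger's
expected sensitivity is therefore ≈ 0.89 (measured 0.876–0.91 across seed
sets) at an empirical FDR of ≈ 0.03–0.04. Raising the dispersion parameter
(less overdispersion) raises sensitivity toward 1; the default is kept
heavy-tailed deliberately.

## Interactome comparison

- **Venn partitions** enumerate all 2^k − 1 exclusive regions; counts always
  sum to the union size.
- **Replicate correlation** is plain Pearson on zero-filled, prey-aligned
  count vectors.
- **Isoform differential**: per prey, log2FC = log2((mean_short + 1) /
  (mean_full + 1)) — the +1 pseudocount keeps zero-count preys finite — with
  a Welch two-sample test on log2(count + 1) across replicates (the test
  function is injectable), BH adjustment over tested preys, and
  classification at |log2FC| ≥ 1, adjusted p < 0.5. The lenient adjusted-p
  default mirrors the volcano convention this analysis reproduces and is
  configurable; swapping the baits negates every fold change and swaps the
  classes.
- **Localization profiles** sum the annotation scores of HCIs per
  compartment and max-normalize, the MS-microscopy convention.
- **Stability scores**: s = nAPMS / (nAPMS + nBioID) on bait-normalized PSM
  (prey count / bait self count per run, averaged per assay). s → 1 marks
  stable, pulldown-visible partners; s → 0 proximal-only ones. One-sided
  preys get the boundary value and a flag. This bounded ratio is this
  package's own formulation — the original interaction-distance metric it
  gestures at lives in supplementary material not reproduced here, and the
  score should not be reported as that metric.
- **Dot-plot tables** export (bait, prey, avg_spec, relative abundance,
  BFDR) with per-prey max-normalization within a stratum, restricted to
  user-supplied complex memberships.

## ChIP integration

Coordinates are 0-based half-open throughout; overlap means ≥ 1 shared
base. Multi-set overlap builds connected components of the overlap graph
(the findOverlapsOfPeaks convention), so each physical region is counted
once toward the region named by the labels present. Binding comparison
classifies condition A's peaks as lost (no B overlap) or shared, and B's
non-overlapping peaks as gained; lost + shared always partitions A.

Peak annotation is nearest-TSS to the peak center (floor((start+end)/2)),
ties to the lexicographically smallest gene id — a deterministic
simplification of feature-hierarchy annotators, sufficient for targetome
sets. Top-N targetomes rank peaks by score with (chrom, start) tie-breaks.

Signal matrices average step-function coverage in fixed bins across
[center − window, center + window) via an exact prefix-integral (no
sampling); rows order by own mean signal, or by a caller-supplied reference
ordering when one sample's heatmap is displayed against another's ranking.

The motif scanner matches the palindromic NFI half-sites TTGGC / GCCAA
around a degenerate spacer of 3–7 bases with a per-half mismatch budget
(default 1). A consensus-with-mismatch scanner, not a PWM: the motif's
information content is concentrated in the half-sites, and a mismatch
budget is exactly enumerable against a brute-force oracle. N never matches.
Both strands are scanned; at zero mismatches the motif is its own reverse
complement, so coincident hits merge keeping the plus-strand record. Motif
enrichment reports the fraction of peaks containing a full hit and an
empirical p-value against uniform per-chromosome re-placement of
equal-length intervals, p = (1 + #{shuffles ≥ observed}) / (1 + n).

## Enrichment

One-sided hypergeometric upper tail, computed exactly via log-gamma
binomials (no normal approximation), BH-adjusted. The universe defaults to
the union of the gene-set collection when not supplied — an external
service's internal background cannot be reproduced, and an explicit
universe is always honored. Plain BH is used; some legacy services report a
subtly different "Benjamini" column.

## Pipeline

`run_pipeline` executes simulate → score → filter → compare → chip from a
validated nested config (unknown keys rejected at every level), writes every
intermediate in the package's TSV dialects, and emits a JSON manifest with
SHA-256 checksums per output. The master seed fans out to per-stage seeds by
hashing stage names, so toggling one stage never perturbs another's stream;
identical config + seed reproduces identical checksums.

## Problem sizes

Tests and the acceptance script run the simulators at the default design
(4 baits × 2 times × 3 replicates × 100 preys; 10–20 seeds per recovery or
calibration measurement), peak sets of 30–50 peaks on 80–100 kb toy
chromosomes, and brute-force oracle sweeps of 50–100 random instances —
sizes at which the brute-force oracles remain exact and fast while every
code path is exercised.
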