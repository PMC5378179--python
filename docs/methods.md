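# Methods

This note documents the models, defaults and numerical choices behind
`enuscreen`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## The 96-channel convention

Every single-base substitution is expressed with the mutated pyrimidine
of its Watson–Crick pair; purine-reference calls are reverse
complemented, flanks included. Channels are ordered class-major — the six
classes C>A, C>G, C>T, T>A, T>C, T>G, and within each class the 16
flanking contexts by 5' then 3' base, each A<C<G<T — the layout used by
standard signature bar charts. All catalogs, signatures and spectra in
the package use this fixed order (`enuscreen.channels.CHANNEL_NAMES`).

## Synthetic screens

### Genome model

A synthetic exome of single-exon ORFs: each gene is a run of codons drawn
uniformly from the 61 sense codons (no in-frame internal stop), placed on
~23 chromosomes with 100-bp random spacers so variants carry ordinary
chromosomal coordinates and REF alleles check against the FASTA.
Defaults: 19,000 genes (human protein-coding scale), mean CDS 900 bp
(~17 Mb coding), 100 disjoint pathways of 2–5 genes with the designated
resistance pathway fixed at 4 genes — mirroring the four canonical MAPK
genes that dominate resistance to EGFR-targeted therapy (KRAS, NRAS,
BRAF, MAP2K1). Keeping the pathway collection's footprint at ~2% of the
coding genome puts per-sample pathway-hit probabilities in the
informative regime (p_i ~ 0.05–0.2 for a 470-mutation clone), comparable
to the situation of a focussed pathway against a 50-Mb exome.

### Clones

Substitutions are sampled by drawing a 96-channel from the signature and
then a uniform coding site whose pyrimidine-normalized context matches
that channel (sites without a complete in-gene trinucleotide context —
the two terminal CDS bases — are excluded from sampling). A channel with
positive probability but no context site genome-wide raises an error
naming the channel. Indels of 1–10 bp are placed uniformly over coding
sites, insertion or deletion with equal probability.

Defaults per clone: 470 substitutions plus a 4% indel fraction (~20
indels); parental depth 150 with 0 alt reads for mutagen-induced
variants. The ENU-like default signature puts 3% of mass on C>G —
the one class the mutagen under-produces — and spreads the remaining 97%
evenly over the other five classes, uniformly within class; the full
per-class profile is configurable because only the C>G depletion is an
established quantity, the rest of the profile being a stand-in, not a
claim.

A 24-clone screen by default contains: three related sets of four clones,
each set sharing 10 implanted parental subclonal variants — five at 1%
parental allele fraction (removed by the 0.5% filter) and five at 0.1%
(retained, and the signal that drives downstream clone merging); and two
hypermutator clones at 10x burden whose extra mutations come from a
constructed MSI-like profile (C>T-heavy with an NpCpG preference plus
T>C; a synthetic stand-in for a mismatch-repair-deficiency process) with
a proportionally multiplied indel load. Every clone receives exactly one
driver: a per-gene recurrent missense "hotspot" variant in a gene of the
resistance pathway, emulating the strong hotspot recurrence seen in real
resistance screens. Randomness flows from one master seed through
documented per-clone streams (`SeedSequence(seed, spawn_key=(1, i))`), so
adding clones does not perturb earlier ones.

What the generator does **not** emulate: sequencing reads and base
quality, alignment artifacts, copy-number change, multi-exon gene
structure (hence no splice-site mutations by default), transcriptional
strand bias, regional mutation-rate covariates (replication timing,
expression), and real pathway topology. Passing tests therefore
demonstrate the statistical machinery under the generative model's
assumptions — uniform rates within context classes, independent clones —
not robustness to those additional features of real exomes.

## Parental subclonal filter

A variant is removed iff parental depth > 0 and parental_alt/depth ≥
0.005 — "0.5% or more" is a closed threshold, so exactly 0.5% is removed.
Variants with no parental coverage are kept and flagged
(`no_parental_evidence`) rather than silently dropped. On simulated
screens the implanted 1%-VAF variants are exactly the removed set
(precision = recall = 1 by construction of the read counts).

## Signature deciphering

Catalogs (96 x samples) are factorized with scikit-learn's
multiplicative-update NMF under the generalized Kullback–Leibler
objective (the natural choice for count data; Frobenius available via
`objective="frobenius"`), max 1000 iterations, tolerance 1e-6, best of
`n_restarts` random initializations (default 10). Stability per signature
is the mean cosine similarity, after Hungarian matching, between the
consensus signatures and those refit on catalogs resampled
multinomially per sample (preserving totals; default 100 bootstraps).
The selected k is the largest k in the scanned range with mean stability
≥ 0.8 — a documented stand-in for the reproducibility/error trade-off of
the original deciphering framework, whose exact rule is not restated
here. Exposures for fixed signatures solve a non-negative least-squares
problem (`scipy.optimize.nnls`).

## Pathway enrichment

For sample i with burden n_i (qualifying nonsynonymous mutations,
indels included, counted over the genes of the pathway collection) and a
pathway with exon-block length L_P out of background L_bg:

- poisson model (default): p_i = 1 − exp(−n_i·L_P/L_bg)
- bernoulli model: p_i = 1 − (1 − L_P/L_bg)^n_i

The two differ at O((L_P/L_bg)^2). The background defaults to the total
exon-block length of the pathway collection's genes (the network actually
tested), not the whole exome; both the model and the background are
configurable. The observed statistic o is the number of samples with ≥ 1
mutated member gene in the binary event matrix; its null distribution is
Poisson binomial, computed exactly by O(n²) dynamic-programming
convolution (no normal approximation; n here is tens to hundreds of
samples). The p-value is the upper tail P(X ≥ o); q-values are
Benjamini–Hochberg over all tested pathways; a pathway is reported
enriched iff q < 0.05 (configurable) **and** its exclusive coverage — the
fraction of covered samples with exactly one mutated member gene — is at
least 0.8. The 0.8 cutoff is a package default exposed in the
configuration: the mutual-exclusivity filter itself is standard, its
numeric cutoff is not published.

Because o is discrete, the exact tail p-value is conservative: its CDF
touches the diagonal only at attainable values. Calibration diagnostics
therefore use the randomized transform P(X > o) + U·P(X = o), which is
exactly Uniform(0,1) when the model is correct
(`poisson_binomial_randomized_pvalue`); the raw p-values are separately
checked to be conservative, never anticonservative.

## Selection analysis (dN/dS)

**Clone merging.** Two clones are connected iff they share strictly more
than 3 variants (by chrom/pos/ref/alt); groups are connected components
and a group's variant set is the deduplicated union. Note that two
hypermutator clones can legitimately share > 3 variants by chance — at
10x burden concentrated in a narrow context class the expected overlap is
~2 — so hypermutators occasionally merge; this is a property of the rule,
not an artifact.

**Spectrum.** Per-channel relative rates are observed channel counts
divided by available context sites, normalized to mean 1; zero-count
channels are floored at 0.5 pseudo-counts to avoid zero expectations;
channels whose context does not exist in the genome are excluded. The
default estimator uses all substitutions (in a mutagenesis screen,
passengers outnumber drivers by orders of magnitude, so driver
contamination is negligible); `synonymous_only` is available.

**Opportunities.** For each gene, all 3L single-base changes are
enumerated (vectorized, cached per genome), classified through the
genetic code, and summed as spectrum rates per consequence class:
R_syn, R_mis, R_non (+ R_splice, zero for single-exon genes). The two
CDS-terminal bases lack a complete in-gene context and enter at the mean
rate 1.0. An exhaustive translation-based oracle in the test suite checks
exact agreement.

**Test.** Counts per class are modeled as Poisson with means
λ·R_class·ω_class, where λ is the gene's local rate and ω = 1 under
neutrality. λ is estimated from the gene's synonymous count with
conjugate Gamma shrinkage toward the exome-wide synonymous rate g: the
prior contributes θ pseudo-mutations at rate g, where θ is the
cross-gene rate-dispersion shape fitted by negative-binomial maximum
likelihood to the per-gene synonymous counts (capped at 1e6). When gene
rates are homogeneous θ is large and the gene rate is pinned near g —
giving power for genes with recurrent nonsynonymous hits but no
synonymous mutations; when rates are overdispersed θ is small, shrinkage
is weak, and calibration is protected. This adaptive scheme replaces a
fixed-weight blend, whose constant prior weight is either negligible
(no power on sparse screens) or unjustified (anticonservative under rate
variation). Hypotheses are compared by likelihood-ratio tests with λ
profiled: H0 ω_mis = 1 (1 df) for p_mis, H0 ω_mis = ω_trunc = 1 (2 df,
trunc pooling nonsense and splice) for p_sub_global; two-sided by
default, one-sided enrichment optional. Simulated size at realistic
counts is 0.045–0.05 (see the acceptance tests).

**Indels.** With no synonymous-like neutral reference, gene-level indel
recurrence is tested against the exome-wide coding indel rate
(total coding indels across groups per coding base): p_ind =
P(K ≥ n_ind), K ~ Poisson(rate x coding length).

**Combination and FDR.** p_sub_global and p_ind are combined by Fisher's
method (−2(ln p₁ + ln p₂) ~ χ²₄). Benjamini–Hochberg FDR is applied over
tested genes (those with ≥ 1 observed coding mutation), by default in a
single stratum; `strata="opportunity_tertiles"` stratifies by gene
opportunity. Significance: q_mis < 0.05 OR q_global < 0.05, results
ranked by min q.

## Validation problem sizes

The acceptance tests and `scripts/acceptance.py` run at the package's
default study conditions: 24-clone screens on the 19,000-gene genome for
filtering, calibration (50 and 30 driver-free screens respectively,
pooled randomized p-values, KS at α = 0.01) and planted-pathway power
(20 seeds); 19 singleton groups with a driver implanted in 8 of them for
selection power (20 seeds); neutral dN/dS calibration on a 2,000-gene
genome with ~60,000 spectrum-drawn substitutions per replicate (per-gene
counts of tens, the regime where the χ² asymptotics of the LRT apply —
sparser data makes the discrete test conservative rather than
miscalibrated); 20 catalogs of 500 (or 5,000 for the two
hypermutator-like samples) mutations for signature recovery; and 60–110
random probability vectors with n ≤ 15 for the exhaustive
Poisson-binomial check.

## Known limitations

- Single-exon gene models: splice-site machinery exists in the
  consequence vocabulary and opportunity slots but is exercised only if
  multi-exon models are supplied.
- The dN/dS shrinkage assumes the synonymous counts are selection-free
  and that rate variation is captured by a single Gamma dispersion; real
  exomes have structured covariates the package deliberately does not
  model.
- The Poisson-binomial model treats samples as independent; clones
  sharing a subclonal origin violate this mildly (the shared variants are
  few), and the selection stage — not the enrichment stage — is where
  relatedness is handled, by merging.
- Burden-based p_i assumes mutations land uniformly over the background
  coding length; signature-context heterogeneity across genes perturbs
  this only at second order.
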