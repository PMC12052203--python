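# Methods

## Kinetic model

`slamkin` treats each gene's transcript pool as a single first-order
species at steady state. During a metabolic-labeling pulse of length
`t` hours, the fraction of the pool synthesized within the pulse is
`f = 1 − exp(−k_deg · t)`; the half-life is `t_1/2 = ln 2 / k_deg`. In a
compartment-targeted library, `k_deg` is a *localized* turnover constant
that conflates decay with exit from the compartment — that conflation is
the point: the localized/global ratio `R` measures how quickly transcripts
leave the neighborhood of the epitope relative to their overall turnover.

Assumptions worth keeping in mind:

- steady state over the pulse (no synthesis or decay rate changes);
- one rate per gene (no isoform or cell-to-cell rate mixtures);
- uniform conversion probabilities per thymine, identical across reads of
  a class (new/old) — no read-quality or positional effects;
- reads are conditionally independent given their age class.

## Conversion counting

The library is forward-stranded, so a read's sequence matches the
transcribed strand. A labeled uridine appears as a reference-T read-C
mismatch on + strand genes and a reference-A read-G mismatch (reference
top strand) on − strand genes; both are counted as the same T>C event.
Reference bases are recovered from MD tags (or a FASTA fallback);
insertions and soft-clips cover no reference base and contribute nothing.
Positions behaving like homozygous T>C variants — control-library
coverage ≥ 10 and apparent conversion rate > 0.8 — are masked genome-wide.
The coverage floor and rate threshold are heuristics for homozygous
variants; heterozygous sites (rate ≈ 0.5) are deliberately not masked
because at typical `p_c` they are rarely confusable with labeling, and
masking them would discard half their signal.

Reads are assigned to the gene whose span contains the read midpoint on
the matching strand; ambiguous midpoints (overlapping same-strand genes)
are dropped with a counter rather than guessed.

## Estimation

**Background rate** `p_e` is pooled over the unlabeled control:
`(Σk + 0.5)/(ΣT + 1)`. The pseudocount keeps downstream likelihoods off
the `p = 0` boundary in clean controls.

**Labeled rate** `p_c` is estimated by EM on the pooled two-component
mixture over genes with ≥ 50 reads, each gene carrying a free mixture
weight and all genes sharing one `p_c` (convergence: Δlog-likelihood
< 1e−8 or 500 iterations). If the data carry no labeling signal (all-old
reads; estimated `p_c ≤ p_e`) the estimate is refused and the pipeline
falls back to the configured value, recording the provenance in
`rates.json`.

**Fraction-new** is a one-dimensional bounded MLE on `[ε, 1−ε]`,
`ε = 1e−4` (Brent-style scalar minimization, `xatol = 1e−10`; the mixture
likelihood in `f` is unimodal for fixed rates). The clamp keeps `k_deg`
finite and positive; estimates pinned at the clamp are flagged
`boundary` and retained. Standard errors come from a central-difference
observed Fisher information on `logit f` (step 1e−4) and are propagated
to `ln k_deg` with `d ln k/d logit f = f / (−ln(1−f))`. Genes below 50
reads are flagged `low_reads` with no estimate; replicates are pooled
into one histogram by default (a per-replicate mode combines replicate
fits by inverse-variance weighting on `logit f`).

## Differential kinetics

Genes with `ok`-flagged estimates in both libraries are tested; others
are reported `not_tested`. Benjamini–Hochberg runs across tested genes
only. Labels: transient at `R ≥ 2` and `padj < 0.05` (threshold
inclusive); persistent at `R ≤ 1` with no significance requirement (a
strict mode demands `padj ≥ α`); intermediate otherwise. A config switch
interprets the threshold on the log2 scale (transient at `R ≥ 4`) for
designs quoted as "log2 FC > 2".

Two statistics are provided:

- **Wald z** on the log rates, `z = Δ ln k / √(se² + se²)`, computable
  from estimate tables alone.
- **Likelihood-ratio test** (the pipeline default): twice the gap between
  the free-fraction maxima and the shared-fraction maximum on the pooled
  histogram, referred to χ²(1). With equal pulse length a shared rate is
  a shared fraction, so the null costs exactly one parameter.

The LRT is the default because the Wald statistic collapses where
labeling saturates: above `f ≈ 0.99` the mixture log-likelihood is nearly
flat in `f` on the high side but falls steeply on the low side, so the
quadratic (Fisher) approximation wildly overstates the uncertainty of
fast genes — measured on simulations, the Wald SE averages ~4× the
empirical spread of `ln k̂` at `f ≈ 0.99`, and Wald power at a 4-fold
rate difference plateaus around 0.75 regardless of depth, while the LRT
retains the information in the steep tail and stays correctly calibrated
under the null (KS-uniform p-values, ~3.5% of tests below 0.05).

A hard information limit remains and no statistic removes it: with a 4-h
pulse, genes with localized half-life under ~1.2 h are > 99.9% labeled in
the compartment library, and conversion data cannot distinguish
fractions-new in that regime. Such genes either pin at the clamp (flagged,
not tested) or yield uninformative interior estimates. Turnover faster
than roughly a third of the pulse length is simply outside the design's
resolvable range; in the resolvable regime the LRT detects 4-fold ratio
changes at ≥ 95% power at 200 reads/gene.

## Enrichment testing

A deliberately small negative-binomial Wald test, not a re-implementation
of any published differential-expression stack; its acceptance surface is
calibration on simulations. Median-of-ratios size factors (linear-scale
median over genes expressed everywhere) keep log fold changes exactly
invariant to library rescaling. Per-gene dispersion is method-of-moments
from the pooled within-condition variance, clipped to [0, 10], shrunk
50/50 toward a fitted `α(μ) = a0 + a1/μ` trend. The Wald statistic on the
ln fold change uses `Var(ln mean) ≈ (1/n)(1/μ + α)` per condition and is
referred to Student t with `n_t + n_c − 2` degrees of freedom — the
heavier tail compensates for dispersion-estimation noise at 3+3
replicates (measured null type-I ≈ 1–5% at nominal 5%). Genes with mean
normalized count below 5 are excluded from the BH family. Enriched means
fold change > 2 with `padj < 0.05`; a flag interprets the threshold as
log2 FC > 2 instead. Set overlap is reported as a percentage of the
union, `100 · shared / (n_a + n_b − shared)`, to one decimal.

## Genomic-context features

Peak distance is the edge-to-edge gap from the gene body (0 on overlap;
missing when the chromosome has no peak) — gene-body anchored, not TSS
anchored. State assignment takes the label with maximal bp overlap with
the gene span, ties broken by the smaller start of the earliest
overlapping segment, then maps raw labels through a consolidation table
to {speckle, active, repressive, lamina}. Signal matrices count read
5′ ends (not coverage) in equal bins over feature bodies or a fixed
window upstream of the strand-aware 3′ end (default 500 bp), mirror
minus-strand features so column 1 is always 5′-most, and normalize to
counts-per-million per library. Per-intron enrichment is
`log2((target + 1)/(control + 1))` on CPM sums with a default 2-fold
threshold — the threshold and pseudocount are declared defaults, chosen
rather than derived.

## Synthetic data generator

The generator's defaults encode the study design the analysis assumes:
4-h pulse; three replicates of a nucleoplasmic control (IgG) and two
compartment libraries plus one unlabeled library; 100 bp single-end
forward-stranded reads; `p_e = 0.001`, `p_c = 0.05` (typical
conversion-chemistry values); 50,000 reads per library. Three gene
classes: 40 `polycomb_adjacent` genes (log-normal gene length, median
156 kb, ~13 exons so intron medians land near 12.7 kb; low expression;
8-fold capture in the repressive-mark library; mostly not yet
polyadenylated), 40 `speckle` genes (double the background exon count,
8-fold capture in the speckle library), 120 `background` genes. Global
half-lives are log-normal per class (medians 3.2/6/4 h, σ = 0.5, clipped
to [0.3, 24] h). Localized/global ratios are drawn per enriched gene from
a three-regime mixture — transient `R ∈ [2.5, 6]` (55% / 69% of the two
classes), persistent `R ∈ [0.6, 0.9]`, intermediate `R ∈ [1.3, 1.8]` —
so the truth labels implied by the thresholds are unambiguous at
realistic depths. Repressive-mark peaks are placed so that 19% of the
long-gene class directly overlaps a peak and the distance *mixture*
(zeros included) has its median at the configured 25 kb; an
offset-adjusted log-normal supplies the nonzero part. Background peaks
are scattered only in intergenic space so the planted distances stay in
control of the proximity statistics.

Reference sequences are synthetic and lattice-structured — T at positions
≡ 0 (mod 5), A at ≡ 2 (mod 5), G/C elsewhere — so every 100 bp read
covers exactly 20 assayable thymines on either strand, matching the
default per-read T content with no per-read bookkeeping. Read placement
is 3′-biased for polyadenylated genes (60% of reads exponentially
distanced from the 3′ end, scale 500 bp, the rest uniform) and anchored
at gene-specific internal points otherwise, emulating oligo(dT) priming
at poly(A) tails vs internal A-rich stretches. Homozygous T>C/A>G
variants (default 30) are planted at well-covered sites so the
control-library mask is exercised end to end. SAM is written as plain
text with MD/NM tags (deterministic: equal seeds give byte-identical
files); all randomness derives from integer seed lists, per library and
replicate.

What the generator does *not* emulate — hence what passing tests do not
show about real data: sequencing error beyond the uniform background
conversion rate, base qualities, PCR duplicates, multimapping, isoform
structure and splicing intermediates, intron-specific retention signal
(compartment enrichment is uniform across a gene body, so simulated
per-intron enrichment fractions are far higher than real ones),
cell-to-cell rate variability, and any correlation between expression
level and turnover.

## Pipeline and reproducibility

Stages communicate only through plain-text files in the run directory
(GTF, BED, TSV, SAM, JSON); each stage re-validates the merged config
(unknown keys are collected and reported together) and writes a manifest
with the config hash, seed, package version, and SHA-256 of every
output. `run-all` finishes in well under a minute at the default design
on one CPU. Default problem sizes throughout (200 genes, 50k reads per
library, 300-gene recovery suites, 2,000-gene calibration tests) were
chosen so the full test suite and the acceptance script each complete in
about a minute while keeping Monte-Carlo error small relative to the
margins being tested.

## Known limitations

- Per-gene maximum likelihood with no shrinkage across genes: low-count
  genes get wide intervals rather than borrowed strength. This is a
  deliberate simplicity choice; a hierarchical model would change
  uncertainties, not point estimates, at the depths simulated here.
- The steady-state model cannot separate decay from compartment exit, nor
  handle pulse-chase or multi-timepoint designs.
- Rates outside `t_1/2 ∈ [~t/3, ~24 h]` for pulse length `t` are at or
  beyond the design's information limit (see Differential kinetics).
- The enrichment test omits GLM covariates, outlier handling, and
  fold-change shrinkage.
- Chromosome naming is exact-match; no "chr" aliasing.
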