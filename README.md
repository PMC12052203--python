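# slamkin

Compartment-localized RNA kinetics from nucleotide-conversion metabolic
labeling.

Antibody-tethered compartment RNA assays (e.g. targeting H3K27me3-marked
Polycomb domains or SC35-marked nuclear speckles, with a nucleoplasmic IgG
control) capture the transcripts near a nuclear epitope. Combining such an
assay with a 4-thiouridine (s⁴U) pulse marks RNA made during the pulse:
alkylated s⁴U is read as C during reverse transcription, so new transcripts
carry T>C conversions. From the per-read conversion counts one can ask not
just *which* transcripts live in a compartment but *how long they stay
there* — whether a transcript is transiently passing through or persistently
retained.

`slamkin` implements this analysis end to end, together with a synthetic
data generator that emulates the study design for testing:

- **simulate** — gene models in three classes (long-intron genes adjacent to
  repressive-mark peaks, exon-rich speckle genes, background), per-gene
  global and compartment-localized degradation rates, compartment capture
  enrichment, and single-end stranded SAM reads with MD tags carrying the
  conversions, plus a truth table.
- **conversions** — per-read T>C counting on the transcribed strand
  (reference A>G for minus-strand genes), homozygous-variant masking from a
  control library, and aggregation into compact per-gene conversion
  histograms ("cB-style" tables).
- **kinetics** — per-gene fraction-new by binomial-mixture maximum
  likelihood and conversion of fractions to rates and half-lives.
- **diffkin** — localized-vs-global differential kinetics with
  Benjamini–Hochberg correction and transient / persistent / intermediate
  classification.
- **enrichment** — compartment-vs-control negative-binomial Wald test on
  gene counts (median-of-ratios normalization, trended dispersion
  shrinkage) and gene-set overlap arithmetic.
- **features** — peak proximity, compartment-state (SPIN-like) assignment
  with 4-group consolidation, and intron/TES signal matrices.

## Model

Reads from gene *g* are a two-component binomial mixture: a read made
during the pulse converts each of its $n_T$ covered thymines with
probability $p_c$, a pre-existing read with background probability $p_e$:

$$L(f) = \prod_{\text{reads}} \left[ f\,\mathrm{Bin}(k; n_T, p_c) + (1-f)\,\mathrm{Bin}(k; n_T, p_e) \right]$$

The fraction-new $\hat f$ is the per-gene MLE. Under first-order
steady-state turnover during a pulse of length $t$,

$$f = 1 - e^{-k_{\mathrm{deg}} t} \quad\Rightarrow\quad
k_{\mathrm{deg}} = -\ln(1-f)/t, \qquad t_{1/2} = \ln 2 / k_{\mathrm{deg}}.$$

Within a compartment library, $k_{\mathrm{deg}}$ reflects both decay and
exit from the compartment, so the ratio
$R = k_{\mathrm{deg}}^{\mathrm{loc}} / k_{\mathrm{deg}}^{\mathrm{glob}}$
defines dynamics: **transient** if $R \ge 2$ with BH-adjusted $p < 0.05$,
**persistent** if $R \le 1$, **intermediate** otherwise. The default
per-gene test is a likelihood-ratio test of a shared fraction-new against
free per-library fractions (χ², 1 df); a Wald z on the log rates with
delta-method standard errors is available as an option.

## Worked example

Run the full synthetic pipeline (simulate → count → kinetics → diffkin →
enrich → features) at the default design — 200 genes, 50,000 reads per
library, three replicates of IgG/H3K27me3/SC35 plus one unlabeled control,
a 4-hour pulse, $p_e = 0.001$, $p_c = 0.05$:

```sh
slamkin run-all --outdir run --seed 1
```

The closing report (also written to `run/summary.json`) compares the
pipeline's calls with the simulator's truth table:

```json
{
  "enrichment_sensitivity_h3k27me3": 1.0,
  "enrichment_sensitivity_sc35": 1.0,
  "label_accuracy_h3k27me3": 0.8125,
  "label_accuracy_sc35": 1.0,
  "label_accuracy_overall": 0.9166666666666666,
  "n_labeled_overall": 72
}
```

i.e. every truly enriched gene was recovered by the count-level test, and
92% of the tested enriched genes received their true dynamics label. The
conversion-rate parameters were re-estimated from the data alone
(`run/rates.json`): $\hat p_e = 0.000994$ from the unlabeled library and
$\hat p_c = 0.0503$ by pooled EM, against true values 0.001 and 0.05.
Per-gene estimates land in `run/kinetics_<library>.tsv`, e.g.

```
gene_id            sample  n_reads  f_hat    kdeg_per_h  t_half_h  flag
background_0003    igg     1085     0.660    0.270       2.57      ok
```

(a gene with fraction-new 0.66 after a 4-h pulse turns over at
0.27 h⁻¹, half-life 2.6 h), and the differential table
`run/diffkin_h3k27me3.tsv` lists, per gene, the localized/global rate
ratio, test statistic, adjusted p, and label.

Each stage can also be re-run individually from the files of its
predecessor (`slamkin simulate|count|kinetics|diffkin|enrich|features`),
with a YAML config overriding any default (see
`slamkin run-all --help`).

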