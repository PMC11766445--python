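# Methods

## Codon frequency metrics and the gene-set T-statistic

For gene *j* with codon counts `n_ij`, the **isoacceptor frequency** of
codon *i* is `n_ij / Σ_{k∈family(i)} n_kj`, the share of its synonymous
family (the codons read by the same amino acid's isoacceptor tRNAs). The
**total frequency** is `n_ij / Σ_k n_kj` over all sense codons. STOP codons
are excluded from both metrics; the initiator ATG is counted as an ordinary
Met codon (family sizes therefore span 1–6; only 2–6-codon families are
eligible for isoacceptor statistics, since Met and Trp have constant
frequency 1). When a family does not occur in a gene its isoacceptor
frequencies are *undefined* (NaN), never 0 — imputing 0 would drag the
genome mean of rare families toward zero.

The genome baseline `µ_i` is the unweighted per-gene mean of each metric
over the supplied gene universe (all FASTA records), with the sample SD and
contributing-gene count; codons with fewer than two contributing genes are
flagged and excluded downstream. Per tissue, the top-N and bottom-N genes
by normalized expression (N = 200 by default; replicate columns are
averaged; ties broken lexicographically by gene id within one global
ranking, which keeps the two sets disjoint) define gene sets, and each
codon gets a one-sample T against `µ_i`:

```
T_i = (x̄_i − µ_i) / (s_i / √n)
```

with `n` the number of set genes where the metric is defined. Two-sided
p-values from Student t with df = n−1 are attached for reference; the
conventional cutoff |T| > 2 corresponds to p ≈ 0.047 at n = 200. No
multiple-testing correction is applied — the |T| > 2 rule is the working
convention and per-codon p-values are exposed for users who want to
correct. The A/T- vs G/C-ending bias summary averages defined T values
within each third-position class and reports the signed gap.

## Modification profiles

LC-MS/MS peak areas are normalized to the summed UV signal of the four
canonical nucleosides (area ratios; homogeneous of degree 0 in any common
scale factor). Tissue abundances are replicate means of area ratios, and
per modification the across-tissue **Z-score** is
`(value − row mean) / row sample SD`. Sample SD (ddof = 1) is used
throughout the package. Constant rows yield all-zero Z with a warning
rather than NaN so exported tables stay rectangular. Z-scores are computed
on raw area ratios by default, with a log2 option — on log scale the
synthetic generator's exponential link is inverted exactly, so noiseless
recovery of the true profile is perfect there, while raw-scale recovery is
monotone but slightly warped (r ≈ 0.96 for the default queuosine profile).
Pearson matrices use pairwise-complete observations with a minimum of three
per pair; zero-variance vectors give NA against all partners. A bundled
46-entry catalogue of small-RNA modifications (abbreviation, full name,
occurrence classes) labels outputs and filters tRNA-borne species.

## Linkage

For each codon, the across-tissue vector of gene-set T values is Pearson-
correlated with each modification's Z profile (pairwise deletion of
undefined T values; minimum three matched tissues, else NA; zero variance
is an error for the single-pair API and NA in the matrix report). No
p-values are attached: with seven tissues the coefficients themselves are
the result of interest and significance would be underpowered. Within a
two-codon family the isoacceptor frequencies of the partners sum to one
gene by gene, so their T vectors are exact mirrors and the synonymous-pair
correlation is −1 by construction *under the isoacceptor metric with both
codons always defined*; under the total-frequency metric, or with partial
definition, the pair correlation is informative rather than forced —
which is why the analysis reports both metrics and expects the
codon–modification linkage to weaken under total frequency when the signal
lives in family composition rather than amino-acid usage.

## A-site pausing

A footprint's A-site is `start + offset(length)` with a fixed per-length
offset table (15 nt for 27–30 nt fragments, 16 for 31–33, 17 for 34–35;
standard ribosome geometry, configurable). Footprints whose A-site falls
out of frame 0 or outside the CDS are dropped — no P-site fallback, for
determinism. Pause score = observed/expected A-site counts, with expected
counts formed from each gene's codon composition weighted by that gene's
assignable footprint total, so one deeply covered gene cannot impose its
composition (an unweighted pooled mode is available). Composition is
restricted to *observable* codon positions — the offset geometry makes the
first ~5 codons and a short 3′ tail of every CDS unreachable, so the
initiator and STOP codons never receive scores and edge composition cannot
deflate the rest. Codons with expected below a configurable minimum
(default 5) are masked. Between tissues, `log2(score_A / score_B)` is
reported; **negative log2FC = less dwelling = faster decoding in tissue
A**.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the study's scale: 7 tissues (brain, heart, muscle, kidney, liver, lung,
spleen), 1000 genes of 300 codons, 4 modification replicates, 10⁵
footprints per tissue.

* **Sequences.** Amino acids uniform over the 18 multi-codon families with
  Met/Trp at 5%; within a family, a C/G-ending codon is chosen with
  probability `logistic(b_g)`, `b_g ~ Uniform(−1, 1)` per gene, uniformly
  within the ending class. This makes synonymous composition (GC3) the
  per-gene trait that expression can couple to.
* **Modifications.** `a[m,t,r] = exp(log base_m + τ·Ztrue[m,t] + ε)`,
  `ε ~ N(0, 0.1)`, τ = 0.5. Fixed true Z profiles put Q and manQ highest
  in brain and lowest in liver/spleen, galQ flat, mcm5U brain- and
  lung-high; five further modifications get seed-drawn random profiles to
  populate the correlation layer.
* **Decoding and expression.** C-ending Q-family codons have efficiency
  `exp(β_C·Ztrue_Q)`, T-ending partners `exp(β_U·Ztrue_Q)` (defaults
  β_C = +0.8, β_U = −0.2: queuosine speeds NAC decoding strongly, NAU
  weakly opposite), all others 1. Expression couples through
  `log x = log base_g + α·Σ_c f_c·(e_c − 1) + N(0, 0.3)` with α = 2, so
  NAC-rich genes rise in Q-high tissues and the top gene sets inherit the
  codon bias.
* **Footprints.** Per tissue, gene totals are multinomial with probability
  ∝ expression; within a gene the A-site codon is drawn ∝ dwell
  `1/e[c,t]` per occurrence, restricted to positions where every generated
  fragment length (28–31 nt) can be assigned; the 5′ start is
  back-computed from the same offset table the pausing module uses, so
  assignment round-trips exactly.

Everything flows from one `numpy.random.default_rng(seed)` (PCG64) stream;
identical seeds give byte-identical outputs. Ground truth (Z profiles,
efficiencies, dwell, GC3 biases) is serialized beside the tables.

What the generator does **not** emulate: sequencing error, rRNA/ncRNA
contamination, isodecoder-level tRNA pools, realistic codon
autocorrelation along transcripts, 5′ ramps or initiation/termination
pausing, or amino-acid composition differences between gene sets. Passing
recovery tests therefore show that the statistics correctly invert this
generative model, not that real tissue data will be as clean; in
particular real NAC/NAT pair correlations will not be exactly −1 and real
pause scores carry biases (ligation preference, multimapping) that
observed/expected normalization cannot remove.

## Numerical and design choices

* Sample SD (ddof = 1) everywhere a SD appears.
* DNA (T) is the internal alphabet; U is mapped to T on input, and an RNA
  display mode renders labels with U.
* Gene-set selection sorts once by (expression desc, gene id asc); top and
  bottom are head and tail of that ranking.
* Recoding swaps are restricted to the 2-codon NAY pairs; larger families
  (the mcm5U set) are recodable only through explicit preferred-codon
  rules, since "ending" is ambiguous beyond two codons. Every recoding is
  verified translation-invariant before it is returned.
* Default recovery problem sizes: sign recovery over 10 seeds and
  null-model centering over 20 seeds run without footprints (the linkage
  layer does not need them); pause recovery uses one dataset at 10⁵
  footprints per tissue, where Poisson error per codon is ~2–3% and the
  true dwell contrasts span ~4 log2 units.

## Known limitations

* The pause-score definition (observed/expected with per-gene weighting)
  is this package's own; published pause pipelines differ in site
  conventions and normalization, so absolute scores are comparable only
  within this package — the between-tissue log2FC is the robust quantity.
* With seven tissues, linkage correlations are noisy (SD ≈ 0.4 under the
  null); signs and magnitudes should be read across seeds or datasets, not
  from single coefficients.
* The genome baseline is computed from whatever gene universe is supplied;
  restricting the FASTA to detected genes will shift `µ_i` accordingly.
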