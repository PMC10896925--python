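# Methods

## Scope and model

cernaforge infers competing-endogenous-RNA (ceRNA) relationships from a
two-group RNA-seq experiment. The statistical model has three layers:

* **Counts.** Feature counts are negative binomial,
  `K_ij ~ NB(mean = s_j μ_ig, dispersion = α_i)`, with per-sample size
  factors `s_j` (median-of-ratios) and a group mean `μ_ig`. Differential
  expression is a Wald test on `log(μ_iMOD) − log(μ_iNOR)` with the
  delta-method variance `1/(n_g μ_g) + α/n_g` per group.
* **Binding.** A miRNA binds a transcript where a strict 5′ seed
  (positions 2–7, perfect antiparallel Watson–Crick, no G·U) anchors a
  gapped duplex whose alignment score S and additive pair energy ΔG clear
  S ≥ 150 and ΔG ≤ −30 kcal/mol.
* **Competition.** Two transcripts compete when they share significantly
  many targeting miRNAs (upper-tail hypergeometric over the miRNA
  universe), score highly on a four-component MuTaME-style composite, and
  are positively co-expressed (Pearson r ≥ 0.8, p < 0.05).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| lncRNA candidate filter | length > 200, exons > 2 | nt, count | inherited filter, strict inequalities as printed; `>= 2` exons is the field convention, so both bounds are overridable |
| expression filter | group mean count > 2 | counts | strict >, either group |
| DE call | log2FC ≥ 1 (inclusive), adjusted p < 0.05 (strict) | — | inherited thresholds; `use_adjusted=False` switches to raw p; a legacy `fold_ratio` mode (ratio strictly > 2, raw p) covers unreplicated designs |
| duplex weights | WC +5, G·U +2, mm −3, gaps −8/−2, seed scale ×4 on positions 2–8 | score units | a fully specified surrogate for miRanda internals; with these weights a perfect 22-mer complement scores 7·20 + 15·5 = 215 |
| pair energies | G-C −3, A-U −2, G·U −1 | kcal/mol | additive surrogate for duplex thermodynamics; 10 G-C pairs sit exactly on the −30 threshold |
| site thresholds | S ≥ 150, ΔG ≤ −30 | score, kcal/mol | inherited; both inclusive as printed |
| co-expression | r ≥ 0.8, p < 0.05, lncRNA < 6000 nt | — | `mode="absolute"` for the exploratory stage, `mode="positive"` for the ceRNA intersection |
| hypergeometric universe | all input miRNAs | — | mirrors using the full differential-miRNA set as universe |
| PWM scan | pseudocount 0.25/cell, uniform background, relative score ≥ 0.8, both strands | — | relative score = (score − min)/(max − min) with columnwise extrema |
| intergenic window | 100 kb | bp | nearest-gene search for positional classes; ties toward the genomically 5′ gene |
| network truncation | top 100 ceRNA pairs, top 500 TF triplets, top 30 terms | — | inherited presentation sizes |

## Numerical and algorithmic choices

* **Duplex alignment.** The seed hexamer is a fixed block; the miRNA 5′
  base and the 3′ remainder are extended by affine-gap DP (first gap
  position −8, each further −2) with free distal ends, so unpaired
  termini cost nothing and S ≥ 140 at any anchored seed. The seed scale
  multiplies match/mismatch scores only, never gap costs. ΔG is summed
  over the paired positions of the S-optimal alignment (mismatch columns
  contribute 0). When a repetitive window admits several seed anchors the
  best-scoring one is used (ties leftmost).
* **Overlap resolution before thresholding.** Candidate sites of one
  miRNA on one transcript are resolved for overlap greedily by descending
  S (ties leftmost) over *all* scored candidates, and the survivors are
  then filtered by the S/ΔG thresholds. Resolving after filtering would
  let a weakened threshold admit a high-scoring site that displaces a
  previously reported one; resolving first makes threshold weakening
  strictly monotone (it can only add sites) and cannot suppress a planted
  full-complement site, which is unbeatable for its own miRNA.
* **Zero handling in the Wald test.** Group means enter the fold change
  and the variance as `μ_g + c` with pseudo-mean c = 0.5, so an all-zero
  group yields a finite log2FC and p → 1 when both groups are zero.
* **MuTaME components.** The composite is normative for this package:
  s1 = |shared miRNAs|, s2 = mean shared-MRE count per kb, s3 = mean
  fractional span (max site end − min site start)/length of shared-miRNA
  sites, s4 = mean shared fraction of all MREs; raw = s1·s2·s3·s4,
  normalized to 100 · raw/max(raw). Ranking ties break by p_hyper, then
  lexicographic ids. Pairs with an undefined component (a partner without
  MREs) are dropped with a warning.
* **Single hypergeometric core.** The shared-miRNA test and gene-set
  enrichment call the same upper-tail implementation, so they can never
  disagree on identical (N, K, n, k).
* **Scale invariance.** Rescaling one sample's counts rescales all
  median-of-ratios-normalized counts by the m-th root of the factor, so
  p-values are stable only up to the mean-dependent `1/(n μ)` variance
  term (the same is true of GLM-based NB tests); fold-change signs are
  preserved exactly.
* **Coordinates.** GTF input/output is 1-based closed; every internal
  site coordinate is 0-based half-open on the transcript sense strand;
  miRNAs are never reverse-complemented (the target window is read
  antiparallel). Sequences are RNA internally; DNA input (FASTA, PWM
  consensus) is mapped T↔U at the boundary.

## The synthetic generator

The generator emulates the targeted study design: two groups of
NB-distributed counts (default 3 replicates each, dispersion 0.05, means
log-uniform on [50, 500]), a planted DE fraction (default 0.15 at
|log2FC| = 2), and planted ceRNA triplets. The scaled-down problem sizes
— 120 mRNAs, 40 lncRNAs, a 60-miRNA universe, transcripts of 0.3–1.5 kb —
were chosen once as a regime where a 3-shared-miRNA module is
statistically detectable against the background rate of chance
threshold-passing sites (about 0.05 per miRNA-transcript pair at these
lengths); real transcriptomes are larger in every direction, and the
background rate grows linearly with transcript length.

* **Planted sites** are full reverse complements of the miRNA, which
  deterministically clear S ≥ 150 (score 215) and ΔG ≤ −30 (worst case
  −44 for an all-A/U miRNA), giving exact ground truth. Sites are placed
  in equal-width slots so they never overlap; a transcript too short for
  its quota raises an error naming it.
* **Triplet miRNA sets are disjoint** across triplets whenever the
  universe allows, modelling independent ceRNA modules; this keeps
  cross-triplet pairs out of the planted truth and makes
  precision/recall well defined.
* **Co-expression** comes from a shared log-normal latent factor on the
  pair's log means. Both partners are planted as upregulated, and the
  group shift itself contributes shared variance `(ln2 · lfc)²/4`; the
  latent scale tops the shared variance up to `r/(1−r)` times the NB
  noise floor `1/μ + α` (with a 1.2 safety margin), so the expected
  Pearson r of log counts meets the target (default 0.9) without
  inflating within-group variance more than necessary.
* **TF edges** embed the motif consensus in the triplet's lncRNA at a
  position free of planted MREs and register the (TF, partner mRNA)
  regulation pair, plus decoy pairs.
* **Exon structure is synthetic**: lncRNAs get exactly 3 exons (so they
  pass the exons > 2 filter), mRNAs 2–12, all uniform splits with 100-bp
  introns on a 5-chromosome layout. Genomic positions are sequential,
  which makes most lncRNAs intergenic in the positional classification.
* **Determinism.** Every stage draws from
  `numpy.random.default_rng([seed, stage])`, so identical configurations
  produce byte-identical bundles and pipeline outputs.

What the generator does **not** emulate: read-level noise and mapping
artefacts, isoform complexity, GC/length biases, batch effects,
non-uniform base composition, miRNA expression levels, and genome-scale
transcript counts. Passing recovery tests therefore demonstrates the
correctness and calibration of the inference chain under its own model
assumptions, not performance on real libraries — in particular the
published analysis's headline counts depend on its deposited raw data and
database versions and are outside desk-scale reproduction.

## Benchmark experiments

`cernaforge.benchmark` fixes the standard experiments: null calibration
(2,000 NB features, α = 0.05, 5 samples/group), planted recall (200
features at log2FC = 2, μ = 200, embedded in 1,800 nulls so size factors
stay anchored), ceRNA recovery (10 triplets, 3 shared miRNAs, 2 MREs per
transcript, r target 0.9, 10 samples/group, ~5,000 candidate pairs,
pooled over 5 seeds) and TF-edge recovery. Problem sizes keep each
experiment in the seconds range.

## Known limitations

* The NB test is a transparent Wald-on-group-means variant: no dispersion
  shrinkage, no GLM, no outlier handling; with estimated (method-of-
  moments) dispersion at n = 5/group it is mildly anticonservative
  (empirically ≈ 0.08 at nominal 0.05), which is why calibration is
  stated at known dispersion.
* The duplex model is additive; no nearest-neighbor thermodynamics, no
  conservation or accessibility terms.
* The "combined hypergeometric" pair p-value of the original workflow is
  implemented as the single shared-miRNA upper-tail test; nothing is
  combined across components.
* PWM scanning targets the lncRNA transcript sequence (promoters are out
  of scope unless supplied explicitly), with uniform background and no
  motif p-value calibration.
* Gene-set enrichment treats terms as flat sets (no GO-DAG propagation);
  the universe defaults to the union of the supplied GMT.
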