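# Methods

This note documents the models and procedures implemented in `phyloturn`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## The analysis pipeline

The pipeline targets small amplicon surveys of microbial eukaryote (or
prokaryote) communities: a samples × OTUs count table, a rooted phylogeny
of the OTUs with branch lengths, and per-sample environmental metadata
(here, water depth in meters). Stages run in a fixed order:

1. **Curation.** OTUs with fewer than 2 reads in the whole data set
   (singletons) are removed, then OTUs detected in only one sample, then
   OTUs whose taxonomic lineage contains an excluded token (default
   `Metazoa`, since multicellular animals are not part of a protist
   community). Order matters — the singleton filter can change what the
   occupancy filter sees — so the chain is fixed and the OTU count after
   each stage is logged. OTUs absent from the taxonomy are retained: an
   unassigned OTU cannot be positively identified as a member of the
   excluded group.
2. **Rarefaction** to a common depth (default 5,792 reads/sample), one
   multivariate-hypergeometric draw per sample. A single draw, not an
   average over repeated rarefactions, is used for all downstream tables;
   rarefaction *curves* (repeated subsampling over a depth grid) are a
   separate alpha-diversity product.
3. **Alpha diversity** on the rarefied table: observed OTUs, bias-corrected
   Chao1 `S_obs + F1(F1−1)/(2(F2+1))`, and Shannon `H = −Σ p_i ln p_i`
   (natural log; a base flag exists). The classic Chao1 form
   `S_obs + F1²/(2F2)` is available behind a flag and falls back to the
   corrected form when F2 = 0.
4. **Beta diversity.** Bray-Curtis on counts, and weighted UniFrac
   `Σ_b l_b |p_A(b) − p_B(b)|` over tree branches, where `p_X(b)` is the
   fraction of sample X's reads descending from branch `b`. The raw
   (non-normalized) form is the default; `normalized=True` divides by
   `Σ_b l_b (p_A(b)+p_B(b))`, bounding the metric by 1. PCoA is classical
   Gower double-centering of −½D² with eigendecomposition; negative
   eigenvalues are reported untouched (no Cailliez/Lingoes correction) and
   excluded from `proportion_explained`. Axis signs are canonicalized
   (largest-magnitude loading positive) purely for reproducibility.
   Depth decay is tested two ways: a Mantel test of the UniFrac matrix
   against pairwise |Δdepth| (one-sided, testing positive correlation, the
   ecological convention), and OLS of the first PCoA axis on depth.
   When n! does not exceed the requested permutation count the Mantel null
   is enumerated exhaustively — for six samples that is exactly 720
   relabelings, identity included, and `p = #(r_perm ≥ r_obs)/720`;
   otherwise Monte-Carlo with `p = (1+#)/(1+n_perm)`.
5. **Assembly partitioning** (the core): see below.

## Null-model partitioning of turnover

For every sample pair the abundance-weighted **betaMNTD** is

    βMNTD(A,B) = ½ [ Σ_{i∈A} f_iA · min_{j∈B} d(i,j)
                   + Σ_{j∈B} f_jB · min_{i∈A} d(i,j) ]

with `f` the within-sample relative abundances and `d` the patristic
distance (presence/absence weights `1/S` in unweighted mode). A taxon
shared by both communities finds itself at distance zero. **betaNTI** is
the z-score of the observed βMNTD against 999 "taxa shuffle" null values:
taxon identities are randomized across the phylogeny's tips, which is a
joint permutation of the rows/columns of the patristic matrix; community
structure is untouched. All pairs share one stream of null trees — this
is cheaper than independent streams and removes between-pair null
variance, at the price of correlated z-scores within one survey (see the
calibration note below). `|βNTI| > 2` is read as selection (species
sorting): `> +2` variable selection across divergent habitats, `< −2`
homogeneous selection.

Pairs not explained by selection go to the abundance-based **Raup-Crick**
step. Each of 999 replicates rebuilds both communities from the
metacommunity (all samples of the analyzed table): observed richness S is
preserved; S species are drawn without replacement with probability
proportional to occupancy (number of samples occupied); each selected
species gets one read and the remaining N−S reads are placed multinomially
in proportion to metacommunity relative abundance. Bray-Curtis between
the two null communities is compared with the observed value and

    RC = 2 · [ (n_less + ½·n_equal) / n_reps − ½ ]  ∈ [−1, 1].

`RC > +0.95` → dispersal limitation; `RC < −0.95` → mass effects
(homogenizing dispersal); otherwise drift. Ties are counted after
rounding Bray-Curtis to 12 decimals so tie counts are platform-stable.

Edge cases and conventions:

* Thresholds are strict inequalities; `|βNTI| = 2` or `|RC| = 0.95` fall
  to the non-selection / drift side.
* If a pair's null distribution is degenerate (sd = 0 — e.g. both samples
  contain exactly the same taxa, so every nearest-taxon distance is zero
  under any shuffle), βNTI is undefined and flagged as NaN; the pipeline
  classifies such pairs by RC alone, since no phylogenetic deviation is
  measurable. If the observation differs from a constant null the z-score
  is ±inf and the pair counts as selection.
* RC is computed for every pair (cheap at this scale) but is decisive
  only when `|βNTI| < 2`.
* The two null models draw from seeds derived independently from the one
  master seed; every output records seed and replicate count, and reruns
  are bit-identical.

## Synthetic surveys and what they show

The generator emulates a six-sample benthic survey along a 79–2,939 m
depth gradient with a few hundred OTUs at 5,792 reads/sample, under four
known regimes. Common machinery: a Yule tree (`n_tips=400`,
`birth_rate=1`), a Brownian niche trait (`bm_sigma2=1` — the scale is
immaterial because the environment is mapped onto the trait's quantiles),
and log-normal metacommunity abundances (`σ=1`, a typical rank-abundance
skew). Counts are one multinomial draw per sample, so totals are exact.

* **selection** — `λ_ik ∝ m_i · exp(−(t_i − e_k)²/(2σ_w²))`. Depth is
  mapped affinely onto the trait's quantiles, clamped to [0.10, 0.90]: a
  linear map onto the trait *range* would strand the gradient extremes in
  the near-empty tails of the Brownian trait distribution and collapse
  those samples to a handful of OTUs. `σ_w` defaults to 0.05× the trait
  range — a narrow niche producing strong, phylogenetically conserved
  sorting.
* **neutral_drift** — `λ_ik ∝ m_i · g_ik`, `g ~ Gamma(α, 1/α)` i.i.d.
  (mean 1, variance 1/α): independent local birth/death fluctuation
  around the shared metacommunity. `α = 200` was calibrated once so that
  observed Bray-Curtis sits centered in the Raup-Crick null distribution,
  and then frozen: much stronger fluctuation (small α) reads as dispersal
  limitation, none at all reads as mass effects, both of which would
  misrepresent drift.
* **mass_effects** — one shared realized community; each sample copies it
  and resamples only 2% of reads. The homogenization signal must live at
  the count level: independent multinomial draws from one shared λ are
  generatively identical to drift and carry no extra similarity for the
  null model to detect.
* **dispersal_limitation** — tips are split into two random regional
  pools (independent of the trait, so no phylogenetic signal); each
  sample draws only from its region's pool with neutral weights.

Truth labels are regime-level expectations per pair (cross-gradient →
sorting, cross-pool → dispersal limitation, etc.), not per-realization
guarantees; recovery is therefore assessed as a majority rate (≥70% of
diagnostic pairs at a frozen seed), not per-pair exactness.

What passing these tests shows: the estimator stack detects each process
when it is the dominant generative force at realistic survey size, and
stays calibrated when no process is acting. What it does not show: field
data involve mixtures of processes, taxon-specific dispersal, PCR and
sequencing bias, extracellular DNA from the water column, and trees
estimated with error — none of which the generator emulates. Recovery
rates here are upper bounds on what the framework can resolve in nature.

## Calibration of betaNTI under its own null

When communities are assembled independently of the phylogeny, βNTI
should be a standard z-score (mean ≈ 0, sd ≈ 1). Within one survey,
however, pair-level z-scores are strongly correlated — all pairs share
the tree, the metacommunity and the shared null stream; across
realizations the per-survey mean has a standard deviation near 0.45. The
calibration test therefore pools 1,120 pairs from 40 independent surveys
(8 samples × 150 tips × 500 reads, 999 reps each), treating the survey as
the independent replicate, and checks mean ∈ (−0.2, 0.2) and
sd ∈ (0.8, 1.2). Pairs whose βNTI is undefined (identical support) are
excluded from the pooled estimate.

## Numerical choices

* Distance matrices enforce symmetry to 1e-12 and an exactly zero
  diagonal; non-negativity is deliberately not enforced because the
  Raup-Crick matrix lives in [−1, 1].
* Patristic distances come from the edge×tip incidence matrix via
  `d(i,j) = depth_i + depth_j − 2·shared(i,j)`, clipped at zero against
  roundoff; the same incidence drives weighted UniFrac as one matrix
  product per survey.
* Weighted sampling without replacement (Raup-Crick species draws) uses
  the Gumbel top-k trick (Efraimidis–Spirakis), exact and vectorized.
* PCoA eigenvalues below `1e-12·|λ_max|` are treated as zero; no axes are
  returned for them.
* Null sd uses ddof = 1. RNG is numpy's PCG64 throughout; sub-seeds are
  derived with `SeedSequence.spawn`, so one master seed reproduces every
  stage.
* Rooting of the input tree is taken as given. Weighted UniFrac and
  patristic distances both depend on it; with an unrooted or re-rooted
  tree the same pipeline runs but distances differ.

## Problem sizes used in the shipped tests

Oracle-equivalence checks run on 50 random instances of ≤10 samples × ≤30
taxa. Regime-recovery tests run at the survey scale described above
(6 × 5,792 × 400 tips, 999 + 999 null replicates; a few seconds per
regime). The calibration test pools 40 small surveys. The full suite
completes in well under a minute on one CPU, apart from the recovery and
calibration tests which together take roughly half a minute.

## Known limitations

* The Raup-Crick null fixes richness and fills abundances from the pooled
  table; with very few samples the metacommunity estimate is itself noisy
  and RC saturates at ±1 quickly.
* βNTI is undefined for identical-support pairs (flagged NaN); surveys
  rarefied to high depth with few taxa will produce such pairs.
* The Mantel test and the axis regression use untransformed meters by
  default; a `log_depth` flag exists, and the two choices can disagree on
  strongly skewed gradients.
* Composition summaries use per-sample denominators (OTUs detected in
  that sample), so OTU percentages are comparable within a sample but not
  directly convertible to pooled fractions.
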