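# phyloturn

Phylogenetic null-model analysis of microbial community turnover.

`phyloturn` is a small, fully tested pipeline for amplicon surveys of
microbial (especially protist) communities: it curates an OTU count
table, computes alpha and beta diversity, and partitions the turnover
between every pair of samples into four ecological processes — **species
sorting** (selection by the local environment), **dispersal limitation**,
**mass effects** (homogenizing dispersal) and **drift** — using the
βMNTD / βNTI / RC_bray null-model framework standard in microbial
ecology. It ships a synthetic-community simulator so that every stage of
the pipeline can be validated against data with a known generative
process, without downloading anything.

It is aimed at researchers with a samples × OTUs table (TSV), a rooted
phylogeny of the OTUs (Newick, branch lengths required), per-sample
metadata with water depth (or any one-dimensional gradient), and an
optional taxonomy table.

## The statistics at the core

For a sample pair (A, B), the abundance-weighted **β mean nearest taxon
distance** is

    βMNTD(A,B) = ½ [ Σ_{i∈A} f_iA · min_{j∈B} d(i,j) + Σ_{j∈B} f_jB · min_{i∈A} d(i,j) ]

with f the within-sample relative abundances and d the patristic
distance. The **β nearest taxon index** βNTI is the z-score of the
observed βMNTD against 999 randomizations that shuffle taxon identities
across the tips of the phylogeny; |βNTI| > 2 indicates selection
(βNTI > +2 variable, < −2 homogeneous). Pairs with |βNTI| < 2 are passed
to the abundance-based **Raup-Crick** metric on Bray-Curtis: 999 null
community pairs are assembled from the metacommunity (richness preserved;
species drawn by occupancy; reads filled by metacommunity abundance) and

    RC_bray = 2·[ (n_less + ½·n_equal)/999 − ½ ]  ∈ [−1, 1].

RC > +0.95 → dispersal limitation, RC < −0.95 → mass effects, otherwise
drift. The beta-diversity block additionally provides Bray-Curtis,
weighted UniFrac (raw and normalized), PCoA with sign-canonicalized axes,
an exhaustive-when-possible Mantel test (for 6 samples: all 720
relabelings), and OLS of PCoA axis 1 on depth.

See `docs/methods.md` for the full model description, parameter defaults
and numerical conventions.

## Worked example

Simulate a six-station survey (79–2,939 m depth gradient, 400-OTU pool,
5,792 reads/sample) under strong species sorting, curate it, and run the
full analysis:

```python
from phyloturn import (SimulationConfig, simulate_dataset, analyze_assembly,
                       weighted_unifrac, mantel, pcoa, axis_regression)
from phyloturn.beta import depth_distance
from phyloturn.filters import curate
from phyloturn.alpha import alpha_table

cfg = SimulationConfig(regime="selection", seed=11)
table, tree, metadata, truth = simulate_dataset(cfg)
table, accounting = curate(table, None)
print("accounting:", accounting)
print(alpha_table(table).round(2))

wu = weighted_unifrac(table, tree)
dd = depth_distance(metadata, sample_ids=list(table.sample_ids))
m = mantel(wu, dd, n_permutations=999, seed=11)
print(f"Mantel r = {m.r:.2f}, p = {m.p:.4f}, permutations = {m.n_permutations}")
r2, p = axis_regression(pcoa(wu), metadata, axis=0)
print(f"PCo1 ~ depth r^2 = {r2:.2f} (p = {p:.4f})")

res = analyze_assembly(table, tree, n_reps=999, seed=12)
print(res.partition.to_frame().to_string(index=False))
```

Output:

```
accounting: [('input', 400), ('min_total', 389), ('min_occupancy', 365)]
           observed_otus   chao1  shannon
sample_id
S1                   128  149.38     4.00
S2                   231  258.56     4.71
S3                   246  257.61     4.78
S4                   249  270.00     4.90
S5                   174  177.00     4.31
S6                   157  168.33     4.21
Mantel r = 0.95, p = 0.0014, permutations = 720
PCo1 ~ depth r^2 = 0.92 (p = 0.0025)
             process  n_pairs  percent
     species_sorting       13     86.7
dispersal_limitation        0      0.0
        mass_effects        1      6.7
               drift        1      6.7
```

Reading it: curation dropped 11 singleton OTUs and 24 single-sample OTUs
(no taxonomy was supplied, so no taxon exclusion). Community dissimilarity
tracks the depth gradient strongly (Mantel r = 0.95 over all 720
exhaustive permutations; 92% of PCo1 variance explained by depth), and the
null models attribute 13 of the 15 sample pairs (86.7%) to species
sorting — the process that actually generated the data.

The same analysis is available from the shell:

```bash
phyloturn simulate --regime selection --seed 11 --outdir sim
phyloturn run --otu-table sim/otu_table.tsv --tree sim/tree.nwk \
              --metadata sim/metadata.tsv --depth 5792 --seed 11 --outdir out
```

which writes the filtered and rarefied tables, alpha metrics, distance
matrices, PCoA coordinates, Mantel results, per-pair βNTI/RC records, the
process partition and a run log (all TSV) under `out/`.

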