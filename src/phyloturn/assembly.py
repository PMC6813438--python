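"""Phylogenetic null models for community assembly.

This module partitions pairwise community turnover into four ecological
processes using the two-step null-model framework standard in microbial
ecology:

1.  The abundance-weighted beta mean nearest taxon distance (betaMNTD) is
    computed for every sample pair and compared to a null distribution
    obtained by shuffling taxa across the tips of the phylogeny.  The
    resulting z-score, the beta nearest taxon index (betaNTI), measures
    how much phylogenetic turnover deviates from chance.  |betaNTI| > 2
    indicates selection ("species sorting"): betaNTI > +2 variable
    selection (divergent habitats), betaNTI < -2 homogeneous selection.

2.  Pairs not explained by selection (|betaNTI| < 2) are examined with the
    abundance-based Raup-Crick metric on Bray-Curtis (RC_bray): observed
    Bray-Curtis is compared with dissimilarities among null communities
    assembled probabilistically from the metacommunity, rescaled to
    [-1, 1].  RC > +0.95 indicates dispersal limitation, RC < -0.95 mass
    effects (homogenizing dispersal), and intermediate values drift.

Pairs falling exactly on a threshold (|betaNTI| = 2, |RC| = 0.95) go to
the non-selection / drift side; the thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta import DistanceMatrix
from .io import PhyloTree

__all__ = [
    "patristic_distances",
    "bmntd",
    "bnti",
    "raup_crick_bray",
    "classify_pair",
    "partition_processes",
    "analyze_assembly",
    "AssemblyPartition",
    "AssemblyResult",
    "PROCESS_LABELS",
    "rc_from_counts",
]

PROCESS_LABELS = ("species_sorting", "dispersal_limitation", "mass_effects", "drift")

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95
_RC_ROUND = 12  # decimals used when counting Bray-Curtis ties


def patristic_distances(tree):
    """Tip-to-tip path-length distances as a :class:`DistanceMatrix`."""
    if not isinstance(tree, PhyloTree):
        raise TypeError("tree must be a PhyloTree")
    ids, dist = tree.patristic_matrix()
    return DistanceMatrix(ids, dist)


def _align_taxdist(table, taxdist):
    """Patristic submatrix in table OTU order; errors on missing OTUs."""
    pos = {o: i for i, o in enumerate(taxdist.ids)}
    missing = [o for o in table.otu_ids if o not in pos]
    if missing:
        raise KeyError(f"OTUs absent from the taxon distance matrix: {missing}")
    idx = [pos[o] for o in table.otu_ids]
    return taxdist.values[np.ix_(idx, idx)]


def _weights(table, abundance_weighted):
    """Per-sample taxon weights f (rows sum to 1)."""
    presence = table.presence()
    if np.any(~presence.any(axis=1)):
        empty = [s for s, ok in zip(table.sample_ids, presence.any(axis=1)) if not ok]
        raise ValueError(f"samples with no OTUs: {empty}")
    if abundance_weighted:
        return table.proportions(), presence
    richness = presence.sum(axis=1).astype(float)
    return presence / richness[:, None], presence


def _bmntd_values(weights, presence, dist):
    """betaMNTD for all pairs given weights (S,T), presence (S,T), dist (T,T).

    For each sample B, ``m[B, i]`` is the distance from taxon i to its
    nearest taxon present in B (zero when i itself is in B).  Then
    betaMNTD(A, B) = 0.5 * (f_A . m_B + f_B . m_A), computed for all
    pairs at once as one matrix product.
    """
    n_samples, n_taxa = weights.shape
    m = np.empty((n_samples, n_taxa))
    for k in range(n_samples):
        m[k] = dist[:, presence[k]].min(axis=1)
    g = weights @ m.T  # g[a, b] = f_a . m_b
    out = 0.5 * (g + g.T)
    np.fill_diagonal(out, 0.0)
    return out


def bmntd(table, taxdist, abundance_weighted=True):
    """Between-community mean nearest taxon distance for every sample pair.

    betaMNTD(A, B) = 0.5 * [ sum_{i in A} f_iA * min_{j in B} d(i, j)
                           + sum_{j in B} f_jB * min_{i in A} d(i, j) ]

    where f are within-sample relative abundances (``abundance_weighted``)
    or 1/S_A (presence-absence mode), and d is the patristic distance.
    A taxon shared by both samples finds itself at distance zero.
    """
    dist = _align_taxdist(table, taxdist)
    weights, presence = _weights(table, abundance_weighted)
    vals = _bmntd_values(weights, presence, dist)
    return DistanceMatrix(list(table.sample_ids), vals)


def bnti(table, taxdist, n_reps=999, seed=0, abundance_weighted=True):
    """betaNTI: z-score of observed betaMNTD against a taxa-shuffle null.

    The null randomizes taxon placement on the phylogeny by jointly
    permuting the rows and columns of the patristic matrix; community
    structure (which sample holds which abundance) is untouched.  All
    sample pairs share one stream of ``n_reps`` randomized trees, which
    is cheaper and lowers between-pair null variance.

    Returns a DataFrame with one row per unordered sample pair and columns
    ``sample_a, sample_b, bmntd_obs, null_mean, null_sd, bnti, n_reps,
    seed``.  Pairs whose null standard deviation is zero get ``bnti = NaN``
    (flagged, never silently zeroed).
    """
    if table.n_otus < 2:
        raise ValueError("betaNTI needs at least 2 OTUs")
    dist = _align_taxdist(table, taxdist)
    weights, presence = _weights(table, abundance_weighted)
    obs = _bmntd_values(weights, presence, dist)
    n = table.n_samples
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    null = np.empty((n_reps, iu[0].size))
    n_taxa = table.n_otus
    for r in range(n_reps):
        perm = rng.permutation(n_taxa)
        vals = _bmntd_values(weights, presence, dist[np.ix_(perm, perm)])
        null[r] = vals[iu]
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    diff = obs[iu] - null_mean
    z = np.empty_like(diff)
    ok = null_sd > 0
    z[ok] = diff[ok] / null_sd[ok]
    # degenerate null (sd = 0): no deviation measurable -> NaN (flagged);
    # a genuinely different observation against a constant null -> +-inf
    with np.errstate(invalid="ignore"):
        z[~ok] = np.where(
            np.abs(diff[~ok]) <= 1e-12, np.nan, np.sign(diff[~ok]) * np.inf
        )
    return pd.DataFrame(
        {
            "sample_a": [table.sample_ids[i] for i in iu[0]],
            "sample_b": [table.sample_ids[j] for j in iu[1]],
            "bmntd_obs": obs[iu],
            "null_mean": null_mean,
            "null_sd": null_sd,
            "bnti": z,
            "n_reps": n_reps,
            "seed": seed,
        }
    )


def _bray_curtis_pair(a, b):
    tot = float(a.sum() + b.sum())
    return float(np.abs(a - b).sum()) / tot


def rc_from_counts(n_less, n_equal, n_reps):
    """Rescale null-comparison counts to Raup-Crick in [-1, 1].

    RC = 2 * ((n_less + 0.5 * n_equal) / n_reps - 0.5) where ``n_less`` is
    the number of null replicates with Bray-Curtis strictly below the
    observed value and ``n_equal`` the number of ties.
    """
    if not 0 <= n_less + n_equal <= n_reps:
        raise ValueError("inconsistent null counts")
    return 2.0 * ((n_less + 0.5 * n_equal) / n_reps - 0.5)


def _weighted_sample_without_replacement(rng, weights, k):
    """Efraimidis-Spirakis via Gumbel keys: k indices, P(select) ~ weights."""
    keys = np.log(weights) + rng.gumbel(size=weights.size)
    if k >= weights.size:
        return np.arange(weights.size)
    return np.argpartition(keys, -k)[-k:]


def raup_crick_bray(table, n_reps=999, seed=0):
    """Abundance-based Raup-Crick dissimilarity (RC_bray) for all pairs.

    For each pair, ``n_reps`` null replicates rebuild both communities
    from the metacommunity (all samples of ``table``): the observed
    richness S is preserved; S species are drawn without replacement with
    probability proportional to metacommunity occupancy (number of samples
    occupied); each selected species receives one read and the remaining
    N - S reads are assigned multinomially with probability proportional
    to metacommunity relative read abundance.  Bray-Curtis between the two
    null communities is compared with the observed value (ties counted
    after rounding to 12 decimals) and rescaled to [-1, 1].
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    presence = table.presence()
    richness = presence.sum(axis=1)
    if np.any(richness == 0):
        empty = [s for s, r in zip(table.sample_ids, richness) if r == 0]
        raise ValueError(f"samples with zero richness: {empty}")
    totals = table.sample_totals()
    occupancy = table.occupancy().astype(float)
    gamma = table.otu_totals().astype(float)
    pool = np.flatnonzero(occupancy > 0)
    occ_w = occupancy[pool]
    gamma_w = gamma[pool]
    n = table.n_samples
    rng = np.random.default_rng(seed)

    def null_community(s_obs, n_reads):
        sel = pool[_weighted_sample_without_replacement(rng, occ_w, s_obs)]
        counts = np.ones(sel.size, dtype=np.int64)
        rest = int(n_reads) - sel.size
        if rest > 0:
            p = gamma[sel] / gamma[sel].sum()
            counts += rng.multinomial(rest, p)
        vec = np.zeros(table.n_otus, dtype=np.int64)
        vec[sel] = counts
        return vec

    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            obs = round(_bray_curtis_pair(table.counts[i], table.counts[j]), _RC_ROUND)
            n_less = 0
            n_equal = 0
            for _ in range(n_reps):
                a = null_community(int(richness[i]), totals[i])
                b = null_community(int(richness[j]), totals[j])
                bc = round(_bray_curtis_pair(a, b), _RC_ROUND)
                if bc < obs:
                    n_less += 1
                elif bc == obs:
                    n_equal += 1
            out[i, j] = rc_from_counts(n_less, n_equal, n_reps)
    out = out + out.T
    return DistanceMatrix(list(table.sample_ids), out)


def classify_pair(bnti_value, rc_value=None):
    """Assign one of the four process labels to a sample pair.

    |betaNTI| > 2 -> ``species_sorting`` regardless of RC; otherwise RC
    decides: > +0.95 ``dispersal_limitation``, < -0.95 ``mass_effects``,
    else ``drift``.  An RC value is required whenever |betaNTI| <= 2.
    """
    if bnti_value is None or np.isnan(bnti_value):
        raise ValueError("betaNTI is undefined for this pair")
    if abs(bnti_value) > BNTI_THRESHOLD:
        return "species_sorting"
    if rc_value is None or not np.isfinite(rc_value):
        raise ValueError("RC_bray required when |betaNTI| <= 2")
    if rc_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_value < -RC_THRESHOLD:
        return "mass_effects"
    return "drift"


def selection_mode(bnti_value):
    """Sub-label for selection: variable (> +2) vs homogeneous (< -2)."""
    if bnti_value > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    return None


@dataclass
class AssemblyPartition:
    """Counts and percentages of sample pairs attributed to each process."""

    counts: dict
    percentages: dict
    n_pairs: int
    selection_split: dict = field(default_factory=dict)

    def to_frame(self):
        return pd.DataFrame(
            {
                "process": list(PROCESS_LABELS),
                "n_pairs": [self.counts[k] for k in PROCESS_LABELS],
                "percent": [round(self.percentages[k], 1) for k in PROCESS_LABELS],
            }
        )


def partition_processes(labels, bnti_values=None):
    """Tally process labels into an :class:`AssemblyPartition`.

    ``bnti_values`` (optional, parallel to ``labels``) enables the
    variable/homogeneous split of the selection fraction.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no classified pairs")
    unknown = sorted(set(labels) - set(PROCESS_LABELS))
    if unknown:
        raise ValueError(f"unknown process labels: {unknown}")
    n = len(labels)
    counts = {k: labels.count(k) for k in PROCESS_LABELS}
    pct = {k: counts[k] / n * 100.0 for k in PROCESS_LABELS}
    split = {"variable_selection": 0, "homogeneous_selection": 0}
    if bnti_values is not None:
        for lab, z in zip(labels, bnti_values):
            if lab == "species_sorting":
                mode = selection_mode(z)
                if mode:
                    split[mode] += 1
    return AssemblyPartition(counts=counts, percentages=pct, n_pairs=n, selection_split=split)


@dataclass
class AssemblyResult:
    """Per-pair records plus the aggregate process partition."""

    records: pd.DataFrame
    partition: AssemblyPartition


def analyze_assembly(table, tree, n_reps=999, seed=0, abundance_weighted=True):
    """Run the full two-step analysis: betaNTI, RC_bray, classify, tally.

    ``tree`` may be a :class:`PhyloTree` or a precomputed patristic
    :class:`DistanceMatrix`.  RC is computed for every pair (cheap at this
    scale) but only consumed when |betaNTI| < 2.  Two independent seeds are
    derived from ``seed`` for the two null models.
    """
    taxdist = patristic_distances(tree) if isinstance(tree, PhyloTree) else tree
    ss = np.random.SeedSequence(seed)
    seed_bnti, seed_rc = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    records = bnti(
        table, taxdist, n_reps=n_reps, seed=seed_bnti, abundance_weighted=abundance_weighted
    )
    rc = raup_crick_bray(table, n_reps=n_reps, seed=seed_rc)
    rc_vals = [rc.pair(a, b) for a, b in zip(records["sample_a"], records["sample_b"])]
    records = records.assign(rc_bray=rc_vals)

    def _label(z, r):
        # a pair with a degenerate null (sd = 0 and observed == null) carries
        # no phylogenetic deviation signal; it falls through to the RC step
        if np.isnan(z):
            return classify_pair(0.0, r)
        return classify_pair(z, r)

    records["process"] = [
        _label(z, r) for z, r in zip(records["bnti"], records["rc_bray"])
    ]
    partition = partition_processes(records["process"], records["bnti"])
    return AssemblyResult(records=records, partition=partition)
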