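"""OTU-table curation: rare-OTU filters, taxon exclusion, rarefaction,
and taxonomic composition summaries.

The canonical curation order applied by the pipeline is

    remove_singletons -> remove_single_sample_otus -> remove_taxon_group

followed by rarefaction to a fixed read depth.  Order matters: removing
singletons first can change which OTUs an occupancy filter subsequently
sees, so the pipeline applies the documented order and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CommunityTable

__all__ = [
    "remove_singletons",
    "remove_single_sample_otus",
    "remove_taxon_group",
    "curate",
    "rarefy",
    "taxonomic_composition",
    "CompositionSummary",
]


def remove_singletons(table, min_total=2):
    """Drop OTUs whose pooled count across all samples is below ``min_total``.

    With the default ``min_total=2`` this removes singletons: OTUs with a
    single read in the entire data set.
    """
    return table.select_otus(table.otu_totals() >= min_total)


def remove_single_sample_otus(table, min_occupancy=2):
    """Drop OTUs detected (count > 0) in fewer than ``min_occupancy`` samples."""
    return table.select_otus(table.occupancy() >= min_occupancy)


def remove_taxon_group(table, taxonomy, group="Metazoa"):
    """Drop OTUs whose lineage contains ``group`` at any rank.

    OTUs absent from the taxonomy are retained: an unassigned OTU cannot be
    positively identified as a member of the excluded group.
    """
    keep = np.array(
        [not taxonomy.has_token(otu, group) for otu in table.otu_ids], dtype=bool
    )
    return table.select_otus(keep)


def curate(table, taxonomy=None, min_total=2, min_occupancy=2, exclude_taxon="Metazoa"):
    """Apply the standard curation chain in its documented order.

    Returns ``(curated_table, accounting)`` where ``accounting`` is a list
    of ``(stage_name, n_otus_after)`` entries, the initial table included.
    """
    accounting = [("input", table.n_otus)]
    table = remove_singletons(table, min_total=min_total)
    accounting.append(("min_total", table.n_otus))
    table = remove_single_sample_otus(table, min_occupancy=min_occupancy)
    accounting.append(("min_occupancy", table.n_otus))
    if taxonomy is not None and exclude_taxon:
        table = remove_taxon_group(table, taxonomy, group=exclude_taxon)
        accounting.append((f"exclude_{exclude_taxon}", table.n_otus))
    return table, accounting


def rarefy(table, depth, seed, drop_shallow=False):
    """Subsample every sample to exactly ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample (a single rarefaction,
    not an average over repeats).  Deterministic for a fixed ``seed``.

    Parameters
    ----------
    depth : int
        Target reads per sample; must be positive.
    seed : int
        RNG seed; mandatory so that runs are reproducible.
    drop_shallow : bool
        When True, samples with fewer than ``depth`` reads are dropped
        instead of raising.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be a positive integer")
    totals = table.sample_totals()
    shallow = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if shallow:
        if not drop_shallow:
            raise ValueError(
                f"samples with fewer than {depth} reads: {shallow} "
                "(pass drop_shallow=True to drop them)"
            )
        keep = [s for s in table.sample_ids if s not in set(shallow)]
        if not keep:
            raise ValueError("all samples are shallower than the requested depth")
        table = table.select_samples(keep)
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return CommunityTable(list(table.sample_ids), list(table.otu_ids), out)


@dataclass
class CompositionSummary:
    """Per-sample and mean taxonomic composition percentages.

    Attributes
    ----------
    read_percent : DataFrame, groups x samples
        Percentage of each sample's reads belonging to each group.
    otu_percent : DataFrame, groups x samples
        Percentage of the OTUs *detected in that sample* belonging to each
        group (per-sample denominators, so each column sums to 100).
    mean_read_percent, mean_otu_percent : Series
        Unweighted means of the per-sample percentages across samples.
    """

    read_percent: pd.DataFrame
    otu_percent: pd.DataFrame

    @property
    def mean_read_percent(self):
        return self.read_percent.mean(axis=1)

    @property
    def mean_otu_percent(self):
        return self.otu_percent.mean(axis=1)


UNASSIGNED = "unassigned"


def taxonomic_composition(table, taxonomy, rank_level):
    """Summarize read-% and OTU-% per taxonomic group at ``rank_level``.

    OTUs missing from the taxonomy (or whose lineage is shallower than
    ``rank_level``) are pooled into the ``"unassigned"`` group, so each
    sample's percentages sum to 100 over all groups.
    """
    if rank_level < 0:
        raise ValueError("rank_level must be >= 0")
    groups = []
    for otu in table.otu_ids:
        g = taxonomy.rank(otu, rank_level)
        groups.append(g if g is not None else UNASSIGNED)
    groups = np.asarray(groups, dtype=object)
    group_names = sorted(set(groups))
    totals = table.sample_totals().astype(float)
    if np.any(totals == 0):
        raise ValueError("cannot summarize composition of an empty sample")
    detected = (table.counts > 0).sum(axis=1).astype(float)
    read_rows = {}
    otu_rows = {}
    for g in group_names:
        mask = groups == g
        read_rows[g] = table.counts[:, mask].sum(axis=1) / totals * 100.0
        otu_rows[g] = (table.counts[:, mask] > 0).sum(axis=1) / detected * 100.0
    read_df = pd.DataFrame(read_rows, index=table.sample_ids).T
    otu_df = pd.DataFrame(otu_rows, index=table.sample_ids).T
    return CompositionSummary(read_percent=read_df, otu_percent=otu_df)
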