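"""Containers and file formats for community-ecology pipelines.

This module defines the in-memory objects the rest of the package operates
on — a samples-by-OTUs count table, a rooted phylogeny with branch lengths,
a sample metadata table and an OTU taxonomy map — together with strict,
tab-delimited readers and writers for each.

Conventions
-----------
* All text files are UTF-8, tab-delimited.  Lines starting with ``#`` are
  treated as comments and skipped (classic QIIME-era convention).
* OTU tables on disk default to rows = OTUs, columns = samples, the layout
  most legacy amplicon exports use; an ``otus_as_rows`` flag flips this.
* Trees are Newick with branch lengths.  Missing branch lengths are
  rejected by default because every downstream phylogenetic metric needs
  patristic distances; ``allow_missing_lengths=True`` converts them to 0
  with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "PhyloTree",
    "TaxonomyMap",
    "read_otu_table",
    "write_otu_table",
    "read_newick",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
]


def _check_unique(ids, what):
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CommunityTable:
    """Samples x OTUs matrix of non-negative integer read counts.

    Parameters
    ----------
    sample_ids : list of str
        Row labels, unique.
    otu_ids : list of str
        Column labels, unique.
    counts : ndarray of shape (n_samples, n_otus)
        Non-negative integers.  Zero OTUs is permitted (a filter may
        legitimately empty a table); zero samples is not.
    """

    sample_ids: list
    otu_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(self.sample_ids) < 1:
            raise ValueError("table must contain at least one sample")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if counts.size:
            if np.issubdtype(counts.dtype, np.floating):
                if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                    raise ValueError("counts must be integral")
            elif not np.issubdtype(counts.dtype, np.integer):
                raise ValueError("counts must be numeric integers")
            if np.any(counts < 0):
                raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self):
        return len(self.sample_ids)

    @property
    def n_otus(self):
        return len(self.otu_ids)

    def sample_totals(self):
        """Reads per sample, shape (n_samples,)."""
        return self.counts.sum(axis=1)

    def otu_totals(self):
        """Reads per OTU pooled over samples, shape (n_otus,)."""
        return self.counts.sum(axis=0)

    def occupancy(self):
        """Number of samples each OTU is detected in, shape (n_otus,)."""
        return (self.counts > 0).sum(axis=0)

    def presence(self):
        """Boolean detection matrix, shape (n_samples, n_otus)."""
        return self.counts > 0

    def proportions(self):
        """Within-sample relative abundances; rows sum to 1."""
        totals = self.sample_totals().astype(float)
        if np.any(totals == 0):
            empty = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValueError(f"samples with zero reads: {empty}")
        return self.counts / totals[:, None]

    # -- subsetting ------------------------------------------------------
    def select_otus(self, keep):
        """Return a new table restricted to OTUs where ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        idx = np.flatnonzero(keep)
        return CommunityTable(
            list(self.sample_ids),
            [self.otu_ids[i] for i in idx],
            self.counts[:, idx].copy(),
        )

    def select_samples(self, sample_ids):
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CommunityTable(list(sample_ids), list(self.otu_ids), self.counts[idx].copy())

    def to_dataframe(self):
        """Samples-by-OTUs DataFrame (index = sample ids)."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def copy(self):
        return CommunityTable(list(self.sample_ids), list(self.otu_ids), self.counts.copy())

    def __eq__(self, other):
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


def _read_tsv_rows(path):
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return rows


def read_otu_table(path, otus_as_rows=True):
    """Read a tab-separated OTU count table.

    The first column of each data row is an id; the header row carries the
    ids of the other axis.  With ``otus_as_rows=True`` (default) rows are
    OTUs and columns are samples; the returned table is always oriented
    samples x OTUs.
    """
    rows = _read_tsv_rows(path)
    header = rows[0]
    width = len(header)
    if width < 2:
        raise ValueError(f"{path}: header must contain at least one data column")
    col_ids = header[1:]
    row_ids = []
    data = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row {lineno}: expected {width} fields, got {len(row)}"
            )
        row_ids.append(row[0])
        vals = []
        for cell in row[1:]:
            try:
                v = int(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer count {cell!r} in row {lineno}"
                ) from None
            if v < 0:
                raise ValueError(f"{path}: negative count {v} in row {lineno}")
            vals.append(v)
        data.append(vals)
    counts = np.asarray(data, dtype=np.int64)
    if otus_as_rows:
        return CommunityTable(col_ids, row_ids, counts.T)
    return CommunityTable(row_ids, col_ids, counts)


def write_otu_table(table, path, otus_as_rows=True, id_header="OTU_ID"):
    """Write a :class:`CommunityTable` as TSV (inverse of :func:`read_otu_table`)."""
    with open(path, "w", encoding="utf-8") as fh:
        if otus_as_rows:
            fh.write("\t".join([id_header] + table.sample_ids) + "\n")
            for j, otu in enumerate(table.otu_ids):
                fh.write("\t".join([otu] + [str(c) for c in table.counts[:, j]]) + "\n")
        else:
            fh.write("\t".join(["sample_id"] + table.otu_ids) + "\n")
            for i, s in enumerate(table.sample_ids):
                fh.write("\t".join([s] + [str(c) for c in table.counts[i]]) + "\n")


class PhyloTree:
    """A rooted phylogeny with labeled tips and non-negative branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the
    invariants the downstream metrics rely on (unique tip labels, branch
    lengths present and >= 0) and exposes the two derived structures the
    package needs: the edge/tip incidence matrix (weighted UniFrac) and the
    tip-to-tip patristic distance matrix (betaMNTD).
    """

    def __init__(self, tree, allow_missing_lengths=False):
        if not isinstance(tree, dendropy.Tree):
            raise TypeError("tree must be a dendropy.Tree")
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if label is None or str(label) == "":
                raise ValueError("every tip must be labeled")
            labels.append(str(label))
        _check_unique(labels, "tip")
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        n_missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:  # the root's synthetic edge
                continue
            if edge.length is None:
                if not allow_missing_lengths:
                    raise ValueError(
                        "missing branch length (pass allow_missing_lengths=True "
                        "to treat as zero)"
                    )
                edge.length = 0.0
                n_missing += 1
            elif edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        if n_missing:
            warnings.warn(
                f"{n_missing} missing branch lengths treated as 0", stacklevel=2
            )
        self.tip_labels = labels

    @property
    def n_tips(self):
        return len(self.tip_labels)

    @property
    def dendropy_tree(self):
        return self._tree

    @classmethod
    def from_newick(cls, newick, allow_missing_lengths=False):
        if newick.count("(") != newick.count(")"):
            raise ValueError("unbalanced parentheses in Newick string")
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise ValueError(f"Newick parse error: {exc}") from exc
        return cls(tree, allow_missing_lengths=allow_missing_lengths)

    def as_newick(self):
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def write(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.as_newick() + "\n")

    # -- derived structures ---------------------------------------------
    def edge_matrix(self):
        """Edge lengths and the edge-by-tip incidence of the tree.

        Returns
        -------
        lengths : ndarray of shape (n_edges,)
        incidence : bool ndarray of shape (n_edges, n_tips)
            ``incidence[e, t]`` is True when tip ``t`` descends from edge
            ``e``.  Tips are ordered as :attr:`tip_labels`.  The root's
            synthetic edge is excluded.
        """
        tip_index = {lbl: i for i, lbl in enumerate(self.tip_labels)}
        n = self.n_tips
        lengths = []
        rows = []
        # postorder so each node's tip set is the union of its children's
        below = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon is not None else node.label
                mask = np.zeros(n, dtype=bool)
                mask[tip_index[str(label)]] = True
            else:
                mask = np.zeros(n, dtype=bool)
                for child in node.child_nodes():
                    mask |= below[child]
            below[node] = mask
            if node.edge.tail_node is not None:
                lengths.append(float(node.edge.length))
                rows.append(mask)
        return np.asarray(lengths, dtype=float), np.asarray(rows, dtype=bool)

    def patristic_matrix(self):
        """Tip-to-tip path-length (patristic) distance matrix.

        Uses the identity d(i, j) = depth_i + depth_j - 2 * shared(i, j)
        where depth is the root-to-tip path length and shared is the path
        length common to both tips, both read off the edge incidence.
        """
        lengths, inc = self.edge_matrix()
        incf = inc.astype(float)
        shared = incf.T @ (lengths[:, None] * incf)
        depth = np.diag(shared)
        dist = depth[:, None] + depth[None, :] - 2.0 * shared
        dist[dist < 0] = 0.0  # clip numerical noise
        np.fill_diagonal(dist, 0.0)
        return list(self.tip_labels), dist


def read_newick(path, allow_missing_lengths=False):
    """Read a rooted Newick tree with branch lengths from ``path``."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    return PhyloTree.from_newick(text, allow_missing_lengths=allow_missing_lengths)


_SAMPLE_COLS = ("sample_id", "sample", "#sampleid", "id")
_DEPTH_COLS = ("depth_m", "depth", "depth (m)", "water_depth_m")


def read_metadata(path):
    """Read a sample metadata TSV into a DataFrame indexed by sample id.

    The header must contain a sample-id column and a depth column (meters);
    latitude/longitude columns are carried through when present.  Depths
    may contain thousands separators ("2,939"); they must parse to a
    positive number.
    """
    rows = _read_tsv_rows(path)
    header = [h.strip() for h in rows[0]]
    lower = [h.lower() for h in header]

    def find(cands):
        for c in cands:
            if c in lower:
                return lower.index(c)
        return None

    si = find(_SAMPLE_COLS)
    di = find(_DEPTH_COLS)
    if si is None or di is None:
        raise ValueError(
            f"{path}: metadata header must include a sample id and a depth column; got {header}"
        )
    records = {}
    extra_cols = [
        (k, lower.index(k)) for k in ("latitude", "longitude") if k in lower
    ]
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(f"{path}: ragged row {lineno}")
        sid = row[si].strip()
        if sid in records:
            raise ValueError(f"{path}: duplicate sample id {sid!r}")
        raw = row[di].strip().replace(",", "")
        try:
            depth = float(raw)
        except ValueError:
            raise ValueError(
                f"{path}: cannot parse depth {row[di]!r} for sample {sid!r}"
            ) from None
        if not math.isfinite(depth) or depth <= 0:
            raise ValueError(f"{path}: depth must be positive, got {depth} for {sid!r}")
        rec = {"depth_m": depth}
        for name, ci in extra_cols:
            try:
                rec[name] = float(row[ci])
            except ValueError:
                rec[name] = np.nan
        records[sid] = rec
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "sample_id"
    return df


def write_metadata(metadata, path):
    metadata.to_csv(path, sep="\t", index=True)


@dataclass
class TaxonomyMap:
    """Mapping from OTU id to an ordered, ranked lineage.

    Lineages are tuples of rank names ordered from the broadest rank down
    (e.g. ``("Rhizaria", "Cercozoa", "Thecofilosea")``).  OTUs absent from
    the map are simply unknown, not errors.
    """

    lineages: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for otu, lineage in self.lineages.items():
            lineage = tuple(str(t).strip() for t in lineage)
            if not lineage or any(t == "" for t in lineage):
                raise ValueError(f"empty lineage for OTU {otu!r}")
            clean[str(otu)] = lineage
        self.lineages = clean

    def __contains__(self, otu):
        return otu in self.lineages

    def __len__(self):
        return len(self.lineages)

    def lineage(self, otu):
        return self.lineages.get(otu)

    def rank(self, otu, level):
        """Rank name at ``level`` (0-based), or None when unknown/too shallow."""
        lineage = self.lineages.get(otu)
        if lineage is None or level >= len(lineage):
            return None
        return lineage[level]

    def has_token(self, otu, token):
        """True when ``token`` appears at any level of the OTU's lineage."""
        lineage = self.lineages.get(otu)
        return lineage is not None and token in lineage


def read_taxonomy(path):
    """Read a two-column TSV of otu_id -> semicolon-delimited lineage."""
    rows = _read_tsv_rows(path)
    start = 0
    if rows and rows[0] and rows[0][0].strip().lower() in ("otu_id", "otu", "feature_id"):
        start = 1
    lineages = {}
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 2:
            raise ValueError(f"{path}: row {lineno} lacks a lineage column")
        otu = row[0].strip()
        if otu in lineages:
            raise ValueError(f"{path}: duplicate OTU id {otu!r}")
        tokens = [t.strip() for t in row[1].split(";") if t.strip() != ""]
        if not tokens:
            raise ValueError(f"{path}: empty lineage for OTU {otu!r} (row {lineno})")
        lineages[otu] = tuple(tokens)
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, lineage in taxonomy.lineages.items():
            fh.write(f"{otu}\t{';'.join(lineage)}\n")
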