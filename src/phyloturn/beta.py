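"""Beta diversity: Bray-Curtis, weighted UniFrac, PCoA, Mantel test,
and depth-decay regression.

Distance matrices are symmetric with an exactly-zero diagonal.  The
Raup-Crick metric reuses this container with entries in [-1, 1], so
non-negativity is deliberately not enforced here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy import stats

__all__ = [
    "DistanceMatrix",
    "bray_curtis",
    "weighted_unifrac",
    "pcoa",
    "OrdinationResult",
    "mantel",
    "MantelResult",
    "depth_distance",
    "axis_regression",
]

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise sample dissimilarities."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if np.max(np.abs(v - v.T), initial=0.0) > _SYM_TOL:
            raise ValueError("matrix is not symmetric")
        if np.max(np.abs(np.diag(v)), initial=0.0) > _SYM_TOL:
            raise ValueError("diagonal must be zero")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self):
        return len(self.ids)

    def condensed(self):
        """Upper-triangle entries in scipy ``squareform`` order."""
        return squareform(self.values, checks=False)

    def pair(self, a, b):
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def reorder(self, ids):
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"ids not in matrix: {missing}")
        idx = [pos[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self):
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path):
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def bray_curtis(table):
    """Pairwise Bray-Curtis dissimilarity on raw counts.

    BC(A, B) = sum_i |a_i - b_i| / sum_i (a_i + b_i), in [0, 1].
    """
    totals = table.sample_totals()
    if np.any(totals == 0):
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"empty samples: {empty}")
    x = table.counts.astype(float)
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        tot = (x[i] + x[i + 1 :]).sum(axis=1)
        out[i, i + 1 :] = diff / tot
    out = out + out.T
    return DistanceMatrix(list(table.sample_ids), out)


def weighted_unifrac(table, tree, normalized=False):
    """Abundance-weighted UniFrac distance between every pair of samples.

    Raw (default) form: ``sum_b l_b * |p_A(b) - p_B(b)]`` over the tree's
    branches, where ``p_X(b)`` is the fraction of sample X's reads whose
    OTUs descend from branch ``b``.  The normalized form divides by
    ``sum_b l_b * (p_A(b) + p_B(b))``, bounding the metric by 1.

    Every OTU with a non-zero count must be a tip of ``tree``.
    """
    present = np.asarray(table.otu_ids)[table.otu_totals() > 0]
    tipset = set(tree.tip_labels)
    missing = [o for o in present if o not in tipset]
    if missing:
        raise KeyError(f"OTUs not found in tree: {missing}")
    lengths, inc = tree.edge_matrix()
    # map table columns onto the tree's tip order; absent tips get weight 0
    col = {o: j for j, o in enumerate(table.otu_ids)}
    props = table.proportions()
    p_tips = np.zeros((table.n_samples, tree.n_tips))
    for t, label in enumerate(tree.tip_labels):
        j = col.get(label)
        if j is not None:
            p_tips[:, t] = props[:, j]
    # per-branch descending proportion for every sample: (S, E)
    p_branch = p_tips @ inc.T.astype(float)
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = float(np.sum(lengths * np.abs(p_branch[i] - p_branch[j])))
            if normalized:
                den = float(np.sum(lengths * (p_branch[i] + p_branch[j])))
                out[i, j] = num / den if den > 0 else 0.0
            else:
                out[i, j] = num
    out = out + out.T
    return DistanceMatrix(list(table.sample_ids), out)


@dataclass
class OrdinationResult:
    """Principal coordinates of a distance matrix.

    ``eigenvalues`` holds the full spectrum in descending order, negative
    values included (a diagnostic for non-Euclidean input, not corrected).
    ``coordinates`` has one column per strictly positive eigenvalue;
    ``proportion_explained`` is computed over the positive part only.
    """

    ids: list
    eigenvalues: np.ndarray
    coordinates: np.ndarray
    proportion_explained: np.ndarray

    def axis(self, k):
        return self.coordinates[:, k]


def pcoa(dm):
    """Classical (metric) multidimensional scaling / PCoA.

    Gower double-centering of -0.5 * D^2 followed by an eigendecomposition.
    Axis signs are canonicalized by making the largest-magnitude coordinate
    on each axis positive, so repeated runs are bit-identical.
    """
    d = dm.values
    n = dm.n
    b = -0.5 * d * d
    row_mean = b.mean(axis=1, keepdims=True)
    col_mean = b.mean(axis=0, keepdims=True)
    b = b - row_mean - col_mean + b.mean()
    evals, evecs = np.linalg.eigh(0.5 * (b + b.T))
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > max(1e-12, 1e-12 * abs(evals[0]) if n else 0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    # canonical signs: largest |loading| per axis is positive
    for k in range(coords.shape[1]):
        jmax = int(np.argmax(np.abs(coords[:, k])))
        if coords[jmax, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = evals[pos].sum()
    prop = np.where(pos, evals, 0.0) / pos_sum if pos_sum > 0 else np.zeros(n)
    return OrdinationResult(
        ids=list(dm.ids),
        eigenvalues=evals,
        coordinates=coords,
        proportion_explained=prop[pos],
    )


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    exhaustive: bool


def _pearson_condensed(x, y):
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float((x * x).sum()) * float((y * y).sum()))
    if denom == 0:
        raise ValueError("zero variance in distance entries")
    return float((x * y).sum()) / denom


def mantel(dm1, dm2, n_permutations=999, seed=0):
    """Mantel test of matrix correlation with a one-sided permutation null.

    The statistic is the Pearson correlation of the two condensed
    (upper-triangle) distance vectors.  The null permutes the sample
    labels of ``dm2``.  When n! does not exceed ``n_permutations`` all n!
    relabelings are enumerated (identity included) and
    p = #(r_perm >= r_obs) / n!; otherwise ``n_permutations`` Monte-Carlo
    permutations are drawn and p = (1 + #(r_perm >= r_obs)) / (1 + n_perm).
    """
    if dm1.ids != dm2.ids:
        if set(dm1.ids) != set(dm2.ids):
            raise ValueError("distance matrices have different ids")
        dm2 = dm2.reorder(dm1.ids)
    n = dm1.n
    if n < 3:
        raise ValueError("Mantel test needs at least 3 samples")
    x = dm1.condensed()
    m2 = dm2.values
    r_obs = _pearson_condensed(x, squareform(m2, checks=False))
    exhaustive = math.factorial(n) <= n_permutations
    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            perm = np.asarray(perm)
            y = squareform(m2[np.ix_(perm, perm)], checks=False)
            if _pearson_condensed(x, y) >= r_obs:
                count += 1
            total += 1
        p = count / total
        return MantelResult(r=r_obs, p=p, n_permutations=total, exhaustive=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        y = squareform(m2[np.ix_(perm, perm)], checks=False)
        if _pearson_condensed(x, y) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(r=r_obs, p=p, n_permutations=n_permutations, exhaustive=False)


def depth_distance(metadata, sample_ids=None, log_depth=False):
    """Pairwise absolute water-depth differences (meters) between samples."""
    if sample_ids is None:
        sample_ids = list(metadata.index)
    missing = [s for s in sample_ids if s not in metadata.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    depth = metadata.loc[sample_ids, "depth_m"].to_numpy(dtype=float)
    if np.any(~np.isfinite(depth)):
        raise ValueError("non-finite depth values")
    if log_depth:
        depth = np.log10(depth)
    vals = np.abs(depth[:, None] - depth[None, :])
    return DistanceMatrix(list(sample_ids), vals)


def axis_regression(ordination, metadata, axis=0, log_depth=False):
    """OLS of a PCoA axis on water depth; returns (r_squared, p_value).

    p is the two-sided test of the Pearson coefficient.
    """
    if axis >= ordination.coordinates.shape[1]:
        raise ValueError(f"axis {axis} not available")
    coords = ordination.axis(axis)
    if np.allclose(coords.std(), 0):
        raise ValueError("zero-variance ordination axis")
    depth = metadata.loc[ordination.ids, "depth_m"].to_numpy(dtype=float)
    if log_depth:
        depth = np.log10(depth)
    res = stats.linregress(depth, coords)
    return float(res.rvalue**2), float(res.pvalue)
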