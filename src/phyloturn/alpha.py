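"""Alpha diversity: observed richness, Chao1, Shannon, rarefaction curves.

All estimators operate on a single sample's count vector.  The pipeline
computes them on a table already rarefied to a common depth so that
richness comparisons across samples are not confounded by sequencing
effort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "shannon",
    "chao1",
    "alpha_table",
    "rarefaction_curve",
    "expected_richness",
    "RarefactionCurve",
    "AlphaRecord",
]


def _clean(counts):
    counts = np.asarray(counts)
    if counts.size == 0 or np.all(counts == 0):
        raise ValueError("count vector must contain at least one positive count")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return counts[counts > 0].astype(float)


def shannon(counts, base=None):
    """Shannon diversity H = -sum p_i log p_i over non-zero counts.

    Natural log by default (nats); pass ``base=2`` for bits.
    """
    c = _clean(counts)
    p = c / c.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts, bias_corrected=True):
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form (default): ``S_obs + F1*(F1-1) / (2*(F2+1))``
    where F1 and F2 are the numbers of OTUs with exactly 1 and 2 reads in
    the sample.  The classic form ``S_obs + F1^2 / (2*F2)`` is available
    with ``bias_corrected=False`` (it falls back to the corrected form
    when F2 = 0, where it is undefined).
    """
    c = _clean(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected or f2 == 0:
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    return float(s_obs + f1 * f1 / (2.0 * f2))


@dataclass
class AlphaRecord:
    sample_id: str
    observed_otus: int
    chao1: float
    shannon: float


def alpha_table(table):
    """Per-sample observed OTUs, Chao1 and Shannon as a DataFrame."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        rows.append(
            {
                "sample_id": sid,
                "observed_otus": int((c > 0).sum()),
                "chao1": chao1(c),
                "shannon": shannon(c),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class RarefactionCurve:
    sample_id: str
    depths: np.ndarray
    mean_observed: np.ndarray
    sd_observed: np.ndarray
    n_reps: int
    seed: int


def rarefaction_curve(table, depths, n_reps=10, seed=0):
    """Mean observed-OTU count at each subsampling depth, per sample.

    For each sample and each depth not exceeding that sample's total,
    ``n_reps`` independent without-replacement subsamples are drawn and
    the number of OTUs observed is averaged.  Depths larger than a
    sample's total are skipped for that sample.
    """
    depths = sorted(int(d) for d in depths)
    if not depths:
        raise ValueError("depth list must be non-empty")
    if depths[0] <= 0:
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(seed)
    curves = []
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        total = int(counts.sum())
        usable = [d for d in depths if d <= total]
        means = np.empty(len(usable))
        sds = np.empty(len(usable))
        for k, d in enumerate(usable):
            obs = np.empty(n_reps)
            for r in range(n_reps):
                sub = rng.multivariate_hypergeometric(counts, d)
                obs[r] = (sub > 0).sum()
            means[k] = obs.mean()
            sds[k] = obs.std(ddof=1) if n_reps > 1 else 0.0
        curves.append(
            RarefactionCurve(sid, np.asarray(usable), means, sds, n_reps, seed)
        )
    return curves


def expected_richness(counts, depth):
    """Analytic expected number of OTUs observed in a subsample of ``depth``.

    Hypergeometric inclusion probability: E[S] = sum_i (1 - C(T-c_i, d)/C(T, d)),
    evaluated in log space for numerical stability.
    """
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = counts.sum()
    if depth > total:
        raise ValueError("depth exceeds sample total")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    denom = log_comb(total, depth)
    p_absent = np.zeros(counts.size)
    feasible = total - counts >= depth
    p_absent[feasible] = np.exp(log_comb(total - counts[feasible], depth) - denom)
    return float((1.0 - p_absent).sum())


def curves_to_frame(curves):
    """Long-format DataFrame (sample, depth, mean, sd) for serialization."""
    rows = []
    for cv in curves:
        for d, m, s in zip(cv.depths, cv.mean_observed, cv.sd_observed):
            rows.append({"sample_id": cv.sample_id, "depth": int(d), "mean": m, "sd": s})
    return pd.DataFrame(rows)
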