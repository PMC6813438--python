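"""Synthetic phylogenies and OTU tables under known assembly regimes.

The generator emulates a small benthic amplicon survey — a handful of
samples along a water-depth gradient, a few hundred OTUs, equal read
depth per sample — while controlling which assembly process produced the
between-sample turnover, so that the null-model pipeline can be tested
against a known answer.

Generative model
----------------
*   Phylogeny: a Yule (pure-birth) tree with ``n_tips`` tips.
*   Niche traits: Brownian motion along the tree (variance rate
    ``bm_sigma2``), so close relatives have similar environmental optima —
    the phylogenetic signal that betaNTI requires.
*   Metacommunity abundances: log-normal, shared by all samples.
*   Per-sample expected relative abundances ``lambda`` depend on the
    regime (see :func:`simulate_community`); observed counts are one
    multinomial draw of ``reads_per_sample`` reads per sample.

The environmental axis is interpreted as water depth in meters; the
default gradient spans 79-2,939 m over six samples, a typical basin-scale
benthic design.  Depth values are affinely rescaled onto the realized
trait range so that the niche breadth ``sigma_w`` is expressed in trait
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .io import CommunityTable, PhyloTree, TaxonomyMap

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_community",
    "simulate_dataset",
    "toy_taxonomy",
    "REGIMES",
    "DEFAULT_DEPTHS_M",
]

REGIMES = ("selection", "dispersal_limitation", "mass_effects", "neutral_drift")

# a six-station basin-scale depth gradient (meters), shallow shelf to deep basin
DEFAULT_DEPTHS_M = (79.0, 880.0, 1250.0, 1469.0, 2801.0, 2939.0)


def simulate_yule_tree(n_tips, birth_rate=1.0, seed=0):
    """Simulate a rooted pure-birth (Yule) tree with ``n_tips`` tips.

    Starting from two lineages at the root, each waiting time is
    exponential with rate ``k * birth_rate`` for ``k`` extant lineages; a
    uniformly chosen lineage then splits.  After the last split every
    pendant branch is extended by one more exponential waiting time, so
    no tip subtends a zero-length branch.  The tree is ultrametric with
    branch lengths in units of 1/``birth_rate``.
    """
    n_tips = int(n_tips)
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    active = [root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)]
    while len(active) < n_tips:
        k = len(active)
        dt = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node.edge.length += dt
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        active.append(parent.new_child(edge_length=0.0))
        active.append(parent.new_child(edge_length=0.0))
    dt = rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node.edge.length += dt
    labels = [f"OTU{i + 1:04d}" for i in range(n_tips)]
    order = rng.permutation(n_tips)
    leaves = [nd for nd in tree.leaf_node_iter()]
    for leaf, k in zip(leaves, order):
        leaf.taxon = tree.taxon_namespace.new_taxon(label=labels[k])
    return PhyloTree(tree)


def simulate_bm_traits(tree, sigma2=1.0, root_value=0.0, seed=0):
    """Evolve a continuous trait along ``tree`` by Brownian motion.

    Each branch adds an independent Gaussian increment with variance
    ``sigma2 * branch_length``.  Returns ``{tip_label: trait_value}``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    values = {}
    traits = {}
    for node in dtree.preorder_node_iter():
        if node.edge.tail_node is None:
            values[node] = float(root_value)
        else:
            parent = values[node.edge.tail_node]
            step = rng.normal(0.0, np.sqrt(sigma2 * float(node.edge.length)))
            values[node] = parent + step
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            traits[str(label)] = values[node]
    return traits


@dataclass
class SimulationConfig:
    """Parameters of one synthetic survey.

    Defaults mirror a small benthic amplicon study: 6 samples along a
    79-2,939 m depth gradient, ~400 OTUs before curation, 5,792 reads per
    sample.

    Attributes
    ----------
    n_tips : int
        Tips of the simulated phylogeny (= OTU pool size).
    birth_rate : float
        Yule speciation rate; sets the tree's time scale.
    bm_sigma2 : float
        Brownian-motion variance rate of the niche trait.
    n_samples : int
    env_values : tuple of float or None
        Water depth (m) per sample; None uses the default 6-station
        gradient (or an even grid over the same range for other n).
    niche_breadth : float or None
        Gaussian niche width sigma_w in trait units (selection regime).
        None uses 0.05x the realized trait range — a narrow niche that
        produces strong species sorting.
    reads_per_sample : int
        Multinomial read depth N per sample.
    regime : str
        One of ``selection``, ``dispersal_limitation``, ``mass_effects``,
        ``neutral_drift``.
    n_region_pools : int
        Number of disjoint regional species pools (dispersal regime).
    lognormal_sigma : float
        sigma of the log-normal metacommunity abundance distribution.
    drift_alpha : float
        Gamma concentration of per-sample abundance perturbation in the
        drift regime (mean 1, variance 1/alpha): independent local
        birth/death fluctuation around the shared metacommunity.
    mass_jitter : float
        Fraction of reads resampled per sample in the mass-effects
        regime; the rest of the community is copied verbatim from one
        shared realization (near-complete homogenization).
    seed : int
    """

    n_tips: int = 400
    birth_rate: float = 1.0
    bm_sigma2: float = 1.0
    n_samples: int = 6
    env_values: tuple = None
    niche_breadth: float = None
    reads_per_sample: int = 5792
    regime: str = "neutral_drift"
    n_region_pools: int = 2
    lognormal_sigma: float = 1.0
    drift_alpha: float = 200.0
    mass_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.reads_per_sample < self.n_tips and self.regime != "selection":
            # only regimes spreading reads over the whole pool need N >= n_tips
            pass
        if self.env_values is None:
            if self.n_samples == len(DEFAULT_DEPTHS_M):
                self.env_values = DEFAULT_DEPTHS_M
            else:
                lo, hi = DEFAULT_DEPTHS_M[0], DEFAULT_DEPTHS_M[-1]
                self.env_values = tuple(np.linspace(lo, hi, self.n_samples))
        self.env_values = tuple(float(e) for e in self.env_values)
        if len(self.env_values) != self.n_samples:
            raise ValueError("env_values length must equal n_samples")
        for name in ("birth_rate", "bm_sigma2", "lognormal_sigma", "drift_alpha"):
            if getattr(self, name) <= 0 and not (name == "bm_sigma2" and self.bm_sigma2 == 0):
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.mass_jitter < 1:
            raise ValueError("mass_jitter must be in [0, 1)")

    def sample_ids(self):
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated table: regime, per-pair expected label.

    Labels are regime-level expectations (what a perfect classifier should
    say for that pair), not per-realization guarantees.
    """

    regime: str
    pair_labels: pd.DataFrame  # sample_a, sample_b, expected_process
    sample_env: dict
    sample_pool: dict
    params: dict


def _pair_frame(sample_ids, label_fn):
    rows = []
    for i in range(len(sample_ids)):
        for j in range(i + 1, len(sample_ids)):
            a, b = sample_ids[i], sample_ids[j]
            rows.append({"sample_a": a, "sample_b": b, "expected_process": label_fn(a, b)})
    return pd.DataFrame(rows)


def simulate_community(tree, traits, config):
    """Draw one OTU table under ``config.regime``; returns (table, truth).

    Expected relative abundances per sample:

    * ``selection``: lambda_ik ~ m_i * exp(-(t_i - e_k)^2 / (2 sigma_w^2))
      with m the log-normal metacommunity abundance, t the Brownian trait
      and e the depth gradient rescaled to trait units.
    * ``neutral_drift``: lambda_ik ~ m_i * g_ik with g ~ Gamma(alpha,
      1/alpha) i.i.d. — shared metacommunity plus independent local
      abundance fluctuation.
    * ``mass_effects``: one shared realized community; each sample copies
      it and resamples only a ``mass_jitter`` fraction of reads, leaving
      the samples more similar than independent draws could be.
    * ``dispersal_limitation``: tips are split into ``n_region_pools``
      random pools (independent of the trait); each sample draws only
      from its region's pool with neutral weights within the pool.
    """
    rng = np.random.default_rng(config.seed)
    tips = list(tree.tip_labels)
    missing = [t for t in tips if t not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:5]}...")
    n_taxa = len(tips)
    n = config.n_samples
    big_n = int(config.reads_per_sample)
    sample_ids = config.sample_ids()
    env = np.asarray(config.env_values, dtype=float)
    m = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n_taxa)
    m /= m.sum()
    sample_pool = {s: 0 for s in sample_ids}

    if config.regime == "selection":
        t = np.asarray([traits[x] for x in tips], dtype=float)
        t_lo, t_hi = float(t.min()), float(t.max())
        # map depth onto trait *quantiles* so every optimum sits in occupied
        # trait space (a linear map onto the range would strand the gradient
        # extremes in the sparse tails of the Brownian trait distribution)
        if env.max() > env.min():
            q = 0.10 + 0.80 * (env - env.min()) / (env.max() - env.min())
            e_scaled = np.quantile(t, q)
        else:
            e_scaled = np.full(n, float(np.median(t)))
        sigma_w = config.niche_breadth
        if sigma_w is None:
            sigma_w = 0.05 * (t_hi - t_lo)
        if sigma_w <= 0:
            raise ValueError("niche_breadth must be positive under selection")
        lam = m[None, :] * np.exp(
            -((t[None, :] - e_scaled[:, None]) ** 2) / (2.0 * sigma_w**2)
        )
        counts = np.vstack(
            [rng.multinomial(big_n, row / row.sum()) for row in lam]
        )
        env_of = dict(zip(sample_ids, env))
        truth_df = _pair_frame(
            sample_ids,
            lambda a, b: "species_sorting" if env_of[a] != env_of[b] else "drift",
        )

    elif config.regime == "neutral_drift":
        g = rng.gamma(shape=config.drift_alpha, scale=1.0 / config.drift_alpha, size=(n, n_taxa))
        lam = m[None, :] * g
        counts = np.vstack([rng.multinomial(big_n, row / row.sum()) for row in lam])
        truth_df = _pair_frame(sample_ids, lambda a, b: "drift")

    elif config.regime == "mass_effects":
        base = rng.multinomial(big_n, m)
        counts = np.empty((n, n_taxa), dtype=np.int64)
        k = int(round(config.mass_jitter * big_n))
        for i in range(n):
            kept = rng.multivariate_hypergeometric(base, big_n - k) if k else base.copy()
            added = rng.multinomial(k, m) if k else 0
            counts[i] = kept + added
        truth_df = _pair_frame(sample_ids, lambda a, b: "mass_effects")

    elif config.regime == "dispersal_limitation":
        pools = rng.integers(0, config.n_region_pools, size=n_taxa)
        # guarantee every pool is non-empty
        for p in range(config.n_region_pools):
            if not np.any(pools == p):
                pools[rng.integers(n_taxa)] = p
        sample_pool = {
            s: (i * config.n_region_pools) // n for i, s in enumerate(sample_ids)
        }
        counts = np.empty((n, n_taxa), dtype=np.int64)
        for i, s in enumerate(sample_ids):
            mask = pools == sample_pool[s]
            lam = np.where(mask, m, 0.0)
            counts[i] = rng.multinomial(big_n, lam / lam.sum())
        truth_df = _pair_frame(
            sample_ids,
            lambda a, b: "dispersal_limitation"
            if sample_pool[a] != sample_pool[b]
            else "drift",
        )
    else:  # pragma: no cover - guarded by SimulationConfig
        raise ValueError(f"unknown regime {config.regime!r}")

    table = CommunityTable(sample_ids, tips, counts)
    truth = SyntheticTruth(
        regime=config.regime,
        pair_labels=truth_df,
        sample_env=dict(zip(sample_ids, env)),
        sample_pool=sample_pool,
        params=asdict(config),
    )
    return table, truth


def simulate_dataset(config):
    """Tree + traits + table + metadata in one call.

    Sub-seeds for the tree, the traits and the community are derived from
    ``config.seed`` so the whole dataset is reproducible from one integer.

    Returns ``(table, tree, metadata, truth)`` where ``metadata`` is a
    DataFrame indexed by sample id with a ``depth_m`` column.
    """
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_traits, s_comm = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    tree = simulate_yule_tree(config.n_tips, config.birth_rate, seed=s_tree)
    traits = simulate_bm_traits(tree, config.bm_sigma2, seed=s_traits)
    comm_config = SimulationConfig(**{**asdict(config), "seed": s_comm})
    table, truth = simulate_community(tree, traits, comm_config)
    truth.params = asdict(config)
    metadata = pd.DataFrame(
        {"depth_m": list(config.env_values)}, index=config.sample_ids()
    )
    metadata.index.name = "sample_id"
    return table, tree, metadata, truth


_TOY_GROUPS = (
    ("Rhizaria", "Cercozoa"),
    ("Alveolata", "Dinoflagellata"),
    ("Opisthokonta", "Fungi"),
    ("Stramenopiles", "stramenopiles_X"),
    ("Rhizaria", "Radiolaria"),
)


def toy_taxonomy(otu_ids, metazoa_fraction=0.1, seed=0):
    """Toy ranked lineages for filter tests: a few protist groups plus a
    ``metazoa_fraction`` of OTUs tagged Opisthokonta;Metazoa."""
    rng = np.random.default_rng(seed)
    lineages = {}
    for otu in otu_ids:
        if rng.random() < metazoa_fraction:
            lineages[otu] = ("Opisthokonta", "Metazoa")
        else:
            lineages[otu] = _TOY_GROUPS[int(rng.integers(len(_TOY_GROUPS)))]
    return TaxonomyMap(lineages)
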