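"""End-to-end pipeline: curation -> rarefaction -> diversity -> null models.

The stage order is fixed and mirrors standard amplicon practice: rare-OTU
filters first (singletons, then single-sample OTUs, then taxon exclusion),
rarefaction to a common depth, alpha diversity on the rarefied table, then
the phylogenetic beta-diversity block (weighted UniFrac, PCoA, Mantel
against depth) and finally the betaNTI / RC_bray process partition.  All
randomness flows from one master seed; rerunning the same config is
bit-identical.
"""

from __future__ import annotations

import logging
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import alpha as alpha_mod
from . import assembly as assembly_mod
from . import beta as beta_mod
from . import filters as filters_mod
from . import io as io_mod

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("phyloturn")


@dataclass
class PipelineConfig:
    otu_table: str
    tree: str
    metadata: str
    taxonomy: str = None
    outdir: str = "phyloturn_out"
    otus_as_rows: bool = True
    depth: int = 5792
    reps: int = 999
    mantel_permutations: int = 999
    seed: int = 0
    min_total: int = 2
    min_occupancy: int = 2
    exclude_taxon: str = "Metazoa"
    normalized_unifrac: bool = False
    abundance_weighted: bool = True
    log_depth: bool = False
    drop_shallow: bool = False

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.reps <= 0 or self.mantel_permutations <= 0:
            raise ValueError("replicate counts must be positive")
        for name in ("otu_table", "tree", "metadata"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.taxonomy is not None and not Path(self.taxonomy).exists():
            raise FileNotFoundError(f"taxonomy file not found: {self.taxonomy}")


def load_config(path, **overrides):
    """Read a flat TOML config file; keyword arguments override file keys."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _stage(name, log):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.error("stage %s: FAILED: %s", name, exc)
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_pipeline(config):
    """Execute every stage and write TSV outputs under ``config.outdir``.

    Returns a dict of the in-memory results keyed by stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results = {}
    try:
        logger.info("phyloturn %s", __version__)
        for k, v in asdict(config).items():
            logger.info("config %s = %r", k, v)
        ss = np.random.SeedSequence(config.seed)
        seed_rarefy, seed_assembly = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)
        )

        with _stage("read_inputs", logger):
            table = io_mod.read_otu_table(config.otu_table, otus_as_rows=config.otus_as_rows)
            tree = io_mod.read_newick(config.tree)
            metadata = io_mod.read_metadata(config.metadata)
            taxonomy = (
                io_mod.read_taxonomy(config.taxonomy) if config.taxonomy else None
            )
            missing = [s for s in table.sample_ids if s not in metadata.index]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing}")

        with _stage("filters", logger):
            table, accounting = filters_mod.curate(
                table,
                taxonomy,
                min_total=config.min_total,
                min_occupancy=config.min_occupancy,
                exclude_taxon=config.exclude_taxon,
            )
            for stage_name, n_otus in accounting:
                logger.info("filter accounting: %s -> %d OTUs", stage_name, n_otus)
            io_mod.write_otu_table(table, outdir / "filtered_table.tsv")
            results["accounting"] = accounting

        with _stage("rarefy", logger):
            table = filters_mod.rarefy(
                table, config.depth, seed=seed_rarefy, drop_shallow=config.drop_shallow
            )
            io_mod.write_otu_table(table, outdir / "rarefied_table.tsv")
            results["table"] = table

        with _stage("alpha", logger):
            alpha_df = alpha_mod.alpha_table(table)
            alpha_df.to_csv(outdir / "alpha.tsv", sep="\t")
            results["alpha"] = alpha_df

        with _stage("beta", logger):
            bc = beta_mod.bray_curtis(table)
            bc.to_tsv(outdir / "braycurtis.tsv")
            wu = beta_mod.weighted_unifrac(table, tree, normalized=config.normalized_unifrac)
            wu.to_tsv(outdir / "wunifrac.tsv")
            results["braycurtis"] = bc
            results["wunifrac"] = wu

        with _stage("ordination", logger):
            ordination = beta_mod.pcoa(wu)
            coords = pd.DataFrame(
                ordination.coordinates,
                index=ordination.ids,
                columns=[f"PCo{k + 1}" for k in range(ordination.coordinates.shape[1])],
            )
            coords.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t", index_label="sample_id")
            pd.DataFrame(
                {
                    "eigenvalue": ordination.eigenvalues,
                }
            ).to_csv(outdir / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis")
            results["pcoa"] = ordination
            r2, p_reg = beta_mod.axis_regression(
                ordination, metadata, axis=0, log_depth=config.log_depth
            )
            results["axis_regression"] = (r2, p_reg)
            logger.info("PCo1 ~ depth: r2 = %.4f, p = %.4g", r2, p_reg)

        with _stage("mantel", logger):
            dd = beta_mod.depth_distance(
                metadata, sample_ids=list(table.sample_ids), log_depth=config.log_depth
            )
            mres = beta_mod.mantel(
                wu, dd, n_permutations=config.mantel_permutations, seed=config.seed
            )
            pd.DataFrame(
                [
                    {
                        "r": mres.r,
                        "p": mres.p,
                        "n_permutations": mres.n_permutations,
                        "exhaustive": mres.exhaustive,
                        "r_squared_pco1": results["axis_regression"][0],
                        "p_pco1": results["axis_regression"][1],
                    }
                ]
            ).to_csv(outdir / "mantel.tsv", sep="\t", index=False)
            results["mantel"] = mres
            logger.info(
                "Mantel r = %.4f, p = %.4g (%d permutations, exhaustive=%s)",
                mres.r,
                mres.p,
                mres.n_permutations,
                mres.exhaustive,
            )

        with _stage("assembly", logger):
            ares = assembly_mod.analyze_assembly(
                table,
                tree,
                n_reps=config.reps,
                seed=seed_assembly,
                abundance_weighted=config.abundance_weighted,
            )
            records = ares.records.assign(package_version=__version__)
            records.to_csv(outdir / "assembly_pairs.tsv", sep="\t", index=False)
            part = ares.partition.to_frame().assign(
                seed=config.seed, reps=config.reps, package_version=__version__
            )
            part.to_csv(outdir / "partition.tsv", sep="\t", index=False)
            results["assembly"] = ares
            for k in assembly_mod.PROCESS_LABELS:
                logger.info(
                    "partition %s: %d pairs (%.1f%%)",
                    k,
                    ares.partition.counts[k],
                    ares.partition.percentages[k],
                )
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results
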