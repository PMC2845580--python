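"""Jackknife branch support: resample OG pairs, rebuild trees, take consensus.

Each replicate independently removes a fraction (default e^-1 ~ 36.8%) of
every genome's OG pairs while preserving the relative order of survivors,
recomputes the distance matrix and tree, and the replicates are summarized
as a majority-rule consensus with percentage supports.  RNG substreams are
keyed by (seed, replicate, genome), so replicates are order-independent.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, replace

import numpy as np

from .distance import OGDistanceParams, distance_matrix
from .og_identify import OGPair
from .trees import PhyloTree, majority_consensus, nj, upgma

logger = logging.getLogger(__name__)

__all__ = ["JackknifeConfig", "jackknife_sample", "jackknife_support"]

DEFAULT_REMOVAL_FRACTION = math.exp(-1)


@dataclass(frozen=True)
class JackknifeConfig:
    removal_fraction: float = DEFAULT_REMOVAL_FRACTION
    replicates: int = 1000
    seed: int = 0
    tree_method: str = "upgma"
    exact_count: bool = False  # remove exactly round(f*N) pairs instead of Bernoulli
    max_failure_fraction: float = 0.10

    def __post_init__(self):
        if not (0 <= self.removal_fraction < 1):
            raise ValueError("removal_fraction must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.tree_method not in ("upgma", "nj"):
            raise ValueError(f"unknown tree method {self.tree_method!r}")


def _genome_rng(cfg: JackknifeConfig, replicate_index: int, genome_id: str):
    key = zlib.crc32(genome_id.encode())
    ss = np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(replicate_index, key)
    )
    return np.random.default_rng(ss)


def _reindex(pairs: list[OGPair]) -> list[OGPair]:
    """Re-number surviving pairs consecutively per chromosome, keeping order."""
    counters: dict[str, int] = {}
    out = []
    for p in sorted(pairs, key=lambda p: (p.chromosome_id, p.position_index)):
        idx = counters.get(p.chromosome_id, 0)
        counters[p.chromosome_id] = idx + 1
        out.append(replace(p, position_index=idx))
    return out


def jackknife_sample(
    og_pairs_by_genome: dict[str, list[OGPair]],
    cfg: JackknifeConfig,
    replicate_index: int,
) -> dict[str, list[OGPair]]:
    """One jackknife resample of every genome's OG pairs.

    By default each pair is removed independently with probability
    ``removal_fraction``; with ``exact_count`` a fixed round(f*N) pairs are
    removed instead.  Survivors keep their original relative order and are
    re-indexed consecutively.
    """
    out = {}
    for genome_id in sorted(og_pairs_by_genome):
        pairs = og_pairs_by_genome[genome_id]
        rng = _genome_rng(cfg, replicate_index, genome_id)
        if cfg.exact_count:
            n_remove = round(cfg.removal_fraction * len(pairs))
            drop = set(rng.choice(len(pairs), size=n_remove, replace=False))
            keep = [p for i, p in enumerate(pairs) if i not in drop]
        else:
            u = rng.random(len(pairs))
            keep = [p for p, ui in zip(pairs, u) if ui >= cfg.removal_fraction]
        out[genome_id] = _reindex(keep)
    return out


def jackknife_support(
    og_pairs_by_genome: dict[str, list[OGPair]],
    ortholog_maps,
    cfg: JackknifeConfig,
    dist_params: OGDistanceParams = OGDistanceParams(),
    replicate_sink=None,
) -> PhyloTree:
    """Full jackknife: resample -> distance matrices -> trees -> consensus.

    Failed replicates (e.g. a pair with n = 0 under the hard-error policy)
    are counted; more than ``max_failure_fraction`` of them aborts the run.
    ``replicate_sink``, when given, receives each replicate tree's Newick
    string (e.g. a file handle's ``write``).
    """
    build = upgma if cfg.tree_method == "upgma" else nj
    replicate_trees: list[PhyloTree] = []
    failures = 0
    for rep in range(cfg.replicates):
        resampled = jackknife_sample(og_pairs_by_genome, cfg, rep)
        try:
            matrix, _ = distance_matrix(resampled, ortholog_maps, dist_params)
            tree = build(matrix)
        except ValueError as exc:
            failures += 1
            logger.warning("replicate %d failed: %s", rep, exc)
            continue
        replicate_trees.append(tree)
        if replicate_sink is not None:
            replicate_sink(tree.to_newick() + "\n")
    if failures > cfg.max_failure_fraction * cfg.replicates:
        raise RuntimeError(
            f"{failures}/{cfg.replicates} jackknife replicates failed "
            f"(> {cfg.max_failure_fraction:.0%}); aborting"
        )
    if failures:
        logger.warning("%d/%d replicates failed and were skipped",
                       failures, cfg.replicates)
    return majority_consensus(replicate_trees)
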