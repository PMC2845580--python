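"""Bidirectional-best-hit orthology and matching of orthologous OG pairs.

BBH orthologs between two genomes are genes that are each other's best
surviving similarity hit after threshold filtering (e-value <= 1e-8, both
coverages >= 0.85, similarity >= 45% by default).  Two OG pairs from
different genomes match when their genes are mutual orthologs and the pairs
share the same directional pattern; the count of such matches, n, is the
character count entering the distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import SimilarityHit, best_hits_per_pair
from .og_identify import OGPair

logger = logging.getLogger(__name__)

__all__ = [
    "BBHThresholds",
    "OrthologMap",
    "OrthologousOGPairMatch",
    "OrthologousOGPairSet",
    "bbh_orthologs",
    "match_orthologous_og_pairs",
    "import_ortholog_table",
]


@dataclass(frozen=True)
class BBHThresholds:
    max_evalue: float = 1e-8
    min_coverage: float = 0.85  # applied to both query and subject
    min_similarity: float = 45.0  # percent


@dataclass
class OrthologMap:
    """One-to-one putative ortholog assignment between two genomes."""

    genome_i_id: str = ""
    genome_j_id: str = ""
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        lefts = [a for a, _ in self.pairs]
        rights = [b for _, b in self.pairs]
        if len(lefts) != len(set(lefts)) or len(rights) != len(set(rights)):
            raise ValueError("ortholog map is not one-to-one")
        self._fwd = dict(self.pairs)
        self._rev = {b: a for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, gene_i: str) -> str | None:
        return self._fwd.get(gene_i)

    def get_reverse(self, gene_j: str) -> str | None:
        return self._rev.get(gene_j)

    def transpose(self) -> "OrthologMap":
        return OrthologMap(
            genome_i_id=self.genome_j_id,
            genome_j_id=self.genome_i_id,
            pairs={(b, a) for a, b in self.pairs},
        )


@dataclass(frozen=True)
class OrthologousOGPairMatch:
    """A matched pair of OG pairs with relative orientation.

    ``relative_sign`` is +1 when the ortholog of ``pair_i.first`` is
    ``pair_j.first`` (coordinate orders agree) and -1 when the orthologs
    appear in swapped coordinate order in the other genome.
    """

    pair_i: OGPair
    pair_j: OGPair
    relative_sign: int

    def __post_init__(self):
        if self.relative_sign not in (1, -1):
            raise ValueError("relative_sign must be +1 or -1")
        if self.pair_i.pattern != self.pair_j.pattern:
            raise ValueError("matched OG pairs must share a directional pattern")


@dataclass
class OrthologousOGPairSet:
    matches: list[OrthologousOGPairMatch] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.matches)


def _passes(h: SimilarityHit, t: BBHThresholds) -> bool:
    return (
        h.evalue <= t.max_evalue
        and h.query_coverage >= t.min_coverage
        and h.subject_coverage >= t.min_coverage
        and h.similarity >= t.min_similarity
    )


def _best_per_query(hits: list[SimilarityHit]) -> dict[str, str]:
    """Best surviving subject per query: lowest e-value, then highest
    bitscore, then lexicographically smallest subject id."""
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (
            cur.evalue, -cur.bitscore, cur.subject_id,
        ):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def bbh_orthologs(
    hits_ij: list[SimilarityHit],
    hits_ji: list[SimilarityHit],
    thresholds: BBHThresholds = BBHThresholds(),
    genome_i_id: str = "",
    genome_j_id: str = "",
) -> OrthologMap:
    """Bidirectional best hits between two genomes.

    ``hits_ij`` are searches with genome-i genes as queries against genome j,
    ``hits_ji`` the reverse.  Hits failing any threshold are discarded before
    best-hit selection; (a, b) is mapped iff b is a's best surviving hit and
    a is b's.
    """
    fwd = _best_per_query(best_hits_per_pair([h for h in hits_ij if _passes(h, thresholds)]))
    rev = _best_per_query(best_hits_per_pair([h for h in hits_ji if _passes(h, thresholds)]))
    pairs = {(a, b) for a, b in fwd.items() if rev.get(b) == a}
    return OrthologMap(genome_i_id=genome_i_id, genome_j_id=genome_j_id, pairs=pairs)


def match_orthologous_og_pairs(
    ogs_i: list[OGPair],
    ogs_j: list[OGPair],
    ortholog_map: OrthologMap,
) -> OrthologousOGPairSet:
    """Match OG pairs across two genomes through the ortholog map.

    A match is emitted for (p, q) iff the orthologs of p's two genes are
    exactly q's two genes and the two pairs share the same directional
    pattern.  Because the map is one-to-one, each OG pair participates in at
    most one match.
    """
    by_genes = {frozenset((q.first, q.second)): q for q in ogs_j}
    matches = []
    for p in ogs_i:
        of = ortholog_map.get(p.first)
        os_ = ortholog_map.get(p.second)
        if of is None or os_ is None:
            continue
        q = by_genes.get(frozenset((of, os_)))
        if q is None or q.pattern != p.pattern:
            continue
        sign = 1 if of == q.first else -1
        matches.append(OrthologousOGPairMatch(pair_i=p, pair_j=q, relative_sign=sign))
    return OrthologousOGPairSet(matches=matches)


def import_ortholog_table(path, genome_i_id: str = "", genome_j_id: str = "") -> OrthologMap:
    """Read a two-column TSV of ortholog gene-id pairs into a one-to-one map.

    Rows violating the one-to-one constraint are collected and reported in a
    single validation error.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pairs.append((cols[0], cols[1]))
    lefts: dict[str, int] = {}
    rights: dict[str, int] = {}
    bad = []
    for a, b in pairs:
        lefts[a] = lefts.get(a, 0) + 1
        rights[b] = rights.get(b, 0) + 1
    for a, b in pairs:
        if lefts[a] > 1 or rights[b] > 1:
            bad.append((a, b))
    if bad:
        raise ValueError(
            f"{path}: {len(bad)} rows violate one-to-one mapping: {bad[:10]}"
        )
    return OrthologMap(
        genome_i_id=genome_i_id, genome_j_id=genome_j_id, pairs=set(pairs)
    )
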