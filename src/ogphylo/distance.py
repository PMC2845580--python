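"""Pairwise overlapping-gene distance and matrix assembly.

The distance between genomes i and j combines an order term (the weighted
rearrangement distance r over the n matched orthologous OG pairs, normalized
by n) with a content term (how far n falls short of the genomes' total OG
counts x_i and x_j):

    D = w_o * (r / n) + w_c * (1 - 2n / (x_i + x_j))

with default weights w_o = 1 and w_c = 2.  D lies in [0, w_o + w_c]; it is 0
exactly when the two genomes share all their OG pairs in identical order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .og_identify import OGPair
from .orthology import OrthologMap, match_orthologous_og_pairs
from .rearrangement import build_signed_orders, weighted_rearrangement_distance

logger = logging.getLogger(__name__)

__all__ = [
    "OGDistanceParams",
    "PairwiseInputs",
    "PairDiagnostics",
    "DistanceMatrix",
    "og_distance",
    "pairwise_inputs",
    "distance_matrix",
    "write_diagnostics",
]


@dataclass(frozen=True)
class OGDistanceParams:
    """Weights of the order and content terms, plus the n = 0 policy."""

    w_o: float = 1.0
    w_c: float = 2.0
    max_distance_fallback: bool = False

    def __post_init__(self):
        if self.w_o < 0 or self.w_c < 0:
            raise ValueError("weights must be >= 0")

    @property
    def max_distance(self) -> float:
        return self.w_o + self.w_c


@dataclass(frozen=True)
class PairwiseInputs:
    """The four numbers the distance needs for one genome pair."""

    r: int
    n: int
    x_i: int
    x_j: int

    def __post_init__(self):
        if self.n > 0 and not (0 <= self.r <= self.n):
            raise ValueError(f"require 0 <= r <= n, got r={self.r}, n={self.n}")
        if self.n > min(self.x_i, self.x_j):
            raise ValueError(
                f"n={self.n} exceeds min(x_i, x_j)=({self.x_i}, {self.x_j})"
            )


class NoSharedOGPairsError(ValueError):
    """Raised when a genome pair shares no orthologous OG pairs (n = 0)."""


def og_distance(p: PairwiseInputs, params: OGDistanceParams = OGDistanceParams()) -> float:
    if p.n == 0:
        if params.max_distance_fallback:
            logger.warning(
                "n = 0: substituting maximum distance %g", params.max_distance
            )
            return params.max_distance
        raise NoSharedOGPairsError(
            "no orthologous OG pairs between the two genomes; enable the "
            "max-distance fallback or extend gene regions"
        )
    order_term = p.r / p.n
    content_term = 1.0 - 2.0 * p.n / (p.x_i + p.x_j)
    return params.w_o * order_term + params.w_c * content_term


@dataclass
class PairDiagnostics:
    taxon_i: str
    taxon_j: str
    n: int
    r: int
    x_i: int
    x_j: int
    order_term: float
    content_term: float
    distance: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over labeled taxa."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.taxa)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("matrix diagonal is not zero")

    def get(self, a: str, b: str) -> float:
        return self.values[self.taxa.index(a), self.taxa.index(b)]


def pairwise_inputs(
    ogs_i: list[OGPair],
    ogs_j: list[OGPair],
    ortholog_map: OrthologMap,
) -> PairwiseInputs:
    """Run the per-pair chain: match OG pairs, build signed orders, compute r."""
    matched = match_orthologous_og_pairs(ogs_i, ogs_j, ortholog_map)
    if matched.n == 0:
        return PairwiseInputs(r=0, n=0, x_i=len(ogs_i), x_j=len(ogs_j))
    order_i, order_j = build_signed_orders(matched)
    result = weighted_rearrangement_distance(order_i, order_j)
    return PairwiseInputs(
        r=result.distance, n=matched.n, x_i=len(ogs_i), x_j=len(ogs_j)
    )


def distance_matrix(
    og_pairs_by_genome: dict[str, list[OGPair]],
    ortholog_maps: dict[tuple[str, str], OrthologMap],
    params: OGDistanceParams = OGDistanceParams(),
) -> tuple[DistanceMatrix, list[PairDiagnostics]]:
    """Assemble the full symmetric OG distance matrix.

    ``ortholog_maps`` is keyed by ordered (genome_i, genome_j) tuples; either
    orientation of each unordered pair is accepted (the map is transposed as
    needed).  Entries are computed pair-independently, so results do not
    depend on evaluation order.
    """
    taxa = sorted(og_pairs_by_genome)
    k = len(taxa)
    values = np.zeros((k, k))
    diagnostics: list[PairDiagnostics] = []
    for i in range(k):
        for j in range(i + 1, k):
            ti, tj = taxa[i], taxa[j]
            if (ti, tj) in ortholog_maps:
                omap = ortholog_maps[(ti, tj)]
            elif (tj, ti) in ortholog_maps:
                omap = ortholog_maps[(tj, ti)].transpose()
            else:
                raise KeyError(f"no ortholog map for pair ({ti}, {tj})")
            p = pairwise_inputs(og_pairs_by_genome[ti], og_pairs_by_genome[tj], omap)
            d = og_distance(p, params)
            values[i, j] = values[j, i] = d
            order_term = p.r / p.n if p.n else float("nan")
            content_term = (
                1.0 - 2.0 * p.n / (p.x_i + p.x_j) if (p.x_i + p.x_j) else float("nan")
            )
            diagnostics.append(
                PairDiagnostics(
                    taxon_i=ti, taxon_j=tj, n=p.n, r=p.r, x_i=p.x_i, x_j=p.x_j,
                    order_term=order_term, content_term=content_term, distance=d,
                )
            )
            logger.info("pair (%s, %s): n=%d r=%d D=%.4f", ti, tj, p.n, p.r, d)
    return DistanceMatrix(taxa=taxa, values=values), diagnostics


def write_diagnostics(diagnostics: list[PairDiagnostics], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "taxon_i\ttaxon_j\tn\tr\tx_i\tx_j\torder_term\tcontent_term\tD\n"
        )
        for d in diagnostics:
            fh.write(
                f"{d.taxon_i}\t{d.taxon_j}\t{d.n}\t{d.r}\t{d.x_i}\t{d.x_j}\t"
                f"{d.order_term:.6f}\t{d.content_term:.6f}\t{d.distance:.6f}\n"
            )
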