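"""Overlapping-gene (OG) pair identification.

A gene region is optionally extended by fixed margins covering its promoter
(upstream of the 5' end, default 385 bp) and terminator (downstream of the
3' end, default 50 bp); two adjacent retained genes form an OG pair when
their (extended) intervals share at least 1 bp.  Each pair carries one of
three directional patterns determined by the strand combination:
(+,+)/(-,-) unidirectional, (+,-) convergent, (-,+) divergent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .io_formats import ChromosomeAnnotation, GeneRecord, GenomeAnnotation

__all__ = [
    "ExtensionParams",
    "ExtendedGene",
    "OGPair",
    "extend_gene",
    "find_og_pairs",
    "count_ogs",
    "write_og_report",
    "UNIDIRECTIONAL",
    "CONVERGENT",
    "DIVERGENT",
]

UNIDIRECTIONAL = "unidirectional"
CONVERGENT = "convergent"
DIVERGENT = "divergent"

# strand of (first, second) -> (pattern, unidirectional orientation)
_PATTERN = {
    ("+", "+"): (UNIDIRECTIONAL, "forward"),
    ("-", "-"): (UNIDIRECTIONAL, "reverse"),
    ("+", "-"): (CONVERGENT, None),
    ("-", "+"): (DIVERGENT, None),
}


@dataclass(frozen=True)
class ExtensionParams:
    """Fixed regulatory-region margins added to each CDS."""

    ext5: int = 385
    ext3: int = 50
    use_extension: bool = True

    def __post_init__(self):
        if self.ext5 < 0 or self.ext3 < 0:
            raise ValueError("extension margins must be >= 0")


@dataclass(frozen=True)
class ExtendedGene:
    gene: GeneRecord
    ext_start: int
    ext_end: int
    wraps_origin: bool = False


@dataclass(frozen=True)
class OGPair:
    """Two adjacent genes whose (extended) regions overlap.

    ``first`` is the gene with the smaller start coordinate;
    ``position_index`` is the 0-based rank of the pair along its chromosome.
    """

    first: str
    second: str
    chromosome_id: str
    pattern: str
    uni_orientation: Optional[str]
    position_index: int
    overlap_bp: int = 0
    extended: bool = True

    @property
    def key(self) -> tuple[str, str]:
        return (self.first, self.second)


def extend_gene(
    gene: GeneRecord, chrom: ChromosomeAnnotation, params: ExtensionParams
) -> ExtendedGene:
    """Extend a gene by the strand-aware 5'/3' margins.

    On the + strand the 5' margin grows the interval leftward and the 3'
    margin rightward; on the - strand the roles swap.  Linear chromosomes
    clip to [1, length]; circular chromosomes wrap modulo the length and set
    ``wraps_origin``.
    """
    if not params.use_extension:
        return ExtendedGene(gene=gene, ext_start=gene.start, ext_end=gene.end)
    if gene.strand == "+":
        lo = gene.start - params.ext5
        hi = gene.end + params.ext3
    else:
        lo = gene.start - params.ext3
        hi = gene.end + params.ext5
    wraps = False
    if chrom.topology == "circular" and chrom.length > 0:
        span = hi - lo + 1
        if span >= chrom.length:
            lo, hi = 1, chrom.length
        else:
            if lo < 1 or hi > chrom.length:
                wraps = True
            lo = (lo - 1) % chrom.length + 1
            hi = (hi - 1) % chrom.length + 1
    else:
        lo = max(1, lo)
        hi = min(chrom.length, hi) if chrom.length > 0 else hi
    return ExtendedGene(gene=gene, ext_start=lo, ext_end=hi, wraps_origin=wraps)


def _intervals(eg: ExtendedGene, chrom_length: int) -> list[tuple[int, int]]:
    """Linearized interval(s) of an extended gene (two pieces when wrapping)."""
    if eg.wraps_origin:
        # ext_start > ext_end after modular wrap: [ext_start, L] + [1, ext_end]
        return [(eg.ext_start, chrom_length), (1, eg.ext_end)]
    return [(eg.ext_start, eg.ext_end)]


def _overlap_bp(a: ExtendedGene, b: ExtendedGene, chrom_length: int) -> int:
    total = 0
    for a_lo, a_hi in _intervals(a, chrom_length):
        for b_lo, b_hi in _intervals(b, chrom_length):
            total += max(0, min(a_hi, b_hi) - max(a_lo, b_lo) + 1)
    return total


def find_og_pairs(
    genome: GenomeAnnotation,
    params: ExtensionParams = ExtensionParams(),
    test_origin_adjacency: bool = True,
) -> list[OGPair]:
    """Identify OG pairs among adjacent retained genes of every chromosome.

    Adjacency is computed among retained genes only (excluded genes are
    invisible).  On circular chromosomes the last-to-first adjacency is also
    tested when ``test_origin_adjacency`` is set.  Pairs are ordered along
    each chromosome and numbered per chromosome via ``position_index``.
    """
    pairs: list[OGPair] = []
    for chrom in genome.chromosomes:
        genes = chrom.retained_genes()
        if len(genes) < 2:
            continue
        extended = [extend_gene(g, chrom, params) for g in genes]
        idx = 0
        candidates = list(zip(extended, extended[1:]))
        if (
            chrom.topology == "circular"
            and test_origin_adjacency
            and len(genes) > 2
        ):
            candidates.append((extended[-1], extended[0]))
        for a, b in candidates:
            ov = _overlap_bp(a, b, chrom.length)
            if ov < 1:
                continue
            first, second = a.gene, b.gene
            if (second.start, second.end, second.gene_id) < (
                first.start, first.end, first.gene_id,
            ):
                first, second = second, first
            pattern, uni = _PATTERN[(first.strand, second.strand)]
            pairs.append(
                OGPair(
                    first=first.gene_id,
                    second=second.gene_id,
                    chromosome_id=chrom.chromosome_id,
                    pattern=pattern,
                    uni_orientation=uni,
                    position_index=idx,
                    overlap_bp=ov,
                    extended=params.use_extension,
                )
            )
            idx += 1
    return pairs


def count_ogs(genome: GenomeAnnotation, pairs: list[OGPair]) -> int:
    """Total number of OG pairs in the genome (the content-term count x)."""
    return len(pairs)


def write_og_report(genome_id: str, pairs: list[OGPair], path) -> None:
    """TSV report of the OG pairs found in one genome."""
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tchromosome_id\tfirst\tsecond\tpattern\t"
            "overlap_bp\textended\n"
        )
        for p in pairs:
            fh.write(
                f"{genome_id}\t{p.chromosome_id}\t{p.first}\t{p.second}\t"
                f"{p.pattern}\t{p.overlap_bp}\t{'yes' if p.extended else 'no'}\n"
            )
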