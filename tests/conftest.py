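import numpy as np
import pytest

from ogphylo.io_formats import ChromosomeAnnotation, GeneRecord, GenomeAnnotation


def make_genome(rows, genome_id="G", chrom_length=None, topology="linear"):
    """Build a one-or-more-chromosome genome from terse tuples.

    rows: (gene_id, chrom_id, start, end, strand[, product])
    """
    by_chrom = {}
    for row in rows:
        gene_id, chrom_id, start, end, strand = row[:5]
        product = row[5] if len(row) > 5 else ""
        by_chrom.setdefault(chrom_id, []).append(
            GeneRecord(
                gene_id=gene_id, chromosome_id=chrom_id, start=start, end=end,
                strand=strand, product=product,
            )
        )
    chromosomes = []
    for cid in sorted(by_chrom):
        genes = by_chrom[cid]
        length = chrom_length or max(g.end for g in genes) + 1000
        chromosomes.append(
            ChromosomeAnnotation(
                chromosome_id=cid, length=length, genes=genes, topology=topology
            )
        )
    return GenomeAnnotation(genome_id=genome_id, chromosomes=chromosomes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_signed_order(rng, n, max_chromosomes=2):
    """Random signed genome on elements 1..n split over up to k chromosomes."""
    from ogphylo.rearrangement import SignedGenomeOrder

    perm = rng.permutation(np.arange(1, n + 1))
    signs = rng.choice([-1, 1], size=n)
    seq = list(perm * signs)
    k = min(int(rng.integers(1, max_chromosomes + 1)), n)
    if k == 1 or n < 2:
        return SignedGenomeOrder([seq])
    cuts = sorted(rng.choice(np.arange(1, n), size=k - 1, replace=False))
    chroms, prev = [], 0
    for c in list(cuts) + [n]:
        chroms.append(seq[prev:c])
        prev = c
    return SignedGenomeOrder(chroms)
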