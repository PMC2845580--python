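"""Readers and writers for the formats the pipeline consumes and produces.

Coordinates are 1-based inclusive throughout (GenBank convention); strand is
``+``/``-`` and carries orientation while start/end are always on the forward
strand.  Supported formats: GenBank flat files (read, via Biopython), a
tab-delimited gene table dialect (read/write), BLAST tabular outfmt-6 with
optional qlen/slen columns (read), PHYLIP square distance matrices (write)
and Newick trees (read/write, delegating to :mod:`ogphylo.trees`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from . import trees as _trees

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "ChromosomeAnnotation",
    "GenomeAnnotation",
    "SimilarityHit",
    "read_genbank",
    "read_gene_table",
    "write_gene_table",
    "filter_genes",
    "read_blast_tab",
    "best_hits_per_pair",
    "write_phylip_matrix",
    "write_newick",
    "read_newick",
]

GENE_TABLE_COLUMNS = ["gene_id", "chromosome_id", "start", "end", "strand", "product"]

DEFAULT_EXCLUDE_KEYWORDS = ["unknown", "hypothetical", "putative"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One annotated coding gene on a chromosome (1-based inclusive coords)."""

    gene_id: str
    chromosome_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    is_excluded: bool = False

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 1 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ChromosomeAnnotation:
    """Genes of one replicon, sorted by (start, end, gene_id)."""

    chromosome_id: str
    length: int
    genes: list[GeneRecord] = field(default_factory=list)
    topology: str = "linear"

    def __post_init__(self):
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        if self.topology == "linear":
            for g in self.genes:
                if g.end > self.length:
                    raise ValueError(
                        f"gene {g.gene_id} ends at {g.end} beyond linear "
                        f"chromosome length {self.length}"
                    )

    def retained_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if not g.is_excluded]


@dataclass
class GenomeAnnotation:
    genome_id: str
    chromosomes: list[ChromosomeAnnotation] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.chromosome_id for c in self.chromosomes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chromosome ids in genome {self.genome_id}")
        gene_ids = [g.gene_id for c in self.chromosomes for g in c.genes]
        if len(gene_ids) != len(set(gene_ids)):
            dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
            raise ValueError(
                f"duplicate gene ids in genome {self.genome_id}: {dupes[:5]}"
            )

    def all_genes(self) -> list[GeneRecord]:
        return [g for c in self.chromosomes for g in c.genes]

    def retained_genes(self) -> list[GeneRecord]:
        return [g for g in self.all_genes() if not g.is_excluded]


@dataclass(frozen=True)
class SimilarityHit:
    """One similarity search hit (e.g. a BLASTP HSP) between two genes."""

    query_id: str
    subject_id: str
    evalue: float
    similarity: float  # percent identity/similarity, 0..100
    query_coverage: float  # fraction of query aligned, 0..1
    subject_coverage: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if not (0 <= self.similarity <= 100):
            raise ValueError(f"similarity {self.similarity} outside [0, 100]")
        for cov in (self.query_coverage, self.subject_coverage):
            if not (0 <= cov <= 1.0 + 1e-9):
                raise ValueError(f"coverage {cov} outside [0, 1]")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def read_genbank(path) -> GenomeAnnotation:
    """Read CDS features from a GenBank flat file into a genome annotation.

    One gene per CDS feature; multi-record files yield multiple chromosomes.
    Fuzzy location bounds are truncated to their numeric positions with a
    warning; compound (joined) locations spanning the origin or introns are
    skipped with a warning since their linear extent is ill-defined.
    """
    from Bio import SeqIO
    from Bio.SeqFeature import CompoundLocation

    path = Path(path)
    chromosomes = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed GenBank file: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")

    genome_id = path.stem
    for rec in records:
        genes = []
        is_circular = rec.annotations.get("topology", "linear") == "circular"
        counter = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            counter += 1
            if isinstance(feat.location, CompoundLocation):
                logger.warning(
                    "%s: skipping CDS with compound location %s", rec.id, feat.location
                )
                continue
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or quals.get("protein_id", [None])[0]
                or f"{rec.id}_cds{counter}"
            )
            product = quals.get("product", quals.get("note", [""]))[0]
            start = int(feat.location.start) + 1  # biopython is 0-based half-open
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    chromosome_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                )
            )
        chromosomes.append(
            ChromosomeAnnotation(
                chromosome_id=rec.id,
                length=len(rec.seq) if rec.seq is not None else max(
                    (g.end for g in genes), default=0
                ),
                genes=genes,
                topology="circular" if is_circular else "linear",
            )
        )
    return GenomeAnnotation(genome_id=genome_id, chromosomes=chromosomes)


# ---------------------------------------------------------------------------
# Gene table TSV
# ---------------------------------------------------------------------------

def read_gene_table(path) -> GenomeAnnotation:
    """Read the package's tab-delimited gene-table dialect.

    Header: ``gene_id  chromosome_id  start  end  strand  product``.
    Pragma lines ``##chromosome <id> length=<bp> topology=<linear|circular>``
    before the header declare replicon metadata; chromosomes without a pragma
    default to linear with length = max gene end.
    """
    path = Path(path)
    chrom_meta: dict[str, tuple[int, str]] = {}
    rows: list[dict] = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##chromosome"):
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: bad chromosome pragma")
                cid = parts[1]
                length, topology = 0, "linear"
                for p in parts[2:]:
                    if p.startswith("length="):
                        length = int(p.split("=", 1)[1])
                    elif p.startswith("topology="):
                        topology = p.split("=", 1)[1]
                chrom_meta[cid] = (length, topology)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields[: len(GENE_TABLE_COLUMNS)] != GENE_TABLE_COLUMNS:
                    raise FormatError(
                        f"{path}:{lineno}: expected header {GENE_TABLE_COLUMNS}, "
                        f"got {fields}"
                    )
                header = fields
                continue
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 columns")
            row = dict(zip(GENE_TABLE_COLUMNS, fields + [""] * (6 - len(fields))))
            row["lineno"] = lineno
            rows.append(row)
    if header is None:
        raise FormatError(f"{path}: missing gene-table header")

    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    seen_ids: set[str] = set()
    for row in rows:
        lineno = row["lineno"]
        if row["gene_id"] in seen_ids:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {row['gene_id']!r}")
        seen_ids.add(row["gene_id"])
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start > end:
            raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
        if row["strand"] not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: unknown strand {row['strand']!r}")
        gene = GeneRecord(
            gene_id=row["gene_id"],
            chromosome_id=row["chromosome_id"],
            start=start,
            end=end,
            strand=row["strand"],
            product=row["product"],
        )
        genes_by_chrom.setdefault(row["chromosome_id"], []).append(gene)

    chromosomes = []
    for cid in sorted(set(genes_by_chrom) | set(chrom_meta)):
        genes = genes_by_chrom.get(cid, [])
        length, topology = chrom_meta.get(
            cid, (max((g.end for g in genes), default=0), "linear")
        )
        if length == 0:
            length = max((g.end for g in genes), default=0)
        chromosomes.append(
            ChromosomeAnnotation(
                chromosome_id=cid, length=length, genes=genes, topology=topology
            )
        )
    return GenomeAnnotation(genome_id=path.stem, chromosomes=chromosomes)


def write_gene_table(genome: GenomeAnnotation, path) -> None:
    """Write a genome annotation in the gene-table dialect (round-trips)."""
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(
                f"##chromosome {chrom.chromosome_id} "
                f"length={chrom.length} topology={chrom.topology}\n"
            )
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for chrom in genome.chromosomes:
            for g in chrom.genes:
                fh.write(
                    f"{g.gene_id}\t{g.chromosome_id}\t{g.start}\t{g.end}\t"
                    f"{g.strand}\t{g.product}\n"
                )


# ---------------------------------------------------------------------------
# Gene filtering
# ---------------------------------------------------------------------------

def filter_genes(
    genome: GenomeAnnotation,
    keywords: Iterable[str] = (),
    hgt_ids: Iterable[str] = (),
) -> GenomeAnnotation:
    """Mark unreliable genes as excluded.

    A gene is excluded when its product contains any keyword
    (case-insensitive substring match) or its id is in ``hgt_ids``.
    Downstream adjacency is computed among retained genes only.  Idempotent;
    with empty keywords and ids the genome is returned unchanged in content.
    """
    kws = [k.lower() for k in keywords]
    hgt = set(hgt_ids)
    n_kw = n_hgt = 0
    chromosomes = []
    for chrom in genome.chromosomes:
        genes = []
        for g in chrom.genes:
            excluded = g.is_excluded
            product = (g.product or "").lower()
            if any(k in product for k in kws):
                excluded = True
                n_kw += 1
            if g.gene_id in hgt:
                excluded = True
                n_hgt += 1
            genes.append(replace(g, is_excluded=excluded))
        chromosomes.append(
            ChromosomeAnnotation(
                chromosome_id=chrom.chromosome_id,
                length=chrom.length,
                genes=genes,
                topology=chrom.topology,
            )
        )
    logger.info(
        "filter_genes(%s): %d keyword-excluded, %d HGT-excluded of %d genes",
        genome.genome_id, n_kw, n_hgt, len(genome.all_genes()),
    )
    return GenomeAnnotation(genome_id=genome.genome_id, chromosomes=chromosomes)


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tab(path, lengths: Optional[dict[str, int]] = None) -> list[SimilarityHit]:
    """Read BLAST tabular (outfmt 6) hits.

    Standard 12 columns: qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore.  Coverage requires sequence lengths:
    either two extra columns (qlen slen) or a ``lengths`` mapping from id to
    length.  Multiple HSPs per (query, subject) pair are all returned; use
    :func:`best_hits_per_pair` to reduce to one representative.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: expected >= 12 columns")
            q, s = cols[0], cols[1]
            try:
                pident = float(cols[2])
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            if len(cols) >= 14:
                qlen, slen = int(cols[12]), int(cols[13])
            elif lengths is not None:
                try:
                    qlen, slen = lengths[q], lengths[s]
                except KeyError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: no length known for {exc.args[0]!r}"
                    ) from exc
            else:
                raise FormatError(
                    f"{path}:{lineno}: coverage needs qlen/slen columns or a "
                    "companion length table"
                )
            qcov = min(1.0, (abs(qend - qstart) + 1) / qlen)
            scov = min(1.0, (abs(send - sstart) + 1) / slen)
            hits.append(
                SimilarityHit(
                    query_id=q, subject_id=s, evalue=evalue, similarity=pident,
                    query_coverage=qcov, subject_coverage=scov, bitscore=bitscore,
                )
            )
    return hits


def best_hits_per_pair(hits: list[SimilarityHit]) -> list[SimilarityHit]:
    """Keep one HSP per ordered (query, subject) pair.

    The representative is the hit with the lowest e-value; ties broken by
    highest bitscore.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[key] = h
    return list(best.values())


# ---------------------------------------------------------------------------
# PHYLIP matrix
# ---------------------------------------------------------------------------

def write_phylip_matrix(matrix, path, mapping_path=None) -> dict[str, str]:
    """Write a square PHYLIP distance matrix.

    Taxon names longer than 10 characters are replaced by unique padded
    aliases (``T0000001``-style); the alias -> name mapping is returned and,
    when ``mapping_path`` is given, also written as a two-column TSV sidecar.
    """
    taxa = list(matrix.taxa)
    values = np.asarray(matrix.values, dtype=float)
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("refusing to write a non-symmetric matrix")
    mapping: dict[str, str] = {}
    names = []
    for i, t in enumerate(taxa):
        if len(t) > 10:
            alias = f"T{i + 1:07d}"
            mapping[alias] = t
            names.append(alias)
        else:
            names.append(t)
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)}\n")
        for name, row in zip(names, values):
            fh.write(name.ljust(10) + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
    if mapping and mapping_path is not None:
        with open(mapping_path, "w") as fh:
            for alias, name in mapping.items():
                fh.write(f"{alias}\t{name}\n")
    return mapping


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path):
    with open(path) as fh:
        return _trees.parse_newick(fh.read())
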