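"""Genome data model and I/O: hosts, genes, promoters/intergenic regions.

Every coordinate in the package is 0-based half-open on the forward
genomic strand; GFF3 (1-based inclusive) and GenBank records are
converted on read. CDS sequences are always stored in coding
orientation (reverse-complemented for minus-strand genes).

A *promoter* is the up-to-200 bp immediately 5' of a gene's start on the
gene's own strand, truncated at the contig edge or at the previous
same-strand feature. *Intergenic* sequence is everything on a strand
that is neither ORF nor promoter, split at feature boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import has_internal_stop, is_iupac, reverse_complement, translate

log = logging.getLogger(__name__)

PROMOTER_LENGTH = 200
MIN_PROMOTER_LENGTH = 30

START_CODONS = ("ATG", "GTG", "TTG")


class SelectiGeneError(Exception):
    """Base class for structured errors raised by this package."""


class MissingAnnotationError(SelectiGeneError):
    """Raised when an input genome has no usable CDS annotation."""


@dataclass
class GeneRecord:
    """One protein-coding gene: CDS in coding orientation plus genomic placement."""

    gene_id: str
    cds_seq: str
    strand: str = "+"
    contig_id: str = ""
    start: int = 0
    end: int = 0
    expression: float | None = None
    product: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        self.cds_seq = self.cds_seq.upper()
        if len(self.cds_seq) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.expression is not None and self.expression < 0:
            raise ValueError(f"{self.gene_id}: expression must be non-negative")
        if not self.partial and self.cds_seq[:3] not in START_CODONS:
            self.partial = True

    @property
    def protein(self) -> str:
        return translate(self.cds_seq)


@dataclass
class RegionSet:
    """Promoters (per gene) and intergenic stretches of one host."""

    promoters: list[tuple[str, str]] = field(default_factory=list)
    intergenic: list[str] = field(default_factory=list)
    # forward-strand intervals per (contig, strand), for partition checks
    promoter_intervals: dict = field(default_factory=dict)
    intergenic_intervals: dict = field(default_factory=dict)

    def promoter_of(self, gene_id: str) -> str | None:
        for gid, seq in self.promoters:
            if gid == gene_id:
                return seq
        return None


@dataclass
class HostGenome:
    """One organism: its CDS set, regions, and optional auxiliary data."""

    host_id: str
    role: str  # "wanted" | "unwanted"
    genes: list[GeneRecord] = field(default_factory=list)
    contigs: dict[str, str] = field(default_factory=dict)
    regions: RegionSet | None = None
    tgcn: dict[str, int] | None = None
    tdr: dict[str, float] | None = None
    enzymes: list[str] = field(default_factory=list)
    rrna_16s: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("wanted", "unwanted"):
            raise ValueError(f"role must be 'wanted' or 'unwanted', got {self.role!r}")
        if self.tgcn is not None and any(v < 0 for v in self.tgcn.values()):
            raise ValueError("tGCN copy numbers must be >= 0")
        bad = [s for s in self.enzymes if not is_iupac(s)]
        if bad:
            raise ValueError(f"non-IUPAC enzyme sites: {bad}")


@dataclass
class Microbiome:
    """The design target: wanted (A) and unwanted (B) host sets."""

    hosts: list[HostGenome]

    def __post_init__(self) -> None:
        ids = [h.host_id for h in self.hosts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate host_id in microbiome")

    @property
    def A(self) -> list[HostGenome]:
        return [h for h in self.hosts if h.role == "wanted"]

    @property
    def B(self) -> list[HostGenome]:
        return [h for h in self.hosts if h.role == "unwanted"]

    def require_design_ready(self) -> None:
        if not self.A or not self.B:
            raise SelectiGeneError(
                "design requires at least one wanted and one unwanted host "
                f"(got |A|={len(self.A)}, |B|={len(self.B)})"
            )

    def host(self, host_id: str) -> HostGenome:
        for h in self.hosts:
            if h.host_id == host_id:
                return h
        raise KeyError(host_id)


# ---------------------------------------------------------------------------
# loading


def _add_gene(genes: list[GeneRecord], gene_id: str, seq: str, strand: str,
              contig_id: str, start: int, end: int, product: str) -> None:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        log.warning("skipping %s: CDS length %d not divisible by 3", gene_id, len(seq))
        return
    if set(seq) <= set("ACGT") and has_internal_stop(seq):
        log.warning("skipping %s: internal stop codon", gene_id)
        return
    genes.append(GeneRecord(gene_id=gene_id, cds_seq=seq, strand=strand,
                            contig_id=contig_id, start=start, end=end,
                            product=product))


def _load_genbank(path: Path, role: str, host_id: str | None) -> HostGenome:
    contigs: dict[str, str] = {}
    genes: list[GeneRecord] = []
    n_cds = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        contigs[rec.id] = str(rec.seq).upper()
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n_cds += 1
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            seq = contigs[rec.id][start:end]
            if strand == "-":
                seq = reverse_complement(seq)
            q = feat.qualifiers
            gid = (q.get("locus_tag") or q.get("gene")
                   or q.get("protein_id") or [f"cds{n_cds}"])[0]
            _add_gene(genes, gid, seq, strand, rec.id, start, end,
                      (q.get("product") or [""])[0])
    if n_cds == 0:
        raise MissingAnnotationError(f"{path}: no CDS features found")
    return HostGenome(host_id=host_id or path.stem, role=role,
                      genes=genes, contigs=contigs)


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _load_fasta_gff(genome_path: Path, annotation_path: Path, role: str,
                    host_id: str | None) -> HostGenome:
    contigs = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(genome_path), "fasta")}
    genes: list[GeneRecord] = []
    n_cds = 0
    with open(annotation_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "CDS":
                continue
            n_cds += 1
            contig, start1, end = cols[0], int(cols[3]), int(cols[4])
            start = start1 - 1  # GFF3 is 1-based inclusive
            strand = cols[6]
            if contig not in contigs:
                log.warning("CDS on unknown contig %s skipped", contig)
                continue
            seq = contigs[contig][start:end]
            if strand == "-":
                seq = reverse_complement(seq)
            attrs = _parse_gff_attributes(cols[8])
            gid = attrs.get("ID") or attrs.get("locus_tag") or f"cds{n_cds}"
            _add_gene(genes, gid, seq, strand, contig, start, end,
                      attrs.get("product", ""))
    if n_cds == 0:
        raise MissingAnnotationError(f"{annotation_path}: no CDS features found")
    return HostGenome(host_id=host_id or genome_path.stem, role=role,
                      genes=genes, contigs=contigs)


def load_host(genome_path: str | Path, annotation_path: str | Path | None = None,
              role: str = "wanted", host_id: str | None = None) -> HostGenome:
    """Load one host genome from GenBank or FASTA+GFF3.

    With *annotation_path* the genome is read as FASTA and the annotation
    as GFF3; without it the genome file must be GenBank. CDS features
    whose length is not a multiple of 3, or that contain an internal stop,
    are skipped with a warning.
    """
    genome_path = Path(genome_path)
    if annotation_path is None:
        host = _load_genbank(genome_path, role, host_id)
    else:
        host = _load_fasta_gff(genome_path, Path(annotation_path), role, host_id)
    if not host.genes:
        raise MissingAnnotationError(f"{genome_path}: no usable CDS records")
    return host


def load_expression(path: str | Path) -> dict[str, float]:
    """Read a gene_id<TAB>value expression table."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gid, val = line.rstrip("\n").split("\t")[:2]
            out[gid] = float(val)
    return out


def load_tgcn(path: str | Path) -> dict[str, int]:
    """Read an anticodon<TAB>copy_number tGCN table."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            ac, val = line.rstrip("\n").split("\t")[:2]
            out[ac.upper()] = int(val)
    return out


def attach_expression(host: HostGenome, table: dict[str, float]) -> None:
    for g in host.genes:
        if g.gene_id in table:
            g.expression = table[g.gene_id]


# ---------------------------------------------------------------------------
# writing (fixtures and round-trips go through these)


def write_host(host: HostGenome, directory: str | Path) -> dict[str, Path]:
    """Write genome FASTA + GFF3 (+ expression/tGCN TSV when present).

    Returns the paths written, keyed by kind.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = directory / f"{host.host_id}.fasta"
    recs = [SeqRecord(Seq(seq), id=cid, description="")
            for cid, seq in host.contigs.items()]
    SeqIO.write(recs, str(fasta), "fasta")
    paths["fasta"] = fasta

    gff = directory / f"{host.host_id}.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in host.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write("\t".join([g.contig_id, "selectigene", "CDS",
                                str(g.start + 1), str(g.end), ".", g.strand,
                                "0", attrs]) + "\n")
    paths["gff3"] = gff

    if any(g.expression is not None for g in host.genes):
        expr = directory / f"{host.host_id}.expression.tsv"
        with open(expr, "w") as fh:
            for g in host.genes:
                if g.expression is not None:
                    fh.write(f"{g.gene_id}\t{g.expression:.6g}\n")
        paths["expression"] = expr

    if host.tgcn:
        tg = directory / f"{host.host_id}.tgcn.tsv"
        with open(tg, "w") as fh:
            for ac, n in sorted(host.tgcn.items()):
                fh.write(f"{ac}\t{n}\n")
        paths["tgcn"] = tg
    return paths


def write_cds_fasta(host: HostGenome, path: str | Path) -> Path:
    """Write every CDS (coding orientation) to a FASTA file."""
    path = Path(path)
    recs = [SeqRecord(Seq(g.cds_seq), id=g.gene_id, description="")
            for g in host.genes]
    SeqIO.write(recs, str(path), "fasta")
    return path


def load_goi(path: str | Path) -> GeneRecord:
    """Read the gene of interest from a single-record CDS FASTA."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return GeneRecord(gene_id=rec.id, cds_seq=str(rec.seq).upper())


# ---------------------------------------------------------------------------
# region extraction


def extract_regions(host: HostGenome) -> RegionSet:
    """Derive promoters and intergenic stretches from gene coordinates.

    Promoters shorter than ``MIN_PROMOTER_LENGTH`` after truncation are
    omitted (with a warning). Promoters overlapping an upstream ORF are
    truncated at the ORF boundary.
    """
    if not host.contigs:
        raise SelectiGeneError(f"{host.host_id}: no contig sequences available")
    rs = RegionSet()
    for contig_id, contig_seq in host.contigs.items():
        clen = len(contig_seq)
        for strand in ("+", "-"):
            genes = sorted(
                (g for g in host.genes
                 if g.contig_id == contig_id and g.strand == strand),
                key=lambda g: g.start)
            orf_iv = [(g.start, g.end) for g in genes]
            prom_iv: list[tuple[int, int]] = []
            for i, g in enumerate(genes):
                if strand == "+":
                    lo = max(0, g.start - PROMOTER_LENGTH)
                    if i > 0:
                        lo = max(lo, genes[i - 1].end)
                    hi = g.start
                else:
                    lo = g.end
                    hi = min(clen, g.end + PROMOTER_LENGTH)
                    if i + 1 < len(genes):
                        hi = min(hi, genes[i + 1].start)
                if hi - lo < MIN_PROMOTER_LENGTH:
                    log.warning("%s/%s: promoter of %s only %d bp, omitted",
                                host.host_id, contig_id, g.gene_id, hi - lo)
                    continue
                seq = contig_seq[lo:hi]
                if strand == "-":
                    seq = reverse_complement(seq)
                rs.promoters.append((g.gene_id, seq))
                prom_iv.append((lo, hi))
            # intergenic = contig minus ORFs minus promoters, same strand
            covered = sorted(orf_iv + prom_iv)
            pos = 0
            inter_iv = []
            for lo, hi in covered:
                if lo > pos:
                    inter_iv.append((pos, lo))
                pos = max(pos, hi)
            if pos < clen:
                inter_iv.append((pos, clen))
            for lo, hi in inter_iv:
                if hi - lo >= 1:
                    seq = contig_seq[lo:hi]
                    if strand == "-":
                        seq = reverse_complement(seq)
                    rs.intergenic.append(seq)
            rs.promoter_intervals[(contig_id, strand)] = prom_iv
            rs.intergenic_intervals[(contig_id, strand)] = inter_iv
    host.regions = rs
    return rs


def select_reference_genes(host: HostGenome, fraction: float = 1 / 3,
                           ) -> list[GeneRecord]:
    """Pick the top ``ceil(fraction * n)`` genes as the highly expressed set.

    Genes are ranked by measured expression when available; otherwise by
    CAI against a ribosomal-protein reference (falling back to the whole
    proteome when no gene is annotated as a ribosomal protein). Ties are
    broken by gene_id so the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not host.genes:
        raise SelectiGeneError(f"{host.host_id}: no genes to rank")
    n_take = math.ceil(fraction * len(host.genes))

    if any(g.expression is not None for g in host.genes):
        def key(g: GeneRecord):
            return (-(g.expression if g.expression is not None else 0.0),
                    g.gene_id)
    else:
        from .cub_engine import cai_weights, gene_score
        ribo = [g for g in host.genes if "ribosomal protein" in g.product.lower()]
        wt = cai_weights(ribo if ribo else host.genes, host_id=host.host_id)
        scores = {g.gene_id: gene_score(g.cds_seq, wt).value for g in host.genes}

        def key(g: GeneRecord):
            return (-scores[g.gene_id], g.gene_id)

    return sorted(host.genes, key=key)[:n_take]
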