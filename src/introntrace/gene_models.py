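"""Gene structures, intron extraction and per-species intron statistics.

A :class:`GeneModel` is strand-normalized: its ``sequence`` is the sense
strand of the gene span and exon intervals are 0-based half-open positions
on that span.  Introns are the inter-exon gaps; each carries a phase
(position relative to the reading frame), a region class (CDS / 5'UTR /
3'UTR), its splice dinucleotides and GC content.
"""

from __future__ import annotations

import io
import json
import statistics
from dataclasses import dataclass, field

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

STOP = object()  # sentinel unused; kept minimal

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GeneModelError(ValueError):
    """A gene annotation violates the model invariants."""


@dataclass
class GeneModel:
    """One gene's exon/CDS structure plus sense-strand sequence.

    ``exons`` are 0-based half-open intervals in gene-span coordinates;
    ``cds_start``/``cds_end`` are 0-based positions in spliced-transcript
    coordinates.  ``strand_original`` records provenance only: minus-strand
    genes are reverse-complemented on load so every model reads 5'->3'.
    """

    gene_id: str
    species_id: str
    sequence: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    strand_original: str = "+"
    incomplete: bool = False  # CDS length not divisible by 3

    def validate(self) -> None:
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise GeneModelError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise GeneModelError(f"{self.gene_id}: overlapping/unsorted exons")
            prev_end = e
        if self.exons[0][0] != 0 or self.exons[-1][1] != len(self.sequence):
            raise GeneModelError(
                f"{self.gene_id}: exons do not span the gene sequence"
            )
        sl = self.spliced_length
        if not (0 <= self.cds_start < self.cds_end <= sl):
            raise GeneModelError(f"{self.gene_id}: CDS outside spliced transcript")

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def spliced(self) -> str:
        return "".join(self.sequence[s:e] for s, e in self.exons)

    @property
    def cds_sequence(self) -> str:
        return self.spliced[self.cds_start:self.cds_end]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class IntronRecord:
    """One intron: coordinates, phase/region, splice class and GC."""

    gene_id: str
    ordinal: int            # 1-based, 5'->3'
    start: int              # gene-span coordinates, half-open
    end: int
    sequence: str
    phase: str              # "0" | "1" | "2" | "UTR5" | "UTR3"
    splice_class: str       # GT-AG | GC-AG | AT-AC | other
    gc: float | None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> str:
        return f"{self.gene_id}.I{self.ordinal}"


@dataclass
class IntronStats:
    """Per-species summary of intron structure."""

    species_id: str
    n_genes: int
    n_introns: int
    mean_length: float | None
    median_length: float | None
    length_histogram: list[int]
    bin_edges: list[float]
    phase_fractions: tuple[float, float, float] | None
    region_counts: tuple[int, int, int]  # (cds, utr5, utr3)
    splice_class_fractions: dict[str, float]
    mean_gc_introns: float | None
    mean_gc_cds: float | None
    introns_per_gene_mean: float

    def to_json(self) -> str:
        d = dict(self.__dict__)
        return json.dumps(d, indent=2, default=list)


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from numerator and denominator.

    Raises ``ValueError`` on an empty or all-N sequence rather than
    returning a misleading 0.
    """
    if not seq:
        raise ValueError("gc_fraction of empty sequence is undefined")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise ValueError("gc_fraction undefined: no unambiguous bases")
    return gc / acgt


def _splice_class(seq: str) -> str:
    if len(seq) < 4:
        return "other"
    donor, acceptor = seq[:2].upper(), seq[-2:].upper()
    if (donor, acceptor) == ("GT", "AG"):
        return "GT-AG"
    if (donor, acceptor) == ("GC", "AG"):
        return "GC-AG"
    if (donor, acceptor) == ("AT", "AC"):
        return "AT-AC"
    return "other"


def extract_introns(gene: GeneModel) -> list[IntronRecord]:
    """One record per inter-exon gap, ordered 5'->3'.

    Phase of a CDS intron is (coding nucleotides 5' of the insertion
    point) mod 3.  An insertion point at or before ``cds_start`` is UTR5;
    at or beyond ``cds_end`` is UTR3 (phases only for introns strictly
    inside the CDS).
    """
    gene.validate()
    records: list[IntronRecord] = []
    transcript_pos = 0
    for i in range(len(gene.exons) - 1):
        ex_s, ex_e = gene.exons[i]
        nxt_s = gene.exons[i + 1][0]
        transcript_pos += ex_e - ex_s
        t = transcript_pos  # insertion point, spliced coordinates
        if t <= gene.cds_start:
            phase = "UTR5"
        elif t >= gene.cds_end:
            phase = "UTR3"
        else:
            phase = str((t - gene.cds_start) % 3)
        seq = gene.sequence[ex_e:nxt_s]
        try:
            gc = gc_fraction(seq)
        except ValueError:
            gc = None
        records.append(
            IntronRecord(
                gene_id=gene.gene_id,
                ordinal=i + 1,
                start=ex_e,
                end=nxt_s,
                sequence=seq,
                phase=phase,
                splice_class=_splice_class(seq),
                gc=gc,
            )
        )
    return records


def load_gene_models(
    gff3_path: str,
    fasta_path: str,
    species_id: str = "",
) -> tuple[list[GeneModel], list[str]]:
    """Parse GFF3 gene/mRNA/exon/CDS features against a FASTA.

    Minus-strand genes are reverse-complemented and their coordinates
    remapped so every returned model is sense-strand.  Genes that fail an
    invariant are reported in the second return value (list of messages),
    not silently dropped; a CDS length not divisible by 3 flags the model
    ``incomplete`` instead of rejecting it.  A contig referenced by a gene
    but absent from the FASTA is a hard error.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    problems: list[str] = []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if len(mrnas) != 1:
            problems.append(
                f"{gid}: expected exactly one mRNA, found {len(mrnas)}; gene rejected"
            )
            continue
        mrna = mrnas[0]
        if gene.seqid not in contigs:
            raise GeneModelError(
                f"{gid}: contig {gene.seqid!r} missing from FASTA"
            )
        contig = contigs[gene.seqid]
        exon_feats = sorted(
            db.children(mrna, featuretype="exon"), key=lambda f: f.start
        )
        cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not exon_feats:
            exon_feats = cds_feats
        if not exon_feats:
            problems.append(f"{gid}: no exon or CDS features; gene rejected")
            continue
        g0 = gene.start - 1  # GFF3 is 1-based inclusive
        g1 = gene.end
        strand = gene.strand if gene.strand in "+-" else "+"
        span = contig[g0:g1]
        # gene-span plus-strand coordinates first
        exons = [(f.start - 1 - g0, f.end - g0) for f in exon_feats]
        cds_iv = [(f.start - 1 - g0, f.end - g0) for f in cds_feats]
        if strand == "-":
            L = g1 - g0
            span = revcomp(span)
            exons = sorted((L - e, L - s) for s, e in exons)
            cds_iv = sorted((L - e, L - s) for s, e in cds_iv)
        # CDS bounds in spliced-transcript coordinates
        if not cds_iv:
            problems.append(f"{gid}: no CDS features; gene rejected")
            continue
        cds_lo = cds_iv[0][0]
        cds_hi = cds_iv[-1][1]
        tpos = 0
        cds_start = cds_end = None
        for s, e in exons:
            if s <= cds_lo < e:
                cds_start = tpos + (cds_lo - s)
            if s < cds_hi <= e:
                cds_end = tpos + (cds_hi - s)
            tpos += e - s
        if cds_start is None or cds_end is None:
            problems.append(f"{gid}: CDS bounds outside exons; gene rejected")
            continue
        model = GeneModel(
            gene_id=gid,
            species_id=species_id,
            sequence=span,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
            strand_original=strand,
        )
        try:
            model.validate()
        except GeneModelError as exc:
            problems.append(str(exc))
            continue
        if (cds_end - cds_start) % 3 != 0:
            model.incomplete = True
            problems.append(
                f"{gid}: CDS length {cds_end - cds_start} not divisible by 3; "
                "flagged incomplete (excluded from phase statistics)"
            )
        models.append(model)
    return models, problems


def summarize_intron_stats(
    introns: list[IntronRecord],
    genes: list[GeneModel],
    bin_edges: list[float] | None = None,
    species_id: str = "",
    max_n_fraction: float = 0.10,
) -> IntronStats:
    """Aggregate intron statistics for one species.

    Median uses the lower of the two central values for even n (the
    convention common in genome summary tables).  Introns whose sequence
    is more than ``max_n_fraction`` N are kept for length/phase counts but
    excluded from GC averages.  Genes flagged incomplete contribute introns
    to length statistics but not to phase fractions.
    """
    if bin_edges is None:
        bin_edges = [0, 50, 100, 150, 200, 300, 500, 1000, float("inf")]
    incomplete = {g.gene_id for g in genes if g.incomplete}
    lengths = [r.length for r in introns]
    n = len(introns)
    if n:
        mean_length = sum(lengths) / n
        ls = sorted(lengths)
        median_length = float(ls[(n - 1) // 2])  # lower central value when even
    else:
        mean_length = median_length = None
    hist = [0] * (len(bin_edges) - 1)
    for L in lengths:
        for b in range(len(bin_edges) - 1):
            if bin_edges[b] <= L < bin_edges[b + 1]:
                hist[b] += 1
                break
    phase_counts = [0, 0, 0]
    region = {"cds": 0, "utr5": 0, "utr3": 0}
    for r in introns:
        if r.phase in "012":
            region["cds"] += 1
            if r.gene_id not in incomplete:
                phase_counts[int(r.phase)] += 1
        elif r.phase == "UTR5":
            region["utr5"] += 1
        else:
            region["utr3"] += 1
    tot_ph = sum(phase_counts)
    phase_fractions = tuple(c / tot_ph for c in phase_counts) if tot_ph else None
    sc: dict[str, int] = {}
    for r in introns:
        sc[r.splice_class] = sc.get(r.splice_class, 0) + 1
    splice_fr = {k: v / n for k, v in sc.items()} if n else {}
    gcs = [
        r.gc
        for r in introns
        if r.gc is not None
        and r.sequence.upper().count("N") <= max_n_fraction * max(r.length, 1)
    ]
    mean_gc_introns = sum(gcs) / len(gcs) if gcs else None
    cds_gcs = []
    for g in genes:
        try:
            cds_gcs.append(gc_fraction(g.cds_sequence))
        except ValueError:
            pass
    mean_gc_cds = sum(cds_gcs) / len(cds_gcs) if cds_gcs else None
    return IntronStats(
        species_id=species_id,
        n_genes=len(genes),
        n_introns=n,
        mean_length=mean_length,
        median_length=median_length,
        length_histogram=hist,
        bin_edges=list(bin_edges),
        phase_fractions=phase_fractions,
        region_counts=(region["cds"], region["utr5"], region["utr3"]),
        splice_class_fractions=splice_fr,
        mean_gc_introns=mean_gc_introns,
        mean_gc_cds=mean_gc_cds,
        introns_per_gene_mean=(n / len(genes)) if genes else 0.0,
    )


def introns_to_bed(introns: list[IntronRecord]) -> str:
    """BED6 text; name = gene_id.Iordinal, score = phase or -1 for UTR."""
    lines = []
    for r in introns:
        score = r.phase if r.phase in "012" else "-1"
        lines.append(
            f"{r.gene_id}\t{r.start}\t{r.end}\t{r.key}\t{score}\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def introns_to_fasta(introns: list[IntronRecord]) -> str:
    out = io.StringIO()
    for r in introns:
        out.write(f">{r.key} phase={r.phase} class={r.splice_class}\n")
        for i in range(0, len(r.sequence), 70):
            out.write(r.sequence[i:i + 70] + "\n")
    return out.getvalue()
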