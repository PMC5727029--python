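"""Gene annotation models: strand-aware exon/intron structure and region calls.

Every downstream stage (PAS region assignment, intronic ordinals, CDS
counting) relies on the representation built here.  All internal coordinates
are 0-based half-open; GTF input (1-based inclusive) and BED output convert
at the boundary.

Isoform handling: all annotated isoforms of a gene are merged.  Exons are the
interval union across isoforms; introns are the gaps between merged exons
(regions exonic in no isoform); the 3'-most exon is the most distal merged
block among the last exons of all isoforms, and every merged last-exon block
is treated as 3'UTR territory when classifying positions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import gffutils
from intervaltree import IntervalTree

__all__ = [
    "AnnotationError",
    "RegionClass",
    "GeneModel",
    "GeneModelSet",
    "load_annotation",
    "UTR3",
    "INTRON",
    "OTHER",
]

UTR3 = "UTR3"
INTRON = "INTRON"
OTHER = "OTHER"

#: intron ordinal labels in 5'->3' transcription order
ORDINALS = ("+1", "+2", "MIDDLE", "-2", "-1")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent gene annotation."""


@dataclass(frozen=True)
class RegionClass:
    """Region call for one genomic position relative to one gene."""

    label: str                     # UTR3 | INTRON | OTHER
    intron_ordinal: Optional[str]  # one of ORDINALS iff label == INTRON

    def __post_init__(self) -> None:
        if (self.label == INTRON) != (self.intron_ordinal is not None):
            raise ValueError("intron_ordinal must be set iff label is INTRON")


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intron_ordinal(index: int, n_introns: int) -> str:
    """Ordinal label of the intron at 0-based transcription-order `index`.

    First/last take precedence over second/second-to-last so that short genes
    get a deterministic labelling; genes with exactly four introns use
    {+1, +2, -2, -1} and MIDDLE is empty.
    """
    if index == 0:
        return "+1"
    if index == n_introns - 1:
        return "-1"
    if index == 1:
        return "+2"
    if index == n_introns - 2:
        return "-2"
    return "MIDDLE"


@dataclass
class GeneModel:
    """One gene's merged, strand-aware exon/intron/CDS structure."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]          # genomic order, merged across isoforms
    cds: list[tuple[int, int]] = field(default_factory=list)
    last_exon_blocks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: no exons")
        self.exons = _merge_intervals(self.exons)
        self.cds = _merge_intervals(self.cds)
        if not self.last_exon_blocks:
            self.last_exon_blocks = [self.three_prime_most_exon]
        else:
            self.last_exon_blocks = _merge_intervals(self.last_exon_blocks)

    # -- structure ---------------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exons_tx(self) -> list[tuple[int, int]]:
        """Exons in transcription order (reversed genomic order on '-')."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Introns in transcription order: gaps between consecutive exons."""
        gaps = [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]
        return gaps if self.strand == "+" else gaps[::-1]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def three_prime_most_exon(self) -> tuple[int, int]:
        blocks = self.last_exon_blocks or self.exons
        return max(blocks) if self.strand == "+" else min(blocks)

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the transcription-order 3' end (0-based)."""
        s, e = self.three_prime_most_exon
        return e - 1 if self.strand == "+" else s

    # -- classification ----------------------------------------------------
    def classify_position(self, pos: int, utr3_extension: int = 1000) -> RegionClass:
        """Region call for a genomic position on this gene's chromosome.

        UTR3 for positions in any merged last-exon block, or up to
        `utr3_extension` nt downstream of the 3'-most exon (unannotated
        extended 3'UTRs); INTRON with a transcription-order ordinal for
        positions in a merged intron; OTHER for everything else (internal
        exons, outside the gene).
        """
        for s, e in self.last_exon_blocks:
            if s <= pos < e:
                return RegionClass(UTR3, None)
        for i, (s, e) in enumerate(self.introns):
            if s <= pos < e:
                return RegionClass(INTRON, intron_ordinal(i, self.n_introns))
        s, e = self.three_prime_most_exon
        if self.strand == "+" and e <= pos < e + utr3_extension:
            return RegionClass(UTR3, None)
        if self.strand == "-" and s - utr3_extension <= pos < s:
            return RegionClass(UTR3, None)
        return RegionClass(OTHER, None)

    def utr3_offset(self, pos: int) -> int:
        """Transcript-orientation distance (nt) from the 3'-most exon start.

        Used as the 3'UTR length proxy of an isoform ending at `pos`; only
        differences between isoforms of one gene are ever interpreted.
        """
        s, e = self.three_prime_most_exon
        return (pos - s + 1) if self.strand == "+" else (e - pos)


class GeneModelSet:
    """Collection of gene models with positional lookup."""

    def __init__(self, models: Iterable[GeneModel], utr3_extension: int = 1000):
        self.models: dict[str, GeneModel] = {}
        self.utr3_extension = int(utr3_extension)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for m in models:
            if m.gene_id in self.models:
                raise AnnotationError(f"duplicate gene_id {m.gene_id}")
            self.models[m.gene_id] = m
        for m in self.models.values():
            s, e = m.span
            if m.strand == "+":
                e = e + self.utr3_extension
            else:
                s = max(0, s - self.utr3_extension)
            self._trees.setdefault((m.chrom, m.strand), IntervalTree()).addi(
                s, e, m.gene_id
            )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.models.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.models[gene_id]

    def assign_gene(self, chrom: str, strand: str, pos: int) -> Optional[str]:
        """Gene containing `pos` on the matching strand, or None.

        A gene whose annotated span contains the position beats one that only
        reaches it through the downstream 3'UTR extension; remaining ties go
        to the gene whose 3'-most exon is nearest the position.
        """
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return None
        hits = [iv.data for iv in tree.at(pos)]
        if not hits:
            return None
        if len(hits) == 1:
            return hits[0]
        in_span = [
            g for g in hits
            if self.models[g].span[0] <= pos < self.models[g].span[1]
        ]
        pool = in_span or hits
        return min(pool, key=lambda g: (abs(self.models[g].three_prime_end - pos), g))

    # -- I/O ---------------------------------------------------------------
    def to_bed(self, path: str) -> None:
        """BED6 export of 3'-most exons and introns (name = gene_id|ordinal)."""
        rows = []
        for m in self:
            s, e = m.three_prime_most_exon
            rows.append((m.chrom, s, e, f"{m.gene_id}|UTR3", 0, m.strand))
            for i, (is_, ie) in enumerate(m.introns):
                label = intron_ordinal(i, m.n_introns)
                rows.append((m.chrom, is_, ie, f"{m.gene_id}|{label}", 0, m.strand))
        with open(path, "w") as fh:
            for r in sorted(rows):
                fh.write("\t".join(map(str, r)) + "\n")


def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields"
                )
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}: line {lineno}: bad coordinate range {start}-{end}"
                )
            if parts[6] not in "+-.":
                raise AnnotationError(f"{path}: line {lineno}: bad strand {parts[6]!r}")


def load_annotation(path: str, utr3_extension: int = 1000) -> GeneModelSet:
    """Load a GTF with gene/transcript/exon/CDS features into merged models.

    GTF coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Genes without CDS features are flagged
    non-coding.  Malformed lines raise :class:`AnnotationError` naming the
    line number; a gene spanning two chromosomes or strands is rejected.
    """
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        last_blocks: list[tuple[int, int]] = []
        chroms = {gene.seqid}
        strands = {gene.strand}
        for tx in db.children(gene, featuretype="transcript"):
            tx_exons = []
            for ex in db.children(tx, featuretype="exon"):
                chroms.add(ex.seqid)
                strands.add(ex.strand)
                tx_exons.append((ex.start - 1, ex.end))
            for c in db.children(tx, featuretype="CDS"):
                cds.append((c.start - 1, c.end))
            if tx_exons:
                tx_exons.sort()
                exons.extend(tx_exons)
                last_blocks.append(tx_exons[-1] if gene.strand == "+" else tx_exons[0])
        if len(chroms) > 1:
            raise AnnotationError(f"gene {gid} spans multiple chromosomes: {chroms}")
        if len(strands) > 1:
            raise AnnotationError(f"gene {gid} mixes strands: {strands}")
        if not exons:
            continue
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                last_exon_blocks=last_blocks,
            )
        )
    return GeneModelSet(models, utr3_extension=utr3_extension)


def write_gtf(models: Iterable[GeneModel], path: str, source: str = "apakit") -> None:
    """Write gene models as GTF (one transcript per gene, merged exons)."""
    with open(path, "w") as fh:
        for m in models:
            s, e = m.span
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
            fh.write(
                "\t".join(
                    [m.chrom, source, "gene", str(s + 1), str(e), ".", m.strand, ".",
                     f'gene_id "{m.gene_id}";']
                )
                + "\n"
            )
            fh.write(
                "\t".join(
                    [m.chrom, source, "transcript", str(s + 1), str(e), ".", m.strand,
                     ".", attrs]
                )
                + "\n"
            )
            for es, ee in m.exons:
                fh.write(
                    "\t".join(
                        [m.chrom, source, "exon", str(es + 1), str(ee), ".", m.strand,
                         ".", attrs]
                    )
                    + "\n"
                )
            for cs, ce in m.cds:
                fh.write(
                    "\t".join(
                        [m.chrom, source, "CDS", str(cs + 1), str(ce), ".", m.strand,
                         "0", attrs]
                    )
                    + "\n"
                )


def classify_position(model: GeneModel, pos: int, utr3_extension: int = 1000) -> RegionClass:
    """Functional alias for :meth:`GeneModel.classify_position`."""
    return model.classify_position(pos, utr3_extension=utr3_extension)
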