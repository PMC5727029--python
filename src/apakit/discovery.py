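"""Poly(A)-site discovery from 3'-end sequencing alignments.

Reads whose tail-side soft clip is a run of >= 2 untemplated adenosines
(transcript orientation) mark genuine cleavage events; cleavage positions
within 24 nt of each other are merged by single-linkage chaining into PAS
clusters; clusters sitting immediately upstream of genomic A-rich tracts are
discarded as internal-priming artefacts; surviving clusters are quantified
per sample into a :class:`~apakit.matrix.PASCountMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .matrix import PASCountMatrix

__all__ = [
    "PASRead",
    "PASCluster",
    "extract_pas_reads",
    "single_linkage_partition",
    "cluster_pas",
    "filter_internal_priming",
    "quantify",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass(frozen=True)
class PASRead:
    """One accepted PAS-supporting read collapsed to its cleavage position."""

    sample: str
    chrom: str
    strand: str     # transcript strand
    position: int   # genomic coordinate of the last transcribed base (0-based)


@dataclass
class PASCluster:
    """A single-linkage cluster of cleavage positions (one poly(A) site)."""

    chrom: str
    strand: str
    members: dict                 # position -> total read count
    sample_counts: dict           # sample -> read count
    representative_pos: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty cluster")
        best = max(self.members.values())
        candidates = [p for p, c in self.members.items() if c == best]
        # ties break toward the transcript-3'-most (distal) position
        self.representative_pos = (
            max(candidates) if self.strand == "+" else min(candidates)
        )

    @property
    def pas_id(self) -> str:
        return f"{self.chrom}:{self.strand}:{self.representative_pos}"

    @property
    def total_reads(self) -> int:
        return sum(self.sample_counts.values())


def _clip_is_tail(clip: str, expected_base: str) -> bool:
    """Tail clips must be a strict run of the expected base (A or T)."""
    return len(clip) > 0 and set(clip.upper()) <= {expected_base}


def extract_pas_reads(
    sam_path: str,
    sample: str,
    genome: Optional[dict] = None,
    min_unaligned_t: int = 2,
    orientation: str = "sense",
) -> list[PASRead]:
    """Collect cleavage positions from tail-clipped alignments.

    A read qualifies iff its transcript-3' soft clip is a strict run of
    poly(A)-tail bases of which at least `min_unaligned_t` are untemplated
    (do not match the genome beyond the alignment).  With ``orientation=
    "sense"`` the read maps on the transcript strand; ``"antisense"`` flips
    the inferred transcript strand.  Without a genome, templated-ness cannot
    be checked and every clipped tail base counts as unaligned.
    """
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"unknown orientation {orientation!r}")
    out: list[PASRead] = []
    n_reads = 0
    n_clipped = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            n_reads += 1
            cig = read.cigartuples
            if not cig:
                continue
            read_strand = "-" if read.is_reverse else "+"
            tx_strand = (
                read_strand if orientation == "sense"
                else ("-" if read_strand == "+" else "+")
            )
            seq = read.query_sequence or ""
            chrom = read.reference_name
            ref_seq = genome.get(chrom) if genome is not None else None
            if tx_strand == "+":
                # tail clip at the genomic right end; bases are A on the
                # forward strand
                if cig[-1][0] != 4:  # BAM_CSOFT_CLIP
                    continue
                k = cig[-1][1]
                n_clipped += 1
                clip = seq[len(seq) - k:]
                if not _clip_is_tail(clip, "A"):
                    continue
                end = read.reference_end  # first position after alignment
                if ref_seq is None:
                    unaligned = len(clip)
                else:
                    unaligned = sum(
                        1
                        for i in range(k)
                        if end + i >= len(ref_seq) or ref_seq[end + i].upper() != "A"
                    )
                if unaligned >= min_unaligned_t:
                    out.append(PASRead(sample, chrom, tx_strand, read.reference_end - 1))
            else:
                # tail clip at the genomic left end; poly(A) reads T on the
                # forward strand
                if cig[0][0] != 4:
                    continue
                k = cig[0][1]
                n_clipped += 1
                clip = seq[:k]
                if not _clip_is_tail(clip, "T"):
                    continue
                start = read.reference_start
                if ref_seq is None:
                    unaligned = len(clip)
                else:
                    unaligned = sum(
                        1
                        for i in range(1, k + 1)
                        if start - i < 0 or ref_seq[start - i].upper() != "T"
                    )
                if unaligned >= min_unaligned_t:
                    out.append(PASRead(sample, chrom, tx_strand, start))
    if n_reads > 0 and n_clipped == 0:
        warnings.warn(
            f"{sam_path}: no soft-clip information on any read; "
            "no PAS-supporting reads extracted",
            stacklevel=2,
        )
    return out


def single_linkage_partition(positions: Sequence[int], max_gap: int = 24) -> list[list[int]]:
    """Partition sorted-able 1-D positions by single-linkage chaining.

    Two positions share a cluster iff connected by a chain of steps each
    <= max_gap.  On a line this is equivalent to splitting the sorted unique
    positions wherever consecutive values differ by more than max_gap.
    """
    uniq = sorted(set(int(p) for p in positions))
    clusters: list[list[int]] = []
    for p in uniq:
        if clusters and p - clusters[-1][-1] <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def cluster_pas(reads: Iterable[PASRead], max_gap: int = 24) -> list[PASCluster]:
    """Single-linkage clustering of cleavage positions per chromosome+strand."""
    grouped: dict[tuple[str, str], list[PASRead]] = {}
    for r in reads:
        grouped.setdefault((r.chrom, r.strand), []).append(r)
    clusters: list[PASCluster] = []
    for (chrom, strand), rs in sorted(grouped.items()):
        pos_counts: dict[int, int] = {}
        pos_samples: dict[int, dict] = {}
        for r in rs:
            pos_counts[r.position] = pos_counts.get(r.position, 0) + 1
            pos_samples.setdefault(r.position, {})
            pos_samples[r.position][r.sample] = (
                pos_samples[r.position].get(r.sample, 0) + 1
            )
        for member_positions in single_linkage_partition(pos_counts, max_gap):
            members = {p: pos_counts[p] for p in member_positions}
            sample_counts: dict[str, int] = {}
            for p in member_positions:
                for s, c in pos_samples[p].items():
                    sample_counts[s] = sample_counts.get(s, 0) + c
            clusters.append(
                PASCluster(chrom=chrom, strand=strand, members=members,
                           sample_counts=sample_counts)
            )
    return clusters


def filter_internal_priming(
    clusters: Iterable[PASCluster],
    genome: dict,
    window: int = 10,
    min_a: int = 6,
    enabled: bool = True,
) -> list[PASCluster]:
    """Drop clusters whose downstream genomic window is adenosine-rich.

    The window runs `window` nt downstream of the representative cleavage
    site in transcript orientation; a cluster with >= min_a A residues there
    is treated as an internal-priming artefact.  Bases beyond the contig end
    count as non-A.
    """
    if not enabled:
        return list(clusters)
    kept = []
    for cl in clusters:
        seq = genome.get(cl.chrom, "")
        p = cl.representative_pos
        if cl.strand == "+":
            down = seq[p + 1:p + 1 + window].upper()
            n_a = down.count("A")
        else:
            down = seq[max(p - window, 0):p].upper()
            n_a = down.count("T")  # A in transcript sense
        if n_a < min_a:
            kept.append(cl)
    return kept


def quantify(
    clusters: Iterable[PASCluster],
    sample_sheet: pd.DataFrame,
    min_cluster_reads: int = 0,
) -> PASCountMatrix:
    """Assemble the PAS x sample count matrix from clusters.

    Every accepted read sits in exactly one cluster, so column sums equal the
    per-sample accepted-read totals.  Samples present in the clusters but
    absent from the sheet raise; clusters below `min_cluster_reads` total are
    dropped when the floor is positive.
    """
    clusters = list(clusters)
    known = set(sample_sheet.index)
    seen = {s for cl in clusters for s in cl.sample_counts}
    unknown = sorted(seen - known)
    if unknown:
        raise ValueError(f"samples missing from sample sheet: {unknown}")
    if min_cluster_reads > 0:
        clusters = [c for c in clusters if c.total_reads >= min_cluster_reads]
    index = pd.Index([c.pas_id for c in clusters], name="pas_id")
    counts = pd.DataFrame(
        0, index=index, columns=list(sample_sheet.index), dtype=int
    )
    meta = pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "strand": [c.strand for c in clusters],
            "position": [c.representative_pos for c in clusters],
        },
        index=index,
    )
    for c in clusters:
        for s, n in c.sample_counts.items():
            counts.at[c.pas_id, s] = n
    return PASCountMatrix(counts, meta, sample_sheet)


def write_clusters_bed(clusters: Iterable[PASCluster], path: str) -> None:
    """BED6 export: name = cluster id, score = total supporting reads."""
    rows = sorted(
        (c.chrom, c.representative_pos, c.representative_pos + 1,
         c.pas_id, c.total_reads, c.strand)
        for c in clusters
    )
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
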