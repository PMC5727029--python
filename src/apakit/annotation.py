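"""PAS annotation: poly(A) signal hexamers, gene regions, and census tables.

The poly(A) signal is searched in the -40..-1 nt window upstream of the
cleavage site in transcript orientation, with the priority
AAUAAA > AUUAAA > close single-substitution variants > none; DNA is read as
RNA (T == U) and the minus strand is reverse-complemented.  Region
assignment routes through :mod:`apakit.gene_models`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .gene_models import GeneModelSet, INTRON, UTR3
from .matrix import PASCountMatrix
from .stats import StatResult, binomial_test
from .synthetic import (
    HEX_AAUAAA,
    HEX_AUUAAA,
    HEX_NONE,
    HEX_OTHER,
    VARIANT_HEXAMERS_DNA,
)

__all__ = [
    "HexamerClass",
    "classify_hexamer",
    "annotate_hexamers",
    "annotate_regions",
    "census",
    "region_fraction_test",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class HexamerClass:
    """Result of the upstream poly(A)-signal search for one PAS."""

    label: str               # AAUAAA | AUUAAA | OTHER_VARIANT | NONE
    matched_hexamer: str     # RNA alphabet; empty iff label == NONE
    offset: Optional[int]    # match start relative to the PAS (e.g. -20)

    def __post_init__(self) -> None:
        if (self.label == HEX_NONE) != (self.matched_hexamer == ""):
            raise ValueError("matched_hexamer must be empty iff label is NONE")


def _upstream_window(genome: dict, chrom: str, strand: str, position: int,
                     window: tuple[int, int]) -> str:
    """Transcript-sense sequence of the window (e.g. -40..-1) upstream of PAS."""
    seq = genome.get(chrom, "")
    lo, hi = window  # e.g. (-40, -1), inclusive, transcript orientation
    if strand == "+":
        a, b = position + lo, position + hi + 1
        return seq[max(a, 0):max(b, 0)].upper()
    a, b = position - hi, position - lo + 1
    sub = seq[max(a, 0):max(b, 0)].upper()
    return sub.translate(_RC)[::-1]


def classify_hexamer(
    genome: dict,
    chrom: str,
    strand: str,
    position: int,
    window: tuple[int, int] = (-40, -1),
    variant_set: tuple[str, ...] = VARIANT_HEXAMERS_DNA,
) -> HexamerClass:
    """Classify the poly(A) signal upstream of one cleavage site.

    Within a priority tier the occurrence nearest the PAS wins.  A window
    truncated by the contig edge is searched as far as it exists; the search
    never raises.
    """
    up = _upstream_window(genome, chrom, strand, position, window)
    tiers = (
        (HEX_AAUAAA, ("AATAAA",)),
        (HEX_AUUAAA, ("ATTAAA",)),
        (HEX_OTHER, tuple(variant_set)),
    )
    for label, hexamers in tiers:
        best = None  # (start index in `up`, hexamer)
        for h in hexamers:
            start = up.rfind(h)  # right-most = nearest the PAS
            if start >= 0 and (best is None or start > best[0]):
                best = (start, h)
        if best is not None:
            start, h = best
            # index 0 of `up` sits at window[1] - (len(up) - 1) relative to PAS
            offset = window[1] - (len(up) - 1) + start
            return HexamerClass(label, h.replace("T", "U"), offset)
    return HexamerClass(HEX_NONE, "", None)


def annotate_hexamers(matrix: PASCountMatrix, genome: dict, **kwargs) -> PASCountMatrix:
    """Fill the matrix meta's `hexamer` column from the genome sequence."""
    labels = []
    for pas_id, m in matrix.meta.iterrows():
        hc = classify_hexamer(genome, m["chrom"], m["strand"], int(m["position"]),
                              **kwargs)
        labels.append(hc.label)
    matrix.meta["hexamer"] = labels
    return matrix


def annotate_regions(
    matrix: PASCountMatrix,
    models: GeneModelSet,
) -> PASCountMatrix:
    """Assign each PAS to at most one gene and classify its region.

    The PAS goes to the containing gene on the matching strand (nearest
    3'-most exon on ties); region and intron ordinal come from the gene
    model.  Unassigned or internal-exon PASs are retained with region OTHER
    and excluded from APA testing downstream.
    """
    gene_ids, regions, ordinals, n_introns, offsets = [], [], [], [], []
    for pas_id, m in matrix.meta.iterrows():
        gid = models.assign_gene(m["chrom"], m["strand"], int(m["position"]))
        if gid is None:
            gene_ids.append(np.nan)
            regions.append("OTHER")
            ordinals.append(None)
            n_introns.append(np.nan)
            offsets.append(np.nan)
            continue
        model = models[gid]
        rc = model.classify_position(int(m["position"]),
                                     utr3_extension=models.utr3_extension)
        gene_ids.append(gid)
        regions.append(rc.label)
        ordinals.append(rc.intron_ordinal)
        n_introns.append(model.n_introns)
        offsets.append(
            model.utr3_offset(int(m["position"])) if rc.label == UTR3 else np.nan
        )
    matrix.meta["gene_id"] = gene_ids
    matrix.meta["region"] = regions
    matrix.meta["intron_ordinal"] = ordinals
    matrix.meta["n_introns"] = n_introns
    matrix.meta["utr3_offset"] = offsets
    return matrix


@dataclass
class CensusResult:
    """Summary tables of the PAS census."""

    pas_per_gene: pd.Series           # k -> number of genes with k detected PASs
    hexamer_fractions: pd.DataFrame   # condition x hexamer class
    region_counts: pd.DataFrame       # condition x region (detected PASs)

    def region_fraction_p(self, condition_a: str, condition_b: str) -> StatResult:
        """Binomial test of the intronic-PAS fraction, condition A vs B."""
        ra = self.region_counts.loc[condition_a]
        rb = self.region_counts.loc[condition_b]
        return region_fraction_test(
            int(ra.get(INTRON, 0)), int(ra.get(UTR3, 0)),
            int(rb.get(INTRON, 0)), int(rb.get(UTR3, 0)),
        )


def census(matrix: PASCountMatrix, min_cluster_reads: int = 2) -> CensusResult:
    """Detected-PAS census: per-gene counts, hexamer and region composition.

    A PAS counts as detected in a condition when it has at least
    `min_cluster_reads` reads in at least one sample of that condition.
    """
    conditions = list(matrix.samples["condition"].unique())
    detected = {}
    for cond in conditions:
        cols = matrix.samples_of(cond)
        detected[cond] = (matrix.counts[cols] >= min_cluster_reads).any(axis=1)
    any_detected = pd.concat(detected, axis=1).any(axis=1)

    assigned = matrix.meta["gene_id"].notna() & any_detected
    per_gene = matrix.meta.loc[assigned].groupby("gene_id").size()
    pas_per_gene = per_gene.value_counts().sort_index()
    pas_per_gene.index.name = "n_pas"

    hex_rows = {}
    region_rows = {}
    for cond in conditions:
        sel = detected[cond]
        hx = matrix.meta.loc[sel, "hexamer"].dropna()
        hex_rows[cond] = hx.value_counts(normalize=True) if len(hx) else pd.Series(dtype=float)
        region_rows[cond] = matrix.meta.loc[sel, "region"].value_counts()
    hexamer_fractions = (
        pd.DataFrame(hex_rows).T.reindex(
            columns=[HEX_AAUAAA, HEX_AUUAAA, HEX_OTHER, HEX_NONE]
        ).fillna(0.0)
    )
    region_counts = pd.DataFrame(region_rows).T.fillna(0).astype(int)
    return CensusResult(pas_per_gene, hexamer_fractions, region_counts)


def region_fraction_test(
    count_intronic_a: int,
    count_utr3_a: int,
    count_intronic_b: int,
    count_utr3_b: int,
) -> StatResult:
    """Exact two-sided binomial test of region fractions between conditions.

    The intronic count in condition A is tested against the intronic fraction
    estimated from condition B.  Zero totals in either condition are
    undefined (NaN p).
    """
    n_a = count_intronic_a + count_utr3_a
    n_b = count_intronic_b + count_utr3_b
    if n_a == 0 or n_b == 0:
        return StatResult(np.nan, np.nan, "binomial-exact")
    p0 = count_intronic_b / n_b
    return binomial_test(count_intronic_a, n_a, p0)
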