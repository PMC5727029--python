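"""Functional consequences of APA calls.

3'UTR shortening can strip miRNA target sites that lie in the alternative
UTR (between the proximal and distal PAS); intronic APA activation truncates
the transcript and can remove or split protein domains encoded downstream of
the activated site.  Classification is interval logic in genomic
coordinates against the called PAS positions — no transcript re-splicing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_models import GeneModelSet

__all__ = [
    "read_features",
    "write_features",
    "removed_mirna_sites",
    "removed_domains",
    "gene_set_overlap",
    "OverlapResult",
]

FEATURE_COLUMNS = ["chrom", "start", "end", "feature_id", "score", "strand",
                   "gene_id", "kind"]

REMOVED = "REMOVED"
RETAINED = "RETAINED"
TRUNCATED = "TRUNCATED"


def read_features(path: str) -> pd.DataFrame:
    """Read a BED6+2 feature file (feature_id in name, gene_id/kind appended)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 7:
        raise ValueError(f"{path}: expected BED6 plus a gene_id column")
    df = df.iloc[:, :8]
    df.columns = FEATURE_COLUMNS[: df.shape[1]]
    if "kind" not in df.columns:
        df["kind"] = ""
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: feature with start >= end")
    return df


def write_features(features: pd.DataFrame, path: str) -> None:
    features[FEATURE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _autr_interval(prox_pos: int, dist_pos: int) -> tuple[int, int]:
    """Genomic half-open interval strictly between the two PAS positions."""
    lo, hi = sorted((prox_pos, dist_pos))
    return lo + 1, hi


@dataclass
class TallyResult:
    """Per-feature classifications plus feature- and gene-level tallies."""

    features: pd.DataFrame     # input columns + status
    feature_tally: pd.Series   # status -> count (analysed gene set)
    gene_tally: pd.Series      # genes with >= 1 removed vs none


def removed_mirna_sites(events: pd.DataFrame, sites: pd.DataFrame) -> TallyResult:
    """Classify miRNA target sites as removed or retained by 3'UTR shortening.

    A site of a SHORTENED gene is REMOVED iff it lies strictly within the
    aUTR of that gene's proximal/distal PAS pair; all other sites (outside
    the aUTR, or in genes without a shortening call) are RETAINED.  Sites on
    the wrong strand are ignored with a warning.  Tallies cover sites of
    genes with a shortening call.
    """
    ev = events.set_index("gene_id")
    pas_pos = {}
    for gid, row in ev.iterrows():
        if row["event_class"] == "SHORTENED":
            # pas_id format chrom:strand:pos
            prox = int(str(row["proximal_id"]).rsplit(":", 1)[1])
            dist = int(str(row["distal_id"]).rsplit(":", 1)[1])
            pas_pos[gid] = _autr_interval(prox, dist)

    statuses = []
    for _, site in sites.iterrows():
        gid = site["gene_id"]
        if gid in pas_pos:
            lo, hi = pas_pos[gid]
            status = REMOVED if (site["start"] >= lo and site["end"] <= hi) else RETAINED
        else:
            status = RETAINED
        statuses.append(status)
    out = sites.copy()
    out["status"] = statuses

    analysed = out[out["gene_id"].isin(pas_pos)]
    feature_tally = analysed["status"].value_counts().reindex(
        [REMOVED, RETAINED], fill_value=0
    )
    by_gene = analysed.groupby("gene_id")["status"].apply(
        lambda s: REMOVED if (s == REMOVED).any() else RETAINED
    )
    gene_tally = by_gene.value_counts().reindex([REMOVED, RETAINED], fill_value=0)
    return TallyResult(out, feature_tally, gene_tally)


def removed_domains(
    events: pd.DataFrame,
    domains: pd.DataFrame,
    models: GeneModelSet,
) -> TallyResult:
    """Classify protein domains affected by intronic APA activation.

    For a gene with an ACTIVATED intronic event, a domain entirely
    downstream (transcript orientation) of the activated intronic PAS is
    REMOVED, one spanning it is TRUNCATED, one entirely upstream is
    RETAINED; domains of non-activated genes are RETAINED.  Domains not
    overlapping any exon of their gene are RETAINED with a warning.
    Feature tallies are reported both ways the field counts them: the gene
    tally uses REMOVED-or-TRUNCATED as the affected category.
    """
    ev = events.set_index("gene_id")
    if "intronic_pas_pos" not in ev.columns:
        raise ValueError("removed_domains needs intronic-mode events "
                         "(with intronic_pas_pos)")
    bp = {
        gid: int(row["intronic_pas_pos"])
        for gid, row in ev.iterrows()
        if row["event_class"] == "ACTIVATED" and np.isfinite(row["intronic_pas_pos"])
    }

    statuses = []
    for _, dom in domains.iterrows():
        gid = dom["gene_id"]
        if gid not in bp:
            statuses.append(RETAINED)
            continue
        model = models[gid]
        if not any(dom["start"] < e and dom["end"] > s for s, e in model.exons):
            warnings.warn(
                f"domain {dom['feature_id']} does not overlap exons of {gid}",
                stacklevel=2,
            )
            statuses.append(RETAINED)
            continue
        p = bp[gid]
        if model.strand == "+":
            downstream = dom["start"] > p
            upstream = dom["end"] <= p
        else:
            downstream = dom["end"] <= p
            upstream = dom["start"] > p
        if downstream:
            statuses.append(REMOVED)
        elif upstream:
            statuses.append(RETAINED)
        else:
            statuses.append(TRUNCATED)
    out = domains.copy()
    out["status"] = statuses

    analysed = out[out["gene_id"].isin(bp)]
    feature_tally = analysed["status"].value_counts().reindex(
        [REMOVED, TRUNCATED, RETAINED], fill_value=0
    )
    by_gene = analysed.groupby("gene_id")["status"].apply(
        lambda s: REMOVED if s.isin([REMOVED, TRUNCATED]).any() else RETAINED
    )
    gene_tally = by_gene.value_counts().reindex([REMOVED, RETAINED], fill_value=0)
    return TallyResult(out, feature_tally, gene_tally)


@dataclass(frozen=True)
class OverlapResult:
    """Exact overlap statistics between two gene sets."""

    n_a: int
    n_b: int
    n_common: int
    percent_of_a: float  # 100 * |A ∩ B| / |A|, one decimal; NaN for empty A


def gene_set_overlap(set_a, set_b) -> OverlapResult:
    """Count the overlap of two gene-identifier sets.

    The percentage is of set A covered by the intersection, rounded to one
    decimal; an empty A yields NaN.
    """
    a, b = set(set_a), set(set_b)
    common = a & b
    pct = round(100.0 * len(common) / len(a), 1) if a else float("nan")
    return OverlapResult(len(a), len(b), len(common), pct)
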