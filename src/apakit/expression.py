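"""Gene-level differential expression and APA-expression coupling.

Expression is quantified from CDS-overlapping reads only, so 3'UTR changes
cannot leak into the gene-level signal.  The differential test is a Welch
t-test on log2 library-size-normalised counts with Benjamini-Hochberg FDR;
genes pass at |fold change| > fc_cut and FDR < fdr_cut.  Coupling analyses
compare the expression log2 ratios of genes grouped by their APA class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import pysam
from scipy import stats as _sps

from .gene_models import GeneModel, GeneModelSet
from .matrix import CONTROL, TREATED
from .stats import StatResult, bh_fdr, log2_ratio, size_factors, wilcoxon_rank_sum

__all__ = [
    "DifferentialExpressionModel",
    "DEResults",
    "count_cds_reads",
    "de_test",
    "apa_expression_coupling",
    "region_restricted_ratio",
    "platform_correlation",
    "UP",
    "DOWN",
]

UP = "UP"
DOWN = "DOWN"
NC = "NC"


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_cds_reads(
    sam_paths: dict,
    models: GeneModelSet,
    stranded: bool = True,
) -> pd.DataFrame:
    """Gene x sample counts of reads overlapping coding sequence.

    A primary alignment counts toward a gene iff >= 1 bp of it overlaps that
    gene's CDS on the matching strand; reads touching the CDS of more than
    one gene are discarded as ambiguous.
    """
    from intervaltree import IntervalTree

    trees: dict[tuple[str, Optional[str]], IntervalTree] = {}
    for m in models:
        key = (m.chrom, m.strand if stranded else None)
        tree = trees.setdefault(key, IntervalTree())
        for s, e in m.cds:
            tree.addi(s, e, m.gene_id)

    genes = [m.gene_id for m in models]
    data = {}
    for sample, path in sam_paths.items():
        counts = {g: 0 for g in genes}
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for read in sam:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                strand = ("-" if read.is_reverse else "+") if stranded else None
                tree = trees.get((read.reference_name, strand))
                if tree is None:
                    continue
                hits = {
                    iv.data
                    for iv in tree.overlap(read.reference_start, read.reference_end)
                }
                if len(hits) == 1:
                    counts[hits.pop()] += 1
        data[sample] = [counts[g] for g in genes]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DifferentialExpressionModel:
    """Two-condition differential expression on a gene x sample count matrix.

    Size factors are median-of-ratios; the per-gene test is a two-sided
    moderated t-test on log2(normalised count + 1): the pooled within-group
    variance is shrunk toward the median across genes with `prior_df`
    pseudo-degrees of freedom, the standard remedy for the instability of
    per-gene variances at a handful of replicates.  FDR is
    Benjamini-Hochberg; UP/DOWN requires FDR < fdr_cut and fold change
    beyond fc_cut.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        design: pd.DataFrame,
        fc_cut: float = 1.2,
        fdr_cut: float = 0.1,
        prior_df: float = 10.0,
        control: str = CONTROL,
        treated: str = TREATED,
    ):
        self.counts = counts
        self.design = design
        self.fc_cut = float(fc_cut)
        self.fdr_cut = float(fdr_cut)
        self.prior_df = float(prior_df)
        self.control = control
        self.treated = treated
        for cond in (control, treated):
            if (design["condition"] == cond).sum() < 2:
                raise ValueError(f"need >= 2 replicates for condition {cond!r}")

    def fit(self) -> "DEResults":
        sf = size_factors(self.counts)
        norm = self.counts / sf
        ctrl = [s for s in self.counts.columns
                if self.design.at[s, "condition"] == self.control]
        trt = [s for s in self.counts.columns
               if self.design.at[s, "condition"] == self.treated]
        log_ctrl = np.log2(norm[ctrl].to_numpy() + 1.0)
        log_trt = np.log2(norm[trt].to_numpy() + 1.0)
        n_c, n_t = log_ctrl.shape[1], log_trt.shape[1]
        df_resid = n_c + n_t - 2
        var_c = log_ctrl.var(axis=1, ddof=1)
        var_t = log_trt.var(axis=1, ddof=1)
        s2 = ((n_c - 1) * var_c + (n_t - 1) * var_t) / df_resid
        s2_prior = float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 0.0
        s2_shrunk = (self.prior_df * s2_prior + df_resid * s2) / (
            self.prior_df + df_resid
        )
        diff = log_trt.mean(axis=1) - log_ctrl.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(s2_shrunk * (1.0 / n_c + 1.0 / n_t))
            tstat = diff / se
            p = 2.0 * _sps.t.sf(np.abs(tstat), df=self.prior_df + df_resid)
        mean_c = norm[ctrl].mean(axis=1)
        mean_t = norm[trt].mean(axis=1)
        log2_fc = np.log2((mean_t + 0.5) / (mean_c + 0.5))
        all_zero = (self.counts.sum(axis=1) == 0).to_numpy()
        p = np.where(all_zero, np.nan, p)
        fdr = bh_fdr(p)
        lfc_cut = np.log2(self.fc_cut)
        classes = np.where(
            np.isfinite(fdr) & (fdr < self.fdr_cut) & (np.abs(log2_fc) > lfc_cut),
            np.where(log2_fc > 0, UP, DOWN),
            NC,
        )
        table = pd.DataFrame(
            {
                "base_mean": norm.mean(axis=1),
                "log2_ratio": log2_fc,
                "p_value": p,
                "fdr": fdr,
                "de_class": classes,
            },
            index=self.counts.index,
        )
        return DEResults(model=self, table=table, size_factors_=sf)


@dataclass
class DEResults:
    """Differential-expression table with per-class tallies."""

    model: DifferentialExpressionModel
    table: pd.DataFrame
    size_factors_: pd.Series

    def class_counts(self) -> pd.Series:
        return self.table["de_class"].value_counts().reindex(
            [UP, DOWN, NC], fill_value=0
        )

    def summary(self) -> str:
        cc = self.class_counts()
        return (
            f"Differential expression: {len(self.table)} genes, "
            f"fc_cut={self.model.fc_cut}, fdr_cut={self.model.fdr_cut}\n"
            f"  UP: {cc[UP]}  DOWN: {cc[DOWN]}  NC: {cc[NC]}"
        )


def de_test(counts: pd.DataFrame, design: pd.DataFrame, fc_cut: float = 1.2,
            fdr_cut: float = 0.1, **kwargs) -> DEResults:
    """Functional wrapper over :class:`DifferentialExpressionModel`."""
    return DifferentialExpressionModel(counts, design, fc_cut=fc_cut,
                                       fdr_cut=fdr_cut, **kwargs).fit()


# ---------------------------------------------------------------------------
# coupling analyses
# ---------------------------------------------------------------------------

@dataclass
class CouplingResult:
    """Expression change distributions per APA class with pairwise tests."""

    summary: pd.DataFrame    # per class: n, median, q1, q3, mean
    pairwise_p: pd.DataFrame # class x class Wilcoxon p (NaN on diagonal)
    values: dict             # class -> log2 ratio array


def apa_expression_coupling(events: pd.DataFrame, de_table: pd.DataFrame) -> CouplingResult:
    """Relate APA classes to gene-expression log2 ratios.

    `events` is an APAResults.events frame; `de_table` a DEResults.table.
    Classes with a single gene get summaries but NaN test entries.
    """
    merged = events.set_index("gene_id").join(de_table[["log2_ratio"]], how="inner")
    classes = [c for c in merged["event_class"].unique()]
    values = {
        c: merged.loc[merged["event_class"] == c, "log2_ratio"].dropna().to_numpy()
        for c in classes
    }
    rows = []
    for c in classes:
        v = values[c]
        rows.append(
            dict(event_class=c, n=len(v),
                 median=np.median(v) if len(v) else np.nan,
                 q1=np.percentile(v, 25) if len(v) else np.nan,
                 q3=np.percentile(v, 75) if len(v) else np.nan,
                 mean=v.mean() if len(v) else np.nan)
        )
    summary = pd.DataFrame(rows).set_index("event_class")
    pairwise = pd.DataFrame(np.nan, index=classes, columns=classes)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            if len(values[a]) >= 2 and len(values[b]) >= 2:
                p = wilcoxon_rank_sum(values[a], values[b]).p_value
                pairwise.loc[a, b] = pairwise.loc[b, a] = p
    return CouplingResult(summary=summary, pairwise_p=pairwise, values=values)


def region_restricted_ratio(
    sam_paths: dict,
    design: pd.DataFrame,
    model: GeneModel,
    breakpoint: int,
    pseudocount: float = 0.5,
    control: str = CONTROL,
    treated: str = TREATED,
    stranded: bool = True,
) -> pd.DataFrame:
    """Condition log2 ratios for the gene regions flanking an intronic PAS.

    Reads are split at `breakpoint` (genomic coordinate inside the gene) into
    the transcript-orientation upstream and downstream regions; each region's
    treated/control ratio is computed on pooled counts.  A region with zero
    reads in both conditions reports NaN.
    """
    s, e = model.span
    if not s <= breakpoint < e:
        raise ValueError(f"breakpoint {breakpoint} outside gene {model.gene_id}")
    counts = {"upstream": {control: 0, treated: 0},
              "downstream": {control: 0, treated: 0}}
    for sample, path in sam_paths.items():
        cond = design.at[sample, "condition"]
        if cond not in (control, treated):
            continue
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for read in sam:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.reference_name != model.chrom:
                    continue
                if stranded:
                    rs = "-" if read.is_reverse else "+"
                    if rs != model.strand:
                        continue
                mid = (read.reference_start + read.reference_end) // 2
                if not s <= mid < e:
                    continue
                after_bp = mid >= breakpoint
                downstream = after_bp if model.strand == "+" else not after_bp
                counts["downstream" if downstream else "upstream"][cond] += 1
    rows = []
    for region in ("upstream", "downstream"):
        c, t = counts[region][control], counts[region][treated]
        ratio = log2_ratio(t, c, pseudocount) if (c + t) > 0 else np.nan
        rows.append(dict(region=region, control=c, treated=t, log2_ratio=ratio))
    return pd.DataFrame(rows).set_index("region")


def platform_correlation(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    design_a: pd.DataFrame,
    design_b: pd.DataFrame,
    genes: Optional[list] = None,
    pseudocount: float = 0.5,
    control: str = CONTROL,
    treated: str = TREATED,
) -> float:
    """Pearson r of per-gene condition log2 ratios between two count sources.

    Ratios use replicate-pooled, library-size-normalised counts.  Returns NaN
    when either ratio vector is constant or fewer than 3 genes are shared.
    """
    shared = counts_a.index.intersection(counts_b.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    if len(shared) < 3:
        return float("nan")

    def ratios(counts, design):
        sf = size_factors(counts)
        norm = counts / sf
        ctrl = [s for s in counts.columns if design.at[s, "condition"] == control]
        trt = [s for s in counts.columns if design.at[s, "condition"] == treated]
        return np.log2((norm[trt].mean(axis=1) + pseudocount)
                       / (norm[ctrl].mean(axis=1) + pseudocount))

    ra = ratios(counts_a, design_a).loc[shared]
    rb = ratios(counts_b, design_b).loc[shared]
    if ra.std(ddof=0) == 0 or rb.std(ddof=0) == 0:
        return float("nan")
    return float(_sps.pearsonr(ra, rb)[0])
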