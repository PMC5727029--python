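"""Differential APA statistics: the core model of the package.

For each gene the two most abundant 3'UTR poly(A) sites define a
proximal/distal isoform pair; their relative expression RE =
log2(distal/proximal) per condition and the relative expression difference
RED = RE(treated) - RE(control) quantify 3'UTR length regulation (RED < 0 is
a shift toward the proximal site, i.e. shortening).  Intronic APA treats the
pooled intronic-PAS set against the pooled 3'UTR-PAS set the same way.
Isoform switches are tested with a replicate-pooled two-sided Fisher's exact
test, with a majority sign-consistency requirement across replicate pairs,
and called significant at p < alpha with a relative-abundance change above
min_delta (fraction points).

The public surface follows the Model/Results idiom: build
:class:`APAUsageModel` from a count matrix, ``fit()`` to get
:class:`APAResults` carrying per-gene events, class tallies, aUTR-bin trend
and intron-position polarity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import PASCountMatrix, CONTROL, TREATED
from .stats import (
    StatResult,
    fisher_exact,
    log2_ratio,
    size_factors,
    wilcoxon_rank_sum,
)

__all__ = [
    "APAUsageModel",
    "APAResults",
    "select_top2_utr3",
    "re_red",
    "test_isoform_switch",
    "call_utr3_apa",
    "call_intronic_apa",
    "weighted_utr3_length",
    "intron_position_profile",
    "apa_quadrants",
    "SHORTENED",
    "LENGTHENED",
    "ACTIVATED",
    "REPRESSED",
    "NC",
]

SHORTENED = "SHORTENED"
LENGTHENED = "LENGTHENED"
ACTIVATED = "ACTIVATED"
REPRESSED = "REPRESSED"
NC = "NC"

ORDINAL_ORDER = ["+1", "+2", "MIDDLE", "-2", "-1"]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def select_top2_utr3(
    pas_ids: list,
    positions: dict,
    pooled_counts: dict,
    strand: str,
) -> Optional[tuple]:
    """Pick the gene's two most abundant 3'UTR PASs as (proximal, distal).

    Abundance is summed over all samples; a tie for the second slot keeps the
    more distal candidate.  Returns None when fewer than two sites exist.
    """
    if len(pas_ids) < 2:
        return None
    distal_rank = (lambda p: positions[p]) if strand == "+" else (lambda p: -positions[p])
    ranked = sorted(pas_ids, key=lambda p: (-pooled_counts[p], -distal_rank(p)))
    top2 = ranked[:2]
    prox, dist = sorted(top2, key=distal_rank)
    return prox, dist


@dataclass(frozen=True)
class REResult:
    re_ctrl: float
    re_trt: float
    red: float
    delta_abundance: float  # distal-isoform fraction, treated - control


def re_red(
    prox_ctrl: float, dist_ctrl: float,
    prox_trt: float, dist_trt: float,
    pseudocount: float = 0.5,
) -> Optional[REResult]:
    """RE per condition, RED, and the distal relative-abundance change.

    Counts are replicate-pooled per condition.  RE uses a pseudocount to
    avoid infinities; the abundance fractions use raw counts.  Returns None
    when a condition has no reads on either isoform.
    """
    tot_c = prox_ctrl + dist_ctrl
    tot_t = prox_trt + dist_trt
    if tot_c == 0 or tot_t == 0:
        return None
    re_c = log2_ratio(dist_ctrl, prox_ctrl, pseudocount)
    re_t = log2_ratio(dist_trt, prox_trt, pseudocount)
    delta = dist_trt / tot_t - dist_ctrl / tot_c
    return REResult(re_c, re_t, re_t - re_c, float(delta))


def test_isoform_switch(
    prox_reps: dict,
    dist_reps: dict,
    control: str = CONTROL,
    treated: str = TREATED,
) -> tuple[StatResult, bool]:
    """Fisher's exact test on pooled counts plus replicate sign-consistency.

    `prox_reps`/`dist_reps` map condition -> per-replicate count arrays in a
    common replicate order.  The 2x2 table is isoform x condition on pooled
    counts; the consistency flag requires a strict majority of replicate
    pairs to shift the distal fraction in the pooled direction.
    """
    pc = np.asarray(prox_reps[control], dtype=float)
    pt = np.asarray(prox_reps[treated], dtype=float)
    dc = np.asarray(dist_reps[control], dtype=float)
    dt = np.asarray(dist_reps[treated], dtype=float)
    table = [[int(pc.sum()), int(pt.sum())], [int(dc.sum()), int(dt.sum())]]
    res = fisher_exact(table)

    tot_c, tot_t = pc.sum() + dc.sum(), pt.sum() + dt.sum()
    if tot_c == 0 or tot_t == 0:
        return res, False
    pooled_delta = dt.sum() / tot_t - dc.sum() / tot_c
    n_pairs = min(len(pc), len(pt))
    agree = 0
    for i in range(n_pairs):
        tc, tt = pc[i] + dc[i], pt[i] + dt[i]
        if tc == 0 or tt == 0:
            continue
        d_i = dt[i] / tt - dc[i] / tc
        if d_i != 0 and np.sign(d_i) == np.sign(pooled_delta):
            agree += 1
    consistent = n_pairs > 0 and agree > n_pairs / 2
    return res, consistent


def weighted_utr3_length(lengths, reads) -> float:
    """Read-weighted mean 3'UTR length over all isoforms of one gene."""
    lengths = np.asarray(lengths, dtype=float)
    reads = np.asarray(reads, dtype=float)
    total = reads.sum()
    if total == 0:
        return float("nan")
    return float((lengths * reads).sum() / total)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class APAUsageModel:
    """Differential poly(A)-site usage model over a PAS count matrix.

    Parameters
    ----------
    matrix : PASCountMatrix
        Annotated counts (meta must carry gene_id and region).
    alpha : float
        Per-gene significance level for the isoform-switch test (unadjusted,
        per the field's convention for APA calls).
    min_delta : float
        Minimum absolute relative-abundance change (fraction points, 0.05 =
        5 percentage points) for a significant call.
    pseudocount : float
        Added inside log2 ratios only; the exact test uses raw counts.
    min_gene_reads : int
        Total read floor (summed over samples and the tested isoform sets)
        below which a gene is excluded.
    """

    def __init__(
        self,
        matrix: PASCountMatrix,
        alpha: float = 0.05,
        min_delta: float = 0.05,
        pseudocount: float = 0.5,
        min_gene_reads: int = 20,
        control: str = CONTROL,
        treated: str = TREATED,
    ):
        self.matrix = matrix
        self.alpha = float(alpha)
        self.min_delta = float(min_delta)
        self.pseudocount = float(pseudocount)
        self.min_gene_reads = int(min_gene_reads)
        self.control = control
        self.treated = treated
        for cond in (control, treated):
            if not matrix.samples_of(cond):
                raise ValueError(f"no samples for condition {cond!r}")

    # -- internals ---------------------------------------------------------
    def _replicate_columns(self) -> tuple[list, list]:
        sheet = self.matrix.samples
        ctrl = sorted(self.matrix.samples_of(self.control),
                      key=lambda s: sheet.at[s, "replicate"])
        trt = sorted(self.matrix.samples_of(self.treated),
                     key=lambda s: sheet.at[s, "replicate"])
        return ctrl, trt

    def _classify(self, p: float, delta: float, consistent: bool,
                  neg_label: str, pos_label: str) -> str:
        if (
            np.isfinite(p)
            and p < self.alpha
            and abs(delta) > self.min_delta
            and consistent
        ):
            return neg_label if delta < 0 else pos_label
        return NC

    def _event_rows_utr3(self) -> list[dict]:
        mx = self.matrix
        ctrl_cols, trt_cols = self._replicate_columns()
        utr = mx.meta[(mx.meta["region"] == "UTR3") & mx.meta["gene_id"].notna()]
        pooled = mx.counts.sum(axis=1)
        rows = []
        for gene_id, sub in utr.groupby("gene_id"):
            ids = list(sub.index)
            strand = sub["strand"].iloc[0]
            sel = select_top2_utr3(
                ids,
                {p: int(sub.at[p, "position"]) for p in ids},
                {p: int(pooled[p]) for p in ids},
                strand,
            )
            if sel is None:
                continue
            prox, dist = sel
            if pooled[prox] + pooled[dist] < self.min_gene_reads:
                continue
            pc = mx.counts.loc[prox, ctrl_cols].to_numpy()
            pt = mx.counts.loc[prox, trt_cols].to_numpy()
            dc = mx.counts.loc[dist, ctrl_cols].to_numpy()
            dt = mx.counts.loc[dist, trt_cols].to_numpy()
            rr = re_red(pc.sum(), dc.sum(), pt.sum(), dt.sum(), self.pseudocount)
            test, consistent = test_isoform_switch(
                {self.control: pc, self.treated: pt},
                {self.control: dc, self.treated: dt},
                self.control, self.treated,
            )
            autr = abs(int(sub.at[dist, "position"]) - int(sub.at[prox, "position"]))
            if rr is None:
                rows.append(
                    dict(gene_id=gene_id, mode="UTR3", proximal_id=prox,
                         distal_id=dist, prox_ctrl=int(pc.sum()),
                         prox_trt=int(pt.sum()), dist_ctrl=int(dc.sum()),
                         dist_trt=int(dt.sum()), re_ctrl=np.nan, re_trt=np.nan,
                         red=np.nan, delta_abundance=np.nan, p_value=np.nan,
                         sign_consistent=False, event_class=NC, autr_len=autr)
                )
                continue
            cls = self._classify(test.p_value, rr.delta_abundance, consistent,
                                 SHORTENED, LENGTHENED)
            rows.append(
                dict(gene_id=gene_id, mode="UTR3", proximal_id=prox,
                     distal_id=dist, prox_ctrl=int(pc.sum()),
                     prox_trt=int(pt.sum()), dist_ctrl=int(dc.sum()),
                     dist_trt=int(dt.sum()), re_ctrl=rr.re_ctrl,
                     re_trt=rr.re_trt, red=rr.red,
                     delta_abundance=rr.delta_abundance, p_value=test.p_value,
                     sign_consistent=consistent, event_class=cls, autr_len=autr)
            )
        return rows

    def _event_rows_intronic(self) -> list[dict]:
        mx = self.matrix
        ctrl_cols, trt_cols = self._replicate_columns()
        meta = mx.meta[mx.meta["gene_id"].notna()]
        rows = []
        for gene_id, sub in meta.groupby("gene_id"):
            intr_ids = list(sub.index[sub["region"] == "INTRON"])
            utr_ids = list(sub.index[sub["region"] == "UTR3"])
            if not intr_ids or not utr_ids:
                continue
            # intronic set plays the proximal role, 3'UTR set the distal
            pc = mx.counts.loc[intr_ids, ctrl_cols].sum(axis=0).to_numpy()
            pt = mx.counts.loc[intr_ids, trt_cols].sum(axis=0).to_numpy()
            dc = mx.counts.loc[utr_ids, ctrl_cols].sum(axis=0).to_numpy()
            dt = mx.counts.loc[utr_ids, trt_cols].sum(axis=0).to_numpy()
            if pc.sum() + pt.sum() + dc.sum() + dt.sum() < self.min_gene_reads:
                continue
            rr = re_red(pc.sum(), dc.sum(), pt.sum(), dt.sum(), self.pseudocount)
            test, consistent = test_isoform_switch(
                {self.control: pc, self.treated: pt},
                {self.control: dc, self.treated: dt},
                self.control, self.treated,
            )
            # dominant intronic site: used downstream for truncation calls
            pooled_intr = mx.counts.loc[intr_ids].sum(axis=1)
            top_intr = pooled_intr.idxmax()
            base = dict(gene_id=gene_id, mode="INTRONIC",
                        proximal_id=f"intronic_set[{len(intr_ids)}]",
                        distal_id=f"utr3_set[{len(utr_ids)}]",
                        prox_ctrl=int(pc.sum()), prox_trt=int(pt.sum()),
                        dist_ctrl=int(dc.sum()), dist_trt=int(dt.sum()),
                        autr_len=np.nan,
                        intronic_pas_pos=int(sub.at[top_intr, "position"]))
            if rr is None:
                rows.append(dict(base, re_ctrl=np.nan, re_trt=np.nan, red=np.nan,
                                 delta_abundance=np.nan, p_value=np.nan,
                                 sign_consistent=False, event_class=NC))
                continue
            # delta_abundance < 0: the 3'UTR set loses share to the intronic
            # set, i.e. intronic activation
            cls = self._classify(test.p_value, rr.delta_abundance, consistent,
                                 ACTIVATED, REPRESSED)
            rows.append(dict(base, re_ctrl=rr.re_ctrl, re_trt=rr.re_trt,
                             red=rr.red, delta_abundance=rr.delta_abundance,
                             p_value=test.p_value, sign_consistent=consistent,
                             event_class=cls))
        return rows

    # -- API ---------------------------------------------------------------
    def fit(self, mode: str = "utr3") -> "APAResults":
        """Run the per-gene APA tests; mode is 'utr3' or 'intronic'."""
        if mode == "utr3":
            rows = self._event_rows_utr3()
        elif mode == "intronic":
            rows = self._event_rows_intronic()
        else:
            raise ValueError(f"unknown mode {mode!r}")
        columns = ["gene_id", "mode", "proximal_id", "distal_id", "prox_ctrl",
                   "prox_trt", "dist_ctrl", "dist_trt", "re_ctrl", "re_trt",
                   "red", "delta_abundance", "p_value", "sign_consistent",
                   "event_class", "autr_len"]
        if mode == "intronic":
            columns.append("intronic_pas_pos")
        events = pd.DataFrame(rows, columns=columns)
        return APAResults(model=self, mode=mode, events=events)

    def intron_position_profile(self, min_introns: int = 4, min_reads: int = 2):
        return intron_position_profile(
            self.matrix, min_introns=min_introns, min_reads=min_reads,
            pseudocount=self.pseudocount, control=self.control,
            treated=self.treated,
        )


@dataclass
class ProfileResult:
    """Intron-position polarity profile (mean-centred log2 usage changes)."""

    table: pd.DataFrame          # index ordinal: n, mean, centered, sem
    p_first_vs_last: StatResult  # Wilcoxon, +1 vs -1 isoform-level values
    values: dict = field(default_factory=dict)  # ordinal -> isoform values


@dataclass
class APAResults:
    """Fitted APA events with summary and trend analyses."""

    model: APAUsageModel
    mode: str
    events: pd.DataFrame

    # -- tallies -----------------------------------------------------------
    def class_counts(self) -> pd.Series:
        labels = ([SHORTENED, LENGTHENED, NC] if self.mode == "utr3"
                  else [ACTIVATED, REPRESSED, NC])
        return self.events["event_class"].value_counts().reindex(labels, fill_value=0)

    def significant(self) -> pd.DataFrame:
        return self.events[self.events["event_class"] != NC]

    # -- 3'UTR length ------------------------------------------------------
    def weighted_utr3_lengths(self) -> pd.DataFrame:
        """Per-gene read-weighted mean 3'UTR length per condition, and change.

        Uses all 3'UTR isoforms of each tested gene (not only the top pair);
        the per-isoform length is the transcript-orientation offset of the
        PAS within the 3'-most exon.
        """
        mx = self.model.matrix
        pooled = mx.condition_sums()
        utr = mx.meta[
            (mx.meta["region"] == "UTR3")
            & mx.meta["gene_id"].isin(self.events["gene_id"])
            & mx.meta["utr3_offset"].notna()
        ]
        rows = []
        for gene_id, sub in utr.groupby("gene_id"):
            lengths = sub["utr3_offset"].to_numpy(dtype=float)
            lc = weighted_utr3_length(lengths, pooled.loc[sub.index, self.model.control])
            lt = weighted_utr3_length(lengths, pooled.loc[sub.index, self.model.treated])
            rows.append(dict(gene_id=gene_id, length_control=lc,
                             length_treated=lt, length_change=lt - lc))
        return pd.DataFrame(rows, columns=["gene_id", "length_control",
                                           "length_treated", "length_change"])

    def median_length_change_by_class(self) -> pd.Series:
        lengths = self.weighted_utr3_lengths().set_index("gene_id")
        ev = self.events.set_index("gene_id")
        joined = lengths.join(ev["event_class"], how="inner")
        return joined.groupby("event_class")["length_change"].median()

    # -- aUTR size trend ---------------------------------------------------
    def autr_bins(self, n_bins: int = 5) -> tuple[pd.DataFrame, StatResult]:
        """Mean RED +/- SEM in aUTR-size quantile bins, extreme bins compared.

        Bins have approximately equal gene counts; the Wilcoxon rank-sum test
        compares RED between the smallest- and largest-aUTR bins.
        """
        ev = self.events.dropna(subset=["red", "autr_len"])
        if len(ev) < n_bins:
            empty = pd.DataFrame(columns=["n", "mean_red", "sem", "autr_range"])
            return empty, StatResult(np.nan, np.nan, "wilcoxon")
        bins = pd.qcut(ev["autr_len"].rank(method="first"), n_bins,
                       labels=range(1, n_bins + 1))
        rows = []
        for b in range(1, n_bins + 1):
            sel = ev[bins == b]
            rows.append(
                dict(bin=b, n=len(sel), mean_red=sel["red"].mean(),
                     sem=sel["red"].std(ddof=1) / np.sqrt(max(len(sel), 1)),
                     autr_min=sel["autr_len"].min(), autr_max=sel["autr_len"].max())
            )
        table = pd.DataFrame(rows).set_index("bin")
        p = wilcoxon_rank_sum(ev.loc[bins == 1, "red"], ev.loc[bins == n_bins, "red"])
        return table, p

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        cc = self.class_counts()
        lines = [
            f"APA usage model ({self.mode}): {len(self.events)} genes tested",
            f"  alpha={self.model.alpha}  min_delta={self.model.min_delta}  "
            f"pseudocount={self.model.pseudocount}  "
            f"min_gene_reads={self.model.min_gene_reads}",
        ]
        for label, n in cc.items():
            lines.append(f"  {label:>10}: {n}")
        sig = self.events["p_value"] < self.model.alpha
        lines.append(f"  p < alpha: {int(sig.sum())}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def call_utr3_apa(matrix: PASCountMatrix, alpha: float = 0.05,
                  min_delta: float = 0.05, **kwargs) -> APAResults:
    """3'UTR shortening/lengthening calls (proximal vs distal PAS)."""
    return APAUsageModel(matrix, alpha=alpha, min_delta=min_delta, **kwargs).fit("utr3")


def call_intronic_apa(matrix: PASCountMatrix, alpha: float = 0.05,
                      min_delta: float = 0.05, **kwargs) -> APAResults:
    """Intronic APA activation/repression calls (intronic vs 3'UTR set)."""
    return APAUsageModel(matrix, alpha=alpha, min_delta=min_delta,
                         **kwargs).fit("intronic")


def intron_position_profile(
    matrix: PASCountMatrix,
    min_introns: int = 4,
    min_reads: int = 2,
    pseudocount: float = 0.5,
    control: str = CONTROL,
    treated: str = TREATED,
) -> ProfileResult:
    """Mean-centred usage change of intronic PAS isoforms by intron position.

    Intronic isoforms of genes with >= min_introns introns and >= min_reads
    supporting reads are grouped by intron ordinal (+1, +2, MIDDLE, -2, -1).
    Per isoform the log2 treated/control ratio of library-size-normalised
    counts is computed; group means are centred by subtracting the mean of
    the group means; a Wilcoxon rank-sum test compares the first- and
    last-intron groups.
    """
    sf = size_factors(matrix.gene_totals())
    norm = matrix.counts / sf
    meta = matrix.meta
    sel = (
        (meta["region"] == "INTRON")
        & meta["gene_id"].notna()
        & (meta["n_introns"] >= min_introns)
        & (matrix.counts.sum(axis=1) >= min_reads)
    )
    ctrl_cols = matrix.samples_of(control)
    trt_cols = matrix.samples_of(treated)
    values: dict[str, list[float]] = {o: [] for o in ORDINAL_ORDER}
    for pas_id in meta.index[sel]:
        o = meta.at[pas_id, "intron_ordinal"]
        if o not in values:
            continue
        mc = float(norm.loc[pas_id, ctrl_cols].mean())
        mt = float(norm.loc[pas_id, trt_cols].mean())
        values[o].append(log2_ratio(mt, mc, pseudocount))
    means = {o: (np.mean(v) if v else np.nan) for o, v in values.items()}
    finite = [means[o] for o in ORDINAL_ORDER if np.isfinite(means[o])]
    grand = np.mean(finite) if finite else np.nan
    rows = []
    for o in ORDINAL_ORDER:
        v = np.asarray(values[o], dtype=float)
        rows.append(
            dict(ordinal=o, n=len(v),
                 mean=means[o],
                 centered=means[o] - grand if np.isfinite(means[o]) else np.nan,
                 sem=(v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan))
        )
    table = pd.DataFrame(rows).set_index("ordinal")
    if values["+1"] and values["-1"]:
        p = wilcoxon_rank_sum(values["+1"], values["-1"])
    else:
        p = StatResult(np.nan, np.nan, "wilcoxon")
    return ProfileResult(table=table, p_first_vs_last=p, values=values)


def apa_quadrants(utr3_results: APAResults, intronic_results: APAResults) -> pd.DataFrame:
    """Joint 3'UTR x intronic APA class counts (the coupling quadrants)."""
    u = utr3_results.events.set_index("gene_id")["event_class"]
    i = intronic_results.events.set_index("gene_id")["event_class"]
    joined = pd.concat({"utr3": u, "intronic": i}, axis=1, join="inner")
    table = pd.crosstab(joined["utr3"], joined["intronic"])
    return table.reindex(index=[SHORTENED, LENGTHENED, NC],
                         columns=[ACTIVATED, REPRESSED, NC], fill_value=0)
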