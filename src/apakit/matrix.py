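"""PAS x sample count matrix with site metadata and sample design.

The central in-memory container of the pipeline: a pandas count matrix
(rows = poly(A) site clusters, columns = samples), a metadata frame per PAS
(location, gene assignment, region class, hexamer) and a sample sheet
(condition / timepoint / replicate).  Serialised as a single annotated TSV
plus a sample-sheet TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = ["PASCountMatrix", "make_design", "CONTROL", "TREATED"]

CONTROL = "control"
TREATED = "treated"

#: metadata columns carried for every PAS (NaN where unknown)
META_COLUMNS = [
    "chrom", "strand", "position", "gene_id", "region", "intron_ordinal",
    "n_introns", "hexamer", "utr3_offset",
]


def make_design(
    n_replicates: int = 3,
    conditions: Iterable[str] = (CONTROL, TREATED),
    timepoint: str = "3hr",
) -> pd.DataFrame:
    """Sample sheet with `n_replicates` per condition at one timepoint."""
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{cond}_{timepoint}_r{rep}",
                    "condition": cond,
                    "timepoint": timepoint,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class PASCountMatrix:
    """Reads per PAS per sample plus per-PAS metadata and the sample design."""

    counts: pd.DataFrame                 # index pas_id, columns sample_id
    meta: pd.DataFrame                   # index pas_id, META_COLUMNS
    samples: pd.DataFrame                # index sample_id: condition/timepoint/replicate

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            self.meta = self.meta.reindex(self.counts.index)
        missing = [c for c in self.counts.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples absent from sample sheet: {missing}")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = np.nan
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    # -- convenience -------------------------------------------------------
    @property
    def pas_ids(self) -> pd.Index:
        return self.counts.index

    def samples_of(self, condition: str) -> list[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        return [s for s in self.counts.columns if s in set(sel)]

    def condition_sums(self) -> pd.DataFrame:
        """Replicate-pooled counts per condition (columns = conditions)."""
        out = {}
        for cond in self.samples["condition"].unique():
            out[cond] = self.counts[self.samples_of(cond)].sum(axis=1)
        return pd.DataFrame(out)

    def subset(self, pas_ids) -> "PASCountMatrix":
        return PASCountMatrix(
            self.counts.loc[pas_ids], self.meta.loc[pas_ids], self.samples
        )

    def gene_totals(self) -> pd.DataFrame:
        """Gene x sample totals (PAS counts summed within genes)."""
        assigned = self.meta["gene_id"].notna()
        return self.counts[assigned].groupby(self.meta.loc[assigned, "gene_id"]).sum()

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, table_path: str, sheet_path: Optional[str] = None) -> None:
        table = pd.concat([self.meta, self.counts], axis=1)
        table.to_csv(table_path, sep="\t", index_label="pas_id")
        if sheet_path is not None:
            self.samples.to_csv(sheet_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, table_path: str, sheet_path: str) -> "PASCountMatrix":
        table = pd.read_csv(table_path, sep="\t", index_col="pas_id")
        samples = pd.read_csv(sheet_path, sep="\t", index_col="sample_id")
        meta_cols = [c for c in META_COLUMNS if c in table.columns]
        count_cols = [c for c in table.columns if c not in META_COLUMNS]
        counts = table[count_cols].astype(int)
        return cls(counts, table[meta_cols].copy(), samples)

    def write_bedgraph(self, outdir: str) -> list[str]:
        """Per-sample bedGraph browser tracks of PAS read counts."""
        import os

        paths = []
        pos_ok = self.meta["position"].notna()
        for sample in self.counts.columns:
            path = os.path.join(outdir, f"{sample}.bedgraph")
            rows = []
            for pas_id in self.counts.index[pos_ok]:
                c = int(self.counts.at[pas_id, sample])
                if c == 0:
                    continue
                m = self.meta.loc[pas_id]
                p = int(m["position"])
                sign = 1 if m["strand"] == "+" else -1
                rows.append((m["chrom"], p, p + 1, sign * c))
            with open(path, "w") as fh:
                fh.write(f'track type=bedGraph name="{sample}"\n')
                for r in sorted(rows):
                    fh.write("\t".join(map(str, r)) + "\n")
            paths.append(path)
        return paths
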