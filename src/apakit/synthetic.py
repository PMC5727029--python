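"""Synthetic genome, annotation and 3'-end sequencing data generator.

Emulates the statistical structure of an activity-dependent APA experiment:
multi-exon genes carrying proximal/distal 3'UTR poly(A) sites and optional
intronic sites, per-condition isoform-usage fractions with programmed
shortening / lengthening / intronic-activation effects, gene-level expression
multipliers, negative-binomial replicate noise, poly(A) signal hexamers
planted in the -40..-1 window of true cleavage sites, and simulated reads
bearing untemplated adenosines soft-clipped at the transcript 3' end.

Two emission paths: a count-matrix fast path (`simulate_counts`) for testing
the statistics, and a read path (`simulate_reads`) for testing discovery.
All randomness flows from a single top-level seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .gene_models import GeneModel, GeneModelSet, write_gtf
from .matrix import PASCountMatrix, CONTROL, TREATED

__all__ = [
    "ReferenceConfig",
    "ApaProgram",
    "PASTruth",
    "GeneTruth",
    "TruthTable",
    "SyntheticReference",
    "generate_reference",
    "simulate_counts",
    "simulate_gene_counts",
    "simulate_reads",
    "generate_features",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")

# hexamer classes; DNA alphabet internally (T for U)
HEX_AAUAAA = "AAUAAA"
HEX_AUUAAA = "AUUAAA"
HEX_OTHER = "OTHER_VARIANT"
HEX_NONE = "NONE"

#: single-substitution A[A/U]UAAA variants beyond the two canonical signals
VARIANT_HEXAMERS_DNA = (
    "AGTAAA", "TATAAA", "CATAAA", "GATAAA", "AATATA",
    "AATACA", "AATAGA", "AATGAA", "ACTAAA", "AAGAAA",
)

#: non-A pattern planted downstream of true cleavage sites so genuine PASs
#: survive the internal-priming filter
_GUARD = "GTCGTCGTCG"


class ConfigError(ValueError):
    """Raised for infeasible generator configuration."""


@dataclass(frozen=True)
class ReferenceConfig:
    """Geometry and sequence-element parameters of the toy genome."""

    n_genes: int = 200
    n_chroms: int = 2
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (250, 700)
    n_introns: tuple[int, int] = (4, 7)          # >=4 keeps every gene eligible
                                                 # for the intron-position profile
    utr3_exon_length: tuple[int, int] = (400, 1500)
    n_utr3_pas: int = 2
    min_pas_spacing: int = 60                    # > 24-nt cluster gap: true sites
                                                 # never merge during clustering
    p_intronic_pas: float = 0.5
    intron_pas_ordinals: tuple[str, ...] = ("+1", "+2", "MIDDLE", "-2", "-1")
    # hexamer class probabilities: AAUAAA, AUUAAA, other variant, none
    hexamer_probs: tuple[float, float, float, float] = (0.55, 0.17, 0.20, 0.08)
    intergenic: int = 300
    n_decoy_tracts: int = 0                      # internal-priming decoy sites

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if abs(sum(self.hexamer_probs) - 1.0) > 1e-9:
            raise ConfigError("hexamer_probs must sum to 1")
        if self.intron_length[0] < 80:
            raise ConfigError("introns shorter than 80 nt cannot hold a PAS "
                              "with its upstream hexamer window")
        if self.utr3_exon_length[0] < 240:
            raise ConfigError("3'UTR exon too short for two spaced PASs")


@dataclass(frozen=True)
class ApaProgram:
    """Programmed per-condition effects: the ground-truth regulation."""

    frac_shortened: float = 0.0
    frac_lengthened: float = 0.0
    frac_intronic_activated: float = 0.0
    frac_intronic_repressed: float = 0.0
    delta: float = 0.3                   # programmed |change| in isoform fraction
    frac_expr_up: float = 0.0
    frac_expr_down: float = 0.0
    expr_fold: float = 2.0
    autr_coupled: bool = False           # shortening magnitude grows with log aUTR
    first_intron_only: bool = False      # place intronic PASs only in intron +1
    activated_ordinal: Optional[str] = None  # restrict intronic activation to
                                             # genes whose PAS sits in this intron

    # programmed_class labels
    SHORTENED = "SHORTENED"
    LENGTHENED = "LENGTHENED"
    INTRONIC_ACTIVATED = "INTRONIC_ACTIVATED"
    INTRONIC_REPRESSED = "INTRONIC_REPRESSED"
    NULL = "NULL"


@dataclass
class PASTruth:
    """One true poly(A) site of one gene."""

    pas_id: str
    position: int          # genomic 0-based coordinate of the cleavage base
    pre: int               # pre-mRNA (unspliced transcript) coordinate
    region: str            # UTR3 | INTRON
    intron_ordinal: Optional[str]
    hexamer: str           # planted hexamer class
    utr3_offset: Optional[int]  # 3'UTR length proxy (UTR3 sites only)


@dataclass
class GeneTruth:
    """Ground truth for one synthetic gene."""

    gene_id: str
    chrom: str
    strand: str
    model: GeneModel
    pas: list[PASTruth]
    usage: dict                      # condition -> fraction vector over pas
    base_expr: float                 # relative abundance multiplier, both conditions
    expr_mult: dict                  # condition -> multiplier
    programmed_class: str

    def __post_init__(self) -> None:
        for cond, frac in self.usage.items():
            if abs(float(np.sum(frac)) - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.gene_id}: usage fractions for {cond} do not sum to 1"
                )


@dataclass
class TruthTable:
    """Per-gene ground truth of the synthetic experiment."""

    genes: list[GeneTruth]
    seed: int
    program: ApaProgram

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_class(self, programmed_class: str) -> list[str]:
        return [g.gene_id for g in self.genes if g.programmed_class == programmed_class]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            for i, p in enumerate(g.pas):
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "pas_id": p.pas_id,
                        "chrom": g.chrom,
                        "strand": g.strand,
                        "position": p.position,
                        "region": p.region,
                        "intron_ordinal": p.intron_ordinal,
                        "hexamer": p.hexamer,
                        "usage_control": g.usage[CONTROL][i],
                        "usage_treated": g.usage[TREATED][i],
                        "expr_mult_treated": g.expr_mult[TREATED],
                        "programmed_class": g.programmed_class,
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SyntheticReference:
    """Genome + annotation + ground truth from one generator run."""

    genome: dict                      # chrom -> str (uppercase DNA)
    models: GeneModelSet
    truth: TruthTable
    decoy_sites: list                 # (chrom, cleavage_pos) internal-priming decoys
    config: ReferenceConfig
    seed: int

    def write_fasta(self, path: str) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.genome.items()
        ]
        SeqIO.write(records, path, "fasta")

    def write_gtf(self, path: str) -> None:
        write_gtf(list(self.models), path)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _tx_to_genomic(gstart: int, tx_len: int, strand: str, pre: int) -> int:
    """Map a pre-mRNA coordinate to the genome (strand-aware)."""
    return gstart + pre if strand == "+" else gstart + tx_len - 1 - pre


def _write_tx_seq(chrom_arr: bytearray, gstart: int, tx_len: int, strand: str,
                  pre_start: int, seq: str) -> None:
    """Write `seq` (transcript sense, 5'->3' from pre_start) into the genome."""
    if strand == "+":
        g = gstart + pre_start
        chrom_arr[g:g + len(seq)] = seq.encode()
    else:
        g_end = gstart + tx_len - pre_start  # exclusive
        rc = seq.encode().translate(_COMPLEMENT)[::-1]
        chrom_arr[g_end - len(seq):g_end] = rc


def _draw_hexamer(rng: np.random.Generator, probs) -> tuple[str, Optional[str]]:
    """Draw a hexamer class and the DNA 6-mer to plant (None for NONE)."""
    cls = rng.choice(4, p=np.asarray(probs, dtype=float))
    if cls == 0:
        return HEX_AAUAAA, "AATAAA"
    if cls == 1:
        return HEX_AUUAAA, "ATTAAA"
    if cls == 2:
        return HEX_OTHER, str(rng.choice(VARIANT_HEXAMERS_DNA))
    return HEX_NONE, None


def _scrub_window(rng: np.random.Generator) -> str:
    """A 40-nt window with no adenosine: cannot contain any A[A/U]UAAA variant."""
    return "".join(np.take(np.array(list("CGT")), rng.integers(0, 3, 40)))


def _ordinal_indices(n_introns: int) -> dict:
    out: dict[str, list[int]] = {"+1": [0], "-1": [n_introns - 1]}
    if n_introns >= 2:
        out["+2"] = [1]
        out["-2"] = [n_introns - 2]
    if n_introns >= 5:
        out["MIDDLE"] = list(range(2, n_introns - 2))
    return out


def generate_reference(
    config: ReferenceConfig = ReferenceConfig(),
    seed: int = 0,
    program: ApaProgram = ApaProgram(),
    with_sequence: bool = True,
) -> SyntheticReference:
    """Build the toy genome, gene models and ground-truth APA program.

    With ``with_sequence=False`` only the models and truth table are built
    (fast path for count-level simulations that never touch the sequence).
    Identical arguments and seed give byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    cursors = {c: 200 for c in chrom_names}
    placements = []  # (gene geometry dicts)

    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        n_int = int(rng.integers(config.n_introns[0], config.n_introns[1] + 1))
        exon_lens = [int(rng.integers(*config.exon_length)) for _ in range(n_int)]
        last_len = int(rng.integers(*config.utr3_exon_length))
        exon_lens.append(last_len)
        intron_lens = [int(rng.integers(*config.intron_length)) for _ in range(n_int)]

        # PAS offsets within the last exon (transcript coordinates)
        distal = last_len - 30
        lo, hi = config.min_pas_spacing, distal - 140
        if hi <= lo:
            raise ConfigError("3'UTR exon too short for the requested PAS spacing")
        utr_offsets = [distal]
        if config.n_utr3_pas >= 2:
            autr = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            utr_offsets.insert(0, distal - autr)
            for _ in range(config.n_utr3_pas - 2):
                extra_hi = utr_offsets[0] - config.min_pas_spacing
                if extra_hi <= 140:
                    break
                utr_offsets.insert(0, int(rng.integers(140, extra_hi)))

        # optional intronic PAS
        intron_pas = None  # (intron_index, offset_in_intron, ordinal)
        if rng.random() < config.p_intronic_pas:
            idx_map = _ordinal_indices(n_int)
            if program.first_intron_only:
                choices = ["+1"]
            else:
                choices = [o for o in config.intron_pas_ordinals if o in idx_map]
            ordinal = str(rng.choice(choices))
            intron_index = int(rng.choice(idx_map[ordinal]))
            offset = int(rng.integers(45, intron_lens[intron_index] - 15))
            intron_pas = (intron_index, offset, ordinal)

        gstart = cursors[chrom]
        tx_len = sum(exon_lens) + sum(intron_lens)
        cursors[chrom] = gstart + tx_len + config.intergenic
        placements.append(
            dict(
                gene_id=f"g{gi + 1:04d}", chrom=chrom, strand=strand,
                gstart=gstart, tx_len=tx_len, exon_lens=exon_lens,
                intron_lens=intron_lens, utr_offsets=utr_offsets,
                intron_pas=intron_pas,
            )
        )

    # decoy internal-priming tracts in the tail region of chr1
    decoy_sites = []
    decoy_specs = []
    for d in range(config.n_decoy_tracts):
        chrom = chrom_names[0]
        pos = cursors[chrom] + 100 + 200 * d
        decoy_specs.append((chrom, pos))
        decoy_sites.append((chrom, pos - 1))  # cleavage just upstream of the tract
    if decoy_specs:
        cursors[chrom_names[0]] = decoy_specs[-1][1] + 300

    chrom_lens = {c: cursors[c] + 200 for c in chrom_names}
    # draw the base stream unconditionally so the truth table is identical
    # whether or not the sequence is materialised
    genome_arrs: dict[str, bytearray] = {}
    for c in chrom_names:
        idx = rng.integers(0, 4, size=chrom_lens[c])
        if with_sequence:
            genome_arrs[c] = bytearray(bytes(np.take(_BASES, idx)))

    # build models + truth skeleton, planting sequence elements
    genes: list[GeneTruth] = []
    models: list[GeneModel] = []
    for pl in placements:
        strand, gstart, tx_len = pl["strand"], pl["gstart"], pl["tx_len"]
        chrom = pl["chrom"]
        exon_lens, intron_lens = pl["exon_lens"], pl["intron_lens"]

        # pre-mRNA segment layout: e1 i1 e2 i2 ... en
        pre = 0
        exon_pre: list[tuple[int, int]] = []
        intron_pre: list[tuple[int, int]] = []
        for i, el in enumerate(exon_lens):
            exon_pre.append((pre, pre + el))
            pre += el
            if i < len(intron_lens):
                intron_pre.append((pre, pre + intron_lens[i]))
                pre += intron_lens[i]

        def g_of(p: int, _gs=gstart, _tl=tx_len, _st=strand) -> int:
            return _tx_to_genomic(_gs, _tl, _st, p)

        def interval_of(pre_iv: tuple[int, int]) -> tuple[int, int]:
            a, b = g_of(pre_iv[0]), g_of(pre_iv[1] - 1)
            return (a, b + 1) if a <= b else (b, a + 1)

        exons_genomic = sorted(interval_of(iv) for iv in exon_pre)
        # CDS: from 30 nt into exon 1 through 60 nt into the last exon
        cds_pre = [(exon_pre[0][0] + 30, exon_pre[0][1])]
        cds_pre += exon_pre[1:-1]
        cds_pre.append((exon_pre[-1][0], exon_pre[-1][0] + 60))
        cds_genomic = sorted(interval_of(iv) for iv in cds_pre)
        last_block = interval_of(exon_pre[-1])
        model = GeneModel(
            gene_id=pl["gene_id"], chrom=chrom, strand=strand,
            exons=exons_genomic, cds=cds_genomic, last_exon_blocks=[last_block],
        )
        models.append(model)

        pas_list: list[PASTruth] = []
        last_start_pre = exon_pre[-1][0]
        for off in pl["utr_offsets"]:
            p_pre = last_start_pre + off
            hex_cls, hex_seq = _draw_hexamer(rng, config.hexamer_probs)
            o_h = int(rng.integers(10, 36))  # hexamer start offset upstream
            window = _scrub_window(rng)
            if with_sequence:
                arr = genome_arrs[chrom]
                _write_tx_seq(arr, gstart, tx_len, strand, p_pre - 40, window)
                if hex_seq is not None:
                    _write_tx_seq(arr, gstart, tx_len, strand, p_pre - o_h, hex_seq)
                _write_tx_seq(arr, gstart, tx_len, strand, p_pre + 1, _GUARD)
            gpos = g_of(p_pre)
            pas_list.append(
                PASTruth(
                    pas_id=f"{chrom}:{strand}:{gpos}", position=gpos, pre=p_pre,
                    region="UTR3", intron_ordinal=None, hexamer=hex_cls,
                    utr3_offset=off + 1,
                )
            )
        if pl["intron_pas"] is not None:
            ii, off, ordinal = pl["intron_pas"]
            p_pre = intron_pre[ii][0] + off
            hex_cls, hex_seq = _draw_hexamer(rng, config.hexamer_probs)
            o_h = int(rng.integers(10, 36))
            window = _scrub_window(rng)
            if with_sequence:
                arr = genome_arrs[chrom]
                _write_tx_seq(arr, gstart, tx_len, strand, p_pre - 40, window)
                if hex_seq is not None:
                    _write_tx_seq(arr, gstart, tx_len, strand, p_pre - o_h, hex_seq)
                _write_tx_seq(arr, gstart, tx_len, strand, p_pre + 1, _GUARD)
            gpos = g_of(p_pre)
            pas_list.append(
                PASTruth(
                    pas_id=f"{chrom}:{strand}:{gpos}", position=gpos, pre=p_pre,
                    region="INTRON", intron_ordinal=ordinal, hexamer=hex_cls,
                    utr3_offset=None,
                )
            )
        genes.append(
            GeneTruth(
                gene_id=pl["gene_id"], chrom=chrom, strand=strand, model=model,
                pas=pas_list, usage={}, base_expr=1.0,
                expr_mult={CONTROL: 1.0, TREATED: 1.0},
                programmed_class=ApaProgram.NULL,
            )
        )

    if with_sequence:
        for chrom, pos in decoy_specs:
            genome_arrs[chrom][pos:pos + 12] = b"A" * 10 + b"GG"

    _assign_program(genes, program, rng)

    genome = {c: genome_arrs[c].decode() for c in genome_arrs} if with_sequence else {}
    truth = TruthTable(genes=genes, seed=seed, program=program)
    return SyntheticReference(
        genome=genome, models=GeneModelSet(models), truth=truth,
        decoy_sites=decoy_sites, config=config, seed=seed,
    )


def _assign_program(genes: list[GeneTruth], program: ApaProgram,
                    rng: np.random.Generator) -> None:
    """Assign programmed classes, usage fractions and expression multipliers."""
    n = len(genes)
    order = rng.permutation(n)
    utr3_eligible = [i for i in order
                     if sum(p.region == "UTR3" for p in genes[i].pas) >= 2]
    intronic_eligible = [i for i in order
                         if any(p.region == "INTRON" for p in genes[i].pas)]
    activation_pool = intronic_eligible
    if program.activated_ordinal is not None:
        activation_pool = [
            i for i in intronic_eligible
            if any(p.region == "INTRON"
                   and p.intron_ordinal == program.activated_ordinal
                   for p in genes[i].pas)
        ]

    classes = [ApaProgram.NULL] * n
    taken: set[int] = set()

    def take(pool, k, label):
        got = 0
        for i in pool:
            if got >= k:
                break
            if i in taken:
                continue
            classes[i] = label
            taken.add(i)
            got += 1

    if program.autr_coupled:
        take(utr3_eligible, len(utr3_eligible), ApaProgram.SHORTENED)
    else:
        take(utr3_eligible, round(program.frac_shortened * n), ApaProgram.SHORTENED)
        take(utr3_eligible, round(program.frac_lengthened * n), ApaProgram.LENGTHENED)
    take(activation_pool, round(program.frac_intronic_activated * n),
         ApaProgram.INTRONIC_ACTIVATED)
    take(intronic_eligible, round(program.frac_intronic_repressed * n),
         ApaProgram.INTRONIC_REPRESSED)

    # expression program, independent of the APA program
    expr_order = rng.permutation(n)
    n_up = round(program.frac_expr_up * n)
    n_down = round(program.frac_expr_down * n)
    up = set(expr_order[:n_up])
    down = set(expr_order[n_up:n_up + n_down])

    # precompute log-aUTR range for coupled shortening
    if program.autr_coupled:
        autrs = {}
        for i in utr3_eligible:
            offs = sorted(p.utr3_offset for p in genes[i].pas if p.region == "UTR3")
            autrs[i] = offs[-1] - offs[-2]
        la = np.log([max(v, 1) for v in autrs.values()])
        la_min, la_max = float(la.min()), float(max(la.max(), la.min() + 1e-9))

    for i, g in enumerate(genes):
        g.programmed_class = classes[i]
        g.base_expr = float(np.exp(rng.normal(0.0, 0.4)))
        g.expr_mult = {CONTROL: 1.0, TREATED: 1.0}
        if i in up:
            g.expr_mult[TREATED] = program.expr_fold
        elif i in down:
            g.expr_mult[TREATED] = 1.0 / program.expr_fold

        k = len(g.pas)
        utr_idx = [j for j, p in enumerate(g.pas) if p.region == "UTR3"]
        int_idx = [j for j, p in enumerate(g.pas) if p.region == "INTRON"]

        delta = program.delta
        if classes[i] == ApaProgram.SHORTENED and program.autr_coupled:
            offs = sorted(p.utr3_offset for p in g.pas if p.region == "UTR3")
            la_g = np.log(max(offs[-1] - offs[-2], 1))
            delta = 0.05 + (program.delta - 0.05) * (la_g - la_min) / (la_max - la_min)

        # intronic mass
        if int_idx:
            if classes[i] == ApaProgram.INTRONIC_ACTIVATED:
                i_c = float(rng.uniform(0.10, 0.25))
                i_t = i_c + delta
            elif classes[i] == ApaProgram.INTRONIC_REPRESSED:
                i_c = float(rng.uniform(delta + 0.05, min(delta + 0.25, 0.85)))
                i_t = i_c - delta
            else:
                i_c = i_t = float(rng.uniform(0.10, 0.30))
        else:
            i_c = i_t = 0.0

        # distal fraction within the proximal/distal 3'UTR pair
        if len(utr_idx) >= 2:
            if classes[i] == ApaProgram.SHORTENED:
                d_c = float(rng.uniform(delta + 0.10, 0.90))
                d_t = d_c - delta
            elif classes[i] == ApaProgram.LENGTHENED:
                d_c = float(rng.uniform(0.10, 0.90 - delta))
                d_t = d_c + delta
            else:
                d_c = d_t = float(rng.uniform(0.30, 0.70))
        else:
            d_c = d_t = 1.0

        # minor extra 3'UTR PASs share a small slice of the UTR3 mass
        minor = [float(rng.uniform(0.02, 0.06)) for _ in range(max(len(utr_idx) - 2, 0))]
        minor_sum = sum(minor)

        frac = {}
        for cond, i_m, d_m in ((CONTROL, i_c, d_c), (TREATED, i_t, d_t)):
            v = np.zeros(k)
            utr_mass = 1.0 - i_m
            pair_mass = utr_mass * (1.0 - minor_sum)
            if len(utr_idx) >= 2:
                # the two most 3' UTR3 sites are the proximal/distal pair
                v[utr_idx[-1]] = pair_mass * d_m
                v[utr_idx[-2]] = pair_mass * (1.0 - d_m)
                for m, j in zip(minor, utr_idx[:-2]):
                    v[j] = utr_mass * m
            elif utr_idx:
                v[utr_idx[0]] = utr_mass
            for j in int_idx:
                v[j] = i_m / len(int_idx)
            v = np.clip(v, 0.0, None)
            frac[cond] = v / v.sum()
        g.usage = frac


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with Var = mean + dispersion * mean^2 (Poisson at 0)."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _draw_gene_counts(truth: TruthTable, design: pd.DataFrame, depth: float,
                      dispersion: float, rng: np.random.Generator):
    """Yield (sample_id, condition, {gene -> pas count vector})."""
    for sample_id, row in design.iterrows():
        cond = row["condition"]
        per_gene = {}
        for g in truth:
            mu = depth * g.base_expr * g.expr_mult[cond]
            total = _nb_draw(rng, mu, dispersion)
            if total > 0:
                per_gene[g.gene_id] = rng.multinomial(total, g.usage[cond])
            else:
                per_gene[g.gene_id] = np.zeros(len(g.pas), dtype=int)
        yield sample_id, cond, per_gene


def simulate_counts(
    truth: TruthTable,
    design: pd.DataFrame,
    depth: float = 500.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> PASCountMatrix:
    """Fast-path PAS x sample counts straight from the truth table.

    Per sample, each gene's total is negative-binomial around
    depth x base_expr x condition multiplier (dispersion 0 degrades to
    Poisson); reads are apportioned to the gene's PASs by a multinomial with
    the condition's usage fractions.
    """
    if dispersion < 0:
        raise ConfigError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    pas_rows = []
    meta_rows = []
    for g in truth:
        for p in g.pas:
            pas_rows.append(p.pas_id)
            meta_rows.append(
                {
                    "chrom": g.chrom, "strand": g.strand, "position": p.position,
                    "gene_id": g.gene_id, "region": p.region,
                    "intron_ordinal": p.intron_ordinal,
                    "n_introns": g.model.n_introns, "hexamer": p.hexamer,
                    "utr3_offset": p.utr3_offset,
                }
            )
    meta = pd.DataFrame(meta_rows, index=pd.Index(pas_rows, name="pas_id"))
    data = {}
    for sample_id, _cond, per_gene in _draw_gene_counts(
        truth, design, depth, dispersion, rng
    ):
        col = np.concatenate([per_gene[g.gene_id] for g in truth])
        data[sample_id] = col
    counts = pd.DataFrame(data, index=meta.index)
    return PASCountMatrix(counts, meta, design)


def simulate_gene_counts(
    truth: TruthTable,
    design: pd.DataFrame,
    depth: float = 1000.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x sample totals emulating an independent expression assay.

    Shares the truth table's expression multipliers but draws independent
    noise — the stand-in for CDS-restricted RNA-seq counts on the fast path.
    """
    rng = np.random.default_rng(seed)
    genes = [g.gene_id for g in truth]
    data = {}
    for sample_id, row in design.iterrows():
        cond = row["condition"]
        data[sample_id] = [
            _nb_draw(rng, depth * g.base_expr * g.expr_mult[cond], dispersion)
            for g in truth
        ]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    ref: SyntheticReference,
    design: pd.DataFrame,
    outdir: str,
    depth: float = 50.0,
    dispersion: float = 0.1,
    read_length: int = 50,
    tail_mean: float = 3.0,
    tail_fixed: Optional[int] = None,
    cluster_jitter: int = 10,
    decoy_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Write one SAM per sample with PAS-supporting reads.

    Each read aligns so its transcript-3' end sits at the (jittered) cleavage
    site with k untemplated adenosines soft-clipped beyond it; k is
    2 + Poisson(tail_mean - 2) by default (every read carries >= 2 untemplated
    As) unless ``tail_fixed`` overrides it.  A ``decoy_fraction`` of reads end
    one base upstream of planted A-rich tracts with a partly templated tail:
    they pass tail extraction but are removable by the internal-priming
    filter.  Returns (sample -> SAM path, emitted per-PAS truth counts).
    """
    if not ref.genome:
        raise ConfigError("simulate_reads needs a reference built with sequence")
    rng = np.random.default_rng(seed)
    os.makedirs(outdir, exist_ok=True)
    chroms = list(ref.genome)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(ref.genome[c])} for c in chroms],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}

    def draw_tail() -> int:
        if tail_fixed is not None:
            return int(tail_fixed)
        return 2 + int(rng.poisson(max(tail_mean - 2.0, 0.0)))

    paths = {}
    emitted = []
    for sample_id, cond, per_gene in _draw_gene_counts(
        ref.truth, design, depth, dispersion, rng
    ):
        path = os.path.join(outdir, f"{sample_id}.sam")
        paths[sample_id] = path
        total_reads = 0
        with pysam.AlignmentFile(path, "w", header=header) as sam:
            rcount = 0
            for g in ref.truth:
                counts_vec = per_gene[g.gene_id]
                seq = ref.genome[g.chrom]
                for p, c in zip(g.pas, counts_vec):
                    if c > 0:
                        emitted.append(
                            {"sample_id": sample_id, "pas_id": p.pas_id,
                             "gene_id": g.gene_id, "count": int(c)}
                        )
                    for _ in range(int(c)):
                        total_reads += 1
                        jitter = (
                            int(rng.integers(-cluster_jitter, cluster_jitter + 1))
                            if cluster_jitter > 0 else 0
                        )
                        sign = 1 if g.strand == "+" else -1
                        cpos = p.position + sign * jitter
                        k = draw_tail()
                        read = pysam.AlignedSegment(header)
                        read.query_name = f"{sample_id}.{rcount}"
                        rcount += 1
                        read.mapping_quality = 60
                        read.reference_id = tid[g.chrom]
                        if g.strand == "+":
                            start = max(cpos - read_length + 1, 0)
                            matched = seq[start:cpos + 1]
                            read.reference_start = start
                            read.cigarstring = f"{len(matched)}M{k}S" if k else f"{len(matched)}M"
                            read.query_sequence = matched + "A" * k
                            read.flag = 0
                        else:
                            end = min(cpos + read_length, len(seq))
                            matched = seq[cpos:end]
                            read.reference_start = cpos
                            read.cigarstring = f"{k}S{len(matched)}M" if k else f"{len(matched)}M"
                            read.query_sequence = "T" * k + matched
                            read.flag = 16
                        sam.write(read)
            # internal-priming decoy reads
            if decoy_fraction > 0 and ref.decoy_sites:
                n_decoy = int(round(decoy_fraction * total_reads))
                for d in range(n_decoy):
                    chrom, cpos = ref.decoy_sites[d % len(ref.decoy_sites)]
                    seq = ref.genome[chrom]
                    k = 12  # 10 templated (the tract) + 2 untemplated As
                    start = max(cpos - read_length + 1, 0)
                    matched = seq[start:cpos + 1]
                    read = pysam.AlignedSegment(header)
                    read.query_name = f"{sample_id}.decoy{d}"
                    read.mapping_quality = 60
                    read.reference_id = tid[chrom]
                    read.reference_start = start
                    read.cigarstring = f"{len(matched)}M{k}S"
                    read.query_sequence = matched + "A" * k
                    read.flag = 0
                    sam.write(read)
    emitted_df = pd.DataFrame(emitted, columns=["sample_id", "pas_id", "gene_id", "count"])
    return paths, emitted_df


# ---------------------------------------------------------------------------
# functional-consequence feature generation
# ---------------------------------------------------------------------------

def generate_features(
    ref: SyntheticReference,
    seed: int = 0,
    p_site_in_autr: float = 0.6,
    p_site_common: float = 0.4,
    p_domain_downstream: float = 0.7,
    p_domain_upstream: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic miRNA target sites and protein-domain intervals.

    Sites are placed inside the aUTR (between proximal and distal PAS) or in
    the common 3'UTR upstream of the proximal PAS; domains inside CDS exons
    up/downstream of the gene's intronic PAS.  Returned as BED-like frames
    (chrom, start, end, feature_id, score, strand, gene_id, kind).
    """
    rng = np.random.default_rng(seed)
    sites = []
    domains = []
    for g in ref.truth:
        m = g.model
        utr = [p for p in g.pas if p.region == "UTR3"]
        if len(utr) >= 2:
            prox, dist = utr[-2], utr[-1]
            lo = min(prox.position, dist.position)
            hi = max(prox.position, dist.position)
            if rng.random() < p_site_in_autr and hi - lo > 30:
                s = int(rng.integers(lo + 8, hi - 8))
                sites.append((m.chrom, s, s + 7, f"mir_{g.gene_id}_a", 0,
                              m.strand, g.gene_id, "MIRNA_SITE"))
            if rng.random() < p_site_common:
                # common UTR: between last-exon start and the proximal PAS
                es, ee = m.three_prime_most_exon
                if m.strand == "+":
                    a, b = es + 70, min(prox.position, dist.position) - 10
                else:
                    a, b = max(prox.position, dist.position) + 10, ee - 70
                if b - a > 10:
                    s = int(rng.integers(a, b - 7))
                    sites.append((m.chrom, s, s + 7, f"mir_{g.gene_id}_c", 0,
                                  m.strand, g.gene_id, "MIRNA_SITE"))
        ipas = [p for p in g.pas if p.region == "INTRON"]
        if ipas:
            p = ipas[0]
            exons_tx = m.exons_tx
            introns_tx = m.introns
            idx = next(i for i, iv in enumerate(introns_tx)
                       if iv[0] <= p.position < iv[1])
            if rng.random() < p_domain_downstream and idx + 1 < len(exons_tx):
                es, ee = exons_tx[idx + 1]
                s = es + 10
                e = min(ee - 10, s + 60)
                if e > s:
                    domains.append((m.chrom, s, e, f"dom_{g.gene_id}_dn", 0,
                                    m.strand, g.gene_id, "DOMAIN"))
            if rng.random() < p_domain_upstream:
                es, ee = exons_tx[0]
                s = es + 40
                e = min(ee - 10, s + 60)
                if e > s:
                    domains.append((m.chrom, s, e, f"dom_{g.gene_id}_up", 0,
                                    m.strand, g.gene_id, "DOMAIN"))
    cols = ["chrom", "start", "end", "feature_id", "score", "strand",
            "gene_id", "kind"]
    return (pd.DataFrame(sites, columns=cols),
            pd.DataFrame(domains, columns=cols))
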