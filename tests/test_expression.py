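"""CDS counting, differential expression, coupling and platform correlation."""

import numpy as np
import pandas as pd
import pysam
import pytest

from apakit.expression import (
    DOWN,
    DifferentialExpressionModel,
    UP,
    apa_expression_coupling,
    count_cds_reads,
    de_test,
    platform_correlation,
    region_restricted_ratio,
)
from apakit.gene_models import GeneModel, GeneModelSet
from apakit.matrix import CONTROL, TREATED, make_design
from apakit.synthetic import (
    ApaProgram,
    ReferenceConfig,
    generate_reference,
    simulate_counts,
    simulate_gene_counts,
)


def _gene():
    # exons [100,300) and [500,900); CDS [150,300)+[500,600); 3'UTR beyond 600
    return GeneModel(
        gene_id="g1", chrom="chr1", strand="+",
        exons=[(100, 300), (500, 900)], cds=[(150, 300), (500, 600)],
    )


def _write_sam(path, rows, length=2000):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": length}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, (flag, start, n) in enumerate(rows):
            r = pysam.AlignedSegment(header)
            r.query_name = f"r{i}"
            r.flag = flag
            r.reference_id = 0
            r.reference_start = start
            r.cigarstring = f"{n}M"
            r.query_sequence = "A" * n
            r.mapping_quality = 60
            sam.write(r)
    return str(path)


class TestCDSCounting:
    def test_utr_only_reads_do_not_count(self, tmp_path):
        models = GeneModelSet([_gene()])
        sam = _write_sam(tmp_path / "s.sam", [
            (0, 700, 50),   # fully in 3'UTR
            (0, 580, 50),   # overlaps CDS end by 20 bp
            (0, 299, 30),   # 1 bp CDS overlap
            (16, 200, 50),  # wrong strand
        ])
        counts = count_cds_reads({"s1": sam}, models)
        assert counts.loc["g1", "s1"] == 2

    def test_ambiguous_reads_discarded(self, tmp_path):
        g2 = GeneModel(gene_id="g2", chrom="chr1", strand="+",
                       exons=[(250, 700)], cds=[(260, 650)])
        models = GeneModelSet([_gene(), g2])
        sam = _write_sam(tmp_path / "s.sam", [(0, 270, 20)])  # CDS of both
        counts = count_cds_reads({"s1": sam}, models)
        assert counts["s1"].sum() == 0


class TestDETest:
    def _null_counts(self, n_genes=800, seed=0):
        ref = generate_reference(
            ReferenceConfig(n_genes=n_genes, n_utr3_pas=1, p_intronic_pas=0.0),
            seed=seed, with_sequence=False,
        )
        design = make_design(3)
        return simulate_gene_counts(ref.truth, design, depth=1000,
                                    dispersion=0.05, seed=seed + 1), design

    def test_programmed_fold_change_recovered(self):
        ref = generate_reference(
            ReferenceConfig(n_genes=300, n_utr3_pas=1, p_intronic_pas=0.0),
            seed=50,
            program=ApaProgram(frac_expr_up=0.2, expr_fold=2.0),
            with_sequence=False,
        )
        design = make_design(3)
        counts = simulate_gene_counts(ref.truth, design, depth=1000,
                                      dispersion=0.05, seed=51)
        res = de_test(counts, design)
        programmed_up = {
            g.gene_id for g in ref.truth if g.expr_mult[TREATED] > 1
        }
        called_up = set(res.table.index[res.table.de_class == UP])
        recovered = len(programmed_up & called_up) / len(programmed_up)
        # power at three replicates is well below 1; the estimate, not the
        # call rate, is the pinned quantity
        assert recovered >= 0.7
        lfc = res.table.loc[sorted(programmed_up), "log2_ratio"]
        assert lfc.mean() == pytest.approx(1.0, abs=0.2)
        assert (res.table.drop(index=programmed_up)["p_value"] < 0.05).mean() < 0.15

    def test_null_simulation_controls_fdr(self):
        counts, design = self._null_counts(seed=52)
        res = de_test(counts, design)
        # no programmed effect: every call is a false discovery
        assert (res.table.de_class != "NC").mean() <= 0.1

    def test_identical_conditions_give_zero_calls(self):
        rng = np.random.default_rng(53)
        half = pd.DataFrame(rng.poisson(100, size=(200, 3)),
                            columns=["control_3hr_r1", "control_3hr_r2",
                                     "control_3hr_r3"])
        mirrored = half.copy()
        mirrored.columns = ["treated_3hr_r1", "treated_3hr_r2", "treated_3hr_r3"]
        counts = pd.concat([half, mirrored], axis=1)
        res = de_test(counts, make_design(3))
        assert (res.table.de_class == "NC").all()

    def test_all_zero_gene_is_nc_with_nan_stats(self):
        counts, design = self._null_counts(n_genes=50, seed=54)
        counts.iloc[0] = 0
        res = de_test(counts, design)
        assert res.table.iloc[0]["de_class"] == "NC"
        assert np.isnan(res.table.iloc[0]["p_value"])

    def test_gene_order_invariance(self):
        counts, design = self._null_counts(n_genes=60, seed=55)
        a = de_test(counts, design).table
        b = de_test(counts.iloc[::-1], design).table
        assert a.sort_index().equals(b.sort_index())


class TestCoupling:
    def _events(self, genes, classes):
        return pd.DataFrame({"gene_id": genes, "event_class": classes})

    def test_programmed_coupling_detected_with_direction(self):
        rng = np.random.default_rng(56)
        genes = [f"g{i}" for i in range(300)]
        classes = ["SHORTENED"] * 100 + ["LENGTHENED"] * 100 + ["NC"] * 100
        lfc = np.concatenate([
            rng.normal(0, 0.2, 100),
            rng.normal(-1.0, 0.2, 100),   # lengthened genes downregulated
            rng.normal(0, 0.2, 100),
        ])
        de = pd.DataFrame({"log2_ratio": lfc}, index=genes)
        res = apa_expression_coupling(self._events(genes, classes), de)
        assert res.summary.loc["LENGTHENED", "median"] < \
            res.summary.loc["SHORTENED", "median"]
        assert res.pairwise_p.loc["LENGTHENED", "SHORTENED"] < 1e-6

    def test_single_gene_class_gets_summary_but_no_test(self):
        genes = ["g1", "g2", "g3"]
        de = pd.DataFrame({"log2_ratio": [0.5, 0.1, -0.2]}, index=genes)
        res = apa_expression_coupling(
            self._events(genes, ["SHORTENED", "NC", "NC"]), de
        )
        assert res.summary.loc["SHORTENED", "n"] == 1
        assert np.isnan(res.pairwise_p.loc["SHORTENED", "NC"])


class TestRegionRatio:
    def test_downstream_only_drop(self, tmp_path):
        model = _gene()
        design = make_design(1)
        rows_ctrl, rows_trt = [], []
        rng = np.random.default_rng(57)
        bp = 500
        for _ in range(400):  # upstream reads, both conditions alike
            start = int(rng.integers(110, 280))
            rows_ctrl.append((0, start, 20))
            rows_trt.append((0, start, 20))
        for i in range(400):  # downstream reads drop 2-fold in treated
            start = int(rng.integers(510, 870))
            rows_ctrl.append((0, start, 20))
            if i % 2 == 0:
                rows_trt.append((0, start, 20))
        sams = {
            "control_3hr_r1": _write_sam(tmp_path / "c.sam", rows_ctrl),
            "treated_3hr_r1": _write_sam(tmp_path / "t.sam", rows_trt),
        }
        res = region_restricted_ratio(sams, design, model, bp)
        assert res.loc["upstream", "log2_ratio"] == pytest.approx(0.0, abs=0.05)
        assert res.loc["downstream", "log2_ratio"] == pytest.approx(-1.0, abs=0.1)

    def test_breakpoint_at_gene_start_equals_whole_gene(self, tmp_path):
        model = _gene()
        design = make_design(1)
        rows = [(0, 550, 20)] * 10
        sams = {
            "control_3hr_r1": _write_sam(tmp_path / "c.sam", rows),
            "treated_3hr_r1": _write_sam(tmp_path / "t.sam", rows * 2),
        }
        res = region_restricted_ratio(sams, design, model, model.span[0])
        assert res.loc["upstream", "control"] == 0
        assert res.loc["downstream", "log2_ratio"] == pytest.approx(
            np.log2(20.5 / 10.5)
        )

    def test_breakpoint_outside_gene_raises(self, tmp_path):
        with pytest.raises(ValueError, match="breakpoint"):
            region_restricted_ratio({}, make_design(1), _gene(), 5000)


class TestPlatformCorrelation:
    def test_identical_sources_give_r_one(self):
        design = make_design(3)
        ref = generate_reference(
            ReferenceConfig(n_genes=100, n_utr3_pas=1, p_intronic_pas=0.0),
            seed=58, program=ApaProgram(frac_expr_up=0.3, expr_fold=2.5),
            with_sequence=False,
        )
        counts = simulate_gene_counts(ref.truth, design, seed=59)
        r = platform_correlation(counts, counts, design, design)
        assert r == pytest.approx(1.0)

    def test_shared_truth_correlates_independent_noise_does_not(self):
        design = make_design(3)
        ref = generate_reference(
            ReferenceConfig(n_genes=500, n_utr3_pas=1, p_intronic_pas=0.0),
            seed=60, program=ApaProgram(frac_expr_up=0.25, frac_expr_down=0.25,
                                        expr_fold=3.0),
            with_sequence=False,
        )
        a = simulate_gene_counts(ref.truth, design, depth=1000,
                                 dispersion=0.1, seed=61)
        b = simulate_gene_counts(ref.truth, design, depth=1000,
                                 dispersion=0.1, seed=62)
        assert platform_correlation(a, b, design, design) > 0.8
        null = generate_reference(
            ReferenceConfig(n_genes=500, n_utr3_pas=1, p_intronic_pas=0.0),
            seed=63, with_sequence=False,
        )
        c = simulate_gene_counts(null.truth, design, depth=1000,
                                 dispersion=0.1, seed=64)
        assert abs(platform_correlation(a, c, design, design)) < 0.2

    def test_constant_vector_is_undefined(self):
        design = make_design(2)
        cols = list(design.index)
        a = pd.DataFrame(1, index=["g1", "g2", "g3"], columns=cols)
        assert np.isnan(platform_correlation(a, a, design, design))
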