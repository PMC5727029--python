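"""Differential APA calls: RE/RED arithmetic, recovery, symmetry, trends."""

import numpy as np
import pandas as pd
import pytest

from apakit.apa import (
    ACTIVATED,
    APAUsageModel,
    LENGTHENED,
    NC,
    REPRESSED,
    SHORTENED,
    apa_quadrants,
    re_red,
    select_top2_utr3,
    weighted_utr3_length,
)
from apakit.apa import test_isoform_switch as isoform_switch
from apakit.matrix import CONTROL, TREATED, make_design
from apakit.synthetic import (
    ApaProgram,
    ReferenceConfig,
    generate_reference,
    simulate_counts,
)

from oracles import fisher_two_sided


def _swap_conditions(matrix):
    samples = matrix.samples.copy()
    samples["condition"] = samples["condition"].map(
        {CONTROL: TREATED, TREATED: CONTROL}
    )
    from apakit.matrix import PASCountMatrix

    return PASCountMatrix(matrix.counts.copy(), matrix.meta.copy(), samples)


class TestPrimitives:
    def test_top2_selection_by_abundance(self):
        sel = select_top2_utr3(
            ["a", "b", "c"],
            {"a": 100, "b": 300, "c": 500},
            {"a": 50, "b": 40, "c": 5},
            "+",
        )
        assert sel == ("a", "b")

    def test_top2_tie_keeps_more_distal(self):
        sel = select_top2_utr3(
            ["a", "b", "c"],
            {"a": 100, "b": 300, "c": 500},
            {"a": 50, "b": 40, "c": 40},
            "+",
        )
        assert sel == ("a", "c")

    def test_single_pas_is_excluded(self):
        assert select_top2_utr3(["a"], {"a": 1}, {"a": 10}, "+") is None

    def test_re_arithmetic(self):
        rr = re_red(100, 400, 100, 400)
        assert rr.re_ctrl == pytest.approx(np.log2(400.5 / 100.5))
        assert rr.re_ctrl == pytest.approx(1.995, abs=5e-3)
        assert rr.red == 0.0 and rr.delta_abundance == 0.0

    def test_red_antisymmetries(self):
        a = re_red(100, 400, 300, 200)
        swapped_cond = re_red(300, 200, 100, 400)
        assert swapped_cond.red == pytest.approx(-a.red)
        swapped_iso = re_red(400, 100, 200, 300)
        assert swapped_iso.re_ctrl == pytest.approx(-a.re_ctrl)

    def test_zero_condition_is_na_event(self):
        assert re_red(0, 0, 10, 20) is None

    def test_fisher_matches_enumeration(self):
        res, _ = isoform_switch(
            {CONTROL: [90], TREATED: [50]},
            {CONTROL: [10], TREATED: [50]},
        )
        assert res.p_value == pytest.approx(fisher_two_sided(90, 50, 10, 50),
                                            rel=1e-9)

    def test_balanced_table_p_one(self):
        res, _ = isoform_switch(
            {CONTROL: [25, 25], TREATED: [25, 25]},
            {CONTROL: [25, 25], TREATED: [25, 25]},
        )
        assert res.p_value == 1.0

    def test_sign_consistency_requires_majority(self):
        # one deep replicate drives the pooled shift up while the majority of
        # replicate pairs move down: the call must not be sign-consistent
        res, consistent = isoform_switch(
            {CONTROL: [500, 50, 50], TREATED: [10, 60, 60]},
            {CONTROL: [500, 50, 50], TREATED: [990, 40, 40]},
        )
        assert not consistent
        # and a coherent shift is
        _, ok = isoform_switch(
            {CONTROL: [50, 50, 50], TREATED: [80, 80, 80]},
            {CONTROL: [50, 50, 50], TREATED: [20, 20, 20]},
        )
        assert ok

    def test_weighted_length(self):
        assert weighted_utr3_length([200, 1000], [30, 10]) == pytest.approx(400)
        assert weighted_utr3_length([700], [5]) == 700
        assert np.isnan(weighted_utr3_length([700], [0]))

    def test_weighted_length_convexity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            lengths = rng.uniform(50, 2000, size=4)
            reads = rng.integers(0, 100, size=4)
            if reads.sum() == 0:
                continue
            w = weighted_utr3_length(lengths, reads)
            assert lengths.min() <= w <= lengths.max()


class TestCalls:
    def test_programmed_shortening_recovered(self, small_ref, small_matrix):
        res = APAUsageModel(small_matrix).fit("utr3")
        truth = set(small_ref.truth.by_class(ApaProgram.SHORTENED))
        called = set(res.events.loc[res.events.event_class == SHORTENED, "gene_id"])
        assert truth, "fixture must program shortened genes"
        assert len(truth & called) / len(truth) >= 0.9

    def test_programmed_intronic_activation_recovered(self, small_ref, small_matrix):
        res = APAUsageModel(small_matrix).fit("intronic")
        truth = set(small_ref.truth.by_class(ApaProgram.INTRONIC_ACTIVATED))
        called = set(res.events.loc[res.events.event_class == ACTIVATED, "gene_id"])
        assert truth
        assert len(truth & called) / len(truth) >= 0.9

    def test_small_delta_is_nc_even_if_significant(self):
        """A <5-point shift stays NC regardless of the p-value."""
        ref = generate_reference(
            ReferenceConfig(n_genes=30, p_intronic_pas=0.0),
            seed=40, program=ApaProgram(frac_shortened=1.0, delta=0.03),
            with_sequence=False,
        )
        mx = simulate_counts(ref.truth, make_design(3), depth=20000,
                             dispersion=0.0, seed=41)
        res = APAUsageModel(mx).fit("utr3")
        sig = res.events[res.events.p_value < 0.05]
        assert len(sig) > 0  # huge depth: tiny shifts are significant
        assert (res.events.event_class == NC).all()

    def test_condition_swap_mirrors_classes(self, small_matrix):
        model = APAUsageModel(small_matrix)
        fwd = model.fit("utr3").events.set_index("gene_id")
        rev = APAUsageModel(_swap_conditions(small_matrix)).fit("utr3") \
            .events.set_index("gene_id")
        swap = {SHORTENED: LENGTHENED, LENGTHENED: SHORTENED, NC: NC}
        for gid in fwd.index:
            assert rev.at[gid, "event_class"] == swap[fwd.at[gid, "event_class"]]
            assert rev.at[gid, "p_value"] == pytest.approx(
                fwd.at[gid, "p_value"], rel=1e-9
            )
            assert rev.at[gid, "red"] == pytest.approx(-fwd.at[gid, "red"],
                                                       abs=1e-9)

    def test_intronic_swap_mirrors_classes(self, small_matrix):
        fwd = APAUsageModel(small_matrix).fit("intronic").events
        rev = APAUsageModel(_swap_conditions(small_matrix)).fit("intronic").events
        swap = {ACTIVATED: REPRESSED, REPRESSED: ACTIVATED, NC: NC}
        assert list(rev.event_class) == [swap[c] for c in fwd.event_class]

    def test_quadrant_bookkeeping(self, small_matrix):
        model = APAUsageModel(small_matrix)
        q = apa_quadrants(model.fit("utr3"), model.fit("intronic"))
        assert q.shape == (3, 3)
        assert (q.to_numpy() >= 0).all()


class TestLengthAndTrend:
    def test_weighted_lengths_shift_down_for_shortened(self, small_ref,
                                                       small_matrix):
        res = APAUsageModel(small_matrix).fit("utr3")
        med = res.median_length_change_by_class()
        assert med[SHORTENED] < 0
        assert abs(med.get(NC, 0)) < abs(med[SHORTENED])

    def test_autr_bins_have_equal_sizes(self, small_matrix):
        res = APAUsageModel(small_matrix).fit("utr3")
        table, _ = res.autr_bins(n_bins=5)
        sizes = table["n"].to_numpy()
        assert sizes.sum() == len(res.events.dropna(subset=["red", "autr_len"]))
        assert sizes.max() - sizes.min() <= 1

    def test_coupled_program_gives_monotone_bins(self):
        """RED scaling with log aUTR shows up as monotone bin means."""
        ref = generate_reference(
            ReferenceConfig(n_genes=300, p_intronic_pas=0.0),
            seed=42, program=ApaProgram(autr_coupled=True, delta=0.35),
            with_sequence=False,
        )
        mx = simulate_counts(ref.truth, make_design(3), depth=800,
                             dispersion=0.05, seed=43)
        res = APAUsageModel(mx).fit("utr3")
        table, p = res.autr_bins(n_bins=5)
        means = table["mean_red"].to_numpy()
        assert (np.diff(means) < 0).all()
        assert p.p_value < 1e-6


class TestIntronProfile:
    def test_first_intron_activation_has_max_centered_value(self):
        ref = generate_reference(
            ReferenceConfig(n_genes=250, p_intronic_pas=0.8, n_introns=(5, 7)),
            seed=44,
            program=ApaProgram(frac_intronic_activated=0.0, delta=0.25),
            with_sequence=False,
        )
        # activate every +1-intron PAS by hand: doubles treated usage share
        for g in ref.truth:
            intr = [i for i, p in enumerate(g.pas)
                    if p.region == "INTRON" and p.intron_ordinal == "+1"]
            if intr:
                u = g.usage[TREATED].copy()
                u[intr] *= 2.5
                g.usage[TREATED] = u / u.sum()
        mx = simulate_counts(ref.truth, make_design(3), depth=500, seed=45)
        prof = APAUsageModel(mx).intron_position_profile()
        centered = prof.table["centered"]
        assert centered.idxmax() == "+1"
        assert prof.p_first_vs_last.p_value < 0.05

    def test_gene_and_read_floors_exclude(self, design3):
        ref = generate_reference(
            ReferenceConfig(n_genes=40, n_introns=(2, 3), p_intronic_pas=1.0),
            seed=46, with_sequence=False,
        )
        mx = simulate_counts(ref.truth, design3, depth=400, seed=47)
        prof = APAUsageModel(mx).intron_position_profile(min_introns=4)
        assert prof.table["n"].sum() == 0  # all genes have < 4 introns

    def test_doubling_only_plus1_counts(self, design3):
        ref = generate_reference(
            ReferenceConfig(n_genes=120, p_intronic_pas=1.0, n_introns=(5, 6)),
            seed=48, with_sequence=False,
        )
        mx = simulate_counts(ref.truth, design3, depth=400, seed=49)
        trt = mx.samples_of(TREATED)
        plus1 = mx.meta["intron_ordinal"] == "+1"
        mx.counts.loc[plus1, trt] = mx.counts.loc[plus1, trt] * 2
        prof = APAUsageModel(mx).intron_position_profile()
        assert prof.table["centered"].idxmax() == "+1"
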