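"""Tail-read extraction, clustering, internal-priming filter, quantification."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from apakit.discovery import (
    cluster_pas,
    extract_pas_reads,
    filter_internal_priming,
    PASRead,
    quantify,
    single_linkage_partition,
)
from apakit.matrix import make_design
from apakit.synthetic import ReferenceConfig, generate_reference, simulate_reads

from oracles import single_linkage_brute

GENOME = {"chr1": "ACGTACGTAC" * 30 + "G" + "C" * 50}  # no A run at the tail


def _write_sam(path, rows, chrom="chr1", length=None):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"},
         "SQ": [{"SN": chrom, "LN": length or len(GENOME["chr1"])}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, (flag, start, cigar, seq) in enumerate(rows):
            r = pysam.AlignedSegment(header)
            r.query_name = f"r{i}"
            r.flag = flag
            r.reference_id = 0
            r.reference_start = start
            r.cigarstring = cigar
            r.query_sequence = seq
            r.mapping_quality = 60
            sam.write(r)
    return str(path)


class TestExtraction:
    def test_three_untemplated_as_accepted(self, tmp_path):
        seq = GENOME["chr1"][0:20] + "AAA"
        sam = _write_sam(tmp_path / "a.sam", [(0, 0, "20M3S", seq)])
        reads = extract_pas_reads(sam, "s1", genome=GENOME)
        assert reads == [PASRead("s1", "chr1", "+", 19)]

    def test_single_untemplated_a_rejected(self, tmp_path):
        seq = GENOME["chr1"][0:20] + "A"
        sam = _write_sam(tmp_path / "a.sam", [(0, 0, "20M1S", seq)])
        assert extract_pas_reads(sam, "s1", genome=GENOME) == []

    def test_templated_clip_rejected(self, tmp_path):
        # clipped bases continue the genome: not unaligned
        g = {"chr1": "ACGT" * 5 + "AAAA" + "ACGT" * 5}
        seq = g["chr1"][0:20] + "AAA"
        sam = _write_sam(tmp_path / "a.sam", [(0, 0, "20M3S", seq)],
                         length=len(g["chr1"]))
        assert extract_pas_reads(sam, "s1", genome=g) == []

    def test_minus_strand_leading_t_clip(self, tmp_path):
        seq = "TTT" + GENOME["chr1"][100:120]
        sam = _write_sam(tmp_path / "a.sam", [(16, 100, "3S20M", seq)])
        reads = extract_pas_reads(sam, "s1", genome=GENOME)
        assert reads == [PASRead("s1", "chr1", "-", 100)]

    def test_mixed_base_clip_is_not_a_tail(self, tmp_path):
        seq = GENOME["chr1"][0:20] + "AGA"
        sam = _write_sam(tmp_path / "a.sam", [(0, 0, "20M3S", seq)])
        assert extract_pas_reads(sam, "s1", genome=GENOME) == []

    def test_no_softclips_warns_and_returns_empty(self, tmp_path):
        seq = GENOME["chr1"][0:20]
        sam = _write_sam(tmp_path / "a.sam", [(0, 0, "20M", seq)])
        with pytest.warns(UserWarning, match="no soft-clip"):
            assert extract_pas_reads(sam, "s1", genome=GENOME) == []

    def test_unknown_orientation_rejected(self, tmp_path):
        sam = _write_sam(tmp_path / "a.sam", [])
        with pytest.raises(ValueError, match="orientation"):
            extract_pas_reads(sam, "s1", orientation="sideways")


class TestClustering:
    def test_gap_over_24_splits(self):
        assert single_linkage_partition([100, 110, 140]) == [[100, 110], [140]]

    def test_chaining_links_through_intermediates(self):
        assert single_linkage_partition([100, 120, 140]) == [[100, 120, 140]]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(1, 50))
            pos = rng.integers(0, 500, size=n).tolist()
            assert single_linkage_partition(pos) == single_linkage_brute(pos, 24)

    @given(st.lists(st.integers(0, 300), min_size=1, max_size=40),
           st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_brute_force_equivalence_property(self, pos, gap):
        assert single_linkage_partition(pos, gap) == single_linkage_brute(pos, gap)

    def test_permutation_invariance_and_idempotence(self):
        rng = np.random.default_rng(2)
        pos = rng.integers(0, 1000, size=60).tolist()
        a = single_linkage_partition(pos)
        b = single_linkage_partition(list(reversed(pos)))
        assert a == b
        reps = [c[0] for c in a]
        # re-clustering representatives >24 apart reproduces the partition
        if all(q - p > 24 for p, q in zip(reps, reps[1:])):
            assert single_linkage_partition(reps) == [[r] for r in reps]

    def test_representative_is_mode_ties_distal(self):
        reads = (
            [PASRead("s1", "chr1", "+", 100)] * 3
            + [PASRead("s1", "chr1", "+", 110)] * 3
            + [PASRead("s1", "chr1", "+", 120)] * 1
        )
        (cl,) = cluster_pas(reads)
        assert cl.representative_pos == 110  # tie 100 vs 110 -> distal on +
        reads_minus = [PASRead("s1", "chr1", "-", p.position) for p in reads]
        (clm,) = cluster_pas(reads_minus)
        assert clm.representative_pos == 100  # distal on - is the smaller coord


class TestInternalPriming:
    def test_a_rich_window_dropped_plain_kept(self):
        g = {"chr1": "C" * 100 + "AAAAAAAAAA" + "C" * 100}
        dropped = cluster_pas([PASRead("s", "chr1", "+", 99)] * 3)
        kept = cluster_pas([PASRead("s", "chr1", "+", 150)] * 3)
        out = filter_internal_priming(dropped + kept, g)
        assert [c.representative_pos for c in out] == [150]

    def test_minus_strand_checks_upstream_ts(self):
        g = {"chr1": "C" * 100 + "TTTTTTTTTT" + "C" * 100}
        # '-' strand cleavage at 110: transcript-downstream is genome [100,110) = T-run
        cl = cluster_pas([PASRead("s", "chr1", "-", 110)] * 2)
        assert filter_internal_priming(cl, g) == []

    def test_contig_edge_counts_missing_as_non_a(self):
        g = {"chr1": "C" * 20 + "AAA"}  # window runs off the contig
        cl = cluster_pas([PASRead("s", "chr1", "+", 19)] * 2)
        assert len(filter_internal_priming(cl, g)) == 1

    def test_planted_decoys_removed_true_sites_kept(self, tmp_path, design3):
        ref = generate_reference(
            ReferenceConfig(n_genes=15, n_decoy_tracts=6), seed=13
        )
        paths, _ = simulate_reads(ref, design3, str(tmp_path), depth=20,
                                  cluster_jitter=0, decoy_fraction=0.1, seed=14)
        reads = []
        for s, p in paths.items():
            reads.extend(extract_pas_reads(p, s, genome=ref.genome))
        clusters = cluster_pas(reads)
        kept = filter_internal_priming(clusters, ref.genome)
        decoy_pos = {pos for _, pos in ref.decoy_sites}
        surviving_decoys = [c for c in kept if c.representative_pos in decoy_pos]
        assert len(surviving_decoys) == 0  # >= 95% required; all are removed
        true_ids = {p.pas_id for g in ref.truth for p in g.pas}
        assert {c.pas_id for c in kept} <= true_ids
        assert len({c.pas_id for c in kept}) == len(
            {c.pas_id for c in clusters} & true_ids
        )


class TestQuantify:
    def test_single_position_single_sample(self, design3):
        reads = [PASRead(design3.index[0], "chr1", "+", 50)] * 10
        mx = quantify(cluster_pas(reads), design3)
        assert mx.counts.shape == (1, 6)
        assert mx.counts.iloc[0].sum() == 10

    def test_column_sums_conserve_reads(self, design3):
        rng = np.random.default_rng(3)
        samples = list(design3.index)
        reads = [
            PASRead(samples[int(rng.integers(len(samples)))], "chr1",
                    "+-"[int(rng.integers(2))], int(rng.integers(0, 2000)))
            for _ in range(500)
        ]
        mx = quantify(cluster_pas(reads), design3)
        per_sample = {s: sum(r.sample == s for r in reads) for s in samples}
        for s in samples:
            assert mx.counts[s].sum() == per_sample[s]

    def test_unknown_sample_raises(self, design3):
        reads = [PASRead("mystery", "chr1", "+", 10)] * 2
        with pytest.raises(ValueError, match="mystery"):
            quantify(cluster_pas(reads), design3)

    def test_closed_loop_counts_match_simulation(self, tmp_path, design3):
        """At zero jitter, discovery reproduces the emitted per-PAS counts."""
        ref = generate_reference(ReferenceConfig(n_genes=25), seed=15)
        paths, emitted = simulate_reads(ref, design3, str(tmp_path), depth=30,
                                        cluster_jitter=0, seed=16)
        reads = []
        for s, p in paths.items():
            reads.extend(extract_pas_reads(p, s, genome=ref.genome))
        mx = quantify(
            filter_internal_priming(cluster_pas(reads), ref.genome), design3
        )
        truth = emitted.pivot_table(index="pas_id", columns="sample_id",
                                    values="count", fill_value=0, aggfunc="sum")
        assert set(mx.counts.index) == set(truth.index)
        for s in design3.index:
            got = mx.counts[s].sort_index()
            want = truth.reindex(got.index)[s] if s in truth.columns else 0
            assert (got == want).all()

    def test_no_tail_reads_discover_nothing(self, tmp_path, design3):
        ref = generate_reference(ReferenceConfig(n_genes=5), seed=17)
        paths, _ = simulate_reads(ref, design3, str(tmp_path), depth=10,
                                  tail_fixed=1, cluster_jitter=0, seed=18)
        reads = []
        for s, p in paths.items():
            reads.extend(extract_pas_reads(p, s, genome=ref.genome))
        assert reads == []
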