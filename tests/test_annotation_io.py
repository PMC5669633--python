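"""Transcription-unit construction, coverage IO and the coordinate contract."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pauselimit.annotation_io import (
    CountTable,
    GeneModel,
    StrandedCoverage,
    build_tus,
    expression_filter,
    load_coverage,
    merge_intervals,
    read_gtf,
    tu_local_view,
    write_bedgraph,
)
from pauselimit.synthetic_data import generate_cohort


def exon_base_set(isoform):
    return set(itertools.chain.from_iterable(range(s, e) for s, e in isoform))


class TestBuildTus:
    def test_single_isoform_three_exons(self):
        gene = GeneModel("g1", "chr1", "+", ((
            (100, 200), (300, 400), (500, 650)),))
        (tu,) = build_tus([gene])
        assert (tu.start, tu.end) == (100, 650)
        assert tu.length == 550
        assert tu.tss == 100
        assert tu.unique_tss
        assert tu.nonfirst_constitutive_exons == [(300, 400), (500, 650)]
        assert tu.first_exon_end_offset() == 100
        assert tu.first_intron_length == 100

    def test_differing_tss_is_not_unique(self):
        gene = GeneModel("g1", "chr1", "+", (
            ((100, 200), (300, 400)),
            ((150, 200), (300, 400)),
        ))
        (tu,) = build_tus([gene])
        assert not tu.unique_tss

    def test_constitutive_exons_match_base_set_intersection(self):
        # exon2 present in only one isoform must be absent from the
        # non-first constitutive set; oracle = brute-force base-set ops
        iso_a = ((100, 200), (300, 400), (500, 650))
        iso_b = ((100, 200), (500, 650))
        (tu,) = build_tus([GeneModel("g1", "chr1", "+", (iso_a, iso_b))])
        expected = exon_base_set(iso_a) & exon_base_set(iso_b)
        expected -= set(range(100, 200))  # first merged exon
        assert exon_base_set(tu.nonfirst_constitutive_exons) == expected
        assert (300, 400) not in tu.nonfirst_constitutive_exons

    def test_minus_strand_orientation(self):
        gene = GeneModel("g1", "chr1", "-", ((
            (100, 250), (400, 500), (600, 700)),))
        (tu,) = build_tus([gene])
        assert tu.tss == 699
        assert tu.first_exon == (600, 700)
        assert tu.first_exon_end_offset() == 100
        assert tu.first_intron_length == 100
        assert tu.to_local(699) == 0
        assert tu.to_local(600) == 99

    def test_isoform_order_invariance(self):
        isos = (((100, 200), (300, 400)), ((100, 220), (300, 400)),
                ((100, 200), (350, 400)))
        results = []
        for perm in itertools.permutations(isos):
            (tu,) = build_tus([GeneModel("g", "chr1", "+", perm)])
            results.append((tu.start, tu.end, tuple(tu.exons),
                            tuple(tu.nonfirst_constitutive_exons), tu.unique_tss))
        assert len(set(results)) == 1

    def test_gene_without_exons_rejected(self):
        assert build_tus([GeneModel("g", "chr1", "+", ((),))]) == []


class TestExpressionFilter:
    def make_tu(self, tu_id, length):
        return build_tus([GeneModel(tu_id, "chr1", "+", (((0, length),),))])[0]

    def test_rpk_boundary(self):
        tu = self.make_tu("a", 10_000)
        counts = pd.DataFrame({"r1": [600.0], "r2": [400.0]}, index=["a"])
        assert expression_filter([tu], counts, 100.0) == [tu]
        counts_low = pd.DataFrame({"r1": [600.0], "r2": [399.0]}, index=["a"])
        assert expression_filter([tu], counts_low, 100.0) == []

    def test_matches_bruteforce_on_mixed_cohort(self, rng):
        tus = [self.make_tu(f"t{i}", int(rng.integers(1_000, 50_000))) for i in range(50)]
        counts = pd.DataFrame(
            rng.uniform(0, 5_000, size=(50, 2)), index=[t.tu_id for t in tus],
            columns=["r1", "r2"],
        )
        kept = {t.tu_id for t in expression_filter(tus, counts, 100.0)}
        brute = {
            t.tu_id for t in tus
            if counts.loc[t.tu_id].sum() / (t.length / 1000) >= 100.0
        }
        assert kept == brute

    def test_threshold_zero_keeps_all_with_counts(self):
        tus = [self.make_tu("a", 5_000), self.make_tu("b", 5_000)]
        counts = pd.DataFrame({"r1": [1.0, 0.0], "r2": [0.0, 0.0]}, index=["a", "b"])
        kept = expression_filter(tus, counts, 0.0)
        assert [t.tu_id for t in kept] == ["a", "b"]  # rpk >= 0 holds for both

    def test_missing_tu_excluded(self):
        tu = self.make_tu("absent", 1_000)
        assert expression_filter([tu], pd.DataFrame(columns=["r1"]), 100.0) == []


class TestCoverageIO:
    def test_bedgraph_semantics(self, tmp_path):
        plus = tmp_path / "s.plus.bedgraph"
        plus.write_text("chr1\t0\t5\t2.0\n")
        (tmp_path / "s.minus.bedgraph").write_text("")
        cov = load_coverage(plus, tmp_path / "s.minus.bedgraph", {"chr1": 10},
                            "s", "ttseq", "control")
        assert np.array_equal(cov.plus["chr1"][:6], [2, 2, 2, 2, 2, 0])
        assert cov.minus["chr1"].sum() == 0  # empty file -> all-zero track

    def test_roundtrip_exact(self, tmp_path, rng):
        track = {"chr1": rng.integers(0, 30, 500).astype(float)}
        write_bedgraph(track, tmp_path / "t.bedgraph")
        (tmp_path / "e.bedgraph").write_text("")
        cov = load_coverage(tmp_path / "t.bedgraph", tmp_path / "e.bedgraph",
                            {"chr1": 500}, "s", "ttseq", "control")
        assert np.array_equal(cov.plus["chr1"], track["chr1"])

    def test_overlap_and_negative_errors(self, tmp_path):
        bad = tmp_path / "bad.bedgraph"
        bad.write_text("chr1\t0\t5\t1.0\nchr1\t3\t8\t1.0\n")
        (tmp_path / "e.bedgraph").write_text("")
        with pytest.raises(ValueError, match="overlap"):
            load_coverage(bad, tmp_path / "e.bedgraph", {"chr1": 10}, "s", "ttseq", "control")
        bad.write_text("chr1\t0\t5\t-1.0\n")
        with pytest.raises(ValueError, match="negative"):
            load_coverage(bad, tmp_path / "e.bedgraph", {"chr1": 10}, "s", "ttseq", "control")


class TestTuLocalView:
    def make_cov(self, plus, minus):
        return StrandedCoverage("s", "ttseq", "control", 1,
                                plus={"chr1": np.asarray(plus, dtype=float)},
                                minus={"chr1": np.asarray(minus, dtype=float)})

    def test_plus_strand_window(self):
        cov = self.make_cov(np.arange(10), np.zeros(10))
        (tu,) = build_tus([GeneModel("g", "chr1", "+", (((2, 9),),))])
        assert np.array_equal(tu_local_view(cov, tu, (0, 3)), [2, 3, 4])

    def test_strand_mirror_symmetry(self):
        # mirror-image fixtures on opposite strands give identical views
        sig = np.array([1.0, 4.0, 2.0, 7.0, 0.0, 3.0])
        cov_p = self.make_cov(sig, np.zeros(6))
        cov_m = self.make_cov(np.zeros(6), sig[::-1])
        (tu_p,) = build_tus([GeneModel("g", "chr1", "+", (((0, 6),),))])
        (tu_m,) = build_tus([GeneModel("g", "chr1", "-", (((0, 6),),))])
        for window in [(0, 6), (1, 4), (2, 3)]:
            assert np.array_equal(
                tu_local_view(cov_p, tu_p, window), tu_local_view(cov_m, tu_m, window)
            )

    def test_antisense_view_uses_opposite_track(self):
        cov = self.make_cov(np.arange(10), np.arange(10) * 10)
        (tu,) = build_tus([GeneModel("g", "chr1", "+", (((0, 10),),))])
        assert np.array_equal(tu_local_view(cov, tu, (0, 3), antisense=True), [0, 10, 20])

    def test_out_of_bounds_truncated(self):
        cov = self.make_cov(np.ones(10), np.zeros(10))
        (tu,) = build_tus([GeneModel("g", "chr1", "+", (((5, 10),),))])
        assert tu_local_view(cov, tu, (0, 20)).size == 5


def test_merge_intervals_is_union(rng):
    for _ in range(20):
        ivs = [(int(s), int(s + rng.integers(1, 20)))
               for s in rng.integers(0, 100, size=8)]
        merged = merge_intervals(ivs)
        base = set(itertools.chain.from_iterable(range(s, e) for s, e in ivs))
        assert exon_base_set(merged) == base
        assert all(merged[i][1] < merged[i + 1][0] for i in range(len(merged) - 1))


def test_gtf_roundtrip(tmp_path):
    cohort = generate_cohort(n_tus=4, seed=5, length_range=(10_000, 30_000),
                             two_isoform_fraction=0.5)
    from pauselimit.annotation_io import write_gtf

    write_gtf(cohort.genes, tmp_path / "a.gtf")
    back = read_gtf(tmp_path / "a.gtf")
    orig_tus = {t.tu_id: t for t in build_tus(cohort.genes)}
    for tu in build_tus(back):
        ref = orig_tus[tu.tu_id]
        assert (tu.start, tu.end, tu.strand, tu.exons) == (ref.start, ref.end, ref.strand, ref.exons)
        assert tu.unique_tss == ref.unique_tss


def test_count_table_alignment_and_negativity():
    s = pd.DataFrame({"x": [1.0]}, index=["f"])
    with pytest.raises(ValueError):
        CountTable(sense=s, antisense=pd.DataFrame({"x": [-1.0]}, index=["f"]))
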