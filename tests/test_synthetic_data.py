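"""The coverage simulator: velocity profiles, labeling bias, size selection,
TT-seq/mNET-seq generation and cohort plumbing."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from pauselimit.annotation_io import build_tus
from pauselimit.synthetic_data import (
    GlobalSimParams,
    TruthTU,
    VelocityProfile,
    elongation_position,
    expected_mnet_occupancy,
    expected_ttseq_coverage,
    generate_cohort,
    labeling_bias,
    sample_ttseq_coverage,
    simulate_mnet_tu,
    simulate_spikeins,
    simulate_ttseq_tu,
    size_selection_weight,
    default_spikeins,
)


def make_truth(length=30_000, v=1000.0, I=2.0, pause=80, d=1.0, r=0.5):
    return TruthTU(
        tu_id="t", length=length, velocity=v, initiation_frequency_I=I,
        pause_position=pause, pause_duration_d=d, response_ratio_r=r,
        pause_duration_d_inhibited=2 * d, initiation_frequency_I_inhibited=I * (1 - r),
        first_exon_length=400, first_intron_length=2_000,
    )


class TestElongationPosition:
    def test_constant_velocity(self):
        prof = VelocityProfile([0.0], [1000.0])
        assert elongation_position(prof, 5.0) == pytest.approx(5000.0)
        assert elongation_position(prof, 0.0) == 0.0

    def test_pause_dwell_piecewise(self):
        # 0.08 min to reach 80 bp, 2 min dwell in the 1-bp pause segment
        prof = VelocityProfile.with_pause(1000.0, 80, 2.0)
        assert elongation_position(prof, 2.08) == pytest.approx(81.0)
        assert elongation_position(prof, 1.0) == pytest.approx(80.0 + 0.92 / 2)

    def test_monotone_and_inverse(self):
        prof = VelocityProfile.with_pause(2000.0, 100, 0.5)
        t = np.linspace(0, 3, 50)
        pos = prof.position(t)
        assert np.all(np.diff(pos) >= 0)
        assert np.allclose(prof.time_at(prof.position(t)), t, atol=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            VelocityProfile([0.0], [1000.0]).position(-1.0)


class TestLabelingBias:
    def test_zero_length(self):
        assert labeling_bias(0) == 0.0

    def test_printed_example(self):
        # 100 bp at 28% U content: 28 uracils, 1 - 0.95^28
        assert labeling_bias(100, 0.05, 0.28) == pytest.approx(1 - 0.95**28)
        assert labeling_bias(100, 0.05, 0.28) == pytest.approx(0.7622, abs=2e-4)

    def test_saturation_and_bounds(self):
        assert labeling_bias(4, 1.0) == 1.0
        with pytest.raises(ValueError):
            labeling_bias(10, 1.5)


class TestSizeSelection:
    def test_midpoint_half(self):
        assert size_selection_weight(80.0, 80.0, 10.0) == pytest.approx(0.5)

    def test_limits_and_monotonicity(self):
        assert size_selection_weight(1e6) == pytest.approx(1.0)
        lens = np.linspace(0, 400, 100)
        w = size_selection_weight(lens)
        assert np.all(np.diff(w) > 0)


class TestTTseqExpectation:
    def test_zero_labeling_duration_gives_zero_track(self):
        params = GlobalSimParams()
        params.labeling_duration = 0.0
        _, sampled = simulate_ttseq_tu(make_truth(), params)
        assert sampled.sum() == 0

    def test_flat_interior_and_conservation(self):
        truth = make_truth(length=40_000, v=2000.0, I=2.0, d=0.0, pause=80)
        params = GlobalSimParams()
        cov = expected_ttseq_coverage(truth, params)
        interior = cov[12_000:35_000]
        # expected coverage ~ I * t_lab with near-unit weights, flat
        assert interior.mean() == pytest.approx(
            truth.initiation_frequency_I * params.labeling_duration, rel=0.02)
        assert interior.std() / interior.mean() < 0.02

    def test_superposition_in_initiation_rate(self):
        t1 = make_truth(I=1.0)
        t3 = make_truth(I=3.0)
        params = GlobalSimParams()
        assert np.allclose(3 * expected_ttseq_coverage(t1, params),
                           expected_ttseq_coverage(t3, params), rtol=1e-9)

    def test_pause_shortage_monotone_in_duration(self):
        # longer pausing starves the TSS-to-pause region of labeled RNA
        params = GlobalSimParams()
        means = []
        for d in (0.5, 1.0, 2.0):
            truth = make_truth(length=30_000, v=2000.0, d=d, r=0.0)
            cov = expected_ttseq_coverage(truth, params)
            means.append(cov[: truth.pause_position].mean())
        assert means[0] > means[1] > means[2]

    def test_full_response_empties_window_and_spares_distal_gene_body(self):
        truth = make_truth(length=60_000, v=2000.0, I=2.0, d=0.5, r=1.0)
        params = GlobalSimParams()
        ctrl = expected_ttseq_coverage(truth, params)
        inh = expected_ttseq_coverage(truth, params, "inhibited")
        x_resp = truth.pause_position + int(
            truth.velocity * (params.treatment_duration - params.labeling_duration))
        assert inh[500: x_resp - 100].max() == 0.0
        assert np.allclose(inh[x_resp + 1:], ctrl[x_resp + 1:])

    def test_kinetic_thinning_smears_the_window_edge(self):
        truth = make_truth(length=60_000, v=2000.0, d=1.0, r=1.0)
        sharp = GlobalSimParams()
        kinetic = GlobalSimParams(thinning="kinetic")
        ctrl = expected_ttseq_coverage(truth, sharp)
        inh_k = expected_ttseq_coverage(truth, kinetic, "inhibited")
        x_resp = truth.pause_position + 20_000
        probe = x_resp + int(truth.velocity * sharp.labeling_duration / 2)
        assert inh_k[probe] < 0.7 * ctrl[probe]          # still depleted mid-ramp
        assert np.allclose(inh_k[-4_000:], ctrl[-4_000:], rtol=1e-6)  # intact far away

    def test_short_tu_rejected(self):
        with pytest.raises(ValueError):
            expected_ttseq_coverage(make_truth(length=150), GlobalSimParams())


class TestTTseqSampling:
    def test_sampled_tracks_are_nonnegative_integers(self, rng):
        truth = make_truth(length=5_000, v=1000.0)
        track = sample_ttseq_coverage(truth, GlobalSimParams(), "control", 1.0, rng)
        assert track.dtype.kind == "i"
        assert (track >= 0).all()
        assert track.sum() > 0

    def test_monte_carlo_mean_matches_expectation(self, rng):
        truth = make_truth(length=4_000, v=1000.0, I=2.0, d=0.5)
        params = GlobalSimParams(kappa_true=2.0)
        rho = expected_ttseq_coverage(truth, params)
        n_rep = 400
        # window sums away from edges, where read anchoring does not smear
        windows = [(500, 1_500), (2_000, 3_500)]
        sums = np.zeros((n_rep, len(windows)))
        for k in range(n_rep):
            tr = sample_ttseq_coverage(truth, params, "control", 1.0, rng, rho=rho)
            sums[k] = [tr[a:b].sum() for a, b in windows]
        for j, (a, b) in enumerate(windows):
            expect = rho[a:b].sum() * params.kappa_true
            se = sums[:, j].std(ddof=1) / np.sqrt(n_rep)
            assert abs(sums[:, j].mean() - expect) < 3 * se + 1e-9


class TestMnet:
    def test_uniform_occupancy_without_pause(self):
        truth = make_truth(d=0.0)
        occ = expected_mnet_occupancy(truth, GlobalSimParams())
        assert np.allclose(occ, occ[0])

    def test_doubling_dwell_doubles_pause_mass(self):
        params = GlobalSimParams()
        t1 = make_truth(d=1.0)
        t2 = make_truth(d=2.0)
        body = t1.initiation_frequency_I / t1.velocity
        m1 = (expected_mnet_occupancy(t1, params) - body)[:400].sum()
        m2 = (expected_mnet_occupancy(t2, params) - body)[:400].sum()
        assert m2 == pytest.approx(2 * m1, rel=1e-6)

    def test_pause_to_body_ratio_closed_form(self):
        # window mass ratio = (I*d) / (I*w/v) for a w-wide body window
        params = GlobalSimParams()
        truth = make_truth(length=50_000, v=2000.0, I=3.0, d=1.5)
        occ = expected_mnet_occupancy(truth, params)
        w = 200
        pause_mass = occ[:400].sum() - 400 * truth.initiation_frequency_I / truth.velocity
        body_mass = occ[20_000: 20_000 + w].sum()
        expected_ratio = truth.pause_duration_d / (w / truth.velocity)
        assert pause_mass / body_mass == pytest.approx(expected_ratio, rel=1e-3)

    def test_multinomial_depth_and_determinism(self):
        truth = make_truth(length=3_000)
        _, counts = simulate_mnet_tu(truth, GlobalSimParams(), "control", depth=5_000, seed=9)
        assert counts.sum() == 5_000
        _, again = simulate_mnet_tu(truth, GlobalSimParams(), "control", depth=5_000, seed=9)
        assert np.array_equal(counts, again)

    def test_inhibited_shifts_occupancy_to_pause(self):
        params = GlobalSimParams()
        truth = make_truth(length=60_000, v=2000.0, d=1.0, r=0.6)
        ctrl = expected_mnet_occupancy(truth, params)
        inh = expected_mnet_occupancy(truth, params, "inhibited")
        assert inh[:300].sum() > ctrl[:300].sum()       # more paused Pol II
        assert inh[5_000:20_000].sum() < ctrl[5_000:20_000].sum()  # emptier body


class TestSpikeins:
    def test_zero_bleed_means_zero_antisense(self):
        counts = simulate_spikeins(default_spikeins(1), 5.0, 0.0, {"s": 1.0}, seed=0)
        assert counts.antisense["s"].sum() == 0

    def test_bleed_rate_recovered(self):
        counts = simulate_spikeins(default_spikeins(1), 5.0, 0.03, {"s": 1.0}, seed=0)
        labeled = counts.sense["s"] > 1_000
        ratio = (counts.antisense["s"][labeled] / counts.sense["s"][labeled]).median()
        assert ratio == pytest.approx(0.03, rel=0.05)

    def test_requires_labeled_spikein(self):
        spikes = [s for s in default_spikeins(1) if not s.labeled]
        with pytest.raises(ValueError):
            simulate_spikeins(spikes, 5.0, 0.0, {"s": 1.0}, seed=0)


class TestGenerateCohort:
    def test_same_seed_byte_identical(self, tmp_path):
        def digest(d: Path) -> dict:
            return {
                p.name: hashlib.md5(p.read_bytes()).hexdigest()
                for p in sorted(d.iterdir())
            }

        generate_cohort(n_tus=2, seed=42, length_range=(10_000, 20_000),
                        write_dir=tmp_path / "a")
        generate_cohort(n_tus=2, seed=42, length_range=(10_000, 20_000),
                        write_dir=tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_single_tu_cohort(self):
        cohort = generate_cohort(n_tus=1, seed=0, length_range=(10_000, 20_000))
        assert len(cohort.genes) == 1
        for cov in cohort.coverages:
            total = sum(arr.sum() for arr in cov.plus.values()) + \
                sum(arr.sum() for arr in cov.minus.values())
            assert total > 0

    def test_steric_constraint_holds_in_truth(self):
        cohort = generate_cohort(n_tus=60, seed=8, length_range=(10_000, 40_000))
        truth = cohort.truth.frame()
        prod = truth["pause_duration_d"] * truth["initiation_frequency_I"]
        assert (200.0 / prod >= 50.0 - 1e-9).all()

    def test_unconstrained_sampler_admits_violations(self):
        cohort = generate_cohort(n_tus=120, seed=8, length_range=(10_000, 20_000),
                                 steric_constraint=False)
        truth = cohort.truth.frame()
        prod = truth["pause_duration_d"] * truth["initiation_frequency_I"]
        assert (200.0 / prod < 50.0).any()

    def test_annotation_consistent_with_truth(self):
        cohort = generate_cohort(n_tus=10, seed=4, length_range=(10_000, 50_000))
        tus = {t.tu_id: t for t in build_tus(cohort.genes)}
        for tr in cohort.truth.tus:
            tu = tus[tr.tu_id]
            assert tu.length == tr.length
            assert tu.first_exon_end_offset() == tr.first_exon_length
            assert tr.pause_position < tr.first_exon_length
            # planted pause-site base reads C on the sense strand
            g = tu.tss + tr.pause_position if tu.strand == "+" else tu.tss - tr.pause_position
            base = cohort.genome[tu.chrom][g]
            if tu.strand == "-":
                base = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
            assert base == "C"
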