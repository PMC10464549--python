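import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from modsite import (
    InvalidArgumentError,
    ModProfile,
    SimConfig,
    effective_error,
    g_score,
    make_reference,
    pileup_from_bam,
    simulate_pileups,
    simulate_reads,
)
from conftest import mod_error_vector


class TestMakeReference:
    def test_deterministic_for_fixed_seed(self):
        a = make_reference(1869, gc=0.5, seed=1)
        b = make_reference(1869, gc=0.5, seed=1)
        assert a.sequence == b.sequence
        assert a.length == 1869
        assert make_reference(1869, gc=0.5, seed=2).sequence != a.sequence

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_reference(10)

    def test_gc_content_within_binomial_bound(self):
        ref = make_reference(1000, gc=0.8, seed=7)
        gc_count = sum(ref.sequence.count(b) for b in "GC")
        assert abs(gc_count - 800) <= 3 * np.sqrt(1000 * 0.8 * 0.2)


class TestEffectiveError:
    def test_endpoints_recover_pure_profiles(self):
        prof = ModProfile(site=50)
        np.testing.assert_array_equal(effective_error(prof, 0.0, 0), prof.base_error)
        np.testing.assert_array_equal(effective_error(prof, 1.0, 0), prof.mod_error)

    def test_quarter_mixture_arithmetic(self):
        base = np.array([0.98, 0.02, 0.0, 0.0, 0.0, 0.0])
        mod = np.array([0.60, 0.40, 0.0, 0.0, 0.0, 0.0])
        prof = ModProfile(site=50, base_error=base, mod_error=mod)
        assert effective_error(prof, 0.25, 0)[1] == pytest.approx(0.115)  # 0.75*0.02+0.25*0.40

    @given(s=st.floats(0, 1), offset=st.sampled_from(range(-3, 4)))
    @settings(deadline=None)
    def test_linearity_and_normalisation(self, s, offset):
        prof = ModProfile(
            site=50, context_kernel={o: 0.5 if o else 1.0 for o in range(-3, 4)}
        )
        v = effective_error(prof, s, offset)
        assert v.sum() == pytest.approx(1.0, abs=1e-12)
        half = effective_error(prof, s / 2, offset)
        zero = effective_error(prof, 0.0, offset)
        # linear in s: v(s/2) is the midpoint of v(0) and v(s)
        np.testing.assert_allclose(half, (zero + v) / 2, atol=1e-12)


class TestSimulatePileups:
    def test_depth_conserved_everywhere(self, small_ref):
        prof = ModProfile(site=100)
        for pm in simulate_pileups(small_ref, [prof], 1.0, SimConfig(1000, 3, seed=1)):
            np.testing.assert_array_equal(pm.depth, 1000)

    def test_deterministic_for_fixed_seed(self, small_ref):
        cfg = SimConfig(500, 2, seed=9)
        a = simulate_pileups(small_ref, [], 0.0, cfg)
        b = simulate_pileups(small_ref, [], 0.0, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_site_out_of_range_rejected(self, small_ref):
        with pytest.raises(InvalidArgumentError):
            simulate_pileups(small_ref, [ModProfile(site=999)], 1.0, SimConfig(10, 1, seed=0))

    def test_injected_mismatch_count_matches_binomial_expectation(self, small_ref):
        prof = ModProfile(site=100, mod_error=mod_error_vector(0.40, 0.02, 0.01))
        pm = simulate_pileups(
            small_ref, [prof], 1.0, SimConfig(1000, 1, kappa=np.inf, seed=3)
        )[0]
        ref_base = small_ref.sequence[99]
        mismatches = pm.depth[99] - pm.counts[99, 4] - pm.counts[99, "ACGT".index(ref_base)]
        assert abs(mismatches - 400) <= 3 * np.sqrt(1000 * 0.40 * 0.60)

    def test_zero_stoichiometry_statistically_null(self, small_ref):
        """s>0 with an empty profile list is distributionally identical to s=0."""
        cfg_a = SimConfig(800, 1, kappa=np.inf, seed=21)
        cfg_b = SimConfig(800, 1, kappa=np.inf, seed=22)
        a = simulate_pileups(small_ref, [], 0.0, cfg_a)[0]
        b = simulate_pileups(small_ref, [], 0.7, cfg_b)[0]
        g = np.array(
            [g_score(a.counts[i, :4], b.counts[i, :4]) for i in range(small_ref.length)]
        )
        exceed = (g > chi2.ppf(0.99, 3)).mean()
        assert exceed < 0.05


class TestSimulateReads:
    def test_read_count_and_orientation(self, small_ref, tmp_path):
        import pysam

        path = simulate_reads(small_ref, [], 0.0, SimConfig(50, 1, seed=4), tmp_path)[0]
        with pysam.AlignmentFile(str(path)) as af:
            reads = list(af.fetch(until_eof=True))
        assert len(reads) == 50
        assert all(not r.is_reverse and not r.is_secondary for r in reads)
        assert all(r.reference_start == 0 for r in reads)

    def test_byte_identical_for_fixed_seed(self, small_ref, tmp_path):
        cfg = SimConfig(30, 1, seed=8)
        a = simulate_reads(small_ref, [], 0.0, cfg, tmp_path / "a")[0]
        b = simulate_reads(small_ref, [], 0.0, cfg, tmp_path / "b")[0]
        assert a.read_bytes() == b.read_bytes()

    def test_bam_pileup_reproduces_injected_mismatch_fraction(self, small_ref, tmp_path):
        """Round trip: the pileup of the emitted BAM is a draw from the pileup model."""
        mm = 0.30
        prof = ModProfile(site=100, mod_error=mod_error_vector(mm, 0.0, 0.0))
        path = simulate_reads(
            small_ref, [prof], 1.0, SimConfig(1000, 1, kappa=np.inf, seed=5), tmp_path
        )[0]
        pm = pileup_from_bam(path)
        ref_base = small_ref.sequence[99]
        mismatches = pm.depth[99] - pm.counts[99, 4] - pm.counts[99, "ACGT".index(ref_base)]
        # at s=1 and w0=1 the site's mismatch probability is mod_error's 0.30
        assert abs(mismatches - 1000 * mm) <= 3 * np.sqrt(1000 * mm * (1 - mm))

    def test_pileup_distribution_matches_pileup_model(self, small_ref, tmp_path):
        """Goodness of fit between BAM-derived and directly simulated pileups."""
        cfg1 = SimConfig(800, 1, kappa=np.inf, seed=31)
        cfg2 = SimConfig(800, 1, kappa=np.inf, seed=32)
        bam = simulate_reads(small_ref, [], 0.0, cfg1, tmp_path)[0]
        from_bam = pileup_from_bam(bam)
        direct = simulate_pileups(small_ref, [], 0.0, cfg2)[0]
        pos = np.arange(0, 100)
        g = np.array([g_score(from_bam.counts[i, :4], direct.counts[i, :4]) for i in pos])
        assert (g > chi2.ppf(0.99, 3)).mean() < 0.05
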