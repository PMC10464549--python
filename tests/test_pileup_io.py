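import numpy as np
import pandas as pd
import pysam
import pytest

from modsite import (
    AlignmentFilterConfig,
    EmptyInputError,
    FormatError,
    InvalidArgumentError,
    downsample_bam,
    mix_bams,
    pileup_from_bam,
)
from modsite.pileup_io import PileupMatrix, round_half_away


class TestPileupFromToySam:
    def test_manual_counts_at_deletion_column(self, toy_sam):
        """Reads AAAA/AACA/AA-A over ref AAAA: position 3 has A:1, C:1, del:1."""
        pm = pileup_from_bam(toy_sam)
        row = pm.to_frame().set_index("pos").loc[3]
        assert row["n_A"] == 1 and row["n_C"] == 1 and row["n_del"] == 1
        assert row["depth"] == 3
        np.testing.assert_array_equal(pm.depth, 3)

    def test_reference_reconstructed_from_md(self, toy_sam):
        assert pileup_from_bam(toy_sam).ref_seq == "AAAA"

    def test_secondary_alignment_contributes_nothing(self, toy_sam, tmp_path):
        sam = toy_sam.read_text() + "r4\t256\ttoyref\t1\t60\t4M\t*\t0\t0\tGGGG\t*\tMD:Z:4\n"
        p = tmp_path / "sec.sam"
        p.write_text(sam)
        pm = pileup_from_bam(p)
        assert pm.counts[:, 2].sum() == 0  # no G ever called by primaries

    def test_reverse_strand_excluded_by_default(self, toy_sam, tmp_path):
        sam = toy_sam.read_text() + "r5\t16\ttoyref\t1\t60\t4M\t*\t0\t0\tTTTT\t*\tMD:Z:4\n"
        p = tmp_path / "rev.sam"
        p.write_text(sam)
        assert pileup_from_bam(p).counts[:, 3].sum() == 0
        relaxed = pileup_from_bam(p, filters=AlignmentFilterConfig(forward_strand_only=False))
        assert relaxed.counts[:, 3].sum() == 4

    def test_insertion_counted_once_per_read_at_left_anchor(self, tmp_path):
        sam = (
            "@HD\tVN:1.6\n@SQ\tSN:toyref\tLN:4\n"
            "r1\t0\ttoyref\t1\t60\t2M2I2M\t*\t0\t0\tAAGGAA\t*\tMD:Z:4\n"
        )
        p = tmp_path / "ins.sam"
        p.write_text(sam)
        pm = pileup_from_bam(p)
        np.testing.assert_array_equal(pm.counts[:, 5], [0, 1, 0, 0])

    def test_no_md_and_no_reference_is_a_format_error(self, tmp_path):
        sam = "@HD\tVN:1.6\n@SQ\tSN:toyref\tLN:4\nr1\t0\ttoyref\t1\t60\t4M\t*\t0\t0\tAAAA\t*\n"
        p = tmp_path / "nomd.sam"
        p.write_text(sam)
        with pytest.raises(FormatError):
            pileup_from_bam(p)

    def test_zero_passing_reads_is_empty_input(self, tmp_path):
        sam = "@HD\tVN:1.6\n@SQ\tSN:toyref\tLN:4\nr1\t4\ttoyref\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"
        p = tmp_path / "unmapped.sam"
        p.write_text(sam)
        with pytest.raises(EmptyInputError):
            pileup_from_bam(p)

    def test_missing_bam_index_is_io_error(self, small_bam_pools, tmp_path):
        import shutil

        orphan = tmp_path / "orphan.bam"
        shutil.copy(small_bam_pools["wt"], orphan)
        with pytest.raises(IOError):
            pileup_from_bam(orphan)


class TestPileupMatrixInvariants:
    def test_count_conservation_on_simulated_fixture(self, small_bam_pools):
        pm = pileup_from_bam(small_bam_pools["wt"])
        assert (pm.counts[:, :5].sum(axis=1) == pm.depth).all()
        assert (pm.counts[:, 5] <= pm.depth).all()

    def test_tsv_round_trip(self, small_bam_pools, tmp_path):
        pm = pileup_from_bam(small_bam_pools["wt"])
        pm.to_tsv(tmp_path / "p.tsv")
        back = PileupMatrix.from_tsv(tmp_path / "p.tsv")
        np.testing.assert_array_equal(back.counts, pm.counts)
        assert back.ref_seq == pm.ref_seq


class TestDownsample:
    def test_exact_read_count_and_depth(self, small_bam_pools, tmp_path):
        out = downsample_bam(small_bam_pools["wt"], 200, seed=1, out_path=tmp_path / "d.bam")
        pm = pileup_from_bam(out)
        np.testing.assert_array_equal(pm.depth, 200)

    def test_same_seed_selects_same_reads(self, small_bam_pools, tmp_path):
        names = []
        for tag in ("a", "b"):
            out = downsample_bam(
                small_bam_pools["wt"], 100, seed=7, out_path=tmp_path / f"{tag}.bam"
            )
            with pysam.AlignmentFile(str(out)) as af:
                names.append({r.query_name for r in af.fetch(until_eof=True)})
        assert names[0] == names[1]

    def test_oversampling_rejected(self, small_bam_pools, tmp_path):
        with pytest.raises(InvalidArgumentError):
            downsample_bam(small_bam_pools["wt"], 10_000, seed=0, out_path=tmp_path / "x.bam")


class TestMix:
    def test_mixture_arithmetic_and_provenance(self, small_bam_pools, tmp_path):
        out = mix_bams(
            small_bam_pools["wt"], small_bam_pools["ko"], 800, 0.25, seed=3,
            out_path=tmp_path / "m.bam",
        )
        prov = pd.read_csv(str(out) + ".sources.tsv", sep="\t")
        assert (prov["source"] == "a").sum() == 200
        assert (prov["source"] == "b").sum() == 600

    @pytest.mark.parametrize("frac,n_a", [(0.0, 0), (1.0, 400), (0.005, 2)])
    def test_edge_fractions(self, small_bam_pools, tmp_path, frac, n_a):
        out = mix_bams(
            small_bam_pools["wt"], small_bam_pools["ko"], 400, frac, seed=5,
            out_path=tmp_path / f"m{frac}.bam",
        )
        prov = pd.read_csv(str(out) + ".sources.tsv", sep="\t")
        assert (prov["source"] == "a").sum() == n_a

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(1000 * 0.005) == 5
        assert round_half_away(2.5) == 3
        assert round_half_away(2.4) == 2

    def test_insufficient_pool_rejected(self, small_bam_pools, tmp_path):
        with pytest.raises(InvalidArgumentError):
            mix_bams(
                small_bam_pools["wt"], small_bam_pools["ko"], 2000, 0.5, seed=0,
                out_path=tmp_path / "big.bam",
            )
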