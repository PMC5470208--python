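import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadfuse.fourc import Viewpoint, assign_reads, smooth_profile
from tadfuse.fragmap import digest_genome, valid_fragments
from tadfuse.fusion import (BreakpointSpec, balance_sides, build_derivative,
                            derivative_to_native, native_to_derivative,
                            rescale_derivative)

from conftest import make_profile


@pytest.fixture
def two_chrom_genome():
    return {"chrA": "A" * 100, "chrB": "C" * 200}


class TestBuildDerivative:
    def test_plain_junction_length(self, two_chrom_genome):
        spec = BreakpointSpec("chrA", 60, "chrB", 50)
        dg, der = build_derivative(two_chrom_genome, spec)
        assert dg.length == 210 == len(der.seq)
        assert der.seq == "A" * 60 + "C" * 150

    def test_22bp_insertion_length(self, two_chrom_genome):
        spec = BreakpointSpec("chrA", 60, "chrB", 50, insertion="G" * 22)
        dg, _ = build_derivative(two_chrom_genome, spec)
        assert dg.length == 232

    def test_whole_chromosome_join(self, two_chrom_genome):
        spec = BreakpointSpec("chrA", 100, "chrB", 0)
        dg, der = build_derivative(two_chrom_genome, spec)
        assert der.seq == two_chrom_genome["chrA"] + two_chrom_genome["chrB"]

    def test_out_of_range_raises(self, two_chrom_genome):
        with pytest.raises(ValueError):
            build_derivative(two_chrom_genome, BreakpointSpec("chrA", 101, "chrB", 0))

    def test_invalid_insertion_alphabet(self):
        with pytest.raises(ValueError):
            BreakpointSpec("chrA", 1, "chrB", 1, insertion="GNX")


class TestCoordinateMaps:
    @pytest.fixture
    def dg(self, two_chrom_genome):
        spec = BreakpointSpec("chrA", 60, "chrB", 50, insertion="G" * 22)
        dg, _ = build_derivative(two_chrom_genome, spec)
        return dg

    def test_origin_maps_to_zero(self, dg):
        assert native_to_derivative(dg, "chrA", 0) == 0

    def test_chromB_start_offset(self, dg):
        assert native_to_derivative(dg, "chrB", 50) == 60 + 22

    def test_unretained_positions_map_to_none(self, dg):
        assert native_to_derivative(dg, "chrA", 60) is None
        assert native_to_derivative(dg, "chrB", 49) is None

    def test_insertion_interior(self, dg):
        assert derivative_to_native(dg, 60) == ("insertion", 0)
        assert derivative_to_native(dg, 81) == ("insertion", 21)

    def test_out_of_range_raises(self, dg):
        with pytest.raises(ValueError):
            derivative_to_native(dg, 232)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 231))
    def test_round_trip_identity(self, pos):
        spec = BreakpointSpec("chrA", 60, "chrB", 50, insertion="G" * 22)
        dg, _ = build_derivative({"chrA": "A" * 100, "chrB": "C" * 200}, spec)
        chrom, native = derivative_to_native(dg, pos)
        if chrom != "insertion":
            assert native_to_derivative(dg, chrom, native) == pos


def _derivative_profile(vp_side="A"):
    """Profile on a 210 bp toy derivative with junction at 100."""
    ends = np.array([10, 40, 70, 130, 160, 190])
    raw = np.array([5.0, 3.0, 2.0, 4.0, 2.0, 1.0])
    pos = 10 if vp_side == "A" else 160
    prof = make_profile(raw, ends=ends, frag_len=20, viewpoint_pos=pos)
    return prof


class TestRescaleDerivative:
    @pytest.fixture
    def dg(self):
        genome = {"chrA": "A" * 100, "chrB": "C" * 110}
        dg, _ = build_derivative(genome, BreakpointSpec("chrA", 100, "chrB", 0))
        return dg

    def test_far_side_doubled(self, dg):
        prof = _derivative_profile("A")
        out = rescale_derivative(prof, dg)
        assert np.array_equal(out.raw, [5, 3, 2, 8, 4, 2])

    def test_total_is_original_plus_far_side(self, dg):
        prof = _derivative_profile("A")
        far_total = prof.raw[3:].sum()
        out = rescale_derivative(prof, dg)
        assert out.raw.sum() == prof.raw.sum() + far_total

    def test_viewpoint_on_b_side_doubles_a(self, dg):
        prof = _derivative_profile("B")
        out = rescale_derivative(prof, dg)
        assert np.array_equal(out.raw, [10, 6, 4, 4, 2, 1])

    def test_all_zero_far_side_unchanged(self, dg):
        prof = _derivative_profile("A")
        prof.raw[3:] = 0
        out = rescale_derivative(prof, dg)
        assert np.array_equal(out.raw[3:], [0, 0, 0])

    def test_second_application_refused(self, dg):
        out = rescale_derivative(_derivative_profile("A"), dg)
        with pytest.raises(ValueError, match="already"):
            rescale_derivative(out, dg)


class TestBalanceSides:
    def test_already_balanced_identity(self):
        prof = make_profile(np.ones(10), frag_len=50)
        prof.smoothed = np.full(10, 2.0)
        out = balance_sides(prof, breakpoint_pos=250, flank=250)
        assert np.allclose(out.side_scalars, (1.0, 1.0))
        assert np.allclose(out.smoothed, 2.0)

    def test_geometric_mean_convention(self):
        prof = make_profile(np.ones(10), frag_len=50)
        prof.smoothed = np.where(np.arange(10) < 5, 2.0, 4.0)
        out = balance_sides(prof, breakpoint_pos=250, flank=250)
        sL, sR = out.side_scalars
        # relative far/near scalar is 0.5; both move toward the geometric mean
        assert np.isclose(sR / sL, 0.5)
        g = np.sqrt(2.0 * 4.0)
        assert np.isclose(out.smoothed[0], g)
        assert np.isclose(out.smoothed[-1], g)

    def test_postcondition_flank_means_equal(self):
        rng = np.random.default_rng(3)
        prof = make_profile(np.ones(20), frag_len=50)
        prof.smoothed = rng.uniform(0.5, 5.0, size=20)
        out = balance_sides(prof, breakpoint_pos=500, flank=500)
        left = out.smoothed[out.ends < 500].mean()
        right = out.smoothed[out.ends >= 500].mean()
        assert np.isclose(left, right)

    def test_zero_flank_mean_raises(self):
        prof = make_profile(np.ones(10), frag_len=50)
        prof.smoothed = np.where(np.arange(10) < 5, 0.0, 4.0)
        with pytest.raises(ValueError):
            balance_sides(prof, 250, 250)


class TestDerivativeFragmentMap:
    def test_fused_map_splices_native_maps(self):
        frag = "GATC" + "A" * 20 + "GTAC" + "C" * 22  # 50 bp valid fragment
        genome = {"chrA": frag * 6, "chrB": frag * 6}
        spec = BreakpointSpec("chrA", 150, "chrB", 150)
        _, der = build_derivative(genome, spec)
        native = valid_fragments(digest_genome(genome, "GATC", "GTAC"))
        fused = valid_fragments(digest_genome({der.name: der.seq},
                                              "GATC", "GTAC"))
        native_a = [(f.start, f.end) for f in native.fragments["chrA"]
                    if f.end <= 150]
        native_b = [(f.start + 0, f.end) for f in native.fragments["chrB"]
                    if f.start >= 150]
        expected = native_a + [(s - 150 + 150, e - 150 + 150)
                               for s, e in native_b]
        got = [(f.start, f.end) for f in fused.fragments[der.name]]
        assert got == expected
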