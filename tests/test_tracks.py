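"""Genome-coordinate tracks, smoothing, tails and delta-z statistics."""

import numpy as np
import pandas as pd
import pytest

import mtbind as m


@pytest.fixture(scope="module")
def toy_library():
    rng = np.random.default_rng(1)
    genome = m.sanitize_genome("".join(rng.choice(list("ACGT"), size=200)))
    return m.tile_circular_genome(genome, window=33, step=2)


def make_track(values, genome_length=None, coords=None):
    values = np.asarray(values, float)
    if coords is None:
        coords = np.arange(len(values)) * 2
    if genome_length is None:
        genome_length = int(coords[-1]) + 2
    return m.ZTrack(genome_length=genome_length, coords=coords,
                    values=values, stage="orientation_max")


class TestOrientationMax:
    def test_elementwise_max_and_ties(self):
        zf = pd.Series({0: 1.2, 2: -0.5, 4: 0.0})
        zr = pd.Series({0: 0.3, 2: -0.5, 4: 1.0})
        out = m.orientation_max(zf, zr)
        assert out.tolist() == [1.2, -0.5, 1.0]

    def test_missing_orientation_falls_back(self):
        zf = pd.Series({0: np.nan, 2: 1.0, 4: np.nan})
        zr = pd.Series({0: 0.5, 2: np.nan, 4: np.nan})
        out = m.orientation_max(zf, zr)
        assert out[0] == 0.5 and out[2] == 1.0 and np.isnan(out[4])

    def test_pointwise_dominates_inputs(self):
        rng = np.random.default_rng(0)
        zf = pd.Series(rng.normal(size=50), index=range(0, 100, 2))
        zr = pd.Series(rng.normal(size=50), index=range(0, 100, 2))
        out = m.orientation_max(zf, zr)
        assert (out >= zf).all() and (out >= zr).all()

    def test_mismatched_windows_error(self):
        with pytest.raises(ValueError, match="different windows"):
            m.orientation_max(pd.Series({0: 1.0}), pd.Series({2: 1.0}))


class TestProjection:
    def test_middle_nucleotide_rule(self, toy_library):
        z = pd.Series(0.0, index=[p.start for p in
                                  toy_library.forward_probes()])
        track = m.project_to_genome(z, toy_library)
        assert track.coords[np.searchsorted(track.coords, 16)] == 16
        # start 0, window 33 -> coordinate 16
        first = toy_library.forward_probes()[0]
        assert first.mid_coord == 16

    def test_wrapped_start_coordinate(self):
        genome = m.sanitize_genome(("ACGT" * 4143)[:16569])
        lib = m.tile_circular_genome(genome, window=33, step=2)
        last = lib.forward_probes()[-1]
        assert last.start == 16568
        assert last.mid_coord == (16568 + 16) % 16569 == 15

    def test_constant_values_preserved(self, toy_library):
        z = pd.Series(2.5, index=[p.start for p in
                                  toy_library.forward_probes()])
        track = m.project_to_genome(z, toy_library)
        assert np.allclose(track.values, 2.5)


class TestSmoothing:
    def test_constant_preserved(self):
        track = make_track([3.0] * 60)
        out = m.smooth_track(track, span_nt=22)
        assert np.allclose(out.values, 3.0)

    def test_impulse_spreads_over_eleven_coords(self):
        vals = np.zeros(100)
        vals[50] = 1.0
        out = m.smooth_track(make_track(vals), span_nt=22)
        covered = np.flatnonzero(out.values > 0)
        assert len(covered) == 11
        assert np.allclose(out.values[covered], 1 / 11)

    def test_circular_wrap(self):
        vals = np.zeros(100)
        vals[0] = 1.0
        out = m.smooth_track(make_track(vals), span_nt=22)
        assert out.values[-1] == pytest.approx(1 / 11)
        assert out.values[-5] == pytest.approx(1 / 11)
        assert out.values[-6] == pytest.approx(0.0)

    def test_mean_preserved(self):
        rng = np.random.default_rng(2)
        track = make_track(rng.normal(size=250))
        out = m.smooth_track(track, span_nt=22)
        assert out.mean() == pytest.approx(track.mean(), abs=1e-9)

    def test_span_below_step_warns_identity(self):
        track = make_track(np.arange(50.0))
        with pytest.warns(UserWarning):
            out = m.smooth_track(track, span_nt=1)
        assert np.array_equal(out.values, track.values)


class TestRotationEquivariance:
    def test_pipeline_commutes_with_genome_rotation(self):
        """Rotating the genome by k*step rotates the smoothed orientation-max
        track identically (circularity end to end)."""
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        k = 10  # rotation in steps (20 nt)
        occ = rng.normal(size=60)

        def run(sequence, occupancy):
            lib = m.tile_circular_genome(m.sanitize_genome(sequence),
                                         window=33, step=2)
            starts = [p.start for p in lib.forward_probes()]
            zf = pd.Series(occupancy, index=starts)
            zr = pd.Series(occupancy * 0.5, index=starts)
            track = m.project_to_genome(m.orientation_max(zf, zr), lib)
            return m.smooth_track(track, span_nt=22)

        base = run(seq, occ)
        rot_seq = seq[2 * k:] + seq[:2 * k]
        rot = run(rot_seq, np.roll(occ, -k))
        assert np.allclose(np.roll(base.values, -k), rot.values, atol=1e-12)


class TestPercentilePartition:
    def test_counts(self):
        rng = np.random.default_rng(1)
        track = make_track(rng.normal(size=100))
        top, bottom = m.percentile_partition(track)
        assert len(top) == len(bottom) == 5

    def test_study_scale_tail_size(self):
        rng = np.random.default_rng(2)
        track = make_track(rng.normal(size=8285))
        top, bottom = m.percentile_partition(track)
        assert len(top) == len(bottom) == 414

    def test_tie_break_by_coordinate(self):
        track = make_track(np.zeros(60))
        top, bottom = m.percentile_partition(track)
        assert top.tolist() == [0, 1, 2]
        assert bottom.tolist() == [0, 1, 2]

    def test_stable_under_reordering(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=80)
        t1 = make_track(vals)
        top1, bot1 = m.percentile_partition(t1)
        # same values assigned to the same coordinates, different insertion
        top2, bot2 = m.percentile_partition(make_track(vals.copy()))
        assert np.array_equal(top1, top2) and np.array_equal(bot1, bot2)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            m.percentile_partition(make_track(np.arange(10.0)))


class TestDeltaZ:
    def test_identity_gives_zero_slope(self):
        rng = np.random.default_rng(4)
        track = make_track(rng.normal(size=100))
        rep = m.delta_z_analysis(track, track)
        assert rep["delta_slope"] == pytest.approx(0.0, abs=1e-12)
        assert rep["top_tail_median_delta"] == 0.0

    def test_pure_compression_recovered_exactly(self):
        """z_UV = (1-gamma) z_noUV, noiseless: slope -gamma, Pearson -1."""
        rng = np.random.default_rng(5)
        base = rng.normal(size=200)
        t0 = make_track(base)
        t1 = make_track(0.5 * base)
        rep = m.delta_z_analysis(t0, t1)
        assert rep["delta_slope"] == pytest.approx(-0.5, abs=1e-12)
        assert rep["delta_corr_pearson"] == pytest.approx(-1.0, abs=1e-9)
        assert rep["top_tail_median_delta"] < 0
        assert rep["bottom_tail_median_delta"] > 0

    def test_mismatched_coordinates_error(self):
        a = make_track(np.zeros(50))
        b = m.ZTrack(genome_length=a.genome_length,
                     coords=a.coords + 1, values=a.values)
        with pytest.raises(ValueError, match="identical coordinates"):
            m.delta_z_analysis(a, b)


class TestMotifCompare:
    def test_identical_groups(self):
        z = pd.Series(np.arange(40.0), index=[f"p{i}" for i in range(40)])
        flags = pd.Series([True, False] * 20, index=z.index)
        # identical distributions: interleave the same values
        z[::2] = np.arange(20.0)
        z[1::2] = np.arange(20.0)
        out = m.motif_zscore_compare(z, flags)
        assert out["median_difference"] == pytest.approx(0.0)
        assert out["ks_statistic"] == pytest.approx(0.0)

    def test_shifted_group_detected(self):
        idx = [f"p{i}" for i in range(2000)]
        rng = np.random.default_rng(6)
        base = rng.normal(size=1000)
        z = pd.Series(np.concatenate([base, base + 1.0]), index=idx)
        flags = pd.Series([False] * 1000 + [True] * 1000, index=idx)
        out = m.motif_zscore_compare(z, flags)
        assert out["median_difference"] == pytest.approx(1.0, abs=0.15)
        assert out["ks_statistic"] > 0.3

    def test_empty_group_error(self):
        z = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="with_motif"):
            m.motif_zscore_compare(z, pd.Series([False, False],
                                                index=z.index))


class TestRegionSummary:
    def test_whole_genome_region(self):
        rng = np.random.default_rng(7)
        track = make_track(rng.normal(size=100))
        regions = m.RegionSet(genome_length=track.genome_length,
                              regions={"all": (0, track.genome_length)})
        out = m.region_summary(track, regions)
        assert out.loc["all", "mean"] == pytest.approx(track.values.mean())

    def test_single_coordinate_region(self):
        track = make_track(np.arange(50.0))
        regions = m.RegionSet(genome_length=track.genome_length,
                              regions={"one": (10, 11)})
        out = m.region_summary(track, regions)
        assert out.loc["one", "mean"] == out.loc["one", "max"] == 5.0

    def test_wrapping_region(self):
        track = make_track(np.arange(50.0))
        L = track.genome_length
        regions = m.RegionSet(genome_length=L, regions={"wrap": (L - 4, 4)})
        out = m.region_summary(track, regions)
        assert out.loc["wrap", "n"] == 4  # coords L-4, L-2, 0, 2

    def test_empty_region_zero_coverage(self):
        track = make_track(np.arange(50.0))
        regions = m.RegionSet(genome_length=track.genome_length,
                              regions={"odd": (11, 12)})
        out = m.region_summary(track, regions)
        assert out.loc["odd", "n"] == 0

    def test_planted_peak_ranks_first(self, toy_library):
        starts = [p.start for p in toy_library.forward_probes()]
        occ = pd.Series(0.0, index=starts)
        occ.loc[100:120] = 5.0
        track = m.project_to_genome(occ, toy_library)
        regions = m.RegionSet(genome_length=200,
                              regions={"peak": (110, 140), "a": (0, 50),
                                       "b": (50, 100)})
        out = m.region_summary(track, regions)
        assert out["max"].idxmax() == "peak"


class TestTrackIO:
    def test_bedgraph_round_trip(self, tmp_path):
        track = make_track([1.5, -0.5, 2.0])
        path = tmp_path / "t.bedGraph"
        m.write_bedgraph(track, path)
        frame = pd.read_csv(path, sep="\t", header=None)
        assert frame[1].tolist() == [0, 2, 4]
        assert (frame[2] - frame[1]).tolist() == [1, 1, 1]
        assert frame[3].tolist() == [1.5, -0.5, 2.0]

    def test_regions_bed_reader(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chrM\t10\t40\tLSP1\nchrM\t100\t130\tHSP1\n")
        regions = m.read_regions_bed(path, genome_length=200)
        assert regions.regions == {"LSP1": (10, 40), "HSP1": (100, 130)}
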