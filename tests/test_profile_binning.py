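"""Anchor averaging, sliding-window binning, heatmap export and contact calling."""

import numpy as np
import pandas as pd
import pytest

from fivec import normalization as nz
from fivec import profile_binning as pb
from fivec import synthetic_locus as sl
from fivec.genome_model import GenomicInterval, LocusSpec
from fivec.workflow import counts_to_ifl, profile_and_call


def _locus(length=1_000_000, tss=500_000):
    return LocusSpec("toy", GenomicInterval("chrT", 1, length), tss=tss)


def _profile(points, locus=None):
    return pb.AnchorProfile(locus or _locus(), ("R0",), tuple(points))


class TestAnchorAverage:
    def _norm(self, study, values):
        return nz.NormalizedIFL("L", values)

    def test_identical_anchor_rows_idempotent(self, study):
        f_ids = [p.id for p in study.design.forward_primers]
        r_ids = [p.id for p in study.design.reverse_primers]
        values = {(f, r): 0.5 for f in f_ids for r in r_ids}
        prof = pb.anchor_average(self._norm(study, values), study.design, study.fragments, study.locus)
        assert all(v == pytest.approx(0.5) for _, v in prof.points)
        assert len(prof.points) == len(f_ids)

    def test_arithmetic_mean_across_anchors(self, study):
        f_ids = [p.id for p in study.design.forward_primers]
        r0, r1 = (p.id for p in study.design.reverse_primers)
        values = {(f, r0): 2.0 for f in f_ids} | {(f, r1): 4.0 for f in f_ids}
        prof = pb.anchor_average(self._norm(study, values), study.design, study.fragments, study.locus)
        assert all(v == pytest.approx(3.0) for _, v in prof.points)

    def test_single_anchor_identity(self, study):
        f_ids = [p.id for p in study.design.forward_primers]
        r0 = study.design.reverse_primers[0].id
        values = {(f, r0): float(k) for k, f in enumerate(f_ids)}
        prof = pb.anchor_average(
            self._norm(study, values), study.design, study.fragments, study.locus, anchor_ids=[r0]
        )
        assert sorted(v for _, v in prof.points) == sorted(float(k) for k in range(len(f_ids)))

    def test_partial_anchor_coverage_flagged(self, study):
        f_ids = [p.id for p in study.design.forward_primers]
        r0, r1 = (p.id for p in study.design.reverse_primers)
        values = {(f, r0): 1.0 for f in f_ids}
        values[(f_ids[0], r1)] = 3.0  # only one fragment seen by the second anchor
        prof = pb.anchor_average(self._norm(study, values), study.design, study.fragments, study.locus)
        assert len(prof.single_anchor_points) == len(f_ids) - 1

    def test_anchor_without_contacts_raises(self, study):
        f_ids = [p.id for p in study.design.forward_primers]
        r0 = study.design.reverse_primers[0].id
        values = {(f, r0): 1.0 for f in f_ids}
        with pytest.raises(ValueError, match="no contacts"):
            pb.anchor_average(self._norm(study, values), study.design, study.fragments, study.locus)


class TestBinProfile:
    def test_constant_profile_preserved_exactly(self):
        points = [(float(x), 2.5) for x in range(10_000, 900_000, 7_000)]
        binned = pb.bin_profile(_profile(points), bin_width=80_000, step_divisor=6)
        non_missing = [b.value for b in binned.bins if b.value is not None]
        assert non_missing and all(v == 2.5 for v in non_missing)

    def test_hand_enumerated_two_point_example(self):
        profile = _profile([(100_000.0, 1.0), (150_000.0, 3.0)])
        binned = pb.bin_profile(profile, bin_width=80_000, step_divisor=2)
        by_window = {(b.window.start, b.window.end): b for b in binned.bins}
        w1 = by_window[(80_001, 160_000)]
        w2 = by_window[(120_001, 200_000)]
        assert w1.value == pytest.approx(2.0) and w1.n_points == 2
        assert w2.value == pytest.approx(3.0) and w2.n_points == 1

    def test_step_divisor_one_partitions_points(self):
        points = [(float(x), 1.0) for x in range(5_000, 995_000, 9_000)]
        binned = pb.bin_profile(_profile(points), bin_width=100_000, step_divisor=1)
        assert sum(b.n_points for b in binned.bins) == len(points)

    def test_window_semantics_inclusive_exclusive(self):
        locus = LocusSpec("toy", GenomicInterval("chrT", 1, 200_000), 100_000)
        profile = _profile([(100_000.0, 1.0)], locus)
        binned = pb.bin_profile(profile, bin_width=50_000, step_divisor=1)
        counts = {b.window.start: b.n_points for b in binned.bins}
        # midpoint 100000 lies in [50001, 100001) — inclusive start, exclusive end
        assert counts[50_001] == 1 and counts[100_001] == 0

    def test_missing_bins_are_none_never_zero(self):
        profile = _profile([(10_000.0, 1.0), (900_000.0, 2.0)])
        binned = pb.bin_profile(profile, bin_width=50_000, step_divisor=1)
        gap_bins = [b for b in binned.bins if b.n_points == 0]
        assert gap_bins and all(b.value is None for b in gap_bins)

    def test_translation_covariance(self):
        pts = [(float(x), float(x % 7)) for x in range(20_000, 400_000, 11_000)]
        shift = 60_000
        locus_a = LocusSpec("toy", GenomicInterval("chrT", 1, 500_000), 100_000)
        locus_b = LocusSpec("toy", GenomicInterval("chrT", 1 + shift, 500_000 + shift), 100_000 + shift)
        a = pb.bin_profile(pb.AnchorProfile(locus_a, ("R0",), tuple(pts)))
        b = pb.bin_profile(
            pb.AnchorProfile(locus_b, ("R0",), tuple((m + shift, v) for m, v in pts))
        )
        assert [x.value for x in a.bins] == [x.value for x in b.bins]
        assert [x.window.start + shift for x in a.bins] == [x.window.start for x in b.bins]

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pb.bin_profile(_profile([]))


class TestCallStrongRegions:
    def _flat_binned(self, value=1.0, n=40):
        pts = [(float(20_000 + 12_000 * k), value) for k in range(n)]
        locus = LocusSpec("toy", GenomicInterval("chrT", 1, 600_000), 250_000)
        return pb.bin_profile(pb.AnchorProfile(locus, ("R0",), tuple(pts)), 36_000, 6), locus

    def test_flat_profile_yields_nothing(self):
        binned, locus = self._flat_binned()
        regions = pb.call_strong_regions(binned, locus, [250_000.0], z_threshold=2.0)
        assert regions == []

    def test_planted_spike_found(self):
        rng = np.random.default_rng(0)
        locus = LocusSpec("toy", GenomicInterval("chrT", 1, 600_000), 300_000)
        pts = []
        for k in range(45):
            mid = 15_000.0 + 13_000 * k
            d = max(abs(mid - 300_000.0), 10_000.0)
            v = (d + 5_000) ** -1.0 * float(np.exp(rng.normal(0, 0.02)))
            if abs(mid - 106_000) < 6_000:
                v *= 10.0  # the spike
            pts.append((mid, v))
        binned = pb.bin_profile(pb.AnchorProfile(locus, ("R0",), tuple(pts)), 39_000, 6)
        regions = pb.call_strong_regions(binned, locus, [300_000.0], z_threshold=3.0, count_scale=1e6)
        assert len(regions) >= 1
        top = regions[0]
        assert top.interval.start <= 106_000 <= top.interval.end

    def test_degenerate_distances_raise(self):
        locus = LocusSpec("toy", GenomicInterval("chrT", 1, 600_000), 300_000)
        pts = [(100_000.0 + k, 1.0 + 0.01 * k) for k in range(15)]  # all ~same distance
        binned = pb.bin_profile(pb.AnchorProfile(locus, ("R0",), tuple(pts)), 600_000, 1)
        with pytest.raises(ValueError):
            pb.call_strong_regions(binned, locus, [500_000.0], min_distance=1.0)

    def test_too_few_bins_rejected(self):
        locus = LocusSpec("toy", GenomicInterval("chrT", 1, 100_000), 50_000)
        pts = [(10_000.0, 1.0), (90_000.0, 1.0)]
        binned = pb.bin_profile(pb.AnchorProfile(locus, ("R0",), tuple(pts)), 50_000, 1)
        with pytest.raises(ValueError, match="scorable bins"):
            pb.call_strong_regions(binned, locus, [50_000.0])

    def test_loop_recovery_from_simulation(self, study):
        lib = sl.LibrarySpec("L", 100_000, seed=42)
        _, truth = sl.simulate_library(study.design, study.fragments, study.model, lib)
        norm = nz.depth_normalize(counts_to_ifl(truth, "L", lib.total_reads))
        result = profile_and_call(study, norm, lib.total_reads)
        mids = {f.index: f.midpoint for f in study.fragments}
        top3 = result.regions[:3]
        for loop_frag in study.loop_fragments:
            assert any(
                r.interval.start <= mids[loop_frag] <= r.interval.end for r in top3
            )


class TestHeatmapExport:
    def _binned(self, values, bin_width=30_000):
        locus = LocusSpec("toy", GenomicInterval("chrT", 1, 300_000), 150_000)
        pts = [(float(30_000 * (k + 1)), v) for k, v in enumerate(values)]
        return pb.bin_profile(pb.AnchorProfile(locus, ("R0",), tuple(pts)), bin_width, 1)

    def test_single_cell_matrix(self):
        locus = LocusSpec("toy", GenomicInterval("chrT", 1, 1_000), 500)
        binned = pb.bin_profile(pb.AnchorProfile(locus, ("R0",), ((500.0, 1.5),)), 1_000, 1)
        mat = pb.export_heatmap({"lib": binned})
        assert mat.shape == (1, 1)
        assert mat.iloc[0, 0] == 1.5

    def test_tsv_round_trip_exact(self, tmp_path):
        mat = pb.export_heatmap(
            {"a": self._binned([1.0, 2.0, 4.0]), "b": self._binned([0.5, 0.25, 8.0])},
            path=tmp_path / "heat.tsv",
        )
        back = pb.import_heatmap(tmp_path / "heat.tsv")
        pd.testing.assert_frame_equal(back, mat)

    def test_missing_bins_exported_as_na(self, tmp_path):
        locus = LocusSpec("toy", GenomicInterval("chrT", 1, 300_000), 150_000)
        binned = pb.bin_profile(
            pb.AnchorProfile(locus, ("R0",), ((30_000.0, 1.0), (250_000.0, 2.0))), 30_000, 1
        )
        mat = pb.export_heatmap({"lib": binned}, path=tmp_path / "heat.tsv")
        assert mat.isna().any(axis=None)
        text = (tmp_path / "heat.tsv").read_text()
        assert "NA" in text
        back = pb.import_heatmap(tmp_path / "heat.tsv")
        assert back.isna().sum().sum() == mat.isna().sum().sum()

    def test_misaligned_bins_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            pb.export_heatmap(
                {"a": self._binned([1.0, 2.0]), "b": self._binned([1.0, 2.0], bin_width=60_000)}
            )

    def test_image_export_writes_file(self, tmp_path):
        pb.export_heatmap(
            {"a": self._binned([1.0, 2.0, 4.0])},
            image_path=tmp_path / "heat.png",
            per_row_scaling=True,
        )
        assert (tmp_path / "heat.png").stat().st_size > 0
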