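"""Peak parsing, filtering, labeling, balancing and splitting rules."""

import numpy as np
import pandas as pd
import pytest

from shapebind.dataset import (
    DatasetManifest,
    Peak,
    PipelineAbort,
    balance_ratio,
    compute_sample_weights,
    detect_homodimer,
    exclude_organelles,
    filter_artifacts,
    filter_frip,
    label_hits,
    normalize_signal,
    read_narrowpeak,
    split_dataset,
    write_narrowpeak,
)
from shapebind.motifs import MotifHit


def hit(contig="Chr1", start=0, end=6, strand="+", score=1.0):
    return MotifHit(
        contig=contig, start=start, end=end, strand=strand,
        score=score, pvalue=1e-4, matched_seq="",
    )


def peak(contig="Chr1", summit=1000, signal=10.0):
    return Peak(
        contig=contig, start=summit - 100, end=summit + 100,
        summit=summit, signal=signal,
    )


def labeled_frame(n_bound, n_unbound):
    rows = []
    for i in range(n_bound + n_unbound):
        rows.append(
            {
                "contig": "Chr1", "start": 300 * i, "end": 300 * i + 6,
                "strand": "+", "score": 1.0, "pvalue": 1e-4,
                "bound": i < n_bound, "signal": 10.0 + i if i < n_bound else 0.0,
                "peak_id": i if i < n_bound else -1,
            }
        )
    return pd.DataFrame(rows)


class TestNarrowPeak:
    def test_parse_line(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t1000\t1200\tp1\t0\t.\t37.5\t-1\t-1\t100\n")
        peaks = read_narrowpeak(p)
        assert peaks[0] == Peak(
            contig="chr1", start=1000, end=1200, summit=1100, signal=37.5, name="p1"
        )

    def test_missing_summit_falls_back_to_midpoint(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t1000\t1200\tp1\t0\t.\t5\t-1\t-1\t-1\n")
        with pytest.warns(UserWarning, match="midpoint"):
            peaks = read_narrowpeak(p)
        assert peaks[0].summit == 1100

    def test_nine_columns_rejected(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t1000\t1200\tp1\t0\t.\t5\t-1\t-1\n")
        with pytest.raises(ValueError, match="10 columns"):
            read_narrowpeak(p)

    def test_foreign_width_accepted_with_warning(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t1000\t1500\tp1\t0\t.\t5\t-1\t-1\t10\n")
        with pytest.warns(UserWarning, match="width"):
            peaks = read_narrowpeak(p)
        assert peaks[0].end - peaks[0].start == 500

    def test_write_read_roundtrip(self, tmp_path):
        peaks = [peak(summit=500, signal=3.25), peak(summit=5000, signal=88.0)]
        path = tmp_path / "rt.narrowPeak"
        write_narrowpeak(path, peaks)
        back = read_narrowpeak(path)
        for a, b in zip(peaks, back):
            assert (a.contig, a.start, a.end, a.summit) == (
                b.contig, b.start, b.end, b.summit
            )
            assert a.signal == pytest.approx(b.signal)


class TestFripFilter:
    def mk(self, frips, target="d0"):
        return DatasetManifest(
            entries=[(f"d{i}", f"d{i}.np", f) for i, f in enumerate(frips)],
            target_id=target,
        )

    def test_strict_threshold(self):
        out = filter_frip(self.mk([0.051, 0.04, 0.05]))
        assert [e[0] for e in out.entries] == ["d0"]

    def test_all_pass_identity(self):
        out = filter_frip(self.mk([0.3, 0.2]))
        assert len(out.entries) == 2

    def test_target_failure_aborts(self):
        with pytest.raises(PipelineAbort, match="d0"):
            filter_frip(self.mk([0.03, 0.5]))


class TestArtifactFilter:
    def sets(self, n_datasets, co_occurring):
        """Dataset 0 holds the probe peak; `co_occurring` others share it."""
        probe = peak(summit=5000)
        sets = {"d0": [probe]}
        for i in range(1, n_datasets):
            own = [peak(summit=50_000 + 1000 * i)]
            if i <= co_occurring:
                own.append(peak(summit=5050))  # within 100 bp of the probe
            sets[f"d{i}"] = own
        return probe, sets

    def test_recurrent_peak_discarded(self):
        probe, sets = self.sets(10, co_occurring=3)  # 4/10 > 1/3
        assert filter_artifacts([probe], sets) == []

    def test_borderline_peak_kept(self):
        probe, sets = self.sets(10, co_occurring=2)  # 3/10 <= 1/3
        assert filter_artifacts([probe], sets) == [probe]

    def test_skipped_below_three_datasets(self):
        probe, sets = self.sets(2, co_occurring=1)
        with pytest.warns(UserWarning, match="skipped"):
            kept = filter_artifacts([probe], sets)
        assert kept == [probe]

    def test_summit_distance_rule(self):
        probe = peak(summit=5000)
        far = {"d0": [probe], "d1": [peak(summit=5101)], "d2": [peak(summit=5101)]}
        assert filter_artifacts([probe], far, max_fraction=1 / 3) == [probe]
        near = {"d0": [probe], "d1": [peak(summit=5100)], "d2": [peak(summit=5100)]}
        assert filter_artifacts([probe], near, max_fraction=1 / 3) == []


class TestLabelHits:
    def test_distance_78_bound(self):
        out = label_hits([hit(start=1078, end=1084)], [peak(summit=1000)])
        assert bool(out["bound"][0]) is True

    def test_distance_81_unbound(self):
        out = label_hits([hit(start=1081, end=1087)], [peak(summit=1000)])
        assert bool(out["bound"][0]) is False

    def test_summit_inside_motif_distance_zero(self):
        out = label_hits([hit(start=998, end=1004)], [peak(summit=1000)])
        assert bool(out["bound"][0]) is True

    def test_no_peaks_all_unbound(self):
        out = label_hits([hit(start=s) for s in (0, 500, 900)], [])
        assert not out["bound"].any()

    def test_highest_signal_peak_wins(self):
        peaks = [peak(summit=1000, signal=5.0), peak(summit=1040, signal=9.0)]
        out = label_hits([hit(start=1010, end=1016)], peaks)
        assert out["signal"][0] == 9.0 and out["peak_id"][0] == 1


class TestHomodimer:
    def frame(self, multi_peaks, single_peaks):
        rows = []
        pid = 0
        for _ in range(multi_peaks):
            for j in range(2):
                rows.append({"bound": True, "peak_id": pid, "site": f"m{pid}_{j}"})
            pid += 1
        for _ in range(single_peaks):
            rows.append({"bound": True, "peak_id": pid, "site": f"s{pid}"})
            pid += 1
        rows.append({"bound": False, "peak_id": -1, "site": "u"})
        return pd.DataFrame(rows)

    def test_majority_multi_drops_single(self):
        mode, out = detect_homodimer(self.frame(6, 4))
        assert mode is True
        assert len(out[out["bound"]]) == 12  # only multi-occurrence hits

    def test_majority_single_drops_multi(self):
        mode, out = detect_homodimer(self.frame(4, 6))
        assert mode is False
        assert len(out[out["bound"]]) == 6

    def test_tie_defaults_to_single(self):
        mode, out = detect_homodimer(self.frame(5, 5))
        assert mode is False
        assert len(out[out["bound"]]) == 5

    def test_unbound_never_dropped(self):
        for multi, single in [(6, 4), (4, 6)]:
            _, out = detect_homodimer(self.frame(multi, single))
            assert (~out["bound"]).sum() == 1


class TestOrganelles:
    def frame(self, contigs):
        return pd.DataFrame(
            {"contig": contigs, "bound": [False] * len(contigs)}
        )

    def test_default_names_removed(self):
        out = exclude_organelles(self.frame(["Chr1", "ChrC", "ChrM", "Chr2"]))
        assert list(out["contig"]) == ["Chr1", "Chr2"]

    def test_no_organelles_identity(self):
        out = exclude_organelles(self.frame(["Chr1", "Chr2"]))
        assert len(out) == 2

    def test_custom_name_set(self):
        out = exclude_organelles(self.frame(["Chr1", "Pltd"]), {"Pltd"})
        assert list(out["contig"]) == ["Chr1"]


class TestBalanceRatio:
    def test_ratio_forced_to_five(self):
        out = balance_ratio(labeled_frame(100, 1000), seed=0)
        assert int(out["bound"].sum()) == 100
        assert int((~out["bound"]).sum()) == 500

    def test_cap_forces_ratio_three(self):
        out = balance_ratio(labeled_frame(30_000, 600_000), seed=0)
        assert int(out["bound"].sum()) == 30_000
        assert int((~out["bound"]).sum()) == 90_000
        assert len(out) == 120_000

    def test_already_balanced_unchanged(self):
        df = labeled_frame(100, 300)
        out = balance_ratio(df, seed=0)
        assert len(out) == 400

    def test_no_bound_aborts(self):
        with pytest.raises(PipelineAbort):
            balance_ratio(labeled_frame(0, 10), seed=0)

    def test_seeded_determinism(self):
        a = balance_ratio(labeled_frame(10, 200), seed=7)
        b = balance_ratio(labeled_frame(10, 200), seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestNormalizeSignal:
    def test_min_max_scaling(self):
        df = labeled_frame(3, 1)
        df.loc[df["bound"], "signal"] = [10.0, 20.0, 30.0]
        out = normalize_signal(df)
        assert list(out.loc[out["bound"], "label"]) == [0.0, 500.0, 1000.0]

    def test_single_bound_site_gets_1000(self):
        out = normalize_signal(labeled_frame(1, 2))
        assert list(out.loc[out["bound"], "label"]) == [1000.0]

    def test_unbound_zero(self):
        out = normalize_signal(labeled_frame(3, 5))
        assert (out.loc[~out["bound"], "label"] == 0).all()


class TestSampleWeights:
    def test_ratio_weighting(self):
        out = compute_sample_weights(labeled_frame(100, 500))
        assert (out.loc[out["bound"], "weight"] == 5.0).all()
        assert (out.loc[~out["bound"], "weight"] == 1.0).all()

    def test_balanced_all_ones(self):
        out = compute_sample_weights(labeled_frame(50, 50))
        assert (out["weight"] == 1.0).all()

    def test_strictly_positive(self):
        out = compute_sample_weights(labeled_frame(7, 3))
        assert (out["weight"] > 0).all()


class TestSplit:
    def test_stratification_counts(self):
        df = labeled_frame(20, 80)
        train, val = split_dataset(df, validation_fraction=0.2, seed=0)
        assert len(val) == 20 and len(train) == 80
        assert df.iloc[val]["bound"].sum() == 4

    def test_disjoint_and_complete(self):
        df = labeled_frame(20, 80)
        train, val = split_dataset(df, seed=3)
        assert set(train) & set(val) == set()
        assert sorted(np.r_[train, val].tolist()) == list(range(100))

    def test_different_seeds_same_strata(self):
        df = labeled_frame(20, 80)
        t1, v1 = split_dataset(df, seed=1)
        t2, v2 = split_dataset(df, seed=2)
        assert not np.array_equal(v1, v2)
        assert df.iloc[v1]["bound"].sum() == df.iloc[v2]["bound"].sum()

    def test_zero_fraction_warns(self):
        with pytest.warns(UserWarning, match="empty validation"):
            train, val = split_dataset(labeled_frame(5, 5), validation_fraction=0)
        assert len(val) == 0 and len(train) == 10
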