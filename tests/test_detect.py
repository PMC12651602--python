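"""Event detection: segmentation stand-in, SD thresholds, size and ring filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from picscan.detect import (DetectionConfig, channel_stats, classify_phenotype,
                            detect_ctc_candidates, detect_events,
                            detect_lev_candidates, filter_dapi_low,
                            segment_nucleated_cells)
from picscan.errors import (ConfigurationError, DegenerateDistributionError,
                            InsufficientDataError)
from picscan.simulate import SimConfig, SlideImage, generate_slide

from conftest import empty_config


def _events(dapi=None, ck=None, cd45=None):
    """Hand-built event table for threshold arithmetic tests."""
    n = len(next(v for v in (dapi, ck, cd45) if v is not None))
    df = pd.DataFrame({
        "event_id": np.arange(1, n + 1), "kind": "cell",
        "label": np.arange(1, n + 1), "cy": 0.0, "cx": 0.0,
        "area_px": 100.0, "equivalent_diameter_um": 5.0,
        "mean_dapi": dapi if dapi is not None else np.linspace(480.0, 520.0, n),
        "mean_ck": ck if ck is not None else np.full(n, 100.0),
        "mean_cd45": cd45 if cd45 is not None else np.full(n, 100.0),
        "mean_bf": np.full(n, 10000.0),
    })
    return df


class TestSegmentation:
    def test_fifty_wbcs_recovered_one_to_one(self):
        cfg = empty_config(width=768, height=768, n_wbc=50, seed=5)
        img, gt = generate_slide(cfg)
        labels, events = segment_nucleated_cells(img)
        assert len(events) == 50
        d, _ = cKDTree(events[["cy", "cx"]].to_numpy()).query(
            gt.objects[["cy", "cx"]].to_numpy())
        assert d.max() < 2.0
        assert labels.min() == 0 and labels.max() == 50

    def test_blank_image_zero_regions(self):
        img, _ = generate_slide(empty_config(seed=4))
        _, events = segment_nucleated_cells(img)
        assert len(events) == 0

    def test_two_nearby_nuclei_get_distinct_labels(self):
        # two disks with >= 2 px background between them
        from picscan.simulate import SlideCanvas
        cfg = empty_config(width=128, height=128, seed=0)
        canvas = SlideCanvas(cfg)
        canvas._paint_object("wbc", 50.0, 50.0, 8.0)
        canvas._record("wbc", 50.0, 50.0, 8.0)
        canvas._paint_object("wbc", 50.0, 69.0, 8.0)  # 3 px gap
        canvas._record("wbc", 50.0, 69.0, 8.0)
        img, _ = canvas.finalize()
        _, events = segment_nucleated_cells(img)
        assert len(events) == 2

    def test_missing_dapi_channel_errors(self):
        img, _ = generate_slide(empty_config())
        broken = SlideImage(channels={"ck": img.channels["ck"]},
                            pixel_scale=img.pixel_scale)
        with pytest.raises(ConfigurationError):
            segment_nucleated_cells(broken)


class TestChannelStats:
    def test_arithmetic(self):
        mu, sd = channel_stats(_events(ck=[90.0, 100.0, 110.0]), "ck")
        assert mu == pytest.approx(100.0)
        assert sd == pytest.approx(10.0)

    def test_constant_events_give_zero_sd(self):
        mu, sd = channel_stats(_events(ck=[100.0] * 5), "ck")
        assert sd == 0.0

    def test_insufficient_events(self):
        with pytest.raises(InsufficientDataError):
            channel_stats(_events(ck=[1.0]), "ck")

    def test_sampling_estimates(self, rng):
        draws = rng.normal(100.0, 10.0, size=10_000)
        mu, sd = channel_stats(_events(ck=draws), "ck")
        assert abs(mu - 100.0) < 3 * 10.0 / np.sqrt(10_000)
        assert abs(sd - 10.0) < 3 * 10.0 / np.sqrt(2 * 10_000)


class TestDapiLowFilter:
    def test_cutoff_arithmetic(self):
        # population engineered to mean 500, sd 50 -> cutoff 350 at k=3
        base = [450.0] * 4 + [550.0] * 4 + [500.0, 500.0]
        vals = np.array(base)
        vals = (vals - vals.mean()) / vals.std(ddof=1) * 50.0 + 500.0
        probe = np.concatenate([vals, [340.0, 360.0]])
        out = filter_dapi_low(_events(dapi=probe), k_dapi_low=3.0)
        mu, sd = channel_stats(_events(dapi=probe), "dapi")
        cutoff = mu - 3.0 * sd
        assert out.attrs["dapi_cutoff"] == pytest.approx(cutoff)
        np.testing.assert_array_equal(out["dapi_low_excluded"], probe < cutoff)
        assert len(out) == len(probe)  # flagged, never deleted

    def test_k_zero_retains_only_above_mean(self):
        vals = np.array([400.0, 500.0, 600.0])
        out = filter_dapi_low(_events(dapi=vals), k_dapi_low=1e-12)
        assert list(out["dapi_low_excluded"]) == [True, False, False]

    def test_degenerate_distribution_errors(self):
        with pytest.raises(DegenerateDistributionError):
            filter_dapi_low(_events(dapi=[500.0] * 4))

    def test_artifact_exclusion_rate(self, rng):
        real = rng.normal(500.0, 50.0, 950)
        artifacts = rng.normal(20.0, 5.0, 50)
        out = filter_dapi_low(_events(dapi=np.concatenate([real, artifacts])))
        excl = out["dapi_low_excluded"].to_numpy()
        assert excl[950:].mean() >= 0.95  # >= 95% of artifacts caught
        assert excl[:950].mean() < 0.05


class TestCtcDetection:
    def test_threshold_arithmetic_and_strictness(self):
        base = np.array([90.0, 100.0, 110.0] * 10)
        base = (base - base.mean()) / base.std(ddof=1) * 10.0 + 100.0
        ck = np.concatenate([base, [161.0, 159.0]])
        ev = filter_dapi_low(_events(ck=ck))
        out = detect_ctc_candidates(ev, k_ck=6.0)
        thr = out.attrs["ck_threshold"]
        assert (out["ctc_candidate"] == (ck > thr)).all()

    def test_monotone_in_k(self):
        ck = np.concatenate([np.full(200, 100.0) + np.linspace(-20, 20, 200),
                             [200.0, 300.0, 400.0]])
        ev = filter_dapi_low(_events(ck=ck))
        prev = None
        for k in (2.0, 4.0, 6.0, 8.0):
            cand = set(detect_ctc_candidates(ev, k_ck=k).query("ctc_candidate")["event_id"])
            if prev is not None:
                assert cand <= prev
            prev = cand

    def test_no_candidates_without_planted_ctcs(self):
        cfg = empty_config(width=768, height=768, n_wbc=120, seed=6)
        img, _ = generate_slide(cfg)
        res = detect_events(img)
        assert int(res.cells["ctc_candidate"].sum()) == 0

    def test_planted_ctcs_all_recovered(self, mini_slide, mini_detection):
        cfg, img, gt = mini_slide
        res = mini_detection
        planted = gt.objects[gt.objects["cls"].isin(["epi_ctc", "im_ctc"])]
        cand = res.cells[res.cells["ctc_candidate"]]
        d, _ = cKDTree(cand[["cy", "cx"]].to_numpy()).query(
            planted[["cy", "cx"]].to_numpy())
        assert (d < 5.0).all()


class TestLevDetection:
    def test_size_cutoff_arithmetic(self):
        # pixel scale 0.5 µm/px: 20 px -> 2.52 µm passes, 19 px -> 2.46 fails
        assert 2 * np.sqrt(20 / np.pi) * 0.5 >= 2.5
        assert 2 * np.sqrt(19 / np.pi) * 0.5 < 2.5
        img, _ = generate_slide(empty_config(width=128, height=128, seed=1))
        ck = img.channels["ck"].astype(np.float64).copy()
        # plant two CK squares: 4x5=20 px and 19 px
        ck[30:34, 30:35] = 9000.0
        sq = np.zeros((5, 4), bool)
        sq[:4, :] = True
        sq[4, :3] = True
        ys, xs = np.where(sq)
        ck[70 + ys, 70 + xs] = 9000.0
        img2 = SlideImage(channels={**img.channels, "ck": ck.astype(np.uint16)},
                          pixel_scale=0.5)
        cells = _events(dapi=[500.0, 500.0])
        cells.attrs["ck_threshold"] = 5000.0
        cells.attrs["dapi_cutoff"] = 350.0
        cfg = DetectionConfig(smooth_sigma=0.0, ring_tau=-np.inf)
        _, levs = detect_lev_candidates(img2, cells, cfg)
        flags = dict(zip(levs["area_px"], levs["size_excluded"]))
        assert flags[20] == False  # noqa: E712
        assert flags[19] == True  # noqa: E712

    def test_planted_levs_detected_with_phenotype(self, mini_slide, mini_detection):
        cfg, img, gt = mini_slide
        res = mini_detection
        kept = res.levs[res.levs["lev_candidate"]]
        for cls, pheno in (("epi_lev", "epi"), ("im_lev", "im")):
            planted = gt.objects[(gt.objects["cls"] == cls) & gt.objects["detectable"]]
            sub = kept[kept["phenotype"] == pheno]
            assert len(sub) == len(planted)
            d, _ = cKDTree(sub[["cy", "cx"]].to_numpy()).query(
                planted[["cy", "cx"]].to_numpy())
            assert (d < 5.0).all()

    def test_nucleated_ck_blob_excluded_from_levs(self, mini_slide, mini_detection):
        cfg, img, gt = mini_slide
        res = mini_detection
        # planted CTC positions must not appear among retained LEVs
        ctcs = gt.objects[gt.objects["cls"].isin(["epi_ctc", "im_ctc"])]
        kept = res.levs[res.levs["lev_candidate"]]
        if len(kept):
            d, _ = cKDTree(kept[["cy", "cx"]].to_numpy()).query(
                ctcs[["cy", "cx"]].to_numpy())
            assert (d > 5.0).all()
        # and those CK components are flagged as nucleated
        d, idx = cKDTree(res.levs[["cy", "cx"]].to_numpy()).query(
            ctcs[["cy", "cx"]].to_numpy())
        assert res.levs.iloc[idx[d < 5.0]]["dapi_excluded"].all()

    def test_missing_brightfield_warns_and_skips_ring(self, mini_slide):
        cfg, img, gt = mini_slide
        partial = SlideImage(channels={k: v for k, v in img.channels.items()
                                       if k != "bf"},
                             pixel_scale=img.pixel_scale)
        from picscan.detect import filter_dapi_low as fdl
        _, cells = segment_nucleated_cells(partial)
        cells = fdl(cells)
        cells = detect_ctc_candidates(cells)
        with pytest.warns(UserWarning, match="brightfield"):
            _, levs = detect_lev_candidates(partial, cells)
        assert levs["ring_skipped"].all()
        assert not levs["ring_failed"].any()


class TestPhenotypeRule:
    def test_boundary_is_epi(self):
        ev = _events(cd45=[100.0, 100.0 + 1e-9, 99.0])
        out = classify_phenotype(ev, wbc_cd45_mu=300.0, wbc_cd45_sd=100.0)
        # cutoff = 300 - 2*100 = 100; strictly-above rule
        assert list(out["phenotype"]) == ["epi", "im", "epi"]

    def test_partition_cells_vs_levs(self, mini_slide, mini_detection):
        """No event is both a CTC and a LEV."""
        cfg, img, gt = mini_slide
        res = mini_detection
        ctc = res.cells[res.cells["ctc_candidate"]]
        lev = res.levs[res.levs["lev_candidate"]]
        d, _ = cKDTree(lev[["cy", "cx"]].to_numpy()).query(
            ctc[["cy", "cx"]].to_numpy())
        assert (d > 5.0).all()
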