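"""Spot detection, matching and colocalization scoring."""

import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from cosmokin import (
    FieldImage,
    KineticTruth,
    SimConfig,
    Spot,
    colocalization_fraction,
    detect_spots,
    estimate_chance_colocalization,
    match_spots,
    score_field_series,
    simulate_field_pair,
)
from cosmokin.imaging import CHANNEL_DNA, CHANNEL_GFP
from cosmokin.synthetic import render_field


def spot(x, y, channel=CHANNEL_DNA):
    return Spot(x, y, peak_intensity=100.0, background=10.0, channel=channel)


def single_spot_image(x, y, snr=10.0, size=256, sigma=1.3, seed=0):
    rng = np.random.default_rng(seed)
    px = render_field(np.array([[x, y]]), size, sigma, snr * 10.0, rng,
                      background=100.0, noise_sd=10.0)
    return FieldImage(px, CHANNEL_DNA)


class TestDetect:
    def test_constant_image_yields_no_spots(self):
        img = FieldImage(np.full((128, 128), 50.0), CHANNEL_DNA)
        assert detect_spots(img, 1.3, 5.0) == []

    def test_noise_only_yields_no_spots(self):
        rng = np.random.default_rng(1)
        img = FieldImage(100 + rng.normal(0, 10, (256, 256)), CHANNEL_DNA)
        assert len(detect_spots(img, 1.3, 5.0)) <= 1  # rare noise excursions only

    def test_single_spot_subpixel_centroid(self):
        img = single_spot_image(100.3, 200.7, snr=10.0, size=256)
        spots = detect_spots(img, 1.3, 5.0)
        assert len(spots) == 1
        s = spots[0]
        assert np.hypot(s.x_px - 100.3, s.y_px - 200.7) < 0.2

    def test_two_well_separated_spots(self):
        rng = np.random.default_rng(2)
        pos = np.array([[60.0, 60.0], [60.0 + 8 * 1.3, 60.0]])  # 8 sigma apart
        px = render_field(pos, 128, 1.3, 100.0, rng, background=100.0, noise_sd=10.0)
        spots = detect_spots(FieldImage(px, CHANNEL_DNA), 1.3, 5.0)
        assert len(spots) == 2

    def test_nonfinite_pixels_error(self):
        px = np.full((128, 128), 10.0)
        px[5, 5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            detect_spots(FieldImage(px, CHANNEL_DNA), 1.3, 5.0)

    def test_precision_recall_and_localization_at_snr5(self):
        cfg = SimConfig(seed=7, n_dna_per_field=300, dna_snr=5.0)
        dna, _, truth = simulate_field_pair(cfg, 0.0, 0, seed=11)
        spots = detect_spots(dna, cfg.psf_sigma_px, 5.0)
        det = np.array([[s.x_px, s.y_px] for s in spots])
        d, idx = cKDTree(truth.dna_positions).query(det)
        matched = d < 1.5
        precision = matched.mean()
        recall = len(set(idx[matched])) / len(truth.dna_positions)
        assert precision >= 0.95
        assert recall >= 0.95
        resid = det[matched] - truth.dna_positions[idx[matched]]
        assert np.sqrt((resid**2).mean()) <= 0.2  # per-axis RMS

    @pytest.mark.parametrize("bad_sigma", [0.2, 6.0])
    def test_psf_sigma_bounds(self, bad_sigma):
        img = FieldImage(np.full((128, 128), 50.0), CHANNEL_DNA)
        with pytest.raises(ValueError):
            detect_spots(img, bad_sigma, 5.0)


class TestMatch:
    def test_simple_geometry(self):
        m = match_spots([spot(10, 10)], [spot(10.5, 10)], radius_px=1.5)
        assert m == [(0, 0, 0.5)]

    def test_beyond_radius_no_match(self):
        assert match_spots([spot(10, 10)], [spot(12, 10)], radius_px=1.5) == []

    def test_tie_breaks_toward_lower_ref_index(self):
        ref = [spot(9, 10), spot(11, 10)]
        query = [spot(10, 10)]  # equidistant from both refs
        m = match_spots(ref, query, radius_px=1.5)
        assert len(m) == 1
        assert m[0][0] == 0

    def test_one_to_one(self):
        ref = [spot(10, 10)]
        query = [spot(10.2, 10), spot(10.4, 10)]
        m = match_spots(ref, query, radius_px=1.5)
        assert len(m) == 1
        assert m[0][1] == 0  # the closer query wins

    def test_monotone_in_radius(self, rng):
        ref = [spot(x, y) for x, y in rng.uniform(0, 100, (40, 2))]
        query = [spot(x, y) for x, y in rng.uniform(0, 100, (40, 2))]
        prev = -1
        for radius in (0.5, 1.0, 2.0, 4.0, 8.0):
            n = len(match_spots(ref, query, radius))
            assert n >= prev
            prev = n

    def test_order_invariance_without_ties(self, rng):
        pts_r = rng.uniform(0, 100, (30, 2))
        pts_q = rng.uniform(0, 100, (30, 2))
        ref = [spot(x, y) for x, y in pts_r]
        query = [spot(x, y) for x, y in pts_q]
        m1 = {(i, j) for i, j, _ in match_spots(ref, query, 3.0)}
        perm = rng.permutation(30)
        ref_shuffled = [ref[i] for i in perm]
        m2 = {(int(perm[i]), j) for i, j, _ in match_spots(ref_shuffled, query, 3.0)}
        assert m1 == m2


class TestColocalization:
    def test_identical_positions_full_colocalization(self):
        dna = [spot(x, 50.0) for x in np.linspace(10, 90, 100)]
        gfp = [spot(s.x_px, s.y_px, CHANNEL_GFP) for s in dna]
        res = colocalization_fraction(dna, gfp, 1.5)
        assert res.fraction == 1.0
        assert res.n_colocalized == 100

    def test_no_gfp_zero_fraction(self):
        res = colocalization_fraction([spot(10, 10)], [], 1.5)
        assert res.fraction == 0.0

    def test_no_dna_missing_not_zero(self):
        res = colocalization_fraction([], [spot(10, 10)], 1.5)
        assert res.fraction is None
        assert res.n_dna == 0

    def test_translation_invariance(self, rng):
        pts = rng.uniform(20, 200, (50, 2))
        bound = pts[:30] + rng.normal(0, 0.3, (30, 2))
        dna = [spot(x, y) for x, y in pts]
        gfp = [spot(x, y, CHANNEL_GFP) for x, y in bound]
        f0 = colocalization_fraction(dna, gfp, 1.5).fraction
        dx, dy = 7.3, -4.1
        dna_t = [spot(s.x_px + dx, s.y_px + dy) for s in dna]
        gfp_t = [spot(s.x_px + dx, s.y_px + dy, CHANNEL_GFP) for s in gfp]
        assert colocalization_fraction(dna_t, gfp_t, 1.5).fraction == f0


class TestChanceColocalization:
    def test_independent_gfp_chance_matches_raw(self, rng):
        # GFP placed independently of DNA: the transposed-coordinates
        # estimate should agree with the directly measured fraction
        raws, chances = [], []
        for _ in range(40):
            dna = [spot(x, y) for x, y in rng.uniform(5, 507, (200, 2))]
            gfp = [spot(x, y, CHANNEL_GFP) for x, y in rng.uniform(5, 507, (200, 2))]
            raws.append(colocalization_fraction(dna, gfp, 1.5).fraction)
            chances.append(estimate_chance_colocalization(dna, gfp, 1.5, (512, 512)))
        assert np.mean(chances) == pytest.approx(np.mean(raws), abs=0.003)

    def test_true_binding_exceeds_chance(self, rng):
        pts = rng.uniform(20, 492, (150, 2))
        dna = [spot(x, y) for x, y in pts]
        gfp = [spot(x, y, CHANNEL_GFP) for x, y in pts]
        raw = colocalization_fraction(dna, gfp, 1.5).fraction
        chance = estimate_chance_colocalization(dna, gfp, 1.5, (512, 512))
        assert raw == 1.0
        assert chance < 0.1 * raw

    def test_no_gfp_returns_zero(self):
        assert estimate_chance_colocalization([spot(1, 1)], [], 1.5) == 0.0


class TestScoreSeries:
    def test_all_bound_single_field(self):
        cfg = SimConfig(
            seed=3, n_dna_per_field=100, n_fields_per_timepoint=1,
            field_size_px=256, n_replicates=1,
            kinetic_truth=KineticTruth(1, 10.0, 1.0),
        )
        dna, gfp, _ = simulate_field_pair(cfg, 180.0, 0, seed=9)
        with pytest.warns(UserWarning, match="below the 3000"):
            series = score_field_series({(180.0, 0): [(dna, gfp)]}, cfg.psf_sigma_px)
        row = series.data.iloc[0]
        assert row["n_colocalized"] / row["n_dna"] == pytest.approx(1.0, abs=0.02)

    def test_end_to_end_series_tracks_ground_truth(self):
        # measured fraction within +/-0.03 of the realized bound fraction at
        # every timepoint of a full schedule
        cfg = SimConfig(
            seed=21, n_dna_per_field=200, n_fields_per_timepoint=2,
            n_replicates=1, kinetic_truth=KineticTruth(1, 0.1057, 0.87),
        )
        groups, truth_frac = {}, {}
        for t in cfg.timepoints_min:
            pairs, bound, total = [], 0, 0
            for i in range(cfg.n_fields_per_timepoint):
                dna, gfp, tr = simulate_field_pair(cfg, t, 0, seed=1000 + 31 * i + int(t))
                pairs.append((dna, gfp))
                bound += tr.bound_state.sum()
                total += len(tr.bound_state)
            groups[(t, 0)] = pairs
            truth_frac[t] = bound / total
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = score_field_series(groups, cfg.psf_sigma_px)
        for _, row in series.data.iterrows():
            measured = row["n_colocalized"] / row["n_dna"]
            assert measured == pytest.approx(truth_frac[row["time_min"]], abs=0.03)

    def test_mixed_pixel_sizes_rejected(self):
        img_a = FieldImage(np.full((128, 128), 50.0), CHANNEL_DNA, pixel_size_um=0.11)
        img_b = FieldImage(np.full((128, 128), 50.0), CHANNEL_GFP, pixel_size_um=0.16)
        rng = np.random.default_rng(0)
        px = render_field(np.array([[64, 64]]), 128, 1.3, 100.0, rng)
        good = FieldImage(px, CHANNEL_DNA, pixel_size_um=0.11)
        with pytest.raises(ValueError, match="pixel sizes"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                score_field_series(
                    {(0.0, 0): [(good, img_a)], (5.0, 0): [(good, img_b)]}, 1.3
                )

    def test_empty_timepoint_recorded_missing(self):
        flat = FieldImage(np.full((128, 128), 100.0), CHANNEL_DNA)
        flat_g = FieldImage(np.full((128, 128), 100.0), CHANNEL_GFP)
        rng = np.random.default_rng(0)
        px = render_field(np.array([[64, 64]]), 128, 1.3, 100.0, rng)
        good = FieldImage(px, CHANNEL_DNA)
        with pytest.warns(UserWarning):
            series = score_field_series(
                {(0.0, 0): [(flat, flat_g)], (5.0, 0): [(good, flat_g)]}, 1.3
            )
        assert list(series.data["time_min"]) == [5.0]
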