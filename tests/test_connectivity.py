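"""Seeds, correlation maps, GSR, Fisher-z contrasts and the weekly screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypoxmap import (
    ScenarioConfig,
    connectivity_matrix,
    epoch_contrast,
    extract_seeds,
    fisher_z,
    global_signal_regression,
    longitudinal_normoxia_screen,
    seed_pixel_correlation_map,
    seed_timecourse,
    simulate_calcium,
)
from hypoxmap.connectivity import ConnectivityMatrix, _disk_offsets
from hypoxmap.synthetic import make_atlas


@pytest.fixture(scope="module")
def atlas_seeds():
    atlas, regions, brain = make_atlas((48, 48))
    from hypoxmap import make_brain_mask

    mask = make_brain_mask(atlas, edge_margin_px=2)
    return atlas, regions, mask, extract_seeds(regions, mask)


def traces_as_maps(traces: pd.DataFrame, seeds, shape=(48, 48)) -> np.ndarray:
    """Paint each region's trace onto its seed pixels (zero elsewhere)."""
    maps = np.zeros((len(traces), *shape), dtype=np.float32)
    for k, name in enumerate(traces.columns):
        sd = seeds.seeds[k]
        rr = [p[0] for p in sd.pixels]
        cc = [p[1] for p in sd.pixels]
        maps[:, rr, cc] = traces[name].to_numpy()[:, None]
    return maps


class TestGSR:
    def test_uniform_movie_residual_zero(self):
        mask = np.ones((6, 6), bool)
        maps = np.sin(np.arange(100.0))[:, None, None] * np.ones((1, 6, 6))
        out = global_signal_regression(maps, mask)
        assert np.abs(out).max() < 1e-10

    def test_residuals_orthogonal_to_global_signal(self, rng):
        mask = np.ones((8, 8), bool)
        maps = rng.standard_normal((300, 8, 8))
        out = global_signal_regression(maps, mask)
        g = maps[:, mask].mean(axis=1)
        r = np.corrcoef(np.column_stack([g, out[:, mask]]).T)[0, 1:]
        assert np.abs(r).max() < 1e-10

    def test_pixel_with_additive_global_recovers_noise(self, rng):
        mask = np.ones((4, 4), bool)
        g = np.sin(np.arange(500.0) / 7.0)
        noise = 0.1 * rng.standard_normal(500)
        maps = np.broadcast_to(g[:, None, None], (500, 4, 4)).copy()
        maps[:, 2, 2] = g + noise
        out = global_signal_regression(maps, mask)
        resid = out[:, 2, 2]
        # g absorbs 1/n_pixels of the pixel's own noise, so recovery is
        # near-perfect but not exact
        assert np.corrcoef(resid, noise)[0, 1] > 0.99

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_signal_regression(np.zeros((10, 4, 4)), np.zeros((4, 4), bool))


class TestSeeds:
    def test_disk_has_29_lattice_points(self):
        assert len(_disk_offsets(3)) == 29

    def test_eight_seeds_with_cluster_partition(self, atlas_seeds):
        *_, seeds = atlas_seeds
        assert len(seeds) == 8
        kinds = [seeds.pair_kind(i, j) for i, j in seeds.pairs()]
        assert len(kinds) == 28
        assert kinds.count("within") == 12 and kinds.count("between") == 16

    def test_full_disk_inside_mask(self, atlas_seeds):
        *_, seeds = atlas_seeds
        sizes = [len(s.pixels) for s in seeds]
        assert max(sizes) == 29

    def test_mirrored_regions_have_mirrored_centroids(self, atlas_seeds):
        _, regions, _, seeds = atlas_seeds
        by_name = {s.name: s for s in seeds}
        for base in ("Mot", "Sen", "Ret", "Vis"):
            left, right = by_name[f"{base}L"], by_name[f"{base}R"]
            assert left.centroid[0] == right.centroid[0]

    def test_centroid_outside_mask_is_relocated(self, atlas_seeds, caplog):
        import logging

        _, regions, mask, _ = atlas_seeds
        bad = regions.copy()
        bad.loc[0, ["centroid_row", "centroid_col"]] = [0, 0]  # corner, off-brain
        with caplog.at_level(logging.WARNING):
            seeds = extract_seeds(bad, mask)
        assert "moved" in caplog.text
        assert mask[seeds.seeds[0].centroid]


class TestSeedTimecourse:
    def test_identical_pixels_return_that_trace(self, atlas_seeds):
        *_, seeds = atlas_seeds
        trace = np.arange(50.0)
        maps = np.broadcast_to(trace[:, None, None], (50, 48, 48)).copy()
        assert seed_timecourse(maps, seeds.seeds[0]) == pytest.approx(trace)

    def test_balanced_signs_cancel(self):
        from hypoxmap.connectivity import Seed

        seed = Seed("x", "anterior", (1, 1), ((0, 0), (0, 1)))
        maps = np.zeros((10, 2, 2))
        maps[:, 0, 0] = 1.0
        maps[:, 0, 1] = -1.0
        assert np.abs(seed_timecourse(maps, seed)).max() == 0.0

    def test_averaging_beats_single_pixel(self, atlas_seeds, rng):
        *_, seeds = atlas_seeds
        truth = np.sin(np.arange(2000.0) / 5.0)
        seed = seeds.seeds[0]
        maps = np.zeros((2000, 48, 48))
        for r, c in seed.pixels:
            maps[:, r, c] = truth + rng.standard_normal(2000)
        r_seed = np.corrcoef(seed_timecourse(maps, seed), truth)[0, 1]
        r_pix = np.corrcoef(maps[:, seed.pixels[0][0], seed.pixels[0][1]], truth)[0, 1]
        assert r_seed > r_pix


class TestSeedPixelMap:
    def test_own_disk_correlates_perfectly_noise_free(self, atlas_seeds):
        *_, mask, seeds = atlas_seeds
        cfg = ScenarioConfig(duration_s=240.0, rng_seed=51)
        traces, _, _ = simulate_calcium(cfg)
        maps = traces_as_maps(traces, seeds)
        m = seed_pixel_correlation_map(maps, seeds.seeds[0], mask, 20.0, window_min=(0.5, 3.5))
        rr = [p[0] for p in seeds.seeds[0].pixels]
        cc = [p[1] for p in seeds.seeds[0].pixels]
        assert np.nanmin(m[rr, cc]) > 0.9999

    def test_cluster_structure_visible_in_map(self, atlas_seeds):
        *_, mask, seeds = atlas_seeds
        cfg = ScenarioConfig(
            duration_s=480.0, within_cluster_r=0.8, between_cluster_r=0.2, rng_seed=52
        )
        traces, _, _ = simulate_calcium(cfg)
        maps = traces_as_maps(traces, seeds)
        mot_l = seeds.seeds[0]
        m = seed_pixel_correlation_map(maps, mot_l, mask, 20.0, window_min=(0.0, 2.0))
        own = [s for s in seeds if s.macrocluster == "anterior" and s.name != "MotL"]
        other = [s for s in seeds if s.macrocluster == "posterior"]
        own_r = np.nanmean([np.nanmean(m[[p[0] for p in s.pixels], [p[1] for p in s.pixels]]) for s in own])
        other_r = np.nanmean([np.nanmean(m[[p[0] for p in s.pixels], [p[1] for p in s.pixels]]) for s in other])
        assert own_r > other_r + 0.3

    def test_sign_flip_negates_correlation(self, atlas_seeds):
        *_, mask, seeds = atlas_seeds
        cfg = ScenarioConfig(duration_s=120.0, rng_seed=53)
        traces, _, _ = simulate_calcium(cfg)
        maps = traces_as_maps(traces, seeds)
        seed = seeds.seeds[2]
        px = seeds.seeds[5].pixels[0]
        m1 = seed_pixel_correlation_map(maps, seed, mask, 20.0, window_min=(0.0, 1.5))
        maps[:, px[0], px[1]] *= -1
        m2 = seed_pixel_correlation_map(maps, seed, mask, 20.0, window_min=(0.0, 1.5))
        assert m2[px] == pytest.approx(-m1[px], abs=1e-10)


class TestConnectivityMatrix:
    def test_identical_traces_give_finite_clipped_z(self, atlas_seeds):
        *_, seeds = atlas_seeds
        trace = np.sin(np.arange(6000.0) / 9.0)
        maps = np.broadcast_to(trace[:, None, None], (6000, 48, 48)).copy()
        cm = connectivity_matrix(maps, seeds, 20.0, (0.0, 5.0))
        assert cm.r == pytest.approx(np.ones((8, 8)))
        assert np.isfinite(cm.z).all()

    def test_fisher_value_closed_form(self):
        assert fisher_z(np.array(0.5)) == pytest.approx(0.5493061443)

    def test_simulator_targets_recovered(self, atlas_seeds):
        *_, seeds = atlas_seeds
        cfg = ScenarioConfig(
            duration_s=1200.0, within_cluster_r=0.8, between_cluster_r=0.2, rng_seed=54
        )
        traces, corr_n, _ = simulate_calcium(cfg)
        maps = traces_as_maps(traces, seeds)
        cm = connectivity_matrix(maps, seeds, 20.0, (0.0, 5.0))
        assert np.abs(cm.r - corr_n).max() <= 0.05

    def test_short_window_rejected(self, atlas_seeds):
        *_, seeds = atlas_seeds
        maps = np.zeros((100, 48, 48))
        with pytest.raises(ValueError, match="frames"):
            connectivity_matrix(maps, seeds, 20.0, (0.0, 0.02))


def cohort_matrices(seeds, n_subjects=7, between_hypoxia=0.1, seed0=100, duration=2400.0):
    hyp, nor = [], []
    for s in range(n_subjects):
        cfg = ScenarioConfig(
            duration_s=duration, rng_seed=seed0 + s,
            within_cluster_r=0.8, between_cluster_r=0.5,
            between_cluster_r_hypoxia=between_hypoxia,
        )
        traces, _, _ = simulate_calcium(cfg)
        maps = traces_as_maps(traces, seeds)
        hyp.append(connectivity_matrix(maps, seeds, 20.0, (12.5, 17.5)))
        nor.append(connectivity_matrix(maps, seeds, 20.0, (2.5, 7.5)))
    return hyp, nor


class TestEpochContrast:
    def test_identical_epochs_give_zero_contrast(self, atlas_seeds):
        *_, seeds = atlas_seeds
        cfg = ScenarioConfig(duration_s=300.0, rng_seed=55)
        traces, _, _ = simulate_calcium(cfg)
        maps = traces_as_maps(traces, seeds)
        cms = [connectivity_matrix(maps, seeds, 20.0, (0.0, 2.0)) for _ in range(6)]
        ec = epoch_contrast(cms, cms, seeds)
        assert np.abs(ec.dz).max() == 0.0
        assert (ec.pair_stats["q"] > 0.9).all()

    def test_swapping_epochs_negates_dz(self, atlas_seeds):
        *_, seeds = atlas_seeds
        hyp, nor = cohort_matrices(seeds, n_subjects=5, duration=1200.0)
        fwd = epoch_contrast(hyp, nor, seeds)
        rev = epoch_contrast(nor, hyp, seeds)
        assert fwd.dz == pytest.approx(-rev.dz)

    def test_small_cohort_skips_tests_with_warning(self, atlas_seeds, caplog):
        import logging

        *_, seeds = atlas_seeds
        hyp, nor = cohort_matrices(seeds, n_subjects=3, duration=1200.0)
        with caplog.at_level(logging.WARNING):
            ec = epoch_contrast(hyp, nor, seeds)
        assert "skipped" in caplog.text
        assert "p" not in ec.pair_stats.columns
        assert len(ec.pair_stats) == 28

    def test_mismatched_cohorts_rejected(self, atlas_seeds):
        *_, seeds = atlas_seeds
        hyp, nor = cohort_matrices(seeds, n_subjects=2, duration=1200.0)
        with pytest.raises(ValueError, match="matched"):
            epoch_contrast(hyp, nor[:1], seeds)


class TestLongitudinalScreen:
    @staticmethod
    def weekly_from_z(z_by_week, seeds):
        out = {}
        for w, subj_zs in z_by_week.items():
            mats = []
            for z in subj_zs:
                r = np.tanh(z)
                np.fill_diagonal(r, 1.0)
                mats.append(
                    ConnectivityMatrix("gcamp", (150.0, 450.0), r, fisher_z(r), seeds.names)
                )
            out[w] = mats
        return out

    def base_z(self, rng, n_sub=7):
        z = 0.6 + 0.05 * rng.standard_normal((n_sub, 8, 8))
        z = (z + z.transpose(0, 2, 1)) / 2
        return z

    def test_stationary_weeks_yield_no_discoveries(self, atlas_seeds, rng):
        *_, seeds = atlas_seeds
        weeks = {f"w{k}": list(self.base_z(rng)) for k in range(7)}
        df = longitudinal_normoxia_screen(self.weekly_from_z(weeks, seeds), seeds)
        assert (df["q"] >= 0.05).all()

    def test_injected_trend_is_flagged(self, atlas_seeds, rng):
        *_, seeds = atlas_seeds
        weeks = {}
        for k in range(7):
            z = self.base_z(rng)
            z[:, 0, 1] += 0.25 * k   # steady weekly drift in the MotL-MotR pair
            z[:, 1, 0] = z[:, 0, 1]
            weeks[f"w{k}"] = list(z)
        df = longitudinal_normoxia_screen(self.weekly_from_z(weeks, seeds), seeds)
        flagged = df[(df.seed_a == "MotL") & (df.seed_b == "MotR")]
        assert (flagged["q"] < 0.05).all()
        assert len(flagged["kruskal_vs_week1"].iloc[0]) == 6

    def test_identical_weeks_zero_statistic(self, atlas_seeds, rng):
        *_, seeds = atlas_seeds
        z = self.base_z(rng)
        weeks = {f"w{k}": list(z.copy()) for k in range(4)}
        df = longitudinal_normoxia_screen(self.weekly_from_z(weeks, seeds), seeds)
        assert (df["friedman_stat"] == 0.0).all()

    def test_too_few_weeks_rejected(self, atlas_seeds, rng):
        *_, seeds = atlas_seeds
        weeks = {f"w{k}": list(self.base_z(rng)) for k in range(2)}
        with pytest.raises(ValueError, match="3 weeks"):
            longitudinal_normoxia_screen(self.weekly_from_z(weeks, seeds), seeds)


@settings(derandomize=True, max_examples=60)
@given(st.floats(min_value=-0.999, max_value=0.999))
def test_fisher_z_is_odd_and_monotone(r):
    assert fisher_z(np.array(-r)) == pytest.approx(-fisher_z(np.array(r)))
    eps = 1e-4
    if r + eps < 1:
        assert fisher_z(np.array(r + eps)) > fisher_z(np.array(r))
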