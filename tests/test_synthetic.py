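"""Generator tests: layout geometry, event statistics, forward imaging model."""

import numpy as np
import pytest
from scipy import stats

from sptcorral.synthetic import (
    BindingEvent,
    PatternLayout,
    SimulationConfig,
    kon_for_active_density,
    make_pattern_layout,
    mixture_mean_observed_dwell,
    quantize_dwells,
    render_ligand_channel,
    render_movie,
    render_nucleus_image,
    simulate_binding_events,
    simulate_corral_ratio_dataset,
)


class TestPatternLayout:
    def test_single_corral_centered(self):
        lay = make_pattern_layout(1, 1, radius=2.5, spacing=10.0)
        assert lay.n_corrals == 1
        assert np.allclose(lay.centers[0], [5.0, 5.0])
        assert lay.region_class[0] == "mobile"

    def test_checkerboard_alternation(self):
        lay = make_pattern_layout(2, 2, radius=2.5, spacing=10.0, alternating=True)
        # row-major order: (0,0) mobile, (0,1) immobile, (1,0) immobile, (1,1) mobile
        assert list(lay.region_class) == ["mobile", "immobile", "immobile", "mobile"]

    def test_grid_disks_pairwise_disjoint_bruteforce(self):
        lay = make_pattern_layout(4, 4, radius=2.5, spacing=6.0)
        for i in range(lay.n_corrals):
            for j in range(i + 1, lay.n_corrals):
                d = np.hypot(*(lay.centers[i] - lay.centers[j]))
                assert d > lay.radii[i] + lay.radii[j]

    def test_overlapping_spacing_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_pattern_layout(2, 2, radius=2.5, spacing=5.0)

    def test_constructor_rejects_out_of_field_corral(self):
        with pytest.raises(ValueError, match="inside the field"):
            PatternLayout(
                corral_id=np.array([0]), centers=np.array([[1.0, 1.0]]),
                radii=np.array([2.0]), region_class=np.array(["mobile"], dtype=object),
                field_size=(10.0, 10.0), pixel_size=0.1,
            )


class TestSimulationConfig:
    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dwell_f1=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(dwell_tau1=0.5, dwell_tau2=0.1)
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.0)


class TestBindingEvents:
    def test_zero_rate_gives_no_events(self, layout_4x4):
        cfg = SimulationConfig(k_on=0.0)
        assert simulate_binding_events(layout_4x4, cfg) == []

    def test_mean_dwell_matches_mixture_mean_without_bleaching(self, layout_4x4):
        # long movie so movie-end truncation is negligible
        cfg = SimulationConfig(k_on=0.05, k_bleach=0.0, n_frames=20000,
                               dwell_f1=0.6, dwell_tau1=0.1, dwell_tau2=0.5)
        ev = simulate_binding_events(layout_4x4, cfg,
                                     np.random.default_rng(1))
        obs = np.array([e.observed_dwell for e in ev
                        if e.arrival_time < cfg.movie_length - 10 * 0.5])
        mean_true = 0.6 * 0.1 + 0.4 * 0.5
        se = obs.std() / np.sqrt(len(obs))
        assert abs(obs.mean() - mean_true) < 3 * se

    def test_mean_observed_dwell_under_bleach_competition(self, layout_4x4):
        # min of the mixture and an exponential bleach: closed form
        # f1/(1/tau1+kb) + (1-f1)/(1/tau2+kb) = 0.6/10.2 + 0.4/2.2
        cfg = SimulationConfig(k_on=0.05, k_bleach=0.2, n_frames=20000,
                               dwell_f1=0.6, dwell_tau1=0.1, dwell_tau2=0.5)
        ev = simulate_binding_events(layout_4x4, cfg, np.random.default_rng(2))
        obs = np.array([e.observed_dwell for e in ev
                        if e.arrival_time < cfg.movie_length - 5.0])
        expected = mixture_mean_observed_dwell(0.6, 0.1, 0.5, 0.2)
        assert abs(expected - 0.2406) < 5e-4
        se = obs.std() / np.sqrt(len(obs))
        assert abs(obs.mean() - expected) < 3 * se

    def test_positions_stay_inside_their_corral(self, layout_4x4):
        cfg = SimulationConfig(k_on=0.3, rng_seed=3)
        ev = simulate_binding_events(layout_4x4, cfg)
        by_id = {int(c): i for i, c in enumerate(layout_4x4.corral_id)}
        for e in ev:
            i = by_id[e.corral_id]
            d = np.hypot(e.positions[:, 0] - layout_4x4.centers[i, 0],
                         e.positions[:, 1] - layout_4x4.centers[i, 1])
            assert np.all(d <= layout_4x4.radii[i] + 1e-9)

    def test_same_seed_bit_identical(self, layout_4x4_puncta):
        cfg = SimulationConfig(k_on=0.5, rng_seed=7)
        ev1 = simulate_binding_events(layout_4x4_puncta, cfg)
        ev2 = simulate_binding_events(layout_4x4_puncta, cfg)
        assert len(ev1) == len(ev2)
        for a, b in zip(ev1, ev2):
            assert a.arrival_time == b.arrival_time
            assert a.observed_dwell == b.observed_dwell
            assert np.array_equal(a.positions, b.positions)
        m1 = render_movie(ev1[:50], layout_4x4_puncta, cfg)
        m2 = render_movie(ev2[:50], layout_4x4_puncta, cfg)
        assert np.array_equal(m1.data, m2.data)

    def test_arrival_counts_are_poisson(self):
        # chi-square goodness of fit of per-corral arrival counts against
        # the configured Poisson mean, across 100 seeds
        lay = make_pattern_layout(8, 8, radius=1.0, spacing=2.5)
        cfg = SimulationConfig(k_on=0.5, n_frames=200,
                               dwell_tau1=0.05, dwell_tau2=0.05, dwell_f1=1.0)
        mean = 0.5 * np.pi * 1.0**2 * cfg.movie_length
        cuts = stats.poisson.ppf([0.2, 0.4, 0.6, 0.8], mean).astype(int)
        edges = np.concatenate([[-0.5], cuts + 0.5, [np.inf]])
        cdf = stats.poisson.cdf(cuts, mean)
        prob = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
        passed = 0
        for seed in range(100):
            ev = simulate_binding_events(lay, cfg, np.random.default_rng(seed))
            counts = np.bincount([e.corral_id for e in ev], minlength=64)
            obs, _ = np.histogram(counts, bins=edges)
            p = stats.chisquare(obs, 64 * prob).pvalue
            passed += p > 0.01
        assert passed >= 95

    def test_quantize_dwells_is_frame_ceiling(self):
        q = quantize_dwells(np.array([0.001, 0.049, 0.05, 0.051, 0.23]), 0.05)
        assert np.allclose(q, [0.05, 0.05, 0.05, 0.10, 0.25])


class TestRenderMovie:
    def test_zero_events_zero_background_all_zero(self, layout_4x4):
        cfg = SimulationConfig(background=0.0, read_noise=0.0, n_frames=3)
        stack = render_movie([], layout_4x4, cfg)
        assert stack.data.shape[0] == 3
        assert np.all(stack.data == 0)

    def test_noiseless_frame_signal_equals_photons(self, layout_4x4):
        cfg = SimulationConfig(background=0.0, n_frames=5, photons_per_frame=500)
        ev = BindingEvent(
            event_id=0, corral_id=0, region_class="mobile", arrival_time=0.0,
            true_dwell=1.0, bleach_time=np.inf, observed_dwell=0.25,
            first_frame=0, positions=np.tile(layout_4x4.centers[0], (5, 1)),
        )
        stack = render_movie([ev], layout_4x4, cfg, noise=False)
        total = stack.data[0].sum()
        assert abs(total - 500) / 500 < 0.005  # Gaussian tail loss only

    def test_event_outside_field_rejected(self, layout_4x4):
        ev = BindingEvent(
            event_id=0, corral_id=0, region_class="mobile", arrival_time=0.0,
            true_dwell=1.0, bleach_time=np.inf, observed_dwell=0.05,
            first_frame=0, positions=np.array([[-3.0, 5.0]]),
        )
        with pytest.raises(ValueError, match="field"):
            render_movie([ev], layout_4x4, SimulationConfig(n_frames=2))

    def test_steady_state_active_density_near_half_per_um2(self, layout_4x4):
        # arrival rate derived from the target via the closed-form mean
        # observed dwell should produce ~0.5 active molecules/µm² in corrals
        cfg = SimulationConfig(rng_seed=11)
        kon = kon_for_active_density(0.5, cfg.dwell_f1["mobile"],
                                     cfg.dwell_tau1["mobile"],
                                     cfg.dwell_tau2["mobile"], cfg.k_bleach,
                                     dt=cfg.dt)
        cfg = SimulationConfig(k_on=kon, rng_seed=11)
        ev = simulate_binding_events(layout_4x4, cfg)
        active = np.zeros(cfg.n_frames)
        for e in ev:
            active[e.first_frame:e.first_frame + e.n_visible_frames] += 1
        corral_area = float(layout_4x4.areas().sum())
        density = active[100:].mean() / corral_area  # skip warm-up
        assert abs(density - 0.5) / 0.5 < 0.10


class TestLigandChannel:
    def test_no_clustering_makes_classes_indistinguishable(self, layout_4x4_puncta):
        img = render_ligand_channel(layout_4x4_puncta, 100.0, 0.0)
        sums = []
        for i in range(layout_4x4_puncta.n_corrals):
            cx, cy = layout_4x4_puncta.centers[i] / 0.1
            r = layout_4x4_puncta.radii[i] / 0.1
            yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= (r + 1) ** 2
            sums.append((layout_4x4_puncta.region_class[i], img[disk].sum()))
        mob = [s for c, s in sums if c == "mobile"]
        imm = [s for c, s in sums if c == "immobile"]
        assert abs(np.mean(mob) / np.mean(imm) - 1) < 0.02

    def test_total_intensity_conserved_under_clustering(self, layout_4x4_puncta):
        # same density => same per-corral total, clustered or not
        img = render_ligand_channel(layout_4x4_puncta, 100.0, 0.95)
        per_corral = []
        for i in range(layout_4x4_puncta.n_corrals):
            cx, cy = layout_4x4_puncta.centers[i] / 0.1
            r = layout_4x4_puncta.radii[i] / 0.1
            yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= (r + 1) ** 2
            per_corral.append(img[disk].sum())
        expected = 100.0 * np.pi * 2.0**2
        assert np.allclose(per_corral, expected, rtol=0.02)

    def test_density_100_total_equals_100_pi_r2(self, layout_4x4_puncta):
        img = render_ligand_channel(layout_4x4_puncta, 100.0, 0.0)
        assert abs(img.sum() - 16 * 100.0 * np.pi * 4.0) / (1600 * np.pi * 4) < 0.02

    def test_bad_clustered_fraction_rejected(self, layout_4x4_puncta):
        with pytest.raises(ValueError):
            render_ligand_channel(layout_4x4_puncta, 100.0, 1.2)


class TestCorralRatioDataset:
    def test_noiseless_unit_fold_all_ratios_one(self):
        tbl = simulate_corral_ratio_dataset(5, 5, fold_change=1.0, cv=0.0)
        num = tbl[tbl.channel == "numerator"].set_index("corral_id").net_intensity
        den = tbl[tbl.channel == "denominator"].set_index("corral_id").net_intensity
        assert np.allclose(num / den, 1.0)

    def test_noiseless_fold_exact(self):
        tbl = simulate_corral_ratio_dataset(5, 5, fold_change=1.6, cv=0.0)
        num = tbl[tbl.channel == "numerator"].set_index("corral_id").net_intensity
        den = tbl[tbl.channel == "denominator"].set_index("corral_id").net_intensity
        ratios = (num / den).to_frame("r").join(
            tbl[tbl.channel == "numerator"].set_index("corral_id").region_class
        )
        mob = ratios[ratios.region_class == "mobile"].r.mean()
        imm = ratios[ratios.region_class == "immobile"].r.mean()
        assert mob / imm == pytest.approx(1.6, rel=1e-12)

    def test_monte_carlo_fold_recovery(self):
        folds = []
        for seed in range(100):
            tbl = simulate_corral_ratio_dataset(20, 20, 1.6, 0.2, rng_seed=seed)
            num = tbl[tbl.channel == "numerator"]
            den = tbl[tbl.channel == "denominator"].set_index("corral_id")
            r = num.set_index("corral_id").net_intensity / den.net_intensity
            cls = num.set_index("corral_id").region_class
            folds.append(r[cls == "mobile"].mean() / r[cls == "immobile"].mean())
        folds = np.asarray(folds)
        # single-experiment SE of the fold at n=20/20, CV 20% is ~6%, so the
        # Monte-Carlo mean must recover the truth and most draws stay close
        assert abs(np.mean(folds) - 1.6) / 1.6 < 0.02
        assert np.mean(np.abs(folds - 1.6) / 1.6 < 0.10) >= 0.80

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            simulate_corral_ratio_dataset(0, 5, 1.6, 0.2)
        with pytest.raises(ValueError):
            simulate_corral_ratio_dataset(5, 5, -1.0, 0.2)


def test_nucleus_image_has_configured_contrast(rng):
    img, mask = render_nucleus_image(80.0, background=50.0, noise_sd=0.0, rng=rng)
    assert img[mask].mean() == pytest.approx(130.0)
    assert np.median(img[~mask]) == pytest.approx(50.0)
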