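"""Corral-wise intensity quantification, ratios, heat maps, nuclear measures."""

import numpy as np
import pandas as pd
import pytest

from sptcorral.quantify import (
    channel_ratio_per_cell,
    corral_mean_intensity,
    max_and_cumulative,
    nuclear_ratio,
    percent_increase,
    timelapse_heatmap,
)
from sptcorral.regions import mask_from_layout
from sptcorral.synthetic import (
    assign_puncta,
    make_pattern_layout,
    render_ligand_channel,
    render_nucleus_image,
    simulate_corral_ratio_dataset,
    simulate_recruitment_series,
)


@pytest.fixture
def small_mask():
    layout = make_pattern_layout(2, 2, radius=0.8, spacing=2.0, pixel_size=0.1)
    return layout, mask_from_layout(layout)


def _disk_image(mask, corral_value, background):
    img = np.full(mask.labels.shape, float(background))
    img[mask.labels > 0] = corral_value
    return img


class TestCorralMeanIntensity:
    def test_uniform_corrals_over_background(self, small_mask):
        _, mask = small_mask
        tbl = corral_mean_intensity(_disk_image(mask, 100.0, 10.0), mask)
        assert len(tbl) == 4
        assert np.allclose(tbl.net_intensity, 90.0)

    def test_background_only_gives_zero_net(self, small_mask):
        _, mask = small_mask
        tbl = corral_mean_intensity(np.full(mask.labels.shape, 10.0), mask)
        assert np.allclose(tbl.net_intensity, 0.0)

    def test_local_annulus_background_mode(self, small_mask):
        _, mask = small_mask
        img = _disk_image(mask, 100.0, 10.0)
        tbl = corral_mean_intensity(img, mask, background_mode="local")
        assert np.allclose(tbl.net_intensity, 90.0)
        with pytest.raises(ValueError):
            corral_mean_intensity(img, mask, background_mode="weird")

    def test_generator_totals_recovered_within_two_percent(self):
        layout = assign_puncta(
            make_pattern_layout(2, 2, radius=1.0, spacing=3.0, pixel_size=0.1),
            np.random.default_rng(0),
        )
        img = render_ligand_channel(layout, 100.0, 0.0)
        mask = mask_from_layout(layout)
        tbl = corral_mean_intensity(img, mask)
        # uniform disk at density 100/µm²: mean pixel value = 100·px²·(N/npix)…
        # equivalently total/npix; compare net mean · npix to 100·π·r²
        for _, row in tbl.iterrows():
            npix = (mask.labels == row.corral_id).sum()
            total = row.net_intensity * npix
            assert abs(total - 100 * np.pi * 1.0**2) / (100 * np.pi) < 0.02


class TestChannelRatio:
    def test_identical_channels_ratio_one(self, small_mask):
        _, mask = small_mask
        tbl = corral_mean_intensity(_disk_image(mask, 100.0, 10.0), mask)
        per_cell, per_corral, n_exc = channel_ratio_per_cell(tbl, tbl)
        assert n_exc == 0
        assert np.allclose(per_corral.ratio, 1.0)
        assert np.allclose(per_cell.mean_ratio, 1.0)

    def test_nonpositive_denominator_excluded(self, small_mask):
        _, mask = small_mask
        a = corral_mean_intensity(_disk_image(mask, 100.0, 10.0), mask)
        b = a.copy()
        b.loc[b.index[0], "net_intensity"] = 0.0
        per_cell, per_corral, n_exc = channel_ratio_per_cell(a, b)
        assert n_exc == 1
        assert len(per_corral) == 3

    def test_ratio_dataset_fold_recovered(self):
        tbl = simulate_corral_ratio_dataset(8, 8, 1.6, 0.2, rng_seed=0,
                                            n_cells=26)
        a = tbl[tbl.channel == "numerator"].copy()
        b = tbl[tbl.channel == "denominator"].copy()
        per_cell, _, _ = channel_ratio_per_cell(a, b)
        mob = per_cell[per_cell.region_class == "mobile"].mean_ratio.mean()
        imm = per_cell[per_cell.region_class == "immobile"].mean_ratio.mean()
        assert abs(percent_increase(mob, imm) - 60.0) < 6.0

    def test_slight_decrease_direction_preserved(self):
        tbl = simulate_corral_ratio_dataset(8, 8, 0.95, 0.1, rng_seed=1,
                                            n_cells=22)
        a = tbl[tbl.channel == "numerator"]
        b = tbl[tbl.channel == "denominator"]
        per_cell, _, _ = channel_ratio_per_cell(a, b)
        mob = per_cell[per_cell.region_class == "mobile"].mean_ratio.mean()
        imm = per_cell[per_cell.region_class == "immobile"].mean_ratio.mean()
        assert mob < imm

    def test_gain_invariance_of_ratios(self, small_mask):
        _, mask = small_mask
        rng = np.random.default_rng(2)
        img_a = _disk_image(mask, 120.0, 10.0) + rng.normal(0, 1, mask.labels.shape)
        img_b = _disk_image(mask, 80.0, 10.0) + rng.normal(0, 1, mask.labels.shape)
        a1 = corral_mean_intensity(img_a, mask)
        b1 = corral_mean_intensity(img_b, mask)
        a2 = corral_mean_intensity(img_a * 5.0, mask)
        b2 = corral_mean_intensity(img_b * 5.0, mask)
        _, r1, _ = channel_ratio_per_cell(a1, b1)
        _, r2, _ = channel_ratio_per_cell(a2, b2)
        assert np.allclose(r1.ratio, r2.ratio)


class TestHeatmap:
    def test_constant_series_all_ones(self):
        series, _ = simulate_recruitment_series(1, 2, 2, 1.0, 0.0,
                                                rise_time=1e-9)
        mat, flag = timelapse_heatmap(series)
        assert not flag
        assert np.allclose(mat.to_numpy()[:, 1:], 1.0)

    def test_single_ramp_normalized_to_unit_max(self):
        rows = [(0, 0, "mobile", float(t), "s", float(t) * 10) for t in range(11)]
        series = pd.DataFrame(rows, columns=["cell_id", "corral_id",
                                             "region_class", "timepoint",
                                             "channel", "net_intensity"])
        mat, flag = timelapse_heatmap(series)
        assert mat.to_numpy()[0, 0] == 0.0
        assert mat.to_numpy()[0, -1] == 1.0

    def test_max_is_exactly_one_and_argmax_preserved(self):
        series, _ = simulate_recruitment_series(1, 4, 4, 1.6, 0.3, rng_seed=5)
        mat, flag = timelapse_heatmap(series)
        arr = mat.to_numpy()
        assert not flag
        assert np.nanmax(arr) == 1.0
        raw = series.pivot_table(index="corral_id", columns="timepoint",
                                 values="net_intensity").to_numpy()
        assert np.array_equal(np.argmax(arr, axis=1), np.argmax(raw, axis=1))

    def test_all_zero_series_flagged(self):
        rows = [(0, 0, "mobile", 0.0, "s", 0.0), (0, 0, "mobile", 30.0, "s", 0.0)]
        series = pd.DataFrame(rows, columns=["cell_id", "corral_id",
                                             "region_class", "timepoint",
                                             "channel", "net_intensity"])
        mat, flag = timelapse_heatmap(series)
        assert flag
        assert np.all(mat.to_numpy() == 0)


class TestMaxAndCumulative:
    def _constant_series(self, value, n_points=61, sampling=30.0):
        rows = [(0, 0, "mobile", i * sampling, "s", value)
                for i in range(n_points)]
        return pd.DataFrame(rows, columns=["cell_id", "corral_id",
                                           "region_class", "timepoint",
                                           "channel", "net_intensity"])

    def test_constant_signal_closed_form(self):
        series = self._constant_series(50.0)  # 30 min at 30 s/frame
        out = max_and_cumulative(series, window=1800.0, ligand={0: 100.0})
        assert out.max_per_ligand.iloc[0] == pytest.approx(0.5)
        assert out.cumulative_per_ligand.iloc[0] == pytest.approx(
            50.0 * 1800.0 / 100.0)

    def test_zero_series_gives_zero(self):
        out = max_and_cumulative(self._constant_series(0.0), 1800.0, {0: 100.0})
        assert out.max_per_ligand.iloc[0] == 0.0
        assert out.cumulative_per_ligand.iloc[0] == 0.0

    def test_cumulative_additive_over_adjacent_windows(self):
        series, ligand = simulate_recruitment_series(1, 3, 3, 1.6, 0.2,
                                                     rng_seed=3)
        full = max_and_cumulative(series, 1800.0, ligand)
        first = max_and_cumulative(series, 900.0, ligand)
        second = series[series.timepoint >= 900.0].copy()
        second_out = max_and_cumulative(second, 900.0, ligand)
        total = first.set_index("corral_id").cumulative_per_ligand + \
            second_out.set_index("corral_id").cumulative_per_ligand
        assert np.allclose(total,
                           full.set_index("corral_id").cumulative_per_ligand)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            max_and_cumulative(self._constant_series(1.0), 3600.0, {0: 1.0})

    def test_missing_ligand_excludes_corral(self):
        out = max_and_cumulative(self._constant_series(1.0), 1800.0, {})
        assert len(out) == 0


class TestNuclearRatio:
    def test_signal_equal_to_background_gives_zero(self):
        img = np.full((40, 40), 50.0)
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        assert nuclear_ratio(img, mask, 100.0) == 0.0

    def test_known_contrast_recovered(self):
        img, mask = render_nucleus_image(80.0, noise_sd=0.0)
        assert nuclear_ratio(img, mask, 100.0) == pytest.approx(0.8)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            nuclear_ratio(np.zeros((10, 10)), np.zeros((10, 10), bool), 1.0)

    def test_condition_fold_recovered_at_sample_size(self):
        rng = np.random.default_rng(7)
        sig2 = np.log(1 + 0.3**2)
        vals = {}
        for cond, fold, n in (("mobile", 1.5, 103), ("immobile", 1.0, 82)):
            ratios = []
            for _ in range(n):
                mean = 60.0 * fold * rng.lognormal(-sig2 / 2, np.sqrt(sig2))
                img, mask = render_nucleus_image(mean, noise_sd=2.0, rng=rng)
                ratios.append(nuclear_ratio(img, mask, 100.0))
            vals[cond] = np.mean(ratios)
        assert abs(percent_increase(vals["mobile"], vals["immobile"]) - 50.0) < 15.0


def test_percent_increase_definition():
    assert percent_increase(1.6, 1.0) == pytest.approx(60.0)
    with pytest.raises(ValueError):
        percent_increase(1.0, 0.0)


def test_heatmap_png_written(tmp_path):
    from sptcorral.quantify import save_heatmap_png

    series, _ = simulate_recruitment_series(1, 3, 3, 1.6, 0.2, rng_seed=0)
    mat, _ = timelapse_heatmap(series)
    out = tmp_path / "heatmap.png"
    save_heatmap_png(mat, out)
    assert out.stat().st_size > 0
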