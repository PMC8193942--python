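import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazeits import (ImagePanel, PanelConfig, build_image_panel, detect_events,
                     gadf, gasf, gaze_heatmap, mtf, mtf_reduced, paa,
                     remove_blink_samples, rescale_unit)
from gazeits.events import Blink
from gazeits.imaging import DegenerateInputError, normalize_image

from conftest import make_trial


# ---------------------------------------------------------------- oracles
def oracle_gaf(x, kind):
    """Naive double loop through explicit polar angles."""
    phi = np.arccos(np.clip(x, -1, 1))
    n = len(x)
    G = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            G[i, j] = (np.cos(phi[i] + phi[j]) if kind == "gasf"
                       else np.sin(phi[i] - phi[j]))
    return G


def oracle_mtf(x, q):
    """Hand transition counting + double loop."""
    edges = np.unique(np.quantile(x, np.arange(1, q) / q))
    bins = np.searchsorted(edges, x, side="left")
    nb = len(edges) + 1
    W = np.zeros((nb, nb))
    for a, b in zip(bins[:-1], bins[1:]):
        W[a, b] += 1
    for r in range(nb):
        s = W[r].sum()
        W[r] = W[r] / s if s > 0 else 1.0 / nb
    n = len(x)
    M = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            M[i, j] = W[bins[i], bins[j]]
    return M


class TestRescaleAndPaa:
    def test_rescale_examples(self):
        np.testing.assert_allclose(rescale_unit([2, 4, 6]), [-1, 0, 1])
        np.testing.assert_allclose(rescale_unit([5, 5, 5]), [0, 0, 0])
        np.testing.assert_allclose(rescale_unit([0, 1, 3]), [-1, -1 / 3, 1])

    def test_paa_segment_means(self):
        np.testing.assert_allclose(paa([1, 2, 3, 4], 2), [1.5, 3.5])

    def test_paa_identity_and_constants(self):
        x = np.arange(7.0)
        np.testing.assert_array_equal(paa(x, 7), x)
        np.testing.assert_allclose(paa(np.full(10, 2.5), 3), [2.5] * 3)

    def test_paa_fractional_boundaries_preserve_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        for m in (2, 3, 5, 6, 10):  # n divisible by m
            assert paa(x, m).mean() == pytest.approx(x.mean(), abs=1e-9)

    def test_paa_target_too_large_rejected(self):
        with pytest.raises(ValueError):
            paa([1, 2, 3], 4)


class TestGAFExamples:
    def test_gasf_three_point(self):
        np.testing.assert_allclose(
            gasf(np.array([-1.0, 0.0, 1.0])).matrix,
            [[1, 0, -1], [0, -1, 0], [-1, 0, 1]], atol=1e-12)

    def test_gasf_zero_series_is_minus_one(self):
        np.testing.assert_allclose(gasf(np.zeros(5)).matrix, -1.0)

    def test_gadf_three_point(self):
        np.testing.assert_allclose(
            gadf(np.array([-1.0, 0.0, 1.0])).matrix,
            [[0, 1, 0], [-1, 0, 1], [0, -1, 0]], atol=1e-12)

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError):
            gasf(np.array([0.0, 1.5]))


class TestMTFExamples:
    def test_hand_counted_two_bins(self):
        M = mtf(np.array([1.0, 1.0, 2.0, 2.0]), 2).matrix
        np.testing.assert_allclose(
            M, [[.5, .5, .5, .5], [.5, .5, .5, .5],
                [0, 0, 1, 1], [0, 0, 1, 1]])

    def test_constant_series_single_bin(self):
        with pytest.warns(UserWarning):
            M = mtf(np.ones(4), 2).matrix
        np.testing.assert_allclose(M, 1.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            mtf(np.array([1.0]), 2)


def test_transform_oracle_suite():
    """GASF/GADF/MTF match naive double-loop computation within 1e-9 on
    500 random series, and the structural invariants hold on each."""
    rng = np.random.default_rng(123)
    for rep in range(500):
        n = int(rng.integers(4, 65))
        raw = rng.normal(size=n)
        x = rescale_unit(raw)
        G = gasf(x).matrix
        D = gadf(x).matrix
        np.testing.assert_allclose(G, oracle_gaf(x, "gasf"), atol=1e-9)
        np.testing.assert_allclose(D, oracle_gaf(x, "gadf"), atol=1e-9)
        # invariants
        np.testing.assert_allclose(np.diag(G), 2 * x ** 2 - 1, atol=1e-9)
        np.testing.assert_array_equal(G, G.T)
        np.testing.assert_allclose(D, -D.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)
        q = int(rng.integers(2, 9))
        M = mtf(raw, q).matrix
        np.testing.assert_allclose(M, oracle_mtf(raw, q), atol=1e-9)
        assert M.min() >= 0.0 and M.max() <= 1.0


def test_mtf_blur_equals_full_field_patch_average():
    rng = np.random.default_rng(7)
    x = rng.normal(size=96)
    size = 24
    M_full = mtf(x, 8).matrix
    blurred = M_full.reshape(size, 4, size, 4).mean(axis=(1, 3))
    M_fast = mtf_reduced(x, 8, size, "blur-field").matrix
    np.testing.assert_allclose(M_fast, blurred, atol=1e-9)


def test_mtf_paa_series_strategy_differs_but_valid():
    rng = np.random.default_rng(8)
    x = rng.normal(size=200)
    M = mtf_reduced(x, 8, 48, "paa-series").matrix
    assert M.shape == (48, 48)
    assert 0.0 <= M.min() and M.max() <= 1.0


class TestBlinkRemoval:
    def test_sample_count_arithmetic(self):
        ts = np.arange(2500) / 250.0
        series = np.arange(2500.0)
        blinks = [Blink(1.0, 1.06)]  # 15 samples at 250 Hz
        out = remove_blink_samples(series, blinks, ts)
        assert len(out) == 2485

    def test_no_blinks_is_identity(self):
        ts = np.arange(100) / 250.0
        x = np.arange(100.0)
        np.testing.assert_array_equal(remove_blink_samples(x, [], ts), x)

    def test_blink_spanning_trial_is_degenerate(self):
        ts = np.arange(100) / 250.0
        with pytest.raises(DegenerateInputError):
            remove_blink_samples(np.zeros(100), [Blink(0.0, 1.0)], ts)


class TestPanel:
    def test_default_panel_layout(self, small_dataset):
        trial = small_dataset.trials[0]
        blinks = detect_events(trial).blinks
        panel = build_image_panel(trial, blinks)
        stack = panel.stack()
        tiled = panel.tiled()
        assert stack.shape == (12, 48, 48)
        assert tiled.shape == (144, 192)
        assert tiled.min() >= -1.0 and tiled.max() <= 1.0

    def test_tiling_is_a_bijection(self, small_dataset):
        trial = small_dataset.trials[1]
        panel = build_image_panel(trial, detect_events(trial).blinks)
        back = ImagePanel.from_tiled(panel.tiled(), panel.side,
                                     trial_id=panel.trial_id,
                                     condition=panel.condition)
        for key, img in panel.images.items():
            np.testing.assert_array_equal(back.images[key], img)

    def test_pre_deleting_blink_samples_is_equivalent(self):
        rng = np.random.default_rng(3)
        n = 600
        x = rng.normal(0, 1, n).cumsum() * 0.05
        valid = np.ones(n, dtype=bool)
        valid[200:230] = False
        trial = make_trial(x, -x, valid=valid)
        blinks = detect_events(trial).blinks
        assert len(blinks) == 1
        panel_a = build_image_panel(trial, blinks)
        keep = np.ones(n, dtype=bool)
        keep[200:230] = False
        trial_b = make_trial(x[keep], -x[keep])
        panel_b = build_image_panel(trial_b, [])
        for key in panel_a.images:
            np.testing.assert_allclose(panel_a.images[key],
                                       panel_b.images[key], atol=1e-12)

    def test_insufficient_samples_error_names_channel(self):
        trial = make_trial(np.random.default_rng(0).normal(size=30),
                           np.zeros(30))
        with pytest.raises(DegenerateInputError, match="left_x"):
            build_image_panel(trial, [], PanelConfig(image_size=48))

    @pytest.mark.parametrize("size", [12, 24, 36])
    def test_reduced_resolutions(self, size, small_dataset):
        trial = small_dataset.trials[2]
        panel = build_image_panel(trial, detect_events(trial).blinks,
                                  PanelConfig(image_size=size))
        assert panel.stack().shape == (12, size, size)


class TestHeatmap:
    def test_constant_gaze_single_cell(self, constant_gaze_trial):
        img = gaze_heatmap(constant_gaze_trial, grid=48)
        assert (img.matrix == img.matrix.max()).sum() == 1

    def test_two_clusters_two_maxima(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-6, 0.2, 300), rng.normal(6, 0.2, 300)])
        y = np.concatenate([rng.normal(-6, 0.2, 300), rng.normal(6, 0.2, 300)])
        img = gaze_heatmap(make_trial(x, y), grid=24).matrix
        top = np.unravel_index(np.argsort(img, axis=None)[-2:], img.shape)
        cells = set(zip(*top))
        assert len(cells) == 2
        (r0, c0), (r1, c1) = sorted(cells)
        assert abs(r0 - r1) > 5 and abs(c0 - c1) > 5

    def test_degenerate_extent_rejected(self, constant_gaze_trial):
        with pytest.raises(ValueError):
            gaze_heatmap(constant_gaze_trial, extent=((0, 0), (0, 1)))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_normalize_image_bounds(seed):
    rng = np.random.default_rng(seed)
    img = rng.normal(size=(8, 8)) * rng.uniform(0, 10)
    out = normalize_image(img)
    assert out.min() >= -1.0 - 1e-12 and out.max() <= 1.0 + 1e-12
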