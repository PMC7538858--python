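"""Binarization and morphological cleaning against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilstrat.preprocess import (
    IntensityImage,
    PreprocessConfig,
    binarize_channel,
    fill_small_holes,
    make_mask_pair,
    remove_small_components,
)

from _helpers import tiny_params

# ---------------------------------------------------------------------------
# brute-force flood-fill oracles, independent of the scipy-based implementation


def _bf_label(mask, conn8):
    """Pure-python BFS connected-component labeling."""
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    if conn8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                labels[i, j] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
    return labels, nxt


def _bf_remove_small(mask, min_area_um2, px):
    labels, n = _bf_label(mask, conn8=True)
    out = mask.copy()
    for k in range(1, n + 1):
        comp = labels == k
        if comp.sum() * px**2 < min_area_um2:
            out[comp] = False
    return out


def _bf_fill_holes(mask, max_area_um2, px):
    labels, n = _bf_label(~mask, conn8=False)
    out = mask.copy()
    border = set(np.unique(np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])))
    for k in range(1, n + 1):
        if k in border:
            continue
        comp = labels == k
        if comp.sum() * px**2 < max_area_um2:
            out[comp] = True
    return out


# ---------------------------------------------------------------------------


class TestBinarize:
    def test_distinct_values_nearest_rank(self):
        """100 distinct values 1..100 at q=90: exactly the top 10 survive."""
        img = IntensityImage(np.arange(1.0, 101.0).reshape(10, 10), 1.0)
        mask = binarize_channel(img, 90.0)
        assert mask.sum() == 10
        assert (img.pixels[mask] > 90).all()

    def test_constant_image_all_zero_with_warning(self):
        img = IntensityImage(np.full((8, 8), 3.0), 1.0)
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize_channel(img, 90.0)
        assert not mask.any()

    def test_all_zero_image(self):
        with pytest.warns(UserWarning):
            mask = binarize_channel(IntensityImage(np.zeros((5, 5)), 1.0), 90.0)
        assert not mask.any()

    @given(
        n=st.integers(min_value=20, max_value=400),
        q=st.floats(min_value=5.0, max_value=95.0),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_positive_fraction_matches_percentile(self, n, q, seed):
        """For N distinct values, positive fraction = (100-q)/100 within 1/N."""
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(n, dtype=float) + rng.uniform(0, 0.5))
        side = int(np.ceil(np.sqrt(n)))
        img = np.zeros(side * side)
        img[:n] = vals + 1.0  # keep padding zeros distinct-ish below the data
        image = IntensityImage(img.reshape(side, side), 1.0)
        frac = binarize_channel(image, q).sum() / (side * side)
        assert frac == pytest.approx((100 - q) / 100, abs=1 / n + (side * side - n) / (side * side))

    def test_noisy_synthetic_channel_default_q(self):
        """Continuous noise: positive fraction ~= 0.10 +- 0.01 at q=90."""
        rng = np.random.default_rng(0)
        img = IntensityImage(rng.gamma(2.0, 10.0, size=(200, 200)), 1.0)
        frac = binarize_channel(img, 90.0).mean()
        assert abs(frac - 0.10) < 0.01


class TestMorphology:
    def test_empty_mask_unchanged(self):
        m = np.zeros((20, 20), bool)
        assert not remove_small_components(m, 200.0, 0.5).any()
        assert not fill_small_holes(m, 200.0, 0.5).any()

    def test_area_rule_is_strict(self):
        """799 px at 0.5 um/px (199.75 um^2) removed; 800 px (200 um^2) kept."""
        for n_px, kept in [(799, False), (800, True)]:
            m = np.zeros((40, 40), bool)
            m.ravel()[:n_px] = True  # one contiguous raster-order component
            assert m.sum() == n_px
            out = remove_small_components(m, 200.0, 0.5)
            assert out.any() == kept

    def test_two_components_selective_removal(self):
        """900 px survives the 200 um^2 rule at 0.5 um/px; 700 px does not."""
        big = np.zeros((80, 80), bool)
        big[:30, :30] = True
        small = np.zeros_like(big)
        small[50:70, 45:80] = True
        assert big.sum() == 900 and small.sum() == 700
        out = remove_small_components(big | small, 200.0, 0.5)
        assert (out == big).all()

    def test_hole_filling_by_size(self):
        """25 um^2 hole filled; 250 um^2 hole untouched (0.5 um/px)."""
        ring = np.ones((60, 60), bool)
        ring[20:30, 20:30] = False  # 100 px = 25 um^2
        assert fill_small_holes(ring, 200.0, 0.5).all()
        ring2 = np.ones((80, 80), bool)
        ring2[20:45, 20:60] = False  # 1000 px = 250 um^2
        assert (fill_small_holes(ring2, 200.0, 0.5) == ring2).all()

    def test_solid_disc_unchanged(self):
        yy, xx = np.mgrid[:50, :50]
        disc = (yy - 25) ** 2 + (xx - 25) ** 2 <= 15**2
        assert (fill_small_holes(disc, 200.0, 0.5) == disc).all()

    def test_border_touching_background_never_filled(self):
        m = np.ones((30, 30), bool)
        m[0:5, 10:20] = False  # notch open to the border
        assert (fill_small_holes(m, 1e9, 0.5) == m).all()

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            remove_small_components(np.arange(9).reshape(3, 3), 200.0, 0.5)
        with pytest.raises(ValueError, match="binary"):
            fill_small_holes(np.arange(9).reshape(3, 3) * 0.5, 200.0, 0.5)

    def test_idempotence_random_masks(self, rng):
        for _ in range(20):
            m = rng.random((50, 50)) < rng.uniform(0.2, 0.6)
            r1 = remove_small_components(m, 50.0, 1.0)
            assert (remove_small_components(r1, 50.0, 1.0) == r1).all()
            f1 = fill_small_holes(m, 50.0, 1.0)
            assert (fill_small_holes(f1, 50.0, 1.0) == f1).all()

    @pytest.mark.parametrize("trial_block", range(4))
    def test_flood_fill_oracle_equivalence(self, trial_block):
        """Component removal and hole filling match a brute-force BFS oracle
        on random 50x50 masks (>= 200 trials across parametrized blocks)."""
        rng = np.random.default_rng(9000 + trial_block)
        px = 1.0
        for _ in range(50):
            density = rng.uniform(0.1, 0.7)
            m = rng.random((50, 50)) < density
            area = rng.uniform(2.0, 60.0)
            got = remove_small_components(m, area, px)
            want = _bf_remove_small(m, area, px)
            assert (got == want).all()
            got_f = fill_small_holes(m, area, px)
            want_f = _bf_fill_holes(m, area, px)
            assert (got_f == want_f).all()


class TestMaskPair:
    def test_blank_channels_blank_pair(self):
        blank = IntensityImage(np.zeros((64, 64)), 2.0)
        with pytest.warns(UserWarning):
            mp = make_mask_pair(blank, blank)
        assert not mp.panck.any() and not mp.cd8.any()

    def test_shape_mismatch_rejected(self):
        a = IntensityImage(np.zeros((10, 10)), 1.0)
        b = IntensityImage(np.zeros((10, 12)), 1.0)
        with pytest.raises(ValueError, match="shapes"):
            make_mask_pair(a, b)
        c = IntensityImage(np.zeros((10, 10)), 2.0)
        with pytest.raises(ValueError, match="pixel size"):
            make_mask_pair(a, c)

    def test_noiseless_full_infiltration_centers_covered(self):
        """noise_sd=0, p_in=1: the PanCK mask contains every T-cell center."""
        from tilstrat.synthetic import generate_patient

        p = generate_patient(tiny_params(p_in=1.0, noise_sd=0.0, n_tcells=40, seed=7))
        mp = make_mask_pair(p.panck, p.cd8)
        rows = p.tcell_centers[:, 0].astype(int)
        cols = p.tcell_centers[:, 1].astype(int)
        assert mp.panck[rows, cols].all()

    def test_composed_pipeline_idempotent(self):
        """Re-cleaning an already cleaned mask changes nothing."""
        from tilstrat.synthetic import generate_patient

        cfg = PreprocessConfig()
        p = generate_patient(tiny_params(seed=3))
        mp = make_mask_pair(p.panck, p.cd8, cfg)
        px = mp.pixel_size_um
        panck2 = fill_small_holes(
            remove_small_components(mp.panck, cfg.min_component_um2, px),
            cfg.max_hole_um2,
            px,
        )
        cd82 = remove_small_components(mp.cd8, cfg.min_component_um2, px)
        assert (panck2 == mp.panck).all()
        assert (cd82 == mp.cd8).all()
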