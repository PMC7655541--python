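"""CRF limits, morphology oracles, component labeling and size filtering."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from nodulepipe import postprocess as pp


# ---------------------------------------------------------------------------
# CRF
# ---------------------------------------------------------------------------


def _flat_image(h, w, value=80):
    return np.full((h, w, 3), value, dtype=np.uint8)


def test_crf_zero_weights_is_identity():
    rng = np.random.default_rng(0)
    prob = rng.random((24, 24))
    params = pp.CrfParams(appearance_weight=0.0, smoothness_weight=0.0)
    out = pp.crf_refine(prob, _flat_image(24, 24), params)
    assert np.allclose(out, prob, atol=1e-12)


def test_crf_suppresses_isolated_speckle():
    # a single weak-foreground pixel on a uniform background must vanish
    prob = np.full((32, 32), 0.05)
    prob[16, 16] = 0.6
    out = pp.crf_refine(prob, _flat_image(32, 32), pp.CrfParams())
    assert out[16, 16] < 0.5


def test_crf_keeps_confident_coherent_blob():
    prob = np.full((48, 48), 0.05)
    prob[18:30, 18:30] = 0.95
    img = _flat_image(48, 48, 60)
    img[18:30, 18:30] = 200  # blob is also brighter, appearance-coherent
    out = pp.crf_refine(prob, img, pp.CrfParams())
    assert out[20:28, 20:28].min() > 0.5
    assert out[:10, :10].max() < 0.5


def test_crf_uniform_half_stays_half():
    # perfectly ambiguous input with symmetric energies stays ambiguous
    prob = np.full((16, 16), 0.5)
    out = pp.crf_refine(prob, _flat_image(16, 16), pp.CrfParams())
    assert np.allclose(out, 0.5, atol=1e-6)


def test_crf_validates_inputs():
    with pytest.raises(ValueError):
        pp.crf_refine(np.zeros((8, 8)), _flat_image(9, 9), pp.CrfParams())
    with pytest.raises(ValueError):
        pp.CrfParams(n_iterations=0).validate()


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------


def test_closing_fills_width2_annular_gap():
    # a solid core and an outer ring separated by a 2-pixel-wide annular
    # gap: closing with the default radius-2 disk (plus hole filling)
    # yields one solid blob
    h = w = 40
    yy, xx = np.ogrid[:h, :w]
    d2 = (yy - 20) ** 2 + (xx - 20) ** 2
    broken = (d2 <= 6**2) | ((d2 > 8**2) & (d2 <= 10**2))
    solid = d2 <= 10**2
    out = pp.close_and_fill(broken, pp.PostprocessParams())
    assert out[solid].all()
    assert pp.label_components(out, 8).max() == 1


def test_close_and_fill_is_extensive():
    rng = np.random.default_rng(1)
    mask = rng.random((32, 32)) < 0.2
    out = pp.close_and_fill(mask, pp.PostprocessParams())
    assert (out | mask).sum() == out.sum()  # output contains input


def test_binarize_threshold_is_inclusive():
    prob = np.array([[0.49, 0.5, 0.51]])
    out = pp.binarize(prob, pp.PostprocessParams(prob_threshold=0.5))
    assert out.tolist() == [[False, True, True]]


# ---------------------------------------------------------------------------
# Components: flood-fill oracle
# ---------------------------------------------------------------------------


def _flood_fill_count(mask, connectivity):
    """Independent component count via iterative flood fill."""
    mask = mask.copy()
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                 if (di, dj) != (0, 0)]
    count = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                count += 1
                stack = [(i, j)]
                mask[i, j] = False
                while stack:
                    r, c = stack.pop()
                    for di, dj in steps:
                        r2, c2 = r + di, c + dj
                        if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                            mask[r2, c2] = False
                            stack.append((r2, c2))
    return count


def test_label_components_matches_flood_fill_oracle(rng):
    for _ in range(100):
        mask = rng.random((32, 32)) < rng.uniform(0.1, 0.5)
        for conn in (4, 8):
            labels = pp.label_components(mask, conn)
            assert labels.max() == _flood_fill_count(mask, conn)
            # labels partition exactly the foreground
            assert np.array_equal(labels > 0, mask)


def test_connectivity_diagonal_difference():
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, 0] = mask[1, 1] = True  # diagonal touch
    assert pp.label_components(mask, 8).max() == 1
    assert pp.label_components(mask, 4).max() == 2
    with pytest.raises(ValueError):
        pp.label_components(mask, 6)


# ---------------------------------------------------------------------------
# Size filter
# ---------------------------------------------------------------------------


def _mask_with_components(sizes):
    """Horizontal runs of the given pixel counts, one per row stripe."""
    mask = np.zeros((len(sizes) * 3, max(sizes) + 2), dtype=bool)
    for i, s in enumerate(sizes):
        mask[i * 3, 1 : 1 + s] = True
    return mask


def test_size_filter_bounds_are_inclusive():
    mask = _mask_with_components([3, 4, 5, 9, 10, 11])
    labels = pp.label_components(mask, 8)
    params = pp.PostprocessParams(
        min_component_mm2=None, min_component_size=4, max_component_size=10
    )
    out = pp.filter_by_size(labels, params)
    kept = sorted(np.bincount(out.ravel())[1:][np.bincount(out.ravel())[1:] > 0])
    assert kept == [4, 5, 9, 10]  # 3 dropped (< min), 11 dropped (> max)


def test_size_filter_keeps_label_ids():
    mask = _mask_with_components([2, 8])
    labels = pp.label_components(mask, 8)
    params = pp.PostprocessParams(min_component_mm2=None, min_component_size=5)
    out = pp.filter_by_size(labels, params)
    surviving = set(np.unique(out)) - {0}
    assert surviving <= set(np.unique(labels)) - {0}
    assert len(surviving) == 1


def test_mm2_threshold_conversion():
    params = pp.PostprocessParams(min_component_mm2=1.0)
    assert params.pixel_min_size(0.5) == 4  # 1 mm^2 / (0.5 mm)^2
    assert params.pixel_min_size(0.2) == 25
    with pytest.raises(ValueError):
        params.pixel_min_size(None)  # physical threshold needs a scale
    direct = pp.PostprocessParams(min_component_size=7)
    assert direct.pixel_min_size(None) == 7


def test_postprocess_probability_chain():
    # without CRF: threshold + closing/fill of a clean blob is idempotent
    prob = np.zeros((32, 32))
    prob[8:16, 8:16] = 0.9
    img = np.full((32, 32, 3), 100, dtype=np.uint8)
    out = pp.postprocess_probability(prob, img, None, pp.PostprocessParams())
    assert np.array_equal(out, prob >= 0.5)
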