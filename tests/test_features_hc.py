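"""Handcrafted feature bank: counts, invariances, and texture-matrix oracles."""

import itertools

import numpy as np
import pytest

from shellrad import HCConfig, Volume, extract_handcrafted, make_shell_mask
from shellrad.features_hc import feature_names
from shellrad.features_hc._texture import (
    discretize,
    glcm_features,
    glrlm_features,
    glszm_features,
)

_DIRECTIONS = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
]


class TestFeatureCount:
    def test_default_configuration_yields_1688(self, noise_volume, center_voxel):
        m = make_shell_mask(noise_volume, center_voxel, 0.0, 3.0)
        fv = extract_handcrafted(noise_volume, m)
        assert len(fv) == 1688
        assert fv.names == feature_names()
        assert len(set(fv.names)) == 1688

    def test_count_decomposition(self):
        # 14 shape + 93 per variant × 18 variants
        assert HCConfig().n_features == 14 + 93 * 18 == 1688
        assert HCConfig.reduced().n_features == 14 + 93


def test_constant_partition_has_zero_variance_and_range(center_voxel):
    v = Volume(np.full((40, 40, 40), 100.0), np.ones(3), np.zeros(3))
    m = make_shell_mask(v, center_voxel, 0.0, 4.0)
    fv = extract_handcrafted(v, m, HCConfig.reduced())
    assert fv.values["original_firstorder_Variance"] == 0.0
    assert fv.values["original_firstorder_Range"] == 0.0


def test_degenerate_and_anisotropic_inputs_rejected(noise_volume, center_voxel):
    m = make_shell_mask(noise_volume, center_voxel, 0.0, 3.0)
    m_single = make_shell_mask(noise_volume, center_voxel, 0.0, 0.5)
    assert m_single.voxel_count == 1
    with pytest.raises(ValueError, match="degenerate"):
        extract_handcrafted(noise_volume, m_single, HCConfig.reduced())
    aniso = Volume(noise_volume.data, (1, 1, 2), (0, 0, 0))
    with pytest.raises(ValueError, match="isotropic"):
        extract_handcrafted(aniso, m, HCConfig.reduced())


def test_determinism_bitwise(noise_volume, center_voxel):
    m = make_shell_mask(noise_volume, center_voxel, 3.0, 6.0)
    a = extract_handcrafted(noise_volume, m, HCConfig.reduced())
    b = extract_handcrafted(noise_volume, m, HCConfig.reduced())
    assert a.values.equals(b.values)


def test_translation_invariance_whole_voxel_shift(noise_volume, center_voxel):
    """Shifting volume + centroid by whole voxels leaves all features unchanged
    (interior shift, so filter context is identical)."""
    shift = np.array([2, 1, 3])
    m = make_shell_mask(noise_volume, center_voxel, 0.0, 3.0)
    fv = extract_handcrafted(noise_volume, m)
    rolled = Volume(
        np.roll(noise_volume.data, shift, axis=(0, 1, 2)),
        noise_volume.spacing,
        noise_volume.origin,
    )
    m2 = make_shell_mask(rolled, center_voxel + shift, 0.0, 3.0)
    fv2 = extract_handcrafted(rolled, m2)
    assert np.array_equal(fv.values.to_numpy(), fv2.values.to_numpy())


def test_intensity_shift_moves_mean_only(noise_volume, center_voxel):
    m = make_shell_mask(noise_volume, center_voxel, 0.0, 4.0)
    base = extract_handcrafted(noise_volume, m, HCConfig.reduced())
    shifted_vol = Volume(
        noise_volume.data + 50.0, noise_volume.spacing, noise_volume.origin
    )
    shifted = extract_handcrafted(shifted_vol, m, HCConfig.reduced())
    assert shifted.values["original_firstorder_Mean"] == pytest.approx(
        base.values["original_firstorder_Mean"] + 50.0
    )
    shape_cols = [n for n in base.names if "_shape_" in n]
    assert np.allclose(base.values[shape_cols], shifted.values[shape_cols])
    # Discretization is anchored at the region minimum, so the texture
    # matrices on the original image are unaffected by the shift.
    glcm_cols = [n for n in base.names if n.startswith("original_glcm_")]
    assert np.allclose(base.values[glcm_cols], shifted.values[glcm_cols])


# ------------------------------------------------------------------ oracles

def _naive_glcm_joint_entropy(g: np.ndarray) -> float:
    """Hand enumeration of co-occurring pairs, averaged over directions."""
    ng = g.max()
    entropies = []
    for off in _DIRECTIONS:
        counts = np.zeros((ng, ng))
        for idx in itertools.product(*(range(n) for n in g.shape)):
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(not 0 <= n_ < s for n_, s in zip(nb, g.shape)):
                continue
            a, b = g[idx], g[nb]
            if a > 0 and b > 0:
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
        total = counts.sum()
        if total == 0:
            continue
        p = counts / total
        p = p[p > 0]
        entropies.append(float(-np.sum(p * np.log2(p))))
    return float(np.mean(entropies))


def test_glcm_joint_entropy_matches_hand_tally():
    """2×2×2 toy grid with printed intensities vs a brute-force tally."""
    vals = np.array([[[10, 35], [60, 10]], [[35, 35], [60, 85]]], dtype=float)
    g = discretize(vals, 25.0)  # levels 1..4
    out = glcm_features(g, int(g.max()))
    assert out["JointEntropy"] == pytest.approx(_naive_glcm_joint_entropy(g))


def _naive_runs(g: np.ndarray):
    """All (gray, length) runs along every direction, by explicit walking."""
    runs = []
    for off in _DIRECTIONS:
        for idx in itertools.product(*(range(n) for n in g.shape)):
            if g[idx] == 0:
                continue
            prev = tuple(i - o for i, o in zip(idx, off))
            if all(0 <= p < s for p, s in zip(prev, g.shape)) and g[prev] == g[idx]:
                continue  # not a run start
            length = 0
            cur = idx
            while (
                all(0 <= c < s for c, s in zip(cur, g.shape)) and g[cur] == g[idx]
            ):
                length += 1
                cur = tuple(c + o for c, o in zip(cur, off))
            runs.append((off, g[idx], length))
    return runs


def test_glrlm_emphases_match_naive_run_walking():
    rng = np.random.default_rng(5)
    g = rng.integers(0, 4, size=(4, 4, 4)).astype(np.int64)
    n_voxels = int((g > 0).sum())
    out = glrlm_features(g, int(g.max()), n_voxels)
    runs = _naive_runs(g)
    sre, lre, rp = [], [], []
    for off in _DIRECTIONS:
        rs = [(gr, ln) for o, gr, ln in runs if o == off]
        n = len(rs)
        sre.append(sum(1.0 / ln**2 for _, ln in rs) / n)
        lre.append(sum(float(ln**2) for _, ln in rs) / n)
        rp.append(n / n_voxels)
    assert out["ShortRunEmphasis"] == pytest.approx(np.mean(sre))
    assert out["LongRunEmphasis"] == pytest.approx(np.mean(lre))
    assert out["RunPercentage"] == pytest.approx(np.mean(rp))


def _naive_zones(g: np.ndarray):
    """Flood-fill (26-connected) zones per gray level, by explicit BFS."""
    seen = np.zeros(g.shape, dtype=bool)
    zones = []
    for idx in itertools.product(*(range(n) for n in g.shape)):
        if g[idx] == 0 or seen[idx]:
            continue
        level = g[idx]
        queue = [idx]
        seen[idx] = True
        size = 0
        while queue:
            cur = queue.pop()
            size += 1
            for off in itertools.product((-1, 0, 1), repeat=3):
                if off == (0, 0, 0):
                    continue
                nb = tuple(c + o for c, o in zip(cur, off))
                if (
                    all(0 <= n_ < s for n_, s in zip(nb, g.shape))
                    and not seen[nb]
                    and g[nb] == level
                ):
                    seen[nb] = True
                    queue.append(nb)
        zones.append((level, size))
    return zones


def test_glszm_matches_naive_flood_fill():
    rng = np.random.default_rng(11)
    g = rng.integers(0, 3, size=(5, 5, 5)).astype(np.int64)
    n_voxels = int((g > 0).sum())
    out = glszm_features(g, int(g.max()), n_voxels)
    zones = _naive_zones(g)
    n = len(zones)
    assert out["ZonePercentage"] == pytest.approx(n / n_voxels)
    assert out["SmallAreaEmphasis"] == pytest.approx(
        sum(1.0 / s**2 for _, s in zones) / n
    )
    assert out["LargeAreaEmphasis"] == pytest.approx(
        sum(float(s**2) for _, s in zones) / n
    )
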