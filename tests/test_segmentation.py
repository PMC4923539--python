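"""Segmentation operations against independent oracles.

The Otsu threshold is checked against an exhaustive search over all candidate
levels computed directly from raw pixels, and the graph cut against exhaustive
enumeration of all labelings on instances with few free voxels.
"""

import numpy as np
import pytest

from perifem import (
    BACKGROUND,
    IMPLANT,
    TRABECULAR,
    GraphCutParams,
    LabelMap,
    SegmentationSeeds,
    VoxelImage,
    clean_components,
    denoise,
    dice,
    discriminant_threshold,
    graphcut_energy,
    graphcut_refine,
    pseudocolor,
    threshold_segment,
)
from perifem.errors import DegenerateImageError, SeedingError
from perifem.segmentation import _NEIGHBOR_OFFSETS


def vol(arr, voxel=1.0):
    arr = np.asarray(arr)
    return VoxelImage(arr, np.full(3, voxel))


# ---------------------------------------------------------------- denoise


class TestDenoise:
    def test_constant_unchanged(self):
        img = vol(np.full((6, 6, 6), 7.0))
        for method in ("median", "gaussian"):
            assert np.allclose(denoise(img, method).values, 7.0)

    def test_median_removes_impulse(self):
        arr = np.full((7, 7, 7), 5.0)
        arr[3, 3, 3] = 500.0
        out = denoise(vol(arr), "median")
        assert np.all(out.values == 5.0)

    def test_median_reduces_mse(self, rng):
        clean = np.zeros((12, 12, 12))
        clean[4:8] = 100.0
        noisy = clean + rng.normal(0, 10, clean.shape)
        out = denoise(vol(noisy), "median").values
        assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_gaussian_preserves_mean(self, rng):
        arr = rng.uniform(0, 100, (10, 11, 12))
        out = denoise(vol(arr), "gaussian", radius_mm=2.0).values
        assert out.mean() == pytest.approx(arr.mean(), rel=1e-9)


# ------------------------------------------------- discriminant threshold


def otsu_bruteforce_uint8(values: np.ndarray) -> float:
    """Independent oracle: exhaustive search over all integer thresholds,
    maximizing between-class variance from raw pixels; ties -> lower."""
    v = values.ravel().astype(float)
    best_t, best_sb = None, -1.0
    for t in range(int(values.min()), int(values.max())):
        lo = v[v <= t]
        hi = v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / v.size
        sb = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2
        if sb > best_sb + 1e-12:
            best_sb, best_t = sb, t
    return float(best_t)


class TestOtsu:
    def test_two_delta_histogram(self):
        arr = np.array([20.0] * 40 + [100.0] * 60).reshape(10, 10, 1)
        t = discriminant_threshold(vol(arr))
        assert 20.0 <= t < 100.0
        assert np.all(arr[arr <= t] == 20.0) and np.all(arr[arr > t] == 100.0)

    def test_shift_equivariance(self, rng):
        arr = rng.uniform(0, 50, (8, 8, 8))
        t0 = discriminant_threshold(vol(arr))
        t1 = discriminant_threshold(vol(arr + 17.5))
        assert t1 == pytest.approx(t0 + 17.5, abs=1e-9)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mode = seed % 3
        if mode == 0:
            arr = rng.integers(0, 256, (8, 8, 8)).astype(np.uint8)
        elif mode == 1:  # bimodal
            arr = np.where(
                rng.random((8, 8, 8)) < 0.4,
                rng.normal(40, 10, (8, 8, 8)),
                rng.normal(180, 15, (8, 8, 8)),
            ).clip(0, 255).astype(np.uint8)
        else:  # trimodal
            u = rng.random((8, 8, 8))
            arr = np.select(
                [u < 0.3, u < 0.7],
                [rng.normal(30, 8, u.shape), rng.normal(120, 10, u.shape)],
                rng.normal(220, 8, u.shape),
            ).clip(0, 255).astype(np.uint8)
        assert discriminant_threshold(vol(arr)) == otsu_bruteforce_uint8(arr)

    def test_agrees_with_skimage(self, rng):
        from skimage.filters import threshold_otsu

        arr = np.where(
            rng.random((16, 16, 16)) < 0.5,
            rng.normal(50, 5, (16, 16, 16)),
            rng.normal(200, 5, (16, 16, 16)),
        ).clip(0, 255).astype(np.uint8)
        ours = discriminant_threshold(vol(arr))
        theirs = threshold_otsu(arr)
        # conventions differ by <= one level; both must split the modes purely
        assert abs(ours - theirs) <= 1.0

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            discriminant_threshold(vol(np.full((4, 4, 4), 3.0)))


class TestThresholdSegment:
    def test_noiseless_trimodal_recovers_truth(self):
        from perifem import ScannerSpec, simulate_scan
        from test_specimen import two_implant_truth

        _, truth = two_implant_truth()
        img = simulate_scan(truth, ScannerSpec())
        seg = threshold_segment(img)
        assert np.array_equal(seg.labels == IMPLANT, truth.labels == IMPLANT)
        truth_bone = np.isin(truth.labels, (1, 2))
        assert np.array_equal(seg.labels == TRABECULAR, truth_bone)

    def test_no_implant_class_leaves_label3_negligible(self, rng):
        arr = np.where(
            rng.random((16, 16, 16)) < 0.5,
            rng.normal(20, 4, (16, 16, 16)),
            rng.normal(100, 4, (16, 16, 16)),
        )
        seg = threshold_segment(vol(arr))
        assert (seg.labels == IMPLANT).mean() < 0.001

    def test_artifact_lowers_interimplant_recall(self):
        from perifem import ScannerSpec, simulate_scan
        from test_specimen import two_implant_truth

        spec, truth = two_implant_truth()
        img = simulate_scan(
            truth, ScannerSpec(artifact_amplitude=0.6, blur_sigma_mm=0.1, noise_sd=8.0)
        )
        seg = threshold_segment(img, n_classes=3)
        X, _, _ = truth.voxel_centers()
        x = np.broadcast_to(X, truth.dims)
        bone = np.isin(truth.labels, (1, 2))
        xs = [i.axis_entry_point_mm[0] for i in spec.implants]
        got = seg.labels == TRABECULAR

        def recall(region):
            sel = bone & region
            return got[sel].mean()

        r = spec.implants[0].outer_radius_mm
        between = (x > min(xs)) & (x < max(xs))
        distal = (x < min(xs) - r - 0.4) | (x > max(xs) + r + 0.4)
        assert (bone & distal).any()
        assert recall(between) < recall(distal)

    def test_label_set_closure(self, rng):
        arr = rng.uniform(0, 255, (10, 10, 10))
        seg = threshold_segment(vol(arr))
        assert set(np.unique(seg.labels)) <= {BACKGROUND, TRABECULAR, IMPLANT}


class TestPseudocolor:
    def test_constant_image_constant_color(self):
        rgb = pseudocolor(vol(np.full((4, 4, 2), 5.0)))
        assert np.all(rgb == rgb.reshape(-1, 3)[0])

    def test_endpoints_hit_colormap_ends(self):
        import matplotlib as mpl

        arr = np.linspace(0, 1, 8).reshape(2, 2, 2)
        rgb = pseudocolor(vol(arr), "viridis")
        cmap = mpl.colormaps["viridis"]
        assert np.allclose(rgb[0, 0, 0], cmap(0.0)[:3])
        assert np.allclose(rgb[1, 1, 1], cmap(1.0)[:3])

    def test_monotone_luminance_under_gray(self):
        arr = np.linspace(0, 1, 27).reshape(3, 3, 3)
        rgb = pseudocolor(vol(arr), "gray")
        lum = rgb.reshape(-1, 3).mean(axis=1)
        assert np.all(np.diff(lum[np.argsort(arr.ravel())]) >= 0)

    def test_unknown_colormap(self):
        with pytest.raises(ValueError):
            pseudocolor(vol(np.zeros((2, 2, 2))), "no_such_map")


# --------------------------------------------------------------- graph cut


def enumerate_min_energy(image, initial, seeds, params):
    """Oracle: exhaustive, vectorized enumeration over all 2^k labelings of
    the free voxels, with unaries and pairwise terms recomputed from the
    energy definition (independently of the implementation)."""
    dims = image.dims
    vals = image.values.astype(float)
    movable = (initial.labels != IMPLANT).ravel()

    # seeded-histogram unaries with add-one smoothing
    bins = params.histogram_bins
    vmin, vmax = vals.min(), vals.max()
    span = (vmax - vmin) or 1.0
    binned = np.clip(((vals - vmin) / span * bins).astype(int), 0, bins - 1).ravel()
    seed_flat = np.ravel_multi_index(seeds.indices.T, dims)
    D = {}
    for lab in (BACKGROUND, TRABECULAR):
        h = np.bincount(binned[seed_flat[seeds.labels == lab]], minlength=bins) + 1.0
        D[lab] = -np.log(h / h.sum())[binned]

    is_seed = np.zeros(vals.size, dtype=bool)
    is_seed[seed_flat] = True
    seed_label = np.zeros(vals.size, dtype=int)
    seed_label[seed_flat] = seeds.labels
    free = np.flatnonzero(movable & ~is_seed)
    k = free.size
    assert k <= 16
    pos = -np.ones(vals.size, dtype=int)
    pos[free] = np.arange(k)

    # all 2^k bone/background assignments of the free voxels
    bits = (np.arange(2**k)[:, None] >> np.arange(k)) & 1  # (2^k, k)

    energy = np.zeros(2**k)
    energy += bits @ D[TRABECULAR][free] + (1 - bits) @ D[BACKGROUND][free]
    const = float(D[TRABECULAR][seed_flat[seeds.labels == TRABECULAR]].sum())
    const += float(D[BACKGROUND][seed_flat[seeds.labels == BACKGROUND]].sum())

    grid = np.arange(vals.size).reshape(dims)
    lam, inv2s2 = params.lambda_smooth, 1.0 / (2 * params.sigma_edge**2)
    if lam > 0:
        for off in _NEIGHBOR_OFFSETS[params.neighborhood]:
            sl_a = tuple(
                slice(0, dims[a] - abs(off[a])) if off[a] >= 0 else slice(abs(off[a]), dims[a])
                for a in range(3)
            )
            sl_b = tuple(
                slice(abs(off[a]), dims[a]) if off[a] >= 0 else slice(0, dims[a] - abs(off[a]))
                for a in range(3)
            )
            for u, v in zip(grid[sl_a].ravel(), grid[sl_b].ravel()):
                if not (movable[u] and movable[v]):
                    continue
                w = lam * np.exp(-((vals.ravel()[u] - vals.ravel()[v]) ** 2) * inv2s2)
                lu = bits[:, pos[u]] if pos[u] >= 0 else int(seed_label[u] == TRABECULAR)
                lv = bits[:, pos[v]] if pos[v] >= 0 else int(seed_label[v] == TRABECULAR)
                if pos[u] < 0 and pos[v] < 0:
                    const += w * (lu != lv)
                else:
                    energy += w * (lu != lv)
    return float(np.min(energy) + const)


def random_instance(seed):
    rng = np.random.default_rng(seed)
    dims = (3, 3, 2)  # 18 voxels; 2 seeded + up to 2 implant -> <= 16 free
    arr = rng.uniform(0, 100, dims)
    lab = np.zeros(dims, dtype=np.int8)
    n_imp = rng.integers(0, 3)
    flat = rng.choice(arr.size, size=2 + n_imp, replace=False)
    imp_idx = flat[2:]
    lab.ravel()[imp_idx] = IMPLANT
    seeds = SegmentationSeeds(
        np.array(np.unravel_index(flat[:2], dims)).T,
        np.array([TRABECULAR, BACKGROUND]),
    )
    params = GraphCutParams(
        lambda_smooth=float(rng.uniform(0, 3)),
        sigma_edge=float(rng.uniform(5, 50)),
        histogram_bins=8,
        neighborhood=(6, 26)[int(rng.integers(0, 2))],
    )
    initial = LabelMap(lab, np.ones(3))
    return VoxelImage(arr, np.ones(3)), initial, seeds, params


class TestGraphCut:
    def test_lambda_zero_gives_ml_labels(self, rng):
        arr = rng.uniform(0, 100, (4, 4, 4))
        initial = LabelMap(np.zeros((4, 4, 4), dtype=np.int8), np.ones(3))
        seeds = SegmentationSeeds(
            [[0, 0, 0], [3, 3, 3]], [TRABECULAR, BACKGROUND]
        )
        params = GraphCutParams(lambda_smooth=0.0)
        out = graphcut_refine(vol(arr), initial, seeds, params)
        from perifem.segmentation import _seed_histogram_unaries

        D = _seed_histogram_unaries(vol(arr), seeds, params.histogram_bins)
        ml = np.where(D[TRABECULAR] < D[BACKGROUND], TRABECULAR, BACKGROUND)
        ml[0, 0, 0] = TRABECULAR
        ml[3, 3, 3] = BACKGROUND
        free = np.abs(D[TRABECULAR] - D[BACKGROUND]) > 1e-9
        assert np.array_equal(out.labels[free], ml[free])

    def test_all_seeded_returns_seeds(self, rng):
        dims = (3, 3, 3)
        arr = rng.uniform(0, 100, dims)
        idx = np.argwhere(np.ones(dims, dtype=bool))
        labs = rng.choice([BACKGROUND, TRABECULAR], size=idx.shape[0])
        labs[0], labs[1] = TRABECULAR, BACKGROUND  # both classes present
        seeds = SegmentationSeeds(idx, labs)
        initial = LabelMap(np.zeros(dims, dtype=np.int8), np.ones(3))
        out = graphcut_refine(vol(arr), initial, seeds, GraphCutParams())
        assert np.array_equal(out.labels.ravel(), labs)

    @pytest.mark.parametrize("seed", range(100))
    def test_energy_matches_enumeration(self, seed):
        image, initial, seeds, params = random_instance(seed)
        out = graphcut_refine(image, initial, seeds, params)
        e_cut = graphcut_energy(out, image, seeds, params)
        e_min = enumerate_min_energy(image, initial, seeds, params)
        # equal up to integer-capacity quantization of the max-flow backend
        assert e_cut <= e_min + 2e-4

    def test_missing_seed_class_rejected(self, rng):
        arr = rng.uniform(0, 100, (3, 3, 3))
        initial = LabelMap(np.zeros((3, 3, 3), dtype=np.int8), np.ones(3))
        seeds = SegmentationSeeds([[0, 0, 0]], [TRABECULAR])
        with pytest.raises(SeedingError):
            graphcut_refine(vol(arr), initial, seeds, GraphCutParams())

    def test_conflicting_seeds_rejected(self):
        seeds = SegmentationSeeds([[0, 0, 0], [0, 0, 0]], [TRABECULAR, BACKGROUND])
        with pytest.raises(SeedingError):
            seeds.validate_against((2, 2, 2))

    def test_implant_held_fixed(self, rng):
        arr = rng.uniform(0, 100, (4, 4, 4))
        lab = np.zeros((4, 4, 4), dtype=np.int8)
        lab[1:3, 1:3, 1:3] = IMPLANT
        initial = LabelMap(lab, np.ones(3))
        seeds = SegmentationSeeds([[0, 0, 0], [3, 3, 3]], [TRABECULAR, BACKGROUND])
        out = graphcut_refine(vol(arr), initial, seeds, GraphCutParams())
        assert np.array_equal(out.labels == IMPLANT, lab == IMPLANT)


class TestCleanComponents:
    def test_single_component_unchanged(self):
        lab = np.zeros((6, 6, 6), dtype=np.int8)
        lab[0:3] = TRABECULAR  # touches a domain face
        lm = LabelMap(lab, np.ones(3))
        out = clean_components(lm, min_voxels=2)
        assert np.array_equal(out.labels, lab)

    def test_floating_island_removed(self):
        lab = np.zeros((8, 8, 8), dtype=np.int8)
        lab[0] = TRABECULAR
        lab[4, 4, 4] = TRABECULAR  # 1-voxel island
        lm = LabelMap(lab, np.ones(3))
        out = clean_components(lm, min_voxels=2)
        assert out.count(TRABECULAR) == (lab == TRABECULAR).sum() - 1
        assert out.labels[4, 4, 4] == BACKGROUND

    def test_implant_adjacent_bone_kept(self):
        lab = np.zeros((8, 8, 8), dtype=np.int8)
        lab[3:5, 3:5, 3:5] = IMPLANT
        lab[5, 3, 3] = TRABECULAR  # face-adjacent to implant, not to boundary
        lm = LabelMap(lab, np.ones(3))
        out = clean_components(lm, min_voxels=1)
        assert out.labels[5, 3, 3] == TRABECULAR

    def test_noise_field_leaves_anchored_bone_only(self, rng):
        from scipy import ndimage

        lab = (rng.random((10, 10, 10)) < 0.2).astype(np.int8)
        lm = LabelMap(lab, np.ones(3))
        out = clean_components(lm, min_voxels=3)
        bone = out.labels == TRABECULAR
        comp, n = ndimage.label(bone, ndimage.generate_binary_structure(3, 1))
        face = np.zeros(bone.shape, bool)
        for ax in range(3):
            sl = [slice(None)] * 3
            for end in (0, -1):
                sl[ax] = end
                face[tuple(sl)] = True
        for c in range(1, n + 1):
            sel = comp == c
            assert sel.sum() >= 3
            assert (sel & face).any()


def test_dice_helper():
    a = np.zeros((4, 4, 4), bool)
    b = np.zeros((4, 4, 4), bool)
    a[:2] = True
    b[1:3] = True
    assert dice(a, b) == pytest.approx(0.5)
    assert dice(a, a) == 1.0
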