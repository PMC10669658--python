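"""The gene-to-image transform: Fisher scores, binning, LDA placement,
minimal-rectangle alignment, rasterization and rendering."""

import numpy as np
import pytest
from scipy.linalg import eig as generalized_eig
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from expr2img.errors import ConfigError, DegeneracyError
from expr2img.genemap import (
    GeneImageMapper,
    categorize,
    fisher_scores,
    lda_project,
    min_rectangle_align,
    rasterize,
    render_images,
)
from expr2img.ingest import make_pair_subset, merge_and_normalize
from expr2img.simdata import SimConfig, simulate_cohort


# ---------------------------------------------------------------------------
# Fisher scores
# ---------------------------------------------------------------------------

def test_fisher_hand_example():
    X = np.array([[0.0], [2.0], [4.0], [6.0]])
    y = np.array([0, 0, 1, 1])
    # means 1 vs 5, population variances 1 and 1 -> (5-1)^2 / 2 = 8
    np.testing.assert_allclose(fisher_scores(X, y), [8.0], rtol=1e-12)


def test_fisher_zero_for_identical_classes():
    X = np.array([[1.0], [2.0], [1.0], [2.0]])
    y = np.array([0, 0, 1, 1])
    np.testing.assert_allclose(fisher_scores(X, y), [0.0], atol=1e-15)


def test_fisher_degenerate_constant_classes_is_zero_not_nan():
    X = np.full((6, 3), 2.5)
    y = np.array([0, 0, 0, 1, 1, 1])
    assert np.all(fisher_scores(X, y) == 0)


def test_fisher_requires_two_per_class():
    with pytest.raises(ValueError):
        fisher_scores(np.zeros((3, 2)), np.array([0, 1, 1]))


def test_fisher_matches_bruteforce_on_random_matrices(rng):
    for _ in range(20):
        n, g = rng.integers(4, 30), rng.integers(1, 20)
        X = rng.normal(size=(n, g))
        y = np.r_[np.zeros(2), np.ones(2), rng.integers(0, 2, n - 4)].astype(int)
        expected = []
        for j in range(g):  # naive per-gene loop, the independent oracle
            a, b = X[y == 0, j], X[y == 1, j]
            expected.append((b.mean() - a.mean()) ** 2 / (b.var() + a.var() + 1e-12))
        np.testing.assert_allclose(fisher_scores(X, y), expected, atol=1e-10)


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

def test_equal_division_thirty_genes_fifteen_bins(rng):
    cats = categorize(rng.normal(size=30), 15)
    assert np.bincount(cats, minlength=15).tolist() == [2] * 15


def test_uneven_division_is_deterministic(rng):
    scores = rng.normal(size=31)
    cats = categorize(scores, 15)
    sizes = np.bincount(cats, minlength=15)
    # the single larger block goes to the lowest category
    assert sizes.tolist() == [3] + [2] * 14
    np.testing.assert_array_equal(cats, categorize(scores, 15))


def test_tied_scores_fall_back_to_gene_index():
    cats = categorize(np.zeros(10), 5)
    np.testing.assert_array_equal(cats, [0, 0, 1, 1, 2, 2, 3, 3, 4, 4])


def test_categories_are_rank_monotone(rng):
    scores = rng.normal(size=47)
    for k in (7, 9, 11, 13, 15, 17):
        cats = categorize(scores, k)
        order = np.argsort(scores, kind="stable")
        assert np.all(np.diff(cats[order]) >= 0)
        assert np.ptp(np.bincount(cats, minlength=k)) <= 1


def test_too_few_genes_for_categories():
    with pytest.raises(ConfigError):
        categorize(np.arange(5.0), 6)


# ---------------------------------------------------------------------------
# LDA projection of genes
# ---------------------------------------------------------------------------

def _clustered_genes(rng, n_per=10, sep=10.0, noise=0.1, n_features=5):
    """Three gene clusters separated along feature 0."""
    F, cats = [], []
    for c in range(3):
        F.append(rng.normal(scale=noise, size=(n_per, n_features)) + np.eye(1, n_features, 0) * sep * c)
        cats += [c] * n_per
    return np.vstack(F), np.array(cats)


def test_lda_axis_tracks_separating_feature(rng):
    F, cats = _clustered_genes(rng)
    coords = lda_project(F, cats)
    r = np.corrcoef(coords[:, 0], F[:, 0])[0, 1]
    assert abs(r) > 0.99
    assert coords.shape == (len(F), 2)


def test_lda_translation_invariance(rng):
    F, cats = _clustered_genes(rng)
    np.testing.assert_allclose(lda_project(F, cats), lda_project(F + 7.3, cats), atol=1e-8)


def test_lda_matches_generalized_eigendecomposition_oracle(rng):
    """Independent oracle: scipy's generalized eigensolver on the scatter
    matrices, compared up to per-axis sign/scale."""
    for _ in range(5):
        F, cats = _clustered_genes(rng, n_per=12, sep=4.0, noise=0.5, n_features=4)
        coords = lda_project(F, cats)
        # oracle: direct generalized eigenproblem Sb v = w Sw v
        mu = F.mean(0)
        Sw = sum((F[cats == c] - F[cats == c].mean(0)).T @ (F[cats == c] - F[cats == c].mean(0)) for c in range(3))
        Sb = sum((cats == c).sum() * np.outer(F[cats == c].mean(0) - mu, F[cats == c].mean(0) - mu) for c in range(3))
        w, v = generalized_eig(Sb, Sw)
        order = np.argsort(w.real)[::-1]
        oracle = (F - mu) @ v[:, order[:2]].real
        for axis in range(2):
            c = np.corrcoef(coords[:, axis], oracle[:, axis])[0, 1]
            assert abs(c) > 1 - 1e-6


def test_lda_agrees_with_sklearn_on_well_conditioned_data(rng):
    F, cats = _clustered_genes(rng, n_per=15, sep=6.0, noise=0.4, n_features=4)
    ours = lda_project(F, cats)
    ref = LinearDiscriminantAnalysis(solver="eigen").fit(F, cats).transform(F)[:, :2]
    for axis in range(2):
        c = np.corrcoef(ours[:, axis], ref[:, axis])[0, 1]
        assert abs(c) > 1 - 1e-6


def test_lda_needs_three_categories(rng):
    F = rng.normal(size=(10, 3))
    with pytest.raises(ConfigError):
        lda_project(F, np.array([0] * 5 + [1] * 5))


def test_lda_rejects_identical_genes():
    with pytest.raises(DegeneracyError):
        lda_project(np.ones((9, 4)), np.array([0, 0, 0, 1, 1, 1, 2, 2, 2]))


# ---------------------------------------------------------------------------
# minimal enclosing rectangle
# ---------------------------------------------------------------------------

def _sweep_min_area(points, step_deg=0.01):
    """Brute-force oracle: scan rotation angles at fixed resolution."""
    best = np.inf
    for deg in np.arange(0.0, 90.0, step_deg):
        t = np.deg2rad(deg)
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        rot = points @ R.T
        span = rot.max(0) - rot.min(0)
        best = min(best, span[0] * span[1])
    return best


def test_axis_aligned_square_unchanged():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    rotated, angle = min_rectangle_align(square)
    assert angle == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(rotated, square, atol=1e-12)


def test_rotated_square_is_restored():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    t = np.deg2rad(45)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    rotated, angle = min_rectangle_align(square @ R.T)
    span = rotated.max(0) - rotated.min(0)
    assert span[0] * span[1] == pytest.approx(1.0, abs=1e-9)
    assert abs(angle) == pytest.approx(np.pi / 4, abs=1e-9)


def test_min_rectangle_beats_bounding_box_on_random_clouds(rng):
    for _ in range(10):
        pts = rng.normal(size=(rng.integers(5, 40), 2)) @ rng.normal(size=(2, 2))
        rotated, _ = min_rectangle_align(pts)
        span = rotated.max(0) - rotated.min(0)
        area = span[0] * span[1]
        aabb = np.prod(pts.max(0) - pts.min(0))
        assert area <= aabb + 1e-9
        assert area <= _sweep_min_area(pts, step_deg=0.05) * (1 + 1e-4) + 1e-12


def test_collinear_points_degenerate():
    with pytest.raises(DegeneracyError):
        min_rectangle_align(np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float))


# ---------------------------------------------------------------------------
# rasterization + rendering
# ---------------------------------------------------------------------------

def test_corner_points_map_one_per_pixel():
    pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
    gm = rasterize(pts, (2, 2))
    assert sorted(map(tuple, gm.pixel_of_gene.tolist())) == [(0, 0), (0, 1), (1, 0), (1, 1)]
    assert all(len(v) == 1 for v in gm.genes_of_pixel.values())


def test_coincident_points_share_pixel():
    pts = np.array([[0, 0], [0, 0], [1, 1], [0.5, 0.5]], dtype=float)
    gm = rasterize(pts, (3, 3))
    pix = gm.genes_of_pixel
    assert pix[tuple(gm.pixel_of_gene[0])] == [0, 1]


def test_occupancy_non_increasing_with_resolution(rng):
    pts = rng.uniform(size=(100, 2))
    occupied = [len(rasterize(pts, (r, r)).genes_of_pixel) for r in (50, 20, 10, 5)]
    assert occupied == sorted(occupied, reverse=True)


def test_zero_range_axis_rejected():
    with pytest.raises(DegeneracyError):
        rasterize(np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]]), (4, 4))


def test_half_up_rounding_is_frozen():
    # x = 0.5 in pixel units rounds up, not to even
    pts = np.array([[0.0, 0.0], [0.5, 0.0], [1.0, 1.0]])
    gm = rasterize(pts, (3, 3))
    assert tuple(gm.pixel_of_gene[1]) == (0, 1)


def test_render_averages_colliding_genes():
    pts = np.array([[0, 0], [0, 0], [1, 1]], dtype=float)
    gm = rasterize(pts, (2, 2))
    imgs = render_images(np.array([[0.2, 0.4, 0.9]]), gm)
    r, c = gm.pixel_of_gene[0]
    assert imgs[0, r, c] == pytest.approx(0.3)  # mean of 0.2 and 0.4
    r1, c1 = gm.pixel_of_gene[2]
    assert imgs[0, r1, c1] == pytest.approx(0.9)  # singleton pixel is exact


def test_render_conservation_against_bruteforce(rng):
    pts = rng.uniform(size=(40, 2))
    gm = rasterize(pts, (6, 6))
    X = rng.uniform(size=(3, 40))
    imgs = render_images(X, gm)
    for s in range(3):
        expected = np.zeros((6, 6))
        for (r, c), genes in gm.genes_of_pixel.items():
            expected[r, c] = X[s, genes].mean()
        np.testing.assert_allclose(imgs[s], expected, atol=1e-12)
    # unoccupied pixels are exactly zero
    occupied = np.zeros((6, 6), dtype=bool)
    for (r, c) in gm.genes_of_pixel:
        occupied[r, c] = True
    assert np.all(imgs[:, ~occupied] == 0)


def test_render_dimension_mismatch():
    gm = rasterize(np.array([[0, 0], [1, 0], [0, 1]], dtype=float), (2, 2))
    with pytest.raises(ValueError):
        render_images(np.zeros((2, 5)), gm)


# ---------------------------------------------------------------------------
# full mapper
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cohort_subset():
    cfg = SimConfig(
        n_datasets=2, samples_per_class_per_dataset=25, n_genes=90,
        n_informative=10, effect_size=1.5, classes=("AD", "MCI", "NC"), seed=17,
    )
    return merge_and_normalize(simulate_cohort(cfg))


def test_full_map_is_deterministic(cohort_subset):
    sub = make_pair_subset(cohort_subset, "AD_vs_NC")
    maps = []
    for _ in range(2):
        m = GeneImageMapper(n_categories=5, resolution=(10, 10))
        m.fit(sub.X, sub.binary_labels, sample_ids=sub.sample_ids)
        maps.append(m.map_)
    assert maps[0].pixel_of_gene.tobytes() == maps[1].pixel_of_gene.tobytes()
    assert maps[0].coords_2d.tobytes() == maps[1].coords_2d.tobytes()
    assert maps[0].fitted_on == sub.sample_ids


def test_maps_are_task_specific(cohort_subset):
    pix = {}
    for task in ("AD_vs_NC", "AD_vs_MCI"):
        sub = make_pair_subset(cohort_subset, task)
        m = GeneImageMapper(n_categories=5, resolution=(10, 10))
        m.fit(sub.X, sub.binary_labels, sample_ids=sub.sample_ids)
        pix[task] = m.map_.pixel_of_gene
    assert not np.array_equal(pix["AD_vs_NC"], pix["AD_vs_MCI"])


def test_map_json_round_trip(cohort_subset, tmp_path):
    from expr2img.genemap import GeneMap

    sub = make_pair_subset(cohort_subset, "AD_vs_NC")
    m = GeneImageMapper(n_categories=5, resolution=(10, 10))
    m.fit(sub.X, sub.binary_labels, sample_ids=sub.sample_ids)
    m.map_.to_json(tmp_path / "map.json", probe_ids=cohort_subset.probe_ids)
    back, ids = GeneMap.from_json(tmp_path / "map.json")
    assert ids == cohort_subset.probe_ids
    np.testing.assert_array_equal(back.pixel_of_gene, m.map_.pixel_of_gene)
    assert back.resolution == m.map_.resolution
    assert back.fitted_on == m.map_.fitted_on
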