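"""Phantom generator: determinism, geometry, class structure, texture knobs."""

import numpy as np
import pytest

import petromics as pm
from petromics.features import extract_all, glcm, glcm_features, quantize


def test_identical_spec_and_seed_is_bit_identical():
    spec = pm.PhantomSpec(n_slices=7, in_plane_extent=(30, 26), seed=7)
    a = pm.generate_tumor(spec)
    b = pm.generate_tumor(spec)
    assert np.array_equal(a.values, b.values)


def test_volume_is_nonnegative_with_positive_uptake_per_slice(small_volume):
    assert np.all(small_volume.values >= 0)
    for j in range(small_volume.n_slices):
        assert small_volume.axial_slice(j).max() > 0


def test_background_stays_below_delineation_threshold(small_volume):
    # every slice: the 40% rule must cleanly separate lesion from background
    for j in range(small_volume.n_slices):
        sl = small_volume.axial_slice(j)
        mask = sl >= 0.4 * sl.max()
        assert mask.any()
        border = np.concatenate([sl[0, :], sl[-1, :], sl[:, 0], sl[:, -1]])
        assert border.max() < 0.4 * sl.max()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"base_uptake": 0.0},
        {"base_uptake": -1.0},
        {"n_slices": 3},
        {"n_slices": 40},
        {"in_plane_extent": (10, 10)},
        {"in_plane_extent": (120, 80)},
    ],
)
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(ValueError):
        pm.PhantomSpec(**kwargs)


def test_extent_override_flag_allows_out_of_cohort_geometry():
    spec = pm.PhantomSpec(n_slices=3, in_plane_extent=(10, 10), allow_any_extent=True)
    vol = pm.generate_tumor(spec)
    assert vol.values.shape == (10, 10, 3)


def test_heterogeneity_raises_quantized_glcm_contrast():
    """Zero heterogeneity leaves only the smooth envelope, so neighboring
    voxels sit in nearby gray levels; the multiplicative texture at
    heterogeneity 1 drives up the co-occurrence contrast. (Entropy is *not*
    a monotone readout here: the heavy-tailed texture concentrates the
    equal-width bins, so contrast is the discriminating statistic.)"""

    def glcm_contrast(h):
        spec = pm.PhantomSpec(
            n_slices=6, in_plane_extent=(30, 28), heterogeneity=h, seed=5
        )
        roi = pm.delineate(pm.generate_tumor(spec))
        return glcm_features(glcm(quantize(roi)))["glcm_contrast"]

    assert glcm_contrast(0.0) < glcm_contrast(1.0)


def test_heterogeneity_monotone_in_roi_variance():
    """Paired over seeds, higher heterogeneity increases first-order variance
    of the normalized ROI uptake."""
    wins = 0
    n_seeds = 20
    for seed in range(n_seeds):
        out = []
        for h in (0.3, 1.2):
            spec = pm.PhantomSpec(
                n_slices=6, in_plane_extent=(30, 28), heterogeneity=h, seed=seed
            )
            roi = pm.delineate(pm.generate_tumor(spec))
            v = roi.masked_values()
            out.append((v / v.max()).var())
        wins += out[1] > out[0]
    assert wins >= 18  # strict increase in all but at most 2 of 20 pairs


def test_cohort_default_imbalance_matches_study():
    vols = pm.generate_cohort(seed=3)
    labels = np.array([v.label for v in vols])
    assert len(vols) == 107
    assert (labels == 1).sum() == 38
    assert (labels == 0).sum() == 69


def test_cohort_balanced_counts_and_reproducibility():
    a = pm.generate_cohort(n_per_class=10, seed=1)
    b = pm.generate_cohort(n_per_class=10, seed=1)
    assert len(a) == 20
    assert sum(v.label == 1 for v in a) == 10
    assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))


def test_cohort_identical_class_distributions_warns():
    dist = pm.PhantomDistribution(class_label=1, heterogeneity=(0.5, 0.5))
    dist0 = pm.PhantomDistribution(class_label=0, heterogeneity=(0.5, 0.5))
    with pytest.warns(UserWarning, match="indistinguishable"):
        pm.generate_cohort(n_per_class=1, responder_dist=dist, nonresponder_dist=dist0)


def test_every_cohort_volume_segments_to_full_roi():
    vols = pm.generate_cohort(n_per_class=5, seed=9)
    for vol in vols:
        roi = pm.delineate(vol)
        assert roi.n_slices == vol.n_slices
        assert all(m.any() for m in roi.masks)


def test_full_descriptor_runs_on_phantom_roi(small_roi):
    fv = extract_all(small_roi)
    assert len(fv) == 103
    assert np.all(np.isfinite(fv.values))


def test_cohort_slice_counts_span_cohort_range():
    vols = pm.generate_cohort(counts=(60, 60), seed=2)
    ns = np.array([v.n_slices for v in vols])
    assert ns.min() >= 4 and ns.max() <= 32
    # skewed-low distribution: typical tumor has ~10 slices
    assert 8 <= np.median(ns) <= 14


def test_slice_shuffle_preserves_slice_multiset():
    """The shuffled variant permutes axial order only: the multiset of
    slices (hence every per-slice and whole-tumor statistic) is identical
    to the coherent volume's."""
    base = pm.PhantomSpec(
        n_slices=8, in_plane_extent=(30, 28), heterogeneity=1.0,
        axial_correlation_length=40.0, seed=17,
    )
    coherent = pm.generate_tumor(base)
    shuffled = pm.generate_tumor(
        pm.PhantomSpec(**{**base.__dict__, "shuffle_slices": True})
    )
    key = lambda vol: sorted(
        vol.values[:, :, j].tobytes() for j in range(vol.n_slices)
    )
    assert key(coherent) == key(shuffled)
    assert not np.array_equal(coherent.values, shuffled.values)


def test_write_cohort_roundtrip(tmp_path):
    vols = pm.generate_cohort(n_per_class=2, seed=5)
    manifest = pm.phantom.write_cohort(vols, tmp_path, compress=False)
    assert manifest.exists()
    reloaded = pm.load_volume(tmp_path / f"{vols[0].subject_id}.nii", label=vols[0].label)
    np.testing.assert_allclose(reloaded.values, vols[0].values, rtol=1e-6)
    assert reloaded.spacing == pytest.approx(vols[0].spacing)
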