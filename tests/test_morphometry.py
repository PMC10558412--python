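"""Nuclear morphometry: segmentation, shape statistics, profiles, foci."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.special import ellipe

from nucleomech.core import Image2D
from nucleomech.morphometry import (
    LaminProfileClassifier,
    analyze_nuclei,
    area_fold_change,
    circularity,
    classify_profile,
    count_foci,
    extract_profile,
    mean_profile,
    nuclear_area,
    osmotic_classify,
    segment_nuclei,
)
from nucleomech.synthetic import make_nucleus_image


def _disk(r=50, pad=10):
    n = 2 * (r + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = r + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= r**2


class TestSegmentation:
    def test_disjoint_nuclei_found(self):
        channels, truth = make_nucleus_image(n_nuclei=5, seed=3)
        mask = segment_nuclei(channels["DAPI"])
        assert mask.n_objects == 5

    def test_blank_image_empty_mask(self):
        img = Image2D(np.zeros((64, 64)), 0.1, "DAPI")
        assert segment_nuclei(img).n_objects == 0

    def test_touching_ellipses_split_with_high_iou(self):
        yy, xx = np.mgrid[0:200, 0:300].astype(float)
        m1 = ((yy - 100) / 40) ** 2 + ((xx - 100) / 45) ** 2 <= 1
        m2 = ((yy - 100) / 40) ** 2 + ((xx - 188) / 45) ** 2 <= 1
        img = Image2D((m1 | m2).astype(float), 0.1, "DAPI")
        merged = segment_nuclei(img, split_touching=False)
        assert merged.n_objects == 1
        split = segment_nuclei(img, split_touching=True)
        assert split.n_objects == 2
        for truth_mask in (m1, m2):
            iou = max(
                (truth_mask & (split.labels == l)).sum()
                / (truth_mask | (split.labels == l)).sum()
                for l in (1, 2)
            )
            assert iou > 0.9

    def test_segmentation_matches_truth_masks(self):
        channels, truth = make_nucleus_image(n_nuclei=3, noise_sd=0.05, seed=9)
        mask = segment_nuclei(channels["DAPI"])
        assert mask.n_objects == 3
        for lab in (1, 2, 3):
            tm = truth.true_masks.labels == lab
            iou = max(
                (tm & (mask.labels == l)).sum() / (tm | (mask.labels == l)).sum()
                for l in range(1, 4)
            )
            assert iou > 0.9


class TestAreaAndShape:
    def test_area_arithmetic(self):
        region = np.zeros((20, 20), bool)
        region[:10, :10] = True  # 100 px
        assert nuclear_area(region, 0.5) == pytest.approx(25.0)

    def test_area_of_rasterized_disk(self):
        assert nuclear_area(_disk(50), 0.1) == pytest.approx(np.pi * 25, rel=0.02)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            nuclear_area(np.zeros((5, 5), bool), 0.1)

    def test_area_scales_exactly_with_pixel_size_squared(self):
        region = _disk(40)
        assert nuclear_area(region, 0.2) == pytest.approx(4 * nuclear_area(region, 0.1))

    def test_circularity_circle_limit(self):
        assert circularity(_disk(50)) == pytest.approx(1.0, abs=0.02)

    def test_circularity_square_analytic(self):
        sq = np.zeros((201, 201), bool)
        sq[50:150, 50:150] = True
        assert circularity(sq) == pytest.approx(np.pi / 4, abs=0.02)

    def test_circularity_ellipse_vs_elliptic_integral_oracle(self):
        yy, xx = np.mgrid[0:201, 0:201]
        ell = ((yy - 100) / 40.0) ** 2 + ((xx - 100) / 80.0) ** 2 <= 1
        # oracle: perimeter of a 2:1 ellipse via the complete elliptic integral
        a, b = 80.0, 40.0
        perimeter = 4 * a * ellipe(1 - (b / a) ** 2)
        oracle = 4 * np.pi * (np.pi * a * b) / perimeter**2
        assert circularity(ell) == pytest.approx(oracle, abs=0.02)

    def test_circularity_rotation_invariance(self):
        yy, xx = np.mgrid[0:201, 0:201]
        ell = ((yy - 100) / 40.0) ** 2 + ((xx - 100) / 80.0) ** 2 <= 1
        assert circularity(np.rot90(ell)) == pytest.approx(circularity(ell), rel=1e-12)
        rot30 = ndimage.rotate(ell.astype(float), 30, reshape=True, order=1) > 0.5
        assert circularity(rot30) == pytest.approx(circularity(ell), rel=0.03)


class TestFoldChangeAndOsmotic:
    @pytest.mark.parametrize(
        "pre,post,expected", [(40, 100, 2.5), (50, 50, 1.0), (100, 70, 0.7)]
    )
    def test_fold_change(self, pre, post, expected):
        assert area_fold_change(pre, post) == pytest.approx(expected)

    def test_fold_change_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            area_fold_change(0.0, 10.0)

    @pytest.mark.parametrize(
        "pre,post,expected",
        [(100, 85, "shrunk"), (100, 160, "swollen"), (100, 105, "unchanged")],
    )
    def test_osmotic_classification(self, pre, post, expected):
        assert osmotic_classify(pre, post) == expected


class TestProfiles:
    def test_peripheral_profile_end_peaks(self):
        channels, truth = make_nucleus_image(n_nuclei=1, lamin_mode="peripheral", seed=4)
        region = truth.true_masks.labels == 1
        prof = extract_profile(channels["laminB1"], region)
        assert len(prof) == 101
        assert prof.max() == pytest.approx(1.0)
        outer = int(0.2 * 101)
        assert max(prof[:outer]) > 0.8 and max(prof[-outer:]) > 0.8
        assert np.mean(prof[30:70]) < 0.3

    def test_uniform_disk_profile_flat_interior(self):
        region = _disk(40)
        img = Image2D(region.astype(float), 0.1, "x")
        prof = extract_profile(img, region)
        interior = prof[20:81]
        assert interior.max() <= 1.05 * interior.mean()

    def test_profile_endpoints_on_boundary(self):
        channels, truth = make_nucleus_image(n_nuclei=1, seed=4)
        region = truth.true_masks.labels == 1
        prof = extract_profile(channels["DAPI"], region)
        # endpoints sit on the mask boundary: DAPI is 1 inside, 0 outside
        assert prof[0] > 0.3 and prof[-1] > 0.3

    def test_empty_region_rejected(self):
        img = Image2D(np.zeros((32, 32)), 0.1, "x")
        with pytest.raises(ValueError):
            extract_profile(img, np.zeros((32, 32), bool))

    def test_mean_profile_identical_and_mirror(self):
        p = np.linspace(0, 1, 101)
        mean, sd = mean_profile([p, p, p])
        np.testing.assert_allclose(mean, p)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)
        mean2, _ = mean_profile([p, p[::-1]])
        np.testing.assert_allclose(mean2, mean2[::-1])

    def test_mean_profile_matches_noiseless_truth(self):
        profs = []
        for seed in range(8):
            ch, tr = make_nucleus_image(n_nuclei=1, lamin_mode="peripheral",
                                        noise_sd=0.05, seed=seed)
            profs.append(extract_profile(ch["laminB1"], tr.true_masks.labels == 1))
        mean, sd = mean_profile(profs)
        outer = int(0.2 * 101)
        assert max(mean[:outer]) > 0.6
        assert np.mean(mean[35:65]) < 0.4


class TestClassifyProfile:
    def test_flat_profile_aberrant_score_one(self):
        label, peaks, score = classify_profile(np.full(101, 0.5))
        assert label == "aberrant"
        assert score == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["peripheral", "aberrant"])
    def test_generator_classes_recovered(self, mode):
        hits = 0
        for seed in range(10):
            ch, tr = make_nucleus_image(n_nuclei=1, lamin_mode=mode, noise_sd=0.0,
                                        seed=seed)
            prof = extract_profile(ch["laminB1"], tr.true_masks.labels == 1)
            label, peaks, score = classify_profile(prof)
            hits += label == mode
            if mode == "peripheral":
                assert peaks == 2
        assert hits == 10

    def test_classifier_estimator_api(self):
        profs = []
        want = []
        for seed in range(6):
            mode = "peripheral" if seed % 2 else "aberrant"
            ch, tr = make_nucleus_image(n_nuclei=1, lamin_mode=mode, seed=seed)
            profs.append(extract_profile(ch["laminB1"], tr.true_masks.labels == 1))
            want.append(mode)
        clf = LaminProfileClassifier()
        got = clf.fit(profs).predict(profs)
        assert list(got) == want
        scores = clf.score_samples(profs)
        assert all(s > 1 for s, w in zip(scores, want) if w == "peripheral")


class TestFoci:
    @pytest.mark.parametrize("n_foci", range(7))
    def test_exact_counts_and_high_rule(self, n_foci):
        channels, truth = make_nucleus_image(
            n_nuclei=1, n_foci=n_foci, noise_sd=0.0, seed=40 + n_foci
        )
        count, high = count_foci(channels["gH2AX"], truth.true_masks.labels == 1)
        assert count == n_foci
        assert high == (n_foci > 2)

    def test_counts_restricted_to_mask(self):
        channels, truth = make_nucleus_image(n_nuclei=2, n_foci=2, noise_sd=0.0, seed=8)
        for lab in (1, 2):
            count, _ = count_foci(channels["gH2AX"], truth.true_masks.labels == lab)
            assert count == 2


def test_analyze_nuclei_full_record():
    channels, truth = make_nucleus_image(
        n_nuclei=3, lamin_mode="peripheral", n_foci=4, noise_sd=0.02, seed=21
    )
    records = analyze_nuclei(channels, condition="control")
    assert len(records) == 3
    for rec, true_area in zip(records, sorted(truth.true_area_um2)):
        assert rec.foci_count == 4 and rec.high_foci
        assert rec.profile_class == "peripheral"
        assert 0 < rec.circularity <= 1.02
    got = sorted(r.area_um2 for r in records)
    want = sorted(truth.true_area_um2)
    np.testing.assert_allclose(got, want, rtol=0.05)
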