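"""Li thresholding against an exhaustive cross-entropy oracle; fiber rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striodens.geometry import ControlSquare, GeometryError
from striodens.image import SectionImage
from striodens.segmentation import (
    DegenerateSectorError,
    apply_fiber_exclusion,
    fiber_threshold,
    li_threshold,
    li_threshold_image,
    segment_sector,
)
from striodens.synthetic import default_effect_model, generate_section, render_section


def cross_entropy(counts, values, threshold):
    """Li & Tam criterion of a split, from first principles.

    ``sum c*v*log(v/mu)`` over each class; ``v = 0`` terms vanish and an
    empty class is inadmissible (+inf).
    """
    counts = np.asarray(counts, float)
    values = np.asarray(values, float)
    lower = values <= threshold
    total = 0.0
    for cls in (lower, ~lower):
        if counts[cls].sum() == 0:
            return math.inf
        mu = np.average(values[cls], weights=counts[cls])
        for c, v in zip(counts[cls], values[cls]):
            if v > 0:
                total += c * v * math.log(v / mu)
    return total


def brute_force_minimum(counts, values):
    """Global minimum of the criterion over every admissible split point."""
    values = np.sort(np.unique(np.asarray(values, float)))
    return min(cross_entropy(counts, values, t) for t in values[:-1])


class TestLiThreshold:
    def test_two_level_histogram(self):
        counts = np.array([50, 50])
        values = np.array([100.0, 200.0])
        t = li_threshold(counts, values)
        assert 100 < t < 200
        assert cross_entropy(counts, values, t) == pytest.approx(
            brute_force_minimum(counts, values)
        )

    def test_bimodal_mixture(self):
        rng = np.random.default_rng(5)
        vals = np.clip(
            np.concatenate([rng.normal(80, 10, 50_000), rng.normal(180, 10, 50_000)]),
            0,
            255,
        ).astype(int)
        t = li_threshold_image(vals)
        assert 110 <= t <= 150
        uniq, counts = np.unique(vals, return_counts=True)
        assert cross_entropy(counts, uniq, t) == pytest.approx(
            brute_force_minimum(counts, uniq)
        )

    def test_constant_histogram_degenerate(self):
        with pytest.raises(DegenerateSectorError):
            li_threshold(np.array([100]), np.array([42.0]))
        with pytest.raises(DegenerateSectorError):
            li_threshold_image(np.full(500, 17))

    @settings(max_examples=220, derandomize=True, deadline=None)
    @given(st.data())
    def test_achieves_global_minimum_on_random_histograms(self, data):
        """Implementation threshold attains the exhaustive criterion minimum
        on arbitrary 8-bit histograms (>= 200 random cases)."""
        n_levels = data.draw(st.integers(2, 40))
        values = np.sort(
            np.asarray(
                data.draw(
                    st.lists(
                        st.integers(0, 255),
                        min_size=n_levels,
                        max_size=n_levels,
                        unique=True,
                    )
                ),
                float,
            )
        )
        counts = np.asarray(
            data.draw(
                st.lists(
                    st.integers(1, 1000), min_size=n_levels, max_size=n_levels
                )
            ),
            float,
        )
        t = li_threshold(counts, values)
        assert values.min() <= t < values.max()
        assert cross_entropy(counts, values, t) == pytest.approx(
            brute_force_minimum(counts, values), abs=1e-7
        )


class TestSegmentSector:
    def test_noise_free_sector_recovers_truth_exactly(self, noise_free_section):
        landmarks, truth, image = noise_free_section
        for hemi in ("left", "right"):
            sector = truth.sector_masks[hemi]["whole"]
            result = segment_sector(image, sector, exclude_below=60)
            result = apply_fiber_exclusion(result, image, 60)
            expected = truth.striosome_mask & sector
            np.testing.assert_array_equal(result.striosome_mask, expected)

    def test_noisy_sector_jaccard(self, noisy_section):
        """sd 5 noise on a 60-gray-level gap: Jaccard >= 0.95 vs truth."""
        landmarks, truth, image = noisy_section
        for hemi in ("left", "right"):
            sector = truth.sector_masks[hemi]["whole"]
            result = segment_sector(image, sector, exclude_below=70)
            truth_strio = truth.striosome_mask & sector
            inter = (result.striosome_mask & truth_strio).sum()
            union = (result.striosome_mask | truth_strio).sum()
            assert inter / union >= 0.95

    def test_forced_null_sector_reports_no_striosomes(self):
        """Caudal WT (gain 0): striosome fraction < 0.02 or undetectable."""
        effects = default_effect_model()
        rng = np.random.default_rng(9)
        _, truth = generate_section("caudal", effects, rng, genotype="WT")
        image = render_section(truth, effects, rng)
        for hemi in ("left", "right"):
            sector = truth.sector_masks[hemi]["whole"]
            result = segment_sector(image, sector, exclude_below=70)
            fraction = result.striosome_mask.sum() / sector.sum()
            assert (not result.detectable) or fraction < 0.02

    def test_partition_preserved(self, noisy_section):
        _, truth, image = noisy_section
        sector = truth.sector_masks["left"]["whole"]
        result = segment_sector(image, sector)
        for thr in (0, 40, 80, 200):
            res = apply_fiber_exclusion(result, image, thr)
            combined = res.striosome_mask | res.matrix_mask | res.excluded_mask
            assert (combined == sector).all()
            assert not (res.striosome_mask & res.matrix_mask).any()
            assert not (res.striosome_mask & res.excluded_mask).any()
            assert not (res.matrix_mask & res.excluded_mask).any()


class TestFiberThreshold:
    def _image_with_squares(self, means, pixel_size=10.0):
        """50 um squares are 5x5 px at 10 um/px; fill to hit exact means."""
        pixels = np.full((60, 60), 150, dtype=np.uint16)
        squares = []
        for i, mean in enumerate(means):
            y0, x0 = 10, 10 + 20 * i
            target_sum = round(mean * 25)
            flat = np.full(25, target_sum // 25, dtype=np.uint16)
            flat[: target_sum % 25] += 1
            pixels[y0 : y0 + 5, x0 : x0 + 5] = flat.reshape(5, 5)
            squares.append(ControlSquare(center=(x0 + 2.5, y0 + 2.5), side_um=50.0))
        return SectionImage(pixels=pixels, pixel_size_um=pixel_size), squares

    def test_truncation_rule(self):
        # square means 40.6 and 41.0 -> combined 40.8 -> threshold 40
        image, squares = self._image_with_squares([40.6, 41.0])
        assert fiber_threshold(image, squares) == 40

    def test_zero_control_squares_exclude_nothing(self):
        image, squares = self._image_with_squares([0.0, 0.0])
        thr = fiber_threshold(image, squares)
        assert thr == 0
        sector = np.zeros(image.shape, dtype=bool)
        sector[30:50, 30:50] = True  # all values 150 >= 1
        result = segment_sector(image, sector, min_separation_sds=0.0)
        res = apply_fiber_exclusion(result, image, thr)
        assert res.excluded_mask.sum() == 0

    def test_square_outside_image_rejected(self):
        image, _ = self._image_with_squares([10.0])
        with pytest.raises(GeometryError, match="outside"):
            fiber_threshold(image, [ControlSquare(center=(59.0, 59.0))])

    def test_exclusion_recovers_fiber_truth(self):
        """Noise-free generator at fiber intensity 30: excluded mask matches
        ground-truth fiber within each sector (Jaccard >= 0.9)."""
        effects = default_effect_model(
            noise_sd=0.0, shading_amplitude=0.0, fiber_intensity=30
        )
        rng = np.random.default_rng(12)
        landmarks, truth = generate_section("rostral", effects, rng)
        image = render_section(truth, effects, rng)
        thr = fiber_threshold(image, landmarks.fiber_control_squares)
        assert thr == 30
        for hemi in ("left", "right"):
            sector = truth.sector_masks[hemi]["whole"]
            result = segment_sector(image, sector, exclude_below=thr)
            res = apply_fiber_exclusion(result, image, thr)
            truth_fiber = truth.fiber_mask & sector
            if truth_fiber.sum() == 0:
                continue
            inter = (res.excluded_mask & truth_fiber).sum()
            union = (res.excluded_mask | truth_fiber).sum()
            assert inter / union >= 0.9

    def test_exclusion_raises_compartment_means(self, noise_free_section):
        """Fiber pixels are dimmer than tissue: excluding them can only
        raise the measured compartment means."""
        _, truth, image = noise_free_section
        sector = truth.sector_masks["left"]["whole"]
        if not (truth.fiber_mask & sector).any():
            pytest.skip("no internal fiber in this realization")
        result = segment_sector(image, sector, exclude_below=60)
        with_excl = apply_fiber_exclusion(result, image, 60)
        mean_without = image.pixels[result.matrix_mask].mean()
        mean_with = image.pixels[with_excl.matrix_mask].mean()
        assert mean_with >= mean_without

    def test_total_exclusion_flagged(self, noise_free_section):
        _, truth, image = noise_free_section
        sector = truth.sector_masks["left"]["whole"]
        result = segment_sector(image, sector)
        res = apply_fiber_exclusion(result, image, int(image.pixels.max()))
        assert res.excluded_mask.sum() == sector.sum()
        from striodens.quantify import measure_region

        record = measure_region(image, res)
        assert not record.valid

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 200), st.integers(0, 200))
    def test_exclusion_monotone(self, noisy_section, t1, t2):
        _, truth, image = noisy_section
        sector = truth.sector_masks["left"]["whole"]
        result = segment_sector(image, sector)
        lo, hi = sorted((t1, t2))
        excl_lo = apply_fiber_exclusion(result, image, lo).excluded_mask
        excl_hi = apply_fiber_exclusion(result, image, hi).excluded_mask
        assert (excl_lo <= excl_hi).all()
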