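"""The recruitment ratio R, positivity classification, and line scans."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from optiquant.errors import InvalidParameterError, NoClusterError, UndefinedRatioError
from optiquant.quantify import (
    CohortField,
    classify_positive,
    compute_ratio,
    line_scan,
    quantify_cohort,
)
from optiquant.segment import CellRoi, ClusterRoi
from optiquant.simulate import FieldImage, SimulationParams, simulate_cohort, simulate_field

from conftest import NOISE_FREE


def _fixture_rois(shape=(64, 64)):
    """A cell ROI and a disjoint single-pixel cluster ROI."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cell = (yy - 32) ** 2 + (xx - 28) ** 2 <= 15**2
    cluster = np.zeros(shape, dtype=bool)
    cluster[32, 46] = True  # atop the cell edge, outside ROI1
    return CellRoi(cell), ClusterRoi(cluster, 1)


def test_constant_image_gives_ratio_one():
    roi1, roi2 = _fixture_rois()
    img = np.full((64, 64), 50.0)
    rec = compute_ratio(img, roi1, roi2)
    assert rec.ratio == pytest.approx(1.0)


def test_twofold_peak_hits_positivity_boundary():
    """Cell mean 71 counts, brightest attachment-site pixel 142 counts -> R = 2."""
    roi1, roi2 = _fixture_rois()
    img = np.zeros((64, 64))
    img[roi1.mask] = 71.0
    img[roi2.mask] = 142.0
    rec = compute_ratio(img, roi1, roi2)
    assert rec.max_roi2 == 142.0
    assert rec.mean_roi1 == 71.0
    assert rec.ratio == 2.0
    assert classify_positive(rec.ratio) is True


def test_roi1_mean_includes_roi2_pixels():
    """ROI2 pixels inside ROI1 contribute to the ROI1 mean (no exclusion rule)."""
    yy, xx = np.ogrid[:64, :64]
    cell = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2
    inner = np.zeros((64, 64), dtype=bool)
    inner[32, 32] = True
    img = np.zeros((64, 64))
    img[cell] = 10.0
    img[32, 32] = 100.0
    rec = compute_ratio(img, CellRoi(cell), ClusterRoi(inner, 1))
    expected_mean = (10.0 * (cell.sum() - 1) + 100.0) / cell.sum()
    assert rec.mean_roi1 == pytest.approx(expected_mean)


@pytest.mark.parametrize("enrichment", [1.0, 2.0, 3.0, 5.0])
def test_ground_truth_rois_recover_enrichment_exactly(enrichment):
    p = SimulationParams(seed=13, enrichment_factor=enrichment, **NOISE_FREE)
    field, truth = simulate_field(p)
    rec = compute_ratio(
        field.channels["poi"], CellRoi(truth.cell_mask), ClusterRoi(truth.cluster_mask, 1)
    )
    assert rec.ratio == pytest.approx(enrichment, rel=1e-12)


@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_ratio_invariant_under_multiplicative_scaling(scale):
    roi1, roi2 = _fixture_rois()
    rng = np.random.default_rng(0)
    img = rng.uniform(10.0, 100.0, size=(64, 64))
    r0 = compute_ratio(img, roi1, roi2).ratio
    r1 = compute_ratio(img * scale, roi1, roi2).ratio
    assert r1 == pytest.approx(r0, rel=1e-9)


def test_additive_offset_attenuates_ratio_toward_one():
    p = SimulationParams(seed=13, **NOISE_FREE)
    field, truth = simulate_field(p)
    roi1, roi2 = CellRoi(truth.cell_mask), ClusterRoi(truth.cluster_mask, 1)
    poi = field.channels["poi"]
    ratios = [compute_ratio(poi + b, roi1, roi2).ratio for b in (0.0, 20.0, 80.0, 400.0)]
    assert all(r > 1 for r in ratios)
    assert ratios == sorted(ratios, reverse=True)  # strictly toward 1
    assert ratios[-1] == pytest.approx(1.0, abs=0.25)


def test_background_subtraction_undoes_additive_offset():
    p = SimulationParams(seed=13, **NOISE_FREE)
    field, truth = simulate_field(p)
    roi1, roi2 = CellRoi(truth.cell_mask), ClusterRoi(truth.cluster_mask, 1)
    poi = field.channels["poi"]
    r0 = compute_ratio(poi, roi1, roi2).ratio
    r1 = compute_ratio(poi + 25.0, roi1, roi2, background_offset=25.0).ratio
    assert r1 == pytest.approx(r0, rel=1e-12)


def test_empty_roi_is_precondition_error():
    roi1, _ = _fixture_rois()
    empty = ClusterRoi(np.zeros((64, 64), dtype=bool), 0)
    with pytest.raises(InvalidParameterError):
        compute_ratio(np.ones((64, 64)), roi1, empty)


def test_zero_mean_cell_is_undefined_ratio():
    roi1, roi2 = _fixture_rois()
    img = np.zeros((64, 64))
    img[roi2.mask] = 5.0
    with pytest.raises(UndefinedRatioError):
        compute_ratio(img, roi1, roi2)


class TestClassifyPositive:
    def test_published_examples(self):
        assert classify_positive(2.84) is True  # recruiting wild-type tail
        assert classify_positive(1.5) is False  # volume-marker negative control
        assert classify_positive(1.8) is False  # talin-binding-deficient mutant

    def test_boundary_inclusive_by_default(self):
        assert classify_positive(2.0) is True
        assert classify_positive(2.0, strict=True) is False

    @given(
        r1=st.floats(min_value=0.01, max_value=50.0),
        r2=st.floats(min_value=0.01, max_value=50.0),
    )
    def test_monotone(self, r1, r2):
        lo, hi = sorted((r1, r2))
        if classify_positive(lo):
            assert classify_positive(hi)

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_positive(0.0)


class TestLineScan:
    def _field(self, arr):
        return FieldImage(channels={"poi": arr})

    def test_constant_channel_is_flat_ones(self):
        fld = self._field(np.full((32, 32), 9.0))
        prof = line_scan(fld, (5, 5), (25, 25), n_samples=11)
        np.testing.assert_allclose(prof.profiles["poi"], 1.0)

    def test_single_bright_pixel_peaks_at_one(self):
        arr = np.ones((32, 32))
        arr[16, 16] = 100.0
        prof = line_scan(self._field(arr), (16, 0), (16, 31), n_samples=32)
        assert prof.profiles["poi"].max() == pytest.approx(1.0)
        assert int(np.argmax(prof.profiles["poi"])) == 16

    def test_all_zero_channel_reported_as_zero(self):
        prof = line_scan(self._field(np.zeros((32, 32))), (0, 0), (31, 31))
        np.testing.assert_array_equal(prof.profiles["poi"], 0.0)

    def test_out_of_bounds_endpoint_rejected(self):
        with pytest.raises(InvalidParameterError):
            line_scan(self._field(np.ones((32, 32))), (0, 0), (40, 10))

    def test_poi_and_receptor_peaks_colocalize_through_cluster(self):
        p = SimulationParams(seed=17, **NOISE_FREE)
        field, truth = simulate_field(p)
        com = np.argwhere(truth.cluster_mask).mean(axis=0)
        center = p.resolved_center
        direction = (com - center) / np.linalg.norm(com - center)
        p1 = com + direction * 25.0
        n = 101
        prof = line_scan(field, tuple(center), tuple(p1), n_samples=n)
        poi_peak = int(np.argmax(prof.profiles["poi"]))
        rec_peak = int(np.argmax(prof.profiles["receptor"]))
        assert abs(poi_peak - rec_peak) <= 2


def test_non_enriched_cohort_rarely_scores_positive():
    """With E = 1 (no recruitment) and default noise, at most a small
    minority of cells cross the positivity threshold, as for negative
    controls."""
    cells = simulate_cohort(
        [("ctl", SimulationParams(field_shape=(128, 128), cell_radius=40.0,
                                  enrichment_factor=1.0))],
        30,
        seed=71,
    )
    records, _ = quantify_cohort(
        [CohortField(c.cell_id, c.condition, c.experiment, c.field) for c in cells]
    )
    assert len(records) == 30
    assert np.mean([r.positive for r in records]) <= 0.20


def test_quantify_cohort_counts_and_exclusions():
    cells = simulate_cohort(
        [("wt", SimulationParams(field_shape=(128, 128), cell_radius=40.0))], 5, seed=21
    )
    items = [CohortField(c.cell_id, c.condition, c.experiment, c.field) for c in cells]
    # append a cell whose receptor channel carries no cluster signal
    flat = FieldImage(
        channels={
            "bacteria": np.zeros((128, 128)),
            "receptor": np.full((128, 128), 3.0),
            "poi": items[0].field.channels["poi"].copy(),
        }
    )
    items.append(CohortField("broken", "wt", "exp1", flat))
    records, exclusions = quantify_cohort(items)
    assert len(records) == 5
    assert len(exclusions) == 1
    assert exclusions[0].cell_id == "broken"
    assert exclusions[0].reason == "NoClusterError"
    assert all(r.positive is not None for r in records)
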