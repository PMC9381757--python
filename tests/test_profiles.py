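"""Profile extraction, chromocenter delineation and the PCC statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromoquant import (
    ImageStack,
    delineate_chromocenter,
    extract_profile,
    pcc_enrichment,
    summarize_pcc,
)
from conftest import make_profile

# ----------------------------------------------------------------- oracles


def brute_pearson(x, y):
    """Textbook Pearson formula, no numpy statistics."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def brute_segment(dapi):
    """Independent threshold-crossing scan for the above-mean bell."""
    dapi = list(map(float, dapi))
    thr = sum(dapi) / len(dapi)
    above = [v > thr for v in dapi]
    if not any(above):
        return None
    peak = max(range(len(dapi)), key=lambda i: dapi[i])
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(dapi) - 1 and above[hi + 1]:
        hi += 1
    return lo, hi, thr, peak


# ------------------------------------------------------------- extraction


def test_constant_image_gives_constant_profile(flat_image):
    p = extract_profile(flat_image, center=(20, 20), half_length=1.0)
    assert np.allclose(p.channel("DAPI"), 500.0)
    assert np.allclose(p.channel("marker"), 500.0)
    # sampling grid: symmetric around 0, step = half the pixel pitch
    assert p.positions[0] == -p.positions[-1]
    assert np.allclose(np.diff(p.positions), 0.05)


def test_unknown_channel_rejected(flat_image):
    with pytest.raises(KeyError, match="nonexistent"):
        extract_profile(flat_image, (20, 20), channels=["nonexistent"])


def test_profile_truncated_at_border(flat_image):
    p = extract_profile(flat_image, center=(20, 2), half_length=1.5)
    assert p.truncated
    assert p.positions.min() > -1.5  # samples beyond the border trimmed


def test_noiseless_colocalized_profile_matches_generative_gaussian(noiseless_colocalized):
    """Sampled DAPI values reproduce the generator's Gaussian at the sample
    coordinates, and both channels peak at position 0."""
    spec, image, truth = noiseless_colocalized
    center = truth.centroids_px[0]
    sigma = truth.sigmas_um[0]
    p = extract_profile(image, center, half_length=1.0)
    dapi = p.channel("DAPI")
    marker = p.channel("marker")
    assert abs(p.positions[np.argmax(dapi)]) < 1e-9
    assert abs(p.positions[np.argmax(marker)]) < 1e-9

    # independent evaluation of the generative formula along the line,
    # including neighbouring foci (negligible here but exact)
    amp = spec.nucleoplasm_level * (spec.dapi_focus_contrast - 1)
    cy, cx = truth.centroids_um[0]
    expected = np.full_like(p.positions, spec.nucleoplasm_level)
    for (fy, fx), s in zip(truth.centroids_um, truth.sigmas_um):
        d2 = (cy - fy) ** 2 + (cx + p.positions - fx) ** 2
        expected += amp * np.exp(-d2 / (2 * s**2))
    # bilinear interpolation of a smooth Gaussian on a 0.1 µm grid
    assert np.allclose(dapi, expected, rtol=5e-3)


def test_noiseless_cloudy_profile_bimodal_around_dapi_peak(noiseless_cloudy):
    """Cloudy marker dips at the DAPI maximum: two flanking maxima."""
    spec, image, truth = noiseless_cloudy
    p = extract_profile(image, truth.centroids_px[0], half_length=1.0)
    marker = p.channel("marker")
    c = np.argmax(p.channel("DAPI"))
    left, right = marker[:c], marker[c + 1 :]
    assert marker[c] < left.max()
    assert marker[c] < right.max()
    # matches direct evaluation of the shell formula along the line
    rho = spec.cloudy_shell_position * truth.radii_um[0]
    s_shell = spec.cloudy_ring_width / 2
    cy, cx = truth.centroids_um[0]
    expected = np.full_like(p.positions, spec.marker_baseline)
    amp = spec.nucleoplasm_level * (spec.dapi_focus_contrast - 1)
    for (fy, fx), r in zip(truth.centroids_um, truth.radii_um):
        d = np.sqrt((cy - fy) ** 2 + (cx + p.positions - fx) ** 2)
        expected += spec.marker_gain * amp * np.exp(
            -((d - spec.cloudy_shell_position * r) ** 2) / (2 * s_shell**2)
        )
    # bilinear interpolation carries O(f'' h^2) error on the 0.1 µm grid and
    # cannot represent the cone apex of the radial shell at the centroid, so
    # samples within one pixel pitch of position 0 are excluded here (the
    # bimodality asserts above already cover the centre)
    away = np.abs(p.positions) > 0.1
    assert np.allclose(marker[away], expected[away], rtol=2e-2, atol=30.0)


def test_3d_profile_sampled_on_single_plane():
    arr = np.zeros((5, 40, 40))
    arr[2] = 100.0  # only plane 2 carries signal
    img = ImageStack({"DAPI": arr}, voxel_size=(0.5, 0.1, 0.1))
    p = extract_profile(img, center=(2, 20, 20), half_length=0.5)
    assert p.source_plane == 2
    assert np.allclose(p.channel("DAPI"), 100.0)


# ------------------------------------------------------------ delineation


def test_flat_profile_has_no_chromocenter():
    p = make_profile([5.0] * 9)
    assert delineate_chromocenter(p) is None


def test_hand_evaluated_bell_segment():
    # mean = 25/9; strictly-above run containing the max is indices 3..5
    p = make_profile([1, 1, 1, 5, 9, 5, 1, 1, 1])
    seg = delineate_chromocenter(p)
    assert (seg.start_index, seg.end_index, seg.peak_index) == (3, 5, 4)
    assert seg.threshold == pytest.approx(25 / 9)


def test_secondary_runs_ignored_and_counted():
    p = make_profile([1, 6, 1, 1, 5, 9, 5, 1, 6, 1])
    seg = delineate_chromocenter(p)
    assert (seg.start_index, seg.end_index) == (4, 6)
    assert seg.n_ignored_runs == 2


@settings(deadline=None, max_examples=200)
@given(
    amp=st.floats(1.0, 100.0),
    sigma=st.floats(0.5, 4.0),
    base=st.floats(0.0, 50.0),
    n=st.integers(15, 80),
    noise_seed=st.integers(0, 10_000),
)
def test_delineation_matches_threshold_scan_oracle(amp, sigma, base, n, noise_seed):
    """Random noisy bell-on-baseline profiles: bounds equal the oracle's."""
    rng = np.random.default_rng(noise_seed)
    x = np.arange(n, dtype=float)
    dapi = base + amp * np.exp(-((x - n / 2) ** 2) / (2 * sigma**2))
    dapi += rng.normal(0, amp / 20, size=n)
    p = make_profile(dapi)
    seg = delineate_chromocenter(p)
    oracle = brute_segment(dapi)
    if oracle is None:
        assert seg is None
    else:
        assert (seg.start_index, seg.end_index, seg.peak_index) == (
            oracle[0], oracle[1], oracle[3],
        )
        assert seg.threshold == pytest.approx(oracle[2])


def test_segment_halfwidth_tracks_gaussian_mean_crossing(noiseless_colocalized):
    """The delineated half-width sits within one sample spacing of the
    radius where the generative Gaussian crosses the profile mean."""
    spec, image, truth = noiseless_colocalized
    for center, s in zip(truth.centroids_px, truth.sigmas_um):
        p = extract_profile(image, center, half_length=2.0)
        seg = delineate_chromocenter(p)
        dapi = p.channel("DAPI")
        # brute-force scan of the sampled profile for the mean crossing
        thr = dapi.mean()
        amp_at_peak = dapi.max() - spec.nucleoplasm_level
        if thr <= spec.nucleoplasm_level or amp_at_peak <= 0:
            continue
        r_cross = s * np.sqrt(2 * np.log(amp_at_peak / (thr - spec.nucleoplasm_level)))
        step = p.positions[1] - p.positions[0]
        half_width = (seg.end_index - seg.start_index) / 2 * step
        assert abs(half_width - r_cross) <= step + 1e-9


# -------------------------------------------------------------------- PCC


def test_pcc_affine_marker_is_one():
    dapi = np.array([2.0, 4, 8, 4, 2, 1, 1, 1, 1])
    p = make_profile(dapi, 2 * dapi + 10)
    seg = delineate_chromocenter(p)
    rec = pcc_enrichment(p, seg, "marker")
    assert rec.pcc == pytest.approx(1.0, abs=1e-12)


def test_pcc_anticorrelated_marker_is_minus_one():
    dapi = np.array([2.0, 4, 8, 4, 2, 1, 1, 1, 1])
    p = make_profile(dapi, -dapi)
    seg = delineate_chromocenter(p)
    rec = pcc_enrichment(p, seg, "marker")
    assert rec.pcc == pytest.approx(-1.0, abs=1e-12)


def test_pcc_equals_brute_force_pearson():
    dapi = [2.0, 4, 8, 4, 2]
    marker = [1.0, 2, 3, 2, 1]
    # pad with low baseline so the above-mean run is exactly the bell
    p = make_profile(dapi + [0.1] * 10, marker + [0.0] * 10)
    seg = delineate_chromocenter(p)
    assert (seg.start_index, seg.end_index) == (0, 4)
    rec = pcc_enrichment(p, seg, "marker")
    assert rec.pcc == pytest.approx(brute_pearson(dapi, marker), abs=1e-12)


def test_zero_variance_marker_is_undefined_not_zero():
    dapi = np.array([1.0, 1, 5, 9, 5, 1, 1])
    p = make_profile(dapi, np.full(7, 3.0))
    seg = delineate_chromocenter(p)
    rec = pcc_enrichment(p, seg, "marker")
    assert rec.undefined
    assert np.isnan(rec.pcc)


def test_short_segment_rejected():
    p = make_profile([1.0, 1, 1, 9, 1, 1, 1], [1.0] * 7)
    seg = delineate_chromocenter(p)
    assert len(seg) < 3
    with pytest.raises(ValueError, match="at least 3"):
        pcc_enrichment(p, seg, "marker")


@settings(deadline=None, max_examples=100)
@given(
    seed=st.integers(0, 10_000),
    scale_d=st.floats(0.1, 50.0),
    shift_d=st.floats(-100.0, 100.0),
    scale_m=st.floats(0.1, 50.0),
    shift_m=st.floats(-100.0, 100.0),
)
def test_pcc_invariant_under_positive_affine_transforms(seed, scale_d, shift_d, scale_m, shift_m):
    rng = np.random.default_rng(seed)
    n = 21
    x = np.arange(n, dtype=float)
    dapi = 10 + 50 * np.exp(-((x - 10) ** 2) / 8) + rng.normal(0, 1, n)
    marker = rng.normal(20, 5, n)
    p0 = make_profile(dapi, marker)
    p1 = make_profile(scale_d * dapi + shift_d, scale_m * marker + shift_m)
    seg0 = delineate_chromocenter(p0)
    seg1 = delineate_chromocenter(p1)
    assert (seg0.start_index, seg0.end_index) == (seg1.start_index, seg1.end_index)
    r0 = pcc_enrichment(p0, seg0, "marker")
    r1 = pcc_enrichment(p1, seg1, "marker")
    assert -1.0 <= r0.pcc <= 1.0
    assert r0.pcc == pytest.approx(r1.pcc, abs=1e-9)


# ---------------------------------------------------------------- summary


def test_summarize_single_and_small_groups():
    from chromoquant import PCCRecord

    records = [PCCRecord(pcc=0.5, marker="H3K27me3", stage="2-cell")]
    summary, long = summarize_pcc(records)
    assert summary.loc[0, "median"] == 0.5
    assert summary.loc[0, "n"] == 1

    records = [PCCRecord(pcc=v, marker="H3K27me3", stage="16-cell") for v in (0.2, 0.4, 0.9)]
    summary, long = summarize_pcc(records)
    assert summary.loc[0, "median"] == pytest.approx(0.4)
    assert len(long) == 3


def test_summarize_excludes_and_counts_undefined():
    from chromoquant import PCCRecord

    records = [
        PCCRecord(pcc=0.3, marker="m", stage="2-cell"),
        PCCRecord(pcc=float("nan"), marker="m", stage="2-cell", undefined=True),
    ]
    summary, long = summarize_pcc(records)
    assert summary.loc[0, "n"] == 1
    assert summary.loc[0, "n_undefined"] == 1
    assert len(long) == 1


def test_metadata_vocabulary_enforced():
    from chromoquant import PCCRecord

    with pytest.raises(ValueError, match="stage"):
        PCCRecord(pcc=0.5, marker="m", stage="nonsense-stage")
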