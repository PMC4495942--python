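"""Polynomial calibration family: anchors, distortion conditions, oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolcal.data import ValidationError
from poolcal.polynomial import (
    METHODS,
    ClusterCentres,
    PolynomialCalibration,
    PolynomialCalibrationResults,
    UncalibratableSNPError,
    calibrate,
    distortion,
    estimate_cluster_centres,
    estimate_k,
    hermite_map,
    homozygous_coefficients,
    homozygous_correct,
    k_correction_direct,
)

CLOSED_FORMS = ("k_correction", "piecewise_linear", "lagrange_ppc")
DISTORTION_METHODS = tuple(m for m in METHODS if m != "none")


def lagrange_direct(f, c: ClusterCentres):
    """Independent oracle: the quadratic through the three anchor points.

    Evaluates the second-order Lagrange interpolant of
    {(f_BB, 0), (f_AB, 1/2), (f_AA, 1)} directly from the basis product
    form, without the homozygous-correction + distortion decomposition.
    """
    term_aa = ((f - c.f_AB) * (f - c.f_BB)) / (
        (c.f_AA - c.f_AB) * (c.f_AA - c.f_BB)
    )
    term_ab = 0.5 * ((f - c.f_AA) * (f - c.f_BB)) / (
        (c.f_AB - c.f_AA) * (c.f_AB - c.f_BB)
    )
    return term_aa + term_ab


def hermite_basis_direct(t, y0, y1):
    """Brute-force zero-derivative cubic Hermite via the four basis cubics."""
    h00 = 2 * t**3 - 3 * t**2 + 1
    h01 = -2 * t**3 + 3 * t**2
    return y0 * h00 + y1 * h01  # zero derivatives kill h10, h11


centre_triples = st.tuples(
    st.floats(0.55, 1.0), st.floats(0.25, 0.75), st.floats(0.0, 0.45)
).filter(lambda t: t[2] + 0.02 < t[1] < t[0] - 0.02)


# ---------------------------------------------------------------------------
# homozygous correction


@pytest.mark.parametrize(
    "f_AA,f_BB,d0,d1",
    [(0.9, 0.1, -0.125, 0.25), (1.0, 0.0, 0.0, 0.0)],
)
def test_homozygous_coefficients_examples(f_AA, f_BB, d0, d1):
    c = ClusterCentres(f_AA=f_AA, f_AB=(f_AA + f_BB) / 2, f_BB=f_BB)
    coeffs = homozygous_coefficients(c)
    assert coeffs.d0 == pytest.approx(d0, abs=1e-12)
    assert coeffs.d1 == pytest.approx(d1, abs=1e-12)


def test_homozygous_correct_pins_anchors(example_centres):
    coeffs = homozygous_coefficients(example_centres)
    assert homozygous_correct(0.6, coeffs) == pytest.approx(0.625, abs=1e-12)
    assert homozygous_correct(example_centres.f_AA, coeffs) == pytest.approx(1.0, abs=1e-12)
    assert homozygous_correct(example_centres.f_BB, coeffs) == pytest.approx(0.0, abs=1e-12)


def test_degenerate_centres_rejected():
    c = ClusterCentres(f_AA=0.5, f_AB=0.5, f_BB=0.5)
    with pytest.raises(UncalibratableSNPError):
        homozygous_coefficients(c)


# ---------------------------------------------------------------------------
# distortion corrections


@pytest.mark.parametrize(
    "method,f1,f1_AB,expected",
    [
        ("lagrange_ppc", 0.625, 0.375, 0.125),
        ("piecewise_linear", 0.2, 0.4, 0.05),
        ("k_correction", 0.75, 0.75, -0.25),  # k = 3, E = -0.25
        ("none", 0.3, 0.3, 0.0),
    ],
)
def test_distortion_examples(method, f1, f1_AB, expected):
    assert distortion(method, f1, f1_AB) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("method", CLOSED_FORMS)
@pytest.mark.parametrize("f1_AB", [0.2, 0.375, 0.5, 0.61, 0.8])
def test_distortion_boundary_conditions(method, f1_AB):
    """D(0) = 0, D(1) = 0 and D at the heterozygous centre equals E."""
    E = 0.5 - f1_AB
    assert distortion(method, 0.0, f1_AB) == pytest.approx(0.0, abs=1e-12)
    assert distortion(method, 1.0, f1_AB) == pytest.approx(0.0, abs=1e-12)
    assert distortion(method, f1_AB, f1_AB) == pytest.approx(E, abs=1e-12)


@pytest.mark.parametrize("method", CLOSED_FORMS)
def test_distortion_vanishes_without_heterozygous_error(method):
    """A perfect heterozygous centre (E = 0) leaves the map untouched."""
    grid = np.linspace(0.0, 1.0, 10_001)
    D = distortion(method, grid, 0.5)
    assert np.max(np.abs(D)) < 1e-12


def test_k_correction_distortion_consistency():
    """At f1 = f1_AB = k/(1+k), the k-correction distortion returns E."""
    for k in np.logspace(-1, 1, 25):
        f1_AB = k / (1 + k)
        E = 0.5 - f1_AB
        assert distortion("k_correction", f1_AB, f1_AB) == pytest.approx(E, abs=1e-12)


def test_distortion_rejects_invalid_centre():
    with pytest.raises(ValidationError):
        distortion("lagrange_ppc", 0.5, 0.0)
    with pytest.raises(ValidationError):
        distortion("lagrange_ppc", 0.5, 1.0)


# ---------------------------------------------------------------------------
# Hermite maps


def test_hermite_piecewise_against_basis_evaluation():
    """The piecewise map matches brute-force Hermite basis evaluation."""
    a = 0.3
    for x in np.linspace(0, 1, 41):
        if x <= a:
            expected = hermite_basis_direct(x / a, 0.0, 0.5)
        else:
            expected = hermite_basis_direct((x - a) / (1 - a), 0.5, 1.0)
        assert hermite_map("piecewise", x, a) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("variant", ["piecewise", "equal_deriv", "equal_domain"])
@pytest.mark.parametrize("a", [0.25, 0.3, 0.5, 0.7])
def test_hermite_anchors_and_midpoint(variant, a):
    assert hermite_map(variant, 0.0, a) == pytest.approx(0.0, abs=1e-12)
    assert hermite_map(variant, 1.0, a) == pytest.approx(1.0, abs=1e-12)
    assert hermite_map(variant, a, a) == pytest.approx(0.5, abs=1e-12)


def test_hermite_piecewise_midpoint_is_mean_of_endpoints():
    # zero-derivative cubic at the segment midpoint = mean of endpoint values
    assert hermite_map("piecewise", 0.15, 0.3) == pytest.approx(0.25, abs=1e-12)


def test_hermite_equal_deriv_unit_slope_at_centre():
    a = 0.35
    eps = 1e-6
    slope = (hermite_map("equal_deriv", a + eps, a) - hermite_map("equal_deriv", a - eps, a)) / (2 * eps)
    assert slope == pytest.approx(1.0, abs=1e-4)


def test_hermite_equal_domain_odd_symmetry():
    a = 0.3
    for dx in np.linspace(0, 0.3, 13):
        up = hermite_map("equal_domain", a + dx, a)
        down = hermite_map("equal_domain", a - dx, a)
        assert up + down == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("variant", ["piecewise", "equal_deriv", "equal_domain"])
@pytest.mark.parametrize("a", [0.15, 0.4, 0.5, 0.8])
def test_hermite_monotone(variant, a):
    grid = np.linspace(0, 1, 2001)
    vals = hermite_map(variant, grid, a)
    assert np.all(np.diff(vals) >= -1e-12)


def test_piecewise_linear_monotone():
    for a in (0.2, 0.45, 0.6, 0.85):
        grid = np.linspace(0, 1, 2001)
        vals = grid + distortion("piecewise_linear", grid, a)
        assert np.all(np.diff(vals) >= -1e-12)


# ---------------------------------------------------------------------------
# full calibration


def test_lagrange_equals_direct_quadratic_example(example_centres):
    assert calibrate("lagrange_ppc", 0.6, example_centres) == pytest.approx(
        lagrange_direct(0.6, example_centres), abs=1e-12
    )
    assert calibrate("lagrange_ppc", 0.6, example_centres) == pytest.approx(0.75, abs=1e-12)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(centre_triples, st.floats(0.0, 1.0))
def test_quadratic_equivalence_property(triple, f):
    """Decomposed Lagrange equals the direct three-point quadratic."""
    c = ClusterCentres(*triple)
    assert calibrate("lagrange_ppc", f, c) == pytest.approx(
        lagrange_direct(f, c), abs=1e-12
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(centre_triples)
def test_anchor_conditions_all_methods(triple):
    """Every distortion method maps the three centres to 0, 1/2, 1."""
    c = ClusterCentres(*triple)
    for method in DISTORTION_METHODS:
        assert calibrate(method, c.f_BB, c) == pytest.approx(0.0, abs=1e-9)
        assert calibrate(method, c.f_AB, c) == pytest.approx(0.5, abs=1e-9)
        assert calibrate(method, c.f_AA, c) == pytest.approx(1.0, abs=1e-9)


def test_identity_limit_closed_forms():
    """Ideal centres (1, 1/2, 0) make the closed-form methods the identity."""
    c = ClusterCentres(f_AA=1.0, f_AB=0.5, f_BB=0.0)
    grid = np.linspace(0, 1, 101)
    for method in ("none",) + CLOSED_FORMS:
        np.testing.assert_allclose(calibrate(method, grid, c), grid, atol=1e-12)


def test_calibrate_clamps_on_request(example_centres):
    raw = calibrate("lagrange_ppc", 1.0, example_centres, clamp=False)
    assert raw > 1.0  # outside the anchor span, the quadratic overshoots
    assert calibrate("lagrange_ppc", 1.0, example_centres, clamp=True) == 1.0


# ---------------------------------------------------------------------------
# k-correction on raw channels


@pytest.mark.parametrize(
    "HA,HB,k,expected",
    [((2, 2), None, 1.0, 0.5), ((3, 1), None, 3.0, 0.5)],
)
def test_k_correction_direct_examples(HA, HB, k, expected):
    h_a, h_b = HA
    assert k_correction_direct(h_a, h_b, k) == pytest.approx(expected)


def test_estimate_k_from_ab_cluster(one_snp_records):
    ab = one_snp_records[one_snp_records["call"] == "AB"]
    assert estimate_k(ab) == pytest.approx(4.0 / 6.0)


def test_k_correction_rejects_nonpositive_k():
    with pytest.raises(ValidationError):
        k_correction_direct(1.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# cluster centres


def test_estimate_cluster_centres(one_snp_records):
    centres = estimate_cluster_centres(one_snp_records)
    assert centres.f_AA == pytest.approx(0.9)
    assert centres.f_AB == pytest.approx(0.4)
    assert centres.f_BB == pytest.approx(0.1)
    assert (centres.n_AA, centres.n_AB, centres.n_BB) == (3, 3, 4)


def test_centres_from_class_means():
    # mean of the class channel responses, then the frequency of the mean
    from poolcal.data import records_to_frame, IntensityRecord

    recs = records_to_frame(
        [
            IntensityRecord("s", "a", 4, 0, "AA"),
            IntensityRecord("s", "b", 2, 0, "AA"),
            IntensityRecord("s", "c", 3, 1, "AB"),
            IntensityRecord("s", "d", 3, 1, "AB"),
            IntensityRecord("s", "e", 0, 1, "BB"),
        ]
    )
    centres = estimate_cluster_centres(recs)
    assert centres.f_AA == 1.0
    assert centres.f_AB == 0.75
    assert centres.f_BB == 0.0


def test_empty_genotype_class_is_uncalibratable(one_snp_records):
    no_bb = one_snp_records[one_snp_records["call"] != "BB"]
    with pytest.raises(UncalibratableSNPError):
        estimate_cluster_centres(no_bb)


# ---------------------------------------------------------------------------
# model object and serialization


def test_model_fit_predict_roundtrip(one_snp_records, tmp_path):
    results = PolynomialCalibration(one_snp_records, method="lagrange_ppc").fit()
    assert results.snp_ids == ("snpX",)
    f = np.array([0.1, 0.4, 0.6, 0.9])
    preds = results.predict(f, "snpX")
    np.testing.assert_allclose(preds, [0.0, 0.5, 0.75, 1.0], atol=1e-12)

    path = tmp_path / "model.json"
    results.to_json(path)
    loaded = PolynomialCalibrationResults.from_json(path)
    np.testing.assert_allclose(loaded.predict(f, "snpX"), preds, atol=1e-15)


def test_uncalibratable_snp_passes_through(one_snp_records):
    flipped = one_snp_records.copy()
    flipped["call"] = flipped["call"].map({"AA": "BB", "BB": "AA", "AB": "AB"})
    results = PolynomialCalibration(flipped, method="lagrange_ppc").fit()
    assert "snpX" in results.uncalibratable
    assert results.predict(0.37, "snpX") == pytest.approx(0.37)
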