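"""Polynomial calibration of pooled allele frequencies.

Every classical calibration of a two-channel genotyping platform maps the
three per-SNP cluster-centre frequencies (f_BB, f_AB, f_AA), measured on
individual samples, onto the ideal allele frequencies (0, 1/2, 1) and
interpolates in between. All of them decompose into the same two steps:

1. a *homozygous correction* — the affine map
   ``f1 = f + d1*f + d0`` with ``d0 = -f_BB/(f_AA - f_BB)`` and
   ``d1 = (1 - (f_AA - f_BB))/(f_AA - f_BB)``, which pins the homozygous
   centres onto 0 and 1; and
2. a method-specific *distortion correction* ``D`` applied additively,
   ``f' = f1 + D(f1)``, which repairs the heterozygous centre while leaving
   the endpoints fixed: D(0) = 0, D(1) = 0, D(f1_AB) = E where
   ``E = 1/2 - f1_AB`` is the residual heterozygous error, and for the
   closed-form methods E = 0 implies D vanishes identically.

The distortion families implemented:

- ``none``            — homozygous correction only;
- ``k_correction``    — differential-PCR-amplification correction via the
                        heterozygous channel ratio k = f1_AB/(1 - f1_AB);
- ``piecewise_linear``— linear interpolation on each side of the
                        heterozygous centre;
- ``lagrange_ppc``    — the unique quadratic through the three anchors
                        (probe-specific-correction style);
- ``hermite_piecewise``, ``hermite_equal_domain``, ``hermite_equal_deriv``
                      — cubic Hermite interpolants (see :func:`hermite_map`).

The Hermite variants are genuine S-curves: they satisfy the three anchor
conditions but not the E = 0 ⟹ D ≡ 0 degeneracy condition, so they reshape
the response even on a SNP whose heterozygous centre is already perfect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data import ValidationError, raw_allele_frequency

__all__ = [
    "METHODS",
    "HERMITE_VARIANTS",
    "ClusterCentres",
    "HomozygousCoefficients",
    "UncalibratableSNPError",
    "estimate_cluster_centres",
    "homozygous_coefficients",
    "homozygous_correct",
    "distortion",
    "hermite_map",
    "calibrate",
    "k_correction_direct",
    "estimate_k",
    "PolynomialCalibration",
    "PolynomialCalibrationResults",
]

#: Closed set of method names; ``none`` first (canonical tie-break order).
METHODS = (
    "none",
    "k_correction",
    "piecewise_linear",
    "lagrange_ppc",
    "hermite_piecewise",
    "hermite_equal_deriv",
    "hermite_equal_domain",
)

HERMITE_VARIANTS = ("piecewise", "equal_deriv", "equal_domain")


class UncalibratableSNPError(ValidationError):
    """A SNP's cluster structure cannot support calibration."""


@dataclass(frozen=True)
class ClusterCentres:
    """Per-SNP anchor frequencies derived from individual genotype clusters.

    ``f_XX`` is the raw allele frequency of the mean (H_A, H_B) response of
    the XX genotype class; ``n_XX`` counts the individuals contributing.
    A calibratable SNP requires the strict ordering f_BB < f_AB < f_AA.
    """

    f_AA: float
    f_AB: float
    f_BB: float
    n_AA: int = 0
    n_AB: int = 0
    n_BB: int = 0

    def validate(self, min_count: int = 1) -> None:
        if not (0.0 <= self.f_BB < self.f_AB < self.f_AA <= 1.0):
            raise UncalibratableSNPError(
                "cluster centres must satisfy 0 <= f_BB < f_AB < f_AA <= 1; "
                f"got ({self.f_AA}, {self.f_AB}, {self.f_BB})"
            )
        counts = (self.n_AA, self.n_AB, self.n_BB)
        if any(n < min_count for n in counts):
            raise UncalibratableSNPError(
                f"genotype class occupancy {counts} below minimum {min_count}"
            )


@dataclass(frozen=True)
class HomozygousCoefficients:
    """Affine coefficients pinning the homozygous centres to 0 and 1."""

    d0: float
    d1: float


def estimate_cluster_centres(records: pd.DataFrame) -> ClusterCentres:
    """Cluster centres of one SNP from called individual records.

    For each genotype class the centre is the raw frequency of the class's
    mean channel response: ``f_XX = mean(H_A) / (mean(H_A) + mean(H_B))``.

    Raises
    ------
    UncalibratableSNPError
        If any genotype class is empty or the centres are not strictly
        ordered f_BB < f_AB < f_AA.
    """
    snps = records["snp_id"].unique()
    if len(snps) != 1:
        raise ValidationError(f"records span {len(snps)} SNPs; expected one")
    if records["is_pool"].any():
        raise ValidationError("cluster centres are estimated from individuals")
    centres: dict[str, float] = {}
    counts: dict[str, int] = {}
    for geno in ("AA", "AB", "BB"):
        cls = records[records["call"] == geno]
        counts[geno] = len(cls)
        if cls.empty:
            raise UncalibratableSNPError(
                f"SNP {snps[0]!r}: no {geno} individuals"
            )
        centres[geno] = raw_allele_frequency(
            cls["H_A"].mean(), cls["H_B"].mean()
        )
    result = ClusterCentres(
        f_AA=centres["AA"], f_AB=centres["AB"], f_BB=centres["BB"],
        n_AA=counts["AA"], n_AB=counts["AB"], n_BB=counts["BB"],
    )
    result.validate()
    return result


def homozygous_coefficients(centres: ClusterCentres) -> HomozygousCoefficients:
    """Coefficients of the homozygous correction for the given centres.

    ``d0 = -f_BB/(f_AA - f_BB)``, ``d1 = (1 - (f_AA - f_BB))/(f_AA - f_BB)``,
    chosen so the corrected frequency hits 1 at f_AA and 0 at f_BB.
    """
    span = centres.f_AA - centres.f_BB
    if span == 0:
        raise UncalibratableSNPError("degenerate SNP: f_AA == f_BB")
    return HomozygousCoefficients(
        d0=-centres.f_BB / span,
        d1=(1.0 - span) / span,
    )


def homozygous_correct(f, coeffs: HomozygousCoefficients):
    """Homozygous-corrected frequency ``f1 = f + d1*f + d0`` (no clamping)."""
    f = np.asarray(f, dtype=float)
    out = f + coeffs.d1 * f + coeffs.d0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Distortion corrections


def _check_f1_ab(f1_AB: float) -> float:
    if not (0.0 < f1_AB < 1.0):
        raise ValidationError(
            f"corrected heterozygous centre must lie in (0, 1); got {f1_AB}"
        )
    return float(f1_AB)


def _d_piecewise_linear(f1: np.ndarray, f1_AB: float, E: float) -> np.ndarray:
    # Branches assigned so that D(0) = D(1) = 0 and D(f1_AB) = E hold
    # exactly; the conventional printed form of this rule swaps them, which
    # breaks the D(1) = 0 endpoint condition. Both branches agree at
    # f1 == f1_AB (value E), so the <= tie convention is immaterial.
    lower = (f1 / f1_AB) * E
    upper = ((1.0 - f1) / (1.0 - f1_AB)) * E
    return np.where(f1 <= f1_AB, lower, upper)


def _d_lagrange(f1: np.ndarray, f1_AB: float, E: float) -> np.ndarray:
    return E * f1 * (1.0 - f1) / (f1_AB * (1.0 - f1_AB))


def _d_k_correction(f1: np.ndarray, f1_AB: float) -> np.ndarray:
    k = f1_AB / (1.0 - f1_AB)  # inverse of f1_AB = k/(1+k)
    denom = f1 * (1.0 - k) + k
    if np.any(denom == 0):
        raise ValidationError("k-correction distortion denominator is zero")
    return f1 * (1.0 - k) * (1.0 - f1) / denom


def distortion(method: str, f1, f1_AB: float):
    """Additive distortion correction D(f1) of the requested method.

    ``f1`` is the homozygous-corrected frequency and ``f1_AB`` the corrected
    heterozygous centre. All methods satisfy D(0) = 0, D(1) = 0 and
    D(f1_AB) = E = 1/2 - f1_AB; the three closed forms additionally vanish
    identically when E = 0. For Hermite variants D = H(f1) - f1 where H is
    the corresponding :func:`hermite_map`.
    """
    f1_AB = _check_f1_ab(f1_AB)
    f1 = np.asarray(f1, dtype=float)
    E = 0.5 - f1_AB
    if method == "none":
        out = np.zeros_like(f1)
    elif method == "piecewise_linear":
        out = _d_piecewise_linear(f1, f1_AB, E)
    elif method == "lagrange_ppc":
        out = _d_lagrange(f1, f1_AB, E)
    elif method == "k_correction":
        out = _d_k_correction(f1, f1_AB)
    elif method.startswith("hermite_"):
        out = hermite_map(method.removeprefix("hermite_"), f1, f1_AB) - f1
    else:
        raise ValueError(f"unknown method {method!r}; one of {METHODS}")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Hermite interpolants


def _cubic_hermite(t, y0, y1, m0, m1, width):
    """Cubic Hermite basis on t in [0,1]; m are derivatives in x units."""
    t2 = t * t
    t3 = t2 * t
    h00 = 2.0 * t3 - 3.0 * t2 + 1.0
    h10 = t3 - 2.0 * t2 + t
    h01 = -2.0 * t3 + 3.0 * t2
    h11 = t3 - t2
    return y0 * h00 + width * m0 * h10 + y1 * h01 + width * m1 * h11


def _smoothstep(t):
    """Zero-derivative cubic Hermite from 0 to 1 on [0, 1]."""
    return t * t * (3.0 - 2.0 * t)


def hermite_map(variant: str, f1, f1_AB: float):
    """Cubic-Hermite calibration map H(f1) through the three anchors.

    variant ``piecewise``
        One zero-derivative cubic segment on [0, f1_AB] from (0, 0) to
        (f1_AB, 1/2) and one on [f1_AB, 1] to (1, 1); derivative zero at
        all three nodes. Outside [0, 1] the map extends by the nearest
        node value.
    variant ``equal_domain``
        With half-width h = min(f1_AB, 1 - f1_AB), a map on
        [f1_AB - h, f1_AB + h] with odd symmetry about (f1_AB, 1/2), built
        from the zero-derivative Hermite segment on the half-domain (the
        symmetric window maps onto the full [0, 1] range); outside the
        window the map continues linearly to the anchors (0, 0) and (1, 1).
    variant ``equal_deriv``
        The equal-domain construction with the derivative at the
        heterozygous centre forced to 1 instead of 0.
    """
    f1_AB = _check_f1_ab(f1_AB)
    x = np.asarray(f1, dtype=float)
    a = f1_AB
    if variant == "piecewise":
        lo = 0.5 * _smoothstep(np.clip(x / a, 0.0, 1.0))
        hi = 0.5 + 0.5 * _smoothstep(np.clip((x - a) / (1.0 - a), 0.0, 1.0))
        out = np.where(x <= a, lo, hi)
    elif variant in ("equal_domain", "equal_deriv"):
        h = min(a, 1.0 - a)
        if variant == "equal_domain":
            upper = 0.5 + 0.5 * _smoothstep(np.clip((x - a) / h, 0.0, 1.0))
        else:
            # derivative 1 at the centre, 0 at the window edge
            t = np.clip((x - a) / h, 0.0, 1.0)
            upper = _cubic_hermite(t, 0.5, 1.0, 1.0, 0.0, h)
        t_low = np.clip((a - x) / h, 0.0, 1.0)
        if variant == "equal_domain":
            lower = 0.5 - 0.5 * _smoothstep(t_low)
        else:
            lower = 1.0 - _cubic_hermite(t_low, 0.5, 1.0, 1.0, 0.0, h)
        out = np.where(x >= a, upper, lower)
        # linear continuation to (0,0) and (1,1): the window already spans
        # the full [0,1] range, so the continuation is flat at the anchors
        out = np.where(x <= a - h, 0.0, out)
        out = np.where(x >= a + h, 1.0, out)
    else:
        raise ValueError(
            f"unknown Hermite variant {variant!r}; one of {HERMITE_VARIANTS}"
        )
    # extend by nearest node value outside [0, 1]
    out = np.where(x <= 0.0, 0.0, out)
    out = np.where(x >= 1.0, 1.0, out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Full calibration


def calibrate(
    method: str,
    f,
    centres: ClusterCentres,
    clamp: bool = False,
):
    """Fully calibrated frequency ``f' = f1 + D(f1)`` for the given centres.

    ``method='none'`` applies the homozygous correction only. With
    ``clamp=True`` the output is clipped to [0, 1] (recommended when
    reporting pool frequencies; leave off inside error decompositions so
    bias and variance reflect the raw mapping).
    """
    centres.validate(min_count=0)
    coeffs = homozygous_coefficients(centres)
    f1 = homozygous_correct(f, coeffs)
    if method == "none":
        out = np.asarray(f1, dtype=float)
    else:
        f1_AB = homozygous_correct(centres.f_AB, coeffs)
        out = np.asarray(f1, dtype=float) + distortion(method, f1, f1_AB)
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def k_correction_direct(H_A, H_B, k: float):
    """k-corrected frequency ``f' = H_A / (H_A + k*H_B)`` from raw channels.

    k is the differential amplification ratio, estimated as the ratio of
    mean channel responses over the heterozygous cluster
    (``k = mean(H_A | AB) / mean(H_B | AB)``); k = 1 means no differential
    amplification.
    """
    if not (k > 0):
        raise ValidationError(f"amplification ratio k must be > 0; got {k}")
    H_A = np.asarray(H_A, dtype=float)
    H_B = np.asarray(H_B, dtype=float)
    total = H_A + k * H_B
    if np.any(total <= 0):
        raise ValidationError("k-corrected frequency undefined: H_A + k*H_B <= 0")
    out = H_A / total
    return float(out) if out.ndim == 0 else out


def estimate_k(ab_records: pd.DataFrame) -> float:
    """Amplification ratio from the heterozygous cluster of one SNP."""
    ab = ab_records[ab_records["call"] == "AB"]
    if ab.empty:
        raise UncalibratableSNPError("no AB individuals to estimate k")
    mean_b = ab["H_B"].mean()
    if mean_b <= 0:
        raise UncalibratableSNPError("mean H_B of AB cluster is zero")
    return float(ab["H_A"].mean() / mean_b)


# ---------------------------------------------------------------------------
# Model / Results objects


@dataclass(frozen=True)
class _SnpCalibrator:
    snp_id: str
    method: str
    centres: ClusterCentres
    coeffs: HomozygousCoefficients
    k: float | None

    def predict(self, f, clamp: bool = True):
        return calibrate(self.method, f, self.centres, clamp=clamp)


class PolynomialCalibration:
    """Per-SNP polynomial calibration model.

    Built from called *individual* intensity records (canonical DataFrame,
    any number of SNPs). ``fit`` estimates each SNP's cluster centres and
    homozygous coefficients; SNPs whose cluster structure violates the
    ordering requirement (or with an empty genotype class) are passed
    through uncalibrated with method ``none`` and reported.

    Parameters
    ----------
    data : DataFrame
        Canonical intensity records of individuals with genotype calls.
    method : str
        One of :data:`METHODS`.
    clamp : bool
        Clip predictions to [0, 1] (default True).
    min_class_count : int
        Minimum individuals per genotype class (default 1).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        method: str = "lagrange_ppc",
        clamp: bool = True,
        min_class_count: int = 1,
    ):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; one of {METHODS}")
        self.data = data
        self.method = method
        self.clamp = clamp
        self.min_class_count = min_class_count

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PolynomialCalibration":
        return cls(data, **kwargs)

    def fit(self) -> "PolynomialCalibrationResults":
        calibrators: dict[str, _SnpCalibrator] = {}
        uncalibratable: dict[str, str] = {}
        for snp_id, grp in self.data.groupby("snp_id", sort=True):
            grp = grp[(~grp["is_pool"]) & (grp["call"] != "NoCall")]
            try:
                centres = estimate_cluster_centres(grp)
                centres.validate(self.min_class_count)
                coeffs = homozygous_coefficients(centres)
                k = estimate_k(grp) if self.method == "k_correction" else None
                calibrators[str(snp_id)] = _SnpCalibrator(
                    str(snp_id), self.method, centres, coeffs, k
                )
            except UncalibratableSNPError as exc:
                uncalibratable[str(snp_id)] = str(exc)
        return PolynomialCalibrationResults(
            self, calibrators, uncalibratable
        )


class PolynomialCalibrationResults:
    """Fitted per-SNP polynomial calibrators."""

    def __init__(
        self,
        model: PolynomialCalibration,
        calibrators: Mapping[str, _SnpCalibrator],
        uncalibratable: Mapping[str, str],
    ):
        self.model = model
        self.calibrators = dict(calibrators)
        self.uncalibratable = dict(uncalibratable)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(self.calibrators)

    def predict(self, f, snp_id: str, clamp: bool | None = None):
        """Calibrate raw frequencies of one SNP."""
        clamp = self.model.clamp if clamp is None else clamp
        snp_id = str(snp_id)
        if snp_id in self.calibrators:
            return self.calibrators[snp_id].predict(f, clamp=clamp)
        if snp_id in self.uncalibratable:
            # pass-through: no calibration possible for this SNP
            out = np.asarray(f, dtype=float)
            if clamp:
                out = np.clip(out, 0.0, 1.0)
            return float(out) if out.ndim == 0 else out
        raise KeyError(f"SNP {snp_id!r} was not in the training data")

    def predict_frame(self, records: pd.DataFrame, clamp: bool | None = None) -> pd.Series:
        """Calibrate a canonical intensity table row-wise; returns f'."""
        f = raw_allele_frequency(
            records["H_A"].to_numpy(), records["H_B"].to_numpy()
        )
        out = np.empty(len(records), dtype=float)
        snp_arr = records["snp_id"].to_numpy()
        for snp_id in pd.unique(snp_arr):
            mask = snp_arr == snp_id
            out[mask] = self.predict(np.asarray(f)[mask], str(snp_id), clamp)
        return pd.Series(out, index=records.index, name="f_calibrated")

    def summary(self) -> str:
        lines = [
            f"PolynomialCalibration: method={self.model.method}, "
            f"clamp={self.model.clamp}",
            f"SNPs calibrated: {len(self.calibrators)}; "
            f"uncalibratable (passed through): {len(self.uncalibratable)}",
            "",
            f"{'snp_id':<14}{'f_BB':>8}{'f_AB':>8}{'f_AA':>8}"
            f"{'d0':>9}{'d1':>9}{'k':>8}{'n':>6}",
        ]
        for snp_id, cal in sorted(self.calibrators.items()):
            c = cal.centres
            k = f"{cal.k:.3f}" if cal.k is not None else "-"
            lines.append(
                f"{snp_id:<14}{c.f_BB:>8.3f}{c.f_AB:>8.3f}{c.f_AA:>8.3f}"
                f"{cal.coeffs.d0:>9.4f}{cal.coeffs.d1:>9.4f}{k:>8}"
                f"{c.n_AA + c.n_AB + c.n_BB:>6d}"
            )
        for snp_id, reason in sorted(self.uncalibratable.items()):
            lines.append(f"{snp_id:<14} UNCALIBRATABLE: {reason}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": "poolcal.polynomial",
            "method": self.model.method,
            "clamp": self.model.clamp,
            "snps": [
                {
                    "snp_id": cal.snp_id,
                    "method": cal.method,
                    "f_AA": cal.centres.f_AA,
                    "f_AB": cal.centres.f_AB,
                    "f_BB": cal.centres.f_BB,
                    "n_AA": cal.centres.n_AA,
                    "n_AB": cal.centres.n_AB,
                    "n_BB": cal.centres.n_BB,
                    "d0": cal.coeffs.d0,
                    "d1": cal.coeffs.d1,
                    "k": cal.k,
                }
                for cal in self.calibrators.values()
            ],
            "uncalibratable": self.uncalibratable,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PolynomialCalibrationResults":
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or "\n" not in str(source) and Path(str(source)).exists()
            else str(source)
        )
        payload = json.loads(text)
        if payload.get("kind") != "poolcal.polynomial":
            raise ValidationError("not a serialized polynomial calibration")
        model = PolynomialCalibration(
            data=pd.DataFrame(columns=["snp_id"]),
            method=payload["method"],
            clamp=payload["clamp"],
        )
        calibrators = {}
        for entry in payload["snps"]:
            centres = ClusterCentres(
                f_AA=entry["f_AA"], f_AB=entry["f_AB"], f_BB=entry["f_BB"],
                n_AA=entry["n_AA"], n_AB=entry["n_AB"], n_BB=entry["n_BB"],
            )
            calibrators[entry["snp_id"]] = _SnpCalibrator(
                entry["snp_id"],
                entry["method"],
                centres,
                HomozygousCoefficients(d0=entry["d0"], d1=entry["d1"]),
                entry["k"],
            )
        return cls(model, calibrators, payload.get("uncalibratable", {}))
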