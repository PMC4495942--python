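"""Error metrics and decompositions for calibrated allele frequencies.

The measurement error E of a calibrated frequency splits into a fixed bias
E_B and a zero-mean random part E_N, with MSE = E_B^2 + mean(E_N^2). The
split is estimable only where repeated measurements share the same true
frequency — i.e. on individual samples, stratified by (SNP, genotype
class). Pools have continuously-valued truths, so pool-regime reports carry
MSE only.

Also here: the duplicate-based estimate of the irreducible measurement
variance (sum d^2 / 2m over m duplicate pairs — the within-pair difference
d carries twice the per-measurement variance), the squared standardized
allele-frequency difference Z^2 = (f_a - f_b)^2 / (V_a + V_b) that powers a
pooled association test, and the per-SNP best-method tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .data import ValidationError
from .polynomial import METHODS

__all__ = [
    "ErrorReport",
    "BestMethodReport",
    "mse",
    "bias_variance_decomposition",
    "duplicate_variance",
    "z_statistic",
    "best_method_per_snp",
]


@dataclass(frozen=True)
class ErrorReport:
    """MSE and (when estimable) its bias/variance split.

    ``mse == bias_sq + variance`` exactly (within float tolerance) when all
    three are computed from the same strata; ``bias_sq`` and ``variance``
    are NaN when no stratification is available.
    """

    mse: float
    bias_sq: float
    variance: float
    n: int
    grouping: str

    def summary(self) -> str:
        parts = [f"MSE={self.mse:.6f} (n={self.n}, grouping={self.grouping})"]
        if np.isfinite(self.bias_sq):
            parts.append(
                f"bias^2={self.bias_sq:.6f}, variance={self.variance:.6f}"
            )
        return "; ".join(parts)


def mse(predictions, truths, weights=None) -> ErrorReport:
    """Flat mean squared error over all (prediction, truth) entries."""
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(truths, dtype=float)
    if pred.size == 0:
        raise ValidationError("cannot compute MSE of an empty set")
    if pred.shape != true.shape:
        raise ValidationError("predictions and truths differ in length")
    w = np.ones_like(pred) if weights is None else np.asarray(weights, float)
    total = float(np.sum(w))
    value = float(np.sum(w * (pred - true) ** 2) / total)
    return ErrorReport(
        mse=value, bias_sq=np.nan, variance=np.nan,
        n=int(round(total)), grouping="pooled",
    )


def bias_variance_decomposition(errors, strata) -> ErrorReport:
    """Split signed errors into squared-bias and variance components.

    ``strata`` labels each error with its (SNP, true-frequency-class)
    group — the only grouping in which several measurements share an
    identical truth. Per stratum the bias is the mean error and the
    variance the mean squared deviation from it; the report aggregates
    strata weighted by their entry counts, so that
    ``mse = bias_sq + variance`` holds exactly.
    """
    err = np.asarray(errors, dtype=float)
    if err.size == 0:
        raise ValidationError("no errors to decompose")
    labels = [s if isinstance(s, (str, int, float)) else tuple(s) for s in strata]
    if len(labels) != err.size:
        raise ValidationError("errors and strata differ in length")
    frame = pd.DataFrame({"error": err, "stratum": labels})
    grouped = frame.groupby("stratum")["error"]
    counts = grouped.count()
    means = grouped.mean()
    variances = grouped.var(ddof=0).fillna(0.0)
    n = int(counts.sum())
    bias_sq = float((counts * means**2).sum() / n)
    variance = float((counts * variances).sum() / n)
    return ErrorReport(
        mse=float((err**2).mean()),
        bias_sq=bias_sq,
        variance=variance,
        n=n,
        grouping="(snp, true-frequency class)",
    )


def duplicate_variance(duplicate_pairs) -> float:
    """Irreducible measurement variance from paired repeat measurements.

    ``duplicate_pairs`` is an (m, 2) array-like of repeated frequency
    measurements of the same samples. The within-pair difference d has
    twice the single-measurement variance, so the estimator is
    ``sum(d^2) / (2m)``. Samples measured more than twice contribute only
    their first two replicates (pairs are formed upstream).
    """
    pairs = np.asarray(duplicate_pairs, dtype=float)
    if pairs.size == 0:
        raise ValidationError("no duplicate pairs supplied")
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValidationError("duplicate_pairs must be of shape (m, 2)")
    d = pairs[:, 0] - pairs[:, 1]
    m = pairs.shape[0]
    return float(np.sum(d**2) / (2 * m))


def z_statistic(f_alpha: float, f_beta: float, V_alpha: float, V_beta: float) -> float:
    """Squared standardized allele-frequency difference between two pools.

    ``Z^2 = (f_alpha - f_beta)^2 / (V_alpha + V_beta)`` — the test statistic
    of a two-pool association comparison; calibration raises power by
    shrinking the variance denominators.
    """
    total_var = V_alpha + V_beta
    if total_var <= 0:
        raise ValidationError("total variance must be positive")
    return float((f_alpha - f_beta) ** 2 / total_var)


@dataclass(frozen=True)
class BestMethodReport:
    """Per-method selection percentages and the per-SNP-oracle MSE."""

    selection_pct: pd.Series
    best_method: pd.Series
    oracle_mse: float
    n_snps: int

    def summary(self) -> str:
        lines = [f"Best method per SNP over {self.n_snps} SNPs "
                 f"(oracle MSE {self.oracle_mse:.6f}):"]
        for method, pct in self.selection_pct.items():
            lines.append(f"  {method:<22} {pct:5.1f}%")
        return "\n".join(lines)


def best_method_per_snp(
    mse_table: pd.DataFrame,
    snp_weights: pd.Series | None = None,
) -> BestMethodReport:
    """Select the minimal-MSE method per SNP and tabulate selections.

    ``mse_table`` is indexed by method name with one column per SNP. Ties
    go to the method appearing earlier in the canonical order
    (:data:`poolcal.polynomial.METHODS`, with ``none`` first; methods not
    in that list follow in table order). The oracle MSE applies the winning
    method to each SNP, weighting SNPs by ``snp_weights`` (entry counts)
    when given, else equally.
    """
    if mse_table.empty:
        raise ValidationError("empty MSE table")
    canonical = [m for m in METHODS if m in mse_table.index]
    canonical += [m for m in mse_table.index if m not in canonical]
    table = mse_table.loc[canonical]
    best = table.idxmin(axis=0)  # idxmin takes the first minimum: canonical tie-break
    counts = best.value_counts().reindex(canonical, fill_value=0)
    pct = 100.0 * counts / counts.sum()
    per_snp_min = table.min(axis=0)
    if snp_weights is not None:
        w = snp_weights.reindex(per_snp_min.index)
        oracle = float((per_snp_min * w).sum() / w.sum())
    else:
        oracle = float(per_snp_min.mean())
    return BestMethodReport(
        selection_pct=pct,
        best_method=best,
        oracle_mse=oracle,
        n_snps=table.shape[1],
    )
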