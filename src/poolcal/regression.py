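"""Per-SNP machine-learned calibration and train/test regime construction.

Instead of interpolating between three cluster centres, a regression
calibrator learns the map from raw frequency f to ground-truth frequency f*
directly from (f, f*) training pairs — individuals contribute pairs with
f* in {0, 1/2, 1}, calibration pools contribute pairs at intermediate
frequencies. Three families are supported:

- ``LR``  — weighted least-squares line;
- ``MLP`` — small multilayer perceptron (sigmoid hidden layers, linear
  output, SGD with momentum);
- ``SVR`` — nu-support-vector regression with a Gaussian kernel.

Each SNP is modelled separately. Because real data sets contain far fewer
pool than individual measurements, *combined* (mixed) sets replicate each
pool row an integer number of times until pool rows match individual rows,
so both sources contribute equally to the fitted map and to the error.

Training/testing regimes (individuals / combined / pools) are assembled by
:func:`build_regime_datasets` following a fixed 3x3 cell table; where train
and test draw on the same source, the source's samples are first
partitioned into cross-validation blocks so no measurement (and no
replicate of it) appears on both sides of a fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.svm import NuSVR

from .data import ValidationError

__all__ = [
    "FAMILIES",
    "REGIMES",
    "PAIR_COLUMNS",
    "ModelSpec",
    "RegimeDataset",
    "DegenerateTrainingError",
    "make_training_pairs",
    "combine_sources",
    "build_regime_datasets",
    "fit_calibrator",
    "apply_calibrator",
    "cross_validate",
    "CrossValidationReport",
    "RegressionCalibration",
    "RegressionCalibrationResults",
]

FAMILIES = ("LR", "MLP", "SVR")
REGIMES = ("individuals", "combined", "pools")

#: Canonical columns of a training-pair table.
PAIR_COLUMNS = ("snp_id", "sample_id", "replicate_id", "f", "f_star", "source", "weight")


class DegenerateTrainingError(ValidationError):
    """Training set cannot identify a calibration map."""


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of a regression calibrator family.

    Defaults are the tuned operating point of each family; the searched
    ranges are recorded in :attr:`SEARCH_RANGES` for reference but no
    automated search is performed here.
    """

    family: str = "SVR"
    mlp_layers: int = 2
    mlp_nodes_per_layer: int = 2
    mlp_learning_rate: float = 0.1
    mlp_momentum: float = 0.15
    mlp_epochs: int = 500
    svr_nu: float = 0.092
    svr_C: float = 0.027
    svr_gamma: float | str = "auto"  # Gaussian bandwidth: 1/n_features
    seed: int = 0

    SEARCH_RANGES = {
        "mlp_layers": (1, 3),
        "mlp_nodes_per_layer": (1, 6),
        "mlp_learning_rate": (0.01, 1.0),
        "mlp_momentum": (0.01, 1.0),
        "svr_nu": (0.01, 1.0),
        "svr_C": (0.01, 1.0),
    }

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")


@dataclass
class RegimeDataset:
    """One (train, test) cell instance, possibly one fold of many."""

    train_regime: str
    test_regime: str
    fold_index: int | None
    train_pairs: pd.DataFrame
    test_pairs: pd.DataFrame


# ---------------------------------------------------------------------------
# Pair construction


def make_training_pairs(
    records: pd.DataFrame,
    truth: pd.DataFrame,
) -> pd.DataFrame:
    """Join intensity records with ground truth into (f, f*) training pairs.

    ``truth`` has columns (sample_id, snp_id, true_f). Records without a
    matching truth entry (e.g. pool x SNP cells whose ground truth is
    undefined) are dropped.
    """
    from .data import raw_allele_frequency

    df = records.copy()
    df["f"] = raw_allele_frequency(df["H_A"].to_numpy(), df["H_B"].to_numpy())
    merged = df.merge(truth, on=["sample_id", "snp_id"], how="inner")
    merged = merged[np.isfinite(merged["true_f"])]
    pairs = pd.DataFrame(
        {
            "snp_id": merged["snp_id"].astype(str),
            "sample_id": merged["sample_id"].astype(str),
            "replicate_id": merged.get("replicate_id"),
            "f": merged["f"].astype(float),
            "f_star": merged["true_f"].astype(float),
            "source": np.where(merged["is_pool"], "pool", "individual"),
            "weight": 1,
        }
    )
    bad = pairs[(pairs["f_star"] < 0) | (pairs["f_star"] > 1)]
    if len(bad):
        raise ValidationError("ground-truth frequencies must lie in [0, 1]")
    return pairs.reset_index(drop=True)


def combine_sources(
    individual_pairs: pd.DataFrame,
    pool_pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Mix individual and pool pairs with pool rows replicated to balance.

    Each pool row receives an integer weight floor(n_ind/n_pool) or that
    plus one, distributed deterministically so total pool weight equals the
    number of individual rows exactly (when pools are the minority source).
    """
    n_ind = int(individual_pairs["weight"].sum()) if len(individual_pairs) else 0
    n_pool = len(pool_pairs)
    pools = pool_pairs.copy()
    if n_pool and n_ind > n_pool:
        base = n_ind // n_pool
        remainder = n_ind - base * n_pool
        order = np.lexsort(
            (pools["snp_id"].to_numpy(), pools["sample_id"].to_numpy())
        )
        weights = np.full(n_pool, base, dtype=int)
        weights[order[:remainder]] += 1
        pools["weight"] = weights
    out = pd.concat([individual_pairs, pools], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Regime datasets


def _fold_blocks(sample_ids: Sequence[str], n_folds: int, rng: np.random.Generator):
    ids = np.array(sorted(set(map(str, sample_ids))))
    if n_folds > len(ids):
        raise ValidationError(
            f"n_folds={n_folds} exceeds the {len(ids)} available samples"
        )
    rng.shuffle(ids)
    return [set(block) for block in np.array_split(ids, n_folds)]


def build_regime_datasets(
    individuals: pd.DataFrame,
    pools: pd.DataFrame,
    train_regime: str,
    test_regime: str,
    n_folds: int = 10,
    seed: int = 0,
) -> list[RegimeDataset]:
    """Assemble the (train, test) sets of one regime cell.

    ``individuals`` and ``pools`` are training-pair tables
    (:data:`PAIR_COLUMNS`). The cell logic:

    ====================  =========================================
    (train, test)         (training set ; testing set)
    ====================  =========================================
    individuals, individuals   (I_train ; I_test)            folded
    individuals, combined      (I_train ; I_test + P_all)    folded
    individuals, pools         (I_all   ; P_all)             single
    combined,    individuals   (I_train + P_all ; I_test)    folded
    combined,    combined      (C_train ; C_test)            folded
    combined,    pools         (I_all + P_train ; P_test)    folded
    pools,       individuals   (P_all   ; I_all)             single
    pools,       combined      (P_train ; P_test + I_all)    folded
    pools,       pools         (P_train ; P_test)            folded
    ====================  =========================================

    Mixed ("+") sets balance pool against individual rows by replication
    (see :func:`combine_sources`). Folding partitions *sample identifiers*
    (individuals and pools independently) before any replication, so no
    pool measurement can leak across a fold boundary through its copies.
    """
    if train_regime not in REGIMES or test_regime not in REGIMES:
        raise ValueError(f"regimes must be one of {REGIMES}")
    if train_regime != "pools" and individuals.empty:
        raise ValidationError("individuals required for this regime cell")
    if (train_regime != "individuals" or test_regime != "individuals") and pools.empty:
        raise ValidationError("pools required for this regime cell")

    cell = (train_regime, test_regime)
    if cell == ("individuals", "pools"):
        return [RegimeDataset(*cell, None, individuals.copy(), pools.copy())]
    if cell == ("pools", "individuals"):
        return [RegimeDataset(*cell, None, pools.copy(), individuals.copy())]

    rng = np.random.default_rng(seed)
    need_ind_folds = cell in (
        ("individuals", "individuals"),
        ("individuals", "combined"),
        ("combined", "individuals"),
        ("combined", "combined"),
    )
    need_pool_folds = cell in (
        ("combined", "combined"),
        ("combined", "pools"),
        ("pools", "combined"),
        ("pools", "pools"),
    )
    ind_blocks = (
        _fold_blocks(individuals["sample_id"], n_folds, rng)
        if need_ind_folds
        else [set()] * n_folds
    )
    pool_blocks = (
        _fold_blocks(pools["sample_id"], n_folds, rng)
        if need_pool_folds
        else [set()] * n_folds
    )

    datasets = []
    for i in range(n_folds):
        in_i = individuals["sample_id"].isin(ind_blocks[i])
        in_p = pools["sample_id"].isin(pool_blocks[i])
        I_tr, I_te = individuals[~in_i], individuals[in_i]
        P_tr, P_te = pools[~in_p], pools[in_p]
        if cell == ("individuals", "individuals"):
            train, test = I_tr, I_te
        elif cell == ("individuals", "combined"):
            train, test = I_tr, combine_sources(I_te, pools)
        elif cell == ("combined", "individuals"):
            train, test = combine_sources(I_tr, pools), I_te
        elif cell == ("combined", "combined"):
            train = combine_sources(I_tr, P_tr)
            test = combine_sources(I_te, P_te)
        elif cell == ("combined", "pools"):
            train, test = combine_sources(individuals, P_tr), P_te
        elif cell == ("pools", "combined"):
            train, test = P_tr, combine_sources(individuals, P_te)
        else:  # ("pools", "pools")
            train, test = P_tr, P_te
        datasets.append(
            RegimeDataset(
                train_regime,
                test_regime,
                i,
                train.reset_index(drop=True),
                test.reset_index(drop=True),
            )
        )
    return datasets


# ---------------------------------------------------------------------------
# Fitting


def _expand_by_weight(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    w = pairs["weight"].to_numpy(dtype=int)
    X = np.repeat(pairs["f"].to_numpy(dtype=float), w)[:, None]
    y = np.repeat(pairs["f_star"].to_numpy(dtype=float), w)
    return X, y


@dataclass
class FittedCalibrator:
    """A fitted per-SNP regression calibrator (opaque estimator inside)."""

    snp_id: str
    spec: ModelSpec
    estimator: object
    n_train: int

    def predict(self, f, clamp: bool = False):
        return apply_calibrator(self, f, clamp=clamp)


def _build_estimator(spec: ModelSpec):
    if spec.family == "LR":
        return LinearRegression()
    if spec.family == "MLP":
        # Small minibatches approximate the online (per-sample) updates the
        # stated learning rate is calibrated to; with large batches the
        # network makes only a couple of steps per epoch and stalls at the
        # training mean. Training stops at mlp_epochs or on plateau.
        return MLPRegressor(
            hidden_layer_sizes=(spec.mlp_nodes_per_layer,) * spec.mlp_layers,
            activation="logistic",
            solver="sgd",
            batch_size=8,
            learning_rate="constant",
            learning_rate_init=spec.mlp_learning_rate,
            momentum=spec.mlp_momentum,
            max_iter=spec.mlp_epochs,
            tol=1e-6,
            n_iter_no_change=25,
            random_state=spec.seed,
        )
    return NuSVR(nu=spec.svr_nu, C=spec.svr_C, kernel="rbf", gamma=spec.svr_gamma)


def fit_calibrator(spec: ModelSpec, pairs: pd.DataFrame) -> FittedCalibrator:
    """Fit one family on the training pairs of a single SNP.

    Replicated rows (weight > 1) count multiply. Raises
    :class:`DegenerateTrainingError` when fewer than two distinct raw
    frequencies are present (no map is identifiable).
    """
    snps = pairs["snp_id"].unique()
    if len(snps) != 1:
        raise ValidationError(f"pairs span {len(snps)} SNPs; expected one")
    if pairs["f"].nunique() < 2:
        raise DegenerateTrainingError(
            f"SNP {snps[0]!r}: fewer than 2 distinct raw frequencies"
        )
    X, y = _expand_by_weight(pairs)
    est = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return FittedCalibrator(str(snps[0]), spec, est, len(y))


def apply_calibrator(model: FittedCalibrator, f, clamp: bool = False):
    """Deterministic prediction f -> f' from a fitted calibrator."""
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    out = model.estimator.predict(f_arr[:, None])
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if np.ndim(f) == 0 else out


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CrossValidationReport:
    """Pooled and per-fold MSE of one (family, train-regime, test-regime) cell."""

    family: str
    train_regime: str
    test_regime: str
    pooled_mse: float
    fold_mse: list[float]
    fold_std: float
    n: int
    entries: pd.DataFrame = field(repr=False, default=None)
    skipped_snps: tuple[str, ...] = ()

    def summary(self) -> str:
        return (
            f"{self.family} train={self.train_regime} test={self.test_regime}: "
            f"MSE={self.pooled_mse:.6f} (fold sd {self.fold_std:.6f}, "
            f"n={self.n}, folds={len(self.fold_mse)})"
        )


def cross_validate(
    spec: ModelSpec,
    individuals: pd.DataFrame,
    pools: pd.DataFrame,
    train_regime: str,
    test_regime: str,
    n_folds: int = 10,
    seed: int = 0,
    clamp: bool = False,
) -> CrossValidationReport:
    """Fit per SNP per fold and aggregate squared error over all test entries.

    The pooled MSE sums weighted squared errors over every test entry of
    every fold and divides by the total (weighted) count; the per-fold
    standard deviation is reported across fold MSEs. SNPs whose training
    pairs are degenerate in some fold are skipped (recorded) in that fold.
    """
    datasets = build_regime_datasets(
        individuals, pools, train_regime, test_regime, n_folds, seed
    )
    entries = []
    fold_mse = []
    skipped: set[str] = set()
    for ds in datasets:
        fold_sq, fold_w = 0.0, 0.0
        for snp_id, test_grp in ds.test_pairs.groupby("snp_id", sort=True):
            train_grp = ds.train_pairs[ds.train_pairs["snp_id"] == snp_id]
            if train_grp.empty:
                skipped.add(str(snp_id))
                continue
            try:
                fitted = fit_calibrator(replace(spec), train_grp)
            except DegenerateTrainingError:
                skipped.add(str(snp_id))
                continue
            pred = apply_calibrator(
                fitted, test_grp["f"].to_numpy(), clamp=clamp
            )
            err = pred - test_grp["f_star"].to_numpy()
            w = test_grp["weight"].to_numpy(dtype=float)
            fold_sq += float(np.sum(w * err**2))
            fold_w += float(np.sum(w))
            entries.append(
                pd.DataFrame(
                    {
                        "snp_id": str(snp_id),
                        "sample_id": test_grp["sample_id"].to_numpy(),
                        "fold": ds.fold_index if ds.fold_index is not None else -1,
                        "f": test_grp["f"].to_numpy(),
                        "f_star": test_grp["f_star"].to_numpy(),
                        "f_hat": pred,
                        "error": err,
                        "weight": w,
                        "source": test_grp["source"].to_numpy(),
                    }
                )
            )
        if fold_w > 0:
            fold_mse.append(fold_sq / fold_w)
    if not entries:
        raise ValidationError("cross-validation produced no test entries")
    all_entries = pd.concat(entries, ignore_index=True)
    total_w = float(all_entries["weight"].sum())
    pooled = float(
        np.sum(all_entries["weight"] * all_entries["error"] ** 2) / total_w
    )
    return CrossValidationReport(
        family=spec.family,
        train_regime=train_regime,
        test_regime=test_regime,
        pooled_mse=pooled,
        fold_mse=fold_mse,
        fold_std=float(np.std(fold_mse, ddof=1)) if len(fold_mse) > 1 else 0.0,
        n=int(round(total_w)),
        entries=all_entries,
        skipped_snps=tuple(sorted(skipped)),
    )


# ---------------------------------------------------------------------------
# Model / Results objects


class RegressionCalibration:
    """Per-SNP regression calibration model over a training-pair table."""

    def __init__(self, pairs: pd.DataFrame, spec: ModelSpec | None = None):
        self.pairs = pairs
        self.spec = spec or ModelSpec()

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        truth: pd.DataFrame,
        spec: ModelSpec | None = None,
    ) -> "RegressionCalibration":
        return cls(make_training_pairs(records, truth), spec)

    def fit(self) -> "RegressionCalibrationResults":
        fitted: dict[str, FittedCalibrator] = {}
        skipped: dict[str, str] = {}
        for snp_id, grp in self.pairs.groupby("snp_id", sort=True):
            try:
                fitted[str(snp_id)] = fit_calibrator(self.spec, grp)
            except DegenerateTrainingError as exc:
                skipped[str(snp_id)] = str(exc)
        if not fitted:
            raise DegenerateTrainingError("no SNP could be fitted")
        return RegressionCalibrationResults(self, fitted, skipped)


class RegressionCalibrationResults:
    """Fitted per-SNP regression calibrators with serialization support."""

    def __init__(
        self,
        model: RegressionCalibration,
        fitted: Mapping[str, FittedCalibrator],
        skipped: Mapping[str, str],
    ):
        self.model = model
        self.fitted = dict(fitted)
        self.skipped = dict(skipped)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(self.fitted)

    def predict(self, f, snp_id: str, clamp: bool = False):
        snp_id = str(snp_id)
        if snp_id not in self.fitted:
            raise KeyError(f"no fitted calibrator for SNP {snp_id!r}")
        return apply_calibrator(self.fitted[snp_id], f, clamp=clamp)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"RegressionCalibration: family={spec.family}, seed={spec.seed}",
            f"SNPs fitted: {len(self.fitted)}; skipped: {len(self.skipped)}",
        ]
        if spec.family == "MLP":
            lines.append(
                f"  MLP: {spec.mlp_layers} layers x {spec.mlp_nodes_per_layer} "
                f"sigmoid nodes, lr={spec.mlp_learning_rate}, "
                f"momentum={spec.mlp_momentum}, epochs={spec.mlp_epochs}"
            )
        elif spec.family == "SVR":
            lines.append(
                f"  nu-SVR: nu={spec.svr_nu}, C={spec.svr_C}, "
                f"Gaussian kernel (gamma={spec.svr_gamma})"
            )
        for snp_id, cal in sorted(self.fitted.items()):
            lines.append(f"  {snp_id}: n_train={cal.n_train}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def _serialize_estimator(self, cal: FittedCalibrator) -> dict:
        est = cal.estimator
        spec = cal.spec
        if spec.family == "LR":
            return {
                "coef": est.coef_.tolist(),
                "intercept": float(est.intercept_),
            }
        if spec.family == "MLP":
            return {
                "coefs": [w.tolist() for w in est.coefs_],
                "intercepts": [b.tolist() for b in est.intercepts_],
            }
        return {
            "support_vectors": est.support_vectors_.tolist(),
            "dual_coef": est.dual_coef_.tolist(),
            "intercept": est.intercept_.tolist(),
            "gamma": float(est._gamma),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        spec = self.model.spec
        payload = {
            "kind": "poolcal.regression",
            "spec": {
                "family": spec.family,
                "mlp_layers": spec.mlp_layers,
                "mlp_nodes_per_layer": spec.mlp_nodes_per_layer,
                "mlp_learning_rate": spec.mlp_learning_rate,
                "mlp_momentum": spec.mlp_momentum,
                "mlp_epochs": spec.mlp_epochs,
                "svr_nu": spec.svr_nu,
                "svr_C": spec.svr_C,
                "svr_gamma": spec.svr_gamma
                if isinstance(spec.svr_gamma, str)
                else float(spec.svr_gamma),
                "seed": spec.seed,
            },
            "snps": {
                snp_id: {
                    "n_train": cal.n_train,
                    "params": self._serialize_estimator(cal),
                }
                for snp_id, cal in self.fitted.items()
            },
            "skipped": self.skipped,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "_PortableRegressionResults":
        if isinstance(source, Path) or (
            "\n" not in str(source) and Path(str(source)).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        if payload.get("kind") != "poolcal.regression":
            raise ValidationError("not a serialized regression calibration")
        return _PortableRegressionResults(payload)


class _PortableRegressionResults:
    """Prediction-only view of a deserialized regression calibration.

    Re-implements the three prediction rules from stored parameters, so a
    model fitted elsewhere can be applied without unpickling estimators.
    """

    def __init__(self, payload: dict):
        self.spec = ModelSpec(**payload["spec"])
        self._snps = payload["snps"]
        self.skipped = payload.get("skipped", {})

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(self._snps)

    def predict(self, f, snp_id: str, clamp: bool = False):
        snp_id = str(snp_id)
        if snp_id not in self._snps:
            raise KeyError(f"no fitted calibrator for SNP {snp_id!r}")
        params = self._snps[snp_id]["params"]
        x = np.atleast_1d(np.asarray(f, dtype=float))[:, None]
        fam = self.spec.family
        if fam == "LR":
            out = x @ np.asarray(params["coef"]) + params["intercept"]
        elif fam == "MLP":
            h = x
            coefs = [np.asarray(w) for w in params["coefs"]]
            intercepts = [np.asarray(b) for b in params["intercepts"]]
            for i, (W, b) in enumerate(zip(coefs, intercepts)):
                h = h @ W + b
                if i < len(coefs) - 1:  # sigmoid hidden, linear output
                    h = 1.0 / (1.0 + np.exp(-h))
            out = h.ravel()
        else:  # SVR: sum of Gaussian kernels at the support vectors
            sv = np.asarray(params["support_vectors"])
            dual = np.asarray(params["dual_coef"]).ravel()
            gamma = params["gamma"]
            K = np.exp(-gamma * (x - sv.ravel()[None, :]) ** 2)
            out = K @ dual + params["intercept"][0]
        out = np.asarray(out, dtype=float).ravel()
        if clamp:
            out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if np.ndim(f) == 0 else out
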