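"""End-to-end benchmark pipeline: QC -> calibration -> error reports.

Runs every requested polynomial method and ML family under the requested
train/test regimes on one data set (simulated or loaded), and writes three
tidy CSV tables:

- ``polynomial_mse.csv``  — per polynomial method, MSE on the individuals /
  combined / pools test sets, with the bias/variance split on individuals;
- ``best_method.csv``     — percentage of SNPs on which each polynomial
  method wins, per test set, plus the per-SNP-oracle MSE row;
- ``ml_mse.csv``          — per (family, train regime, test regime), pooled
  cross-validated MSE with fold standard deviation.

Every output carries the run seed and a hash of the configuration so that
a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import errors as err_mod
from .data import QcConfig, apply_qc
from .polynomial import METHODS, PolynomialCalibration
from .regression import (
    FAMILIES,
    REGIMES,
    ModelSpec,
    combine_sources,
    cross_validate,
    make_training_pairs,
)
from .simulate import DEFAULT_SATURATION, simulate_panel

__all__ = ["RunConfig", "BenchmarkReport", "run_benchmark", "ConfigError"]

logger = logging.getLogger("poolcal")


class ConfigError(ValueError):
    """A run configuration is unusable."""


@dataclass
class RunConfig:
    """Configuration of one benchmark run (see module docstring)."""

    seed: int = 0
    out_dir: str | None = None
    # simulation settings (used unless input paths are given)
    simulate: bool = True
    n_snps: int = 20
    n_individuals: int = 200
    n_pools: int = 20
    pool_size: int = 25
    tau: float = 0.0
    noise_sd: float = 0.08
    saturation: float = DEFAULT_SATURATION
    # input paths (records + truth sidecar), alternative to simulation
    records_path: str | None = None
    truth_path: str | None = None
    # analysis settings
    qc: QcConfig = field(default_factory=QcConfig)
    methods: tuple[str, ...] = METHODS
    families: tuple[str, ...] = FAMILIES
    train_regimes: tuple[str, ...] = REGIMES
    test_regimes: tuple[str, ...] = REGIMES
    n_folds: int = 10
    clamp: bool = False
    verbosity: int = 1

    def config_hash(self) -> str:
        payload = asdict(self)
        # where results are written (and how chatty the run is) does not
        # change them; keep the hash a fingerprint of the analysis itself
        payload.pop("out_dir", None)
        payload.pop("verbosity", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if not self.methods:
            raise ConfigError("empty polynomial method list")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigError(f"unknown polynomial methods: {sorted(unknown)}")
        if set(self.families) - set(FAMILIES):
            raise ConfigError(f"unknown ML families: {self.families}")
        for regime in (*self.train_regimes, *self.test_regimes):
            if regime not in REGIMES:
                raise ConfigError(f"unknown regime {regime!r}")


@dataclass
class BenchmarkReport:
    """Result bundle of one benchmark run."""

    polynomial_mse: pd.DataFrame
    best_method: pd.DataFrame
    ml_mse: pd.DataFrame
    per_snp_mse: dict[str, pd.DataFrame]
    config_hash: str
    seed: int


def _stage(name: str):
    logger.info("stage: %s", name)


def _polynomial_tables(config: RunConfig, individuals, pools):
    """Evaluate each polynomial method on the three test regimes."""
    from .polynomial import PolynomialCalibrationResults

    test_sets = {
        "individuals": individuals,
        "pools": pools,
        "combined": combine_sources(individuals, pools),
    }
    rows = []
    per_snp: dict[str, pd.DataFrame] = {}
    results_by_method = {}
    # fit once per method on all individuals
    ind_records = individuals.attrs["records"]
    for method in config.methods:
        results = PolynomialCalibration(
            ind_records, method=method, clamp=config.clamp
        ).fit()
        results_by_method[method] = results
    for regime, pairs in test_sets.items():
        if regime not in config.test_regimes:
            continue
        snp_tables = []
        for method in config.methods:
            results = results_by_method[method]
            preds = np.empty(len(pairs))
            for snp_id, grp in pairs.groupby("snp_id", sort=True):
                preds[pairs["snp_id"] == snp_id] = results.predict(
                    grp["f"].to_numpy(), str(snp_id), clamp=config.clamp
                )
            errors = preds - pairs["f_star"].to_numpy()
            w = pairs["weight"].to_numpy(dtype=float)
            flat = err_mod.mse(preds, pairs["f_star"].to_numpy(), weights=w)
            row = {
                "method": method,
                "test_regime": regime,
                "mse": flat.mse,
                "bias_sq": np.nan,
                "variance": np.nan,
                "n": flat.n,
            }
            if regime == "individuals":
                strata = list(zip(pairs["snp_id"], pairs["f_star"]))
                decomp = err_mod.bias_variance_decomposition(errors, strata)
                row["bias_sq"] = decomp.bias_sq
                row["variance"] = decomp.variance
            rows.append(row)
            # per-SNP weighted MSE for the best-method tabulation
            df = pd.DataFrame(
                {"snp_id": pairs["snp_id"], "sq": w * errors**2, "w": w}
            )
            g = df.groupby("snp_id")
            snp_tables.append((g["sq"].sum() / g["w"].sum()).rename(method))
        per_snp[regime] = pd.DataFrame(snp_tables)
    table = pd.DataFrame(rows)
    return table, per_snp


def _best_method_table(per_snp: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for regime, table in per_snp.items():
        report = err_mod.best_method_per_snp(table)
        for method, pct in report.selection_pct.items():
            rows.append(
                {
                    "test_regime": regime,
                    "method": method,
                    "selection_pct": round(float(pct), 6),
                    "oracle_mse": report.oracle_mse,
                }
            )
    return pd.DataFrame(rows)


def _ml_table(config: RunConfig, individuals, pools) -> pd.DataFrame:
    rows = []
    for family in config.families:
        spec = ModelSpec(family=family, seed=config.seed)
        for train_regime in config.train_regimes:
            for test_regime in config.test_regimes:
                report = cross_validate(
                    spec,
                    individuals,
                    pools,
                    train_regime,
                    test_regime,
                    n_folds=config.n_folds,
                    seed=config.seed,
                    clamp=config.clamp,
                )
                row = {
                    "family": family,
                    "train_regime": train_regime,
                    "test_regime": test_regime,
                    "mse": report.pooled_mse,
                    "fold_std": report.fold_std,
                    "n": report.n,
                    "bias_sq": np.nan,
                    "variance": np.nan,
                }
                if test_regime == "individuals":
                    ent = report.entries
                    decomp = err_mod.bias_variance_decomposition(
                        ent["error"], list(zip(ent["snp_id"], ent["f_star"]))
                    )
                    row["bias_sq"] = decomp.bias_sq
                    row["variance"] = decomp.variance
                rows.append(row)
    return pd.DataFrame(rows)


def run_benchmark(config: RunConfig) -> BenchmarkReport:
    """Execute the full pipeline described in the module docstring."""
    config.validate()
    level = logging.INFO if config.verbosity else logging.WARNING
    logging.basicConfig(stream=sys.stderr, level=level)

    _stage("data")
    if config.simulate and not config.records_path:
        panel = simulate_panel(
            n_snps=config.n_snps,
            n_individuals=config.n_individuals,
            n_pools=config.n_pools,
            pool_size=config.pool_size,
            tau=config.tau,
            seed=config.seed,
            noise_sd=config.noise_sd,
            saturation=config.saturation,
        )
        records, truth = panel.records, panel.truth
    else:
        from .data import read_intensity_table

        if not (config.records_path and config.truth_path):
            raise ConfigError("records_path and truth_path required")
        records = read_intensity_table(config.records_path)
        truth = pd.read_csv(config.truth_path)

    _stage("qc")
    records, qc_report = apply_qc(records, config.qc)
    if records.empty:
        raise ConfigError("no records left after QC")

    _stage("pairs")
    pairs = make_training_pairs(records, truth)
    individuals = pairs[pairs["source"] == "individual"].reset_index(drop=True)
    pools = pairs[pairs["source"] == "pool"].reset_index(drop=True)
    individuals.attrs["records"] = records[~records["is_pool"]]

    _stage("polynomial calibration")
    poly_table, per_snp = _polynomial_tables(config, individuals, pools)

    _stage("best-method tabulation")
    best_table = _best_method_table(per_snp)

    _stage("regression calibration")
    ml_table = _ml_table(config, individuals, pools)

    report = BenchmarkReport(
        polynomial_mse=poly_table,
        best_method=best_table,
        ml_mse=ml_table,
        per_snp_mse=per_snp,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    if config.out_dir:
        _stage("write outputs")
        _write_outputs(config, report, qc_report)
    return report


def _write_outputs(config: RunConfig, report: BenchmarkReport, qc_report) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# poolcal seed={report.seed} config={report.config_hash}\n"
    for name, table in (
        ("polynomial_mse.csv", report.polynomial_mse),
        ("best_method.csv", report.best_method),
        ("ml_mse.csv", report.ml_mse),
    ):
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            table.to_csv(fh, index=False, float_format="%.10g")
    (out / "qc_report.json").write_text(qc_report.to_json())
    (out / "run.json").write_text(
        json.dumps(
            {"seed": report.seed, "config_hash": report.config_hash},
            indent=2,
        )
    )
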