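"""Data model, file IO, quality control and pool ground-truth bookkeeping.

Two-channel genotyping platforms report a pair of detector responses
``(H_A, H_B)`` per (SNP, sample). The raw A-allele frequency is
``f = H_A / (H_A + H_B)``. Individual samples additionally carry a discrete
genotype call (AA / AB / BB, or NoCall when the caller abstains); pooled
samples never carry a call because their allele frequency is a real value
in [0, 1], not one of the three genotype quanta.

Tables of such measurements are represented as :class:`pandas.DataFrame`
objects with the canonical columns :data:`CANONICAL_COLUMNS`; the
:class:`IntensityRecord` dataclass is the row-level view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CALL_FREQUENCY",
    "CANONICAL_COLUMNS",
    "VALID_CALLS",
    "IntensityRecord",
    "PoolComposition",
    "QcConfig",
    "QcReport",
    "FormatError",
    "ValidationError",
    "read_intensity_table",
    "write_intensity_table",
    "read_pool_composition",
    "raw_allele_frequency",
    "signal_amplitude",
    "apply_qc",
    "pool_ground_truth",
    "records_to_frame",
]

#: A-allele frequency implied by each discrete genotype call.
CALL_FREQUENCY = {"AA": 1.0, "AB": 0.5, "BB": 0.0}

VALID_CALLS = ("AA", "AB", "BB", "NoCall")

CANONICAL_COLUMNS = (
    "snp_id",
    "sample_id",
    "H_A",
    "H_B",
    "call",
    "is_pool",
    "replicate_id",
)


class FormatError(ValueError):
    """An input table cannot be interpreted (missing/unresolvable columns)."""


class ValidationError(ValueError):
    """An input value violates a data-model invariant."""


@dataclass(frozen=True)
class IntensityRecord:
    """One (SNP, sample) two-channel measurement.

    ``replicate_id`` distinguishes duplicate measurements of the same
    physical sample; duplicates are ordinary independent rows everywhere
    except the duplicate-variance estimator.
    """

    snp_id: str
    sample_id: str
    H_A: float
    H_B: float
    call: str = "NoCall"
    is_pool: bool = False
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        if self.H_A < 0 or self.H_B < 0:
            raise ValidationError(
                f"negative intensity for ({self.snp_id}, {self.sample_id}): "
                f"H_A={self.H_A}, H_B={self.H_B}"
            )
        if self.call not in VALID_CALLS:
            raise ValidationError(f"unknown genotype call {self.call!r}")
        if self.is_pool and self.call != "NoCall":
            raise ValidationError(
                f"pool sample {self.sample_id!r} carries a genotype call; "
                "pools have no discrete genotype"
            )


@dataclass(frozen=True)
class PoolComposition:
    """Mapping from one pool sample to its member individuals."""

    pool_sample_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.member_ids) == 0:
            raise ValidationError(
                f"pool {self.pool_sample_id!r} has no members"
            )
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValidationError(
                f"pool {self.pool_sample_id!r} lists a member twice"
            )

    @property
    def declared_size(self) -> int:
        return len(self.member_ids)


def validate_pool_memberships(pools: Sequence[PoolComposition]) -> None:
    """Check that no individual appears in more than one pool."""
    seen: dict[str, str] = {}
    for pool in pools:
        for member in pool.member_ids:
            if member in seen:
                raise ValidationError(
                    f"individual {member!r} is in pools "
                    f"{seen[member]!r} and {pool.pool_sample_id!r}"
                )
            seen[member] = pool.pool_sample_id


@dataclass(frozen=True)
class QcConfig:
    """Quality-control thresholds.

    min_call_rate : float
        Minimum fraction of (retained, signal-passing) SNP measurements of
        an individual sample that must carry a genotype call. Default 0.8.
    min_signal : float
        Minimum amplitude statistic R of a single measurement. R is the
        total signal ``H_A + H_B`` unless the input table supplies a
        precomputed ``R`` column. Default 1.0.
    bad_snp_ids : tuple
        SNPs excluded outright before any other filtering.
    """

    min_call_rate: float = 0.8
    min_signal: float = 1.0
    bad_snp_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_call_rate <= 1.0):
            raise ValidationError("min_call_rate must lie in [0, 1]")
        if not np.isfinite(self.min_signal) or self.min_signal < 0:
            raise ValidationError("min_signal must be finite and >= 0")


@dataclass
class QcReport:
    """Per-stage removal counts produced by :func:`apply_qc`."""

    n_input: int = 0
    n_removed_bad_snp: int = 0
    n_removed_call_rate: int = 0
    n_removed_low_signal: int = 0
    n_retained: int = 0
    removed_samples: tuple[str, ...] = ()

    def to_json(self) -> str:
        payload = {
            "n_input": self.n_input,
            "n_removed_bad_snp": self.n_removed_bad_snp,
            "n_removed_call_rate": self.n_removed_call_rate,
            "n_removed_low_signal": self.n_removed_low_signal,
            "n_retained": self.n_retained,
            "removed_samples": list(self.removed_samples),
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# IO


def _normalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "call" not in df.columns:
        df["call"] = "NoCall"
    df["call"] = df["call"].fillna("NoCall").replace("", "NoCall")
    bad_calls = set(df["call"].unique()) - set(VALID_CALLS)
    if bad_calls:
        raise ValidationError(f"unknown genotype calls: {sorted(bad_calls)}")
    if "is_pool" not in df.columns:
        df["is_pool"] = False
    df["is_pool"] = df["is_pool"].astype(bool)
    if "replicate_id" not in df.columns:
        df["replicate_id"] = None
    df["replicate_id"] = (
        df["replicate_id"].astype(object).where(df["replicate_id"].notna(), None)
    )
    for ch in ("H_A", "H_B"):
        df[ch] = pd.to_numeric(df[ch])
        neg = df.index[df[ch] < 0]
        if len(neg):
            raise ValidationError(
                f"negative intensity in column {ch} at row(s) {list(neg[:5])}"
            )
    pooled_calls = df[(df["is_pool"]) & (df["call"] != "NoCall")]
    if len(pooled_calls):
        raise ValidationError(
            "pool records carry genotype calls at rows "
            f"{list(pooled_calls.index[:5])}"
        )
    ordered = [c for c in CANONICAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def read_intensity_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited intensity table into canonical form.

    Parameters
    ----------
    path : path
        CSV/TSV file with a header row.
    dialect : mapping, optional
        Maps canonical column names (``snp_id``, ``sample_id``, ``H_A``,
        ``H_B``, optionally ``call``, ``is_pool``, ``replicate_id``, ``R``)
        to the column names used in the file.
    sep : str, optional
        Field separator; sniffed by pandas when omitted.

    Row order is preserved; a missing call column (or empty call cells)
    yields ``NoCall``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if dialect:
        rename = {src: canon for canon, src in dialect.items()}
        missing = [src for src in dialect.values() if src not in df.columns]
        if missing:
            raise FormatError(f"columns not found in {path.name}: {missing}")
        df = df.rename(columns=rename)
    required = ("snp_id", "sample_id", "H_A", "H_B")
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise FormatError(
            f"cannot resolve required column(s) {absent} in {path.name}; "
            "supply a dialect mapping"
        )
    return _normalise_frame(df)


def write_intensity_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a canonical intensity table back to delimited text."""
    df.to_csv(path, sep=sep, index=False)


def read_pool_composition(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[PoolComposition]:
    """Read a (pool_id, member_id) long-format table into compositions."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if dialect:
        df = df.rename(columns={src: canon for canon, src in dialect.items()})
    if not {"pool_id", "member_id"} <= set(df.columns):
        raise FormatError("pool composition needs columns pool_id, member_id")
    pools = [
        PoolComposition(str(pid), tuple(str(m) for m in grp["member_id"]))
        for pid, grp in df.groupby("pool_id", sort=True)
    ]
    validate_pool_memberships(pools)
    return pools


def records_to_frame(records: Iterable[IntensityRecord]) -> pd.DataFrame:
    """Assemble IntensityRecords into a canonical DataFrame."""
    rows = [
        (r.snp_id, r.sample_id, r.H_A, r.H_B, r.call, r.is_pool, r.replicate_id)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


# ---------------------------------------------------------------------------
# Core quantities


def raw_allele_frequency(H_A, H_B):
    """Raw A-allele frequency ``f = H_A / (H_A + H_B)``.

    Accepts scalars or arrays. Scale invariant: multiplying both channels
    by a positive constant leaves f unchanged.

    Raises
    ------
    ValidationError
        If any total signal ``H_A + H_B`` is zero (frequency undefined).
    """
    H_A = np.asarray(H_A, dtype=float)
    H_B = np.asarray(H_B, dtype=float)
    total = H_A + H_B
    if np.any(total <= 0):
        raise ValidationError(
            "allele frequency undefined where H_A + H_B <= 0"
        )
    f = H_A / total
    return float(f) if f.ndim == 0 else f


def signal_amplitude(df: pd.DataFrame) -> pd.Series:
    """Amplitude statistic R per record.

    Uses a precomputed ``R`` column when present, else the total signal
    ``H_A + H_B`` (the denominator of the raw-frequency ratio).
    """
    if "R" in df.columns:
        return pd.to_numeric(df["R"])
    return df["H_A"] + df["H_B"]


# ---------------------------------------------------------------------------
# Quality control


def apply_qc(df: pd.DataFrame, config: QcConfig) -> tuple[pd.DataFrame, QcReport]:
    """Three-stage quality control: bad SNPs, low-call-rate samples, weak signals.

    Stages, in order:

    1. drop every record of a SNP in ``config.bad_snp_ids``;
    2. drop every record of an individual sample whose call rate — the
       fraction of its signal-passing measurements on retained SNPs that
       carry a genotype call — is below ``min_call_rate`` (pools are exempt:
       they carry no calls);
    3. drop records whose amplitude statistic R is below ``min_signal``.

    Call rates are evaluated on signal-passing rows so that the filter is
    idempotent: re-applying it to its own output removes nothing.
    """
    report = QcReport(n_input=len(df))
    df = _normalise_frame(df)

    stage1 = df[~df["snp_id"].isin(config.bad_snp_ids)]
    report.n_removed_bad_snp = len(df) - len(stage1)

    # Call rate per individual sample, counted over signal-passing rows.
    strong = signal_amplitude(stage1) >= config.min_signal
    individuals = stage1[~stage1["is_pool"] & strong]
    removed_samples: list[str] = []
    if len(individuals) and config.min_call_rate > 0:
        called = individuals["call"] != "NoCall"
        rate = called.groupby(individuals["sample_id"]).mean()
        removed_samples = sorted(rate.index[rate < config.min_call_rate])
    # Individuals with *no* signal-passing rows have an undefined call rate;
    # they fail the filter whenever one is required.
    if config.min_call_rate > 0:
        all_ind = set(stage1.loc[~stage1["is_pool"], "sample_id"])
        silent = all_ind - set(individuals["sample_id"])
        removed_samples = sorted(set(removed_samples) | silent)
    stage2 = stage1[~stage1["sample_id"].isin(removed_samples)]
    report.n_removed_call_rate = len(stage1) - len(stage2)
    report.removed_samples = tuple(removed_samples)

    keep = signal_amplitude(stage2) >= config.min_signal
    stage3 = stage2[keep]
    report.n_removed_low_signal = len(stage2) - len(stage3)

    report.n_retained = len(stage3)
    return stage3.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Pool ground truth


def pool_ground_truth(
    pool: PoolComposition,
    member_calls: pd.DataFrame,
) -> pd.Series:
    """Per-SNP ground-truth allele frequency of a pool from its members' calls.

    ``member_calls`` holds the QC-passing individual records (columns
    ``sample_id``, ``snp_id``, ``call``). For each SNP the ground truth is
    the unweighted mean of member genotype frequencies (AA→1, AB→0.5, BB→0)
    over members with a passing call at that SNP; members without one are
    excluded from that SNP's mean. SNPs where no member passes are NaN
    (undefined).
    """
    if pool.declared_size == 0:  # pragma: no cover - blocked by dataclass
        raise ValidationError("empty member list")
    rows = member_calls[
        member_calls["sample_id"].isin(pool.member_ids)
        & (member_calls["call"] != "NoCall")
    ]
    snps = pd.Index(member_calls["snp_id"].unique(), name="snp_id")
    if rows.empty:
        return pd.Series(np.nan, index=snps, name=pool.pool_sample_id)
    # A member genotyped twice at a SNP contributes its (single) genotype
    # once: collapse duplicates before averaging.
    per_member = (
        rows.assign(freq=rows["call"].map(CALL_FREQUENCY))
        .groupby(["snp_id", "sample_id"])["freq"]
        .mean()
    )
    truth = per_member.groupby("snp_id").mean()
    return truth.reindex(snps).rename(pool.pool_sample_id)
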