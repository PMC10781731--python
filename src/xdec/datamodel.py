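"""Containers and preprocessing for mixed-type cohort tables.

A cohort is a per-sample table holding a *numeric* block (continuous,
discrete and ordinal variables) and a *binary* block (0/1 categorical
variables), described by a variable manifest.  All preprocessing used by
the clustering models lives here: missingness filters, repeated-measurement
summarisation, z-scaling with development-cohort statistics, and the
clinical encoding rules (presence indicators, conditional constant fills).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUMERICAL = "numerical"
BINARY = "binary"

_DATATYPES = (NUMERICAL, BINARY)
_ROLES = ("input", "outcome", "identifier")


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    datatype: str
    role: str = "input"

    def __post_init__(self):
        if self.datatype not in _DATATYPES:
            raise ValueError(
                f"variable {self.name!r}: datatype must be one of {_DATATYPES}, "
                f"got {self.datatype!r}"
            )
        if self.role not in _ROLES:
            raise ValueError(
                f"variable {self.name!r}: role must be one of {_ROLES}, got {self.role!r}"
            )


class VariableManifest:
    """Ordered collection of variable descriptions (name, datatype, role)."""

    def __init__(self, entries: Iterable[ManifestEntry]):
        self.entries = list(entries)
        names = [e.name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate variable names in manifest: {sorted(dupes)}")

    @property
    def input_numeric(self) -> list[str]:
        return [e.name for e in self.entries if e.role == "input" and e.datatype == NUMERICAL]

    @property
    def input_binary(self) -> list[str]:
        return [e.name for e in self.entries if e.role == "input" and e.datatype == BINARY]

    @property
    def input_names(self) -> list[str]:
        return [e.name for e in self.entries if e.role == "input"]

    def subset(self, keep: Sequence[str]) -> "VariableManifest":
        keep = set(keep)
        return VariableManifest([e for e in self.entries if e.name in keep])

    def __len__(self):
        return len(self.entries)

    def __eq__(self, other):
        return isinstance(other, VariableManifest) and self.entries == other.entries

    def fingerprint(self) -> str:
        """Stable hash of the input-variable schema (order, names, datatypes)."""
        text = ";".join(f"{e.name}:{e.datatype}" for e in self.entries if e.role == "input")
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.name, e.datatype, e.role) for e in self.entries],
            columns=["name", "datatype", "role"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VariableManifest":
        required = {"name", "datatype", "role"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest file must have columns {sorted(required)}")
        return cls(
            ManifestEntry(str(r["name"]), str(r["datatype"]), str(r["role"]))
            for _, r in df.iterrows()
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "VariableManifest":
        return cls.from_frame(pd.read_csv(path, dtype=str))


class MixedDataset:
    """Aligned numeric and binary blocks over a shared set of samples.

    Blocks are pandas DataFrames indexed by sample id.  Missing cells are
    NaN.  Binary cells may only hold 0, 1 or NaN.
    """

    def __init__(self, numeric: pd.DataFrame, binary: pd.DataFrame,
                 manifest: VariableManifest):
        if not numeric.index.equals(binary.index):
            raise ValueError("numeric and binary blocks must share the same sample index")
        if numeric.index.has_duplicates:
            dup = numeric.index[numeric.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        if list(numeric.columns) != manifest.input_numeric:
            raise ValueError("numeric block columns do not match manifest numerical inputs")
        if list(binary.columns) != manifest.input_binary:
            raise ValueError("binary block columns do not match manifest binary inputs")
        for col in binary.columns:
            vals = binary[col].dropna().unique()
            bad = [v for v in vals if v not in (0, 1, 0.0, 1.0)]
            if bad:
                raise ValueError(
                    f"binary variable {col!r} contains non-{{0,1}} values: {bad[:5]}"
                )
        self.numeric = numeric.astype(float)
        self.binary = binary.astype(float)
        self.manifest = manifest

    # -- basic introspection -------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.numeric.index

    @property
    def n_samples(self) -> int:
        return len(self.numeric)

    @property
    def p_num(self) -> int:
        return self.numeric.shape[1]

    @property
    def p_cat(self) -> int:
        return self.binary.shape[1]

    def copy(self) -> "MixedDataset":
        return MixedDataset(self.numeric.copy(), self.binary.copy(), self.manifest)

    def is_complete(self) -> bool:
        return not (self.numeric.isna().any().any() or self.binary.isna().any().any())

    def to_matrix(self) -> np.ndarray:
        """Single float matrix, numeric columns first then binary columns."""
        return np.hstack([self.numeric.to_numpy(float), self.binary.to_numpy(float)])

    def blocks(self) -> tuple[np.ndarray, np.ndarray]:
        return self.numeric.to_numpy(float), self.binary.to_numpy(float)

    def take(self, indices: Sequence[int]) -> "MixedDataset":
        """Positional row subset (used by the stability subsampler)."""
        return MixedDataset(
            self.numeric.iloc[list(indices)], self.binary.iloc[list(indices)], self.manifest
        )

    def __eq__(self, other):
        return (
            isinstance(other, MixedDataset)
            and self.manifest == other.manifest
            and self.numeric.equals(other.numeric)
            and self.binary.equals(other.binary)
        )


@dataclass
class OutcomeTable:
    """Per-sample clinical outcomes: LOS (days), ICU mortality, admission
    diagnosis category, and vasoactive-medication requirement."""

    frame: pd.DataFrame  # columns: los_days, mortality, diagnosis_category, vasoactive

    REQUIRED = ("los_days", "mortality", "diagnosis_category", "vasoactive")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"outcome table missing columns: {missing}")
        if (self.frame["los_days"].dropna() < 0).any():
            raise ValueError("los_days must be non-negative")
        for col in ("mortality", "vasoactive"):
            bad = set(self.frame[col].dropna().unique()) - {0, 1, 0.0, 1.0}
            if bad:
                raise ValueError(f"{col} must be 0/1; found {sorted(bad)[:5]}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def aligned_to(self, ds: MixedDataset) -> "OutcomeTable":
        if not set(ds.sample_ids).issubset(set(self.frame.index)):
            missing = set(ds.sample_ids) - set(self.frame.index)
            raise ValueError(f"outcomes missing for samples: {sorted(missing)[:5]}")
        return OutcomeTable(self.frame.loc[ds.sample_ids])

    def write(self, path) -> None:
        self.frame.to_csv(path, index_label="sample_id")

    @classmethod
    def read(cls, path) -> "OutcomeTable":
        return cls(pd.read_csv(path, index_col="sample_id"))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_dataset(data_path, manifest_path) -> MixedDataset:
    """Read a cohort from a CSV (header row, empty cell = missing) plus a
    manifest file.  The first column of the CSV is the sample id."""
    manifest = VariableManifest.read(manifest_path)
    df = pd.read_csv(data_path, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample id(s) in {data_path}: {dup[:5]}")
    unknown = [c for c in df.columns if c not in manifest.input_names]
    if unknown:
        raise ValueError(f"columns absent from manifest: {unknown}")
    absent = [c for c in manifest.input_names if c not in df.columns]
    if absent:
        raise ValueError(f"manifest variables absent from data: {absent}")
    return MixedDataset(df[manifest.input_numeric], df[manifest.input_binary], manifest)


def write_dataset(ds: MixedDataset, data_path, manifest_path) -> None:
    full = pd.concat([ds.numeric, ds.binary], axis=1)
    full.to_csv(data_path, index_label="sample_id")
    ds.manifest.write(manifest_path)


# ---------------------------------------------------------------------------
# missingness filters (strict ">" threshold)
# ---------------------------------------------------------------------------

def filter_variables_by_missingness(ds: MixedDataset, threshold: float = 0.4) -> MixedDataset:
    """Drop input variables whose missing fraction strictly exceeds *threshold*."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    removed = []
    keep_num, keep_bin = [], []
    for block, keep in ((ds.numeric, keep_num), (ds.binary, keep_bin)):
        frac = block.isna().mean(axis=0)
        for col in block.columns:
            (removed if frac[col] > threshold else keep).append(col)
    if not keep_num and not keep_bin:
        raise ValueError("all variables exceed the missingness threshold")
    if removed:
        logger.info("removed %d variable(s) over %.0f%% missing: %s",
                    len(removed), 100 * threshold, removed)
    kept = keep_num + keep_bin
    manifest = ds.manifest.subset(
        kept + [e.name for e in ds.manifest.entries if e.role != "input"])
    return MixedDataset(ds.numeric[keep_num], ds.binary[keep_bin], manifest)


def filter_samples_by_missingness(ds: MixedDataset, threshold: float = 0.4) -> MixedDataset:
    """Drop samples whose missing fraction over all input variables jointly
    strictly exceeds *threshold*."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    joint = pd.concat([ds.numeric, ds.binary], axis=1)
    frac = joint.isna().mean(axis=1)
    keep = frac <= threshold
    dropped = ds.sample_ids[~keep].tolist()
    if not keep.any():
        raise ValueError("all samples exceed the missingness threshold")
    if dropped:
        logger.info("removed %d sample(s) over %.0f%% missing: %s",
                    len(dropped), 100 * threshold, dropped[:10])
    return MixedDataset(ds.numeric.loc[keep], ds.binary.loc[keep], ds.manifest)


# ---------------------------------------------------------------------------
# repeated-measurement summarisation
# ---------------------------------------------------------------------------

def summarise_repeats(long_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated measurements to per-sample mean and SD columns.

    *long_table* has columns (sample_id, variable, value).  Each variable
    yields two output columns, ``<var>_mean`` and ``<var>_sd``; the SD uses
    the sample (n-1) convention, so a singleton measurement yields a missing
    SD.  Doubles the variable count (23 laboratory variables become 46
    summary columns in the motivating cohorts).
    """
    required = {"sample_id", "variable", "value"}
    if not required.issubset(long_table.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    g = long_table.groupby(["sample_id", "variable"])["value"]
    means = g.mean().unstack("variable")
    sds = g.std(ddof=1).unstack("variable")
    out = pd.DataFrame(index=means.index)
    for var in means.columns:
        out[f"{var}_mean"] = means[var]
        out[f"{var}_sd"] = sds[var]
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# z-scaling with development-cohort statistics
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Per-variable mean and SD (sample convention) of the fitting cohort."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self):
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0].tolist()
            raise ValueError(f"non-positive SD for variable(s): {bad}")

    def write(self, path) -> None:
        pd.DataFrame({"mean": self.mean, "sd": self.sd}).to_csv(path, index_label="variable")

    @classmethod
    def read(cls, path) -> "ScalerParams":
        df = pd.read_csv(path, index_col="variable")
        return cls(df["mean"], df["sd"])

    def __eq__(self, other):
        return (isinstance(other, ScalerParams)
                and self.mean.equals(other.mean) and self.sd.equals(other.sd))


def fit_scaler(ds: MixedDataset) -> ScalerParams:
    """Fit per-variable z-scaling statistics on the numeric block."""
    if ds.numeric.isna().any().any():
        raise ValueError("fit_scaler requires a complete numeric block")
    mean = ds.numeric.mean(axis=0)
    sd = ds.numeric.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant numeric variable(s) cannot be scaled: {constant}")
    return ScalerParams(mean, sd)


def apply_scaler(ds: MixedDataset, params: ScalerParams) -> MixedDataset:
    """Standardise the numeric block with previously fitted statistics.

    The external-validation contract: an external cohort is scaled with the
    development cohort's means and SDs, never its own.
    """
    missing = [c for c in ds.numeric.columns if c not in params.mean.index]
    if missing:
        raise ValueError(f"scaler has no parameters for variable(s): {missing}")
    scaled = (ds.numeric - params.mean[ds.numeric.columns]) / params.sd[ds.numeric.columns]
    return MixedDataset(scaled, ds.binary.copy(), ds.manifest)


def inverse_scaler(ds: MixedDataset, params: ScalerParams) -> MixedDataset:
    scaled = ds.numeric * params.sd[ds.numeric.columns] + params.mean[ds.numeric.columns]
    return MixedDataset(scaled, ds.binary.copy(), ds.manifest)


# ---------------------------------------------------------------------------
# clinical encoding rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PresenceIndicator:
    """Replace an invasively/sparsely measured numeric variable with a binary
    measured-at-all indicator (e.g. central venous pressure)."""
    source: str
    new_name: str
    drop_source: bool = True


@dataclass(frozen=True)
class ConstantFill:
    """Set *target* to a constant for samples where *flag* is 0 (e.g. PEEP
    set to 5 cmH2O for non-ventilated patients to mimic low PEEP)."""
    target: str
    flag: str
    value: float


EncodingRule = PresenceIndicator | ConstantFill


def apply_encoding_rules(ds: MixedDataset, rules: Sequence[EncodingRule]) -> MixedDataset:
    """Apply encoding rules in order, updating data and manifest."""
    numeric, binary = ds.numeric.copy(), ds.binary.copy()
    entries = list(ds.manifest.entries)
    for rule in rules:
        if isinstance(rule, PresenceIndicator):
            if rule.source not in numeric.columns:
                raise ValueError(f"presence_indicator: unknown numeric variable {rule.source!r}")
            binary[rule.new_name] = (~numeric[rule.source].isna()).astype(float)
            entries.append(ManifestEntry(rule.new_name, BINARY, "input"))
            if rule.drop_source:
                numeric = numeric.drop(columns=[rule.source])
                entries = [e for e in entries if e.name != rule.source]
        elif isinstance(rule, ConstantFill):
            if rule.target not in numeric.columns:
                raise ValueError(f"constant_fill: unknown numeric variable {rule.target!r}")
            if rule.flag not in binary.columns:
                raise ValueError(f"constant_fill: unknown binary flag {rule.flag!r}")
            mask = binary[rule.flag] == 0
            numeric.loc[mask, rule.target] = rule.value
        else:
            raise TypeError(f"unknown encoding rule: {rule!r}")
    manifest = VariableManifest(entries)
    return MixedDataset(numeric[manifest.input_numeric], binary[manifest.input_binary], manifest)


def impute_simple(ds: MixedDataset) -> MixedDataset:
    """Mean/mode single imputation for cells still missing after filtering.

    A deliberately simple, documented fallback for incomplete data; the
    model-fitting entry points otherwise reject incomplete datasets.
    """
    numeric = ds.numeric.fillna(ds.numeric.mean(axis=0))
    binary = ds.binary.copy()
    for col in binary.columns:
        if binary[col].isna().any():
            mode = binary[col].mode(dropna=True)
            fill = float(mode.iloc[0]) if len(mode) else 0.0
            binary[col] = binary[col].fillna(fill)
    return MixedDataset(numeric, binary, ds.manifest)
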