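"""Descriptor tables, train/test splitting, and the packaged reference data.

A :class:`DescriptorTable` holds one row per compound: a string identifier,
real-valued molecular descriptors, the response lg(IC50) (log10 of IC50 in
nM), and an optional train/test split flag.  The packaged reference data
transcribes the measured activities of 92 EGFR triple-mutant inhibitors and
the predictions of six QSAR models for them, with the published 73/19
train/test partition.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from mixqsar.errors import ConfigurationError, DataError, IntegrityError

SPLIT_VALUES = ("train", "test", "unassigned")

#: Model columns of the reference-prediction table, in publication order.
REFERENCE_MODELS = ("hm", "rf", "gep", "gbdt", "poly_svm", "mix_svm")

#: Published summary statistics (train R2, train RMSE, test R2, test RMSE)
#: for the six reference models.  Only the mixed-kernel SVR column of the
#: packaged per-compound table is numerically consistent with these values;
#: ``mixqsar.validation.compare_reference_statistics`` flags the rest.
REPORTED_STATISTICS = {
    "hm": {"train_r2": 0.8094, "train_rmse": 0.5497, "test_r2": 0.7892, "test_rmse": 0.6215},
    "rf": {"train_r2": 0.8940, "train_rmse": 0.2188, "test_r2": 0.8779, "test_rmse": 0.3163},
    "gep": {"train_r2": 0.7631, "train_rmse": 0.3812, "test_r2": 0.7036, "test_rmse": 0.4546},
    "gbdt": {"train_r2": 0.7780, "train_rmse": 0.3319, "test_r2": 0.6478, "test_rmse": 0.4769},
    "poly_svm": {"train_r2": 0.8242, "train_rmse": 0.3026, "test_r2": 0.8956, "test_rmse": 0.2240},
    "mix_svm": {"train_r2": 0.9445, "train_rmse": 0.1659, "test_r2": 0.9490, "test_rmse": 0.1814},
}

_REFERENCE_CSV = "table6_reference.csv"
_REFERENCE_SHA256 = "b65489f176684d2b6520eef9b568d9508af043a2135bbb3c3a91452d2c3717d4"


@dataclass
class DescriptorTable:
    """Compounds x named real descriptors, plus response and split flags."""

    compound_ids: list[str]
    descriptors: pd.DataFrame
    response: np.ndarray
    split_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptors = pd.DataFrame(self.descriptors).reset_index(drop=True)
        self.response = np.asarray(self.response, dtype=float)
        n = len(self.compound_ids)
        if self.split_flag is None:
            self.split_flag = np.full(n, "unassigned", dtype=object)
        self.split_flag = np.asarray(self.split_flag, dtype=object)
        if len(self.descriptors) != n or len(self.response) != n or len(self.split_flag) != n:
            raise DataError(
                f"row mismatch: {n} ids, {len(self.descriptors)} descriptor rows, "
                f"{len(self.response)} responses, {len(self.split_flag)} flags"
            )
        if len(set(self.compound_ids)) != n:
            raise DataError("compound identifiers are not unique")
        cols = list(self.descriptors.columns)
        if len(set(cols)) != len(cols):
            raise DataError("descriptor column names are not unique")
        if self.descriptors.size and not np.isfinite(self.descriptors.to_numpy()).all():
            raise DataError("non-finite descriptor value")
        if n and not np.isfinite(self.response).all():
            raise DataError("non-finite response value")
        bad = set(self.split_flag) - set(SPLIT_VALUES)
        if bad:
            raise DataError(f"invalid split flags: {sorted(bad)}")

    # -- convenience views ------------------------------------------------

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.descriptors.columns)

    @property
    def X(self) -> np.ndarray:
        return self.descriptors.to_numpy(dtype=float)

    @property
    def train_mask(self) -> np.ndarray:
        return self.split_flag == "train"

    @property
    def test_mask(self) -> np.ndarray:
        return self.split_flag == "test"

    def subset(self, mask: np.ndarray) -> "DescriptorTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return DescriptorTable(
            [self.compound_ids[i] for i in idx],
            self.descriptors.iloc[idx],
            self.response[idx],
            self.split_flag[idx].copy(),
        )

    def train_subset(self) -> "DescriptorTable":
        return self.subset(self.train_mask)

    def test_subset(self) -> "DescriptorTable":
        return self.subset(self.test_mask)

    def with_descriptors(self, names: list[str]) -> "DescriptorTable":
        missing = [c for c in names if c not in self.descriptors.columns]
        if missing:
            raise ConfigurationError(f"unknown descriptors: {missing}")
        return DescriptorTable(
            self.compound_ids, self.descriptors[names], self.response, self.split_flag.copy()
        )

    def to_frame(
        self, id_column: str = "id", response_column: str = "response", include_split: bool = True
    ) -> pd.DataFrame:
        frame = pd.DataFrame({id_column: self.compound_ids})
        frame = pd.concat([frame, self.descriptors.reset_index(drop=True)], axis=1)
        frame[response_column] = self.response
        if include_split:
            frame["split"] = self.split_flag
        return frame

    def to_csv(self, path, **kwargs) -> None:
        self.to_frame(**kwargs).to_csv(path, index=False)


def load_descriptor_table(
    path,
    response_column: str = "response",
    id_column: str = "id",
    split_column: str | None = "split",
) -> DescriptorTable:
    """Read a descriptor table from CSV.

    The file must be comma-separated UTF-8 with a header row; every column
    other than the identifier, response, and (optional) split column is
    treated as a descriptor and must parse as a real number.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (id_column, response_column):
        if col not in frame.columns:
            raise ConfigurationError(f"column {col!r} not found in {path}")
    split = None
    if split_column and split_column in frame.columns:
        split = frame[split_column].to_numpy(dtype=object)
        frame = frame.drop(columns=[split_column])
    ids = frame[id_column].tolist()
    numeric = frame.drop(columns=[id_column])
    parsed = {}
    for col in numeric.columns:
        try:
            parsed[col] = pd.to_numeric(numeric[col], errors="raise")
        except (ValueError, TypeError):
            bad = numeric[col][pd.to_numeric(numeric[col], errors="coerce").isna()]
            row = int(bad.index[0])
            raise DataError(
                f"non-numeric value {bad.iloc[0]!r} in column {col!r}, row {row}"
            ) from None
    parsed_frame = pd.DataFrame(parsed)
    response = parsed_frame.pop(response_column).to_numpy(dtype=float)
    return DescriptorTable(ids, parsed_frame, response, split)


def split_train_test(table: DescriptorTable, test_fraction: float, seed: int) -> DescriptorTable:
    """Assign train/test flags by seeded sampling without replacement.

    The test set holds ``round(n * test_fraction)`` compounds; the complement
    is the training set.  Row order is preserved; the same seed always yields
    the same assignment.
    """
    n = table.n_compounds
    if n < 2:
        raise DataError("need at least 2 compounds to split")
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError("test_fraction must lie in (0, 1)")
    n_test = int(round(n * test_fraction))
    if n_test < 1 or n_test >= n:
        raise ConfigurationError(
            f"test_fraction={test_fraction} yields an empty train or test set for n={n}"
        )
    rng = np.random.default_rng(seed)
    test_idx = rng.choice(n, size=n_test, replace=False)
    flags = np.full(n, "train", dtype=object)
    flags[test_idx] = "test"
    return DescriptorTable(table.compound_ids, table.descriptors, table.response, flags)


@dataclass
class ReferencePredictions:
    """The packaged per-compound reference table (measured + six models)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if len(f) != 92:
            raise IntegrityError(f"expected 92 compounds, found {len(f)}")
        if int(f["is_test"].sum()) != 19:
            raise IntegrityError(f"expected 19 test compounds, found {int(f['is_test'].sum())}")
        expected = {"compound", "measured_ic50_nm", "measured", "is_test", *REFERENCE_MODELS}
        missing = expected - set(f.columns)
        if missing:
            raise IntegrityError(f"reference table missing columns {sorted(missing)}")

    @property
    def compound_ids(self) -> list[str]:
        return self.frame["compound"].astype(str).tolist()

    @property
    def measured(self) -> np.ndarray:
        return self.frame["measured"].to_numpy(dtype=float)

    @property
    def is_test(self) -> np.ndarray:
        return self.frame["is_test"].to_numpy(dtype=bool)

    def predicted(self, model: str) -> np.ndarray:
        if model not in REFERENCE_MODELS:
            raise ConfigurationError(f"unknown model {model!r}; expected one of {REFERENCE_MODELS}")
        return self.frame[model].to_numpy(dtype=float)

    def as_table(self) -> DescriptorTable:
        """Expose measured responses and split flags as a DescriptorTable
        (no descriptors: the publication did not release per-compound
        descriptor values)."""
        flags = np.where(self.is_test, "test", "train").astype(object)
        return DescriptorTable(
            self.compound_ids, pd.DataFrame(index=range(92)), self.measured, flags
        )


def load_reference_predictions() -> ReferencePredictions:
    """Load the packaged 92-compound reference table, verifying its checksum."""
    text = resources.files("mixqsar.data").joinpath(_REFERENCE_CSV).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _REFERENCE_SHA256:
        raise IntegrityError(
            f"reference table checksum mismatch: {digest} != {_REFERENCE_SHA256}"
        )
    from io import StringIO

    frame = pd.read_csv(StringIO(text))
    frame["is_test"] = frame["is_test"].astype(bool)
    return ReferencePredictions(frame)
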