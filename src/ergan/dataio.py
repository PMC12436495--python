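"""Dataset container, CSV round-trip, normalisation and splitting.

The partitioning protocol matters here: a stratified 75:25 hold-out is
taken *before* any generative training, so that no feature of the test
records can leak into the synthetic waveforms.  The container carries a
``partition`` tag and the GAN trainer refuses datasets that are not tagged
as a training partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from .grid import TimeGrid

META_COLUMNS = ["id", "subject", "eye", "group", "strength", "replicate", "synthetic"]


@dataclass(frozen=True)
class Normalization:
    """Dataset-level amplitude normalisation with stored constants."""

    mode: str  # "minmax" (to [-1, 1]) or "zscore"
    c0: float  # minmax: data min;  zscore: mean
    c1: float  # minmax: data max;  zscore: sd

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.mode == "minmax":
            return 2.0 * (x - self.c0) / (self.c1 - self.c0) - 1.0
        return (x - self.c0) / self.c1

    def invert(self, x: np.ndarray) -> np.ndarray:
        if self.mode == "minmax":
            return (x + 1.0) * (self.c1 - self.c0) / 2.0 + self.c0
        return x * self.c1 + self.c0

    def to_dict(self) -> dict:
        return {"mode": self.mode, "c0": float(self.c0), "c1": float(self.c1)}


@dataclass
class LabeledDataset:
    """Waveforms plus per-record metadata.

    ``X`` is (n_records, grid.n_samples); ``meta`` has one row per record
    with columns id, subject, eye, group (0 = control, 1 = case), strength,
    replicate, synthetic.  ``normalization`` records the transform currently
    applied to ``X`` (None means raw data units).  ``partition`` tags the
    dataset's role after a hold-out split ("train"/"test").
    """

    X: np.ndarray
    meta: pd.DataFrame
    grid: TimeGrid = field(default_factory=TimeGrid)
    normalization: Normalization | None = None
    partition: str | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != self.grid.n_samples:
            raise ValueError(
                f"waveform block must be (n, {self.grid.n_samples}), got {self.X.shape}"
            )
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("metadata rows do not match waveform count")
        labels = set(self.meta["group"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"group labels must be binary 0/1, found {sorted(labels)}")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def y(self) -> np.ndarray:
        return self.meta["group"].to_numpy(dtype=int)

    @property
    def strengths(self) -> np.ndarray:
        return self.meta["strength"].to_numpy(dtype=float)

    def subset(self, idx, partition: str | None = "keep") -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            X=self.X[idx].copy(),
            meta=self.meta.iloc[idx].reset_index(drop=True),
            grid=self.grid,
            normalization=self.normalization,
            partition=self.partition if partition == "keep" else partition,
        )

    def class_counts(self) -> dict[int, int]:
        vc = self.meta["group"].value_counts()
        return {int(k): int(v) for k, v in vc.items()}

    def concat(self, other: "LabeledDataset") -> "LabeledDataset":
        if other.grid != self.grid:
            raise ValueError("cannot concatenate datasets on different grids")
        if (self.normalization is None) != (other.normalization is None):
            raise ValueError("cannot mix normalised and raw datasets")
        import warnings

        with warnings.catch_warnings():
            # all-NA strength columns (class-conditional synthetic records)
            # have matching float dtype on both sides
            warnings.simplefilter("ignore", FutureWarning)
            meta = pd.concat([self.meta, other.meta], ignore_index=True)
        return LabeledDataset(
            X=np.vstack([self.X, other.X]),
            meta=meta,
            grid=self.grid,
            normalization=self.normalization,
            partition=self.partition,
        )


# -- CSV round-trip -----------------------------------------------------------

def write_dataset(ds: LabeledDataset, path: str | Path) -> Path:
    """Write a wide CSV (metadata + s0..s234) and a YAML sidecar."""
    path = Path(path)
    sig_cols = [f"s{i}" for i in range(ds.grid.n_samples)]
    df = pd.concat(
        [ds.meta[META_COLUMNS], pd.DataFrame(ds.X, columns=sig_cols)], axis=1
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "grid": ds.grid.to_dict(),
        "normalization": ds.normalization.to_dict() if ds.normalization else None,
        "partition": ds.partition,
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))
    return path


class DatasetFormatError(ValueError):
    pass


def read_dataset(path: str | Path, grid: TimeGrid | None = None) -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset`.

    The signal block must have exactly ``grid.n_samples`` columns and group
    labels must be binary; violations raise :class:`DatasetFormatError`
    naming the offending row or column count.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    normalization = None
    partition = None
    if sidecar_path.exists():
        sidecar = yaml.safe_load(sidecar_path.read_text())
        grid = grid or TimeGrid.from_dict(sidecar["grid"])
        if sidecar.get("normalization"):
            normalization = Normalization(**sidecar["normalization"])
        partition = sidecar.get("partition")
    grid = grid or TimeGrid()

    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DatasetFormatError(f"{path} is empty") from None
    if df.empty:
        raise DatasetFormatError(f"{path} contains no records")
    sig_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    if len(sig_cols) != grid.n_samples:
        raise DatasetFormatError(
            f"{path}: expected {grid.n_samples} signal columns, found {len(sig_cols)}"
        )
    bad = df[~df["group"].isin([0, 1])]
    if len(bad):
        raise DatasetFormatError(
            f"{path}: non-binary group label at row {int(bad.index[0])}"
        )
    sig_cols = sorted(sig_cols, key=lambda c: int(c[1:]))
    return LabeledDataset(
        X=df[sig_cols].to_numpy(dtype=np.float64),
        meta=df[META_COLUMNS].copy(),
        grid=grid,
        normalization=normalization,
        partition=partition,
    )


# -- normalisation ------------------------------------------------------------

def fit_normalization(ds: LabeledDataset, mode: str = "minmax") -> Normalization:
    """Compute normalisation constants on this dataset only."""
    if mode == "minmax":
        lo, hi = float(ds.X.min()), float(ds.X.max())
        if hi == lo:
            raise ValueError("constant dataset: min-max normalisation undefined")
        return Normalization("minmax", lo, hi)
    if mode == "zscore":
        mu, sd = float(ds.X.mean()), float(ds.X.std())
        if sd == 0.0:
            raise ValueError("zero-variance dataset: z-score normalisation undefined")
        return Normalization("zscore", mu, sd)
    raise ValueError(f"unknown normalisation mode {mode!r}")


def normalize(
    ds: LabeledDataset, mode: str = "minmax", using: Normalization | None = None
) -> LabeledDataset:
    """Return a normalised copy of ``ds``.

    When ``using`` is given its constants are applied (e.g. train-set
    constants applied to the test set); otherwise constants are fitted on
    ``ds`` itself.
    """
    if ds.normalization is not None:
        raise ValueError("dataset is already normalised")
    norm = using if using is not None else fit_normalization(ds, mode)
    return replace(ds, X=norm.apply(ds.X), normalization=norm)


def denormalize(ds: LabeledDataset) -> LabeledDataset:
    if ds.normalization is None:
        return ds
    return replace(ds, X=ds.normalization.invert(ds.X), normalization=None)


# -- splitting ---------------------------------------------------------------

@dataclass
class SplitResult:
    train: LabeledDataset
    test: LabeledDataset
    fraction: float
    grouped_by_subject: bool

    def manifest(self) -> dict:
        return {
            "fraction": self.fraction,
            "stratified_by": "group",
            "grouped_by_subject": self.grouped_by_subject,
            "train_ids": self.train.meta["id"].tolist(),
            "test_ids": self.test.meta["id"].tolist(),
        }

    def write_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.manifest(), indent=1))
        return path


def split_train_test(
    ds: LabeledDataset,
    fraction: float = 0.25,
    seed: int = 0,
    group_by_subject: bool = False,
) -> SplitResult:
    """Stratified hold-out split taken before any generative training.

    Per group label, ``fraction`` of the records (to within one record) go
    to the test side.  With ``group_by_subject`` all records of a subject
    stay on one side; the per-group fraction then holds only approximately.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(ds), dtype=bool)
    for g in (0, 1):
        g_idx = np.flatnonzero(ds.y == g)
        if len(g_idx) < 2:
            raise ValueError(f"group {g} has {len(g_idx)} record(s); cannot stratify")
        n_test = int(round(fraction * len(g_idx)))
        n_test = min(max(n_test, 1), len(g_idx) - 1)
        if group_by_subject:
            subjects = ds.meta["subject"].to_numpy()[g_idx]
            uniq = rng.permutation(np.unique(subjects))
            taken = 0
            for s in uniq:
                s_idx = g_idx[subjects == s]
                if taken >= n_test:
                    break
                test_mask[s_idx] = True
                taken += len(s_idx)
        else:
            chosen = rng.permutation(g_idx)[:n_test]
            test_mask[chosen] = True
    train = ds.subset(np.flatnonzero(~test_mask), partition="train")
    test = ds.subset(np.flatnonzero(test_mask), partition="test")
    return SplitResult(train=train, test=test, fraction=fraction,
                       grouped_by_subject=group_by_subject)


def kfold_indices(
    ds: LabeledDataset, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (fit, validation) index pairs over ``ds``."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(fit, val) for fit, val in skf.split(np.zeros(len(ds)), ds.y)]
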