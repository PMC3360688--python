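"""Reading, validation and preprocessing of per-tube cell matrices.

One flow cytometry *sample* is split into several staining tubes; each tube of
each sample arrives as a CSV file with one header row of channel names and one
row per cell.  Channels are assumed compensated and transformed upstream: FSC
on a linear scale, SSC and the fluorescence markers on a logarithmic scale.

Because linear-scale FSC has a far larger spread than the log-scale channels,
it would dominate any L1-distance computation downstream.  :func:`normalize_fsc`
therefore rescales the FSC column of each file to mean 0 / standard deviation
0.1 (comparable to the log channels) and leaves every other column untouched.

:func:`channel_histograms` produces per-sample density curves for one channel
on a common grid — an advisory quality-control view used to confirm that
marker distributions are aligned across samples; it never excludes samples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    DegenerateInputError,
    FormatError,
    ParseError,
    SchemaError,
)

REQUIRED_CHANNELS = ("FSC", "SSC")


@dataclass
class CellMatrix:
    """One tube of one sample: a cells x channels matrix of float intensities.

    Parameters
    ----------
    sample_id : str
        Identifier of the biological sample.
    tube_id : int
        Staining tube number (1-8 in the standard panel layout).
    channels : list of str
        Ordered, unique channel names; must contain ``FSC`` and ``SSC``.
    values : ndarray of shape (n_cells, n_channels)
        Transformed intensities; all finite.
    """

    sample_id: str
    tube_id: int
    channels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D cells x channels matrix")
        if self.values.shape[0] < 1:
            raise FormatError("a cell matrix must contain at least one cell")
        if self.values.shape[1] != len(self.channels):
            raise SchemaError(
                f"{len(self.channels)} channel names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.channels)) != len(self.channels):
            raise FormatError(f"duplicate channel names in {self.channels}")
        for ch in REQUIRED_CHANNELS:
            if ch not in self.channels:
                raise FormatError(f"required channel {ch!r} missing")
        if not np.isfinite(self.values).all():
            raise FormatError("cell matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise SchemaError(f"unknown channel {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channels)


@dataclass
class DensityCurve:
    """Per-sample density estimates for one channel on a shared grid."""

    channel: str
    grid: np.ndarray  # bin centers, shape (grid_size,)
    densities: np.ndarray  # shape (n_samples, grid_size), each row >= 0
    sample_ids: list[str] = field(default_factory=list)


def read_tube_csv(
    path: str | Path, sample_id: str | None = None, tube_id: int = 0
) -> CellMatrix:
    """Read one (sample, tube) CSV file into a :class:`CellMatrix`.

    The file must have a single header row naming the channels and numeric
    cells throughout; row order is preserved.

    Raises
    ------
    FormatError
        Missing or duplicate channel columns.
    ParseError
        A non-numeric cell; the message names the offending data row (0-based)
        and column.
    """
    path = Path(path)
    with open(path, newline="") as handle:
        header = next(csv.reader(handle), None)
    if not header:
        raise FormatError(f"{path}: empty file, no header row")
    header = [h.strip() for h in header]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate channel columns {dupes}")

    df = pd.read_csv(
        path, header=0, names=header, skipinitialspace=True,
        float_precision="round_trip",
    )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else 0
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r} at row {row}"
            )
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise ParseError(f"{path}: missing value in column {col!r} at row {row}")

    if sample_id is None:
        sample_id = path.stem
    return CellMatrix(sample_id, int(tube_id), header, df.to_numpy(dtype=float))


def write_tube_csv(cells: CellMatrix, path: str | Path) -> Path:
    """Write a :class:`CellMatrix` as a headered CSV that round-trips exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g preserves every float64 bit pattern through the text round trip
    cells.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    return path


def normalize_fsc(
    cells: CellMatrix, target_mean: float = 0.0, target_sd: float = 0.1
) -> CellMatrix:
    """Affinely rescale the FSC column to ``target_mean`` / ``target_sd``.

    Applied per file so that the linear-scale FSC channel no longer dominates
    L1 distances; all other columns are returned bit-identical.  Sample
    standard deviation uses the n-1 denominator.  The map is idempotent and
    invariant to any prior affine rescaling of FSC.
    """
    if cells.n_cells < 2:
        raise DegenerateInputError("FSC rescaling needs at least two cells")
    j = cells.channel_index("FSC")
    fsc = cells.values[:, j]
    sd = float(fsc.std(ddof=1))
    if sd == 0.0:
        raise DegenerateInputError(
            f"sample {cells.sample_id} tube {cells.tube_id}: FSC has zero variance"
        )
    out = cells.values.copy()
    out[:, j] = (fsc - fsc.mean()) / sd * target_sd + target_mean
    return replace(cells, values=out)


class FscNormalizer(TransformerMixin, BaseEstimator):
    """scikit-learn style transformer wrapping :func:`normalize_fsc`.

    Stateless (the rescale is defined per file), so ``fit`` only records the
    channel count; ``transform`` accepts a single :class:`CellMatrix` or a
    sequence of them.
    """

    def __init__(self, target_mean: float = 0.0, target_sd: float = 0.1):
        self.target_mean = target_mean
        self.target_sd = target_sd

    def fit(self, X, y=None):  # noqa: D102 - sklearn signature
        items = [X] if isinstance(X, CellMatrix) else list(X)
        self.n_features_in_ = len(items[0].channels) if items else 0
        return self

    def transform(self, X):  # noqa: D102 - sklearn signature
        if isinstance(X, CellMatrix):
            return normalize_fsc(X, self.target_mean, self.target_sd)
        return [normalize_fsc(c, self.target_mean, self.target_sd) for c in X]


def channel_histograms(
    cohort: Sequence[CellMatrix], channel: str, grid_size: int = 128
) -> DensityCurve:
    """Per-sample density curves of one channel on a common grid.

    The grid spans the pooled range of the channel across the cohort; each
    curve is a normalized histogram (integrates to 1 over the grid).
    """
    if not cohort:
        raise DegenerateInputError("empty cohort")
    cols = [c.column(channel) for c in cohort]  # raises SchemaError if unknown
    lo = min(float(col.min()) for col in cols)
    hi = max(float(col.max()) for col in cols)
    if lo == hi:  # all mass at a single value: widen so density is defined
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, grid_size + 1)
    dens = np.stack([np.histogram(col, bins=edges, density=True)[0] for col in cols])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityCurve(channel, centers, dens, [c.sample_id for c in cohort])


# ---------------------------------------------------------------------------
# Sample manifest


MANIFEST_COLUMNS = ("sample_id", "tube_id", "path", "label")
VALID_LABELS = {"normal", "AML", "unknown"}


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample manifest.

    Columns ``sample_id, tube_id, path, label`` are required; an optional
    ``split`` column with values ``train``/``test`` marks the held-out set
    (otherwise every sample with a non-``unknown`` label is training).
    (sample_id, tube_id) pairs must be unique and training labels known.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["tube_id"] = df["tube_id"].astype(int)
    if df.duplicated(["sample_id", "tube_id"]).any():
        dup = df[df.duplicated(["sample_id", "tube_id"])].iloc[0]
        raise FormatError(
            f"duplicate manifest entry for sample {dup.sample_id!r} "
            f"tube {dup.tube_id}"
        )
    bad = set(df["label"]) - VALID_LABELS
    if bad:
        raise FormatError(f"unknown labels {sorted(bad)}; expected {sorted(VALID_LABELS)}")
    if "split" not in df.columns:
        df["split"] = np.where(df["label"] == "unknown", "test", "train")
    if ((df["split"] == "train") & (df["label"] == "unknown")).any():
        raise FormatError("training samples must carry a known label")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    validate_manifest(df).to_csv(path, index=False)
    return path
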