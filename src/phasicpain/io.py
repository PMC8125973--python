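"""Readers and writers for the pipeline's file formats.

Formats: OpenFace-style per-frame AU-intensity CSVs, sample manifests,
label files (ground truth or human observer), fold plans (JSON) and
results tables.  Readers validate strictly and reject malformed input;
every writer/reader pair is an exact inverse on valid data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AU_COLUMNS, CLASSES

__all__ = [
    "FormatError",
    "ValidationError",
    "LabelFile",
    "read_au_csv",
    "write_au_csv",
    "read_manifest",
    "write_manifest",
    "read_labels",
    "write_labels",
    "read_results",
    "write_results",
    "read_fold_plan",
    "write_fold_plan",
    "write_frame_pngs",
    "read_frame_pngs",
]


class FormatError(ValueError):
    """A file does not conform to its expected schema."""


class ValidationError(ValueError):
    """File contents are schema-valid but inconsistent with the manifest."""


MANIFEST_COLUMNS = ("sample_id", "subject_id", "class", "au_csv", "frames_dir")


@dataclass
class LabelFile:
    """Per-sample class assignments from ground truth or a human observer.

    Observer files may cover only a subset of the manifest (the observers
    labelled a random 10% of samples); ground-truth files must be complete.
    """

    labels: pd.DataFrame  # columns sample_id, class
    source: str  # "ground_truth" or "observer"

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.labels["sample_id"], self.labels["class"]))


# ---------------------------------------------------------------------------
# AU time-series CSVs (OpenFace dialect)
# ---------------------------------------------------------------------------

def read_au_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an OpenFace-style AU CSV into a (17, T) matrix plus timestamps.

    Rows of the returned matrix follow the canonical AU order; any extra
    columns (pose, gaze, ...) are ignored.  Missing AU columns or an empty
    file raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty AU CSV") from None
    df.columns = [c.strip() for c in df.columns]
    for col in AU_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing AU column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: AU CSV has a header but no rows")
    series = df.loc[:, list(AU_COLUMNS)].to_numpy(dtype=float).T
    if "timestamp" in df.columns:
        timestamps = df["timestamp"].to_numpy(dtype=float)
    else:
        timestamps = np.arange(series.shape[1], dtype=float)
    return series, timestamps


def write_au_csv(sample, path: str | Path) -> None:
    """Write a sample's AU series in the OpenFace CSV dialect."""
    n_t = sample.series.shape[1]
    df = pd.DataFrame({"frame": np.arange(1, n_t + 1),
                       "timestamp": np.arange(n_t) / sample.fps})
    for i, col in enumerate(AU_COLUMNS):
        df[col] = sample.series[i]
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    _check_manifest(manifest, where="manifest to write")
    manifest.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, skipinitialspace=True,
                         dtype={"sample_id": str, "class": str},
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty manifest") from None
    _check_manifest(df, where=str(path))
    df["subject_id"] = df["subject_id"].astype(int)
    return df.loc[:, list(MANIFEST_COLUMNS)]


def _check_manifest(df: pd.DataFrame, where: str) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{where}: missing manifest columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise FormatError(f"{where}: duplicate sample_id values {dupes[:5]}")
    bad = sorted(set(df["class"]) - set(CLASSES))
    if bad:
        raise FormatError(f"{where}: unknown class codes {bad}")


# ---------------------------------------------------------------------------
# label files
# ---------------------------------------------------------------------------

def read_labels(path: str | Path, manifest: pd.DataFrame,
                source: str = "ground_truth") -> LabelFile:
    """Read a label CSV and validate it against the manifest.

    Ground-truth files must cover every manifest sample; observer files may
    be partial but must not reference unknown sample ids.
    """
    if source not in ("ground_truth", "observer"):
        raise ValueError(f"unknown label source {source!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, skipinitialspace=True, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty label file") from None
    for col in ("sample_id", "class"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = sorted(set(df["class"]) - set(CLASSES))
    if bad:
        raise ValidationError(f"{path}: unknown class codes {bad}")
    known = set(manifest["sample_id"])
    unknown = sorted(set(df["sample_id"]) - known)
    if unknown:
        raise ValidationError(f"{path}: sample ids absent from manifest: {unknown[:10]}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated sample ids")
    if source == "ground_truth" and set(df["sample_id"]) != known:
        missing = sorted(known - set(df["sample_id"]))
        raise ValidationError(
            f"{path}: ground-truth labels must cover the manifest; "
            f"missing {len(missing)} ids, e.g. {missing[:5]}"
        )
    return LabelFile(labels=df.loc[:, ["sample_id", "class"]], source=source)


def write_labels(labels: LabelFile, path: str | Path) -> None:
    labels.labels.loc[:, ["sample_id", "class"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results tables, fold plans, frames
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty results file") from None


def write_fold_plan(assignment: dict[int, int], path: str | Path) -> None:
    """Serialize a fold plan as JSON mapping fold index -> subject id list."""
    folds: dict[str, list[int]] = {}
    for subject, fold in sorted(assignment.items()):
        folds.setdefault(str(fold), []).append(int(subject))
    Path(path).write_text(json.dumps(folds, indent=1, sort_keys=True))


def read_fold_plan(path: str | Path) -> dict[int, int]:
    data = json.loads(Path(path).read_text())
    assignment: dict[int, int] = {}
    for fold, subjects in data.items():
        for s in subjects:
            if int(s) in assignment:
                raise ValidationError(f"{path}: subject {s} appears in two folds")
            assignment[int(s)] = int(fold)
    return assignment


def write_frame_pngs(frames: list[np.ndarray], outdir: str | Path) -> list[Path]:
    """Write grayscale float frames (values in [0, 1]) as numbered PNGs."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = outdir / f"frame_{i:05d}.png"
        iio.imwrite(p, (np.clip(frame, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


def read_frame_pngs(frames_dir: str | Path) -> list[np.ndarray]:
    """Read a per-sample frame directory back into float images in [0, 1]."""
    import imageio.v3 as iio

    frames_dir = Path(frames_dir)
    paths = sorted(frames_dir.glob("frame_*.png"))
    if not paths:
        raise FormatError(f"{frames_dir}: no frame_*.png files")
    return [iio.imread(p).astype(float) / 255.0 for p in paths]
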