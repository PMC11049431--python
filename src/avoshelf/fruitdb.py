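"""Labeled fruit-image database: index semantics, Days Left, I/O, dry matter.

The database pairs each photograph (one fruit side on one day) with its
ordinal Ripening Index on both the 5-stage and 10-stage scale, plus the
``Days Left`` annotation: days from the photograph until the fruit first
reaches the end-of-shelf-life stage (stage 5 of 5 / stage 9 of 10).
Samples that never reach the endpoint within the observation window are
censored; their stages remain valid classification labels but Days Left is
undefined and they are excluded from shelf-life regression downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_orchard import END_STAGE10

__all__ = [
    "REQUIRED_COLUMNS",
    "VALID_GROUPS",
    "LabeledImageDatabase",
    "stage5_from_stage10",
    "dry_matter",
    "fruit_dry_matter",
    "annotate_days_left",
    "summarize_counts",
    "write_database",
    "read_database",
]

REQUIRED_COLUMNS = ["sample_id", "side", "group", "day", "date_stamp",
                    "ri5", "ri10", "days_left5", "days_left9", "censored"]
VALID_GROUPS = {"T10", "T20", "Tamb"}
_KEY = ["sample_id", "side", "day"]


def stage5_from_stage10(ri10):
    """Map a 10-stage index to its 5-stage parent: ceil(ri10 / 2).

    Each classical 5-stage phase was halved to form the 10-stage index, so
    10-stage pairs (1,2), (3,4), ... collapse onto 5-stage 1, 2, ...
    Accepts scalars or arrays of integers in 1..10.
    """
    arr = np.asarray(ri10)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("ri10 must be integer-valued")
        arr = arr.astype(int)
    if np.any((arr < 1) | (arr > 10)):
        raise ValueError("ri10 out of range 1..10")
    out = (arr + 1) // 2
    return int(out) if np.isscalar(ri10) or np.ndim(ri10) == 0 else out


def dry_matter(raw_flesh_mass: float, dehydrated_flesh_mass: float) -> float:
    """Dry matter percentage: dehydrated flesh mass over raw flesh mass.

    The standard harvest-maturity proxy for avocado (industry guidance
    recommends harvesting in roughly the 25-30% range).
    """
    if raw_flesh_mass <= 0:
        raise ValueError("raw flesh mass must be positive")
    if dehydrated_flesh_mass < 0 or dehydrated_flesh_mass > raw_flesh_mass:
        raise ValueError("dehydrated mass must lie in [0, raw mass]")
    return dehydrated_flesh_mass / raw_flesh_mass * 100.0


def fruit_dry_matter(samples) -> float:
    """Per-fruit DM%: mean over that fruit's flesh samples of (raw, dehydrated) pairs."""
    vals = [dry_matter(raw, dry) for raw, dry in samples]
    if not vals:
        raise ValueError("at least one flesh sample required")
    return float(np.mean(vals))


@dataclass
class LabeledImageDatabase:
    """Metadata table plus an image locator.

    ``records`` holds one row per photograph.  Images may live on disk
    (``image_dir`` + relative ``image_path`` column) or in memory
    (``images`` dict keyed by (sample_id, side, day)); either source is
    optional — the metadata table alone supports every non-visual analysis.
    """

    records: pd.DataFrame
    image_dir: Path | None = None
    images: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")
        dup = df.duplicated(subset=_KEY)
        if dup.any():
            row = df.loc[dup.idxmax(), _KEY]
            key = (int(row["sample_id"]), str(row["side"]), int(row["day"]))
            raise ValueError(f"duplicate (sample_id, side, day) key: {key}")
        bad_group = ~df["group"].isin(VALID_GROUPS)
        if bad_group.any():
            raise ValueError(f"unknown storage group {df.loc[bad_group.idxmax(), 'group']!r}")
        expected5 = stage5_from_stage10(df["ri10"].to_numpy())
        if np.any(expected5 != df["ri5"].to_numpy()):
            i = int(np.nonzero(expected5 != df["ri5"].to_numpy())[0][0])
            raise ValueError(f"ri5/ri10 inconsistent at row {i}: "
                             f"ri10={df['ri10'].iat[i]} ri5={df['ri5'].iat[i]}")

    def __len__(self) -> int:
        return len(self.records)

    def load_image(self, sample_id: int, side: str, day: int) -> np.ndarray:
        key = (sample_id, side, day)
        if self.images is not None and key in self.images:
            return self.images[key]
        if self.image_dir is not None:
            row = self.records.set_index(_KEY).loc[key]
            path = self.image_dir / row["image_path"]
            from PIL import Image
            return np.asarray(Image.open(path).convert("RGB"))
        raise KeyError(f"no image source for record {key}")


def annotate_days_left(db: LabeledImageDatabase) -> LabeledImageDatabase:
    """(Re)derive days_left5/days_left9 and censoring from stage histories.

    The endpoint day per sample is the first day any of its records reaches
    RI10 >= 9; both Days Left variants count down to that same physical day
    (their regressors differ, not their clocks), clipped at zero at and
    after the endpoint.  Samples never reaching the endpoint are censored
    with undefined Days Left.  Idempotent.
    """
    df = db.records.copy()
    ep = (df[df["ri10"] >= END_STAGE10].groupby("sample_id")["day"].min()
          .rename("_endpoint"))
    df = df.merge(ep, on="sample_id", how="left")
    reached = df["_endpoint"].notna()
    dl = (df["_endpoint"] - df["day"]).clip(lower=0).astype(float)
    df["days_left5"] = dl.where(reached)
    df["days_left9"] = dl.where(reached)
    df["censored"] = ~reached
    df = df.drop(columns="_endpoint")
    return LabeledImageDatabase(records=df, image_dir=db.image_dir, images=db.images)


def summarize_counts(db: LabeledImageDatabase, split=None, index: int = 10) -> pd.DataFrame:
    """Per-stage photograph counts by subset, with row/column totals.

    ``split`` (optional) is a DatasetSplit; without it a single "all"
    column is produced.  Mirrors a descriptive stage-by-subset tally of
    the database.
    """
    col = f"ri{index}"
    stages = list(range(1, index + 1))
    df = db.records
    if split is None:
        subsets = {"all": df}
    else:
        subsets = {name: df[df["sample_id"].isin(ids)]
                   for name, ids in (("train", split.train_ids),
                                     ("val", split.val_ids),
                                     ("test", split.test_ids))}
    out = pd.DataFrame(index=pd.Index(stages, name=col))
    for name, sub in subsets.items():
        counts = sub[col].value_counts().to_dict()
        out[name] = [int(counts.get(s, 0)) for s in stages]
    out["total"] = out.sum(axis=1)
    out.loc["total"] = out.sum(axis=0)
    return out


def write_database(db: LabeledImageDatabase, directory) -> Path:
    """Write metadata.csv (and PNG images when available) under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = db.records.copy()
    if db.images is not None:
        from PIL import Image
        img_dir = directory / "images"
        img_dir.mkdir(exist_ok=True)
        paths = []
        for row in df.itertuples(index=False):
            rel = f"images/s{row.sample_id:04d}_{row.side}_d{row.day:03d}.png"
            Image.fromarray(db.images[(row.sample_id, row.side, row.day)]).save(directory / rel)
            paths.append(rel)
        df["image_path"] = paths
    df.to_csv(directory / "metadata.csv", index=False)
    return directory / "metadata.csv"


def read_database(directory) -> LabeledImageDatabase:
    """Load a database directory; validates keys, groups and image files.

    Malformed rows are reported with their (1-based, header-exclusive) row
    number; duplicate (sample_id, side, day) keys and unknown storage
    groups raise with the offending value named.
    """
    directory = Path(directory)
    path = directory / "metadata.csv"
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("sample_id", "day", "ri5", "ri10"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 1
            raise ValueError(f"{path}: malformed {col!r} at row {row}")
        df[col] = coerced.astype(int)
    df["censored"] = df["censored"].astype(bool)
    has_images = "image_path" in df.columns and df["image_path"].notna().any()
    if has_images:
        for rel in df["image_path"].dropna():
            if not (directory / rel).is_file():
                raise FileNotFoundError(f"missing image file: {directory / rel}")
    return LabeledImageDatabase(records=df, image_dir=directory if has_images else None)
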