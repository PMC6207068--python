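"""Readers and writers for every table the pipeline touches.

Native format is headered TSV. IGV SEG is supported for segment tables
(1-based inclusive coordinates on export, converted back on import). BED
export of calls is 0-based half-open with the call label in the name
column.

Chromosome names are normalized to ``1..22, X, Y`` on input (``chr``
prefixes accepted). Y is legal in probe/segment files — it is removed by
:func:`armcall.preprocess.drop_chrY`, not rejected at parse time.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UnknownChromosomeError, ValidationError

logger = logging.getLogger(__name__)

VALID_CHROMS = [str(c) for c in range(1, 23)] + ["X", "Y"]

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "n_probes", "log2_ratio", "annotation"]
PROBE_COLUMNS = ["sample_id", "chrom", "position", "log2_ratio"]
ANNOTATION_COLUMNS = ["sample_id", "platform"]  # mandatory subset

_SEG_HEADER = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def normalize_chrom(value) -> str:
    name = str(value).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper() if name.upper() in ("X", "Y") else name
    if name not in VALID_CHROMS:
        raise UnknownChromosomeError(f"unknown chromosome {value!r}")
    return name


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    order = {c: i for i, c in enumerate(VALID_CHROMS)}
    return chrom.map(order)


def validate_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Check the SegmentTable invariants; returns the frame sorted."""
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"segment table missing columns: {missing}")
    df = df.copy()
    if df.empty:
        return df.reset_index(drop=True)
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df.n_probes < 1).any():
        raise ValidationError("segments must contain at least one probe")
    if not np.isfinite(df.log2_ratio).all():
        raise ValidationError("segment log2 ratios must be finite")
    if (df.end <= df.start).any():
        raise ValidationError("segments must have end > start")
    df = df.sort_values(["sample_id", "chrom", "start"], key=lambda s: _chrom_sort_key(s) if s.name == "chrom" else s)
    df = df.reset_index(drop=True)
    for (sample, chrom), grp in df.groupby(["sample_id", "chrom"], sort=False):
        overlap = grp.start.values[1:] < grp.end.values[:-1]
        if overlap.any():
            i = int(np.argmax(overlap))
            rows = (int(grp.index[i]), int(grp.index[i + 1]))
            raise ValidationError(
                f"overlapping segments for sample {sample} chrom {chrom}: rows {rows[0]} and {rows[1]}"
            )
    return df


def read_segments(path, dialect: str = "native", label_map: dict | None = None) -> pd.DataFrame:
    """Read a segment table.

    Parameters
    ----------
    dialect
        ``"native"`` (headered TSV with armcall's column names) or
        ``"seg"`` (IGV SEG; 1-based inclusive, converted to 0-based
        half-open).
    label_map
        Optional mapping applied to the annotation column, for ingesting
        externally produced tables whose call vocabulary differs.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={1: str})
    if dialect == "native":
        missing = [c for c in SEGMENT_COLUMNS[:-1] if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        if "annotation" not in df.columns:
            df["annotation"] = ""
    elif dialect == "seg":
        if list(df.columns[:6]) != _SEG_HEADER:
            raise ValidationError(f"{path}: not an IGV SEG header: {list(df.columns)}")
        df = df.rename(
            columns={
                "ID": "sample_id",
                "loc.start": "start",
                "loc.end": "end",
                "num.mark": "n_probes",
                "seg.mean": "log2_ratio",
            }
        )
        df["start"] = df["start"] - 1  # 1-based inclusive -> 0-based half-open
        df["annotation"] = df.get("annotation", "")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df["annotation"] = df["annotation"].fillna("")
    if label_map:
        df["annotation"] = df["annotation"].map(lambda x: label_map.get(x, x))
    return validate_segments(df[SEGMENT_COLUMNS])


def write_segments(df: pd.DataFrame, path, dialect: str = "native") -> None:
    df = validate_segments(df)
    path = Path(path)
    if dialect == "native":
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "seg":
        out = pd.DataFrame(
            {
                "ID": df.sample_id,
                "chrom": df.chrom,
                "loc.start": df.start + 1,  # 0-based half-open -> 1-based inclusive
                "loc.end": df.end,
                "num.mark": df.n_probes,
                "seg.mean": df.log2_ratio,
                "annotation": df.annotation,
            }
        )
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_probes(path) -> pd.DataFrame:
    """Read a probe-level table; out-of-order rows are sorted with a warning."""
    df = pd.read_csv(path, sep="\t", dtype={1: str})
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    sorted_df = df.sort_values(
        ["sample_id", "chrom", "position"],
        key=lambda s: _chrom_sort_key(s) if s.name == "chrom" else s,
        kind="stable",
    ).reset_index(drop=True)
    if not (df.reset_index(drop=True)[PROBE_COLUMNS] == sorted_df[PROBE_COLUMNS]).all().all():
        logger.warning("probe table %s was not sorted by (sample, chrom, position); sorting", path)
    dup = sorted_df.duplicated(["sample_id", "chrom", "position"])
    if dup.any():
        raise ValidationError(f"{path}: duplicate probe positions at rows {list(sorted_df.index[dup][:5])}")
    return sorted_df[PROBE_COLUMNS]


def write_probes(df: pd.DataFrame, path) -> None:
    df[PROBE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read the per-sample annotation table (platform, MYCN status, survival, ...)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.sample_id.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_ids")
    for time_col, event_col in (("os_time", "os_event"), ("efs_time", "efs_event")):
        if time_col in df.columns:
            times = df[time_col].dropna()
            if (times < 0).any():
                raise ValidationError(f"{path}: negative {time_col}")
        if event_col in df.columns:
            events = df[event_col].dropna()
            if not events.isin([0, 1]).all():
                raise ValidationError(f"{path}: {event_col} must be 0/1")
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(calls: pd.DataFrame, path) -> None:
    """Write aberrant segments as BED (0-based half-open, label in name column)."""
    aberrant = calls[calls.annotation.ne("") & calls.annotation.ne("normal")]
    out = pd.DataFrame(
        {
            "chrom": aberrant.chrom,
            "start": aberrant.start,
            "end": aberrant.end,
            "name": aberrant.sample_id.astype(str) + ":" + aberrant.annotation.astype(str),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"], dtype={0: str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    parts = df.name.str.split(":", n=1, expand=True)
    df["sample_id"] = parts[0]
    df["annotation"] = parts[1]
    return df
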