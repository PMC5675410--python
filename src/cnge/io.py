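"""Readers and writers for the tab-separated formats used by the pipeline.

Dialect: tab-separated, header row, UTF-8, '.' decimal.  Chromosome names are
normalized internally to bare labels ("chr1" and "1" both become "1"); the
probe-set filter is the stage that rejects Y.  Round-trips of canonical files
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .copynumber import Segment, SegmentedProfile

__all__ = [
    "normalize_chromosome",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_clinical",
    "write_clinical",
    "read_seg",
    "write_seg",
    "write_bed",
    "file_checksum",
]

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "num_markers", "seg_mean"]
ANNOTATION_COLUMNS = ["probe_set", "gene", "chromosome", "start", "stop"]
CLINICAL_COLUMNS = ["sample", "os_months", "event", "histology", "age", "stage"]


def normalize_chromosome(name) -> str:
    """Map 'chr1'/'1' dialects to the bare label '1' (likewise X, Y)."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def read_matrix(path: str | Path, index_name: str | None = None) -> pd.DataFrame:
    """Numeric TSV matrix with row identifiers in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                ) from exc
        raise
    if index_name:
        df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation missing columns {missing}")
    df["chromosome"] = df["chromosome"].map(
        lambda v: normalize_chromosome(v) if pd.notna(v) else v
    )
    return df.set_index("probe_set")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample", "os_months", "event") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {missing}")
    if (df["os_months"] <= 0).any():
        raise ValueError(f"{path}: os_months must be positive")
    return df.set_index("sample")


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_seg(path: str | Path) -> list[SegmentedProfile]:
    """SEG file -> per-sample profiles (sample order as first seen)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: SEG file missing columns {missing}")
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    profiles = []
    for sample, grp in df.groupby("sample", sort=False):
        segments = [
            Segment(
                chromosome=row.chromosome,
                start=int(row.start),
                end=int(row.end),
                n_markers=int(row.num_markers),
                mean_cn=float(row.seg_mean),
            )
            for row in grp.itertuples()
        ]
        profiles.append(SegmentedProfile(sample_id=sample, segments=segments))
    return profiles


def write_seg(profiles: list[SegmentedProfile], path: str | Path) -> None:
    frames = [p.to_frame() for p in profiles]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SEG_COLUMNS)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def write_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Hotspot regions as BED: chrom, start-1 (0-based half-open), end, name,
    gene count as score."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in regions.itertuples():
            fh.write(
                f"{row.chromosome}\t{int(row.start) - 1}\t{int(row.end)}\t"
                f"{row.name_}\t{int(row.n_genes)}\n"
            )


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
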