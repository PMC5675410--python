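"""Reference-centered copy-number estimation, segmentation, calls and tracks.

Copy numbers are expressed on a linear scale centered at 2: per marker, the
tumor intensity is divided by the median intensity across a panel of
non-cancer reference samples and multiplied by two, so a value of 2 means the
tumor equals the reference median, 4 means a doubling, and so on.  Marker
values are then segmented per sample and per chromosome with circular binary
segmentation, segment means are discretized into aberration calls, and
cohort-level frequency and quantile tracks are derived for plotting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .cbs import segment_values

logger = logging.getLogger(__name__)

__all__ = [
    "CopyNumberMatrix",
    "Segment",
    "SegmentedProfile",
    "CallCategory",
    "CallThresholds",
    "estimate_copy_number",
    "segment_profile",
    "segment_cohort",
    "segments_to_marker_matrix",
    "call_segments",
    "call_cohort",
    "aberration_frequency",
    "quantile_track",
]

#: marker table columns
MARKER_COLS = ["chromosome", "position"]


@dataclass
class CopyNumberMatrix:
    """Marker-level copy numbers on the 2-centered linear scale.

    ``values``: DataFrame (marker id index, one column per sample), >= 0.
    ``markers``: DataFrame (same index) with ``chromosome`` and ``position``;
    positions are 1-based and strictly increasing within each chromosome.
    """

    values: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.markers.index):
            raise ValueError("values and markers must share a marker index")
        for chrom, grp in self.markers.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"marker positions not strictly increasing on {chrom}"
                )
        if (self.values.to_numpy() < 0).any():
            raise ValueError("copy numbers must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chromosome"]))


@dataclass(frozen=True)
class Segment:
    chromosome: str
    start: int  # bp, 1-based inclusive
    end: int  # bp, 1-based inclusive
    n_markers: int
    mean_cn: float


@dataclass
class SegmentedProfile:
    """Piecewise-constant copy-number profile of one sample."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.sample_id, s.chromosome, s.start, s.end, s.n_markers, s.mean_cn)
                for s in self.segments
            ],
            columns=["sample", "chromosome", "start", "end", "num_markers", "seg_mean"],
        )


class CallCategory(IntEnum):
    """Aberration call; integer codes follow the common {-2..2} convention."""

    homozygous_deletion = -2
    loss = -1
    normal = 0
    gain = 1
    high_gain = 2


@dataclass(frozen=True)
class CallThresholds:
    """Segment-mean thresholds on the 2-centered scale.

    Boundary values are assigned to the lower-severity side: a mean exactly at
    ``gain`` is still normal, one exactly at ``high_gain`` is still gain.
    """

    homozygous_deletion: float = 0.75
    loss: float = 1.7
    gain: float = 2.3
    high_gain: float = 4.0

    def __post_init__(self) -> None:
        t = (self.homozygous_deletion, self.loss, self.gain, self.high_gain)
        if not all(a < b for a, b in zip(t, t[1:])):
            raise ValueError(f"call thresholds must be strictly increasing: {t}")

    def call(self, mean_cn: float) -> CallCategory:
        if mean_cn < self.homozygous_deletion:
            return CallCategory.homozygous_deletion
        if mean_cn < self.loss:
            return CallCategory.loss
        if mean_cn <= self.gain:
            return CallCategory.normal
        if mean_cn <= self.high_gain:
            return CallCategory.gain
        return CallCategory.high_gain


def estimate_copy_number(
    tumor_intensities: pd.DataFrame,
    reference_intensities: pd.DataFrame,
    markers: pd.DataFrame,
) -> CopyNumberMatrix:
    """CN_{m,i} = 2 * tumor intensity / median reference intensity at marker m.

    Markers whose reference median is zero (or negative) cannot be centered;
    they are dropped with a logged count.
    """
    if not tumor_intensities.index.equals(reference_intensities.index):
        raise ValueError("tumor and reference matrices must share the marker set and order")
    ref_median = reference_intensities.median(axis=1)
    bad = ref_median <= 0
    if bad.any():
        logger.warning(
            "excluding %d markers with non-positive reference median", int(bad.sum())
        )
    keep = ~bad
    values = 2.0 * tumor_intensities.loc[keep].div(ref_median.loc[keep], axis=0)
    return CopyNumberMatrix(values=values, markers=markers.loc[keep, MARKER_COLS])


def segment_profile(
    values: pd.Series | np.ndarray,
    markers: pd.DataFrame,
    sample_id: str = "sample",
    alpha: float = 0.01,
    n_perm: int = 10_000,
    min_width: int = 2,
    seed: int | np.random.Generator | None = 0,
    n_perm_cap: int = 199,
) -> SegmentedProfile:
    """Segment one sample's marker values per chromosome with CBS."""
    vals = np.asarray(values, dtype=float)
    if vals.size != len(markers):
        raise ValueError("values and markers differ in length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    segments: list[Segment] = []
    offset = 0
    for chrom, grp in markers.groupby("chromosome", sort=False):
        m = len(grp)
        pos = grp["position"].to_numpy()
        x = vals[offset : offset + m]
        if m < min_width:
            warnings.warn(
                f"chromosome {chrom}: {m} markers < min_width {min_width}; "
                "returning a single trivial segment"
            )
            pieces = [(0, m, float(x.mean()))]
        else:
            pieces = segment_values(
                x, alpha=alpha, n_perm=n_perm, min_width=min_width, seed=rng,
                n_perm_cap=n_perm_cap,
            )
        for s, e, mean in pieces:
            segments.append(
                Segment(
                    chromosome=chrom,
                    start=int(pos[s]),
                    end=int(pos[e - 1]),
                    n_markers=e - s,
                    mean_cn=mean,
                )
            )
        offset += m
    return SegmentedProfile(sample_id=sample_id, segments=segments)


def segment_cohort(
    cnm: CopyNumberMatrix,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    min_width: int = 2,
    seed: int = 0,
    n_perm_cap: int = 199,
) -> list[SegmentedProfile]:
    """Segment every sample of a cohort; one child RNG stream per sample."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(cnm.samples))
    profiles = []
    for child, sample in zip(children, cnm.samples):
        profiles.append(
            segment_profile(
                cnm.values[sample].to_numpy(),
                cnm.markers,
                sample_id=sample,
                alpha=alpha,
                n_perm=n_perm,
                min_width=min_width,
                seed=np.random.default_rng(child),
                n_perm_cap=n_perm_cap,
            )
        )
    return profiles


def segments_to_marker_matrix(
    profiles: list[SegmentedProfile], markers: pd.DataFrame
) -> pd.DataFrame:
    """Marker x sample matrix of segment means (segmented CN values)."""
    out = {}
    chrom_arr = markers["chromosome"].to_numpy()
    pos_arr = markers["position"].to_numpy()
    for prof in profiles:
        col = np.empty(len(markers))
        col.fill(np.nan)
        for seg in prof.segments:
            mask = (chrom_arr == seg.chromosome) & (pos_arr >= seg.start) & (pos_arr <= seg.end)
            col[mask] = seg.mean_cn
        out[prof.sample_id] = col
    return pd.DataFrame(out, index=markers.index)


def call_segments(
    profile: SegmentedProfile,
    markers: pd.DataFrame,
    thresholds: CallThresholds | None = None,
) -> pd.Series:
    """Per-marker call codes for one sample; each marker inherits the call of
    its covering segment."""
    thresholds = thresholds or CallThresholds()
    chrom_arr = markers["chromosome"].to_numpy()
    pos_arr = markers["position"].to_numpy()
    codes = np.zeros(len(markers), dtype=int)
    for seg in profile.segments:
        mask = (chrom_arr == seg.chromosome) & (pos_arr >= seg.start) & (pos_arr <= seg.end)
        codes[mask] = int(thresholds.call(seg.mean_cn))
    return pd.Series(codes, index=markers.index, name=profile.sample_id)


def call_cohort(
    profiles: list[SegmentedProfile],
    markers: pd.DataFrame,
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    """Marker x sample matrix of call codes."""
    return pd.concat(
        [call_segments(p, markers, thresholds) for p in profiles], axis=1
    )


def aberration_frequency(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-marker fraction of samples in each call category.

    Also reports the combined gain (gain + high_gain) and combined loss
    (loss + homozygous_deletion) fractions used in frequency plots.
    """
    if calls.shape[1] < 1:
        raise ValueError("at least one sample required")
    n = calls.shape[1]
    arr = calls.to_numpy()
    out = pd.DataFrame(index=calls.index)
    for cat in CallCategory:
        out[cat.name] = (arr == int(cat)).sum(axis=1) / n
    out["any_gain"] = out["gain"] + out["high_gain"]
    out["any_loss"] = out["loss"] + out["homozygous_deletion"]
    return out


def quantile_track(segmented: pd.DataFrame, q: float) -> pd.Series:
    """Per-marker ``q``-quantile of segmented CN values across samples.

    Uses the linear-interpolation quantile definition (numpy default), so for
    five samples [2, 2, 2, 2, 6] the 0.95 quantile is 5.2.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if segmented.shape[1] == 0:
        raise ValueError("empty sample set")
    return pd.Series(
        np.quantile(segmented.to_numpy(), q, axis=1),
        index=segmented.index,
        name=f"q{q:g}",
    )
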