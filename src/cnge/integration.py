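"""Probe-set to genome integration: positions, filtering, CN matching, tracks.

Each expression probe set is assigned a single genomic position (the midpoint
of its annotated min start / max stop, floored), filtered for usable
localization (unique autosomal/X chromosome), and matched per sample to the
copy-number segment covering that position.  The result is the paired
CN-expression table that the correlation stage consumes, plus plot-ready
moving-statistic tracks.

Coordinates are 1-based, fully closed intervals throughout.  A position tied
between two segments resolves to the covering segment with the smaller start;
a position falling in a gap between segments is matched to the nearest
segment on the same chromosome (distance recorded in the exclusion log).
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .copynumber import CallThresholds, SegmentedProfile

logger = logging.getLogger(__name__)

__all__ = [
    "PairedData",
    "derive_probe_position",
    "filter_probesets",
    "match_cn",
    "build_paired_data",
    "moving_track",
]

_AMBIGUOUS = re.compile(r"///|[,;|]")


@dataclass
class PairedData:
    """Matched expression / segmented-CN vectors per retained probe set."""

    annotation: pd.DataFrame  # includes derived 'position'
    expression: pd.DataFrame  # probe set x sample (linear scale)
    cn: pd.DataFrame  # probe set x sample (segment means)
    calls: pd.DataFrame  # probe set x sample (call codes)
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (
            self.expression.columns.equals(self.cn.columns)
            and self.expression.index.equals(self.cn.index)
        ):
            raise ValueError("expression and CN matrices must align")


def derive_probe_position(min_start: int, max_stop: int) -> int:
    """floor((min_start + max_stop) / 2); ties round down."""
    return (int(min_start) + int(max_stop)) // 2


def filter_probesets(annotation: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop probe sets without a usable genomic localization.

    Removed: missing chromosome, ambiguous chromosome (several entries), and
    chromosome Y.  Returns the retained table (with a derived ``position``
    column) and a log of exclusion counts per reason.
    """
    chrom = annotation["chromosome"]
    as_str = chrom.astype("string").str.strip()
    missing = chrom.isna() | (as_str == "")
    ambiguous = ~missing & as_str.str.contains(_AMBIGUOUS, regex=True, na=False)
    chry = ~missing & ~ambiguous & (as_str.str.upper() == "Y")
    keep = ~(missing | ambiguous | chry)
    retained = annotation.loc[keep].copy()
    retained["position"] = [
        derive_probe_position(s, e)
        for s, e in zip(retained["start"], retained["stop"])
    ]
    bad = retained["start"] > retained["stop"]
    if bad.any():
        raise ValueError(
            f"annotation rows with start > stop: {list(retained.index[bad])[:5]}"
        )
    log = {
        "retained": int(keep.sum()),
        "excluded_missing": int(missing.sum()),
        "excluded_ambiguous": int(ambiguous.sum()),
        "excluded_chrY": int(chry.sum()),
    }
    logger.info("probe-set filter: %s", log)
    return retained, log


def _segment_arrays(profile: SegmentedProfile) -> dict:
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in dict.fromkeys(s.chromosome for s in profile.segments):
        segs = sorted(
            (s for s in profile.segments if s.chromosome == chrom),
            key=lambda s: s.start,
        )
        by_chrom[chrom] = (
            np.array([s.start for s in segs]),
            np.array([s.end for s in segs]),
            np.array([s.mean_cn for s in segs]),
        )
    return by_chrom


def match_cn(
    annotation: pd.DataFrame,
    profiles: list[SegmentedProfile],
    max_gap: float = math.inf,
) -> tuple[pd.DataFrame, dict]:
    """Per probe set and sample, the mean CN of the covering segment.

    ``annotation`` must carry the derived ``position`` column (see
    :func:`filter_probesets`).  Positions in gaps between segments use the
    nearest segment within ``max_gap`` bp.  Probe sets on chromosomes absent
    from the CN data are dropped and logged.
    """
    cn_chroms = set()
    for p in profiles:
        cn_chroms |= {s.chromosome for s in p.segments}
    probe_chroms = set(annotation["chromosome"])
    if not probe_chroms & cn_chroms:
        raise ValueError(
            "no overlap in chromosome names between annotation "
            f"({sorted(probe_chroms)[:5]}...) and CN segments "
            f"({sorted(cn_chroms)[:5]}...); check naming"
        )
    keep = annotation["chromosome"].isin(cn_chroms)
    dropped = annotation.index[~keep]
    ann = annotation.loc[keep]
    out = np.empty((len(ann), len(profiles)))
    gap_hits = 0
    max_gap_seen = 0
    for j, profile in enumerate(profiles):
        by_chrom = _segment_arrays(profile)
        for chrom, grp in ann.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            rows = ann.index.get_indexer(grp.index)
            starts, ends, means = by_chrom[chrom]
            # covering segment: last one with start <= pos (ties -> smaller start
            # handled by searchsorted side='right' picking the first cover)
            k = np.searchsorted(starts, pos, side="right") - 1
            k = np.clip(k, 0, len(starts) - 1)
            # boundary tie: if the previous segment also covers (overlapping
            # ends), the segment with the smaller start wins
            prev_covers = (k > 0) & (pos <= ends[np.maximum(k - 1, 0)])
            k = np.where(prev_covers, k - 1, k)
            covered = (starts[k] <= pos) & (pos <= ends[k])
            vals = means[k].copy()
            if not covered.all():
                for where in np.nonzero(~covered)[0]:
                    p = pos[where]
                    d_prev = p - ends[k[where]] if p > ends[k[where]] else np.inf
                    nxt = min(k[where] + 1, len(starts) - 1)
                    d_next = starts[nxt] - p if starts[nxt] > p else np.inf
                    d = min(d_prev, d_next)
                    if d > max_gap:
                        vals[where] = np.nan
                        continue
                    # ties go to the downstream segment
                    vals[where] = means[nxt] if d_next <= d_prev else means[k[where]]
                    gap_hits += 1
                    max_gap_seen = max(max_gap_seen, int(d))
            out[rows, j] = vals
    cn = pd.DataFrame(out, index=ann.index, columns=[p.sample_id for p in profiles])
    log = {
        "dropped_no_cn_chromosome": int(len(dropped)),
        "gap_matches": gap_hits,
        "max_gap_bp": max_gap_seen,
    }
    if len(dropped):
        logger.info("dropped %d probe sets on chromosomes without CN data", len(dropped))
    return cn, log


def build_paired_data(
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    profiles: list[SegmentedProfile],
    thresholds: CallThresholds | None = None,
    max_gap: float = math.inf,
) -> PairedData:
    """Filter probe sets, match CN segments, and align expression.

    Expression values pass through unchanged; only rows are subset.
    """
    thresholds = thresholds or CallThresholds()
    retained, filter_log = filter_probesets(annotation)
    missing_expr = retained.index.difference(expression.index)
    if len(missing_expr):
        logger.warning(
            "%d annotated probe sets missing from the expression matrix",
            len(missing_expr),
        )
        retained = retained.loc[retained.index.intersection(expression.index)]
    cn, match_log = match_cn(retained, profiles, max_gap=max_gap)
    retained = retained.loc[cn.index]
    expr = expression.loc[cn.index, cn.columns]
    v = cn.to_numpy()
    codes = np.select(
        [
            v < thresholds.homozygous_deletion,
            v < thresholds.loss,
            v <= thresholds.gain,
            v <= thresholds.high_gain,
        ],
        [-2, -1, 0, 1],
        default=2,
    )
    codes[~np.isfinite(v)] = 0
    calls = pd.DataFrame(codes, index=cn.index, columns=cn.columns)
    return PairedData(
        annotation=retained,
        expression=expr,
        cn=cn,
        calls=calls,
        log={**filter_log, **match_log},
    )


def moving_track(
    values: pd.Series,
    chromosomes: pd.Series,
    window: int = 301,
    statistic: str = "median",
    q: float | None = None,
) -> pd.Series:
    """Centered moving statistic over probe sets in genomic order.

    Computed per chromosome (windows never span chromosome boundaries) with
    the window truncated at chromosome ends.  ``statistic`` is ``"median"``
    or ``"quantile"`` (with ``q``); the default window of 301 probe sets is
    the convention for expression tracks.
    """
    if window <= 0 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if statistic not in ("median", "quantile"):
        raise ValueError("statistic must be 'median' or 'quantile'")
    if statistic == "quantile" and not (q is not None and 0 < q < 1):
        raise ValueError("quantile statistic needs q in (0, 1)")
    out = []
    for chrom, grp in values.groupby(chromosomes, sort=False):
        if window > len(grp):
            warnings.warn(
                f"window {window} exceeds {len(grp)} probe sets on chromosome "
                f"{chrom}; using the whole-chromosome statistic"
            )
        roll = grp.rolling(window, center=True, min_periods=1)
        track = roll.median() if statistic == "median" else roll.quantile(q)
        out.append(track)
    return pd.concat(out).loc[values.index]
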