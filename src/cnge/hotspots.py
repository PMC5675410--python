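"""Genomic hotspot scan: windows dense in highly correlating genes.

The genome is scanned with fixed-width windows (defaults 5, 10, 15, 20 and
50 Mbp) for regions containing at least ``min_genes`` (default 10) highly
correlating genes; qualifying windows are merged into maximal regions.

Candidate windows are anchored at the positions of highly correlating genes
(left edge).  Window counts only change at gene positions, so anchoring at
them finds every qualifying window that any continuous "moving" placement
would: a window W with >= k flagged genes can be slid right until its left
edge hits its leftmost flagged member without losing any member, producing an
anchored window with the same (or larger) count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HotspotConfig",
    "gene_table",
    "scan_windows",
    "merge_regions",
    "find_hotspots",
]


@dataclass(frozen=True)
class HotspotConfig:
    window_widths: tuple[int, ...] = (
        5_000_000,
        10_000_000,
        15_000_000,
        20_000_000,
        50_000_000,
    )
    min_genes: int = 10
    unit: str = "genes"  # or "probe_sets"

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.window_widths):
            raise ValueError("window widths must be positive")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if self.unit not in ("genes", "probe_sets"):
            raise ValueError("unit must be 'genes' or 'probe_sets'")


def gene_table(eccc_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe-set ECCC table to gene level.

    A gene is highly correlating if any of its probe sets is; its position is
    the median of its probe-set positions; its ECCC is the max over probe
    sets (several probe sets may target one gene).
    """
    grp = eccc_table.groupby("gene", sort=False)
    out = pd.DataFrame(
        {
            "chromosome": grp["chromosome"].first(),
            "position": grp["position"].median().astype(int),
            "eccc": grp["eccc"].max(),
            "flagged": grp["high_correlation"].any(),
            "n_flagged_probesets": grp["high_correlation"].sum().astype(int),
            "n_probesets": grp.size(),
        }
    )
    return out.sort_values(["chromosome", "position"], kind="stable")


def scan_windows(
    genes: pd.DataFrame, width: int, min_genes: int = 10, unit: str = "genes"
) -> list[dict]:
    """Qualifying windows [p, p + width] anchored at flagged gene positions.

    ``genes`` is the output of :func:`gene_table` (positions sorted within
    chromosome).  With ``unit='probe_sets'`` the count is of flagged probe
    sets instead of distinct flagged genes.
    """
    windows = []
    flagged = genes[genes["flagged"]]
    for chrom, grp in flagged.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        n_ps = grp["n_flagged_probesets"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        n_ps = n_ps[order]
        names = grp.index.to_numpy()[order]
        for a, p in enumerate(pos):
            hi = np.searchsorted(pos, p + width, side="right")
            members = names[a:hi]
            n_genes = hi - a
            n_probesets = int(n_ps[a:hi].sum())
            count = n_genes if unit == "genes" else n_probesets
            if count >= min_genes:
                windows.append(
                    {
                        "chromosome": chrom,
                        "start": int(p),
                        "end": int(p + width),
                        "width": int(width),
                        "n_genes": int(n_genes),
                        "n_probesets": n_probesets,
                        "members": list(members),
                        "member_positions": pos[a:hi].tolist(),
                        "member_ps": n_ps[a:hi].tolist(),
                    }
                )
    return windows


def merge_regions(windows: list[dict]) -> pd.DataFrame:
    """Union overlapping/adjacent qualifying windows of one width.

    Region boundaries are clipped to the outermost member gene positions;
    member lists and counts are recomputed over the distinct union.
    """
    if not windows:
        return pd.DataFrame(
            columns=[
                "chromosome",
                "start",
                "end",
                "width",
                "n_genes",
                "n_probesets",
                "members",
                "name_",
            ]
        )
    widths = {w["width"] for w in windows}
    if len(widths) > 1:
        raise ValueError("merge_regions expects windows from a single width")
    rows = []
    by_chrom: dict[str, list[dict]] = {}
    for w in windows:
        by_chrom.setdefault(w["chromosome"], []).append(w)
    for chrom in by_chrom:
        ws = sorted(by_chrom[chrom], key=lambda w: w["start"])
        cluster = [ws[0]]
        for w in ws[1:]:
            if w["start"] <= cluster[-1]["end"] + 1:  # overlapping or adjacent
                cluster.append(w)
            else:
                rows.append(_collapse(chrom, cluster))
                cluster = [w]
        rows.append(_collapse(chrom, cluster))
    out = pd.DataFrame(rows)
    out["name_"] = [
        f"hotspot_{r.chromosome}_{i}" for i, r in enumerate(out.itertuples())
    ]
    return out.sort_values(["chromosome", "start"], ignore_index=True)


def _collapse(chrom: str, cluster: list[dict]) -> dict:
    positions: dict[str, int] = {}
    ps_count: dict[str, int] = {}
    for w in cluster:
        for g, p, k in zip(w["members"], w["member_positions"], w["member_ps"]):
            positions[g] = p
            ps_count[g] = k
    member_list = sorted(positions, key=lambda g: positions[g])
    return {
        "chromosome": chrom,
        "start": int(min(positions.values())),
        "end": int(max(positions.values())),
        "width": cluster[0]["width"],
        "n_genes": len(member_list),
        "n_probesets": int(sum(ps_count.values())),
        "members": member_list,
    }


def find_hotspots(
    eccc_table: pd.DataFrame, config: HotspotConfig | None = None
) -> dict[int, pd.DataFrame]:
    """Merged hotspot regions per window width."""
    config = config or HotspotConfig()
    genes = gene_table(eccc_table)
    out = {}
    for width in config.window_widths:
        windows = scan_windows(genes, width, config.min_genes, config.unit)
        out[width] = merge_regions(windows)
    return out
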