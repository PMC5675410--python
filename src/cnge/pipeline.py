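"""End-to-end orchestration: CN estimation -> segmentation -> calls and
frequency tracks -> probe-set integration -> ECCC -> hotspots -> survival
screening and meta-analysis -> enrichment.

A run is driven by a single :class:`RunConfig` (loadable from YAML) and a
root seed; every stochastic stage derives its generator from that seed, so
two runs with the same config produce checksum-identical artifacts.  Stages
degrade gracefully: without clinical tables the survival stages are skipped
with an explicit notice while correlation outputs are still produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .copynumber import (
    CallThresholds,
    aberration_frequency,
    call_cohort,
    estimate_copy_number,
    quantile_track,
    segment_cohort,
    segments_to_marker_matrix,
)
from .correlation import (
    CenteringSpec,
    eccc_table,
    permutation_null,
    quantile_class_analysis,
)
from .hotspots import HotspotConfig, find_hotspots
from .integration import build_paired_data, moving_track
from .survival import (
    auc,
    cox_univariate,
    detect_duplicates,
    dichotomize_two_year,
    enrichment_fisher,
    meta_analyze_probesets,
)
from .synthetic import SimulationConfig, generate_cohort, simulate_meta_cohorts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultBundle", "run_all"]


@dataclass
class RunConfig:
    """All pipeline parameters; paths are optional when ``synthetic=True``."""

    out_dir: str = "cnge_run"
    seed: int = 0
    synthetic: bool = True
    synthetic_params: dict = field(default_factory=dict)
    # file inputs (used when synthetic=False)
    expression_path: str | None = None
    annotation_path: str | None = None
    tumor_intensities_path: str | None = None
    reference_intensities_path: str | None = None
    markers_path: str | None = None  # TSV: marker, chromosome, position
    seg_path: str | None = None  # alternative to intensities
    clinical_path: str | None = None
    # stage parameters
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 10_000
    cbs_n_perm_cap: int = 199
    cbs_min_width: int = 2
    call_thresholds: dict = field(default_factory=dict)
    cn_center: float = 2.0
    high_threshold: float = 0.7
    moderate_threshold: float = 0.5
    fdr_threshold: float = 0.05
    null_n_perm: int = 20
    moving_window: int = 301
    hotspot_widths: tuple[int, ...] = (5_000_000, 10_000_000, 15_000_000, 20_000_000, 50_000_000)
    hotspot_min_genes: int = 10
    run_meta: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hotspot_widths" in data:
            data["hotspot_widths"] = tuple(data["hotspot_widths"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    out_dir: Path
    manifest: dict[str, str]  # relative path -> sha256
    metadata: dict
    notices: list[str]

    def write(self) -> None:
        cio.write_json(
            {"manifest": self.manifest, "metadata": self.metadata, "notices": self.notices},
            self.out_dir / "bundle.json",
        )


def _load_inputs(config: RunConfig):
    if config.synthetic:
        params = dict(config.synthetic_params)
        params.setdefault("seed", config.seed)
        sim = SimulationConfig(**params)
        cohort = generate_cohort(sim)
        meta_cohorts = simulate_meta_cohorts(sim) if config.run_meta else []
        return cohort, meta_cohorts, sim
    expression = cio.read_matrix(config.expression_path)
    annotation = cio.read_annotation(config.annotation_path)
    markers = None
    tumor = reference = None
    if config.tumor_intensities_path:
        tumor = cio.read_matrix(config.tumor_intensities_path)
        reference = cio.read_matrix(config.reference_intensities_path)
        markers = pd.read_csv(config.markers_path, sep="\t", index_col=0,
                              dtype={"chromosome": str})
        markers["chromosome"] = markers["chromosome"].map(cio.normalize_chromosome)
    clinical = cio.read_clinical(config.clinical_path) if config.clinical_path else None
    from .synthetic import GroundTruth, SyntheticCohort

    cohort = SyntheticCohort(
        name="input",
        tumor_intensities=tumor,
        reference_intensities=reference,
        markers=markers,
        expression=expression,
        annotation=annotation,
        clinical=clinical,
        ground_truth=GroundTruth({}, {}, {}, []),
    )
    return cohort, [], None


def run_all(config: RunConfig) -> ResultBundle:
    """Execute every stage and write the artifact bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notices: list[str] = []
    t0 = time.time()

    cohort, meta_cohorts, _sim = _load_inputs(config)

    # --- copy number ------------------------------------------------------
    profiles = None
    if cohort.tumor_intensities is not None:
        cnm = estimate_copy_number(
            cohort.tumor_intensities, cohort.reference_intensities, cohort.markers
        )
        cio.write_matrix(cnm.values.round(6), out / "copy_number.tsv")
        profiles = segment_cohort(
            cnm,
            alpha=config.cbs_alpha,
            n_perm=config.cbs_n_perm,
            min_width=config.cbs_min_width,
            seed=config.seed,
            n_perm_cap=config.cbs_n_perm_cap,
        )
        cio.write_seg(profiles, out / "segments.seg")
        thresholds = CallThresholds(**config.call_thresholds)
        calls = call_cohort(profiles, cnm.markers, thresholds)
        calls.to_csv(out / "calls.tsv", sep="\t", lineterminator="\n")
        freq = aberration_frequency(calls)
        freq.round(6).to_csv(out / "aberration_frequency.tsv", sep="\t", lineterminator="\n")
        segmented = segments_to_marker_matrix(profiles, cnm.markers)
        track95 = quantile_track(segmented, 0.95)
        track95.round(6).to_csv(out / "cn_q95_track.tsv", sep="\t", lineterminator="\n")
    elif config.seg_path:
        profiles = cio.read_seg(config.seg_path)
    else:
        raise ValueError("neither intensities nor a SEG file provided")

    # --- integration ------------------------------------------------------
    thresholds = CallThresholds(**config.call_thresholds)
    paired = build_paired_data(
        cohort.expression, cohort.annotation, profiles, thresholds=thresholds
    )
    cio.write_json(paired.log, out / "integration_log.json")

    ge_median = paired.expression.median(axis=1)
    tracks = pd.DataFrame(
        {
            "chromosome": paired.annotation["chromosome"],
            "position": paired.annotation["position"],
            "median_ge": ge_median,
            "moving_median_ge": moving_track(
                ge_median, paired.annotation["chromosome"], config.moving_window
            ),
            "moving_q05_ge": moving_track(
                ge_median, paired.annotation["chromosome"], config.moving_window,
                "quantile", q=0.05,
            ),
            "moving_q95_ge": moving_track(
                ge_median, paired.annotation["chromosome"], config.moving_window,
                "quantile", q=0.95,
            ),
        }
    )
    tracks.round(6).to_csv(out / "expression_tracks.tsv", sep="\t", lineterminator="\n")

    # --- correlation ------------------------------------------------------
    centering = CenteringSpec(cn_center=config.cn_center)
    records = eccc_table(
        paired,
        centering,
        high_threshold=config.high_threshold,
        moderate_threshold=config.moderate_threshold,
        fdr_threshold=config.fdr_threshold,
    )
    records.round(6).to_csv(out / "eccc.tsv", sep="\t", lineterminator="\n")
    null = permutation_null(paired, n_perm=config.null_n_perm, seed=config.seed,
                            centering=centering)
    pd.Series(null["null_values"]).round(6).to_csv(
        out / "eccc_null.tsv", sep="\t", lineterminator="\n", header=["null_eccc"]
    )
    classes = {
        strat: quantile_class_analysis(records, strat)
        for strat in ("median_ge", "median_cn")
    }
    cio.write_json(classes, out / "quantile_classes.json")

    # --- hotspots ---------------------------------------------------------
    hs_config = HotspotConfig(
        window_widths=tuple(config.hotspot_widths), min_genes=config.hotspot_min_genes
    )
    regions_by_width = find_hotspots(records, hs_config)
    for width, regions in regions_by_width.items():
        exportable = regions.drop(columns=["members"]).assign(
            members=[";".join(m) for m in regions["members"]] if len(regions) else []
        )
        exportable.to_csv(
            out / f"hotspots_{width // 1_000_000}Mbp.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
        if len(regions):
            cio.write_bed(regions, out / f"hotspots_{width // 1_000_000}Mbp.bed")

    # --- survival ---------------------------------------------------------
    if cohort.clinical is not None:
        clinical = cohort.clinical.loc[paired.expression.columns]
        outcome, n_excluded = dichotomize_two_year(clinical)
        known = outcome.notna()
        auc_rows = []
        expr_arr = paired.expression.loc[:, clinical.index[known]].to_numpy()
        cn_arr = paired.cn.loc[:, clinical.index[known]].to_numpy()
        out_known = outcome[known]
        for i, ps in enumerate(paired.expression.index):
            auc_rows.append(
                (ps, auc(expr_arr[i], out_known), auc(cn_arr[i], out_known))
            )
        auc_df = pd.DataFrame(
            auc_rows, columns=["probe_set", "auc_expression", "auc_cn"]
        ).set_index("probe_set")
        auc_df.round(6).to_csv(out / "auc_two_year.tsv", sep="\t", lineterminator="\n")

        flagged = records.index[records["high_correlation"]]
        cox_rows = []
        for ps in flagged:
            res = cox_univariate(
                paired.expression.loc[ps, clinical.index].to_numpy(), clinical, name=ps
            )
            cox_rows.append(dataclasses.asdict(res))
        cox_df = pd.DataFrame(cox_rows)
        if len(cox_df):
            cox_df = cox_df.set_index("probe_set")
        cox_df.round(6).to_csv(out / "cox_highly_correlating.tsv", sep="\t",
                               lineterminator="\n")

        if meta_cohorts:
            dup = detect_duplicates(
                {c.name: c.expression for c in meta_cohorts}
            )
            dup.to_csv(out / "duplicates.tsv", sep="\t", index=False, lineterminator="\n")
            removed = set(zip(dup["remove_cohort"], dup["remove_sample"]))
            cohorts = {}
            for c in meta_cohorts:
                keep = [s for s in c.expression.columns if (c.name, s) not in removed]
                cohorts[c.name] = (c.expression[keep], c.clinical.loc[keep])
            meta = meta_analyze_probesets(cohorts, list(flagged))
            meta_out = meta.drop(columns=["studies", "study_log_hr", "study_se",
                                          "study_weight"])
            meta_out.round(6).to_csv(out / "meta_analysis.tsv", sep="\t",
                                     lineterminator="\n")
            forest_rows = []
            for ps, row in meta.iterrows():
                for study, b, s, w in zip(row["studies"], row["study_log_hr"],
                                          row["study_se"], row["study_weight"]):
                    forest_rows.append((ps, study, b, s, b - 1.96 * s, b + 1.96 * s, w))
                if np.isfinite(row["pooled_log_hr"]):
                    forest_rows.append(
                        (ps, "pooled", row["pooled_log_hr"], row["pooled_se"],
                         row["ci_low"], row["ci_high"], 1.0)
                    )
            pd.DataFrame(
                forest_rows,
                columns=["probe_set", "study", "log_hr", "se", "ci_low", "ci_high", "weight"],
            ).round(6).to_csv(out / "forest_data.tsv", sep="\t", index=False,
                              lineterminator="\n")

            # enrichment over the full probe-set universe: prognostic (meta
            # FDR < 0.05 among screened) vs highly correlating
            all_cohorts_ps = records.index
            prognostic = pd.Series(False, index=all_cohorts_ps)
            sig = meta.index[meta["fdr_q"] < config.fdr_threshold]
            prognostic.loc[sig] = True
            hc_flags = records["high_correlation"]
            if prognostic.any() and not prognostic.all():
                enr = enrichment_fisher(hc_flags, prognostic)
                cio.write_json(enr, out / "enrichment.json")
            else:
                notices.append("enrichment skipped: degenerate prognostic margin")
    else:
        notices.append("clinical table missing: survival stages skipped")

    # --- bundle -----------------------------------------------------------
    manifest = {
        p.name: cio.file_checksum(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "bundle.json"
    }
    bundle = ResultBundle(
        out_dir=out,
        manifest=manifest,
        metadata={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "elapsed_s": round(time.time() - t0, 2),
            "n_artifacts": len(manifest),
        },
        notices=notices,
    )
    bundle.write()
    return bundle
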