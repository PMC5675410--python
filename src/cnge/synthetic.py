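"""Synthetic paired copy-number / expression / survival cohorts.

Emulates the structure of an NSCLC integration study: ~190 tumors in three
histology groups; marker-level copy numbers on a 2-centered linear scale with
focal high-gain amplicons carried by small patient fractions at designated
loci (plus a broad, frequent loss region); expression linearly coupled to
copy number for a designated dosage-gene subset; survival under proportional
hazards driven by a prognostic-gene subset; and a collection of independent
cohorts for meta-analysis with planted near-duplicate samples.

All randomness flows from one root seed through named independent substreams
(reference panel, landscape, expression, survival, meta cohorts), so each
stage can be regenerated independently and the whole cohort is bit-identical
under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_reference_panel",
    "simulate_cn_landscape",
    "simulate_expression",
    "simulate_survival",
    "simulate_meta_cohorts",
    "generate_cohort",
]


@dataclass(frozen=True)
class Locus:
    """A copy-number event: target CN carried by a fraction of samples."""

    chromosome: str
    start: int
    end: int
    target_cn: float
    carrier_fraction: float


def _default_amplicons() -> list[Locus]:
    return [
        Locus("1", 10_000_000, 15_000_000, 6.0, 0.05),
        Locus("2", 20_000_000, 25_000_000, 6.0, 0.08),
        Locus("3", 30_000_000, 35_000_000, 6.0, 0.12),
        Locus("4", 5_000_000, 10_000_000, 6.0, 0.15),
    ]


def _default_losses() -> list[Locus]:
    # a broad, frequent loss emulating common chromosome-arm losses
    return [Locus("3", 40_000_000, 48_000_000, 1.3, 0.6)]


@dataclass
class SimulationConfig:
    n_samples: int = 190
    n_markers: int = 5000
    n_probesets: int = 2000
    n_chromosomes: int = 4
    chrom_length_bp: int = 50_000_000
    n_reference: int = 90
    dosage_gene_fraction: float = 0.10
    dosage_slope_range: tuple[float, float] = (0.8, 1.5)
    amplicon_loci: list[Locus] = field(default_factory=_default_amplicons)
    loss_loci: list[Locus] = field(default_factory=_default_losses)
    noise_sd_expression: float = 0.4
    noise_sd_marker: float = 0.1
    prognostic_gene_fraction: float = 0.01
    log_hazard_per_sd: float = 0.2
    censoring_rate: float = 0.5
    histology_proportions: tuple[float, float, float] = (0.55, 0.33, 0.12)
    n_cohorts_meta: int = 10
    duplicate_pairs: int = 2
    coupling: str = "linear"  # or "multiplicative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers <= 0 or self.n_reference <= 0:
            raise ValueError("n_markers and n_reference must be positive")
        if self.n_probesets <= 0 or self.n_samples <= 0:
            raise ValueError("n_probesets and n_samples must be positive")
        for frac in (
            self.dosage_gene_fraction,
            self.prognostic_gene_fraction,
            self.censoring_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if abs(sum(self.histology_proportions) - 1.0) > 1e-9:
            raise ValueError("histology proportions must sum to 1")
        if self.noise_sd_expression < 0 or self.noise_sd_marker < 0:
            raise ValueError("noise standard deviations must be >= 0")
        chroms = {str(c + 1) for c in range(self.n_chromosomes)}
        for locus in list(self.amplicon_loci) + list(self.loss_loci):
            if not 0.0 <= locus.carrier_fraction <= 1.0:
                raise ValueError("carrier fraction outside [0, 1]")
            if round(locus.carrier_fraction * self.n_samples) < 1:
                raise ValueError(
                    f"locus {locus}: carrier_fraction x n_samples < 1"
                )
            if locus.chromosome not in chroms:
                raise ValueError(f"locus chromosome {locus.chromosome} not simulated")
            if not 1 <= locus.start <= locus.end <= self.chrom_length_bp:
                raise ValueError(f"locus {locus} outside [1, chrom_length_bp]")
        for locus in self.amplicon_loci:
            if locus.target_cn <= 2:
                raise ValueError("amplicon target CN must exceed 2")
        for locus in self.loss_loci:
            if not 0 <= locus.target_cn < 2:
                raise ValueError("loss target CN must be in [0, 2)")
        if self.coupling not in ("linear", "multiplicative"):
            raise ValueError("coupling must be 'linear' or 'multiplicative'")

    # substream indices are fixed so stages are independently regenerable
    _STREAMS = ("reference", "landscape", "expression", "survival", "cohorts")

    def rng(self, stream: str) -> np.random.Generator:
        idx = self._STREAMS.index(stream)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(idx,))
        )


@dataclass
class GroundTruth:
    true_segments: dict  # sample -> list of (chromosome, start, end, cn)
    dosage_genes: dict  # probe set -> (alpha, beta)
    prognostic_genes: dict  # probe set -> gamma
    duplicate_pairs: list  # [((cohort_i, sample), (cohort_j, sample)), ...]
    alphas: pd.Series | None = None  # intercept per probe set


@dataclass
class SyntheticCohort:
    name: str
    tumor_intensities: pd.DataFrame | None
    reference_intensities: pd.DataFrame | None
    markers: pd.DataFrame | None
    expression: pd.DataFrame
    annotation: pd.DataFrame
    clinical: pd.DataFrame
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# genome layout


def make_markers(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced markers over the simulated chromosomes."""
    per = [config.n_markers // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_markers % config.n_chromosomes):
        per[i] += 1
    rows = []
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        step = config.chrom_length_bp / per[c]
        for k in range(per[c]):
            rows.append((f"m_{chrom}_{k:05d}", chrom, int((k + 0.5) * step) + 1))
    return pd.DataFrame(rows, columns=["marker", "chromosome", "position"]).set_index(
        "marker"
    )


def make_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Probe-set annotation: probe_set, gene, chromosome, start, stop.

    Probe sets are laid out evenly; roughly every fourth gene carries two
    probe sets (microarrays commonly probe one gene several times).
    """
    per = [config.n_probesets // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_probesets % config.n_chromosomes):
        per[i] += 1
    rows = []
    gene_idx = 0
    ps_idx = 0
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        step = config.chrom_length_bp / per[c]
        k = 0
        while k < per[c]:
            gene_idx += 1
            gene = f"G{gene_idx:05d}"
            n_ps = 2 if (gene_idx % 4 == 0 and k + 1 < per[c]) else 1
            for _ in range(n_ps):
                center = int((k + 0.5) * step) + 1
                half = 10_000
                start = max(1, center - half)
                stop = min(config.chrom_length_bp, center + half)
                rows.append((f"ps_{ps_idx:05d}", gene, chrom, start, stop))
                ps_idx += 1
                k += 1
    return pd.DataFrame(
        rows, columns=["probe_set", "gene", "chromosome", "start", "stop"]
    ).set_index("probe_set")


# ---------------------------------------------------------------------------
# stages


def generate_reference_panel(
    config: SimulationConfig, baseline: np.ndarray | None = None
) -> pd.DataFrame:
    """Marker x reference-sample intensity matrix around a per-marker baseline
    with multiplicative lognormal noise."""
    markers = make_markers(config)
    rng = config.rng("reference")
    if baseline is None:
        baseline = _baseline(config)
    noise = (
        np.ones((config.n_markers, config.n_reference))
        if config.noise_sd_marker == 0
        else rng.lognormal(0.0, config.noise_sd_marker, (config.n_markers, config.n_reference))
    )
    return pd.DataFrame(
        baseline[:, None] * noise,
        index=markers.index,
        columns=[f"ref_{i:03d}" for i in range(config.n_reference)],
    )


def _baseline(config: SimulationConfig) -> np.ndarray:
    """Per-marker baseline intensity; deterministic in the root seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(99,)))
    return rng.lognormal(math.log(1000.0), 0.25, config.n_markers)


def _draw_carriers(
    config: SimulationConfig, rng: np.random.Generator, samples: list[str]
) -> dict[Locus, np.ndarray]:
    carriers = {}
    n = len(samples)
    for locus in list(config.amplicon_loci) + list(config.loss_loci):
        k = int(round(locus.carrier_fraction * n))
        carriers[locus] = rng.choice(n, size=k, replace=False)
    # overlapping gain and loss events on the same samples are contradictory
    for amp in config.amplicon_loci:
        for loss in config.loss_loci:
            if amp.chromosome == loss.chromosome and not (
                amp.end < loss.start or loss.end < amp.start
            ):
                shared = set(carriers[amp]) & set(carriers[loss])
                if shared:
                    raise ValueError(
                        f"amplicon {amp} and loss {loss} overlap on samples {shared}"
                    )
    return carriers


def simulate_cn_landscape(
    config: SimulationConfig,
    samples: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Tumor marker intensities and per-sample true segments.

    Baseline true CN is 2 everywhere; each locus raises/lowers it to the
    target CN in its carriers.  Tumor intensity at marker m of sample i is
    ``baseline_m * trueCN/2 * lognormal noise``.
    """
    markers = make_markers(config)
    if samples is None:
        samples = [f"s_{i:03d}" for i in range(config.n_samples)]
    if rng is None:
        rng = config.rng("landscape")
    carriers = _draw_carriers(config, rng, samples)
    baseline = _baseline(config)
    pos = markers["position"].to_numpy()
    chrom = markers["chromosome"].to_numpy()
    true_cn = np.full((len(markers), len(samples)), 2.0)
    events_per_sample: dict[str, list[Locus]] = {s: [] for s in samples}
    for locus, idx in carriers.items():
        mmask = (chrom == locus.chromosome) & (pos >= locus.start) & (pos <= locus.end)
        for i in idx:
            true_cn[mmask, i] = locus.target_cn
            events_per_sample[samples[i]].append(locus)
    true_segments = {
        s: _tile_segments(config, events_per_sample[s]) for s in samples
    }
    noise = (
        np.ones_like(true_cn)
        if config.noise_sd_marker == 0
        else rng.lognormal(0.0, config.noise_sd_marker, true_cn.shape)
    )
    intensities = pd.DataFrame(
        baseline[:, None] * (true_cn / 2.0) * noise,
        index=markers.index,
        columns=samples,
    )
    return intensities, true_segments


def _tile_segments(config: SimulationConfig, events: list[Locus]) -> list[tuple]:
    """Non-overlapping (chromosome, start, end, cn) tiling every chromosome."""
    out = []
    for c in range(config.n_chromosomes):
        chromv = str(c + 1)
        evs = sorted(
            [e for e in events if e.chromosome == chromv], key=lambda e: e.start
        )
        cursor = 1
        for e in evs:
            if e.start > cursor:
                out.append((chromv, cursor, e.start - 1, 2.0))
            out.append((chromv, e.start, e.end, e.target_cn))
            cursor = e.end + 1
        if cursor <= config.chrom_length_bp:
            out.append((chromv, cursor, config.chrom_length_bp, 2.0))
    return out


def true_cn_at_probesets(
    config: SimulationConfig, annotation: pd.DataFrame, true_segments: dict
) -> pd.DataFrame:
    """Ground-truth CN per probe set per sample from the covering segment."""
    positions = ((annotation["start"] + annotation["stop"]) // 2).to_numpy()
    chroms = annotation["chromosome"].to_numpy()
    samples = list(true_segments)
    out = np.full((len(annotation), len(samples)), 2.0)
    for j, s in enumerate(samples):
        for chromv, start, end, cn in true_segments[s]:
            if cn == 2.0:
                continue
            mask = (chroms == chromv) & (positions >= start) & (positions <= end)
            out[mask, j] = cn
    return pd.DataFrame(out, index=annotation.index, columns=samples)


def assign_coefficients(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-probe-set intercepts alpha and dosage slopes beta.

    Dosage genes are genes located inside amplicon loci (their expression is
    copy-number coupled); a gene is selected with all of its probe sets.  The
    selection is capped at ``dosage_gene_fraction`` of probe sets.
    """
    if rng is None:
        rng = config.rng("expression")
    alphas = pd.Series(
        rng.uniform(3.0, 10.0, len(annotation)), index=annotation.index, name="alpha"
    )
    positions = (annotation["start"] + annotation["stop"]) // 2
    in_amplicon = pd.Series(False, index=annotation.index)
    for locus in config.amplicon_loci:
        in_amplicon |= (
            (annotation["chromosome"] == locus.chromosome)
            & (positions >= locus.start)
            & (positions <= locus.end)
        )
    candidate_genes = list(dict.fromkeys(annotation.loc[in_amplicon, "gene"]))
    target = int(round(config.dosage_gene_fraction * len(annotation)))
    betas = pd.Series(0.0, index=annotation.index, name="beta")
    count = 0
    lo, hi = config.dosage_slope_range
    for gene in candidate_genes:
        ps = annotation.index[annotation["gene"] == gene]
        if count + len(ps) > target:
            break
        betas.loc[ps] = rng.uniform(lo, hi, len(ps))
        count += len(ps)
    if count < target:
        logger.info(
            "dosage-gene fraction capped by amplicon span: %d of %d probe sets",
            count,
            target,
        )
    return alphas, betas


def simulate_expression(
    true_cn: pd.DataFrame,
    alphas: pd.Series,
    betas: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """GE = alpha + beta * (CN - 2) + Normal(0, sd) noise, floored at 0.05.

    With ``coupling='multiplicative'`` the systematic part is
    ``alpha * (CN / 2) ** beta`` instead.
    """
    if (alphas <= 0).any():
        raise ValueError("expression intercepts alpha must be positive")
    if rng is None:
        rng = config.rng("expression")
    a = alphas.to_numpy()[:, None]
    b = betas.to_numpy()[:, None]
    cn = true_cn.to_numpy()
    if config.coupling == "linear":
        mean = a + b * (cn - 2.0)
    else:
        mean = a * (cn / 2.0) ** b
    noise = rng.normal(0.0, config.noise_sd_expression, cn.shape) if config.noise_sd_expression else 0.0
    return pd.DataFrame(
        np.maximum(mean + noise, 0.05), index=true_cn.index, columns=true_cn.columns
    )


def assign_prognostic(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Per-probe-set log-hazard coefficients gamma (0 for non-prognostic)."""
    if rng is None:
        rng = config.rng("survival")
    k = int(round(config.prognostic_gene_fraction * len(annotation)))
    chosen = rng.choice(len(annotation), size=k, replace=False)
    gammas = pd.Series(0.0, index=annotation.index, name="gamma")
    signs = rng.choice([-1.0, 1.0], size=k)
    gammas.iloc[chosen] = signs * config.log_hazard_per_sd
    return gammas


def simulate_survival(
    expression: pd.DataFrame,
    gammas: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    baseline_median_months: float = 30.0,
) -> pd.DataFrame:
    """Clinical table with exponential event times under proportional hazards.

    hazard_i = lambda0 * exp(sum_g gamma_g z_{g,i}) with z the per-gene
    standardized expression; censoring is independent uniform, with its upper
    limit calibrated so the achieved censoring fraction approximates the
    configured rate.
    """
    if expression.shape[1] == 0 or expression.shape[0] == 0:
        raise ValueError("empty expression matrix")
    if rng is None:
        rng = config.rng("survival")
    active = gammas[gammas != 0]
    lp = np.zeros(expression.shape[1])
    if len(active):
        sub = expression.loc[active.index].to_numpy()
        sd = sub.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        lp = active.to_numpy() @ z
    lam0 = math.log(2.0) / baseline_median_months
    hazard = lam0 * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    event = np.ones(len(t_event), dtype=int)
    os_months = t_event
    if config.censoring_rate > 0:
        c_max = _calibrate_censoring(t_event, config.censoring_rate)
        c = rng.uniform(0.0, c_max, len(t_event))
        event = (t_event <= c).astype(int)
        os_months = np.minimum(t_event, c)
    os_months = np.maximum(os_months, 1e-3)
    n = expression.shape[1]
    histology = rng.choice(
        ["adeno", "squamous", "large_cell"], size=n, p=list(config.histology_proportions)
    )
    age = np.round(rng.normal(67.0, 9.0, n), 1)
    stage = rng.choice([1, 2, 3], size=n, p=[0.55, 0.25, 0.20])
    return pd.DataFrame(
        {
            "sample": expression.columns,
            "os_months": os_months,
            "event": event,
            "histology": histology,
            "age": age,
            "stage": stage,
        }
    ).set_index("sample")


def _calibrate_censoring(t_event: np.ndarray, rate: float) -> float:
    """Uniform(0, c_max) censoring limit achieving ~`rate` censored."""

    def frac_censored(c_max: float) -> float:
        # P(C < t) for C ~ U(0, c_max), averaged over observed event times
        return float(np.mean(np.minimum(t_event / c_max, 1.0)))

    lo, hi = 1e-6, float(t_event.max()) * 4
    for _ in range(200):
        while frac_censored(hi) > rate:
            hi *= 2.0
        mid = 0.5 * (lo + hi)
        if frac_censored(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SimulationConfig, name: str = "uppsala") -> SyntheticCohort:
    """The full primary cohort: intensities, expression, clinical, truth."""
    markers = make_markers(config)
    annotation = make_annotation(config)
    reference = generate_reference_panel(config)
    intensities, true_segments = simulate_cn_landscape(config)
    expr_rng = config.rng("expression")
    alphas, betas = assign_coefficients(config, annotation, rng=expr_rng)
    cn_ps = true_cn_at_probesets(config, annotation, true_segments)
    expression = simulate_expression(cn_ps, alphas, betas, config, rng=expr_rng)
    surv_rng = config.rng("survival")
    gammas = assign_prognostic(config, annotation, rng=surv_rng)
    clinical = simulate_survival(expression, gammas, config, rng=surv_rng)
    truth = GroundTruth(
        true_segments=true_segments,
        dosage_genes={
            ps: (float(alphas[ps]), float(betas[ps]))
            for ps in annotation.index[betas > 0]
        },
        prognostic_genes={
            ps: float(gammas[ps]) for ps in annotation.index[gammas != 0]
        },
        duplicate_pairs=[],
        alphas=alphas,
    )
    return SyntheticCohort(
        name=name,
        tumor_intensities=intensities,
        reference_intensities=reference,
        markers=markers,
        expression=expression,
        annotation=annotation,
        clinical=clinical,
        ground_truth=truth,
    )


def simulate_meta_cohorts(
    config: SimulationConfig, sizes: list[int] | None = None
) -> list[SyntheticCohort]:
    """Independent cohorts sharing annotation and generative coefficients.

    Marker-level intensities are not materialized for the meta cohorts (the
    meta-analysis consumes expression + clinical only); copy-number events are
    drawn freshly per cohort.  ``duplicate_pairs`` near-duplicates are planted
    by copying one sample's expression vector into the next cohort with
    negligible noise (correlation >= 0.999).
    """
    if config.n_cohorts_meta < 2:
        raise ValueError("n_cohorts_meta must be >= 2")
    rng = config.rng("cohorts")
    annotation = make_annotation(config)
    alphas, betas = assign_coefficients(config, annotation, rng=rng)
    gammas = assign_prognostic(config, annotation, rng=rng)
    if sizes is None:
        sizes = rng.integers(80, 250, size=config.n_cohorts_meta).tolist()
    if config.duplicate_pairs > min(sizes):
        raise ValueError("duplicate_pairs exceeds the smallest cohort size")
    cohorts = []
    for c, size in enumerate(sizes):
        samples = [f"c{c}_s{i:03d}" for i in range(size)]
        sub = replace(config, n_samples=size, seed=config.seed)
        carriers_rng = rng  # shared stream keeps cohorts independent but seeded
        _, true_segments = simulate_cn_landscape(sub, samples=samples, rng=carriers_rng)
        cn_ps = true_cn_at_probesets(sub, annotation, true_segments)
        expression = simulate_expression(cn_ps, alphas, betas, sub, rng=rng)
        clinical = simulate_survival(expression, gammas, sub, rng=rng)
        truth = GroundTruth(
            true_segments=true_segments,
            dosage_genes={
                ps: (float(alphas[ps]), float(betas[ps]))
                for ps in annotation.index[betas > 0]
            },
            prognostic_genes={
                ps: float(gammas[ps]) for ps in annotation.index[gammas != 0]
            },
            duplicate_pairs=[],
            alphas=alphas,
        )
        cohorts.append(
            SyntheticCohort(
                name=f"cohort_{c}",
                tumor_intensities=None,
                reference_intensities=None,
                markers=None,
                expression=expression,
                annotation=annotation,
                clinical=clinical,
                ground_truth=truth,
            )
        )
    pairs = []
    for d in range(config.duplicate_pairs):
        src, dst = d % len(cohorts), (d + 1) % len(cohorts)
        s_src = cohorts[src].expression.columns[d]
        s_dst = cohorts[dst].expression.columns[-(d + 1)]
        vec = cohorts[src].expression[s_src].to_numpy()
        jitter = rng.normal(0.0, 1e-5 * max(vec.std(), 1e-12), len(vec))
        cohorts[dst].expression[s_dst] = np.maximum(vec + jitter, 0.05)
        pairs.append(((cohorts[src].name, s_src), (cohorts[dst].name, s_dst)))
    for cohort in cohorts:
        cohort.ground_truth.duplicate_pairs = pairs
    return cohorts
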