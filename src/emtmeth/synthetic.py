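"""Seeded generators for every input the pipeline consumes.

A small synthetic genome carries EMT signature genes with promoter CpGs
plus background CpGs.  From it we generate: cell-line pairs with
EMT-structured promoter shifts and designated hyper/hypo background CpGs,
paired standard/TAB matrices with a configurable 5mC-to-5hmC turnover
model, healthy-blood and tumor reference cohorts, and longitudinal
patient coverage files produced by mixing a patient tumor methylome into
blood background at a known ctDNA fraction with binomial read sampling.

All randomness flows from ``SimConfig.seed`` through named streams, so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .formats import (
    BetaMatrix,
    CoverageRecord,
    CpGSite,
    GeneAnnotation,
    annotate_promoters,
    load_packaged_exclusion_list,
    load_packaged_signature,
)

__all__ = [
    "SimConfig",
    "Genome",
    "CellLinePair",
    "ReferenceCohorts",
    "PatientSeries",
    "GroundTruth",
    "rng_for",
    "make_genome",
    "simulate_cellline_pair",
    "simulate_reference_cohorts",
    "simulate_patient_series",
    "simulate_controls",
    "default_cohort_trajectories",
]

# methylation levels used to construct cell-line betas
LOW_LEVEL = 0.10
HIGH_LEVEL = 0.85
# patient tumor methylation of signature promoters at the epithelial (s=0)
# and mesenchymal (s=1) extremes of the EMT state
EPI_PROMOTER_RANGE = (0.05, 0.70)   # epithelial promoters gain methylation
MES_PROMOTER_RANGE = (0.70, 0.05)   # mesenchymal promoters lose methylation


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent, reproducible generator for a named stream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_cpgs: int = 4000
    n_target_cpgs: int = 2000
    n_genes: int = 60
    n_epithelial: int = 16
    n_mesenchymal: int = 34
    cpgs_per_promoter: int = 6
    emt_effect: float = 0.4          # promoter delta-beta magnitude
    background_sd: float = 0.05
    blood_beta_mean: float = 0.01
    blood_beta_conc: float = 50.0
    excluded_blood_mean: float = 0.30
    tumor_beta_mean: float = 0.40
    tumor_beta_conc: float = 3.0     # spread of per-CpG tumor means
    tumor_sample_conc: float = 20.0
    n_blood: int = 20
    n_tumor: int = 50
    coverage_mean: float = 100.0
    f_ctdna: tuple[float, ...] = (0.1, 0.2)
    tet_kappa_parental: float = 0.4
    tet_kappa_resistant: float = 0.1
    tet_kappa_stable: float | None = None   # default: mean of the pair
    expression_effect: float = 2.0
    dispersion: float = 0.0          # 0 -> Poisson read/count depths
    n_hyper_bg: int = 150
    n_hypo_bg: int = 100
    patient_tumor_sd: float = 0.10

    def __post_init__(self):
        if not 0.0 <= self.emt_effect < 1.0:
            raise ValueError("emt_effect must be in [0, 1)")
        for name in ("blood_beta_mean", "excluded_blood_mean", "tumor_beta_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for f in self.f_ctdna:
            if not 0.0 <= f <= 1.0:
                raise ValueError("f_ctdna entries must be in [0, 1]")
        for name in ("n_cpgs", "n_target_cpgs", "n_genes", "n_epithelial",
                     "n_mesenchymal", "n_blood", "n_tumor", "cpgs_per_promoter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_target_cpgs > self.n_cpgs:
            raise ValueError("n_target_cpgs cannot exceed n_cpgs")
        if self.cpgs_per_promoter < 3:
            raise ValueError("need >= 3 CpGs per signature promoter")

    @property
    def kappa_stable(self) -> float:
        if self.tet_kappa_stable is not None:
            return self.tet_kappa_stable
        return 0.5 * (self.tet_kappa_parental + self.tet_kappa_resistant)


@dataclass
class Genome:
    """Synthetic CpG/gene layout shared by all generators."""

    sites: list[CpGSite]
    genes: list[GeneAnnotation]
    signature: pd.DataFrame
    promoter_map: dict[str, set[str]]
    excluded_genes: list[str]
    target_ids: list[str]
    group: dict[str, str]   # site id -> epi_promoter | mes_promoter |
    #                         excluded_promoter | hyper_bg | hypo_bg | background

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.sites]

    def group_array(self) -> np.ndarray:
        return np.array([self.group[s.id] for s in self.sites])


def make_genome(
    config: SimConfig,
    signature: pd.DataFrame | None = None,
    excluded_genes: list[str] | None = None,
) -> Genome:
    """Lay out signature genes with promoter CpGs on chr1 and background
    CpGs on chr2.

    When the configured class sizes match the packaged 50-gene signature it
    is used verbatim (with the packaged cfDNA exclusion list); otherwise
    synthetic gene names are generated.
    """
    if signature is None:
        packaged = load_packaged_signature()
        n_epi = (packaged["klass"] == "epithelial").sum()
        n_mes = (packaged["klass"] == "mesenchymal").sum()
        if config.n_epithelial == n_epi and config.n_mesenchymal == n_mes:
            signature = packaged
            if excluded_genes is None:
                excluded_genes = load_packaged_exclusion_list()
        else:
            signature = pd.DataFrame(
                {
                    "gene": [f"EPI{i:02d}" for i in range(config.n_epithelial)]
                    + [f"MES{i:02d}" for i in range(config.n_mesenchymal)],
                    "klass": ["epithelial"] * config.n_epithelial
                    + ["mesenchymal"] * config.n_mesenchymal,
                }
            )
    if excluded_genes is None:
        excluded_genes = []
    excluded = [g for g in excluded_genes if g in set(signature["gene"])]

    n_sig = len(signature)
    if config.n_genes < n_sig:
        raise ValueError("n_genes smaller than the signature")
    genes = []
    all_names = list(signature["gene"]) + [
        f"NONSIG{i:02d}" for i in range(config.n_genes - n_sig)
    ]
    for i, name in enumerate(all_names):
        genes.append(
            GeneAnnotation(name, "chr1", 100_000 + i * 20_000, "+" if i % 2 == 0 else "-")
        )
    gene_by_name = {g.gene: g for g in genes}

    # promoter CpGs: offsets in upstream-relative coordinates, all inside
    # the -2000/+500 window
    k = config.cpgs_per_promoter
    offsets = np.linspace(-400, 1400, k).round().astype(int)
    sites: list[CpGSite] = []
    group: dict[str, str] = {}
    counter = 1
    excluded_set = set(excluded)
    for gene_name, klass in zip(signature["gene"], signature["klass"]):
        g = gene_by_name[gene_name]
        for off in offsets:
            pos = g.tss - int(off) if g.strand == "+" else g.tss + int(off)
            sid = f"cpg_{counter:06d}"
            counter += 1
            sites.append(CpGSite(sid, g.chrom, pos))
            if gene_name in excluded_set:
                group[sid] = "excluded_promoter"
            else:
                group[sid] = "epi_promoter" if klass == "epithelial" else "mes_promoter"

    n_promoter = len(sites)
    n_background = config.n_cpgs - n_promoter
    if n_background < config.n_hyper_bg + config.n_hypo_bg:
        raise ValueError("n_cpgs too small for the designated hyper/hypo sets")
    for i in range(n_background):
        sid = f"cpg_{counter:06d}"
        counter += 1
        sites.append(CpGSite(sid, "chr2", 1_000 + i * 500))
        if i < config.n_hyper_bg:
            group[sid] = "hyper_bg"
        elif i < config.n_hyper_bg + config.n_hypo_bg:
            group[sid] = "hypo_bg"
        else:
            group[sid] = "background"

    promoter_map = annotate_promoters(sites, genes)

    # capture targets: retained signature promoter CpGs plus stable
    # background CpGs, up to n_target_cpgs
    target_ids = [
        s.id for s in sites if group[s.id] in ("epi_promoter", "mes_promoter")
    ]
    for s in sites:
        if len(target_ids) >= config.n_target_cpgs:
            break
        if group[s.id] == "background":
            target_ids.append(s.id)

    return Genome(sites, genes, signature, promoter_map, excluded, target_ids, group)


@dataclass
class GroundTruth:
    hyper_ids: set[str] = field(default_factory=set)
    hypo_ids: set[str] = field(default_factory=set)
    tet_regime: dict[str, str] = field(default_factory=dict)
    m_parental: np.ndarray | None = None
    m_resistant: np.ndarray | None = None
    lfc_true: pd.DataFrame | None = None
    f_ctdna: list[float] = field(default_factory=list)
    emt_state: list[float] = field(default_factory=list)
    tumor_profiles: dict[str, np.ndarray] = field(default_factory=dict)
    m_meas: dict[str, np.ndarray] = field(default_factory=dict)


def _beta_draw(rng: np.random.Generator, mean, conc: float, size) -> np.ndarray:
    """Beta draws parameterized by (mean, concentration); degenerate means
    of exactly 0 or 1 give constant output."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    out = np.empty(size, dtype=float)
    zero = mean <= 0.0
    one = mean >= 1.0
    mid = ~zero & ~one
    out[zero] = 0.0
    out[one] = 1.0
    if mid.any():
        a = mean[mid] * conc
        b = (1.0 - mean[mid]) * conc
        out[mid] = rng.beta(a, b)
    return out


# -- cell-line pair ----------------------------------------------------------

@dataclass
class CellLinePair:
    standard: BetaMatrix
    tab: BetaMatrix
    expression: pd.DataFrame
    truth: GroundTruth
    n_clipped: int


def simulate_cellline_pair(config: SimConfig, genome: Genome | None = None) -> CellLinePair:
    """Parental/resistant pair: standard and TAB beta matrices plus an
    expression count table with signature-structured fold changes.

    Epithelial promoter CpGs start low and shift +delta in the resistant
    line, mesenchymal promoters start high and shift -delta.  Designated
    background hyper/hypo CpGs cross the 0.3/0.7 thresholds whenever
    delta > 0.  5hmC follows h = kappa * m * (1 - m) with kappa switched
    between parental and resistant for hyper (down) and hypo (up) CpGs.
    """
    if genome is None:
        genome = make_genome(config)
    rng = rng_for(config.seed, "cellline")
    groups = genome.group_array()
    n = len(genome.sites)
    delta = config.emt_effect
    sd = config.background_sd

    base = np.empty(n)
    shift = np.zeros(n)
    swing = HIGH_LEVEL - LOW_LEVEL
    is_epi = groups == "epi_promoter"
    is_mes = groups == "mes_promoter"
    is_excl = groups == "excluded_promoter"
    is_hyper = groups == "hyper_bg"
    is_hypo = groups == "hypo_bg"
    is_bg = groups == "background"
    base[is_epi] = LOW_LEVEL
    base[is_mes] = HIGH_LEVEL
    base[is_excl] = LOW_LEVEL
    base[is_hyper] = LOW_LEVEL
    base[is_hypo] = HIGH_LEVEL
    # stable background: fixed 50/50 low/high modes
    modes = rng.random(is_bg.sum()) < 0.5
    base[is_bg] = np.where(modes, LOW_LEVEL, HIGH_LEVEL)
    shift[is_epi] = +delta
    shift[is_mes] = -delta
    if delta > 0:
        shift[is_hyper] = +swing
        shift[is_hypo] = -swing

    noise_par = rng.standard_normal(n) * sd
    noise_res = rng.standard_normal(n) * sd
    raw_par = base + noise_par
    raw_res = base + shift + noise_res
    n_clipped = int(((raw_par < 0) | (raw_par > 1)).sum()
                    + ((raw_res < 0) | (raw_res > 1)).sum())
    if n_clipped > 0.1 * 2 * n:
        raise ValueError(
            f"{n_clipped} of {2 * n} beta values fell outside [0, 1]; "
            "reduce emt_effect or background_sd"
        )
    m_par = np.clip(raw_par, 0.0, 1.0)
    m_res = np.clip(raw_res, 0.0, 1.0)

    kappa_par = np.full(n, config.kappa_stable)
    kappa_res = np.full(n, config.kappa_stable)
    if delta > 0:
        # TET regimes only exist where methylation actually changes
        kappa_par[is_hyper] = config.tet_kappa_parental
        kappa_res[is_hyper] = config.tet_kappa_resistant
        kappa_par[is_hypo] = config.tet_kappa_resistant
        kappa_res[is_hypo] = config.tet_kappa_parental
    sd_h = sd / 5.0
    h_par = np.clip(kappa_par * m_par * (1 - m_par)
                    + rng.standard_normal(n) * sd_h, 0.0, 1.0)
    h_res = np.clip(kappa_res * m_res * (1 - m_res)
                    + rng.standard_normal(n) * sd_h, 0.0, 1.0)

    samples = ["parental", "resistant"]
    standard = BetaMatrix(
        genome.sites, samples,
        np.column_stack([np.clip(m_par + h_par, 0, 1), np.clip(m_res + h_res, 0, 1)]),
        channel="standard",
    )
    tab = BetaMatrix(genome.sites, samples,
                     np.column_stack([h_par, h_res]), channel="tab")

    # expression counts with signature-structured fold changes
    gene_names = [g.gene for g in genome.genes]
    klass = dict(zip(genome.signature["gene"], genome.signature["klass"]))
    lfc = np.array(
        [
            config.expression_effect
            * {"mesenchymal": 1.0, "epithelial": -1.0}.get(klass.get(g), 0.0)
            for g in gene_names
        ]
    )
    base_mean = np.exp(rng.uniform(np.log(50), np.log(2000), len(gene_names)))
    mean_par = base_mean
    mean_res = base_mean * 2.0**lfc

    def draw_counts(mean):
        if config.dispersion > 0:
            r = config.dispersion
            return rng.negative_binomial(r, r / (r + mean))
        return rng.poisson(mean)

    expression = pd.DataFrame(
        {
            "gene": gene_names,
            "parental": draw_counts(mean_par),
            "resistant": draw_counts(mean_res),
        }
    )

    truth = GroundTruth(
        hyper_ids={s.id for s, g in zip(genome.sites, groups) if g == "hyper_bg"}
        if delta > 0 else set(),
        hypo_ids={s.id for s, g in zip(genome.sites, groups) if g == "hypo_bg"}
        if delta > 0 else set(),
        tet_regime={
            s.id: {"hyper_bg": "hyper", "hypo_bg": "hypo"}.get(g, "stable")
            for s, g in zip(genome.sites, groups)
        },
        m_parental=m_par,
        m_resistant=m_res,
        lfc_true=pd.DataFrame({"gene": gene_names, "log2fc": lfc}),
    )
    return CellLinePair(standard, tab, expression, truth, n_clipped)


# -- reference cohorts -------------------------------------------------------

@dataclass
class ReferenceCohorts:
    blood: BetaMatrix
    tumor: BetaMatrix
    tumor_mu: np.ndarray     # per-CpG population tumor means

    @property
    def blood_means(self) -> np.ndarray:
        return np.nanmean(self.blood.values, axis=1)

    @property
    def tumor_means(self) -> np.ndarray:
        return np.nanmean(self.tumor.values, axis=1)


def simulate_reference_cohorts(
    config: SimConfig, genome: Genome | None = None
) -> ReferenceCohorts:
    """Healthy-blood and tumor reference beta matrices.

    Designated target CpGs draw low blood betas (mean
    ``blood_beta_mean``); promoter CpGs of the cfDNA-excluded markers draw
    elevated, variable blood betas; remaining background CpGs follow a
    bimodal mixture.  Tumor betas are hierarchical: a per-CpG population
    mean (exposed as ``tumor_mu``) with per-sample variation around it.
    """
    if genome is None:
        genome = make_genome(config)
    rng = rng_for(config.seed, "cohorts")
    n = len(genome.sites)
    target = np.isin(np.array(genome.site_ids), np.array(genome.target_ids))
    groups = genome.group_array()
    is_excl = groups == "excluded_promoter"

    blood_mean = np.empty(n)
    blood_conc = np.full(n, config.blood_beta_conc)
    blood_mean[target] = config.blood_beta_mean
    blood_mean[is_excl] = config.excluded_blood_mean
    blood_conc[is_excl] = 10.0
    other = ~target & ~is_excl
    modes = rng.random(other.sum()) < 0.5
    blood_mean[other] = np.where(modes, 0.05, HIGH_LEVEL)
    blood_conc[other] = np.where(modes, 50.0, 10.0)

    # draw per sample, respecting the per-CpG concentration
    cols = []
    for _ in range(config.n_blood):
        col = np.empty(n)
        for conc in np.unique(blood_conc):
            mask = blood_conc == conc
            col[mask] = _beta_draw(rng, blood_mean[mask], float(conc), int(mask.sum()))
        cols.append(col)
    blood = BetaMatrix(
        genome.sites,
        [f"blood_{i + 1:03d}" for i in range(config.n_blood)],
        np.column_stack(cols),
        channel="standard",
    )

    tumor_mu = np.empty(n)
    tumor_mu[target] = _beta_draw(
        rng, config.tumor_beta_mean, config.tumor_beta_conc, int(target.sum())
    )
    tumor_mu[~target] = _beta_draw(rng, 0.5, 1.5, int((~target).sum()))
    tumor_cols = [
        _beta_draw(rng, tumor_mu, config.tumor_sample_conc, n)
        for _ in range(config.n_tumor)
    ]
    tumor = BetaMatrix(
        genome.sites,
        [f"tumor_{i + 1:03d}" for i in range(config.n_tumor)],
        np.column_stack(tumor_cols),
        channel="standard",
    )
    return ReferenceCohorts(blood, tumor, tumor_mu)


# -- patient series ----------------------------------------------------------

@dataclass
class PatientSeries:
    patient: str
    sample_ids: list[str]
    records: dict[str, list[CoverageRecord]]
    sheet: pd.DataFrame
    truth: GroundTruth


def _patient_tumor_profile(
    config: SimConfig,
    genome: Genome,
    refs: ReferenceCohorts,
    state: float,
    jitter: np.ndarray,
) -> np.ndarray:
    """Per-CpG tumor methylome at EMT state ``state`` in [0, 1]."""
    profile = np.clip(refs.tumor_means + jitter, 0.0, 1.0)
    groups = genome.group_array()
    epi = (groups == "epi_promoter")
    mes = (groups == "mes_promoter") | (groups == "excluded_promoter")
    lo, hi = EPI_PROMOTER_RANGE
    profile[epi] = lo + (hi - lo) * state
    lo, hi = MES_PROMOTER_RANGE
    profile[mes] = lo + (hi - lo) * state
    return profile


def simulate_patient_series(
    config: SimConfig,
    genome: Genome,
    refs: ReferenceCohorts,
    trajectory: list[tuple[int, str, float, float]],
    patient: str = "patient_1",
    outcome: str = "acquired_resistance",
    exact: bool = False,
    rng: np.random.Generator | None = None,
) -> PatientSeries:
    """Longitudinal coverage files for one patient.

    ``trajectory`` lists (day, label, f_ctdna, emt_state) per timepoint.
    Per CpG the true mixture is M = f * M_tumor + (1 - f) * M_blood with
    M_blood the blood-cohort mean; read depth is Poisson around
    ``coverage_mean`` (negative binomial when dispersion > 0) and
    methylated counts are binomial.  ``exact=True`` uses a constant depth
    with deterministically rounded counts for noise-free oracle tests.
    """
    if not trajectory:
        raise ValueError("trajectory must contain at least one timepoint")
    if rng is None:
        rng = rng_for(config.seed, f"patient:{patient}")
    n = len(genome.sites)
    m_blood = refs.blood_means
    jitter = rng.standard_normal(n) * config.patient_tumor_sd

    truth = GroundTruth()
    records: dict[str, list[CoverageRecord]] = {}
    sheet_rows = []
    sample_ids = []
    for t_idx, (day, label, f, state) in enumerate(trajectory):
        m_tumor = _patient_tumor_profile(config, genome, refs, state, jitter)
        m_true = f * m_tumor + (1.0 - f) * m_blood
        sample_id = f"{patient}_t{t_idx}"
        if exact:
            depth = np.full(n, int(round(config.coverage_mean)))
            count = np.rint(m_true * depth).astype(int)
        else:
            if config.dispersion > 0:
                r = config.dispersion
                depth = rng.negative_binomial(
                    r, r / (r + config.coverage_mean), n
                )
            else:
                depth = rng.poisson(config.coverage_mean, n)
            count = rng.binomial(depth, m_true)
        recs = [
            CoverageRecord(
                s.chrom, s.pos, s.pos,
                100.0 * c / d if d else 0.0, int(c), int(d - c),
            )
            for s, c, d in zip(genome.sites, count, depth)
        ]
        records[sample_id] = recs
        sample_ids.append(sample_id)
        sheet_rows.append(
            {"patient": patient, "sample": sample_id, "day": day,
             "label": label, "outcome": outcome}
        )
        truth.f_ctdna.append(f)
        truth.emt_state.append(state)
        truth.m_meas[sample_id] = m_true
        truth.tumor_profiles[sample_id] = m_tumor
    return PatientSeries(patient, sample_ids, records, pd.DataFrame(sheet_rows), truth)


def simulate_controls(
    config: SimConfig,
    genome: Genome,
    refs: ReferenceCohorts,
    n_controls: int = 4,
) -> list[PatientSeries]:
    """Healthy-control cfDNA samples: single-timepoint series at f = 0."""
    out = []
    for i in range(n_controls):
        out.append(
            simulate_patient_series(
                config, genome, refs,
                [(0, "start", 0.0, 0.0)],
                patient=f"control_{i + 1}",
                outcome="control",
                rng=rng_for(config.seed, f"control:{i}"),
            )
        )
    return out


def default_cohort_trajectories() -> dict[str, tuple[str, list[tuple[int, str, float, float]]]]:
    """A 12-patient study layout: 6 acquired-resistance patients whose EMT
    state rises over treatment, 3 durable responders with a stable
    epithelial state, and 3 intrinsically resistant patients sampled twice.

    Returns patient -> (outcome, [(day, label, f_ctdna, emt_state), ...]).
    """
    cohort: dict[str, tuple[str, list[tuple[int, str, float, float]]]] = {}
    acquired_f = [(0.12, 0.10, 0.30), (0.10, 0.08, 0.25), (0.15, 0.10, 0.35),
                  (0.12, 0.09, 0.28), (0.10, 0.12, 0.32), (0.14, 0.10, 0.30)]
    for i, (f0, f1, f2) in enumerate(acquired_f):
        cohort[f"patient_{i + 1}"] = (
            "acquired_resistance",
            [(0, "start", f0, 0.0),
             (60 + 10 * i, "on_treatment", f1, 0.30),
             (180 + 15 * i, "progression", f2, 0.90)],
        )
    response_f = [(0.15, 0.10), (0.12, 0.10), (0.14, 0.11)]
    for i, (f0, f1) in enumerate(response_f):
        cohort[f"patient_{i + 7}"] = (
            "response",
            [(0, "start", f0, 0.0),
             (200 + 20 * i, "end_of_study", f1, 0.0)],
        )
    intrinsic_f = [(0.18, 0.35), (0.15, 0.30), (0.20, 0.40)]
    for i, (f0, f1) in enumerate(intrinsic_f):
        cohort[f"patient_{i + 10}"] = (
            "intrinsic_resistance",
            [(0, "start", f0, 0.55),
             (45 + 5 * i, "progression", f1, 0.60)],
        )
    return cohort
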