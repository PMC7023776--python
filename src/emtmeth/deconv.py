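"""Liquid-biopsy mixture model.

The measured cfDNA methylation at panel CpGs is modelled as
M_meas = M_tumor * f_ctDNA + M_blood * (1 - f_ctDNA).  Because panel CpGs
are selected to be unmethylated in healthy blood the blood term is close
to zero, and f_ctDNA is the through-origin least-squares slope of M_meas
on the tumor reference; dividing the measurements by the estimated
fraction reconstructs the tumor methylome.  On top of that sit the
marker-exclusion filter, the longitudinal EMT trajectory and the
tissue-liquid correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .formats import BetaMatrix, CoverageRecord, CpGSite
from .synthetic import rng_for

__all__ = [
    "CfDNAMethylome",
    "DeconvResult",
    "TumorReference",
    "EMTTrajectory",
    "methylome_from_coverage",
    "estimate_f_ctdna",
    "reconstruct_tumor_methylation",
    "exclude_unreliable_markers",
    "emt_trajectory",
    "correlate_tissue_liquid",
]

MIN_DEPTH = 10
MIN_CPGS = 50
F_FLOOR = 0.01
TREND_TAU = 0.05


@dataclass
class CfDNAMethylome:
    """Per-CpG measured methylated fraction for one liquid-biopsy sample.

    CpGs with depth below ``min_depth`` are masked to NaN.
    """

    sample: str
    site_ids: np.ndarray
    m_meas: np.ndarray
    depth: np.ndarray
    min_depth: int = MIN_DEPTH

    def __post_init__(self):
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.m_meas = np.asarray(self.m_meas, dtype=float)
        self.depth = np.asarray(self.depth, dtype=int)
        low = self.depth < self.min_depth
        self.m_meas = np.where(low, np.nan, self.m_meas)

    def subset(self, ids: set[str]) -> "CfDNAMethylome":
        keep = np.array([s in ids for s in self.site_ids])
        out = CfDNAMethylome(self.sample, self.site_ids[keep],
                             self.m_meas[keep], self.depth[keep], self.min_depth)
        return out

    def series(self) -> pd.Series:
        return pd.Series(self.m_meas, index=self.site_ids)


def methylome_from_coverage(
    records: list[CoverageRecord],
    sites: list[CpGSite],
    sample: str,
    min_depth: int = MIN_DEPTH,
) -> CfDNAMethylome:
    """Match coverage records to CpG sites by (chrom, position)."""
    by_pos = {(r.chrom, r.start): r for r in records}
    m = np.full(len(sites), np.nan)
    depth = np.zeros(len(sites), dtype=int)
    for i, s in enumerate(sites):
        rec = by_pos.get((s.chrom, s.pos))
        if rec is None or rec.depth == 0:
            continue
        depth[i] = rec.depth
        m[i] = rec.frac_meth
    return CfDNAMethylome(sample, np.array([s.id for s in sites], dtype=object),
                          m, depth, min_depth)


@dataclass
class TumorReference:
    site_ids: np.ndarray
    m_tumor: np.ndarray
    cohort_size: int

    @classmethod
    def from_matrix(cls, tumor: BetaMatrix, site_ids: list[str] | None = None
                    ) -> "TumorReference":
        means = np.nanmean(tumor.values, axis=1)
        ids = np.array(tumor.site_ids, dtype=object)
        if site_ids is not None:
            keep = np.isin(ids, np.array(site_ids, dtype=object))
            ids, means = ids[keep], means[keep]
        return cls(ids, means, len(tumor.samples))

    def series(self) -> pd.Series:
        return pd.Series(self.m_tumor, index=self.site_ids)


@dataclass
class DeconvResult:
    sample: str
    f_ctdna: float
    n_cpgs: int
    reliable: bool
    residual_sd: float
    rank_corr: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    f_floor: float = F_FLOOR
    intercept: float = 0.0

    @property
    def f_cfdna(self) -> float:
        return 1.0 - self.f_ctdna


def _aligned(meas: CfDNAMethylome, tumor: TumorReference) -> tuple[np.ndarray, np.ndarray]:
    m = meas.series()
    t = tumor.series()
    common = m.index.intersection(t.index)
    y = m.loc[common].to_numpy(dtype=float)
    x = t.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    return y[ok], x[ok]


def estimate_f_ctdna(
    meas: CfDNAMethylome,
    tumor: TumorReference,
    blood: pd.Series | None = None,
    min_cpgs: int = MIN_CPGS,
    f_floor: float = F_FLOOR,
    n_boot: int = 200,
    seed: int = 0,
    free_intercept: bool = False,
) -> DeconvResult:
    """ctDNA fraction as the through-origin least-squares slope of measured
    methylation on the tumor reference over panel CpGs, clamped to [0, 1].

    When a ``blood`` series of per-CpG healthy-cfDNA means is supplied the
    mixture is solved without the blood-is-zero approximation, regressing
    (M_meas - M_blood) on (M_tumor - M_blood).  ``free_intercept=True``
    fits an ordinary regression for diagnostics; the slope is still the
    reported fraction.  A seeded CpG bootstrap yields a 95% interval.
    """
    m = meas.series()
    t = tumor.series()
    common = m.index.intersection(t.index)
    y = m.loc[common].to_numpy(dtype=float)
    x = t.loc[common].to_numpy(dtype=float)
    if blood is not None:
        b = blood.reindex(common).to_numpy(dtype=float)
        y = y - b
        x = x - b
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = int(y.size)
    if n < min_cpgs:
        raise ValueError(f"only {n} usable CpGs, need >= {min_cpgs}")
    if not np.any(x != 0):
        raise ValueError("all-zero tumor reference")

    def slope(xv, yv):
        if free_intercept:
            A = np.column_stack([xv, np.ones_like(xv)])
            coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
            return float(coef[0]), float(coef[1])
        return float(xv @ yv / (xv @ xv)), 0.0

    raw_f, intercept = slope(x, y)
    f = float(np.clip(raw_f, 0.0, 1.0))
    resid = y - (raw_f * x + intercept)
    if n > 2 and np.ptp(x) > 0 and np.ptp(y) > 0:
        rho = spearmanr(x, y).statistic
    else:
        rho = float("nan")
    rng = rng_for(seed, f"deconv-boot:{meas.sample}")
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        xs, ys = x[idx], y[idx]
        if np.any(xs != 0):
            boots.append(np.clip(slope(xs, ys)[0], 0.0, 1.0))
    ci_low, ci_high = (np.percentile(boots, [2.5, 97.5]) if boots
                       else (float("nan"), float("nan")))
    reliable = (f >= f_floor) and (n >= min_cpgs)
    return DeconvResult(
        sample=meas.sample,
        f_ctdna=f,
        n_cpgs=n,
        reliable=reliable,
        residual_sd=float(np.std(resid, ddof=1)),
        rank_corr=float(rho),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        f_floor=f_floor,
        intercept=intercept,
    )


def reconstruct_tumor_methylation(
    meas: CfDNAMethylome,
    f: DeconvResult,
    site_ids: list[str] | None = None,
    force: bool = False,
) -> pd.Series:
    """Invert the mixture: M_tumor_hat = min(1, M_meas / f_ctdna) per CpG.

    Refuses to divide by an unreliable fraction unless ``force`` is set.
    The number of clipped CpGs is stored in ``result.attrs['n_clipped']``.
    """
    if not f.reliable and not force:
        raise ValueError(
            f"ctDNA fraction for {f.sample!r} is unreliable "
            f"(f={f.f_ctdna:.4g}, n={f.n_cpgs}); refusing to reconstruct"
        )
    m = meas.series()
    if site_ids is not None:
        m = m.reindex(site_ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        recon = m / f.f_ctdna
    n_clipped = int((recon > 1.0).sum())
    recon = recon.clip(upper=1.0)
    recon.attrs["n_clipped"] = n_clipped
    return recon


@dataclass
class MarkerExclusion:
    retained: pd.DataFrame      # gene, klass
    report: pd.DataFrame        # gene, klass, control_mean, control_sd, status, reason


def exclude_unreliable_markers(
    controls: list[CfDNAMethylome],
    signature: pd.DataFrame,
    promoter_map: dict[str, set[str]],
    mean_cap: float = 0.05,
    sd_cap: float = 0.05,
) -> MarkerExclusion:
    """Drop signature genes whose promoter methylation in healthy-control
    cfDNA is high (mean > mean_cap) or variable across controls
    (sd > sd_cap); genes without measured promoter CpGs are excluded with
    their own reason code.
    """
    if len(controls) < 2:
        raise ValueError("need >= 2 control samples")
    rows = []
    for gene, klass in zip(signature["gene"], signature["klass"]):
        sids = promoter_map.get(gene, set())
        per_control = []
        for ctrl in controls:
            sub = ctrl.series().reindex(sorted(sids)).dropna()
            if len(sub):
                per_control.append(float(sub.mean()))
        if not per_control:
            rows.append((gene, klass, np.nan, np.nan, "excluded", "no_promoter_cpgs"))
            continue
        mean = float(np.mean(per_control))
        sd = float(np.std(per_control, ddof=1)) if len(per_control) > 1 else 0.0
        if mean > mean_cap:
            rows.append((gene, klass, mean, sd, "excluded", "high"))
        elif sd > sd_cap:
            rows.append((gene, klass, mean, sd, "excluded", "variable"))
        else:
            rows.append((gene, klass, mean, sd, "retained", ""))
    report = pd.DataFrame(
        rows, columns=["gene", "klass", "control_mean", "control_sd", "status", "reason"]
    )
    retained = report.loc[report["status"] == "retained", ["gene", "klass"]].reset_index(drop=True)
    return MarkerExclusion(retained=retained, report=report)


@dataclass
class TrajectoryPoint:
    day: int
    sample: str
    f_ctdna: float
    mean_epithelial: float
    sem_epithelial: float
    mean_mesenchymal: float
    sem_mesenchymal: float
    score: float             # epithelial mean - mesenchymal mean
    relative_score: float    # score - score(t0)


@dataclass
class EMTTrajectory:
    patient: str
    points: list[TrajectoryPoint]
    trend: str               # emt_shift | no_shift | reverse_shift
    tau: float
    anchor_index: int = 0
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.points]).assign(
            patient=self.patient, trend=self.trend
        )


def emt_trajectory(
    samples: list[tuple[CfDNAMethylome, DeconvResult, int]],
    signature: pd.DataFrame,
    promoter_map: dict[str, set[str]],
    tau: float = TREND_TAU,
) -> EMTTrajectory:
    """Longitudinal EMT score from reconstructed tumor methylomes.

    Per timepoint, class means (+/- SEM) over retained EMT promoter CpGs
    are computed from M_meas / f_ctdna; the score is epithelial minus
    mesenchymal mean, reported relative to the first reliable timepoint.
    The trend at the last timepoint is emt_shift when the relative score
    exceeds ``tau``, reverse_shift below ``-tau``, no_shift otherwise.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 timepoints")
    epi_ids = sorted(
        set().union(*(promoter_map.get(g, set())
                      for g in signature.loc[signature["klass"] == "epithelial", "gene"]))
        if (signature["klass"] == "epithelial").any() else set()
    )
    mes_ids = sorted(
        set().union(*(promoter_map.get(g, set())
                      for g in signature.loc[signature["klass"] == "mesenchymal", "gene"]))
        if (signature["klass"] == "mesenchymal").any() else set()
    )
    if not epi_ids or not mes_ids:
        raise ValueError("signature class without promoter CpGs")

    notes = []
    reliable_idx = [i for i, (_, f, _) in enumerate(samples) if f.reliable]
    if len(reliable_idx) < 2:
        raise ValueError("need >= 2 timepoints with a reliable ctDNA fraction")
    anchor = reliable_idx[0]
    if anchor != 0:
        notes.append(f"t0 unreliable; trajectory anchored at timepoint {anchor}")

    def sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")

    points = []
    score0 = None
    patient = samples[0][0].sample.rsplit("_t", 1)[0]
    for i in reliable_idx:
        meas, fres, day = samples[i]
        recon = reconstruct_tumor_methylation(meas, fres)
        e = recon.reindex(epi_ids).dropna().to_numpy()
        m = recon.reindex(mes_ids).dropna().to_numpy()
        if e.size == 0 or m.size == 0:
            notes.append(f"{meas.sample}: no measured promoter CpGs; skipped")
            continue
        score = float(e.mean() - m.mean())
        if score0 is None:
            score0 = score
        points.append(
            TrajectoryPoint(
                day=day, sample=meas.sample, f_ctdna=fres.f_ctdna,
                mean_epithelial=float(e.mean()), sem_epithelial=sem(e),
                mean_mesenchymal=float(m.mean()), sem_mesenchymal=sem(m),
                score=score, relative_score=score - score0,
            )
        )
    if len(points) < 2:
        raise ValueError("fewer than 2 usable timepoints after filtering")
    last = points[-1].relative_score
    trend = "emt_shift" if last > tau else ("reverse_shift" if last < -tau else "no_shift")
    return EMTTrajectory(patient=patient, points=points, trend=trend,
                         tau=tau, anchor_index=anchor, notes=notes)


def correlate_tissue_liquid(
    tissue: pd.Series,
    liquids: list[tuple[CfDNAMethylome, DeconvResult]],
    min_common: int = MIN_CPGS,
) -> pd.DataFrame:
    """Spearman rank correlation between a tissue methylome and each
    liquid biopsy's reconstructed tumor methylome (the ctDNA-fraction
    correction).  The best-correlated liquid sample is flagged."""
    rows = []
    for meas, fres in liquids:
        recon = reconstruct_tumor_methylation(meas, fres, force=True)
        common = tissue.index.intersection(recon.index)
        t = tissue.loc[common].to_numpy(dtype=float)
        l = recon.loc[common].to_numpy(dtype=float)
        ok = np.isfinite(t) & np.isfinite(l)
        if ok.sum() < min_common:
            raise ValueError(
                f"{meas.sample}: only {int(ok.sum())} common CpGs, need >= {min_common}"
            )
        rho, p = spearmanr(t[ok], l[ok])
        rows.append({"sample": meas.sample, "rho": float(rho), "p": float(p),
                     "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    out["best"] = out["rho"] == out["rho"].max()
    return out
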