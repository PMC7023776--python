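"""Differential CpG methylation analysis.

Delta-beta computation, hyper/hypo CpG calling at the 0.3/0.7 thresholds,
promoter-level EMT methylation scoring, quadrant enrichment of methylation
versus expression changes, the shared-overlap binomial test between
resistant models, and TAB-based separation of the 5mC-specific signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .formats import BetaMatrix
from .stats import MannWhitneyResult, binom_sf_log, mann_whitney_u

__all__ = [
    "DMC_LO",
    "DMC_HI",
    "OverlapTest",
    "QuadrantEnrichment",
    "PromoterEMTScore",
    "split_5mc",
    "classify_dmcs",
    "promoter_emt_methylation",
    "quadrant_enrichment",
    "overlap_binomial",
]

DMC_LO = 0.3
DMC_HI = 0.7


def split_5mc(standard: BetaMatrix, tab: BetaMatrix) -> BetaMatrix:
    """5mC-specific signal: standard beta minus TAB (5hmC) beta, floored
    at zero.  The number of floored entries is recorded in
    ``result.n_floored``."""
    if standard.site_ids != tab.site_ids:
        raise ValueError("standard and TAB matrices cover different sites")
    if standard.samples != tab.samples:
        raise ValueError("standard and TAB matrices cover different samples")
    diff = standard.values - tab.values
    with np.errstate(invalid="ignore"):
        n_floored = int(np.nansum(diff < 0))
    mc = BetaMatrix(standard.sites, list(standard.samples),
                    np.clip(diff, 0.0, None), channel="mc_specific")
    mc.n_floored = n_floored
    return mc


def classify_dmcs(
    parental: np.ndarray,
    resistant: np.ndarray,
    site_ids: list[str] | None = None,
    lo: float = DMC_LO,
    hi: float = DMC_HI,
) -> pd.DataFrame:
    """Call each CpG hyper, hypo or stable from paired beta values.

    hyper: beta_parental < lo and beta_resistant > hi (strict); hypo is the
    mirror image.  CpGs missing in either sample are dropped; the dropped
    count is stored in ``result.attrs['n_missing']``.
    """
    if not lo < hi:
        raise ValueError(f"require lo < hi, got lo={lo}, hi={hi}")
    parental = np.asarray(parental, dtype=float)
    resistant = np.asarray(resistant, dtype=float)
    if parental.shape != resistant.shape:
        raise ValueError("parental and resistant vectors differ in length")
    if site_ids is None:
        site_ids = [f"cpg_{i:06d}" for i in range(parental.size)]
    ok = np.isfinite(parental) & np.isfinite(resistant)
    n_missing = int((~ok).sum())
    par, res = parental[ok], resistant[ok]
    ids = [s for s, keep in zip(site_ids, ok) if keep]
    call = np.full(par.size, "stable", dtype=object)
    call[(par < lo) & (res > hi)] = "hyper"
    call[(par > hi) & (res < lo)] = "hypo"
    out = pd.DataFrame(
        {
            "site": ids,
            "beta_parental": par,
            "beta_resistant": res,
            "delta_beta": res - par,
            "call": call,
        }
    )
    out.attrs["n_missing"] = n_missing
    return out


@dataclass
class PromoterEMTScore:
    """Class-level delta-beta summary plus per-gene promoter means."""

    delta_epithelial: np.ndarray
    delta_mesenchymal: np.ndarray
    mean_epithelial: float
    sem_epithelial: float
    mean_mesenchymal: float
    sem_mesenchymal: float
    test: MannWhitneyResult     # one-sided: mesenchymal delta < epithelial delta
    gene_means: pd.DataFrame    # gene, klass, n_cpgs, mean per sample, delta
    genes_without_cpgs: list[str] = field(default_factory=list)

    @property
    def p(self) -> float:
        return self.test.p


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def promoter_emt_methylation(
    beta: BetaMatrix,
    promoter_map: dict[str, set[str]],
    signature: pd.DataFrame,
    parental: str,
    resistant: str,
) -> PromoterEMTScore:
    """Pool per-CpG delta-beta by signature class and test whether
    mesenchymal promoter CpGs lose methylation relative to epithelial ones
    (one-sided Mann-Whitney, mesenchymal < epithelial).

    Per-gene promoter methylation is the unweighted mean over the gene's
    promoter CpGs; signature genes without promoter CpGs are reported and
    excluded.
    """
    idx = {sid: i for i, sid in enumerate(beta.site_ids)}
    par = beta.column(parental)
    res = beta.column(resistant)
    deltas: dict[str, list[float]] = {"epithelial": [], "mesenchymal": []}
    rows = []
    no_cpgs = []
    for gene, klass in zip(signature["gene"], signature["klass"]):
        sids = sorted(promoter_map.get(gene, set()))
        rows_i = [idx[s] for s in sids if s in idx]
        if not rows_i:
            no_cpgs.append(gene)
            continue
        p_vals = par[rows_i]
        r_vals = res[rows_i]
        ok = np.isfinite(p_vals) & np.isfinite(r_vals)
        deltas[klass].extend((r_vals - p_vals)[ok].tolist())
        rows.append(
            {
                "gene": gene,
                "klass": klass,
                "n_cpgs": int(len(rows_i)),
                "mean_parental": float(np.nanmean(p_vals)),
                "mean_resistant": float(np.nanmean(r_vals)),
                "delta": float(np.nanmean(r_vals) - np.nanmean(p_vals)),
            }
        )
    d_epi = np.array(deltas["epithelial"], dtype=float)
    d_mes = np.array(deltas["mesenchymal"], dtype=float)
    if d_epi.size == 0 or d_mes.size == 0:
        raise ValueError("a signature class has no promoter CpGs in the matrix")
    test = mann_whitney_u(d_mes, d_epi, alternative="less")
    return PromoterEMTScore(
        delta_epithelial=d_epi,
        delta_mesenchymal=d_mes,
        mean_epithelial=float(d_epi.mean()),
        sem_epithelial=_sem(d_epi),
        mean_mesenchymal=float(d_mes.mean()),
        sem_mesenchymal=_sem(d_mes),
        test=test,
        gene_means=pd.DataFrame(rows),
        genes_without_cpgs=no_cpgs,
    )


@dataclass
class QuadrantEnrichment:
    klass: str
    counts: dict[str, int]          # quadrant -> gene count
    n_on_axis: int
    fraction_expected_quadrant: float   # NaN when denominator empty
    expected_fraction: float = 0.25

    @property
    def enriched(self) -> bool:
        f = self.fraction_expected_quadrant
        return bool(np.isfinite(f) and f > self.expected_fraction)


_QUADRANTS = ("upper_left", "upper_right", "lower_left", "lower_right")
_EXPECTED_QUADRANT = {"mesenchymal": "upper_left", "epithelial": "lower_right"}


def quadrant_enrichment(
    fc: pd.DataFrame,
    promoter_delta: pd.DataFrame,
    signature: pd.DataFrame,
) -> dict[str, QuadrantEnrichment]:
    """Place each signature gene in a (delta-beta, log2fc) quadrant and
    report the fraction falling in the EMT-expected quadrant per class
    (upper-left for mesenchymal, lower-right for epithelial; expected
    fraction under no association is 0.25).

    Genes with an exact zero on either axis join no quadrant and leave the
    denominator.  ``promoter_delta`` needs 'gene' and 'delta' columns.
    """
    merged = (
        fc.merge(promoter_delta[["gene", "delta"]], on="gene")
        .merge(signature, on="gene")
    )
    out: dict[str, QuadrantEnrichment] = {}
    for klass in ("epithelial", "mesenchymal"):
        sub = merged[merged["klass"] == klass]
        counts = {q: 0 for q in _QUADRANTS}
        on_axis = 0
        for _, row in sub.iterrows():
            d, f = row["delta"], row["log2fc"]
            if d == 0 or f == 0 or not (np.isfinite(d) and np.isfinite(f)):
                on_axis += 1
                continue
            vert = "upper" if f > 0 else "lower"
            horiz = "left" if d < 0 else "right"
            counts[f"{vert}_{horiz}"] += 1
        denom = sum(counts.values())
        frac = counts[_EXPECTED_QUADRANT[klass]] / denom if denom else float("nan")
        out[klass] = QuadrantEnrichment(klass, counts, on_axis, frac)
    return out


@dataclass
class OverlapTest:
    pair_a: str
    pair_b: str
    direction: str
    n_common: int        # CpGs assayed in both pairs
    n_a: int             # differential CpGs in A (on the common set)
    n_b: int
    k: int               # shared differential CpGs
    expected: float      # n_a * n_b / n_common
    p: float
    method: str

    def __post_init__(self):
        if not 0 <= self.k <= min(self.n_a, self.n_b):
            raise ValueError("k out of range")


def overlap_binomial(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    direction: str,
    pair_a: str = "A",
    pair_b: str = "B",
    condition_on: str = "smaller",
    method: str = "binomial",
) -> OverlapTest:
    """One-sided test for excess sharing of hyper- or hypomethylated CpGs
    between two resistant models.

    N is the set of CpGs assayed (non-missing) in both models; with n_a
    shared-direction calls in one model and n_b in the other, the observed
    shared count k is compared to Binomial(n_a, n_b / N), with n_a taken as
    the smaller count by default (``condition_on`` in {'smaller', 'a',
    'b'}).  ``method='hypergeometric'`` uses the hypergeometric null
    instead.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    common = set(calls_a["site"]) & set(calls_b["site"])
    n_common = len(common)
    if n_common == 0:
        raise ValueError("no CpGs assayed in both pairs")
    in_a = set(calls_a.loc[calls_a["call"] == direction, "site"]) & common
    in_b = set(calls_b.loc[calls_b["call"] == direction, "site"]) & common
    k = len(in_a & in_b)
    n_a, n_b = len(in_a), len(in_b)
    if condition_on == "smaller":
        n_draw, n_pool = sorted((n_a, n_b))
    elif condition_on == "a":
        n_draw, n_pool = n_a, n_b
    elif condition_on == "b":
        n_draw, n_pool = n_b, n_a
    else:
        raise ValueError("condition_on must be 'smaller', 'a' or 'b'")
    if n_pool > n_common:
        raise ValueError("differential count exceeds the common assayed set")
    expected = n_a * n_b / n_common
    if method == "binomial":
        p = binom_sf_log(k, n_draw, n_pool / n_common) if n_draw else 1.0
    elif method == "hypergeometric":
        p = float(hypergeom.sf(k - 1, n_common, n_pool, n_draw)) if n_draw else 1.0
    else:
        raise ValueError("method must be 'binomial' or 'hypergeometric'")
    return OverlapTest(pair_a, pair_b, direction, n_common, n_a, n_b, k,
                       expected, p, method)
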