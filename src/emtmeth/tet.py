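"""5mC-decile 5hmC analysis for inferring TET-activity differences.

CpGs are binned per sample by their 5mC level; within each bin the 5hmC
of variably methylated CpGs (hyper or hypo between parental and resistant)
is contrasted with that of stably methylated CpGs.  Elevated 5hmC of
variable CpGs in the low bins of the sample where they are unmethylated,
combined with depressed 5hmC in the high bins of the sample where they are
methylated, is the signature of TET-driven methylation change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import BetaMatrix
from .stats import mann_whitney_u

__all__ = [
    "DEFAULT_ANALYSIS_BINS",
    "BinComparison",
    "TETBinAnalysis",
    "bin_by_methylation",
    "compare_variable_vs_stable",
    "tet_signature_flag",
]

DEFAULT_ANALYSIS_BINS = (1, 2, 3, 8, 9, 10)
LOW_BINS = (1, 2, 3)
HIGH_BINS = (8, 9, 10)


def bin_by_methylation(mc: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Assign each CpG to a methylation decile (1-based).

    Bin i covers [(i-1)/n, i/n) half-open; the last bin is closed at 1.0.
    NaN maps to bin 0 (unassigned).
    """
    mc = np.asarray(mc, dtype=float)
    finite = mc[np.isfinite(mc)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("methylation values outside [0, 1]")
    bins = np.zeros(mc.shape, dtype=int)
    ok = np.isfinite(mc)
    bins[ok] = np.minimum(np.floor(mc[ok] * n_bins).astype(int), n_bins - 1) + 1
    return bins


@dataclass
class BinComparison:
    sample: str
    bin: int
    bin_lo: float
    bin_hi: float
    group: str            # 'hyper' or 'hypo'
    n_variable: int
    n_stable: int
    mean_hmc_variable: float
    mean_hmc_stable: float
    delta: float          # mean(stable) - mean(variable)
    p: float              # two-sided Mann-Whitney; NaN when not comparable
    comparable: bool


@dataclass
class TETBinAnalysis:
    comparisons: list[BinComparison]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])


def compare_variable_vs_stable(
    mc: BetaMatrix,
    hmc: BetaMatrix,
    calls: pd.DataFrame,
    sample: str,
    bins: tuple[int, ...] = DEFAULT_ANALYSIS_BINS,
    n_bins: int = 10,
    min_group: int = 2,
) -> TETBinAnalysis:
    """Per bin and variable group, contrast 5hmC of variable versus stable
    CpGs in one sample (binned by that sample's 5mC).

    Bins with fewer than ``min_group`` CpGs in either group are reported
    as non-comparable with no p value.
    """
    if sample not in mc.samples or sample not in hmc.samples:
        raise KeyError(f"sample {sample!r} absent from a matrix")
    if mc.site_ids != hmc.site_ids:
        raise ValueError("5mC and 5hmC matrices cover different sites")
    call_by_site = dict(zip(calls["site"], calls["call"]))
    status = np.array([call_by_site.get(s, "stable") for s in mc.site_ids])
    m = mc.column(sample)
    h = hmc.column(sample)
    assignment = bin_by_methylation(m, n_bins)
    out: list[BinComparison] = []
    for b in bins:
        in_bin = assignment == b
        stable_h = h[in_bin & (status == "stable") & np.isfinite(h)]
        for group in ("hyper", "hypo"):
            var_h = h[in_bin & (status == group) & np.isfinite(h)]
            if var_h.size == 0:
                continue  # group not present in this bin
            comparable = var_h.size >= min_group and stable_h.size >= min_group
            if comparable:
                res = mann_whitney_u(var_h, stable_h, alternative="two-sided")
                p = res.p
                delta = float(stable_h.mean() - var_h.mean())
            else:
                p = float("nan")
                delta = float("nan")
            out.append(
                BinComparison(
                    sample=sample,
                    bin=b,
                    bin_lo=(b - 1) / n_bins,
                    bin_hi=b / n_bins,
                    group=group,
                    n_variable=int(var_h.size),
                    n_stable=int(stable_h.size),
                    mean_hmc_variable=float(var_h.mean()) if var_h.size else float("nan"),
                    mean_hmc_stable=float(stable_h.mean()) if stable_h.size else float("nan"),
                    delta=delta,
                    p=p,
                    comparable=comparable,
                )
            )
    return TETBinAnalysis(out)


def _majority_signif(comps: list[BinComparison], want_delta_negative: bool,
                     alpha: float) -> bool:
    """True when most comparable bins show the wanted direction at p < alpha.

    delta = stable - variable, so delta < 0 means variable CpGs carry more
    5hmC than stable CpGs of the same bin.
    """
    usable = [c for c in comps if c.comparable]
    if not usable:
        return False
    hits = sum(
        1
        for c in usable
        if c.p < alpha and ((c.delta < 0) == want_delta_negative)
    )
    return hits * 2 >= len(usable)


def tet_signature_flag(
    parental_analysis: TETBinAnalysis,
    resistant_analysis: TETBinAnalysis,
    alpha: float = 0.05,
) -> bool:
    """TET-driven signature: variable CpGs show significantly more 5hmC
    than stable CpGs in the low bins of the sample where they are
    unmethylated (hyper CpGs in parental, hypo CpGs in resistant) and
    significantly less in the high bins of the sample where they are
    methylated (hyper in resistant, hypo in parental)."""
    hyper_low = [c for c in parental_analysis.comparisons
                 if c.group == "hyper" and c.bin in LOW_BINS]
    hyper_high = [c for c in resistant_analysis.comparisons
                  if c.group == "hyper" and c.bin in HIGH_BINS]
    hypo_low = [c for c in resistant_analysis.comparisons
                if c.group == "hypo" and c.bin in LOW_BINS]
    hypo_high = [c for c in parental_analysis.comparisons
                 if c.group == "hypo" and c.bin in HIGH_BINS]
    conditions = []
    if hyper_low or hyper_high:
        conditions.append(
            _majority_signif(hyper_low, want_delta_negative=True, alpha=alpha)
            and _majority_signif(hyper_high, want_delta_negative=False, alpha=alpha)
        )
    if hypo_low or hypo_high:
        conditions.append(
            _majority_signif(hypo_low, want_delta_negative=True, alpha=alpha)
            and _majority_signif(hypo_high, want_delta_negative=False, alpha=alpha)
        )
    return bool(conditions) and all(conditions)
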