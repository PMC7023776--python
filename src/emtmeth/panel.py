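"""Capture-panel design: select CpGs that are unmethylated in healthy
blood and tile them into capture regions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import BetaMatrix, CpGSite

__all__ = ["PanelDesign", "select_target_cpgs", "build_capture_regions", "design_panel"]

DEFAULT_THRESHOLD = 0.03
DEFAULT_MERGE_GAP = 200
DEFAULT_MIN_LEN = 60


def select_target_cpgs(blood: BetaMatrix, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """CpGs with mean blood-cohort beta strictly below ``threshold``.

    The per-CpG mean is the unweighted pairwise-complete mean over blood
    samples; CpGs with no observed value never qualify.
    """
    if len(blood.samples) == 0:
        raise ValueError("empty blood cohort")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(blood.values, axis=1)
    keep = np.isfinite(means) & (means < threshold)
    return pd.DataFrame(
        {
            "id": [s.id for s, k in zip(blood.sites, keep) if k],
            "chrom": [s.chrom for s, k in zip(blood.sites, keep) if k],
            "pos": [s.pos for s, k in zip(blood.sites, keep) if k],
            "mean_beta": means[keep],
        }
    )


@dataclass
class PanelDesign:
    targets: pd.DataFrame                     # id, chrom, pos, mean_beta
    regions: list[tuple[str, int, int]]       # 1-based inclusive
    threshold: float

    @property
    def region_lengths(self) -> np.ndarray:
        return np.array([end - start + 1 for _, start, end in self.regions])

    def summary(self) -> dict:
        lengths = self.region_lengths
        return {
            "n_targets": int(len(self.targets)),
            "n_regions": int(len(self.regions)),
            "median_length": float(np.median(lengths)) if lengths.size else float("nan"),
            "min_length": int(lengths.min()) if lengths.size else 0,
            "max_length": int(lengths.max()) if lengths.size else 0,
            "threshold": self.threshold,
        }


def build_capture_regions(
    targets: list[CpGSite] | pd.DataFrame,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[tuple[str, int, int]]:
    """Merge target CpGs within ``merge_gap`` bp into regions and pad any
    region shorter than ``min_len`` symmetrically.

    A reproducible stand-in for vendor probe tiling.  Input is sorted by
    (chrom, pos) internally if needed; coordinates are 1-based inclusive.
    """
    if isinstance(targets, pd.DataFrame):
        rows = list(zip(targets["chrom"], targets["pos"]))
    else:
        rows = [(s.chrom, s.pos) for s in targets]
    if not rows:
        return []
    rows = sorted(rows)
    regions: list[list] = []
    for chrom, pos in rows:
        if regions and regions[-1][0] == chrom and pos - regions[-1][2] <= merge_gap:
            regions[-1][2] = max(regions[-1][2], pos)
        else:
            regions.append([chrom, pos, pos])
    padded: list[tuple[str, int, int]] = []
    for chrom, start, end in regions:
        length = end - start + 1
        if length < min_len:
            pad = min_len - length
            left = pad // 2
            start = max(1, start - left)
            end = start + min_len - 1
        padded.append((chrom, start, end))
    # padding may have re-introduced overlaps; merge once more
    merged: list[list] = []
    for chrom, start, end in padded:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2] + 1:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(r) for r in merged]


def design_panel(
    blood: BetaMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_len: int = DEFAULT_MIN_LEN,
) -> PanelDesign:
    targets = select_target_cpgs(blood, threshold)
    regions = build_capture_regions(targets, merge_gap, min_len)
    return PanelDesign(targets=targets, regions=regions, threshold=threshold)
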