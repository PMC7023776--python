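"""EMT scoring from expression data.

CPM log2 fold changes between a resistant and a parental sample, the
delta-delta-Ct method with data-driven housekeeper selection, and the
epithelial-versus-mesenchymal rank comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import MannWhitneyResult, mann_whitney_u

__all__ = [
    "EMTExpressionScore",
    "cpm_log2fc",
    "ddct_log2fc",
    "emt_expression_score",
]

ALPHA = 0.05


@dataclass
class EMTExpressionScore:
    epithelial: pd.Series      # log2fc of epithelial signature genes present
    mesenchymal: pd.Series
    median_epithelial: float
    median_mesenchymal: float
    test: MannWhitneyResult
    alpha: float
    full_emt: bool

    @property
    def p(self) -> float:
        return self.test.p

    @property
    def u(self) -> float:
        return self.test.u


def cpm_log2fc(
    counts: pd.DataFrame,
    parental: str,
    resistant: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2((CPM_resistant + pc) / (CPM_parental + pc)) per gene.

    ``counts`` must have a 'gene' column and one numeric column per sample.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    for sample in (parental, resistant):
        if sample not in counts.columns:
            raise KeyError(f"sample {sample!r} not in count table")
    par = counts[parental].to_numpy(dtype=float)
    res = counts[resistant].to_numpy(dtype=float)
    if (par < 0).any() or (res < 0).any():
        raise ValueError("negative counts")
    tot_par, tot_res = par.sum(), res.sum()
    if tot_par == 0 or tot_res == 0:
        raise ValueError("zero total counts in a sample")
    cpm_par = 1e6 * par / tot_par
    cpm_res = 1e6 * res / tot_res
    lfc = np.log2((cpm_res + pseudocount) / (cpm_par + pseudocount))
    return pd.DataFrame({"gene": counts["gene"].to_numpy(), "log2fc": lfc})


def select_housekeepers(
    ct: pd.DataFrame,
    candidates: list[str],
    n_select: int = 2,
) -> list[str]:
    """Pick the ``n_select`` candidate genes with the lowest Ct standard
    deviation pooled across all samples and conditions."""
    sample_cols = [c for c in ct.columns if c != "gene"]
    sub = ct[ct["gene"].isin(candidates)]
    present = list(sub["gene"])
    missing = [g for g in candidates if g not in present]
    if len(present) < n_select:
        raise ValueError(
            f"need >= {n_select} housekeeper candidates, found {len(present)}"
            + (f" (missing: {missing})" if missing else "")
        )
    vals = sub.set_index("gene")[sample_cols].astype(float)
    if vals.isna().any(axis=None):
        bad = vals.index[vals.isna().any(axis=1)].tolist()
        raise ValueError(f"housekeeper candidate(s) with missing Ct: {bad}")
    sds = vals.std(axis=1, ddof=1).sort_values(kind="stable")
    return list(sds.index[:n_select])


def ddct_log2fc(
    ct: pd.DataFrame,
    parental: str,
    resistant: str,
    housekeepers: list[str],
    n_select: int = 2,
) -> pd.DataFrame:
    """Delta-delta-Ct log2 fold changes, resistant versus parental.

    Technical duplicates must already be averaged.  The ``n_select`` most
    stable housekeepers (lowest pooled Ct sd) normalise each sample:
    dCt = Ct_gene - mean(Ct_housekeepers); log2fc = -(dCt_res - dCt_par).
    """
    selected = select_housekeepers(ct, housekeepers, n_select)
    hk = ct[ct["gene"].isin(selected)]
    hk_par = hk[parental].astype(float).mean()
    hk_res = hk[resistant].astype(float).mean()
    targets = ct[~ct["gene"].isin(housekeepers)]
    dct_par = targets[parental].astype(float).to_numpy() - hk_par
    dct_res = targets[resistant].astype(float).to_numpy() - hk_res
    lfc = -(dct_res - dct_par)
    out = pd.DataFrame({"gene": targets["gene"].to_numpy(), "log2fc": lfc})
    out.attrs["housekeepers"] = selected
    return out


def emt_expression_score(
    fc: pd.DataFrame,
    signature: pd.DataFrame,
    alternative: str = "two-sided",
    alpha: float = ALPHA,
) -> EMTExpressionScore:
    """Compare log2 fold changes of epithelial versus mesenchymal signature
    genes with a Mann-Whitney U test (epithelial as the first sample).

    The full-EMT call requires mesenchymal median > 0, epithelial
    median < 0 and p < alpha.
    """
    merged = fc.merge(signature, on="gene")
    epi = merged.loc[merged["klass"] == "epithelial", ["gene", "log2fc"]]
    mes = merged.loc[merged["klass"] == "mesenchymal", ["gene", "log2fc"]]
    for name, sub in (("epithelial", epi), ("mesenchymal", mes)):
        if len(sub) < 2:
            raise ValueError(f"fewer than 2 {name} signature genes present in fold changes")
    test = mann_whitney_u(
        epi["log2fc"].to_numpy(), mes["log2fc"].to_numpy(), alternative=alternative
    )
    med_e = float(epi["log2fc"].median())
    med_m = float(mes["log2fc"].median())
    full = (med_m > 0) and (med_e < 0) and (test.p < alpha)
    return EMTExpressionScore(
        epithelial=epi.set_index("gene")["log2fc"],
        mesenchymal=mes.set_index("gene")["log2fc"],
        median_epithelial=med_e,
        median_mesenchymal=med_m,
        test=test,
        alpha=alpha,
        full_emt=full,
    )
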