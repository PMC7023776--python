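"""Readers/writers for on-disk formats and promoter annotation.

All genomic coordinates are 1-based inclusive internally (the Bismark
coverage convention).  BED exports are converted to 0-based half-open at
write time.  Missing beta values are encoded as NaN and excluded pairwise
from downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CpGSite",
    "BetaMatrix",
    "GeneAnnotation",
    "CoverageRecord",
    "BetaMatrixError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_bismark_cov",
    "write_bismark_cov",
    "read_signature",
    "write_signature",
    "load_packaged_signature",
    "load_packaged_exclusion_list",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_bed",
    "annotate_promoters",
]

VALID_CHANNELS = ("standard", "tab", "mc_specific")

SAMPLE_SHEET_LABELS = ("start", "on_treatment", "progression", "end_of_study")
SAMPLE_SHEET_OUTCOMES = ("acquired_resistance", "intrinsic_resistance", "response", "control")


class BetaMatrixError(ValueError):
    """Raised on malformed or out-of-range beta matrix input."""


@dataclass(frozen=True)
class CpGSite:
    """A single CpG; ``pos`` is the 1-based position of the C."""

    id: str
    chrom: str
    pos: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"CpG {self.id}: pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene}: unknown strand {self.strand!r}")


@dataclass(frozen=True)
class CoverageRecord:
    """One line of a Bismark coverage file (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    pct_meth: float
    count_meth: int
    count_unmeth: int

    @property
    def depth(self) -> int:
        return self.count_meth + self.count_unmeth

    @property
    def has_coverage(self) -> bool:
        return self.depth > 0

    @property
    def frac_meth(self) -> float:
        """Methylated fraction recomputed from counts; NaN when depth 0."""
        if self.depth == 0:
            return float("nan")
        return self.count_meth / self.depth


@dataclass
class BetaMatrix:
    """CpG x sample methylation fractions with genomic coordinates.

    ``values`` is a float array of shape (n_sites, n_samples) with NaN for
    missing entries; row order matches ``sites``.
    """

    sites: list[CpGSite]
    samples: list[str]
    values: np.ndarray
    channel: str = "standard"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sites), len(self.samples)):
            raise BetaMatrixError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.channel not in VALID_CHANNELS:
            raise BetaMatrixError(f"unknown channel {self.channel!r}")
        ids = [s.id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise BetaMatrixError("duplicate CpG ids in matrix")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere((self.values < 0) | (self.values > 1))
            r, c = bad[0]
            raise BetaMatrixError(
                f"beta value {self.values[r, c]} outside [0, 1] at "
                f"site {ids[r]} (row {r + 1}), sample {self.samples[c]}"
            )

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.sites]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def column(self, sample: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample)]

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "id": [s.id for s in self.sites],
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
            }
        )
        vals = pd.DataFrame(self.values, columns=self.samples)
        return pd.concat([meta, vals], axis=1)


def read_beta_matrix(path: str | Path, channel: str = "standard") -> BetaMatrix:
    """Parse a tab-separated beta matrix (id, chrom, pos, then one column
    per sample).  Values outside [0, 1] raise a validation error naming the
    offending data row; non-numeric cells raise a parse error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 4:
        raise BetaMatrixError(f"{path}: expected >= 4 columns (id, chrom, pos, samples)")
    if df.empty:
        raise BetaMatrixError(f"{path}: no CpG rows")
    id_col, chrom_col, pos_col = df.columns[:3]
    sample_cols = list(df.columns[3:])
    for col in sample_cols:
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise BetaMatrixError(
                f"{path}: non-numeric value {raw.iloc[row]!r} at data row "
                f"{row + 1}, column {col!r}"
            )
        out_of_range = numeric.notna() & ((numeric < 0) | (numeric > 1))
        if out_of_range.any():
            row = int(np.flatnonzero(out_of_range.to_numpy())[0])
            raise BetaMatrixError(
                f"{path}: beta value {numeric.iloc[row]} outside [0, 1] at "
                f"data row {row + 1}, column {col!r}"
            )
        df[col] = numeric
    sites = [
        CpGSite(str(i), str(c), int(p))
        for i, c, p in zip(df[id_col], df[chrom_col], df[pos_col])
    ]
    return BetaMatrix(sites, sample_cols, df[sample_cols].to_numpy(dtype=float), channel)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path, float_format: str = "%.6f") -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format=float_format)


def read_bismark_cov(path: str | Path, pct_tolerance: float = 0.5) -> list[CoverageRecord]:
    """Parse a 6-column Bismark coverage file.

    The percent column is recomputed from the counts; a discrepancy above
    ``pct_tolerance`` (percentage points) triggers a warning, not an error,
    since rounding dialects differ.
    """
    path = Path(path)
    records: list[CoverageRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            chrom, start, end, pct, n_meth, n_unmeth = fields
            n_meth, n_unmeth = int(n_meth), int(n_unmeth)
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative read count")
            rec = CoverageRecord(chrom, int(start), int(end), float(pct), n_meth, n_unmeth)
            if rec.depth > 0:
                recomputed = 100.0 * rec.count_meth / rec.depth
                if abs(recomputed - rec.pct_meth) > pct_tolerance:
                    warnings.warn(
                        f"{path}:{lineno}: stated %meth {rec.pct_meth} differs "
                        f"from recomputed {recomputed:.4g}",
                        stacklevel=2,
                    )
            records.append(rec)
    return records


def write_bismark_cov(records: Iterable[CoverageRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            pct = 100.0 * r.count_meth / r.depth if r.depth else 0.0
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{pct:.6f}\t{r.count_meth}\t{r.count_unmeth}\n"
            )


# -- signature tables --------------------------------------------------------

def read_signature(path: str | Path) -> pd.DataFrame:
    """Read a 2-column gene/class table; classes are 'epithelial' or
    'mesenchymal' and both must be present."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["gene", "klass"] + list(df.columns[2:])
    df = df[["gene", "klass"]].copy()
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate signature gene {dup!r}")
    bad = set(df["klass"]) - {"epithelial", "mesenchymal"}
    if bad:
        raise ValueError(f"unknown signature class(es): {sorted(bad)}")
    if set(df["klass"]) != {"epithelial", "mesenchymal"}:
        raise ValueError("signature must contain both epithelial and mesenchymal genes")
    return df


def write_signature(sig: pd.DataFrame, path: str | Path) -> None:
    sig.rename(columns={"klass": "class"}).to_csv(path, sep="\t", index=False)


def load_packaged_signature() -> pd.DataFrame:
    """The packaged 50-gene EMT signature (16 epithelial, 34 mesenchymal)."""
    with resources.as_file(resources.files("emtmeth.data") / "emt_signature.tsv") as p:
        return read_signature(p)


def load_packaged_exclusion_list() -> list[str]:
    """Marker genes excluded from cfDNA analysis for high or variable
    methylation in healthy-control cfDNA."""
    text = (resources.files("emtmeth.data") / "cfdna_excluded_markers.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


# -- gene annotation and sample sheets ---------------------------------------

def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    df.columns = ["gene", "chrom", "tss", "strand"] + list(df.columns[4:])
    genes = [
        GeneAnnotation(str(g), str(c), int(t), str(s))
        for g, c, t, s in zip(df["gene"], df["chrom"], df["tss"], df["strand"])
    ]
    names = [g.gene for g in genes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene in annotation")
    return genes


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene, g.chrom, g.tss, g.strand) for g in genes],
        columns=["gene", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"patient", "sample", "day", "label", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")
    if (df["day"] < 0).any():
        raise ValueError("sample sheet: negative day")
    for patient, sub in df.groupby("patient"):
        days = sub["day"].to_numpy()
        if not np.all(np.diff(days) > 0):
            raise ValueError(f"sample sheet: days not strictly increasing for {patient}")
    bad = set(df["label"]) - set(SAMPLE_SHEET_LABELS)
    if bad:
        raise ValueError(f"sample sheet: unknown label(s) {sorted(bad)}")
    bad = set(df["outcome"]) - set(SAMPLE_SHEET_OUTCOMES)
    if bad:
        raise ValueError(f"sample sheet: unknown outcome(s) {sorted(bad)}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def write_bed(regions: Iterable[tuple[str, int, int]], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    """Write regions given in 1-based inclusive coordinates as BED
    (0-based half-open)."""
    regions = list(regions)
    if names is None:
        names = [f"region_{i + 1}" for i in range(len(regions))]
    with open(path, "w") as fh:
        for (chrom, start, end), name in zip(regions, names):
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


# -- promoter annotation -----------------------------------------------------

def promoter_window(gene: GeneAnnotation, upstream: int = 2000,
                    downstream: int = 500) -> tuple[int, int]:
    """1-based inclusive promoter window around the TSS, strand-aware:
    'upstream' extends against the direction of transcription."""
    if gene.strand == "+":
        return gene.tss - upstream, gene.tss + downstream
    return gene.tss - downstream, gene.tss + upstream


def annotate_promoters(
    sites: Iterable[CpGSite],
    genes: Iterable[GeneAnnotation],
    upstream: int = 2000,
    downstream: int = 500,
) -> dict[str, set[str]]:
    """Map each gene to the set of CpG ids inside its promoter window.

    Windows are inclusive at both endpoints; a CpG may map to several
    genes, and genes without CpGs map to the empty set.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    sites = list(sites)
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    site_df = pd.DataFrame(
        {"id": [s.id for s in sites], "chrom": [s.chrom for s in sites],
         "pos": [s.pos for s in sites]}
    )
    for chrom, sub in site_df.groupby("chrom"):
        by_chrom[str(chrom)] = (sub["pos"].to_numpy(), list(sub["id"]))
    mapping: dict[str, set[str]] = {}
    for gene in genes:
        lo, hi = promoter_window(gene, upstream, downstream)
        pos, ids = by_chrom.get(gene.chrom, (np.array([], dtype=int), []))
        mask = (pos >= lo) & (pos <= hi)
        mapping[gene.gene] = {ids[i] for i in np.flatnonzero(mask)}
    return mapping
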