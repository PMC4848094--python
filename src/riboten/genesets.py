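"""Rank-based gene-set shift tests with optional ORF-length correction.

A gene set (closed-loop association group, RP/MRP set, GO-style category)
is compared against the remaining genes with a one-sided Mann-Whitney U
test on per-gene dTE values. Because many interesting sets are biased
toward short ORFs — and dTE itself depends on ORF length — a corrected
variant first regresses dTE on log10 ORF length over the whole universe
and re-runs the rank test on the residuals, isolating any set shift beyond
what length alone explains. Residual association cannot assign causality;
it is reported as association only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "GeneSet",
    "GeneSetTestResult",
    "ResidualCorrectionResult",
    "load_genesets",
    "mwu_geneset_test",
    "length_corrected_test",
    "geneset_percent_summary",
]

logger = logging.getLogger(__name__)

# exact MWU p-values up to this product of group sizes (tie-free data only)
EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class GeneSet:
    """A named, unique, nonempty collection of gene ids."""

    name: str
    members: frozenset[str]
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_ids(cls, name: str, ids: Iterable[str], category: Optional[str] = None) -> "GeneSet":
        ids = list(ids)
        unique = frozenset(ids)
        if len(unique) < len(ids):
            warnings.warn(f"gene set {name!r}: duplicate members deduplicated")
        return cls(name, unique, category)


@dataclass(frozen=True)
class GeneSetTestResult:
    set_name: str
    n_in: int
    n_out: int
    u: float
    p: float  # one-sided, in the tested direction
    alternative: str
    p_other_side: float
    median_in: float
    median_out: float
    median_shift: float
    exact: bool

    def __post_init__(self) -> None:
        if not 0 <= self.u <= self.n_in * self.n_out:
            raise DataError("U statistic out of range")


def load_genesets(path: str | Path, format: str = "auto") -> list[GeneSet]:
    """Parse gene sets from GMT (name, description, members...) or two-column
    TSV (gene_id, group), autodetected by extension."""
    path = Path(path)
    if format == "auto":
        format = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    sets: list[GeneSet] = []
    if format == "gmt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise DataError(f"{path}:{lineno}: GMT line needs >= 3 fields")
                sets.append(GeneSet.from_ids(fields[0], fields[2:], category=fields[1]))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise DataError(f"{path}: two-column TSV (gene_id, group) expected")
        gene_col, group_col = df.columns[:2]
        for group, sub in df.groupby(group_col, sort=True):
            sets.append(GeneSet.from_ids(str(group), sub[gene_col], category=str(group)))
    else:
        raise DataError(f"unknown gene set format {format!r}")
    return sets


def _one_sided_mwu(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float, bool]:
    """U of x-vs-y plus one-sided p; exact when small and tie-free."""
    if np.ptp(np.concatenate([x, y])) == 0:
        # fully tied data carries no shift information
        return len(x) * len(y) / 2.0, 0.5, False
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact = (len(x) * len(y) <= EXACT_LIMIT) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue), exact


def mwu_geneset_test(
    values: pd.Series,
    gene_set: GeneSet,
    alternative: str = "less",
    complement: Optional[Sequence[str]] = None,
) -> GeneSetTestResult:
    """One-sided Mann-Whitney U test of a gene set's values against the rest.

    ``alternative="less"`` tests whether the set's values are shifted
    downward relative to the complement (the direction for decreased TE).
    The opposite side's p-value is reported alongside for transparency.
    By default the complement is every universe gene outside the set; pass
    ``complement`` to compare against an explicit background (e.g. the
    "other" closed-loop group).
    """
    if alternative not in ("less", "greater"):
        raise DataError("alternative must be 'less' or 'greater'")
    universe = values.index
    in_ids = [g for g in universe if g in gene_set.members]
    if not in_ids:
        missing = sorted(gene_set.members)[:10]
        raise DataError(
            f"gene set {gene_set.name!r} has no member in the universe "
            f"(e.g. {missing})"
        )
    if complement is None:
        out_ids = universe.difference(pd.Index(in_ids))
    else:
        out_ids = pd.Index(complement).intersection(universe).difference(pd.Index(in_ids))
    if len(out_ids) == 0:
        raise DataError(f"gene set {gene_set.name!r}: empty complement")
    x = values.loc[in_ids].to_numpy(float)
    y = values.loc[out_ids].to_numpy(float)
    u, p, exact = _one_sided_mwu(x, y, alternative)
    other = "greater" if alternative == "less" else "less"
    _, p_other, _ = _one_sided_mwu(x, y, other)
    return GeneSetTestResult(
        set_name=gene_set.name,
        n_in=len(x),
        n_out=len(y),
        u=u,
        p=p,
        alternative=alternative,
        p_other_side=p_other,
        median_in=float(np.median(x)),
        median_out=float(np.median(y)),
        median_shift=float(np.median(x) - np.median(y)),
        exact=exact,
    )


@dataclass(frozen=True)
class ResidualCorrectionResult:
    """Length-corrected gene-set tests: the global dTE-vs-length fit and the
    rank test re-run on its residuals."""

    slope: float
    intercept: float
    residuals: pd.Series
    tests: dict[str, GeneSetTestResult]


def length_corrected_test(
    dte_log2: pd.Series,
    orf_length: pd.Series,
    sets: Sequence[GeneSet],
    alternative: str = "less",
    log_length: bool = True,
    complement: Optional[Sequence[str]] = None,
) -> ResidualCorrectionResult:
    """Gene-set rank tests on dTE residuals after regressing out ORF length.

    Fits ordinary least squares of dte_log2 on log10(ORF length) — lengths
    span orders of magnitude, so the log scale is the default; pass
    ``log_length=False`` for raw nt — over the entire universe, then applies
    :func:`mwu_geneset_test` to the residuals for each set.
    """
    common = dte_log2.index.intersection(orf_length.index)
    y = dte_log2[common].to_numpy(float)
    L = orf_length[common].to_numpy(float)
    x = np.log10(L) if log_length else L
    if len(np.unique(x)) < 3:
        raise DataError("length_corrected_test: need >= 3 distinct lengths")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    # snap numerically-zero residuals to exact zero so a perfect linear
    # relationship yields genuinely tied residuals
    scale = np.max(np.abs(y)) or 1.0
    resid[np.abs(resid) < 1e-10 * scale] = 0.0
    residuals = pd.Series(resid, index=common, name="residual")
    tests = {
        s.name: mwu_geneset_test(residuals, s, alternative, complement=complement)
        for s in sets
    }
    return ResidualCorrectionResult(float(slope), float(intercept), residuals, tests)


def geneset_percent_summary(
    dte_percent: pd.Series,
    orf_length: pd.Series,
    sets: Sequence[GeneSet],
    min_size: int = 21,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-set percent-dTE summary for sets with > 20 in-universe members.

    Returns a frame (set, n, median_length, median_pct, mean_pct) ordered by
    median ORF length, and the list of sets skipped for being under
    ``min_size`` members inside the universe.
    """
    universe = dte_percent.index
    rows, skipped = [], []
    for s in sets:
        in_ids = universe.intersection(pd.Index(sorted(s.members)))
        if len(in_ids) < min_size:
            skipped.append(s.name)
            continue
        rows.append(
            {
                "set": s.name,
                "n": len(in_ids),
                "median_length": float(orf_length[in_ids].median()),
                "median_pct": float(dte_percent[in_ids].median()),
                "mean_pct": float(dte_percent[in_ids].mean()),
            }
        )
    if skipped:
        logger.info("geneset_percent_summary: skipped undersized sets: %s", skipped)
    out = pd.DataFrame(rows, columns=["set", "n", "median_length", "median_pct", "mean_pct"])
    return out.sort_values("median_length", kind="mergesort").reset_index(drop=True), skipped
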