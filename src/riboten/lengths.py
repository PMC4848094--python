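"""ORF-length dependence of TE changes.

The central observation this module serves: when initiation-promoting
factors are lost, short-ORF mRNAs lose the most translational efficiency,
so dTE correlates positively with ORF length. Tools here are a binned
length profile (bins of 100 genes sorted by length), rank and partial-rank
correlations against gene attributes, and z-score selection of the most
affected genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "CorrelationResult",
    "binned_profile",
    "correlate_attribute",
    "partial_spearman",
    "select_decreased",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its two-sided p-value and sample size."""

    r: float
    p: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if self.n >= 3 and np.isfinite(self.r) and not -1 <= self.r <= 1 + 1e-12:
            raise DataError(f"correlation out of range: {self.r}")


def binned_profile(
    dte_percent: pd.Series,
    orf_length: pd.Series,
    bin_size: int = 100,
    exclude_ids: Sequence[str] = (),
) -> pd.DataFrame:
    """Mean percent TE change in consecutive bins of genes sorted by ORF length.

    Genes are sorted by length ascending (ties broken by gene_id for
    determinism) and cut into consecutive bins of ``bin_size``; the final
    partial bin is retained. Excluded ids (e.g. the mutated gene itself)
    are removed before binning.

    Returns a frame with columns bin, n, mean_length, mean_pct, sd_pct
    (sample s.d., ddof=1).
    """
    if bin_size < 2:
        raise DataError("binned_profile: bin_size must be >= 2")
    common = dte_percent.index.intersection(orf_length.index).difference(
        pd.Index(exclude_ids)
    )
    df = pd.DataFrame(
        {"dte_percent": dte_percent[common], "orf_length": orf_length[common]}
    )
    # length ties broken by gene_id for determinism
    df = (
        df.assign(_gid=df.index.astype(str))
        .sort_values(["orf_length", "_gid"], kind="mergesort")
        .drop(columns="_gid")
    )
    if len(df) < bin_size:
        warnings.warn("binned_profile: fewer genes than one bin; single-bin profile")
    bins = np.arange(len(df)) // bin_size
    grouped = df.groupby(bins)
    out = pd.DataFrame(
        {
            "n": grouped.size(),
            "mean_length": grouped["orf_length"].mean(),
            "mean_pct": grouped["dte_percent"].mean(),
            "sd_pct": grouped["dte_percent"].std(ddof=1).fillna(0.0),
        }
    )
    out.index.name = "bin"
    return out.reset_index()


def correlate_attribute(
    dte: pd.Series, attribute: pd.Series, method: str = "spearman"
) -> CorrelationResult:
    """Correlate per-gene dTE with a gene/mRNA attribute.

    Pairs with a missing value on either side are dropped. Spearman
    (default, tie-corrected) or Pearson. A constant input yields r = NaN.
    """
    joined = pd.concat([dte, attribute], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise DataError(f"correlate_attribute: need >= 3 paired values, got {n}")
    x, y = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, method)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise DataError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(r), float(p), n, method)


def partial_spearman(
    y: pd.Series, x: pd.Series, control: pd.Series
) -> CorrelationResult:
    """Spearman correlation of y and x after regressing out a control variable.

    Both y and x are residualized by ordinary least squares on the control
    (with intercept) and the residual vectors are rank-correlated. A
    constant control reduces to the ordinary Spearman correlation.
    """
    joined = pd.concat([y, x, control], axis=1, join="inner").dropna()
    if len(joined) < 4:
        raise DataError("partial_spearman: need >= 4 complete triples")
    yv, xv, cv = (joined.iloc[:, i].to_numpy(float) for i in range(3))
    design = np.column_stack([np.ones_like(cv), cv])
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    if np.ptp(ry) == 0 or np.ptp(rx) == 0:
        return CorrelationResult(np.nan, np.nan, len(joined), "partial_spearman")
    r, p = stats.spearmanr(ry, rx)
    return CorrelationResult(float(r), float(p), len(joined), "partial_spearman")


def select_decreased(
    dte_log2: pd.Series, z_threshold: float = -1.0
) -> pd.Index:
    """Genes whose dTE z-score falls at or below the threshold.

    z = (dte_log2 - mean) / sd (sample sd). The default threshold of -1
    selects the most translationally decreased genes. Zero spread yields an
    empty selection with a warning.
    """
    if len(dte_log2) < 2:
        raise DataError("select_decreased: need >= 2 genes")
    sd = dte_log2.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("select_decreased: zero spread; empty selection")
        return dte_log2.index[:0]
    z = (dte_log2 - dte_log2.mean()) / sd
    return dte_log2.index[z <= z_threshold]
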