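"""Library normalization and translational-efficiency tables.

Normalization is median-of-ratios: each library j gets a size factor

    s_j = median_g  k_gj / (prod_j' k_gj')^(1/m)

taken over genes with nonzero counts in every library, and normalized counts
are k_gj / s_j. This removes depth and composition effects without the
transcript-length bias of RPKM.

Translational efficiency (TE) for a gene is normalized footprint density
over normalized total-RNA density; the change between mutant and wild type
is reported both as ``dte_log2 = log2(TE_mut / TE_wt)`` and as
``dte_percent = 100 * (TE_mut / TE_wt - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .counting import CountMatrix, pool_filter_genes
from .errors import DataError

__all__ = [
    "size_factors",
    "MedianOfRatiosNormalizer",
    "apply_pseudocount",
    "compute_te",
    "compute_delta_te",
    "te_analysis",
    "TEResult",
]


def size_factors(
    counts: pd.DataFrame | CountMatrix, gene_subset: Optional[Sequence[str]] = None
) -> pd.Series:
    """Median-of-ratios size factor per library.

    Only genes with nonzero counts in every library (within ``gene_subset``
    if given) contribute to the medians. Raises :class:`DataError` when no
    such gene exists, which is the cue to use pseudocount mode upstream.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if gene_subset is not None:
        df = df.loc[list(gene_subset)]
    arr = df.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise DataError(
            "size_factors: no gene has nonzero counts in every library; "
            "consider pseudocount mode"
        )
    sub = arr[all_nonzero]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    s = np.median(sub / geo, axis=0)
    return pd.Series(s, index=df.columns, name="size_factor")


class MedianOfRatiosNormalizer:
    """Median-of-ratios normalizer with a scikit-learn-style fit/transform API.

    Attributes
    ----------
    size_factors_ : pd.Series
        Per-library size factors, available after :meth:`fit`.
    """

    def __init__(self, gene_subset: Optional[Sequence[str]] = None):
        self.gene_subset = gene_subset

    def get_params(self, deep: bool = True) -> dict:
        return {"gene_subset": self.gene_subset}

    def set_params(self, **params) -> "MedianOfRatiosNormalizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame | CountMatrix, y=None) -> "MedianOfRatiosNormalizer":
        self.size_factors_ = size_factors(X, self.gene_subset)
        return self

    def transform(self, X: pd.DataFrame | CountMatrix) -> pd.DataFrame:
        df = X.counts if isinstance(X, CountMatrix) else X
        if not hasattr(self, "size_factors_"):
            raise DataError("MedianOfRatiosNormalizer: call fit before transform")
        return df / self.size_factors_

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def apply_pseudocount(matrix: CountMatrix) -> tuple[CountMatrix, pd.Series]:
    """Add a pseudocount of one read where >1 read is seen in some but not all libraries.

    For each gene whose maximum count over libraries exceeds 1 while its
    minimum is 0, one read is added to that gene in *every* library. Genes
    with zero counts everywhere are left unchanged and flagged for exclusion.

    Returns the adjusted matrix and a per-gene flag Series with values in
    {"", "pseudocounted", "excluded_all_zero"}.
    """
    df = matrix.counts
    gene_max = df.max(axis=1)
    gene_min = df.min(axis=1)
    pseudo = (gene_max > 1) & (gene_min == 0)
    all_zero = gene_max == 0
    out = df.copy()
    out.loc[pseudo] += 1
    flags = pd.Series("", index=df.index, name="flag")
    flags[pseudo] = "pseudocounted"
    flags[all_zero] = "excluded_all_zero"
    return CountMatrix(out), flags


def _replicate_average(per_rep: pd.DataFrame, policy: str) -> pd.Series:
    if policy == "geometric":
        with np.errstate(divide="ignore"):
            return np.exp(np.log(per_rep).mean(axis=1))
    if policy == "arithmetic":
        return per_rep.mean(axis=1)
    raise DataError(f"unknown replicate_policy {policy!r}")


def compute_te(
    fp: pd.DataFrame,
    total: pd.DataFrame,
    replicate_policy: str = "geometric",
) -> pd.Series:
    """Per-gene TE for one condition from normalized FP and total-RNA counts.

    ``fp`` and ``total`` are genes x replicates frames of *normalized*
    counts with matching replicate order. Per replicate TE = FP / total;
    the condition TE averages replicates geometrically by default (TE is
    analyzed in log space) or arithmetically. Genes where any replicate has
    zero normalized total get TE = NaN (undefined).
    """
    if fp.shape != total.shape:
        raise DataError("compute_te: FP and total frames must have the same shape")
    if not fp.index.equals(total.index):
        raise DataError("compute_te: FP and total gene universes differ")
    fp_arr = fp.to_numpy(dtype=float)
    tot_arr = total.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(tot_arr > 0, fp_arr / np.where(tot_arr > 0, tot_arr, 1.0), np.nan)
    per_rep = pd.DataFrame(ratios, index=fp.index)
    te = _replicate_average(per_rep, replicate_policy)
    te[per_rep.isna().any(axis=1)] = np.nan
    te.name = "te"
    return te


def compute_delta_te(te_wt: pd.Series, te_mut: pd.Series) -> pd.DataFrame:
    """TE-change table over the shared gene universe.

    Genes where either TE is undefined (NaN) or zero are dropped; the
    returned frame carries the drop tally in ``.attrs["n_dropped"]``.
    """
    if not te_wt.index.equals(te_mut.index):
        raise DataError("compute_delta_te: gene universes differ")
    ok = (te_wt > 0) & (te_mut > 0)
    ratio = te_mut[ok] / te_wt[ok]
    table = pd.DataFrame(
        {
            "te_wt": te_wt[ok],
            "te_mut": te_mut[ok],
            "dte_log2": np.log2(ratio),
            "dte_percent": 100.0 * (ratio - 1.0),
        }
    )
    table.attrs["n_dropped"] = int((~ok).sum())
    return table


@dataclass
class TEResult:
    """Output of :func:`te_analysis`.

    table
        Per-gene TE table (te_wt, te_mut, dte_log2, dte_percent).
    size_factors
        Per-library size factors used.
    n_input, n_retained, n_dropped
        Gene tallies through filtering and TE definition.
    pseudocount_flags
        Present only in pseudocount mode.
    """

    table: pd.DataFrame
    size_factors: pd.Series
    n_input: int
    n_retained: int
    n_dropped: int
    pseudocount_flags: Optional[pd.Series] = field(default=None)


def te_analysis(
    matrix: CountMatrix,
    wt: str = "WT",
    mut: str = "mut",
    min_pooled: int = 128,
    pseudocount: bool = False,
    replicate_policy: str = "geometric",
    joint_size_factors: bool = False,
) -> TEResult:
    """Raw counts to TE/dTE table for a mutant-vs-WT comparison.

    Two modes mirror the two analyses this pipeline serves:

    * filtered (default): genes must pool ``min_pooled`` reads over all
      libraries used; no pseudocount.
    * ``pseudocount=True``: no read-count filter; the pseudocount rule of
      :func:`apply_pseudocount` is applied first (used for gene-set tests
      over the whole transcriptome).

    Size factors are computed separately for FP and total-RNA libraries by
    default (the two assays have different count compositions); pass
    ``joint_size_factors=True`` to normalize them together.
    """
    conditions = (wt, mut)
    used_cols = [
        lib.id for lib in matrix.libraries if lib.condition in conditions
    ]
    matrix = CountMatrix(matrix.counts[used_cols])
    n_input = len(matrix.gene_ids)

    flags = None
    if pseudocount:
        matrix, flags = apply_pseudocount(matrix)
        retained = matrix.gene_ids[flags != "excluded_all_zero"]
    else:
        retained = pool_filter_genes(matrix, min_pooled=min_pooled)

    if joint_size_factors:
        sf = size_factors(matrix)
    else:
        sf_fp = size_factors(matrix.select(assay="FP"))
        sf_total = size_factors(matrix.select(assay="total"))
        sf = pd.concat([sf_fp, sf_total])
    norm = matrix.counts.loc[retained] / sf.reindex(matrix.counts.columns)

    def condition_te(cond: str) -> pd.Series:
        fp_cols = sorted(
            lib.id for lib in matrix.libraries if lib.assay == "FP" and lib.condition == cond
        )
        tot_cols = sorted(
            lib.id
            for lib in matrix.libraries
            if lib.assay == "total" and lib.condition == cond
        )
        if len(fp_cols) != len(tot_cols) or not fp_cols:
            raise DataError(
                f"condition {cond!r}: need matching FP and total replicate libraries"
            )
        return compute_te(norm[fp_cols], norm[tot_cols], replicate_policy)

    table = compute_delta_te(condition_te(wt), condition_te(mut))
    if flags is not None:
        table["pseudocounted"] = (flags.reindex(table.index) == "pseudocounted")
    return TEResult(
        table=table,
        size_factors=sf,
        n_input=n_input,
        n_retained=len(retained),
        n_dropped=table.attrs["n_dropped"],
        pseudocount_flags=flags,
    )


def write_te_table(result: TEResult, path) -> None:
    """TE table TSV with size-factor header metadata lines."""
    with open(path, "w") as fh:
        for lib, s in result.size_factors.items():
            fh.write(f"# size_factor lib={lib} value={s:.10g}\n")
        result.table.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.8g")


def read_te_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
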