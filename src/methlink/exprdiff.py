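"""Count normalization and negative-binomial differential expression.

Normalization is DESeq-style median-of-ratios. The per-gene test is a
simplified NB Wald test: group means on the normalized scale, a
method-of-moments dispersion pooled across the two groups (floored at
1e-8), a delta-method standard error for the log2 fold change, and a
Student-t reference with n_a + n_b - 2 degrees of freedom for the Wald
statistic (the t reference, rather than the asymptotic normal, keeps the
test calibrated at the small replicate numbers this design uses).
Benjamini–Hochberg adjustment is applied over all tested genes. No
dispersion shrinkage, no independent filtering, no outlier handling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["size_factors", "test_de", "NBDifferentialExpression", "DEResults"]

_LN2_SQ = np.log(2.0) ** 2
PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample column.

    Genes with any zero count (zero geometric mean) are skipped when
    taking the per-sample median of count/geomean ratios.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(mat)
    all_pos = np.all(mat > 0, axis=1)
    if not all_pos.any():
        raise ValueError(
            "size factors undefined: no gene has all-positive counts")
    log_geomean = logc[all_pos].mean(axis=1)
    log_ratios = logc[all_pos] - log_geomean[:, None]
    s = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


class DEResults:
    """Per-gene differential-expression results for one contrast.

    ``table`` columns: gene_id, baseMean, log2fc, se, stat, p, q, is_deg.
    ``excluded`` lists genes with zero counts in every sample of both
    groups, which are not tested.
    """

    def __init__(self, table: pd.DataFrame, excluded: list[str],
                 contrast: tuple[str, str], fdr_threshold: float):
        self.table = table
        self.excluded = excluded
        self.contrast = contrast
        self.fdr_threshold = fdr_threshold

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["is_deg"]]

    def summary(self) -> str:
        a, b = self.contrast
        n = len(self.table)
        nd = int(self.table["is_deg"].sum())
        up = int((self.table["is_deg"] & (self.table["log2fc"] > 0)).sum())
        lines = [
            "NB Wald differential expression",
            f"  contrast:        {b} vs {a}",
            f"  genes tested:    {n}  (excluded all-zero: {len(self.excluded)})",
            f"  DEGs (q < {self.fdr_threshold:g}): {nd}  "
            f"({up} up, {nd - up} down in {b})",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<DEResults {self.contrast[1]} vs {self.contrast[0]}, n={len(self.table)}>"


class NBDifferentialExpression:
    """NB Wald model over a counts matrix and a sample design table.

    Parameters
    ----------
    counts : genes x samples integer DataFrame.
    design : DataFrame with sample_id and condition columns.
    factors : optional precomputed size factors; estimated by
        median-of-ratios when omitted.
    """

    def __init__(self, counts: pd.DataFrame, design: pd.DataFrame,
                 factors: pd.Series | None = None):
        missing = [s for s in counts.columns if s not in set(design["sample_id"])]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        self.counts = counts
        self.design = design
        self.factors = size_factors(counts) if factors is None else factors

    def _group_columns(self, condition: str) -> list[str]:
        ids = self.design.loc[self.design["condition"] == condition,
                              "sample_id"].tolist()
        cols = [s for s in ids if s in self.counts.columns]
        if not cols:
            raise ValueError(f"contrast condition {condition!r} absent from design")
        if len(cols) < 2:
            raise ValueError(f"condition {condition!r} has < 2 replicates")
        return cols

    def fit(self, contrast: tuple[str, str],
            fdr_threshold: float = 0.05) -> DEResults:
        """Test ``contrast[1]`` versus ``contrast[0]`` (log2fc is b over a)."""
        a, b = contrast
        cols_a, cols_b = self._group_columns(a), self._group_columns(b)
        ya = (self.counts[cols_a] / self.factors[cols_a]).to_numpy(dtype=float)
        yb = (self.counts[cols_b] / self.factors[cols_b]).to_numpy(dtype=float)

        raw_zero = (self.counts[cols_a + cols_b].to_numpy() == 0).all(axis=1)
        keep = ~raw_zero
        excluded = self.counts.index[raw_zero].tolist()
        ya, yb = ya[keep], yb[keep]
        na, nb = ya.shape[1], yb.shape[1]

        ma, mb = ya.mean(axis=1), yb.mean(axis=1)
        va = ya.var(axis=1, ddof=1)
        vb = yb.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            aa = (va - ma) / np.square(ma)
            ab = (vb - mb) / np.square(mb)
        aa = np.where(np.isfinite(aa), aa, 0.0)
        ab = np.where(np.isfinite(ab), ab, 0.0)
        alpha = np.maximum((aa + ab) / 2.0, DISPERSION_FLOOR)

        pc = PSEUDOCOUNT
        log2fc = np.log2(mb + pc) - np.log2(ma + pc)
        # delta-method variance of log2 of a group mean of NB draws
        var_a = (ma + alpha * ma ** 2) / na / (np.square(ma + pc) * _LN2_SQ)
        var_b = (mb + alpha * mb ** 2) / nb / (np.square(mb + pc) * _LN2_SQ)
        se = np.sqrt(var_a + var_b)
        se = np.where(se > 0, se, np.nan)

        with np.errstate(invalid="ignore"):
            stat = np.where(np.isnan(se), 0.0, log2fc / np.where(np.isnan(se), 1.0, se))
        df = na + nb - 2
        p = np.where(np.isnan(se), 1.0, 2.0 * stats.t.sf(np.abs(stat), df))
        p = np.clip(p, 0.0, 1.0)
        q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

        table = pd.DataFrame({
            "gene_id": self.counts.index[keep],
            "baseMean": np.concatenate([ya, yb], axis=1).mean(axis=1),
            "log2fc": log2fc,
            "se": np.where(np.isnan(se), 0.0, se),
            "stat": stat,
            "p": p,
            "q": q,
            "is_deg": q < fdr_threshold,
        }).reset_index(drop=True)
        return DEResults(table, excluded, (a, b), fdr_threshold)


def test_de(counts: pd.DataFrame, design: pd.DataFrame,
            contrast: tuple[str, str], factors: pd.Series | None = None,
            fdr_threshold: float = 0.05) -> DEResults:
    """Functional wrapper: fit the NB Wald model for one contrast."""
    return NBDifferentialExpression(counts, design, factors).fit(
        contrast, fdr_threshold=fdr_threshold)
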