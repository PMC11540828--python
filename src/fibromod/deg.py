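"""Normalization and differential expression with the study's DEG thresholds.

A gene counts as differentially expressed (DEG) when its Benjamini-Hochberg
adjusted p-value is below 0.05 and its absolute log2 fold change is at least
1.  The built-in test is a Welch two-sample t-test on log-CPM values; DEG
tables produced by external tools can be ingested instead via
:func:`read_deg_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

PADJ_CUT = 0.05
LFC_CUT = 1.0

DEG_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj", "is_deg"]


def cpm_log_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization followed by log2(x + 1).

    Each sample (column) is scaled to one million, making the output
    invariant to sequencing depth.  All values must be non-negative and no
    sample may be all-zero.
    """
    values = matrix.to_numpy(float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    colsums = values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        names = [str(matrix.columns[i]) for i in zero]
        raise ValueError(f"all-zero sample column(s): {names}")
    cpm = values / colsums * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=matrix.index, columns=matrix.columns)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorting ascending, ``q_i = min_{j >= i} p_j * m / j`` clipped at 1 —
    the literal step-up arithmetic, so results are bit-identical to the
    textbook definition (library implementations can differ in the last ulp
    through a different association of the same formula).
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


@dataclass(frozen=True)
class Contrast:
    """A treated-vs-control sample split for one differential test."""

    treated: tuple[str, ...]
    control: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.treated) < 2 or len(self.control) < 2:
            raise ValueError("each group needs >= 2 samples")
        overlap = set(self.treated) & set(self.control)
        if overlap:
            raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")


def differential_expression(matrix: pd.DataFrame, contrast: Contrast) -> pd.DataFrame:
    """Per-gene Welch t-test on a (log-scale) expression matrix.

    log2fc is the treated-minus-control mean difference; p-values come from
    the two-sided Welch test with Satterthwaite degrees of freedom.  Genes
    with zero variance in both groups get p = 1 when the means agree and
    p = 0 otherwise.
    """
    missing = [s for s in contrast.treated + contrast.control
               if s not in matrix.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing[:5]}")
    a = matrix.loc[:, list(contrast.treated)].to_numpy(float)
    b = matrix.loc[:, list(contrast.control)].to_numpy(float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, float)
    degenerate = np.isnan(pvals)
    if degenerate.any():
        pvals[degenerate] = np.where(np.isclose(log2fc[degenerate], 0.0), 1.0, 0.0)
    table = pd.DataFrame({
        "gene_id": matrix.index,
        "log2fc": log2fc,
        "pvalue": pvals,
        "padj": bh_adjust(pvals),
    })
    return call_degs(table)


def call_degs(table: pd.DataFrame, padj_cut: float = PADJ_CUT,
              lfc_cut: float = LFC_CUT) -> pd.DataFrame:
    """Flag DEGs: padj strictly below the cut and |log2fc| at or above it."""
    out = table.copy()
    out["is_deg"] = (out["padj"] < padj_cut) & (out["log2fc"].abs() >= lfc_cut)
    return out


def deg_counts(table: pd.DataFrame) -> tuple[int, int]:
    """(up, down) counts among flagged DEGs."""
    deg = table[table["is_deg"]]
    return int((deg["log2fc"] > 0).sum()), int((deg["log2fc"] < 0).sum())


def read_deg_table(path: str | Path, padj_cut: float = PADJ_CUT,
                   lfc_cut: float = LFC_CUT) -> pd.DataFrame:
    """Read a DEG TSV (gene_id, log2fc, pvalue, padj[, is_deg]).

    Externally produced tables may omit ``is_deg``; the flag is (re)computed
    from the thresholds either way so the stated DEG definition always holds.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DEG table {path} missing columns: {sorted(missing)}")
    return call_degs(table, padj_cut=padj_cut, lfc_cut=lfc_cut)


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, DEG_COLUMNS].to_csv(path, sep="\t", index=False)
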