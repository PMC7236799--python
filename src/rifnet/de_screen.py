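"""Differential-expression screen and per-target summary statistics.

For every gene j the screen computes, on the stored log scale:

* ``x_j``   — mean expression across all samples,
* ``x_jS``  — mean across treated (S) samples,
* ``x_jC``  — mean across control (C) samples,
* ``d_j``   — differential expression, ``x_jS - x_jC``,
* ``p_value`` — two-sided Welch t-test probability for the S vs C contrast.

Genes with ``p_value < threshold`` (strict) form the DE target set that
parameterizes both the regulatory impact factors and the phenotypic impact
factor.  p-values are compared raw against the threshold; no multiplicity
correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CONTROL, TREATED, ExpressionStudy

__all__ = ["summarize_targets", "select_de_targets", "EmptyDESetError"]

SUMMARY_COLUMNS = ["gene_id", "x_j", "x_jS", "x_jC", "d_j", "p_value", "degenerate"]


class EmptyDESetError(RuntimeError):
    """No gene passed the DE threshold; RIF is undefined over an empty target set."""


def summarize_targets(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene abundance, differential expression and Welch p-value.

    Returns one row per gene, in the study's gene order, with the columns
    ``gene_id, x_j, x_jS, x_jC, d_j, p_value, degenerate``.  A gene with zero
    variance in *both* conditions is flagged ``degenerate`` and assigned
    ``p_value = 1.0`` rather than raising.  Zero variance in only one
    condition goes through the Welch formula unchanged (the pooled standard
    error stays positive).
    """
    s_mat = study.matrix(TREATED)
    c_mat = study.matrix(CONTROL)

    x_s = s_mat.mean(axis=1)
    x_c = c_mat.mean(axis=1)
    x_all = study.matrix().mean(axis=1)
    d = x_s - x_c

    var_s = s_mat.var(axis=1, ddof=1)
    var_c = c_mat.var(axis=1, ddof=1)
    degenerate = (var_s == 0.0) & (var_c == 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(s_mat, c_mat, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    p[degenerate] = 1.0
    p = np.nan_to_num(p, nan=1.0)

    return pd.DataFrame(
        {
            "gene_id": study.gene_ids,
            "x_j": x_all,
            "x_jS": x_s,
            "x_jC": x_c,
            "d_j": d,
            "p_value": p,
            "degenerate": degenerate,
        }
    )


def select_de_targets(summaries: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """DE target set: exactly the genes with ``p_value < threshold`` (strict).

    Returns the selected rows (original gene order preserved) with an
    ``is_DE`` column added; raises :class:`EmptyDESetError` when nothing
    passes, since every downstream RIF/PIF quantity averages over this set.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold!r}")
    de = summaries.loc[summaries["p_value"] < threshold].copy()
    if de.empty:
        raise EmptyDESetError(
            f"no gene has p < {threshold}; relax the threshold — the regulatory "
            "impact factors are undefined over an empty DE target set"
        )
    de["is_DE"] = True
    return de.reset_index(drop=True)


def annotate_de(summaries: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Full summary table with an ``is_DE`` flag (for export)."""
    out = summaries.copy()
    out["is_DE"] = out["p_value"] < threshold
    return out
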