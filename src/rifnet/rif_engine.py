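"""Regulatory impact factors: condition-wise co-expression, differential
co-expression, RIF1/RIF2, and the ranked regulator table.

For a candidate regulator r and the set of nDE differentially expressed
targets j, with r_rjS and r_rjC the regulator-target correlation computed
within the treated (S) and control (C) samples and DC_rj = r_rjS - r_rjC:

    RIF1_r = (1/nDE) * sum_j  x_j * d_j * DC_rj^2
    RIF2_r = (1/nDE) * sum_j [(x_jS * r_rjS)^2 - (x_jC * r_rjC)^2]

RIF1 rewards regulators that are consistently differentially co-expressed
with the abundant, strongly shifted targets; RIF2 rewards regulators whose
ability to predict target abundance changes most between conditions.  Raw
scores are z-standardized across the regulator universe and combined as
|z1| + |z2| (configurable to the half average), which is the score the
regulator ranking is sorted on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CONTROL, TREATED, ExpressionStudy, ValidationError

__all__ = [
    "condition_correlations",
    "coexpression_links",
    "rif1",
    "rif2",
    "score_regulators",
    "export_rif_scatter",
    "export_ma_plot",
]


def _row_standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows to zero mean / unit norm; zero-variance rows become all-zero.

    Returns (standardized matrix, boolean mask of zero-variance rows).
    """
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    flat = norms[:, 0] == 0.0
    norms[flat] = 1.0
    return centered / norms, flat


def condition_correlations(
    study: ExpressionStudy,
    regulator_ids: list[str],
    target_ids: list[str],
    *,
    method: str = "pearson",
) -> dict[str, np.ndarray]:
    """Regulator-by-target correlation matrices for each condition.

    Returns a dict with ``r_S`` and ``r_C`` (each shape
    ``(n_regulators, n_targets)``), and ``flagged`` marking pairs where one
    side had zero variance within a condition; that side's correlation is
    defined as 0 and the regulator retained, so the standardization
    population is unchanged.  A regulator that is itself a target carries a
    self-link fixed at r = 1 on both sides (DC = 0).
    """
    missing = [g for g in set(regulator_ids) | set(target_ids) if g not in study.values.index]
    if missing:
        raise ValidationError(f"genes absent from study: {sorted(missing)[:5]}")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")

    out: dict[str, np.ndarray] = {}
    flagged = np.zeros((len(regulator_ids), len(target_ids)), dtype=bool)
    for role, key in ((TREATED, "r_S"), (CONTROL, "r_C")):
        cols = study.samples(role)
        reg = study.values.loc[regulator_ids, cols].to_numpy(dtype=float)
        tgt = study.values.loc[target_ids, cols].to_numpy(dtype=float)
        if method == "spearman":
            reg = stats.rankdata(reg, axis=1)
            tgt = stats.rankdata(tgt, axis=1)
        zr, reg_flat = _row_standardize(reg)
        zt, tgt_flat = _row_standardize(tgt)
        r = np.clip(zr @ zt.T, -1.0, 1.0)
        flagged |= reg_flat[:, None] | tgt_flat[None, :]
        out[key] = r

    # self-links: exact r = 1 both sides regardless of floating-point noise
    tgt_pos = {g: j for j, g in enumerate(target_ids)}
    for i, g in enumerate(regulator_ids):
        j = tgt_pos.get(g)
        if j is not None:
            out["r_S"][i, j] = 1.0
            out["r_C"][i, j] = 1.0
            flagged[i, j] = False
    out["flagged"] = flagged
    return out


def _differential_coexpression(r_s: np.ndarray, r_c: np.ndarray, fisher_z: bool) -> np.ndarray:
    if not fisher_z:
        return r_s - r_c
    clip = 1.0 - 1e-7
    return np.arctanh(np.clip(r_s, -clip, clip)) - np.arctanh(np.clip(r_c, -clip, clip))


def coexpression_links(
    study: ExpressionStudy,
    regulators: list[str],
    de_targets: pd.DataFrame,
    *,
    method: str = "pearson",
    fisher_z: bool = False,
) -> pd.DataFrame:
    """Tidy table of per-pair co-expression links.

    One row per (regulator, target) pair with columns ``regulator_id,
    target_id, r_S, r_C, dc, flagged`` where ``dc = r_S - r_C`` (or the
    Fisher-z difference when requested).
    """
    target_ids = de_targets["gene_id"].tolist()
    corr = condition_correlations(study, regulators, target_ids, method=method)
    dc = _differential_coexpression(corr["r_S"], corr["r_C"], fisher_z)
    n_r, n_t = len(regulators), len(target_ids)
    return pd.DataFrame(
        {
            "regulator_id": np.repeat(regulators, n_t),
            "target_id": np.tile(target_ids, n_r),
            "r_S": corr["r_S"].ravel(),
            "r_C": corr["r_C"].ravel(),
            "dc": dc.ravel(),
            "flagged": corr["flagged"].ravel(),
        }
    )


def _aligned_links(de_targets: pd.DataFrame, links: pd.DataFrame) -> pd.DataFrame:
    """Validate that links cover every DE target exactly once; align by target."""
    counts = links["target_id"].value_counts()
    wanted = de_targets["gene_id"]
    missing = [g for g in wanted if counts.get(g, 0) == 0]
    if missing:
        raise ValidationError(f"missing link for DE targets: {missing[:5]}")
    dup = [g for g in wanted if counts.get(g, 0) > 1]
    if dup:
        raise ValidationError(f"multiple links for DE targets: {dup[:5]}")
    merged = de_targets.merge(links, left_on="gene_id", right_on="target_id", how="left")
    return merged


def rif1(de_targets: pd.DataFrame, links: pd.DataFrame) -> float:
    """RIF1 for one regulator: mean over DE targets of x_j * d_j * DC_rj^2."""
    m = _aligned_links(de_targets, links)
    return float(np.mean(m["x_j"] * m["d_j"] * m["dc"] ** 2))


def rif2(de_targets: pd.DataFrame, links: pd.DataFrame) -> float:
    """RIF2 for one regulator: mean over DE targets of (x_jS r_S)^2 - (x_jC r_C)^2."""
    m = _aligned_links(de_targets, links)
    return float(np.mean((m["x_jS"] * m["r_S"]) ** 2 - (m["x_jC"] * m["r_C"]) ** 2))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise ValidationError("raw RIF scores are constant across the regulator universe; "
                              "standardization is undefined")
    return (v - v.mean()) / sd


def score_regulators(
    study: ExpressionStudy,
    regulators: list[str],
    de_targets: pd.DataFrame,
    *,
    method: str = "pearson",
    fisher_z: bool = False,
    combine: str = "sum_abs",
) -> pd.DataFrame:
    """Score and rank every regulator in the universe.

    Returns a DataFrame sorted by descending combined score with columns
    ``regulator_id, rif1_raw, rif2_raw, rif1_z, rif2_z, combined, rank``.
    Ranking uses a stable sort with a lexical ``regulator_id`` tie-break so
    output is deterministic.
    """
    if len(regulators) < 2:
        raise ValidationError("need >= 2 regulators to standardize RIF scores")
    if len(set(regulators)) != len(regulators):
        raise ValidationError("regulator list contains duplicates")
    target_ids = de_targets["gene_id"].tolist()
    corr = condition_correlations(study, regulators, target_ids, method=method)
    r_s, r_c = corr["r_S"], corr["r_C"]
    dc = _differential_coexpression(r_s, r_c, fisher_z)

    x = de_targets["x_j"].to_numpy(dtype=float)
    d = de_targets["d_j"].to_numpy(dtype=float)
    x_s = de_targets["x_jS"].to_numpy(dtype=float)
    x_c = de_targets["x_jC"].to_numpy(dtype=float)

    rif1_raw = (dc**2) @ (x * d) / len(target_ids)
    rif2_raw = ((r_s * x_s) ** 2 - (r_c * x_c) ** 2).mean(axis=1)

    z1 = _zscore(rif1_raw)
    z2 = _zscore(rif2_raw)
    combined = np.abs(z1) + np.abs(z2)
    if combine == "mean_abs":
        combined = combined / 2.0
    elif combine != "sum_abs":
        raise ValidationError(f"unknown combine rule {combine!r}")

    scores = pd.DataFrame(
        {
            "regulator_id": regulators,
            "rif1_raw": rif1_raw,
            "rif2_raw": rif2_raw,
            "rif1_z": z1,
            "rif2_z": z2,
            "combined": combined,
        }
    )
    scores = scores.sort_values(
        ["combined", "regulator_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    scores["rank"] = np.arange(1, len(scores) + 1)
    return scores


def export_rif_scatter(scores: pd.DataFrame) -> pd.DataFrame:
    """Plot-data projection for the RIF1-vs-RIF2 scatter: (rif1_z, rif2_z, label)."""
    if scores.empty:
        return pd.DataFrame(columns=["rif1_z", "rif2_z", "label"])
    return pd.DataFrame(
        {
            "rif1_z": scores["rif1_z"].to_numpy(),
            "rif2_z": scores["rif2_z"].to_numpy(),
            "label": scores["regulator_id"].to_numpy(),
        }
    )


def export_ma_plot(summaries: pd.DataFrame) -> pd.DataFrame:
    """Plot-data projection for the MA / rocket plot: (x_j, d_j, is_DE)."""
    cols = ["gene_id", "x_j", "d_j"]
    if summaries.empty:
        return pd.DataFrame(columns=cols + ["is_DE"])
    out = summaries[cols].copy()
    out["is_DE"] = summaries["is_DE"] if "is_DE" in summaries else False
    return out
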