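"""Hypergeometric enrichment of gene sets in the extremes of a ranked list.

Given a ranked gene list of length N and a gene set with B members in that
universe, the scan walks prefix cutoffs n = step, 2*step, ..., N/2, counts
the b set members inside each prefix, computes the hypergeometric upper
tail P(X >= b | N, B, n), and reports the minimum over cutoffs together
with the cutoff where it was attained.  ``direction="tail"`` scans the
other end of the list by reversing it first.  Benjamini-Hochberg correction
is applied across sets (not across cutoffs).

Caveat: the minimum over cutoffs is an optimisation over many correlated
tests, so the reported ``p_min`` is anti-conservative (a random set attains
p_min < 0.05 far more often than 5% of the time).  For calibrated inference
use the optional seeded permutation p-value (``n_permutations > 0``), which
compares the observed minimum with minima for random sets of the same size.
The exact minimum-hypergeometric (mHG) correction used by tools such as
GOrilla is deliberately not reimplemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSet", "read_gmt", "ranked_enrichment"]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; members are unique and the set is nonempty."""

    set_id: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.set_id!r} has duplicate members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated id, description, members."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 tab-separated fields")
        members = tuple(dict.fromkeys(m for m in fields[2:] if m))
        sets.append(GeneSet(fields[0], members, fields[1]))
    return sets


def _min_tail_p(hits: np.ndarray, n_universe: int, n_set: int, cutoffs: np.ndarray):
    """Minimum upper-tail hypergeometric p over the given prefix cutoffs.

    ``hits`` is the 0/1 membership indicator in rank order.
    """
    b_at = np.cumsum(hits)[cutoffs - 1]
    p_at = stats.hypergeom.sf(b_at - 1, n_universe, n_set, cutoffs)
    i = int(np.argmin(p_at))
    return float(p_at[i]), int(cutoffs[i]), int(b_at[i])


def ranked_enrichment(
    ranked_ids: list[str],
    sets: list[GeneSet],
    *,
    direction: str = "head",
    step: int | None = None,
    n_permutations: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Scan ranked-list prefixes for enrichment of each gene set.

    Returns one row per set with columns ``set_id, best_cutoff, b, B, N,
    p_min, q`` (plus ``p_empirical`` when permutations are requested) where
    ``b`` is the number of set members inside the best prefix, ``B`` the set
    size after intersection with the universe and ``N`` the universe size.
    Sets with an empty intersection are reported with ``p_min = 1`` and
    flagged rather than dropped.
    """
    if direction not in ("head", "tail"):
        raise ValueError(f"direction must be 'head' or 'tail', got {direction!r}")
    if len(ranked_ids) == 0:
        raise ValueError("ranked list is empty")
    if len(set(ranked_ids)) != len(ranked_ids):
        raise ValueError("ranked list contains duplicate ids")

    ids = list(reversed(ranked_ids)) if direction == "tail" else list(ranked_ids)
    n = len(ids)
    pos = {g: i for i, g in enumerate(ids)}
    if step is None:
        step = max(1, n // 100)
    cutoffs = np.arange(step, n // 2 + 1, step, dtype=int)
    if cutoffs.size == 0:
        cutoffs = np.array([max(1, n // 2)], dtype=int)

    rng = np.random.default_rng(seed) if n_permutations > 0 else None

    rows = []
    for gs in sets:
        inside = sorted({m for m in gs.members if m in pos})
        B = len(inside)
        if B == 0:
            rows.append(
                dict(set_id=gs.set_id, best_cutoff=0, b=0, B=0, N=n, p_min=1.0,
                     empty_overlap=True, p_empirical=np.nan)
            )
            continue
        hits = np.zeros(n, dtype=np.int64)
        hits[[pos[m] for m in inside]] = 1
        p_min, best_cutoff, b = _min_tail_p(hits, n, B, cutoffs)
        row = dict(set_id=gs.set_id, best_cutoff=best_cutoff, b=b, B=B, N=n,
                   p_min=p_min, empty_overlap=False, p_empirical=np.nan)
        if rng is not None:
            null_min = np.empty(n_permutations)
            perm_hits = np.zeros(n, dtype=np.int64)
            for k in range(n_permutations):
                perm_hits[:] = 0
                perm_hits[rng.choice(n, size=B, replace=False)] = 1
                null_min[k], _, _ = _min_tail_p(perm_hits, n, B, cutoffs)
            row["p_empirical"] = float((1 + np.sum(null_min <= p_min)) / (1 + n_permutations))
        rows.append(row)

    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p_min"].to_numpy(), method="fdr_bh")[1]
    if n_permutations == 0:
        out = out.drop(columns=["p_empirical"])
    cols = ["set_id", "best_cutoff", "b", "B", "N", "p_min", "q", "empty_overlap"]
    if n_permutations > 0:
        cols.append("p_empirical")
    return out[cols]
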