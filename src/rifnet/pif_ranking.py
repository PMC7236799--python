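"""Target ranking around a focal regulator: PIF times absolute differential
co-expression.

Each DE target j gets a phenotypic impact factor PIF_j = x_j * d_j (the
product of its average abundance and its differential expression) and a
signed link score

    product_j = PIF_j * |DC_rj|

to the focal regulator r.  Because the differential co-expression enters in
absolute value, the sign of the product follows the direction of DE:
positive means higher expression in the treated (S) condition, negative
means higher in the control (C) condition.  The list is sorted ascending so
the extreme negative products head one end and the extreme positives the
other — the two tails that downstream enrichment interrogates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import ValidationError

__all__ = ["pif_rank_targets"]


def pif_rank_targets(
    focal_regulator: str,
    de_targets: pd.DataFrame,
    links: pd.DataFrame,
    *,
    pif_variant: str = "overall_mean",
) -> pd.DataFrame:
    """Rank DE targets by the signed PIF x |DC| product to ``focal_regulator``.

    ``links`` is the tidy link table from
    :func:`rifnet.rif_engine.coexpression_links`; it must contain one link
    from the focal regulator to every DE target.  ``pif_variant`` selects the
    abundance term: ``"overall_mean"`` uses x_j (mean over all samples);
    ``"half_sum"`` uses (x_jS + x_jC) / 2.

    Returns columns ``target_id, pif_j, abs_dc, product, rank`` sorted
    ascending by product with a deterministic ``target_id`` tie-break.
    """
    mine = links.loc[links["regulator_id"] == focal_regulator]
    if mine.empty:
        raise ValidationError(f"focal regulator {focal_regulator!r} absent from link set")
    merged = de_targets.merge(
        mine[["target_id", "dc"]], left_on="gene_id", right_on="target_id", how="left"
    )
    if merged["dc"].isna().any():
        missing = merged.loc[merged["dc"].isna(), "gene_id"].tolist()
        raise ValidationError(
            f"focal regulator {focal_regulator!r} lacks links to DE targets: {missing[:5]}"
        )

    if pif_variant == "overall_mean":
        abundance = merged["x_j"].to_numpy(dtype=float)
    elif pif_variant == "half_sum":
        abundance = (merged["x_jS"].to_numpy(dtype=float) + merged["x_jC"].to_numpy(dtype=float)) / 2.0
    else:
        raise ValidationError(f"unknown pif_variant {pif_variant!r}")

    pif = abundance * merged["d_j"].to_numpy(dtype=float)
    abs_dc = np.abs(merged["dc"].to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "target_id": merged["gene_id"].to_numpy(),
            "pif_j": pif,
            "abs_dc": abs_dc,
            "product": pif * abs_dc,
        }
    )
    out = out.sort_values(["product", "target_id"], kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
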