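"""Data model and tabular I/O for two-condition expression studies.

An :class:`ExpressionStudy` holds a gene-by-sample matrix of normalized,
log-scale expression values together with an assignment of each sample to
one of two condition roles: treated (``"S"``) or control (``"C"``).  All
downstream statistics (differential expression, differential co-expression,
RIF, PIF) consume this container.

The loader performs no transformation of the values: they are assumed to be
already normalized and on a log scale.  Preprocessing (background
correction, normalization, probe annotation) is out of scope.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TREATED",
    "CONTROL",
    "ExpressionStudy",
    "StudyConfig",
    "StudyFormatError",
    "ReconciliationError",
    "ValidationError",
    "read_expression_study",
    "write_expression_study",
    "read_result_table",
    "write_result_table",
]

logger = logging.getLogger(__name__)

#: Canonical condition role labels: treated and control.
TREATED = "S"
CONTROL = "C"


class StudyFormatError(ValueError):
    """A file violates the expected tabular format (duplicates, non-numeric cells)."""


class ReconciliationError(ValueError):
    """Sample IDs in the matrix and the condition table cannot be reconciled."""


class ValidationError(ValueError):
    """A study or configuration violates its invariants."""


@dataclass(frozen=True)
class StudyConfig:
    """Analysis-wide settings shared by the pipeline stages.

    Parameters
    ----------
    de_pvalue_threshold:
        Strict upper bound on the per-gene p-value for a gene to enter the
        differentially expressed (DE) target set.
    correlation_method:
        ``"pearson"`` (default) or ``"spearman"``; used for all condition-wise
        co-expression calculations.
    min_samples_per_condition:
        Correlation is undefined below 3 samples; studies with fewer are rejected.
    combine:
        How standardized RIF1/RIF2 are folded into one score: ``"sum_abs"``
        (|z1| + |z2|, default) or ``"mean_abs"`` ((|z1| + |z2|) / 2).
    fisher_z:
        If True, differential co-expression is the difference of Fisher
        z-transformed correlations instead of the raw correlation difference.
    pif_variant:
        ``"overall_mean"``: PIF_j = x_j * d_j with x_j the mean over all samples
        (default); ``"half_sum"``: x replaced by (x_jS + x_jC) / 2.
    seed:
        Seed for any stochastic step (permutation p-values, simulation).
    """

    de_pvalue_threshold: float = 0.001
    correlation_method: str = "pearson"
    min_samples_per_condition: int = 3
    combine: str = "sum_abs"
    fisher_z: bool = False
    pif_variant: str = "overall_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.de_pvalue_threshold < 1.0 or not np.isfinite(self.de_pvalue_threshold):
            raise ValidationError(
                f"de_pvalue_threshold must lie in (0, 1), got {self.de_pvalue_threshold!r}"
            )
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValidationError(f"unknown correlation_method {self.correlation_method!r}")
        if self.min_samples_per_condition < 3:
            raise ValidationError("min_samples_per_condition must be >= 3")
        if self.combine not in ("sum_abs", "mean_abs"):
            raise ValidationError(f"unknown combine rule {self.combine!r}")
        if self.pif_variant not in ("overall_mean", "half_sum"):
            raise ValidationError(f"unknown pif_variant {self.pif_variant!r}")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ExpressionStudy:
    """A validated two-condition expression study.

    Attributes
    ----------
    values:
        Gene-by-sample DataFrame (index: gene IDs, columns: sample IDs) of
        log-scale expression.
    condition_of:
        Mapping from sample ID to condition role, ``"S"`` (treated) or
        ``"C"`` (control).
    """

    values: pd.DataFrame
    condition_of: dict[str, str] = field(default_factory=dict)
    min_samples_per_condition: int = 3

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if len(idx) == 0:
            raise ValidationError("study has no genes")
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise StudyFormatError(f"duplicate gene IDs: {dups}")
        cols = self.values.columns
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise StudyFormatError(f"duplicate sample IDs: {dups}")

        matrix_samples = set(map(str, cols))
        table_samples = set(self.condition_of)
        if matrix_samples != table_samples:
            only_matrix = sorted(matrix_samples - table_samples)
            only_table = sorted(table_samples - matrix_samples)
            raise ReconciliationError(
                "sample IDs do not reconcile between matrix and condition table: "
                f"only in matrix {only_matrix}, only in condition table {only_table}"
            )
        bad_roles = {s: c for s, c in self.condition_of.items() if c not in (TREATED, CONTROL)}
        if bad_roles:
            raise ValidationError(f"condition roles must be 'S' or 'C', got {bad_roles}")
        for role in (TREATED, CONTROL):
            n = sum(1 for c in self.condition_of.values() if c == role)
            if n < self.min_samples_per_condition:
                raise ValidationError(
                    f"condition {role!r} has {n} samples; "
                    f"need >= {self.min_samples_per_condition} for correlation"
                )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise StudyFormatError("expression matrix contains non-numeric values")
        if np.isnan(arr).any():
            rows, cols_ = np.nonzero(np.isnan(arr))
            first = (self.values.index[rows[0]], self.values.columns[cols_[0]])
            raise ValidationError(
                f"missing values in expression matrix (first at gene {first[0]!r}, "
                f"sample {first[1]!r}); reject or drop genes explicitly at load time"
            )

    # -- accessors ----------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def samples(self, role: str) -> list[str]:
        """Sample IDs assigned to condition role ``"S"`` or ``"C"``, in matrix order."""
        return [s for s in self.sample_ids if self.condition_of[s] == role]

    def n_samples(self, role: str) -> int:
        return len(self.samples(role))

    def matrix(self, role: str | None = None) -> np.ndarray:
        """Expression values as ndarray; optionally restricted to one condition."""
        if role is None:
            return self.values.to_numpy(dtype=float)
        return self.values[self.samples(role)].to_numpy(dtype=float)

    def swap_conditions(self) -> "ExpressionStudy":
        """Return a copy with the treated/control role assignment exchanged."""
        flipped = {s: (CONTROL if c == TREATED else TREATED) for s, c in self.condition_of.items()}
        return ExpressionStudy(
            self.values.copy(), flipped, min_samples_per_condition=self.min_samples_per_condition
        )


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def _resolve_roles(
    labels: set[str], treated_label: str | None, control_label: str | None
) -> dict[str, str]:
    """Map the condition table's free-string labels onto the S/C roles."""
    if len(labels) != 2:
        raise ValidationError(f"expected exactly two condition labels, got {sorted(labels)}")
    if treated_label is not None or control_label is not None:
        if treated_label is None or control_label is None:
            raise ValidationError("treated_label and control_label must be given together")
        if {treated_label, control_label} != labels:
            raise ValidationError(
                f"configured labels {{{treated_label!r}, {control_label!r}}} do not match "
                f"the condition table's labels {sorted(labels)}"
            )
        return {treated_label: TREATED, control_label: CONTROL}
    # Default: lexically first label is control, second is treated, so that the
    # literal labels "C"/"S" land on their conventional roles.
    lo, hi = sorted(labels)
    if (lo, hi) != (CONTROL, TREATED):
        logger.warning(
            "no treated/control mapping given; defaulting %r -> control, %r -> treated",
            lo,
            hi,
        )
    return {hi: TREATED, lo: CONTROL}


def read_expression_study(
    matrix_path: str | Path,
    conditions_path: str | Path,
    *,
    treated_label: str | None = None,
    control_label: str | None = None,
    sep: str | None = None,
    missing: str = "reject",
    min_samples_per_condition: int = 3,
) -> ExpressionStudy:
    """Load and validate a study from a delimited matrix and a condition table.

    The matrix file holds gene IDs in the first column and sample IDs in the
    header row; the condition table has columns ``sample_id`` and
    ``condition``.  Samples are reconciled by ID, never by position.

    ``missing="reject"`` (default) raises on any missing value;
    ``missing="drop_genes"`` removes genes with any missing value and logs
    how many were dropped.
    """
    matrix_path = Path(matrix_path)
    conditions_path = Path(conditions_path)
    if missing not in ("reject", "drop_genes"):
        raise ValidationError(f"unknown missing-value policy {missing!r}")

    raw = pd.read_csv(
        matrix_path, sep=_sep_for(matrix_path, sep), index_col=0, comment="#", dtype=str
    )
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique().tolist())
        raise StudyFormatError(f"duplicate gene IDs in {matrix_path.name}: {dups}")

    values = raw.apply(pd.to_numeric, errors="coerce")
    # Cells that were text but failed numeric conversion are parse errors;
    # cells that were empty in the file are missing values (policy-controlled).
    was_text = raw.notna()
    bad = values.isna() & was_text
    if bad.to_numpy().any():
        r, c = np.nonzero(bad.to_numpy())
        coords = [
            f"(gene {values.index[i]!r}, sample {values.columns[j]!r})"
            for i, j in zip(r[:5], c[:5])
        ]
        raise StudyFormatError(f"non-numeric cells in {matrix_path.name} at {', '.join(coords)}")
    if values.isna().to_numpy().any():
        if missing == "reject":
            r, c = np.nonzero(values.isna().to_numpy())
            raise ValidationError(
                f"missing values in {matrix_path.name} (first at gene "
                f"{values.index[r[0]]!r}, sample {values.columns[c[0]]!r}); "
                "pass missing='drop_genes' to remove affected genes"
            )
        keep = ~values.isna().any(axis=1)
        logger.warning("dropping %d genes with missing values", int((~keep).sum()))
        values = values.loc[keep]

    cond = pd.read_csv(
        conditions_path, sep=_sep_for(conditions_path, sep), comment="#", dtype=str
    )
    if not {"sample_id", "condition"}.issubset(cond.columns):
        raise StudyFormatError(
            f"{conditions_path.name} must have columns 'sample_id' and 'condition'"
        )
    if cond["sample_id"].duplicated().any():
        dups = sorted(cond.loc[cond["sample_id"].duplicated(), "sample_id"].tolist())
        raise StudyFormatError(f"duplicate sample IDs in {conditions_path.name}: {dups}")

    matrix_samples = set(values.columns)
    table_samples = set(cond["sample_id"])
    if matrix_samples != table_samples:
        only_matrix = sorted(matrix_samples - table_samples)
        only_table = sorted(table_samples - matrix_samples)
        raise ReconciliationError(
            f"sample IDs do not reconcile: only in matrix {only_matrix}, "
            f"only in condition table {only_table}"
        )

    role_of_label = _resolve_roles(set(cond["condition"]), treated_label, control_label)
    condition_of = {
        row.sample_id: role_of_label[row.condition] for row in cond.itertuples(index=False)
    }
    return ExpressionStudy(
        values.astype(float),
        condition_of,
        min_samples_per_condition=min_samples_per_condition,
    )


def write_expression_study(
    study: ExpressionStudy,
    matrix_path: str | Path,
    conditions_path: str | Path,
    *,
    sep: str = "\t",
) -> None:
    """Write a study back to the matrix + condition-table pair it was read from.

    Gene and sample order are preserved; the files round-trip through
    :func:`read_expression_study` to within float formatting precision.
    """
    study.validate()
    matrix_path = Path(matrix_path)
    conditions_path = Path(conditions_path)
    out = study.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep=sep, float_format="%.10g")
    cond = pd.DataFrame(
        {"sample_id": study.sample_ids, "condition": [study.condition_of[s] for s in study.sample_ids]}
    )
    cond.to_csv(conditions_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# result tables (downstream TSV outputs with a provenance comment line)


def write_result_table(
    df: pd.DataFrame, path: str | Path, *, meta: Mapping[str, object] | None = None
) -> None:
    """Write a result table as TSV with a leading ``#`` provenance comment."""
    from . import __version__

    path = Path(path)
    parts = [f"rifnet v{__version__}"]
    for k, v in (meta or {}).items():
        parts.append(f"{k}={v}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + " ".join(parts) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
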