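"""Attractor-versus-expression comparison and the differential filter.

Model attractors and measured expression profiles are compared the same
way: a factor x condition table (conditions LMPP and proB) is normalized
per factor by its maximum across conditions, so each factor reaches 1 in
exactly one condition, and the cross-condition *direction* (up in LMPP, up
in proB, or flat) is compared between model and data.  Factors whose
normalized difference is below a flatness tolerance are excluded from the
concordance denominator -- only factors whose expression varies by a
meaningful amount are scored.

A generic differential-expression filter is also provided: keep rows with
|linear fold change| >= 2 and p < 0.05, partitioned into up- and
down-regulated sets by the sign of the fold change.  p-values are inputs
here; no microarray preprocessing is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ModelInputError, get_model
from .dynamics import Equilibrium

__all__ = [
    "ConcordanceResult",
    "attractors_to_table",
    "normalize_max",
    "concordance",
    "de_filter",
    "read_expression_table",
    "write_expression_table",
]

#: normalized |difference| below which a factor counts as flat
FLAT_TOL = 0.1

CONDITIONS = ("LMPP", "proB")


def _check_table(table: pd.DataFrame, name: str = "table") -> pd.DataFrame:
    if not isinstance(table, pd.DataFrame):
        raise ModelInputError(f"{name} must be a pandas DataFrame")
    if table.columns.duplicated().any() or table.index.duplicated().any():
        raise ModelInputError(f"{name} has duplicate factors or conditions")
    if (table.values < 0).any():
        raise ModelInputError(f"{name} contains negative expression values")
    return table.astype(float)


def attractors_to_table(model, labelled: dict[str, np.ndarray]) -> pd.DataFrame:
    """Build a factor x condition table from labelled attractors.

    ``labelled`` maps condition names (e.g. from
    :func:`bswitch.screening.label_attractors`) to state vectors.
    """
    spec = get_model(model)
    cols = {}
    for name, state in labelled.items():
        cols[name] = pd.Series(np.asarray(state, float), index=spec.states)
    return pd.DataFrame(cols)


def normalize_max(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each factor (row) by its maximum across conditions.

    Every row then lies in [0, 1] with value 1 in its higher condition.
    All-zero rows are left unchanged, with a warning.
    """
    table = _check_table(table)
    row_max = table.max(axis=1)
    zero = row_max == 0
    if zero.any():
        warnings.warn(
            f"all-zero factor(s) left unnormalized: "
            f"{', '.join(map(str, table.index[zero]))}",
            stacklevel=2,
        )
    safe = row_max.replace(0, 1.0)
    return table.div(safe, axis=0)


@dataclass
class ConcordanceResult:
    """Per-factor direction agreement between model attractors and data."""

    per_factor: pd.DataFrame
    fraction: float
    n_scored: int
    n_matched: int


def _directions(norm: pd.DataFrame, cond_a: str, cond_b: str,
                flat_tol: float) -> pd.Series:
    diff = norm[cond_a] - norm[cond_b]
    out = pd.Series("flat", index=norm.index, dtype=object)
    out[diff > flat_tol] = f"up_{cond_a}"
    out[diff < -flat_tol] = f"up_{cond_b}"
    return out


def concordance(
    model_table: pd.DataFrame,
    data_table: pd.DataFrame,
    factor_map: dict[str, str] | None = None,
    flat_tol: float = FLAT_TOL,
    conditions=CONDITIONS,
) -> ConcordanceResult:
    """Fraction of shared factors whose cross-condition direction agrees.

    ``factor_map`` translates data-table row names to model state names.
    Factors called flat in *both* tables are excluded from the denominator;
    a factor flat in exactly one table counts as a mismatch.
    """
    cond_a, cond_b = conditions
    data = data_table.rename(index=factor_map or {})
    shared = [f for f in model_table.index if f in data.index]
    if not shared:
        raise ModelInputError("no shared factors between model and data tables")
    for t, nm in ((model_table, "model table"), (data, "data table")):
        missing = [c for c in conditions if c not in t.columns]
        if missing:
            raise ModelInputError(f"{nm} lacks condition column(s): {missing}")

    m_dir = _directions(normalize_max(model_table.loc[shared, list(conditions)]),
                        cond_a, cond_b, flat_tol)
    d_dir = _directions(normalize_max(data.loc[shared, list(conditions)]),
                        cond_a, cond_b, flat_tol)
    per = pd.DataFrame({"model": m_dir, "data": d_dir})
    per["scored"] = ~((per["model"] == "flat") & (per["data"] == "flat"))
    per["match"] = (per["model"] == per["data"]) & per["scored"]
    n_scored = int(per["scored"].sum())
    n_matched = int(per["match"].sum())
    frac = n_matched / n_scored if n_scored else float("nan")
    return ConcordanceResult(per, frac, n_scored, n_matched)


def de_filter(
    table: pd.DataFrame,
    fold_col: str = "fold_change_linear",
    p_col: str = "p_value",
    fold_cutoff: float = 2.0,
    p_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, int, int]:
    """Keep rows with |linear fold change| >= cutoff and p below cutoff.

    Returns ``(filtered_table, n_up, n_down)`` where the partition follows
    the sign of the fold change (positive = up in the first condition).
    """
    for col in (fold_col, p_col):
        if col not in table.columns:
            raise ModelInputError(f"missing required column '{col}'")
    keep = (table[fold_col].abs() >= fold_cutoff) & (table[p_col] < p_cutoff)
    kept = table.loc[keep]
    n_up = int((kept[fold_col] > 0).sum())
    n_down = int((kept[fold_col] < 0).sum())
    return kept, n_up, n_down


def read_expression_table(path) -> pd.DataFrame:
    """Read a TSV expression table (first column = factor names)."""
    return _check_table(pd.read_csv(path, sep="\t", index_col=0))


def write_expression_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
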