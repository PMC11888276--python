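"""Comparison of VIP predictions with massively parallel reporter assay
(MPRA) expression changes, per cell class."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class MpraRecord:
    """Measured expression change of one variant in one cell class."""

    variant_id: str
    cell_class: str
    expression_change: float  # variant minus reference, assay units
    reference_expression: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.expression_change):
            raise ValueError(f"{self.variant_id}/{self.cell_class}: "
                             "non-finite expression change")


def read_mpra_table(path: str | Path) -> list[MpraRecord]:
    """TSV with columns variant_id, cell_class and either expression_change or
    the pair (variant_expression, reference_expression) to difference."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "expression_change" not in df.columns:
        if {"variant_expression", "reference_expression"} <= set(df.columns):
            df["expression_change"] = (df["variant_expression"]
                                       - df["reference_expression"])
        else:
            raise ValueError(f"{path}: need expression_change or "
                             "variant_expression + reference_expression columns")
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (str(row.variant_id), str(row.cell_class))
        if key in seen:
            raise ValueError(f"{path}: duplicate record {key}")
        seen.add(key)
        ref = getattr(row, "reference_expression", None)
        records.append(MpraRecord(
            variant_id=str(row.variant_id), cell_class=str(row.cell_class),
            expression_change=float(row.expression_change),
            reference_expression=None if ref is None or pd.isna(ref) else float(ref)))
    return records


def join_vip_mpra(vip_table: pd.DataFrame, mpra: Sequence[MpraRecord],
                  class_map: Mapping[str, str]) -> pd.DataFrame:
    """Inner join of per-variant VIP scores with MPRA expression changes.

    ``vip_table`` carries an ``id`` column and one ``vip_<model>`` column per
    model; ``class_map`` maps each model label to the MPRA cell class it is
    compared against.  Unmatched variant ids are logged.
    """
    mpra_df = pd.DataFrame([{
        "variant_id": r.variant_id, "cell_class": r.cell_class,
        "expression_change": r.expression_change,
        "reference_expression": r.reference_expression} for r in mpra])
    if mpra_df.duplicated(["variant_id", "cell_class"]).any():
        raise ValueError("duplicate (variant_id, cell_class) keys in MPRA data")
    out_rows = []
    for model, cell_class in class_map.items():
        col = f"vip_{model}"
        if col not in vip_table.columns:
            raise KeyError(f"VIP table has no column {col}")
        sub = mpra_df[mpra_df["cell_class"] == cell_class]
        merged = vip_table[["id", col]].merge(
            sub, left_on="id", right_on="variant_id", how="inner")
        missing = set(vip_table["id"]) - set(merged["id"])
        if missing:
            log.info("model %s / class %s: %d variants without MPRA measurement",
                     model, cell_class, len(missing))
        for row in merged.itertuples(index=False):
            out_rows.append({
                "variant_id": row.id, "model": model, "cell_class": cell_class,
                "vip": getattr(row, col),
                "expression_change": row.expression_change,
                "reference_expression": row.reference_expression})
    if not out_rows:
        raise ValueError("empty intersection between VIP table and MPRA records")
    return pd.DataFrame(out_rows)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; requires n >= 3 and non-zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    return float(stats.pearsonr(x, y).statistic)


def correlation_by_class(joined: pd.DataFrame,
                         method: str = "pearson") -> pd.DataFrame:
    """Per-cell-class correlation of VIP with expression change.

    Classes with fewer than 3 pairs are excluded (logged).  Mean reference
    expression accompanies each correlation when available, so that low
    wild-type expression can be read alongside low |r|.
    """
    rows = []
    for cell_class, group in joined.groupby("cell_class", sort=True):
        if len(group) < 3:
            log.info("class %s: only %d pairs, excluded from correlation",
                     cell_class, len(group))
            continue
        if method == "pearson":
            r = pearson_correlation(group["vip"], group["expression_change"])
        elif method == "spearman":
            r = float(stats.spearmanr(group["vip"],
                                      group["expression_change"]).statistic)
        else:
            raise ValueError(f"unknown method {method!r}")
        ref = group["reference_expression"].dropna()
        rows.append({"cell_class": cell_class, "n": len(group), "r": r,
                     "mean_reference_expression":
                         float(ref.mean()) if len(ref) else np.nan})
    return pd.DataFrame(rows)
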