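"""Differential-expression handling.

Quantile normalization, the DiffScore <-> p-value conversion
(DiffScore = 10 * sgn * log10(1/p); |40| corresponds to p = 1e-4),
significance calling (detected AND |DiffScore| >= threshold), and the
four regulation groups obtained by comparing the two cell lines.

Tables are tidy/long pandas DataFrames with columns
``gene_id, cell_line, time_h, log2fc, diffscore, detection_p``.
Cell lines are named ``"wt"`` and ``"beta"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionRecord",
    "RegulationGroup",
    "quantile_normalize",
    "diffscore_to_p",
    "p_to_diffscore",
    "call_regulated",
    "classify_regulation",
    "read_expression_table",
    "write_expression_table",
]

WT = "wt"
BETA = "beta"
TIMEPOINTS = (0, 2, 4, 8)


class RegulationGroup(Enum):
    WT_ONLY = "wt_only"
    BOTH_CONCORDANT = "both_concordant"
    BETA_ONLY = "beta_only"
    OPPOSITE = "opposite"


@dataclass
class ExpressionRecord:
    """Per-gene measurements across timepoints for the two cell lines.

    ``log2fc`` and ``diffscore`` map cell line -> {time_h: value}; the
    fold-change at t=0 is 0 by construction (each timepoint is compared
    against 0 h).
    """

    gene_id: str
    log2fc: dict[str, dict[int, float]] = field(default_factory=dict)
    diffscore: dict[str, dict[int, float]] = field(default_factory=dict)
    detection_p: dict[str, dict[int, float]] = field(default_factory=dict)


def quantile_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a probes x samples matrix (columns = samples).

    After normalization every sample carries the identical sorted value
    vector: the across-sample mean of order statistics.  Ties within a
    sample receive the mean of the target values their positions span.
    Missing values are an error (impute upstream).
    """
    if frame.shape[1] < 2:
        raise ValueError("need >= 2 samples to quantile-normalize")
    if frame.isna().any().any():
        raise ValueError("missing values: impute before normalization")
    values = frame.to_numpy(dtype=float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = target
        # average the targets over tied input values
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def diffscore_to_p(ds: float) -> float:
    """p = 10^(-|ds| / 10); a score of +-40 corresponds to p = 1e-4."""
    if not np.isfinite(ds):
        raise ValueError("DiffScore must be finite")
    return float(10.0 ** (-abs(ds) / 10.0))


def p_to_diffscore(p: float, direction: int = 1) -> float:
    """Inverse conversion; ``direction`` carries the sign of the change."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    return float(direction * 10.0 * np.log10(1.0 / p))


def call_regulated(
    table: pd.DataFrame,
    diffscore_min: float = 40.0,
    detection_p_max: float = 0.01,
) -> pd.DataFrame:
    """Per (gene, cell line) regulation flags with direction.

    A gene is regulated in a cell line at a timepoint iff it is detected
    (detection p strictly below ``detection_p_max``) AND
    |DiffScore| >= ``diffscore_min``; the gene-level flag is regulation
    at any timepoint.  Direction is the sign of the DiffScore at the
    latest timepoint (falling back to the latest regulated timepoint when
    the final score is 0), since end-of-course behaviour drives the
    group comparison.

    Returns a frame indexed by (gene_id, cell_line) with columns
    ``regulated`` (bool) and ``direction`` (-1, 0, +1).
    """
    required = {"gene_id", "cell_line", "time_h", "diffscore", "detection_p"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"expression table lacks columns {sorted(missing)}")
    work = table.copy()
    work["hit"] = (work["detection_p"] < detection_p_max) & (
        work["diffscore"].abs() >= diffscore_min
    )
    rows = []
    for (gene, line), group in work.groupby(["gene_id", "cell_line"], sort=True):
        group = group.sort_values("time_h")
        regulated = bool(group["hit"].any())
        direction = 0
        if regulated:
            last = group.iloc[-1]
            direction = int(np.sign(last["diffscore"]))
            if direction == 0:
                hit_rows = group[group["hit"]]
                direction = int(np.sign(hit_rows.iloc[-1]["diffscore"]))
        rows.append((gene, line, regulated, direction))
    out = pd.DataFrame(
        rows, columns=["gene_id", "cell_line", "regulated", "direction"]
    ).set_index(["gene_id", "cell_line"])
    logger.info(
        "call_regulated: %d regulated (gene, line) pairs of %d",
        int(out["regulated"].sum()), len(out),
    )
    return out


def classify_regulation(calls: pd.DataFrame) -> dict[str, RegulationGroup]:
    """Assign each gene regulated in >= 1 cell line to a regulation group.

    Regulated in one line only -> WT_ONLY / BETA_ONLY; regulated in both
    -> BOTH_CONCORDANT when directions agree, OPPOSITE otherwise.  Genes
    regulated in neither line are excluded (not an error).
    """
    groups: dict[str, RegulationGroup] = {}
    for gene, sub in calls.groupby(level="gene_id", sort=True):
        sub = sub.droplevel("gene_id")
        wt_reg = bool(sub.loc[WT, "regulated"]) if WT in sub.index else False
        beta_reg = bool(sub.loc[BETA, "regulated"]) if BETA in sub.index else False
        if not wt_reg and not beta_reg:
            continue
        if wt_reg and not beta_reg:
            groups[gene] = RegulationGroup.WT_ONLY
        elif beta_reg and not wt_reg:
            groups[gene] = RegulationGroup.BETA_ONLY
        else:
            concordant = sub.loc[WT, "direction"] == sub.loc[BETA, "direction"]
            groups[gene] = (
                RegulationGroup.BOTH_CONCORDANT if concordant else RegulationGroup.OPPOSITE
            )
    counts = group_counts(groups)
    logger.info("classify_regulation: %s", counts)
    return groups


def group_counts(groups: Mapping[str, RegulationGroup]) -> dict[str, int]:
    counts = {g.value: 0 for g in RegulationGroup}
    for g in groups.values():
        counts[g.value] += 1
    counts["total"] = len(groups)
    return counts


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy tab-separated expression table.

    Expected columns: gene_id, cell_line, time_h, log2fc, diffscore,
    detection_p.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "cell_line", "time_h", "diffscore", "detection_p"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_expression_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
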