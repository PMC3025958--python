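"""Over-representation screening of TFBS matrices against a genome background.

Observed match counts in a site group are compared with the count expected
from the matrix's background per-bp hit rate.  Significance uses the
continuity-corrected normal approximation to the binomial,

    z = (O - E - 0.5) / sqrt(E * (1 - p_bg)),     E = p_bg * T,

a documented open-choice statistic matching the published semantics
(observed over expected, expressed as a Z-score).  Overlapping matches are
counted individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .motif_scan import PWM, scan

__all__ = [
    "EnrichmentRecord",
    "background_rate",
    "enrichment",
    "filter_enriched",
    "enrichment_grid",
    "read_rate_table",
    "write_rate_table",
]

# sentinels used in the heat-grid report
ABSENT = "absent"  # no match at all in the group (O = 0)
LOW_Z = "low-z"  # enriched but below the Z cutoff


@dataclass(frozen=True)
class EnrichmentRecord:
    matrix: str
    observed: int  # O: matches in the site group
    scanned_bp: int  # T: total bp scanned
    p_bg: float  # background per-bp hit probability
    expected: float  # E = p_bg * T
    fold: float  # O / E (inf when E == 0 and O > 0, 0 when O == 0)
    z_score: float  # nan when undefined (E == 0)

    def passes(self, z_min: float = 3.0, fold_min: float = 4.0) -> bool:
        return (
            not math.isnan(self.z_score)
            and self.z_score >= z_min
            and self.fold >= fold_min
        )


def background_rate(
    pwm: PWM,
    background: Mapping[str, float] | Sequence[str],
    core_min: float = 0.75,
    mat_min: float = 0.80,
) -> float:
    """Background per-bp hit probability for one matrix.

    ``background`` is either a precomputed {matrix name: rate} table
    (avoids whole-genome scans) or a collection of sequences to scan.
    When scanning, hits on both strands are counted over forward-strand
    positions: rate = total hits / total bp.
    """
    if isinstance(background, Mapping):
        if pwm.name not in background:
            raise KeyError(f"matrix {pwm.name!r} absent from rate table")
        return float(background[pwm.name])
    sequences = list(background)
    total_bp = sum(len(s) for s in sequences)
    if total_bp == 0:
        raise ValueError("empty background")
    total_hits = sum(len(scan(s, pwm, core_min, mat_min)) for s in sequences)
    return total_hits / total_bp


def enrichment(
    observed: int, scanned_bp: int, p_bg: float, matrix: str = ""
) -> EnrichmentRecord:
    """Build one over-representation record from raw counts."""
    if scanned_bp <= 0:
        raise ValueError("scanned_bp must be > 0")
    if observed < 0:
        raise ValueError("observed must be >= 0")
    expected = p_bg * scanned_bp
    if expected == 0.0:
        fold = math.inf if observed > 0 else 0.0
        z = math.nan
    else:
        fold = observed / expected
        z = (observed - expected - 0.5) / math.sqrt(expected * (1.0 - p_bg))
    return EnrichmentRecord(
        matrix=matrix,
        observed=observed,
        scanned_bp=scanned_bp,
        p_bg=p_bg,
        expected=expected,
        fold=fold,
        z_score=z,
    )


def filter_enriched(
    records: Iterable[EnrichmentRecord],
    z_min: float = 3.0,
    fold_min: float = 4.0,
) -> list[EnrichmentRecord]:
    """Keep records that are both significant (z >= z_min) and highly
    enriched (fold >= fold_min); both cutoffs are inclusive."""
    return [r for r in records if r.passes(z_min, fold_min)]


def enrichment_grid(
    records_by_group: Mapping[str, Sequence[EnrichmentRecord]],
    z_min: float = 3.0,
) -> dict[str, dict[str, float | str]]:
    """Heat-grid of fold values gated by the Z cutoff.

    Cell values: the numeric fold when z >= z_min; the sentinel
    ``"low-z"`` when the matrix matched but z < z_min; ``"absent"``
    when the matrix never matched in that group (O = 0).
    Returned as {group: {matrix: cell}}.
    """
    grid: dict[str, dict[str, float | str]] = {}
    for group, records in records_by_group.items():
        row: dict[str, float | str] = {}
        for rec in records:
            if rec.observed == 0:
                row[rec.matrix] = ABSENT
            elif math.isnan(rec.z_score) or rec.z_score < z_min:
                row[rec.matrix] = LOW_Z
            else:
                row[rec.matrix] = rec.fold
        grid[group] = row
    return grid


def grid_to_tsv(grid: Mapping[str, Mapping[str, float | str]], path: str | Path) -> None:
    matrices = sorted({m for row in grid.values() for m in row})
    with open(path, "w") as handle:
        handle.write("group\t" + "\t".join(matrices) + "\n")
        for group, row in grid.items():
            cells = [
                f"{row[m]:.3f}" if isinstance(row.get(m), float) else str(row.get(m, ABSENT))
                for m in matrices
            ]
            handle.write(group + "\t" + "\t".join(cells) + "\n")


def records_to_tsv(
    records: Iterable[EnrichmentRecord],
    path: str | Path,
    z_min: float = 3.0,
    fold_min: float = 4.0,
) -> None:
    """Tab-separated enrichment report (matrix, O, E, fold, z, pass/fail)."""
    with open(path, "w") as handle:
        handle.write("matrix\tobserved\texpected\tfold\tz_score\tpass\n")
        for r in records:
            handle.write(
                f"{r.matrix}\t{r.observed}\t{r.expected:.4f}\t{r.fold:.4f}"
                f"\t{r.z_score:.4f}\t{'pass' if r.passes(z_min, fold_min) else 'fail'}\n"
            )


def read_rate_table(path: str | Path) -> dict[str, float]:
    """Read a two-column {matrix name, per-bp rate} background table."""
    rates: dict[str, float] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, rate = line.split("\t")[:2]
            rates[name] = float(rate)
    return rates


def write_rate_table(rates: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, rate in rates.items():
            handle.write(f"{name}\t{rate:.10g}\n")
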