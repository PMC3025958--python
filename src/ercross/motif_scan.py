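"""Position-weight-matrix scanning for full and hemi-palindromic response elements.

Scoring follows the classic core/matrix-similarity scheme: each matrix
position carries an information value

    ci(l) = (100 / ln 4) * sum_b f(l, b) ln f(l, b) + 100

(0 for a uniform column, 100 for a fully conserved one) and a window is
scored by the information-weighted frequency of its bases relative to the
best attainable score:

    sim = sum_l ci(l) f(l, b_l) / sum_l ci(l) max_b f(l, b).

Core similarity applies the same ratio restricted to the four consecutive
highest-information positions.  The default full-element matrix is an open
stand-in built from the 13-bp palindromic consensus GGTCAnnnTGACC; the
hemi-palindrome is matched exactly as RGGTCA (R = A/G) on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PWM",
    "MotifHit",
    "EREClass",
    "information_vector",
    "matrix_similarity",
    "core_similarity",
    "scan",
    "scan_half_site",
    "classify_sites",
    "default_ere_pwm",
    "read_pwm",
    "write_pwm",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

HALF_SITE = "RGGTCA"  # Pu-GGTCA hemi-palindrome
ERE_CONSENSUS = "GGTCANNNTGACC"  # palindromic full element


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def information_vector(freqs: np.ndarray) -> np.ndarray:
    """Per-position information values on a 0-100 scale.

    ``freqs`` is an (L, 4) row-stochastic matrix; 0*ln(0) is taken as 0.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0):
        raise ValueError("negative frequencies")
    if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("frequency rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
    ci = (100.0 / np.log(4.0)) * terms.sum(axis=1) + 100.0
    return np.clip(ci, 0.0, 100.0)


@dataclass(frozen=True)
class PWM:
    """A per-position base-frequency matrix with derived information vector."""

    name: str
    freqs: np.ndarray  # (L, 4) in A, C, G, T order
    ci: np.ndarray  # (L,) information values in [0, 100]
    core_positions: tuple[int, ...]  # consecutive window used for core similarity

    @classmethod
    def from_frequencies(cls, name: str, freqs, core_width: int = 4) -> "PWM":
        freqs = np.asarray(freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[1] != 4:
            raise ValueError("frequency matrix must be (L, 4)")
        if freqs.shape[0] < core_width:
            raise ValueError(
                f"matrix length {freqs.shape[0]} shorter than core width {core_width}"
            )
        ci = information_vector(freqs)
        # core = consecutive window maximizing total information; ties leftmost
        window_sums = np.convolve(ci, np.ones(core_width), mode="valid")
        start = int(np.argmax(window_sums))
        core = tuple(range(start, start + core_width))
        return cls(name=name, freqs=freqs, ci=ci, core_positions=core)

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    """A scored matrix match inside one site sequence."""

    site_id: str | None
    offset: int  # 0-based offset of the match on the forward strand
    strand: str  # '+' or '-'
    core_similarity: float
    matrix_similarity: float
    sequence: str  # matched subsequence, as scored (reverse-complemented for '-')


class EREClass(Enum):
    ERE_PLUS = "ERE+"  # at least one full-element matrix hit
    HERE_PLUS = "hERE+"  # no full hit, but >= 1 exact half-site match
    NONE = "none"


def _encode(sequence: str) -> np.ndarray:
    """Map a sequence to base indices; anything not ACGT becomes -1 (N)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _similarity(codes: np.ndarray, freqs: np.ndarray, ci: np.ndarray) -> float:
    denom = float((ci * freqs.max(axis=1)).sum())
    if denom == 0.0:
        return 0.0
    valid = codes >= 0
    num = float((ci[valid] * freqs[valid, codes[valid]]).sum())
    return num / denom


def matrix_similarity(window: str, pwm: PWM) -> float:
    """Information-weighted similarity of ``window`` to the full matrix."""
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(pwm)}"
        )
    return _similarity(_encode(window), pwm.freqs, pwm.ci)


def core_similarity(window: str, pwm: PWM) -> float:
    """Similarity restricted to the matrix's core positions."""
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(pwm)}"
        )
    core = np.asarray(pwm.core_positions)
    return _similarity(_encode(window)[core], pwm.freqs[core], pwm.ci[core])


def _scan_strand(
    codes: np.ndarray, pwm: PWM, core_min: float, mat_min: float
) -> list[tuple[int, float, float]]:
    """All (offset, core_sim, mat_sim) passing both thresholds, vectorized."""
    L = len(pwm)
    n = codes.shape[0] - L + 1
    if n <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)  # (n, L)
    valid = windows >= 0
    safe = np.where(valid, windows, 0)
    pos = np.arange(L)
    scores = np.where(valid, pwm.freqs[pos, safe], 0.0)

    denom_full = float((pwm.ci * pwm.freqs.max(axis=1)).sum())
    core = np.asarray(pwm.core_positions)
    denom_core = float((pwm.ci[core] * pwm.freqs[core].max(axis=1)).sum())
    mat = (scores * pwm.ci).sum(axis=1) / denom_full if denom_full else np.zeros(n)
    core_sim = (
        (scores[:, core] * pwm.ci[core]).sum(axis=1) / denom_core
        if denom_core
        else np.zeros(n)
    )
    keep = np.flatnonzero((mat >= mat_min) & (core_sim >= core_min))
    return [(int(i), float(core_sim[i]), float(mat[i])) for i in keep]


def scan(
    sequence: str,
    pwm: PWM,
    core_min: float = 0.75,
    mat_min: float = 0.80,
    site_id: str | None = None,
) -> list[MotifHit]:
    """Scan both strands of ``sequence`` for matrix hits.

    A hit requires core similarity >= ``core_min`` AND matrix similarity
    >= ``mat_min``.  Reverse-strand hits are found by scanning the
    reverse complement; their offsets are mapped back to the forward
    strand.  Overlapping hits are all reported.
    """
    if not 0.0 <= core_min <= 1.0 or not 0.0 <= mat_min <= 1.0:
        raise ValueError("thresholds must be in [0, 1]")
    L = len(pwm)
    hits: list[MotifHit] = []
    fwd = sequence.upper()
    for offset, core_sim, mat in _scan_strand(_encode(fwd), pwm, core_min, mat_min):
        hits.append(MotifHit(site_id, offset, "+", core_sim, mat, fwd[offset : offset + L]))
    rev = reverse_complement(fwd)
    for offset, core_sim, mat in _scan_strand(_encode(rev), pwm, core_min, mat_min):
        fwd_offset = len(fwd) - L - offset
        hits.append(
            MotifHit(site_id, fwd_offset, "-", core_sim, mat, rev[offset : offset + L])
        )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_half_site(sequence: str, site_id: str | None = None) -> list[MotifHit]:
    """Exact matches to the RGGTCA hemi-palindrome on either strand.

    A reverse-strand match appears as TGACCY on the forward text.
    Overlapping matches are all reported; similarity scores are 1 by
    definition of an exact match.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for i in range(len(seq) - 5):
        window = seq[i : i + 6]
        if window[0] in "AG" and window[1:] == "GGTCA":
            hits.append(MotifHit(site_id, i, "+", 1.0, 1.0, window))
        if window[:5] == "TGACC" and window[5] in "CT":
            hits.append(MotifHit(site_id, i, "-", 1.0, 1.0, reverse_complement(window)))
    return hits


def classify_sites(
    site_sequences: Mapping[str, str],
    ere_pwms: Sequence[PWM] | None = None,
    core_min: float = 0.75,
    mat_min: float = 0.80,
) -> tuple[dict[str, EREClass], dict[str, float]]:
    """Classify each site as ERE+, hERE+ or none.

    A site with >= 1 full-matrix hit from any of ``ere_pwms`` is ERE+
    (counted once per site regardless of how many matrices match); a
    remaining site with an exact half-site match is hERE+; the rest are
    none.  Returns the per-site labels and the three summary fractions.
    """
    if ere_pwms is None:
        ere_pwms = [default_ere_pwm()]
    labels: dict[str, EREClass] = {}
    for site_id, sequence in site_sequences.items():
        if sequence is None or sequence == "":
            raise ValueError(f"missing sequence for site {site_id}")
        if any(scan(sequence, pwm, core_min, mat_min) for pwm in ere_pwms):
            labels[site_id] = EREClass.ERE_PLUS
        elif scan_half_site(sequence):
            labels[site_id] = EREClass.HERE_PLUS
        else:
            labels[site_id] = EREClass.NONE
    n = len(labels)
    fractions = {
        cls.value: (sum(1 for v in labels.values() if v is cls) / n if n else 0.0)
        for cls in EREClass
    }
    return labels, fractions


def default_ere_pwm(
    consensus_freq: float = 0.85, name: str = "ERE_consensus"
) -> PWM:
    """Open full-element matrix built from the palindromic consensus.

    Consensus positions get ``consensus_freq`` for the consensus base and
    the remainder split evenly; the three spacer positions (N) are
    uniform.  This is a documented stand-in for proprietary matrices, not
    a clone of them.
    """
    if not 0.25 <= consensus_freq <= 1.0:
        raise ValueError("consensus_freq must be in [0.25, 1.0]")
    off = (1.0 - consensus_freq) / 3.0
    rows = []
    for base in ERE_CONSENSUS:
        if base == "N":
            rows.append([0.25] * 4)
        else:
            rows.append(
                [consensus_freq if b == base else off for b in BASES]
            )
    return PWM.from_frequencies(name, np.array(rows))


def read_pwm(path: str | Path) -> PWM:
    """Read a PWM from a tab-separated position x {A,C,G,T} frequency table.

    Format: optional ``# name`` comment line, a header line ``A C G T``
    (tab-separated), then one row of four frequencies per position.
    """
    name = Path(path).stem
    rows = []
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    for line in lines:
        if line.startswith("#"):
            name = line[1:].strip() or name
            continue
        fields = line.split("\t")
        if [f.strip().upper() for f in fields[-4:]] == list(BASES):
            continue  # header
        rows.append([float(x) for x in fields[-4:]])
    if not rows:
        raise ValueError(f"{path}: no frequency rows")
    return PWM.from_frequencies(name, np.array(rows))


def write_pwm(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# {pwm.name}\n")
        handle.write("A\tC\tG\tT\n")
        for row in pwm.freqs:
            handle.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def hits_to_bed_rows(hits: Iterable[MotifHit]) -> list[str]:
    """Render hits as BED6 lines (matrix similarity in the score column)."""
    rows = []
    for h in hits:
        rows.append(
            f"{h.site_id or '.'}\t{h.offset}\t{h.offset + len(h.sequence)}"
            f"\t{h.sequence}\t{h.matrix_similarity:.4f}\t{h.strand}"
        )
    return rows
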