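"""Synthetic-data generators for every pipeline stage.

Each generator is deterministic given (config, rng seed) and returns a
truth table alongside the data, so recovery tests never need to re-derive
the planted structure.  Peaks are laid out on a slot grid with guard gaps
wider than twice the extension flank, which makes the planted co-binding
class of every site exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_de import BETA, TIMEPOINTS, WT
from .genomic_io import (
    GeneModel,
    GenomicInterval,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_gene_table,
)
from .motif_scan import (
    ERE_CONSENSUS,
    HALF_SITE,
    PWM,
    default_ere_pwm,
    reverse_complement,
    scan,
    scan_half_site,
)

__all__ = [
    "SimConfig",
    "PeakSim",
    "simulate_peaks",
    "simulate_sequences",
    "simulate_expression",
    "simulate_mirna",
    "simulate_genes",
    "simulate_all",
]

BASES = "ACGT"
MITO_CHROM = "simM"


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic genome; see field comments for semantics."""

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "sim1": 5_000_000,
            "sim2": 5_000_000,
            "sim3": 5_000_000,
            MITO_CHROM: 16_569,  # mitochondrial surrogate
        }
    )
    n_beta: int = 400
    # per-beta-peak probabilities of the four beta-site classes
    class_probs: tuple[float, float, float, float] = (0.25, 0.35, 0.30, 0.10)
    n_alpha_class5: int = 40  # isolated alpha sites (tagged cells only)
    n_alpha_class6: int = 40  # alpha sites backed by the wt map, no beta
    flank: int = 1000
    peak_len_median: float = 200.0
    peak_len_sigma: float = 0.3  # log-normal shape
    peak_len_min: int = 60
    peak_len_max: int = 500
    n_genes: int = 60
    exons_per_gene: int = 3
    gene_tu_len: int = 4000
    gene_link_fraction: float = 0.5  # fraction of genes with a planted nearby region
    n_mirna: int = 40
    mirna_near_fraction: float = 0.0  # planted proximity enrichment
    mirna_len: int = 80
    window: int = 10_000
    # planted sequence-composition fractions (full element, half site)
    ere_fraction: float = 0.5
    here_fraction: float = 0.3
    ere_mismatches: int = 0  # 0 or 1 mismatches in planted full elements
    gc_content: float = 0.5  # background base composition
    # expression design: proportions of the four regulation groups
    group_props: tuple[float, float, float, float] = (0.25, 0.17, 0.52, 0.02)
    effect_diffscore: float = 60.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        for name in ("ere_fraction", "here_fraction", "mirna_near_fraction",
                     "gene_link_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ere_fraction + self.here_fraction > 1.0 + 1e-9:
            raise ValueError("ere_fraction + here_fraction must be <= 1")
        if sum(self.group_props) > 1.0 + 1e-9:
            raise ValueError("group_props must sum to <= 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.ere_mismatches not in (0, 1):
            raise ValueError("ere_mismatches must be 0 or 1 (more can break "
                             "the planted classification)")


@dataclass(frozen=True)
class PeakSim:
    beta: tuple[GenomicInterval, ...]
    alpha_tap: tuple[GenomicInterval, ...]
    alpha_wt: tuple[GenomicInterval, ...]
    truth: dict[str, str]  # peak id -> intended class name (beta + alpha_tap)


def _autosomes(config: SimConfig) -> list[str]:
    return [c for c in config.chrom_sizes if c != MITO_CHROM]


def _slot_layout(config: SimConfig, n_units: int, slot_bp: int, rng) -> list[tuple[str, int]]:
    """Assign units to disjoint genome slots (shuffled); error when infeasible."""
    slots: list[tuple[str, int]] = []
    for chrom in _autosomes(config):
        for k in range(config.chrom_sizes[chrom] // slot_bp):
            slots.append((chrom, k * slot_bp))
    if n_units > len(slots):
        raise ValueError(
            f"infeasible design: {n_units} units but only {len(slots)} "
            f"slots of {slot_bp} bp"
        )
    chosen = rng.choice(len(slots), size=n_units, replace=False)
    return [slots[i] for i in chosen]


def _draw_lengths(config: SimConfig, n: int, rng) -> np.ndarray:
    lengths = rng.lognormal(np.log(config.peak_len_median), config.peak_len_sigma, n)
    return np.clip(np.round(lengths), config.peak_len_min, config.peak_len_max).astype(int)


def simulate_peaks(config: SimConfig, rng: np.random.Generator) -> PeakSim:
    """Generate three peak sets with planted six-class structure.

    Each binding unit occupies one slot; companion peaks of a unit are
    placed within 800 bp of the anchor peak (so their extended regions are
    guaranteed to merge/overlap at the default 1000 bp flank), and slots
    are wide enough that no two units can interact.
    """
    config.validate()
    n_units = config.n_beta + config.n_alpha_class5 + config.n_alpha_class6
    slot_bp = 4 * config.flank + 2 * config.peak_len_max + 2000
    anchors = _slot_layout(config, n_units, slot_bp, rng)

    beta: list[GenomicInterval] = []
    alpha_tap: list[GenomicInterval] = []
    alpha_wt: list[GenomicInterval] = []
    truth: dict[str, str] = {}

    beta_classes = rng.choice(4, size=config.n_beta, p=config.class_probs) + 1
    margin = config.flank + config.peak_len_max + 1000  # keep companions inside the slot

    def companion(chrom: str, anchor: int, length: int) -> GenomicInterval:
        offset = int(rng.integers(-800, 801))
        start = max(0, anchor + offset)
        return GenomicInterval(chrom, start, start + length)

    unit = 0
    for i in range(config.n_beta):
        chrom, slot_start = anchors[unit]
        unit += 1
        anchor = slot_start + margin
        length = int(_draw_lengths(config, 1, rng)[0])
        peak_id = f"beta_{i:05d}"
        beta.append(GenomicInterval(chrom, anchor, anchor + length, id=peak_id))
        cls = int(beta_classes[i])
        truth[peak_id] = f"CLASS{cls}"
        if cls in (1, 2):
            c = companion(chrom, anchor, int(_draw_lengths(config, 1, rng)[0]))
            alpha_wt.append(replace_id(c, f"alphawt_b{i:05d}"))
        if cls in (2, 4):
            c = companion(chrom, anchor, int(_draw_lengths(config, 1, rng)[0]))
            atap_id = f"alphatap_b{i:05d}"
            alpha_tap.append(replace_id(c, atap_id))
            truth[atap_id] = f"CLASS{cls}"

    for j in range(config.n_alpha_class5):
        chrom, slot_start = anchors[unit]
        unit += 1
        anchor = slot_start + margin
        length = int(_draw_lengths(config, 1, rng)[0])
        peak_id = f"alphatap_c5_{j:05d}"
        alpha_tap.append(GenomicInterval(chrom, anchor, anchor + length, id=peak_id))
        truth[peak_id] = "CLASS5"

    for j in range(config.n_alpha_class6):
        chrom, slot_start = anchors[unit]
        unit += 1
        anchor = slot_start + margin
        length = int(_draw_lengths(config, 1, rng)[0])
        peak_id = f"alphatap_c6_{j:05d}"
        alpha_tap.append(GenomicInterval(chrom, anchor, anchor + length, id=peak_id))
        truth[peak_id] = "CLASS6"
        c = companion(chrom, anchor, int(_draw_lengths(config, 1, rng)[0]))
        alpha_wt.append(replace_id(c, f"alphawt_c6_{j:05d}"))

    return PeakSim(tuple(beta), tuple(alpha_tap), tuple(alpha_wt), truth)


def replace_id(iv: GenomicInterval, new_id: str) -> GenomicInterval:
    return GenomicInterval(iv.chrom, iv.start, iv.end, id=new_id,
                           score=iv.score, tag_count=iv.tag_count)


# ---------------------------------------------------------------------------
# sequences

def _random_seq(n: int, gc: float, rng) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def _scrub(seq: str, rng, gc: float, pwm: PWM, core_min: float, mat_min: float,
           protect: tuple[int, int] | None = None, forbid_full: bool = True,
           forbid_half: bool = True, max_rounds: int = 80) -> str:
    """Redraw windows until the sequence carries no unintended element.

    Offending spans are resampled base by base, leaving the ``protect``
    span (the planted motif) untouched; a span lying entirely inside the
    protected region is the intended hit and is kept.
    """
    chars = list(seq)
    for _ in range(max_rounds):
        dirty: list[tuple[int, int]] = []
        text = "".join(chars)
        if forbid_half:
            for hit in scan_half_site(text):
                dirty.append((hit.offset, hit.offset + len(HALF_SITE)))
        if forbid_full:
            for hit in scan(text, pwm, core_min, mat_min):
                dirty.append((hit.offset, hit.offset + len(pwm)))
        redraw: set[int] = set()
        for s, e in dirty:
            positions = [
                k for k in range(s, e)
                if protect is None or not protect[0] <= k < protect[1]
            ]
            if positions:  # an empty list marks the intended, protected hit
                redraw.update(positions)
        if not redraw:
            return text
        for k in redraw:
            chars[k] = _random_seq(1, gc, rng)
    raise RuntimeError("could not scrub unintended motifs from background")


def _planted_full_element(rng, mismatches: int) -> str:
    motif = [
        b if b != "N" else BASES[rng.integers(4)] for b in ERE_CONSENSUS
    ]
    if mismatches:
        conserved = [i for i, b in enumerate(ERE_CONSENSUS) if b != "N"]
        pos = int(rng.choice(conserved))
        alternatives = [b for b in BASES if b != motif[pos]]
        motif[pos] = alternatives[int(rng.integers(3))]
    return "".join(motif)


def _planted_half_site(rng) -> str:
    return ("A" if rng.integers(2) else "G") + "GGTCA"


def simulate_sequences(
    sites: Sequence[GenomicInterval],
    config: SimConfig,
    rng: np.random.Generator,
    core_min: float = 0.75,
    mat_min: float = 0.80,
) -> tuple[dict[str, str], dict[str, str]]:
    """One sequence per site with planted element composition.

    A configured fraction of sites carries a full palindromic element
    (with up to one mismatch), a second fraction carries only the exact
    half site, and the rest are scrubbed background.  Backgrounds are
    cleaned of chance matches so the truth labels are exact.  Returns
    ``(sequences, truth)`` keyed by site id, truth values in
    {"ERE+", "hERE+", "none"}.
    """
    config.validate()
    pwm = default_ere_pwm()
    labels = rng.choice(
        3,
        size=len(sites),
        p=[
            config.ere_fraction,
            config.here_fraction,
            1.0 - config.ere_fraction - config.here_fraction,
        ],
    )
    sequences: dict[str, str] = {}
    truth: dict[str, str] = {}
    for site, label in zip(sites, labels):
        site_id = site.id or f"{site.chrom}:{site.start}-{site.end}"
        n = site.length
        if label == 0:
            motif = _planted_full_element(rng, config.ere_mismatches)
        elif label == 1:
            motif = _planted_half_site(rng)
        else:
            motif = ""
        if motif and n < len(motif):
            raise ValueError(
                f"site {site_id} ({n} bp) shorter than planted motif"
            )
        background = _random_seq(n, config.gc_content, rng)
        if motif:
            if rng.integers(2):
                motif = reverse_complement(motif)
            pos = int(rng.integers(0, n - len(motif) + 1))
            seq = background[:pos] + motif + background[pos + len(motif):]
            protect = (pos, pos + len(motif))
        else:
            seq, protect = background, None
        if label == 1:
            # half-site sites must carry no chance full element
            seq = _scrub(seq, rng, config.gc_content, pwm, core_min, mat_min,
                         protect, forbid_full=True, forbid_half=True)
        elif label == 2:
            seq = _scrub(seq, rng, config.gc_content, pwm, core_min, mat_min,
                         None, forbid_full=True, forbid_half=True)
        # full-element sites need no scrubbing: extra chance matches cannot
        # change their class
        sequences[site_id] = seq
        truth[site_id] = ("ERE+", "hERE+", "none")[int(label)]
    return sequences, truth


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    gene_ids: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """Tidy expression table with planted regulation groups.

    Regulated (gene, line) pairs get |DiffScore| = ``effect_diffscore`` at
    the non-zero timepoints and a fold-change ramp in the chosen
    direction; unregulated pairs get zero signal.  Gaussian noise of width
    ``noise_sigma`` is added to the fold-changes and DiffScores of the
    non-anchored timepoints; at sigma = 0 the planted groups are recovered
    exactly.  Truth values are regulation-group names or None.
    """
    config.validate()
    props = list(config.group_props) + [1.0 - sum(config.group_props)]
    assignment = rng.choice(5, size=len(gene_ids), p=props)
    group_names = ("wt_only", "both_concordant", "beta_only", "opposite", None)
    rows = []
    truth: dict[str, str | None] = {}
    for gene, idx in zip(gene_ids, assignment):
        group = group_names[int(idx)]
        truth[gene] = group
        direction = int(rng.choice([-1, 1]))
        per_line = {WT: 0, BETA: 0}
        if group == "wt_only":
            per_line[WT] = direction
        elif group == "beta_only":
            per_line[BETA] = direction
        elif group == "both_concordant":
            per_line[WT] = per_line[BETA] = direction
        elif group == "opposite":
            per_line[WT], per_line[BETA] = direction, -direction
        for line in (WT, BETA):
            d = per_line[line]
            for i, t in enumerate(TIMEPOINTS):
                if t == 0:
                    log2fc, ds = 0.0, 0.0
                elif d != 0:
                    log2fc = d * (0.5 + 0.5 * i) + rng.normal(0, config.noise_sigma)
                    ds = d * config.effect_diffscore + rng.normal(
                        0, config.noise_sigma
                    )
                else:
                    log2fc = rng.normal(0, config.noise_sigma)
                    ds = rng.normal(0, config.noise_sigma)
                rows.append((gene, line, t, log2fc, ds, 0.001))
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "cell_line", "time_h", "log2fc", "diffscore", "detection_p"],
    )
    return table, truth


# ---------------------------------------------------------------------------
# genes and small-RNA loci

def simulate_genes(
    config: SimConfig,
    rng: np.random.Generator,
    regions: Sequence = (),
) -> tuple[list[GeneModel], dict[str, bool]]:
    """Gene models, a configured fraction planted near the given regions.

    A 'linked' gene is placed with its TU start a sub-window distance from
    a randomly chosen region; the rest go into slots guaranteed to be
    farther than the window from every region.  Returns (genes, truth)
    where truth marks the intended linkage.
    """
    config.validate()
    n_linked = int(round(config.gene_link_fraction * config.n_genes)) if regions else 0
    genes: list[GeneModel] = []
    truth: dict[str, bool] = {}

    region_list = list(regions)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for r in region_list:
        occupied.setdefault(r.chrom, []).append((r.start, r.end))
    for spans in occupied.values():
        spans.sort()

    def far_from_regions(chrom: str, start: int, end: int) -> bool:
        for s, e in occupied.get(chrom, []):
            if start - config.window - 1000 < e and s < end + config.window + 1000:
                return False
        return True

    for i in range(config.n_genes):
        gene_id = f"gene_{i:04d}"
        strand = "+" if rng.integers(2) else "-"
        if i < n_linked:
            region = region_list[int(rng.integers(len(region_list)))]
            gap = int(rng.integers(0, config.window // 2))
            chrom = region.chrom
            tx_start = min(
                region.end + gap,
                config.chrom_sizes[chrom] - config.gene_tu_len,
            )
            truth[gene_id] = True
        else:
            chrom = _autosomes(config)[int(rng.integers(len(_autosomes(config))))]
            chrom_len = config.chrom_sizes[chrom]
            for _ in range(1000):
                tx_start = int(rng.integers(0, chrom_len - config.gene_tu_len))
                if far_from_regions(chrom, tx_start, tx_start + config.gene_tu_len):
                    break
            else:
                raise RuntimeError("could not place an unlinked gene; genome too full")
            truth[gene_id] = False
        tx_end = tx_start + config.gene_tu_len
        exon_len = max(50, config.gene_tu_len // (3 * config.exons_per_gene))
        step = config.gene_tu_len // config.exons_per_gene
        exons = tuple(
            (tx_start + k * step, tx_start + k * step + exon_len)
            for k in range(config.exons_per_gene)
        )
        genes.append(GeneModel(gene_id, chrom, strand, tx_start, tx_end, exons))
    return genes, truth


def simulate_mirna(
    config: SimConfig,
    rng: np.random.Generator,
    sites: Sequence[GenomicInterval] = (),
) -> tuple[list[GenomicInterval], dict[str, bool]]:
    """Small-RNA precursor loci with a planted proximity fraction.

    A fraction ``mirna_near_fraction`` of loci is placed within the
    proximity window of a randomly chosen site; the rest land uniformly on
    the autosome surrogates.  Truth records the planting intent (uniform
    loci may still fall near a site by chance).
    """
    config.validate()
    if config.mirna_near_fraction > 0 and not sites:
        raise ValueError("cannot plant proximity without sites")
    n_near = int(round(config.mirna_near_fraction * config.n_mirna))
    loci: list[GenomicInterval] = []
    truth: dict[str, bool] = {}
    site_list = list(sites)
    for i in range(config.n_mirna):
        locus_id = f"mir_{i:04d}"
        if i < n_near:
            site = site_list[int(rng.integers(len(site_list)))]
            gap = int(rng.integers(0, config.window // 2))
            start = site.end + gap
            chrom = site.chrom
            chrom_len = config.chrom_sizes[chrom]
            start = min(start, chrom_len - config.mirna_len)
            truth[locus_id] = True
        else:
            chrom = _autosomes(config)[int(rng.integers(len(_autosomes(config))))]
            chrom_len = config.chrom_sizes[chrom]
            start = int(rng.integers(0, chrom_len - config.mirna_len))
            truth[locus_id] = False
        loci.append(
            GenomicInterval(chrom, start, start + config.mirna_len, id=locus_id)
        )
    return loci, truth


# ---------------------------------------------------------------------------
# bundle

TINY = SimConfig(
    chrom_sizes={"sim1": 1_000_000, "sim2": 1_000_000, MITO_CHROM: 16_569},
    n_beta=40, n_alpha_class5=5, n_alpha_class6=5,
    n_genes=12, n_mirna=10,
)

PAPER_SCALE = SimConfig(
    chrom_sizes={
        "sim1": 25_000_000, "sim2": 25_000_000, "sim3": 25_000_000,
        MITO_CHROM: 16_569,
    },
    n_beta=9702, n_alpha_class5=600, n_alpha_class6=770,
    n_genes=900, n_mirna=200, mirna_near_fraction=0.15,
)

PRESETS = {"tiny": TINY, "paper-scale": PAPER_SCALE}


def simulate_all(config: SimConfig, seed: int | None = None) -> dict:
    """Run every generator off a single seed; returns an in-memory bundle."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    peaks = simulate_peaks(config, rng)
    sequences, seq_truth = simulate_sequences(peaks.beta[: min(len(peaks.beta), 200)],
                                              config, rng)
    from .interval_algebra import extend, merge  # local import avoids a cycle

    regions = merge(extend(peaks.beta, config.flank, config.chrom_sizes))
    genes, gene_truth = simulate_genes(config, rng, regions)
    table, expr_truth = simulate_expression([g.gene_id for g in genes], config, rng)
    loci, mirna_truth = simulate_mirna(config, rng, peaks.beta)
    return {
        "config": config,
        "peaks": peaks,
        "sequences": sequences,
        "sequence_truth": seq_truth,
        "beta_regions": regions,
        "genes": genes,
        "gene_truth": gene_truth,
        "expression": table,
        "expression_truth": expr_truth,
        "mirna_loci": loci,
        "mirna_truth": mirna_truth,
    }


def write_bundle(bundle: dict, outdir: str | Path) -> None:
    """Write a simulated bundle as plain-text files plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config: SimConfig = bundle["config"]
    peaks: PeakSim = bundle["peaks"]
    write_bed(peaks.beta, outdir / "beta_peaks.bed")
    write_bed(peaks.alpha_tap, outdir / "alpha_tap_peaks.bed")
    write_bed(peaks.alpha_wt, outdir / "alpha_wt_peaks.bed")
    write_chrom_sizes(config.chrom_sizes, outdir / "chrom.sizes")
    write_fasta(bundle["sequences"], outdir / "site_sequences.fa")
    write_gene_table(bundle["genes"], outdir / "genes.tsv")
    bundle["expression"].to_csv(outdir / "expression.tsv", sep="\t", index=False)
    write_bed(bundle["mirna_loci"], outdir / "mirna_loci.bed")
    truth = {
        "peak_classes": peaks.truth,
        "sequence_classes": bundle["sequence_truth"],
        "gene_linked": bundle["gene_truth"],
        "expression_groups": bundle["expression_truth"],
        "mirna_planted_near": bundle["mirna_truth"],
    }
    with open(outdir / "truth.json", "w") as handle:
        json.dump(truth, handle, indent=2)
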