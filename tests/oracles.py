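"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (per-basepair boolean masks,
all-pairs loops, direct formula evaluation) and shares no code with the
implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def mask_merge(intervals, chrom_lens):
    """Connected components of the overlap graph via a per-bp boolean mask.

    ``intervals`` are (chrom, start, end) triples.  Returns a sorted list
    of (chrom, start, end) merged spans.
    """
    spans = []
    for chrom in sorted(chrom_lens):
        mask = np.zeros(chrom_lens[chrom], dtype=bool)
        for c, s, e in intervals:
            if c == chrom:
                mask[s:e] = True
        padded = np.concatenate(([False], mask, [False])).astype(np.int8)
        diff = np.diff(padded)
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        spans.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return spans


def graph_merge(intervals):
    """Connected components of the share->=1bp overlap graph, by union-find.

    Returns sorted (chrom, start, end) component spans.  Unlike the mask
    oracle this does NOT join book-ended intervals.
    """
    items = list(intervals)
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i], items[j]
            if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                parent[find(i)] = find(j)
    components = {}
    for i, (c, s, e) in enumerate(items):
        root = find(i)
        if root in components:
            cc, cs, ce = components[root]
            components[root] = (cc, min(cs, s), max(ce, e))
        else:
            components[root] = (c, s, e)
    return sorted(components.values())


def mask_overlaps_any(query, targets, chrom_lens):
    """Does (chrom, start, end) share >= 1 bp with any target? Mask-based."""
    chrom, start, end = query
    mask = np.zeros(chrom_lens[chrom], dtype=bool)
    for c, s, e in targets:
        if c == chrom:
            mask[s:e] = True
    return bool(mask[start:end].any())


def pairwise_overlap(a, b):
    """Share >= 1 bp, by direct comparison of (chrom, start, end) triples."""
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def classify_six_bruteforce(beta_peaks, beta_regions, tap_regions, wt_regions,
                            tap_peaks=()):
    """All-pairs re-derivation of the six-class labels.

    Peaks/regions are (id, chrom, start, end) / (chrom, start, end).
    """
    labels = {}

    def containing(peak, regions):
        matches = [
            r for r in regions
            if r[0] == peak[1] and r[1] <= peak[2] and peak[3] <= r[2]
        ]
        assert len(matches) == 1, f"peak {peak} in {len(matches)} regions"
        return matches[0]

    def hits(region, others):
        return any(pairwise_overlap(region, o) for o in others)

    for peak in beta_peaks:
        region = containing(peak, beta_regions)
        wt, tap = hits(region, wt_regions), hits(region, tap_regions)
        if wt and not tap:
            labels[peak[0]] = "CLASS1"
        elif wt and tap:
            labels[peak[0]] = "CLASS2"
        elif not wt and not tap:
            labels[peak[0]] = "CLASS3"
        else:
            labels[peak[0]] = "CLASS4"
    for peak in tap_peaks:
        region = containing(peak, tap_regions)
        beta, wt = hits(region, beta_regions), hits(region, wt_regions)
        if beta:
            labels[peak[0]] = "CLASS2" if wt else "CLASS4"
        elif wt:
            labels[peak[0]] = "CLASS6"
        else:
            labels[peak[0]] = "CLASS5"
    return labels


# --- motif scoring -------------------------------------------------------

def info_value(column):
    """Direct evaluation of the information formula for one frequency row."""
    total = 0.0
    for f in column:
        if f > 0:
            total += f * math.log(f)
    return (100.0 / math.log(4.0)) * total + 100.0


def similarity_bruteforce(window, freqs, positions=None):
    """Information-weighted similarity via explicit loops."""
    order = "ACGT"
    L = len(freqs)
    if positions is None:
        positions = range(L)
    ci = [info_value(row) for row in freqs]
    num = 0.0
    denom = 0.0
    for l in positions:
        denom += ci[l] * max(freqs[l])
        base = window[l]
        if base in order:
            num += ci[l] * freqs[l][order.index(base)]
    return num / denom if denom else 0.0


def core_window_bruteforce(freqs, width=4):
    """Exhaustive search for the max-information consecutive window."""
    ci = [info_value(row) for row in freqs]
    best, best_sum = 0, -1.0
    for start in range(len(ci) - width + 1):
        s = sum(ci[start : start + width])
        if s > best_sum + 1e-12:
            best, best_sum = start, s
    return tuple(range(best, best + width))


def scan_bruteforce(sequence, freqs, core_positions, core_min, mat_min):
    """All-offsets, both-strands hit finding by direct scoring."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(sequence))
    L = len(freqs)
    hits = []
    for text, strand in ((sequence, "+"), (rc, "-")):
        for i in range(len(text) - L + 1):
            window = text[i : i + L]
            mat = similarity_bruteforce(window, freqs)
            core = similarity_bruteforce(window, freqs, core_positions)
            if mat >= mat_min and core >= core_min:
                offset = i if strand == "+" else len(text) - L - i
                hits.append((offset, strand))
    return sorted(hits)


# --- proximity -----------------------------------------------------------

def interval_distance(a, b):
    """Edge-to-edge distance of two (chrom, start, end); None across chroms."""
    if a[0] != b[0]:
        return None
    return max(0, max(a[1], b[1]) - min(a[2], b[2]))


def proximity_bruteforce(sites, loci, window):
    """All-pairs proximity statistics on (chrom, start, end) triples."""
    near_site = [
        any(
            (d := interval_distance(s, l)) is not None and d <= window
            for l in loci
        )
        for s in sites
    ]
    near_locus = [
        any(
            (d := interval_distance(s, l)) is not None and d <= window
            for s in sites
        )
        for l in loci
    ]
    pairs = sum(
        1
        for s in sites
        for l in loci
        if (d := interval_distance(s, l)) is not None and d <= window
    )
    return sum(near_site), sum(near_locus), pairs
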