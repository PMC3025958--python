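"""Primary-target assignment: linking binding regions to genes.

A gene is a 'primary' target when at least one binding region lies inside
its transcription unit or within a fixed window (default 10 kb) of it.
Linked sites are annotated by location relative to the gene (promoter /
exon / intron / upstream / downstream, strand-aware, by site midpoint) and
each gene receives either the single class shared by all its linked sites
or the COMBINATION label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .genomic_io import GeneModel, GenomicInterval
from .interval_algebra import BindingRegion, SiteClass

logger = logging.getLogger(__name__)

__all__ = [
    "COMBINATION",
    "PrimaryTarget",
    "link",
    "annotate_location",
    "assign_gene_class",
    "build_primary_targets",
]

COMBINATION = "COMBINATION"

LOCATIONS = ("promoter", "exon", "intron", "upstream", "downstream")


@dataclass(frozen=True)
class PrimaryTarget:
    gene_id: str
    region_ids: tuple[str, ...]
    region_classes: tuple[SiteClass, ...]
    gene_class: SiteClass | str  # one SiteClass, or COMBINATION
    locations: tuple[str, ...]  # per linked region, parallel to region_ids


def _region_key(region: BindingRegion) -> str:
    return f"{region.chrom}:{region.start}-{region.end}"


def link(
    genes: Sequence[GeneModel],
    regions: Sequence[BindingRegion],
    window_bp: int = 10_000,
) -> dict[str, list[BindingRegion]]:
    """Link each gene to the regions inside or within ``window_bp`` of its TU.

    A region is linked iff it overlaps ``[tx_start - window_bp,
    tx_end + window_bp)``; a region may link to several genes.  Only genes
    with >= 1 link appear in the result.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, list[BindingRegion]] = {}
    for region in regions:
        by_chrom.setdefault(region.chrom, []).append(region)
    for group in by_chrom.values():
        group.sort(key=lambda r: (r.start, r.end))
    links: dict[str, list[BindingRegion]] = {}
    for gene in genes:
        lo = max(0, gene.tx_start - window_bp)
        hi = gene.tx_end + window_bp
        hits = [
            r for r in by_chrom.get(gene.chrom, [])
            if r.start < hi and lo < r.end
        ]
        if hits:
            links[gene.gene_id] = hits
    logger.info(
        "link: %d of %d genes have >= 1 region within %d bp",
        len(links), len(genes), window_bp,
    )
    return links


def annotate_location(
    site: GenomicInterval | BindingRegion,
    gene: GeneModel,
    promoter_bp: int = 1000,
    use_midpoint: bool = True,
) -> str:
    """Label a linked site's position relative to a gene.

    The site is reduced to its midpoint (or to its start with
    ``use_midpoint=False``, a containment-style alternative) and placed
    strand-aware:

    - promoter: within ``promoter_bp`` 5' of the TSS;
    - exon / intron: inside the TU, by exon containment;
    - upstream: 5' of the promoter; downstream: 3' of the TU.

    Precedence at boundaries is promoter > exon > intron.
    """
    if site.chrom != gene.chrom:
        raise ValueError(
            f"site on {site.chrom} not linked to gene {gene.gene_id} on {gene.chrom}"
        )
    point = (site.start + site.end) // 2 if use_midpoint else site.start
    if gene.strand == "+":
        promoter_lo, promoter_hi = gene.tss - promoter_bp, gene.tss
        upstream = point < promoter_lo
        downstream = point >= gene.tx_end
    else:
        promoter_lo, promoter_hi = gene.tss + 1, gene.tss + 1 + promoter_bp
        upstream = point >= promoter_hi
        downstream = point < gene.tx_start
    if promoter_lo <= point < promoter_hi:
        return "promoter"
    if gene.tx_start <= point < gene.tx_end:
        for s, e in gene.exons:
            if s <= point < e:
                return "exon"
        return "intron"
    if upstream:
        return "upstream"
    if downstream:
        return "downstream"
    raise ValueError(
        f"site midpoint {point} could not be placed relative to {gene.gene_id}; "
        "is the site linked to this gene?"
    )


def assign_gene_class(classes: Sequence[SiteClass]) -> SiteClass | str:
    """The unique class when all linked sites agree, else COMBINATION."""
    if not classes:
        raise ValueError("gene has no linked site classes")
    unique = set(classes)
    return classes[0] if len(unique) == 1 else COMBINATION


def build_primary_targets(
    genes: Sequence[GeneModel],
    regions: Sequence[BindingRegion],
    region_classes: Mapping[str, SiteClass],
    window_bp: int = 10_000,
    promoter_bp: int = 1000,
) -> list[PrimaryTarget]:
    """End-to-end primary-target table.

    ``region_classes`` maps region keys (``chrom:start-end``) to site
    classes (all member peaks of a region share one class by
    construction of the taxonomy).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    targets = []
    for gene_id, linked in link(genes, regions, window_bp).items():
        gene = gene_by_id[gene_id]
        keys = tuple(_region_key(r) for r in linked)
        classes = tuple(region_classes[k] for k in keys)
        locations = tuple(
            annotate_location(r, gene, promoter_bp=promoter_bp) for r in linked
        )
        targets.append(
            PrimaryTarget(
                gene_id=gene_id,
                region_ids=keys,
                region_classes=classes,
                gene_class=assign_gene_class(classes),
                locations=locations,
            )
        )
    return targets


def targets_to_tsv_rows(targets: Sequence[PrimaryTarget]) -> list[str]:
    rows = ["gene_id\tgene_class\tregion\tregion_class\tlocation"]
    for t in targets:
        gene_class = t.gene_class if isinstance(t.gene_class, str) else t.gene_class.name
        for key, cls, loc in zip(t.region_ids, t.region_classes, t.locations):
            rows.append(f"{t.gene_id}\t{gene_class}\t{key}\t{cls.name}\t{loc}")
    return rows
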