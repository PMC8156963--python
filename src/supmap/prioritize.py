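"""Candidate suppressor gene ranking inside mapped QTL regions.

Genes under the strongest selected sites of a region are ranked by their
functional relationship to the query gene on a fixed priority ladder:
co-complex (highest), co-pathway, co-expression, co-localisation, and
essentiality of the candidate (lowest). Known general modifier genes are
appended as manual candidates. Validated suppressors are classified as
gain- or loss-of-function from prior genetic interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationSet, QTLRegion
from .bsa import DeltaTrack

logger = logging.getLogger("supmap.prioritize")

TIER_NAMES = ("co_complex", "co_pathway", "co_expressed", "co_localized",
              "essential")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    essential: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class PriorityScore:
    gene_id: str
    tier_vector: tuple[bool, bool, bool, bool, bool]
    rank: int
    manual: bool = False
    distance_to_peak: int = 0


@dataclass
class InteractionEvidence:
    suppressor_gene: str
    query_allele: str
    deletion_interaction: str = "unknown"  # exacerbates|suppresses|none|unknown
    overexpression_interaction: str = "unknown"

    _DOMAIN = {"exacerbates", "suppresses", "none", "unknown"}

    def __post_init__(self) -> None:
        for v in (self.deletion_interaction, self.overexpression_interaction):
            if v not in self._DOMAIN:
                raise ValueError(f"unknown interaction value {v!r}")


def candidate_window(region: QTLRegion, delta: DeltaTrack,
                     genes: list[GeneModel], tolerance: float = 0.03
                     ) -> list[GeneModel]:
    """Genes under the strongest selected sites of a QTL region.

    The peak value is max |delta| over the region's sites; a gene qualifies
    when any site overlapping its gene body has |delta| within ``tolerance``
    (absolute frequency units) of the peak. Sorted by genomic position.
    """
    if delta.chrom != region.chrom:
        raise ValueError("delta track chromosome does not match region")
    in_region = (delta.positions >= region.start) & (delta.positions <= region.end)
    if not in_region.any():
        logger.warning("region %s:%d-%d covers no sites", region.chrom,
                       region.start, region.end)
        return []
    peak = float(np.max(np.abs(delta.delta[in_region])))
    cutoff = peak - tolerance
    selected = []
    for gene in genes:
        if gene.chrom != region.chrom:
            continue
        overlap = in_region & (delta.positions >= gene.start) & \
            (delta.positions <= gene.end)
        if overlap.any() and np.max(np.abs(delta.delta[overlap])) >= cutoff:
            selected.append(gene)
    if not selected:
        logger.warning("no genes within tolerance in region %s:%d-%d",
                       region.chrom, region.start, region.end)
    return sorted(selected, key=lambda g: (g.start, g.gene_id))


def tier_vector(candidate: GeneModel, query_gene: str,
                annotations: AnnotationSet) -> tuple[bool, ...]:
    """Functional-relationship ladder of a candidate against the query."""
    return (
        annotations.co_complex(candidate.gene_id, query_gene),
        annotations.co_pathway(candidate.gene_id, query_gene),
        annotations.co_expressed(candidate.gene_id, query_gene),
        annotations.co_localized(candidate.gene_id, query_gene),
        candidate.gene_id in annotations.essential,
    )


def rank_candidates(candidates: list[GeneModel], query_gene: str,
                    annotations: AnnotationSet,
                    region: QTLRegion | None = None,
                    all_genes: list[GeneModel] | None = None
                    ) -> list[PriorityScore]:
    """Rank candidates lexicographically on the priority ladder.

    Ties after the full tier vector break by genomic distance to the region
    peak, then by gene id. Known general modifiers located in the region are
    appended with ``manual=True`` even when their frequency change did not
    reach the candidate window.
    """
    peak = region.peak_pos if region is not None else 0

    def distance(g: GeneModel) -> int:
        if region is None:
            return 0
        if g.start <= peak <= g.end:
            return 0
        return min(abs(g.start - peak), abs(g.end - peak))

    entries = [(g, tier_vector(g, query_gene, annotations), False)
               for g in candidates]
    present = {g.gene_id for g in candidates}
    if region is not None and all_genes is not None:
        for g in all_genes:
            if g.gene_id in annotations.known_general_modifiers and \
                    g.gene_id not in present and g.chrom == region.chrom and \
                    g.start <= region.end and g.end >= region.start:
                entries.append((g, tier_vector(g, query_gene, annotations), True))
    entries.sort(key=lambda e: (tuple(not b for b in e[1]), distance(e[0]),
                                e[0].gene_id))
    return [PriorityScore(g.gene_id, tuple(tv), rank + 1, manual, distance(g))
            for rank, (g, tv, manual) in enumerate(entries)]


def classify_gof_lof(evidence: InteractionEvidence) -> str:
    """Gain/loss-of-function call for a validated suppressor allele.

    Deletion of the suppressor exacerbating the query defect while its
    overexpression suppresses it implies the wild allele acts by gain of
    function; deletion itself suppressing implies loss of function.
    """
    if evidence.deletion_interaction == "suppresses":
        return "loss_of_function"
    if evidence.deletion_interaction == "exacerbates" and \
            evidence.overexpression_interaction == "suppresses":
        return "gain_of_function"
    return "inconclusive"
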