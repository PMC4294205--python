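"""Single-category genomic-context assignment of binding sites.

Each CLIP cluster is mapped to exactly one of eight categories by a fixed
priority order (CDS > 3'UTR > 5'UTR > lncRNA > pseudogene > sncRNA > intron
> intergenic): among all derived features the site overlaps by at least one
base, the highest-priority category wins.  Ties within the winning category
go to the feature with the largest overlap, then lexicographically smallest
gene_id.  A site overlapping nothing is intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .genome import (
    ALL_CATEGORIES,
    CATEGORY_PRIORITY,
    AnnotationSet,
    BindingSite,
    overlap_length,
)

logger = logging.getLogger(__name__)

_RANK = {cat: i for i, cat in enumerate(CATEGORY_PRIORITY)}


@dataclass(frozen=True)
class ContextCall:
    site: BindingSite
    category: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in ALL_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.gene_id is None) != (self.category == "intergenic"):
            raise ValueError("gene_id must be present iff category != intergenic")


@dataclass
class ContextDistribution:
    rbp: str
    counts: dict[str, int]
    fractions: dict[str, float]
    flagged_empty: bool = False


def assign_feature(
    site: BindingSite, ann: AnnotationSet, same_strand: bool = True
) -> ContextCall:
    """Classify one binding site by the category priority order."""
    hits = ann.query_overlaps(site.interval, same_strand=same_strand)
    best = None
    best_key = None
    for feat in hits:
        ov = overlap_length(site.interval, feat.interval)
        if ov <= 0:
            continue
        key = (_RANK[feat.category], -ov, feat.gene_id)
        if best_key is None or key < best_key:
            best_key = key
            best = feat
    if best is None:
        return ContextCall(site, "intergenic", None)
    return ContextCall(site, best.category, best.gene_id)


def context_distribution(
    sites: Iterable[BindingSite],
    ann: AnnotationSet,
    rbp: Optional[str] = None,
    same_strand: bool = True,
    by_base: bool = False,
) -> ContextDistribution:
    """Tally category calls for one RBP's sites.

    With ``by_base`` each site contributes its length in bases rather than a
    single count (the category is still the site-level priority call).
    """
    sites = list(sites)
    name = rbp if rbp is not None else (sites[0].rbp if sites else "")
    counts = {cat: 0 for cat in ALL_CATEGORIES}
    for s in sites:
        call = assign_feature(s, ann, same_strand=same_strand)
        counts[call.category] += s.interval.length() if by_base else 1
    total = sum(counts.values())
    if total == 0:
        logger.warning("context_distribution: no sites for RBP %r", name)
        return ContextDistribution(name, counts, {c: 0.0 for c in counts}, True)
    fractions = {c: n / total for c, n in counts.items()}
    return ContextDistribution(name, counts, fractions)
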