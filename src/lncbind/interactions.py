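"""RBP-lncRNA interaction calling, co-binding detection and motif scanning.

An interaction is called at gene level: an RBP interacts with a lncRNA gene
iff at least one of its CLIP clusters overlaps (>= 1 bp, strand-aware by
default) at least one exon of at least one transcript of that gene.
Intronic-only overlap never qualifies.  Shared ("identical") binding sites
of several RBPs are reported as maximal regions jointly covered by the
required number of distinct RBPs, with a Jaccard statistic so callers can
impose stricter identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .genome import (
    AnnotationSet,
    BindingSite,
    GenomicInterval,
    IntervalIndex,
    overlap_length,
    strands_compatible,
)


@dataclass
class Interaction:
    rbp: str
    gene_id: str
    gene_symbol: str
    sites: list[BindingSite]
    transcript_ids: set[str] = field(default_factory=set)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_experiments(self) -> int:
        return len({s.experiment_id for s in self.sites})


def call_interactions(
    sites_by_rbp: Mapping[str, Iterable[BindingSite]],
    ann: AnnotationSet,
    same_strand: bool = True,
) -> list[Interaction]:
    """Exon-level overlap of each RBP's sites against lncRNA genes.

    ``ann`` should already have coding-overlapping lncRNAs filtered out
    (see :func:`lncbind.genome.filter_lncrnas`).
    """
    exon_index = IntervalIndex()
    for g in ann.genes_by_biotype("lncRNA"):
        for t in g.transcripts:
            for e in t.exons:
                exon_index.add(e, (g.gene_id, g.gene_symbol, t.transcript_id))

    found: dict[tuple[str, str], Interaction] = {}
    for rbp in sorted(sites_by_rbp):
        for site in sites_by_rbp[rbp]:
            hits = exon_index.query(site.interval, same_strand=same_strand)
            genes_hit = {}
            for _, (gid, gsym, tid) in hits:
                genes_hit.setdefault(gid, (gsym, set()))[1].add(tid)
            for gid, (gsym, tids) in genes_hit.items():
                key = (rbp, gid)
                if key not in found:
                    found[key] = Interaction(rbp, gid, gsym, [])
                if site not in found[key].sites:
                    found[key].sites.append(site)
                found[key].transcript_ids |= tids
    return [found[k] for k in sorted(found)]


def rbp_count_per_lncrna(
    interactions: Iterable[Interaction],
    ann: Optional[AnnotationSet] = None,
) -> tuple[dict[str, int], dict[int, int]]:
    """Distinct RBPs per lncRNA gene, plus a histogram over those counts.

    When ``ann`` is given, lncRNA genes with no interaction appear with
    count 0 (the denominator of a "fraction bound" statistic).
    """
    rbps_per_gene: dict[str, set[str]] = {}
    for it in interactions:
        rbps_per_gene.setdefault(it.gene_id, set()).add(it.rbp)
    counts = {g: len(s) for g, s in rbps_per_gene.items()}
    if ann is not None:
        for g in ann.genes_by_biotype("lncRNA"):
            counts.setdefault(g.gene_id, 0)
    histogram: dict[int, int] = {}
    for n in counts.values():
        histogram[n] = histogram.get(n, 0) + 1
    return counts, histogram


@dataclass
class SharedSite:
    region: GenomicInterval
    rbps: frozenset[str]
    jaccard: float
    contributing: list[BindingSite] = field(default_factory=list)


def shared_sites(
    sites_by_rbp: Mapping[str, Iterable[BindingSite]],
    min_overlap: int = 1,
    min_rbps: int = 2,
) -> list[SharedSite]:
    """Maximal regions jointly covered by >= ``min_rbps`` distinct RBPs.

    A sweep over site boundaries partitions each chromosome into segments of
    constant covering-RBP set; qualifying segments (set size >= min_rbps,
    length >= min_overlap) are reported once.  The Jaccard value is the
    minimum intersection/union ratio over cross-RBP pairs of contributing
    sites, i.e. a lower bound on how "identical" the shared site is.
    """
    if min_overlap < 1 or min_rbps < 2:
        raise ValueError("need min_overlap >= 1 and min_rbps >= 2")
    all_sites: list[BindingSite] = []
    for rbp in sites_by_rbp:
        for s in sites_by_rbp[rbp]:
            if s.rbp != rbp:
                s = BindingSite(rbp, s.interval, s.experiment_id, s.cell_type, s.score)
            all_sites.append(s)

    by_chrom: dict[str, list[BindingSite]] = {}
    for s in all_sites:
        by_chrom.setdefault(s.interval.chrom, []).append(s)

    out: list[SharedSite] = []
    for chrom in sorted(by_chrom):
        sites = by_chrom[chrom]
        bounds = sorted({s.interval.start for s in sites} | {s.interval.end for s in sites})
        prev_rbps: Optional[frozenset[str]] = None
        seg_start = None
        for a, b in zip(bounds, bounds[1:]):
            covering = [
                s for s in sites if s.interval.start <= a and s.interval.end >= b
            ]
            rbps = frozenset(s.rbp for s in covering)
            if rbps != prev_rbps:
                if prev_rbps is not None and len(prev_rbps) >= min_rbps:
                    out.extend(
                        _emit_segment(chrom, seg_start, a, sites, min_overlap, min_rbps)
                    )
                prev_rbps = rbps
                seg_start = a
            if b == bounds[-1] and len(rbps) >= min_rbps:
                out.extend(
                    _emit_segment(chrom, seg_start, b, sites, min_overlap, min_rbps)
                )
    return out


def _emit_segment(
    chrom: str,
    start: int,
    end: int,
    sites: list[BindingSite],
    min_overlap: int,
    min_rbps: int,
) -> list[SharedSite]:
    if end - start < min_overlap:
        return []
    covering = [
        s for s in sites if s.interval.start <= start and s.interval.end >= end
    ]
    rbps = frozenset(s.rbp for s in covering)
    if len(rbps) < min_rbps:
        return []
    # strand consistency: require compatible strands among contributors
    strands = {s.interval.strand for s in covering if s.interval.strand != "."}
    if len(strands) > 1:
        return []
    strand = strands.pop() if strands else "."
    jac = 1.0
    for i, a in enumerate(covering):
        for b in covering[i + 1 :]:
            if a.rbp == b.rbp:
                continue
            inter = overlap_length(a.interval, b.interval)
            union = a.interval.length() + b.interval.length() - inter
            jac = min(jac, inter / union)
    region = GenomicInterval(chrom, start, end, strand)
    return [SharedSite(region, rbps, jac, covering)]


# ---------------------------------------------------------------------------
# IUPAC motif scanning
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "TU", "U": "TU",
    "R": "AG", "Y": "CTU", "S": "CG", "W": "ATU",
    "K": "GTU", "M": "AC", "B": "CGTU", "D": "AGTU",
    "H": "ACTU", "V": "ACG", "N": "ACGTU",
}


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    matched: str


def iupac_to_regex(motif: str) -> str:
    """Translate an IUPAC degenerate motif to a regex character-class string."""
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
        allowed = IUPAC[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return "".join(parts)


def scan_motif(seq: str, motif: str, sequence_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) IUPAC motif matches on the given strand.

    Case-insensitive; T and U are equivalent on both sides.
    """
    pattern = re.compile(f"(?=({iupac_to_regex(motif)}))", re.IGNORECASE)
    seq_u = seq.upper()
    return [
        MotifHit(sequence_id, m.start(), m.group(1))
        for m in pattern.finditer(seq_u)
    ]
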