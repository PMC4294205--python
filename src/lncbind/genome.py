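"""Core genomic data model: intervals, transcripts, annotation sets, GTF/BED I/O.

All internal coordinates are 0-based half-open (BED convention); GTF's
1-based closed coordinates are converted at the file boundary.  Strands are
"+", "-" or "." (unknown); "." acts as a wildcard in strand-aware queries.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "sncRNA", "other")

#: Default mapping of annotation-source biotype strings to the five
#: canonical classes.  GENCODE/Ensembl vocabulary varies by release, so this
#: table is user-overridable in :func:`read_gtf`.
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "antisense_RNA": "lncRNA",
    "processed_transcript": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "3prime_overlapping_ncRNA": "lncRNA",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
    "unitary_pseudogene": "pseudogene",
    "polymorphic_pseudogene": "pseudogene",
    "miRNA": "sncRNA",
    "snoRNA": "sncRNA",
    "snRNA": "sncRNA",
    "scaRNA": "sncRNA",
    "sRNA": "sncRNA",
    "misc_RNA": "sncRNA",
    "rRNA": "sncRNA",
    "tRNA": "sncRNA",
    "Mt_tRNA": "sncRNA",
    "Mt_rRNA": "sncRNA",
    "vaultRNA": "sncRNA",
}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chrom/start/end/strand span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def strands_compatible(a: str, b: str) -> bool:
    """True unless both strands are known and opposite ('.' is a wildcard)."""
    return a == "." or b == "." or a == b


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered exon chain with optional CDS span.

    ``cds`` is a genomic (start, end) span; UTRs are derived from it at
    feature-derivation time, never stored.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    biotype: str
    exons: tuple[GenomicInterval, ...]
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple "
                "chromosomes or strands"
            )
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a} and {b}"
                )
        if self.cds is not None:
            lo, hi = self.cds
            if not (self.span.start <= lo < hi <= self.span.end):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS {self.cds} outside "
                    "transcript span"
                )
            if self.biotype != "protein_coding":
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS on non-coding "
                    f"biotype {self.biotype}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons (may be empty for single-exon)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass(frozen=True)
class GeneModel:
    """Gene-level aggregation of one or more transcripts."""

    gene_id: str
    biotype: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        if any(t.gene_id != self.gene_id for t in self.transcripts):
            raise ValueError(f"gene {self.gene_id}: transcript gene_id mismatch")

    @property
    def gene_symbol(self) -> str:
        return self.transcripts[0].gene_symbol

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(
            self.transcripts[0].chrom, start, end, self.transcripts[0].strand
        )


@dataclass(frozen=True)
class BindingSite:
    """One CLIP cluster attributed to an RBP and experiment."""

    rbp: str
    interval: GenomicInterval
    experiment_id: str = ""
    cell_type: Optional[str] = None
    score: Optional[float] = None


# Categories a binding site or SNP can fall into, in the priority order used
# for single-category assignment (highest first, intergenic = no overlap).
CATEGORY_PRIORITY = (
    "CDS",
    "3UTR",
    "5UTR",
    "lncRNA",
    "pseudogene",
    "sncRNA",
    "intron",
)
ALL_CATEGORIES = CATEGORY_PRIORITY + ("intergenic",)


@dataclass(frozen=True)
class Feature:
    """A derived transcript feature carried by the annotation index."""

    interval: GenomicInterval
    category: str
    gene_id: str
    transcript_id: str


@dataclass(frozen=True)
class SpliceSite:
    """The 2 intronic nt adjacent to an exon-intron junction."""

    interval: GenomicInterval
    role: str  # "donor" or "acceptor"
    transcript_id: str = ""
    gene_id: str = ""
    flagged: bool = False  # intron < 4 bp: donor/acceptor windows overlap


def derive_features(t: TranscriptModel) -> list[tuple[GenomicInterval, str]]:
    """Partition a transcript span into non-overlapping category intervals.

    Coding transcripts split exonic bases into 5'UTR / CDS / 3'UTR relative
    to the CDS span read in transcript orientation; non-coding transcripts
    label exonic bases with their biotype.  Inter-exon gaps are introns.
    A coding transcript without a CDS is labelled all-CDS with a warning.
    """
    out: list[tuple[GenomicInterval, str]] = []
    strand = t.strand
    if t.biotype == "protein_coding":
        cds = t.cds
        if cds is None:
            logger.warning(
                "protein_coding transcript %s has no CDS; labelling exons CDS",
                t.transcript_id,
            )
            for e in t.exons:
                out.append((e, "CDS"))
        else:
            lo, hi = cds
            # genomic left of CDS is 5'UTR on +, 3'UTR on -
            left_label = "5UTR" if strand != "-" else "3UTR"
            right_label = "3UTR" if strand != "-" else "5UTR"
            for e in t.exons:
                if e.end <= lo:
                    out.append((e, left_label))
                    continue
                if e.start >= hi:
                    out.append((e, right_label))
                    continue
                if e.start < lo:
                    out.append(
                        (GenomicInterval(e.chrom, e.start, lo, strand), left_label)
                    )
                a, b = max(e.start, lo), min(e.end, hi)
                out.append((GenomicInterval(e.chrom, a, b, strand), "CDS"))
                if e.end > hi:
                    out.append(
                        (GenomicInterval(e.chrom, hi, e.end, strand), right_label)
                    )
    else:
        label = t.biotype if t.biotype in ("lncRNA", "pseudogene", "sncRNA") else "lncRNA"
        if t.biotype == "other":
            label = "sncRNA"  # conservative: misc small RNAs
        for e in t.exons:
            out.append((e, label))
    for i in t.introns():
        out.append((i, "intron"))
    out.sort(key=lambda fc: fc[0].start)
    return out


def extract_splice_sites(t: TranscriptModel) -> list[tuple[GenomicInterval, str]]:
    """Per intron, the two 2-nt intronic windows flanking the exons.

    The window adjacent to the exon upstream in transcript orientation is the
    donor; the one adjacent to the downstream exon is the acceptor.  On the
    minus strand the genomic-left window is therefore the acceptor.
    Introns shorter than 4 bp still yield both windows (they overlap).
    """
    sites: list[tuple[GenomicInterval, str]] = []
    for intron in t.introns():
        left = GenomicInterval(
            t.chrom, intron.start, min(intron.start + 2, intron.end), t.strand
        )
        right = GenomicInterval(
            t.chrom, max(intron.end - 2, intron.start), intron.end, t.strand
        )
        if intron.length() < 4:
            logger.warning(
                "transcript %s: intron %s shorter than 4 bp; splice-site "
                "windows overlap",
                t.transcript_id,
                intron,
            )
        if t.strand == "-":
            sites.append((left, "acceptor"))
            sites.append((right, "donor"))
        else:
            sites.append((left, "donor"))
            sites.append((right, "acceptor"))
    return sites


class IntervalIndex:
    """Strand-aware per-chromosome interval index over arbitrary payloads."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, interval: GenomicInterval, payload) -> None:
        self._trees.setdefault(interval.chrom, IntervalTree()).addi(
            interval.start, interval.end, (interval, payload)
        )

    def query(
        self, q: GenomicInterval, same_strand: bool = True
    ) -> list[tuple[GenomicInterval, object]]:
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(q.start, q.end):
            interval, payload = iv.data
            if same_strand and not strands_compatible(q.strand, interval.strand):
                continue
            hits.append((interval, payload))
        hits.sort(key=lambda h: (h[0].start, h[0].end))
        return hits

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


class AnnotationSet:
    """A collection of genes plus interval indexes over derived features.

    Feature, transcript-span and splice-site indexes are built lazily and
    invalidated never (the object is treated as immutable once constructed).
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._feature_index: Optional[IntervalIndex] = None
        self._splice_sites: Optional[list[SpliceSite]] = None
        self._splice_index: Optional[IntervalIndex] = None

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationSet) and self.genes == other.genes

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self.genes.values():
            yield from g.transcripts

    def genes_by_biotype(self, biotype: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.biotype == biotype]

    @property
    def feature_index(self) -> IntervalIndex:
        if self._feature_index is None:
            idx = IntervalIndex()
            for t in self.transcripts():
                for interval, category in derive_features(t):
                    idx.add(
                        interval,
                        Feature(interval, category, t.gene_id, t.transcript_id),
                    )
            self._feature_index = idx
        return self._feature_index

    def query_overlaps(
        self, q: GenomicInterval, same_strand: bool = True
    ) -> list[Feature]:
        """All derived features overlapping ``q`` by >= 1 bp."""
        return [payload for _, payload in self.feature_index.query(q, same_strand)]

    def splice_sites(self) -> list[SpliceSite]:
        if self._splice_sites is None:
            out = []
            for t in self.transcripts():
                for interval, role in extract_splice_sites(t):
                    out.append(
                        SpliceSite(
                            interval,
                            role,
                            t.transcript_id,
                            t.gene_id,
                            flagged=interval.length() < 2
                            or any(i.length() < 4 for i in t.introns()),
                        )
                    )
            self._splice_sites = out
        return self._splice_sites

    @property
    def splice_index(self) -> IntervalIndex:
        if self._splice_index is None:
            idx = IntervalIndex()
            for ss in self.splice_sites():
                idx.add(ss.interval, ss)
            self._splice_index = idx
        return self._splice_index


def query_overlaps(index, q: GenomicInterval, same_strand: bool = True):
    """Overlap query against an :class:`AnnotationSet` or :class:`IntervalIndex`."""
    if isinstance(index, AnnotationSet):
        return index.query_overlaps(q, same_strand)
    return index.query(q, same_strand)


def build_site_index(sites: Iterable[BindingSite]) -> IntervalIndex:
    idx = IntervalIndex()
    for s in sites:
        idx.add(s.interval, s)
    return idx


def filter_lncrnas(ann: AnnotationSet, policy: str = "same_strand") -> AnnotationSet:
    """Drop lncRNA transcripts whose span overlaps a protein-coding gene span.

    ``policy`` is ``same_strand`` (only same-strand overlap removes; '.'
    matches either) or ``any_strand``.  Genes left without transcripts are
    dropped.  Idempotent.
    """
    if policy not in ("same_strand", "any_strand"):
        raise ValueError(f"unknown policy {policy!r}")
    coding_index = IntervalIndex()
    for g in ann.genes_by_biotype("protein_coding"):
        coding_index.add(g.span, g.gene_id)

    kept: list[GeneModel] = []
    n_removed = 0
    for g in ann.genes.values():
        if g.biotype != "lncRNA":
            kept.append(g)
            continue
        surviving = []
        for t in g.transcripts:
            hits = coding_index.query(t.span, same_strand=(policy == "same_strand"))
            if hits:
                n_removed += 1
            else:
                surviving.append(t)
        if surviving:
            kept.append(GeneModel(g.gene_id, g.biotype, tuple(surviving)))
    logger.info("filter_lncrnas: removed %d lncRNA transcripts (%s)", n_removed, policy)
    return AnnotationSet(kept)


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl/GENCODE dialect: exon and CDS feature lines; attributes
# gene_id / transcript_id / gene_type or gene_biotype / gene_name).
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


def _parse_attrs(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path, biotype_map: Optional[dict[str, str]] = None) -> AnnotationSet:
    """Assemble an AnnotationSet from GTF exon and CDS lines.

    GTF coordinates (1-based, closed) are converted to 0-based half-open.
    Unknown source biotypes map to "other".  Raises :class:`GtfParseError`
    naming the offending line number on malformed input.
    """
    bmap = DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feat, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feat not in ("exon", "CDS"):
                continue
            try:
                start = int(start_s) - 1  # 1-based closed -> 0-based half-open
                end = int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start < 0 or end <= start:
                raise GtfParseError(f"{path}: line {lineno}: invalid span {start_s}-{end_s}")
            attrs = _parse_attrs(attr_s)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"{path}: line {lineno}: missing gene_id/transcript_id"
                )
            tid = attrs["transcript_id"]
            if feat == "exon":
                exons.setdefault(tid, []).append(
                    GenomicInterval(chrom, start, end, strand)
                )
                meta.setdefault(tid, attrs)
            else:
                cds.setdefault(tid, []).append((start, end))

    by_gene: dict[str, list[TranscriptModel]] = {}
    n_skipped = 0
    for tid, attrs in meta.items():
        ex = exons.get(tid, [])
        if not ex:
            n_skipped += 1
            continue
        raw_bt = attrs.get("gene_type") or attrs.get("gene_biotype") or ""
        biotype = bmap.get(raw_bt, "other")
        cds_span = None
        if tid in cds:
            cds_span = (min(s for s, _ in cds[tid]), max(e for _, e in cds[tid]))
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=attrs["gene_id"],
            gene_symbol=attrs.get("gene_name", attrs["gene_id"]),
            biotype=biotype,
            exons=tuple(ex),
            cds=cds_span if biotype == "protein_coding" else None,
        )
        by_gene.setdefault(t.gene_id, []).append(t)
    if n_skipped:
        logger.warning("read_gtf: skipped %d transcripts with zero exons", n_skipped)

    genes = []
    for gid, ts in by_gene.items():
        ts.sort(key=lambda t: t.transcript_id)
        genes.append(GeneModel(gid, ts[0].biotype, tuple(ts)))
    genes.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    return AnnotationSet(genes)


def write_gtf(ann: AnnotationSet, path, source: str = "lncbind") -> None:
    """Emit exon and CDS lines, sorted, converting back to 1-based closed."""
    lines = []
    for g in sorted(ann.genes.values(), key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
        for t in g.transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_type "{_export_biotype(t.biotype)}"; gene_name "{t.gene_symbol}";'
            )
            for e in t.exons:
                lines.append(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}"
                )
            if t.cds is not None:
                lo, hi = t.cds
                for e in t.exons:
                    a, b = max(e.start, lo), min(e.end, hi)
                    if a < b:
                        lines.append(
                            f"{e.chrom}\t{source}\tCDS\t{a + 1}\t{b}\t.\t"
                            f"{e.strand}\t.\t{attrs}"
                        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _export_biotype(biotype: str) -> str:
    # canonical classes are valid GENCODE-style strings except sncRNA
    return {"sncRNA": "snoRNA", "other": "misc_RNA"}.get(biotype, biotype)


# ---------------------------------------------------------------------------
# BED I/O (BED3/BED6)
# ---------------------------------------------------------------------------


def read_bed(path, rbp: str = "", experiment_id: str = "") -> list[BindingSite]:
    """Read BED3/BED6 binding clusters into :class:`BindingSite` records.

    BED6 strand and score are preserved; BED3 records get strand ".".
    Records with start >= end are rejected and counted in the log.
    """
    sites: list[BindingSite] = []
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end or start < 0:
                n_rejected += 1
                continue
            strand = fields[5] if len(fields) >= 6 else "."
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            sites.append(
                BindingSite(
                    rbp=rbp or (fields[3] if len(fields) >= 4 else ""),
                    interval=GenomicInterval(chrom, start, end, strand),
                    experiment_id=experiment_id,
                    score=score,
                )
            )
    if n_rejected:
        logger.warning("read_bed %s: rejected %d malformed records", path, n_rejected)
    return sites


def _fmt_score(score: Optional[float]) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(sites: Iterable[BindingSite], path) -> None:
    """Emit sorted BED6 (name = rbp, score, strand)."""
    rows = sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    with open(path, "w") as fh:
        for s in rows:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.rbp or '.'}\t"
                f"{_fmt_score(s.score)}\t{iv.strand}\n"
            )
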