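"""Core genomic model: coordinates, I/O round-trips, overlap engine,
feature derivation, lncRNA filtering and splice sites."""

import numpy as np
import pytest

from lncbind.genome import (
    AnnotationSet,
    BindingSite,
    GeneModel,
    GenomicInterval,
    GtfParseError,
    IntervalIndex,
    TranscriptModel,
    derive_features,
    extract_splice_sites,
    filter_lncrnas,
    overlap_length,
    query_overlaps,
    read_bed,
    read_gtf,
    write_bed,
    write_gtf,
)

from conftest import random_transcript


# ---------------------------------------------------------------------------
# intervals and overlap
# ---------------------------------------------------------------------------


def test_interval_invariants():
    iv = GenomicInterval("chr1", 100, 150, "+")
    assert iv.length() == 50
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 150, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (("chr1", 100, 150), ("chr1", 140, 160), 10),
        (("chr1", 100, 150), ("chr2", 100, 150), 0),
        (("chr1", 100, 150), ("chr1", 150, 200), 0),
        (("chr1", 0, 10), ("chr1", 0, 10), 10),
    ],
)
def test_overlap_length_examples(a, b, expected):
    ia, ib = GenomicInterval(*a), GenomicInterval(*b)
    assert overlap_length(ia, ib) == expected
    assert overlap_length(ib, ia) == expected  # symmetric


def test_overlap_length_matches_per_base_counting(rng):
    """Random pairs agree with brute-force membership counting."""
    for _ in range(200):
        a = sorted(rng.integers(0, 500, size=2))
        b = sorted(rng.integers(0, 500, size=2))
        if a[0] == a[1] or b[0] == b[1]:
            continue
        ia = GenomicInterval("chr1", int(a[0]), int(a[1]))
        ib = GenomicInterval("chr1", int(b[0]), int(b[1]))
        brute = sum(1 for x in range(a[0], a[1]) if b[0] <= x < b[1])
        assert overlap_length(ia, ib) == brute


# ---------------------------------------------------------------------------
# interval index vs exhaustive scan
# ---------------------------------------------------------------------------


def test_query_identity_and_gap():
    idx = IntervalIndex()
    exon = GenomicInterval("chr1", 100, 200, "+")
    idx.add(exon, "exon1")
    assert [p for _, p in idx.query(exon)] == ["exon1"]
    assert idx.query(GenomicInterval("chr1", 250, 260, "+")) == []
    assert idx.query(GenomicInterval("chrX", 100, 200, "+")) == []


def test_query_strand_semantics():
    idx = IntervalIndex()
    idx.add(GenomicInterval("chr1", 0, 100, "+"), "plus")
    idx.add(GenomicInterval("chr1", 0, 100, "-"), "minus")
    idx.add(GenomicInterval("chr1", 0, 100, "."), "dot")
    q = GenomicInterval("chr1", 50, 60, "+")
    assert {p for _, p in idx.query(q, same_strand=True)} == {"plus", "dot"}
    assert {p for _, p in idx.query(q, same_strand=False)} == {"plus", "minus", "dot"}
    qdot = GenomicInterval("chr1", 50, 60, ".")
    assert {p for _, p in idx.query(qdot, same_strand=True)} == {"plus", "minus", "dot"}


def test_query_overlaps_equals_exhaustive_scan(rng):
    """500 random queries against 2000 random features match an O(n^2) scan."""
    features = []
    idx = IntervalIndex()
    for i in range(2000):
        chrom = f"chr{int(rng.integers(1, 4))}"
        start = int(rng.integers(0, 100_000))
        end = start + int(rng.integers(1, 500))
        strand = ["+", "-", "."][int(rng.integers(0, 3))]
        iv = GenomicInterval(chrom, start, end, strand)
        features.append((iv, i))
        idx.add(iv, i)
    for _ in range(500):
        chrom = f"chr{int(rng.integers(1, 4))}"
        start = int(rng.integers(0, 100_000))
        q = GenomicInterval(chrom, start, start + int(rng.integers(1, 400)),
                            ["+", "-", "."][int(rng.integers(0, 3))])
        got = {p for _, p in idx.query(q, same_strand=True)}
        brute = {
            i for iv, i in features
            if overlap_length(iv, q) > 0
            and (q.strand == "." or iv.strand == "." or q.strand == iv.strand)
        }
        assert got == brute


# ---------------------------------------------------------------------------
# feature derivation
# ---------------------------------------------------------------------------


def _per_base_labels(t):
    """Independent per-base classification oracle."""
    labels = {}
    exonic = set()
    for e in t.exons:
        exonic.update(range(e.start, e.end))
    span = t.span
    for x in range(span.start, span.end):
        if x not in exonic:
            labels[x] = "intron"
        elif t.biotype == "protein_coding" and t.cds is not None:
            lo, hi = t.cds
            if lo <= x < hi:
                labels[x] = "CDS"
            elif x < lo:
                labels[x] = "5UTR" if t.strand != "-" else "3UTR"
            else:
                labels[x] = "3UTR" if t.strand != "-" else "5UTR"
        elif t.biotype == "protein_coding":
            labels[x] = "CDS"
        else:
            labels[x] = t.biotype if t.biotype != "other" else "sncRNA"
    return labels


def test_derive_features_plus_strand_utrs():
    t = TranscriptModel(
        "t", "g", "G", "protein_coding",
        (GenomicInterval("chr1", 0, 100, "+"), GenomicInterval("chr1", 200, 300, "+")),
        cds=(50, 250),
    )
    feats = {(iv.start, iv.end): cat for iv, cat in derive_features(t)}
    assert feats == {
        (0, 50): "5UTR", (50, 100): "CDS", (100, 200): "intron",
        (200, 250): "CDS", (250, 300): "3UTR",
    }


def test_derive_features_minus_strand_swaps_utrs():
    t = TranscriptModel(
        "t", "g", "G", "protein_coding",
        (GenomicInterval("chr1", 0, 100, "-"), GenomicInterval("chr1", 200, 300, "-")),
        cds=(50, 250),
    )
    feats = {(iv.start, iv.end): cat for iv, cat in derive_features(t)}
    assert feats[(0, 50)] == "3UTR"
    assert feats[(250, 300)] == "5UTR"


def test_single_exon_lncrna_has_no_intron():
    t = TranscriptModel("t", "g", "G", "lncRNA",
                        (GenomicInterval("chr1", 100, 200, "+"),))
    feats = derive_features(t)
    assert len(feats) == 1 and feats[0][1] == "lncRNA"


def test_derive_features_matches_per_base_oracle(rng):
    for i in range(60):
        t = random_transcript(rng, coding=(i % 2 == 0))
        expected = _per_base_labels(t)
        got = {}
        for iv, cat in derive_features(t):
            for x in range(iv.start, iv.end):
                assert x not in got, "features overlap"
                got[x] = cat
        assert got == expected  # also proves the partition tiles the span


# ---------------------------------------------------------------------------
# splice sites
# ---------------------------------------------------------------------------


def test_splice_sites_plus_strand():
    t = TranscriptModel(
        "t", "g", "G", "lncRNA",
        (GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 300, 400, "+")),
    )
    sites = extract_splice_sites(t)
    assert ((sites[0][0].start, sites[0][0].end), sites[0][1]) == ((200, 202), "donor")
    assert ((sites[1][0].start, sites[1][0].end), sites[1][1]) == ((298, 300), "acceptor")


def test_splice_sites_minus_strand_roles_swap():
    t = TranscriptModel(
        "t", "g", "G", "lncRNA",
        (GenomicInterval("chr1", 100, 200, "-"), GenomicInterval("chr1", 300, 400, "-")),
    )
    roles = {(iv.start, iv.end): role for iv, role in extract_splice_sites(t)}
    assert roles == {(200, 202): "acceptor", (298, 300): "donor"}


def test_splice_sites_single_exon_empty():
    t = TranscriptModel("t", "g", "G", "lncRNA",
                        (GenomicInterval("chr1", 100, 200, "+"),))
    assert extract_splice_sites(t) == []


def test_splice_sites_length_and_count_property(rng):
    for _ in range(40):
        t = random_transcript(rng)
        sites = extract_splice_sites(t)
        assert len(sites) == 2 * (len(t.exons) - 1)
        introns = t.introns()
        for iv, role in sites:
            assert role in ("donor", "acceptor")
            assert iv.length() == 2
            assert any(i.start <= iv.start and iv.end <= i.end for i in introns)


def test_short_intron_windows_still_emitted():
    t = TranscriptModel(
        "t", "g", "G", "lncRNA",
        (GenomicInterval("chr1", 0, 100, "+"), GenomicInterval("chr1", 103, 200, "+")),
    )
    sites = extract_splice_sites(t)
    assert len(sites) == 2
    assert {(iv.start, iv.end) for iv, _ in sites} == {(100, 102), (101, 103)}


# ---------------------------------------------------------------------------
# lncRNA filter
# ---------------------------------------------------------------------------


def _mini_annotation():
    pc_ex = (GenomicInterval("chr1", 1000, 1400, "+"), GenomicInterval("chr1", 1800, 2200, "+"))
    pc = TranscriptModel("pc_T1", "PC1", "PC1", "protein_coding", pc_ex, (1100, 2100))
    inside = TranscriptModel("li_T1", "LI1", "LI1", "lncRNA",
                             (GenomicInterval("chr1", 1500, 1700, "+"),))
    anti = TranscriptModel("la_T1", "LA1", "LA1", "lncRNA",
                           (GenomicInterval("chr1", 1450, 1750, "-"),))
    far = TranscriptModel("lf_T1", "LF1", "LF1", "lncRNA",
                          (GenomicInterval("chr2", 100, 500, "+"),))
    return AnnotationSet([
        GeneModel("PC1", "protein_coding", (pc,)),
        GeneModel("LI1", "lncRNA", (inside,)),
        GeneModel("LA1", "lncRNA", (anti,)),
        GeneModel("LF1", "lncRNA", (far,)),
    ])


def test_filter_policies_and_strand():
    ann = _mini_annotation()
    same = filter_lncrnas(ann, "same_strand")
    assert "LI1" not in same.genes       # same-strand overlap: removed
    assert "LA1" in same.genes           # antisense: retained under same_strand
    assert "LF1" in same.genes           # different chromosome: retained
    any_ = filter_lncrnas(ann, "any_strand")
    assert "LI1" not in any_.genes
    assert "LA1" not in any_.genes       # removed under any_strand
    assert "LF1" in any_.genes
    assert "PC1" in same.genes and "PC1" in any_.genes


def test_filter_is_idempotent():
    ann = _mini_annotation()
    once = filter_lncrnas(ann, "same_strand")
    twice = filter_lncrnas(once, "same_strand")
    assert once == twice


# ---------------------------------------------------------------------------
# GTF / BED I/O
# ---------------------------------------------------------------------------


def test_gtf_coordinate_convention(tmp_path):
    gtf = tmp_path / "a.gtf"
    gtf.write_text(
        'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; gene_type "lncRNA";\n'
        'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; gene_type "lncRNA";\n'
    )
    ann = read_gtf(gtf)
    t = ann.genes["g1"].transcripts[0]
    assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]


def test_gtf_malformed_line_names_line_number(tmp_path):
    gtf = tmp_path / "bad.gtf"
    gtf.write_text("chr1\tonly\tthree\n")
    with pytest.raises(GtfParseError, match="line 1"):
        read_gtf(gtf)


def test_gtf_round_trip_on_synthetic_annotation(tmp_path, scenario):
    """read_gtf(write_gtf(A)) == A, and a second write is byte-identical."""
    p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
    write_gtf(scenario.annotation, p1)
    back = read_gtf(p1)
    assert back == scenario.annotation
    write_gtf(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_bed_parsing_examples(tmp_path):
    bed = tmp_path / "a.bed"
    bed.write_text("chr1\t100\t150\tsite1\t200\t+\nchr2\t5\t10\n")
    sites = read_bed(bed, rbp="HuR", experiment_id="e1")
    assert sites[0].interval == GenomicInterval("chr1", 100, 150, "+")
    assert sites[0].score == 200
    assert sites[1].interval.strand == "."


def test_bed_rejects_inverted_records(tmp_path):
    bed = tmp_path / "a.bed"
    bed.write_text("chr1\t150\t100\tbad\t0\t+\nchr1\t10\t20\tok\t1\t+\n")
    sites = read_bed(bed, rbp="X", experiment_id="e")
    assert len(sites) == 1


def test_bed_round_trip_1000_sites(tmp_path, rng):
    sites = []
    for _ in range(1000):
        start = int(rng.integers(0, 1_000_000))
        sites.append(
            BindingSite(
                "RBPX",
                GenomicInterval(f"chr{int(rng.integers(1, 5))}", start,
                                start + int(rng.integers(1, 200)),
                                ["+", "-"][int(rng.integers(0, 2))]),
                "expA",
                score=float(int(rng.integers(0, 1000))),
            )
        )
    p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
    write_bed(sites, p1)
    back = read_bed(p1, rbp="RBPX", experiment_id="expA")
    assert sorted(back, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end)) == sorted(
        sites, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end)
    )
    write_bed(back, p2)
    assert p1.read_bytes() == p2.read_bytes()
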