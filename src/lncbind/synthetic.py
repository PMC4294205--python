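"""Synthetic scenario generator with machine-readable planted ground truth.

Every pipeline input is generated from a single :class:`ScenarioConfig`
(deterministically, as a pure function of the config including its seed):

* a toy genome annotation exercising all eight context categories,
  including lncRNAs deliberately overlapping coding genes (to exercise the
  coding-overlap filter) and an antisense lncRNA (to exercise the strand
  policy);
* per-RBP binding-site sets realizing a planted per-category context mix
  and a planted RBP-lncRNA interaction set exactly;
* per-cohort expression matrices with planted Pearson correlations on the
  log2 scale (values are 2**z - 1 for bivariate-normal z, so the screen's
  default log2(x+1) transform recovers the planted correlation);
* diploid genotype panels whose haplotype frequencies realize planted
  pairwise r2 targets;
* SNP catalogs with planted placements (lncRNA exon / splice site / RBP
  binding site / intergenic), cross-catalog duplicates, rsID merge chains
  and deleted rsIDs.

Generators fail loudly when a planted target is infeasible rather than
silently approximating the truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .coexpression import ExpressionMatrix
from .genome import (
    AnnotationSet,
    BindingSite,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    derive_features,
    extract_splice_sites,
    filter_lncrnas,
    write_bed,
    write_gtf,
)
from .gwas import GenotypePanel, SnpRecord


@dataclass
class ScenarioConfig:
    """Everything the generators need; defaults give the standard scenario
    (~50 genes, 5 RBPs, 2 cohorts x 200 samples, 2 populations x 120
    diploids) sized for fast desk-scale runs."""

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 600_000), ("chr2", 600_000))
    n_coding_genes: int = 20
    n_lncrna_genes: int = 20
    n_pseudogenes: int = 4
    n_sncrna_genes: int = 4
    n_overlapping_lncrnas: int = 3  # same-strand coding-overlap casualties
    include_antisense_lncrna: bool = True
    site_length_range: tuple[int, int] = (20, 60)
    # (rbp, lncRNA gene id, number of exonic sites)
    planted_interactions: tuple[tuple[str, str, int], ...] = (
        ("RBP1", "LNC0001", 2),
        ("RBP1", "LNC0002", 1),
        ("RBP2", "LNC0002", 3),
        ("RBP3", "LNC0005", 1),
        ("RBP4", "LNC0007", 2),
    )
    # per-RBP planted context mix (category -> site count); "lncRNA" entries
    # create additional interactions on generator-chosen retained lncRNAs
    planted_context_mix: tuple[tuple[str, tuple[tuple[str, int], ...]], ...] = tuple(
        (
            rbp,
            (
                ("CDS", 3), ("3UTR", 2), ("5UTR", 2), ("lncRNA", 2),
                ("pseudogene", 1), ("sncRNA", 1), ("intron", 3), ("intergenic", 4),
            ),
        )
        for rbp in ("RBP1", "RBP2", "RBP3", "RBP4", "RBP5")
    )
    # cohort name -> sample count
    cohorts: tuple[tuple[str, int], ...] = (("cohortA", 200), ("cohortB", 200))
    # (rbp, lncrna, cohort, rho)
    planted_correlations: tuple[tuple[str, str, str, float], ...] = (
        ("RBP1", "LNC0001", "cohortA", 0.8),
        ("RBP2", "LNC0002", "cohortB", 0.5),
        ("RBP3", "LNC0005", "cohortA", -0.6),
    )
    n_null_expression_genes: int = 40
    expression_log_mean: float = 8.0
    expression_log_sd: float = 1.0
    # (rsid_a, rsid_b, population, target r2); loci exist in every panel but
    # are linked only in the named population
    planted_ld: tuple[tuple[str, str, str, float], ...] = (
        ("rs1000", "rs1001", "CEU", 0.8),
        ("rs2000", "rs2001", "CEU", 0.2),
        ("rs3000", "rs3001", "YRI", 0.9),
        ("rs4000", "rs4001", "YRI", 0.3),
    )
    populations: tuple[str, ...] = ("CEU", "YRI")
    n_diploids: int = 120
    ld_allele_freq: float = 0.5
    n_filler_loci: int = 6
    # (rsid, placement class)
    planted_snp_placements: tuple[tuple[str, str], ...] = (
        ("rs5000", "exon"), ("rs5001", "exon"), ("rs5002", "exon"),
        ("rs5003", "splice_site"), ("rs5004", "splice_site"),
        ("rs5005", "binding_site"), ("rs5006", "binding_site"),
        ("rs5007", "intergenic"), ("rs5008", "intergenic"), ("rs5009", "intergenic"),
    )
    snp_sources: tuple[str, ...] = ("gwas_catalog", "johnson", "dbgap", "gad")
    r2_threshold: float = 0.5


@dataclass
class GroundTruth:
    """Realized truth for every planted quantity."""

    filter_casualties: list[str] = field(default_factory=list)  # gene ids
    antisense_gene: Optional[str] = None
    contexts: pd.DataFrame = field(default_factory=pd.DataFrame)
    interactions: set[tuple[str, str]] = field(default_factory=set)
    correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    ld: pd.DataFrame = field(default_factory=pd.DataFrame)
    expected_proxies: set[str] = field(default_factory=set)
    snp_placements: pd.DataFrame = field(default_factory=pd.DataFrame)
    merge_chains: list[list[str]] = field(default_factory=list)
    deleted_rsids: set[str] = field(default_factory=set)
    n_unique_snps: int = 0

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.contexts.to_csv(outdir / "truth_contexts.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.interactions), columns=["rbp", "gene_id"]
        ).to_csv(outdir / "truth_interactions.tsv", sep="\t", index=False)
        self.correlations.to_csv(outdir / "truth_correlations.tsv", sep="\t", index=False)
        self.ld.to_csv(outdir / "truth_ld.tsv", sep="\t", index=False)
        self.snp_placements.to_csv(outdir / "truth_snp_placements.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": self.filter_casualties}).to_csv(
            outdir / "truth_filter_casualties.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def generate_annotation(cfg: ScenarioConfig) -> tuple[AnnotationSet, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    chroms = list(cfg.genome)
    cursors = {c: 10_000 for c, _ in chroms}
    genes: list[GeneModel] = []
    coding_spans: list[GenomicInterval] = []

    def place(chrom_i: int, length_needed: int) -> tuple[str, int]:
        chrom, clen = chroms[chrom_i]
        gap = int(rng.integers(2_000, 5_000))
        start = cursors[chrom] + gap
        if start + length_needed > clen - 10_000:
            raise ValueError(
                f"genome too small: {chrom} cannot fit a gene of "
                f"{length_needed} bp at offset {start}"
            )
        cursors[chrom] = start + length_needed
        return chrom, start

    def make_exons(chrom, start, strand, n_exons, exon_rng, intron_rng):
        exons = []
        pos = start
        for i in range(n_exons):
            elen = int(rng.integers(*exon_rng))
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen
            if i < n_exons - 1:
                pos += int(rng.integers(*intron_rng))
        return tuple(exons), pos - start

    idx = 0
    for i in range(cfg.n_coding_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        span_est = n_exons * 400 + (n_exons - 1) * 800
        chrom, start = place(idx % len(chroms), span_est)
        idx += 1
        exons, _ = make_exons(chrom, start, strand, n_exons, (250, 401), (300, 801))
        # CDS leaves genuine UTRs inside the terminal exons
        utr_left = int(rng.integers(60, 121))
        utr_right = int(rng.integers(80, 151))
        cds = (exons[0].start + utr_left, exons[-1].end - utr_right)
        gid = f"PCG{i + 1:04d}"
        t = TranscriptModel(f"{gid}_T1", gid, gid, "protein_coding", exons, cds)
        genes.append(GeneModel(gid, "protein_coding", (t,)))
        coding_spans.append(t.span)

    for i in range(cfg.n_lncrna_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        span_est = n_exons * 500 + max(0, n_exons - 1) * 800
        chrom, start = place(idx % len(chroms), span_est)
        idx += 1
        exons, _ = make_exons(chrom, start, strand, n_exons, (200, 501), (300, 801))
        gid = f"LNC{i + 1:04d}"
        t = TranscriptModel(f"{gid}_T1", gid, gid, "lncRNA", exons)
        genes.append(GeneModel(gid, "lncRNA", (t,)))

    for i in range(cfg.n_pseudogenes):
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, start = place(idx % len(chroms), 400)
        idx += 1
        gid = f"PSG{i + 1:02d}"
        e = GenomicInterval(chrom, start, start + int(rng.integers(150, 301)), strand)
        genes.append(
            GeneModel(gid, "pseudogene",
                      (TranscriptModel(f"{gid}_T1", gid, gid, "pseudogene", (e,)),))
        )

    for i in range(cfg.n_sncrna_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, start = place(idx % len(chroms), 200)
        idx += 1
        gid = f"SNC{i + 1:02d}"
        e = GenomicInterval(chrom, start, start + int(rng.integers(80, 151)), strand)
        genes.append(
            GeneModel(gid, "sncRNA",
                      (TranscriptModel(f"{gid}_T1", gid, gid, "sncRNA", (e,)),))
        )

    # lncRNAs planted inside coding-gene spans: same-strand ones are filter
    # casualties under both policies; the antisense one survives same_strand.
    host_ids = rng.choice(cfg.n_coding_genes, size=cfg.n_overlapping_lncrnas + 1,
                          replace=False)
    for k in range(cfg.n_overlapping_lncrnas):
        host = genes[host_ids[k]]
        span = host.span
        gid = f"LNCOVL{k + 1:02d}"
        s = span.start + 10
        e = min(span.end - 10, s + 300)
        iv = GenomicInterval(span.chrom, s, e, span.strand)
        genes.append(
            GeneModel(gid, "lncRNA",
                      (TranscriptModel(f"{gid}_T1", gid, gid, "lncRNA", (iv,)),))
        )
        truth.filter_casualties.append(gid)
    if cfg.include_antisense_lncrna:
        host = genes[host_ids[-1]]
        span = host.span
        gid = "LNCAS01"
        anti = "-" if span.strand == "+" else "+"
        iv = GenomicInterval(span.chrom, span.start + 20, min(span.end - 20, span.start + 320), anti)
        genes.append(
            GeneModel(gid, "lncRNA",
                      (TranscriptModel(f"{gid}_T1", gid, gid, "lncRNA", (iv,)),))
        )
        truth.antisense_gene = gid

    return AnnotationSet(genes), truth


# ---------------------------------------------------------------------------
# Binding sites
# ---------------------------------------------------------------------------


def generate_binding_sites(
    cfg: ScenarioConfig, ann: AnnotationSet, truth: GroundTruth
) -> dict[str, list[BindingSite]]:
    """Place per-RBP sites realizing the planted context mix and the planted
    interaction set exactly; records realized truth in ``truth``."""
    rng = np.random.default_rng(cfg.seed + 1)
    filtered = filter_lncrnas(ann, "same_strand")
    lmin, lmax = cfg.site_length_range

    # category -> candidate feature intervals (filtered annotation, antisense
    # lncRNA excluded so truth holds under either filter policy)
    pools: dict[str, list[tuple[GenomicInterval, str]]] = {c: [] for c in
        ("CDS", "3UTR", "5UTR", "lncRNA", "pseudogene", "sncRNA", "intron")}
    for t in filtered.transcripts():
        if truth.antisense_gene and t.gene_id == truth.antisense_gene:
            continue
        for iv, cat in derive_features(t):
            if iv.length() >= lmax + 2 and cat in pools:
                pools[cat].append((iv, t.gene_id))

    # intergenic gaps with a safety margin from every gene span
    spans = sorted((g.span for g in ann.genes.values()),
                   key=lambda s: (s.chrom, s.start))
    gaps: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in spans:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, clen in cfg.genome:
        prev_end = 500
        for s in by_chrom.get(chrom, []):
            if s.start - 300 - (prev_end + 300) >= lmax + 2:
                gaps.append(GenomicInterval(chrom, prev_end + 300, s.start - 300, "."))
            prev_end = max(prev_end, s.end)

    def sub_interval(iv: GenomicInterval, strand: str) -> GenomicInterval:
        length = int(rng.integers(lmin, lmax + 1))
        length = min(length, iv.length())
        off = int(rng.integers(0, iv.length() - length + 1))
        return GenomicInterval(iv.chrom, iv.start + off, iv.start + off + length, strand)

    sites_by_rbp: dict[str, list[BindingSite]] = {}
    context_rows = []

    def add_site(rbp: str, iv: GenomicInterval, category: str, gene_id: str) -> None:
        exp = f"{rbp}_exp{1 + len(sites_by_rbp.get(rbp, [])) % 2}"
        site = BindingSite(rbp, iv, exp, score=float(int(rng.integers(10, 1000))))
        sites_by_rbp.setdefault(rbp, []).append(site)
        context_rows.append(
            {"rbp": rbp, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "strand": iv.strand, "category": category,
             "gene_id": gene_id if category != "intergenic" else ""}
        )

    # named planted interactions: sites inside exons of the named gene
    for rbp, gid, n_sites in cfg.planted_interactions:
        if gid not in filtered.genes:
            raise ValueError(f"planted interaction gene {gid} not in filtered annotation")
        gene = filtered.genes[gid]
        exons = [e for t in gene.transcripts for e in t.exons]
        for k in range(n_sites):
            e = exons[k % len(exons)]
            add_site(rbp, sub_interval(e, e.strand), "lncRNA", gid)
        truth.interactions.add((rbp, gid))

    # context mixes
    for rbp, mix in cfg.planted_context_mix:
        for category, count in mix:
            if category == "intergenic":
                if not gaps:
                    raise ValueError("no intergenic gaps available for placement")
                for _ in range(count):
                    gap = gaps[int(rng.integers(0, len(gaps)))]
                    add_site(rbp, sub_interval(gap, "."), "intergenic", "")
                continue
            pool = pools.get(category, [])
            if not pool:
                raise ValueError(f"category {category!r} absent from annotation")
            for _ in range(count):
                iv, gid = pool[int(rng.integers(0, len(pool)))]
                add_site(rbp, sub_interval(iv, iv.strand), category, gid)
                if category == "lncRNA":
                    truth.interactions.add((rbp, gid))

    truth.contexts = pd.DataFrame(context_rows)
    return sites_by_rbp


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(cfg: ScenarioConfig) -> tuple[list[ExpressionMatrix], GroundTruth]:
    """Per-cohort matrices; planted pairs drawn bivariate-normal on log2 scale."""
    rng = np.random.default_rng(cfg.seed + 2)
    mu, sd = cfg.expression_log_mean, cfg.expression_log_sd
    planted = list(cfg.planted_correlations)
    all_genes: list[str] = []
    for rbp, lnc, _, _ in planted:
        for g in (rbp, lnc):
            if g not in all_genes:
                all_genes.append(g)
    all_genes += [f"NULLG{i + 1:03d}" for i in range(cfg.n_null_expression_genes)]

    matrices = []
    corr_rows = []
    for cohort, n_samples in cfg.cohorts:
        cohort_planted = [(r, l, rho) for r, l, c, rho in planted if c == cohort]
        planted_genes = {g for r, l, _ in cohort_planted for g in (r, l)}
        if len(planted_genes) < 2 * len(cohort_planted):
            raise ValueError(f"cohort {cohort}: a gene appears in two planted pairs")
        z = pd.DataFrame(
            rng.normal(mu, sd, size=(len(all_genes), n_samples)),
            index=all_genes,
            columns=[f"{cohort}_S{j + 1:03d}" for j in range(n_samples)],
        )
        for rbp, lnc, rho in cohort_planted:
            cov = np.array([[1.0, rho], [rho, 1.0]]) * sd * sd
            zz = rng.multivariate_normal([mu, mu], cov, size=n_samples).T
            z.loc[rbp] = zz[0]
            z.loc[lnc] = zz[1]
            corr_rows.append(
                {"rbp": rbp, "lncrna": lnc, "cohort": cohort, "rho": rho,
                 "n_samples": n_samples}
            )
        values = np.maximum(np.exp2(z) - 1.0, 0.0)
        matrices.append(ExpressionMatrix(cohort, values))
    truth = GroundTruth(correlations=pd.DataFrame(corr_rows))
    return matrices, truth


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _hap_freqs_for_r2(
    target_r2: float, p_a: float, p_b: Optional[float] = None
) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) achieving ``target_r2`` at
    the given alt-allele frequencies; errors (naming the feasible maximum)
    when the target exceeds what the frequencies allow."""
    if p_b is None:
        p_b = p_a
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    d_needed = np.sqrt(target_r2 * denom)
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    if d_needed > d_max + 1e-12:
        feasible = d_max * d_max / denom
        raise ValueError(
            f"target r2 {target_r2} infeasible at allele frequencies "
            f"({p_a}, {p_b}); feasible maximum is {feasible:.4f}"
        )
    f = np.array([
        p_a * p_b + d_needed,
        p_a * (1 - p_b) - d_needed,
        (1 - p_a) * p_b - d_needed,
        (1 - p_a) * (1 - p_b) + d_needed,
    ])
    if np.any(f < -1e-12):
        raise ValueError(f"target r2 {target_r2} yields negative haplotype frequency")
    return np.clip(f, 0.0, 1.0)


def generate_genotypes(cfg: ScenarioConfig) -> tuple[list[GenotypePanel], GroundTruth]:
    """Panels realizing planted pairwise r2; pair loci are linked only in
    their named population and independent elsewhere."""
    rng = np.random.default_rng(cfg.seed + 3)
    chrom = cfg.genome[0][0]
    base_pos = cfg.genome[0][1] - 150_000  # tail region past all genes
    locus_rows = []
    pos = base_pos
    for rsid_a, rsid_b, _, _ in cfg.planted_ld:
        locus_rows.append((rsid_a, chrom, pos))
        locus_rows.append((rsid_b, chrom, pos + 5_000))
        pos += 20_000
    for i in range(cfg.n_filler_loci):
        locus_rows.append((f"rs77{i:02d}", chrom, pos))
        pos += 3_000

    ld_rows = []
    panels = []
    n = cfg.n_diploids
    p = cfg.ld_allele_freq
    for popu in cfg.populations:
        gt_cols = {}
        for rsid_a, rsid_b, pair_pop, target in cfg.planted_ld:
            if pair_pop == popu:
                f = _hap_freqs_for_r2(target, p)
                haps = rng.choice(4, size=2 * n, p=f)
                a_allele = (haps <= 1).astype(np.int8)  # AB or Ab carries alt at A
                b_allele = ((haps == 0) | (haps == 2)).astype(np.int8)
                gt_cols[rsid_a] = a_allele[0::2] + a_allele[1::2]
                gt_cols[rsid_b] = b_allele[0::2] + b_allele[1::2]
            else:
                for rsid in (rsid_a, rsid_b):
                    gt_cols[rsid] = rng.binomial(2, p, size=n).astype(np.int8)
        for i in range(cfg.n_filler_loci):
            freq = float(rng.uniform(0.3, 0.7))
            gt_cols[f"rs77{i:02d}"] = rng.binomial(2, freq, size=n).astype(np.int8)
        loci = pd.DataFrame(
            [(r, c, q, "A", "G") for r, c, q in locus_rows],
            columns=["rsid", "chrom", "pos", "allele_ref", "allele_alt"],
        )
        gt = np.stack([gt_cols[r] for r in loci["rsid"]], axis=1)
        panels.append(
            GenotypePanel(popu, [f"{popu}_S{j + 1:03d}" for j in range(n)], loci, gt)
        )
    for rsid_a, rsid_b, pair_pop, target in cfg.planted_ld:
        ld_rows.append(
            {"rsid_a": rsid_a, "rsid_b": rsid_b, "population": pair_pop,
             "target_r2": target,
             "expected_proxy": target > cfg.r2_threshold}
        )
    truth = GroundTruth(ld=pd.DataFrame(ld_rows))
    truth.expected_proxies = {
        row["rsid_b"] for row in ld_rows if row["expected_proxy"]
    }
    return panels, truth


# ---------------------------------------------------------------------------
# SNP catalogs
# ---------------------------------------------------------------------------


def generate_snp_catalog(
    cfg: ScenarioConfig,
    ann: AnnotationSet,
    sites_by_rbp: dict[str, list[BindingSite]],
    truth: GroundTruth,
    panels: Optional[list[GenotypePanel]] = None,
) -> tuple[dict[str, list[SnpRecord]], dict[str, str], set[str]]:
    """Catalogs keyed by source, plus rsID merge table and deletion history.

    Plants: SNPs at the configured placement classes, the LD seed SNPs (so
    the expansion stage has seeds), cross-catalog duplicates, a merge chain
    onto one placement SNP, and two deleted rsIDs.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    filtered = filter_lncrnas(ann, "same_strand")
    site_ivs = [s.interval for sites in sites_by_rbp.values() for s in sites]

    def in_any_site(pos: int, chrom: str) -> bool:
        return any(iv.chrom == chrom and iv.start <= pos < iv.end for iv in site_ivs)

    lnc_exons = []
    splice_windows = []
    for g in filtered.genes_by_biotype("lncRNA"):
        if truth.antisense_gene and g.gene_id == truth.antisense_gene:
            continue
        for t in g.transcripts:
            lnc_exons.extend(t.exons)
            splice_windows.extend(iv for iv, _ in extract_splice_sites(t))
    exonic_sites = [
        s for sites in sites_by_rbp.values() for s in sites
        if any(e.chrom == s.interval.chrom
               and e.start <= s.interval.start and s.interval.end <= e.end
               for e in lnc_exons)
    ]
    spans = [g.span for g in ann.genes.values()]

    placements = []
    for rsid, placement in cfg.planted_snp_placements:
        if placement == "exon":
            for _ in range(200):
                e = lnc_exons[int(rng.integers(0, len(lnc_exons)))]
                pos_ = int(rng.integers(e.start, e.end))
                if not in_any_site(pos_, e.chrom):
                    placements.append((rsid, e.chrom, pos_, placement))
                    break
            else:
                raise ValueError("could not place an exonic SNP outside binding sites")
        elif placement == "splice_site":
            if not splice_windows:
                raise ValueError("no splice sites in annotation for SNP placement")
            w = splice_windows[int(rng.integers(0, len(splice_windows)))]
            placements.append((rsid, w.chrom, int(rng.integers(w.start, w.end)), placement))
        elif placement == "binding_site":
            if not exonic_sites:
                raise ValueError("no exonic binding sites for SNP placement")
            s = exonic_sites[int(rng.integers(0, len(exonic_sites)))]
            iv = s.interval
            placements.append((rsid, iv.chrom, int(rng.integers(iv.start, iv.end)), placement))
        elif placement == "intergenic":
            chrom, clen = cfg.genome[int(rng.integers(0, len(cfg.genome)))]
            for _ in range(500):
                pos_ = int(rng.integers(1_000, clen - 160_000))
                clear_of_genes = not any(
                    sp.chrom == chrom and sp.start - 300 <= pos_ < sp.end + 300
                    for sp in spans
                )
                if clear_of_genes and not in_any_site(pos_, chrom):
                    placements.append((rsid, chrom, pos_, placement))
                    break
            else:
                raise ValueError("could not place an intergenic SNP")
        else:
            raise ValueError(f"unknown placement class {placement!r}")

    truth.snp_placements = pd.DataFrame(
        placements, columns=["rsid", "chrom", "pos", "placement"]
    )

    traits = ["type II diabetes mellitus", "coronary artery disease",
              "rheumatoid arthritis", "asthma", "schizophrenia"]
    records: list[SnpRecord] = []
    for i, (rsid, chrom, pos_, _) in enumerate(placements):
        records.append(SnpRecord(rsid, chrom, pos_, traits[i % len(traits)], ""))

    # LD seeds go into the catalogs so the expansion stage has inputs
    panel_pos = {}
    if panels:
        for row in panels[0].loci.itertuples():
            panel_pos[row.rsid] = (row.chrom, int(row.pos))
    for i, (rsid_a, _, _, _) in enumerate(cfg.planted_ld):
        chrom, pos_ = panel_pos.get(rsid_a, (cfg.genome[0][0], cfg.genome[0][1] - 150_000))
        records.append(SnpRecord(rsid_a, chrom, pos_, traits[i % len(traits)], ""))

    # distribute across sources; first two records duplicated with new traits
    catalogs: dict[str, list[SnpRecord]] = {s: [] for s in cfg.snp_sources}
    sources = list(cfg.snp_sources)
    for i, rec in enumerate(records):
        src = sources[i % len(sources)]
        catalogs[src].append(dataclasses.replace(rec, source=src))
    for k in range(min(2, len(records))):
        rec = records[k]
        alt_src = sources[(k + 1) % len(sources)]
        catalogs[alt_src].append(
            dataclasses.replace(rec, trait=traits[(k + 3) % len(traits)], source=alt_src)
        )

    # merge chain rs8000 -> rs8001 -> <first placement rsid>; catalog carries
    # the stale id.  Deleted ids: rs9999 (listed directly) and rs9000 which
    # merges onto deleted rs9998.
    target = records[0]
    merge_table = {"rs8000": "rs8001", "rs8001": target.rsid, "rs9000": "rs9998"}
    history = {"rs9999", "rs9998"}
    stale_src = sources[2 % len(sources)]
    catalogs[stale_src].append(
        dataclasses.replace(target, rsid="rs8000", trait=traits[4], source=stale_src)
    )
    dead_src = sources[3 % len(sources)]
    catalogs[dead_src].append(
        SnpRecord("rs9999", cfg.genome[0][0], 123, traits[0], dead_src)
    )
    catalogs[dead_src].append(
        SnpRecord("rs9000", cfg.genome[0][0], 456, traits[1], dead_src)
    )

    truth.merge_chains = [["rs8000", "rs8001", target.rsid], ["rs9000", "rs9998"]]
    truth.deleted_rsids = history
    truth.n_unique_snps = len(records)  # placements + LD seeds, post-resolution
    return catalogs, merge_table, history


# ---------------------------------------------------------------------------
# Whole-scenario convenience
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    cfg: ScenarioConfig
    annotation: AnnotationSet
    sites_by_rbp: dict[str, list[BindingSite]]
    matrices: list[ExpressionMatrix]
    panels: list[GenotypePanel]
    catalogs: dict[str, list[SnpRecord]]
    merge_table: dict[str, str]
    history: set[str]
    truth: GroundTruth


def generate_scenario(cfg: Optional[ScenarioConfig] = None) -> Scenario:
    """Generate every input in memory; deterministic in cfg (incl. seed)."""
    cfg = cfg or ScenarioConfig()
    ann, truth = generate_annotation(cfg)
    sites = generate_binding_sites(cfg, ann, truth)
    matrices, expr_truth = generate_expression(cfg)
    truth.correlations = expr_truth.correlations
    panels, ld_truth = generate_genotypes(cfg)
    truth.ld = ld_truth.ld
    truth.expected_proxies = ld_truth.expected_proxies
    catalogs, merge_table, history = generate_snp_catalog(cfg, ann, sites, truth, panels)
    return Scenario(cfg, ann, sites, matrices, panels, catalogs, merge_table, history, truth)


def write_scenario(scenario: Scenario, outdir) -> dict[str, str]:
    """Write every input and truth table as text files; returns path map."""
    from .gwas import write_snp_catalog

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    gtf = outdir / "annotation.gtf"
    write_gtf(scenario.annotation, gtf)
    paths["annotation"] = str(gtf)
    bed_dir = outdir / "sites"
    bed_dir.mkdir(exist_ok=True)
    for rbp, sites in scenario.sites_by_rbp.items():
        path = bed_dir / f"{rbp}.bed"
        write_bed(sites, path)
        paths[f"sites:{rbp}"] = str(path)
    for mat in scenario.matrices:
        path = outdir / f"expression_{mat.cohort}.tsv"
        mat.to_tsv(path)
        paths[f"expression:{mat.cohort}"] = str(path)
    for panel in scenario.panels:
        path = outdir / f"genotypes_{panel.population}.tsv"
        panel.to_tsv(path)
        paths[f"genotypes:{panel.population}"] = str(path)
    for source, snps in scenario.catalogs.items():
        path = outdir / f"snps_{source}.tsv"
        write_snp_catalog(snps, path)
        paths[f"catalog:{source}"] = str(path)
    with open(outdir / "rs_merge.tsv", "w") as fh:
        for old, new in sorted(scenario.merge_table.items()):
            fh.write(f"{old}\t{new}\n")
    paths["merge_table"] = str(outdir / "rs_merge.tsv")
    with open(outdir / "rs_history.tsv", "w") as fh:
        for rsid in sorted(scenario.history):
            fh.write(f"{rsid}\n")
    paths["history"] = str(outdir / "rs_history.tsv")
    truth_dir = outdir / "truth"
    scenario.truth.write(truth_dir)
    paths["truth"] = str(truth_dir)
    return paths
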