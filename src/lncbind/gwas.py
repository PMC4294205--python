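"""Disease-SNP curation, linkage disequilibrium and regulatory-site mapping.

The disease-SNP set is built by resolving rsIDs through merge/history
tables, deduplicating across catalogs, and expanding by LD: any genotype-
panel locus within a window of a seed SNP whose r^2 with it exceeds the
threshold (strictly) in at least one population panel is included as a
proxy.  r^2 is computed from unphased diploid genotypes by maximum-
likelihood haplotype-frequency estimation (two-locus EM under
Hardy-Weinberg; only the double-heterozygote cell has ambiguous phase).
Finally SNPs are mapped onto lncRNA exons, splice sites (the 2 intronic nt
flanking each junction) and RBP binding sites.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    AnnotationSet,
    BindingSite,
    GenomicInterval,
    IntervalIndex,
    build_site_index,
)

logger = logging.getLogger(__name__)

_RSID_RE = re.compile(r"rs\d+$")


@dataclass(frozen=True)
class SnpRecord:
    rsid: str
    chrom: str
    pos: int  # 0-based
    trait: str = ""
    source: str = ""
    ld_proxy_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position for {self.rsid}")
        if not _RSID_RE.match(self.rsid):
            raise ValueError(f"malformed rsid {self.rsid!r}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1, ".")


@dataclass
class GenotypePanel:
    """Unphased diploid genotypes: samples x loci coded 0/1/2 alt copies.

    Missing genotypes are coded -1.
    """

    population: str
    sample_ids: list[str]
    loci: pd.DataFrame  # columns: rsid, chrom, pos, allele_ref, allele_alt
    genotypes: np.ndarray  # shape (n_samples, n_loci), int8, -1 = missing

    def __post_init__(self) -> None:
        if self.loci["rsid"].duplicated().any():
            raise ValueError("duplicate rsids in panel loci")
        if self.genotypes.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError("genotype matrix shape mismatch")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotypes must be coded 0/1/2 or -1 (missing)")
        self._locus_idx = {r: i for i, r in enumerate(self.loci["rsid"])}

    def locus_index(self, rsid: str) -> Optional[int]:
        return self._locus_idx.get(rsid)

    def to_tsv(self, path) -> None:
        gt = pd.DataFrame(
            self.genotypes.T, index=self.loci["rsid"], columns=self.sample_ids
        )
        out = pd.concat([self.loci.set_index("rsid"), gt], axis=1)
        out.to_csv(path, sep="\t", index_label="rsid")

    @classmethod
    def from_tsv(cls, path, population: str) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta_cols = ["chrom", "pos", "allele_ref", "allele_alt"]
        loci = df[meta_cols].reset_index()
        samples = [c for c in df.columns if c not in meta_cols]
        gt = df[samples].to_numpy(dtype=np.int8).T
        return cls(population, samples, loci, gt)


@dataclass(frozen=True)
class LdPair:
    rsid_a: str
    rsid_b: str
    population: str
    r2: float
    d_prime: float
    hap_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab); A,B = alt
    n_used: int
    flagged_monomorphic: bool = False


# ---------------------------------------------------------------------------
# rsID resolution and catalog merging
# ---------------------------------------------------------------------------

TOMBSTONE = None  # sentinel: rsid deleted from dbSNP history


def resolve_rsid(
    rsid: str,
    merge_table: Mapping[str, str],
    history: Optional[set[str]] = None,
    _max_depth: int = 10_000,
) -> Optional[str]:
    """Follow merge chains to the terminal rsid; deleted rsids -> None.

    Raises on a cycle, naming the rsids involved.
    """
    history = history or set()
    seen = [rsid]
    cur = rsid
    while cur in merge_table:
        cur = merge_table[cur]
        if cur in seen:
            cycle = " -> ".join(seen + [cur])
            raise ValueError(f"cycle in rsid merge chain: {cycle}")
        seen.append(cur)
        if len(seen) > _max_depth:
            raise ValueError(f"merge chain from {rsid} exceeds {_max_depth} steps")
    if cur in history:
        logger.info("rsid %s resolved to deleted id %s; tombstoned", rsid, cur)
        return TOMBSTONE
    return cur


def dedup_snps(catalogs: Sequence[Sequence[SnpRecord]]) -> list[SnpRecord]:
    """Union the catalogs, unique by rsid; traits/sources semicolon-joined.

    Records whose position conflicts across catalogs are excluded and
    logged.  rsids must already be resolved.
    """
    by_rsid: dict[str, list[SnpRecord]] = {}
    order: list[str] = []
    for cat in catalogs:
        for rec in cat:
            if rec.rsid not in by_rsid:
                order.append(rec.rsid)
            by_rsid.setdefault(rec.rsid, []).append(rec)

    out: list[SnpRecord] = []
    n_conflicts = 0
    for rsid in order:
        recs = by_rsid[rsid]
        positions = {(r.chrom, r.pos) for r in recs}
        if len(positions) > 1:
            n_conflicts += 1
            logger.warning("rsid %s: conflicting positions %s; excluded", rsid, positions)
            continue
        traits = list(dict.fromkeys(r.trait for r in recs if r.trait))
        sources = list(dict.fromkeys(r.source for r in recs if r.source))
        out.append(
            SnpRecord(
                rsid=rsid,
                chrom=recs[0].chrom,
                pos=recs[0].pos,
                trait=";".join(traits),
                source=";".join(sources),
            )
        )
    if n_conflicts:
        logger.warning("dedup_snps: excluded %d rsids with conflicting positions", n_conflicts)
    return out


# ---------------------------------------------------------------------------
# Two-locus EM and r^2
# ---------------------------------------------------------------------------


def genotype_table(
    panel: GenotypePanel, rsid_a: str, rsid_b: str
) -> tuple[np.ndarray, int]:
    """3x3 joint genotype counts (alt copies at A x alt copies at B)."""
    ia, ib = panel.locus_index(rsid_a), panel.locus_index(rsid_b)
    if ia is None or ib is None:
        missing = [r for r, i in ((rsid_a, ia), (rsid_b, ib)) if i is None]
        raise KeyError(f"loci not in panel {panel.population}: {missing}")
    ga = panel.genotypes[:, ia]
    gb = panel.genotypes[:, ib]
    ok = (ga >= 0) & (gb >= 0)
    ga, gb = ga[ok], gb[ok]
    table = np.zeros((3, 3), dtype=int)
    np.add.at(table, (ga, gb), 1)
    return table, int(ok.sum())


def em_haplotype_freq(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[float, float, float, float]:
    """ML haplotype frequencies (AB, Ab, aB, ab) for two biallelic loci.

    ``counts[i, j]`` is the number of diploids with i alt copies at locus A
    and j at locus B.  Under HWE only the double heterozygote (1,1) is
    phase-ambiguous; EM iterates its expected split until the log-likelihood
    changes by less than ``tol``.  Haplotype labels: A/B = alt alleles.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3) or counts.sum() < 1:
        raise ValueError("need a 3x3 table with total count >= 1")
    n = counts.sum()
    # Haplotype counts fixed by unambiguous cells.  Cell (i,j) contributes
    # known haplotypes except (1,1), which is AB/ab or Ab/aB.
    base = np.zeros(4)  # AB, Ab, aB, ab
    contrib = {
        (2, 2): (2, 0, 0, 0), (2, 1): (1, 1, 0, 0), (2, 0): (0, 2, 0, 0),
        (1, 2): (1, 0, 1, 0), (1, 0): (0, 1, 0, 1),
        (0, 2): (0, 0, 2, 0), (0, 1): (0, 0, 1, 1), (0, 0): (0, 0, 0, 2),
    }
    for (i, j), hap in contrib.items():
        base += counts[i, j] * np.asarray(hap)
    n_dh = counts[1, 1]
    f = np.full(4, 0.25)
    ll_prev = -np.inf
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        phase_cis = 0.5 if denom == 0 else f[0] * f[3] / denom
        hap_counts = base.copy()
        hap_counts[0] += n_dh * phase_cis
        hap_counts[3] += n_dh * phase_cis
        hap_counts[1] += n_dh * (1 - phase_cis)
        hap_counts[2] += n_dh * (1 - phase_cis)
        f = hap_counts / (2 * n)
        ll = _loglik(counts, f)
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    return tuple(float(x) for x in f)


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    fAB, fAb, faB, fab = f
    # genotype probabilities under HWE from haplotype frequencies
    probs = np.empty((3, 3))
    probs[2, 2] = fAB ** 2
    probs[2, 1] = 2 * fAB * fAb
    probs[2, 0] = fAb ** 2
    probs[1, 2] = 2 * fAB * faB
    probs[1, 1] = 2 * (fAB * fab + fAb * faB)
    probs[1, 0] = 2 * fAb * fab
    probs[0, 2] = faB ** 2
    probs[0, 1] = 2 * faB * fab
    probs[0, 0] = fab ** 2
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    mask = counts > 0
    if np.any(np.isneginf(logp[mask])):
        return -np.inf
    return float((counts[mask] * logp[mask]).sum())


def ld_from_hap_freqs(
    f: Sequence[float],
) -> tuple[float, float, bool]:
    """(r^2, D', monomorphic flag) from (AB, Ab, aB, ab) frequencies."""
    fAB, fAb, faB, fab = f
    pA = fAB + fAb
    pB = fAB + faB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return 0.0, 0.0, True
    D = fAB - pA * pB
    r2 = D * D / denom
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if dmax == 0 else abs(D) / dmax
    return float(min(r2, 1.0)), float(min(d_prime, 1.0)), False


def ld_r2(panel: GenotypePanel, rsid_a: str, rsid_b: str) -> LdPair:
    """Pairwise LD from unphased genotypes via the two-locus EM."""
    table, n_used = genotype_table(panel, rsid_a, rsid_b)
    if n_used < 2:
        raise ValueError(
            f"fewer than 2 complete samples for ({rsid_a}, {rsid_b}) "
            f"in {panel.population}"
        )
    f = em_haplotype_freq(table)
    r2, d_prime, mono = ld_from_hap_freqs(f)
    if mono:
        logger.info(
            "monomorphic locus among (%s, %s) in %s; r2 defined as 0",
            rsid_a, rsid_b, panel.population,
        )
    return LdPair(rsid_a, rsid_b, panel.population, r2, d_prime, f, n_used, mono)


def phased_hap_freqs(haplotypes: np.ndarray) -> tuple[float, float, float, float]:
    """Direct counting oracle for phased haplotypes, shape (2n, 2) of 0/1."""
    h = np.asarray(haplotypes)
    n = len(h)
    fAB = np.mean((h[:, 0] == 1) & (h[:, 1] == 1))
    fAb = np.mean((h[:, 0] == 1) & (h[:, 1] == 0))
    faB = np.mean((h[:, 0] == 0) & (h[:, 1] == 1))
    fab = np.mean((h[:, 0] == 0) & (h[:, 1] == 0))
    return (float(fAB), float(fAb), float(faB), float(fab))


# ---------------------------------------------------------------------------
# LD expansion and feature mapping
# ---------------------------------------------------------------------------


def expand_ld(
    seeds: Sequence[SnpRecord],
    panels: Sequence[GenotypePanel],
    r2_threshold: float = 0.5,
    window: int = 250_000,
) -> list[SnpRecord]:
    """Seeds plus every panel locus in LD with a seed above the threshold.

    A locus within ``window`` bp of a seed on the same chromosome is a proxy
    if r^2 > r2_threshold (strict) in at least one population.  Proxies
    inherit the seed's trait and carry ``ld_proxy_of``.  Output is
    deduplicated by rsid with seed records taking precedence.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    if window <= 0:
        raise ValueError("window must be positive")
    out: dict[str, SnpRecord] = {s.rsid: s for s in seeds}
    for seed in seeds:
        in_any_panel = False
        for panel in panels:
            if panel.locus_index(seed.rsid) is None:
                continue
            in_any_panel = True
            loci = panel.loci
            near = loci[
                (loci["chrom"] == seed.chrom)
                & ((loci["pos"] - seed.pos).abs() <= window)
                & (loci["rsid"] != seed.rsid)
            ]
            for _, row in near.iterrows():
                rsid_b = row["rsid"]
                if rsid_b in out:
                    continue  # seeds take precedence; first proxy wins
                try:
                    pair = ld_r2(panel, seed.rsid, rsid_b)
                except ValueError:
                    continue
                # strict "over threshold", with a small guard so values
                # equal to the threshold up to EM round-off are excluded
                if pair.r2 > r2_threshold + 1e-9:
                    out[rsid_b] = SnpRecord(
                        rsid=rsid_b,
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        trait=seed.trait,
                        source="LD",
                        ld_proxy_of=seed.rsid,
                    )
        if not in_any_panel:
            logger.info("seed %s absent from all panels; kept without proxies", seed.rsid)
    return list(out.values())


def map_snps_to_features(
    snps: Sequence[SnpRecord],
    ann: AnnotationSet,
    sites_by_rbp: Optional[Mapping[str, Iterable[BindingSite]]] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate each SNP with lncRNA-exon, splice-site and RBP-site hits.

    SNPs are 1-bp half-open intervals with unknown strand (they match both).
    Returns a per-SNP table and a summary of class counts plus distinct
    transcripts/genes/RBPs hit.
    """
    exon_index = IntervalIndex()
    for g in ann.genes_by_biotype("lncRNA"):
        for t in g.transcripts:
            for e in t.exons:
                exon_index.add(e, (g.gene_id, t.transcript_id))
    splice_index = IntervalIndex()
    for g in ann.genes_by_biotype("lncRNA"):
        for t in g.transcripts:
            from .genome import extract_splice_sites

            for iv, role in extract_splice_sites(t):
                splice_index.add(iv, (g.gene_id, t.transcript_id, role))
    site_index = IntervalIndex()
    if sites_by_rbp:
        for rbp, sites in sites_by_rbp.items():
            for s in sites:
                site_index.add(s.interval, rbp)

    rows = []
    for snp in snps:
        q = snp.interval
        exon_hits = exon_index.query(q, same_strand=False)
        splice_hits = splice_index.query(q, same_strand=False)
        rbp_hits = site_index.query(q, same_strand=False)
        genes = sorted({gid for _, (gid, _) in exon_hits})
        transcripts = sorted({tid for _, (_, tid) in exon_hits})
        roles = sorted({role for _, (_, _, role) in splice_hits})
        splice_tx = sorted({tid for _, (_, tid, _) in splice_hits})
        rbps = sorted({rbp for _, rbp in rbp_hits})
        rows.append(
            {
                "rsid": snp.rsid,
                "chrom": snp.chrom,
                "pos": snp.pos,
                "trait": snp.trait,
                "ld_proxy_of": snp.ld_proxy_of or "",
                "in_lncrna_exon": bool(exon_hits),
                "exon_genes": ";".join(genes),
                "exon_transcripts": ";".join(transcripts),
                "in_splice_site": bool(splice_hits),
                "splice_roles": ";".join(roles),
                "splice_transcripts": ";".join(splice_tx),
                "in_binding_site": bool(rbps),
                "rbps": ";".join(rbps),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        summary = {
            "n_snps": 0, "n_exonic": 0, "n_splice_site": 0, "n_in_binding_site": 0,
            "n_exonic_and_binding": 0, "n_distinct_genes": 0,
            "n_distinct_transcripts": 0, "n_distinct_rbps": 0,
        }
        return table, summary
    all_genes = {g for cell in table["exon_genes"] if cell for g in cell.split(";")}
    all_tx = {t for cell in table["exon_transcripts"] if cell for t in cell.split(";")}
    all_rbps = {r for cell in table["rbps"] if cell for r in cell.split(";")}
    summary = {
        "n_snps": len(table),
        "n_exonic": int(table["in_lncrna_exon"].sum()),
        "n_splice_site": int(table["in_splice_site"].sum()),
        "n_in_binding_site": int(table["in_binding_site"].sum()),
        "n_exonic_and_binding": int(
            (table["in_lncrna_exon"] & table["in_binding_site"]).sum()
        ),
        "n_distinct_genes": len(all_genes),
        "n_distinct_transcripts": len(all_tx),
        "n_distinct_rbps": len(all_rbps),
    }
    return table, summary


# ---------------------------------------------------------------------------
# Catalog / merge-table I/O
# ---------------------------------------------------------------------------


def read_snp_catalog(path, source: str = "") -> list[SnpRecord]:
    """TSV with columns rsid, chrom, pos, trait (tab-separated, with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SnpRecord(
            rsid=row["rsid"],
            chrom=row["chrom"],
            pos=int(row["pos"]),
            trait=str(row.get("trait", "") or ""),
            source=source or str(row.get("source", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def write_snp_catalog(snps: Iterable[SnpRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "rsid": s.rsid, "chrom": s.chrom, "pos": s.pos,
                "trait": s.trait, "source": s.source,
                "ld_proxy_of": s.ld_proxy_of or "",
            }
            for s in snps
        ]
    ).to_csv(path, sep="\t", index=False)


def read_merge_table(path) -> dict[str, str]:
    """Two-column TSV (old rsid, new rsid), mirroring dbSNP's merge archive."""
    df = pd.read_csv(path, sep="\t", header=None, names=["old", "new"], comment="#")
    return dict(zip(df["old"], df["new"]))


def read_history(path) -> set[str]:
    """One-column file of deleted rsids, mirroring dbSNP's SNP history."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
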