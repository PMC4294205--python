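"""rsID resolution, catalog dedup, two-locus EM, r2/D', LD expansion and
SNP-to-feature mapping."""

import numpy as np
import pandas as pd
import pytest

from lncbind.genome import (
    AnnotationSet,
    BindingSite,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from lncbind.gwas import (
    GenotypePanel,
    SnpRecord,
    dedup_snps,
    em_haplotype_freq,
    expand_ld,
    genotype_table,
    ld_from_hap_freqs,
    ld_r2,
    map_snps_to_features,
    phased_hap_freqs,
    resolve_rsid,
    _loglik,
)


# ---------------------------------------------------------------------------
# rsID resolution / dedup
# ---------------------------------------------------------------------------


def test_resolve_follows_merge_chain():
    merge = {"rs100": "rs200", "rs200": "rs300"}
    assert resolve_rsid("rs100", merge) == "rs300"
    assert resolve_rsid("rs200", merge) == "rs300"


def test_resolve_identity_and_tombstone():
    assert resolve_rsid("rs42", {}, set()) == "rs42"
    assert resolve_rsid("rs1", {"rs1": "rs2"}, {"rs2"}) is None
    assert resolve_rsid("rs9", {}, {"rs9"}) is None


def test_resolve_cycle_raises_naming_cycle():
    with pytest.raises(ValueError, match="rs1 -> rs2 -> rs1"):
        resolve_rsid("rs1", {"rs1": "rs2", "rs2": "rs1"})


def test_dedup_union_semantics():
    a = [SnpRecord("rs1", "chr1", 100, "gout", "catA")]
    b = [SnpRecord("rs1", "chr1", 100, "asthma", "catB"),
         SnpRecord("rs2", "chr1", 200, "asthma", "catB")]
    out = dedup_snps([a, b])
    assert len(out) == 2
    rec = next(r for r in out if r.rsid == "rs1")
    assert rec.trait == "gout;asthma" and rec.source == "catA;catB"


def test_dedup_disjoint_and_conflicting_positions():
    a = [SnpRecord(f"rs{i}", "chr1", 10 * i, "t", "A") for i in range(1, 4)]
    b = [SnpRecord(f"rs{i}", "chr1", 10 * i, "t", "B") for i in range(4, 8)]
    assert len(dedup_snps([a, b])) == 7
    conflict = [SnpRecord("rs1", "chr1", 10, "t", "A")], [SnpRecord("rs1", "chr1", 99, "t", "B")]
    assert dedup_snps(list(conflict)) == []


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------


def _collapse_unambiguous(hap_counts):
    """Pair haplotypes (AB, Ab, aB, ab counts) into diploids with no
    double heterozygote, returning the 3x3 genotype table."""
    nAB, nAb, naB, nab = hap_counts
    table = np.zeros((3, 3), dtype=int)
    pools = [(nAB, (1, 1)), (nAb, (1, 0)), (naB, (0, 1)), (nab, (0, 0))]
    singles = []
    for count, allele in pools:
        table[2 * allele[0], 2 * allele[1]] += count // 2
        if count % 2:
            singles.append(allele)
    # leftovers paired so neither AB+ab nor Ab+aB arises
    while singles:
        a = singles.pop()
        if not singles:
            raise ValueError("odd total haplotype count")
        partner = None
        for i, b in enumerate(singles):
            if {a, b} not in ({(1, 1), (0, 0)}, {(1, 0), (0, 1)}):
                partner = i
                break
        if partner is None:
            raise ValueError("cannot pair without double heterozygote")
        b = singles.pop(partner)
        table[a[0] + b[0], a[1] + b[1]] += 1
    return table


def test_em_matches_closed_form_without_double_hets():
    """No double heterozygotes: haplotypes countable directly; EM exact."""
    table = _collapse_unambiguous((40, 10, 10, 40))
    assert table[1, 1] == 0
    f = em_haplotype_freq(table)
    assert np.allclose(f, (0.4, 0.1, 0.1, 0.4), atol=1e-12)


def test_em_matches_phased_counting_oracle(rng):
    """Haplotypes sampled from interior frequencies, collapsed without
    phase ambiguity: EM equals direct phased counting to 1e-6."""
    for _ in range(25):
        probs = rng.dirichlet([5, 5, 5, 5])
        draws = 2 * rng.multinomial(100, probs)  # even counts: pairable
        n_hap = int(draws.sum())
        haps = np.repeat(np.array([(1, 1), (1, 0), (0, 1), (0, 0)]), draws, axis=0)
        direct = phased_hap_freqs(haps)
        table = _collapse_unambiguous(tuple(draws))
        f = em_haplotype_freq(table)
        assert np.allclose(f, direct, atol=1e-6)


def test_em_loglik_nondecreasing(rng):
    """EM monotonicity on random genotype tables."""
    for _ in range(100):
        table = rng.integers(0, 30, size=(3, 3)).astype(float)
        if table.sum() < 1:
            continue
        # re-run EM manually, tracking the log-likelihood trajectory
        base = np.zeros(4)
        contrib = {
            (2, 2): (2, 0, 0, 0), (2, 1): (1, 1, 0, 0), (2, 0): (0, 2, 0, 0),
            (1, 2): (1, 0, 1, 0), (1, 0): (0, 1, 0, 1),
            (0, 2): (0, 0, 2, 0), (0, 1): (0, 0, 1, 1), (0, 0): (0, 0, 0, 2),
        }
        for (i, j), hap in contrib.items():
            base += table[i, j] * np.asarray(hap)
        n_dh = table[1, 1]
        f = np.full(4, 0.25)
        lls = []
        for _ in range(40):
            denom = f[0] * f[3] + f[1] * f[2]
            cis = 0.5 if denom == 0 else f[0] * f[3] / denom
            hc = base.copy()
            hc += n_dh * np.array([cis, 1 - cis, 1 - cis, cis])
            f = hc / (2 * table.sum())
            lls.append(_loglik(table, f))
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_em_rejects_empty_table():
    with pytest.raises(ValueError):
        em_haplotype_freq(np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# r2 / D'
# ---------------------------------------------------------------------------


def _panel_from_table(table, population="CEU"):
    """Expand a 3x3 genotype table into an explicit GenotypePanel."""
    ga, gb = [], []
    for i in range(3):
        for j in range(3):
            ga.extend([i] * int(table[i, j]))
            gb.extend([j] * int(table[i, j]))
    gt = np.array([ga, gb], dtype=np.int8).T
    loci = pd.DataFrame(
        {"rsid": ["rsA", "rsB"], "chrom": ["chr1", "chr1"],
         "pos": [100, 200], "allele_ref": ["A", "A"], "allele_alt": ["G", "G"]}
    )
    return GenotypePanel(population, [f"s{i}" for i in range(len(ga))], loci, gt)


def test_r2_hand_checked_value():
    """Haplotypes 40/10/10/40: D = 0.4 - 0.25 = 0.15, r2 = 0.15^2/0.0625."""
    panel = _panel_from_table(_collapse_unambiguous((40, 10, 10, 40)))
    pair = ld_r2(panel, "rsA", "rsB")
    assert pair.r2 == pytest.approx(0.36, abs=1e-9)
    assert sum(pair.hap_freqs) == pytest.approx(1.0, abs=1e-9)


def test_r2_complete_ld_and_equilibrium():
    panel = _panel_from_table(_collapse_unambiguous((50, 0, 0, 50)))
    assert ld_r2(panel, "rsA", "rsB").r2 == pytest.approx(1.0)
    # haplotype freqs equal to the product of allele freqs -> r2 = 0
    panel0 = _panel_from_table(_collapse_unambiguous((36, 24, 24, 16)))
    assert ld_r2(panel0, "rsA", "rsB").r2 == pytest.approx(0.0, abs=1e-9)


def test_r2_monomorphic_flagged_zero():
    table = np.zeros((3, 3))
    table[0, 1] = 30
    table[0, 0] = 30
    table[0, 2] = 10
    panel = _panel_from_table(table)
    pair = ld_r2(panel, "rsA", "rsB")
    assert pair.flagged_monomorphic and pair.r2 == 0.0


def test_ld_symmetry_and_bounds(rng):
    for _ in range(20):
        table = rng.integers(0, 25, size=(3, 3))
        if table.sum() < 2:
            continue
        panel = _panel_from_table(table)
        ab = ld_r2(panel, "rsA", "rsB")
        # swap loci: transpose the table
        panel_t = _panel_from_table(table.T)
        ba = ld_r2(panel_t, "rsA", "rsB")
        assert ab.r2 == pytest.approx(ba.r2, abs=1e-9)
        assert 0.0 <= ab.r2 <= 1.0 and 0.0 <= ab.d_prime <= 1.0
        assert sum(ab.hap_freqs) == pytest.approx(1.0, abs=1e-9)


def test_r2_recomputable_from_hap_freqs(rng):
    for _ in range(20):
        table = rng.integers(1, 20, size=(3, 3))
        pair = ld_r2(_panel_from_table(table), "rsA", "rsB")
        fAB, fAb, faB, fab = pair.hap_freqs
        pA, pB = fAB + fAb, fAB + faB
        denom = pA * (1 - pA) * pB * (1 - pB)
        if denom > 0:
            D = fAB - pA * pB
            assert pair.r2 == pytest.approx(D * D / denom, abs=1e-9)


def test_ld_r2_too_few_samples():
    loci = pd.DataFrame(
        {"rsid": ["rsA", "rsB"], "chrom": ["chr1"] * 2, "pos": [1, 2],
         "allele_ref": ["A"] * 2, "allele_alt": ["G"] * 2}
    )
    gt = np.array([[1, -1], [-1, 1], [0, 0]], dtype=np.int8)
    panel = GenotypePanel("CEU", ["s1", "s2", "s3"], loci, gt)
    with pytest.raises(ValueError, match="fewer than 2"):
        ld_r2(panel, "rsA", "rsB")


# ---------------------------------------------------------------------------
# LD expansion
# ---------------------------------------------------------------------------


def _two_pop_panels():
    """One CEU panel of 30 diploids where rs601 duplicates the seed
    genotypes (r2 = 1) and rs602 sits at exactly r2 = 0.5 with the seed
    (haplotype counts (AB,Ab,aB,ab) = (30,0,10,20), no double
    heterozygotes), plus an unlinked YRI panel."""
    half = _collapse_unambiguous((30, 0, 10, 20))
    ga, gb = [], []
    for i in range(3):
        for j in range(3):
            ga.extend([i] * int(half[i, j]))
            gb.extend([j] * int(half[i, j]))
    n = len(ga)
    loci = pd.DataFrame(
        {"rsid": ["rs600", "rs601", "rs602"], "chrom": ["chr1"] * 3,
         "pos": [1000, 2000, 3000], "allele_ref": ["A"] * 3, "allele_alt": ["G"] * 3}
    )
    gt_ceu = np.array([ga, ga, gb], dtype=np.int8).T
    rng = np.random.default_rng(0)
    gt_yri = rng.binomial(1, 0.5, size=(n, 3)).astype(np.int8)
    ceu = GenotypePanel("CEU", [f"c{i}" for i in range(n)], loci, gt_ceu)
    yri = GenotypePanel("YRI", [f"y{i}" for i in range(n)], loci.copy(), gt_yri)
    return ceu, yri


def test_expand_ld_one_population_suffices():
    ceu, yri = _two_pop_panels()
    seed = SnpRecord("rs600", "chr1", 1000, "asthma", "cat")
    out = expand_ld([seed], [ceu, yri], r2_threshold=0.5, window=250_000)
    rsids = {s.rsid for s in out}
    assert "rs601" in rsids  # r2 = 1 in CEU, noise in YRI
    proxy = next(s for s in out if s.rsid == "rs601")
    assert proxy.ld_proxy_of == "rs600" and proxy.trait == "asthma"
    assert {s.rsid for s in out if s.ld_proxy_of is None} == {"rs600"}


def test_expand_ld_threshold_is_strict():
    """A proxy at exactly r2 = 0.5 is excluded ('over 0.5' is strict)."""
    ceu, yri = _two_pop_panels()
    pair = ld_r2(ceu, "rs600", "rs602")
    assert pair.r2 == pytest.approx(0.5, abs=1e-9)
    seed = SnpRecord("rs600", "chr1", 1000, "asthma", "cat")
    out = expand_ld([seed], [ceu], r2_threshold=0.5, window=250_000)
    assert "rs602" not in {s.rsid for s in out}
    # and it is included once the threshold drops below 0.5
    out2 = expand_ld([seed], [ceu], r2_threshold=0.49, window=250_000)
    assert "rs602" in {s.rsid for s in out2}


def test_expand_ld_window_and_absent_seed():
    ceu, _ = _two_pop_panels()
    seed = SnpRecord("rs600", "chr1", 1000, "t", "cat")
    out = expand_ld([seed], [ceu], r2_threshold=0.5, window=500)
    assert {s.rsid for s in out} == {"rs600"}  # proxies outside window
    ghost = SnpRecord("rs999999", "chr9", 5, "t", "cat")
    out2 = expand_ld([ghost], [ceu])
    assert {s.rsid for s in out2} == {"rs999999"}


def test_expand_ld_no_duplicate_rsids_and_superset(scenario):
    from lncbind.gwas import dedup_snps

    seeds = [SnpRecord(a, "chr1", 1, "t", "c")
             for a, _, _, _ in scenario.cfg.planted_ld]
    # use real panel positions for the seeds
    pos = {r.rsid: (r.chrom, r.pos) for r in scenario.panels[0].loci.itertuples()}
    seeds = [SnpRecord(s.rsid, pos[s.rsid][0], int(pos[s.rsid][1]), "t", "c")
             for s in seeds]
    out = expand_ld(seeds, scenario.panels)
    rsids = [s.rsid for s in out]
    assert len(rsids) == len(set(rsids))
    assert {s.rsid for s in seeds} <= set(rsids)


# ---------------------------------------------------------------------------
# SNP-to-feature mapping
# ---------------------------------------------------------------------------


def _lnc_ann():
    t = TranscriptModel(
        "L1_T1", "L1", "L1", "lncRNA",
        (GenomicInterval("chr1", 100, 200, "+"), GenomicInterval("chr1", 300, 400, "+")),
    )
    return AnnotationSet([GeneModel("L1", "lncRNA", (t,))])


def test_snp_exonic_plus_rbp_hit():
    ann = _lnc_ann()
    sites = {"HuR": [BindingSite("HuR", GenomicInterval("chr1", 140, 160, "+"), "e")]}
    snp = SnpRecord("rs1", "chr1", 150, "t", "c")
    table, summary = map_snps_to_features([snp], ann, sites)
    row = table.iloc[0]
    assert row.in_lncrna_exon and row.rbps == "HuR"
    assert summary["n_exonic_and_binding"] == 1


def test_snp_intergenic_no_flags():
    table, summary = map_snps_to_features(
        [SnpRecord("rs1", "chr1", 5000, "t", "c")], _lnc_ann(), {}
    )
    row = table.iloc[0]
    assert not (row.in_lncrna_exon or row.in_splice_site or row.in_binding_site)
    assert summary["n_exonic"] == 0


def test_snp_splice_site_hits_with_role():
    ann = _lnc_ann()  # donor (200,202), acceptor (298,300) on + strand
    snps = [SnpRecord("rs1", "chr1", 200, "t", "c"),
            SnpRecord("rs2", "chr1", 299, "t", "c"),
            SnpRecord("rs3", "chr1", 250, "t", "c")]
    table, summary = map_snps_to_features(snps, ann, {})
    assert summary["n_splice_site"] == 2
    assert table.iloc[0].splice_roles == "donor"
    assert table.iloc[1].splice_roles == "acceptor"
    # splice hits lie within 2 bp of an exon boundary
    for _, row in table[table.in_splice_site].iterrows():
        assert min(abs(row.pos - 200), abs(row.pos - 300 + 1), abs(row.pos - 199),
                   abs(row.pos - 300)) <= 2


def test_scenario_snp_placements_recovered(scenario, filtered_ann):
    """Planted placement classes recovered exactly from the scenario."""
    truth = scenario.truth.snp_placements
    snps = [SnpRecord(r.rsid, r.chrom, int(r.pos), "t", "c")
            for r in truth.itertuples()]
    table, summary = map_snps_to_features(snps, filtered_ann, scenario.sites_by_rbp)
    tab = table.set_index("rsid")
    for r in truth.itertuples():
        row = tab.loc[r.rsid]
        if r.placement == "exon":
            assert row.in_lncrna_exon and not row.in_binding_site
        elif r.placement == "splice_site":
            assert row.in_splice_site
        elif r.placement == "binding_site":
            assert row.in_binding_site
        else:
            assert not (row.in_lncrna_exon or row.in_splice_site or row.in_binding_site)
    n_splice_planted = (truth.placement == "splice_site").sum()
    assert summary["n_splice_site"] >= n_splice_planted
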