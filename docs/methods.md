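# Methods

This note documents the models and procedures implemented in `lncbind`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Coordinate model

All internal coordinates are 0-based half-open (`[start, end)`), matching
BED; GTF's 1-based closed coordinates are converted at the file boundary
and converted back on write. Strand is `+`, `-` or `.`; in strand-aware
queries `.` matches either strand, which keeps BED3 inputs (no strand
column) usable against stranded annotation. Binding-site-versus-feature
intersection defaults to same-strand matching because CLIP protocols are
strand-specific; it is configurable wherever it matters.

## Feature derivation and context assignment

A transcript's span is partitioned into disjoint category intervals:
coding transcripts split exonic bases into 5'UTR / CDS / 3'UTR around the
genomic CDS span, read in transcript orientation (on the minus strand the
genomic-left UTR is the 3'UTR); non-coding transcripts label exonic bases
with their biotype class; inter-exon gaps are introns. A coding
transcript lacking a CDS record is labelled all-CDS with a warning rather
than rejected. Source biotype vocabularies vary across annotation
releases, so biotypes are canonicalised to
{protein_coding, lncRNA, pseudogene, sncRNA, other} through an editable
mapping table with GENCODE-style defaults (`lincRNA`, `antisense` →
lncRNA; `miRNA`, `snoRNA`, ... → sncRNA).

Each binding site receives exactly one category: among all features it
overlaps by at least 1 bp under the strand policy, the highest-priority
category wins (CDS > 3'UTR > 5'UTR > lncRNA > pseudogene > sncRNA >
intron; no overlap → intergenic). The 1 bp minimum matches standard
intersect semantics. A site spanning an exon–intron junction is therefore
assigned to the exonic category — the priority list already encodes this,
and no fractional assignment is attempted. Ties within the winning
category go to the largest overlap, then the lexicographically smallest
gene id, making the call deterministic. Distributions count sites;
counting site-bases instead is available behind a flag (`by_base`), since
either convention is defensible for summarising binding context.

## lncRNA filtering and interaction calling

lncRNA transcripts overlapping protein-coding genes are removed before
interaction calling. Overlap is evaluated at gene-span level (transcript
span vs coding gene span, ≥ 1 bp) — the conservative reading when the
overlap granularity is unspecified — with the strand policy configurable:
`same_strand` (default) keeps antisense lncRNAs, `any_strand` removes
them. The filter is idempotent and logs removal counts.

Interactions are called at gene level: an (RBP, lncRNA gene) pair exists
iff at least one of the RBP's clusters overlaps at least one exon of at
least one transcript of the gene. Intronic-only overlap never qualifies.
Site records and transcript ids are retained on the interaction for
drill-down; `n_experiments` counts distinct experiment ids as the
confidence proxy, and interactions are deduplicated across experiments
and cell types by default.

Co-bound ("identical") sites are computed by a sweep over site
boundaries: each chromosome is partitioned into maximal segments with a
constant set of covering RBPs, and segments with ≥ `min_rbps` distinct
RBPs and length ≥ `min_overlap` (default 1 bp) are reported. Because CLIP
cluster boundaries are method-dependent, "identical" is deliberately
operationalised as co-coverage rather than exact coordinate equality; the
reported Jaccard value — the minimum intersection/union ratio over
cross-RBP pairs of contributing sites — lets users impose stricter
identity downstream. Contributors on opposite known strands never form a
shared site.

Motif scanning expands IUPAC degenerate codes into character classes with
T ≡ U and case-insensitive matching, and reports all (possibly
overlapping) match offsets on the given strand.

## Co-expression screen

Expression values are log2(x+1)-transformed by default (standard for
normalised RNA-seq abundance; the transform is a flag). For each
candidate pair and cohort with both genes measured, samples missing
either value are dropped pairwise; pairs with fewer than 3 complete
samples or zero variance are skipped and logged, not raised. The
two-sided p-value comes from the t distribution with n−2 degrees of
freedom; Benjamini–Hochberg q-values are computed within each cohort over
all pairs tested there — cohorts are treated as independent screens. A
pair is "significant" if it passes in at least one cohort; the criterion
defaults to raw p < α (α = 0.05) with q-based selection selectable,
because raw-p-per-cohort and FDR-adjusted reporting are both common and
the package exposes both numbers on every row.

## LD and disease SNPs

rsIDs are resolved by following merge chains to their terminal id (cycle
detection raises, naming the cycle); ids landing in the deletion history
are tombstoned and excluded. Catalogs are then deduplicated by resolved
rsid with traits and sources semicolon-joined in stable order; an rsid
with conflicting positions across catalogs is excluded and logged rather
than guessed.

Pairwise LD is computed from unphased diploid genotypes: the 3×3 joint
genotype table (complete cases only) feeds a two-locus EM under
Hardy–Weinberg in which only the double-heterozygote cell is
phase-ambiguous; the expected cis fraction
$f_{AB}f_{ab} / (f_{AB}f_{ab} + f_{Ab}f_{aB})$ is iterated until the
log-likelihood changes by < 1e-10 (max 1000 iterations). From the ML
haplotype frequencies, $D = f_{AB} - p_A p_B$,
$r^2 = D^2/(p_A p_a p_B p_b)$ and $D'$ are derived; a monomorphic locus
yields r² = 0 with a flag. Note the genotype-likelihood MLE estimates the
*expected* phase split of double heterozygotes, so it equals direct
phased counting exactly only when no double heterozygote is present; with
random pairing the two agree to O(1/n).

LD expansion emits, for each seed SNP, every panel locus on the same
chromosome within a window (default 250 kb, a typical proxy-search span)
whose r² with the seed exceeds the threshold (default 0.5) strictly in at
least one population panel. "Strictly over" is evaluated with a 1e-9
numerical guard so a value equal to the threshold up to EM round-off is
excluded. Proxies inherit the seed's trait and carry `ld_proxy_of`; the
output is seeds ∪ proxies, deduplicated by rsid with seeds taking
precedence. A SNP is a 1-bp half-open interval (an indel entry is treated
as its first base) with wildcard strand, and is mapped against lncRNA
exons, splice sites and binding sites; the summary reports the funnel
(collected → unique → LD-expanded → exonic → in-binding-site) plus
distinct genes/transcripts/RBPs hit. Exon hits are reported at both gene
and transcript level since either deduplication may be wanted.

Splice sites follow the 2-nt definition: for each intron, the first two
and last two intronic bases; the window adjacent to the transcript-5'
exon is the donor, the other the acceptor (roles swap on the minus
strand). Introns shorter than 4 bp still emit both (overlapping) windows,
flagged.

## Synthetic scenarios and what they show

The generators are pure functions of a `ScenarioConfig` (including its
seed): same config, byte-identical outputs. The default scenario is sized
for desk-scale runs — ~50 genes on two 600-kb chromosomes, 5 RBPs with
~20 sites each (site lengths 20–60 bp, typical CLIP cluster widths),
2 cohorts × 200 samples, 2 populations × 120 diploids — and completes the
whole pipeline in seconds.

Design points worth knowing:

* The annotation plants same-strand coding-overlapping lncRNAs (filter
  casualties under both policies) and one antisense lncRNA (removed only
  under `any_strand`), so the filter's policy axis is exercised.
* Binding sites are placed wholly inside a feature of the target
  category, which together with the priority rule makes planted context
  labels exact ground truth rather than approximate.
* Expression pairs are drawn bivariate-normal on the log2 scale (mean 8,
  sd 1) and transformed as 2^z − 1, so the screen's log2(x+1) transform
  recovers the planted correlation without attenuation; the mean is high
  enough that the x ≥ 0 clip never binds in practice.
* Genotype pairs realise a target r² by solving for haplotype frequencies
  at allele frequency 0.5 (D = √(r²)/4) and sampling 2n haplotypes;
  infeasible (r², allele-frequency) combinations raise with the feasible
  maximum instead of silently approximating. Default planted targets
  {0.8, 0.9} (proxies) and {0.2, 0.3} (non-proxies) sit far from the 0.5
  threshold relative to the estimator's sampling sd at n = 120 (~0.06),
  so inclusion truth is stable across seeds.
* SNP catalogs plant cross-catalog duplicates, a 3-step rsID merge chain,
  and two deleted ids (one reached via a merge), covering the resolution
  logic end to end.

Passing on these scenarios demonstrates the interval arithmetic, priority
logic, statistics and LD machinery are correct, and that recovery is
exact when the data match the generative assumptions. It does *not*
demonstrate robustness to real-data pathologies the generator omits:
overlapping gene models beyond the planted cases, multi-transcript genes
with conflicting biotypes, expression heavy-tails or batch structure,
Hardy–Weinberg violations, multi-allelic loci (not supported; such loci
should be split or dropped upstream), or assembly mismatches between
inputs (no liftover is performed — all inputs must share one assembly).

## Numerical and testing notes

Pearson r is computed from centred sums and clipped to [−1, 1]; zero
variance signals NaN (pair skipped) rather than raising. BH q-values are
delegated to a standard step-up implementation and cross-checked in the
tests against an independent sort/cummin construction. The EM
log-likelihood is monotone non-decreasing by construction and verified as
a property test. Calibration tests use ≥ 2000 null (pair, cohort) tests,
and parameter-recovery tests use 100 replicates at n = 500 (correlation)
and n = 120 diploids (r²) — sizes chosen so sampling error is well inside
the asserted tolerances. Pipeline outputs are written atomically
(temp-then-rename) and manifests record a parameters-only config hash
plus content checksums of inputs and outputs, so determinism is testable
by byte comparison across runs.
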