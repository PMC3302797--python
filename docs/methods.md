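# Methods

## Data model and conventions

A panel is a `GenotypeMatrix`: accessions × SNPs over {allele_a, allele_b,
missing}, with SNPs sorted by (chromosome, position). Accessions are inbred
haploid-equivalents; heterozygous input calls are coerced to missing at
load time (a heterozygote in a selfing crop is most often a genotyping
artifact, and carries no haplotype information for inbred lines). All
internal coordinates are 1-based inclusive; BED export converts to 0-based
half-open at the boundary, the only place a conversion happens. Tied SNP
positions within a chromosome are rejected rather than ordered arbitrarily,
so window identity is deterministic. Allele labels are arbitrary: every
statistic in the package is invariant to swapping a/b at any SNP (this is
property-tested). With the default declared alphabet the genotype-TSV
writer/reader round-trips calls exactly; with no declared alphabet the
first symbol observed per column becomes allele_a.

## Statistics

**Informative-SNP QC.** Removal criteria, applied in order for labeling
(membership is order-independent): no genome position; missing+het fraction
strictly greater than `max_missing_fraction` (default 0.5) over all
accessions; minor-allele frequency ≤ `min_allele_freq` (default 0.02)
among non-missing calls only — missing calls carry no allele, and the 2%
rule is a genotyping-error guard, so the non-missing denominator is the
meaningful one. Monomorphic SNPs fall under the frequency criterion.

**Blocks and diversity.** Windows of `window` = 5 consecutive
same-chromosome SNPs at step 1. Step 1 is forced by arithmetic: only a
sliding window makes a 12-chromosome, 3259-SNP panel yield 3259 − 4·12 =
3211 blocks. The diversity index divides the distinct complete 5-call
strings in a group by the group size; accessions with a missing call in the
window are excluded from the numerator but kept in the denominator (the
group size is the stated denominator; a complete-case denominator is
available via `denominator="complete"`). An alternative per-block
polymorphism counter (segregating sites in the window) is provided but not
default: the block's "alleles" are its allele *combinations*.

**Reduced-diversity scan.** The flag rule compares raw distinct-haplotype
counts, not indices, because group sizes differ (41/50/63) and the rule
concerns the number of polymorphisms; an index-based variant is a flag.
Strict inequality and the both-later-groups conjunction; ties do not flag.
Blocks with a zero reference count or an all-missing later group are
excluded by default (`include_zero_reference` admits them). Merging uses
consecutive window indices only (blocks sharing 4 SNPs); a bp-gap tolerance
is deliberately not used, and regions need ≥ `min_blocks` = 2 windows
(every region a scan of this design reports spans at least two windows;
`min_blocks=1` disables the filter). Annotation overlap is closed-interval,
≥ 1 shared bp, same chromosome.

**LD.** Δ² is computed from complete-case haploid frequencies:
D = x − pq, Δ² = D²/(p(1−p)q(1−q)); undefined (NaN) with < 2 complete
observations or a monomorphic side. It equals the squared Pearson
correlation of the 0/1-coded vectors, and the test suite checks the closed
form against that independent oracle. "Neighboring" means consecutive in
map order — the only reading under which "distance between adjacent pairs"
is a meaningful axis — with pairs beyond 2000 kb excluded. Distance bins
are left-open right-closed multiples of 50 kb anchored at zero. Bin means
are restricted to 0 < Δ² < 1 ("complete LD"), with the counts at exactly 0
and 1 reported separately; whether the boundary exclusion is intended or
notational in the source convention is unclear, so an inclusive mode is a
flag and the literal reading is the default.

**Novel polymorphisms.** A novel SNP is monomorphic among the reference
group's non-missing calls with the alternate allele observed in *either*
later group (the union is the weaker reading; per-group frequencies are
reported so the conjunction can be filtered afterwards). Per-cultivar
novel-block counts use complete-case strings on both sides; windows with a
missing cultivar call are uncounted, never imputed, and blocks with an
empty reference census are skipped. The accrual fit is plain OLS with the
classical slope t-test — the stated model is y = a + bx + ε — with the
reference group a parameter (founder group by default; counting against
all earlier-registered cultivars is a documented alternative).

**Ancestry.** Founder frequencies count path occurrences (a founder
reached via two paths counts twice — ancestors are *counted*, not listed),
skipping subtrees entered through a recurrent-parent edge; a
unique-ancestor mode is a flag. Tree building is out of scope: the package
emits the simple-matching distance matrix in PHYLIP square format for any
external neighbor-joining tool. Q-matrix group statistics use SE = sample
sd/√n, two-sided Mann–Whitney tests Bonferroni-corrected per component
across the pairwise group comparisons, and a greedy compact letter display
over groups in descending mean order (non-transitive significance patterns
are resolved greedily; letters are checked for consistency with adjusted
p-values in tests).

## The synthetic generator

The generator emulates the study design the analyses assume, not any real
panel. Defaults: 12 chromosomes × 31.7 Mb (≈380 Mb), 3259 SNPs placed
uniformly per chromosome, 4 ancestral pools, irrigated group sizes
41/50/63 with 22/1/0 non-irrigated accessions (177 in all), registration
years 1931–1974 (phase 2) and 1975–2005 (phase 3), founder bottlenecks of
12 (phase 1→2) and 10 (phase 2→3), Poisson 0.4 crossovers per chromosome
per meiosis, and 3 new haplotype-block polymorphisms per year.

*Phase 1* landraces are mosaic haplotypes over Balding–Nichols pool
frequencies (Fst-like `pool_divergence` = 0.35) with a U-shaped ancestral
spectrum (Beta(0.3, 0.3) scaled to (0.01, 0.99)); the near-fixed tail
yields sites monomorphic across phase 1, the substrate for later novel
mutations. Non-irrigated accessions draw mainly from a dedicated pool.
The true Q-matrix records each accession's realized pool fractions.

*Phases 2 and 3* descend from bottlenecked founder subsets (phase-3
founders are drawn from the late-registered half of phase 2, mirroring the
dominance of recent elite parents) by pedigree-recorded crosses: one
meiosis with Poisson crossovers, thinned ×0.1 inside one centromere-like
interval per chromosome (placed at 0.40–0.55 of the chromosome), so long
merged low-diversity regions can arise there. Parents are drawn with
skewed (Dirichlet-0.5) founder weights, and with probability
`parent_reuse` = 0.6 from the ten most recently registered lines — the
breeding-chain behavior that both concentrates ancestry and lets novel
alleles spread. A fraction of crosses (0.15) is followed by a backcross to
parent 1, recorded with a recurrent-parent flag.

*Novel mutations.* When a cultivar registered in year *y* is bred from
parents with mean reference year *ȳ*, it receives Poisson(μ·(y − ȳ)) new
mutations at unused phase-1-monomorphic sites (phase-1 parents count as the
start year, 1931). Because a child inherits each parental mutation with
probability ½ and two parents contribute, the expected number of carried
mutations telescopes to μ·(y − 1931) for every topology — the accrual is
linear in registration year by construction, while a mutation's population
frequency rises only if its carriers are reused as parents (the phase-2 →
phase-3 frequency rise is emergent, not hard-coded). The clock μ is
calibrated so that `novel_accrual_rate` means *observable* novel
block-polymorphisms per year in the emitted panel: one SNP mutation is
visible in the windows containing it (5 per interior site, fewer at
chromosome ends), only where the carrier's window survives the missing/het
corruption ((1 − miss − het)^5), and with a fixed-point thinning term for
two carried mutations sharing one window. Residual bias of the measured
OLS slope is about −3% of the configured rate over seeds, well inside the
across-seed standard error at the default scale; recombination novelty
adds an intercept (and slight positive slope) because chained lineages
deepen over time.

Missing and heterozygote noise (defaults 0.01 and 0.005) are applied last
and both stored as missing in memory — the analyses treat heterozygotes as
no-signal anyway — with the het mask retained so file emission can write
explicit `H` codes. Identical seeds give identical output.

**What the generator does not emulate:** real SNP density heterogeneity
along chromosomes, coalescent-realistic LD decay, phenotypic selection
(selection enters only as founder-subset bottlenecks), any particular
cultivar's genotype, or a post-QC panel — the U-shaped spectrum leaves
monomorphic and rare sites that the QC stage then removes, as it would on
a raw assay. Consequently, passing tests show the *methods* behave as
specified and that the documented directional effects (diversity collapse,
LD growth, novel-allele spread, founder concentration) emerge from the
stated mechanisms; they do not certify magnitudes on any real panel, whose
observed counts (numbers of flagged regions, novel SNPs, exact
frequencies) are properties of genotypes that were never deposited.

## Problem sizes and numerical choices

The default simulated panel (177 × 3259) runs every stage in a few
seconds; tests and the acceptance study use it directly, with the accrual
recovery averaged over five seeds (the within-fit OLS standard error
understates seed-to-seed scatter because counts are correlated along
lineages, so recovery is judged against the across-seed standard error).
Mann–Whitney p-values come from scipy (`mannwhitneyu`, two-sided;
asymptotic with tie correction where exact is unavailable). Identical
censuses short-circuit to p = 1. Window codes pack the 5 calls into an
integer, so the census is exact string equality — no partial-match
collapsing. Undefined quantities (Δ² without a defined denominator,
distances without comparable sites, SE of singleton groups) are NaN and
flagged, never silently zero.

## Known limitations

- The compact letter display is greedy; with strongly non-transitive
  pairwise patterns the letter partition is one valid choice among several.
- Founder shares are computed over recorded pedigrees only; unrecorded
  parents truncate paths at the deepest recorded ancestor.
- The accrual calibration targets the default analysis (founder-group
  reference, no imputation); strongly different missing rates or window
  sizes shift the observable rate away from the configured value by the
  factors described above.
- VCF input assumes biallelic SNP records with GT; multi-allelic records
  are skipped with a logged count rather than decomposed.
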