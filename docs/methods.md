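# Methods

This note records the models, conventions and numerical choices behind
`phosnp`, in the spirit of a statistical package's model documentation.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and data conventions

All protein and genomic coordinates are 1-based inclusive. TSV is the
canonical exchange format; SNP tables may also arrive in a minimal VCF
dialect (CHROM/POS/ID/REF/ALT plus per-accession genotype columns;
multi-allelic lines split into one record per alt allele). Non-redundant
SNP identity is (chrom, pos, alt).

Gene models are CDS blocks grouped by Parent on either strand; the spliced,
strand-oriented CDS of every generated gene includes its terminal stop
codon, so SNPs in stop codons (premature stops, read-throughs) are
representable. The protein sequence excludes the terminal `*`; the
translation invariant is `translate(spliced CDS) == protein + '*'`, tested
for every synthetic gene. The stop symbol is a first-class 21st residue in
the substitution-cost matrix.

Effects are computed per alt allele against the **reference** CDS; two SNPs
in one codon are never combined into a double-mutant codon. A
(protein, position) pair counts once in the "affected" tally regardless of
how many alleles or accessions hit it, while the synonymous and
nonsynonymous position tallies may overlap (a position can be hit both
ways by different alleles), which is why the two class counts can sum to
more than the affected count. Percentages are reported to two decimals
with round-half-to-even. The headline "affected" percentage uses the
amino-acid-only denominator — affected stop codons are tallied separately
and exposed via `pct_affected_incl_stop` — because the arithmetic of the
published totals is only consistent with stops excluded.

## Substitution enrichment

The 2×2 layout per (from, to) pair is rows = phospho / non-phospho
positions of the from-residue, columns = substituted-to-target / not, so an
odds ratio > 1 reads "enriched at phosphosites". A position counts as
substituted if at least one accession carries that target; the synonymous
self-pair (e.g. T→T) is tested like any other target. The universe is, by
default, proteins with at least one SNP effect on a phosphosite position
("snp_on_site"); a `phosphoproteins` universe (every site-carrying protein)
is a config option, since the two readings are both defensible. Pairs
observed in neither class are reported as "never observed" and excluded
from testing and from the BH family.

Fisher's exact two-sided p sums all hypergeometric outcomes whose
probability does not exceed the observed table's (tie tolerance 1e-9
relative, needed only to absorb floating-point representation of exact
ties); the tests verify agreement with an exact integer-enumeration oracle
to 1e-12 on random tables of N ≤ 60. Odds ratios are sample estimates
a·d/(b·c) with a Haldane–Anscombe 0.5 correction (flagged) when a cell is
zero. BH adjustment delegates to `statsmodels` step-up behind the
package's own `bh_adjust` surface.

## Phosphosite-count null

p = total sites / total S+T+Y is kept as an exact rational so the
conservation identity Σ_x E_x = total observed sites holds exactly, not to
float tolerance. The expected frequency-of-count histogram is the sum over
proteins of Binom(n_STY(x), p) — the minimal model consistent with a
constant, site-count-independent phosphorylation probability; the legend
formula gives only the mean, and the binomial is the unique independent
per-residue completion of it.

## Hotspot scan

Window scores: phosphosite count (experimental mode) or sum of prediction
scores over all S/T/Y in the window (predicted mode). Windows step by one
residue; a window identical to its predecessor in its exact S/T/Y residue
set (not merely its phosphosites) is dropped, implemented as: keep window
*k* iff the residue leaving on the left or entering on the right is S/T/Y.

Background proteomes have the same number of proteins as the real one,
lengths resampled with replacement from the real length multiset, residues
i.i.d. from the global composition, each S/T/Y phosphorylated independently
with its residue-specific rate (or scored from the empirical score pool in
predicted mode). Deduplicated window scores are pooled across **all**
background proteins into a single distribution (stratification by protein
length would be a variant; pooling matches the definition of the empirical
background as the distribution of window scores). Defaults: 10,000
background proteomes in experimental mode, 1,000 in predicted mode.

Raw p-values use the add-one estimator (count of background scores ≥
observed + 1)/(N + 1), so they are never exactly zero. The Bonferroni
multiplier is the number of candidate windows tested proteome-wide per
window size — the most conservative reading of "corrected for multiple
testing". In predicted mode, real candidates (not the background) must
additionally contain at least floor(winsize × global S/T/Y frequency)
phosphorylatable residues. Significant windows merge into runs when
overlapping **or** bookended (end + 1 = next start).

Note that deduplication biases the retained-window score distribution
upward relative to the naive all-windows binomial mean (edge-S/T/Y windows
are preferentially kept); the tests therefore check the background mean
against an independent brute-force resimulation, not a closed form.

The domain-overlap test re-places each hotspot uniformly within its own
protein (same length), counts hotspot–domain intersections per permutation,
and reports add-one p-values for both depletion and enrichment.

## Gain/loss calling

Score thresholds are inclusive: ≥ 1 is a high-confidence site, ≤ −1 a
high-confidence non-site; post-substitution scores strictly inside (−1, 1)
yield no call and are counted separately, as are S/T/Y→S/T/Y central
exchanges at predicted sites (they fit neither status definition).
Experimental losses include exchanges to another phosphorylatable residue
(S→T) by default — removal of the specific site, not of phosphorylatability,
is the event of record — with a `strict` flag restricting to non-S/T/Y
targets. Premature stops introduced by an allele are written as `*` in the
accession sequence; context scoring past a premature stop is a documented
simplification. Accession protein sequences apply **all** of that
accession's coding substitutions for the gene, so ±6 contexts with multiple
nearby SNPs are scored correctly.

### Toy scorer

The shipped scorer is `3·tanh(raw/1.5)` of a central-residue offset
(S +0.2, T 0.0, Y −0.2) plus distance-weighted fixed neighbour values
(weights 0.6/0.6/0.3/0.3/0.15/0.15 at distances 1–6; basic residues
positive, e.g. R +1.0, K +0.8; helix-breaking/acidic negative, e.g. P −1.0,
D −0.8, E −0.7). The constants were chosen once so that (i) scores live in
(−3, 3) like an SVM decision value, (ii) random plant-like sequence yields
a usable fraction of high-confidence sites, and (iii) a single
cost-1 neighbour substitution close to the centre (R↔P) can carry a
marginal score across both bands — which makes every status-1 event
constructible. It is a deterministic stand-in with the interface and band
structure of a real predictor, not a trained model.

## Synthetic data

Defaults are desk-scale renditions of the study conditions: 100 proteins,
log-normal lengths (median 220, σ_log 0.45, minimum 40), a plant-like
residue composition (S/T/Y ≈ 9.0/5.1/2.9 %), per-residue phosphorylation
rates (0.08, 0.0413, 0.0302) chosen so the expected site split is
70.7/20.7/8.6 across pS/pT/pY, SNPs at 0.008 per coding base (the
coding-SNP density of large resequencing panels), 20 accessions each
carrying a given SNP with probability 0.2 (minimum one carrier), 1–4 exons
per gene with 30–120 bp introns, half of genes on the minus strand, domain
coverage 0.25 with lengths 30–80, and 20 annotation terms at base rate
0.10. Every generator output is a pure function of (config, seed); child
generators use disjoint seed sequences, so the proteome is invariant to
downstream options.

Planting is constructive. Hotspots: the window is first rewritten to
guarantee S/T/Y capacity, then the requested number of sites is forced in.
Gain/loss: a 17-residue cassette (centre ± 8, covering every ±6 window any
planted substitution can shift) is written into the protein, a codon pair
differing in one base is chosen for the engineered substitution via the
genetic code, and the cassette is verified against the toy scorer at plant
time; random SNPs are excluded from cassette codons. The T→N substitution
bias places T→N SNPs at `base_rate × factor` on predicted pT and
`base_rate` on other T, using only codons one base from asparagine (codon
choice is independent of phospho status, so the factor is preserved).
Domain placement rounds coverage·length/mean-domain-length
probabilistically so realised coverage is unbiased at any protein length.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no purifying or positive selection (so the
synthetic synonymous:nonsynonymous ratio is the mutational ~1:3, not the
~1:1 of observed polymorphism), no linkage or population structure among
accessions, no codon-usage bias, no clustering of real phosphosites in
disordered regions, and prediction scores from the toy scorer rather than a
trained predictor.

## Problem sizes and numerical choices

The calibration and recovery checks run at: 200 null replicates (100
proteins, window 10, 1,000 background proteomes) for the family-wise error
bound 0.05 + 3·SE; 50 replicates for planted 6-sites-in-10 hotspot
recovery at α = 0.05; 10 mixed-status planted gain/loss events for exact
recovery; 1,000 random tables (N ≤ 60) for Fisher-oracle agreement. The
acceptance script uses 100 null and 25 planted replicates — sizes chosen so
the whole reproduction runs in minutes on one CPU while keeping binomial
standard errors small relative to the thresholds. Background simulation is
vectorised over concatenated residue arrays in ~5-million-residue chunks;
only the S/T/Y identity of background residues is sampled, since window
scores depend on nothing else.

Known limitations: the background pools window scores across proteins
(no length stratification); empirical p-values are bounded below by
1/(N_background_windows + 1), so very strong hotspots share the same
minimal p; the GFF3 reader handles the CDS-grouped-by-Parent subset only;
and the enrichment module assumes term annotations are already propagated
(no ontology DAG handling).
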