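# Methods

This note documents the statistical definitions, conventions, and design
choices behind `mitocam`, and what its synthetic test bed does and does
not establish about real data.

## Genetic code and counting basis

All codon statistics are parameterized by an NCBI translation table; the
default is table 2 (vertebrate mitochondrial: TAA/TAG/AGA/AGG are stops,
ATA = Met, TGA = Trp), giving 60 sense codons partitioned into 12
two-fold, 6 four-fold and 2 six-fold synonymous families. Six-fold
families (Leu, Ser) are treated as single families, not split 4+2 — this
matches Wright's classical treatment and explains small discrepancies
against tools that split them.

Unless stated otherwise, codon counts exclude (a) the first codon of every
CDS regardless of identity (initiation is non-standard in mitochondria, so
the rule is positional, not "drop ATG only"), (b) stop codons, and (c) any
codon containing an ambiguous base (tallied separately rather than
guessed). Species-level statistics use counts concatenated over all 13
PCGs; gene-level statistics use per-CDS counts.

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
intervals are converted at the parser boundary. Features wrapping the
circular origin are kept as two spans joined in feature order. Annotated
CDS lengths (stop included, even when completed by polyadenylation) drive
the organization table's length bookkeeping; codon statistics use only
complete codons. Overlapping tRNA features are summed per feature, not
per base, in the organization table.

## Codon usage statistics

**RSCU.** RSCU_j = x_j / (n_i / k_i) for codon j in family i. Families
with zero total get RSCU 0 throughout and are flagged unused; within every
used family RSCU sums to k_i exactly (a tested invariant).

**ENC.** Wright's estimator generalized to any family-size spectrum: per
family with total n ≥ 2, homozygosity F̂ = (n·Σp_j² − 1)/(n − 1); the
class mean F̄_k averages F̂ over families of size k with n ≥ 2 and F̂ > 0
(F̂ is undefined at n ≤ 1 and uninformative when non-positive); ENC =
Σ_k n_aa(k)/F̄_k, with singleton classes contributing their amino-acid
count directly, capped at the code maximum (60 for table 2, 61 for table
1). If an entire size class has no usable family — routine for per-gene
ENC on very short genes — the class mean is imputed at its uniform-usage
value 1/k and the result is flagged, keeping per-gene ENC defined without
hiding the imputation. Note that F̂ depends on n, not only on the
proportions, so ENC is only asymptotically invariant to duplicating a
count table; the test suite checks near-invariance (1% relative) at
moderate counts.

**GC3s** is computed over third positions of codons from families of size
≥ 2 (all sense codons under table 2) on the standard counting basis.
**PR2** accumulates third-position bases over four-fold families only;
x = G3/(G3+C3), y = A3/(A3+T3), with quadrant II (x < 0.5, y > 0.5)
marking an AC-ending bias and quadrant IV a TG-ending bias. The ENC–GC3s
reference curve is ENC*(s) = 2 + s + 29/(s² + (1 − s)²).

## Codon aversion motifs

A gene's motif is the set of sense codons with zero count on the same
basis as RSCU (so "RSCU = 0" and "count = 0" coincide, including whole
unused families). Motif equality is set equality; the canonical string
form sorts codons lexicographically and joins with "-" purely for stable
output. Genes are eligible for motif comparison when their CDS is at least
301 bp ("over 300 bp"), which keeps 11 of the 13 PCGs (ATP8 at 168 bp and
ND4L at 297 bp fall out). Identification scores each reference species by
the number of eligible genes whose motif sets match the query exactly;
ties are broken by species name and logged as ambiguous.

## Divergence statistics

Per-gene matrices require equal row lengths — for closely related
mitogenomes the per-gene CDS length is typically identical across species,
making positional homology exact; anything else raises an error naming the
offending species rather than silently invoking an aligner.

- **Variable sites**: columns with ≥ 2 distinct unambiguous bases.
- **π**: mean over pairs of (differing sites / comparable sites), i.e.
  Nei's average pairwise difference per site. The default deletion policy
  is pairwise (sites with N are dropped per pair, so the effective length
  is per-pair); complete deletion is available by flag. With no ambiguous
  bases the two policies coincide.
- **ts/tv**: raw counts over all row pairs and differing sites (A↔G, C↔T
  are transitions). This is a count ratio, not a model-based estimate, and
  is labelled as such; multiple substitutions at a site deflate it
  relative to the underlying rate ratio.
- **dN/dS** uses Nei–Gojobori (1986): per codon and position, synonymous
  site fractions among one-step changes (changes to stops excluded from
  the denominator, so sites sum to exactly 3 per codon); observed
  differences partitioned along all orderings of the differing positions,
  excluding pathways through stop codons (falling back to all pathways if
  none survive); proportions Jukes–Cantor corrected, averaged over pairs.
  Pairs beyond the Jukes–Cantor domain (p ≥ 3/4) are dropped with a
  warning. The implementation is verified against an independently coded
  brute-force pathway enumeration to 1e-9. NG86 is a counting
  approximation: it is suitable for ranking genes by selective constraint
  and classifying selection (< 1 purifying, = 1 neutral, > 1 positive),
  not for reproducing maximum-likelihood codon-model estimates, whose
  values can differ substantially.

## ENC-matrix PCA

Rows are species, columns per-gene ENC values (imputation flags carried
through; missing cells are an error unless column-mean imputation is
requested). Columns are centered by default and not unit-scaled — ENC
shares one scale across genes — with scaling available by flag and
recorded in output metadata. Decomposition is by SVD; explained fractions
are σ_i²/Σσ², and each component's sign is fixed by making its
largest-magnitude loading positive so outputs are platform-stable.

## Synthetic data generator

The generator emulates a small clade of mitogenomes with known ground
truth. Defaults are the study conditions: 10 species; 13 genes at the
published per-gene CDS lengths (total 11,400 bp); vertebrate mitochondrial
code; genome-level family bias drawn from a Dirichlet with concentration
0.8 per family member (moderate bias — species-level ENC lands in the low
40s, the weak-bias regime typical of animal mitogenomes) and per-gene
profiles drawn from a Dirichlet concentrated around the genome profile
(concentration 50 — one mutational/selective regime shared by all genes,
so concatenated and per-gene ENC agree); target GC3 0.40 (AT-leaning third
positions), hit exactly in expectation by solving a single multiplicative
reweighting of G/C-ending codons by bisection under uniform amino-acid
usage; per-species planted aversion sets of 2 codons, pairwise distinct,
drawn from distinct families so no family is fully averted; per-branch
substitution probability 0.05 on a star phylogeny (pairwise π near 0.1,
the typical congeneric-to-confamilial mitochondrial range); ts/tv rate
ratio κ = 14 (observed raw count ratios come out lower because of multiple
hits and repair, matching the downward bias of count ratios on real data).

Amino-acid usage is uniform across the 20 families; the ancestor's codons
are i.i.d. from the gene profile with a fixed initial ATG and terminal
TAA. Each species substitutes interior sites independently with
probability p (first and last codons held fixed); a substitution is a
transition with probability κ/(κ+2), else one of the two transversions.
Afterwards, codon-level repair enforces validity: a codon realized as a
stop gets a minimal third-base edit to a sense codon; a codon realized in
the species' planted aversion set is redrawn within its family from the
species profile (zero on averted codons). Repair counts are logged in the
truth object because they perturb realized rates: recovery tests bound the
perturbation by 3 nt per logged repair on top of the Monte-Carlo standard
error.

Closed-form expectations recorded in the truth object (per mutable site,
between two star tips, α = κ/(κ+2), β = 1/(κ+2)):

- P(differ) = 2p(1−p) + p²(1 − α² − 2β²)
- transition density = 2p(1−p)α + 2p²β²
- transversion density = 4p(1−p)β + 4p²αβ

using the fact that the two transversion partners of any base are each
other's transition partners.

What the generator does **not** emulate: indels and rearrangements,
realistic tRNA/rRNA/control-region sequence (placeholder features only),
tree-structured phylogeny (a star is sufficient for π, ts/tv, variable
sites and CAM uniqueness, which are tree-free here), selection on codon
changes (all substitutions are neutral, so synthetic dN/dS sits well above
real mitochondrial values), and within-site rate heterogeneity. Passing
recovery tests therefore validates the estimators and the pipeline
plumbing, not any biological claim about real genomes.

## Numerical and policy choices

- GenBank records with no CDS parse with a warning; an empty or
  unparseable file is an error.
- Unknown gene names are kept verbatim and flagged rather than guessed.
- Sequence matrices: terminal stop codons are trimmed (uniformly) before
  codon-level statistics and kept for nucleotide-level statistics, so
  length bookkeeping matches annotated lengths.
- The pipeline's "Overall" divergence row concatenates the genes common to
  all species and reports nucleotide-level statistics only.
- All reports are written with fixed column order, UNIX newlines, '.'
  decimals and 5-decimal rounding; full-precision values go to a parallel
  JSON; no timing or other wall-clock content enters reports, so re-runs
  are byte-identical.
- Report sizes: the default test suite and the acceptance script run the
  full 10-species, 11,400 bp pipeline (seconds); statistical recovery
  tests use single 10,000-codon genes, where Monte-Carlo standard errors
  are small enough for 3-SE checks to be meaningful.
- Plot files are deliberately not produced; every figure-like quantity
  (RSCU tables, PR2 coordinates, ENC–GC3s pairs with expected values, PCA
  scores/loadings) is written as TSV for plotting with any tool.
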