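# Methods

`ptcpop` analyses premature termination codons (PTCs) segregating in a panel
of inbred strain genomes supplied as chromosome-length consensus sequences
("pseudochromosomes") on reference coordinates. This note documents the
models and rules implemented, the numerical choices made where the design
was open, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Variant model

**Gene models and QC.** A gene is one or more isoforms, each an ordered list
of CDS segments (1-based inclusive genomic intervals, transcription order).
Before calling, genes are removed if any isoform (1) has a CDS length not
divisible by three, (2) contains an internal stop in the reference
translation, or (3) does not start with ATG or end with TAA/TAG/TGA. The
annotated stop codon is taken to be the final three nucleotides of the CDS,
which makes rules (2) and (3) well defined without UTR annotation.

**Site extraction and filters.** Strain genotypes at a position are the
per-strain bases of the pseudochromosome column. Sites are dropped when any
strain carries a two-base IUPAC ambiguity code (treated as an unresolved /
heterozygous call), when the unambiguous bases observed are not exactly two
alleles, or when fewer than 60 informative (A/C/G/T) bases remain. The
60-base floor trades sample size against accuracy of the sample allele
frequency; it is configurable (`min_informative`).

**Classification.** The alternate base is substituted into the reference
codon, strand-aware, isoform by isoform: stop gain = nonsense, amino-acid
change = missense, same residue = synonymous. A site whose reference codon
is already a stop (i.e. the annotated stop codon) is excluded from PTC
calling, which also means a substitution creating a stop at the final codon
position can never be a PTC. A nonsense change is *constitutive* when it
creates a premature stop in every isoform. Truncation is measured in
codons: with L total codons in an isoform (annotated stop included) and a
premature stop at 1-based codon i,

    truncation = (L - i) / (L - 1),

the fraction of the coding region 3' of the new stop, the new stop codon
excluded. A putative PTC is accepted iff it is nonsense, constitutive, and
the truncation is at least 5% (inclusive) in *each* isoform. The codon-based
denominator is a documented choice; a nucleotide-based measure differs by at
most one codon's worth and only matters at the 5% boundary.

Splice disruption is flagged for substitutions in the terminal 2 bp of any
intron of any isoform (the canonical GT/AG dinucleotides — the minimal
base-pair-level definition of an intron boundary). Start-codon loss is
flagged for substitutions inside the ATG of every isoform, mirroring the
constitutive rule. Multiple SNPs in one codon are evaluated independently
against the reference background.

## Polarization and frequency groups

Ancestral states come from two outgroup species aligned to reference
coordinates. The rule is conservative and anchored on the reference base:
the alternate allele is derived iff reference and both outgroups carry the
same base. Sites where the outgroups match the alternate allele instead are
left unpolarized — the rule demands the reference strain share the outgroup
base — as are sites with missing or conflicting outgroup bases. Errors
therefore shrink the polarized set rather than flipping ancestral/derived
(barring parallel substitutions, which the generator does not plant).

The derived allele frequency (DAF) is the sample frequency over informative
bases, with no finite-sample correction. Frequency groups: low (DAF <= 1.5%),
moderate (1.5% < DAF <= 10%), high (DAF > 10%); both boundaries are
inclusive on the left group. DAF-matched control draws (for the allele-
imbalance comparison) use nearest-DAF matching without replacement, seeded.

## Expression summaries

Inputs are a gene x (tissue x replicate) matrix of linear-scale signal
values and a matching present/absent call matrix (4 replicates per tissue
by default). A tissue expresses a gene only when the gene is present in
*all* replicates; expression breadth is the number of such tissues.

Normalization: log10-transform each array, subtract the array mean, add the
grand mean across arrays; per tissue, take the replicate median. Per tissue,
present genes are ranked (ties broken by gene label, making the assignment
deterministic) and split into ten equal-density groups 1–10; absent genes
get group 0. Tissue specificity is computed on these discretized profiles:

    tau = sum_i (1 - x_i / x_max) / (N - 1)

over all N tissues, group-0 tissues included in N (the published formula
does not state this; including them is documented here and keeps tau = 1 for
a single-tissue gene at any N). tau is undefined (NaN), not zero, for genes
absent everywhere. Tissue-specific gene sets use tau > 0.85 (strict). The
top tissue is the argmax of the per-tissue median among expressing tissues,
ties to the lexicographically smallest label; genes expressing nowhere are
the `no_expression` category.

**Allele imbalance.** Per variant, expression of derived-allele strains is
compared with ancestral-allele strains by a two-sided Wilcoxon rank-sum
test. The exact null distribution is used for small tie-free samples
(product of class sizes <= 400), the tie-corrected normal approximation
otherwise. False discovery control uses Storey–Tibshirani q-values with the
fixed-lambda estimator pi0 = #{p > 0.5} / (0.5 m), clipped to [1/m, 1]; the
fixed lambda (no spline) keeps the estimate reproducible on small variant
sets and is asymptotically close to the spline version. Significance is
q < 0.05. Variants with fewer than two strains in either class are skipped
and reported as such.

## Enrichment statistics

Top-tissue composition of a frequency group is compared with the genome
background by a multinomial model: expected counts are group size times the
genome category proportions. The simultaneous 95% band is Monte-Carlo: draw
100,000 multinomials and take per-category quantiles at a common level.
Because counts are discrete, per-category quantiles at the Sidak level
1-(1-alpha)^(1/K) over-cover (measured ~0.974 for nominal 0.95); the level
is therefore widened by bisection to the loosest value whose simulated
family-wide coverage still reaches 1-alpha. All 2x2 enrichments are Fisher
exact tests (two-sided unless stated), and a gene carrying several PTCs is
counted once, in its highest-DAF group.

## Gene age and duplicate divergence

Genes are young (branch >= 1; originated after the Sophophora/Drosophila
subgenus split, roughly the last 60 My) or old, and young genes carry an
origination mechanism: DNA-based duplication, RNA-based duplication
(retroposition), or de novo. Cross-tabulations count genes per age class or
mechanism against the PTC-free/low/moderate/high columns; *strict* mode
keeps only duplicates whose parent is strictly older (de novo genes, having
no parent, are always included). The printed cross-tabulation counts ship
as a packaged fixture (`ptcpop/data/table2_counts.tsv`) and expand into a
per-gene dataset for exact reproduction tests.

Synonymous divergence between a pre-aligned parent-child pair uses the
Nei–Gojobori (1986) pathway-counting method: per-codon synonymous site
fractions (a change to a stop codon counts as nonsynonymous) averaged over
the two sequences; substitutions counted along all orderings of the
within-codon differences with equal weight, stop-codon intermediates
included as ordinary states; Jukes–Cantor correction
d = -(3/4) ln(1 - (4/3) p). Pairs at or past the saturation bound
(p_s >= 0.75) return NaN and are dropped from histograms. NG86 was chosen
over likelihood methods because it is exactly testable against a brute-force
pathway-enumeration oracle; the divergence-distribution contrast it feeds is
qualitative (shape), not numeric. The age trend reports per-branch PTC
fractions against branch midpoints in My (config-supplied; the oldest group
placed at -350 My by convention), with Spearman's rho and a least-squares
line; excluded branches stay in the table, flagged, and out of the fits.

## FPR-stratified resampling

Sanger-validation error rates differ by frequency group (defaults 20%, 13%,
0% for low/moderate/high). Pseudo datasets remove each variant independently
with its group's false-positive probability (Bernoulli; a fixed-count mode
removes exactly round(FPR x n) per group). Each replicate is fully
determined by (seed, replicate index). Summaries are recomputed per
replicate; the stability report gives the median, the 2.5–97.5 percentile
band, and the fraction of replicates preserving a stated ordering.

## Synthetic data: what it emulates, what it does not

The generator emits a reference genome with multi-isoform genes on both
strands (CDS split across GT..AG introns at codon boundaries, so every
isoform is QC-clean by construction; extra isoforms skip one internal
exon), per-strain pseudochromosomes with planted SNPs at exact strain
counts (round(target DAF x n)), IUPAC heterozygote codes and N masks at
configured rates, outgroup bases that satisfy or deliberately violate the
polarization rule, an expression matrix built from archetypes (broad /
single-tissue / sex-restricted / silent) with per-replicate multiplicative
noise and consistent present calls, and an age table with branch,
mechanism, and parent links. Defaults mirror the emulated study design:
162 strains, 30 tissues of which six are sex-related, 4 replicates.

It does **not** emulate demography, linkage, indels (excluded from scope),
recurrent or parallel mutation, read-mapping artefacts, or expression-
genotype coupling (unless a test plants it explicitly). Passing the planted-
recovery tests shows the calling, filtering, polarization and binning logic
is correct under the stated rules — it does not validate the rules against
real sequencing error processes.

## Problem sizes used in the shipped checks

The acceptance run uses a 200-gene, 100-strain clean panel (~60 planted
variants spanning all five classes), 1,000 permuted-label variants for the
imbalance null, 100 resampling replicates over the packaged printed-count
dataset, and 100,000 ribbon draws; these sizes give exact recovery
expectations and sub-percent Monte-Carlo error while keeping the whole run
in a few seconds.

## Known limitations

- How real pseudochromosome assemblies encode heterozygous sites is
  assembly-specific; the IUPAC choice is a stand-in isolated behind the
  het-detection predicate.
- The 5% truncation rule's original denominator (nucleotides vs codons,
  stop included or not) is undocumented upstream; the codon-based choice is
  flagged in output metadata.
- Polarization ignores ancestral misidentification and parallel mutation;
  it only ever abstains.
- NG86 underestimates dS relative to ML methods at high divergence; values
  near saturation are reported as NaN rather than extrapolated.
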