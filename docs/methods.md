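# Methods

This note documents the models, statistics and design choices behind
`citrusdiag`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic panels do and do not show
about real data.

## Problem setting

Two ancestral taxa — called R (*C. reticulata*-like) and M
(*C. maxima*-like) throughout — diverged long enough ago that many SNP
sites are fixed for different alleles between them, while others remain
polymorphic within one taxon or are older than the split. Cultivated
varieties are mosaics: each gene copy descends from one taxon or the other.
Given genotypes of pure representatives, outgroups, and admixed accessions
over a set of genes, the pipeline (i) phases gene haplotypes through a
known pedigree, (ii) finds sites that diagnose taxon of origin, and (iii)
assigns a per-gene ancestry state to every accession.

## Haplotype phasing

Phasing is strictly per gene and purely pedigree-based; no statistical
phasing of unrelated accessions is attempted, because with a handful of
interspecific heterozygotes such inferences are unreliable. Three exact
rules are used:

1. **Haploid complementation.** A haploid derivative of a diploid exposes
   one haplotype H1 directly. The second follows site by site: at a
   heterozygous site H2 carries the other allele of the pair; at a
   homozygous site the same allele; at a missing site H2 is unknown. A
   homozygous genotype contradicting H1 is a *phase conflict* (genotyping
   error or wrong haploid link).
2. **Parent attribution.** For a trio offspring, each haplotype is scored
   against each parent by counting *incongruences*: sites where the parent
   is homozygous for the allele the haplotype does not carry (heterozygous
   parents can transmit either allele and never conflict; missing sites are
   excluded from the tested count). A haplotype is attributable to a parent
   when its incongruence fraction is ≤ a tolerance (default 0 for clean
   data; exposed as `--max-incongruence` because real resequencing calls
   contain errors). The attribution must be a bijection; when both
   orientations are valid (parents locally identical) the input order is
   kept, a logged arbitrary tie-break chosen for determinism.
3. **Propagation.** A fully haplotyped parent determines its descendant's
   haplotypes: the transmitted haplotype is the parental one whose alleles
   are all contained in the descendant's genotypes (this reduces to the
   homozygous-incongruence rule at homozygous sites but also exploits
   heterozygous sites); the other haplotype follows by complementation.
   When neither or both parental haplotypes are compatible the gene is
   flagged ambiguous rather than guessed.

The panel-level driver applies rule 1 to every registered haploid
derivative, rule 2 to every recorded trio, and rule 3 iteratively until no
further accession×gene pair can be phased. Site-level conflicts are masked
(the allele becomes unknown) and reported rather than discarding the whole
gene; the conservative alternative — dropping the gene — can be recovered
by treating any flagged gene as unphased.

## Diversity statistics and marker classes

For each site and population, allele frequencies are computed from the
available observations: one per haplotype, two per pure diploid member,
missing genotypes dropped (no imputation). Gene diversity is
He = 1 − Σpᵢ², and differentiation between populations Ti and Tj is Nei's

    GST = (He_tot − (He_Ti + He_Tj)/2) / He_tot .

He_tot uses the *equal-weight* pooled frequency vector (the plain mean of
the two population vectors) by default. This choice makes GST a pure
function of the two frequency vectors, guarantees GST ∈ [0, 1], and gives
GST = 1 exactly when the two populations are fixed for different alleles —
the property the marker screen relies on. Count-weighted pooling (weights
proportional to observation counts) is available via `pooling="count"`;
with unequal sample sizes it shifts non-fixed values but preserves the
GST = 1 characterisation. GST is undefined (NaN) when a population has no
observations or the pooled site is monomorphic.

Classification per site:

* **RM** — inter-taxon GST = 1 within |GST − 1| < 1e−9. Frequencies are
  rationals, so fixed differences are exact in practice; the tolerance only
  guards against float noise and never admits near-fixed sites.
* **RR / MM** — polymorphic only within R (only within M); when intra-taxon
  subgroup labels are configured, the two subgroups must additionally be
  fixed for different alleles (between-subgroup GST = 1), mirroring how
  clear intraspecific haplotype groups are required before an intraspecific
  marker is accepted.
* **monomorphic** — no variation across the two pools.
* **other** — everything else (e.g. polymorphism in both taxa).

Membership of the pure pools comes from configuration flags, not
inference: pure representatives are declared, as prior knowledge from
earlier genomic work would be.

### Assay candidates

Allele-specific competitive PCR assays need clean flanking sequence, so
each classified site is annotated with the number of other panel SNPs
within 24 b (the "no additional SNP closer than 25 bases" criterion) and
within the 50 bp flanks, plus the verbatim 50 bp up/downstream sequences.
Candidates are ranked by (fewer SNPs within 24 b, exon before intron, fewer
SNPs within the flanks); the flanking-SNP counts are soft ranking criteria,
not hard filters, since assays with one to three flanking SNPs can still be
designed around them. Per gene the best `n_inter` interspecific and
`n_intra` intraspecific candidates are selected (defaults 2 and 1), with
shortfalls reported for genes lacking qualifying sites.

## Ancestry assignment

RM sites become oriented markers: allele_R is the allele fixed among pure-R
members, allele_M among pure-M. Genotypes are coded 0 / 0.5 / 1 (homozygous
R / heterozygous / homozygous M); the ancestral allele of a marker is the
one carried homozygously by the outgroups (unanimity by default,
configurable threshold), on the reasoning that the allele shared by taxa
outside the R/M split predates it.

Per-gene origin calls use **strict unanimity**: the gene state (R/R, M/M or
R/M) is the common state of all non-missing markers of the gene; any
disagreement yields *undetermined*. A majority-vote mode exists behind a
flag but is off by default. A panel-wide agreement rate over accession×gene
cells with ≥ 2 usable markers is emitted alongside. Note that outgroup
accessions legitimately mix R/R and M/M states across the markers of one
gene (their allele matches whichever taxon kept the ancestral allele at
each site), so the agreement statistic is meaningful for the R/M admixture
pool, not for outgroups.

For accessions with one parent from a third taxon that is fixed at the
markers (citron-like), the fixed parental allele c is subtracted: a
heterozygote {c, x} implies the other parent contributed x, a homozygote
{c, c} implies c, and a genotype lacking c contradicts the documented
pedigree and is flagged rather than reinterpreted. Markers at which the
third taxon is not fixed are skipped. The resulting calls take states such
as R/medica or M/medica.

Summary statistics:

* **introgression rate** — total M-allele dosage (R/M → 1, M/M → 2) over
  2 × determined cells of a call table; equals the mean coded value over
  determined marker cells.
* **observed heterozygosity** — fraction of 0.5 entries among non-missing
  coded values of an accession.
* **marker redundancy** — markers with identical coded columns (exact
  match including missingness by default; an optional wildcard mode treats
  missing entries as compatible and groups greedily).
* **PCA** — principal components of the accession×marker coded matrix,
  missing entries mean-imputed per marker; implemented with scikit-learn.
* **heatmap** — reporting-only clustered image of the coded matrix, rows
  ordered by average-linkage clustering on simple-matching distance.

## Synthetic panels

The generator emulates the statistical structure the analysis assumes, so
every stage can be tested against known truth without external data.

* **Site classes.** Each SNP is independently RM with probability
  `p_fixed_interspecific`, RR / MM with `p_intra_R` / `p_intra_M`, and the
  remainder split evenly between *ancestral-shared* (polymorphic in both
  taxa) and *monomorphic* (fixed in both, divergent from the outgroup).
  Defaults 0.31 / 0.087 / 0.088 mirror the observed fractions of a real
  38-gene discovery panel (1024/3347 interspecific, 585/3347 intraspecific);
  no quantitative intra-taxon diversity parameters are published for such
  panels, so these remain free parameters of the simulation.
* **Haplotype structure.** Each taxon carries two founder sub-haplotype
  groups per gene; at RR/MM sites the two subgroups of the polymorphic
  taxon carry different alleles, which gives intraspecific classification a
  clean signal to detect. Pure accessions are assigned alternately to
  subgroups (both their haplotypes from the same founder), so both
  subgroups are represented whenever a taxon has ≥ 2 pure members.
* **Hybrids.** Gamete sampling without within-gene recombination: an F1
  takes one founder haplotype from each pool; a backcross takes one of a
  virtual F1's two haplotypes per gene (independently across genes) plus a
  pure-pool gamete; a trio offspring samples one haplotype per gene from
  each named, already-declared parent and records the pedigree edge.
  Outgroups are homozygous for the ancestral allele everywhere.
* **Gene geometry.** Genes are laid along nine chromosomes with 10 kb gaps;
  exon/intron segments are random partitions (≥ 20 bp each); SNPs are
  placed ≥ 50 bp from gene ends so full flanks are always extractable.
  Defaults (38 genes, 1,432–8,650 bp, 1–14 exons, 27–243 SNPs per gene)
  match the published panel's ranges.
* **Missingness** is site×accession independent Bernoulli (default 1%,
  the order of magnitude reported for the real assay), applied last and
  never to a haploid derivative. The FASTA backbone is i.i.d. uniform
  nucleotides with ref alleles substituted — adequate for flank extraction,
  which only needs coordinates.

What the simulation does **not** model: coalescent genealogies, linkage
disequilibrium decay, within-gene recombination, genotyping error (other
than missingness), multiallelic sites, and read-level artefacts. Passing
tests therefore demonstrate algorithmic correctness under the stated
assumptions, not robustness to real-data noise; the incongruence tolerance
and the majority-vote consensus exist precisely for the noisy case but are
exercised only lightly.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere (VCF/GFF3 convention);
  half-open arithmetic is confined to internals.
* Sites are biallelic SNPs only; multiallelic or indel VCF records are
  skipped with a logged count (the assay chemistry the candidates target is
  biallelic).
* GST fixed-difference tolerance 1e−9 (see above); He of a biallelic site
  lies in [0, 0.5].
* Ref/alt orientation is arbitrary with respect to taxon; taxon orientation
  is assigned only after classification, from the pure pools.
* Zero-variance coded matrices produce a warning and all-zero PCA
  coordinates; empty call tables give NaN rates; a site with no
  observations in a population is reported `undefined`, not an error.
* Seeded `numpy.random.default_rng` throughout; a fixed seed gives
  byte-identical simulation output.

## Problem sizes used in the checks

The packaged checks run on deliberately small panels chosen to make the
tested properties hold structurally rather than marginally: a 6-gene /
~100-SNP clean panel (trio + haploid + F1 + BC1) for phasing and
classification truth recovery, and a 24-gene / 12-accession BC1 panel with
~260 RM markers for the introgression-rate property (expected 0.25, checked
within three binomial standard errors of the ~288 determined cells). The
reference-table checks and the GST grid enumeration (21×21 frequency pairs)
are exact and run in milliseconds.

## Known limitations

* The packaged 38-gene reference table is transcribed verbatim from its
  published source, including two internally inconsistent percentage
  entries for one gene (LCYb_9) and size values that do not always equal
  end − begin + 1; consumers should rely on the count columns.
* The per-gene candidate quota when a gene has no intraspecific SNPs is
  underdetermined; the selector reports shortfalls instead of substituting.
* `GenotypePanel` stores genotypes as an object-dtype matrix — convenient
  and exact for panels of up to a few thousand sites, but not designed for
  genome-scale data.
* Axis-variance figures from factorial analyses of real haplotype data are
  not reproducible from synthetic panels and are out of scope.
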