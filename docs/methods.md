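# Methods

## The selfing mutation-accumulation model

A pure line maintained by single-seed descent is modelled as a single diploid
lineage. Each generation an expected N = μ·G new heterozygous mutations
arise (μ: per-site per-generation mutation probability; G: genome length,
default 373,000,000 bp, the rice reference). Each heterozygous site
segregates independently in the selfed offspring as ¼ fixed homozygous,
½ retained heterozygous, ¼ lost — Mendelian ratios that the
`LineageParams` type pins exactly (retention ½, fixation ¼); other ratios
are rejected rather than silently accepted, because the closed forms below
assume them.

The standing heterozygous load is the geometric series
H(g) = Σ_{k=0..g−1} N·(1/2)^k = N·(2 − 2^(1−g)); the saturation limit 2N is
represented by an explicit `SATURATED` sentinel rather than a large-g
approximation, since every downstream quantity uses the limit directly. At
saturation the expected fixation flux is ¼·2N = N/2 per generation, and a
lineage g generations from its ancestor carries g·N/2 fixed mutations in
expectation. All model quantities are expectations and deliberately
real-valued.

The coding-sequence share uses a default coding fraction of 10.4/69.0
≈ 0.1507. This value is back-computed from the ratio of the model's coding
and genome-wide 50-generation expectations, because the coding genome size
behind those numbers is not independently fixed here; it is overridable
wherever it appears.

Assumptions worth stating: mutations are neutral and uniform along the
genome, sites are independent (no linkage), and the mating system is strict
selfing. Mutation-rate heterogeneity, selection, and outcrossing are out of
scope.

## The forward simulator

`lineage_simulator` is the stochastic counterpart: per generation it
resolves each heterozygous site by a (¼, ½, ¼) multinomial and adds
Poisson(N) new heterozygous sites at fresh integer loci (an infinite-sites
assumption — at hundreds of Mb, recurrent mutation at one site is
negligible). The Poisson dispersion of the new-mutation count is a modelling
choice of this package; the closed forms constrain only the mean. The
segregation probabilities are exposed as parameters so perturbed models can
be probed; the tests use this to check that the stationary resolution flux
(fixed + lost) equals N for asymmetric probabilities and that swapping
fixation and loss probabilities swaps the two fluxes.

All randomness flows through a seeded `numpy` Generator; every `Trajectory`
records its seed. Draw order over existing sites is by sorted locus id, so a
run is bit-reproducible. Stationary summaries exclude a configurable burn-in
(default 100 generations, far beyond the ~log2-scale relaxation time of the
geometric load).

## The synthetic panel generator

`synthetic_data` emulates a genebank panel: one mutant (or several) and
near-isogenic comparators diverged from a common ancestor g generations ago.

Defaults, chosen once as the package's study conditions:

- genome: a single 1 Mb chromosome, uppercase ACGT, 60 genes, target coding
  fraction 0.15. Genes are non-overlapping, on both strands, with 2–4 CDS
  segments (introns 80–300 bp with GT..AG ends), ATG start, intact stop,
  no internal stops; GFF3 is emitted as gene → mRNA → CDS with explicit
  phase.
- panel: three mutants and four comparators, each 50 generations from the
  ancestor; `mutant_a` and `mutant_b` share an extra 25-generation branch
  (clade), which carries the planted causal variant — mirroring a design
  where two related mutant accessions share the causal polymorphism while a
  third mutant and the wild types do not.
- mutation load: each accession receives Poisson(g·N/2) private fixed
  homozygous SNVs at uniform positions, and each clade the same for its
  shared branch. The per-generation N on the toy genome defaults to 0.09 —
  the 373 Mb model's per-bp density scaled to 1 Mb times an excess factor,
  reflecting that genebank panels carry more observed differences than the
  single-lineage theory predicts (residual heterozygosity, curation history);
  it is a single config field.
- planted causal variant: a 4-bp CDS insertion (frameshift) by default;
  `stop_gained` and `missense` plantings are also supported. It is placed
  mid-CDS of a configurable gene, homozygous-alt in its carriers, and never
  perturbed by noise.
- noise: 3% of background sites get one heterozygous call and 2% one missing
  call in a random accession, to exercise the homozygosity filters. Every
  noise event is recorded in the truth manifest so exact oracles can be
  replayed from `truth.json` alone.
- evidence files: a toy land-plant protein alignment for the planted gene
  (nine comparative species, ~80% column identity, the planted residue kept
  fully conserved; the reference row is ungapped) and a per-gene expression
  table in which the planted gene is always flagged and other genes are
  flagged with probability 0.3.

What the generator does *not* emulate: sequencing error and coverage
variation, indel-rich backgrounds, structural variants, multi-chromosome
genomes, linkage between sites, UTRs and alternative transcripts. Passing
end-to-end tests therefore demonstrate the correctness of the set logic,
annotation arithmetic and ranking — not robustness to raw-data artefacts,
which live upstream of this package's VCF input boundary.

Coordinates are 1-based inclusive on disk (VCF, GFF3) and 0-based half-open
internally; indels use the VCF anchor-base convention. Same seed ⇒
byte-identical files.

## VCF comparison

`load_matrix` ingests a multi-sample VCF (via pysam) into a dense matrix of
hom_ref / het / hom_alt / missing codes, splitting multi-allelic records into
biallelic rows: each sample is re-coded by its copy number of the row's ALT
allele, with other ALT alleles counting as reference. Unsorted input and
missing GT are hard errors naming the offending record.

`target_specific` implements the near-isogenic filter: a record is selected
iff every target is homozygous-alt and every comparator homozygous-ref; any
heterozygous or missing call among the involved accessions excludes the site
(dropped, not imputed — pure lines should be homozygous, so a het call is
evidence of artefact or residual heterozygosity either way).

`pairwise_difference_rate` counts positions (a split multi-allelic position
counts once) where two accessions' genotype calls differ, divided by the
reference length. By default het-vs-hom differences count; `hom_only=True`
restricts to homozygous pairs. Rows where either call is missing are skipped
— a missing call asserts no allele, so no difference can be claimed. The
formula measures a difference density, so the output names it
`difference_rate` and reports `similarity = 1 − difference_rate` beside it.

## Effect annotation

`effect_annotator` re-implements the minimal SnpEff-style taxonomy the
workflow needs. Per overlapping transcript: coding SNVs are translated
codon-aware on the coding strand (standard nuclear code; reverse complement
for −); substitutions are classed synonymous / missense / stop_gained /
stop_lost / start_lost with the protein change rendered `R238S`-style.
Coding indels are frameshift iff the net CDS length change ≢ 0 (mod 3),
otherwise inframe insertion/deletion; an insertion counts as coding when
both flanking bases lie in the same CDS segment, and a deletion by the
number of CDS bases it removes. Intronic variants within 2 bp of a CDS
boundary are splice_site (HIGH) — the common convention; the window size is
a constant, not configurable. Variants overlapping no transcript are
intergenic. The impact mapping is fixed: HIGH = frameshift, stop gain/loss,
start loss, splice site; MODERATE = missense, inframe indel; LOW =
synonymous; MODIFIER = intron/UTR/intergenic.

A reference-allele mismatch at the variant position raises immediately; it
is the cheapest guard against off-by-one coordinate bugs. `filter_by_impact`
deduplicates calls by variant×gene keeping the most severe, and keeps
HIGH/MODERATE by default.

Degenerate cases and their resolutions: an insertion at an exact CDS/intron
boundary is classed splice_site rather than coding (its effect on the
protein is undefined without a splicing model); indels are not normalized —
inputs are assumed left-aligned, a documented contract.

## Prioritization

The qualitative judgement "is the altered residue conserved, is the gene
expressed in the right tissue" is operationalized as a linear score:

    composite = w_impact·points + w_cons·conservation + w_expr·expression

with points HIGH = 1.0, MODERATE = 0.5 (LOW = 0.25, MODIFIER = 0 defined for
completeness), default weights (1.0, 1.0, 0.5), and missing evidence
contributing 0. Conservation is the fraction of non-gap aligned sequences
carrying the reference residue at the variant's protein position (for
frameshifts, the first affected residue); a gap-free fully identical column
earns the `*` symbol, a score ≥ 0.9 the `:` symbol. Ties are broken by
(impact severity, genomic position, gene id), making the ranking independent
of input order; scaling all weights by a positive constant preserves it. The
report always exposes the raw evidence columns so the ranking can be
re-judged by eye — the linear score is a transparency device, not a claim
that evidence combines additively in nature.

## Pipeline and reproducibility

`run_pipeline` composes load → target_specific → annotate → filter →
prioritize, writing every intermediate (`specific_variants.vcf`,
`annotations.tsv`, `candidates.tsv`, `report.tsv`) plus a run manifest with
the package version, seed and a SHA-256 of the config. Outputs contain no
timestamps, so identical configs produce byte-identical reports. Stage
failures propagate wrapped with the stage name; an empty candidate set is a
warning, not an error.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: 1 Mb
toy genomes with 60 genes, panels of 7 accessions with a few dozen variants,
5,000-generation simulator runs, and 100-seed end-to-end recovery sweeps.
These sizes make every oracle exhaustively checkable (brute-force per-site
scans on ≤1,000-site fixtures) while exercising the same code paths a
genome-scale run would take.

## Known limitations

- One transcript per gene in the toy data; multi-transcript genes are
  annotated per transcript but canonical-transcript selection is not
  implemented.
- No UTR or regulatory annotation: a causal variant acting through
  expression change (promoter, epigenetic) would be invisible to the
  HIGH/MODERATE filter.
- The difference rate inherits the VCF's notion of callable positions; it
  does not model inaccessible genome.
- Conservation scoring consumes a given alignment; building alignments is
  upstream.
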