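# Methods

## Model and assumptions

The package implements the gene-discovery strategy for an autosomal
recessive disorder segregating in consanguineous families, under the
identity-by-descent (IBD) hypothesis: the causal allele entered each
family once through a common ancestor, so affected individuals are
homozygous by descent for it and for a flanking haplotype.

**Relatedness.** Kinship and inbreeding are computed by the classical
recursion over the pedigree digraph: φ(a,a) = ½(1 + F_a) with
F_a = φ(father_a, mother_a), and, expanding the argument of greater
generation depth (which is never an ancestor of the other),
φ(a,b) = ½[φ(a, father_b) + φ(a, mother_b)]. Founders are assumed
unrelated and non-inbred; known founder relatedness must be encoded by
adding ancestor records. Generation depth comes from a topological sort
of the parent→child graph (lexicographic tie-break for determinism);
consanguinity loops are ordinary diamonds in that DAG and need no special
handling. Autosomal inheritance only — no X-linked kinship.

**Filter cascade.** Per family: (i) trio IBD filter — proband
homozygous-alternate AND both parents heterozygous; a missing call in any
trio member disqualifies the variant rather than fabricating inheritance;
when parents are unsequenced the parental condition is dropped and only
proband homozygosity is required; (ii) region filter: exonic or splice;
(iii) effect filter: non-synonymous or nonsense SNVs and frame-shifting
indels; splice-region variants pass regardless of effect class, in-frame
indels and synonymous changes do not; (iv) exclusion-database filter;
(v) control-panel filter. Candidate lists of the two families are then
intersected on full variant identity (chromosome, position, ref, alt
after multi-allelic splitting and left-trim normalisation), and survivors
ranked by predictor consensus. Every filter is contractive and
idempotent; the frequency and effect filters commute (both are pure
per-variant predicates) — these algebraic properties are tested.

**Exclusion database.** A frequency record becomes a member iff it is not
flagged pathogenic, has frequency information, and the frequency is at
least 1%. The boundary is deliberate: "below 1%" is removed, so exactly
1% is retained. The control panel contains every variant observed
homozygous-alternate in at least one of the unaffected control exomes
(heterozygous control carriers do not exclude a recessive candidate).

**Predictor consensus.** Per-tool damaging rules default to: SIFT-like
score < 0.05 (strict), PolyPhen-like > 0.5, PROVEAN-like ≤ −2.5,
categorical equal to "disease_causing". A variant is flagged
`prioritized` when every tool that scored it calls it damaging
(unanimity); the required count is configurable. Tools are consumed as
annotation columns — no predictor is re-implemented.

**ROH calling.** Over position-sorted, non-missing calls of one sample
and chromosome: maximal windows that start and end on a homozygous call
and contain at most `max_het` heterozygous calls (default 0 — at exome
density a single het is strong evidence against autozygosity), reported
when they hold ≥ `min_variants` homozygous calls (default 10) and span
≥ `min_length_bp` (default 100 kb, the same threshold used to report
shared regions). Missing calls are skipped without breaking a run.
Boundaries are the first and last homozygous call. The scanner is
verified against an exhaustive start/end-pair enumeration oracle on all
instances up to 30 variants. Shared regions are k-wise interval
intersections of per-sample ROH calls (equivalent to a joint scan under
`max_het = 0`), kept when at least 100 kb long; the `n_variants` of an
intersection is the minimum of the contributing counts (approximate — the
exact support would require re-counting inside the overlap).

**Lengths and coordinates.** Internal coordinates are 1-based closed (VCF
convention); BED output converts to 0-based half-open. Region length uses
the difference convention end − start, and Mb rendering rounds half-up —
so 16:4,057,603–7,657,432 is 3,599,829 bp, printed "3.6 Mb", and
16:4,015,729–7,102,036 is 3,086,307 bp, printed "3.1 Mb" or "∼3 Mb".

**STR phasing and the minimal ancestral haplotype.** A child STR allele
is assigned paternal origin iff it occurs in the father's pair and the
orientation is unique given the mother's pair; both-compatible markers
stay unresolved and Mendelian-inconsistent markers are flagged, never
raised. The minimal ancestral haplotype across patients is the longest
run of consecutive panel markers at which every patient is homozygous for
the same allele (leftmost on ties); its bounds are the first flanking
heterozygous-or-discordant marker on each side (panel edge markers bound
edge-touching runs), with the span again by the difference convention.
Marker names and positions are configuration data, not hard-coded.

**Coding consequence.** codon(p) = ⌈p/3⌉, offset(p) = ((p−1) mod 3)+1;
the affected codon is mutated and both codons translated under the
standard nuclear genetic code (the gene of interest is nucleus-encoded,
so the mitochondrial table is irrelevant). A mismatch between the stated
reference base and the supplied CDS raises, guarding against off-by-one
coordinates and transcript-version drift. This is a validator for
annotated candidates, not a genome-wide annotator; no real transcript
sequence is bundled — test fixtures use a synthetic CDS whose codon 76 is
AAC (AAT would behave identically).

## The simulator

The generator emulates the study conditions: two first-cousin-loop
families (nine individuals each; the proband's parents are first cousins,
so F = 1/16), one family sequenced as a trio and the other proband-only;
14 unaffected control exomes for the homozygous-variant panel and 550
control chromosomes for allele counts; a 13-marker STR panel spanning
~8.4 Mb around the causal locus.

* **Genome.** Two autosomes (50 Mb and 90.35 Mb) with ~1,200 SNVs each —
  about one variant per 3 kb of captured exonic sequence, a deliberately
  scaled-down exome that keeps a simulation-plus-analysis cycle under a
  second. Site frequencies come from a spectrum that is Uniform(0.01,
  0.5) with probability 0.8 and a rare tail Uniform(0.0005, 0.01)
  otherwise; the rare tail is what candidate lists are made of after the
  1% exclusion rule.
* **Meiosis.** Haldane map function: crossover count per chromosome
  Poisson with mean equal to the genetic length (1 cM/Mb), positions
  uniform, no interference — interference is irrelevant at the Mb scale
  used. Founder-origin labels are carried through every transmission, so
  autozygosity is label equality and the expected autozygous fraction of
  a proband equals F exactly, site by site.
* **Causal planting.** One ancestral haplotype of the causal chromosome
  is sampled once, given the alternate allele at the causal site
  (population frequency 0), and installed as one founder copy in *each*
  family under a single shared origin label — the founder-mutation
  hypothesis made literal. Each family's causal chromosome is then
  re-dropped with rejection (cap 10,000; counts logged) until the proband
  is homozygous-alternate and no unaffected member is; parents of a
  homozygous proband are then necessarily heterozygous. Rejection rather
  than forced copying preserves the correct IBD tract structure around
  the causal site. Only the causal chromosome is re-dropped: chromosomes
  segregate independently and the acceptance condition involves that
  chromosome alone, so the conditional distribution is unchanged. With
  the default pedigree the acceptance probability is 1/64 per attempt
  (both proband alleles must descend from one specific founder
  haplotype), i.e. ~64 re-drops per family.
* **Predictor scores.** Exonic/splice variants draw per-tool damaging
  scores with probability 0.9 if causal and 0.1 otherwise — enough to
  exercise the consensus rule without modelling any real predictor.
* **Emission.** Per-family VCFs list exactly the sites at which some
  sequenced member carries an alternate allele, as a variant caller
  would; annotation, frequency (causal absent), control-panel,
  control-chromosome and STR tables cover the full site panel. One master
  seed determines every output byte; per-purpose substreams use fixed
  spawn labels so adding a stage never perturbs earlier draws.

**What the simulator does not model** — and hence what passing tests do
not show about real data: genotyping error and missingness, multi-allelic
SNVs and indels (the VCF reader handles them; the simulator never emits
them), variable recombination maps, linkage disequilibrium between
founder haplotypes beyond the planted one, population structure in the
controls, and X/Y/mitochondrial inheritance.

## Numerical and design choices

* Exact binary-representable arithmetic throughout the kinship recursion
  (F = 1/16 is exact); no tolerance needed.
* Deterministic ordering everywhere: candidate sets sorted by variant
  key, report stages in execution order, ties in predictor ranking broken
  by variant order — outputs are byte-reproducible and a seed-7 golden
  run is checked in.
* Degenerate inputs: empty VCFs yield empty candidate sets with zero
  counts; an all-heterozygous patient yields an empty minimal haplotype
  with a diagnostic; point regions have length 0.
* The 50-replicate autozygosity check and the 100-seed end-to-end
  recovery check are the package's own calibration of the simulator
  against pedigree theory; both run in well under a minute at the default
  problem sizes.

## Known limitations

* Proband-only families contribute only alternate-carrying sites to
  their VCF, so a short autozygous tract can fall below the 10-variant
  ROH minimum and escape the shared-region map (observed in ~3% of
  simulations; the candidate cascade itself still recovers the variant).
  Denser capture or a lower `min_variants` trades this against spurious
  short runs.
* `n_variants` on intersected regions is a lower-bound approximation.
* The ROH scanner is a deterministic window rule, not a likelihood-based
  autozygosity HMM; no LOD scores or cM-aware lengths are computed.
* Compound-heterozygous and de-novo inheritance models are out of scope.
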