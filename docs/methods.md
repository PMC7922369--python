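# Methods

This note documents the models and procedures implemented in
`homeobias`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Family identification

Membership in the transcription-factor family is decided by an ungapped
position-specific scoring matrix (PSSM) over the conserved N-terminal
NAC domain.  The bundled profile is built from a 50-residue consensus:
each position emits the consensus residue with probability 0.7 and every
other residue uniformly, scored as log2 odds against a uniform
background.  A window whose summed log-odds reaches the threshold
(default **15 bits**) is a domain hit; a protein with ≥ 1 hit is a
family member.  At 15 bits a random 500-residue protein has an
essentially zero false-positive probability (the null window score is
~10 standard deviations below threshold), while any protein carrying
the intact consensus scores far above it.  `X` residues score 0.

This is a deliberate simplification of a profile-HMM search: no indel
states, one domain model, a bits threshold instead of an E-value.  It
is exact on the synthetic benchmark (the generator plants the consensus
verbatim) and adequate for well-conserved domains, but it will miss
genuinely divergent or indel-containing family members in real data —
for production surveys of real genomes, substitute hits from a real
profile-HMM scanner via the `DomainProfile` file interface.

Protein characteristics use bundled, user-editable tables:

* **Molecular weight** — sum of average residue masses + 18.02 Da for
  one water; `X` counts as the mean residue mass.
* **Isoelectric point** — bisection on the Henderson–Hasselbalch net
  charge (EMBOSS-style pK set: termini plus C, D, E, H, K, R, Y) on
  pH ∈ [0, 14] to |charge| < 1e-4.  The charge curve is strictly
  decreasing, so the root is unique; 200 iterations bound the error far
  below the reporting precision (2 dp).
* **Transmembrane segments** — Kyte–Doolittle hydropathy, window 19
  (odd, the classic choice for TM detection), cutoff 1.6 (the
  conventional "possible transmembrane" level).  Maximal runs of
  qualifying window centers are merged and reported as the covered
  residue span.  On random background composition roughly one protein
  in ten shows a spurious window at this cutoff, mirroring the
  heuristic's behavior on real globular proteins; the synthetic
  benchmark therefore scores *sensitivity* on planted segments, not
  specificity.
* **Subdomains a–e** — reported as fixed fractional intervals of a
  domain hit (18/18/24/22/18% of the hit span), since the subdomain
  architecture is schematic, not coordinate-defined.

## Phylogeny

Distances are alignment-free: d(a, b) = 1 − shared / min(total), where
*shared* counts k-mers (default k = 3) in both sequences with
multiplicity and *total* is each sequence's k-mer count.  This is
deterministic, fast, symmetric and bounded in [0, 1].  It is a
coarser signal than alignment distances — adequate for separating
gene families and recent homeologs (the regimes exercised here), not
for deep phylogeny.  Any user-supplied `DistanceMatrix` can be dropped
in where alignment-based distances are preferred.

Trees are built with the Saitou–Nei neighbor-joining agglomeration
(Q-criterion minimization with the standard branch-length formulas).
Two rules make runs reproducible where the textbook algorithm is
ambiguous:

* taxa are processed in sorted-label order and Q-ties pick the smallest
  (i, j) index pair, so the result is invariant to input order;
* a negative branch-length estimate is clamped to 0 with the deficit
  moved to its sibling branch (standard practice), preserving the pair's
  summed length.

On additive matrices NJ is exact: the acceptance suite verifies exact
topology and patristic-distance recovery on random additive 5–8-taxon
matrices, the 3-taxon closed form to 1e-12, and agreement with an
exhaustive least-squares topology enumeration at 5 taxa.

**Bootstrap support** resamples k-mer columns of the count matrix with
replacement (the alignment-free analogue of resampling alignment
columns), rebuilds the tree per replicate, and reports the fraction of
replicates containing each reference bipartition.  Support is written
onto internal node labels of the Newick output.  The default replicate
count for the `phylo` CLI is 1000; in the end-to-end pipeline bootstrap
is opt-in (`bootstrap_reps`, default 0) because resampling a
family-scale matrix hundreds of times is the single most expensive step
and support values are not consumed downstream.

**Group/subgroup assignment** is nearest-anchor classification on the
same distance matrix: 13 reference anchors (two per Group-I subgroup —
SNAC, ANAC34, SND, NAC1, NAM/CUC3, TIP — plus one Group-II anchor) map
each gene to Group I with a subgroup, or Group II with none.  Distance
ties go to the lexicographically smallest anchor id and are flagged
ambiguous.  The bundled anchor FASTA is a synthetic stand-in
constructed around the bundled domain consensus and per-subgroup
signature peptides; for real analyses supply the curated reference
proteins for your family via `--anchors`/`--anchor-map`.

## Homeolog components

"Clustered together" is operationalized as connected components of the
homology graph whose edges are pairwise distances ≤ `link_threshold`
(default **0.35**).  On synthetic data the within-component distance is
≲ 0.15 (members share a recent ancestor, ~2% substitutions) while
between-component distances exceed ~0.43 (only the domain consensus and
subgroup signature are shared), so 0.35 sits in a wide margin; for real
data the threshold is exposed on every interface.

Component classes, decided from the members' subgenome composition:

* **group** — exactly 3 members, one per subgenome, same chromosome
  number (a complete triad on homologous chromosomes);
* **cluster** — ≥ `cluster_min` (default 4) members covering all three
  subgenomes with ≥ 2 copies in at least one (tandem expansion).  The
  minimum is configurable because "more than four" in survey usage is
  ambiguous between > 4 and ≥ 4; ≥ 4 is the default since a triad plus
  one tandem duplicate already satisfies the two-copies-in-one-subgenome
  condition;
* **pair** — members from exactly two subgenomes, any size (one
  homeolog lost);
* **orphan** — a singleton or a single-subgenome component;
* **unresolved** — a 3-member, three-subgenome component on
  non-matching chromosome numbers: the triad definition explicitly
  requires homologous chromosomes, so these are surfaced rather than
  silently counted as groups.

An unplaced gene (no chromosome) whose placed partners cover exactly two
subgenomes is inferred to come from the missing third; partners covering
one or all three subgenomes leave it unknown.  Inference feeds
classification, so a pair plus an inferred third member counts as a
group.

## Promoters, cis-elements, SNP density

Coordinates are 1-based inclusive throughout (GFF3/VCF native).  The
promoter is the 1500 bp upstream of the start codon, strand-aware and
truncated at chromosome ends (the sequence shortens; nothing is
padded).  Cis-elements are exact IUPAC matches on both strands against
a bundled, editable consensus table; the bundled strings are literature
consensi, not the position-weight matrices of a motif server, and
short patterns (5–6 bp) match random sequence at an appreciable rate —
which is why element abundance uses **gene-presence counts** (a gene
with three ABRE matches contributes one), the convention of family
surveys.  Overlapping and self-overlapping matches are all reported.

SNP density is SNPs/kb over three windows per gene — body
[start, end], and strand-aware 2-kb up/downstream flanks — with flank
truncation shrinking the denominator.  The Group I vs Group II contrast
is the arithmetic mean of gene-body densities per phylogenetic group;
an empty group is reported as absent, never 0.  Densities are reported
in SNPs/kb only (percent-style density figures are ambiguous between
per-bp and per-kb conventions and are not emitted).

## Expression bias

DEG calling on a replicated control/treatment FPKM matrix:

* log2FC = log2((mean_t + 1) / (mean_c + 1)) — pseudocount-stabilized;
* p-value from a **pooled-variance two-sample t-test on
  log2(FPKM + 1)**.  The test is pluggable.  Pooled t was chosen over
  Welch's t because replicate groups here are equal-sized and
  approximately homoskedastic on the log scale, where the pooled test
  is exact under the null; Welch's Satterthwaite approximation is
  measurably conservative at n = 2–3 (≈ 3.5% rejections at nominal 5%
  in simulation), which would defeat the nominal p < 0.05 rule.
  `welch_log2_test` is provided for unequal-variance designs;
* a gene is `up` if p < α and log2FC ≥ log2(fc), `down` symmetrically;
  the fold-change boundary is inclusive (a gene at exactly 2-fold with
  p < 0.05 is called).  Raw p-values by default, matching the fixed
  p < 0.05 convention; Benjamini–Hochberg correction is available via
  `fdr=True` but off by default, so at α = 0.05 roughly 5% of truly
  unresponsive genes will be called — a property of the convention, not
  a bug;
* two replicates per condition are accepted with a warning (df = 2;
  power is low), fewer are an error.

Component verdicts follow the table in the README.  Two reading choices
are explicit and flagged:

* "all members weakly expressed" means every member's **mean FPKM over
  all samples** < 1 (`per_sample_floor=True` switches to requiring
  every individual sample below the floor);
* "similar expressed pattern" is read as *direction-only* agreement —
  all members DE the same way — with no magnitude criterion, since any
  magnitude band would be arbitrary;
* components where all members are DE but in mixed directions do not
  fit the sub/neo dichotomy; they get the distinct status `divergent`,
  reported separately and folded into the neofunctionalization column
  of the survey-style summary (a diverged response pattern is the
  operative signal there).

Pooled summaries over multiple stresses add per-condition counts: a
component responding under two stresses counts once per stress.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with every planted property recorded in ground-truth tables:

* 21 chromosomes (7 × A/B/D), default 300 kb each, uniform-random
  nucleotides except coding sequence (back-translated from the proteins
  with a fixed one-codon-per-residue table) and planted promoter motif
  instances.
* Family structure: 60 groups / 5 clusters (size 4–6) / 4 pairs
  (size 2–3) / 10 orphans by default, plus 30 background genes.  Each
  component descends from one random ancestor protein carrying the
  domain consensus and its subgroup's signature peptide; members differ
  by 2% substitutions outside the conserved blocks.  5% of members get
  a planted 25-residue hydrophobic C-terminal segment (membrane-bound).
* Placement: non-overlapping, inter-gene gaps ≥ 2·flank + 200 bp
  (4.2 kb at defaults) so no two genes' flank windows or promoters
  collide and every SNP-density region is unambiguous.
* SNPs: Poisson per region at the gene's rate — 0.9/kb for Group-I
  components, 2.0/kb for Group-II and background — positions uniform,
  REF taken from the genome.
* Expression: FPKM = lognormal baseline (μ = 3.5, σ = 0.8 on the
  natural-log scale, i.e. median ≈ 33 FPKM — typical of expressed
  regulatory genes and comfortably above the 1-FPKM removal floor) ×
  2^(±effect) in treatment samples of effect-carrying genes ×
  2^(σ_noise·N(0,1)) per cell.  Planted labels per multi-member
  component: *sub* (all members carry the same-direction effect), *neo*
  (exactly one member carries it), *null* (none), at fractions
  0.34/0.33/0.33; default effect |log2FC| = 2, noise σ = 0.25, n = 3
  replicates per condition.  One treatment condition per bundle — the
  pipeline is run once per stress, matching how per-stress datasets are
  analyzed.
* Determinism: one seed feeds per-stage `SeedSequence` streams; the
  same config and seed give byte-identical files.

**What passing the synthetic benchmark shows — and does not.**  Exact
recovery on synthetic data demonstrates that the chain of
identification, clustering, classification and testing is internally
correct and correctly wired, because every planted signal is
recoverable by construction: the domain is planted verbatim, homeolog
divergence is far below the linkage threshold, and effect sizes are
large relative to noise.  Real data violate all of these at once —
divergent domains, gene conversion and translocations that blur
subgenome assignment, alignment-worthy sequence divergence, overdispersed
and correlated expression noise, batch effects.  Recovery rates on this
benchmark are therefore upper bounds, not forecasts, for real genomes.

## Problem sizes

Default study-scale runs (253 genes, ~225-member family) complete in a
few seconds per stage.  The validation suite uses 1,000 random
triangles and 200 additive 5–8-taxon matrices for NJ, 50 × 10-kb
sequences for the motif-scanner oracle, 100 random layouts for SNP
windows, 2,000 null genes for test calibration, and two full
generate-and-analyze runs for the determinism check — sizes chosen so
each check is statistically meaningful while the whole suite stays
interactive.

## Known limitations

* The PSSM scan has no indel states; divergent family members with
  insertions inside the domain are missed (use a profile-HMM scanner
  upstream for real surveys).
* k-mer distances saturate for deep divergence; the NJ guarantees
  proven here are for the distance matrix given, not for distance
  estimation itself.
* The homology graph approximates "phylogenetic clade + synteny"
  evidence by thresholded sequence similarity cross-checked against
  chromosome numbers; no collinearity-block detection is performed.
* The DE model is a per-gene t-test on transformed FPKM; count-based
  shrinkage models (negative binomial) are out of scope, as are read
  mapping and FPKM estimation.
* Indel variants, codon-usage realism and read-level simulation are
  out of scope for the generator.
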