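# Methods

## Model and assumptions

The package analyses a tetraploid under a strict two-subgenome
(allopolyploid) model: the tetraploid genome is treated as the union of
two diploid subgenomes, one per parental lineage, observed through
genotype calls made against a pseudo-reference built from parent 1's
consensus RAD loci. Three processes shape the tetraploid's SNP
composition relative to its parents and are what the category scheme
separates:

- retention of both parental alleles at sites that discriminate the
  parents (homeo-SNPs, CAT5);
- replacement of one subgenome's alleles by the other parent's through
  backcrossing/introgression, or fixation of one parental allele by
  lineage sorting (inter-specific SNPs, CAT1/CAT2);
- mutation after the polyploid's origin (derived SNPs, CAT3/4).

Everything that violates the model's observability assumptions —
heterozygous parents, more than two distinct tetraploid alleles, an
ambiguous reference base — is routed to OTHER rather than forced into a
category. Triploids and higher polyploids with more than two subgenomes
are out of scope for classification (the reduction utilities accept
ploidies 2–8).

The classifier is deterministic and purely per-site; it uses allele
*presence* only. Called allele dosage (2+2 vs 3+1) is never used to
subdivide categories because callers estimate polyploid dosage poorly.
CAT3 and CAT4 are reported as a single CAT34 bucket; the available
sub-definitions are not recoverable from allele presence alone.
Orientation is fixed and recorded in every output header: CAT1 means the
tetraploid matches the pseudo-reference parent (parent 1) only.

Site admission: both samples must reach `min_depth` (default 8×, the
de novo assembly's base-calling threshold) at the site; indel records are
skipped with a reason code; a sample without a VCF record at a position
covered by its depth table is taken as homozygous reference, while a
position absent from the depth table counts as zero depth and is skipped.
No depth-ratio criterion between the two samples is applied.

## γ estimation

For an ordered quartet (outgroup, P1, H, P2), a site is informative when
P1 ≠ P2, the outgroup carries the allele of exactly one parent, and H
carries the allele of exactly one parent. With n₁, n₂ concordant counts,
γ̂ = n₂/(n₁+n₂). This concordant-site ratio is an intentionally simple
estimator: it is exactly binomial under the generator's model, satisfies
γ̂(P1↔P2) = 1−γ̂ identically, and is unbiased for the simulated admixture
proportion (checked to ±0.02 at γ ∈ {0.1,…,0.9} in the test suite). It is
not the invariants-based estimator of dedicated hybridization-detection
tools, and p-values are not comparable to theirs.

Significance gates the event classification. The null "no admixture
signal" is the boundary γ ∈ {0, 1}; it is tested by an exact binomial
test of the minority pattern count against a small null proportion
(`null_boundary`, default 0.02 — allowing for stray discordance from
noise or ILS at the boundary), one-sided, which covers both boundary
cases simultaneously. Bonferroni correction is applied across all triples
of a run. Both the boundary proportion and α are explicit parameters:
with many informative sites the test is sensitive, and equidistant taxa
will legitimately show significant γ̂ ≈ 0.5 without recent hybridization
— the event classes are a screening device, not proof of hybridization.
Significant γ̂ in 0.4–0.6 is classed *recent*, 0.1–0.4 and 0.6–0.9
*intermediate* (low/high), and outside 0.1–0.9 *excluded*; non-significant
results are *nonsignificant* and zero informative sites yield an
*undefined* result with a reason code.

Heterozygous (IUPAC-coded) sites in sequence input are resolved by
sampling one allele uniformly per site per row under the run's seed,
which preserves expected pattern frequencies; fully ambiguous symbols
(N/X) make a site uninformative. In taxon mode, pattern counts are summed
over all individual combinations of a triple before estimation;
individual mode tests each individual separately. The two modes coincide
for single-individual taxa.

## Ploidy reduction

`AATT → AT`: reduction keeps allele presence and discards dosage. One
distinct allele doubles; two distinct alleles are written in lexicographic
order; for more than two distinct alleles (possible at 6x/8x or from
caller artifacts) the two most frequent are kept with lexicographic
tie-breaks — a case the presence-coding convention does not itself define,
so the rule is fixed here and order-independence is tested. uSNP
selection keeps the first polymorphic site per locus in coordinate order.
A flag selects whether polymorphism is judged before or after reduction;
the two orders are provably equivalent under presence-based reduction
(reduction never removes a site's only variation, since any heterozygous
call keeps two alleles), so the flag exists for interface completeness
and is tested as an equivalence.

## Synthetic-data generator

The generator defines the study conditions for all recovery tests. Loci
are 86 bp (single-end RAD read length after adapter/barcode removal) and
default to 1,000 per dataset. An ancestral genome is drawn uniformly;
parent 1 keeps the ancestral state and parent 2 mutates each site with
probability `parent_divergence` (default 0.01), Jukes–Cantor-style
(uniform among the other three bases, no indels — indel variation belongs
to the upstream assembly, which is out of scope). Optional
`parental_heterozygosity` makes a parent heterozygous at a site (IUPAC
consensus), populating OTHER; the default is 0 (fully homozygous
parents), which makes the plain F1 scenario exactly 100 % CAT5.

The tetraploid is the F1 union of both parents' haplotype pairs
(unreduced gametes). Then `round(backcross_fraction × n_loci)` loci,
chosen uniformly, have their parent-2 haplotypes replaced by parent-1
haplotypes — under the fixed orientation this creates CAT1 truth at
formerly discriminating sites (CAT2 arises when the parents' roles are
swapped). Post-origin mutations fire per site with probability
`post_origin_rate` on one uniformly chosen haplotype. There are no
published estimates for either rate in this system; defaults are 0 and
tests vary them explicitly (0–0.5 backcross, 0–0.004 post-origin). Truth
categories are derived from the final simulated allele sets together with
the recorded generating event, so every polymorphic site has exactly one
label. Loci exceeding the assembly caps (20 SNPs/locus; 4 alleles/site is
automatic for a 4-letter alphabet) are re-drawn.

Emission mimics the external mapping/variant-calling stage: a
single-contig pseudo-reference FASTA with a locus-offset TSV, one VCF per
sample (4-allele GT for the tetraploid; REF=N where the reference parent
is heterozygous), and a per-position depth TSV. Depth is drawn per locus
(RAD coverage is per-cluster) from a negative binomial with mean
`depth_mean` (default 52, a typical cluster depth) and shape
`depth_dispersion` (default 5, overdispersed like real RAD coverage), and
locus dropout is applied per sample at `missing_rate`. Per-sample RNG
streams are keyed by sample identity, so swapping which parent is the
reference changes no random draws — parent-swap symmetry (CAT1↔CAT2) is
exact when depth skipping is disabled and holds up to re-calling noise
otherwise.

What the generator does **not** emulate: sequencing/genotyping error,
allele-balance-dependent dosage error, paralogy, restriction-site
dropout, and linkage between loci. Classification recovery on this data
is therefore a correctness check of the rules and the I/O path, not a
measurement of robustness to caller error; the depth filter and skip
accounting are exercised through the overdispersed depth and dropout
only.

Quartet sites for γ are simulated directly: at each informative site P1
and the outgroup carry the ancestral allele, P2 a derived allele, and the
hybrid carries the P2 allele with probability γ. This makes γ̂ exactly
binomial, giving closed-form expectations for calibration tests.

## Numerical and design choices

- Coordinates are 0-based half-open internally; all VCF/depth I/O and the
  public coordinate map are 1-based. The locus order in the
  pseudo-reference is sorted locus id, so reference construction is
  independent of input order.
- All randomness flows from a single integer seed through named
  `SeedSequence`-style substreams (CRC32 of the stream name), so stages
  can be re-run independently yet reproducibly.
- Percentages are reported over classified polymorphic sites (the five
  categories including OTHER); invariant and skipped sites are excluded
  from the denominator but fully accounted in the conservation identity
  classified + skipped + invariant = total input sites, which the
  pipeline enforces.
- Degenerate inputs: empty locus sets, empty call streams, zero
  informative sites, fully missing calls and out-of-range coordinates all
  raise or return explicit reason-coded results rather than silently
  proceeding.
- Problem sizes in the test and acceptance runs (≤1,000 loci × 86 bp;
  50 replicates × 10,000 quartet sites; 20-seed monotonicity batches at
  120 loci) were chosen so each property is measured well inside its
  sampling tolerance while a full run stays interactive on one CPU.

## Known limitations

- The two-subgenome assumption: hexaploid/octoploid categorization and
  triploids are unsupported by design.
- CAT1/CAT2 cannot distinguish backcrossing from incomplete lineage
  sorting; the γ stage and its event classes are subject to the same
  confounding at extreme γ.
- The γ significance procedure is a documented, conservative default, not
  a reimplementation of any published tool's test; absolute p-values
  should not be compared across methods.
- Real-data category proportions depend on sampling of putative parents;
  with wrong or missing parents the OTHER fraction inflates, which the
  model reports but cannot correct.
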