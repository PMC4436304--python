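# Methods

This note records the models and procedures the package implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want spelled out.

## Probe search and domain validation

Candidate domains are found by exact Smith–Waterman local alignment of
each proteome entry against the probe set (one representative domain per
subfamily), with BLOSUM62 and affine gap costs open 11 / extend 1 — the
classic protein-BLAST defaults. E-value statistics are deliberately
absent: nothing downstream consumes them, only the hit footprint. The
score floor (`min_score`, default 60) is a configuration knob, not a
biological constant; raising it can only remove candidates (monotone
filtering, property-tested). When the local alignment is truncated at
either end, the candidate span is padded with subject residues out to the
probe's full width, because validation judges sub-region presence and
needs full-width candidates.

Validation applies two rules to a candidate aligned (semi-global,
BLOSUM62) onto the profile's representative sequence:

1. at least two of the three structural sub-regions — basic, helix1,
   helix2 — must be present, where "present" means ≥80% of the
   sub-region's columns carry candidate residues with no internal gap run
   longer than 2 columns (the tolerance keeps single-residue alignment
   jitter from flipping verdicts);
2. strictly more than 60% of the consensus columns covered by the
   candidate's footprint must match the consensus residue set.

The denominator counts only consensus columns inside the candidate's
aligned span: genome annotations truncate termini, and a candidate should
be judged on the columns it covers. Columns where no residue reaches the
60% conservation tier carry no consensus and never enter the denominator.
The shipped profile (`data/domain_profile.yaml`) defines a 60-column
domain with 24 consensus columns at the 60%/80% tiers and the four
sub-region spans; `build_profile` re-derives all of this from any
user-supplied reference alignment.

## Reference building

All validated proteins are aligned with a progressive scheme: guide order
by UPGMA on 3-mer distances, then profile–profile Needleman–Wunsch using
expected BLOSUM62 column scores with a linear gap penalty of 8 per
column. Divergence between two records ("BL") is the leaf-to-leaf
patristic distance on the NJ tree built from p-distances of that
alignment; a configuration switch (`mode="pdistance"`) substitutes the
raw p-distance. Pairs are labelled by the BL bands — allele < 0.03,
ortholog 0.03–0.15 (closed interval), paralog > 0.15 — and ortholog
groups are single-linkage clusters at the 0.15 cut. Single linkage can
chain a pair above 0.15 into one group; such pairs are kept but labelled
`chained`, because splitting them would make the partition depend on
input order. Within one source, byte-identical proteins are collapsed
first (tandem duplicates encoding the same protein count as one gene);
identical proteins in *different* sources are kept and land in the allele
band. Representatives follow the source priority Gr-JGI > Gr-CGP >
Ga-CGP > Gh-Uni > Go-con > mRNA, ties broken by smallest id, and codes
(`GobHLH` + zero-padded index) follow natural sort of representative ids.

## Phylogenetic classification

Three independent reconstructions over the domain alignment:

- **NJ**: Saitou–Nei on p-distances, deterministic tie-break (the pair
  with the lexicographically smallest minimum leaf labels joins),
  negative limb lengths clamped to zero. On additive matrices the
  algorithm is exact, and the test suite holds it to 1e-9 against an
  additivity oracle and cross-checks topologies against scikit-bio's
  independent implementation.
- **Bootstrap**: columns resampled with replacement, support = percentage
  of replicate trees containing each bipartition of the point tree;
  1000 replicates by default, fully seed-determined.
- **MP**: Fitch parsimony with gaps/X as missing data; exhaustive search
  over all unrooted topologies up to 8 taxa, otherwise NNI hill-climbing
  from the NJ tree with 10 seed-controlled random restarts. Ties resolve
  toward the smallest canonical Newick string.
- **ML**: the Poisson amino-acid model (equal rates, equal frequencies),
  chosen over richer matrices because the classification rule needs only
  topology concordance and Poisson keeps the likelihood closed-form
  checkable — for two sequences the MLE branch length satisfies
  p̂ = (19/20)(1 − e^(−20t/19)). Branch lengths are optimised by bounded
  one-dimensional search (tolerance 1e-6); NNI neighbours are screened at
  current branch lengths and a move is accepted when the log-likelihood
  improves by more than 1e-8, with branches re-optimised after each
  accepted move. All-gap columns are dropped with a warning.

A clade is a candidate subfamily when its NJ bipartition has bootstrap
support strictly above 88 *and* the bipartition occurs in at least one of
the MP/ML trees ("supported by at least two methods", NJ counting as
one; a flag switches to the stricter both-other-methods reading). Each
subfamily is the maximal candidate clade containing all anchors of its
name and no anchor of another; leaves in no named clade are orphans, and
leaves inside nested clades take the most specific one. Two anchors of
different names that no candidate clade separates leave both subfamilies
explicitly unresolved — never silently merged. Subfamily splits and
merges (e.g. treating S5a/S5b as distinct, or pooling S18–S22 under one
name) are expressed purely through the anchor→name map, not in code.

## Homoeolog variant analysis

`map_cds_to_genome` chains exact exon matches of the CDS onto the genomic
sequence under the GT..AG rule with a minimum intron length of 40 nt.
Among exact-coverage chains the mapper prefers the fewest introns
(iterative deepening on intron count) and, within that, the longest
leftmost exon — this uniquely rejects degenerate chains that thread
micro-exons through an inserted element. Genome of origin is the diploid
ortholog with the smaller aligned p-distance; margins below 0.005 are
flagged ambiguous rather than assigned.

Indels are maximal gap runs in the global nucleotide alignment
(match 2, mismatch −3, gap open 10, extend 0.5), reported with the CDS
coordinate on both sequences, length, frame flag (in-frame iff length mod
3 = 0) and 1-based exon ordinal. SSR tracts are maximal perfect tandem
runs of the unit (≥4 copies by default); the comparison helper reports
copy numbers per ortholog and the length difference in nucleotides.

Intron insertions are modelled as a single event: when two orthologous
introns differ in length by ≥500 nt, the split point minimising total
flank mismatches places the insertion (this tolerates substitution-level
flank divergence exactly, where a scoring alignment would fragment the
gap by chance matches inside the element). The placement is ambiguous up
to shifts wherever the flanking base repeats across the insert; the
detector enumerates these equivalent placements and keeps the one whose
direct terminal-repeat identity is maximal. A prefix/suffix repeat pair
of ≥100 nt at ≥85% identity attaches a terminal-repeat record — the
LTR-retrotransposon signature. The ~kb scale of real elements is treated
as descriptive; only the 500-nt gate decides "insertion". Structure
comparison clusters intron junction positions (cumulative CDS
coordinates, tolerance 10 nt) across orthologs and reports introns
present in some genes and absent in others as lost, keyed by consensus
ordinal. All strands are forward; callers reverse-complement upstream.

## Expression

The ΔCt model with two internal standards: per technical replicate the
reference Ct is the arithmetic mean of the two standards' Ct values
(equivalent to the geometric mean of their expression), and the relative
level is 2^−ΔCt with amplification efficiency fixed at 2.0 (no
standard-curve correction). Replicates are averaged; SEM = sd/√n is
reported for ≥2 detected replicates. A replicate is undetected when its
Ct is missing or above 40 (configurable); undetected replicates are
excluded from the mean and a gene is ND only when *all* replicates are
undetected — ND is never imputed as a number. Because the bars in
tissue-profile figures may or may not be per-gene normalised, both a raw
and a max-normalised matrix are emitted.

## Synthetic-data generator

The generator defines the study conditions the tests run under:

- **Families**: 6 subfamilies × 4 genes by default; each gene carries an
  A copy, a D copy and an allele copy of A, on 250-aa proteins with a
  60-column domain. Requested pairwise divergences (allele 0.01,
  ortholog 0.08, paralog 0.4) are converted to per-copy substitution
  rates by inverting q = 2r − (20/19)r², and consensus domain columns are
  shielded from paralog-level divergence so every planted domain remains
  a valid bHLH — as in real families, conserved columns stay conserved.
  Realised divergences are verified post hoc: each class mean must lie
  within ±30% of its target (widened to 3 standard errors for small
  families, where binomial noise on a handful of pairs dominates), every
  within-gene pair must fall below the 0.15 grouping cut and every
  paralog pair above it. A family violating these bands raises instead of
  silently shipping fixtures that no longer probe the thresholds.
- **Sources**: the two D-genome projects both receive the D copy (their
  shared genes land in the allele band), the A-genome project the A copy,
  transcript sources either genome, each with independent dropout
  (default 0.1) and a guarantee that every gene survives in ≥1 source.
- **Genes**: 630-nt CDS over 7 exons with 80–300-nt GT..AG introns;
  junctions are placed evenly with ±10-nt jitter at positions where the
  boundary cannot slide into the donor, so planted structures are
  recovered uniquely.
- **Variants**: an ortholog pair derived from one gene, with a 15-nt
  in-frame exon-6 deletion, a (GAA)₉-vs-₁₃ tract (12-nt difference) and a
  2000-nt intron-4 insertion flanked by identical 300-nt direct repeats
  (sizes follow the tetraploid case study, the insertion scaled from the
  ~5-kb element to keep fixtures desk-sized). Planted features are placed
  at unambiguous sites, kept ≥15 nt apart so alignment gap runs cannot
  merge, and excluded from the background substitution process (rate
  0.005 on the derived ortholog) — recovery is therefore expected to be
  byte-exact, and the acceptance checks hold it to that.
- **Ct tables**: Ct = ref_Ct − log₂(level) + N(0, 0.15) with two
  reference genes and three replicates; ND levels become undetected
  replicates.

What the generator does **not** emulate: insertion/deletion evolution
within domains, codon structure and synonymous/nonsynonymous asymmetry,
rate heterogeneity across sites, assembly/annotation errors other than
whole-gene dropout, and primer efficiency differences. Passing tests
demonstrate algorithmic correctness under the stated divergence bands and
noise levels, not robustness to every artefact of real annotation sets.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run entirely from generated
fixtures: 20 default families for partition recovery, 50 random additive
6-taxon matrices for NJ exactness, 100 random 5-taxon alignments against
the exhaustive parsimony oracle, a 30-taxon family for the end-to-end
pipeline (bootstrap scaled to 200 replicates there; the default stays
1000), 100 seeded variant cases, and 50 Ct-table seeds. These sizes keep
a full run in the minutes range while leaving each statistical check
well-powered. Every source of randomness flows through an explicit seed;
pipeline runs write a manifest (resolved config + output checksums) whose
hash is invariant across reruns.

## Known limitations

- The progressive aligner targets substitution-dominated protein
  families; heavily indel-ridden inputs should be aligned externally and
  supplied as gapped FASTA.
- MP beyond 8 taxa is a heuristic (NNI with restarts); no branch-and-
  bound guarantee.
- The single-event insertion model reports one dominant insertion per
  intron pair; nested or multiple co-located insertions are out of scope.
- Genome-of-origin assignment presumes both diploid orthologs are
  available and alignable.
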