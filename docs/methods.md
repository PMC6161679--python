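# Methods

This note documents the models and procedures implemented in `clonedb`, the
parameters that matter, and the choices made where the design was genuinely
open.

## Germline references and anchor geometry

References are pairs of IMGT-gap-aligned FASTA files (V and J alleles).  The
IMGT gap characters (`.`) place every allele on the standardized codon
numbering, so a single gapped position is biologically comparable across
alleles.  Two conserved landmarks drive everything downstream:

* **V anchor** — the conserved 2nd-CYS codon (IMGT codon 104) at the 3' end of
  the V segment.  Its position is computed from the gap frame
  (`3 x (104 - 1)` in gapped coordinates, mapped to the ungapped sequence).
  For read positioning we use the 9-nt context ending at the Cys codon, which
  in heavy chains covers the strongly conserved Tyr-Tyr-Cys block.
* **J anchor** — the conserved W/F-G-X-G block of the J segment, located by
  scanning each allele for a configurable motif set (default `TGGGG`,
  `TTCGG`, `TTTGG`, covering the Trp-Gly and Phe-Gly encodings) and taking
  the 5'-most hit.

The CDR3 is the interval between the two anchors, *excluding* both conserved
codons; the AIRR `junction` (CDR3 plus both anchor codons) is produced only
at the interchange boundary.  Loading validates that the length from the J
anchor to the 3' end is identical across all J alleles — the anchoring
arithmetic requires a fixed J tail, which holds for IMGT germline sets.

## Anchor-based V/J assignment

Per read: (1) every J-motif occurrence is considered, each germline J tail is
compared over the shared window by Hamming distance (positions where either
symbol is `N` or a gap carry no evidence and are skipped), and the best
placement wins; a read with no motif hit is unidentifiable.  (2) The V anchor
context is searched upstream of the J anchor (within the maximum CDR3 span,
default 99 nt, allowing 2 mismatches in the 9-mer); each germline V is then
compared over the full overlapping window up to the anchor.  The fraction of
matching compared positions is the V identity; the mutation fraction is its
complement.

**Gene ties.** Germlines statistically indistinguishable from the best one
are reported as a tie set.  With best mismatch count `m*` over `L` compared
positions, any gene with `m <= m* + max(1, ceil(p_hat * L * tau))` ties, where
`p_hat` is the sample mean mutation fraction and `tau = 0.5`.  The tolerance
scales with mutational load: a heavily mutated sample cannot distinguish
nearby alleles, an unmutated one can.  Annotation therefore runs in two
passes — the first estimates `p_hat`, the second finalizes tie sets.

**QC.** Reads with overall V identity below 60% are unidentifiable; reads
containing a 30-nt window (on compared, ungapped positions) below 60%
identity are flagged as potential insertion/deletion carriers and kept out of
clonal analysis.  Both thresholds are configurable.  Local-alignment rescue
of unidentifiable reads is deliberately out of scope.

Each identified read also records its substitution set versus the
lexicographically first allele of its V tie set, in germline-frame
coordinates.  Using a deterministic tie-set reference (rather than each
read's best allele) makes mutation sets position-comparable across all reads
of a subject, which the lineage clone method relies on.

## Sequence collapsing (copies, instances, uniques)

`N` marks a base masked for low quality, so two sequences differing only at
`N` positions are the same molecule observed twice.  Collapsing happens at
two levels: within each sample (producing sample-level uniques with a copy
number) and across all samples of a subject.  A subject-level unique carries
*copies* (duplicates summed over samples) and *instances* (number of samples
it occurred in; a lower bound on contributing cells when samples are
biologically independent replicates).

N-equality is not transitive.  Chains are resolved by a deterministic greedy
pass: candidates in decreasing copy order (ties lexicographic) merge into the
first earlier-founded group whose *founding* sequence they N-match; the final
representative is the member with fewest `N`s (tie: highest copy, then
lexicographic).  Only sequences with identical V-tie sets, J-tie sets and
aligned length are compared — collapsing across gene assignments would
corrupt clone keys.  Copy totals are conserved exactly at every level, and
collapsing is idempotent.

## Clonal inference

All three methods start from clone-eligible subject uniques (copies >= 2 by
default, suppressing sequencing-error singletons) and enforce that clone
members share subject, V key, J key and CDR3 length.  The V/J key of a
sequence is its full sorted tie set: sequences whose tie sets differ are kept
in different clones, which mirrors how differing N content splits otherwise
identical rearrangements.

* **similarity** (B cells): sequences visited in decreasing copy order; a
  sequence joins the earliest-founded clone in which its CDR3 amino-acid
  similarity to *every* member is at least 85% (configurable; `X` from
  N-containing codons is a wildcard), else founds a new clone.  The result
  satisfies the pairwise invariant by construction.
* **tcell**: clones require 100% CDR3 nucleotide identity (N wildcarded).  T
  cells lack AID and do not hypermutate, so intra-clone sequence variation is
  treated as artifact.
* **lineage**: per (V key, J key, CDR3 length) bucket, members' mutation sets
  are assembled from the stored V substitutions plus differences from the
  bucket's majority-consensus CDR3.  A neighbor-joining tree (dendropy) is
  built on symmetric-difference distances with an all-germline outgroup as
  root.  Ancestral states are reconstructed by per-mutation Fitch parsimony
  with ambiguities resolved toward the parent, keeping deep nodes
  germline-like.  Traversing from the root, the subtree at the first node
  whose accumulated mutation count reaches the budget (default 4) becomes a
  clone; members above every cut point form one residual clone.  Member
  order never enters the computation, so the method is order-agnostic.

Two filters protect the lineage budget from non-lineage signal:

1. Mutations observed in fewer than 2 bucket members are masked as likely
   sequencing error (the same thresholding recommended for lineage
   visualization).
2. Substitutions carried by *every* bucket member are treated as
   undetected-allele reference differences rather than somatic mutations.
   When a bucket's true allele differs from the tie-set reference allele,
   those positions are shared by all members regardless of clonal structure;
   left in place they exhaust the budget above the first branching point and
   merge unrelated clones (observed directly on simulated data).  This is
   the within-bucket analogue of running novel-allele detection before
   re-identification.

A consequence of path-from-root accumulation is that nested sub-lineages
deeper than the first cut point are grouped into one clone; the planted-clone
simulations here never nest lineages, so recovery tests do not probe that
regime.

## Repertoire statistics

* **Diversity**: Hill numbers `qD = (sum p_i^q)^(1/(1-q))` with `p_i` the
  fraction of the repertoire (copies or instances) in clone `i`.  Order 0 is
  richness; order 1 is evaluated exactly as the Shannon limit
  `exp(-sum p ln p)` (natural log), not by near-1 interpolation; larger
  orders weight large clones.  Profiles are non-increasing in `q`.
* **Rarefaction** (incidence-based): with `s_i` the number of replicates
  clone `i` occurs in out of `S`, the expected richness at `k <= S` drawn
  replicates is `sum_i [1 - C(S - s_i, k) / C(S, k)]` — exact under
  without-replacement subsampling.  For `k > S` richness is extrapolated
  with a Chao2 estimate of the undetected clone count from the singleton and
  doubleton incidence frequencies (`Q1`, `Q2`); the curve is continuous at
  `k = S`.  The estimator choice (hypergeometric interpolation + Chao2) is
  the standard one for biological-replicate incidence data.
* **Clonal overlap**: cosine similarity between per-sample clone copy
  vectors indexed over the full clone universe; 1 iff proportional, 0 iff
  disjoint support.
* **Clone-size distributions**: histograms of clone size measured as copies
  or as instances, with minimum-copy and minimum-instance filters.

## Partition comparison

Two clone partitions over a shared sequence universe are joined on content
(read-provenance sets, not internal ids).  Each clone is labeled against the
other partition: *identical*, *superset*/*subset* (strict containment),
*intersecting* (nonempty proper overlap), or *disjoint*; multiple labels can
co-occur (e.g. superset of one clone, intersecting another).  The report
exposes both per-label tallies (identical counts are symmetric by
construction) and exact label-combination counts.

## Relational store

Each project owns an embedded SQLite database (schema: subjects, samples,
per-read annotations, subject-level collapse, clones + membership links,
stats).  Project names are restricted to alphanumerics and underscores.
Clonal inference is per-subject: re-running it for one subject regenerates
that subject's clone rows (clone ids carry no stability guarantee across
reruns) and leaves every other subject's rows byte-identical.  The pipeline
steps — identify, collapse, clones — are individually resumable against the
store.

## Synthetic data

The generator emulates the study design the pipeline targets: one subject
sampled as several biologically independent replicates, with a repertoire of
expanded clones.  Defaults (all configurable in `SimConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `n_clones` | 20 | planted clones per subject |
| `members_per_clone` | 4–8 | distinct lineage members per clone |
| `copies_per_member` | 2–6 | raw reads (PCR copies) per member |
| `shm_rate` | 0.03 /base | expected member divergence from germline |
| `trunk_fraction` | 0.8 | share of SHM fixed in the clone ancestor |
| `seq_error_rate` | 0.001 /base | per-read substitution error |
| `n_mask_rate` | 0.002 /base | per-read low-quality N-masking |
| `n_samples` | 4 | replicate samples per subject |
| `junction_codons` | 6–15 | CDR3 length (18–45 nt, in-frame) |

Each clone draws a V and J allele and a random-insertion junction between the
V anchor end and the J motif.  Hypermutation is layered: *trunk* mutations
shared by every member (fixed during clonal expansion, 80% of the load —
sampled snapshots of expanded B-cell clones show most of their divergence as
shared trunk) and *private* member mutations (20%).  Mutations hit only
germline-templated positions, never the junction insertion or the conserved
anchor motifs — anchor conservation is the biological premise of the
anchoring method, and an anchor-destroying read would be unidentifiable by
design rather than by error.  Sequencing error and N-masking apply per read.
A truth table records every read's sample, clone, member, alleles and
mutation load.

The synthetic germline sets are structurally realistic (families, allele
variants 4 substitutions apart, IMGT gap regions, conserved anchors, fixed J
tails) but randomly generated in content.  What passing tests show is that
the algorithms recover a known ground truth under this model; what they do
not show is performance under features the generator omits: insertions and
deletions, SHM hotspot bias, junction-region hypermutation, primer and
chimera artifacts, allele variants absent from the reference, and unequal
sequencing depth across replicates.

## Numerical and determinism choices

All internal coordinates are 0-based half-open; conversion to 1-based happens
only at format boundaries.  Tie sets, bucket iteration orders and greedy
visit orders are all explicitly sorted, so every pipeline stage is
deterministic for a fixed input.  Simulation uses a single
`numpy.random.default_rng(seed)` stream; the same seed yields byte-identical
FASTA output.  Problem sizes in the test-suite and in the acceptance script
(roughly 500–1,100 reads, 20 planted clones, 4 replicates) were chosen as the
smallest repertoires at which all planted structure (clone multiplicity per
bucket, replicate overlap, eligible-copy filtering) is actually exercised.

## Known limitations

* No D-gene assignment (by design; light chains are supported naturally).
* No local-alignment rescue: reads with indels or mutated anchors stay
  unidentifiable/flagged.
* Copy numbers are subject to PCR amplification bias; instances are the more
  robust abundance measure and both are carried everywhere.
* Greedy methods (similarity, T-cell with Ns, collapsing) depend on copy
  order only through deterministic tie-breaks; the lineage method is the
  order-agnostic alternative.
* Cross-subject clones (e.g. donor/recipient chimerism) are out of scope:
  clones never span subjects.
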