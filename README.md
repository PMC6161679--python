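# clonedb

Analysis of adaptive immune receptor repertoire (AIRR) sequencing data:
anchor-based V/J germline assignment, N-tolerant sequence collapsing, clonal
inference, repertoire statistics and interchange with the AIRR tool
ecosystem, backed by a queryable relational store.

## Who this is for

Immunology groups doing bulk B-cell or T-cell receptor sequencing of one or
more subjects, each sampled through several biologically independent
replicates (tissues, time points, aliquots of sorted cells).  The package
takes quality-controlled FASTA/FASTQ reads (or pre-annotated AIRR/Change-O
tables), infers which germline V and J alleles produced each read, collapses
duplicates into subject-level unique sequences, groups them into clones, and
summarizes the repertoire.

## The methods at its core

* **Anchored germline assignment.**  Instead of local alignment, each read is
  positioned by two conserved landmarks: the W/F-G-X-G motif of the J segment
  and the 2nd-CYS (codon 104) context of the V segment, located through the
  IMGT gap frame.  Germlines are ranked by Hamming distance over the shared
  window (N bases carry no evidence); alleles statistically indistinguishable
  from the best become *gene ties*, with a tolerance that scales with the
  sample's mutational load.  Reads with <60% V identity are unidentifiable;
  a 30-nt window under 60% identity flags a potential indel.
* **Copies / instances / uniques.**  Sequences differing only at N positions
  collapse within samples and then across a subject's samples.  Each unique
  sequence carries *copies* (raw-read duplicates, PCR-inflatable) and
  *instances* (replicates it occurred in — a lower bound on contributing
  cells).
* **Three clonal-inference methods**, all constrained to one subject, V key,
  J key and CDR3 length: greedy pairwise **CDR3 amino-acid similarity**
  (>= 85%, for B cells), exact **CDR3 nucleotide identity** (for T cells),
  and order-agnostic **lineage separation** — a germline-rooted
  neighbor-joining tree per bucket, cut where the mutation count accumulated
  from the root reaches a budget (default 4).
* **Repertoire statistics.**  Hill diversity
  `qD = (sum_i p_i^q)^(1/(1-q))` (q=0 richness, q=1 the Shannon limit),
  incidence-based rarefaction with Chao2 extrapolation, cosine clonal
  overlap between samples, clone-size distributions.
* **Partition comparison.**  Clones from two methods/tools are labeled
  identical / subset / superset / intersecting / disjoint by exact set
  algebra over shared sequences.

Details, parameter tables and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

Everything below runs on simulated data with known ground truth — no
downloads needed:

```python
from clonedb import (
    SimConfig, simulate_repertoire, synthetic_germline_set,
    annotate_sample, collapse_sample, collapse_subject,
    CloneConfig, eligibility_filter, infer_similarity, diversity,
)
from clonedb.repstats import partition_abundance, overlap_matrix

germlines = synthetic_germline_set(seed=7)
sim = simulate_repertoire(SimConfig(seed=42, n_clones=10), germlines)

sample_uniques = []
for meta in sim.metadata:
    anns, summary = annotate_sample(
        sim.reads_by_sample[meta.sample_name], meta, germlines
    )
    print(f"{meta.sample_name}: {summary['n_identified']}/{summary['n_reads']} "
          f"identified, mean mutation {summary['mean_mutation_fraction']:.3f}")
    sample_uniques.extend(collapse_sample(anns))

uniques = collapse_subject(sample_uniques, "S1")
print(f"{len(uniques)} subject-level unique sequences, "
      f"{sum(u.copies for u in uniques)} total copies")

eligible = eligibility_filter(uniques, CloneConfig())
partition = infer_similarity(eligible)
print(f"{len(partition)} clones from {len(eligible)} eligible sequences")

abundance = partition_abundance(partition, "copies")
print(f"richness {diversity(abundance, 0):.0f}, "
      f"order-2 diversity {diversity(abundance, 2):.2f}")
names, overlap = overlap_matrix(partition)
print(f"overlap({names[0]}, {names[1]}) = {overlap[0, 1]:.3f}")
```

Output:

```
S1_rep1: 62/62 identified, mean mutation 0.030
S1_rep2: 68/68 identified, mean mutation 0.029
S1_rep3: 57/57 identified, mean mutation 0.032
S1_rep4: 60/60 identified, mean mutation 0.030
134 subject-level unique sequences, 247 total copies
10 clones from 51 eligible sequences
richness 10, order-2 diversity 8.97
overlap(S1_rep1, S1_rep2) = 0.887
```

Reading it: all reads were identified because the simulation plants no
indels and conserves the anchor motifs; the mean mutation fraction (~0.03)
matches the configured hypermutation rate; the similarity method recovers
exactly the 10 planted clones; order-2 diversity below richness reflects
unequal clone sizes; and the high replicate overlap follows from clones
being spread across all four replicates.

The same pipeline is available from the shell:

```bash
clonedb synth --seed 42 --n-clones 10 --out data/
clonedb admin-create myproject configs/
clonedb identify configs/myproject.json data/v_germlines.fasta data/j_germlines.fasta data/
clonedb collapse configs/myproject.json
clonedb clones configs/myproject.json similarity
clonedb clone-stats configs/myproject.json
clonedb export configs/myproject.json airr out.tsv
```

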