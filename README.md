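# taxoscaffold

Reference-database curation and taxonomy assignment for SSU rRNA
metabarcoding, built around a putative-taxon cluster scaffold:

- **Reference hygiene** — leave-one-out nearest-centroid screening of
  rank labels (k-mer profiles), exact deduplication, and a two-parent
  chimera screen.
- **Alignment** — semi-global pairwise identity (free terminal gaps,
  affine internal gaps) and best-hit database search with
  maxaccepts/maxrejects scan control.
- **Clustering** — UCLUST-style greedy length-sorted centroid clustering
  and a seven-level hierarchical scaffold (species radius 1.5% divergence,
  then 2.5 / 3.5 / 4.5 / 6 / 11 / 12.5% at shallower levels).
- **Classification** — three tiers: per-rank-thresholded LCA, bootstrapped
  k-mer (SINTAX-style, 80% cutoff) classification, and single-best-hit
  annotation that propagates putative `cl_<rank>_<centroid>` labels and
  masks under-supported ranks with `?`.
- **Database construction** — `build_reference` (screen → dedupe → merge
  outgroups → two-tier annotation of unannotated long reads), `ksgp_plus`
  (fuse LCA lineages with the cluster scaffold so every sequence is fully
  labelled), and relaxed best-hit read classification.
- **Coverage diagnostics** — best-hit similarity profiles, cumulative
  curves by query rank/abundance, paired two-database comparisons.
- **Synthetic communities** — seeded generator for labelled references
  with rank-calibrated divergences, query OTUs, mislabels, duplicates and
  chimeras, with machine-readable truth. This is the test substrate for
  everything else.

## CLI

All stages are exposed under one entry point:

```bash
# synthetic fixtures with truth tables
taxoscaffold simulate --outdir fixtures/ --n-queries 20 --seed 3

# screen a labelled reference FASTA (headers carry ;tax=d:...,p:...)
taxoscaffold clean --in ref.fasta --ranks domain,phylum,class \
    --report screen.tsv --out clean.fasta

# seven-level putative-taxon scaffold
taxoscaffold cluster --in seqs.fasta --levels default --out scaffold.tsv

# classify queries (lca | boot | besthit)
taxoscaffold classify --method lca --queries otus.fasta --db ref.fasta \
    --out tax.tsv --seed 17

# full database construction
taxoscaffold build --core core.fasta --outgroups euk.fasta \
    --unlabelled long.fasta --outdir db/

# database coverage (one db, or paired with --db2)
taxoscaffold coverage --queries otus.fasta --db a.fasta --out cov.tsv
```

FASTA headers use UPARSE-style `;size=N` abundances on queries and
SINTAX-style `;tax=d:...,p:...` lineage annotations on references;
GTDB-style `d__...;p__...` strings are accepted on input. Taxonomy tables
are TSV with `?` marking unresolved ranks.

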