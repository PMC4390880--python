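# arcogkit

Phylogenomic analysis toolkit for quantifying a focal clade's phylogenetic
affinity across large sets of gene trees, built around four pieces of
machinery:

- **Genome weighting** (`arcogkit.genome_weighting`) — relative genome
  weights from a rooted species tree by a two-pass branch-length
  distribution: subtree lengths leaf-to-root, then the root weight split
  among children proportionally to *(incoming branch + subtree length)*.
  Closely related genomes share weight, damping taxon-sampling bias.
- **Phyletic patterns** (`arcogkit.phyletic_patterns`) — weighted
  clade-representation profiles over ortholog-cluster presence/absence,
  core-gene selection (≥ 0.75 representation in every non-excluded clade),
  tree-candidate selection (≥ 4 clades above 0.5), an exclusivity index
  `R_E = (min in-set count + 1e-4) / (max out-set count + 1e-4)` with a
  strict `> 10` screen, and 1–3 contribution units per screened cluster.
- **Alignment filtering** (`arcogkit.alignment_filtering`) — removal of
  columns with gap fraction > 0.5 or homogeneity < 0.1 (mean pairwise
  BLOSUM62 similarity, affinely rescaled to [0, 1]), fragmented-row removal,
  and post-filter clade re-qualification at 0.5 weighted representation.
- **Clade affinity** (`arcogkit.clade_affinity`) — deterministic midpoint
  rooting, selection of the minimal node(s) covering ≥ 0.75 of the target
  clade together with ≥ 0.75 of at least one other clade, per-clade
  affinities `W_i*` / normalized `R_i*` with paralog-node averaging, and
  topology-support classification (class I basal / class II sister / X).

`arcogkit.synthetic_data` generates complete synthetic inputs — a
clade-structured species tree (13 clades by default), gene-tree sets with a
planted topology mixture, and phyletic matrices with planted
exclusively-shared gene sets — so the whole pipeline is testable offline.
`arcogkit.pipeline` orchestrates everything into deterministic TSV reports.

## CLI

```bash
# generate a synthetic input bundle
arcogkit simulate --seed 1 --outdir fixtures/

# genome weights from a rooted species tree (root weight = leaf count)
arcogkit weigh --tree fixtures/species.nwk --root-weight auto --out weights.tsv

# representation, core selection, exclusivity screen
arcogkit patterns --membership fixtures/membership.tsv \
    --clades fixtures/clades.tsv --weights weights.tsv \
    --exclusive-in Thermococci,Methanococci --outdir patterns_out/

# alignment cleaning
arcogkit clean --aln aln.fasta --max-gap 0.5 --min-hom 0.1 \
    --out clean.fasta --report sites.tsv

# per-tree affinity + topology classification
arcogkit affinity --trees fixtures/trees/ --clades fixtures/clades.tsv \
    --weights fixtures/weights.tsv --target Thermococci \
    --out affinity.tsv --summary summary.tsv

# full pipeline from YAML
arcogkit run --config pipeline.yaml
```

Gene-tree leaves are labelled `genome_id|gene_id`; the prefix before the
first `|` keys into the clade map and weight table.

## Layout

```
src/arcogkit/
  tree_io.py              tree/table/alignment data model and I/O
  genome_weighting.py     branch-length weight distribution
  phyletic_patterns.py    representation, core/candidate/exclusivity screens
  alignment_filtering.py  site and row filtering, clade re-qualification
  clade_affinity.py       midpoint rooting, node selection, W*/R*, topology
  synthetic_data.py       species-tree / gene-tree / matrix simulators
  pipeline.py, cli.py     orchestration and the arcogkit command
tests/                    unit, property, and acceptance suites
scripts/acceptance.py     acceptance report generator
```
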