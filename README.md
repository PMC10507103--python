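# endosym

Comparative-genomics toolkit for highly reduced bacterial endosymbiont
genomes recovered from host metagenome assemblies. It covers the full
analysis chain:

- **Binning** — separate endosymbiont contigs from a host assembly using GC
  content, mapped coverage, and PCA of canonical tetranucleotide frequencies
  (2-means on the standardized feature matrix, with optional per-contig
  taxonomy calls overriding the clustering).
- **Read recruitment** — bbduk-style exact canonical k-mer matching
  (`k=31`, min matched k-mer fraction 0.05) to pull reads into a target bin.
- **HGT screening** — classify genes as host→symbiont horizontal-transfer
  candidates from taxon-labelled BLAST-like hit tables: valid hits need
  E-value < 1e-5 and query coverage > 50%; a candidate needs strictly more
  than 2× as many fungal as bacterial hits (≥ 3 fungal when there are no
  bacterial hits). Queries whose fungal hits are all from an excluded
  lineage (default Glomeromycotina) are set aside unless their product
  matches a PknD/LRR exception pattern. Includes flanking-gene context,
  a composition-based contamination flagger for fungal assemblies, and a
  separate phage-origin filter (coverage bound inclusive: ≥ 50%).
- **Genome statistics** — coding density and pseudogene/repeat/phage genome
  fractions from interval unions, protein-length distributions and
  reduction percentages, annotated-vs-hypothetical Wilcoxon rank-sum tests
  with Bonferroni correction, product-pattern counts (e.g. XerC/XerD), and
  presence/absence matrices.
- **Synteny** — promer-style maximal exact amino-acid anchors over all 36
  reading-frame pairs (default ≥ 6 aa, Mollicutes translation table),
  greedy collinear chaining (gap ≤ 30 aa-equivalents), a two-axis weighted
  filter retaining blocks with a single match in each genome ("1:1"), and
  single-copy-ortholog collinearity scores.
- **Cophylogeny** — Robinson–Foulds congruence between host and symbiont
  trees under a leaf association, with a permutation test (null = shuffled
  associations), plus seeded clade assignment.
- **Synthetic data** — seeded generators for every input above with known
  truth: two-source metagenomes (order-3 Markov composition), reads,
  annotations with planted feature-class fractions, hit tables with planted
  HGT genes, rearranged genome pairs with known blocks, and
  congruent/incongruent tree pairs.

## CLI

Every subcommand accepts `--config PATH` (flat `key=value` file holding all
thresholds), `--seed INT`, and `--log-level {debug,info,warn}`, and writes
TSV outputs with a `#` header recording the version and config hash.

```
endosym simulate {metagenome|reads|annotation|hits|synteny|trees} --out DIR
endosym bin      --assembly asm.fasta --depth depth.tsv [--tax tax.tsv] --out bins.tsv
endosym recruit  --reads reads.fasta --target target.fasta --out ids.txt
endosym hgt      --gff ann.gff3 --hits hits.tsv --out report.tsv [--exceptions FILE] [--unique-taxa]
endosym contam   --assembly asm.fasta --depth depth.tsv --hitflags flags.txt --out flags.tsv
endosym stats    --gff a.gff3 [--gff b.gff3 ...] --out summary.tsv [--patterns FILE]
endosym synteny  --a A.fasta --b B.fasta --out DIR
endosym ortho-links --table orthologs.tsv --out links.tsv
endosym cophylo  --host host.nwk --symb symb.nwk --assoc assoc.tsv [--nperm 999] --out result.tsv
endosym clades   --tree t.nwk --seeds seeds.tsv --out clades.tsv
```

Depth is supplied as a 2-column TSV (contig id, mean mapped depth) — SAM/BAM
parsing is out of scope. Hit tables are BLAST outfmt-6 plus three appended
columns: subject kingdom (`fungal|bacterial|archaeal|viral|other`),
`;`-joined subject lineage, and query length (query coverage is computed as
`aln_len/qlen` when no explicit column is present).

The iterative recruit→reassemble loop used to close endosymbiont genomes is
exposed as the single `recruit` step; reassembly is an external tool and the
loop is driven by the user.

## Conventions

- Intervals are 0-based half-open in memory and 1-based inclusive on disk
  (GFF3).
- N bases are excluded from GC and tetranucleotide denominators.
- Tetranucleotides and k-mers are canonical (pooled with the reverse
  complement), so composition and recruitment are strand-invariant.
- Circular genomes are handled linearly.
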