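# ogphylo

Genome trees of prokaryotes from **overlapping-gene (OG) pairs**.

Two adjacent genes form an OG pair when their coding regions — optionally
extended by fixed regulatory margins (385 bp upstream of the 5' end, 50 bp
downstream of the 3' end) — overlap by at least 1 bp. OG pairs matched
across genomes through bidirectional-best-hit (BBH) orthology become the
characters of a pairwise distance

```
D = w_o * (r / n) + w_c * (1 - 2n / (x_i + x_j))        (w_o = 1, w_c = 2)
```

where `n` is the number of orthologous OG pairs shared by the two genomes,
`x_i`/`x_j` their total OG counts, and `r` the minimum weighted
genome-rearrangement distance (reversals and translocations — including
fusions and fissions — weight 1, block-interchanges weight 2) between the
two signed orders of the matched pairs. `r` is computed in polynomial time
by adjacency-graph cycle/odd-path accounting (`r = n - c - i/2`) and is
validated against an exhaustive breadth-first oracle over the actual
operations on small instances. Trees are built with UPGMA or
neighbor-joining, and branch robustness is assessed by jackknife resampling
(each genome independently loses a fraction e⁻¹ ≈ 37% of its OG pairs per
replicate, order of survivors preserved; default 1,000 replicates) followed
by majority-rule consensus.

Works with uni- and multi-chromosomal genomes, linear or circular replicons.

## Layout

| module | contents |
|---|---|
| `ogphylo.io_formats` | GenBank + gene-table readers, BLAST tabular reader, PHYLIP matrix writer, Newick IO, gene filtering (keyword / HGT-list exclusion) |
| `ogphylo.og_identify` | regulatory-region extension, OG-pair detection, directional patterns (unidirectional / convergent / divergent) |
| `ogphylo.orthology` | BBH orthologs (E ≤ 1e-8, coverage ≥ 0.85 both sides, similarity ≥ 45%), orthologous OG-pair matching |
| `ogphylo.rearrangement` | signed genome orders, weighted rearrangement distance, BFS oracle, elementary operations |
| `ogphylo.distance` | combined OG distance, matrix assembly, per-pair diagnostics |
| `ogphylo.trees` | UPGMA, NJ, bipartitions, majority-rule consensus |
| `ogphylo.jackknife` | OG-pair resampling and consensus supports |
| `ogphylo.synth` | synthetic dataset generator with known tree / orthology / event history |
| `ogphylo.cli` | `ogphylo` command-line tool |

## CLI

```bash
# make a synthetic 6-genome dataset with known ground truth
ogphylo simulate --tree "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2);" \
    --genes 120 --seed 1 -o data/

# validate inputs, then run the full pipeline
ogphylo validate -i data/
ogphylo run -i data/ -o out/ --method upgma --jackknife 1000 --seed 1
```

`run` consumes a directory of `<genome>.genes.tsv` gene tables (or GenBank
files) plus per-pair BLAST tabular files `hits.<a>.vs.<b>.tsv` (12 or 14
columns; 14-column includes qlen/slen) or two-column ortholog tables
`orthologs.<a>.vs.<b>.tsv`. It writes per-genome OG reports, a pair
diagnostics TSV (n, r, x_i, x_j, term values), a PHYLIP distance matrix, the
point-estimate tree, the jackknife consensus tree (integer percent
supports), and a manifest JSON with parameters and input checksums. Same
inputs + seed ⇒ byte-identical outputs.

Single stages are exposed as `ogphylo identify-ogs` and `ogphylo orthologs`.

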