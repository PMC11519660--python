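# mitocomp

Comparative analysis of circular mitochondrial genomes, built around the
kind of study that sequences two frog mitogenomes (*Rana jiemuxiensis*,
17,506 bp; *R. hanluica*, 17,505 bp) and compares them with twenty
congeners: annotation arithmetic on the circle, nucleotide composition
and codon-usage bias, pairwise molecular-evolution statistics, and
gene-order rearrangement inference.

## What it computes

**Annotation arithmetic** (`mitocomp.genome_model`) — gene features on
1-based inclusive circular coordinates; lengths that wrap the origin;
intergenic spacers with the usual sign convention (negative = overlap);
signed gene-order extraction; per-gene sequence extraction with
L-strand reverse complementing. Readers/writers for a tab-separated
annotation dialect, GenBank flat files, FASTA and BED.

**Composition and codon usage** (`mitocomp.composition_stats`) — base
percentages on the unambiguous-base denominator, strand skews

    AT skew = (A − T)/(A + T)        GC skew = (G − C)/(G + C),

codon counts and relative synonymous codon usage under the vertebrate
mitochondrial code (RSCU(c) = count(c) divided by its synonymous
family's mean; a uniformly used family has RSCU 1 everywhere), and
start/stop-codon classification including the incomplete T-- / TA-
stops completed by polyadenylation.

**Molecular evolution** (`mitocomp.molevol`) — Kimura two-parameter
distances d = −½ ln(1−2P−Q) − ¼ ln(1−2Q) with pairwise deletion;
sliding-window nucleotide diversity π; Nei–Gojobori (1986) Ka/Ks with
pathway averaging and Jukes–Cantor correction; an entropy-based
substitution-saturation index with a seeded Monte-Carlo critical value;
neighbor-joining trees (scikit-bio) as plumbing.

**Gene-order rearrangements** (`mitocomp.gene_order`) — circular signed
gene orders over the 39-token mitogenome vocabulary, canonicalized by
rotation/strand normalization at an anchor gene (COX1 by default);
exact-match pattern classification; single-event inference of
**TDRL** ("tandem duplication – multiple deletion": a block is
duplicated in tandem and one copy of each gene is lost — feasible
exactly when the derived block arrangement is two ascending runs of
ancestral positions) and **transposition** (excise a block, reinsert it
elsewhere), each validated against a brute-force enumeration oracle.

**Synthetic data** (`mitocomp.synthetic`) — seeded generators for
annotated genomes in any of the three Rana gene-order patterns, K80
sequence-pair divergence, CDS pairs with a chosen Ka/Ks, and gene-order
perturbations with ground truth.

**Pipeline/CLI** (`mitocomp.pipeline`, `mitocomp` command) — `mitocomp
run --config run.cfg` executes everything over a directory of genomes
and writes TSV/JSON tables plus a reproducibility manifest; individual
subcommands (`annotate-stats`, `composition`, `rscu`, `distances`,
`sliding-pi`, `kaks`, `saturation`, `njtree`, `gene-order`, `simulate`)
wrap single stages.

## Worked example

```python
from mitocomp import datasets, gene_length, spacer_table, extract_gene_order
from mitocomp.gene_order import infer_transposition
from mitocomp.synthetic import PATTERNS

rj = datasets.rj_annotation()
print(len(rj), gene_length(rj.feature("ND5"), rj.genome_length))
st = spacer_table(rj)
print(st.n_overlaps, dict(st.entries)["ND5"])
ev = infer_transposition(PATTERNS["pattern2"], PATTERNS["pattern3"])
print(ev.moved_block, ev.insert_after)
```

prints

```
39 1788
13 624
('ND5',) CR
```

i.e. the 39-feature annotation's longest protein-coding gene (ND5) is
1,788 bp; the genome has 13 overlapping junctions and a 624 bp interval
between ND5 and ND6; and the rare third Rana gene order is reached from
the dominant one by moving ND5 alone to just behind the control region.

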