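# evoattract

Tools for asking whether groups of organisms evolve continuously or fall
into discrete **genome attractors** — stable configurations toward which a
group's genomes drift and stay.  The package re-implements two complementary
instruments for protein families (the motivating use case is cytochrome b,
the classic mitochondrial phylogenetic marker), together with the
orbit/distance geometry built on their outputs and a seeded codon-evolution
simulator so that everything is testable without external databases.

## The two methods

**Semihomologous comparison.**  Instead of scoring aligned residues as
merely identical or different, each pair *(a, b)* is classified through the
codons that can encode it under a chosen genetic code (NCBI tables 1 and 2
built in, custom tables loadable):

* `R` — homologous: *a = b*;
* `#` — semihomologous via a **transition**: some codon of *a* becomes a
  codon of *b* by a single A↔G or C↔T exchange;
* `$` — semihomologous via a **transversion**: a single-point codon path
  exists, but only through purine↔pyrimidine exchanges;
* `−` — every codon pair differs at two or three nucleotide positions.

A pairwise comparison reports %R, %(#+$), %(−) over the comparable
positions and the `#/$` factor (transition/transversion position ratio,
undefined when no `$` positions exist).  An all-against-all dot matrix of
the same classes is available for visual inspection.

**Randomly-encoded MLP ensemble.**  Each teaching protein (length-normalized
to *L* residues, default 400) is turned into a 5·*L*-bit vector by mapping
every character to a random five-bit code, and a fully connected three-layer
sigmoid network (hidden size *m* = round(√(n·k)) by the geometric pyramid
rule; for n = 2000 inputs and k = 36 outputs, m = 268) is trained by on-line
backpropagation (learning rate 0.3, momentum 0.1) until the epoch RMSE
against one-hot targets drops below 0.001.  Many such networks — each with
its own random character encoding — are trained in parallel, and an examined
sequence's similarity to each teaching organism is the arithmetic mean of
the member outputs, a value in [0, 1].  Averaging across encodings
neutralizes the arbitrary choice of how characters are coded.

**Attractor geometry.**  Groups of organisms (assigned taxonomically by the
user, not clustered) are placed on orbits around a reference organism at
radius 1/s, where *s* is the group's mean similarity at the reference
output; the **distance factor** between consecutive orbits is the ratio of
the outer to the inner radius (equivalently the inverse similarity ratio,
hence scale-invariant).  **Disturbances** rank the teaching organisms
outside a group's lineage by the mean similarity the group shows at their
outputs.

## Worked example

Simulate a family of proteins descending from one 60-codon ancestor at two
divergence levels, then compare every member against the ancestor:

```sh
cat > sim.yaml <<EOF
n_codons: 60
kappa: 2.0
seed: 17
groups:
  - {name: near, n_members: 3, substitutions_per_site: 0.05}
  - {name: far,  n_members: 3, substitutions_per_site: 0.6}
EOF
evoattract simulate --config sim.yaml --out-fasta family.fasta \
    --out-groups groups.tsv --out-divergences div.tsv
evoattract group-stats --fasta family.fasta --groups groups.tsv \
    --length 60 --out stats.tsv
cat stats.tsv
```

prints (reference group first — the ancestor compared with itself):

```
group	n_members	avg_R	avg_semihomologous	avg_multi	avg_ts_tv
reference	1	100.0	0.0	0.0	
near	3	88.33333333333333	11.666666666666666	0.0	1.25
far	3	31.11111111111111	48.333333333333336	20.555555555555557	1.3932178932178934
```

The weakly diverged group keeps ~88% homologous (`R`) positions and no
position yet needs more than one point mutation; in the strongly diverged
group most homology is gone and positions requiring two or three point
mutations (`−`) have accumulated — exactly the gradient the attractor
analysis reads.
`evoattract teach` / `recognize` then score organisms against a teaching
set, and `orbits` / `disturbances` turn the similarity table into orbit
radii, distance factors and disturbance rankings.

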