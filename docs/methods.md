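# Methods

## Semihomologous classification

The premise of the semihomologous approach is that a single point mutation
in a codon is the most frequent substitution mechanism in homologous
proteins, so the meaningful unit of protein divergence is the codon-level
path between two amino acids, not their identity alone.  For a genetic code
the package precomputes a symmetric 20×20 matrix: for each unordered pair
of distinct amino acids, every codon pair (stop codons removed from both
codon sets first — a path through a stop is not an amino-acid substitution)
is enumerated.  If any pair differs at exactly one nucleotide the amino
acids are semihomologous; the position class is `#` when at least one such
single-difference pair is a transition (A↔G, C↔T) and `$` when all are
transversions.  With no single-difference pair the class is `−` (two or
three point mutations needed).  Identical residues are `R`.

Numerical/degenerate choices:

* **Transition preference.**  When both transition and transversion
  single-point paths exist, the position is `#`.  Transitions are the more
  frequent point-mutation type, which is the premise the method rests on;
  counting the pair twice or preferring `$` would be equally consistent
  internally, but the transition preference is this package's fixed
  convention.
* **Non-comparable symbols.**  Any position where either symbol is not one
  of the 20 standard residues — the pad character `−`, ambiguity codes
  X/B/Z/J, U, O, `*` — is excluded from the comparison length and from
  every percentage denominator.  Pads are a length-normalization artifact,
  not biology.
* **`#/$` factor.**  The ratio of `#` to `$` counts is reported as
  *undefined* (not 0, not ∞) when the `$` count is zero, and undefined
  factors are excluded from group averages (a group where every member's
  factor is undefined has an undefined average).  Substituting a number
  would bias group means.
* **Empty comparisons.**  A comparison with zero comparable positions
  reports NaN percentages rather than fabricating a partition of nothing.
* **Genetic code.**  Default table 1 (standard); table 2 (vertebrate
  mitochondrial) is built in because cytochrome b — the intended marker —
  is mitochondrially encoded, and the two codes classify several pairs
  differently (AGA/AGG/ATA/TGA reassignments).  Custom tables load from a
  two-column text file.  DNA alphabet internally; `U` is normalized to `T`.

## Sequence handling

No alignment is performed anywhere.  Sequences are normalized to the fixed
network input length (default 400 residues) by padding with `−` at the end
or truncating — deliberately crude, so that the recognizer sees raw
sequence structure rather than aligner decisions.  Teaching order is FASTA
file order and fixes the output-neuron assignment.

## The ensemble recognizer

Each ensemble member owns (a) a random encoding mapping every tolerated
character to a five-bit word and (b) a three-layer fully connected MLP in
which the input, hidden and output stages all apply the logistic sigmoid.
Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| sequence length L | 400 residues | network input is 5·L bits (2000) |
| hidden size m | round(√(n·k)) | geometric pyramid rule; 268 at n=2000, k=36 |
| learning rate | 0.3 | on-line gradient step |
| momentum | 0.1 | fraction of the previous weight update re-applied |
| RMSE target | 0.001 | stop when epoch RMSE over all patterns/outputs falls below |
| max epochs | 10 000 | safety cap; exhaustion is recorded, not fatal |
| versions | 50 | ensemble members, each with its own encoding |

Design choices made where the design was genuinely open:

* **Distinct codes.**  The 5-bit codes of one encoding are sampled without
  replacement from the 32 possible words, so two characters never collide
  and the encoding is invertible; an iid mode (`distinct=False`) exists for
  strict literal randomness.  The default alphabet (20 residues, pad, and
  ambiguity codes — 28 symbols) fits the 32-word capacity.
* **Input activation.**  The input layer applies the sigmoid to the raw
  bits by default (all three layers are sigmoid stages); a linear-input
  option is provided since many frameworks treat the input layer as
  pass-through.  With sigmoid inputs the bits 0/1 become 0.5/0.731 — a
  reduced but fully usable contrast.
* **Weight initialization** is uniform in [−0.5, 0.5], seeded, which is
  conventional for sigmoid networks of this size.
* **Biases** are included for hidden and output units.
* **RMSE schedule.**  The error is evaluated once per epoch over all
  patterns after that epoch's updates: RMSE = √(mean over patterns and
  output units of squared error).  Training may oscillate between epochs
  (on-line updates are not monotone) — only the stopping condition is
  guaranteed.
* **Pattern order** is fixed (file order) every epoch by default for
  maximal determinism; seeded shuffling is available.
* **Targets** are one-hot: teaching sequence *i* has 1 at output *i*.  Any
  consistent bijection between sequences and outputs is equivalent.
* **Seeding.**  A single master seed deterministically derives every
  member's encoding seed and weight-init seed (via seed-sequence spawning),
  so a taught ensemble is bit-reproducible.

The model archive is a directory (JSON metadata + NPZ weights) that
round-trips bit-exactly.

## Orbit geometry and disturbances

A group's similarity *s* to the reference is the mean member similarity at
the reference organism's output.  The group's orbit radius is 1/*s*, and
the distance factor between consecutive orbits (groups ordered nearest to
farthest — an explicit user input, assigned taxonomically, never inferred
by clustering) is radius(outer)/radius(inner) = s(inner)/s(outer) ≥ 1.
This reciprocal-similarity convention keeps factors scale-invariant
(rescaling all similarities by a constant changes no factor) and ≥ 1, and
reproduces ratio-style factors such as 1.0013 directly from the similarity
ratio of adjacent groups.  A group whose mean similarity is exactly zero
has no finite radius and is reported as a degenerate-similarity error; an
ordering inconsistent with the computed radii is rejected rather than
silently reordered.

Disturbances rank the teaching outputs outside a group's lineage (the
exclusion set is explicit user input) by the group's mean similarity there,
descending, ties broken by teaching order.

## Synthetic families

The generator emulates the structure of the real study data — families of
~400-residue proteins descended from a common codon ancestor at controlled
divergence — without being a calibrated evolutionary model.  The ancestor
is uniform over sense codons.  Each descendant evolves independently (star
phylogeny): the number of point-substitution events is Poisson with mean
`substitutions_per_site × 3 × n_codons`; each event picks a nucleotide site
uniformly and proposes the transition with probability κ/(κ+2), otherwise
one of the two transversions; events creating a stop codon are resampled.
Realized event counts are recorded per member.  Default conditions used by
the test fixtures: 400 codons, κ = 2 (a typical mammalian mitochondrial
transition bias), groups of 5 members at 0.05 / 0.2 / 0.8 substitutions per
site — divergences chosen to span nearly-identical through saturated
comparisons.

What the generator deliberately omits: selection, indels, rate
heterogeneity across sites, non-star tree shape, and codon-usage bias.
Passing tests therefore demonstrate that the machinery recovers planted
divergence structure under a neutral star process; they do not validate
taxonomic conclusions on real sequences, where alignment length variation,
lineage-specific rates and shared internal branches all intrude.

## Problem sizes in tests and the acceptance script

The network fixtures use six 60-residue teaching proteins (300 inputs,
pyramid-rule hidden layer of 42, learning rate 0.3, momentum 0.1, RMSE
target 0.01) and ensembles of one and five members; generalization is
checked on variants with 5% random substitutions.  These sizes preserve
every architectural ratio of the full-scale recognizer while keeping a
training run in the order of seconds.  The full-scale constants (2000-bit
input, 268 hidden units for 36 teachers) are asserted directly.

## Known limitations

* The recognizer's similarity scale is not an evolutionary distance; no
  correction model (Poisson/Dayhoff/JTT) is applied anywhere, by design.
* Length normalization by pad-or-cut assumes the compared proteins are
  already colinear from the N-terminus; it is wrong for proteins with
  N-terminal extensions.
* Group membership, orbit order and disturbance exclusions are user
  decisions; the package computes their consequences, it does not discover
  groups.
* Training cost grows linearly in ensemble size and epochs; the defaults
  (50 versions, RMSE 0.001) reproduce the intended experimental protocol
  and are sized for a long batch run, not interactive use.
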