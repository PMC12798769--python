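# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `garnet`, and what the test suite does and does not
demonstrate about real protein-design runs.

## Candidate mutations

A substitution is admissible only if it is phylogenetically confirmed:
the target residue must be observed in the homolog-library alignment
column mapped to that template position at least `min_count` times
(default 1 — any observed residue counts; the threshold is exposed
because practice varies). Gap characters never produce candidates, and
insertions/deletions are out of scope throughout. Mutations are
labelled `<position><new residue>` with the PDB's author numbering used
verbatim, so `4E` means "residue 4 to Glu". One mutation per position
is enforced structurally: a GA genome is a position-wise choice vector
holding the wild type or exactly one candidate.

When the library is not pre-aligned, each homolog is aligned to the
template pairwise by global Needleman–Wunsch (BLOSUM62; affine gaps
costing `open + extend·L` with open = 10, extend = 1; traceback ties
broken deterministically diagonal → up → left) and projected onto
template columns. A full progressive MSA is unnecessary because
candidate enumeration only needs per-column residue counts relative to
template numbering.

## Fitness functions

Both scores are minimized and both evaluators are pure (same inputs →
bit-identical outputs).

**HiSol.** The hydrophobicity discrepancy between a sequence and its
homolog library: Σ_p [h(seq_p) − h̄_p], where h is the
Kyte–Doolittle scale (taken from Biopython's published table) and h̄_p
the mean over the non-gap library residues in column p; columns whose
library entries are all gaps contribute nothing. The aggregation
(signed sum) and the scale are configuration options: alternative
definitions of library hydrophobicity discrepancy exist, and users with
a specific one can swap the scale or re-aggregate per column since the
score is exactly additive over positions.

**Structure energy.** At desk scale, a residue-pair contact potential:
for all pairs at sequence separation ≥ 2 whose side-chain centers
(CB, CA for glycine) lie within 6.5 Å, the Miyazawa–Jernigan contact
energy of the (possibly mutated) residue-type pair is summed. The
contact list is purely geometric, so mutations re-type contacts but
never move atoms; the score is rigid-transform invariant by
construction. This is a deliberately coarse stability proxy — it
captures that burial of compatible residue pairs is favorable, nothing
more. An `ExternalEnergyAdapter` delegates scoring to any user command
that reads a mutant PDB and prints one number (results cached by
mutation set), which is the intended route for full-atom force fields.

## Phase I: GA virtual evolution

Defaults: population 50, tournament size 3, uniform crossover at rate
0.7, per-position mutation rate 0.02 (resampling uniformly among
{wild type} ∪ candidates), elitism 2, active-mutation cap 3k (elites
legitimately carry more than k mutations; the cap only bounds drift).
These are conventional GA settings; nothing in the method depends on
their exact values, and all are configurable. Elitism guarantees the
per-generation elite score is non-increasing, which the tests assert.

Each of the m cycles gets its own RNG stream derived from
(seed, cycle index), so any cycle is reproducible in isolation and
unchained cycles are exchangeable. In `reu+hisol` mode the first
⌈m/2⌉ cycles run under the structure energy and the remainder under
HiSol (the extra odd cycle goes to the structure score — an arbitrary,
documented choice). With `chain_cycles` (the pipeline default) cycle
t+1 seeds its population from cycle t's elite so mutations accumulate
across the run; with `chain_cycles=false` every cycle restarts from
the template and the m cycles are independent replicates. Both
readings of "accumulation" are defensible and both are implemented;
the bagging benchmarks below use independent cycles because the
reproducibility mechanism — many independent noisy votes stabilized by
aggregation — is cleanest there, while chaining correlates later
cycles with earlier ones.

Elites are always expressed relative to the original template, so a
cycle's complete network is the clique over exactly the substitutions
separating its elite from the input structure.

## Phase II: network curation and selection

Merging is exact counting; the invariant
edge_count(u,v) ≤ min(node_count(u), node_count(v)) holds by
construction and is property-tested. Count files are canonical JSON
(nodes sorted by count desc then label; edges by count desc then pair),
so write∘read∘write is byte-stable.

**Exponent estimation.** The degree distribution's power-law exponent
is estimated by the discrete maximum-likelihood estimator: maximize
−g·mean(ln x) − ln ζ(g, x_min) over g ∈ (1, 12] with the Hurwitz
zeta function, x_min = 1 by default. Degrees are unweighted edge
counts — co-occurrence weights drive centrality while topology drives
the power law; mixing the two would conflate evidence strength with
connectivity shape. A degenerate degree distribution (fewer than two
distinct values) yields NaN, which curation treats as
"not in target". Recovery tests: bias < 0.05 and RMSE < 0.15 at
n = 5000 over true exponents 2.1–2.9, and ±0.15 in ≥95% of seeded
replicates at 2.2/2.5/2.8.

**Centrality.** Default `weighted_degree` (sum of incident
co-occurrence counts) because the edge weights are the evidence the
method takes pains to record; `degree`, `betweenness` and
`eigenvector` are selectable. All rankings break ties by
(occurrence count desc, label asc), making every downstream selection
deterministic.

**Curation.** Ascending removes the lowest-centrality node (batch
configurable, 1 by default for fidelity; larger batches trade
granularity for speed), recomputing centrality each step and dropping
nodes isolated by edge loss, until g ∈ [2, 3] or a node floor
(`min_nodes`, raised to at least k+i by the pipeline) would be crossed;
if the band is never reached it returns the best-g state seen with an
explicit flag — never silently. Descending ranks once on the full
network and grows the top-ranked prefix until g enters the band. On
merged networks from small toy runs the degree distribution is often
too uniform for any prefix/pruning state to reach the band; the
warning-and-best-state path is the designed behavior there.

**Selection.** For each size s in [k−i, k+i] the top-s prefix of the
curated ranking is taken (same-position clashes resolved by rank: the
higher-ranked label stays, the next-ranked node is pulled in), scored
by the active fitness delta(s) (in combined mode the unweighted sum
ΔE + ΔHiSol — any weighting is a knob), and the best-scoring size wins,
ties toward the smaller set.

**Reproducibility.** Three formulas are provided because the natural
definitions differ and none is canonical: mean pairwise |A∩B|/k
(default), |∩ all runs|/k, and mean pairwise Jaccard — all reported as
percentages, capped at 100 (the over-k variants can nominally exceed
it when run sets are larger than k). Every report states the metric
used.

## Synthetic study conditions

The generators produce every input the pipeline needs, seeded and
text-only:

* **Homolog libraries** — per-column substitution profiles: the
  template residue keeps probability 1 − sub_rate (default 0.2,
  comparable to the within-family identity of typical design
  libraries), with the remainder Dirichlet-split over up to 4
  alternatives (sharpness 0.5 — most columns dominated by one or two
  alternatives, as in real families). Columns are independent and
  indel-free; the generator makes no phylogenetic claim, so passing
  tests show the machinery is correct, not that real families look
  like this.
* **Toy structures** — ideal α-helix backbone+CB (rise 1.5 Å,
  100°/residue, radius 2.28 Å giving CA–CA ≈ 3.8 Å), sufficient for
  the contact potential; no claim of fold realism.
* **Landscapes** — additive effects with a planted beneficial subset
  (uniform in [−2, −0.5]; the remainder ~N(0, 0.05)), sparse pairwise
  epistasis on 5% of pairs (~N(0, 0.3)), optional Gaussian noise.
  With no epistasis and no noise the optimum is analytic, enabling
  exact end-to-end assertions.
* **Planted scale-free networks** — a configuration-model core with
  power-law degrees (exponent 2.5, the middle of the scale-free band)
  whose nodes carry occurrence count 5 (recurring real mutations), plus
  noise entering as one-off 2-cliques of fresh count-1 nodes — the
  exact network signature of a spurious two-mutation elite from a
  single cycle. This noise inflates only the degree-1 head, so the
  fitted exponent starts well above 3 and falls back into [2, 3] as
  noise is pruned. The residual noise at the g = 3 crossing is an
  almost fixed number (≈170 nodes for a 150-node core) set by the
  core's own degree-1 mass, so benchmark networks use a noise count
  large enough (2400) that reaching the band implies >90% of the noise
  is gone; smaller noise loads leave the exponent inside the band from
  the start and curation correctly does nothing.

## Benchmark scales

The headline benchmark uses 100 candidate mutations (one per position)
with 20 planted beneficial, three independent designs of m = 50 cycles
× n = 10 generations at k = 10, and 20 replicate experiments for the
win-rate comparison; exponent recovery uses 100 replicates of n = 5000
samples. These sizes make every property statistically comfortable
while the full suite stays in the minutes range on one CPU.

## Known limitations

* The contact-potential energy is a stability caricature; ΔE values
  are not comparable to full-atom force-field scores, and mutant PDB
  files substitute residue names without rebuilding side chains.
* HiSol here is a documented reconstruction (signed sum against
  column-mean hydrophobicity); exact published variants may normalize
  differently and should be swapped in via the scale/aggregation
  hooks.
* Curation on small dense networks frequently cannot reach the
  scale-free band; the best-g fallback is flagged but still yields a
  centrality ranking dominated by near-ties.
* Multi-chain templates, insertion codes, ligands and indels are
  rejected rather than handled.
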