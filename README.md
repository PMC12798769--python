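# garnet

GA-driven protein redesign that aggregates many short "virtual
evolution" runs through a mutation co-occurrence network.

## The problem

Protein redesign improves a template enzyme (thermostability, soluble
expression, activity) by combining substitutions that already occur in
its homologs. A genetic algorithm can search the combinatorial space of
such phylogenetically confirmed mutations, but a single GA run is a
metaheuristic: repeat it and you get a different mutant. Low
reproducibility makes any single design hard to trust.

`garnet` addresses this with a bagging-style two-phase procedure:

* **Phase I** — run *m* independent (or chained) GA cycles of *n*
  generations each over the candidate-mutation space. Each cycle's best
  final-generation individual (the *lastgen-elite*) is recorded as a
  **complete network**: a clique whose nodes are the elite's mutation
  labels (residue position + new residue, e.g. `4E`) and whose edges
  mark their co-occurrence. The *m* cliques are merged by summation into
  one weighted **mutation network**: node weight = number of cycles a
  mutation appeared in, edge weight = number of cycles a pair co-occurred.
* **Phase II** — curate the merged network toward a scale-free topology,
  monitored by the exponent *g* of a discrete power law fitted to the
  degree distribution by maximum likelihood (scale-free networks are
  expected to have *g* between 2 and 3). Curation either prunes
  low-centrality nodes (*ascending*) or grows from the high-centrality
  nodes (*descending*) until *g* enters [2, 3]. The top *k* (± *i*)
  high-centrality mutations of the curated network become the design;
  the *k* ± *i* scan keeps the set size with the best fitness
  improvement.

Mutations that matter keep re-appearing across cycles and accumulate
node and edge weight; one-off noise does not. Selecting by network
centrality therefore stabilizes the design: across repeated runs the
selected mutation sets overlap far more than single-run GA elites do.

Two fitness functions drive the GA, both minimized: a structure
stability score (by default a Miyazawa–Jernigan contact-potential
surrogate over CB–CB contacts < 6.5 Å; an adapter can delegate to any
external scoring command, e.g. a Rosetta script) and **HiSol**, a
sequence-level hydrophobicity-discrepancy score
Σ_p [h(seq_p) − h̄_p] against the homolog library (Kyte–Doolittle
scale by default). In combined mode, half of the *m* cycles run under
each score.

## Worked example

Generate a synthetic template structure and 16-homolog library, then
design an 8 ± 1 mutant under the HiSol score:

```
garnet synth --length 80 --n-seqs 16 --seed 3 --out fixtures
garnet run --template fixtures/template.pdb --library fixtures/library.fasta \
           --fitness hisol --cycles 30 --generations 8 --k 8 --i 1 \
           --seed 3 --out design_s3
```

prints

```
{
 "chosen": ["14H", "4E", "50Q", "57E", "58Q", "61R", "70Q", "75D", "9E"],
 "size": 9,
 "delta_reu": 34.22999999999993,
 "delta_hisol": -58.89999999999999,
 "g_value": 1.2699246157582988,
 "files": { ... },
 "warnings": ["g-value never entered the target band; best-g state used"]
}
```

The nine chosen mutations are the highest-weighted-degree nodes of the
curated network; the size-9 set won the 7/8/9 scan because it gave the
largest HiSol improvement (ΔHiSol −58.9; the contact energy is not
optimized in `hisol` mode and is reported for information). On toy
networks this small and this densely converged, the degree distribution
is too uniform for the exponent ever to reach the scale-free band, so
the run returns its best-*g* state, says so, and exits with status 2 —
the warning is part of the contract, not a failure. The output
directory holds `mutations.tsv` (the candidate list with centralities
and occurrence counts), `mutant.pdb` (the template with the chosen
residues substituted; side chains beyond CB are not rebuilt), and
`report.json` (the fully resolved configuration, score deltas and
*g* trajectory).

`garnet net` re-curates a network from saved node/edge count files, and
`garnet repro` computes mutation reproducibility across finished run
directories.

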