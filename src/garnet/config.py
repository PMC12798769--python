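"""Run configuration and end-to-end pipeline orchestration.

The full procedure: enumerate phylogenetically confirmed candidate
mutations from the homolog library, run m cycles of GA virtual
evolution (Phase I), record each cycle's elite as a clique, merge the
cliques into the weighted mutation network, curate it toward a
scale-free topology, select the top-k (± i) high-centrality mutations,
and emit the candidate list, mutant structure and report (Phase II).
Every output is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import ga, network, selection
from .fitness import FitnessConfig, TemplateState, delta_scores
from .ga import GAConfig
from .mutations import MutationSpace, enumerate_candidates, export_candidates_tsv
from .seqstruct import (
    ColumnMap,
    ProteinSequence,
    TemplateStructure,
    align_to_template,
    read_fasta,
    read_pdb,
)

log = logging.getLogger("garnet")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class CurationConfig:
    approach: str = "ascending"          # ascending | descending
    measure: str = "weighted_degree"
    g_target: tuple[float, float] = (2.0, 3.0)
    batch: int = 1
    min_nodes: int = 10
    x_min: int = 1


@dataclass
class SelectionConfig:
    k: int = 10
    i: int = 0
    reproducibility_metric: str = "mean_pairwise_over_k"


@dataclass
class RunConfig:
    template_pdb: str = ""
    library_fasta: str = ""
    out_dir: str = "garnet_out"
    chain: str = "A"
    library_is_aligned: bool = True
    min_count: int = 1
    ga: GAConfig = field(default_factory=GAConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    seed: int = 0

    def resolved(self) -> dict:
        d = asdict(self)
        d["fitness"].pop("hydrophobicity_scale", None)  # bulky, standard table
        return d

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        ga_cfg = GAConfig(**raw.pop("ga", {}))
        cur_raw = raw.pop("curation", {})
        if "g_target" in cur_raw:
            cur_raw["g_target"] = tuple(cur_raw["g_target"])
        cur = CurationConfig(**cur_raw)
        sel = SelectionConfig(**raw.pop("selection", {}))
        fit = FitnessConfig(**raw.pop("fitness", {}))
        return cls(ga=ga_cfg, curation=cur, selection=sel, fitness=fit, **raw)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("inputs")
def load_inputs(config: RunConfig):
    structure = read_pdb(config.template_pdb, config.chain)
    library = read_fasta(config.library_fasta)
    return structure, library


@_stage("alignment")
def build_alignment(
    structure: TemplateStructure, library: list[ProteinSequence], config: RunConfig
):
    template_seq = structure.sequence
    numbers = structure.residue_numbers
    if config.library_is_aligned:
        width = len(library[0])
        if any(len(s) != width for s in library):
            raise ValueError("pre-aligned library has inconsistent widths")
        if width == len(template_seq):
            cmap = ColumnMap.identity(numbers)
            return library, cmap
        raise ValueError(
            "pre-aligned library width differs from template length; "
            "supply the template row in the library or use library_is_aligned=false"
        )
    # align each homolog pairwise to the template; per-column residue sets
    # relative to template numbering are all Phase I needs
    aligned = []
    for hom in library:
        a_t, a_h, cmap_h = align_to_template(template_seq, hom, residue_numbers=numbers)
        # project homolog onto template coordinates (drop homolog-insert columns)
        proj = "".join(
            a_h.residues[c] for c, _ in cmap_h.pairs
        )
        aligned.append(ProteinSequence(hom.id, proj))
    return aligned, ColumnMap.identity(numbers)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-phase design; returns a result summary dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        return _run_pipeline(config, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_pipeline(config: RunConfig, out_dir: Path) -> dict:
    structure, library = load_inputs(config)
    aligned, cmap = build_alignment(structure, library, config)

    try:
        space = enumerate_candidates(
            structure.sequence, aligned, cmap, min_count=config.min_count
        )
    except Exception as exc:
        raise PipelineError("candidates", str(exc)) from exc
    if not space.candidates:
        raise PipelineError("candidates", "no candidate mutations in the library")
    export_candidates_tsv(space, out_dir / "candidates.tsv")
    log.info("candidate mutations: %d over %d positions", len(space), len(space.positions))

    state = TemplateState(structure, aligned, cmap, config.fitness)
    ga_cfg = config.ga
    ga_cfg.fitness_mode = config.fitness.mode
    ga_cfg.seed = config.seed

    def fitness_for_mode(mode: str):
        base = state.evaluator(mode)
        cache: dict[frozenset, float] = {}

        def fn(mutations: frozenset) -> float:
            if mutations not in cache:
                cache[mutations] = base(mutations)
            return cache[mutations]

        return fn

    try:
        cycles = ga.run_phase1(space, ga_cfg, fitness_for_mode)
    except Exception as exc:
        raise PipelineError("phase1", str(exc)) from exc
    cycle_log = [
        {
            "cycle": c.cycle_index,
            "fitness_mode": c.fitness_mode,
            "elite": sorted(m.label for m in c.lastgen_elite),
            "trajectory": list(c.trajectory),
        }
        for c in cycles
    ]
    (out_dir / "cycles.json").write_text(json.dumps(cycle_log, indent=1) + "\n")

    try:
        cliques = [network.complete_network(c.lastgen_elite) for c in cycles]
        merged = network.merge_networks(cliques)
        network.write_counts(
            merged, out_dir / "node_count.json", out_dir / "edge_count.json"
        )
    except Exception as exc:
        raise PipelineError("network", str(exc)) from exc
    log.info("merged network: %d nodes, %d edges", merged.n_nodes, len(merged.edge_count))

    cur_cfg = config.curation
    sel_cfg = config.selection
    min_nodes = max(cur_cfg.min_nodes, sel_cfg.k + sel_cfg.i)
    try:
        if cur_cfg.approach == "ascending":
            curated = network.curate_ascending(
                merged, cur_cfg.measure, cur_cfg.g_target, cur_cfg.batch,
                min_nodes, cur_cfg.x_min,
            )
        elif cur_cfg.approach == "descending":
            curated = network.curate_descending(
                merged, cur_cfg.measure, cur_cfg.g_target, cur_cfg.batch, cur_cfg.x_min
            )
        else:
            raise ValueError(f"unknown curation approach {cur_cfg.approach!r}")
    except Exception as exc:
        raise PipelineError("curation", str(exc)) from exc
    log.info(
        "curation (%s): %d nodes retained, g=%.3f, target %s",
        curated.approach, curated.network.n_nodes, curated.g_value,
        "reached" if curated.reached_target else "NOT reached",
    )

    mode = config.fitness.mode

    def combined_delta(mutations: frozenset) -> float:
        rep = delta_scores(state, mutations)
        if mode == "reu":
            return rep.delta_reu
        if mode == "hisol":
            return rep.delta_hisol
        return rep.delta_reu + rep.delta_hisol

    try:
        candidates = selection.select_candidates(
            curated, sel_cfg.k, sel_cfg.i, combined_delta, space.by_label,
            measure=cur_cfg.measure,
        )
    except Exception as exc:
        raise PipelineError("selection", str(exc)) from exc

    report = delta_scores(state, candidates.mutation_set)
    extra = {
        "config": config.resolved(),
        "delta_reu": report.delta_reu,
        "delta_hisol": report.delta_hisol,
        "g_value": curated.g_value,
        "g_trajectory": curated.trajectory,
        "g_target_reached": curated.reached_target,
        "curation_approach": curated.approach,
        "merged_nodes": merged.n_nodes,
        "curated_nodes": curated.network.n_nodes,
    }
    try:
        files = selection.emit_outputs(candidates, structure, out_dir, extra)
    except Exception as exc:
        raise PipelineError("outputs", str(exc)) from exc

    warnings = list(candidates.warnings)
    if not curated.reached_target:
        warnings.append("g-value never entered the target band; best-g state used")
    return {
        "chosen": candidates.labels,
        "size": candidates.size,
        "delta_reu": report.delta_reu,
        "delta_hisol": report.delta_hisol,
        "g_value": curated.g_value,
        "files": {k: str(v) for k, v in files.items()},
        "warnings": warnings,
        "exit_code": 2 if warnings else 0,
    }
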