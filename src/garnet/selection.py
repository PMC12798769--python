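"""Phase II outputs: candidate selection, files, reproducibility.

From the curated network the top-centrality mutations are taken as the
design.  A scan over set sizes k−i … k+i evaluates each candidate set
with the active fitness score(s) and keeps the size with the greatest
improvement (most negative combined delta).  Per-position clashes in a
prefix are resolved by rank — the higher-ranked label stays and the
next-ranked node is pulled in — so selection is a deterministic
function of the network.

Mutation reproducibility quantifies how much of the design is shared
across independent repeated runs; the metric is configurable because
several natural formulas exist (mean pairwise overlap over k, the
common core over k, or mean pairwise Jaccard), and every report states
which one was used.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .mutations import Mutation, MutationError, parse_label
from .network import CurationResult, centrality
from .seqstruct import TemplateStructure, write_mutant_pdb


class SelectionError(ValueError):
    pass


@dataclass
class CandidateList:
    chosen: list[Mutation]
    size: int
    per_size_scores: dict[int, float]
    centrality: dict[str, float]
    node_count: dict[str, int]
    measure: str
    warnings: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.chosen]

    @property
    def mutation_set(self) -> frozenset[Mutation]:
        return frozenset(self.chosen)


def _prefix_without_clashes(
    ranked_labels: Sequence[str], size: int, mutations_by_label: dict[str, Mutation]
) -> list[Mutation]:
    """Top-``size`` prefix of the ranking, skipping same-position clashes."""
    out: list[Mutation] = []
    used_positions: set[int] = set()
    for label in ranked_labels:
        if len(out) == size:
            break
        m = mutations_by_label.get(label)
        if m is None:
            raise SelectionError(f"network label {label!r} has no known mutation")
        if m.position in used_positions:
            continue
        used_positions.add(m.position)
        out.append(m)
    return out


def select_candidates(
    curated: CurationResult,
    k: int,
    i: int,
    score_fn: Callable[[frozenset], float],
    mutations_by_label: dict[str, Mutation],
    measure: str | None = None,
) -> CandidateList:
    """Scan sizes k−i…k+i over the centrality ranking; keep the best-scoring.

    ``score_fn`` maps a mutation set to its combined improvement delta
    (lower is better; in combined fitness mode the pipeline passes
    ΔREU + ΔHiSol).  Ties between sizes resolve toward the smaller set.
    """
    if i < 0 or k < 1:
        raise SelectionError("need k >= 1 and i >= 0")
    if not curated.network.node_count:
        raise SelectionError("curated network is empty")
    measure = measure or curated.measure
    ranked = centrality(curated.network, measure)
    ranked_labels = [n for n, _ in ranked]
    cvals = dict(ranked)
    notes: list[str] = []
    max_avail = len(_prefix_without_clashes(ranked_labels, len(ranked_labels), mutations_by_label))
    lo, hi = max(1, k - i), k + i
    if hi > max_avail:
        notes.append(
            f"requested up to {hi} mutations but only {max_avail} rankable; clamped"
        )
        hi = max_avail
        lo = min(lo, hi)
    per_size: dict[int, float] = {}
    sets: dict[int, list[Mutation]] = {}
    for s in range(lo, hi + 1):
        chosen = _prefix_without_clashes(ranked_labels, s, mutations_by_label)
        sets[s] = chosen
        per_size[s] = score_fn(frozenset(chosen))
    best_size = min(per_size, key=lambda s: (per_size[s], s))
    chosen = sets[best_size]
    return CandidateList(
        chosen=chosen,
        size=best_size,
        per_size_scores=per_size,
        centrality={m.label: cvals[m.label] for m in chosen},
        node_count={m.label: curated.network.node_count[m.label] for m in chosen},
        measure=measure,
        warnings=notes,
    )


def emit_outputs(
    candidates: CandidateList,
    structure: TemplateStructure,
    out_dir: str | Path,
    report_extra: dict | None = None,
) -> dict[str, Path]:
    """Write mutations.tsv, mutant.pdb and report.json into out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = out / "mutations.tsv"
    rows = [
        {
            "label": m.label,
            "position": m.position,
            "wt": m.wt,
            "mut": m.mut,
            "centrality": candidates.centrality[m.label],
            "node_count": candidates.node_count[m.label],
        }
        for m in candidates.chosen
    ]
    pd.DataFrame(
        rows, columns=["label", "position", "wt", "mut", "centrality", "node_count"]
    ).to_csv(tsv, sep="\t", index=False)
    pdb = out / "mutant.pdb"
    write_mutant_pdb(structure, candidates.mutation_set, pdb)
    report = {
        "chosen": candidates.labels,
        "size": candidates.size,
        "per_size_scores": {str(s): v for s, v in candidates.per_size_scores.items()},
        "centrality_measure": candidates.measure,
        "warnings": candidates.warnings,
    }
    if report_extra:
        report.update(report_extra)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, default=str) + "\n")
    return {"mutations": tsv, "mutant_pdb": pdb, "report": report_path}


# ---------------------------------------------------------------------------
# Reproducibility
# ---------------------------------------------------------------------------

_METRICS = ("mean_pairwise_over_k", "intersection_over_k", "mean_pairwise_jaccard")


def reproducibility(
    runs: Sequence[Iterable], k: int, metric: str = "mean_pairwise_over_k"
) -> float:
    """Percent of the design shared across independent runs.

    ``mean_pairwise_over_k``: mean over run pairs of |A∩B| / k.
    ``intersection_over_k``: |common core of all runs| / k.
    ``mean_pairwise_jaccard``: mean over run pairs of |A∩B| / |A∪B|.
    All reported as percentages in [0, 100].
    """
    if metric not in _METRICS:
        raise SelectionError(f"unknown reproducibility metric {metric!r}")
    if k < 1:
        raise SelectionError("k must be >= 1")
    sets = [frozenset(getattr(m, "label", m) for m in run) for run in runs]
    if len(sets) < 2:
        raise SelectionError("need at least two runs")
    if metric == "intersection_over_k":
        core = frozenset.intersection(*sets)
        return min(100.0, 100.0 * len(core) / k)
    vals = []
    for a, b in combinations(sets, 2):
        if metric == "mean_pairwise_over_k":
            vals.append(len(a & b) / k)
        else:
            union = a | b
            vals.append(len(a & b) / len(union) if union else 1.0)
    # over-k metrics can nominally exceed 1 when run sets are larger than k;
    # the reported percentage is capped at 100
    return min(100.0, 100.0 * sum(vals) / len(vals))
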