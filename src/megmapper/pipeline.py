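"""Sweep orchestration: cohort -> Mapper grid -> invariants -> statistics.

Runs the full workflow for every (subject, parameter triple) pair: build
the analysis matrix, compute the filter embedding once per subject, build
the Mapper graph for each triple, label nodes by paradigm dominance,
compute the four centralities and modularity, then evaluate the paradigm
comparison per triple and the modularity-response-time correlation.

Every completed or failed run is recorded in a manifest; a failure in one
run never aborts the sweep.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import graph_analysis as ga
from .exceptions import UsageError
from .mapper import Embedding, MapperGraph, MapperParams, compute_filter, run_mapper
from .preprocessing import LabeledTimeSeries, to_analysis_matrix
from .stats import HypothesisResult, PairedSample, compare_paradigms, correlate

logger = logging.getLogger(__name__)

#: The full production parameter grid: 3 x 4 x 4 = 48 triples.
DEFAULT_INTERVALS = (10, 15, 20)
DEFAULT_OVERLAPS = (30, 40, 50, 60)
DEFAULT_CLUSTERS = (5, 10, 15, 20)


@dataclass
class SweepSpec:
    """Configuration of one parameter sweep."""

    intervals: tuple = DEFAULT_INTERVALS
    overlaps: tuple = DEFAULT_OVERLAPS
    clusters: tuple = DEFAULT_CLUSTERS
    filter_method: str = "tsne"
    filter_seed: int = 0
    comparison: tuple[str, str] = ("demanding", "relaxed")
    hypothesis: str = "a_greater"
    alpha: float = 0.05
    required_fraction: float = 0.95
    n_perm: int = 10_000
    stats_seed: int = 0
    keep_graphs: bool = False
    measures: tuple = ga.CENTRALITY_MEASURES

    def __post_init__(self) -> None:
        if not (self.intervals and self.overlaps and self.clusters):
            raise UsageError("all three parameter domains must be nonempty")


@dataclass
class SweepResult:
    """All artifacts of one sweep."""

    manifest: pd.DataFrame
    summaries: dict
    modularity: dict
    hypotheses: dict[str, HypothesisResult]
    rt_correlations: dict
    embeddings: dict
    graphs: dict = field(default_factory=dict)
    spec: SweepSpec | None = None


def enumerate_grid(spec: SweepSpec) -> list[MapperParams]:
    """All parameter triples of the sweep, sorted lexicographically."""
    triples = sorted(itertools.product(spec.intervals, spec.overlaps, spec.clusters))
    return [
        MapperParams(
            n_intervals=i,
            overlap_pct=o,
            n_clusters=c,
            filter_method=spec.filter_method,
            filter_seed=spec.filter_seed,
        )
        for i, o, c in triples
    ]


def analyze_subject(
    matrix,
    params: MapperParams,
    embedding: Embedding | None = None,
    measures: tuple = ga.CENTRALITY_MEASURES,
) -> tuple[MapperGraph, dict, float]:
    """Mapper graph, per-measure centrality summaries and modularity for
    one subject at one parameter triple."""
    graph = run_mapper(matrix, params, embedding=embedding)
    dominance = ga.label_nodes(graph, matrix.paradigm)
    summaries = {}
    for measure in measures:
        scores = ga.centrality(graph, measure)
        summaries[measure] = ga.paradigm_mean_centrality(
            scores, dominance, subject_id=matrix.subject_id, measure=measure
        )
    q = ga.community_structure(graph).q
    return graph, summaries, q


def run_sweep(
    cohort: list[LabeledTimeSeries],
    spec: SweepSpec,
    response_times: dict[str, float] | None = None,
) -> SweepResult:
    """Execute the sweep over every (subject, triple) pair.

    ``response_times`` optionally maps subject id to reaction time; when
    given, the per-triple modularity-RT Pearson correlation is computed
    across subjects.
    """
    grid = enumerate_grid(spec)
    order = spec.comparison
    rows = []
    summaries: dict = {}
    modularity: dict = {}
    embeddings: dict = {}
    graphs: dict = {}

    matrices = {}
    for session in cohort:
        matrix = to_analysis_matrix(session, order)
        matrices[session.subject_id] = matrix
        # the filter depends only on the matrix and filter settings:
        # compute once per subject, reuse across all triples
        embeddings[session.subject_id] = compute_filter(matrix, grid[0])

    for params in grid:
        for subject_id, matrix in matrices.items():
            t0 = time.perf_counter()
            record = {
                "subject": subject_id,
                "n_intervals": params.n_intervals,
                "overlap_pct": params.overlap_pct,
                "n_clusters": params.n_clusters,
            }
            try:
                graph, subj_summaries, q = analyze_subject(
                    matrix, params, embedding=embeddings[subject_id], measures=spec.measures
                )
            except Exception as exc:  # crash isolation: record, continue
                logger.warning("run (%s, %s) failed: %s", subject_id, params.triple, exc)
                record.update(status="failed", reason=str(exc))
                rows.append(record)
                continue
            g = graph.to_networkx()
            connected = g.number_of_nodes() > 0 and nx.is_connected(g)
            for measure, summary in subj_summaries.items():
                summaries[(subject_id, params.triple, measure)] = summary
            modularity[(subject_id, params.triple)] = q
            if spec.keep_graphs:
                graphs[(subject_id, params.triple)] = graph
            record.update(
                status="ok",
                reason="",
                n_nodes=graph.n_nodes,
                n_edges=graph.n_edges,
                connected=connected,
                modularity=q,
                duration_s=time.perf_counter() - t0,
            )
            rows.append(record)

    manifest = pd.DataFrame(rows)

    hypotheses: dict[str, HypothesisResult] = {}
    for measure in spec.measures:
        samples = {}
        for params in grid:
            pairs = []
            for subject_id in matrices:
                s = summaries.get((subject_id, params.triple, measure))
                if s is None:
                    continue
                a, b = s.means.get(order[0]), s.means.get(order[1])
                if a is not None and b is not None and np.isfinite(a) and np.isfinite(b):
                    pairs.append((subject_id, a, b))
            if len(pairs) >= 2:
                samples[params.triple] = PairedSample(
                    subject_ids=[p[0] for p in pairs],
                    score_a=[p[1] for p in pairs],
                    score_b=[p[2] for p in pairs],
                    label_a=order[0],
                    label_b=order[1],
                )
        if samples:
            hypotheses[measure] = compare_paradigms(
                samples,
                hypothesis=spec.hypothesis,
                alpha=spec.alpha,
                required_fraction=spec.required_fraction,
                n_perm=spec.n_perm,
                seed=spec.stats_seed,
            )

    rt_correlations: dict = {}
    if response_times is not None:
        for params in grid:
            qs, rts = [], []
            for subject_id in matrices:
                q = modularity.get((subject_id, params.triple))
                rt = response_times.get(subject_id)
                if q is not None and rt is not None:
                    qs.append(q)
                    rts.append(rt)
            if len(qs) >= 3 and np.ptp(qs) > 0 and np.ptp(rts) > 0:
                rt_correlations[params.triple] = correlate(qs, rts, method="pearson")

    return SweepResult(
        manifest=manifest,
        summaries=summaries,
        modularity=modularity,
        hypotheses=hypotheses,
        rt_correlations=rt_correlations,
        embeddings=embeddings,
        graphs=graphs,
        spec=spec,
    )


def export_outputs(result: SweepResult, out_dir, formats=("csv", "json", "graphml")) -> list:
    """Materialize sweep artifacts: CSV tables, JSON summary, GraphML graphs.

    Returns the list of written paths. An empty ``formats`` selection
    writes nothing and succeeds.
    """
    from pathlib import Path

    unknown = set(formats) - {"csv", "json", "graphml"}
    if unknown:
        raise UsageError(f"unknown export formats: {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    if "csv" in formats:
        p = out_dir / "manifest.csv"
        # timings stay in memory only, so reruns are byte-identical
        cols = [c for c in result.manifest.columns if c != "duration_s"]
        result.manifest[cols].to_csv(p, index=False)
        written.append(p)

        rows = []
        for (subject, triple, measure), s in sorted(result.summaries.items()):
            for paradigm, mean in sorted(s.means.items()):
                rows.append(
                    {
                        "subject": subject,
                        "triple": "-".join(map(str, triple)),
                        "measure": measure,
                        "paradigm": paradigm,
                        "mean_centrality": mean,
                        "n_nodes": s.counts.get(paradigm, 0),
                    }
                )
        p = out_dir / "centrality_summaries.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)

        rows = [
            {"subject": subject, "triple": "-".join(map(str, triple)), "modularity": q}
            for (subject, triple), q in sorted(result.modularity.items())
        ]
        p = out_dir / "modularity.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)

        if result.rt_correlations:
            rows = [
                {"triple": "-".join(map(str, t)), "correlation": r, "significance": pv}
                for t, (r, pv) in sorted(result.rt_correlations.items())
            ]
            p = out_dir / "modularity_rt_correlation.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            written.append(p)

        for subject, emb in sorted(result.embeddings.items()):
            p = out_dir / f"embedding_{subject}.csv"
            np.savetxt(p, emb.coords, delimiter=",", header="x,y", comments="")
            written.append(p)

    if "json" in formats:
        summary = {
            measure: {
                "hypothesis": h.hypothesis,
                "satisfied": h.satisfied,
                "n_triples": h.n_triples,
                "n_satisfied": h.n_satisfied,
            }
            for measure, h in result.hypotheses.items()
        }
        p = out_dir / "hypotheses.json"
        p.write_text(json.dumps(summary, indent=2))
        written.append(p)

    if "graphml" in formats:
        for (subject, triple), graph in sorted(result.graphs.items()):
            p = out_dir / f"graph_{subject}_{'-'.join(map(str, triple))}.graphml"
            nx.write_graphml(graph.to_networkx(), p)
            written.append(p)

    return written
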