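"""Pipeline orchestration: load -> train -> score -> prioritize -> report.

Two entry modes share the reporting tail:

* **scoring mode** — build the graph and disease map, construct a truth
  table, train the relationship predictor, and score every candidate
  against every process;
* **fixture mode** — consume a pre-computed score matrix TSV (e.g. the
  published strong-relationship sub-matrix) and run only classification,
  selection, and reporting.

All stage seeds derive from one master seed by fixed offsets; a rerun with
the same config and seed produces byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import prioritize as pz
from .disease import (CandidateList, DiseaseMap, load_candidates,
                      load_disease_map, validate)
from .graph import KnowledgeGraph, merge_graphs
from .scoring import (NullParams, ScoreMatrix, build_truth_table, score_all,
                      train_model)

log = logging.getLogger("stenoprio")

SEED_OFFSETS = {"truth_table": 11, "training": 23, "nulls": 37}


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    edges: list[str] = field(default_factory=list)   # "path" or "path:layer"
    disease_map: str | None = None
    candidates: str | None = None
    score_matrix: str | None = None                  # fixture mode when set
    outdir: str = "stenoprio_out"
    master_seed: int = 0
    restart: float = 0.3
    n_null: int = 999
    neg_per_pos: int = 1
    min_neg_distance: int = 2
    hyperparameters: dict = field(default_factory=dict)
    min_motives: int = 3
    include_general: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return int((self.master_seed + SEED_OFFSETS[stage]) % (2 ** 31))


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict
    counts: dict
    output_files: list[str]
    file_sha256: dict
    started: float
    finished: float

    def write(self, path: str | Path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                  sort_keys=True, default=str))
        tmp.replace(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_graph(config: PipelineConfig) -> KnowledgeGraph:
    graphs = []
    for entry in config.edges:
        if ":" in entry and not Path(entry).exists():
            path, layer = entry.rsplit(":", 1)
        else:
            path, layer = entry, "physical"
        graphs.append(KnowledgeGraph.read_edge_list(path, layer=layer))
    return merge_graphs(graphs)


def write_reports(matrix: ScoreMatrix, summary, selections, novel,
                  outdir: str | Path) -> list[Path]:
    """Emit the standard report files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    p = outdir / "scores.tsv"
    matrix.write_tsv(p)
    files.append(p)
    p = outdir / "motive_summary.tsv"
    summary.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = outdir / "multimotive.tsv"
    pz.profiles_to_frame(selections).to_csv(p, sep="\t", index=False)
    files.append(p)
    p = outdir / "novel_candidates.tsv"
    pz.profiles_to_frame(novel).to_csv(p, sep="\t", index=False)
    files.append(p)
    profiles = pz.profiles_from_matrix(matrix)
    classes = {pr.uniprot_id: pz.classify_protein(pr).value for pr in profiles}
    n_strong = sum(1 for c in classes.values() if c == "strong")
    p = outdir / "run_summary.json"
    p.write_text(json.dumps({
        "n_proteins": len(profiles),
        "n_score_rows": len(matrix),
        "n_strong": n_strong,
        "percent_strong": pz.percent_strong(n_strong, len(profiles)) if profiles else 0.0,
        "n_selected_multimotive": len(selections),
        "n_novel": len(novel),
        "protein_class": dict(sorted(classes.items())),
    }, indent=2, sort_keys=True))
    files.append(p)
    return files


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline per the config; see module docstring.

    Any stage failure aborts with the stage named in the exception and
    removes partial outputs.
    """
    started = time.time()
    outdir = Path(config.outdir)
    written: list[Path] = []
    counts: dict = {}
    stage = "setup"
    try:
        if config.score_matrix:
            stage = "fixture-load"
            matrix = ScoreMatrix.read_tsv(config.score_matrix)
            counts["score_rows"] = len(matrix)
        else:
            stage = "graph-load"
            graph = _load_graph(config)
            counts["nodes"] = graph.n_nodes
            counts["edges"] = graph.n_edges
            log.info("graph: %d nodes, %d edges", graph.n_nodes, graph.n_edges)
            stage = "map-load"
            if not config.disease_map or not config.candidates:
                raise ValueError("scoring mode needs disease_map and candidates")
            dmap = load_disease_map(config.disease_map)
            candidates = load_candidates(config.candidates)
            report = validate(dmap, candidates, graph)
            counts["missing_from_graph"] = len(report.missing_from_graph)
            counts["candidates"] = len(candidates)
            stage = "truth-table"
            table = build_truth_table(
                dmap, graph, neg_per_pos=config.neg_per_pos,
                min_neg_distance=config.min_neg_distance,
                seed=config.stage_seed("truth_table"))
            counts["truth_positives"] = len(table.positives())
            counts["truth_negatives"] = len(table.negatives())
            stage = "training"
            model = train_model(table, graph, dmap,
                                hyper=config.hyperparameters or None,
                                seed=config.stage_seed("training"),
                                restart=config.restart)
            counts["holdout_accuracy"] = model.metadata.get("holdout_accuracy")
            stage = "scoring"
            matrix = score_all(graph, model, dmap, candidates,
                               NullParams(n_null=config.n_null,
                                          restart=config.restart,
                                          seed=config.stage_seed("nulls")))
            counts["score_rows"] = len(matrix)
        stage = "prioritization"
        summary = pz.summarize_by_motive(matrix)
        selections = pz.select_multimotive(matrix,
                                           min_motives=config.min_motives,
                                           include_general=config.include_general)
        novel = pz.flag_novel(selections)
        counts["selected"] = len(selections)
        counts["novel"] = len(novel)
        stage = "reporting"
        written = write_reports(matrix, summary, selections, novel, outdir)
        if not config.score_matrix:
            mp = outdir / "model.json"
            model.to_json(mp)
            written.append(mp)
    except Exception as exc:
        for f in written:
            f.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        stage_seeds={s: config.stage_seed(s) for s in SEED_OFFSETS},
        counts=counts,
        output_files=[str(f) for f in written],
        file_sha256={f.name: _sha256(f) for f in written},
        started=started,
        finished=time.time(),
    )
    manifest.write(outdir / "manifest.json")
    return manifest
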