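"""Disease characterization: motives, effector sets, and the candidate list.

A *motive* is one pathophysiological process of the disease (calcification,
inflammation, ...), represented computationally by the set of its effector
proteins and classified by causal level: ``causative`` (drives the disease),
``symptomatic`` (a consequence), or ``both``.  The disease as a whole is
carried as a pseudo-motive (``das_general``) with its own effector set so
scoring and counting treat it uniformly with the named processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .graph import KnowledgeGraph, normalize_accession

GENERAL_MOTIVE_ID = "das_general"
GENERAL_MOTIVE_NAME = "DAS general characterization"


class CausalLevel(str, Enum):
    causative = "causative"
    symptomatic = "symptomatic"
    both = "both"


@dataclass
class Motive:
    motive_id: str
    name: str
    level: CausalLevel
    effectors: frozenset[str]


@dataclass
class DiseaseMap:
    """Motives plus the disease-in-general effector set."""

    motives: list[Motive]
    general_effectors: frozenset[str] = frozenset()

    def motive_ids(self) -> list[str]:
        return [m.motive_id for m in self.motives]

    def get_motive(self, motive_id: str) -> Motive:
        for m in self.motives:
            if m.motive_id == motive_id:
                return m
        raise KeyError(f"unknown motive {motive_id!r}")

    def scoring_units(self) -> list[tuple[str, frozenset[str]]]:
        """(motive_id, effector set) pairs scored by the pipeline.

        The general pseudo-motive is appended when its effector set is
        non-empty, so it is counted as one process like any other.
        """
        units = [(m.motive_id, m.effectors) for m in self.motives]
        if self.general_effectors:
            units.append((GENERAL_MOTIVE_ID, self.general_effectors))
        return units

    def effectors_of(self, motive_id: str) -> frozenset[str]:
        if motive_id == GENERAL_MOTIVE_ID:
            return self.general_effectors
        return self.get_motive(motive_id).effectors

    def all_effectors(self) -> frozenset[str]:
        out: set[str] = set(self.general_effectors)
        for m in self.motives:
            out |= m.effectors
        return frozenset(out)


@dataclass
class CandidateEntry:
    uniprot_id: str
    protein_name: str
    source_refs: list[str] = field(default_factory=list)


@dataclass
class CandidateList:
    entries: list[CandidateEntry]

    def accessions(self) -> list[str]:
        return [e.uniprot_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ValidationReport:
    missing_from_graph: frozenset[str]
    empty_motives: list[str]
    duplicate_candidates: list[str]

    @property
    def is_empty(self) -> bool:
        return (not self.missing_from_graph and not self.empty_motives
                and not self.duplicate_candidates)


# -- disease-map config ------------------------------------------------


def _parse_motive(entry: dict) -> Motive:
    try:
        level = CausalLevel(entry["level"])
    except ValueError:
        raise ValueError(
            f"motive {entry.get('id')!r}: unknown causal level "
            f"{entry.get('level')!r}; expected one of "
            f"{[lv.value for lv in CausalLevel]}") from None
    effectors = frozenset(normalize_accession(a) for a in entry.get("effectors", []))
    if not effectors:
        raise ValueError(f"motive {entry.get('id')!r} has an empty effector set")
    return Motive(motive_id=str(entry["id"]), name=str(entry["name"]),
                  level=level, effectors=effectors)


def load_disease_map(path: str | Path) -> DiseaseMap:
    """Load a YAML disease-map config (schema in the repo README).

    Top-level keys: ``motives`` (list of ``{id, name, level, effectors}``)
    and optional ``general_effectors`` (list of accessions).  Motive order
    is preserved.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "motives" not in raw:
        raise ValueError(f"{path}: disease-map config must have a 'motives' list")
    motives = [_parse_motive(e) for e in raw["motives"]]
    ids = [m.motive_id for m in motives]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate motive ids {dupes}")
    general = frozenset(normalize_accession(a)
                        for a in raw.get("general_effectors", []) or [])
    return DiseaseMap(motives=motives, general_effectors=general)


def save_disease_map(dmap: DiseaseMap, path: str | Path) -> None:
    doc = {
        "motives": [
            {"id": m.motive_id, "name": m.name, "level": m.level.value,
             "effectors": sorted(m.effectors)}
            for m in dmap.motives
        ],
        "general_effectors": sorted(dmap.general_effectors),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# -- candidate list ----------------------------------------------------


def load_candidates(path: str | Path) -> CandidateList:
    """Load a candidate TSV with header ``uniprot_id, protein_name, source_refs``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"uniprot_id", "protein_name"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: candidate TSV must have columns {sorted(required)}")
    entries = []
    for _, row in df.iterrows():
        refs = [r.strip() for r in str(row.get("source_refs", "")).split(";")
                if r.strip()]
        entries.append(CandidateEntry(
            uniprot_id=normalize_accession(row["uniprot_id"]),
            protein_name=str(row["protein_name"]).strip(),
            source_refs=refs))
    accs = [e.uniprot_id for e in entries]
    dupes = sorted({a for a in accs if accs.count(a) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate candidate accessions {dupes}")
    return CandidateList(entries=entries)


def save_candidates(candidates: CandidateList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("uniprot_id\tprotein_name\tsource_refs\n")
        for e in candidates.entries:
            fh.write(f"{e.uniprot_id}\t{e.protein_name}\t{';'.join(e.source_refs)}\n")


def validate(dmap: DiseaseMap, candidates: CandidateList,
             graph: KnowledgeGraph) -> ValidationReport:
    """Cross-check map and candidates against the graph without raising.

    Missing nodes are reported, not fatal: scoring substitutes a sentinel
    feature vector for absent candidates.
    """
    missing: set[str] = set()
    empty: list[str] = []
    for motive_id, effectors in dmap.scoring_units():
        absent = {a for a in effectors if not graph.has_node(a)}
        missing |= absent
        if absent == set(effectors):
            empty.append(motive_id)
    for acc in candidates.accessions():
        if not graph.has_node(acc):
            missing.add(acc)
    accs = candidates.accessions()
    dupes = sorted({a for a in accs if accs.count(a) > 1})
    return ValidationReport(missing_from_graph=frozenset(missing),
                            empty_motives=empty, duplicate_candidates=dupes)


# -- packaged fixtures -------------------------------------------------


def _fixture_path(name: str) -> Path:
    return Path(resources.files("stenoprio.fixtures") / name)


def load_as_disease_map() -> DiseaseMap:
    """The packaged aortic-stenosis characterization (8 motives + general)."""
    return load_disease_map(_fixture_path("disease_map_as.yaml"))


def load_as_candidates() -> CandidateList:
    """The packaged 126-protein candidate list."""
    return load_candidates(_fixture_path("candidates_table1.tsv"))


def load_published_score_matrix() -> pd.DataFrame:
    """The published strong-relationship sub-matrix (22 proteins, sparse)."""
    return pd.read_csv(_fixture_path("score_matrix_table5.tsv"), sep="\t")


def load_published_strong_counts() -> pd.DataFrame:
    """The published per-motive strong-relationship counts."""
    return pd.read_csv(_fixture_path("strong_counts_table4.tsv"), sep="\t")
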