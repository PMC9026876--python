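"""Classification and selection rules over a score matrix.

A protein has a *strong* relationship with the disease if any of its
per-process scores falls in the Very high / High / Medium-High bands, a
*medium* relationship if its best band is Medium, and otherwise a low or no
relationship.  The headline selection keeps proteins strongly related to at
least three processes (the disease-in-general pseudo-process counts as
one), ranked by their highest score; among those, proteins that are not an
effector of any scored process are the *novel* candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .disease import GENERAL_MOTIVE_ID
from .scoring import STRONG_CATEGORIES, Category, ScoreMatrix


class PriorityClass(str, Enum):
    strong = "strong"
    medium = "medium"
    low = "low"


@dataclass
class MotiveRow:
    motive_id: str
    ann_score: float
    category: Category
    is_effector: bool


@dataclass
class ProteinScoreProfile:
    """All scored (motive, score) rows of one protein."""

    uniprot_id: str
    rows: list[MotiveRow]
    gene_name: str = ""
    protein_name: str = ""

    @property
    def best_score(self) -> float:
        return max(r.ann_score for r in self.rows)

    def strong_motive_count(self, include_general: bool = True) -> int:
        return sum(1 for r in self.rows
                   if r.category in STRONG_CATEGORIES
                   and (include_general or r.motive_id != GENERAL_MOTIVE_ID))

    @property
    def is_novel(self) -> bool:
        """True when the protein is an effector of none of its scored motives."""
        return all(not r.is_effector for r in self.rows)


def profiles_from_matrix(matrix: ScoreMatrix) -> list[ProteinScoreProfile]:
    """Group a long-format score matrix into per-protein profiles,
    preserving first-appearance order."""
    profiles: dict[str, ProteinScoreProfile] = {}
    for _, row in matrix.df.iterrows():
        uid = row["uniprot_id"]
        if uid not in profiles:
            profiles[uid] = ProteinScoreProfile(
                uniprot_id=uid, rows=[],
                gene_name=str(row.get("gene_name", "") or ""),
                protein_name=str(row.get("protein_name", "") or ""))
        profiles[uid].rows.append(MotiveRow(
            motive_id=row["motive_id"],
            ann_score=float(row["ann_score"]),
            category=Category(row["category"]),
            is_effector=bool(row["is_effector"])))
    return list(profiles.values())


def classify_protein(profile: ProteinScoreProfile) -> PriorityClass:
    """Three-tier relationship class from the best-scoring process."""
    if not profile.rows:
        raise ValueError(f"protein {profile.uniprot_id!r} has no scored motives")
    cats = {r.category for r in profile.rows}
    if cats & STRONG_CATEGORIES:
        return PriorityClass.strong
    if Category.medium in cats:
        return PriorityClass.medium
    return PriorityClass.low


_SUMMARY_CELLS = [
    ("very_high_effector", Category.very_high, True),
    ("very_high_non_effector", Category.very_high, False),
    ("high_effector", Category.high, True),
    ("high_non_effector", Category.high, False),
    ("medium_high_effector", Category.medium_high, True),
    ("medium_high_non_effector", Category.medium_high, False),
]


def summarize_by_motive(matrix: ScoreMatrix) -> pd.DataFrame:
    """Per-motive cross-tab of strong-band rows by category and effector
    status, with a TOTAL column.  The TOTAL always equals the sum of the six
    cells (asserted on every call)."""
    motive_order = list(dict.fromkeys(matrix.df["motive_id"])) if len(matrix.df) else []
    rows = []
    for mid in motive_order:
        sub = matrix.df[matrix.df["motive_id"] == mid]
        rec: dict[str, object] = {"motive_id": mid}
        for col, cat, eff in _SUMMARY_CELLS:
            rec[col] = int(((sub["category"] == cat.value)
                            & (sub["is_effector"] == eff)).sum())
        rec["total"] = sum(rec[col] for col, _, _ in _SUMMARY_CELLS)
        rows.append(rec)
    cols = ["motive_id"] + [c for c, _, _ in _SUMMARY_CELLS] + ["total"]
    out = pd.DataFrame(rows, columns=cols)
    assert (out["total"] == out[[c for c, _, _ in _SUMMARY_CELLS]].sum(axis=1)).all()
    return out


def select_multimotive(matrix: ScoreMatrix, min_motives: int = 3,
                       include_general: bool = True) -> list[ProteinScoreProfile]:
    """Proteins strongly related to >= ``min_motives`` processes, in
    decreasing order of their best score (ties broken by accession)."""
    if min_motives < 1:
        raise ValueError("min_motives must be >= 1")
    selected = [p for p in profiles_from_matrix(matrix)
                if p.strong_motive_count(include_general) >= min_motives]
    return sorted(selected, key=lambda p: (-p.best_score, p.uniprot_id))


def flag_novel(profiles: list[ProteinScoreProfile]) -> list[ProteinScoreProfile]:
    """Profiles whose every scored motive has ``is_effector = False``."""
    return [p for p in profiles if p.is_novel]


def percent_strong(n_strong: int, n_total: int) -> float:
    """Share of candidates with a strong relationship, as a percentage
    rounded to two decimals (61 of 126 -> 48.41)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_strong / n_total, 2)


def profiles_to_frame(profiles: list[ProteinScoreProfile]) -> pd.DataFrame:
    """Long-format report mirroring the published multimotive table:
    grouped by protein in rank order, one row per scored motive."""
    records = []
    for p in profiles:
        for r in sorted(p.rows, key=lambda r: -r.ann_score):
            records.append({
                "uniprot_id": p.uniprot_id,
                "gene_name": p.gene_name,
                "protein_name": p.protein_name,
                "motive_id": r.motive_id,
                "is_effector": r.is_effector,
                "ann_score": r.ann_score,
            })
    return pd.DataFrame.from_records(
        records, columns=["uniprot_id", "gene_name", "protein_name",
                          "motive_id", "is_effector", "ann_score"])
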