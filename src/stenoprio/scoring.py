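"""Candidate-to-motive relationship scoring.

The score of a (candidate protein, disease process) pair is produced in
four stages:

1. **Proximity features** between the candidate and the process's effector
   set on the interaction network: minimum and mean hop distance, random
   walk with restart mass, neighborhood Jaccard overlap, and log degree.
2. A **feed-forward neural network** (one hidden layer of 8 logistic units,
   logistic output) trained on a truth table of labelled related/unrelated
   protein-process pairs maps the features to a raw relatedness in [0, 1].
3. A **degree-matched permutation null** converts the raw value to an
   empirical p-value: the candidate's raw score is ranked against the raw
   scores of random proteins drawn from the same log2-degree bin, with a +1
   pseudo-count so p is never 0.
4. The p-value is **calibrated to the 0-100 scale** by a piecewise-linear
   map in log10(p) anchored at the published band boundaries
   (p=0.01 -> 92, 0.05 -> 78, 0.15 -> 63, 0.25 -> 38) and banded into the
   categories Very high / High / Medium-High / Medium / Low.

By construction, a fresh degree-matched random candidate lands at or above
any band boundary with probability equal to that band's nominal p.
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .disease import CandidateList, DiseaseMap
from .graph import KnowledgeGraph, UNREACHABLE

FEATURE_NAMES = ("d_min", "d_mean", "rwr_score", "jaccard_nbr", "degree_log")

#: Score anchors of the published category boundaries, as (p, score) pairs.
#: Above p=0.01 the map continues linearly in log10(p) to (0.001, 100) and
#: clamps at 100; below p=0.25 it continues to (1.0, 0).
CALIBRATION_ANCHORS = ((0.001, 100.0), (0.01, 92.0), (0.05, 78.0),
                       (0.15, 63.0), (0.25, 38.0), (1.0, 0.0))

BAND_BOUNDARIES = (92.0, 78.0, 63.0, 38.0)


class Category(str, Enum):
    very_high = "very_high"
    high = "high"
    medium_high = "medium_high"
    medium = "medium"
    low = "low"


#: Categories that constitute a "strong relationship".
STRONG_CATEGORIES = frozenset(
    {Category.very_high, Category.high, Category.medium_high})


def categorize(value: float, boundary: str = "closed") -> Category:
    """Band a 0-100 score.  ``boundary='closed'`` puts a score exactly on a
    boundary in the upper band (92 -> very_high); ``'open'`` in the lower."""
    if boundary not in ("closed", "open"):
        raise ValueError(f"boundary must be 'closed' or 'open', got {boundary!r}")
    vh, hi, mh, md = BAND_BOUNDARIES
    at_or_above = (lambda v, b: v >= b) if boundary == "closed" else (lambda v, b: v > b)
    if at_or_above(value, vh):
        return Category.very_high
    if at_or_above(value, hi):
        return Category.high
    if at_or_above(value, mh):
        return Category.medium_high
    if at_or_above(value, md):
        return Category.medium
    return Category.low


@dataclass
class AnnScore:
    value: float
    p_empirical: float
    category: Category


def calibrate_to_ann(p: float, boundary: str = "closed") -> AnnScore:
    """Map an empirical p-value to the 0-100 score scale.

    Piecewise linear in log10(p) through the published anchors; clamped at
    100 below p=0.001.  Strictly decreasing in p on (0.001, 1].
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    xs = np.log10([a[0] for a in CALIBRATION_ANCHORS])
    ys = np.array([a[1] for a in CALIBRATION_ANCHORS])
    value = float(np.interp(math.log10(p), xs, ys))
    value = min(value, 100.0)
    return AnnScore(value=value, p_empirical=p, category=categorize(value, boundary))


# -- proximity features ------------------------------------------------


@dataclass
class FeatureVector:
    d_min: float
    d_mean: float
    rwr_score: float
    jaccard_nbr: float
    degree_log: float
    missing: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.d_min, self.d_mean, self.rwr_score,
                         self.jaccard_nbr, self.degree_log])


class MotiveContext:
    """Per-motive caches that make feature extraction O(|effectors|) per node.

    Holds one BFS distance map per effector, the motive-seeded random walk
    vector, and the union effector neighborhood.  Effector candidates are
    scored leave-one-out (the candidate is removed from the seed set), for
    which the per-seed caches are reused and only the walk is re-solved.
    """

    def __init__(self, graph: KnowledgeGraph, motive_proteins: frozenset[str] | set[str],
                 restart: float = 0.3) -> None:
        self.graph = graph
        self.motive_proteins = frozenset(motive_proteins)
        if not self.motive_proteins:
            raise ValueError("motive protein set is empty")
        self.restart = restart
        self.seeds = sorted(a for a in self.motive_proteins if graph.has_node(a))
        if not self.seeds:
            raise ValueError("no motive protein is present in the graph")
        self.cap = graph.diameter_cap()
        self._dist = {s: graph.single_source_distances(s) for s in self.seeds}
        self._nbrs = {s: graph.neighbors(s) for s in self.seeds}
        self._rwr = graph.rwr_proximity(self.seeds, restart=restart)
        self._union_nbr: set[str] = set().union(*self._nbrs.values())
        self._loo_rwr: dict[str, dict[str, float]] = {}

    def features(self, candidate: str) -> FeatureVector:
        g = self.graph
        if not g.has_node(candidate):
            return FeatureVector(d_min=float(self.cap), d_mean=float(self.cap),
                                 rwr_score=0.0, jaccard_nbr=0.0,
                                 degree_log=0.0, missing=True)
        member = candidate in self.motive_proteins
        seeds = [s for s in self.seeds if s != candidate]
        if not seeds:
            # candidate is the sole effector present: it seeds itself
            seeds = [candidate]
        dists = [float(self._dist[s].get(candidate, self.cap)) for s in seeds]
        dists = [min(d, float(self.cap)) for d in dists]
        d_min = 0.0 if member else min(dists)
        d_mean = float(np.mean(dists)) if not (member and seeds == [candidate]) else 0.0
        if member and seeds != [candidate]:
            rwr = self._leave_one_out_rwr(candidate, seeds)
        else:
            rwr = self._rwr.get(candidate, 0.0)
        nbr_c = g.neighbors(candidate)
        if member and seeds != [candidate]:
            union = set().union(*(self._nbrs[s] for s in seeds))
        else:
            union = self._union_nbr
        denom = len(nbr_c | union)
        jac = len(nbr_c & union) / denom if denom else 0.0
        return FeatureVector(d_min=d_min, d_mean=d_mean, rwr_score=float(rwr),
                             jaccard_nbr=float(jac),
                             degree_log=float(np.log1p(g.degree(candidate))))

    def _leave_one_out_rwr(self, candidate: str, seeds: list[str]) -> float:
        if candidate not in self._loo_rwr:
            self._loo_rwr[candidate] = self.graph.rwr_proximity(
                seeds, restart=self.restart)
        return self._loo_rwr[candidate].get(candidate, 0.0)

    def feature_matrix(self, nodes: list[str]) -> np.ndarray:
        return np.vstack([self.features(n).as_array() for n in nodes])


def compute_features(graph: KnowledgeGraph, candidate: str,
                     motive_proteins: set[str] | frozenset[str],
                     context: MotiveContext | None = None,
                     restart: float = 0.3) -> FeatureVector:
    """Proximity features of one candidate against one effector set.

    A candidate absent from the graph yields the sentinel vector (distances
    at the unreachability cap, zero walk mass and overlap) with
    ``missing=True``.  An effector scored against its own motive is scored
    leave-one-out and has ``d_min = 0``.
    """
    if context is None:
        context = MotiveContext(graph, motive_proteins, restart=restart)
    return context.features(candidate)


# -- truth table -------------------------------------------------------


@dataclass
class TruthTable:
    """Labelled (protein, motive) training pairs; labels 'related'/'unrelated'."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        by_pair: dict[tuple[str, str], set[str]] = {}
        for uid, mid, label in self.rows:
            if label not in ("related", "unrelated"):
                raise ValueError(f"bad label {label!r} for ({uid}, {mid})")
            by_pair.setdefault((uid, mid), set()).add(label)
        conflicts = [p for p, ls in by_pair.items() if len(ls) > 1]
        if conflicts:
            raise ValueError(f"pairs labelled both related and unrelated: {conflicts}")

    def positives(self) -> list[tuple[str, str]]:
        return [(u, m) for u, m, l in self.rows if l == "related"]

    def negatives(self) -> list[tuple[str, str]]:
        return [(u, m) for u, m, l in self.rows if l == "unrelated"]


def degree_bin(degree: int) -> int:
    """log2 degree bin; degree 0 maps to bin -1."""
    return -1 if degree <= 0 else int(math.floor(math.log2(degree)))


def build_truth_table(dmap: DiseaseMap, graph: KnowledgeGraph,
                      neg_per_pos: int = 1, min_neg_distance: int = 2,
                      seed: int = 0) -> TruthTable:
    """Positives are all (effector, its motive) pairs present in the graph;
    negatives are degree-matched proteins at hop distance >= ``min_neg_distance``
    from the motive's effector set, ``neg_per_pos`` per positive."""
    rng = np.random.default_rng(seed)
    degrees = graph.degree_sequence()
    bins: dict[int, list[str]] = {}
    for node in sorted(degrees):
        bins.setdefault(degree_bin(degrees[node]), []).append(node)
    rows: list[tuple[str, str, str]] = []
    used: set[tuple[str, str]] = set()
    for motive_id, effectors in dmap.scoring_units():
        present = sorted(a for a in effectors if graph.has_node(a))
        if not present:
            continue
        dmin = graph.multi_source_distances(present)
        for eff in present:
            rows.append((eff, motive_id, "related"))
            used.add((eff, motive_id))
        for eff in present:
            target_bin = degree_bin(degrees[eff])
            wanted = neg_per_pos
            for b in sorted(bins, key=lambda b: (abs(b - target_bin), b)):
                if wanted == 0:
                    break
                pool = [n for n in bins[b]
                        if n not in effectors
                        and dmin.get(n, math.inf) >= min_neg_distance
                        and (n, motive_id) not in used]
                if not pool:
                    continue
                take = min(wanted, len(pool))
                for n in rng.choice(pool, size=take, replace=False):
                    rows.append((str(n), motive_id, "unrelated"))
                    used.add((str(n), motive_id))
                wanted -= take
            if wanted > 0:
                raise ValueError(
                    f"could not find {neg_per_pos} negatives at distance >= "
                    f"{min_neg_distance} from motive {motive_id!r}; "
                    f"try a smaller min_neg_distance")
    if not any(l == "related" for _, _, l in rows):
        raise ValueError("disease map has no effectors present in the graph")
    return TruthTable(rows=rows)


# -- the relationship predictor ---------------------------------------


@dataclass
class RelationshipModel:
    """Trained feed-forward predictor, stored as explicit weights.

    Forward pass: standardize features, one hidden layer of logistic units,
    logistic output = raw relatedness in [0, 1].  Deterministic given the
    stored state; JSON-serializable.
    """

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    w_hidden: np.ndarray     # (n_features, n_hidden)
    b_hidden: np.ndarray     # (n_hidden,)
    w_out: np.ndarray        # (n_hidden, 1)
    b_out: np.ndarray        # (1,)
    feature_names: tuple[str, ...] = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)

    def predict_raw(self, features: np.ndarray) -> np.ndarray:
        """Raw relatedness in [0, 1] for an (n, n_features) array."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        z = (X - self.scaler_mean) / self.scaler_scale
        h = expit(z @ self.w_hidden + self.b_hidden)
        return expit(h @ self.w_out + self.b_out).ravel()

    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_names": list(self.feature_names),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RelationshipModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            scaler_mean=np.array(doc["scaler_mean"]),
            scaler_scale=np.array(doc["scaler_scale"]),
            w_hidden=np.array(doc["w_hidden"]),
            b_hidden=np.array(doc["b_hidden"]),
            w_out=np.array(doc["w_out"]),
            b_out=np.array(doc["b_out"]),
            feature_names=tuple(doc["feature_names"]),
            metadata=doc.get("metadata", {}),
        )


DEFAULT_HYPERPARAMETERS = {
    "hidden_units": 8,
    "max_iter": 3000,
    "alpha": 1e-4,
    "test_fraction": 0.25,
}


def train_model(table: TruthTable, graph: KnowledgeGraph, dmap: DiseaseMap,
                hyper: dict | None = None, seed: int = 0,
                restart: float = 0.3) -> RelationshipModel:
    """Fit the relationship predictor on a truth table.

    Features are extracted per motive with shared caches, an internal
    stratified split measures held-out accuracy, and the network is then
    refit on the full table.  L-BFGS training with a fixed seed makes the
    result deterministic.
    """
    hp = dict(DEFAULT_HYPERPARAMETERS)
    if hyper:
        hp.update(hyper)
    labels = {l for _, _, l in table.rows}
    if len(labels) < 2:
        raise ValueError(f"truth table is single-class ({labels}); need both labels")
    contexts: dict[str, MotiveContext] = {}
    for motive_id, effectors in dmap.scoring_units():
        try:
            contexts[motive_id] = MotiveContext(graph, effectors, restart=restart)
        except ValueError:
            continue
    X = np.vstack([contexts[mid].features(uid).as_array()
                   for uid, mid, _ in table.rows])
    y = np.array([1 if l == "related" else 0 for _, _, l in table.rows])

    def _fit(Xf, yf):
        scaler = StandardScaler().fit(Xf)
        clf = MLPClassifier(hidden_layer_sizes=(hp["hidden_units"],),
                            activation="logistic", solver="lbfgs",
                            alpha=hp["alpha"], max_iter=hp["max_iter"],
                            random_state=seed)
        clf.fit(scaler.transform(Xf), yf)
        return scaler, clf

    holdout_acc = None
    if np.bincount(y).min() >= 4:
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=hp["test_fraction"], stratify=y, random_state=seed)
        scaler, clf = _fit(Xtr, ytr)
        holdout_acc = float(clf.score(scaler.transform(Xte), yte))
    scaler, clf = _fit(X, y)
    train_acc = float(clf.score(scaler.transform(X), y))
    return RelationshipModel(
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        w_hidden=clf.coefs_[0].copy(),
        b_hidden=clf.intercepts_[0].copy(),
        w_out=clf.coefs_[1].copy(),
        b_out=clf.intercepts_[1].copy(),
        metadata={"seed": seed, "hyperparameters": hp,
                  "n_related": int(y.sum()), "n_unrelated": int((1 - y).sum()),
                  "train_accuracy": train_acc, "holdout_accuracy": holdout_acc},
    )


# -- permutation null and empirical p ----------------------------------


@dataclass
class NullDistribution:
    """Sorted raw scores of degree-matched random candidates."""

    scores: np.ndarray
    n: int
    seed: int
    target_bin: int
    fallback_bin: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        if self.n < 100:
            raise ValueError(f"null distribution needs N >= 100, got {self.n}")


def permutation_null(graph: KnowledgeGraph, model: RelationshipModel,
                     motive_proteins: set[str] | frozenset[str],
                     candidate_degree: int, N: int = 999, seed: int = 0,
                     context: MotiveContext | None = None) -> NullDistribution:
    """Null raw-score distribution for one (motive, degree bin).

    Draws ``N`` proteins (with replacement) uniformly from the candidate's
    log2-degree bin, excluding the motive's own proteins, scores them, and
    returns the sorted raw scores.  An empty bin falls back to the nearest
    non-empty bin with a warning.
    """
    if N < 100:
        raise ValueError(f"null size must be >= 100, got {N}")
    if context is None:
        context = MotiveContext(graph, motive_proteins)
    degrees = graph.degree_sequence()
    target = degree_bin(candidate_degree)
    bins: dict[int, list[str]] = {}
    for node in sorted(degrees):
        if node in context.motive_proteins:
            continue
        bins.setdefault(degree_bin(degrees[node]), []).append(node)
    if not bins:
        raise ValueError("graph has no non-motive proteins to draw a null from")
    fallback = None
    if target in bins:
        pool = bins[target]
    else:
        fallback = min(bins, key=lambda b: (abs(b - target), b))
        warnings.warn(f"degree bin {target} is empty; falling back to "
                      f"nearest non-empty bin {fallback}")
        pool = bins[fallback]
    rng = np.random.default_rng(seed)
    draws = [pool[i] for i in rng.integers(0, len(pool), size=N)]
    raw = model.predict_raw(context.feature_matrix(draws))
    return NullDistribution(scores=raw, n=N, seed=seed, target_bin=target,
                            fallback_bin=fallback)


def empirical_p(raw: float, null: "NullDistribution | np.ndarray | list") -> float:
    """p = (1 + #{null >= raw}) / (N + 1); never 0, at most 1."""
    scores = null.scores if isinstance(null, NullDistribution) else np.asarray(null)
    n = len(scores)
    return float((1 + int(np.sum(scores >= raw))) / (n + 1))


def null_score_sample(graph: KnowledgeGraph, model: RelationshipModel,
                      motive_proteins: set[str] | frozenset[str],
                      n_draws: int, seed: int = 0, n_null: int = 999,
                      restart: float = 0.3,
                      context: MotiveContext | None = None) -> np.ndarray:
    """Calibrated scores of fresh degree-matched random candidates.

    Draws ``n_draws`` non-motive proteins uniformly, scores each, and ranks
    it against the cached permutation null of its own degree bin — i.e. the
    same sampler the nulls use.  The returned 0-100 scores measure the
    false-positive behavior of the calibration: the fraction at or above a
    band boundary should not exceed that band's nominal p.
    """
    if context is None:
        context = MotiveContext(graph, motive_proteins, restart=restart)
    rng = np.random.default_rng(seed)
    degrees = graph.degree_sequence()
    pool = sorted(n for n in graph.nodes() if n not in context.motive_proteins)
    draws = [pool[i] for i in rng.integers(0, len(pool), size=n_draws)]
    raw = model.predict_raw(context.feature_matrix(draws))
    nulls: dict[int, NullDistribution] = {}
    out = np.empty(n_draws)
    for i, (node, r) in enumerate(zip(draws, raw)):
        b = degree_bin(degrees[node])
        if b not in nulls:
            nulls[b] = permutation_null(
                graph, model, context.motive_proteins, degrees[node],
                N=n_null, seed=_null_seed(seed, "null-sample", b),
                context=context)
        out[i] = calibrate_to_ann(empirical_p(float(r), nulls[b])).value
    return out


# -- the full score matrix ---------------------------------------------

SCORE_COLUMNS = ["uniprot_id", "motive_id", "ann_score", "p_empirical",
                 "category", "is_effector", "qc_flags"]


@dataclass
class ScoreMatrix:
    """Candidate x motive score table (long format, one row per pair).

    Always carries ``uniprot_id, motive_id, ann_score, category,
    is_effector``; published sparse fixtures lack ``p_empirical`` (NaN) and
    may carry extra name columns.
    """

    df: pd.DataFrame

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       boundary: str = "closed") -> "ScoreMatrix":
        df = df.copy()
        for col in ("uniprot_id", "motive_id", "ann_score", "is_effector"):
            if col not in df.columns:
                raise ValueError(f"score matrix is missing column {col!r}")
        if "category" not in df.columns:
            df["category"] = [categorize(v, boundary).value for v in df["ann_score"]]
        if "p_empirical" not in df.columns:
            df["p_empirical"] = np.nan
        if "qc_flags" not in df.columns:
            df["qc_flags"] = ""
        df["is_effector"] = df["is_effector"].astype(bool)
        return cls(df=df)

    def write_tsv(self, path: str | Path) -> None:
        cols = [c for c in SCORE_COLUMNS if c in self.df.columns]
        extra = [c for c in self.df.columns if c not in cols]
        out = self.df[cols + extra].copy()
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t").fillna({"qc_flags": ""})
        return cls.from_dataframe(df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class NullParams:
    """Calibration settings: null size, restart probability, master seed."""

    n_null: int = 999
    restart: float = 0.3
    seed: int = 0
    boundary: str = "closed"


def _null_seed(master: int, motive_id: str, dbin: int) -> int:
    tag = zlib.crc32(f"{motive_id}:{dbin}".encode())
    return int((master + tag) % (2 ** 31))


def score_all(graph: KnowledgeGraph, model: RelationshipModel,
              dmap: DiseaseMap, candidates: CandidateList,
              null_params: NullParams | None = None) -> ScoreMatrix:
    """Score every candidate against every motive (incl. the general
    pseudo-motive), with one cached null distribution per (motive, degree
    bin).  Deterministic under the null seed."""
    np_ = null_params or NullParams()
    contexts: dict[str, MotiveContext] = {}
    units = []
    for motive_id, effectors in dmap.scoring_units():
        try:
            contexts[motive_id] = MotiveContext(graph, effectors,
                                                restart=np_.restart)
            units.append((motive_id, effectors))
        except ValueError:
            warnings.warn(f"motive {motive_id!r} has no effectors in the "
                          f"graph; skipped")
    null_cache: dict[tuple[str, int], NullDistribution] = {}
    records = []
    for entry in candidates.entries:
        uid = entry.uniprot_id
        deg = graph.degree(uid) if graph.has_node(uid) else 0
        dbin = degree_bin(deg)
        for motive_id, effectors in units:
            ctx = contexts[motive_id]
            fv = ctx.features(uid)
            raw = float(model.predict_raw(fv.as_array())[0])
            key = (motive_id, dbin)
            if key not in null_cache:
                null_cache[key] = permutation_null(
                    graph, model, effectors, deg, N=np_.n_null,
                    seed=_null_seed(np_.seed, motive_id, dbin), context=ctx)
            p = empirical_p(raw, null_cache[key])
            ann = calibrate_to_ann(p, boundary=np_.boundary)
            records.append({
                "uniprot_id": uid,
                "motive_id": motive_id,
                "ann_score": round(ann.value, 2),
                "p_empirical": p,
                "category": ann.category.value,
                "is_effector": uid in effectors,
                "qc_flags": "missing_from_graph" if fv.missing else "",
            })
    df = pd.DataFrame.from_records(records, columns=SCORE_COLUMNS)
    return ScoreMatrix(df=df)
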