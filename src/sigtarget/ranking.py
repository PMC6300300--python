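"""Turning feature tables into per-drug target rankings.

Three families of rankers:

* single-feature rankers with lowest-rank-across-cells aggregation
  (and a variant restricted to the most "active" cell);
* a logistic-regression baseline on per-(drug, gene) aggregates;
* two random-forest architectures — "on-the-fly" (drug-specific forest
  trained on drugs profiled in the same cells, features concatenated
  across cells) and "two-level" (a pooled per-cell forest whose
  probabilities are aggregated and fed to a second forest).

All stochastic steps flow from one pipeline seed; leave-one-out folds
derive their seeds as ``seed + fold_index``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import SchemaError, TrainingError
from .features import FEATURE_COLUMNS

log = logging.getLogger(__name__)

RANKABLE_FEATURES = {
    "f_cor": "desc",
    "f_PC": "desc",
    "f_CS": "asc",
    "f_DE_mean": "desc",
    "f_DE_max": "desc",
}

#: single-feature model aliases used by the CLI
FEATURE_MODELS = {
    "dir": "f_cor",
    "ind": "f_PC",
    "cs": None,  # active-cell ranking
    "max": "f_DE_max",
    "mean": "f_DE_mean",
}

LEVEL1_FEATURES = FEATURE_COLUMNS
LEVEL2_FEATURES = ["p_max", "p_mean", "n_cells", "min_f_CS"]
OTF_CELL_FEATURES = ["f_cor", "f_PC", "f_CS", "f_DE_mean", "f_DE_max"]

DEFAULT_NEGATIVE_RATIO = 50
DEFAULT_N_TREES = 500


@dataclass
class RankedTargets:
    """A total ordering of a drug's candidate target genes.

    ``genes`` is in rank order (rank 1 first); ``scores`` is
    non-increasing.
    """

    drug: str
    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing with rank")

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.genes) + 1)

    def rank_of(self, gene: str) -> int | None:
        try:
            return self.genes.index(gene) + 1
        except ValueError:
            return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": self.drug,
                "gene": self.genes,
                "score": self.scores,
                "rank": self.ranks,
            }
        )


@dataclass
class TrainedRanker:
    """A fitted ranking model plus the schema it expects."""

    kind: str  # logistic | rf_on_the_fly | rf_two_level
    models: dict
    feature_schema: list[str]
    seed: int
    cells: list[str] | None = None  # canonical cell order (on-the-fly only)
    meta: dict = field(default_factory=dict)


def _single_drug(table: pd.DataFrame) -> str:
    drugs = table["drug"].unique()
    if len(drugs) != 1:
        raise ValueError(f"expected a single-drug table, got {len(drugs)} drugs")
    return drugs[0]


def _per_cell_ranks(table: pd.DataFrame, feature: str, ascending: bool) -> pd.Series:
    """Rank candidates within each cell (1 = best); ties resolve
    lexicographically by gene id."""
    t = table.sort_values(["cell", "gene"], kind="mergesort")
    ranks = t.groupby("cell")[feature].rank(method="first", ascending=ascending)
    return ranks.reindex(table.index)


def rank_by_feature(
    table: pd.DataFrame, feature: str, direction: str | None = None
) -> RankedTargets:
    """Rank one drug's candidates by a feature with lowest-rank
    aggregation across cells.

    Within each cell candidates are ranked by the feature (descending
    for correlation/enrichment/DE features unless overridden); a gene's
    aggregate score is its minimum per-cell rank, and the final ordering
    sorts that minimum ascending with lexicographic tie-break.
    """
    if feature not in table.columns or feature not in RANKABLE_FEATURES:
        raise KeyError(f"unknown ranking feature {feature!r}")
    drug = _single_drug(table)
    if direction is None:
        direction = RANKABLE_FEATURES[feature]
    ranks = _per_cell_ranks(table, feature, ascending=(direction == "asc"))
    min_rank = (
        pd.DataFrame({"gene": table["gene"], "r": ranks})
        .groupby("gene")["r"]
        .min()
        .sort_index()
    )
    order = min_rank.reset_index().sort_values(["r", "gene"], kind="mergesort")
    return RankedTargets(
        drug=drug,
        genes=order["gene"].tolist(),
        scores=-order["r"].to_numpy(float),
    )


def rank_in_active_cell(table: pd.DataFrame) -> RankedTargets:
    """Rank by direct correlation within the cell with the lowest
    control correlation (the most "active" cell)."""
    if "f_CS" not in table.columns:
        raise KeyError("feature table lacks f_CS")
    drug = _single_drug(table)
    cs = table.groupby("cell")["f_CS"].first().sort_index()
    active = cs.index[np.argmin(cs.to_numpy())]  # ties -> first cell
    sub = table[table["cell"] == active].sort_values(
        ["f_cor", "gene"], ascending=[False, True], kind="mergesort"
    )
    return RankedTargets(
        drug=drug, genes=sub["gene"].tolist(), scores=sub["f_cor"].to_numpy(float)
    )


# --------------------------------------------------------------------------
# training-set construction
# --------------------------------------------------------------------------

def make_training_pairs(
    table: pd.DataFrame,
    targets: dict[str, set[str]],
    negative_ratio: int | str = DEFAULT_NEGATIVE_RATIO,
    seed: int = 0,
    drugs: list[str] | None = None,
) -> pd.DataFrame:
    """Labeled (drug, gene) examples: known targets as positives, a
    seeded sample of non-targets as negatives (``negative_ratio`` per
    positive, or ``"all"``).

    Drugs without a known target inside their candidate frame are
    excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    frame = table.groupby("drug")["gene"].unique()
    for drug in sorted(drugs if drugs is not None else frame.index):
        genes = np.sort(frame[drug])
        pos = sorted(set(targets.get(drug, ())).intersection(genes))
        if not pos:
            log.warning("drug %s: no known target in candidate frame; skipped", drug)
            continue
        neg_pool = np.setdiff1d(genes, pos)
        if negative_ratio == "all":
            neg = list(neg_pool)
        else:
            n_neg = min(len(neg_pool), int(negative_ratio) * len(pos))
            neg = sorted(rng.choice(neg_pool, size=n_neg, replace=False))
        rows += [(drug, g, 1) for g in pos]
        rows += [(drug, g, 0) for g in neg]
    return pd.DataFrame(rows, columns=["drug", "gene", "label"])


def _aggregate_per_gene(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(drug, gene) aggregates for linear models: min per-cell rank
    of each rankable feature across cells, plus min f_CS and f_loc."""
    parts = {}
    for feature, direction in RANKABLE_FEATURES.items():
        if feature == "f_CS":
            continue
        ranks = []
        for _, sub in table.groupby("drug"):
            r = _per_cell_ranks(sub, feature, ascending=(direction == "asc"))
            ranks.append(r)
        allr = pd.concat(ranks)
        parts[f"minrank_{feature}"] = (
            pd.DataFrame(
                {"drug": table["drug"], "gene": table["gene"], "r": allr}
            )
            .groupby(["drug", "gene"])["r"]
            .min()
        )
    agg = pd.DataFrame(parts)
    agg["min_f_CS"] = table.groupby(["drug", "gene"])["f_CS"].min()
    agg["f_loc"] = table.groupby(["drug", "gene"])["f_loc"].first()
    return agg.reset_index()


LOGISTIC_FEATURES = [
    "minrank_f_cor",
    "minrank_f_PC",
    "minrank_f_DE_mean",
    "minrank_f_DE_max",
    "min_f_CS",
    "f_loc",
]


def train_logistic(
    table: pd.DataFrame,
    pairs: pd.DataFrame,
    seed: int = 0,
    agg: pd.DataFrame | None = None,
) -> TrainedRanker:
    """Logistic-regression baseline on per-(drug, gene) aggregates.

    ``agg`` may carry precomputed per-(drug, gene) aggregates (they are
    per-drug transforms, so precomputing once across folds leaks
    nothing).
    """
    if agg is None:
        agg = _aggregate_per_gene(table)
    data = pairs.merge(agg, on=["drug", "gene"], how="inner")
    y = data["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise TrainingError("logistic training needs both classes")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "lr",
                LogisticRegression(
                    class_weight="balanced", max_iter=2000, random_state=seed
                ),
            ),
        ]
    )
    model.fit(data[LOGISTIC_FEATURES].to_numpy(), y)
    return TrainedRanker(
        kind="logistic", models={"lr": model}, feature_schema=LOGISTIC_FEATURES,
        seed=seed,
    )


def _level2_frame(table: pd.DataFrame, p1: np.ndarray) -> pd.DataFrame:
    t = table[["drug", "gene", "f_CS"]].copy()
    t["p1"] = p1
    g = t.groupby(["drug", "gene"])
    out = pd.DataFrame(
        {
            "p_max": g["p1"].max(),
            "p_mean": g["p1"].mean(),
            "n_cells": g["p1"].size().astype(float),
            "min_f_CS": g["f_CS"].min(),
        }
    )
    return out.reset_index()


def _forest(seed: int, n_trees: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        class_weight="balanced_subsample",
        random_state=seed,
        n_jobs=1,
    )


def train_rf_two_level(
    table: pd.DataFrame,
    pairs: pd.DataFrame,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> TrainedRanker:
    """Pooled two-level forest: per-(drug, gene, cell) rows feed a first
    forest; its probabilities are aggregated per (drug, gene) (max,
    mean, cell count, min f_CS) and a second forest produces the final
    score.  Drugs with different cell counts pool without restriction."""
    data = pairs.merge(table, on=["drug", "gene"], how="inner")
    if data.empty:
        raise TrainingError("no training rows after joining pairs with features")
    y1 = data["label"].to_numpy()
    if len(np.unique(y1)) < 2:
        raise TrainingError("two-level training needs both classes")
    rf1 = _forest(seed, n_trees)
    rf1.fit(data[LEVEL1_FEATURES].to_numpy(), y1)
    p1 = rf1.predict_proba(data[LEVEL1_FEATURES].to_numpy())[:, 1]
    lvl2 = _level2_frame(data, p1)
    labels = pairs.set_index(["drug", "gene"])["label"]
    y2 = labels.loc[list(zip(lvl2["drug"], lvl2["gene"]))].to_numpy()
    rf2 = _forest(seed + 1, n_trees)
    rf2.fit(lvl2[LEVEL2_FEATURES].to_numpy(), y2)
    return TrainedRanker(
        kind="rf_two_level",
        models={"rf1": rf1, "rf2": rf2},
        feature_schema=LEVEL1_FEATURES,
        seed=seed,
    )


def _otf_vectors(table: pd.DataFrame, cells: list[str]) -> pd.DataFrame:
    """Fixed-length per-(drug, gene) vectors: per-cell feature blocks in
    canonical (sorted) cell order, then f_loc."""
    sub = table[table["cell"].isin(cells)]
    wide = sub.pivot_table(
        index=["drug", "gene"], columns="cell", values=OTF_CELL_FEATURES, sort=True
    )
    cols = [(feat, c) for c in cells for feat in OTF_CELL_FEATURES]
    if not set(cols).issubset(set(wide.columns)):
        raise SchemaError("training drugs do not cover the query drug's cells")
    wide = wide[cols]
    if wide.isna().any().any():
        raise SchemaError("incomplete feature rows for requested cells")
    wide.columns = [f"{feat}@{c}" for feat, c in cols]
    loc = sub.groupby(["drug", "gene"])["f_loc"].first()
    wide["f_loc"] = loc
    return wide.reset_index()


def train_rf_on_the_fly(
    query_drug: str,
    table: pd.DataFrame,
    pairs: pd.DataFrame,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> TrainedRanker:
    """Drug-specific forest trained on the drugs profiled in (at least)
    the query drug's cells, with features restricted to those cells and
    concatenated in canonical cell order."""
    query_cells = sorted(table.loc[table["drug"] == query_drug, "cell"].unique())
    if not query_cells:
        raise SchemaError(f"query drug {query_drug!r} absent from feature table")
    cells_by_drug = table.groupby("drug")["cell"].agg(lambda s: set(s))
    usable = [
        d
        for d in sorted(set(pairs["drug"]))
        if d != query_drug and set(query_cells) <= cells_by_drug.get(d, set())
    ]
    if len(usable) < 2:
        raise TrainingError(
            f"drug {query_drug!r}: fewer than 2 training drugs share its cell set; "
            "fall back to the two-level model"
        )
    train_pairs = pairs[pairs["drug"].isin(usable)]
    vectors = _otf_vectors(table[table["drug"].isin(usable)], query_cells)
    data = train_pairs.merge(vectors, on=["drug", "gene"], how="inner")
    schema = [c for c in vectors.columns if c not in ("drug", "gene")]
    y = data["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise TrainingError("on-the-fly training needs both classes")
    rf = _forest(seed, n_trees)
    rf.fit(data[schema].to_numpy(), y)
    return TrainedRanker(
        kind="rf_on_the_fly",
        models={"rf": rf},
        feature_schema=schema,
        seed=seed,
        cells=query_cells,
    )


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def _order_by_score(
    drug: str, genes: list[str], scores: np.ndarray, best_cor: np.ndarray
) -> RankedTargets:
    # tie cascade: score desc -> best f_cor desc -> gene id asc
    order = np.lexsort((genes, -best_cor, -scores))
    return RankedTargets(
        drug=drug,
        genes=[genes[i] for i in order],
        scores=scores[order],
    )


def predict_ranking(model: TrainedRanker, table: pd.DataFrame) -> RankedTargets:
    """Score every candidate of a single drug and return a total order."""
    drug = _single_drug(table)
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing columns {missing}")
    if table[FEATURE_COLUMNS].isna().any().any():
        raise SchemaError("feature table contains missing values; no imputation")
    best_cor_s = table.groupby("gene")["f_cor"].max().sort_index()
    genes = best_cor_s.index.tolist()
    cell_counts = table.groupby("gene")["cell"].nunique()
    if cell_counts.nunique() != 1:
        raise SchemaError("candidates cover unequal cell sets; no imputation")

    if model.kind == "logistic":
        agg = _aggregate_per_gene(table).set_index("gene").loc[genes]
        scores = model.models["lr"].predict_proba(
            agg[LOGISTIC_FEATURES].to_numpy()
        )[:, 1]
    elif model.kind == "rf_two_level":
        p1 = model.models["rf1"].predict_proba(
            table[LEVEL1_FEATURES].to_numpy()
        )[:, 1]
        lvl2 = _level2_frame(table, p1).set_index("gene").loc[genes]
        scores = model.models["rf2"].predict_proba(
            lvl2[LEVEL2_FEATURES].to_numpy()
        )[:, 1]
    elif model.kind == "rf_on_the_fly":
        vectors = _otf_vectors(table, model.cells).set_index("gene").loc[genes]
        scores = model.models["rf"].predict_proba(
            vectors[model.feature_schema].to_numpy()
        )[:, 1]
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    return _order_by_score(drug, genes, np.asarray(scores), best_cor_s.to_numpy())


def rank_single_feature_model(table: pd.DataFrame, model: str) -> RankedTargets:
    """Rank one drug's table with a single-feature model alias
    (dir/ind/cs/max/mean)."""
    if model not in FEATURE_MODELS:
        raise KeyError(f"unknown single-feature model {model!r}")
    if model == "cs":
        return rank_in_active_cell(table)
    return rank_by_feature(table, FEATURE_MODELS[model])


# --------------------------------------------------------------------------
# leave-one-out cross-validation
# --------------------------------------------------------------------------

def loocv(
    table: pd.DataFrame,
    targets: dict[str, set[str]],
    model_kind: str,
    seed: int = 0,
    negative_ratio: int | str = DEFAULT_NEGATIVE_RATIO,
    n_trees: int = DEFAULT_N_TREES,
) -> tuple[dict[str, RankedTargets], dict[str, str]]:
    """Leave-one-drug-out evaluation for a learned model kind
    (``logistic``, ``rf_two_level``, ``rf_on_the_fly``).

    Returns (rankings per drug, failures per drug).  The held-out
    drug's examples never enter its fold's training set.
    """
    drugs = sorted(table["drug"].unique())
    if len(drugs) < 3:
        raise TrainingError("leave-one-out needs at least 3 drugs")
    rankings: dict[str, RankedTargets] = {}
    failures: dict[str, str] = {}
    agg = _aggregate_per_gene(table) if model_kind == "logistic" else None
    for fold, drug in enumerate(drugs):
        train_drugs = [d for d in drugs if d != drug]
        fold_seed = seed + fold
        pairs = make_training_pairs(
            table, targets, negative_ratio=negative_ratio, seed=fold_seed,
            drugs=train_drugs,
        )
        query_table = table[table["drug"] == drug].reset_index(drop=True)
        try:
            if model_kind == "logistic":
                model = train_logistic(table, pairs, seed=fold_seed, agg=agg)
            elif model_kind == "rf_two_level":
                model = train_rf_two_level(table, pairs, seed=fold_seed,
                                           n_trees=n_trees)
            elif model_kind == "rf_on_the_fly":
                model = train_rf_on_the_fly(drug, table, pairs, seed=fold_seed,
                                            n_trees=n_trees)
            else:
                raise ValueError(f"unknown model kind {model_kind!r}")
            rankings[drug] = predict_ranking(model, query_table)
        except (TrainingError, SchemaError) as exc:
            log.warning("fold %s (%s) failed: %s", fold, drug, exc)
            failures[drug] = str(exc)
    return rankings, failures


def write_rankings(rankings: dict[str, RankedTargets], path) -> None:
    frames = [rankings[d].to_frame() for d in sorted(rankings)]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_rankings(path) -> dict[str, RankedTargets]:
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "gene": str})
    out = {}
    for drug, sub in df.groupby("drug"):
        sub = sub.sort_values("rank")
        out[drug] = RankedTargets(
            drug=drug, genes=sub["gene"].tolist(), scores=sub["score"].to_numpy()
        )
    return out
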