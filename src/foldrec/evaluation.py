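"""Training and benchmarking protocol for template ranking.

Pairs are split into folds grouped by target protein (every pair of a
target lands in the target's fold), training sets additionally drop any
pair whose template is a test-fold target (leakage removal), and training
negatives may be subsampled to a fixed negatives-per-positive ratio while
positives and test pairs are never touched.

After scoring, each target's templates are ranked by the predicted
same-fold probability and recognition sensitivity is reported per
structural level under the usual exclusion convention for this benchmark:
when evaluating the superfamily level, templates related at the (easier)
family level are removed from the ranking first; at the fold level both
family- and superfamily-related templates are removed.  Sensitivity is the
percentage of eligible targets (those with at least one template related
at exactly the evaluated level) with a correct template in the top-1 or
top-5.  The pooled pair error rate uses the 0.5 probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .benchmark import LEVELS, BenchmarkDataset, target_levels
from .features import feature_columns, relationship_lookup
from .forest import ForestParams, train_forest

#: Easier relationships removed from a ranking before evaluating a level.
EXCLUDED_ABOVE = {
    "family": (),
    "superfamily": ("family",),
    "fold": ("family", "superfamily"),
}


def _derive_seed(base: int, *key: int) -> int:
    """A reproducible sub-seed below 2**31 for (base, key...)."""
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CVPlan:
    """Grouped fold assignment: every target protein belongs to one fold."""

    n_folds: int
    assignments: dict[str, int]
    seed: int

    def fold_targets(self, fold: int) -> set[str]:
        if fold < 0 or fold >= self.n_folds:
            raise ValueError(f"fold index {fold} out of range")
        return {t for t, f in self.assignments.items() if f == fold}


def make_cv_plan(ds: BenchmarkDataset, n_folds: int = 10, seed: int = 0) -> CVPlan:
    """Shuffle targets by seed, deal them round-robin into ``n_folds`` folds.

    Fold sizes (in targets) differ by at most one, and all pairs sharing a
    target automatically share its fold.
    """
    targets = sorted(p.id for p in ds.proteins)
    if len(targets) < n_folds:
        raise ValueError(
            f"{len(targets)} targets cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(targets))
    assignments = {targets[j]: i % n_folds for i, j in enumerate(order)}
    return CVPlan(n_folds=n_folds, assignments=assignments, seed=seed)


def training_pairs_for_fold(
    table: pd.DataFrame, plan: CVPlan, test_fold: int
) -> pd.DataFrame:
    """Training rows for one held-out fold, with template leakage removed.

    Keeps pairs whose target is outside the test fold AND whose template is
    not a target of the test fold.
    """
    test_targets = plan.fold_targets(test_fold)  # validates the index
    tfold = table["target_id"].map(plan.assignments)
    keep = (tfold != test_fold) & ~table["template_id"].isin(test_targets)
    out = table[keep]
    if out.empty:
        raise ValueError(f"no training pairs left for test fold {test_fold}")
    return out


def subsample_negatives(
    training: pd.DataFrame, ratio: float, seed: int = 0
) -> pd.DataFrame:
    """Keep all positives, sample floor(ratio * n_pos) training negatives.

    When the requested count reaches the available negatives, everything is
    kept (the original distribution).  Never applied to test pairs.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    pos_mask = training["relationship"] != "none"
    n_pos = int(pos_mask.sum())
    if n_pos == 0:
        raise ValueError("no positive pairs in the training set")
    neg_idx = training.index[~pos_mask]
    want = int(ratio * n_pos)
    if want >= len(neg_idx):
        return training
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(neg_idx), size=want, replace=False)
    keep = training.index[pos_mask].append(neg_idx[np.sort(chosen)])
    return training.loc[keep.sort_values()]


@dataclass
class RankedTemplates:
    """Templates of one target, best predicted same-fold probability first."""

    target_id: str
    ranking: list[tuple[str, float]]


def rank_templates(target_id: str, scored) -> RankedTemplates:
    """Sort (template_id, probability) pairs descending by probability.

    Ties break lexicographically on template id, so rankings are
    deterministic.
    """
    scored = list(scored)
    if not scored:
        raise ValueError(f"no scored templates for target {target_id!r}")
    ranking = sorted(scored, key=lambda tp: (-tp[1], tp[0]))
    return RankedTemplates(target_id=target_id, ranking=ranking)


@dataclass
class LevelSensitivity:
    n_eligible: int
    top1_count: int
    top5_count: int

    @property
    def top1_pct(self) -> float:
        return 100.0 * self.top1_count / self.n_eligible

    @property
    def top5_pct(self) -> float:
        return 100.0 * self.top5_count / self.n_eligible


@dataclass
class SensitivityReport:
    """Top-1/top-5 recognition counts and percentages per structural level."""

    levels: dict[str, LevelSensitivity]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for lvl in LEVELS:
            s = self.levels[lvl]
            rows.append(
                {
                    "level": lvl,
                    "n_eligible": s.n_eligible,
                    "top1_count": s.top1_count,
                    "top1_pct": s.top1_pct,
                    "top5_count": s.top5_count,
                    "top5_pct": s.top5_pct,
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [f"{'Level':<12}{'N':>5}{'Top1':>8}{'Top1%':>8}{'Top5':>8}{'Top5%':>8}"]
        for lvl in LEVELS:
            s = self.levels[lvl]
            lines.append(
                f"{lvl:<12}{s.n_eligible:>5}{s.top1_count:>8}"
                f"{s.top1_pct:>8.1f}{s.top5_count:>8}{s.top5_pct:>8.1f}"
            )
        return "\n".join(lines)


def topk_sensitivity(
    rankings: list[RankedTemplates],
    ds: BenchmarkDataset,
    level: str,
    k: int,
) -> tuple[int, float]:
    """Hit count and percentage of eligible targets at one level.

    Eligibility and exclusions are decided from the dataset's hierarchy,
    not from the predictions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    rels = relationship_lookup(ds)
    eligible_targets = {
        pid for pid, lvls in target_levels(ds).items() if level in lvls
    }
    if not eligible_targets:
        raise ValueError(f"no targets have any match at the {level} level")
    excluded = EXCLUDED_ABOVE[level]
    hits = 0
    for r in rankings:
        if r.target_id not in eligible_targets:
            continue
        surviving = [
            tid
            for tid, _ in r.ranking
            if rels[(r.target_id, tid)] not in excluded
        ]
        if any(rels[(r.target_id, tid)] == level for tid in surviving[:k]):
            hits += 1
    return hits, 100.0 * hits / len(eligible_targets)


def sensitivity_report(
    rankings: list[RankedTemplates], ds: BenchmarkDataset
) -> SensitivityReport:
    levels = {}
    for lvl in LEVELS:
        top1, _ = topk_sensitivity(rankings, ds, lvl, 1)
        top5, _ = topk_sensitivity(rankings, ds, lvl, 5)
        n_elig = sum(1 for lvls in target_levels(ds).values() if lvl in lvls)
        levels[lvl] = LevelSensitivity(n_elig, top1, top5)
    return SensitivityReport(levels=levels)


def pair_error_rate(predictions, labels) -> float:
    """100 x misclassified / total for 0/1 predictions against 0/1 labels."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels length mismatch")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(100.0 * np.mean(pred != lab))


@dataclass
class CVResult:
    """Pooled outcome of one grouped cross-validation run."""

    report: SensitivityReport
    error_rate: float
    scores: np.ndarray  # P(same fold) per table row, pooled over folds
    rankings: list[RankedTemplates]
    plan: CVPlan
    params: ForestParams
    ratio: float | None
    fold_stats: list[dict] = field(default_factory=list)


def run_cross_validation(
    ds: BenchmarkDataset,
    table: pd.DataFrame,
    params: ForestParams | None = None,
    plan: CVPlan | None = None,
    ratio: float | None = None,
    n_folds: int = 10,
    seed: int = 0,
    features: list[str] | None = None,
) -> CVResult:
    """Train/score every fold, rank templates, report pooled metrics.

    ``ratio`` is the training negatives-per-positive subsampling ratio
    (None keeps the original distribution).  ``features`` restricts the
    model to a subset of feature columns.  Per-fold forest and subsampling
    seeds are derived from ``seed``; with a fixed plan the whole run is
    deterministic.
    """
    params = params or ForestParams()
    if plan is None:
        plan = make_cv_plan(ds, n_folds=n_folds, seed=seed)
    cols = features if features is not None else feature_columns(table)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns absent from table: {missing}")
    X = table[cols].to_numpy(dtype=float)
    y = (table["relationship"] != "none").to_numpy().astype(np.int64)
    tfold = table["target_id"].map(plan.assignments).to_numpy()
    scores = np.full(len(table), np.nan)
    fold_stats: list[dict] = []
    for fold in range(plan.n_folds):
        train_df = training_pairs_for_fold(table, plan, fold)
        if ratio is not None:
            train_df = subsample_negatives(
                train_df, ratio, seed=_derive_seed(seed, fold, 1)
            )
        tr = table.index.get_indexer(train_df.index)
        fold_params = replace(params, seed=_derive_seed(seed, fold, 0))
        forest = train_forest(X[tr], y[tr], fold_params, feature_names=cols)
        test = np.flatnonzero(tfold == fold)
        if len(test):
            scores[test] = forest.predict_proba(X[test])[:, 1]
        fold_stats.append(
            {
                "fold": fold,
                "n_train": int(len(tr)),
                "n_train_pos": int(y[tr].sum()),
                "n_test": int(len(test)),
            }
        )
    if np.isnan(scores).any():
        raise RuntimeError("some pairs were never scored; bad CV plan?")
    pred = (scores > 0.5).astype(np.int64)
    err = pair_error_rate(pred, y)
    rankings = []
    targets = table["target_id"].to_numpy()
    templates = table["template_id"].to_numpy()
    order = np.argsort(targets, kind="stable")
    bounds = np.flatnonzero(
        np.r_[True, targets[order][1:] != targets[order][:-1], True]
    )
    for a, b in zip(bounds[:-1], bounds[1:]):
        rows = order[a:b]
        rankings.append(
            rank_templates(
                targets[rows[0]],
                zip(templates[rows], scores[rows]),
            )
        )
    report = sensitivity_report(rankings, ds)
    return CVResult(
        report=report,
        error_rate=err,
        scores=scores,
        rankings=rankings,
        plan=plan,
        params=params,
        ratio=ratio,
        fold_stats=fold_stats,
    )


def imbalance_sweep(
    ds: BenchmarkDataset,
    table: pd.DataFrame,
    ratios: list[float],
    params: ForestParams | None = None,
    plan: CVPlan | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """One cross-validation per training ratio, sharing a single CV plan.

    Returns a table with per-level top-1/top-5 counts and percentages plus
    the pooled error rate, one row per ratio.
    """
    if not ratios:
        raise ValueError("empty ratio list")
    if plan is None:
        plan = make_cv_plan(ds, n_folds=n_folds, seed=seed)
    rows = []
    for ratio in ratios:
        res = run_cross_validation(
            ds, table, params, plan=plan, ratio=ratio, seed=seed
        )
        row: dict = {"ratio": ratio, "error_rate": res.error_rate}
        for lvl in LEVELS:
            s = res.report.levels[lvl]
            row[f"{lvl}_top1"] = s.top1_count
            row[f"{lvl}_top5"] = s.top5_count
            row[f"{lvl}_top1_pct"] = s.top1_pct
            row[f"{lvl}_top5_pct"] = s.top5_pct
        rows.append(row)
    return pd.DataFrame(rows)


def feature_count_sweep(
    ds: BenchmarkDataset,
    table: pd.DataFrame,
    feature_counts: list[int],
    params: ForestParams | None = None,
    plan: CVPlan | None = None,
    ratio: float | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate on the first ``m`` canonical features for each ``m``."""
    if not feature_counts:
        raise ValueError("empty feature-count list")
    cols = feature_columns(table)
    if plan is None:
        plan = make_cv_plan(ds, n_folds=n_folds, seed=seed)
    rows = []
    for m in feature_counts:
        if m < 1 or m > len(cols):
            raise ValueError(
                f"feature count {m} outside [1, {len(cols)}]"
            )
        res = run_cross_validation(
            ds, table, params, plan=plan, ratio=ratio, seed=seed,
            features=cols[:m],
        )
        row: dict = {"n_features": m, "error_rate": res.error_rate}
        for lvl in LEVELS:
            s = res.report.levels[lvl]
            row[f"{lvl}_top1_pct"] = s.top1_pct
            row[f"{lvl}_top5_pct"] = s.top5_pct
        rows.append(row)
    return pd.DataFrame(rows)
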