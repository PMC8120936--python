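"""Evaluation of scoring functions over decoy sets with known TM-scores.

Three procedures: pairwise ranking accuracy per quality category, per-target
correlation averaging (Pearson / Spearman / Kendall), and average predicted
rank per category — plus Wilcoxon signed-rank comparison of two scorers and
recomputation over class-labeled target subsets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .similarity import QualityCategory, quality_category

log = logging.getLogger(__name__)

CATEGORIES = tuple(QualityCategory)
TABLE_COLUMNS = ("target_id", "model_id", "tm", "score", "is_native")


@dataclass(frozen=True)
class DecoyRecord:
    """One scored model of one target."""

    target_id: str
    model_id: str
    tm: float
    score: float = math.nan
    is_native: bool = False


class DecoySetTable:
    """Decoy records grouped by target, with an optional class-label map."""

    def __init__(self, df: pd.DataFrame,
                 labels: Optional[Mapping[str, str]] = None):
        missing = set(TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = df.loc[:, list(TABLE_COLUMNS)].reset_index(drop=True)
        if df.duplicated(["target_id", "model_id"]).any():
            raise ValueError("(target_id, model_id) pairs must be unique")
        if ((df["tm"] < 0) | (df["tm"] > 1)).any():
            raise ValueError("tm values must lie in [0, 1]")
        if (df.loc[df["is_native"], "tm"] != 1.0).any():
            raise ValueError("native records must have tm = 1")
        sizes = df.groupby("target_id").size()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValueError(f"targets with fewer than 2 records: {small}")
        self.df = df
        self.labels = dict(labels) if labels else None

    @classmethod
    def from_records(cls, records: Iterable[DecoyRecord],
                     labels: Optional[Mapping[str, str]] = None
                     ) -> "DecoySetTable":
        df = pd.DataFrame([r.__dict__ for r in records])
        return cls(df, labels)

    @classmethod
    def from_tsv(cls, path, labels_path=None) -> "DecoySetTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        labels = None
        if labels_path is not None:
            ldf = pd.read_csv(labels_path, sep="\t", comment="#", header=None,
                              names=["target_id", "class_label"])
            labels = dict(zip(ldf["target_id"], ldf["class_label"]))
        return cls(df, labels)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_targets(self) -> int:
        return self.df["target_id"].nunique()

    def subset(self, target_ids: Iterable[str]) -> "DecoySetTable":
        ids = set(target_ids)
        return DecoySetTable(self.df[self.df["target_id"].isin(ids)],
                             self.labels)


def pairwise_outcomes(table: DecoySetTable, min_delta_tm: float = 0.1,
                      attribution: str = "higher") -> pd.DataFrame:
    """Per-pair correctness indicators for all qualifying within-target pairs.

    A pair qualifies when |Δtm| >= ``min_delta_tm``; it is correct when the
    higher-tm member has the strictly lower score.  ``attribution`` assigns
    the pair to the quality category of its higher- or lower-tm member (or
    duplicates it into both).
    """
    if attribution not in ("higher", "lower", "both"):
        raise ValueError("attribution must be 'higher', 'lower' or 'both'")
    frames = []
    for target_id, group in table.df.groupby("target_id", sort=True):
        tm = group["tm"].to_numpy()
        score = group["score"].to_numpy()
        if np.isnan(score).any():
            raise ValueError(f"target {target_id}: missing scores")
        i, j = np.triu_indices(len(group), k=1)
        keep = np.abs(tm[i] - tm[j]) >= min_delta_tm
        i, j = i[keep], j[keep]
        if len(i) == 0:
            continue
        hi = np.where(tm[i] >= tm[j], i, j)
        lo = np.where(tm[i] >= tm[j], j, i)
        correct = score[hi] < score[lo]
        cats_hi = [quality_category(t).value for t in tm[hi]]
        frames.append(pd.DataFrame({
            "target_id": target_id,
            "category": cats_hi if attribution != "lower"
            else [quality_category(t).value for t in tm[lo]],
            "correct": correct,
        }))
        if attribution == "both":
            frames.append(pd.DataFrame({
                "target_id": target_id,
                "category": [quality_category(t).value for t in tm[lo]],
                "correct": correct,
            }))
    if not frames:
        return pd.DataFrame(columns=["target_id", "category", "correct"])
    return pd.concat(frames, ignore_index=True)


def pairwise_accuracy(table: DecoySetTable, min_delta_tm: float = 0.1,
                      attribution: str = "higher",
                      per_target_mean: bool = False
                      ) -> dict[str, Optional[float]]:
    """Percentage of correctly ranked pairs, per category plus overall.

    Categories with no qualifying pairs map to ``None`` (undefined, not 0).
    With ``per_target_mean`` accuracies are averaged over targets instead of
    pooled over pairs.
    """
    outcomes = pairwise_outcomes(table, min_delta_tm, attribution)

    def acc(sub: pd.DataFrame) -> Optional[float]:
        if len(sub) == 0:
            return None
        if per_target_mean:
            return float(100.0 * sub.groupby("target_id")["correct"]
                         .mean().mean())
        return float(100.0 * sub["correct"].mean())

    result: dict[str, Optional[float]] = {
        cat.value: acc(outcomes[outcomes["category"] == cat.value])
        for cat in CATEGORIES
    }
    result["overall"] = acc(outcomes)
    return result


@dataclass
class CorrelationSummary:
    pearson: float
    spearman: float
    kendall: float
    n_targets: int
    n_skipped: int = 0


def per_target_correlations(table: DecoySetTable) -> CorrelationSummary:
    """Correlation between tm and negated score, averaged over targets.

    Positive values mean agreement (better model -> better score).  Targets
    with fewer than 3 records or zero score/tm variance are skipped with a
    warning; an error is raised when nothing is left.
    """
    cc, rho, tau = [], [], []
    n_skipped = 0
    for target_id, group in table.df.groupby("target_id", sort=True):
        tm = group["tm"].to_numpy()
        quality = -group["score"].to_numpy()
        if len(group) < 3 or np.std(quality) == 0 or np.std(tm) == 0:
            log.warning("skipping target %s: too few models or zero variance",
                        target_id)
            n_skipped += 1
            continue
        cc.append(stats.pearsonr(tm, quality).statistic)
        rho.append(stats.spearmanr(tm, quality).statistic)
        tau.append(stats.kendalltau(tm, quality).statistic)
    if not cc:
        raise ValueError("all targets skipped; no correlations computable")
    return CorrelationSummary(float(np.mean(cc)), float(np.mean(rho)),
                              float(np.mean(tau)), len(cc), n_skipped)


def average_predicted_rank(table: DecoySetTable,
                           category: QualityCategory) -> Optional[float]:
    """Mean within-target rank (1 = best score) of records in a category.

    Score ties receive fractional (mean) ranks.  Returns ``None`` when the
    category is empty across all targets.
    """
    ranks = []
    for _, group in table.df.groupby("target_id", sort=True):
        r = group["score"].rank(method="average", ascending=True)
        cats = group["tm"].map(lambda t: quality_category(t))
        ranks.extend(r[cats == category].tolist())
    if not ranks:
        return None
    return float(np.mean(ranks))


@dataclass
class ScorerComparison:
    p_value: Optional[float]
    significant: bool
    no_difference: bool = False


def compare_scorers(outcomes_a, outcomes_b,
                    alpha: float = 0.05) -> ScorerComparison:
    """Wilcoxon signed-rank test on paired correctness indicators.

    Zero-difference pairs are dropped (standard practice); when every pair
    is tied the result is "no difference" with an undefined p-value.
    """
    a = np.asarray(outcomes_a, dtype=float)
    b = np.asarray(outcomes_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("outcome sequences must have equal length")
    if np.all(a == b):
        return ScorerComparison(None, False, no_difference=True)
    res = stats.wilcoxon(a, b, zero_method="wilcox")
    p = float(res.pvalue)
    return ScorerComparison(p, p < alpha)


@dataclass
class BenchmarkResult:
    """Full evaluation of one scorer over one decoy-set table."""

    accuracy: dict[str, Optional[float]]
    pair_counts: dict[str, int]
    correlations: CorrelationSummary
    mean_ranks: dict[str, Optional[float]]
    n_targets: int
    n_records: int
    min_delta_tm: float
    attribution: str = "higher"

    def to_dict(self) -> dict:
        return {
            "accuracy_percent": self.accuracy,
            "pair_counts": self.pair_counts,
            "correlations": {
                "pearson": self.correlations.pearson,
                "spearman": self.correlations.spearman,
                "kendall": self.correlations.kendall,
                "n_targets": self.correlations.n_targets,
                "n_skipped": self.correlations.n_skipped,
            },
            "mean_predicted_rank": self.mean_ranks,
            "n_targets": self.n_targets,
            "n_records": self.n_records,
            "min_delta_tm": self.min_delta_tm,
            "attribution": self.attribution,
        }


def run_benchmark(table: DecoySetTable, min_delta_tm: float = 0.1,
                  attribution: str = "higher") -> BenchmarkResult:
    outcomes = pairwise_outcomes(table, min_delta_tm, attribution)
    counts = {cat.value: int((outcomes["category"] == cat.value).sum())
              for cat in CATEGORIES}
    counts["overall"] = len(outcomes)
    return BenchmarkResult(
        accuracy=pairwise_accuracy(table, min_delta_tm, attribution),
        pair_counts=counts,
        correlations=per_target_correlations(table),
        mean_ranks={cat.value: average_predicted_rank(table, cat)
                    for cat in CATEGORIES},
        n_targets=table.n_targets,
        n_records=len(table),
        min_delta_tm=min_delta_tm,
        attribution=attribution,
    )


def subset_by_class(table: DecoySetTable,
                    labels: Optional[Mapping[str, str]] = None,
                    min_delta_tm: float = 0.1,
                    attribution: str = "higher"
                    ) -> dict[str, BenchmarkResult]:
    """Recompute the benchmark per class of targets.

    Unlabeled targets are excluded with a warning; empty classes are simply
    absent from the output.
    """
    labels = labels if labels is not None else table.labels
    if not labels:
        raise ValueError("no class labels supplied")
    targets = set(table.df["target_id"])
    unlabeled = targets - set(labels)
    if unlabeled:
        log.warning("excluding %d unlabeled targets: %s", len(unlabeled),
                    sorted(unlabeled)[:5])
    by_class: dict[str, list[str]] = {}
    for target, cls in labels.items():
        if target in targets:
            by_class.setdefault(cls, []).append(target)
    return {
        cls: run_benchmark(table.subset(ids), min_delta_tm, attribution)
        for cls, ids in sorted(by_class.items())
        if ids
    }
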