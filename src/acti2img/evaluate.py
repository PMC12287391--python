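"""Train/test splits, confusion matrices, classification metrics and
cohort-level descriptive statistics.

Metrics follow the standard confusion-matrix definitions and are reported
as percentages (2 d.p. in rendered tables)::

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the condition group coded as the positive class (label 1).
Precision/recall with an empty denominator are flagged undefined and F1
then reported as 0.

Two split modes are provided.  ``segment_level`` randomly splits windows
stratified by class - this mirrors evaluation protocols that split "the
data" - but lets windows from one participant land on both sides, which
leaks person-specific information.  ``participant_level`` assigns whole
participants to one side and is the leakage-safe choice; both are exposed
so the gap between them can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .io import CohortManifest, Group
from .segment import Segment


@dataclass
class ConfusionCounts:
    """2x2 confusion-matrix cell counts (condition = positive class)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


@dataclass
class EvalReport:
    """Metrics (percent scale) plus their confusion matrix and split info."""

    confusion: ConfusionCounts
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float
    split: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.as_dict(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "split": self.split,
            "flags": list(self.flags),
        }

    def markdown_row(self, name: str = "") -> str:
        fmt = lambda v: "undef" if v is None else f"{v:.2f}%"
        return (
            f"| {name} | {fmt(self.accuracy)} | {fmt(self.precision)} | "
            f"{fmt(self.recall)} | {fmt(self.f1)} |"
        )


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Count TP/FP/TN/FN from 0/1 label and prediction vectors."""
    y = np.asarray(labels).ravel().astype(int)
    p = np.asarray(predictions).ravel().astype(int)
    if y.size != p.size:
        raise ValueError("labels and predictions must have equal length")
    if y.size == 0:
        raise ValueError("need at least one pair")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same scale as the inputs)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(conf: ConfusionCounts, split: dict | None = None) -> EvalReport:
    """Accuracy / precision / recall / F1 as percentages from counts.

    Undefined precision (TP+FP = 0) or recall (TP+FN = 0) is reported as
    ``None`` with a flag, and F1 is then 0.
    """
    flags: list[str] = []
    accuracy = 100.0 * (conf.tp + conf.tn) / conf.total
    if conf.tp + conf.fp == 0:
        precision = None
        flags.append("precision undefined (no positive predictions)")
    else:
        precision = 100.0 * conf.tp / (conf.tp + conf.fp)
    if conf.tp + conf.fn == 0:
        recall = None
        flags.append("recall undefined (no positive labels)")
    else:
        recall = 100.0 * conf.tp / (conf.tp + conf.fn)
    if precision is None or recall is None:
        f1 = 0.0
    else:
        f1 = f1_from_precision_recall(precision, recall)
    return EvalReport(
        confusion=conf,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        split=split or {},
        flags=flags,
    )


def split_dataset(
    segments: list[Segment],
    mode: str = "segment_level",
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[Segment], list[Segment]]:
    """Deterministic train/test split of labelled segments.

    ``segment_level`` stratifies individual windows by class;
    ``participant_level`` assigns whole participants (stratified by group)
    to one side, so no participant spans both.  Raises if either side ends
    up without one of the classes.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if not segments:
        raise ValueError("no segments to split")
    if mode == "segment_level":
        labels = [s.label for s in segments]
        train_seg, test_seg = train_test_split(
            segments,
            test_size=test_fraction,
            random_state=int(seed) % (2**32),
            stratify=labels,
            shuffle=True,
        )
    elif mode == "participant_level":
        by_group: dict[Group, list[str]] = {Group.CONDITION: [], Group.CONTROL: []}
        seen: set[str] = set()
        for s in segments:
            if s.participant_id not in seen:
                seen.add(s.participant_id)
                by_group[s.group].append(s.participant_id)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
        test_ids: set[str] = set()
        for grp, ids in by_group.items():
            ids = sorted(ids)
            n_test = int(round(test_fraction * len(ids)))
            n_test = min(max(n_test, 1 if ids else 0), max(len(ids) - 1, 0))
            picked = rng.choice(len(ids), size=n_test, replace=False) if n_test else []
            test_ids.update(ids[i] for i in picked)
        train_seg = [s for s in segments if s.participant_id not in test_ids]
        test_seg = [s for s in segments if s.participant_id in test_ids]
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    for name, side in (("train", train_seg), ("test", test_seg)):
        present = {s.label for s in side}
        if present != {0, 1}:
            raise ValueError(
                f"{name} split is missing a class (labels present: {present})"
            )
    return train_seg, test_seg


def group_statistics(cohort: CohortManifest) -> pd.DataFrame:
    """Per-group skewness / excess kurtosis of pooled counts, plus a
    between-group location p-value.

    Skewness and kurtosis are sample moments of all counts pooled within
    each group (Fisher convention: a normal distribution has excess
    kurtosis 0).  The p-value is a two-sided Mann-Whitney U test comparing
    per-participant mean daytime (08:00-17:59) activity between groups - a
    rank-based test because counts are far from normal, restricted to
    waking hours because daytime motor activity is the standard actigraphy
    group contrast and nocturnal wake bursts would otherwise mask a level
    difference.
    """
    pooled: dict[Group, list[np.ndarray]] = {Group.CONDITION: [], Group.CONTROL: []}
    means: dict[Group, list[float]] = {Group.CONDITION: [], Group.CONTROL: []}
    for rec in cohort.recordings:
        pooled[rec.group].append(rec.counts)
        hours = pd.DatetimeIndex(rec.timestamps).hour
        day = (hours >= 8) & (hours < 18)
        daytime = rec.counts[day] if day.any() else rec.counts
        means[rec.group].append(float(daytime.mean()))
    for grp, chunks in pooled.items():
        if len(chunks) < 2:
            raise ValueError(
                f"need at least 2 participants per group (group {grp.value!r} "
                f"has {len(chunks)})"
            )
    mw = stats.mannwhitneyu(
        means[Group.CONDITION], means[Group.CONTROL], alternative="two-sided"
    )
    rows = []
    for grp in (Group.CONDITION, Group.CONTROL):
        counts = np.concatenate(pooled[grp]).astype(np.float64)
        rows.append(
            {
                "group": grp.value,
                "n_participants": len(pooled[grp]),
                "skewness": float(stats.skew(counts)),
                "excess_kurtosis": float(stats.kurtosis(counts, fisher=True)),
                "p_value_between_groups": float(mw.pvalue),
            }
        )
    return pd.DataFrame(rows)
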