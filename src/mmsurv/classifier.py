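"""Feature-set prognosis tree and its survival evaluation.

A fixed two-node tree, not a learned one: the first node sums each
sample's burdens over the hazard-increasing (negative) predictor
signatures and labels the sample poor-prognosis when the sum reaches
the burden threshold (default 2, the same dose at which single-term
effects appear); the second node applies the identical rule to the
top-k protective (positive) predictors, splitting a good-prognosis
group off the remainder, which forms the intermediate group.  The
poor split is evaluated first, so poor-group membership never depends
on k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mmsurv.io_formats import ClinicalTable
from mmsurv.mms import MMSMatrix
from mmsurv.screening import PredictorSet
from mmsurv.survival_stats import TestResult, logrank_test

__all__ = ["TreeConfig", "PrognosisLabels", "tree_classify", "evaluate_groups"]

LABELS = ("poor", "intermediate", "good")


@dataclass(frozen=True)
class TreeConfig:
    """Number of top positive predictors used and the split threshold."""

    k: int = 5
    burden_threshold: int = 2

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.burden_threshold < 1:
            raise ValueError("burden_threshold must be a positive integer")


@dataclass
class PrognosisLabels:
    """Per-sample prognosis assignment; a partition of the cohort."""

    sample_ids: list[str]
    labels: np.ndarray  # strings from LABELS

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.sample_ids) != self.labels.size:
            raise ValueError("labels must align with sample_ids")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def group(self, label: str) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]

    def counts(self) -> dict[str, int]:
        return {l: int(np.sum(self.labels == l)) for l in LABELS}


def tree_classify(
    mms: MMSMatrix, predictors: PredictorSet, config: TreeConfig = TreeConfig()
) -> PrognosisLabels:
    """Assign each sample to poor / good / intermediate prognosis.

    Sums use the capped burden values.  Raises if ``config.k`` exceeds
    the number of available positive predictors.
    """
    if config.k > len(predictors.positive):
        raise ValueError(
            f"k={config.k} exceeds the {len(predictors.positive)} available positive predictors"
        )
    frame = mms.to_frame()
    missing = (set(predictors.negative) | set(predictors.positive[: config.k])) - set(frame.columns)
    if missing:
        raise KeyError(f"predictor terms absent from the burden matrix: {sorted(missing)}")

    neg_sum = (
        frame[list(predictors.negative)].to_numpy().sum(axis=1)
        if predictors.negative
        else np.zeros(len(frame))
    )
    pos_sum = frame[list(predictors.positive[: config.k])].to_numpy().sum(axis=1)

    labels = np.full(len(frame), "intermediate", dtype=object)
    poor = neg_sum >= config.burden_threshold
    good = ~poor & (pos_sum >= config.burden_threshold)
    labels[poor] = "poor"
    labels[good] = "good"
    return PrognosisLabels(sample_ids=list(mms.sample_ids), labels=labels)


def evaluate_groups(
    labels: PrognosisLabels,
    clinical: ClinicalTable,
    endpoint: str = "OS",
    rho: float = 0.0,
) -> TestResult:
    """k-group weighted log-rank across the realized prognosis groups.

    Empty groups are dropped (they simply do not appear among the
    realized labels) with the degrees of freedom reduced accordingly;
    a single realized group raises.
    """
    clin = clinical.subset(labels.sample_ids)
    time, event, keep = clin.endpoint(endpoint)
    groups = labels.labels[keep]
    if np.unique(groups).size < 2:
        raise ValueError("all samples fall in one prognosis group")
    return logrank_test(time, event, groups, rho=rho)
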