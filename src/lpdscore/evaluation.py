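"""Diagnostic evaluation of the combination score against IgH clonality.

The combination score is an ordinal 0-6 axis on which low values indicate
disrupted follicles (MALToma-like) and high values intact follicles
(RFH-like). A :class:`ClassifierSpec` partitions the axis into three
half-open bands — MALToma-like, ALH-like, RFH-like from low to high — and
the evaluation counts, per disease group, how many clonality-evaluable
cases the score calls positive, yielding sensitivity percentages against
the IgH-clonality gold standard.

The published decision rule behind the reported sensitivities is not
recoverable; here "score-positive" defaults to classification into the
lowest (MALToma-like) band, i.e. the score asserts clonal-type
proliferation, and cut-points are fitted by exhaustive search maximizing
balanced accuracy over the diagnosis labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Diagnosis, IghResult
from .scoring import ScorePanel

__all__ = [
    "ClassifierSpec",
    "GroupEvaluation",
    "DiagnosticEvaluation",
    "fit_thresholds",
    "classify",
    "classify_scores",
    "sensitivity_from_counts",
    "evaluate_against_clonality",
]

# class order along the score axis, lowest band first
BAND_ORDER = (Diagnosis.MALTOMA, Diagnosis.ALH, Diagnosis.RFH)

# half-integer grid the mean-combined combination score lives on
SCORE_GRID = tuple(v / 2.0 for v in range(0, 13))


@dataclass(frozen=True)
class ClassifierSpec:
    """Ordered cut-points partitioning [0, 6] into per-class bands.

    Bands are half-open upward: a score s maps to the first band whose
    cut-point is >= s, so boundary scores belong to the lower band.
    ``positive_classes`` defines which predicted classes count as
    "score-positive" in the clonality evaluation.
    """

    thresholds: tuple[float, ...] = (1.5, 3.5)
    classes: tuple[Diagnosis, ...] = BAND_ORDER
    positive_classes: frozenset[Diagnosis] = frozenset({Diagnosis.MALTOMA})

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.thresholds) + 1:
            raise ValueError("need exactly one more class than cut-points")
        if any(t2 <= t1 for t1, t2 in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("cut-points must be strictly increasing")
        if self.thresholds and not (0.0 <= self.thresholds[0] and self.thresholds[-1] < 6.0):
            raise ValueError("cut-points must lie within [0, 6)")


def classify(panel_or_score: ScorePanel | float, spec: ClassifierSpec) -> Diagnosis:
    """Predicted class of one combination score under a classifier spec."""
    s = (
        panel_or_score.combination_score
        if isinstance(panel_or_score, ScorePanel)
        else float(panel_or_score)
    )
    for cut, cls in zip(spec.thresholds, spec.classes):
        if s <= cut:
            return cls
    return spec.classes[-1]


def classify_scores(scores: np.ndarray, spec: ClassifierSpec) -> np.ndarray:
    """Vectorized :func:`classify`; returns an object array of Diagnosis."""
    scores = np.asarray(scores, dtype=float)
    idx = np.searchsorted(np.asarray(spec.thresholds), scores, side="left")
    return np.array([spec.classes[i] for i in idx], dtype=object)


def _balanced_accuracy(pred: np.ndarray, truth: np.ndarray, classes) -> float:
    # compare on .value strings: numpy coerces str-subclass enums via str(),
    # which mangles them to "Diagnosis.X" and breaks elementwise ==
    pred_v = np.array([p.value for p in pred])
    truth_v = np.array([t.value for t in truth])
    recalls = []
    for cls in classes:
        mask = truth_v == cls.value
        if mask.any():
            recalls.append(float((pred_v[mask] == cls.value).mean()))
    return float(np.mean(recalls))


def fit_thresholds(
    scored: pd.DataFrame,
    grid: Sequence[float] = SCORE_GRID,
) -> ClassifierSpec:
    """Exhaustive search for the cut-point pair maximizing balanced accuracy.

    Considers every strictly increasing pair on the discrete score grid.
    Ties are broken toward the widest MALToma-like (lowest) band, i.e. the
    largest first cut-point, then the largest second; the search is
    deterministic.
    """
    need = {"diagnosis", "combination_score"}
    if not need <= set(scored.columns):
        raise ValueError(f"scored cohort must provide columns {sorted(need)}")
    sub = scored.dropna(subset=["combination_score"])
    truth = sub["diagnosis"].map(lambda d: Diagnosis(str(d))).to_numpy(dtype=object)
    scores = sub["combination_score"].to_numpy(dtype=float)
    present = set(truth)
    if len(present) < 2:
        raise ValueError("threshold fitting requires at least two diagnosis classes")
    if np.ptp(scores) == 0:
        raise ValueError(
            "all combination scores identical: no informative cut-points exist"
        )

    best: tuple[float, float, float] | None = None
    best_spec: ClassifierSpec | None = None
    cuts = [c for c in grid if c < 6.0]
    for t1, t2 in itertools.combinations(cuts, 2):
        spec = ClassifierSpec(thresholds=(t1, t2))
        pred = classify_scores(scores, spec)
        acc = _balanced_accuracy(pred, truth, BAND_ORDER)
        key = (acc, t1, t2)
        if best is None or key > best:
            best, best_spec = key, spec
    assert best_spec is not None
    return best_spec


def sensitivity_from_counts(n_positive: int, n_tested: int) -> float:
    """Sensitivity percent: 100 * positives / evaluable (one-decimal display)."""
    if n_tested <= 0:
        raise ValueError("n_tested must be > 0")
    if not (0 <= n_positive <= n_tested):
        raise ValueError(f"n_positive must lie in [0, {n_tested}], got {n_positive}")
    return 100.0 * n_positive / n_tested


@dataclass(frozen=True)
class GroupEvaluation:
    group: Diagnosis
    n_tested: int
    n_positive: int
    n_clonal: int

    @property
    def sensitivity_percent(self) -> float:
        return round(sensitivity_from_counts(self.n_positive, self.n_tested), 1)


@dataclass(frozen=True)
class DiagnosticEvaluation:
    """Per-group score-positivity counts against the IgH-clonality standard.

    Denominators are all clonality-evaluable cases (clonal or polyclonal
    PCR result); QC-failed and untested samples never enter any count.
    """

    spec: ClassifierSpec
    per_group: Mapping[Diagnosis, GroupEvaluation]
    gold_standard: str = "igh_clonality"

    def sensitivity(self, group: Diagnosis | str) -> float:
        return self.per_group[Diagnosis(group)].sensitivity_percent


def evaluate_against_clonality(
    scored: pd.DataFrame, spec: ClassifierSpec
) -> DiagnosticEvaluation:
    """Evaluate score positivity per diagnosis group among clonality-tested cases.

    ``scored`` is a cohort frame with ``combination_score`` appended (see
    :func:`lpdscore.scoring.score_cohort`). A case is evaluable when its
    ``igh_result`` is ``clonal`` or ``polyclonal``; it is score-positive
    when its predicted band is in ``spec.positive_classes``.
    """
    need = {"diagnosis", "combination_score", "igh_result"}
    if not need <= set(scored.columns):
        raise ValueError(f"scored cohort must provide columns {sorted(need)}")
    evaluable = scored[
        scored["igh_result"].isin([IghResult.CLONAL.value, IghResult.POLYCLONAL.value])
        & scored["combination_score"].notna()
    ]
    if evaluable.empty:
        raise ValueError("no clonality-evaluable records with a combination score")

    per_group: dict[Diagnosis, GroupEvaluation] = {}
    for g in Diagnosis:
        sub = evaluable[evaluable["diagnosis"] == g.value]
        if sub.empty:
            continue
        pred = classify_scores(sub["combination_score"].to_numpy(dtype=float), spec)
        positive = np.array([p in spec.positive_classes for p in pred])
        per_group[g] = GroupEvaluation(
            group=g,
            n_tested=int(len(sub)),
            n_positive=int(positive.sum()),
            n_clonal=int((sub["igh_result"] == IghResult.CLONAL.value).sum()),
        )
    return DiagnosticEvaluation(spec=spec, per_group=per_group)
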