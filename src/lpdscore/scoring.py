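"""Ordinal CD23/IgD expression scoring, lymphoid-follicle structure scoring,
and the combination score.

The expression score bins a marker's mean percent-positive rate onto a 0-3
ordinal scale (0; 1-10; 11-20; >= 21 percent). The lymphoid-follicle (LF)
score grades follicle integrity 0-3 from "no staining or few scattered
positive cells" up to "most follicles intact". The combination score is the
sum of the combined expression score and the LF score; low values indicate
disrupted follicles and malignant-type (MALToma-like) proliferation, high
values indicate the intact follicles of reactive hyperplasia.

Because the published bins are printed as integer ranges while HPF averaging
yields real-valued rates, the bins are read as half-open continuous
intervals: 0 / (0, 10] / (10, 20] / (20, 100]. A rate of 0.5% therefore
scores 1, matching the printed behavior at every integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .cohort import CohortValidationError, CohortTable, Marker, N_HPF

__all__ = [
    "ScorePanel",
    "SCORER_CONCORDANCE_LIMIT",
    "LF_CATEGORY_DESCRIPTIONS",
    "mean_positive_rate",
    "scorer_concordance",
    "expression_score",
    "expression_scores",
    "lf_score",
    "combination_score",
    "score_cohort",
    "SCORE_COLUMNS",
]

# variation between the two blinded scorers is expected to stay below 5
# percentage points; pairs at or above the limit are flagged, not rejected
SCORER_CONCORDANCE_LIMIT = 5.0

# upper bin edges of the expression score; scores are 0..3
_EXPRESSION_BIN_EDGES = np.array([0.0, 10.0, 20.0])

LF_CATEGORY_DESCRIPTIONS: dict[int, str] = {
    0: "No staining or few scattered positively stained cells",
    1: "Some scattered disrupted fragments with no intact lymphoid follicles",
    2: "Some intact lymphoid follicles and scattered FDC/MZ fragments",
    3: "Most lymphoid follicles are intact, accompanied by some disrupted fragments",
}
_LF_DESCRIPTION_TO_SCORE = {v: k for k, v in LF_CATEGORY_DESCRIPTIONS.items()}

ExpressionCombiner = Literal["mean", "min", "max", "sum"]

SCORE_COLUMNS = (
    "cd23_score",
    "igd_score",
    "expression_score",
    "lf_score",
    "combination_score",
    "scorer_concordant",
)


@dataclass(frozen=True)
class ScorePanel:
    """Per-patient score set: two marker scores, their combination, the LF
    structure score and the final combination score."""

    cd23_expression_score: int
    igd_expression_score: int
    expression_score: float
    lf_score: int
    combination_score: float

    def __post_init__(self) -> None:
        for name in ("cd23_expression_score", "igd_expression_score", "lf_score"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3):
                raise CohortValidationError(f"{name} must be in {{0,1,2,3}}, got {v!r}")
        if not (0.0 <= self.combination_score <= 6.0):
            raise CohortValidationError(
                f"combination_score must lie in [0, 6], got {self.combination_score}"
            )


def mean_positive_rate(hpf_values: Sequence[float]) -> float:
    """Mean percent-positive rate over exactly five high-power fields."""
    vals = np.asarray(hpf_values, dtype=float)
    if vals.shape != (N_HPF,):
        raise CohortValidationError(
            f"exactly {N_HPF} HPF values are required, got {vals.size}"
        )
    if np.any(~np.isfinite(vals)) or vals.min() < 0 or vals.max() > 100:
        raise CohortValidationError("HPF values must lie in [0, 100]")
    return float(vals.mean())


def scorer_concordance(rate_a: float, rate_b: float) -> bool:
    """True when the two scorers' rates differ by < 5 percentage points."""
    for r in (rate_a, rate_b):
        if not (0.0 <= r <= 100.0):
            raise CohortValidationError(f"rate {r!r} outside [0, 100]")
    return abs(rate_a - rate_b) < SCORER_CONCORDANCE_LIMIT


def expression_scores(rates: np.ndarray) -> np.ndarray:
    """Vectorized expression score: 0 -> 0, (0,10] -> 1, (10,20] -> 2, >20 -> 3."""
    rates = np.asarray(rates, dtype=float)
    if np.any((rates < 0) | (rates > 100) | ~np.isfinite(rates)):
        raise CohortValidationError("expression rates must lie in [0, 100]")
    return np.digitize(rates, _EXPRESSION_BIN_EDGES, right=True).astype(int)


def expression_score(rate: float) -> int:
    """Ordinal 0-3 expression score of a percent-positive rate."""
    return int(expression_scores(np.array([rate]))[0])


def lf_score(category: int | str) -> int:
    """LF structure score: identity on the 0-3 category, or lookup by the
    category's verbatim description."""
    if isinstance(category, str):
        try:
            return _LF_DESCRIPTION_TO_SCORE[category]
        except KeyError:
            raise CohortValidationError(
                f"unknown LF structure category {category!r}"
            ) from None
    if category not in (0, 1, 2, 3):
        raise CohortValidationError(
            f"LF structure category must be 0-3, got {category!r}"
        )
    return int(category)


def _combine_marker_scores(cd23: float, igd: float, combiner: ExpressionCombiner) -> float:
    if combiner == "mean":
        return (cd23 + igd) / 2.0
    if combiner == "min":
        return float(min(cd23, igd))
    if combiner == "max":
        return float(max(cd23, igd))
    if combiner == "sum":
        return float(cd23 + igd)
    raise CohortValidationError(f"unknown expression combiner {combiner!r}")


def combination_score(
    cd23_rate: float,
    igd_rate: float,
    category: int | str,
    combiner: ExpressionCombiner = "mean",
) -> ScorePanel:
    """Score one sample: marker scores, combined expression score, LF score
    and their sum (the combination score).

    With the default ``mean`` combiner the combined expression score stays on
    the 0-3 scale of the per-marker rubric (half-integer steps) and the
    combination score spans [0, 6].
    """
    cd23 = expression_score(cd23_rate)
    igd = expression_score(igd_rate)
    expr = _combine_marker_scores(cd23, igd, combiner)
    lf = lf_score(category)
    return ScorePanel(
        cd23_expression_score=cd23,
        igd_expression_score=igd,
        expression_score=expr,
        lf_score=lf,
        combination_score=expr + lf,
    )


def score_cohort(table: CohortTable, combiner: ExpressionCombiner = "mean"):
    """Score every record of a cohort, returning the cohort frame with the
    score columns appended.

    Per marker, each scorer's rate is the mean of their five HPF values and
    the panel rate is the mean of the two scorers (or the single available
    scorer). ``scorer_concordant`` is True only if every marker with two
    readings shows < 5 pp between scorers. Records missing a marker or the
    LF category get absent score cells.
    """
    import pandas as pd

    frame = table.frame.copy()
    n = len(frame)

    def block_rates(prefix: str, suffix: str) -> np.ndarray:
        cols = [f"{prefix}_hpf{i}{suffix}" for i in range(1, 6)]
        vals = frame[cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        return vals.mean(axis=1)  # NaN if any field absent

    rate = {}
    concordant = np.ones(n, dtype=bool)
    has_pair = np.zeros(n, dtype=bool)
    for marker in ("cd23", "igd"):
        ra = block_rates(marker, "")
        rb = block_rates(marker, "_b")
        both = ~np.isnan(ra) & ~np.isnan(rb)
        r = np.where(both, (ra + rb) / 2.0, np.where(np.isnan(ra), rb, ra))
        rate[marker] = r
        concordant &= ~both | (np.abs(ra - rb) < SCORER_CONCORDANCE_LIMIT) | np.isnan(ra)
        has_pair |= both

    lf_cat = pd.to_numeric(frame["lf_category"], errors="coerce").to_numpy(dtype=float)

    ok = ~np.isnan(rate["cd23"]) & ~np.isnan(rate["igd"]) & ~np.isnan(lf_cat)
    cd23_s = np.full(n, np.nan)
    igd_s = np.full(n, np.nan)
    cd23_s[~np.isnan(rate["cd23"])] = expression_scores(rate["cd23"][~np.isnan(rate["cd23"])])
    igd_s[~np.isnan(rate["igd"])] = expression_scores(rate["igd"][~np.isnan(rate["igd"])])

    if combiner == "mean":
        expr = (cd23_s + igd_s) / 2.0
    elif combiner == "min":
        expr = np.fmin(cd23_s, igd_s)  # propagate NaN via explicit mask below
        expr = np.where(np.isnan(cd23_s) | np.isnan(igd_s), np.nan, expr)
    elif combiner == "max":
        expr = np.where(np.isnan(cd23_s) | np.isnan(igd_s), np.nan, np.fmax(cd23_s, igd_s))
    elif combiner == "sum":
        expr = cd23_s + igd_s
    else:
        raise CohortValidationError(f"unknown expression combiner {combiner!r}")

    comb = np.where(ok, expr + lf_cat, np.nan)

    frame["cd23_score"] = cd23_s
    frame["igd_score"] = igd_s
    frame["expression_score"] = expr
    frame["lf_score"] = lf_cat
    frame["combination_score"] = comb
    frame["scorer_concordant"] = np.where(has_pair, concordant, True)
    frame["cd23_rate"] = rate["cd23"]
    frame["igd_rate"] = rate["igd"]
    return frame
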