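"""Low-level identity prediction from image similarity.

For each of the 27 viewpoint ranges and each imprinted object the model
compares:

* within-object difference — test animation of the imprinted object at
  that range vs the imprinting (input) animation of the imprinted object;
* between-object difference — the unfamiliar object's animation vs the
  same input animation.  The unfamiliar object is always shown from its
  frontal (input-phase) range, which maximizes its similarity to the
  imprinting stimulus.

The model is "correct" for a condition iff the within-object difference is
strictly smaller than the between-object difference (ties score
incorrect).  Model and subject condition-level correctness are compared
with a Pearson chi-square on the 2x2 correct/incorrect table, without
continuity correction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .gabor_model import (
    GaborBank,
    build_gabor_bank,
    default_jet_grid,
    gabor_dissimilarity,
    jet_activations,
)
from .pixel_model import animation_difference_pixel
from .stimuli import (
    AnimationSpec,
    GrayImage,
    ObjectSpec,
    build_test_animations,
    input_animation,
    render_animation,
)

__all__ = [
    "ConditionOutcome",
    "ContingencyTable2x2",
    "evaluate_condition",
    "evaluate_all_conditions",
    "model_performance",
    "chick_condition_counts",
    "compare_chick_vs_model",
]


@dataclass(frozen=True)
class ConditionOutcome:
    object_id: str  # the imprinted object
    range_id: int
    within_difference: float
    between_difference: float

    @property
    def correct(self) -> bool:
        return self.within_difference < self.between_difference


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Correct/incorrect counts for two classifiers over the same conditions."""

    chick_correct: int
    chick_incorrect: int
    model_correct: int
    model_incorrect: int

    def __post_init__(self):
        if min(
            self.chick_correct,
            self.chick_incorrect,
            self.model_correct,
            self.model_incorrect,
        ) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return (
            self.chick_correct
            + self.chick_incorrect
            + self.model_correct
            + self.model_incorrect
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.chick_correct, self.chick_incorrect],
                [self.model_correct, self.model_incorrect],
            ]
        )


class _MetricEngine:
    """Renders animations and scores them under one metric, with caching.

    Jets are cached by image content, so objects whose renders coincide
    across viewpoints (e.g. a sphere) cost a single jet evaluation.
    """

    def __init__(
        self,
        metric: str = "pixel",
        size: int = 128,
        bank: GaborBank | None = None,
        grid_n: int = 10,
    ):
        if metric not in ("pixel", "gabor"):
            raise ValueError("metric must be 'pixel' or 'gabor'")
        self.metric = metric
        self.size = size
        if metric == "gabor":
            self.bank = bank if bank is not None else build_gabor_bank()
            self.grid = default_jet_grid(size, size, grid_n)
        self._renders: dict[tuple, list[GrayImage]] = {}
        self._jets: dict[bytes, np.ndarray] = {}

    def frames(self, obj: ObjectSpec, anim: AnimationSpec) -> list[GrayImage]:
        key = (obj.object_id, anim.range_id)
        if key not in self._renders:
            self._renders[key] = render_animation(obj, anim, size=self.size)
        return self._renders[key]

    def _jet(self, img: GrayImage) -> np.ndarray:
        key = hashlib.sha1(np.ascontiguousarray(img.values)).digest()
        if key not in self._jets:
            self._jets[key] = jet_activations(img, self.bank, self.grid)
        return self._jets[key]

    def animation_difference(self, test, input_) -> float:
        if self.metric == "pixel":
            return animation_difference_pixel(test, input_)
        jt = [self._jet(im) for im in test]
        ji = [self._jet(im) for im in input_]
        return float(np.mean([gabor_dissimilarity(t, i) for t in jt for i in ji]))


def evaluate_condition(
    imprinted: ObjectSpec,
    unfamiliar: ObjectSpec,
    range_id: int,
    metric: str = "pixel",
    size: int = 128,
    bank: GaborBank | None = None,
    grid_n: int = 10,
    _engine: _MetricEngine | None = None,
) -> ConditionOutcome:
    """Score one (imprinted object, viewpoint range) condition."""
    eng = _engine or _MetricEngine(metric, size, bank, grid_n)
    anims = {a.range_id: a for a in build_test_animations(imprinted.object_id)}
    if range_id not in anims:
        raise ValueError(f"range_id {range_id} not in 1..27")
    input_frames = eng.frames(imprinted, input_animation(imprinted.object_id))
    test_frames = eng.frames(imprinted, anims[range_id])
    unfam_frames = eng.frames(unfamiliar, input_animation(unfamiliar.object_id))
    within = eng.animation_difference(test_frames, input_frames)
    between = eng.animation_difference(unfam_frames, input_frames)
    return ConditionOutcome(imprinted.object_id, range_id, within, between)


def evaluate_all_conditions(
    obj_a: ObjectSpec,
    obj_b: ObjectSpec,
    metric: str = "pixel",
    size: int = 128,
    bank: GaborBank | None = None,
    grid_n: int = 10,
) -> list[ConditionOutcome]:
    """All 54 conditions: 27 ranges x both objects as the imprinted one."""
    eng = _MetricEngine(metric, size, bank, grid_n)
    outcomes = []
    for imprinted, unfamiliar in ((obj_a, obj_b), (obj_b, obj_a)):
        for anim in build_test_animations(imprinted.object_id):
            outcomes.append(
                evaluate_condition(
                    imprinted,
                    unfamiliar,
                    anim.range_id,
                    metric=metric,
                    size=size,
                    _engine=eng,
                )
            )
    return outcomes


def model_performance(outcomes) -> dict:
    """Fraction of conditions scored correct, pooled and per imprinted object."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes")
    per_object = {}
    for oid in sorted({o.object_id for o in outcomes}):
        sub = [o for o in outcomes if o.object_id == oid]
        per_object[oid] = sum(o.correct for o in sub) / len(sub)
    pooled = sum(o.correct for o in outcomes) / len(outcomes)
    return {
        "pooled": pooled,
        "per_object": per_object,
        "n_correct": int(sum(o.correct for o in outcomes)),
        "n_conditions": len(outcomes),
    }


def chick_condition_counts(
    trials: pd.DataFrame, subject_objects: dict
) -> tuple[int, int]:
    """Condition-level subject correctness: (n_correct, n_incorrect).

    A condition (imprinted object x viewpoint range) is correct when the
    subjects imprinted to that object spent more time, on average, with the
    imprinted object than the unfamiliar one at that range.  Exact-tie
    conditions count as incorrect.
    """
    t = trials[trials["trial_kind"] == "test"].copy()
    t["imprinted_object"] = t["subject_id"].map(subject_objects)
    if t["imprinted_object"].isna().any():
        missing = sorted(t.loc[t["imprinted_object"].isna(), "subject_id"].unique())
        raise ValueError(f"no imprinted-object assignment for subjects {missing}")
    g = t.groupby(["imprinted_object", "viewpoint_range_id"])[
        ["time_imprinted_s", "time_unfamiliar_s"]
    ].mean()
    correct = (g["time_imprinted_s"] > g["time_unfamiliar_s"]).sum()
    return int(correct), int(len(g) - correct)


def compare_chick_vs_model(
    chick: tuple[int, int], model: tuple[int, int], correction: bool = False
) -> stats.Chi2Result:
    """Pearson chi-square (df = 1) comparing two classifiers' outcome counts."""
    table = ContingencyTable2x2(chick[0], chick[1], model[0], model[1])
    return stats.chi_square_2x2(table.as_array(), correction=correction)
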