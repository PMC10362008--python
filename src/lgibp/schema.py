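"""Measure schema for the neurocognitive battery.

The default schema transcribes the 27 scores of the study battery: twelve
D-KEFS scores, three Attention Network Test (ANT) efficiency scores, nine
Penn Computerized Neurocognitive Battery (CNB) scores, Digit Span forwards
and backwards, and RAVLT delayed recall.  The three ANT efficiency scores
are time-based (lower raw values are better) and are the only measures that
are reverse scored before standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator


class Battery(str, Enum):
    DKEFS = "DKEFS"
    ANT = "ANT"
    CNB = "CNB"
    DIGIT_SPAN = "DigitSpan"
    RAVLT = "RAVLT"


@dataclass(frozen=True)
class MeasureDescriptor:
    """One score of the battery.

    Parameters
    ----------
    measure_id : str
        Short unique identifier, used as the column name in data files.
    battery : Battery
        Instrument family the score comes from.
    subfunction : str
        Neurocognitive subfunction the score taps (free text).
    score_label : str
        Human-readable name of the score used.
    higher_is_better_raw : bool
        Whether larger raw values indicate better performance.
    reverse_score : bool
        Whether the raw score is negated before standardization.  True
        exactly for the three ANT efficiency scores.
    """

    measure_id: str
    battery: Battery
    subfunction: str
    score_label: str
    higher_is_better_raw: bool = True
    reverse_score: bool = False


@dataclass(frozen=True)
class MeasureSchema:
    """Ordered collection of measures defining battery column layout."""

    measures: tuple[MeasureDescriptor, ...]

    def __post_init__(self) -> None:
        ids = [m.measure_id for m in self.measures]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate measure_ids in schema: {dupes}")

    def __len__(self) -> int:
        return len(self.measures)

    def __iter__(self) -> Iterator[MeasureDescriptor]:
        return iter(self.measures)

    @property
    def measure_ids(self) -> list[str]:
        return [m.measure_id for m in self.measures]

    @property
    def reverse_scored_ids(self) -> list[str]:
        return [m.measure_id for m in self.measures if m.reverse_score]

    def index_of(self, measure_id: str) -> int:
        for i, m in enumerate(self.measures):
            if m.measure_id == measure_id:
                return i
        raise KeyError(measure_id)


def _m(measure_id, battery, subfunction, score_label,
       higher_is_better_raw=True, reverse_score=False):
    return MeasureDescriptor(measure_id, battery, subfunction, score_label,
                             higher_is_better_raw, reverse_score)


#: Measure id of the CNB finger-tapping score, subject to the tap-count filter.
FINGER_TAPPING_ID = "cnb_finger_tapping"

_DEFAULT_MEASURES = (
    _m("dkefs_twenty_questions", Battery.DKEFS,
       "abstract categorization, visual attention, and perception",
       "Twenty Questions: Total Questions Asked"),
    _m("dkefs_design_fluency", Battery.DKEFS,
       "cognitive flexibility and inhibition (visual/motor)",
       "Design Fluency: Total Correct"),
    _m("dkefs_proverb", Battery.DKEFS, "verbal abstraction",
       "Proverb: Total Achievement"),
    _m("dkefs_tower_achievement", Battery.DKEFS,
       "spatial planning and rule learning", "Tower: Total Achievement"),
    _m("dkefs_tower_rule_violations", Battery.DKEFS,
       "spatial planning and error detection",
       "Tower: Rule Violations Per Item Ratio", higher_is_better_raw=False),
    _m("dkefs_trails_number_seq", Battery.DKEFS, "attention",
       "Trail-Making: Number Sequencing"),
    _m("dkefs_trails_number_letter", Battery.DKEFS,
       "cognitive flexibility (visual)",
       "Trail-Making: Number-Letter Switching"),
    _m("dkefs_verbal_fluency_switch", Battery.DKEFS,
       "cognitive flexibility (verbal)", "Verbal Fluency: Category Switching"),
    _m("dkefs_cwi_inhibition", Battery.DKEFS,
       "inhibition adjusted for naming", "CWI: Inhibition-Color Naming"),
    _m("dkefs_cwi_switching", Battery.DKEFS,
       "cognitive flexibility adjusted for naming",
       "CWI: Inhibition/Switching-Color Naming"),
    _m("dkefs_cwi_inhibition_errors", Battery.DKEFS,
       "error detection (inhibition)",
       "CWI: Inhibition Uncorrected Errors", higher_is_better_raw=False),
    _m("dkefs_cwi_switching_errors", Battery.DKEFS,
       "error detection (cognitive control)",
       "CWI: Inhibition/Switching Uncorrected Errors",
       higher_is_better_raw=False),
    _m("ant_alerting_eff", Battery.ANT, "alerting attention",
       "ANT Alerting Efficiency", higher_is_better_raw=False,
       reverse_score=True),
    _m("ant_orienting_eff", Battery.ANT, "orienting attention",
       "ANT Orienting Efficiency", higher_is_better_raw=False,
       reverse_score=True),
    _m("ant_executive_eff", Battery.ANT, "executive attention",
       "ANT Executive Attention Efficiency", higher_is_better_raw=False,
       reverse_score=True),
    _m("cnb_mouse_practice", Battery.CNB, "sensorimotor processing speed",
       "Mouse Practice: Efficiency"),
    _m("cnb_cpt", Battery.CNB, "sustained attention",
       "Continuous Performance Test: Efficiency"),
    _m("cnb_conditional_exclusion", Battery.CNB,
       "abstraction and cognitive flexibility",
       "Conditional Exclusion Test: Efficiency"),
    _m("cnb_emotion_differentiation", Battery.CNB, "social cognition",
       "Emotion Differentiation: Efficiency"),
    _m("cnb_emotion_identification", Battery.CNB, "social cognition",
       "Emotion Identification: Efficiency"),
    _m("cnb_word_memory", Battery.CNB, "episodic memory (verbal)",
       "Word Memory: Efficiency"),
    _m("cnb_visual_object_learning", Battery.CNB, "episodic memory (spatial)",
       "Visual Object Learning: Efficiency"),
    _m("cnb_verbal_reasoning", Battery.CNB, "language reasoning",
       "Verbal Reasoning: Efficiency"),
    _m(FINGER_TAPPING_ID, Battery.CNB, "sensorimotor processing speed",
       "Finger Tapping: Sum of mean dominant/non-dominant taps"),
    _m("digit_span_forward", Battery.DIGIT_SPAN,
       "attention and working memory", "Longest Length Forward"),
    _m("digit_span_backward", Battery.DIGIT_SPAN, "working memory",
       "Longest Length Backwards"),
    _m("ravlt_delayed_recall", Battery.RAVLT, "learning and memory",
       "Delayed Recall: Total Correct"),
)


def default_schema() -> MeasureSchema:
    """The bundled 27-measure battery schema."""
    return MeasureSchema(_DEFAULT_MEASURES)
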