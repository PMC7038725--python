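"""Self-report scoring and session labeling.

Perceived stress is measured with the five-item ambulatory Perceived
Stress Scale (PSS-5): happiness (H), cheerfulness (C), anger (A),
sadness (S) and frustration (F), each answered on a 1-6 scale.  The
positive-affect items are reverse-keyed, giving the score

    PercStress = (7 - H) + (7 - C) + A + S + F

which is binarized at 15 into relaxed (< 15) / stressed (>= 15).  Lab
sessions additionally carry a known-context label from the protocol
phase: baseline counts as relaxed, the stressor phase as stressed, and
the recovery phase is excluded from the two-class known-context task.

Note the quoted score range is "zero to 30", but with items restricted
to 1-6 the attainable range is exactly [5, 30]; the formula is applied
as printed and the wider nominal range is accepted by the binarizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

RELAXED = "relaxed"
STRESSED = "stressed"
EXCLUDED = "excluded"

PHASES = ("baseline", "stress", "recovery")

#: reserved token written to tabular files for an absent label
MISSING_TOKEN = "NA"

_ITEM_NAMES = ("H", "C", "A", "S", "F")


@dataclass(frozen=True)
class PSSResponse:
    """One PSS-5 questionnaire response (items each integer in 1..6)."""

    H: int
    C: int
    A: int
    S: int
    F: int

    def __post_init__(self) -> None:
        for name in _ITEM_NAMES:
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and not isinstance(v, bool)):
                raise ValueError(f"PSS-5 item {name} must be an integer, got {v!r}")
            if not 1 <= v <= 6:
                raise ValueError(f"PSS-5 item {name}={v} outside the admissible range [1, 6]")

    def items(self) -> tuple[int, int, int, int, int]:
        return (self.H, self.C, self.A, self.S, self.F)


def score_pss5(r: PSSResponse) -> int:
    """Perceived stress score: reverse-keyed positive affect plus negative affect."""
    return (7 - r.H) + (7 - r.C) + r.A + r.S + r.F


def binarize_stress(score: int, boundary: int = 15) -> str:
    """Map a PSS-5 score to relaxed (< boundary) or stressed (>= boundary).

    The boundary value itself counts as stressed.
    """
    if not 0 <= score <= 30:
        raise ValueError(f"PSS-5 score {score} outside [0, 30]")
    return STRESSED if score >= boundary else RELAXED


def context_label(phase: str) -> str:
    """Known-context label for a lab protocol phase.

    baseline -> relaxed, stress -> stressed; recovery is excluded from the
    two-class known-context task (the classification contrasts stress with
    baseline, not with post-stress recovery).
    """
    if phase not in PHASES:
        raise ValueError(f"unknown lab phase {phase!r}; expected one of {PHASES}")
    if phase == "baseline":
        return RELAXED
    if phase == "stress":
        return STRESSED
    return EXCLUDED


@dataclass
class SessionLabels:
    """Label set attached to one analysis unit (lab phase or daily session).

    Lab units may carry both a known-context phase and a PSS-5 response;
    daily-life units never carry context, only the self-report.
    """

    context: Optional[str] = None          # lab phase name, or None
    pss: Optional[PSSResponse] = None

    @property
    def pss_score(self) -> Optional[int]:
        return None if self.pss is None else score_pss5(self.pss)

    @property
    def stress_binary_selfreport(self) -> Optional[str]:
        return None if self.pss is None else binarize_stress(score_pss5(self.pss))

    @property
    def stress_binary_context(self) -> Optional[str]:
        if self.context is None:
            return None
        lab = context_label(self.context)
        return None if lab == EXCLUDED else lab
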