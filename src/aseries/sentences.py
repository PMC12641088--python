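"""The eleven-sentence A-series task and its published reference scoring.

Each stimulus sentence combines an adverb of time (two past, three
present, two future adverbs) with a verb in past or present tense.
Participants place the described event on a nine-point scale where 1 is
the far past, 5 the present and 9 the far future.  Sentence No. 5
("now" + past tense) acts as the pivotal item: non-demented raters
unanimously score it 5, anchoring the origin of the subjective timeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Adverb = Literal[
    "last_week", "yesterday", "today", "now", "this_week", "tomorrow", "next_week"
]
Tense = Literal["past", "present"]

#: adverbs whose nominal reference is the past / present / future
PAST_ADVERBS = frozenset({"last_week", "yesterday"})
PRESENT_ADVERBS = frozenset({"today", "now", "this_week"})
FUTURE_ADVERBS = frozenset({"tomorrow", "next_week"})


@dataclass(frozen=True)
class Sentence:
    """One stimulus item of the A-series task."""

    id: int
    adverb: Adverb
    tense: Tense
    text: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.id <= 11:
            raise ValueError(f"sentence id must be in 1..11, got {self.id}")
        if self.adverb in FUTURE_ADVERBS and self.tense != "present":
            raise ValueError(
                f"sentence {self.id}: future adverbs take the present tense"
            )
        if self.adverb in PAST_ADVERBS and self.tense != "past":
            raise ValueError(f"sentence {self.id}: past adverbs take the past tense")


#: The task's item set.  Future adverbs pair with present-tense verbs
#: (Japanese expresses future events in the present tense): No. 1, 4, 8.
#: Past adverbs pair with past tense: No. 3, 6, 7, 10.  Present adverbs
#: pair with either present (No. 2, 9) or past tense (No. 5, 11).
SENTENCES: tuple[Sentence, ...] = (
    Sentence(1, "next_week", "present"),
    Sentence(2, "this_week", "present"),
    Sentence(3, "yesterday", "past"),
    Sentence(4, "tomorrow", "present"),
    Sentence(5, "now", "past"),
    Sentence(6, "yesterday", "past"),
    Sentence(7, "last_week", "past"),
    Sentence(8, "next_week", "present"),
    Sentence(9, "this_week", "present"),
    Sentence(10, "last_week", "past"),
    Sentence(11, "today", "past"),
)

#: Published mean response score of the non-demented raters per sentence
#: (the "standard response"); ascending order recovers the nominal
#: past-to-future ordering of the adverbs.
ND_REFERENCE_MEANS: dict[int, float] = {
    7: 2.5, 10: 3.2, 3: 3.8, 6: 3.8, 11: 4.5, 5: 5.0,
    2: 6.0, 9: 6.0, 4: 6.2, 8: 7.0, 1: 7.2,
}

#: Published standard deviations accompanying :data:`ND_REFERENCE_MEANS`.
ND_REFERENCE_SDS: dict[int, float] = {
    7: 0.55, 10: 0.75, 3: 0.41, 6: 0.41, 11: 0.55, 5: 0.0,
    2: 0.0, 9: 0.0, 4: 0.41, 8: 0.63, 1: 0.75,
}


def nominal_category(sentence: Sentence) -> str:
    """Coarse past/present/future category implied by the adverb alone."""
    if sentence.adverb in PAST_ADVERBS:
        return "past"
    if sentence.adverb in FUTURE_ADVERBS:
        return "future"
    return "present"
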