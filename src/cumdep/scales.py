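"""Depression-symptom scales used by the four aging cohorts.

Three self-report instruments are supported: the 8-item CES-D (ELSA, HRS;
0-8), the 10-item CES-D (CHARLS; 0-30) and EURO-D (SHARE; 0-12). Each scale
carries the screening threshold conventionally used to flag elevated
symptoms: a score meeting or exceeding the threshold counts as "high".
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DepressionScale:
    """A bounded integer symptom scale with a screening threshold.

    Attributes
    ----------
    name : str
        Scale identifier ("CESD8", "CESD10" or "EUROD").
    min_score, max_score : int
        Inclusive score range (min is always 0).
    high_threshold : int
        Scores >= this value screen positive for elevated symptoms.
    """

    name: str
    min_score: int
    max_score: int
    high_threshold: int

    def __post_init__(self) -> None:
        if self.min_score != 0:
            raise ValueError("scale minimum must be 0")
        if self.max_score <= self.min_score:
            raise ValueError("max_score must exceed min_score")
        if not (self.min_score <= self.high_threshold <= self.max_score):
            raise ValueError("high_threshold must lie within the scale range")


CESD8 = DepressionScale("CESD8", 0, 8, 3)
CESD10 = DepressionScale("CESD10", 0, 30, 10)
EUROD = DepressionScale("EUROD", 0, 12, 4)

SCALES = {s.name: s for s in (CESD8, CESD10, EUROD)}


def get_scale(name: str) -> DepressionScale:
    try:
        return SCALES[name.upper()]
    except KeyError:
        raise KeyError(f"unknown scale {name!r}; expected one of {sorted(SCALES)}")
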