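"""Ordinal scoring of avian mating systems.

Species are scored 0 (strict monogamy) to 4 (extreme polygamy) from up to
four independent lines of evidence: the fraction of individuals that are
socially polygamous, the fraction of extra-pair offspring (EPP), display
behaviour (lekking or permanent solitary display posts), and qualitative
textual descriptions of the mating system.  Each line of evidence yields an
ordinal component; the species score is the maximum over the defined
components, so sparse evidence can never deflate a score.

All interval thresholds live in one place (:data:`POLYGAMY_THRESHOLDS`,
:data:`EPP_THRESHOLDS`) so the boundary-closure convention is auditable:
bands are lower-closed, the middle band is upper-closed (0.20 maps to 2 on
the polygamy scale, 0.50 maps to 2 on the EPP scale) and the top band is
strictly greater.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DisplayClass",
    "TextualClass",
    "PolygamyRecord",
    "MatingEvidence",
    "SexualSelectionScore",
    "score_component_polygamy",
    "score_component_epp",
    "score_component_display",
    "score_component_textual",
    "score_component_polygamy_record",
    "combine_score",
    "to_bidirectional",
    "filter_by_certainty",
    "score_table",
    "read_evidence",
]


class DisplayClass(str, Enum):
    NONE = "none"
    LEK = "lek"
    SOLITARY_DISPLAY = "solitary_display"


class TextualClass(str, Enum):
    STRICT_MONOGAMY = "strict_monogamy"
    FREQUENT_MONOGAMY = "frequent_monogamy"
    REGULAR_POLYGAMY = "regular_polygamy"
    FREQUENT_POLYGAMY = "frequent_polygamy"


class PolygamyRecord(str, Enum):
    NONE = "none"
    OCCASIONAL = "occasional"
    MULTIPLE = "multiple"
    FREQUENT = "frequent"


#: (upper bound, score) pairs; rate < bound -> score, scanned in order.
#: Final band is open-ended.  Fractions, not percent.
POLYGAMY_THRESHOLDS = ((0.001, 0), (0.05, 1), (0.20, 2))
EPP_THRESHOLDS = ((0.05, 0), (0.25, 1), (0.50, 2))

_TEXTUAL_SCORES = {
    TextualClass.STRICT_MONOGAMY: 0,
    TextualClass.FREQUENT_MONOGAMY: 1,
    TextualClass.REGULAR_POLYGAMY: 2,
    TextualClass.FREQUENT_POLYGAMY: 3,
}

_RECORD_SCORES = {
    PolygamyRecord.NONE: None,  # absence of records is not evidence of monogamy
    PolygamyRecord.OCCASIONAL: 1,
    PolygamyRecord.MULTIPLE: 2,
    PolygamyRecord.FREQUENT: 3,
}

#: Tie-break priority when several criteria attain the maximum component.
#: Affects only the recorded trigger, never the score.
TRIGGER_PRIORITY = ("display", "polygamy", "epp", "textual")


@dataclass
class MatingEvidence:
    """Raw per-species evidence feeding the scoring rubric.

    Rates are fractions in [0, 1]; ``None`` means not measured.
    ``certainty`` grades the evidence 1 (weakest) to 4 (direct published
    observations).
    """

    species_id: str
    polygamy_rate: Optional[float] = None
    polygamy_record: Optional[PolygamyRecord] = None
    epp_rate: Optional[float] = None
    display_class: DisplayClass = DisplayClass.NONE
    textual_class: Optional[TextualClass] = None
    sex_role_reversed: bool = False
    certainty: int = 1

    def __post_init__(self) -> None:
        for name in ("polygamy_rate", "epp_rate"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1] for {self.species_id}")
        if self.certainty not in (1, 2, 3, 4):
            raise ValueError(f"certainty must be 1-4, got {self.certainty!r}")
        if self.polygamy_record is not None:
            self.polygamy_record = PolygamyRecord(self.polygamy_record)
        self.display_class = DisplayClass(self.display_class)
        if self.textual_class is not None:
            self.textual_class = TextualClass(self.textual_class)


@dataclass
class SexualSelectionScore:
    species_id: str
    score: int
    trigger: str
    certainty: int


class UnscorableSpeciesError(ValueError):
    """Raised when a species carries no scorable evidence at all."""


def _band_score(rate: float, thresholds) -> int:
    for bound, score in thresholds:
        if rate < bound or (score == thresholds[-1][1] and rate <= bound):
            return score
    return thresholds[-1][1] + 1


def score_component_polygamy(rate: Optional[float]) -> Optional[int]:
    """Ordinal 0-3 from the fraction of polygamous individuals.

    Bands: <0.1% -> 0; 0.1-5% -> 1; 5-20% -> 2 (20% inclusive); >20% -> 3.
    """
    if rate is None or (isinstance(rate, float) and np.isnan(rate)):
        return None
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"polygamy rate {rate!r} outside [0, 1]")
    return _band_score(rate, POLYGAMY_THRESHOLDS)


def score_component_epp(rate: Optional[float]) -> Optional[int]:
    """Ordinal 0-3 from the fraction of extra-pair offspring.

    Bands are deliberately higher than the polygamy bands: <5% -> 0
    (monogamy despite nonzero EPP), 5-25% -> 1, 25-50% -> 2 (50% inclusive),
    >50% -> 3.
    """
    if rate is None or (isinstance(rate, float) and np.isnan(rate)):
        return None
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"EPP rate {rate!r} outside [0, 1]")
    return _band_score(rate, EPP_THRESHOLDS)


def score_component_display(display_class) -> Optional[int]:
    """Score 4 for communal (lek) or permanent solitary display; else undefined.

    Display-based extreme polygamy is scored independently of polygamy and
    EPP levels.
    """
    display_class = DisplayClass(display_class)
    if display_class in (DisplayClass.LEK, DisplayClass.SOLITARY_DISPLAY):
        return 4
    return None


def score_component_textual(textual_class) -> Optional[int]:
    """Ordinal 0-3 from a qualitative mating-system description."""
    if textual_class is None or (isinstance(textual_class, float) and np.isnan(textual_class)):
        return None
    return _TEXTUAL_SCORES[TextualClass(textual_class)]


def score_component_polygamy_record(record) -> Optional[int]:
    """Ordinal from qualitative polygamy records.

    occasional -> 1, multiple -> 2, frequent -> 3.  ``none`` is treated as
    absence of evidence (undefined), not as evidence of monogamy; strict
    monogamy must be asserted through the textual class.
    """
    if record is None or (isinstance(record, float) and np.isnan(record)):
        return None
    return _RECORD_SCORES[PolygamyRecord(record)]


def combine_score(evidence: MatingEvidence) -> SexualSelectionScore:
    """Maximum over defined evidence components, with trigger provenance.

    Undefined components are excluded from the maximum rather than treated
    as zero.  When several criteria attain the maximum the recorded trigger
    follows :data:`TRIGGER_PRIORITY`.

    Raises
    ------
    UnscorableSpeciesError
        If every component is undefined.
    """
    rate_comp = score_component_polygamy(evidence.polygamy_rate)
    record_comp = score_component_polygamy_record(evidence.polygamy_record)
    if rate_comp is None:
        polygamy = record_comp
    elif record_comp is None:
        polygamy = rate_comp
    else:
        polygamy = max(rate_comp, record_comp)

    components = {
        "display": score_component_display(evidence.display_class),
        "polygamy": polygamy,
        "epp": score_component_epp(evidence.epp_rate),
        "textual": score_component_textual(evidence.textual_class),
    }
    defined = {k: v for k, v in components.items() if v is not None}
    if not defined:
        raise UnscorableSpeciesError(
            f"species {evidence.species_id!r} has no scorable evidence"
        )
    score = max(defined.values())
    trigger = next(k for k in TRIGGER_PRIORITY if defined.get(k) == score)
    return SexualSelectionScore(
        species_id=evidence.species_id,
        score=score,
        trigger=trigger,
        certainty=evidence.certainty,
    )


def to_bidirectional(score: int, sex_role_reversed: bool) -> int:
    """Signed score in [-4, 4]: negative for sex-role-reversed species."""
    if score not in (0, 1, 2, 3, 4):
        raise ValueError(f"score must be 0-4, got {score!r}")
    return -score if sex_role_reversed else score


def filter_by_certainty(scores: pd.DataFrame, min_level: int) -> pd.DataFrame:
    """Retain rows with certainty >= ``min_level``, preserving row order."""
    if min_level not in (1, 2, 3, 4):
        raise ValueError(f"min_level must be 1-4, got {min_level!r}")
    out = scores[scores["certainty"] >= min_level].copy()
    if out.empty:
        logger.warning("certainty filter at level %d removed every row", min_level)
    return out


# ---------------------------------------------------------------------------
# table-level interface

_EVIDENCE_COLUMNS = (
    "species_id",
    "polygamy_rate",
    "polygamy_record",
    "epp_rate",
    "display_class",
    "textual_class",
    "sex_role_reversed",
    "certainty",
)


def _evidence_from_row(row: pd.Series) -> MatingEvidence:
    def opt(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return v

    return MatingEvidence(
        species_id=str(row["species_id"]),
        polygamy_rate=opt(row.get("polygamy_rate")),
        polygamy_record=opt(row.get("polygamy_record")),
        epp_rate=opt(row.get("epp_rate")),
        display_class=opt(row.get("display_class")) or DisplayClass.NONE,
        textual_class=opt(row.get("textual_class")),
        sex_role_reversed=bool(opt(row.get("sex_role_reversed")) or False),
        certainty=int(row.get("certainty", 1)),
    )


def score_table(evidence: pd.DataFrame, bidirectional: bool = False) -> pd.DataFrame:
    """Score every species in an evidence table.

    Returns a frame with columns species_id, score, trigger, certainty.
    Unscorable species are dropped with a warning (their ids are attached
    to the frame as ``result.attrs['unscorable']``).
    """
    rows, unscorable = [], []
    for _, row in evidence.iterrows():
        ev = _evidence_from_row(row)
        try:
            s = combine_score(ev)
        except UnscorableSpeciesError:
            unscorable.append(ev.species_id)
            continue
        score = to_bidirectional(s.score, ev.sex_role_reversed) if bidirectional else s.score
        rows.append((s.species_id, score, s.trigger, s.certainty))
    if unscorable:
        logger.warning("%d species had no scorable evidence", len(unscorable))
    out = pd.DataFrame(rows, columns=["species_id", "score", "trigger", "certainty"])
    out.attrs["unscorable"] = unscorable
    return out


def read_evidence(path) -> pd.DataFrame:
    """Read a delimited evidence table (UTF-8, header row, empty = missing)."""
    df = pd.read_csv(path)
    missing = {"species_id"} - set(df.columns)
    if missing:
        raise ValueError(f"evidence table lacks required columns: {sorted(missing)}")
    return df
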