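"""Family-history classification and family-history-density (FHD) scoring.

The family-history questionnaire asks a parent whether specific blood
relatives of the child ever had problems due to alcohol or due to drugs.
Two quantities are derived from the relative-level indicators:

* **FHSU status** — positive iff *any* blood relative (biological parent,
  biological grandparent, or any other blood relative) is endorsed for
  drug-related problems.  Alcohol-only families are classified negative:
  the screening item is drug-specific.
* **FHD score** — a weighted density of endorsed first/second-degree
  relatives: +0.5 per biological-parent report and +0.25 per
  biological-grandparent report, counted separately per substance
  (alcohol, drugs) and summed.  The score therefore ranges over
  multiples of 0.25 in [0, 4]; other blood relatives do not contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PARENT_WEIGHT = 0.5
GRANDPARENT_WEIGHT = 0.25

#: column order used in family_history.csv
CSV_COLUMNS = (
    "participant_id",
    "mother_drug", "father_drug",
    "mother_alcohol", "father_alcohol",
    "gp1_drug", "gp2_drug", "gp3_drug", "gp4_drug",
    "gp1_alcohol", "gp2_alcohol", "gp3_alcohol", "gp4_alcohol",
    "other_relative_drug",
)


def _as_bools(values: Iterable[Optional[bool]], n: int, label: str) -> tuple:
    vals = tuple(values)
    if len(vals) != n:
        raise ValueError(f"{label} must have exactly {n} entries, got {len(vals)}")
    out = []
    for v in vals:
        if v is None or v != v:  # None or NaN → conservative false
            logger.warning("missing %s indicator treated as False", label)
            v = False
        out.append(bool(v))
    return tuple(out)


@dataclass(frozen=True)
class FamilyHistoryRecord:
    """Relative-level substance-problem indicators for one participant.

    Parent slots are (biological mother, biological father); grandparent
    slots are the four biological grandparents in fixed order.
    """

    parent_drug_problem: Sequence[Optional[bool]] = (False, False)
    parent_alcohol_problem: Sequence[Optional[bool]] = (False, False)
    grandparent_drug_problem: Sequence[Optional[bool]] = (False, False, False, False)
    grandparent_alcohol_problem: Sequence[Optional[bool]] = (False, False, False, False)
    other_blood_relative_drug_problem: bool = False

    def __post_init__(self):
        object.__setattr__(self, "parent_drug_problem",
                           _as_bools(self.parent_drug_problem, 2, "parent_drug_problem"))
        object.__setattr__(self, "parent_alcohol_problem",
                           _as_bools(self.parent_alcohol_problem, 2, "parent_alcohol_problem"))
        object.__setattr__(self, "grandparent_drug_problem",
                           _as_bools(self.grandparent_drug_problem, 4, "grandparent_drug_problem"))
        object.__setattr__(self, "grandparent_alcohol_problem",
                           _as_bools(self.grandparent_alcohol_problem, 4, "grandparent_alcohol_problem"))
        object.__setattr__(self, "other_blood_relative_drug_problem",
                           bool(self.other_blood_relative_drug_problem))

    def to_row(self, participant_id=None) -> dict:
        row = {
            "mother_drug": int(self.parent_drug_problem[0]),
            "father_drug": int(self.parent_drug_problem[1]),
            "mother_alcohol": int(self.parent_alcohol_problem[0]),
            "father_alcohol": int(self.parent_alcohol_problem[1]),
            "other_relative_drug": int(self.other_blood_relative_drug_problem),
        }
        for i in range(4):
            row[f"gp{i + 1}_drug"] = int(self.grandparent_drug_problem[i])
            row[f"gp{i + 1}_alcohol"] = int(self.grandparent_alcohol_problem[i])
        if participant_id is not None:
            row["participant_id"] = participant_id
        return row

    @classmethod
    def from_row(cls, row) -> "FamilyHistoryRecord":
        """Build a record from a mapping/Series with family_history.csv columns."""
        return cls(
            parent_drug_problem=(row["mother_drug"], row["father_drug"]),
            parent_alcohol_problem=(row["mother_alcohol"], row["father_alcohol"]),
            grandparent_drug_problem=tuple(row[f"gp{i}_drug"] for i in range(1, 5)),
            grandparent_alcohol_problem=tuple(row[f"gp{i}_alcohol"] for i in range(1, 5)),
            other_blood_relative_drug_problem=row["other_relative_drug"],
        )


def classify_fhsu(record: FamilyHistoryRecord) -> str:
    """Classify family-history-of-substance-use status from one record.

    Returns ``"positive"`` iff any drug-problem indicator is endorsed for
    any blood relative; alcohol-only records are ``"negative"``.
    """
    any_drug = (
        any(record.parent_drug_problem)
        or any(record.grandparent_drug_problem)
        or record.other_blood_relative_drug_problem
    )
    return "positive" if any_drug else "negative"


def compute_fhd(record: FamilyHistoryRecord) -> float:
    """Family-history density: 0.5 per parent report, 0.25 per grandparent report.

    Reports are counted separately for alcohol and drug problems and
    summed, so a parent endorsed for both substances contributes 1.0.
    Other blood relatives are not weighted.  The result is a multiple of
    0.25 in [0, 4].
    """
    n_parent = sum(record.parent_drug_problem) + sum(record.parent_alcohol_problem)
    n_gp = sum(record.grandparent_drug_problem) + sum(record.grandparent_alcohol_problem)
    return PARENT_WEIGHT * n_parent + GRANDPARENT_WEIGHT * n_gp


def score_family_history_table(fh: pd.DataFrame) -> pd.DataFrame:
    """Score a family_history.csv table: one row per participant.

    Returns a DataFrame with participant_id, fhsu_status and fhd columns,
    suitable for joining back onto the cohort table.
    """
    out = []
    for _, row in fh.iterrows():
        rec = FamilyHistoryRecord.from_row(row)
        out.append({
            "participant_id": row["participant_id"],
            "fhsu_status": classify_fhsu(rec),
            "fhd": compute_fhd(rec),
        })
    return pd.DataFrame(out, columns=["participant_id", "fhsu_status", "fhd"])
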