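"""Dichotomize survival at a horizon with censoring-aware exclusion rules.

A patient dead before the horizon is a nonsurvivor; a patient known to have
lived to the horizon (dead later, or alive at a last contact at/after it) is a
survivor.  A patient alive at a last contact *before* the horizon is excluded
— whether they reached the horizon cannot be ascertained.  Optionally, deaths
from causes other than the cancer are excluded.  Death exactly at the horizon
day counts as survivor by default ("died within H days" read strictly); the
boundary is configurable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd

from multisurv.formats import ClinicalRecord, VitalStatus

SURVIVOR = "survivor"
NONSURVIVOR = "nonsurvivor"


@dataclasses.dataclass
class LabelSet:
    horizon_days: int
    labels: dict[str, str]  # sample -> survivor / nonsurvivor
    excluded: dict[str, str]  # sample -> reason

    @property
    def survivors(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == SURVIVOR]

    @property
    def nonsurvivors(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == NONSURVIVOR]

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="label")

    def binary(self) -> pd.Series:
        """1 = nonsurvivor (positive class: death within horizon), 0 = survivor."""
        return pd.Series({s: int(l == NONSURVIVOR) for s, l in self.labels.items()})

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"sample_id": s, "label": l, "excluded_reason": ""} for s, l in self.labels.items()]
        rows += [{"sample_id": s, "label": "", "excluded_reason": r} for s, r in self.excluded.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str | Path, horizon_days: int) -> "LabelSet":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        labels = {r.sample_id: r.label for r in df.itertuples() if r.label}
        excluded = {r.sample_id: r.excluded_reason for r in df.itertuples() if r.excluded_reason}
        return LabelSet(horizon_days=horizon_days, labels=labels, excluded=excluded)


def dichotomize_survival(
    clinical: Iterable[ClinicalRecord],
    horizon_days: int = 730,
    exclude_non_cancer_death: bool = False,
    death_at_horizon_survives: bool = True,
) -> LabelSet:
    """Assign survivor/nonsurvivor at ``horizon_days``, excluding unresolvable cases."""
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    labels: dict[str, str] = {}
    excluded: dict[str, str] = {}
    seen: set[str] = set()
    for rec in clinical:
        if rec.sample_id in seen:
            raise ValueError(f"duplicate sample id {rec.sample_id!r}")
        seen.add(rec.sample_id)
        days = rec.days_to_last_contact_or_death
        if rec.vital_status is VitalStatus.DEAD:
            if exclude_non_cancer_death and rec.cause_of_death_cancer is False:
                excluded[rec.sample_id] = "non_cancer_death"
                continue
            dies_within = days < horizon_days or (days == horizon_days
                                                  and not death_at_horizon_survives)
            labels[rec.sample_id] = NONSURVIVOR if dies_within else SURVIVOR
        else:
            if days >= horizon_days:
                labels[rec.sample_id] = SURVIVOR
            else:
                excluded[rec.sample_id] = "censored_before_horizon"
    return LabelSet(horizon_days=horizon_days, labels=labels, excluded=excluded)
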