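"""Typed per-eye input records for the four risk domains.

Each profile class validates its own invariants (positive ages, grade
ranges, non-negative times). Optional donor and center fields may be
``None``; a fully missing domain is scored at the documented mid-range
default of 50 with its ``defaulted`` flag set. ``RiskProfileBundle``
groups the four domain records for one eye and flattens them to the
canonical cohort-CSV column names used everywhere else in the package.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

Diagnosis = Literal["FECD", "PBK"]
LensStatus = Literal["phakic", "pseudophakic", "aphakic"]
ScrollGrade = Literal["I", "II", "III", "IV"]
Tamponade = Literal["air", "SF6"]


class PatientProfile(BaseModel):
    model_config = ConfigDict(extra="forbid")

    age: float = Field(gt=0)
    diagnosis: Diagnosis
    diabetes: bool = False
    hypertension: bool = False
    glaucoma: bool = False
    ice_or_iris_abnormality: bool = False
    lens_status: LensStatus = "phakic"
    vascularization_grade: int = Field(default=0, ge=0, le=4)

    def to_row(self) -> dict:
        return {
            "age": self.age,
            "diagnosis": self.diagnosis,
            "diabetes": int(self.diabetes),
            "hypertension": int(self.hypertension),
            "glaucoma": int(self.glaucoma),
            "ice_iris": int(self.ice_or_iris_abnormality),
            "lens_status": self.lens_status,
            "vascularization_grade": self.vascularization_grade,
        }


class DonorProfile(BaseModel):
    model_config = ConfigDict(extra="forbid")

    donor_ecd: Optional[float] = Field(default=None, gt=0)
    donor_age: Optional[float] = Field(default=None, gt=0)
    scroll_grade: Optional[ScrollGrade] = None
    storage_time: Optional[float] = Field(default=None, ge=0)

    def to_row(self) -> dict:
        return {
            "donor_ecd": math.nan if self.donor_ecd is None else self.donor_ecd,
            "donor_age": math.nan if self.donor_age is None else self.donor_age,
            "scroll_grade": self.scroll_grade,
            "storage_days": math.nan if self.storage_time is None else self.storage_time,
        }


class SurgicalProfile(BaseModel):
    model_config = ConfigDict(extra="forbid")

    surgeon_experience_cases: float = Field(ge=0)
    unfolding_time: Optional[float] = Field(default=None, ge=0)
    tamponade: Tamponade = "air"
    triple_dmek: bool = False
    epithelial_debridement: bool = False

    def to_row(self) -> dict:
        return {
            "surgeon_cases": self.surgeon_experience_cases,
            "unfolding_min": math.nan if self.unfolding_time is None else self.unfolding_time,
            "tamponade": self.tamponade,
            "triple_dmek": int(self.triple_dmek),
            "epi_debridement": int(self.epithelial_debridement),
        }


class CenterProfile(BaseModel):
    model_config = ConfigDict(extra="forbid")

    annual_dmek_volume: Optional[float] = Field(default=None, ge=0)
    defaulted: bool = False

    def to_row(self) -> dict:
        return {
            "annual_volume": math.nan
            if self.annual_dmek_volume is None
            else self.annual_dmek_volume,
        }


class RiskProfileBundle(BaseModel):
    """The four domain input records for one eye."""

    model_config = ConfigDict(extra="forbid")

    eye_id: str = "eye-0"
    patient: PatientProfile
    donor: DonorProfile = Field(default_factory=DonorProfile)
    surgical: SurgicalProfile = Field(default_factory=lambda: SurgicalProfile(surgeon_experience_cases=0))
    center: CenterProfile = Field(default_factory=CenterProfile)

    def to_row(self) -> dict:
        row = {"eye_id": self.eye_id}
        for part in (self.patient, self.donor, self.surgical, self.center):
            row.update(part.to_row())
        return row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_row()])


class SubscoreSet(BaseModel):
    """The four 0-100 domain subscores of one eye."""

    model_config = ConfigDict(extra="forbid")

    prp: float = Field(ge=0, le=100)
    dtq: float = Field(ge=0, le=100)
    sci: float = Field(ge=0, le=100)
    cpf: float = Field(ge=0, le=100)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.prp, self.dtq, self.sci, self.cpf)


class DropResult(BaseModel):
    """Subscores, composite score and risk category for one eye."""

    model_config = ConfigDict(extra="forbid")

    subscores: SubscoreSet
    composite: float = Field(ge=0, le=100)
    category: Literal["Low", "Moderate", "High", "VeryHigh"]
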