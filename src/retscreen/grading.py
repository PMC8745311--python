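"""Diagnostic grading: image status, ICDR eye stage, patient aggregation.

The diagnostic convention implemented here is the one used by teleophthalmology
screening programmes:

* an image with any retinopathy lesion is DR regardless of its quality; an
  ungradable image without lesions is UNG; a gradable lesion-free image is NODR;
* an eye is staged on the International Clinical Diabetic Retinopathy severity
  scale (NODR < MILD < MOD < SEV < PROL), with severe non-proliferative disease
  reached through the 4-2-1 rule (hemorrhages in all 4 quadrants, venous beading
  in ≥ 2, or IRMA in ≥ 1);
* diabetic macular edema (DME) is flagged when a bright lesion lies within one
  disc diameter of the fovea;
* a patient takes the worst-eye stage, and is sight-threatening (STDR) when
  staged SEV/PROL or flagged DME in either eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from retscreen.types import BRIGHT_TYPES, EYES, ImageAnalysis

STATUSES = ("UNG", "NODR", "DR")
STAGES = ("NODR", "MILD", "MOD", "SEV", "PROL")
_STAGE_RANK = {s: i for i, s in enumerate(STAGES)}

#: DME rule: a bright lesion within this many disc diameters of the fovea.
DME_FOVEA_DISTANCE_DD = 1.0


@dataclass
class LesionInventory:
    """Per-eye lesion evidence feeding the staging rules.

    Counts come from the detector; ``venous_beading_quadrants``,
    ``irma_quadrants`` and ``neovascularization`` are annotation flags (the
    pixel pipeline does not detect them), so detector-driven grading saturates
    at MOD (+DME).
    """

    ma: int = 0
    hem: int = 0
    ex: int = 0
    cws: int = 0
    hemorrhage_quadrants: int = 0
    venous_beading_quadrants: int = 0
    irma_quadrants: int = 0
    neovascularization: bool = False
    bright_lesion_min_distance_to_fovea: Optional[float] = None  # dd units

    def __post_init__(self) -> None:
        for name in ("ma", "hem", "ex", "cws"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")
        for name in ("hemorrhage_quadrants", "venous_beading_quadrants", "irma_quadrants"):
            v = getattr(self, name)
            if not 0 <= v <= 4:
                raise ValueError(f"{name} must be in 0..4")
        d = self.bright_lesion_min_distance_to_fovea
        if d is not None and d < 0:
            raise ValueError("distance must be non-negative")

    @property
    def any_lesion(self) -> bool:
        return (
            self.ma > 0
            or self.hem > 0
            or self.ex > 0
            or self.cws > 0
            or self.venous_beading_quadrants > 0
            or self.irma_quadrants > 0
            or self.neovascularization
        )


@dataclass
class EyeGrade:
    """Eye-level diagnosis. ``status == "DR"`` iff ``stage != "NODR"``."""

    eye: str
    status: str
    stage: str = "NODR"
    dme: bool = False

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}")
        if self.status not in STATUSES or self.stage not in STAGES:
            raise ValueError("invalid status or stage")
        if (self.status == "DR") != (self.stage != "NODR"):
            raise ValueError("status DR iff stage != NODR")
        if self.status == "UNG" and (self.stage != "NODR" or self.dme):
            raise ValueError("UNG eyes carry no stage or DME flag")


@dataclass
class PatientDiagnosis:
    """Patient-level diagnosis under the worst-eye rule."""

    status: str
    stage: str = "NODR"
    dme: bool = False
    stdr: bool = False
    single_eye: bool = False

    def __post_init__(self) -> None:
        if self.status not in STATUSES or self.stage not in STAGES:
            raise ValueError("invalid status or stage")


def stage_order(stage: str) -> int:
    """Rank of an ICDR stage (NODR=0 … PROL=4)."""
    return _STAGE_RANK[stage]


def grade_image(analysis: ImageAnalysis) -> str:
    """Image status: DR if any lesion (regardless of quality), else UNG/NODR."""
    if analysis.lesions:
        return "DR"
    if not analysis.quality.gradable:
        return "UNG"
    return "NODR"


def stage_eye(inv: LesionInventory) -> str:
    """ICDR stage of a lesion inventory.

    PROL requires neovascularization; SEV requires the 4-2-1 rule; MILD is
    microaneurysms only; any other lesion evidence gives MOD.
    """
    if inv.neovascularization:
        return "PROL"
    if (
        inv.hemorrhage_quadrants == 4
        or inv.venous_beading_quadrants >= 2
        or inv.irma_quadrants >= 1
    ):
        return "SEV"
    others = inv.hem + inv.ex + inv.cws + inv.venous_beading_quadrants + inv.irma_quadrants
    if inv.ma > 0 and others == 0:
        return "MILD"
    if inv.any_lesion:
        return "MOD"
    return "NODR"


def detect_dme(inv: LesionInventory) -> bool:
    """Macular edema: a bright lesion within ``DME_FOVEA_DISTANCE_DD`` of the fovea."""
    d = inv.bright_lesion_min_distance_to_fovea
    return d is not None and d <= DME_FOVEA_DISTANCE_DD


def merge_analyses(
    analyses: Sequence[ImageAnalysis], dedup_distance_dd: float = 0.1
) -> LesionInventory:
    """Union the per-capture lesion candidates of one eye into an inventory.

    Candidates from different captures are deduplicated when their frame
    coordinates lie within ``dedup_distance_dd`` disc diameters; an eye's
    evidence is the union of its captures (maximizing sensitivity, the
    screening posture). Candidates without a frame are kept as-is.
    """
    if not analyses:
        raise ValueError("at least one capture analysis is required")
    merged: list = []
    for analysis in analyses:
        for cand in analysis.lesions:
            dup = False
            if cand.polar is not None:
                for kept in merged:
                    if kept.polar is None or kept.type != cand.type:
                        continue
                    # chord distance between two polar points, in dd
                    r1, t1 = kept.polar
                    r2, t2 = cand.polar
                    dx = r1 * math.cos(math.radians(t1)) - r2 * math.cos(math.radians(t2))
                    dy = r1 * math.sin(math.radians(t1)) - r2 * math.sin(math.radians(t2))
                    if math.hypot(dx, dy) < dedup_distance_dd:
                        dup = True
                        break
            if not dup:
                merged.append(cand)

    counts = {"MA": 0, "HEM": 0, "EX": 0, "CWS": 0}
    hem_quadrants: set[int] = set()
    bright_min: Optional[float] = None
    for cand in merged:
        counts[cand.type] += 1
        if cand.type == "HEM" and cand.quadrant is not None:
            hem_quadrants.add(cand.quadrant)
        if cand.type in BRIGHT_TYPES and cand.polar is not None:
            r = cand.polar[0]
            bright_min = r if bright_min is None else min(bright_min, r)
    return LesionInventory(
        ma=counts["MA"],
        hem=counts["HEM"],
        ex=counts["EX"],
        cws=counts["CWS"],
        hemorrhage_quadrants=len(hem_quadrants),
        bright_lesion_min_distance_to_fovea=bright_min,
    )


def grade_eye(analyses: Sequence[ImageAnalysis], eye: str = "OD") -> EyeGrade:
    """Grade one eye from its 1–3 capture analyses.

    The eye is gradable if at least one capture is; lesions from any capture
    count regardless of quality.
    """
    if not analyses:
        raise ValueError("at least one capture analysis is required")
    inv = merge_analyses(analyses)
    any_gradable = any(a.quality.gradable for a in analyses)
    stage = stage_eye(inv)
    if stage != "NODR":
        return EyeGrade(eye=eye, status="DR", stage=stage, dme=detect_dme(inv))
    if not any_gradable:
        return EyeGrade(eye=eye, status="UNG")
    return EyeGrade(eye=eye, status="NODR")


def grade_eye_from_inventory(inv: LesionInventory, gradable: bool, eye: str = "OD") -> EyeGrade:
    """Grade an eye directly from a lesion inventory plus a gradability flag."""
    stage = stage_eye(inv)
    if stage != "NODR":
        return EyeGrade(eye=eye, status="DR", stage=stage, dme=detect_dme(inv))
    if not gradable:
        return EyeGrade(eye=eye, status="UNG")
    return EyeGrade(eye=eye, status="NODR")


def aggregate_patient(
    od: Optional[EyeGrade],
    os_: Optional[EyeGrade],
    ung_precedence: str = "dr_over_ung",
) -> PatientDiagnosis:
    """Combine the two eye grades into the patient diagnosis.

    Default precedence is DR > UNG > NODR: lesions count regardless of
    gradability, by analogy with the image-level rule. ``ung_precedence=
    "ung_over_dr"`` switches to UNG > DR > NODR for programmes that refuse to
    diagnose a patient with any ungradable eye.
    """
    if ung_precedence not in ("dr_over_ung", "ung_over_dr"):
        raise ValueError("ung_precedence must be 'dr_over_ung' or 'ung_over_dr'")
    eyes = [e for e in (od, os_) if e is not None]
    if not eyes:
        raise ValueError("at least one eye grade is required")
    single = len(eyes) == 1

    statuses = {e.status for e in eyes}
    if ung_precedence == "dr_over_ung":
        order = ("DR", "UNG", "NODR")
    else:
        order = ("UNG", "DR", "NODR")
    status = next(s for s in order if s in statuses)

    if status != "DR":
        return PatientDiagnosis(status=status, single_eye=single)
    dr_eyes = [e for e in eyes if e.status == "DR"]
    stage = max((e.stage for e in dr_eyes), key=stage_order)
    dme = any(e.dme for e in eyes)
    stdr = dme or stage in ("SEV", "PROL")
    return PatientDiagnosis(status="DR", stage=stage, dme=dme, stdr=stdr, single_eye=single)
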