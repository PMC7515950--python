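"""Virtual-subject generation for healthy-volunteer and cancer populations.

Physiological fields are sampled log-normally around declared central
values with per-field CV%, using ``numpy.random.default_rng`` (PCG64) so
that a given seed reproduces the same subjects on any platform. The
central value is the *geometric mean* of the sampled distribution, so a
CV of zero degenerates to the central value exactly and no sampled
quantity can be zero or negative by construction.

Central physiology (documented defaults, healthy adults):

======================  ========  =====================================
field                   central   note
======================  ========  =====================================
body weight             70 kg     CV 15%
liver weight            1650 g    CV 20%
hepatic blood flow      90 L/h    CV 15%
MPPGL                   40 mg/g   CV 30%
CYP3A4 (liver)          137 pmol/mg  CV 40%
CYP2C19                 14 pmol/mg   CV 50%
CYP2D6                  8 pmol/mg    CV 60%
CYP2C8                  24 pmol/mg   CV 40%
CYP2C9                  73 pmol/mg   CV 40%
HLM additional          1 (relative) CV 30%
CYP3A4 (gut, total)     66400 pmol   CV 40%
GFR scalar              1.0       CV 15%
plasma-protein scalar   1.0       CV 10% (multiplies fu)
hematocrit              0.45      CV 8%, clipped to (0.2, 0.6)
======================  ========  =====================================

The cancer population is derived from the healthy one by
:func:`cancer_modifiers`: reduced unbound fraction (raised binding
protein), reduced hepatic and gut CYP3A4 abundance, and slightly lower
body weight. These shifts are a calibrated design choice that reproduces
the qualitative orderings of DDI magnitude between the two populations;
they are not measured values.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .compound import EnzymeId

logger = logging.getLogger(__name__)


class FieldSpec(BaseModel):
    """Central value (geometric mean) and log-normal CV% for one field."""

    model_config = ConfigDict(extra="forbid")

    central: float = Field(gt=0)
    cv_percent: float = Field(default=0.0, ge=0)


class PopulationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = "healthy"
    body_weight: FieldSpec = FieldSpec(central=70.0, cv_percent=15)
    liver_weight: FieldSpec = FieldSpec(central=1650.0, cv_percent=20)
    hepatic_blood_flow: FieldSpec = FieldSpec(central=90.0, cv_percent=15)
    mppgl: FieldSpec = FieldSpec(central=40.0, cv_percent=30)
    enzyme_abundance: Dict[EnzymeId, FieldSpec] = Field(
        default_factory=lambda: {
            EnzymeId.CYP3A4_liver: FieldSpec(central=137.0, cv_percent=40),
            EnzymeId.CYP3A4_gut: FieldSpec(central=66400.0, cv_percent=40),
            EnzymeId.CYP2C19: FieldSpec(central=14.0, cv_percent=50),
            EnzymeId.CYP2D6: FieldSpec(central=8.0, cv_percent=60),
            EnzymeId.CYP2C8: FieldSpec(central=24.0, cv_percent=40),
            EnzymeId.CYP2C9: FieldSpec(central=73.0, cv_percent=40),
            EnzymeId.HLM_additional: FieldSpec(central=1.0, cv_percent=30),
        }
    )
    gfr_scalar: FieldSpec = FieldSpec(central=1.0, cv_percent=15)
    plasma_protein_scalar: FieldSpec = FieldSpec(central=1.0, cv_percent=10)
    hematocrit: FieldSpec = FieldSpec(central=0.45, cv_percent=8)
    age_range: tuple[float, float] = (20.0, 65.0)
    seed: int = 0


@dataclasses.dataclass
class Subject:
    """One sampled virtual subject."""

    body_weight: float  # kg
    liver_weight: float  # g
    hepatic_blood_flow: float  # L/h
    mppgl: float  # mg microsomal protein / g liver
    enzyme_abundance: Dict[EnzymeId, float]  # pmol/mg (gut CYP3A4: total pmol)
    gfr_scalar: float
    plasma_protein_scalar: float
    hematocrit: float

    def validate(self) -> None:
        vals = [
            self.body_weight,
            self.liver_weight,
            self.hepatic_blood_flow,
            self.mppgl,
            self.gfr_scalar,
            self.plasma_protein_scalar,
            *self.enzyme_abundance.values(),
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("subject has a non-positive physiological value")
        if not (0.2 < self.hematocrit < 0.6):
            raise ValueError(f"hematocrit {self.hematocrit} outside (0.2, 0.6)")


def central_subject(spec: PopulationSpec) -> Subject:
    """The zero-variability subject at the spec's central values."""
    return Subject(
        body_weight=spec.body_weight.central,
        liver_weight=spec.liver_weight.central,
        hepatic_blood_flow=spec.hepatic_blood_flow.central,
        mppgl=spec.mppgl.central,
        enzyme_abundance={e: f.central for e, f in spec.enzyme_abundance.items()},
        gfr_scalar=spec.gfr_scalar.central,
        plasma_protein_scalar=spec.plasma_protein_scalar.central,
        hematocrit=spec.hematocrit.central,
    )


def _sample(rng: np.random.Generator, f: FieldSpec, n: int) -> np.ndarray:
    cv = f.cv_percent / 100.0
    if cv == 0:
        return np.full(n, f.central)
    sigma = np.sqrt(np.log1p(cv * cv))
    return f.central * np.exp(sigma * rng.standard_normal(n))


def sample_population(spec: PopulationSpec, n_subjects: int, seed: int | None = None) -> List[Subject]:
    """Draw ``n_subjects`` virtual subjects; deterministic for a fixed seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cols = {
        "body_weight": _sample(rng, spec.body_weight, n_subjects),
        "liver_weight": _sample(rng, spec.liver_weight, n_subjects),
        "hepatic_blood_flow": _sample(rng, spec.hepatic_blood_flow, n_subjects),
        "mppgl": _sample(rng, spec.mppgl, n_subjects),
        "gfr_scalar": _sample(rng, spec.gfr_scalar, n_subjects),
        "plasma_protein_scalar": _sample(rng, spec.plasma_protein_scalar, n_subjects),
        "hematocrit": np.clip(_sample(rng, spec.hematocrit, n_subjects), 0.201, 0.599),
    }
    abund = {e: _sample(rng, f, n_subjects) for e, f in spec.enzyme_abundance.items()}
    subjects = []
    for i in range(n_subjects):
        s = Subject(
            body_weight=float(cols["body_weight"][i]),
            liver_weight=float(cols["liver_weight"][i]),
            hepatic_blood_flow=float(cols["hepatic_blood_flow"][i]),
            mppgl=float(cols["mppgl"][i]),
            enzyme_abundance={e: float(a[i]) for e, a in abund.items()},
            gfr_scalar=float(cols["gfr_scalar"][i]),
            plasma_protein_scalar=float(cols["plasma_protein_scalar"][i]),
            hematocrit=float(cols["hematocrit"][i]),
        )
        s.validate()
        subjects.append(s)
    return subjects


#: Multiplicative shifts applied by :func:`cancer_modifiers`.
CANCER_SHIFTS = {
    "plasma_protein_scalar": 0.80,  # raised alpha-1-acid glycoprotein -> lower fu
    "body_weight": 0.95,
    "mppgl": 0.80,  # reduced functional hepatic enzyme mass
    ("enzyme_abundance", EnzymeId.CYP3A4_liver): 0.75,
    ("enzyme_abundance", EnzymeId.CYP3A4_gut): 0.75,
}


def cancer_modifiers(spec_healthy: PopulationSpec) -> PopulationSpec:
    """Derive the cancer population spec from a healthy one.

    Emits the healthy-vs-cancer difference table to the module logger.
    """
    spec = spec_healthy.model_copy(deep=True)
    spec.name = "cancer"
    rows = []
    for key, factor in CANCER_SHIFTS.items():
        if isinstance(key, tuple):
            field = spec.enzyme_abundance[key[1]]
            old = field.central
            spec.enzyme_abundance[key[1]] = FieldSpec(
                central=old * factor, cv_percent=field.cv_percent
            )
            rows.append((f"enzyme_abundance[{key[1].value}]", old, old * factor))
        else:
            field: FieldSpec = getattr(spec, key)
            old = field.central
            setattr(spec, key, FieldSpec(central=old * factor, cv_percent=field.cv_percent))
            rows.append((key, old, old * factor))
    for name, old, new in rows:
        logger.info("cancer population: %s %.4g -> %.4g", name, old, new)
    return spec


def subjects_frame(subjects: List[Subject]):
    """CSV-ready audit table of sampled subjects (one row per subject)."""
    import pandas as pd

    rows = []
    for i, s in enumerate(subjects):
        row = {
            "subject": i,
            "body_weight_kg": s.body_weight,
            "liver_weight_g": s.liver_weight,
            "hepatic_blood_flow_L_h": s.hepatic_blood_flow,
            "mppgl_mg_g": s.mppgl,
            "gfr_scalar": s.gfr_scalar,
            "plasma_protein_scalar": s.plasma_protein_scalar,
            "hematocrit": s.hematocrit,
        }
        for e, v in s.enzyme_abundance.items():
            row[f"abundance_{e.value}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
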