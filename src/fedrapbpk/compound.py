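"""Compound parameterizations for PBPK DDI simulation.

A :class:`CompoundModel` bundles everything the ODE engine needs to know
about one drug: physicochemical constants, oral absorption, a minimal
distribution model (central + single adjusting compartment), per-enzyme
intrinsic clearances, excretory clearances, and enzyme-interaction
kinetics (reversible inhibition, time-dependent inactivation, induction).

Internal unit system: hours, litres, milligrams; interaction constants are
unbound micromolar. Per-enzyme intrinsic clearances are declared with an
explicit unit per entry ("uL/min/pmol", "uL/min/mg" microsomal protein, or
"L/h" for a subject-independent value) and converted when a model is scaled
to a subject — never inferred implicitly.

Compound configs are YAML or JSON, one file per compound; the shipped
library (fedratinib plus the perpetrator/probe fixtures) lives under
``fedrapbpk/data/compounds`` and is exposed through
:func:`builtin_library`.
"""

from __future__ import annotations

import enum
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Dict, Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

logger = logging.getLogger(__name__)


class EnzymeId(str, enum.Enum):
    """Canonical enzyme/pathway identifiers understood by the engine."""

    CYP3A4_liver = "CYP3A4_liver"
    CYP3A4_gut = "CYP3A4_gut"
    CYP2C19 = "CYP2C19"
    CYP2D6 = "CYP2D6"
    CYP2C8 = "CYP2C8"
    CYP2C9 = "CYP2C9"
    HLM_additional = "HLM_additional"


#: Hepatic (and gut) CYP pools recognised as liver metabolic pathways.
LIVER_ENZYMES = (
    EnzymeId.CYP3A4_liver,
    EnzymeId.CYP2C19,
    EnzymeId.CYP2D6,
    EnzymeId.CYP2C8,
    EnzymeId.CYP2C9,
    EnzymeId.HLM_additional,
)

#: First-order natural degradation rate of each enzyme pool (1/h).
#: Liver CYP3A4 turnover half-life ~36 h, gut ~23 h; other hepatic CYPs
#: use a generic 26-h half-life. These set the recovery timescale after
#: a mechanism-based inhibitor is withdrawn.
KDEG_PER_H: Dict[EnzymeId, float] = {
    EnzymeId.CYP3A4_liver: 0.0193,
    EnzymeId.CYP3A4_gut: 0.03,
    EnzymeId.CYP2C19: 0.026,
    EnzymeId.CYP2D6: 0.026,
    EnzymeId.CYP2C8: 0.026,
    EnzymeId.CYP2C9: 0.026,
    EnzymeId.HLM_additional: 0.026,
}

CLEARANCE_UNITS = ("uL/min/pmol", "uL/min/mg", "L/h")


class ClearanceEntry(BaseModel):
    """One intrinsic-clearance entry with an explicit unit declaration."""

    model_config = ConfigDict(extra="forbid")

    value: float = Field(ge=0)
    unit: str
    provenance: str = "unspecified"

    @field_validator("unit")
    @classmethod
    def _known_unit(cls, v: str) -> str:
        if v not in CLEARANCE_UNITS:
            raise ValueError(f"unknown clearance unit {v!r}; use one of {CLEARANCE_UNITS}")
        return v


class InteractionKinetics(BaseModel):
    """Inhibition/induction constants of a perpetrator on one enzyme pool.

    Any field may be absent, which switches that mechanism off. All
    concentrations are unbound µM at the relevant site (liver inlet/outlet
    for hepatic pools, enterocyte for gut pools).
    """

    model_config = ConfigDict(extra="forbid")

    ki_reversible: Optional[float] = Field(default=None, gt=0, description="µM, competitive")
    kinact: Optional[float] = Field(default=None, gt=0, description="1/h max inactivation rate")
    ki_app: Optional[float] = Field(default=None, gt=0, description="µM TDI half-max")
    ind_max: Optional[float] = Field(default=None, ge=0, description="fold maximal induction")
    ind_c50: Optional[float] = Field(default=None, gt=0, description="µM induction half-max")
    provenance: str

    @model_validator(mode="after")
    def _paired(self) -> "InteractionKinetics":
        if (self.kinact is None) != (self.ki_app is None):
            raise ValueError("kinact and ki_app must be given together")
        if (self.ind_max is not None and self.ind_max > 0) and self.ind_c50 is None:
            raise ValueError("ind_max > 0 requires ind_c50")
        return self

    @property
    def has_turnover_effect(self) -> bool:
        """Whether this entry perturbs the enzyme-turnover ODE."""
        return self.kinact is not None or (self.ind_max or 0) > 0


class CompoundModel(BaseModel):
    """Full PK/interaction parameterization of one drug.

    Distribution follows the minimal-PBPK convention: a central systemic
    volume ``vss`` (L/kg), a single adjusting (peripheral) compartment
    ``v_sac`` (L/kg) and the inter-compartment flow ``q_sac`` (L/h), plus a
    well-stirred liver through which all absorbed drug passes.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    name: str
    mol_weight: float = Field(gt=0, description="g/mol")
    fu_plasma: float = Field(gt=0, le=1)
    blood_plasma_ratio: float = Field(gt=0)

    # absorption
    ka: float = Field(ge=0, description="1/h")
    fa: float = Field(gt=0, le=1)
    lag_time: float = Field(default=0.0, ge=0, description="h")

    # gut first pass
    fg_model: str = Field(default="fixed_fg", pattern="^(fixed_fg|gut_extraction)$")
    fixed_fg: Optional[float] = Field(default=None, gt=0, le=1)
    clint_gut: Optional[float] = Field(
        default=None, ge=0, description="µL/min/pmol gut CYP3A4 (gut_extraction model)"
    )

    # distribution
    vss: float = Field(gt=0, description="L/kg central")
    v_sac: float = Field(ge=0, description="L/kg peripheral")
    q_sac: float = Field(ge=0, description="L/h")

    # elimination
    enzyme_clearances: Dict[EnzymeId, ClearanceEntry] = Field(default_factory=dict)
    cl_renal: float = Field(default=0.0, ge=0, description="L/h")
    cl_biliary: float = Field(default=0.0, ge=0, description="L/h")
    cl_additional: float = Field(default=0.0, ge=0, description="L/h")

    # perpetrator behaviour
    interactions: Dict[EnzymeId, InteractionKinetics] = Field(default_factory=dict)

    # accepted but inert (forward compatibility)
    transporters: Dict[str, float] = Field(default_factory=dict)

    provenance: str = "unspecified"

    @model_validator(mode="after")
    def _check(self) -> "CompoundModel":
        if self.fg_model == "fixed_fg":
            if self.fixed_fg is None:
                raise ValueError(f"{self.name}: fg_model=fixed_fg requires fixed_fg")
        else:
            if self.clint_gut is None:
                raise ValueError(f"{self.name}: fg_model=gut_extraction requires clint_gut")
        if EnzymeId.CYP3A4_gut in self.enzyme_clearances:
            raise ValueError(
                f"{self.name}: gut CYP3A4 clearance is declared via clint_gut, "
                "not enzyme_clearances"
            )
        total_elim = (
            sum(e.value for e in self.enzyme_clearances.values())
            + self.cl_renal
            + self.cl_biliary
            + self.cl_additional
        )
        if total_elim <= 0:
            raise ValueError(f"{self.name}: no elimination pathway is strictly positive")
        if self.transporters:
            logger.info(
                "%s: transporter entries %s parsed but inactive (metabolic DDI only)",
                self.name,
                sorted(self.transporters),
            )
        return self

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = self.model_dump(mode="json", exclude_none=True)
        # drop empty optional maps for tidy files
        for key in ("enzyme_clearances", "interactions", "transporters"):
            if not d.get(key):
                d.pop(key, None)
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_compound(path: str | Path) -> CompoundModel:
    """Read and validate a compound config (YAML or JSON by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: compound config must be a mapping")
    return CompoundModel.model_validate(raw)


def builtin_library() -> Dict[str, CompoundModel]:
    """Load all shipped compound fixtures keyed by compound name.

    The library contains the calibrated fedratinib model plus perpetrator
    and probe-substrate fixtures (ketoconazole, itraconazole, erythromycin,
    diltiazem, fluconazole, efavirenz, rifampin, midazolam, omeprazole,
    metoprolol, repaglinide, warfarin). Each interaction constant documents
    its source in a provenance field.
    """
    lib: Dict[str, CompoundModel] = {}
    pkg = resources.files("fedrapbpk") / "data" / "compounds"
    for entry in sorted(pkg.iterdir(), key=lambda p: p.name):
        if entry.name.endswith(".yaml"):
            model = CompoundModel.model_validate(yaml.safe_load(entry.read_text()))
            lib[model.name] = model
    return lib
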