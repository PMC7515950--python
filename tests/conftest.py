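import numpy as np
import pytest

import fedrapbpk as f
from fedrapbpk.population import FieldSpec, PopulationSpec


@pytest.fixture(scope="session")
def library():
    return f.builtin_library()


@pytest.fixture(scope="session")
def fedratinib(library):
    return library["fedratinib"]


@pytest.fixture(scope="session")
def healthy():
    return PopulationSpec()


@pytest.fixture(scope="session")
def subject(healthy):
    return f.central_subject(healthy)


def zero_cv_spec() -> PopulationSpec:
    """Population with all variability switched off."""
    spec = PopulationSpec()
    for name in ("body_weight", "liver_weight", "hepatic_blood_flow", "mppgl",
                 "gfr_scalar", "plasma_protein_scalar", "hematocrit"):
        field = getattr(spec, name)
        setattr(spec, name, FieldSpec(central=field.central, cv_percent=0))
    spec.enzyme_abundance = {
        e: FieldSpec(central=v.central, cv_percent=0) for e, v in spec.enzyme_abundance.items()
    }
    return spec


@pytest.fixture(scope="session")
def fast_liver_subject(subject):
    """Central subject with near-instant hepatic perfusion, so the liver
    compartment equilibrates with plasma and closed-form one/two-compartment
    oracles apply exactly (effective volume = central + liver)."""
    import dataclasses

    return dataclasses.replace(subject, hepatic_blood_flow=50000.0)


def one_compartment_compound(cl_renal=10.0, vss=None, ka=1.0, name="probe1c"):
    """Renal-only elimination, no peripheral compartment, fg = 1."""
    bw = 70.0
    if vss is None:
        vss = (100.0 - 1.65) / bw  # central + liver = 100 L
    return f.CompoundModel(
        name=name,
        mol_weight=400.0,
        fu_plasma=0.1,
        blood_plasma_ratio=1.0,
        ka=ka,
        fa=1.0,
        lag_time=0.0,
        fg_model="fixed_fg",
        fixed_fg=1.0,
        vss=vss,
        v_sac=0.0,
        q_sac=0.0,
        cl_renal=cl_renal,
        provenance="test construct",
    )
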