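"""Pre-configured virtual DDI studies for the fedratinib program.

Each builder returns a :class:`~fedrapbpk.trials.TrialDesign` mirroring the
clinical/simulated study designs the model was verified against:

* ketoconazole 200 mg BID with a fedratinib 300 mg single dose (victim);
* midazolam 2 mg single dose on top of fedratinib 500 mg QD at steady
  state (perpetrator, sensitive CYP3A4 index substrate);
* repaglinide 0.25 mg and S-warfarin 15 mg single doses on top of
  fedratinib 400 mg QD (perpetrator, CYP2C8/CYP2C9 probes);
* fedratinib 400 mg QD with ketoconazole at steady state (victim,
  repeated-dose scenario);
* fedratinib 400 mg QD accumulation (no perpetrator).

The default replication (10 trials x 10 subjects) matches the virtual
trial sizes used for the reported predictions; tests scale n down.
"""

from __future__ import annotations

from typing import Optional

from .calibration import FmTarget
from .engine import DosingEntry
from .population import PopulationSpec
from .trials import TrialDesign

#: First-dose fm/fe calibration target for fedratinib: the in-vitro
#: hepatocyte split (~63/17/2/18 CYP3A4/2C19/2D6/other of hepatic
#: clearance) refined so the residual non-CYP hepatic share is small,
#: with renal/biliary shares and the dose-normalized AUCinf anchored to
#: clinical estimates.
FEDRATINIB_FM_TARGET = FmTarget(
    fractions={
        "CYP3A4_liver": 0.636,
        "CYP2C19": 0.16,
        "CYP2D6": 0.02,
        "HLM_additional": 0.004,
        "renal": 0.11,
        "biliary": 0.07,
    },
    reference_dose_mg=400.0,
    dn_auc_inf=28.5,  # ng·h/mL per mg
)


def _base(n_trials: int, n_subjects: int, seed: int, population: Optional[PopulationSpec]):
    return {
        "n_trials": n_trials,
        "n_subjects_per_trial": n_subjects,
        "seed": seed,
        "population": population or PopulationSpec(),
    }


def ketoconazole_single_dose(
    n_trials: int = 10, n_subjects: int = 10, seed: int = 1,
    population: Optional[PopulationSpec] = None,
) -> TrialDesign:
    """Fedratinib 300 mg single dose +/- ketoconazole 200 mg BID.

    Ketoconazole starts 48 h before the fedratinib dose and continues
    through the 216-h victim sampling window (AUCinf metric).
    """
    return TrialDesign(
        victim="fedratinib",
        victim_entry=DosingEntry(
            compound="fedratinib", dose_mg=300.0, schedule="single", start_h=48.0
        ),
        perpetrator_entries=[
            DosingEntry(compound="ketoconazole", dose_mg=200.0, schedule="bid",
                        start_h=0.0, n_doses=21)
        ],
        metric="auc_inf",
        sampling_duration_h=216.0,
        **_base(n_trials, n_subjects, seed, population),
    )


def _perpetrator_design(
    victim: str, victim_dose: float, fed_dose: float, sampling_h: float,
    n_trials: int, n_subjects: int, seed: int, population: Optional[PopulationSpec],
) -> TrialDesign:
    run_in_h = 14 * 24.0
    n_doses = int((run_in_h + sampling_h) // 24.0) - 1
    return TrialDesign(
        victim=victim,
        victim_entry=DosingEntry(
            compound=victim, dose_mg=victim_dose, schedule="single", start_h=run_in_h
        ),
        perpetrator_entries=[
            DosingEntry(compound="fedratinib", dose_mg=fed_dose, schedule="qd",
                        start_h=0.0, n_doses=n_doses)
        ],
        metric="auc_inf",
        sampling_duration_h=sampling_h,
        **_base(n_trials, n_subjects, seed, population),
    )


def midazolam_cocktail(
    n_trials: int = 10, n_subjects: int = 10, seed: int = 1,
    population: Optional[PopulationSpec] = None,
) -> TrialDesign:
    """Midazolam 2 mg single dose +/- fedratinib 500 mg QD at steady state."""
    return _perpetrator_design("midazolam", 2.0, 500.0, 48.0,
                               n_trials, n_subjects, seed, population)


def repaglinide_study(
    n_trials: int = 10, n_subjects: int = 10, seed: int = 1,
    population: Optional[PopulationSpec] = None,
) -> TrialDesign:
    """Repaglinide 0.25 mg single dose +/- fedratinib 400 mg QD."""
    return _perpetrator_design("repaglinide", 0.25, 400.0, 48.0,
                               n_trials, n_subjects, seed, population)


def warfarin_study(
    n_trials: int = 10, n_subjects: int = 10, seed: int = 1,
    population: Optional[PopulationSpec] = None,
) -> TrialDesign:
    """S-warfarin 15 mg single dose +/- fedratinib 400 mg QD."""
    return _perpetrator_design("warfarin", 15.0, 400.0, 216.0,
                               n_trials, n_subjects, seed, population)


def fedratinib_ss_ketoconazole(
    n_trials: int = 10, n_subjects: int = 10, seed: int = 1,
    population: Optional[PopulationSpec] = None,
) -> TrialDesign:
    """Fedratinib 400 mg QD at steady state +/- ketoconazole 200 mg BID
    (repeated-dose victim scenario; AUCtau metric on the last dose)."""
    return TrialDesign(
        victim="fedratinib",
        victim_entry=DosingEntry(
            compound="fedratinib", dose_mg=400.0, schedule="qd", start_h=0.0, n_doses=21
        ),
        perpetrator_entries=[
            DosingEntry(compound="ketoconazole", dose_mg=200.0, schedule="bid",
                        start_h=168.0, n_doses=28)
        ],
        metric="auc_tau",
        sample_dose_index=-1,
        sampling_duration_h=24.0,
        **_base(n_trials, n_subjects, seed, population),
    )


def accumulation_study(
    n_trials: int = 10, n_subjects: int = 10, seed: int = 1,
    population: Optional[PopulationSpec] = None,
) -> TrialDesign:
    """Fedratinib 400 mg QD alone, for AUCtau accumulation (28 doses)."""
    return TrialDesign(
        victim="fedratinib",
        victim_entry=DosingEntry(compound="fedratinib", dose_mg=400.0, schedule="qd"),
        metric="auc_tau",
        **_base(n_trials, n_subjects, seed, population),
    )
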