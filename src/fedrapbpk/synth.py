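"""Synthetic "observed" concentration-time datasets.

Clinical mean profiles backing the calibration are not tabulated
anywhere re-usable, so this module manufactures datasets with the
statistical structure the analysis assumes: per-subject engine
simulations multiplied by log-normal residual error (the standard
proportional-error PK assumption), with the generating truth retained so
recovery studies can score themselves. Sampling grids mirror typical
rich-PK designs (dense to 12 h, out to 96+ h after single doses; 28-day
cycles with full profiles on cycle 1 day 1 and cycle 2 day 1 for
repeated dosing).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .compound import CompoundModel
from .engine import Regimen, simulate
from .population import PopulationSpec, central_subject, sample_population

DEFAULT_SINGLE_DOSE_TIMES = np.array(
    [0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 36.0, 48.0, 72.0, 96.0]
)


class SyntheticStudy(BaseModel):
    """Design of one synthetic observed dataset."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    compound: CompoundModel
    dose_mg: float = Field(gt=0)
    schedule: str = Field(default="single", pattern="^(single|qd|bid)$")
    n_doses: int = 1
    sampling_times: Optional[list] = None  # h after the sampled dose
    sample_dose_index: int = 0
    residual_cv_percent: float = Field(default=20.0, ge=0)
    n_subjects: int = Field(default=12, ge=1)
    population: PopulationSpec = Field(default_factory=PopulationSpec)
    #: when False, every "subject" is the central subject and only the
    #: residual error varies (mean-profile emulation)
    sample_physiology: bool = False
    seed: int = 0


def generate_observed(study: SyntheticStudy) -> tuple[pd.DataFrame, dict]:
    """Simulate the study and overlay log-normal residual noise.

    Returns a tidy table (subject_id, time_h, conc_ng_per_mL) plus a
    truth record carrying the generating parameters and the noise-free
    profile grid.
    """
    rng = np.random.default_rng(study.seed)
    times = np.asarray(study.sampling_times or DEFAULT_SINGLE_DOSE_TIMES, dtype=float)
    entry_builder = {"single": Regimen.single, "qd": Regimen.qd, "bid": Regimen.bid}
    name = study.compound.name
    if study.schedule == "single":
        entry = Regimen.single(name, study.dose_mg)
    else:
        entry = entry_builder[study.schedule](name, study.dose_mg, study.n_doses)
    t_dose = float(entry.dose_times()[study.sample_dose_index])
    t_end = t_dose + float(times[-1]) + 1e-6
    # doses after the sampling window do not influence it; truncate them so
    # the integration horizon ends with the window
    if entry.tau is not None:
        n_within = int(np.floor((t_end - entry.start_h) / entry.tau)) + 1
        entry = entry.model_copy(update={"n_doses": max(1, min(entry.n_doses, n_within))})
    tout = np.unique(np.concatenate([[0.0], np.arange(0.0, t_dose, 2.0), t_dose + times]))

    if study.sample_physiology:
        subjects = sample_population(study.population, study.n_subjects, seed=study.seed)
    else:
        subjects = [central_subject(study.population)] * study.n_subjects

    sigma = np.sqrt(np.log1p((study.residual_cv_percent / 100.0) ** 2))
    rows = []
    mean_profile = None
    shared = None  # identical central subjects need a single simulation
    for i, subj in enumerate(subjects):
        if study.sample_physiology or shared is None:
            res = simulate(
                subj, [study.compound], Regimen(entries=[entry]), t_end, output_times=tout
            )
            shared = res
        else:
            res = shared
        sel = np.isin(res.times, t_dose + times)
        clean = res.conc[name][sel]
        if mean_profile is None:
            mean_profile = clean
        noisy = clean * np.exp(sigma * rng.standard_normal(len(clean)))
        rows.append(
            pd.DataFrame(
                {"subject_id": i, "time_h": times, "conc_ng_per_mL": noisy}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    truth = {
        "compound": study.compound.to_dict(),
        "dose_mg": study.dose_mg,
        "schedule": study.schedule,
        "n_doses": study.n_doses,
        "sample_dose_index": study.sample_dose_index,
        "residual_cv_percent": study.residual_cv_percent,
        "seed": study.seed,
        "sampling_times_h": times.tolist(),
        "noise_free_profile_ng_per_mL": np.asarray(mean_profile).tolist(),
    }
    return table, truth


def make_fixture_suite(seed: int, out_dir: str | Path, compound: CompoundModel,
                       n_subjects: int = 8) -> dict:
    """Write the standard synthetic study suite as CSV + JSON truth files.

    Single-dose 300/500 mg studies and repeated-dose 300/400/500 mg QD
    studies with profiles on day 1 and day 29 of consecutive 28-day
    cycles. Regenerates byte-identically for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    studies = []
    for dose in (300, 500):
        studies.append((f"single_{dose}mg", SyntheticStudy(
            compound=compound, dose_mg=dose, schedule="single",
            n_subjects=n_subjects, seed=seed + dose,
        )))
    for dose in (300, 400, 500):
        for label, idx in (("day1", 0), ("day29", 28)):
            studies.append((f"qd_{dose}mg_{label}", SyntheticStudy(
                compound=compound, dose_mg=dose, schedule="qd", n_doses=29,
                sample_dose_index=idx, seed=seed + dose + idx,
                sampling_times=[0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24],
                n_subjects=n_subjects,
            )))
    for name, study in studies:
        table, truth = generate_observed(study)
        csv_path = out_dir / f"{name}.csv"
        table.to_csv(csv_path, index=False, float_format="%.6g")
        (out_dir / f"{name}.truth.json").write_text(json.dumps(truth, indent=1))
        manifest[name] = str(csv_path)
    return manifest
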