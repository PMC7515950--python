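"""Virtual-trial DDI studies: paired arms, GM ratios, PSA, scenarios.

A DDI study simulates every virtual subject twice — victim alone and
victim + perpetrator — with identical physiology and seeds (paired,
crossover-style design), then summarises geometric-mean exposure and the
GM ratio of the co-administration arm over the alone arm. The 90% CI is a
t-interval on the log scale across all subjects pooled over trials (the
per-arm n is carried in the summary).

The AUC metric follows the study design: AUCinf for single-dose victims,
AUCtau at steady state for QD victims.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .calibration import NCAResult, accumulation_ratio, nca
from .compound import CompoundModel, EnzymeId
from .engine import DosingEntry, Regimen, simulate
from .population import PopulationSpec, Subject, central_subject, sample_population

logger = logging.getLogger(__name__)


class TrialDesign(BaseModel):
    """Replicated virtual-trial design for one victim/perpetrator pair."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    n_trials: int = Field(default=10, ge=1)
    n_subjects_per_trial: int = Field(default=10, ge=1)
    population: PopulationSpec = Field(default_factory=PopulationSpec)
    victim: str
    victim_entry: DosingEntry
    perpetrator_entries: List[DosingEntry] = Field(default_factory=list)
    metric: str = Field(default="auc_inf", pattern="^(auc_inf|auc_tau)$")
    #: which victim dose the PK profile is sampled from (0 first, -1 last)
    sample_dose_index: int = -1
    #: hours of sampling after that dose (sets t_end)
    sampling_duration_h: float = 216.0
    seed: int = 1
    failure_policy: str = Field(default="fail", pattern="^(fail|drop)$")
    solver_opts: Optional[dict] = None


@dataclasses.dataclass
class ArmStats:
    gm_cmax: float
    sd_cmax: float
    gm_auc: float
    sd_auc: float
    n: int


@dataclasses.dataclass
class DDISummary:
    """Per-arm exposure statistics and paired GM ratios with 90% CI."""

    victim: str
    metric: str
    alone: ArmStats
    combo: Optional[ArmStats]
    ratio_auc: Optional[tuple]  # (gm, lo90, hi90)
    ratio_cmax: Optional[tuple]
    n_subjects: int
    n_trials: int
    per_subject: pd.DataFrame

    def prediction_errors(self, observed: Dict[str, float]) -> Dict[str, float]:
        """Signed PE% vs observed GMs, e.g. {'ratio_auc': 3.06}."""
        out = {}
        for key, obs in observed.items():
            val = getattr(self, key)
            val = val[0] if isinstance(val, tuple) else val
            out[key] = prediction_error(val, obs)
        return out


def prediction_error(gm_pred: float, gm_obs: float) -> float:
    """PE = (GM_prediction − GM_observation) / GM_observation × 100%."""
    if gm_obs == 0:
        raise ValueError("observed geometric mean must be non-zero")
    return (gm_pred - gm_obs) / gm_obs * 100.0


def _gm_ci(values: np.ndarray, level: float = 0.90):
    logs = np.log(values)
    gm = float(np.exp(logs.mean()))
    n = len(logs)
    if n < 2 or np.allclose(logs.std(ddof=1), 0):
        return gm, gm, gm
    se = logs.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2, n - 1)
    return gm, float(np.exp(logs.mean() - tcrit * se)), float(np.exp(logs.mean() + tcrit * se))


def _arm_stats(cmax: np.ndarray, auc: np.ndarray) -> ArmStats:
    return ArmStats(
        gm_cmax=float(np.exp(np.mean(np.log(cmax)))),
        sd_cmax=float(np.std(cmax, ddof=1)) if len(cmax) > 1 else 0.0,
        gm_auc=float(np.exp(np.mean(np.log(auc)))),
        sd_auc=float(np.std(auc, ddof=1)) if len(auc) > 1 else 0.0,
        n=len(cmax),
    )


def _sampling_grid(t_dose: float, duration: float) -> np.ndarray:
    """Rich PK grid after one dose: 15-min early, coarsening later."""
    rel = np.unique(
        np.concatenate(
            [
                np.arange(0.0, 12.0, 0.25),
                np.arange(12.0, 48.0, 0.5),
                np.arange(48.0, duration + 1e-9, 2.0),
            ]
        )
    )
    rel = rel[rel <= duration + 1e-9]
    return t_dose + rel


def _coarse_grid(t0: float, t1: float) -> np.ndarray:
    if t1 <= t0:
        return np.array([])
    return np.arange(t0, t1, 2.0)


def _simulate_arm(
    subject: Subject,
    victim_model: CompoundModel,
    perp_models: List[CompoundModel],
    victim_entry: DosingEntry,
    perp_entries: List[DosingEntry],
    design: TrialDesign,
) -> NCAResult:
    t_doses = victim_entry.dose_times()
    t_sample = float(t_doses[design.sample_dose_index])
    t_end = t_sample + design.sampling_duration_h
    grid = _sampling_grid(t_sample, design.sampling_duration_h)
    tout = np.unique(np.concatenate([_coarse_grid(0.0, t_sample), grid]))
    entries = [victim_entry] + list(perp_entries)
    reg = Regimen(entries=entries)
    res = simulate(
        subject,
        [victim_model] + perp_models,
        reg,
        t_end,
        output_times=tout,
        solver_opts=design.solver_opts,
    )
    m = res.times >= t_sample - 1e-9
    tau = victim_entry.tau
    return nca(res.times[m] - t_sample, res.conc[victim_model.name][m], tau=tau)


def run_trials(design: TrialDesign, compounds: Dict[str, CompoundModel]) -> DDISummary:
    """Run paired alone/co-administration arms over all virtual subjects."""
    victim_model = compounds[design.victim]
    # a perpetrator with zero dose cannot perturb the system; dropping it
    # keeps the paired arms bit-identical (ratios exactly 1)
    perp_entries = [e for e in design.perpetrator_entries if e.dose_mg > 0]
    perp_models = [compounds[e.compound] for e in perp_entries]
    n_total = design.n_trials * design.n_subjects_per_trial
    subjects = sample_population(design.population, n_total, seed=design.seed)

    rows = []
    for i, subj in enumerate(subjects):
        try:
            alone = _simulate_arm(subj, victim_model, [], design.victim_entry, [], design)
            combo = None
            if design.perpetrator_entries:
                combo = _simulate_arm(
                    subj, victim_model, perp_models, design.victim_entry, perp_entries, design
                )
        except Exception:
            if design.failure_policy == "fail":
                raise
            logger.warning("subject %d failed; dropped", i)
            continue
        metric = design.metric
        row = {
            "subject": i,
            "trial": i // design.n_subjects_per_trial,
            "cmax_alone": alone.cmax,
            "auc_alone": getattr(alone, metric),
        }
        if combo is not None:
            row["cmax_combo"] = combo.cmax
            row["auc_combo"] = getattr(combo, metric)
        rows.append(row)
    per_subject = pd.DataFrame(rows)
    if per_subject.empty or per_subject["auc_alone"].isna().any():
        raise RuntimeError("trial produced missing exposure metrics")

    alone_stats = _arm_stats(per_subject["cmax_alone"].values, per_subject["auc_alone"].values)
    combo_stats = ratio_auc = ratio_cmax = None
    if design.perpetrator_entries:
        combo_stats = _arm_stats(per_subject["cmax_combo"].values, per_subject["auc_combo"].values)
        ratio_auc = _gm_ci((per_subject["auc_combo"] / per_subject["auc_alone"]).values)
        ratio_cmax = _gm_ci((per_subject["cmax_combo"] / per_subject["cmax_alone"]).values)
    return DDISummary(
        victim=design.victim,
        metric=design.metric,
        alone=alone_stats,
        combo=combo_stats,
        ratio_auc=ratio_auc,
        ratio_cmax=ratio_cmax,
        n_subjects=n_total,
        n_trials=design.n_trials,
        per_subject=per_subject,
    )


def run_accumulation(
    design: TrialDesign, compounds: Dict[str, CompoundModel], n_doses: int = 28
) -> pd.DataFrame:
    """Per-subject first-dose vs steady-state AUCtau/Cmax for a QD victim.

    Returns a frame with per-subject accumulation ratios; the GM of
    ``racc_auc`` is the study-level AUC accumulation ratio.
    """
    victim_model = compounds[design.victim]
    tau = 24.0
    entry = DosingEntry(
        compound=design.victim,
        dose_mg=design.victim_entry.dose_mg,
        schedule="qd",
        n_doses=n_doses,
    )
    n_total = design.n_trials * design.n_subjects_per_trial
    subjects = sample_population(design.population, n_total, seed=design.seed)
    fine = np.arange(0.0, tau + 1e-9, 0.25)
    t_last = (n_doses - 1) * tau
    tout = np.unique(np.concatenate([fine, np.arange(tau, t_last, 2.0), t_last + fine]))
    rows = []
    for i, subj in enumerate(subjects):
        res = simulate(
            subj,
            [victim_model],
            Regimen(entries=[entry]),
            n_doses * tau,
            output_times=tout,
            solver_opts=design.solver_opts,
        )
        c = res.conc[design.victim]
        m1 = res.times <= tau + 1e-9
        first = nca(res.times[m1], c[m1], tau=tau)
        m2 = res.times >= t_last - 1e-9
        ss = nca(res.times[m2] - t_last, c[m2], tau=tau)
        rows.append(
            {
                "subject": i,
                "trial": i // design.n_subjects_per_trial,
                "auc_tau_first": first.auc_tau,
                "auc_tau_ss": ss.auc_tau,
                "cmax_first": first.cmax,
                "cmax_ss": ss.cmax,
                "racc_auc": accumulation_ratio(first, ss),
                "racc_cmax": ss.cmax / first.cmax,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter sensitivity analysis
# ---------------------------------------------------------------------------


def _resolve(obj, parts: List[str]):
    for j, part in enumerate(parts[:-1]):
        if isinstance(obj, dict):
            key = EnzymeId(part) if part in EnzymeId.__members__ else part
            obj = obj[key]
        else:
            obj = getattr(obj, part)
    return obj


def set_param(model: CompoundModel, path: str, value: float) -> CompoundModel:
    """Return a copy of ``model`` with the dotted-path parameter replaced."""
    out = model.model_copy(deep=True)
    parts = path.split(".")
    parent = _resolve(out, parts)
    leaf = parts[-1]
    if isinstance(parent, dict):
        key = EnzymeId(leaf) if leaf in EnzymeId.__members__ else leaf
        if not isinstance(parent[key], (int, float)):
            raise TypeError(f"{path} is not numeric")
        parent[key] = value
    else:
        current = getattr(parent, leaf)
        if current is not None and not isinstance(current, (int, float)):
            raise TypeError(f"{path} is not numeric")
        setattr(parent, leaf, value)
    return CompoundModel.model_validate(out.model_dump())


def get_param(model: CompoundModel, path: str) -> float:
    parts = path.split(".")
    parent = _resolve(model, parts)
    leaf = parts[-1]
    if isinstance(parent, dict):
        key = EnzymeId(leaf) if leaf in EnzymeId.__members__ else leaf
        return parent[key]
    return getattr(parent, leaf)


def psa(
    design: TrialDesign,
    compounds: Dict[str, CompoundModel],
    compound_name: str,
    parameter_path: str,
    values: Sequence[float],
) -> pd.DataFrame:
    """One full (seed-matched) trial set per parameter value.

    Returns a table of AUC and Cmax GM ratios versus the varied value.
    """
    rows = []
    for v in values:
        mods = dict(compounds)
        mods[compound_name] = set_param(compounds[compound_name], parameter_path, float(v))
        summ = run_trials(design, mods)
        rows.append(
            {
                "value": float(v),
                "auc_ratio": summ.ratio_auc[0] if summ.ratio_auc else np.nan,
                "cmax_ratio": summ.ratio_cmax[0] if summ.ratio_cmax else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dose re-escalation scenario
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PhaseExposure:
    name: str
    dose_mg: float
    start_h: float
    stop_h: float
    auc_tau: float
    cmax: float


def dose_reescalation_scenario(
    compounds: Dict[str, CompoundModel],
    population: Optional[PopulationSpec] = None,
    victim: str = "fedratinib",
    inhibitor: str = "ketoconazole",
    phase1_dose: float = 200.0,
    phase2_dose: float = 300.0,
    phase3_dose: float = 400.0,
    phase_days: tuple = (14, 14, 21),
    inhibitor_dose: float = 200.0,
    solver_opts: Optional[dict] = None,
):
    """Strong-inhibitor washout schedule with stepwise dose re-escalation.

    Phase 1: reduced victim dose QD + inhibitor BID; the inhibitor stops
    at the end of phase 1; phase 2 steps the victim up for two weeks while
    the inactivated enzyme pool regenerates (rate kdeg); phase 3 restores
    the full dose. Returns the full simulation plus per-phase end-of-phase
    AUCtau/Cmax and the enzyme-recovery trajectory.
    """
    pop = population or PopulationSpec()
    subject = central_subject(pop)
    d1, d2, d3 = phase_days
    t1, t2, t3 = d1 * 24.0, (d1 + d2) * 24.0, (d1 + d2 + d3) * 24.0
    if not (0 < t1 < t2 < t3):
        raise ValueError("phase schedule overlaps or is empty")
    entries = [
        Regimen.qd(victim, phase1_dose, d1, start_h=0.0),
        Regimen.qd(victim, phase2_dose, d2, start_h=t1),
        Regimen.qd(victim, phase3_dose, d3, start_h=t2),
        Regimen.bid(inhibitor, inhibitor_dose, 2 * d1, start_h=0.0),
    ]
    fine = np.arange(0.0, 24.0 + 1e-9, 0.5)
    tout = np.unique(
        np.concatenate(
            [np.arange(0.0, t3, 2.0), (t1 - 24.0) + fine, (t2 - 24.0) + fine, (t3 - 24.0) + fine]
        )
    )
    res = simulate(
        subject,
        [compounds[victim], compounds[inhibitor]],
        Regimen(entries=entries),
        t3,
        output_times=tout,
        solver_opts=solver_opts,
    )
    phases = []
    for name, dose, t_lo, t_hi in [
        ("with_inhibitor", phase1_dose, 0.0, t1),
        ("step_up", phase2_dose, t1, t2),
        ("full_dose", phase3_dose, t2, t3),
    ]:
        m = (res.times >= t_hi - 24.0 - 1e-9) & (res.times <= t_hi + 1e-9)
        metrics = nca(res.times[m] - (t_hi - 24.0), res.conc[victim][m], tau=24.0)
        phases.append(
            PhaseExposure(
                name=name,
                dose_mg=dose,
                start_h=t_lo,
                stop_h=t_hi,
                auc_tau=metrics.auc_tau,
                cmax=metrics.cmax,
            )
        )
    return res, phases
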