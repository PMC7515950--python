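"""Dose-adjustment (label) logic from steady-state DDI magnitude.

Perpetrator classes follow regulatory convention on a sensitive index
substrate: strong >= 5x, moderate 2-5x, weak 1.25-2x AUC increase. The
dose rule itself keys off the victim's steady-state AUC ratio: about
twofold with a strong CYP3A4 inhibitor supports reducing the 400 mg QD
dose to 200 mg, while increases below ~20% support maintaining 400 mg.
"""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass
class LabelRecommendation:
    scenario: str
    recommended_dose_mg: int  # one of 200, 300, 400
    rationale: str


def classify_inhibitor(index_auc_ratio: float) -> str:
    """Regulatory class from the AUC ratio on a sensitive index substrate."""
    if index_auc_ratio >= 5.0:
        return "strong"
    if index_auc_ratio >= 2.0:
        return "moderate"
    if index_auc_ratio >= 1.25:
        return "weak"
    if index_auc_ratio > 0.8:
        return "none"
    return "inducer"


def recommend_dose(
    ss_auc_ratio: float,
    scenario: str = "co-administration",
    reduce_threshold: float = 2.0,
    maintain_threshold: float = 1.2,
) -> LabelRecommendation:
    """Dose recommendation from the victim's steady-state AUC ratio.

    Ratio >= ``reduce_threshold`` (strong-inhibitor magnitude) -> 200 mg;
    ratio < ``maintain_threshold`` -> maintain 400 mg; in between -> the
    intermediate 300 mg step. A ratio exactly at a threshold takes the
    more conservative (lower-dose) branch.
    """
    if ss_auc_ratio is None or ss_auc_ratio <= 0:
        raise ValueError("steady-state AUC ratio unavailable")
    if ss_auc_ratio >= reduce_threshold:
        dose = 200
        why = f"SS AUC ratio {ss_auc_ratio:.2f} >= {reduce_threshold:g} (strong-inhibitor magnitude)"
    elif ss_auc_ratio < maintain_threshold:
        dose = 400
        why = f"SS AUC ratio {ss_auc_ratio:.2f} < {maintain_threshold:g}; exposure increase small"
    else:
        dose = 300
        why = f"SS AUC ratio {ss_auc_ratio:.2f} in [{maintain_threshold:g}, {reduce_threshold:g})"
    return LabelRecommendation(scenario=scenario, recommended_dose_mg=dose, rationale=why)
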