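"""Actuarial diagnosis and biomarker staging at baseline.

The Jak/Bondi actuarial rules label a participant MCI when either

1. two tests within one cognitive domain fall more than 1 SD below the
   demographically corrected normative mean (z < -1), or
2. at least one test in each of the three domains does.

Cognitively normal participants who are positive on any AD biomarker
(CSF pTau181/Abeta42 ratio at or above the cutpoint, amyloid PET, or tau
PET) are staged preclinical AD; a dementia flag excludes the participant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: three domains, two tests each: the fixed default battery
DEFAULT_DOMAINS: dict[str, list[str]] = {
    "speed_executive": ["tmt_a", "tmt_b"],
    "language": ["category_fluency", "bnt"],
    "memory": ["ravlt_delayed_recall", "ravlt_recognition"],
}

CN = "CN"
PRECLINICAL = "PreclinicalAD"
MCI = "MCI"
EXCLUDED_DEMENTIA = "ExcludedDementia"
UNKNOWN = "Unknown"


@dataclass(frozen=True)
class PositivityCutpoints:
    csf_ratio_cutpoint: float = 0.025

    def __post_init__(self):
        if not self.csf_ratio_cutpoint > 0:
            raise ValueError("csf_ratio_cutpoint must be > 0")


def _validate_domains(domains: dict[str, list[str]]) -> None:
    seen: dict[str, str] = {}
    for dom, tests in domains.items():
        for t in tests:
            if t in seen:
                raise ValueError(
                    f"test '{t}' appears in both '{seen[t]}' and '{dom}'")
            seen[t] = dom


def classify_mci(z_baseline: pd.DataFrame,
                 domains: dict[str, list[str]] | None = None,
                 threshold: float = -1.0) -> pd.DataFrame:
    """Apply the actuarial rules to a participants x tests baseline z table.

    Returns a frame indexed like ``z_baseline`` with columns ``label``
    (CN/MCI), ``rule_trace``, and ``complete`` (False rows lack one of the
    six z-scores and are excluded from labeling, logged).
    """
    domains = domains if domains is not None else DEFAULT_DOMAINS
    _validate_domains(domains)
    tests = [t for ts in domains.values() for t in ts]
    missing_cols = [t for t in tests if t not in z_baseline.columns]
    if missing_cols:
        raise ValueError(f"z table lacks tests: {missing_cols}")

    z = z_baseline[tests]
    complete = z.notna().all(axis=1)
    n_excl = int((~complete).sum())
    if n_excl:
        logger.info("classify_mci: %d participants with incomplete baseline "
                    "z-scores excluded", n_excl)

    impaired = z < threshold
    labels, traces = [], []
    for pid, row in impaired.iterrows():
        if not complete.loc[pid]:
            labels.append(UNKNOWN)
            traces.append("incomplete baseline z-scores")
            continue
        two_within = [d for d, ts in domains.items() if row[ts].sum() >= 2]
        one_each = all(row[ts].sum() >= 1 for ts in domains.values())
        if two_within:
            labels.append(MCI)
            traces.append("two impaired tests within domain(s): "
                          + ", ".join(two_within))
        elif one_each:
            labels.append(MCI)
            traces.append("one impaired test in each of the three domains")
        else:
            labels.append(CN)
            traces.append("neither actuarial clause met")
    return pd.DataFrame({"label": labels, "rule_trace": traces,
                         "complete": complete.to_numpy()},
                        index=z_baseline.index)


def stage_baseline(cognitive_labels: pd.DataFrame,
                   baseline_visits: pd.DataFrame,
                   cutpoints: PositivityCutpoints | None = None) -> pd.DataFrame:
    """Combine actuarial labels with biomarker positivity into stage labels.

    ``cognitive_labels``: output of :func:`classify_mci`, indexed by
    participant_id. ``baseline_visits``: one row per participant with the
    biomarker, dementia flag and optional PET flags.
    Returns one row per participant: ``label`` in {CN, PreclinicalAD, MCI,
    ExcludedDementia, Unknown}, ``rule_trace``, ``biomarker_positive``,
    ``positivity_source``.
    """
    cutpoints = cutpoints or PositivityCutpoints()
    base = baseline_visits.set_index("participant_id")
    out = []
    for pid, row in cognitive_labels.iterrows():
        b = base.loc[pid]
        ratio = b.get("csf_ptau_abeta_ratio")
        amyl = b.get("amyloid_pet_positive")
        tau = b.get("tau_pet_positive")
        csf_pos = pd.notna(ratio) and ratio >= cutpoints.csf_ratio_cutpoint
        amyl_pos = pd.notna(amyl) and bool(amyl)
        tau_pos = pd.notna(tau) and bool(tau)
        positive = csf_pos or amyl_pos or tau_pos
        source = ("csf_ratio" if csf_pos else
                  "amyloid_pet" if amyl_pos else
                  "tau_pet" if tau_pos else "")
        any_data = pd.notna(ratio) or pd.notna(amyl) or pd.notna(tau)

        if bool(b.get("dementia_flag", False)):
            label, trace = EXCLUDED_DEMENTIA, "dementia flag set"
        elif row["label"] == MCI:
            label, trace = MCI, row["rule_trace"]
        elif row["label"] == CN:
            if not any_data:
                label, trace = UNKNOWN, "CN with no biomarker data"
                logger.info("participant %s: CN with no biomarker data; "
                            "staged Unknown and excluded", pid)
            elif positive:
                label = PRECLINICAL
                trace = f"CN and biomarker positive ({source})"
            else:
                label, trace = CN, "CN and biomarker negative"
        else:
            label, trace = UNKNOWN, row["rule_trace"]
        out.append({"participant_id": pid, "label": label, "rule_trace": trace,
                    "biomarker_positive": positive,
                    "positivity_source": source})
    return pd.DataFrame(out).set_index("participant_id")


def restrict_biomarker_positive_mci(stages: pd.DataFrame) -> pd.Index:
    """Sensitivity-analysis sample: preclinical plus biomarker-positive MCI."""
    keep = (stages["label"] == PRECLINICAL) | (
        (stages["label"] == MCI) & stages["biomarker_positive"])
    n_mci = int(((stages["label"] == MCI) & stages["biomarker_positive"]).sum())
    if n_mci == 0 and (stages["label"] == MCI).any():
        logger.warning("restrict_biomarker_positive_mci: no biomarker-positive "
                       "MCI participants remain; group models will be skipped")
    return stages.index[keep]
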