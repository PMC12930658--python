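"""Simulation studies: parameter recovery, type-I error, stratified patterns.

These drivers exercise the estimator against the simulator's own truth.
They build the analysis table from the latent-truth stage labels (the
sidecar the pipeline itself never consumes), which isolates the mixed-model
machinery from actuarial misclassification; full-pipeline behaviour with
estimated stages is exercised separately by the pipeline module and tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .change import (assemble_analysis_table, build_memory_composite,
                     compute_lagged_residuals)
from .models import ModelSpec, fit_interaction_model, fit_stratified_models
from .simulate import Cohort, SimulationConfig, simulate_cohort, with_coupling

logger = logging.getLogger(__name__)

THREE_WAY_TERM = "biomarker_change:sex_male:group_mci"


def truth_analysis_table(cohort: Cohort,
                         secondary: bool = False) -> pd.DataFrame:
    """Analysis table using the simulator's true stage labels."""
    visits = cohort.visits[~cohort.visits["is_robust_control"]]
    truth0 = cohort.truth[cohort.truth["visit_index"] == 0]
    truth0 = truth0[truth0["true_stage"] != "control"]
    group = (truth0.set_index("participant_id")["true_stage"] == "mci")

    comp = build_memory_composite(visits)
    merged = visits.merge(comp, on=["participant_id", "visit_index"])
    variables = ["memory_composite", "csf_ptau_abeta_ratio"]
    if secondary:
        variables += ["tmt_b", "cdr_sb"]
    changes, _ = compute_lagged_residuals(merged, variables)
    return assemble_analysis_table(visits, group, comp, changes)


def scaled_down_config(seed: int = 0, cell_scale: float = 0.25,
                       visits: int = 4) -> SimulationConfig:
    """Smaller cohort with the same cell proportions, for replicate-heavy
    studies (null rejection rates)."""
    base = SimulationConfig(seed=seed)
    return replace(
        base,
        n_preclinical_f=max(5, round(base.n_preclinical_f * cell_scale)),
        n_preclinical_m=max(5, round(base.n_preclinical_m * cell_scale)),
        n_mci_f=max(5, round(base.n_mci_f * cell_scale)),
        n_mci_m=max(5, round(base.n_mci_m * cell_scale)),
        n_robust_controls=0,
        visits_per_participant=visits,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    estimates: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    truth: float

    @property
    def mean_estimate(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def mc_ci(self) -> tuple[float, float]:
        """95% Monte-Carlo CI for the mean estimate."""
        se = np.std(self.estimates, ddof=1) / np.sqrt(len(self.estimates))
        m = self.mean_estimate
        return (m - 1.96 * se, m + 1.96 * se)

    @property
    def coverage(self) -> float:
        return float(np.mean((self.ci_low <= self.truth)
                             & (self.truth <= self.ci_high)))

    @property
    def rejection_rate(self) -> float:
        return float(np.mean(self.pvalues < 0.05))


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def recover_three_way(config: SimulationConfig | None = None,
                      truth_value: float = -16.0,
                      n_reps: int = 200,
                      seed: int = 0) -> RecoveryResult:
    """Parameter-recovery study for the 3-way interaction coefficient.

    Simulates ``n_reps`` cohorts whose generative 3-way coupling equals
    ``truth_value``, runs the composite/lagged-residual/LMM machinery on
    each, and collects the estimated coefficient, its Wald CI and p-value.
    """
    base = config or SimulationConfig(n_robust_controls=0)
    base = with_coupling(base, biomarker_x_sex_x_group=truth_value)
    est, lo, hi, pv = [], [], [], []
    for s in _child_seeds(seed, n_reps):
        cohort = simulate_cohort(replace(base, seed=int(s)))
        tab = truth_analysis_table(cohort)
        res = fit_interaction_model(tab, ModelSpec(standardized=False))
        c = res.coef(THREE_WAY_TERM)
        est.append(c["b"]); lo.append(c["ci_low"]); hi.append(c["ci_high"])
        pv.append(c["p"])
    return RecoveryResult(np.array(est), np.array(lo), np.array(hi),
                          np.array(pv), truth_value)


def null_three_way(config: SimulationConfig | None = None,
                   n_reps: int = 1000,
                   seed: int = 0) -> RecoveryResult:
    """Type-I-error study: all generative interaction couplings set to zero;
    returns the rejection-rate machinery for the 3-way term at alpha=.05."""
    base = config or scaled_down_config()
    base = with_coupling(base, biomarker_x_sex=0.0, biomarker_x_group=0.0,
                         biomarker_x_sex_x_group=0.0)
    est, lo, hi, pv = [], [], [], []
    for s in _child_seeds(seed, n_reps):
        cohort = simulate_cohort(replace(base, seed=int(s)))
        tab = truth_analysis_table(cohort)
        res = fit_interaction_model(tab, ModelSpec(standardized=False))
        c = res.coef(THREE_WAY_TERM)
        est.append(c["b"]); lo.append(c["ci_low"]); hi.append(c["ci_high"])
        pv.append(c["p"])
    return RecoveryResult(np.array(est), np.array(lo), np.array(hi),
                          np.array(pv), 0.0)


@dataclass
class StratifiedStudyResult:
    mci_b: np.ndarray
    mci_p: np.ndarray
    pre_ci_low: np.ndarray
    pre_ci_high: np.ndarray

    @property
    def mci_significant_negative_rate(self) -> float:
        return float(np.mean((self.mci_b < 0) & (self.mci_p < 0.05)))

    @property
    def pre_ci_covers_zero_rate(self) -> float:
        return float(np.mean((self.pre_ci_low <= 0) & (0 <= self.pre_ci_high)))


def stratified_coupling_study(mci_slope: float = -15.0,
                              n_reps: int = 25,
                              seed: int = 0,
                              config: SimulationConfig | None = None) -> StratifiedStudyResult:
    """Generator encodes a biomarker->memory coupling only in the MCI
    stratum; collects the stratified biomarker main-effect estimates."""
    base = config or scaled_down_config(cell_scale=0.5, visits=5)
    base = with_coupling(base, biomarker=0.0, biomarker_x_sex=0.0,
                         biomarker_x_group=mci_slope,
                         biomarker_x_sex_x_group=0.0)
    mci_b, mci_p, plo, phi = [], [], [], []
    for s in _child_seeds(seed, n_reps):
        cohort = simulate_cohort(replace(base, seed=int(s)))
        tab = truth_analysis_table(cohort)
        strat = fit_stratified_models(tab, by="group",
                                      spec=ModelSpec(standardized=False))
        cm = strat["mci"].coef("biomarker_change")
        cp = strat["preclinical"].coef("biomarker_change")
        mci_b.append(cm["b"]); mci_p.append(cm["p"])
        plo.append(cp["ci_low"]); phi.append(cp["ci_high"])
    return StratifiedStudyResult(np.array(mci_b), np.array(mci_p),
                                 np.array(plo), np.array(phi))
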