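"""Synthetic longitudinal cohort generator.

Emulates an ADNI-like observational sample: two baseline disease stages
(preclinical AD = cognitively normal but CSF-biomarker positive; MCI by
actuarial criteria) followed roughly annually for several years, plus a
robust normal control group used only to fit normative regressions.

The generative model, per participant i with visits t = 0..T-1:

* CSF pTau181/Abeta42 ratio follows a random walk with a participant-level
  drift: ``B_it = B_i,t-1 + drift_i + e_it``.
* A latent verbal-memory level M evolves by increments

  ``dM_it = practice[stage] + g_sex*male + g_group*mci
            + (g_B + g_BxS*male + g_BxG*mci + g_BxSxG*male*mci) * dB_it
            + u_i + eps_it``

  where u_i is a participant random intercept on the increment mean (the
  generative counterpart of the random intercept in the change-score mixed
  model) and eps_it is increment noise.
* Observed test scores are affine maps of the relevant latent plus
  demographic terms and test noise, clipped to their published ranges;
  timed tests (Trail-Making) decrease with better function.

A separate latent drives the non-memory tests; true-MCI participants carry a
deep deficit there so the actuarial rules identify them, while the memory
latent follows the stage/sex cell structure of the observed-data tables.

The latent truth is emitted in a sidecar table that the analysis pipeline
never consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("preclinical", "mci", "control")
SEXES = ("female", "male")

#: canonical long-format column order for the visit table
VISIT_COLUMNS = [
    "participant_id", "visit_index", "age_at_visit", "years_from_baseline",
    "sex", "education", "income", "apoe_e4_carrier",
    "csf_ptau_abeta_ratio",
    "tmt_a", "tmt_b", "category_fluency", "bnt",
    "ravlt_learning", "ravlt_delayed_recall", "ravlt_recognition",
    "cdr_sb", "dementia_flag",
    "amyloid_pet_positive", "tau_pet_positive",
    "is_robust_control",
]

#: ADNIMERGE-style aliases accepted when ingesting external CSVs
COLUMN_ALIASES = {
    "RID": "participant_id",
    "VISCODE": "visit_index",
    "AGE": "age_at_visit",
    "PTGENDER": "sex",
    "PTEDUCAT": "education",
    "APOE4": "apoe_e4_carrier",
    "TRAASCOR": "tmt_a",
    "TRABSCOR": "tmt_b",
    "CATANIMSC": "category_fluency",
    "BNTTOTAL": "bnt",
    "RAVLT_learning": "ravlt_learning",
    "AVDEL30MIN": "ravlt_delayed_recall",
    "AVDELTOT": "ravlt_recognition",
    "CDRSB": "cdr_sb",
}


@dataclass(frozen=True)
class TestSpec:
    """Affine observation model mapping a latent level to a raw test score."""

    base: float
    load: float              # score units per latent z-unit (signed)
    beta_age: float          # per year of baseline age (centered at 74)
    beta_male: float
    beta_educ: float         # per year of education (centered at 16)
    noise_sd: float          # test noise, in latent z-units
    lo: float
    hi: float
    higher_is_better: bool
    latent: str              # "memory" or "exec"


# Loadings/demographic gradients are on the scale of published ADNI test
# distributions. The RAVLT Learning / Delayed Recall noise SDs are calibrated
# so the pooled raw-score SD over the default analysis population equals the
# loading: the in-sample-standardized memory composite is then on the latent
# memory scale, so generative coupling coefficients are directly comparable
# to fitted ones (see docs/methods.md).
TEST_BATTERY: Mapping[str, TestSpec] = {
    "tmt_a": TestSpec(36.0, -9.0, 0.50, 1.0, -0.40, 0.45, 0.0, 300.0, False, "exec"),
    "tmt_b": TestSpec(95.0, -30.0, 1.20, 2.0, -2.00, 0.40, 0.0, 300.0, False, "exec"),
    "category_fluency": TestSpec(19.0, 4.0, -0.15, 0.5, 0.30, 0.45, 0.0, 60.0, True, "exec"),
    "bnt": TestSpec(26.5, 1.6, -0.05, 0.3, 0.20, 0.40, 0.0, 30.0, True, "exec"),
    "ravlt_learning": TestSpec(42.0, 9.0, -0.25, -3.0, 0.60, 0.18, 0.0, 75.0, True, "memory"),
    "ravlt_delayed_recall": TestSpec(6.5, 2.2, -0.06, -0.7, 0.15, 0.19, 0.0, 15.0, True, "memory"),
    "ravlt_recognition": TestSpec(12.5, 1.2, -0.04, -0.4, 0.05, 0.50, 0.0, 15.0, True, "memory"),
}

#: six tests entering the actuarial diagnosis (recognition, not learning)
DIAGNOSTIC_TESTS = [
    "tmt_a", "tmt_b", "category_fluency", "bnt",
    "ravlt_delayed_recall", "ravlt_recognition",
]


@dataclass(frozen=True)
class CouplingParams:
    """Generative fixed-effect structure for memory-change ~ biomarker-change.

    Units: latent memory z per unit change of the pTau181/Abeta42 ratio for
    the biomarker terms; latent z per visit for the level terms. Reference
    cell is female / preclinical.
    """

    intercept: float = 0.0
    sex: float = -0.04                    # male main effect on increments
    group: float = 0.0                    # MCI main effect (practice term carries stage)
    biomarker: float = -12.25
    biomarker_x_sex: float = 8.27
    biomarker_x_group: float = 5.10
    biomarker_x_sex_x_group: float = -16.63

    def slope(self, male: np.ndarray, mci: np.ndarray) -> np.ndarray:
        """Cell-specific biomarker->memory slope."""
        return (self.biomarker
                + self.biomarker_x_sex * male
                + self.biomarker_x_group * mci
                + self.biomarker_x_sex_x_group * male * mci)

    def level(self, male: np.ndarray, mci: np.ndarray) -> np.ndarray:
        return self.intercept + self.sex * male + self.group * mci


@dataclass
class SimulationConfig:
    """All knobs of the generative model. Defaults reproduce the study shape:

    cell counts 78/73/104/146 (preclinical F/M, MCI F/M), 525 robust
    controls, five annual visits (4-year follow-up), and a biomarker-memory
    coupling whose slope structure mirrors the published fixed effects.
    """

    n_preclinical_f: int = 78
    n_preclinical_m: int = 73
    n_mci_f: int = 104
    n_mci_m: int = 146
    n_robust_controls: int = 525

    visits_per_participant: int = 5
    visit_interval_years: float = 1.0
    dropout_prob_per_visit: float = 0.0

    age_mean: float = 74.0
    age_sd: float = 6.5
    educ_mean: float = 16.0
    educ_sd: float = 2.6
    apoe_carrier_prob: float = 0.57

    # CSF pTau181/Abeta42 ratio process (dimensionless ratio units)
    biomarker_baseline_mean: dict = field(default_factory=lambda: {
        "preclinical": 0.044, "mci": 0.044, "control": 0.015})
    biomarker_baseline_sd: dict = field(default_factory=lambda: {
        "preclinical": 0.018, "mci": 0.028, "control": 0.005})
    biomarker_drift_mean: dict = field(default_factory=lambda: {
        "preclinical": 0.0020, "mci": 0.0045, "control": 0.0})
    biomarker_drift_sd: dict = field(default_factory=lambda: {
        "preclinical": 0.0015, "mci": 0.0025, "control": 0.0005})
    biomarker_noise_sd: float = 0.010
    csf_positivity_cutpoint: float = 0.025   # preclinical baselines truncated above this

    # latent verbal-memory level (z-units)
    memory_baseline_by_sex_stage: dict = field(default_factory=lambda: {
        ("female", "preclinical"): 1.017, ("male", "preclinical"): 0.613,
        ("female", "mci"): 0.071, ("male", "mci"): -0.246,
        ("female", "control"): 0.0, ("male", "control"): 0.0})
    memory_baseline_sd: float = 0.20
    practice_effect_by_stage: dict = field(default_factory=lambda: {
        "preclinical": 0.07, "mci": -0.05, "control": 0.02})
    coupling: CouplingParams = field(default_factory=CouplingParams)
    random_intercept_sd: float = 0.17    # tau: SD of u_i on increment means
    residual_sd: float = 0.20            # sigma: increment noise SD

    # latent non-memory (speed/executive + language) level
    nonmemory_baseline_sd: float = 0.35
    mci_nonmemory_deficit_mean: float = -1.7
    mci_nonmemory_deficit_sd: float = 0.30
    nonmemory_drift_by_stage: dict = field(default_factory=lambda: {
        "preclinical": 0.0, "mci": -0.06, "control": 0.0})
    nonmemory_increment_sd: float = 0.12

    # CDR sum-of-boxes (0-18, half-point quantized)
    cdr_baseline_mean: dict = field(default_factory=lambda: {
        "preclinical": 0.2, "mci": 1.5, "control": 0.05})
    cdr_baseline_sd: dict = field(default_factory=lambda: {
        "preclinical": 0.3, "mci": 1.0, "control": 0.1})
    cdr_coupling: float = 20.0
    cdr_increment_sd: float = 0.30

    pet_observed_prob: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_preclinical_f, self.n_preclinical_m,
                  self.n_mci_f, self.n_mci_m, self.n_robust_controls]
        if any(c < 0 for c in counts):
            raise ValueError("participant counts must be >= 0")
        if self.visits_per_participant < 2:
            raise ValueError("visits_per_participant must be >= 2")
        if not 0.0 <= self.dropout_prob_per_visit <= 1.0:
            raise ValueError("dropout_prob_per_visit must be in [0, 1]")
        if not 0.0 <= self.apoe_carrier_prob <= 1.0:
            raise ValueError("apoe_carrier_prob must be in [0, 1]")
        sds = ([self.age_sd, self.educ_sd, self.biomarker_noise_sd,
                self.memory_baseline_sd, self.random_intercept_sd,
                self.residual_sd, self.nonmemory_baseline_sd,
                self.nonmemory_increment_sd, self.cdr_increment_sd]
               + list(self.biomarker_baseline_sd.values())
               + list(self.biomarker_drift_sd.values()))
        if any(not np.isfinite(s) or s < 0 for s in sds):
            raise ValueError("all SDs must be finite and >= 0")
        for v in (self.age_mean, self.educ_mean, self.visit_interval_years):
            if not np.isfinite(v):
                raise ValueError("non-finite configuration value")


@dataclass
class Cohort:
    """Simulated cohort: observed visit table plus a latent-truth sidecar."""

    visits: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Configuration matching the study's shape: 78/73/104/146 per
    sex-by-stage cell, 525 robust controls, five annual visits (mean
    follow-up 4 years), age ~74, education ~16."""
    return SimulationConfig(seed=seed)


def _draw_participants(cfg: SimulationConfig, rng: np.random.Generator):
    stages, sexes = [], []
    for stage, sex, n in [
        ("preclinical", "female", cfg.n_preclinical_f),
        ("preclinical", "male", cfg.n_preclinical_m),
        ("mci", "female", cfg.n_mci_f),
        ("mci", "male", cfg.n_mci_m),
    ]:
        stages += [stage] * n
        sexes += [sex] * n
    n_ctrl = cfg.n_robust_controls
    stages += ["control"] * n_ctrl
    ctrl_male = rng.random(n_ctrl) < 0.5
    sexes += ["male" if m else "female" for m in ctrl_male]
    return np.array(stages), np.array(sexes)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the cohort. Deterministic under a fixed seed/config."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    stage, sex = _draw_participants(cfg, rng)
    n = stage.size
    T = cfg.visits_per_participant
    male = (sex == "male").astype(float)
    mci = (stage == "mci").astype(float)
    is_ctrl = stage == "control"

    pid = np.arange(1001, 1001 + n)
    age0 = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 55.0, 90.0)
    educ = np.clip(np.round(rng.normal(cfg.educ_mean, cfg.educ_sd, n)), 8, 20)
    apoe = rng.random(n) < cfg.apoe_carrier_prob
    income = rng.integers(1, 11, n)  # ordinal 1-10, optional covariate

    # --- biomarker random walk -------------------------------------------
    b_mean = np.array([cfg.biomarker_baseline_mean[s] for s in stage])
    b_sd = np.array([cfg.biomarker_baseline_sd[s] for s in stage])
    B0 = rng.normal(b_mean, b_sd)
    cut = cfg.csf_positivity_cutpoint
    # preclinical participants are biomarker-positive by definition;
    # controls sit safely below the cutpoint
    pre = stage == "preclinical"
    for _ in range(50):
        bad = pre & (B0 < cut)
        if not bad.any():
            break
        B0[bad] = rng.normal(b_mean[bad], b_sd[bad])
    B0[pre] = np.maximum(B0[pre], cut)
    B0[is_ctrl] = np.clip(B0[is_ctrl], 0.003, cut - 0.002)
    B0 = np.maximum(B0, 0.003)

    drift = rng.normal(np.array([cfg.biomarker_drift_mean[s] for s in stage]),
                       np.array([cfg.biomarker_drift_sd[s] for s in stage]))
    b_noise = rng.normal(0.0, cfg.biomarker_noise_sd, (n, T - 1))
    dB = drift[:, None] + b_noise                     # (n, T-1)
    B = np.concatenate([B0[:, None], B0[:, None] + np.cumsum(dB, axis=1)], axis=1)
    B = np.maximum(B, 0.001)
    dB_eff = np.diff(B, axis=1)                       # after flooring

    # --- latent memory level ---------------------------------------------
    m_base = np.array([cfg.memory_baseline_by_sex_stage[(sx, st)]
                       for sx, st in zip(sex, stage)])
    M0 = rng.normal(m_base, cfg.memory_baseline_sd)
    u = rng.normal(0.0, cfg.random_intercept_sd, n)
    practice = np.array([cfg.practice_effect_by_stage[s] for s in stage])
    slope = cfg.coupling.slope(male, mci)
    level = cfg.coupling.level(male, mci)
    slope[is_ctrl] = 0.0
    level[is_ctrl] = 0.0
    eps = rng.normal(0.0, cfg.residual_sd, (n, T - 1))
    dM = (practice[:, None] + level[:, None]
          + slope[:, None] * dB_eff + u[:, None] + eps)
    M = np.concatenate([M0[:, None], M0[:, None] + np.cumsum(dM, axis=1)], axis=1)

    # --- latent non-memory level (carries the diagnostic deficit) --------
    G0 = rng.normal(0.0, cfg.nonmemory_baseline_sd, n)
    G0 = np.where(stage == "mci",
                  G0 + rng.normal(cfg.mci_nonmemory_deficit_mean,
                                  cfg.mci_nonmemory_deficit_sd, n),
                  G0)
    g_drift = np.array([cfg.nonmemory_drift_by_stage[s] for s in stage])
    dG = g_drift[:, None] + rng.normal(0.0, cfg.nonmemory_increment_sd, (n, T - 1))
    G = np.concatenate([G0[:, None], G0[:, None] + np.cumsum(dG, axis=1)], axis=1)

    # --- CDR sum of boxes -------------------------------------------------
    c_mean = np.array([cfg.cdr_baseline_mean[s] for s in stage])
    c_sd = np.array([cfg.cdr_baseline_sd[s] for s in stage])
    C0 = np.maximum(rng.normal(c_mean, c_sd), 0.0)
    dC = cfg.cdr_coupling * dB_eff + rng.normal(0.0, cfg.cdr_increment_sd, (n, T - 1))
    C = np.concatenate([C0[:, None], C0[:, None] + np.cumsum(dC, axis=1)], axis=1)
    C = np.clip(np.round(C * 2.0) / 2.0, 0.0, 18.0)

    # --- observed test scores --------------------------------------------
    scores = {}
    n_clipped = 0
    for name, spec in TEST_BATTERY.items():
        lat = M if spec.latent == "memory" else G
        noise = rng.normal(0.0, spec.noise_sd, (n, T))
        raw = (spec.base
               + spec.beta_age * (age0[:, None] - 74.0)
               + spec.beta_male * male[:, None]
               + spec.beta_educ * (educ[:, None] - 16.0)
               + spec.load * (lat + noise))
        clipped = np.clip(raw, spec.lo, spec.hi)
        n_clipped += int((clipped != raw).sum())
        scores[name] = clipped
    if n_clipped:
        logger.info("clipped %d score values to their published ranges", n_clipped)

    # --- PET flags (observed for a subset; noisy functions of pathology) --
    pet_obs = rng.random(n) < cfg.pet_observed_prob
    amyl = (B0 + rng.normal(0.0, 0.008, n)) > 0.030
    tau = (B0 + rng.normal(0.0, 0.010, n)) > 0.035
    amyl_col = np.where(pet_obs, amyl, np.nan)
    tau_col = np.where(pet_obs, tau, np.nan)

    # --- dropout: trailing truncation, baseline always kept ---------------
    keep = np.ones((n, T), dtype=bool)
    if cfg.dropout_prob_per_visit > 0:
        cont = rng.random((n, T - 1)) >= cfg.dropout_prob_per_visit
        keep[:, 1:] = np.cumprod(cont, axis=1).astype(bool)

    # --- assemble long tables --------------------------------------------
    t_idx = np.arange(T)
    years = t_idx * cfg.visit_interval_years
    rows = []
    for t in t_idx:
        m = keep[:, t]
        rows.append(pd.DataFrame({
            "participant_id": pid[m],
            "visit_index": t,
            "age_at_visit": age0[m] + years[t],
            "years_from_baseline": years[t],
            "sex": sex[m],
            "education": educ[m].astype(int),
            "income": income[m],
            "apoe_e4_carrier": apoe[m],
            "csf_ptau_abeta_ratio": B[m, t],
            "tmt_a": scores["tmt_a"][m, t],
            "tmt_b": scores["tmt_b"][m, t],
            "category_fluency": scores["category_fluency"][m, t],
            "bnt": scores["bnt"][m, t],
            "ravlt_learning": scores["ravlt_learning"][m, t],
            "ravlt_delayed_recall": scores["ravlt_delayed_recall"][m, t],
            "ravlt_recognition": scores["ravlt_recognition"][m, t],
            "cdr_sb": C[m, t],
            "dementia_flag": False,
            "amyloid_pet_positive": amyl_col[m],
            "tau_pet_positive": tau_col[m],
            "is_robust_control": is_ctrl[m],
        }))
    visits = (pd.concat(rows, ignore_index=True)
              .sort_values(["participant_id", "visit_index"])
              .reset_index(drop=True))

    truth_rows = []
    for t in t_idx:
        m = keep[:, t]
        truth_rows.append(pd.DataFrame({
            "participant_id": pid[m],
            "visit_index": t,
            "true_stage": stage[m],
            "true_memory_level": M[m, t],
            "true_nonmemory_level": G[m, t],
            "true_biomarker_level": B[m, t],
            "true_memory_increment": dM[m, t - 1] if t > 0 else np.nan,
            "true_biomarker_increment": dB_eff[m, t - 1] if t > 0 else np.nan,
            "true_random_intercept": u[m],
            "true_biomarker_drift": drift[m],
            "true_coupling_slope": slope[m],
        }))
    truth = (pd.concat(truth_rows, ignore_index=True)
             .sort_values(["participant_id", "visit_index"])
             .reset_index(drop=True))

    return Cohort(visits=visits, truth=truth, config=cfg)


def write_cohort(cohort: Cohort, visits_path, truth_path=None) -> None:
    cohort.visits.to_csv(visits_path, index=False)
    if truth_path is not None:
        cohort.truth.to_csv(truth_path, index=False)


def read_visits(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a long-format visit CSV, applying ADNIMERGE-style aliases plus
    any user-supplied column map."""
    df = pd.read_csv(path)
    mapping = dict(COLUMN_ALIASES)
    if column_map:
        mapping.update(column_map)
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    missing = [c for c in ("participant_id", "visit_index") if c not in df.columns]
    if missing:
        raise ValueError(f"input table lacks required columns: {missing}")
    if "is_robust_control" not in df.columns:
        df["is_robust_control"] = False
    return df


def config_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    if "coupling" in d and isinstance(d["coupling"], Mapping):
        d["coupling"] = CouplingParams(**d["coupling"])
    tupled = {}
    if "memory_baseline_by_sex_stage" in d and isinstance(d["memory_baseline_by_sex_stage"], Mapping):
        for k, v in d["memory_baseline_by_sex_stage"].items():
            key = tuple(k.split("/")) if isinstance(k, str) else tuple(k)
            tupled[key] = v
        d["memory_baseline_by_sex_stage"] = tupled
    return SimulationConfig(**d)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["memory_baseline_by_sex_stage"] = {
        "/".join(k): v for k, v in cfg.memory_baseline_by_sex_stage.items()}
    return d


def with_coupling(cfg: SimulationConfig, **kw) -> SimulationConfig:
    """Convenience: return a copy of ``cfg`` with coupling fields replaced."""
    return replace(cfg, coupling=replace(cfg.coupling, **kw))
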