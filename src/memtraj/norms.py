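"""Regression-based normative scoring against robust normal controls.

Each test's raw score is regressed on baseline age, sex and education in the
robust control group (participants cognitively normal at every visit); target
scores are converted to z-scores ``(observed - predicted) / residual_scale``
and sign-flipped for timed tests so that lower z always means worse function
and impairment is uniformly ``z < -1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TEST_BATTERY, DIAGNOSTIC_TESTS

logger = logging.getLogger(__name__)


class CollinearDesignError(ValueError):
    """Normative design matrix is rank deficient; names the offending term."""


class DegenerateNormsError(ValueError):
    """Control residual variance is (numerically) zero."""


@dataclass(frozen=True)
class NormativeModel:
    test_name: str
    intercept: float
    beta_age: float
    beta_sex_male: float
    beta_education: float
    residual_scale: float
    higher_is_better: bool
    n_controls: int
    include_sex: bool = True

    def predict(self, age, sex_male, education) -> np.ndarray:
        return (self.intercept
                + self.beta_age * np.asarray(age, float)
                + self.beta_sex_male * np.asarray(sex_male, float)
                + self.beta_education * np.asarray(education, float))

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _design(df: pd.DataFrame, include_sex: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df)), df["age_at_visit"].to_numpy(float)]
    names = ["intercept", "age"]
    if include_sex:
        cols.append((df["sex"] == "male").to_numpy(float))
        names.append("sex")
    cols.append(df["education"].to_numpy(float))
    names.append("education")
    return np.column_stack(cols), names


def fit_norms(control_visits: pd.DataFrame,
              tests: list[str] | None = None,
              min_controls: int = 30,
              include_sex: bool = True) -> dict[str, NormativeModel]:
    """Fit one least-squares normative model per test on control baselines.

    ``control_visits`` should contain the baseline rows of robust controls.
    Raises :class:`CollinearDesignError` for rank-deficient designs (e.g.
    single-sex control samples) naming the collinear term, and
    :class:`DegenerateNormsError` when control residual variance vanishes.
    """
    tests = list(tests) if tests is not None else list(DIAGNOSTIC_TESTS)
    unknown = [t for t in tests if t not in TEST_BATTERY]
    if unknown:
        raise ValueError(f"unknown tests: {unknown}")

    models: dict[str, NormativeModel] = {}
    for test in tests:
        data = control_visits.dropna(subset=[test, "age_at_visit", "sex", "education"])
        if len(data) < min_controls:
            raise ValueError(
                f"{test}: only {len(data)} controls, minimum is {min_controls}")
        X, names = _design(data, include_sex)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            for j, name in enumerate(names):
                if name == "intercept":
                    continue
                if np.ptp(X[:, j]) == 0:
                    raise CollinearDesignError(
                        f"{test}: normative design is rank deficient — "
                        f"term '{name}' is constant in the control sample")
            raise CollinearDesignError(
                f"{test}: normative design is rank deficient "
                f"(rank {rank} < {X.shape[1]})")
        y = data[test].to_numpy(float)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(data) - X.shape[1]
        scale = float(np.sqrt(resid @ resid / dof))
        if scale < 1e-10:
            raise DegenerateNormsError(
                f"{test}: control residual scale is zero — scores are an exact "
                "function of demographics; norms are degenerate")
        coef = dict(zip(names, beta))
        models[test] = NormativeModel(
            test_name=test,
            intercept=float(coef["intercept"]),
            beta_age=float(coef["age"]),
            beta_sex_male=float(coef.get("sex", 0.0)),
            beta_education=float(coef["education"]),
            residual_scale=scale,
            higher_is_better=TEST_BATTERY[test].higher_is_better,
            n_controls=len(data),
            include_sex=include_sex,
        )
    return models


def score_all(visits: pd.DataFrame,
              norms: dict[str, NormativeModel]) -> pd.DataFrame:
    """Long z-score table; one row per participant-visit-test.

    Missing raw scores yield missing z (never imputed). Orientation is
    uniform: impairment is always z < -1 after flipping timed tests.
    """
    frames = []
    male = (visits["sex"] == "male").astype(float)
    for test, model in norms.items():
        if test not in visits.columns:
            raise ValueError(f"norms fitted for '{test}' but column absent")
        pred = model.predict(visits["age_at_visit"], male, visits["education"])
        z = (visits[test].to_numpy(float) - pred) / model.residual_scale
        if not model.higher_is_better:
            z = -z
        frames.append(pd.DataFrame({
            "participant_id": visits["participant_id"],
            "visit_index": visits["visit_index"],
            "test_name": test,
            "z": z,
        }))
    out = pd.concat(frames, ignore_index=True)
    n_missing = int(out["z"].isna().sum())
    if n_missing:
        logger.info("score_all: %d missing z values (left missing)", n_missing)
    return out


def z_wide(ztable: pd.DataFrame, visit_index: int | None = 0) -> pd.DataFrame:
    """Pivot the long z table to participants x tests (default: baseline)."""
    t = ztable if visit_index is None else ztable[ztable["visit_index"] == visit_index]
    return t.pivot_table(index="participant_id", columns="test_name",
                         values="z", aggfunc="first")
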