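"""Memory composite and lag-1 residual change scores.

The verbal-memory composite is the mean of the within-sample standardized
RAVLT Learning and Delayed Recall scores. Change in any repeated measure
(memory composite, CSF ratio, Trails B, CDR-SB) is measured as the lagged
residual: pool all within-participant consecutive visit pairs, regress the
current value on the prior value by ordinary least squares (one global lag
model per variable), and take the residual — the deviation from the
autoregressive expectation. This removes the autocorrelation bias that raw
difference scores carry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LagModel:
    variable: str
    intercept: float
    slope: float
    n_pairs: int


def build_memory_composite(visits: pd.DataFrame,
                           learning_col: str = "ravlt_learning",
                           recall_col: str = "ravlt_delayed_recall") -> pd.DataFrame:
    """Standardize each RAVLT component against the pooled mean/SD of the
    given sample (all visits) and average the two z-scores.

    Missing components give a missing composite. Zero variance in a
    component is an explicit failure.
    """
    out = visits[["participant_id", "visit_index"]].copy()
    zs = []
    for col in (learning_col, recall_col):
        x = visits[col].to_numpy(float)
        mu = np.nanmean(x)
        sd = np.nanstd(x)  # population SD: two-point samples map to -1/+1
        if not np.isfinite(sd) or sd < 1e-12:
            raise ValueError(f"component '{col}' has zero variance; "
                             "composite undefined")
        zs.append((x - mu) / sd)
    out["memory_composite"] = (zs[0] + zs[1]) / 2.0
    return out


def compute_lagged_residuals(df: pd.DataFrame,
                             variables: list[str],
                             max_gap_years: float | None = None,
                             time_col: str = "years_from_baseline") -> tuple[pd.DataFrame, dict[str, LagModel]]:
    """Lag-1 residual change scores for each variable.

    ``df`` is long-format with participant_id / visit_index plus the
    variable columns. Pairs are consecutive *observed* visits within a
    participant; ``max_gap_years`` optionally drops pairs with a longer
    calendar gap. Returns a long change table (rows only where both the
    current and prior value exist) and the fitted lag models.
    """
    d = df.sort_values(["participant_id", "visit_index"]).copy()
    g = d.groupby("participant_id", sort=False)
    frames = []
    models: dict[str, LagModel] = {}
    gap_ok = None
    if max_gap_years is not None and time_col in d.columns:
        gap = d[time_col] - g[time_col].shift(1)
        gap_ok = gap <= max_gap_years

    for var in variables:
        cur = d[var]
        prev = g[var].shift(1)
        valid = cur.notna() & prev.notna()
        if gap_ok is not None:
            valid &= gap_ok.fillna(False)
        x = prev[valid].to_numpy(float)
        y = cur[valid].to_numpy(float)
        if len(x) < 3:
            raise ValueError(f"{var}: need >= 3 (prior, current) pairs, "
                             f"got {len(x)}")
        if np.ptp(x) < 1e-12:
            raise ValueError(f"{var}: prior values are constant; lag slope "
                             "undefined")
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        models[var] = LagModel(var, float(intercept), float(slope), len(x))
        frames.append(pd.DataFrame({
            "participant_id": d.loc[valid, "participant_id"].to_numpy(),
            "visit_index": d.loc[valid, "visit_index"].to_numpy(),
            "variable": var,
            "change": resid,
        }))
    changes = pd.concat(frames, ignore_index=True)
    return changes, models


def assemble_analysis_table(visits: pd.DataFrame,
                            group_mci: pd.Series,
                            composites: pd.DataFrame,
                            changes: pd.DataFrame,
                            include_income: bool = False) -> pd.DataFrame:
    """One row per participant per post-baseline visit with the memory and
    biomarker change scores plus covariates.

    ``group_mci``: boolean Series indexed by participant_id (True = MCI,
    False = preclinical); participants not in its index are excluded.
    Covariate centering (age, education) uses the analysis-sample baseline
    means. Participants with no post-baseline change row are dropped and
    logged (inclusion requires at least one follow-up visit).
    """
    wide = changes.pivot_table(index=["participant_id", "visit_index"],
                               columns="variable", values="change",
                               aggfunc="first").reset_index()
    rename = {"memory_composite": "memory_change",
              "csf_ptau_abeta_ratio": "biomarker_change",
              "tmt_b": "trails_b_change",
              "cdr_sb": "cdr_sb_change"}
    wide = wide.rename(columns={k: v for k, v in rename.items()
                                if k in wide.columns})

    base = (visits[visits["visit_index"] == 0]
            .set_index("participant_id"))
    ids = group_mci.index.intersection(base.index)
    base = base.loc[ids]
    tab = wide[wide["participant_id"].isin(ids)].copy()

    n_all = len(ids)
    with_followup = tab["participant_id"].unique()
    n_dropped = n_all - len(with_followup)
    if n_dropped:
        logger.info("assemble_analysis_table: %d participants without a "
                    "post-baseline change row dropped", n_dropped)

    tab["sex_male"] = (base.loc[tab["participant_id"], "sex"] == "male"
                       ).to_numpy().astype(int)
    tab["group_mci"] = group_mci.loc[tab["participant_id"]].to_numpy().astype(int)
    age0 = base.loc[tab["participant_id"], "age_at_visit"].to_numpy(float)
    educ = base.loc[tab["participant_id"], "education"].to_numpy(float)
    tab["age_c"] = age0 - age0.mean()
    tab["educ_c"] = educ - educ.mean()
    tab["apoe_carrier"] = (base.loc[tab["participant_id"], "apoe_e4_carrier"]
                           .to_numpy().astype(int))
    if include_income and "income" in base.columns:
        tab["income"] = base.loc[tab["participant_id"], "income"].to_numpy(float)

    cells = tab.groupby(["group_mci", "sex_male"])["participant_id"].nunique()
    logger.info("analysis table: %d rows, participants per (group, sex) cell: %s",
                len(tab), cells.to_dict())
    required = ["memory_change", "biomarker_change"]
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise ValueError(f"analysis table lacks change columns: {missing}")
    return tab.dropna(subset=required).reset_index(drop=True)
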