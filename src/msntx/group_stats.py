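"""Case-control statistics on MSN strength maps.

Regional and global contrasts use an ordinary least squares model
``strength = intercept + group + age + sex + TIV`` with a two-sided t-test
on the group coefficient and Bonferroni correction across regions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, RankDeficientDesignError


def _design_matrix(meta: pd.DataFrame, case_mask: np.ndarray) -> np.ndarray:
    sex01 = (meta["sex"].to_numpy() == "F").astype(float)
    return np.column_stack(
        [
            np.ones(len(meta)),
            case_mask.astype(float),
            meta["age"].to_numpy(float),
            sex01,
            meta["tiv"].to_numpy(float),
        ]
    )


def _ols_group_t(design: np.ndarray, Y: np.ndarray):
    """Vectorized OLS of each column of Y on design; t/p for column 1 (group)."""
    n, p = design.shape
    if np.linalg.matrix_rank(design) < p:
        raise RankDeficientDesignError(
            "design matrix is rank deficient (collinear covariates)"
        )
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ Y
    resid = Y - design @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    b_group = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b_group / se, 0.0)
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, b_group, t, p_raw


def fit_region_glm(
    strengths: np.ndarray | pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str] = ("patient", "control"),
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-region group contrast of MSN strength with age/sex/TIV covariates.

    ``contrast = (case_label, control_label)`` selects two groups from
    ``labels`` (default ``meta['group']``); a positive t means higher
    strength in the case group.  Returns a DataFrame indexed by region with
    columns ``beta_group, t, p_raw, p_bonferroni`` and the model metadata in
    ``df.attrs``.
    """
    if isinstance(strengths, pd.DataFrame):
        region_index = strengths.columns
        Y = strengths.to_numpy(float)
    else:
        Y = np.atleast_2d(np.asarray(strengths, dtype=float))
        region_index = pd.RangeIndex(Y.shape[1], name="region_id")
    lab = (labels if labels is not None else meta["group"]).to_numpy()
    case, ctrl = contrast
    keep = (lab == case) | (lab == ctrl)
    if not (lab == case).any() or not (lab == ctrl).any():
        raise ValueError(f"both contrast groups {contrast} must be present")
    sub_meta = meta.loc[keep]
    design = _design_matrix(sub_meta, (lab[keep] == case))
    beta, b_group, t, p_raw = _ols_group_t(design, Y[keep])
    m = Y.shape[1]
    out = pd.DataFrame(
        {
            "beta_group": b_group,
            "t": t,
            "p_raw": p_raw,
            "p_bonferroni": np.minimum(1.0, m * p_raw),
        },
        index=region_index,
    )
    out.attrs["model"] = {
        "covariates": ["age", "sex", "tiv"],
        "contrast": f"{case}-{ctrl}",
        "n_case": int((lab == case).sum()),
        "n_control": int((lab == ctrl).sum()),
        "df_resid": int(design.shape[0] - design.shape[1]),
        "coef_names": ["intercept", "group", "age", "sex", "tiv"],
        "beta_mean": beta.mean(axis=1).tolist(),
    }
    return out


def global_strength_test(
    global_strength: np.ndarray,
    meta: pd.DataFrame,
    contrast: tuple[str, str] = ("patient", "control"),
    labels: pd.Series | None = None,
    method: str = "lrm",
) -> dict:
    """Group test on per-subject global MSN strength.

    ``method='lrm'`` (default) reuses the regional OLS model; ``'ranksum'``
    runs a two-sided Mann-Whitney U test instead.
    """
    g = np.asarray(global_strength, dtype=float)
    lab = (labels if labels is not None else meta["group"]).to_numpy()
    case, ctrl = contrast
    if method == "ranksum":
        u, p = stats.mannwhitneyu(g[lab == case], g[lab == ctrl], alternative="two-sided")
        return {"stat": float(u), "p": float(p), "method": "mannwhitney"}
    res = fit_region_glm(g[:, None], meta, contrast=contrast, labels=labels)
    row = res.iloc[0]
    return {
        "beta": float(row["beta_group"]),
        "t": float(row["t"]),
        "p": float(row["p_raw"]),
        "method": "lrm",
    }


def quadrant_fractions(hc_mean_strength: np.ndarray, tmap: np.ndarray) -> dict[str, float]:
    """Fractions of regions in each (sign of HC strength, sign of t) quadrant.

    decoupling: strength>0 & t<0; dedifferentiation: strength<0 & t>0;
    hypercoupling: strength>0 & t>0; hyperdifferentiation: strength<0 & t<0.
    Regions with a zero in either map belong to no quadrant, so the four
    fractions sum to at most 1.
    """
    s = np.asarray(hc_mean_strength, dtype=float)
    t = np.asarray(tmap, dtype=float)
    if s.shape != t.shape:
        raise ValueError("strength and t maps must share the region index")
    r = s.size
    return {
        "decoupling": float(((s > 0) & (t < 0)).sum() / r),
        "dedifferentiation": float(((s < 0) & (t > 0)).sum() / r),
        "hypercoupling": float(((s > 0) & (t > 0)).sum() / r),
        "hyperdifferentiation": float(((s < 0) & (t < 0)).sum() / r),
    }


@dataclasses.dataclass
class TrajectoryFit:
    """Quadratic age trajectory: value = b0 + b1*age + b2*age**2."""

    coefficients: tuple[float, float, float]
    r_squared: float
    group: str | None = None

    def __call__(self, age):
        b0, b1, b2 = self.coefficients
        age = np.asarray(age, dtype=float)
        return b0 + b1 * age + b2 * age**2


def fit_quadratic_trajectory(age, values, group: str | None = None) -> TrajectoryFit:
    """Least-squares quadratic developmental trajectory fit."""
    age = np.asarray(age, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(np.unique(age)) < 3:
        raise DegenerateInputError("need at least 3 distinct ages for a quadratic fit")
    design = np.column_stack([np.ones_like(age), age, age**2])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    fitted = design @ beta
    ss_res = float(((values - fitted) ** 2).sum())
    ss_tot = float(((values - values.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TrajectoryFit(coefficients=tuple(beta), r_squared=r2, group=group)


def symptom_spearman(
    strengths: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlations between regional strengths and symptom scores.

    ``strengths`` is patients x regions; ``scores`` patients x scales.
    Bonferroni correction is over the full region x scale grid.  Rows with a
    missing score are dropped per scale; ties get average ranks.
    """
    rows = []
    m = strengths.shape[1] * scores.shape[1]
    for scale in scores.columns:
        sc = scores[scale].to_numpy(float)
        ok = np.isfinite(sc)
        if ok.sum() < 4:
            raise ValueError(f"need >=4 patients with scores for {scale!r}")
        if np.unique(sc[ok]).size < 2:
            raise DegenerateInputError(f"score {scale!r} is constant")
        for region in strengths.columns:
            rho, p = stats.spearmanr(strengths[region].to_numpy(float)[ok], sc[ok])
            rows.append(
                {
                    "region": region,
                    "score": scale,
                    "rho": rho,
                    "p_raw": p,
                    "p_bonferroni": min(1.0, m * p),
                }
            )
    return pd.DataFrame(rows)


def demographics_tests(
    meta: pd.DataFrame,
    groups: tuple[str, str] = ("patient", "control"),
    continuous: tuple[str, ...] = ("age", "tiv"),
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Group comparison table: Mann-Whitney U (two-sided) for continuous
    variables, chi-square for sex."""
    lab = (labels if labels is not None else meta["group"]).to_numpy()
    a, b = groups
    ma, mb = lab == a, lab == b
    if not ma.any() or not mb.any():
        raise ValueError(f"both groups {groups} must be non-empty")
    rows = []
    for var in continuous:
        va = meta.loc[ma, var].dropna().to_numpy(float)
        vb = meta.loc[mb, var].dropna().to_numpy(float)
        u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append({"variable": var, "test": "mannwhitney", "stat": float(u), "p": float(p)})
    table = pd.crosstab(lab[ma | mb], meta.loc[ma | mb, "sex"].to_numpy())
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    rows.append({"variable": "sex", "test": "chi2", "stat": float(chi2), "p": float(p)})
    return pd.DataFrame(rows)
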