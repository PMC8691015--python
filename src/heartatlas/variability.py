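"""Structure-specific interobserver variability estimates.

Observed values are indexed by (structure, patient, observer).  For each
structure the module estimates

* CV  — coefficient of variation of positive quantities (volume, DMEAN,
  D2CC) from a log-normal model: log(value) = cell mean (one fixed effect
  per structure x patient cell) + Gaussian error with structure-specific
  sigma; CV = sqrt(exp(sigma^2) - 1).  With a conjugate inverse-gamma
  prior on sigma^2 (cell means given flat priors and profiled out) the
  posterior is available in closed form, yielding exact 95% credible
  intervals without MCMC.
* SD  — standard deviation of the V5GY fraction from a beta regression
  with logit-linked cell means and a structure-specific precision phi
  (maximum likelihood via statsmodels); SD = sqrt(mu(1-mu)/(1+phi)) with
  mu the structure-level mean of cell means; intervals by seeded
  parametric bootstrap.
* ICC(2) — two-way random-effects, absolute-agreement, single-rater
  intraclass correlation from the patients x observers ANOVA, with the
  standard F-distribution confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariabilityEstimate",
    "check_cell_indexed",
    "lognormal_cv",
    "beta_precision_sd",
    "icc2",
    "variability_report",
]

NOT_CALCULATED = "not calculated"


@dataclass
class VariabilityEstimate:
    """Point estimate with a 95% interval for one (structure, metric)."""

    structure: str
    metric: str
    estimate: float
    interval_low: float
    interval_high: float
    interval_kind: str  # "credible" or "confidence"
    flag: str | None = None

    def __post_init__(self):
        if self.flag is None and not (
            self.interval_low <= self.estimate <= self.interval_high
        ):
            raise ValueError("interval must contain the point estimate")


def check_cell_indexed(data: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Validate a tidy (structure, patient, observer, value) table."""
    required = {"structure", "patient", "observer", value_col}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dup = data.duplicated(subset=["structure", "patient", "observer"])
    if dup.any():
        raise ValueError("duplicate (structure, patient, observer) cells")
    return data


# ---------------------------------------------------------------------------
# log-normal CV


def _cv_from_sigma2(s2):
    return np.sqrt(np.expm1(s2))


def lognormal_cv(
    data: pd.DataFrame,
    value_col: str = "value",
    level: float = 0.95,
    prior_a: float = 1e-3,
    prior_b: float = 1e-3,
) -> list[VariabilityEstimate]:
    """Per-structure CV from the log-normal interobserver model.

    The structure x patient cell means are nuisance fixed effects; the
    residual sum of squares on the log scale drives the inverse-gamma
    posterior sigma^2 | data ~ IG(a + df/2, b + SS/2) with df = n_obs -
    n_cells.  The point estimate is the posterior-median sigma^2 mapped
    through CV(sigma^2); the credible interval maps the posterior
    quantiles (CV is monotone in sigma^2).
    """
    check_cell_indexed(data, value_col)
    if (data[value_col] <= 0).any():
        raise ValueError("log-normal CV requires strictly positive values")
    out = []
    alpha = 1.0 - level
    for structure, grp in data.groupby("structure", sort=False):
        sizes = grp.groupby("patient")[value_col].transform("size")
        if (sizes < 2).any():
            warnings.warn(
                f"{structure}: dropping {int((sizes < 2).sum())} singleton cell(s)"
            )
            grp = grp[sizes >= 2]
        n = len(grp)
        n_cells = grp["patient"].nunique()
        if n - n_cells < 2:
            out.append(
                VariabilityEstimate(
                    structure, "cv", np.nan, np.nan, np.nan, "credible",
                    flag=NOT_CALCULATED,
                )
            )
            continue
        logv = np.log(grp[value_col].to_numpy())
        resid = logv - grp.groupby("patient")[value_col].transform(
            lambda v: np.log(v).mean()
        ).to_numpy()
        ss = float(resid @ resid)
        post = stats.invgamma(a=prior_a + (n - n_cells) / 2.0,
                              scale=prior_b + ss / 2.0)
        s2_med, s2_lo, s2_hi = post.ppf([0.5, alpha / 2.0, 1.0 - alpha / 2.0])
        out.append(
            VariabilityEstimate(
                structure,
                "cv",
                float(_cv_from_sigma2(s2_med)),
                float(_cv_from_sigma2(s2_lo)),
                float(_cv_from_sigma2(s2_hi)),
                "credible",
            )
        )
    return out


# ---------------------------------------------------------------------------
# beta-regression SD for V5GY


def beta_sd_closed_form(mu: float, phi: float) -> float:
    """SD of a beta variate with mean mu and precision phi."""
    return float(np.sqrt(mu * (1.0 - mu) / (1.0 + phi)))


def _squeeze(y: np.ndarray) -> np.ndarray:
    """Smithson-Verkuilen transform pulling exact 0/1 into (0, 1)."""
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def _fit_beta_structure(y: np.ndarray, cells: np.ndarray, start=None):
    """MLE of cell means (logit link) + common precision (log link).

    The returned precision carries a degrees-of-freedom correction
    (1 + phi_adj) = (1 + phi_mle) * (n - p) / n for the p estimated cell
    means: the ML precision is otherwise biased upward at few observers
    per cell, exactly as an ML variance without df correction.
    """
    from statsmodels.othermod.betareg import BetaModel

    labels, idx = np.unique(cells, return_inverse=True)
    exog = np.zeros((len(y), len(labels)))
    exog[np.arange(len(y)), idx] = 1.0
    model = BetaModel(y, exog, exog_precision=np.ones((len(y), 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=start, disp=0)
    mu_cells = 1.0 / (1.0 + np.exp(-res.params[:-1]))
    n, p = len(y), len(labels)
    phi_mle = float(np.exp(res.params[-1]))
    phi = max((1.0 + phi_mle) * (n - p) / n - 1.0, 0.05)
    return float(mu_cells.mean()), phi, mu_cells, res.params


def beta_precision_sd(
    data: pd.DataFrame,
    value_col: str = "value",
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[VariabilityEstimate]:
    """Per-structure SD of a fraction (V5GY) from the beta model.

    Structures whose values are all 0 (or all 1) are flagged
    "not calculated" (no variability model is identifiable), mirroring
    how an always-unexposed structure is treated in practice.  Intervals
    are percentile bootstrap over ``n_boot`` parametric resamples.
    """
    check_cell_indexed(data, value_col)
    vals = data[value_col]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("beta model requires values in [0, 1]")
    rng = np.random.default_rng(seed)
    alpha = 1.0 - level
    out = []
    for structure, grp in data.groupby("structure", sort=False):
        y = grp[value_col].to_numpy(float)
        cells = grp["patient"].to_numpy()
        if np.all(y == 0) or np.all(y == 1):
            out.append(
                VariabilityEstimate(
                    structure, "sd", np.nan, np.nan, np.nan, "confidence",
                    flag=NOT_CALCULATED,
                )
            )
            continue
        ysq = _squeeze(y) if (y.min() == 0.0 or y.max() == 1.0) else y
        mu_bar, phi, mu_cells, params = _fit_beta_structure(ysq, cells)
        sd = beta_sd_closed_form(mu_bar, phi)
        # parametric bootstrap from the fitted cell-level beta distributions
        _, cell_idx = np.unique(cells, return_inverse=True)
        mu_obs = mu_cells[cell_idx]
        boots = []
        for _ in range(n_boot):
            yb = rng.beta(mu_obs * phi, (1.0 - mu_obs) * phi)
            yb = np.clip(yb, 1e-9, 1.0 - 1e-9)
            try:
                mb, pb, _, _ = _fit_beta_structure(yb, cells, start=params)
            except Exception:  # rare non-convergence on extreme resamples
                continue
            boots.append(beta_sd_closed_form(mb, pb))
        if len(boots) >= max(10, n_boot // 2):
            lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
            lo, hi = min(lo, sd), max(hi, sd)
        else:
            lo = hi = sd
        out.append(
            VariabilityEstimate(structure, "sd", sd, float(lo), float(hi),
                                "confidence")
        )
    return out


# ---------------------------------------------------------------------------
# ICC(2)


def icc2_from_matrix(values: np.ndarray, level: float = 0.95):
    """ICC(2,1) (two-way random, absolute agreement, single rater) from an
    n x k (patients x observers) matrix, with the F-based CI.

    Returns (icc, low, high).
    """
    x = np.asarray(values, float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 patients and 2 observers")
    if np.isnan(x).any():
        raise ValueError("ICC grid contains missing cells")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 0.0

    # McGraw & Wong (1996) interval for ICC(A,1)
    alpha = 1.0 - level
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        low = high = icc
    return float(icc), float(min(low, icc)), float(max(high, icc))


def icc2(
    data: pd.DataFrame,
    value_col: str = "value",
    level: float = 0.95,
    max_missing: float = 0.10,
) -> list[VariabilityEstimate]:
    """Per-structure ICC(2,1) of the patients x observers grid.

    Patients with incomplete observer sets are dropped (no imputation);
    if more than ``max_missing`` of cells are missing the structure
    errors out.  Structures with zero variance are flagged.
    """
    check_cell_indexed(data, value_col)
    out = []
    for structure, grp in data.groupby("structure", sort=False):
        wide = grp.pivot(index="patient", columns="observer", values=value_col)
        frac_missing = float(wide.isna().to_numpy().mean())
        if frac_missing > max_missing:
            raise ValueError(
                f"{structure}: {frac_missing:.0%} cells missing exceeds "
                f"{max_missing:.0%}; cannot estimate ICC"
            )
        full = wide.dropna(axis=0)
        x = full.to_numpy(float)
        if np.allclose(x.std(), 0):
            out.append(
                VariabilityEstimate(
                    structure, "icc", np.nan, np.nan, np.nan, "confidence",
                    flag=NOT_CALCULATED,
                )
            )
            continue
        icc, lo, hi = icc2_from_matrix(x, level=level)
        out.append(
            VariabilityEstimate(structure, "icc", icc, lo, hi, "confidence")
        )
    return out


# ---------------------------------------------------------------------------
# combined report


def _to_frame(estimates, prefix):
    rows = {}
    for e in estimates:
        rows[e.structure] = {
            prefix: e.estimate,
            f"{prefix}_low": e.interval_low,
            f"{prefix}_high": e.interval_high,
            f"{prefix}_flag": e.flag or "",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def variability_report(
    volumes: pd.DataFrame,
    dmean: pd.DataFrame,
    d2cc: pd.DataFrame,
    v5gy: pd.DataFrame,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per structure: CV(volume), CV(DMEAN), CV(D2CC), SD(V5GY) and
    ICC(2) for each of the four quantities, all with 95% intervals.

    CVs are reported as fractions (0.052 = 5.2%); SD(V5GY) on the V5GY
    fraction scale.  Per-metric "not calculated" flags propagate into
    ``*_flag`` columns.  Deterministic given data + seed.
    """
    parts = []
    for name, df in [("volume", volumes), ("dmean", dmean), ("d2cc", d2cc)]:
        parts.append(_to_frame(lognormal_cv(df, level=level), f"cv_{name}"))
        parts.append(_to_frame(icc2(df, level=level), f"icc_{name}"))
    parts.append(
        _to_frame(
            beta_precision_sd(v5gy, level=level, n_boot=n_boot, seed=seed),
            "sd_v5gy",
        )
    )
    # ICC of V5GY is undefined for structures with all-identical values
    parts.append(_to_frame(icc2(v5gy, level=level), "icc_v5gy"))
    report = pd.concat(parts, axis=1)
    report.index.name = "structure"
    return report.reset_index()
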