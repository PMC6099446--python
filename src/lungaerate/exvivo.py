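"""Ex vivo calibration: density-signal and attenuation-gas-fraction models.

An isolated lung of known mass is scanned at several continuous positive
airway pressure (CPAP) levels.  Each scan yields a segmented lung volume
``V_CPAP`` (mL) and a mean signal ``MRI_CPAP`` (GU, optionally normalized
to a water or muscle reference imaged alongside the sample).  From these:

* tissue density  ``rho = mass / V``  (g/mL),
* gas fraction    ``GAS_F = (V_CPAP - V_0) / V_CPAP``  with the fully
  deflated 0 cmH2O scan as reference,
* signal attenuation  ``MRI_ATT = MRI_CPAP / MRI_0``.

Density is modelled as a linear (``a*x + b``) or quadratic (``a*x^2 + b``)
function of signal with a per-sample random intercept (repeated measures)
and a fixed additive offset for saline-instilled (injured) samples; model
forms are compared by the corrected Akaike information criterion (AICc)
and the injury effect by a likelihood-ratio test.  Attenuation falls
linearly with gas fraction; the fitted line, evaluated at the gas-fraction
cut-offs 0.1 (non-aerated) and 0.5 (poorly aerated), yields the attenuation
thresholds that are later translated to in vivo scans.  Threshold
confidence intervals come from a nonparametric bootstrap over lungs.

All fits use maximum likelihood (not REML) so AICc values are comparable
across fixed-effect structures.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: CPAP levels (cmH2O) in acquisition order; 0 defines the deflated reference
CPAP_LEVELS = (0, 40, 10, 2)

#: gas-fraction cut-offs delimiting non-aerated and poorly aerated tissue
GASF_CUTOFF_NONAERATED = 0.1
GASF_CUTOFF_POOR = 0.5

#: clamp limit for slightly negative gas fractions (measurement noise)
_GASF_CLAMP_FLOOR = -0.05

SAMPLE_TABLE_COLUMNS = [
    "sample_id", "group", "mass_g", "evlw_fraction", "cpap_cmh2o",
    "volume_ml", "mean_signal_gu", "water_ref_gu", "muscle_ref_gu",
    "air_ref_gu",
]


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------

def compute_density(mass_g: float, volume_ml: float) -> float:
    """Tissue density in g/mL from scale mass and MRI-segmented volume."""
    if volume_ml <= 0:
        raise ValueError(f"volume must be > 0 mL, got {volume_ml}")
    return mass_g / volume_ml


def compute_gas_fraction(v_cpap_ml: float, v0_ml: float) -> float:
    """Gas fraction (V_CPAP - V_0)/V_CPAP relative to the deflated scan."""
    if v_cpap_ml <= 0:
        raise ValueError(f"V_CPAP must be > 0 mL, got {v_cpap_ml}")
    if v0_ml <= 0:
        raise ValueError(f"V_0 must be > 0 mL, got {v0_ml}")
    gasf = (v_cpap_ml - v0_ml) / v_cpap_ml
    if gasf < _GASF_CLAMP_FLOOR:
        logger.warning(
            "gas fraction %.3f below %.2f; volumes may be mismatched",
            gasf, _GASF_CLAMP_FLOOR,
        )
    return gasf


def compute_attenuation(mri_cpap_gu: float, mri0_gu: float) -> float:
    """Signal attenuation MRI_CPAP/MRI_0 relative to the deflated scan."""
    if mri0_gu <= 0:
        raise ValueError(f"MRI_0 must be > 0 GU, got {mri0_gu}")
    return mri_cpap_gu / mri0_gu


def aicc(log_likelihood: float, k_parameters: int, n_obs: int) -> float:
    """Corrected Akaike information criterion.

    ``k`` counts fixed-effect coefficients plus variance components.
    """
    if n_obs - k_parameters - 1 <= 0:
        raise ValueError(
            f"AICc undefined for n={n_obs}, k={k_parameters} (need n > k + 1)"
        )
    return (-2.0 * log_likelihood + 2.0 * k_parameters
            + 2.0 * k_parameters * (k_parameters + 1) / (n_obs - k_parameters - 1))


def sample_size_for_correlation(r: float, alpha: float = 0.05,
                                power: float = 0.9) -> int:
    """Smallest n detecting a correlation of magnitude ``r`` (two-sided).

    Standard Fisher-z approximation:
    ``n = ceil(((z_{alpha/2} + z_beta) / atanh(|r|))^2 + 3)``.
    """
    if not 0 < abs(r) < 1:
        raise ValueError(f"need 0 < |r| < 1, got {r}")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return math.ceil(((z_a + z_b) / math.atanh(abs(r))) ** 2 + 3)


def mean_sd_population(values: Iterable[float]) -> tuple[float, float]:
    """Mean and population SD (divisor n), the convention used in reports."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    return float(arr.mean()), float(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

def read_sample_table(path) -> pd.DataFrame:
    """Read the per-(sample, CPAP) CSV table and validate its schema."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in df.columns
               and c not in ("evlw_fraction", "water_ref_gu", "air_ref_gu")]
    if missing:
        raise ValueError(f"sample table missing required column(s): {missing}")
    return validate_sample_table(df)


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    bad_groups = set(df["group"].unique()) - {"healthy", "injured"}
    if bad_groups:
        raise ValueError(f"unknown group label(s): {sorted(bad_groups)}")
    for col, positive in (("mass_g", True), ("volume_ml", True),
                          ("mean_signal_gu", True)):
        bad = df.index[df[col] <= 0] if positive else []
        if len(bad):
            raise ValueError(f"non-positive {col} in row(s) {list(bad)}")
    for sid, sub in df.groupby("sample_id"):
        if 0 not in set(sub["cpap_cmh2o"]):
            raise ValueError(
                f"sample {sid!r} lacks the 0 cmH2O scan defining MRI_0 and V_0"
            )
    return df


def _normalized_signal(df: pd.DataFrame, normalization: str) -> pd.Series:
    if normalization == "none":
        return df["mean_signal_gu"].astype(float)
    col = {"water": "water_ref_gu", "muscle": "muscle_ref_gu"}.get(normalization)
    if col is None:
        raise ValueError(f"unknown normalization {normalization!r}")
    if col not in df.columns or df[col].isna().any():
        raise ValueError(f"normalization {normalization!r} requires column {col}")
    if (df[col] <= 0).any():
        raise ValueError(f"non-positive values in {col}")
    return df["mean_signal_gu"] / df[col]


def attenuation_table(records: pd.DataFrame, normalization: str = "muscle"
                      ) -> pd.DataFrame:
    """Per-(sample, CPAP) gas fraction and attenuation relative to 0 cmH2O.

    Gas fractions slightly below zero are kept raw for fitting (clamping is
    a classification-time concern); values below -0.05 trigger a warning.
    """
    records = validate_sample_table(records)
    sig = _normalized_signal(records, normalization)
    rows = []
    for sid, idx in records.groupby("sample_id").groups.items():
        sub = records.loc[idx]
        ref = sub[sub["cpap_cmh2o"] == 0].iloc[0]
        v0 = float(ref["volume_ml"])
        s0 = float(sig.loc[ref.name])
        for i in idx:
            row = records.loc[i]
            rows.append({
                "sample_id": sid,
                "group": row["group"],
                "cpap_cmh2o": row["cpap_cmh2o"],
                "gas_fraction": compute_gas_fraction(float(row["volume_ml"]), v0),
                "mri_att": compute_attenuation(float(sig.loc[i]), s0),
            })
    return pd.DataFrame(rows)


def descriptive_stats(records: pd.DataFrame) -> dict:
    """Mass and EVLW descriptives (mean +/- population SD) over samples."""
    per_sample = records.drop_duplicates("sample_id")
    mass_mean, mass_sd = mean_sd_population(per_sample["mass_g"])
    out = {
        "n_samples": int(per_sample.shape[0]),
        "mass_mean_g": mass_mean,
        "mass_sd_g": mass_sd,
    }
    injured = per_sample[per_sample["group"] == "injured"]
    if len(injured) and "evlw_fraction" in injured.columns \
            and injured["evlw_fraction"].notna().all():
        m, s = mean_sd_population(injured["evlw_fraction"])
        out["evlw_mean_g_per_g"] = m
        out["evlw_sd_g_per_g"] = s
    return out


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Fitted density-signal relation (one model form x normalization)."""

    model_form: str                 # "linear" | "quadratic"
    normalization: str              # "none" | "water" | "muscle"
    a: float                        # slope (on x or x^2)
    b: float                        # intercept
    injury_offset: float            # fixed additive effect of injury (g/mL)
    random_effect_var: float        # between-sample intercept variance
    residual_var: float
    aicc_value: float
    evlw_effect_p: float
    n_obs: int
    n_samples: int
    mixed: bool = True              # False when the fixed-effects fallback ran

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "model_form", "normalization", "a", "b", "injury_offset",
            "random_effect_var", "residual_var", "aicc_value",
            "evlw_effect_p", "n_obs", "n_samples", "mixed")}


@dataclass
class AttenuationFit:
    """Fitted attenuation-gas-fraction line with derived thresholds."""

    normalization: str
    slope: float
    intercept: float
    r_squared: float
    random_effect_var: float
    residual_var: float
    n_obs: int
    n_samples: int
    mixed: bool = True
    threshold_nonaerated: float | None = None
    ci_nonaerated: tuple[float, float] | None = None
    threshold_poor: float | None = None
    ci_poor: tuple[float, float] | None = None
    bootstrap_reps: int | None = None
    seed: int | None = None
    data: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "normalization", "slope", "intercept", "r_squared",
            "random_effect_var", "residual_var", "n_obs", "n_samples",
            "mixed", "threshold_nonaerated", "threshold_poor",
            "bootstrap_reps", "seed")}
        d["ci_nonaerated"] = list(self.ci_nonaerated) if self.ci_nonaerated else None
        d["ci_poor"] = list(self.ci_poor) if self.ci_poor else None
        return d


_TINY_VAR = 1e-12


def _gaussian_llf(resid: np.ndarray) -> float:
    """ML Gaussian log-likelihood of residuals (variance = SSR/n, floored)."""
    n = resid.size
    sigma2 = max(float(resid @ resid) / n, 1e-30)
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, _gaussian_llf(y - X @ beta)


def _mixedlm_fit(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Random-intercept LMM by ML; returns (beta, re_var, resid_var, llf)
    or None when the fit is singular/degenerate (caller falls back to OLS)."""
    import statsmodels.api as sm

    if np.var(y) < _TINY_VAR:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "powell", "lbfgs"):
            try:
                model = sm.MixedLM(y, X, groups=groups)
                res = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if not np.all(np.isfinite(res.fe_params)):
                continue
            re_var = float(np.asarray(res.cov_re).ravel()[0])
            resid_var = float(res.scale)
            if resid_var < _TINY_VAR * max(1.0, float(np.var(y))):
                return None        # degenerate (e.g. noiseless) data
            return np.asarray(res.fe_params), re_var, resid_var, float(res.llf)
    return None


def fit_density_signal_model(records: pd.DataFrame, model_form: str = "quadratic",
                             normalization: str = "muscle") -> CalibrationCurve:
    """Fit density = a*x + b (or a*x^2 + b) with random sample intercepts.

    ``x`` is the (optionally reference-normalized) mean lung signal.  The
    model carries a fixed additive injury offset; its p-value comes from a
    likelihood-ratio test against the fit without the covariate.  A singular
    mixed fit (zero between-sample variance, or zero residual variance as in
    noiseless synthetic data) falls back to a fixed-effects-only fit.
    """
    if model_form not in ("linear", "quadratic"):
        raise ValueError(f"unknown model form {model_form!r}")
    records = validate_sample_table(records)
    n_samples = records["sample_id"].nunique()
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {n_samples}")

    x = _normalized_signal(records, normalization).to_numpy(dtype=float)
    pred = x if model_form == "linear" else x ** 2
    y = (records["mass_g"] / records["volume_ml"]).to_numpy(dtype=float)
    injured = (records["group"] == "injured").to_numpy(dtype=float)
    groups = records["sample_id"].to_numpy()
    n = y.size

    X_full = np.column_stack([np.ones(n), pred, injured])
    X_red = X_full[:, :2]

    full = _mixedlm_fit(X_full, y, groups)
    red = _mixedlm_fit(X_red, y, groups)
    if full is not None and red is not None:
        beta, re_var, resid_var, llf = full
        _, _, _, llf_red = red
        mixed = True
        k = X_full.shape[1] + 2   # fixed effects + RE variance + residual
    else:
        logger.warning(
            "singular mixed fit (%s/%s); using fixed-effects-only fit",
            model_form, normalization,
        )
        beta, llf = _ols_fit(X_full, y)
        _, llf_red = _ols_fit(X_red, y)
        re_var, resid_var = 0.0, float(np.var(y - X_full @ beta))
        mixed = False
        k = X_full.shape[1] + 1   # fixed effects + residual variance

    lr = max(0.0, 2.0 * (llf - llf_red))
    p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return CalibrationCurve(
        model_form=model_form, normalization=normalization,
        a=float(beta[1]), b=float(beta[0]), injury_offset=float(beta[2]),
        random_effect_var=re_var, residual_var=resid_var,
        aicc_value=aicc(llf, k, n), evlw_effect_p=p,
        n_obs=n, n_samples=n_samples, mixed=mixed,
    )


def fit_attenuation_points(points: pd.DataFrame, normalization: str = "muscle"
                           ) -> AttenuationFit:
    """Fit MRI_ATT = slope * GAS_F + intercept with random sample intercepts.

    ``points`` needs columns sample_id, gas_fraction, mri_att.  R^2 is that
    of the fixed-effect (population) prediction.  The fitted points are
    retained on the result for bootstrap resampling of thresholds.
    """
    g = points["gas_fraction"].to_numpy(dtype=float)
    att = points["mri_att"].to_numpy(dtype=float)
    groups = points["sample_id"].to_numpy()
    n_samples = points["sample_id"].nunique()
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {n_samples}")
    if np.ptp(g) < 1e-12:
        raise ValueError("degenerate gas-fraction range: all values equal")

    X = np.column_stack([np.ones(g.size), g])
    fit = _mixedlm_fit(X, att, groups)
    if fit is not None:
        beta, re_var, resid_var, _ = fit
        mixed = True
    else:
        logger.warning("singular mixed fit for attenuation line; using OLS")
        beta, _ = _ols_fit(X, att)
        re_var, resid_var = 0.0, float(np.var(att - X @ beta))
        mixed = False

    resid = att - X @ beta
    ss_tot = float(((att - att.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return AttenuationFit(
        normalization=normalization, slope=float(beta[1]),
        intercept=float(beta[0]), r_squared=max(0.0, min(1.0, r2)),
        random_effect_var=re_var, residual_var=resid_var,
        n_obs=g.size, n_samples=n_samples, mixed=mixed,
        data=points[["sample_id", "gas_fraction", "mri_att"]].copy(),
    )


def fit_attenuation_line(records: pd.DataFrame, normalization: str = "muscle"
                         ) -> AttenuationFit:
    """Attenuation line from a raw sample table (see attenuation_table)."""
    return fit_attenuation_points(
        attenuation_table(records, normalization), normalization
    )


def derive_thresholds(fit: AttenuationFit,
                      cutoffs: Sequence[float] = (GASF_CUTOFF_NONAERATED,
                                                  GASF_CUTOFF_POOR),
                      n_boot: int = 1000, seed: int = 0) -> AttenuationFit:
    """Attenuation thresholds at the gas-fraction cut-offs, with bootstrap CIs.

    Point estimates are ``slope * cutoff + intercept``.  95% CIs come from a
    nonparametric bootstrap over lungs: resample samples with replacement and
    refit the line (fixed-effects estimator per replicate).  The interval is
    the point estimate +/- t_{0.975, n_samples-2} times the bootstrap SE;
    with few clusters this t-scaled construction holds the nominal level,
    where raw percentile intervals systematically undercover.  Deterministic
    under a fixed seed.
    """
    cutoffs = list(cutoffs)
    if len(cutoffs) != 2:
        raise ValueError("expected exactly two cut-offs (non-aerated, poor)")
    for c in cutoffs:
        if not 0 <= c < 1:
            raise ValueError(f"gas-fraction cut-off must lie in [0, 1), got {c}")
    if fit.data is None:
        raise ValueError("fit carries no per-sample data; cannot bootstrap")

    t_non = fit.slope * cutoffs[0] + fit.intercept
    t_poor = fit.slope * cutoffs[1] + fit.intercept

    rng = np.random.default_rng(seed)
    sample_ids = fit.data["sample_id"].unique()
    by_sample = {
        sid: (sub["gas_fraction"].to_numpy(dtype=float),
              sub["mri_att"].to_numpy(dtype=float))
        for sid, sub in fit.data.groupby("sample_id")
    }
    boot = np.empty((n_boot, 2))
    for i in range(n_boot):
        chosen = rng.choice(sample_ids, size=sample_ids.size, replace=True)
        g = np.concatenate([by_sample[s][0] for s in chosen])
        a = np.concatenate([by_sample[s][1] for s in chosen])
        if np.ptp(g) < 1e-12:
            boot[i] = (t_non, t_poor)
            continue
        X = np.column_stack([np.ones(g.size), g])
        beta, *_ = np.linalg.lstsq(X, a, rcond=None)
        boot[i] = (beta[1] * cutoffs[0] + beta[0],
                   beta[1] * cutoffs[1] + beta[0])
    df = max(1, len(sample_ids) - 2)
    tcrit = stats.t.ppf(0.975, df)
    se = boot.std(axis=0, ddof=1)
    ci_non = (float(t_non - tcrit * se[0]), float(t_non + tcrit * se[0]))
    ci_poor = (float(t_poor - tcrit * se[1]), float(t_poor + tcrit * se[1]))

    return replace(
        fit, threshold_nonaerated=float(t_non), ci_nonaerated=ci_non,
        threshold_poor=float(t_poor), ci_poor=ci_poor,
        bootstrap_reps=n_boot, seed=seed,
    )
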