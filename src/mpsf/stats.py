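"""Nested mixed-effects models linking retinal sensitivity to lesion load.

The core model regresses per-stimulus sensitivity (dB) on drusen volume,
HRF volume, visit number, eccentricity and the drusen-by-visit and
drusen-by-eccentricity interactions, with nested random intercepts for
stimulus within eye within patient.  Volumes are in 1e-3 mm^3 units,
visit is an integer covariate starting at 0 and eccentricity is in
degrees.  Estimation is restricted maximum likelihood by default, with
Wald 95% confidence intervals and z-tests; AIC comparisons use maximum
likelihood refits on identical rows.

Fitting is delegated to ``statsmodels`` MixedLM: the patient is the
grouping factor, and the eye and stimulus intercepts enter as variance
components nested within it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

VOLUME_MODEL_TERMS = ("drusen_vol_e3mm3", "hrf_vol_e3mm3", "visit", "ecc_deg",
                      "drusen_vol_e3mm3:visit", "drusen_vol_e3mm3:ecc_deg")

VOLUME_FORMULA = ("sensitivity_db ~ drusen_vol_e3mm3 + hrf_vol_e3mm3 + visit "
                  "+ ecc_deg + drusen_vol_e3mm3:visit + drusen_vol_e3mm3:ecc_deg")

PRESENCE_FORMULA = ("sensitivity_db ~ drusen_present_i + hrf_present_i + visit")


class DegenerateDesignError(ValueError):
    """Raised when a fixed effect is constant or the nesting collapses."""


@dataclass
class ModelFit:
    """Summary of one fitted mixed model."""

    formula: str
    terms: pd.DataFrame            # estimate, se, ci_low, ci_high, p per term
    variance_components: dict      # patient, eye, spot, residual (variances)
    loglike: float
    n_params: int                  # fixed effects + variance parameters
    reml: bool
    n_obs: int
    n_patients: int
    n_eyes: int
    n_spots: int
    converged: bool
    row_signature: int             # identifies the exact rows modelled

    @property
    def aic(self) -> float:
        """2k - 2 logLik; only meaningful for maximum-likelihood fits."""
        return 2.0 * self.n_params - 2.0 * self.loglike

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "terms": self.terms.reset_index().to_dict(orient="records"),
            "variance_components": self.variance_components,
            "loglike": self.loglike,
            "aic": self.aic,
            "reml": self.reml,
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "n_eyes": self.n_eyes,
            "n_spots": self.n_spots,
            "converged": self.converged,
        }


def _prepare(table: pd.DataFrame, require_cols) -> pd.DataFrame:
    df = table.copy()
    if "in_raster" in df.columns:
        df = df[df["in_raster"].astype(bool)]
    df = df.dropna(subset=[c for c in require_cols if c in df.columns])
    df["spot_uid"] = df["eye_id"].astype(int) * 10000 + df["spot_id"].astype(int)
    return df


def _row_signature(df: pd.DataFrame) -> int:
    key = pd.util.hash_pandas_object(
        df[["patient_id", "eye_id", "spot_id", "visit"]]).to_numpy()
    return int(np.bitwise_xor.reduce(key)) ^ len(df)


def _fit_ols(df: pd.DataFrame, formula: str) -> ModelFit:
    """Degenerate model spec with all random SDs fixed at zero."""
    result = smf.ols(formula, data=df).fit()
    fe = result.params
    se = result.bse
    z = sps.norm.ppf(0.975)
    terms = pd.DataFrame({
        "estimate": fe, "se": se,
        "ci_low": fe - z * se, "ci_high": fe + z * se,
        "p": 2.0 * sps.norm.sf(np.abs(fe / se)),
    })
    terms.index.name = "term"
    return ModelFit(
        formula=formula, terms=terms,
        variance_components={"patient": 0.0, "eye": 0.0, "spot": 0.0,
                             "residual": float(result.scale)},
        loglike=float(result.llf), n_params=len(fe) + 1, reml=False,
        n_obs=len(df), n_patients=int(df["patient_id"].nunique()),
        n_eyes=int(df["eye_id"].nunique()),
        n_spots=int(df["spot_uid"].nunique()), converged=True,
        row_signature=_row_signature(df))


def _fit_mixedlm(df: pd.DataFrame, formula: str, reml: bool):
    if df["patient_id"].nunique() < 2:
        raise DegenerateDesignError("need at least two patients for nested fits")
    vc = {"eye": "0 + C(eye_id)", "spot": "0 + C(spot_uid)"}
    model = smf.mixedlm(formula, data=df, groups="patient_id",
                        re_formula="1", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml, method=["lbfgs"])
        converged = bool(result.converged)
        if not converged:
            result = model.fit(reml=reml, method=["powell", "lbfgs"])
            converged = bool(result.converged)

    fe = result.fe_params
    se = result.bse_fe
    z = sps.norm.ppf(0.975)
    terms = pd.DataFrame({
        "estimate": fe,
        "se": se,
        "ci_low": fe - z * se,
        "ci_high": fe + z * se,
        "p": 2.0 * sps.norm.sf(np.abs(fe / se)),
    })
    terms.index.name = "term"
    scale = float(result.scale)
    # cov_re and vcomp are reported by statsmodels on the response scale
    vcomp = {
        "patient": float(result.cov_re.iloc[0, 0]),
        "eye": float(result.vcomp[0]),
        "spot": float(result.vcomp[1]),
        "residual": scale,
    }
    n_params = len(fe) + 3 + 1  # fixed + (patient, eye, spot) variances + residual
    fit = ModelFit(
        formula=formula,
        terms=terms,
        variance_components=vcomp,
        loglike=float(result.llf),
        n_params=n_params,
        reml=reml,
        n_obs=len(df),
        n_patients=int(df["patient_id"].nunique()),
        n_eyes=int(df["eye_id"].nunique()),
        n_spots=int(df["spot_uid"].nunique()),
        converged=converged,
        row_signature=_row_signature(df),
    )
    return fit, result


def fit_volume_model(table: pd.DataFrame, reml: bool = True,
                     include_random: bool = True) -> ModelFit:
    """Fit the main volume model on a spot-record table.

    Fixed effects: drusen volume, HRF volume, visit, eccentricity,
    drusen x visit and drusen x eccentricity; random intercepts for
    patient, eye within patient and stimulus within eye.  Rows flagged
    out of raster or with missing covariates are excluded.  With
    ``include_random=False`` all random SDs are fixed at zero, which
    collapses the model to ordinary least squares on the same fixed
    effects (useful for cohorts generated without random intercepts).
    """
    df = _prepare(table, ["sensitivity_db", "drusen_vol_e3mm3",
                          "hrf_vol_e3mm3", "visit", "ecc_deg"])
    for col in ("drusen_vol_e3mm3", "hrf_vol_e3mm3", "visit", "ecc_deg"):
        if df[col].nunique() <= 1:
            raise DegenerateDesignError(f"fixed effect '{col}' is constant")
    if not include_random:
        return _fit_ols(df, VOLUME_FORMULA)
    fit, _ = _fit_mixedlm(df, VOLUME_FORMULA, reml)
    return fit


def fit_presence_model(table: pd.DataFrame, reml: bool = True) -> ModelFit:
    """Fit the simplified presence/absence model.

    Drusen presence is volume > 0; HRF presence is post-floor volume > 0.
    Same nested random structure as the volume model.
    """
    df = _prepare(table, ["sensitivity_db", "drusen_present", "hrf_present",
                          "visit"])
    df["drusen_present_i"] = df["drusen_present"].astype(int)
    df["hrf_present_i"] = df["hrf_present"].astype(int)
    for col in ("drusen_present_i", "hrf_present_i"):
        if df[col].nunique() <= 1:
            raise DegenerateDesignError(
                f"presence indicator '{col}' is constant; model not identifiable")
    fit, _ = _fit_mixedlm(df, PRESENCE_FORMULA, reml)
    return fit


@dataclass
class SectorContrast:
    """One pairwise sector difference with Bonferroni adjustment."""

    sector_a: int
    sector_b: int
    estimate: float
    se: float
    p_raw: float
    p_adjusted: float


def fit_sector_model(table: pd.DataFrame, reml: bool = True
                     ) -> tuple[ModelFit, list[SectorContrast]]:
    """Replace eccentricity by the categorical ETDRS sector.

    Returns the fit and all pairwise sector contrasts, Wald-tested and
    Bonferroni-adjusted over the number of reported pairs (36 when all
    nine sectors are populated).  Empty sectors are dropped with a
    warning.
    """
    df = _prepare(table, ["sensitivity_db", "drusen_vol_e3mm3",
                          "hrf_vol_e3mm3", "visit", "sector"])
    df = df[df["sector"] > 0]
    sectors = sorted(df["sector"].unique())
    if len(sectors) < 2:
        raise DegenerateDesignError("need at least two populated sectors")
    if len(sectors) < 9:
        warnings.warn(f"only {len(sectors)} of 9 ETDRS sectors are populated; "
                      "empty sectors dropped", stacklevel=2)
    formula = ("sensitivity_db ~ drusen_vol_e3mm3 + hrf_vol_e3mm3 + visit "
               "+ C(sector)")
    fit, res = _fit_mixedlm(df, formula, reml)

    est = {sectors[0]: 0.0}
    names = {sectors[0]: None}
    for s in sectors[1:]:
        name = f"C(sector)[T.{s}]"
        est[s] = fit.terms.loc[name, "estimate"]
        names[s] = name
    cov = res.cov_params().iloc[:len(fit.terms), :len(fit.terms)]
    pairs = list(itertools.combinations(sectors, 2))
    m = len(pairs)
    contrasts = []
    for a, b in pairs:
        vec = np.zeros(len(fit.terms))
        idx = {t: i for i, t in enumerate(fit.terms.index)}
        if names[a] is not None:
            vec[idx[names[a]]] = 1.0
        if names[b] is not None:
            vec[idx[names[b]]] -= 1.0
        diff = est[a] - est[b]
        se = float(np.sqrt(vec @ cov.to_numpy() @ vec))
        p_raw = float(2.0 * sps.norm.sf(abs(diff) / se)) if se > 0 else 1.0
        contrasts.append(SectorContrast(
            sector_a=a, sector_b=b, estimate=float(diff), se=se,
            p_raw=p_raw, p_adjusted=min(1.0, m * p_raw)))
    return fit, contrasts


@dataclass
class LearningRefit:
    """Visit coefficient from one baseline-exclusion refit."""

    label: str
    estimable: bool
    estimate: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")


def learning_sensitivity(table: pd.DataFrame) -> list[LearningRefit]:
    """Probe the learning effect by excluding early visits.

    Returns the visit coefficient from (a) the full table, (b) the table
    without the baseline visit and (c) without the first two visits.
    Subsets with fewer than two distinct visits are flagged not
    estimable instead of fitted.
    """
    out = []
    visits = sorted(table["visit"].unique())
    subsets = [("all visits", table),
               ("excluding baseline", table[table["visit"] > visits[0]]),
               ("excluding first two visits",
                table[table["visit"] > visits[min(1, len(visits) - 1)]])]
    for label, sub in subsets:
        if sub["visit"].nunique() < 2:
            out.append(LearningRefit(label=label, estimable=False))
            continue
        fit = fit_volume_model(sub)
        row = fit.terms.loc["visit"]
        out.append(LearningRefit(label=label, estimable=True,
                                 estimate=float(row["estimate"]),
                                 ci_low=float(row["ci_low"]),
                                 ci_high=float(row["ci_high"]),
                                 p=float(row["p"])))
    return out


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """AIC table for maximum-likelihood fits on identical rows.

    Refuses REML fits (their likelihoods are not comparable across fixed
    structures) and fits on differing row sets.
    """
    if not fits:
        raise ValueError("no fits to compare")
    if any(f.reml for f in fits):
        raise ValueError("AIC comparison requires maximum-likelihood fits "
                         "(reml=False)")
    sig = fits[0].row_signature
    if any(f.row_signature != sig for f in fits):
        raise ValueError("fits were computed on different row sets")
    aics = np.array([f.aic for f in fits])
    return pd.DataFrame({
        "formula": [f.formula for f in fits],
        "n_params": [f.n_params for f in fits],
        "loglike": [f.loglike for f in fits],
        "aic": aics,
        "delta_aic": aics - aics.min(),
    })
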