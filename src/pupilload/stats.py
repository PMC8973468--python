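"""Per-feature mixed-model analysis of difficulty effects.

For each pupil feature a linear mixed model is fitted with difficulty
(low/medium/high) as a 3-level fixed effect and, per subject, a random
intercept plus — when identifiable — random difficulty effects (the
"slope" term capturing subject-specific sensitivity to load). Estimation
is by REML; the difficulty effect is tested with a likelihood-ratio test
comparing ML refits of the model with and without the fixed effect
(REML log-likelihoods are not comparable across fixed-effect structures),
chi-square with 2 df. Post-hoc pairwise contrasts of the three level
means use a single-step max-|z| adjustment under the joint normal
distribution of the contrast estimates — the mixed-model analogue of a
Tukey HSD family correction, since studentised-range theory does not
apply to LMMs — with a Holm fallback if the joint distribution is
degenerate. Influential observations are screened by standardised
conditional residuals and the model is refitted without them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

LEVELS = ("low", "medium", "high")
CONTRAST_NAMES = ("medium-low", "high-low", "high-medium")

DEFAULT_INFLUENCE_THRESHOLD = 3.0


@dataclass
class LMMSpec:
    """What to fit: response column, random structure, estimation method.

    ``random`` is ``"auto"`` (try intercept + per-level difficulty effects,
    fall back to intercept-only on a singular or non-convergent fit),
    ``"intercept"`` or ``"slope"``.
    """

    response: str
    random: str = "auto"
    method: str = "reml"


@dataclass
class FittedLMM:
    result: object  # statsmodels MixedLMResults (on the standardised response)
    spec: LMMSpec
    random_used: str  # "intercept" or "slope"
    converged: bool
    data: pd.DataFrame

    @property
    def y_scale(self) -> float:
        return getattr(self.result, "_y_scale", 1.0)

    @property
    def fixed_effects(self) -> np.ndarray:
        """(intercept, medium-low, high-low) on the original response scale."""
        return np.asarray(self.result.fe_params) * self.y_scale


@dataclass(frozen=True)
class LRTResult:
    feature: str
    chi2: float
    df: int
    p_value: float
    random_used: str


@dataclass(frozen=True)
class ContrastResult:
    feature: str
    contrast: str  # one of CONTRAST_NAMES
    estimate: float
    std_error: float
    p_raw: float
    p_adjusted: float


class FitError(RuntimeError):
    pass


def _check_data(data: pd.DataFrame, response: str) -> pd.DataFrame:
    for col in (response, "subject_id", "difficulty"):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    data = data.copy()
    data["difficulty"] = pd.Categorical(data["difficulty"], categories=LEVELS, ordered=True)
    if data["difficulty"].isna().any():
        raise ValueError("difficulty labels outside {low, medium, high}")
    present = set(data["difficulty"].unique())
    if present != set(LEVELS):
        raise ValueError(f"all three difficulty levels must be present, got {sorted(present)}")
    if data["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects for a mixed model")
    levels_per_subject = data.groupby("subject_id", observed=True)["difficulty"].nunique()
    if (levels_per_subject < 2).all():
        raise ValueError("each subject must be observed at >= 2 difficulty levels")
    return data


def _design(data: pd.DataFrame, with_difficulty: bool) -> np.ndarray:
    n = len(data)
    cols = [np.ones(n)]
    if with_difficulty:
        cols.append((data["difficulty"] == "medium").to_numpy(float))
        cols.append((data["difficulty"] == "high").to_numpy(float))
    return np.column_stack(cols)


def _fit(
    data: pd.DataFrame,
    response: str,
    with_difficulty: bool,
    random: str,
    reml: bool,
):
    """Fit one MixedLM on the variance-standardised response.

    Standardisation keeps the optimiser away from the degenerate
    likelihoods that tiny raw variances provoke; the scale factor is
    attached to the result (``_y_scale``) so estimates can be mapped back.
    The LRT statistic is invariant to this rescaling because both models
    are transformed identically.
    """
    y = data[response].to_numpy(float)
    y_scale = float(np.std(y))
    if y_scale == 0 or not np.isfinite(y_scale):
        y_scale = 1.0
    X = _design(data, with_difficulty)
    groups = data["subject_id"].to_numpy()
    if random == "slope":
        exog_re = _design(data, with_difficulty=True)
    else:
        exog_re = np.ones((len(data), 1))
    model = MixedLM(y / y_scale, X, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        last_exc: Exception | None = None
        # a boundary optimum can leave lbfgs with a numerically singular
        # Hessian; gradient-free optimisers then still succeed
        for method in (["lbfgs", "bfgs"], "powell", "nm"):
            try:
                result = model.fit(reml=reml, method=method)
            except np.linalg.LinAlgError as exc:
                last_exc = exc
                continue
            if np.isfinite(result.llf):
                result._y_scale = y_scale
                return result
            last_exc = FitError(f"{response}: non-finite log-likelihood")
    raise last_exc


def _is_singular(result, tol: float = 0.005) -> bool:
    """A random-effects covariance with a negligible diagonal entry is
    treated as singular (boundary fit).

    Fits run on the variance-standardised response, so the diagonal is in
    response-variance units; a component explaining under 0.5% of the
    response variance is a boundary artefact, and keeping it makes the ML
    likelihood-ratio test anticonservative for null effects.
    """
    diag = np.diag(np.atleast_2d(np.asarray(result.cov_re)))
    return bool(np.any(diag < tol))


def fit_lmm(data: pd.DataFrame, spec: LMMSpec) -> FittedLMM:
    """Fit the difficulty model for one feature.

    With ``random="auto"`` the richer subject-by-difficulty random
    structure is tried first and silently simplified to a random intercept
    when the fit is singular or fails to converge (logged).
    """
    data = _check_data(data, spec.response)
    reml = spec.method.lower() == "reml"
    order = {"auto": ["slope", "intercept"], "slope": ["slope"], "intercept": ["intercept"]}[
        spec.random
    ]
    last_exc: Exception | None = None
    for random in order:
        try:
            result = _fit(data, spec.response, True, random, reml)
        except Exception as exc:  # numerical failure: try the simpler structure
            last_exc = exc
            continue
        if random == "slope" and len(order) > 1 and (not result.converged or _is_singular(result)):
            logger.info(
                "%s: random difficulty effects singular/non-convergent; "
                "downgraded to random intercept",
                spec.response,
            )
            continue
        if not result.converged and len(order) > 1:
            continue
        return FittedLMM(
            result=result, spec=spec, random_used=random, converged=bool(result.converged), data=data
        )
    raise FitError(f"mixed model for {spec.response} did not converge") from last_exc


def lrt_difficulty(data: pd.DataFrame, spec: LMMSpec) -> LRTResult:
    """Likelihood-ratio test of the 3-level difficulty fixed effect.

    Both the full and the difficulty-free model are refitted by ML with
    the same random structure; 2*(llf_full - llf_reduced) is referred to
    a chi-square with 2 df.
    """
    data = _check_data(data, spec.response)
    if spec.random == "auto":
        fitted = fit_lmm(data, LMMSpec(spec.response, "auto", "reml"))
        random = fitted.random_used
    else:
        random = spec.random
    full = reduced = None
    if random == "slope":
        try:
            full = _fit(data, spec.response, True, "slope", reml=False)
            reduced = _fit(data, spec.response, False, "slope", reml=False)
        except (np.linalg.LinAlgError, ValueError):
            logger.info(
                "%s: ML refit with random difficulty effects failed; "
                "using random intercept for the LRT",
                spec.response,
            )
            random = "intercept"
    if full is None or reduced is None:
        full = _fit(data, spec.response, True, "intercept", reml=False)
        reduced = _fit(data, spec.response, False, "intercept", reml=False)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(sps.chi2.sf(chi2, df=2))
    return LRTResult(feature=spec.response, chi2=float(chi2), df=2, p_value=p, random_used=random)


def _contrast_matrix(k_fixed: int) -> np.ndarray:
    """Rows pick out medium-low, high-low, high-medium from
    (intercept, medium, high) fixed effects."""
    C = np.zeros((3, k_fixed))
    C[0, 1] = 1.0  # medium - low
    C[1, 2] = 1.0  # high - low
    C[2, 1], C[2, 2] = -1.0, 1.0  # high - medium
    return C


def _max_abs_z_adjust(z: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Single-step familywise p-values: P(max_j |Z_j| >= |z_k|) under the
    joint normal with correlation ``corr``."""
    # the three contrasts are linearly dependent (high-low = high-medium +
    # medium-low), so the correlation matrix is rank-2: allow it
    mvn = sps.multivariate_normal(mean=np.zeros(len(z)), cov=corr, allow_singular=True)
    out = np.empty_like(z, dtype=float)
    for k, zk in enumerate(np.abs(z)):
        box = mvn.cdf(np.full(len(z), zk), lower_limit=np.full(len(z), -zk))
        out[k] = min(1.0, max(0.0, 1.0 - float(box)))
    return out


def pairwise_contrasts(fitted: FittedLMM) -> list[ContrastResult]:
    """Estimates, SEs and family-adjusted p-values of the three pairwise
    difficulty contrasts."""
    result = fitted.result
    scale = fitted.y_scale
    fe = np.asarray(result.fe_params) * scale
    V = np.asarray(result.cov_params())[: len(fe), : len(fe)] * scale**2
    C = _contrast_matrix(len(fe))
    est = C @ fe
    cov_c = C @ V @ C.T
    se = np.sqrt(np.diag(cov_c))
    z = est / se
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    corr = cov_c / np.outer(se, se)
    try:
        p_adj = _max_abs_z_adjust(z, corr)
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("%s: joint contrast distribution degenerate; Holm fallback", fitted.spec.response)
        order = np.argsort(p_raw)
        p_adj = np.empty_like(p_raw)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (3 - rank) * p_raw[idx])
            p_adj[idx] = min(1.0, running)
    p_adj = np.maximum(p_adj, p_raw)
    return [
        ContrastResult(
            feature=fitted.spec.response,
            contrast=name,
            estimate=float(est[k]),
            std_error=float(se[k]),
            p_raw=float(p_raw[k]),
            p_adjusted=float(p_adj[k]),
        )
        for k, name in enumerate(CONTRAST_NAMES)
    ]


def influence_screen(
    fitted: FittedLMM, threshold: float = DEFAULT_INFLUENCE_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag observations with |standardised conditional residual| > threshold.

    Residuals are conditional on the predicted random effects and scaled by
    the residual standard deviation. Returns (retained rows, flagged rows).
    """
    data = fitted.data
    resid = np.asarray(fitted.result.resid, dtype=float)
    std_resid = resid / np.sqrt(fitted.result.scale)
    flag = np.abs(std_resid) > threshold
    return data.loc[~flag], data.loc[flag]


@dataclass
class StatsConfig:
    random: str = "auto"
    influence_threshold: float = DEFAULT_INFLUENCE_THRESHOLD
    features: tuple = ("BLPS", "MPDC", "APCPS", "PD", "E_pupil", "TTP", "PDS")


@dataclass
class FeatureAnalysis:
    """Per-feature difficulty analysis: LRT plus initial and post-screen contrasts."""

    lrt: list[LRTResult] = field(default_factory=list)
    contrasts: list[dict] = field(default_factory=list)  # rows with a "stage" key
    n_flagged: dict = field(default_factory=dict)

    def lrt_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"feature": r.feature, "chi2": r.chi2, "df": r.df, "p": r.p_value,
                 "random": r.random_used}
                for r in self.lrt
            ]
        )

    def contrast_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.contrasts)


def run_feature_analysis(features: pd.DataFrame, config: StatsConfig | None = None) -> FeatureAnalysis:
    """LRT and pairwise contrasts for every feature, before and after
    influence screening."""
    config = config or StatsConfig()
    if features["difficulty"].nunique() < 3:
        raise ValueError("all three difficulty levels must be present")
    out = FeatureAnalysis()
    for feat in config.features:
        spec = LMMSpec(response=feat, random=config.random)
        out.lrt.append(lrt_difficulty(features, spec))
        fitted = fit_lmm(features, spec)
        for c in pairwise_contrasts(fitted):
            out.contrasts.append({**vars(c), "stage": "initial"})
        retained, flagged = influence_screen(fitted, config.influence_threshold)
        out.n_flagged[feat] = len(flagged)
        if len(flagged) and retained["subject_id"].nunique() >= 2:
            refit = fit_lmm(retained, spec)
            final = pairwise_contrasts(refit)
        else:
            final = pairwise_contrasts(fitted)
        for c in final:
            out.contrasts.append({**vars(c), "stage": "final"})
    return out
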