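"""Seed-production (fitness) models and field-measurement conversions.

The measurement chain follows the field protocol: seeds are counted on five
flower heads (anthodia) per sampled inflorescence; per-inflorescence seed
number is the mean seeds-per-anthodium times the inflorescence's anthodium
count; plot-level production is the mean per-inflorescence quantity times
the number of inflorescences in the 1 m^2 plot. Fresh seed masses convert
to dry mass as dry = 0.89 x fresh. Braun-Blanquet cover ranks map to the
conventional midpoint percentages.

The four fitness responses (seed number / seed mass, per plot / per
inflorescence) are modelled on standardized predictors: environmental
favorability (logit-transformed ensemble probability of occurrence), trail
distance (human-disturbance proxy), hemiparasite / cushion / woody cover,
and inflorescence height, with an Env x Trail interaction in the full
model. Counts use a Poisson log-link GLMM (observation-level random effect
absorbing overdispersion); masses use a Gaussian LMM on the cube-root
scale. Model simplification is backward stepwise by ML-based AIC with a
2-unit tolerance and interaction-before-main-effect ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed import MixedFit, fit_glmm

__all__ = [
    "BRAUN_BLANQUET_COVER",
    "FitnessModel",
    "braun_blanquet_to_cover",
    "seeds_per_inflorescence",
    "fresh_to_dry",
    "plot_totals",
    "prepare_predictors",
    "build_design",
    "fit_count_model",
    "fit_mass_model",
    "stepwise_backward",
    "r2_nakagawa",
    "significance_flags",
]

FRESH_TO_DRY_COEF = 0.89

BRAUN_BLANQUET_COVER: dict[str, float] = {
    "0": 0.0,   # absent
    "+": 0.5,
    "1": 5.0,
    "2": 17.5,
    "3": 37.5,
    "4": 62.5,
    "5": 87.5,
}


def braun_blanquet_to_cover(rank) -> float:
    """Convert a Braun-Blanquet rank (+, 1..5; 0 = absent) to midpoint % cover."""
    key = str(rank).strip()
    if key in ("0.0",):
        key = "0"
    if key not in BRAUN_BLANQUET_COVER:
        raise ValueError(f"unknown Braun-Blanquet rank {rank!r}")
    return BRAUN_BLANQUET_COVER[key]


def seeds_per_inflorescence(mean_seeds_per_anthodium: float, anthodium_count: int) -> int:
    """Seed count of one inflorescence, rounded half-up to an integer."""
    if mean_seeds_per_anthodium < 0 or anthodium_count < 0:
        raise ValueError("inputs must be non-negative")
    raw = mean_seeds_per_anthodium * anthodium_count
    return int(np.floor(raw + 0.5))


def fresh_to_dry(mass_mg: float) -> float:
    """Dry seed mass from fresh mass (mg): dry = 0.89 x fresh."""
    if np.any(np.asarray(mass_mg) < 0):
        raise ValueError("mass must be non-negative")
    return FRESH_TO_DRY_COEF * mass_mg


def plot_totals(mean_per_inflorescence: float, n_inflorescences: int) -> float:
    """Scale a mean per-inflorescence quantity to the 1 m^2 plot."""
    if n_inflorescences < 0:
        raise ValueError("inflorescence count must be non-negative")
    return mean_per_inflorescence * n_inflorescences


# ---------------------------------------------------------------------------
# design construction

_LOGIT_CLIP = 1e-6


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), _LOGIT_CLIP, 1.0 - _LOGIT_CLIP)
    return np.log(p / (1.0 - p))


def prepare_predictors(
    table: pd.DataFrame,
    predictors: list[str],
    favorability_col: str = "favorability",
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Logit-transform favorability, then center/scale every predictor.

    Returns the standardized design columns and the constants needed to
    reproduce the transform at prediction time:
    ``{column: {"mean": m, "sd": s, "logit": bool}}``.
    """
    design = pd.DataFrame(index=table.index)
    scaling: dict[str, dict[str, float]] = {}
    for col in predictors:
        v = table[col].to_numpy(dtype=float)
        is_fav = col == favorability_col
        if is_fav:
            v = _logit(v)
        m, s = float(np.mean(v)), float(np.std(v, ddof=1))
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"predictor {col!r} has zero variance; cannot standardize")
        design[col] = (v - m) / s
        scaling[col] = {"mean": m, "sd": s, "logit": bool(is_fav)}
    return design, scaling


def build_design(std: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Design matrix from standardized columns; ``a:b`` denotes a product
    interaction; an intercept column is always prepended."""
    X = pd.DataFrame(index=std.index)
    X["(Intercept)"] = 1.0
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            X[t] = std[a].to_numpy() * std[b].to_numpy()
        else:
            X[t] = std[t].to_numpy()
    return X


# ---------------------------------------------------------------------------
# fitted-model container


@dataclass
class FitnessModel:
    response: str                       # e.g. "number_plot"
    family: str                         # "poisson" | "gaussian"
    fit: MixedFit
    scaling: dict[str, dict[str, float]]
    terms: list[str]
    rm2: float = float("nan")
    rc2: float = float("nan")
    aic_trace: list[tuple[str, float]] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return self.fit.aic

    def coef_table(self) -> pd.DataFrame:
        return self.fit.coef_table()

    def predict(self, raw: dict[str, float | np.ndarray]) -> np.ndarray:
        """Population-level prediction on the response scale.

        ``raw`` maps predictor names to raw-scale values; predictors not
        supplied sit at their training means (standardized 0). Counts
        back-transform by exp; masses by cubing the cube-root-scale value.
        """
        lengths = [np.size(v) for v in raw.values()] or [1]
        n = max(lengths)
        std: dict[str, np.ndarray] = {}
        for col, const in self.scaling.items():
            if col in raw:
                v = np.asarray(raw[col], dtype=float)
                if const["logit"]:
                    if np.any(v <= 0) or np.any(v >= 1):
                        v = np.clip(v, _LOGIT_CLIP, 1 - _LOGIT_CLIP)
                    v = _logit(v)
                std[col] = (v - const["mean"]) / const["sd"]
            else:
                std[col] = np.zeros(n)
        eta = np.full(n, 0.0)
        for term, b in zip(self.fit.terms, self.fit.beta):
            if term == "(Intercept)":
                eta = eta + b
            elif ":" in term:
                a, c = term.split(":")
                eta = eta + b * std[a] * std[c]
            else:
                eta = eta + b * std[term]
        if self.family == "poisson":
            return np.exp(eta)
        return eta**3  # Gaussian fit is on the cube-root scale

    @classmethod
    def from_dict(cls, doc: dict) -> "FitnessModel":
        fit = MixedFit(
            family=doc["family"],
            terms=list(doc["terms"]),
            beta=np.asarray(doc["beta"], dtype=float),
            se=np.asarray(doc["se"], dtype=float),
            vc=dict(doc["vc"]),
            loglik=float(doc["loglik"]),
            aic=float(doc["aic"]),
            n=int(doc.get("n", 0)),
        )
        model = cls(
            response=doc["response"],
            family=doc["family"],
            fit=fit,
            scaling=doc["scaling"],
            terms=list(doc["terms"]),
            rm2=doc.get("rm2", float("nan")),
            rc2=doc.get("rc2", float("nan")),
            aic_trace=[tuple(x) for x in doc.get("aic_trace", [])],
        )
        return model

    def to_dict(self) -> dict:
        ci = self.fit.ci
        return {
            "response": self.response,
            "family": self.family,
            "terms": self.fit.terms,
            "beta": self.fit.beta.tolist(),
            "se": self.fit.se.tolist(),
            "ci": ci.tolist(),
            "vc": self.fit.vc,
            "aic": self.fit.aic,
            "loglik": self.fit.loglik,
            "n": self.fit.n,
            "rm2": self.rm2,
            "rc2": self.rc2,
            "scaling": self.scaling,
            "aic_trace": self.aic_trace,
        }


# ---------------------------------------------------------------------------
# model fitting


def _fit(
    response: np.ndarray,
    std: pd.DataFrame,
    terms: list[str],
    groups: dict[str, np.ndarray],
    family: str,
    olre: str | None,
    scaling: dict,
    label: str,
) -> FitnessModel:
    X = build_design(std, terms)
    fit = fit_glmm(response, X, groups=groups, family=family, olre=olre)
    model = FitnessModel(
        response=label, family=family, fit=fit, scaling=scaling, terms=list(terms)
    )
    model.rm2, model.rc2 = r2_nakagawa(model)
    return model


def fit_count_model(
    counts: np.ndarray,
    std: pd.DataFrame,
    terms: list[str],
    groups: dict[str, np.ndarray],
    olre: str | None = None,
    scaling: dict | None = None,
    label: str = "number",
) -> FitnessModel:
    """Poisson log-link GLMM for seed numbers."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return _fit(counts, std, terms, groups, "poisson", olre, scaling or {}, label)


def fit_mass_model(
    masses: np.ndarray,
    std: pd.DataFrame,
    terms: list[str],
    groups: dict[str, np.ndarray],
    scaling: dict | None = None,
    label: str = "mass",
    cube_root: bool = True,
) -> FitnessModel:
    """Gaussian LMM for seed masses, fitted on the cube-root scale."""
    masses = np.asarray(masses, dtype=float)
    if np.any(masses < 0):
        raise ValueError("masses must be non-negative")
    y = np.cbrt(masses) if cube_root else masses
    return _fit(y, std, terms, groups, "gaussian", None, scaling or {}, label)


# ---------------------------------------------------------------------------
# backward stepwise selection


def _droppable(terms: list[str]) -> list[str]:
    """Terms removable this round: a main effect is protected while any
    retained interaction contains it."""
    protected = set()
    for t in terms:
        if ":" in t:
            protected.update(t.split(":"))
    return [t for t in terms if ":" in t or t not in protected]


def stepwise_backward(
    response: np.ndarray,
    std: pd.DataFrame,
    full_terms: list[str],
    groups: dict[str, np.ndarray],
    family: str,
    olre: str | None = None,
    scaling: dict | None = None,
    label: str = "",
    aic_tol: float = 2.0,
) -> FitnessModel:
    """Backward single-term deletion guided by AIC.

    Each round refits the model for every droppable term and removes the
    term whose deletion lowers AIC most (deletions raising AIC by at most
    ``aic_tol`` are still accepted, favoring parsimony); stops when the best
    deletion would raise AIC by more than ``aic_tol`` or would leave the
    model more than ``aic_tol`` above the lowest AIC encountered. Main
    effects are only droppable once their interactions are gone.
    """

    def fit_terms(terms: list[str]) -> FitnessModel:
        if family == "poisson":
            return fit_count_model(response, std, terms, groups, olre=olre,
                                   scaling=scaling or {}, label=label)
        return fit_mass_model(response, std, terms, groups, scaling=scaling or {},
                              label=label, cube_root=False)

    terms = list(full_terms)
    current = fit_terms(terms)
    trace: list[tuple[str, float]] = [("<full>", current.aic)]
    best_aic = current.aic
    while terms:
        candidates = _droppable(terms)
        if not candidates:
            break
        trials = []
        for t in candidates:
            reduced = [x for x in terms if x != t]
            m = fit_terms(reduced)
            trials.append((m.aic, t, reduced, m))
        trials.sort(key=lambda z: z[0])
        aic_new, t_drop, reduced, m_new = trials[0]
        if aic_new > current.aic + aic_tol or aic_new > best_aic + aic_tol:
            break
        terms, current = reduced, m_new
        trace.append((f"-{t_drop}", aic_new))
        best_aic = min(best_aic, aic_new)
    current.aic_trace = trace
    current.terms = terms
    return current


# ---------------------------------------------------------------------------
# summaries


def r2_nakagawa(model: FitnessModel) -> tuple[float, float]:
    """Marginal and conditional R^2 for mixed models.

    Rm^2 uses the variance of the fixed-effect linear predictor over the
    total; Rc^2 adds group-level random-effect variances to the numerator.
    For the Gaussian family the residual variance enters the denominator;
    for the Poisson (log link) the denominator adds the OLRE variance and
    the lognormal distribution-specific variance ln(1 + 1/lambda) with
    lambda = exp(beta_0 + sigma_total^2 / 2).
    """
    fit = model.fit
    var_f = float(np.var(fit.fitted_linear))
    vc = dict(fit.vc)
    if fit.family == "gaussian":
        var_resid = vc.pop("residual", 0.0)
        var_g = sum(vc.values())
        denom = var_f + var_g + var_resid
    else:
        var_olre = vc.pop(fit.olre, 0.0) if fit.olre else 0.0
        var_g = sum(vc.values())
        sigma_tot = var_g + var_olre
        try:
            b0 = fit.beta[fit.terms.index("(Intercept)")]
        except ValueError:
            b0 = float(np.mean(fit.fitted_linear))
        lam = float(np.exp(b0 + sigma_tot / 2.0))
        var_d = float(np.log1p(1.0 / max(lam, 1e-12)))
        denom = var_f + var_g + var_olre + var_d
    if denom <= 0:
        return 0.0, 0.0
    return var_f / denom, (var_f + var_g) / denom


def significance_flags(model: FitnessModel) -> dict[str, bool]:
    """Per-term flag: 95% Wald CI excludes zero."""
    ci = model.fit.ci
    return {
        term: bool(lo > 0 or hi < 0)
        for term, (lo, hi) in zip(model.fit.terms, ci)
    }
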