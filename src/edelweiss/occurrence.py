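"""Presence / pseudo-absence dataset construction and predictor screening.

Pseudo-absences follow the surface range envelope (SRE) strategy: a
rectangular per-variable envelope encloses a stated fraction (default 95%)
of the presence records' environmental values, and absences are drawn
uniformly from grid cells whose conditions fall outside that envelope, at a
fixed absence:presence ratio (default 10:1).

"95% of presence data" is read as symmetric two-sided per-variable quantile
bounds (2.5% and 97.5%), the standard SRE construction; quantiles use the
linear-interpolation definition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

__all__ = [
    "EnvelopeModel",
    "ScreenResult",
    "fit_envelope",
    "sample_pseudo_absences",
    "univariate_importance",
    "spearman_matrix",
    "screen_predictors",
]


@dataclass
class EnvelopeModel:
    """Per-predictor [lower, upper] environmental envelope."""

    bounds: dict[str, tuple[float, float]]
    q: float = 0.95

    @property
    def predictors(self) -> list[str]:
        return list(self.bounds)

    def inside(self, table: pd.DataFrame) -> np.ndarray:
        """True where a record lies inside the envelope on *every* predictor."""
        ok = np.ones(len(table), dtype=bool)
        for name, (lo, hi) in self.bounds.items():
            v = table[name].to_numpy(dtype=float)
            ok &= (v >= lo) & (v <= hi)
        return ok

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"q": self.q, "bounds": {k: list(v) for k, v in self.bounds.items()}}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "EnvelopeModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls({k: (v[0], v[1]) for k, v in doc["bounds"].items()}, q=doc["q"])


def fit_envelope(presences: pd.DataFrame, predictors: list[str], q: float = 0.95) -> EnvelopeModel:
    """Fit the surface range envelope from presence environmental values."""
    if not 0 < q <= 1:
        raise ValueError(f"coverage level q must be in (0, 1], got {q}")
    if len(presences) < 5:
        raise ValueError("need at least 5 presences to fit an envelope")
    bounds: dict[str, tuple[float, float]] = {}
    alpha = (1.0 - q) / 2.0
    for name in predictors:
        v = presences[name].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"missing values in predictor {name!r}")
        lo, hi = np.quantile(v, [alpha, 1.0 - alpha])  # linear interpolation
        bounds[name] = (float(lo), float(hi))
    return EnvelopeModel(bounds, q=q)


def sample_pseudo_absences(
    envelope: EnvelopeModel,
    candidates: pd.DataFrame,
    n_presence: int,
    ratio: int = 10,
    seed: int | np.random.Generator = 0,
    presence_cells: set[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Sample ``ratio * n_presence`` cells outside the envelope, uniformly
    without replacement, excluding presence cells.

    Returns all eligible cells (with a warning) when fewer exist.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = candidates.loc[~envelope.inside(candidates)]
    if presence_cells:
        keep = [
            (r, c) not in presence_cells
            for r, c in zip(eligible["row"].to_numpy(), eligible["col"].to_numpy())
        ]
        eligible = eligible.loc[keep]
    n_target = ratio * n_presence
    if len(eligible) == 0:
        raise ValueError(
            "no candidate cells outside the envelope; enlarge the domain or lower q"
        )
    if len(eligible) < n_target:
        warnings.warn(
            f"only {len(eligible)} eligible cells for {n_target} pseudo-absences; using all",
            stacklevel=2,
        )
        chosen = eligible
    else:
        idx = rng.choice(len(eligible), size=n_target, replace=False)
        chosen = eligible.iloc[np.sort(idx)]
    out = chosen.copy()
    out["label"] = "pseudo_absence"
    return out.reset_index(drop=True)


def univariate_importance(values: np.ndarray, labels: np.ndarray) -> float:
    """Explained deviance D^2 of a univariate binomial (logit) GLM.

    D^2 = 1 - residual deviance / null deviance, clipped to [0, 1]; a
    perfectly separating predictor approaches 1 (with a convergence warning
    rather than an exception).
    """
    y = np.asarray(labels, dtype=float)
    x = np.asarray(values, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 records")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            d2 = 1.0 - fit.deviance / fit.null_deviance
        except Exception:  # perfect separation and friends
            warnings.warn("separation detected; importance capped at 1", stacklevel=2)
            return 1.0
    if not np.isfinite(d2):
        warnings.warn("degenerate fit; importance capped at 1", stacklevel=2)
        return 1.0
    return float(np.clip(d2, 0.0, 1.0))


def spearman_matrix(table: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """Pairwise Spearman rank correlations among predictor columns."""
    sub = table[predictors].to_numpy(dtype=float)
    if len(predictors) == 1:
        rho = np.ones((1, 1))
    else:
        rho = spearmanr(sub).statistic
        rho = np.atleast_2d(rho)
    return pd.DataFrame(rho, index=predictors, columns=predictors)


@dataclass
class ScreenResult:
    importances: dict[str, float]
    retained: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (name, reason)


def screen_predictors(
    importances: dict[str, float] | pd.Series,
    correlations: pd.DataFrame,
    d2_min: float = 0.30,
    rho_max: float = 0.70,
) -> ScreenResult:
    """Two-stage predictor screen.

    1. Drop every predictor with explained deviance D^2 below ``d2_min``.
    2. While any retained pair has |Spearman rho| >= ``rho_max``, take the
       pair with the largest |rho| and drop its lower-D^2 member (ties: the
       later-listed predictor).
    """
    imp = dict(importances)
    names = list(imp)
    if set(correlations.index) < set(names) or set(correlations.columns) < set(names):
        raise ValueError("correlation matrix does not cover all predictors")
    dropped: list[tuple[str, str]] = []
    retained = []
    for name in names:
        if imp[name] < d2_min:
            dropped.append((name, f"importance {imp[name]:.3f} < {d2_min}"))
        else:
            retained.append(name)
    while True:
        best_pair, best_rho = None, -1.0
        for i, a in enumerate(retained):
            for b in retained[i + 1 :]:
                rho = abs(float(correlations.loc[a, b]))
                if rho >= rho_max and rho > best_rho:  # ties: first-listed pair
                    best_pair, best_rho = (a, b), rho
        if best_pair is None:
            break
        a, b = best_pair
        # drop the lower-importance member; on ties the later-listed one
        victim = b if imp[b] <= imp[a] else a
        keeper = a if victim == b else b
        dropped.append((victim, f"|rho|={best_rho:.3f} with {keeper} (kept: higher D2)"))
        retained.remove(victim)
    return ScreenResult(importances=imp, retained=retained, dropped=dropped)
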