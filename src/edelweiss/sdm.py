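"""Ensemble species-distribution modelling.

The workflow mirrors the classic presence/pseudo-absence ensemble recipe:
repeated stratified 80/20 split-sample calibration of several learners,
member evaluation by the true skill statistic (TSS = sensitivity +
specificity - 1, maximized over binarization thresholds), retention of
members whose TSS exceeds a cutoff (default 0.80), and an equal-weight mean
of the retained members' continuous suitability predictions as the ensemble
probability of occurrence.

Four learners are registered natively (unpenalized logistic regression with
optional quadratic terms, the surface range envelope scorer, gradient
boosted trees, random forest); others can be plugged into ``LEARNERS``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from . import occurrence
from .geodata import Raster

__all__ = [
    "MemberModel",
    "EnsembleModel",
    "HabitatSummary",
    "LEARNERS",
    "split_sample",
    "fit_member",
    "tss",
    "tss_from_confusion",
    "build_ensemble",
    "fit_sdm",
    "permutation_importance",
    "response_curve",
    "predict_map",
    "apply_masks",
    "habitat_summary",
    "net_loss",
]


# ---------------------------------------------------------------------------
# learner registry


class _LogisticLearner:
    """Unpenalized-ish logistic regression, optionally with squared terms."""

    def __init__(self, quadratic: bool = True, seed: int = 0):
        self.quadratic = quadratic
        self.model = LogisticRegression(C=1e6, max_iter=2000)

    def _design(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([X, X**2]) if self.quadratic else X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_LogisticLearner":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model.fit(self._design(X), y)
        return self

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(self._design(X))[:, 1]


class _SreLearner:
    """Surface range envelope scorer: 1 inside the presence envelope, else 0."""

    def __init__(self, q: float = 0.95, seed: int = 0):
        self.q = q
        self.envelope: occurrence.EnvelopeModel | None = None
        self.columns: list[str] | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SreLearner":
        cols = [f"p{i}" for i in range(X.shape[1])]
        pres = pd.DataFrame(X[np.asarray(y) == 1], columns=cols)
        self.columns = cols
        self.envelope = occurrence.fit_envelope(pres, cols, q=self.q)
        return self

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        table = pd.DataFrame(X, columns=self.columns)
        return self.envelope.inside(table).astype(float)


class _GbmLearner:
    def __init__(self, seed: int = 0):
        self.model = GradientBoostingClassifier(n_estimators=100, random_state=seed)

    def fit(self, X, y):
        self.model.fit(X, y)
        return self

    def predict_prob(self, X):
        return self.model.predict_proba(X)[:, 1]


class _RfLearner:
    def __init__(self, seed: int = 0):
        self.model = RandomForestClassifier(n_estimators=200, random_state=seed)

    def fit(self, X, y):
        self.model.fit(X, y)
        return self

    def predict_prob(self, X):
        return self.model.predict_proba(X)[:, 1]


LEARNERS: dict[str, type] = {
    "glm": _LogisticLearner,
    "sre": _SreLearner,
    "gbm": _GbmLearner,
    "rf": _RfLearner,
}


# ---------------------------------------------------------------------------
# split-sample protocol


def split_sample(
    labels: np.ndarray,
    calib_frac: float = 0.8,
    reps: int = 10,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified calibration/evaluation splits plus one full-data
    entry (empty evaluation set) appended last."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("dataset needs both classes")
    if not 0 < calib_frac <= 1:
        raise ValueError("calib_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(reps):
        for _attempt in range(100):
            calib_parts, eval_parts = [], []
            for cls in classes:
                idx = np.flatnonzero(y == cls)
                perm = rng.permutation(idx)
                n_cal = int(round(calib_frac * len(idx)))
                calib_parts.append(perm[:n_cal])
                eval_parts.append(perm[n_cal:])
            calib = np.sort(np.concatenate(calib_parts))
            evl = np.sort(np.concatenate(eval_parts))
            if all((y[calib] == cls).any() for cls in classes):
                splits.append((calib, evl))
                break
        else:
            raise RuntimeError("could not build a calibration set with both classes")
    splits.append((np.arange(len(y)), np.array([], dtype=int)))
    return splits


# ---------------------------------------------------------------------------
# evaluation


def tss_from_confusion(tp: float, fn: float, tn: float, fp: float) -> float:
    """Sensitivity + specificity - 1 from confusion-matrix counts."""
    sens = tp / (tp + fn) if tp + fn > 0 else 0.0
    spec = tn / (tn + fp) if tn + fp > 0 else 0.0
    return sens + spec - 1.0


def tss(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Maximum TSS over candidate thresholds and the smallest arg-max.

    Candidates are the sorted unique scores and their midpoints; a record is
    predicted present when its score >= threshold.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("TSS needs both classes")
    uniq = np.unique(s)
    cands = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0]) if len(uniq) > 1 else uniq
    cands = np.sort(cands)
    pos, neg = y == 1, y == 0
    best_tss, best_thr = -np.inf, cands[0]
    for thr in cands:
        pred = s >= thr
        t = tss_from_confusion(
            tp=np.sum(pred & pos), fn=np.sum(~pred & pos),
            tn=np.sum(~pred & neg), fp=np.sum(pred & neg),
        )
        if t > best_tss:  # strictly greater => smallest threshold on ties
            best_tss, best_thr = t, thr
    return float(best_tss), float(best_thr)


# ---------------------------------------------------------------------------
# members and ensemble


@dataclass
class MemberModel:
    learner_id: str
    model: object
    tss: float
    threshold: float
    rep: int  # -1 marks the full-data (no-split) member
    resubstitution: bool = False  # True when TSS was not held-out

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_prob(X)


def fit_member(
    learner_spec: str,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    **kwargs,
) -> object:
    """Instantiate and fit a registered learner; returns the fitted learner."""
    if learner_spec not in LEARNERS:
        raise KeyError(f"unknown learner {learner_spec!r}; registry: {sorted(LEARNERS)}")
    learner = LEARNERS[learner_spec](seed=seed, **kwargs)
    return learner.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int))


@dataclass
class EnsembleModel:
    members: list[MemberModel]
    tss_min: float
    predictors: list[str]
    training_means: dict[str, float] = field(default_factory=dict)

    def predict_prob(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.predictors].to_numpy(dtype=float)
        preds = np.column_stack([m.predict_prob(X) for m in self.members])
        return preds.mean(axis=1)


def build_ensemble(
    members: list[MemberModel],
    tss_min: float = 0.80,
    predictors: list[str] | None = None,
    training_means: dict[str, float] | None = None,
) -> EnsembleModel:
    """Retain members with TSS strictly above ``tss_min``; equal-weight mean."""
    qualified = [m for m in members if m.tss > tss_min]
    if not qualified:
        best = max((m.tss for m in members), default=float("nan"))
        raise ValueError(f"no member exceeds TSS {tss_min}; best member TSS = {best:.3f}")
    return EnsembleModel(
        members=qualified,
        tss_min=tss_min,
        predictors=predictors or [],
        training_means=training_means or {},
    )


def fit_sdm(
    data: pd.DataFrame,
    predictors: list[str],
    learners: list[str] = ("glm", "sre", "gbm", "rf"),
    reps: int = 10,
    calib_frac: float = 0.8,
    tss_min: float = 0.80,
    seed: int = 0,
) -> tuple[EnsembleModel, list[MemberModel]]:
    """Full member-fitting protocol over repeated splits plus no-split fits.

    The no-split members have no held-out records; they inherit the mean
    held-out TSS of their learner's split-sample replicates (flagged via
    ``resubstitution=False`` only for split members).
    """
    y = (data["label"] == "presence").to_numpy().astype(int)
    X = data[predictors].to_numpy(dtype=float)
    splits = split_sample(y, calib_frac=calib_frac, reps=reps, seed=seed)
    members: list[MemberModel] = []
    per_learner_tss: dict[str, list[float]] = {lid: [] for lid in learners}
    full_entry = splits[-1]
    for rep, (calib, evl) in enumerate(splits[:-1]):
        for lid in learners:
            model = fit_member(lid, X[calib], y[calib], seed=seed + rep)
            score, thr = tss(model.predict_prob(X[evl]), y[evl])
            per_learner_tss[lid].append(score)
            members.append(MemberModel(lid, model, score, thr, rep=rep))
    calib, _ = full_entry
    for lid in learners:
        model = fit_member(lid, X[calib], y[calib], seed=seed + reps)
        inherited = float(np.mean(per_learner_tss[lid])) if per_learner_tss[lid] else float("nan")
        _, thr = tss(model.predict_prob(X[calib]), y[calib])
        members.append(MemberModel(lid, model, inherited, thr, rep=-1, resubstitution=True))
    means = {p: float(data[p].mean()) for p in predictors}
    ensemble = build_ensemble(members, tss_min=tss_min, predictors=predictors, training_means=means)
    return ensemble, members


# ---------------------------------------------------------------------------
# interpretation


def permutation_importance(
    ensemble: EnsembleModel,
    data: pd.DataFrame,
    predictor: str,
    n_perm: int = 5,
    seed: int = 0,
) -> float:
    """1 - Pearson correlation between original predictions and predictions
    with one predictor column permuted, averaged over permutations."""
    if predictor not in ensemble.predictors:
        raise KeyError(f"{predictor!r} not among training predictors {ensemble.predictors}")
    rng = np.random.default_rng(seed)
    X = data[ensemble.predictors].to_numpy(dtype=float)
    base = ensemble.predict_prob(X)
    if np.std(base) == 0:
        warnings.warn("constant predictions; permutation importance defined as 0", stacklevel=2)
        return 0.0
    j = ensemble.predictors.index(predictor)
    vals = []
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        perm = ensemble.predict_prob(Xp)
        if np.std(perm) == 0:
            vals.append(1.0 if np.std(base) > 0 else 0.0)
            continue
        r = float(np.corrcoef(base, perm)[0, 1])
        vals.append(1.0 - r)
    return float(np.mean(vals))


def response_curve(
    ensemble: EnsembleModel,
    data: pd.DataFrame,
    predictor: str,
    grid: np.ndarray,
) -> pd.DataFrame:
    """Ensemble predictions along ``grid`` with the other predictors held at
    their training means (evaluation-strip convention)."""
    means = ensemble.training_means or {p: float(data[p].mean()) for p in ensemble.predictors}
    strip = pd.DataFrame({p: np.full(len(grid), means[p]) for p in ensemble.predictors})
    strip[predictor] = np.asarray(grid, dtype=float)
    return pd.DataFrame({predictor: grid, "prediction": ensemble.predict_prob(strip)})


# ---------------------------------------------------------------------------
# maps, masks, habitat accounting


def predict_map(ensemble: EnsembleModel, rasters: dict[str, Raster]) -> Raster:
    """Per-cell ensemble probability of occurrence; nodata propagates."""
    missing = [p for p in ensemble.predictors if p not in rasters]
    if missing:
        raise KeyError(f"missing predictor rasters: {missing}")
    ref = rasters[ensemble.predictors[0]]
    for name in ensemble.predictors[1:]:
        if not rasters[name].aligned_with(ref):
            raise ValueError(f"raster {name!r} is not aligned with {ensemble.predictors[0]!r}")
    stack = np.stack([rasters[p].values for p in ensemble.predictors], axis=-1)
    valid = np.isfinite(stack).all(axis=-1)
    out = np.full(ref.spec.shape, np.nan)
    if valid.any():
        out[valid] = ensemble.predict_prob(stack[valid])
    return Raster(ref.spec, out, name="p_occurrence")


def apply_masks(
    prob: Raster,
    substrate_mask: Raster | None = None,
    landcover_mask: Raster | None = None,
    altitude: Raster | None = None,
    alt_min: float = 394.0,
) -> tuple[Raster, dict[str, int]]:
    """Set cells failing any mask (or below ``alt_min``) to nodata.

    Mask rasters are truthy grids (nonzero/finite = keep). Removal counts are
    attributed to the first failing cause in the order substrate, land cover,
    altitude, so the causes partition the removed cells.
    """
    vals = prob.values.copy()
    alive = np.isfinite(vals)
    removed: dict[str, int] = {}
    causes: list[tuple[str, np.ndarray]] = []
    for name, mask in (("substrate", substrate_mask), ("landcover", landcover_mask)):
        if mask is not None:
            if not mask.aligned_with(prob):
                raise ValueError(f"{name} mask not aligned with probability raster")
            causes.append((name, ~(np.isfinite(mask.values) & (mask.values != 0))))
    if altitude is not None:
        if not altitude.aligned_with(prob):
            raise ValueError("altitude raster not aligned with probability raster")
        causes.append(("altitude", ~(np.isfinite(altitude.values) & (altitude.values >= alt_min))))
    for name, fail in causes:
        kill = alive & fail
        removed[name] = int(kill.sum())
        vals[kill] = np.nan
        alive &= ~fail
    return prob.copy_with(vals), removed


@dataclass
class HabitatSummary:
    label: str
    n_cells: int
    area_km2: float
    masked_counts: dict[str, int] = field(default_factory=dict)


def habitat_summary(
    prob: Raster,
    p_min: float = 0.5,
    cell_area_km2: float = 1.0,
    label: str = "",
    masked_counts: dict[str, int] | None = None,
) -> HabitatSummary:
    """Count cells with probability strictly greater than ``p_min``."""
    with np.errstate(invalid="ignore"):
        n = int(np.nansum(prob.values > p_min))
    return HabitatSummary(
        label=label,
        n_cells=n,
        area_km2=n * cell_area_km2,
        masked_counts=dict(masked_counts or {}),
    )


def net_loss(current: HabitatSummary, future: HabitatSummary) -> float:
    """Percent loss of suitable cells between scenarios (negative = gain)."""
    if current.n_cells <= 0:
        raise ValueError("current habitat is empty; net loss undefined")
    return 100.0 * (current.n_cells - future.n_cells) / current.n_cells
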