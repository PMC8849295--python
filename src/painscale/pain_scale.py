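"""The pain-scale scoring core.

Pipeline (fit on baseline trials with the four natural stimuli — cotton
swab CS, dynamic brush DB, light pinprick LP, heavy pinprick HP):

1. composite nocifensive score = unweighted count of the four binary
   behaviors (orbital tightening, paw shake, jump, paw guard);
2. z-score the three features (composite, paw speed, paw height) against
   the pooled baseline population (sample SD, n − 1);
3. project onto the leading principal component of the z-feature
   covariance, sign-oriented so noxious (HP) trials score above innocuous
   (CS) trials — the single-index "PC1 pain score";
4. train an RBF-kernel SVM (gamma = 1, C = 1) on the scalar PC1 scores of
   CS (nonpain) and HP (pain) trials and calibrate a Platt sigmoid to
   yield a per-trial pain-like probability.

New data are always scored through the *stored* means/SDs/loadings/SVM;
nothing is refit at prediction time, so appending trials never changes
the scores of old trials.

Also here: the traditional ascending von Frey threshold procedure
(smallest force with withdrawal proportion >= 40%) and the 5-trial
percent response at 10 g.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.svm import SVC

from .errors import (
    AmbiguityError,
    DegenerateFeatureError,
    InputError,
    ModelStateError,
    TrialValidationError,
)
from .trial_model import (
    BEHAVIOR_COLUMNS,
    FEATURE_NAMES,
    NOMINAL_CLASS,
    Behaviors,
    ScaleModel,
)

BASELINE_STIMULI = ("CS", "DB", "LP", "HP")
SVM_STIMULI = ("CS", "HP")


# ---------------------------------------------------------------------------
# composite score
# ---------------------------------------------------------------------------


def composite_score(behaviors: Behaviors) -> int:
    """Composite nocifensive score: the number of behaviors shown (0-4)."""
    return int(sum(behaviors.as_tuple()))


def composite_scores(df: pd.DataFrame) -> pd.Series:
    """Vectorized composite score over a trial table."""
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing behavior column(s): {', '.join(missing)}")
    vals = df[list(BEHAVIOR_COLUMNS)]
    if vals.isna().any().any():
        raise TrialValidationError("behavior columns contain missing values")
    return vals.sum(axis=1).astype(int)


def feature_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n, 3) feature matrix in the fixed order (composite, speed, height)."""
    comp = composite_scores(df).to_numpy(dtype=float)
    return np.column_stack(
        [comp, df["paw_speed_mm_per_s"].to_numpy(dtype=float), df["paw_height_mm"].to_numpy(dtype=float)]
    )


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------


class ZScoreParams:
    """Per-feature mean and sample standard deviation (denominator n − 1)."""

    def __init__(self, means: np.ndarray, sds: np.ndarray, feature_names=FEATURE_NAMES):
        self.means = np.asarray(means, dtype=float)
        self.sds = np.asarray(sds, dtype=float)
        self.feature_names = tuple(feature_names)
        if np.any(self.sds <= 0):
            raise DegenerateFeatureError("z-score SDs must be strictly positive")


def fit_zscore(features: np.ndarray, feature_names=FEATURE_NAMES) -> ZScoreParams:
    """Fit normalization on the pooled training population (all stimuli)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise InputError("features must be a 2-D (n, p) array")
    if X.shape[0] < 3:
        raise InputError(f"need at least 3 trials to fit z-scores, got {X.shape[0]}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for j, sd in enumerate(sds):
        if sd <= 1e-12:
            name = feature_names[j] if j < len(feature_names) else f"feature {j}"
            raise DegenerateFeatureError(f"feature {name!r} is constant; cannot z-score")
    return ZScoreParams(means, sds, feature_names)


def apply_zscore(params: ZScoreParams, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    return (X - params.means) / params.sds


# ---------------------------------------------------------------------------
# PC1
# ---------------------------------------------------------------------------


def fit_pc1(z: np.ndarray, stimulus_labels) -> tuple[np.ndarray, float]:
    """Leading eigenvector of the sample covariance of z, pain-oriented.

    The sign is chosen so the mean PC1 score of noxious (HP) trials
    exceeds that of innocuous (CS) trials; ties in the leading eigenvalue
    (within 1e-12) are an error, never a silent pick.  Returns
    ``(unit loadings, explained-variance fraction)``.
    """
    Z = np.asarray(z, dtype=float)
    labels = np.asarray(stimulus_labels)
    if Z.shape[0] < 4:
        raise InputError("need at least 4 trials to fit PC1")
    if Z.shape[0] != labels.shape[0]:
        raise InputError("z rows and orientation labels must align")
    classes = {NOMINAL_CLASS.get(str(l), "ambiguous") for l in labels}
    if "innocuous" not in classes or "noxious" not in classes:
        raise InputError("orientation requires both an innocuous- and a noxious-class stimulus")

    cov = np.cov(Z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] - eigvals[-2] <= 1e-12:
        raise AmbiguityError(
            f"leading eigenvalues tied within 1e-12 ({eigvals[-1]:.3e} vs {eigvals[-2]:.3e}); PC1 ambiguous"
        )
    v = eigvecs[:, -1]
    scores = Z @ v

    hp = labels == "HP"
    cs = labels == "CS"
    if np.any(hp) and np.any(cs):
        hi, lo = scores[hp].mean(), scores[cs].mean()
    else:  # fall back to nominal classes when CS/HP absent but classes present
        nox = np.isin(labels, [l for l in np.unique(labels) if NOMINAL_CLASS.get(str(l)) == "noxious"])
        inn = np.isin(labels, [l for l in np.unique(labels) if NOMINAL_CLASS.get(str(l)) == "innocuous"])
        hi, lo = scores[nox].mean(), scores[inn].mean()
    if hi < lo:
        v = -v
    explained = float(eigvals[-1] / eigvals.sum())
    return v, explained


def project_pc1(model: ScaleModel, features: np.ndarray) -> np.ndarray:
    """PC1 scores of new trials through the stored transformation.

    Uses the stored means/SDs/loadings; never refits on new data.
    """
    if model.pc1_loadings.size == 0:
        raise ModelStateError("model has no fitted PC1 loadings")
    params = ZScoreParams(model.zscore_means, model.zscore_sds, model.feature_names)
    return apply_zscore(params, features) @ model.pc1_loadings


# ---------------------------------------------------------------------------
# SVM + Platt calibration
# ---------------------------------------------------------------------------


def _rbf_decision(scores: np.ndarray, sv: np.ndarray, dual: np.ndarray, b: float, gamma: float) -> np.ndarray:
    s = np.asarray(scores, dtype=float).reshape(-1, 1)
    k = np.exp(-gamma * (s - sv.reshape(1, -1)) ** 2)
    return k @ dual + b


def _fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt's sigmoid fit P = 1 / (1 + exp(a f + b)) with smoothed targets."""
    f = np.asarray(decision, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        a, b = ab
        z = a * f + b
        # log(1 + exp(z)) computed stably
        log1pez = np.logaddexp(0.0, z)
        # p = 1/(1+e^z); NLL = -sum t log p + (1-t) log(1-p)
        return float(np.sum(t * log1pez + (1.0 - t) * (log1pez - z)))

    b0 = np.log((n_neg + 1.0) / (n_pos + 1.0))
    res = minimize(nll, x0=np.array([-1.0, b0]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    a, b = res.x
    return float(a), float(b)


def train_svm(
    pc1_scores: np.ndarray,
    labels: np.ndarray,
    trial_ids=None,
    gamma: float = 1.0,
    C: float = 1.0,
    seed: int = 0,
) -> dict:
    """Train the RBF SVM on scalar PC1 scores with Platt calibration.

    ``labels`` are 0 = nonpain (CS), 1 = pain (HP).  Training inputs are
    sorted by (score, trial_id) first so the result is independent of
    input order.  Returns a dict of serializable SVM + Platt parameters
    plus the training accuracy.
    """
    s = np.asarray(pc1_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape[0] != y.shape[0]:
        raise InputError("scores and labels must align")
    uniq = np.unique(y)
    if not np.array_equal(uniq, np.array([0, 1])):
        raise InputError(f"need both classes 0 and 1 in labels, got {uniq.tolist()}")
    if np.sum(y == 0) < 5 or np.sum(y == 1) < 5:
        raise InputError("need at least 5 trials per class to train the SVM")
    ids = np.array([str(i) for i in (trial_ids if trial_ids is not None else range(s.size))])
    order = np.lexsort((ids, s))
    s, y = s[order], y[order]

    clf = SVC(kernel="rbf", gamma=gamma, C=C, random_state=seed)
    clf.fit(s.reshape(-1, 1), y)
    sv = clf.support_vectors_.ravel().astype(float)
    dual = clf.dual_coef_.ravel().astype(float)
    intercept = float(clf.intercept_[0])

    f_train = _rbf_decision(s, sv, dual, intercept, gamma)
    a, b = _fit_platt(f_train, y)
    prob = 1.0 / (1.0 + np.exp(a * f_train + b))
    acc = float(np.mean((prob > 0.5).astype(int) == y))
    return {
        "gamma": gamma,
        "C": C,
        "support_vectors": sv,
        "dual_coef": dual,
        "intercept": intercept,
        "platt_a": a,
        "platt_b": b,
        "training_accuracy": acc,
    }


def predict_pain_probability(model: ScaleModel, pc1_scores: np.ndarray) -> np.ndarray:
    """Calibrated per-trial pain-like probability from PC1 scores."""
    if model.support_vectors.size == 0:
        raise ModelStateError("model has no trained SVM")
    f = _rbf_decision(np.asarray(pc1_scores, dtype=float), model.support_vectors,
                      model.dual_coef, model.intercept, model.gamma)
    p = 1.0 / (1.0 + np.exp(model.platt_a * f + model.platt_b))
    return np.clip(p, 0.0, 1.0)


def _probability_threshold(model_like, lo: float, hi: float) -> float:
    """PC1 value with calibrated probability 0.5, by grid scan + bisection."""

    def prob(s):
        f = _rbf_decision(np.atleast_1d(s), model_like["support_vectors"], model_like["dual_coef"],
                          model_like["intercept"], model_like["gamma"])
        return float(1.0 / (1.0 + np.exp(model_like["platt_a"] * f + model_like["platt_b"]))[0])

    grid = np.linspace(lo, hi, 513)
    g = np.array([prob(s) - 0.5 for s in grid])
    sign_change = np.flatnonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)
    if g[0] == 0:
        return float(grid[0])
    if sign_change.size == 0:
        # degenerate calibration; fall back to the probability-weighted midpoint
        return float(grid[int(np.argmin(np.abs(g)))])
    a, b = float(grid[sign_change[0]]), float(grid[sign_change[0] + 1])
    for _ in range(80):
        m = 0.5 * (a + b)
        if (prob(a) - 0.5) * (prob(m) - 0.5) <= 0:
            b = m
        else:
            a = m
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# full scale fit / scoring
# ---------------------------------------------------------------------------


def fit_scale(trials: pd.DataFrame, gamma: float = 1.0, C: float = 1.0, seed: int = 0) -> ScaleModel:
    """Fit the whole scale on a baseline trial table.

    z-scores and PC1 are fit on *all* baseline trials pooled across the
    four stimuli; the SVM is fit on CS and HP trials only.
    """
    present = set(trials["stimulus"].unique())
    for stim in BASELINE_STIMULI:
        if stim not in present:
            raise InputError(f"missing stimulus class {stim}")

    base = trials[trials["stimulus"].isin(BASELINE_STIMULI)]
    X = feature_matrix(base)
    zp = fit_zscore(X)
    Z = apply_zscore(zp, X)
    loadings, explained = fit_pc1(Z, base["stimulus"].to_numpy())
    scores = Z @ loadings

    svm_mask = base["stimulus"].isin(SVM_STIMULI).to_numpy()
    y = (base["stimulus"].to_numpy()[svm_mask] == "HP").astype(int)
    svm = train_svm(
        scores[svm_mask], y, trial_ids=base["trial_id"].to_numpy()[svm_mask],
        gamma=gamma, C=C, seed=seed,
    )
    # bracket the P = 0.5 crossing between the two class means: an RBF
    # decision function is non-monotone far outside the training support,
    # so scanning from the global score minimum can find a spurious tail
    # crossing instead of the innocuous/noxious boundary
    cs_mean = float(scores[svm_mask][y == 0].mean())
    hp_mean = float(scores[svm_mask][y == 1].mean())
    threshold = _probability_threshold(svm, cs_mean, hp_mean)

    n_per_class = base.loc[svm_mask, "stimulus"].value_counts().to_dict()
    model = ScaleModel(
        feature_names=FEATURE_NAMES,
        zscore_means=zp.means,
        zscore_sds=zp.sds,
        pc1_loadings=loadings,
        explained_variance_fraction=explained,
        sign_oriented=True,
        gamma=svm["gamma"],
        C=svm["C"],
        support_vectors=svm["support_vectors"],
        dual_coef=svm["dual_coef"],
        intercept=svm["intercept"],
        platt_a=svm["platt_a"],
        platt_b=svm["platt_b"],
        pain_threshold_pc1=threshold,
        provenance={
            "pca_stimuli": list(BASELINE_STIMULI),
            "svm_stimuli": list(SVM_STIMULI),
            "n_trials_pca": int(len(base)),
            "n_per_class": {str(k): int(v) for k, v in n_per_class.items()},
            "training_accuracy": svm["training_accuracy"],
            "seed": int(seed),
        },
    )
    return model


def score_trials(model: ScaleModel, trials: pd.DataFrame) -> pd.DataFrame:
    """Score a trial table through a fitted model.

    Adds columns: composite_score, z_composite, z_speed, z_height,
    pc1_score, pain_probability, pain_call.
    """
    X = feature_matrix(trials)
    zp = ZScoreParams(model.zscore_means, model.zscore_sds, model.feature_names)
    Z = apply_zscore(zp, X)
    scores = Z @ model.pc1_loadings
    prob = predict_pain_probability(model, scores)
    out = trials.copy()
    out["composite_score"] = X[:, 0].astype(int)
    out["z_composite"] = Z[:, 0]
    out["z_speed"] = Z[:, 1]
    out["z_height"] = Z[:, 2]
    out["pc1_score"] = scores
    out["pain_probability"] = prob
    out["pain_call"] = (prob > 0.5).astype(int)
    return out


# ---------------------------------------------------------------------------
# traditional von Frey scoring
# ---------------------------------------------------------------------------


def vfh_threshold(responses) -> float | None:
    """Ascending von Frey threshold.

    ``responses`` maps force (grams, strictly ascending) to
    ``(withdrawals, trials)``.  The threshold is the smallest force at
    which withdrawal responses occurred 40% of the time or more; ``None``
    if no force qualifies.
    """
    items = list(responses.items()) if isinstance(responses, dict) else list(responses)
    if not items:
        raise InputError("empty response series")
    forces = [float(f) for f, _ in items]
    if any(b <= a for a, b in zip(forces, forces[1:])):
        raise InputError(f"forces must be strictly ascending, got {forces}")
    for force, (w, n) in items:
        if n < 1:
            raise InputError(f"force {force} g has no trials")
        if not 0 <= w <= n:
            raise InputError(f"force {force} g: withdrawals {w} outside [0, {n}]")
        if w / n >= 0.40 - 1e-12:
            return float(force)
    return None


def percent_response_at_10g(outcomes) -> float:
    """Percent withdrawal across exactly five 10-g trials."""
    arr = np.asarray(list(outcomes), dtype=float)
    if arr.size != 5:
        raise InputError(f"percent response at 10 g requires exactly 5 outcomes, got {arr.size}")
    if not np.all(np.isin(arr, [0, 1])):
        raise InputError("outcomes must be binary")
    return float(100.0 * arr.sum() / 5.0)
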