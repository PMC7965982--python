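"""Machine-learning surrogate for the impact-simulation library.

A separate binary classifier is trained for each network-damage threshold:
the positive class means "more than this percentage of the DMN was
damaged".  Inputs are the impact boundary conditions (velocity, location,
angle, impactor curvature) plus two geometric features relating the impact
to the network (distance and angle to the closest DMN element).  Features
are screened by greedy forward selection under 5-fold cross-validated
logistic-regression AUC, then five member models — logistic regression,
Gaussian (linear) discriminant analysis, k-nearest-neighbor, naive Bayes
and a support-vector machine — are fitted on the standardized selected
features; the ensemble prediction is the arithmetic mean of the five
member probabilities.  Generalization is measured by leave-one-out
validation with rank-statistic AUC, Brier score, and sensitivity /
specificity / accuracy at a 0.5 probability cutoff.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "LOCATIONS",
    "IMPACTORS",
    "IMPACTOR_RADIUS",
    "LOCATION_UNIT_DIRECTIONS",
    "FEATURE_NAMES",
    "CONTINUOUS_FEATURES",
    "ImpactScenario",
    "FeatureVector",
    "TrainedEnsemble",
    "EvaluationReport",
    "make_scenario",
    "extract_features",
    "features_frame",
    "label_library",
    "forward_feature_selection",
    "train_bagging_ensemble",
    "evaluate_loo",
]

#: The five impact locations of the boundary-condition grid.
LOCATIONS = ("lateral_fronto_parietal", "fronto_polar", "vertex",
             "occipital", "temporal")

#: Impactor shape -> radius of curvature (m).  The flat impactor is
#: represented by a 1 m radius.
IMPACTOR_RADIUS = {
    "blunt_corner": 0.01,
    "round": 0.036,
    "flat": 1.0,
    "sharp_corner": 0.003,
}
IMPACTORS = tuple(IMPACTOR_RADIUS)

#: Representative outward unit directions of the five impact locations on
#: the toy head (x anterior, y left, z superior); the impact point is this
#: direction scaled to the outer skull radius.
LOCATION_UNIT_DIRECTIONS = {
    "lateral_fronto_parietal": np.array([0.55, 0.65, 0.52]),
    "fronto_polar": np.array([0.98, 0.0, 0.2]),
    "vertex": np.array([0.0, 0.0, 1.0]),
    "occipital": np.array([-0.99, 0.0, 0.14]),
    "temporal": np.array([0.0, 1.0, 0.0]),
}
LOCATION_UNIT_DIRECTIONS = {
    k: v / np.linalg.norm(v) for k, v in LOCATION_UNIT_DIRECTIONS.items()
}

#: Candidate features in declaration order (the tie-break order of the
#: greedy selection).
FEATURE_NAMES = (
    "velocity",
    "loc_lateral_fronto_parietal",
    "loc_fronto_polar",
    "loc_vertex",
    "loc_occipital",
    "loc_temporal",
    "perpendicular",
    "radius_of_curvature",
    "dist_to_dmn",
    "angle_to_dmn",
)
#: Features standardized before member fitting (indicators pass through).
CONTINUOUS_FEATURES = frozenset(
    {"velocity", "radius_of_curvature", "dist_to_dmn", "angle_to_dmn"})


@dataclass(frozen=True)
class ImpactScenario:
    """One impact boundary condition.

    velocity in m/s (0 < V <= 16), location one of :data:`LOCATIONS`,
    angle in degrees from the surface perpendicular (|angle| <= 45),
    impactor one of :data:`IMPACTORS` (fixing the radius of curvature),
    impact_point in m and impact_direction a unit vector pointing into
    the head.
    """

    velocity: float
    location: str
    angle: float
    impactor: str
    impact_point: np.ndarray
    impact_direction: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 < self.velocity <= 16.0:
            raise ValueError(f"velocity must be in (0, 16] m/s, got {self.velocity}")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if abs(self.angle) > 45.0:
            raise ValueError(f"|angle| must be <= 45 deg, got {self.angle}")
        if self.impactor not in IMPACTOR_RADIUS:
            raise ValueError(f"unknown impactor {self.impactor!r}")
        p = np.asarray(self.impact_point, dtype=float)
        d = np.asarray(self.impact_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("impact_direction must be non-zero")
        object.__setattr__(self, "impact_point", p)
        object.__setattr__(self, "impact_direction", d / n)

    @property
    def radius_of_curvature(self) -> float:
        return IMPACTOR_RADIUS[self.impactor]

    def key(self) -> tuple:
        """Stable hashable identity used to derive per-scenario RNG streams."""
        return (round(self.velocity, 6), self.location, round(self.angle, 6),
                self.impactor)


def make_scenario(velocity: float, location: str, angle: float = 0.0,
                  impactor: str = "flat", head_radius: float = 0.09) -> ImpactScenario:
    """Build a scenario with the canonical geometry of a location label.

    The impact point is the location's representative surface point on a
    head of outer radius *head_radius*; the direction is the inward normal
    tilted by *angle* degrees about a tangent axis.
    """
    if location not in LOCATION_UNIT_DIRECTIONS:
        raise ValueError(f"unknown location {location!r}")
    u = LOCATION_UNIT_DIRECTIONS[location]
    point = head_radius * u
    inward = -u
    # tangent axis for the tilt; z is a valid fallback only when u is not
    # parallel to z
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    axis = np.cross(u, ref)
    axis = axis / np.linalg.norm(axis)
    direction = Rotation.from_rotvec(np.deg2rad(angle) * axis).apply(inward)
    return ImpactScenario(velocity=velocity, location=location, angle=angle,
                          impactor=impactor, impact_point=point,
                          impact_direction=direction)


@dataclass(frozen=True)
class FeatureVector:
    """Model inputs of one scenario, in :data:`FEATURE_NAMES` order."""

    velocity: float
    location: str
    perpendicular: bool
    radius_of_curvature: float
    dist_to_dmn: float
    angle_to_dmn: float

    def __post_init__(self) -> None:
        if self.dist_to_dmn < 0:
            raise ValueError("dist_to_dmn must be >= 0")
        if not 0.0 <= self.angle_to_dmn <= 180.0:
            raise ValueError("angle_to_dmn must be in [0, 180] deg")

    def as_dict(self) -> dict[str, float]:
        d = {"velocity": self.velocity}
        for loc in LOCATIONS:
            d[f"loc_{loc}"] = float(self.location == loc)
        d["perpendicular"] = float(self.perpendicular)
        d["radius_of_curvature"] = self.radius_of_curvature
        d["dist_to_dmn"] = self.dist_to_dmn
        d["angle_to_dmn"] = self.angle_to_dmn
        return d


def extract_features(scenario: ImpactScenario, mesh, dmn_ids) -> FeatureVector:
    """Features of one scenario given the mesh and its DMN element set.

    ``dist_to_dmn`` is the Euclidean distance from the impact point to the
    closest DMN element centroid; ``angle_to_dmn`` the angle (degrees)
    between the impact direction and the unit vector from the impact point
    to that centroid (0 by convention when the distance is 0).  The
    ``perpendicular`` indicator is ``angle == 0``.
    """
    ids = np.fromiter((int(i) for i in dmn_ids), dtype=int)
    if ids.size == 0:
        raise ValueError("DMN element set is empty")
    cents = mesh.element_centroid[ids]
    delta = cents - scenario.impact_point[None, :]
    dists = np.linalg.norm(delta, axis=1)
    j = int(np.argmin(dists))
    dist = float(dists[j])
    if dist == 0.0:
        angle = 0.0
    else:
        u = delta[j] / dist
        cosang = float(np.clip(np.dot(scenario.impact_direction, u), -1.0, 1.0))
        angle = float(np.degrees(np.arccos(cosang)))
    return FeatureVector(velocity=scenario.velocity, location=scenario.location,
                         perpendicular=(scenario.angle == 0.0),
                         radius_of_curvature=scenario.radius_of_curvature,
                         dist_to_dmn=dist, angle_to_dmn=angle)


def features_frame(records) -> pd.DataFrame:
    """Stack the feature vectors of simulation records into a DataFrame."""
    return pd.DataFrame([r.features.as_dict() for r in records],
                        columns=list(FEATURE_NAMES))


def label_library(records, damage_threshold: float) -> np.ndarray:
    """Binary outcome per record: 1 iff damage % strictly exceeds the
    threshold.  Fractured records must have been filtered out upstream."""
    for r in records:
        if r.fractured:
            raise ValueError("fractured record present: filter the library "
                             "before labeling")
    return np.array([1 if r.damage_percent > damage_threshold else 0
                     for r in records], dtype=int)


# ---------------------------------------------------------------------------
# Feature selection and ensemble
# ---------------------------------------------------------------------------

def _standardizer(X: pd.DataFrame, selected):
    """Mean/sd of the continuous selected columns (indicators pass through)."""
    mean = {}
    sd = {}
    for c in selected:
        if c in CONTINUOUS_FEATURES:
            m, s = float(X[c].mean()), float(X[c].std(ddof=0))
            mean[c], sd[c] = m, (s if s > 0 else 1.0)
        else:
            mean[c], sd[c] = 0.0, 1.0
    return mean, sd


def _apply_standardizer(X: pd.DataFrame, selected, mean, sd) -> np.ndarray:
    cols = [(X[c].to_numpy(dtype=float) - mean[c]) / sd[c] for c in selected]
    return np.column_stack(cols)


def _cv_auc(X: np.ndarray, y: np.ndarray, n_folds: int, seed: int) -> float:
    """Mean stratified-CV AUC of a logistic-regression classifier."""
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in cv.split(X, y):
        if len(np.unique(y[te])) < 2:
            continue
        clf = LogisticRegression(max_iter=1000)
        clf.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.predict_proba(X[te])[:, 1]))
    if not aucs:
        raise ValueError("no fold with both classes; labels too unbalanced")
    return float(np.mean(aucs))


def forward_feature_selection(X: pd.DataFrame, y, n_folds: int = 5,
                              seed: int = 0, tol: float = 1e-4) -> list[str]:
    """Greedy forward feature selection under cross-validated AUC.

    Starting from the empty set, the feature whose addition maximizes the
    mean stratified *n_folds*-fold CV AUC of a logistic regression is added
    until the best improvement falls below *tol*.  Ties are broken by
    declaration order in :data:`FEATURE_NAMES`.  Candidate features are
    standardized on the training folds implicitly through the z-scored
    design (constant features are passed with unit scale and gain nothing).
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    candidates = [c for c in FEATURE_NAMES if c in X.columns]
    selected: list[str] = []
    best_auc = 0.5  # AUC of the uninformative empty model
    while True:
        round_best = None
        round_auc = best_auc
        for c in candidates:
            if c in selected:
                continue
            trial = selected + [c]
            mean, sd = _standardizer(X, trial)
            Xs = _apply_standardizer(X, trial, mean, sd)
            auc = _cv_auc(Xs, y, n_folds, seed)
            if auc > round_auc + 1e-12:  # strict improvement; first wins ties
                round_auc = auc
                round_best = c
        if round_best is None or round_auc - best_auc < tol:
            break
        selected.append(round_best)
        best_auc = round_auc
    if not selected:
        # degenerate library: fall back to the single best candidate
        selected = [candidates[0]]
    return selected


class _PlattSVM:
    """SVM member with a sigmoid probability map fitted on training scores."""

    def __init__(self, seed: int = 0):
        self._svc = SVC(kernel="rbf", C=1.0, gamma="scale")
        self._platt = LogisticRegression(max_iter=1000)

    def fit(self, X, y):
        self._svc.fit(X, y)
        scores = self._svc.decision_function(X).reshape(-1, 1)
        self._platt.fit(scores, y)
        return self

    def predict_proba(self, X):
        scores = self._svc.decision_function(X).reshape(-1, 1)
        return self._platt.predict_proba(scores)


def _make_members(n_train: int, seed: int) -> dict:
    k = int(round(np.sqrt(n_train)))
    if k % 2 == 0:
        k += 1
    k = max(1, min(k, n_train))
    return {
        "logistic_regression": LogisticRegression(max_iter=1000),
        "discriminant_analysis": LinearDiscriminantAnalysis(),
        "k_nearest_neighbor": KNeighborsClassifier(n_neighbors=k),
        "naive_bayes": GaussianNB(),
        "support_vector_machine": _PlattSVM(seed=seed),
    }


@dataclass
class TrainedEnsemble:
    """Five fitted member classifiers averaged into one probability."""

    damage_threshold: float
    selected_features: list[str]
    members: dict = field(repr=False)
    feature_mean: dict = field(repr=False)
    feature_sd: dict = field(repr=False)
    seed: int = 0

    def member_probabilities(self, X: pd.DataFrame) -> pd.DataFrame:
        Xs = _apply_standardizer(X, self.selected_features,
                                 self.feature_mean, self.feature_sd)
        return pd.DataFrame(
            {name: m.predict_proba(Xs)[:, 1] for name, m in self.members.items()})

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Mean of the five member probabilities, in [0, 1]."""
        return self.member_probabilities(X).to_numpy().mean(axis=1)


def train_bagging_ensemble(X: pd.DataFrame, y, selected, seed: int = 0,
                           damage_threshold: float = float("nan")) -> TrainedEnsemble:
    """Fit the five-member ensemble on the standardized selected features."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    selected = list(selected)
    if not selected:
        raise ValueError("selected feature list is empty")
    for c in selected:
        if X[c].nunique() < 2:
            raise ValueError(f"selected feature {c!r} has zero variance")
    mean, sd = _standardizer(X, selected)
    Xs = _apply_standardizer(X, selected, mean, sd)
    members = _make_members(len(y), seed)
    for m in members.values():
        m.fit(Xs, y)
    return TrainedEnsemble(damage_threshold=damage_threshold,
                           selected_features=selected, members=members,
                           feature_mean=mean, feature_sd=sd, seed=seed)


@dataclass(frozen=True)
class EvaluationReport:
    auc: float
    brier: float
    sensitivity: float
    specificity: float
    accuracy: float
    dataset_balance: float
    damage_threshold: float
    n_records: int
    selected_features: tuple = ()


def _loo_probabilities(X, y, selected, seed, model: str) -> np.ndarray:
    probs = np.empty(len(y), dtype=float)
    idx = np.arange(len(y))
    for i in idx:
        tr = idx != i
        ytr = y[tr]
        Xtr = X.loc[tr].reset_index(drop=True)
        if model == "bagging":
            ens = train_bagging_ensemble(Xtr, ytr, selected, seed=seed)
            probs[i] = float(ens.predict_proba(X.iloc[[i]])[0])
        else:  # logistic-only reference
            mean, sd = _standardizer(Xtr, selected)
            clf = LogisticRegression(max_iter=1000)
            clf.fit(_apply_standardizer(Xtr, selected, mean, sd), ytr)
            Xi = _apply_standardizer(X.iloc[[i]], selected, mean, sd)
            probs[i] = float(clf.predict_proba(Xi)[0, 1])
    return probs


def evaluate_loo(records, damage_threshold: float, seed: int = 0,
                 model: str = "bagging", cutoff: float = 0.5) -> EvaluationReport:
    """Leave-one-out validation of the surrogate at one damage threshold.

    Feature selection is performed once on the full library (mirroring its
    use as a pre-step, an optimistic-bias caveat documented in the methods
    note); each record is then predicted by a model trained on the other
    records.  AUC is the rank statistic over the pooled held-out
    (probability, label) pairs; sensitivity/specificity/accuracy use the
    *cutoff* probability.
    """
    records = list(records)
    if len(records) < 10:
        raise ValueError("need at least 10 records for leave-one-out validation")
    if model not in ("bagging", "logistic"):
        raise ValueError(f"unknown model {model!r}")
    y = label_library(records, damage_threshold)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class at this threshold")
    X = features_frame(records)
    selected = forward_feature_selection(X, y, seed=seed)
    probs = _loo_probabilities(X, y, selected, seed, model)
    auc = float(roc_auc_score(y, probs))
    brier = float(np.mean((probs - y) ** 2))
    pred = (probs > cutoff).astype(int)
    pos, neg = y == 1, y == 0
    sens = float(np.mean(pred[pos] == 1))
    spec = float(np.mean(pred[neg] == 0))
    acc = float(np.mean(pred == y))
    return EvaluationReport(auc=auc, brier=brier, sensitivity=sens,
                            specificity=spec, accuracy=acc,
                            dataset_balance=float(np.mean(y)),
                            damage_threshold=damage_threshold,
                            n_records=len(records),
                            selected_features=tuple(selected))
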