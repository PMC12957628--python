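"""SVM sex classification on principal component scores.

A radial-kernel support vector machine is trained on the first m principal
components of the corresponded coordinate matrix, with m swept over 1..30
and chosen by leave-one-out cross-validation: the lowest m attaining the
best LOOCV success rate wins.  Posterior probabilities P(male) come from
Platt-style sigmoid calibration; a symmetric posterior-probability band
around 0.5 leaves low-confidence specimens unclassified, trading coverage
for forensic reliability.  Male is the positive class throughout, which
makes the over-calling tendency Bias = FP / (FP + TN) well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.svm import SVC

from .exceptions import ParameterError
from .morphometrics import PCAModel

MALE, FEMALE, UNCLASSIFIED = "M", "F", "U"
DEFAULT_PC_RANGE = range(1, 31)
DEFAULT_THRESHOLD = 0.9


@dataclass
class ClassifierModel:
    """A fitted radial-kernel SVM (with Platt probability calibration)
    plus the PCA reference used to score new specimens."""

    svc: object
    m: int                              # number of leading PCs used
    space: str
    C: float
    gamma: str | float
    pca: PCAModel | None = None         # training PCA reference
    training_populations: tuple = ()
    loocv_accuracy: float = np.nan

    def scores_for(self, rows_or_scores: np.ndarray) -> np.ndarray:
        """Accept either raw coordinate rows (projected through the training
        PCA) or ready-made score matrices; return the first m columns."""
        arr = np.atleast_2d(np.asarray(rows_or_scores, dtype=np.float64))
        if self.pca is not None and arr.shape[1] == len(self.pca.mean):
            arr = self.pca.transform(arr)
        if arr.shape[1] < self.m:
            raise ParameterError(
                f"need at least {self.m} score columns, got {arr.shape[1]}")
        return arr[:, : self.m]


@dataclass
class ClassificationReport:
    """Decisions, confusion counts and rates for one evaluated group."""

    p_male: np.ndarray
    decisions: np.ndarray          # in {M, F, U}
    true_sex: np.ndarray
    threshold: float
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t, d = self.true_sex, self.decisions
        self.tp = int(((d == MALE) & (t == MALE)).sum())
        self.tn = int(((d == FEMALE) & (t == FEMALE)).sum())
        self.fp = int(((d == MALE) & (t == FEMALE)).sum())
        self.fn = int(((d == FEMALE) & (t == MALE)).sum())

    @property
    def n(self) -> int:
        return len(self.decisions)

    @property
    def n_classified(self) -> int:
        return int((self.decisions != UNCLASSIFIED).sum())

    @property
    def n_unclassified(self) -> int:
        return self.n - self.n_classified

    @property
    def accuracy(self) -> float:
        """Fraction correct among classified specimens."""
        if self.n_classified == 0:
            return np.nan
        return (self.tp + self.tn) / self.n_classified

    @property
    def bias(self) -> float | None:
        """FP / (FP + TN); None when no true female was classified."""
        denom = self.fp + self.tn
        if denom == 0:
            return None
        return self.fp / denom

    def per_sex_rates(self) -> pd.DataFrame:
        """Correct / unclassified / incorrect percentages per sex.

        Rates are relative to each sex's total count, so each column sums
        to 100% — the layout used for transfer-population reporting.
        """
        rows = {}
        for sex in (MALE, FEMALE):
            sel = self.true_sex == sex
            total = int(sel.sum())
            if total == 0:
                rows[sex] = dict(correct=np.nan, unclassified=np.nan,
                                 incorrect=np.nan, n=0)
                continue
            d = self.decisions[sel]
            correct = int((d == sex).sum())
            unclass = int((d == UNCLASSIFIED).sum())
            incorrect = total - correct - unclass
            rows[sex] = dict(correct=100 * correct / total,
                             unclassified=100 * unclass / total,
                             incorrect=100 * incorrect / total, n=total)
        return pd.DataFrame(rows).T

    def summary(self) -> dict:
        sexes = self.per_sex_rates()
        return {
            "n": self.n,
            "threshold": self.threshold,
            "accuracy_classified": self.accuracy,
            "bias": self.bias,
            "confusion": {"TP": self.tp, "TN": self.tn,
                          "FP": self.fp, "FN": self.fn},
            "pct_correct": 100 * (self.tp + self.tn) / self.n,
            "pct_unclassified": 100 * self.n_unclassified / self.n,
            "pct_incorrect": 100 * (self.fp + self.fn) / self.n,
            "per_sex": sexes.to_dict(orient="index"),
            "positive_class": MALE,
            "provenance": self.provenance,
        }


def _make_svc(C: float, gamma, probability: bool, seed: int = 0,
              calibration_folds: int = 5):
    svc = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    if not probability:
        return svc
    # Platt-style sigmoid calibration fitted on internal cross-validated
    # decision values; monotone in the SVM decision function
    return CalibratedClassifierCV(svc, method="sigmoid", ensemble=False,
                                  cv=calibration_folds)


def loocv_accuracy(scores: np.ndarray, sexes: np.ndarray, m: int,
                   C: float = 1.0, gamma="scale") -> float:
    """Leave-one-out accuracy of an RBF SVM on the first m score columns."""
    X = scores[:, :m]
    pred = cross_val_predict(_make_svc(C, gamma, probability=False),
                             X, sexes, cv=LeaveOneOut())
    return float((pred == sexes).mean())


def sweep_and_train(scores: np.ndarray, sexes,
                    pc_range=DEFAULT_PC_RANGE,
                    C: float = 1.0, gamma="scale",
                    space: str = "form",
                    training_populations=(),
                    pca: PCAModel | None = None,
                    seed: int = 0):
    """LOOCV accuracy curve over candidate PC counts + final fitted model.

    The final SVM (with Platt probability calibration) is trained on all
    specimens using the lowest m that attains the maximal cross-validation
    success rate.  PCA is fit once on the training pool and held fixed
    across LOOCV folds.
    """
    scores = np.asarray(scores, dtype=np.float64)
    sexes = np.asarray(sexes).astype(str)
    classes = set(sexes)
    if not {MALE, FEMALE} <= classes:
        raise ParameterError(
            f"training data must contain both sexes, got {sorted(classes)}")
    max_m = min(max(pc_range), scores.shape[1])
    ms = [m for m in pc_range if m <= max_m]
    if not ms:
        raise ParameterError("pc_range contains no feasible component count")
    accs = np.array([loocv_accuracy(scores, sexes, m, C=C, gamma=gamma)
                     for m in ms])
    best = accs.max()
    m_sel = ms[int(np.flatnonzero(accs == best)[0])]  # lowest m at the max
    min_class = int(min(np.sum(sexes == MALE), np.sum(sexes == FEMALE)))
    if min_class < 2:
        raise ParameterError("need at least 2 specimens of each sex")
    svc = _make_svc(C, gamma, probability=True, seed=seed,
                    calibration_folds=min(5, min_class))
    svc.fit(scores[:, :m_sel], sexes)
    curve = pd.DataFrame({"m": ms, "loocv_accuracy": accs})
    model = ClassifierModel(svc=svc, m=m_sel, space=space, C=C, gamma=gamma,
                            pca=pca,
                            training_populations=tuple(training_populations),
                            loocv_accuracy=float(best))
    return curve, model


def predict_pmale(model: ClassifierModel, rows_or_scores) -> np.ndarray:
    """Posterior probability of being male for each specimen."""
    X = model.scores_for(rows_or_scores)
    proba = model.svc.predict_proba(X)
    male_col = list(model.svc.classes_).index(MALE)
    return proba[:, male_col]


def threshold_classify(p_male, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Symmetric posterior-probability band decision.

    M when P(male) >= t, F when P(male) <= 1 - t, unclassified otherwise;
    at t = 0.5 the >= rule classifies everything (boundary goes to M).
    """
    if not 0.5 <= threshold <= 1.0:
        raise ParameterError("threshold must lie in [0.5, 1]")
    p = np.atleast_1d(np.asarray(p_male, dtype=np.float64))
    out = np.full(len(p), UNCLASSIFIED, dtype=object)
    # at t=0.5 both rules fire for p=0.5; assigning M last makes >= win
    out[p <= 1.0 - threshold] = FEMALE
    out[p >= threshold] = MALE
    return out.astype("U1")


def confusion_and_bias(decisions, true_sexes,
                       p_male=None, threshold: float = np.nan,
                       provenance: dict | None = None) -> ClassificationReport:
    """Build a ClassificationReport from decisions and true sexes."""
    decisions = np.asarray(decisions).astype("U1")
    true_sexes = np.asarray(true_sexes).astype("U1")
    if len(decisions) != len(true_sexes):
        raise ParameterError("decisions and truths differ in length")
    if len(decisions) == 0:
        raise ParameterError("empty report")
    if p_male is None:
        p_male = np.full(len(decisions), np.nan)
    return ClassificationReport(p_male=np.asarray(p_male, dtype=np.float64),
                                decisions=decisions, true_sex=true_sexes,
                                threshold=threshold,
                                provenance=provenance or {})


def threshold_sweep(p_male, true_sexes, grid=None) -> pd.DataFrame:
    """Hit / miss / unclassified counts along a threshold grid.

    Returns one row per threshold with overall and per-sex counts, plus a
    ``t_miss_le_5pct`` attribute: the smallest threshold at which the miss
    rate drops to 5% of the sample or below (NaN if never).
    """
    p = np.asarray(p_male, dtype=np.float64)
    truth = np.asarray(true_sexes).astype("U1")
    if grid is None:
        grid = np.round(np.arange(0.5, 1.0001, 0.01), 4)
    grid = np.asarray(grid, dtype=np.float64)
    if not np.all(np.diff(grid) > 0):
        raise ParameterError("threshold grid must be sorted ascending")
    rows = []
    n = len(p)
    for t in grid:
        d = threshold_classify(p, t)
        hit = int((d == truth).sum())
        unclass = int((d == UNCLASSIFIED).sum())
        miss = n - hit - unclass
        row = {"t": t, "hit": hit, "miss": miss, "unclassified": unclass}
        for sex in (MALE, FEMALE):
            sel = truth == sex
            row[f"hit_{sex}"] = int((d[sel] == sex).sum())
            row[f"unclassified_{sex}"] = int((d[sel] == UNCLASSIFIED).sum())
            row[f"miss_{sex}"] = int(sel.sum()) - row[f"hit_{sex}"] \
                - row[f"unclassified_{sex}"]
        rows.append(row)
    df = pd.DataFrame(rows)
    ok = df["miss"] <= 0.05 * n
    df.attrs["t_miss_le_5pct"] = float(df.loc[ok, "t"].iloc[0]) if ok.any() \
        else np.nan
    return df


def cross_population_apply(model: ClassifierModel, rows_or_scores,
                           true_sexes, threshold: float = DEFAULT_THRESHOLD,
                           population: str = "") -> ClassificationReport:
    """Apply a trained model to specimens from another population.

    The specimens must already be corresponded to the training base and
    are projected through the model's own PCA reference; the report embeds
    a provenance record of the training conditions.
    """
    p = predict_pmale(model, rows_or_scores)
    decisions = threshold_classify(p, threshold)
    provenance = {
        "training_populations": list(model.training_populations),
        "m": model.m,
        "space": model.space,
        "C": model.C,
        "gamma": str(model.gamma),
        "threshold": threshold,
        "test_population": population,
    }
    return confusion_and_bias(decisions, true_sexes, p_male=p,
                              threshold=threshold, provenance=provenance)
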