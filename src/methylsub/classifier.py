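"""Prospective methylation-subgroup classifier.

An L1-penalized (lasso) multinomial logistic regression maps a sample's
beta values over a signature probe panel to HM / IM / LM probabilities.
Features are the most variable subgroup-specific DMPs restricted to CpG
islands (default 1,000); the penalty is chosen by 10-fold
cross-validated multinomial deviance over a log-spaced grid descending
four orders of magnitude from the smallest penalty that zeroes every
coefficient. Evaluation uses a permutation-calibrated kappa,

    K = (Acc - AccRand) / (1 - AccRand),

where AccRand is the mean accuracy over random permutations of the
predicted labels — chance-corrected accuracy that stays comparable
across unbalanced test sets.

Internally features are standardized to unit variance for fitting;
reported coefficients are transformed back to the beta scale. The solver
is scikit-learn's saga coordinate method; intercepts are unpenalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from .dmp import select_most_variable
from .io import BetaMatrix, ProbeAnnotation, ProbeSet, ValidationError

_SD_FLOOR = 1e-12


@dataclass
class SubtypeModel:
    """Fitted multinomial lasso: classes x probes coefficients (beta scale)."""

    classes: list
    probe_ids: list
    coefficients: np.ndarray = field(repr=False)  # classes x probes
    intercepts: np.ndarray = field(repr=False)
    penalty: float = 0.0
    cv_curve: pd.Series | None = field(default=None, repr=False)
    seed: int | None = None

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# methylsub subtype model v1\n")
            fh.write(f"penalty\t{float(self.penalty)!r}\n")
            fh.write(f"seed\t{self.seed!r}\n")
            fh.write("classes\t" + "\t".join(self.classes) + "\n")
            fh.write("intercepts\t" + "\t".join(f"{float(v)!r}" for v in self.intercepts) + "\n")
            for j, pid in enumerate(self.probe_ids):
                row = "\t".join(f"{float(v)!r}" for v in self.coefficients[:, j])
                fh.write(f"{pid}\t{row}\n")

    @classmethod
    def from_text(cls, path) -> "SubtypeModel":
        with open(path) as fh:
            header = fh.readline()
            if "subtype model" not in header:
                raise ValidationError("not a subtype model file")
            meta, probes, rows = {}, [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] in {"penalty", "seed", "classes", "intercepts"}:
                    meta[parts[0]] = parts[1:]
                else:
                    probes.append(parts[0])
                    rows.append([float(v) for v in parts[1:]])
        return cls(
            classes=meta["classes"],
            probe_ids=probes,
            coefficients=np.array(rows).T,
            intercepts=np.array([float(v) for v in meta["intercepts"]]),
            penalty=float(meta["penalty"][0]),
            seed=None if meta["seed"][0] == "None" else int(meta["seed"][0]),
        )


@dataclass
class ClassifierEvaluation:
    """Permutation-kappa evaluation of predicted vs true labels."""

    acc: float
    acc_rand: float
    kappa: float
    n_permutations: int
    seed: int


def split_train_test(
    sample_ids, labels: pd.Series, test_fraction: float = 0.2, seed: int = 0
):
    """Stratified, disjoint, exhaustive train/test split (default 4:1)."""
    labels = pd.Series(labels).loc[list(sample_ids)]
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValidationError(f"classes with < 2 samples cannot be split: {small}")
    train, test = train_test_split(
        list(sample_ids),
        test_size=test_fraction,
        stratify=labels.to_numpy(),
        random_state=seed,
    )
    return list(train), list(test)


def select_features(
    jmml_dmps: ProbeSet, ann: ProbeAnnotation, beta: BetaMatrix, k: int = 1000
) -> ProbeSet:
    """The k most variable subgroup DMPs located on CpG islands.

    If fewer than k island DMPs exist, all of them are returned. Variance
    ranking follows the shared most-variable rule (sd across samples,
    lexicographic tie-break).
    """
    island = set(ann.island_probes().probe_ids)
    pool = sorted(set(jmml_dmps.probe_ids) & island & set(beta.probe_ids))
    if not pool:
        raise ValidationError("no island probes among the DMPs")
    sub = beta.select_probes(pool)
    top = select_most_variable(sub, min(k, len(pool)))
    return ProbeSet(
        "classifier_features",
        top.probe_ids,
        f"top {len(top)} most variable island probes of {jmml_dmps.name}",
    )


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0, ddof=0), _SD_FLOOR)
    return (X - mu) / sd, mu, sd


def _lambda_max(Xs: np.ndarray, y_onehot: np.ndarray) -> float:
    """Smallest L1 penalty (glmnet scale) zeroing all coefficients."""
    n = Xs.shape[0]
    priors = y_onehot.mean(axis=0)
    grad = Xs.T @ (y_onehot - priors) / n  # probes x classes
    return float(np.abs(grad).max())


def _fit_path(Xs, y, lambdas, seed, tol=1e-4, max_iter=50_000):
    """Warm-started saga fits along a descending penalty path."""
    n = Xs.shape[0]
    clf = LogisticRegression(
        l1_ratio=1.0, solver="saga", warm_start=True, tol=tol,
        max_iter=max_iter, random_state=seed, fit_intercept=True, C=1.0,
    )
    models = []
    for lam in lambdas:
        clf.C = 1.0 / (n * lam)
        clf.fit(Xs, y)
        if clf.n_iter_[0] >= max_iter:
            raise RuntimeError(
                f"multinomial lasso failed to converge at penalty {lam:.4g}"
            )
        models.append((clf.coef_.copy(), clf.intercept_.copy(), list(clf.classes_)))
    return models


def _deviance(coef, intercept, classes, Xs, y) -> float:
    scores = Xs @ coef.T + intercept
    prob = softmax(scores, axis=1)
    idx = pd.Categorical(y, categories=classes).codes
    ll = np.log(np.clip(prob[np.arange(len(y)), idx], 1e-300, None))
    return float(-2.0 * ll.sum())


def fit_multinomial_lasso(
    train_beta: BetaMatrix,
    train_labels: pd.Series,
    n_folds: int = 10,
    n_lambda: int = 100,
    seed: int = 0,
) -> SubtypeModel:
    """Fit the penalized multinomial model with CV-selected penalty.

    The penalty grid is 100 log-spaced values from lambda_max (all
    coefficients zero) down four orders of magnitude; the grid point
    minimizing mean cross-validated multinomial deviance wins, and the
    final model is refit on the full training data at that penalty.
    """
    labels = pd.Series(train_labels).loc[train_beta.sample_ids]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValidationError("need >= 2 classes to fit the classifier")
    X = train_beta.values.T  # samples x probes
    if np.isnan(X).any():
        raise ValidationError("missing betas in classifier training data")
    y = labels.to_numpy()
    Xs, mu, sd = _standardize(X)
    y_onehot = (y[:, None] == np.array(classes)[None, :]).astype(float)
    lmax = _lambda_max(Xs, y_onehot)
    if lmax <= 0:
        raise ValidationError("degenerate training data: zero score gradient")
    lambdas = np.geomspace(lmax, lmax * 1e-4, n_lambda)

    counts = labels.value_counts()
    if (counts < n_folds).any():
        # still valid CV, but folds may miss a class in training
        import warnings

        warnings.warn(
            "some classes have fewer samples than CV folds", stacklevel=2
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds, len(lambdas)))
    for f, (tr, va) in enumerate(skf.split(Xs, y)):
        models = _fit_path(Xs[tr], y[tr], lambdas, seed)
        for j, (coef, icpt, cls) in enumerate(models):
            dev[f, j] = _deviance(coef, icpt, cls, Xs[va], y[va])
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    lam = float(lambdas[best])

    # final fit: warm path down to the selected penalty, then a tight polish
    coef_s, icpt_s, cls = _fit_path(Xs, y, lambdas[: best + 1], seed)[-1]
    polish = LogisticRegression(
        l1_ratio=1.0, solver="saga", warm_start=True, tol=1e-5,
        max_iter=300_000, random_state=seed, C=1.0 / (len(y) * lam),
    )
    polish.coef_ = coef_s.copy()
    polish.intercept_ = icpt_s.copy()
    polish.classes_ = np.array(cls)
    polish.fit(Xs, y)
    if polish.n_iter_[0] >= 300_000:
        raise RuntimeError(f"final fit failed to converge at penalty {lam:.4g}")
    coef_s, icpt_s, cls = polish.coef_, polish.intercept_, list(polish.classes_)
    if list(cls) != classes:  # pragma: no cover - sklearn sorts classes
        order = [list(cls).index(c) for c in classes]
        coef_s, icpt_s = coef_s[order], icpt_s[order]
    # back-transform to the beta scale
    coef = coef_s / sd
    intercept = icpt_s - coef_s @ (mu / sd)
    return SubtypeModel(
        classes=classes,
        probe_ids=list(train_beta.probe_ids),
        coefficients=coef,
        intercepts=intercept,
        penalty=lam,
        cv_curve=pd.Series(mean_dev, index=lambdas, name="cv_deviance"),
        seed=seed,
    )


def predict(model: SubtypeModel, beta: BetaMatrix):
    """Class probabilities (softmax) and argmax labels for each sample."""
    missing = [p for p in model.probe_ids if p not in beta.probe_ids]
    if missing:
        raise ValidationError(
            f"{len(missing)} model probes missing (e.g. {missing[:5]})"
        )
    X = beta.select_probes(model.probe_ids).values.T
    scores = X @ model.coefficients.T + model.intercepts
    prob = softmax(scores, axis=1)
    prob_df = pd.DataFrame(prob, index=beta.sample_ids, columns=model.classes)
    labels = prob_df.idxmax(axis=1)
    labels.name = "predicted_group"
    return prob_df, labels


def kappa_from_accuracies(acc: float, acc_rand: float) -> float:
    """The chance-corrected kappa K = (Acc - AccRand) / (1 - AccRand)."""
    if acc_rand >= 1.0:
        raise ValidationError("kappa undefined when acc_rand = 1")
    return (acc - acc_rand) / (1.0 - acc_rand)


def evaluate_kappa(
    pred_labels,
    true_labels,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ClassifierEvaluation:
    """Permutation-calibrated kappa: K = (Acc - AccRand) / (1 - AccRand).

    AccRand is the mean accuracy over seeded random permutations of the
    *predicted* labels against the fixed truth.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValidationError("label vectors differ in length")
    acc = float(np.mean(pred == true))
    rng = np.random.default_rng(seed)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        accs[i] = np.mean(rng.permutation(pred) == true)
    acc_rand = float(accs.mean())
    if acc_rand >= 1.0:
        raise ValidationError(
            "acc_rand = 1 (single-class degenerate case): kappa undefined"
        )
    kappa = kappa_from_accuracies(acc, acc_rand)
    return ClassifierEvaluation(
        acc=acc, acc_rand=acc_rand, kappa=kappa,
        n_permutations=n_permutations, seed=seed,
    )


def extract_signature(model: SubtypeModel) -> ProbeSet:
    """Probes with a nonzero coefficient in any class, by max |coefficient|."""
    maxabs = np.abs(model.coefficients).max(axis=0)
    nz = np.flatnonzero(maxabs > 0)
    order = nz[np.argsort(-maxabs[nz], kind="stable")]
    ordered = [model.probe_ids[j] for j in order]
    return ProbeSet(
        "signature",
        frozenset(ordered),
        "nonzero-coefficient probes at penalty "
        f"{model.penalty:.4g}, ordered by max |coefficient|: "
        + ",".join(ordered[:50]),
    )
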