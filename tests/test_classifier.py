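import numpy as np
import pandas as pd
import pytest

import methylsub as ms
from methylsub.classifier import _fit_path, _lambda_max, _standardize
from conftest import make_annotation


def _toy_separable(n_per_class=10, n_noise=7, seed=0):
    """Three classes separated by three informative probes, zero noise."""
    rng = np.random.default_rng(seed)
    blocks = []
    for c in range(3):
        X = np.full((n_per_class, 3 + n_noise), 0.1)
        X[:, c] = 0.9  # each class marked by its own probe
        X[:, 3:] = rng.random((n_per_class, n_noise)) * 0.02 + 0.09
        blocks.append(X)
    X = np.vstack(blocks)
    y = np.repeat(["HM", "IM", "LM"], n_per_class)
    ids = [f"s{i}" for i in range(len(y))]
    probes = [f"cg{j:03d}" for j in range(X.shape[1])]
    beta = ms.BetaMatrix(pd.DataFrame(X.T, index=probes, columns=ids))
    return beta, pd.Series(y, index=ids)


class TestSplit:
    def test_eighty_twenty(self):
        labels = pd.Series(
            np.repeat(["HM", "IM", "LM"], [40, 30, 30]),
            index=[f"s{i}" for i in range(100)],
        )
        train, test = ms.split_train_test(list(labels.index), labels, seed=1)
        assert len(train) == 80 and len(test) == 20
        assert not set(train) & set(test)
        assert set(train) | set(test) == set(labels.index)

    def test_stratification_within_one_sample(self):
        labels = pd.Series(
            np.repeat(["HM", "IM", "LM"], [40, 30, 30]),
            index=[f"s{i}" for i in range(100)],
        )
        train, test = ms.split_train_test(list(labels.index), labels, seed=2)
        for cls, frac in (("HM", 0.4), ("IM", 0.3), ("LM", 0.3)):
            got = sum(labels[t] == cls for t in test)
            assert abs(got - frac * 20) <= 1

    def test_deterministic_given_seed(self):
        labels = pd.Series(["HM"] * 10 + ["LM"] * 10,
                           index=[f"s{i}" for i in range(20)])
        s1 = ms.split_train_test(list(labels.index), labels, seed=3)
        s2 = ms.split_train_test(list(labels.index), labels, seed=3)
        assert s1 == s2

    def test_tiny_class_rejected(self):
        labels = pd.Series(["HM"] * 9 + ["LM"], index=[f"s{i}" for i in range(10)])
        with pytest.raises(ms.ValidationError):
            ms.split_train_test(list(labels.index), labels)


class TestSelectFeatures:
    def test_island_restriction_and_count(self, rng):
        probes = [f"cg{i:03d}" for i in range(60)]
        rel = ["island" if i < 40 else "open_sea" for i in range(60)]
        isl = [f"CGI{i}" if i < 40 else None for i in range(60)]
        ann = make_annotation(probes, cgi_relation=rel, island_id=isl)
        beta = ms.BetaMatrix(
            pd.DataFrame(rng.random((60, 8)), index=probes,
                         columns=[f"s{j}" for j in range(8)])
        )
        dmps = ms.ProbeSet("jmml", frozenset(probes), "")
        feats = ms.select_features(dmps, ann, beta, k=25)
        assert len(feats) == 25
        assert all(p in set(probes[:40]) for p in feats.probe_ids)

    def test_matches_brute_force(self, rng):
        probes = [f"cg{i:03d}" for i in range(30)]
        ann = make_annotation(probes, cgi_relation="island",
                              island_id=[f"C{i}" for i in range(30)])
        vals = rng.random((30, 6))
        beta = ms.BetaMatrix(
            pd.DataFrame(vals, index=probes, columns=[f"s{j}" for j in range(6)])
        )
        dmps = ms.ProbeSet("jmml", frozenset(probes[:20]), "")
        feats = ms.select_features(dmps, ann, beta, k=5)
        sd = np.std(vals[:20], axis=1, ddof=1)
        expect = {probes[i] for i in np.argsort(-sd, kind="stable")[:5]}
        assert feats.probe_ids == expect

    def test_no_island_probes_rejected(self, rng):
        probes = ["cg1", "cg2"]
        ann = make_annotation(probes, cgi_relation="open_sea")
        beta = ms.BetaMatrix(
            pd.DataFrame(rng.random((2, 4)), index=probes,
                         columns=[f"s{j}" for j in range(4)])
        )
        with pytest.raises(ms.ValidationError):
            ms.select_features(ms.ProbeSet("d", frozenset(probes), ""), ann, beta)


@pytest.fixture(scope="module")
def fitted():
    beta, labels = _toy_separable()
    model = ms.fit_multinomial_lasso(
        beta, labels, n_folds=5, n_lambda=30, seed=0
    )
    return beta, labels, model


class TestFitAndPredict:

    def test_separable_toy_perfect_training_accuracy(self, fitted):
        beta, labels, model = fitted
        _, pred = ms.predict(model, beta)
        assert (pred.to_numpy() == labels.to_numpy()).all()

    def test_probabilities_sum_to_one(self, fitted):
        beta, _, model = fitted
        prob, _ = ms.predict(model, beta)
        assert np.allclose(prob.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_model_predicts_priors(self):
        priors = np.array([0.5, 0.3, 0.2])
        model = ms.SubtypeModel(
            classes=["HM", "IM", "LM"], probe_ids=["cg1", "cg2"],
            coefficients=np.zeros((3, 2)), intercepts=np.log(priors),
        )
        beta = ms.BetaMatrix(
            pd.DataFrame([[0.1, 0.9], [0.8, 0.2]], index=["cg1", "cg2"],
                         columns=["a", "b"])
        )
        prob, _ = ms.predict(model, beta)
        for s in ("a", "b"):
            assert np.allclose(prob.loc[s], priors, atol=1e-12)

    def test_penalty_beyond_lambda_max_zeroes_everything(self):
        beta, labels = _toy_separable()
        X = beta.values.T
        Xs, _, _ = _standardize(X)
        y = labels.to_numpy()
        yo = (y[:, None] == np.array(sorted(set(y)))[None, :]).astype(float)
        lmax = _lambda_max(Xs, yo)
        (coef, icpt, _), = _fit_path(Xs, y, [lmax * 1.5], seed=0)
        assert np.abs(coef).max() == 0.0

    def test_signature_recovers_informative_probes(self, fitted):
        _, _, model = fitted
        sig = ms.extract_signature(model)
        assert {"cg000", "cg001", "cg002"} <= sig.probe_ids

    def test_signature_shrinks_with_penalty(self):
        beta, labels = _toy_separable()
        X = beta.values.T
        Xs, _, _ = _standardize(X)
        y = labels.to_numpy()
        yo = (y[:, None] == np.array(sorted(set(y)))[None, :]).astype(float)
        lmax = _lambda_max(Xs, yo)
        lams = np.geomspace(lmax, lmax * 1e-3, 12)
        sizes = [
            int((np.abs(coef).max(axis=0) > 0).sum())
            for coef, _, _ in _fit_path(Xs, y, lams, seed=0)
        ]
        # nonzero count grows (weakly) as the penalty decreases
        assert all(a <= b + 1 for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] <= sizes[-1]

    def test_linear_predictor_matches_brute_force(self, fitted, rng):
        beta, _, model = fitted
        prob, _ = ms.predict(model, beta)
        sid = beta.sample_ids[4]
        x = beta.df[sid].loc[model.probe_ids].to_numpy()
        scores = model.intercepts + model.coefficients @ x
        expect = np.exp(scores) / np.exp(scores).sum()
        assert np.allclose(prob.loc[sid], expect, atol=1e-12)

    def test_model_text_round_trip(self, fitted, tmp_path):
        _, _, model = fitted
        path = tmp_path / "model.txt"
        model.to_text(path)
        back = ms.SubtypeModel.from_text(path)
        assert back.classes == model.classes
        assert back.probe_ids == model.probe_ids
        assert np.array_equal(back.coefficients, model.coefficients)
        assert back.penalty == model.penalty


def test_lasso_solution_matches_glmnet_oracle(tmp_path):
    """At a fixed penalty, the saga solution agrees with R glmnet on a
    pre-standardized fixture (same symmetric multinomial objective)."""
    import subprocess

    rng = np.random.default_rng(3)
    n, p = 30, 40
    X = rng.random((n, p))
    y = np.repeat(["HM", "IM", "LM"], 10)
    X[:10, 0] += 0.8
    X[10:20, 1] += 0.8
    X[20:, 2] += 0.8
    Xs, _, _ = _standardize(X)
    yo = (y[:, None] == np.array(["HM", "IM", "LM"])[None, :]).astype(float)
    lam = _lambda_max(Xs, yo) * 0.05
    (coef, icpt, cls), = _fit_path(Xs, y, [lam], seed=0, tol=1e-6)

    np.savetxt(tmp_path / "X.csv", Xs, delimiter=",")
    (tmp_path / "y.csv").write_text("\n".join(y))
    (tmp_path / "cmp.R").write_text(
        'suppressMessages(library(glmnet))\n'
        'X <- as.matrix(read.csv("X.csv", header=FALSE))\n'
        'y <- factor(readLines("y.csv"))\n'
        f'fit <- glmnet(X, y, family="multinomial", lambda={lam},\n'
        '              standardize=FALSE, type.multinomial="ungrouped",\n'
        '              thresh=1e-12)\n'
        'co <- coef(fit)\n'
        'for (cl in names(co)) {\n'
        '  cat(cl, paste(sprintf("%.10f", as.numeric(co[[cl]])),\n'
        '      collapse=","), "\\n")\n'
        '}\n'
    )
    out = subprocess.run(
        ["Rscript", "cmp.R"], cwd=tmp_path, capture_output=True, text=True
    )
    assert out.returncode == 0, out.stderr
    gl = {}
    for line in out.stdout.strip().splitlines():
        name, vals = line.split(" ", 1)
        gl[name] = np.array([float(v) for v in vals.split(",")])
    for i, cl in enumerate(cls):
        assert abs(gl[cl][0] - icpt[i]) < 5e-3
        assert np.abs(gl[cl][1:] - coef[i]).max() < 5e-3


class TestKappa:
    def test_formula_arithmetic(self):
        assert ms.kappa_from_accuracies(0.9, 0.5) == pytest.approx(0.8)
        assert ms.kappa_from_accuracies(0.5, 0.5) == 0.0
        assert ms.kappa_from_accuracies(1.0, 0.4) == pytest.approx(1.0)

    def test_perfect_balanced_predictions(self):
        y = np.repeat(["HM", "IM", "LM"], 10)
        ev = ms.evaluate_kappa(y, y, n_permutations=500, seed=0)
        assert ev.acc == 1.0
        assert ev.kappa == pytest.approx(1.0, abs=0.05)
        assert ev.kappa <= 1.0

    def test_reported_kappa_satisfies_identity(self, rng):
        true = rng.choice(["HM", "IM", "LM"], 60)
        pred = np.where(rng.random(60) < 0.7, true,
                        rng.choice(["HM", "IM", "LM"], 60))
        ev = ms.evaluate_kappa(pred, true, n_permutations=200, seed=1)
        assert ev.kappa == pytest.approx(
            (ev.acc - ev.acc_rand) / (1 - ev.acc_rand), abs=1e-12
        )

    def test_acc_rand_converges_to_frequency_dot_product(self):
        true = np.repeat(["HM", "IM", "LM"], [30, 20, 10])
        pred = np.repeat(["HM", "IM", "LM"], [10, 20, 30])
        ev = ms.evaluate_kappa(pred, true, n_permutations=10_000, seed=2)
        f_true = np.array([30, 20, 10]) / 60
        f_pred = np.array([10, 20, 30]) / 60
        assert ev.acc_rand == pytest.approx(float(f_true @ f_pred), abs=0.01)

    def test_degenerate_single_class_rejected(self):
        y = np.array(["HM", "HM", "HM"])
        with pytest.raises(ms.ValidationError):
            ms.evaluate_kappa(y, y, n_permutations=10, seed=0)

    def test_empty_signature_for_all_zero_model(self):
        model = ms.SubtypeModel(
            classes=["HM", "LM"], probe_ids=["cg1"],
            coefficients=np.zeros((2, 1)), intercepts=np.zeros(2),
        )
        assert len(ms.extract_signature(model)) == 0
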