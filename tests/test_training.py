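"""Loss closed forms, splits, the training loop, and static baselines."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hftraj.cohort import Cohort
from hftraj.networks import ModelSpec
from hftraj.simulate import planted_signal_profile, simulate_cohort
from hftraj.training import (
    LossConfig,
    TrainConfig,
    TrainingError,
    cross_entropy,
    fit_static_baseline,
    focal_loss,
    multi_task_loss,
    split_cohort,
    train,
)

from conftest import make_timeline


class TestCrossEntropy:
    def test_perfect_prediction_is_near_zero(self):
        assert cross_entropy([1.0], [1.0 - 1e-9]) < 1e-6

    def test_uninformative_prediction_is_log_two(self):
        assert cross_entropy([1.0], [0.5]) == pytest.approx(math.log(2))

    def test_matches_scalar_oracle_on_random_batch(self):
        rng = np.random.default_rng(0)
        y = (rng.random(20) < 0.3).astype(float)
        p = rng.uniform(0.01, 0.99, 20)
        expected = sum(
            -yi * math.log(pi) - (1 - yi) * math.log(1 - pi) for yi, pi in zip(y, p)
        )
        assert cross_entropy(y, p) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([1.0, 0.0], [0.5])


class TestFocalLoss:
    def test_positive_label_closed_form(self):
        # α (1−ŷ)^β at (1, 0.5, 0.25, 2) → 0.25·0.25·ln2
        assert focal_loss([1.0], [0.5]) == pytest.approx(0.25 * 0.25 * math.log(2))

    def test_negative_label_closed_form(self):
        # (1−α) ŷ^β at (0, 0.5, 0.25, 2) → 0.75·0.25·ln2
        assert focal_loss([0.0], [0.5]) == pytest.approx(0.75 * 0.25 * math.log(2))

    def test_beta_zero_reduces_to_alpha_weighted_cross_entropy(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = (rng.random(30) < 0.4).astype(float)
            p = rng.uniform(0.05, 0.95, 30)
            fl = focal_loss(y, p, alpha=0.25, beta=0.0)
            weighted_ce = sum(
                -0.25 * yi * math.log(pi) - 0.75 * (1 - yi) * math.log(1 - pi)
                for yi, pi in zip(y, p)
            )
            assert fl == pytest.approx(weighted_ce, abs=1e-10)

    @given(
        y=st.integers(0, 1),
        p=st.floats(0.01, 0.99),
        beta=st.floats(0.0, 5.0),
    )
    def test_bounded_by_weighted_cross_entropy(self, y, p, beta):
        fl = focal_loss([float(y)], [p], alpha=0.25, beta=beta)
        ce = cross_entropy([float(y)], [p])
        assert fl <= max(0.25, 0.75) * ce + 1e-12


class TestMultiTaskLoss:
    def test_perfect_cm_channels_leave_hf_loss(self):
        targets = np.array([[1.0, 0, 1, 0], [0.0, 1, 0, 0]])
        outputs = targets.copy()
        outputs[:, 0] = [0.6, 0.3]  # imperfect HF channel only
        total, hf, cm = multi_task_loss(targets, outputs, return_components=True)
        assert cm == pytest.approx(0.0, abs=1e-5)
        assert total == pytest.approx(hf, abs=1e-5)

    def test_symmetric_channels_scale_by_four(self):
        targets = np.zeros((3, 4))
        outputs = np.full((3, 4), 0.5)
        total = multi_task_loss(targets, outputs)
        single = focal_loss(np.zeros(3), np.full(3, 0.5))
        assert total == pytest.approx(4 * single)

    def test_matches_channel_by_channel_oracle(self):
        rng = np.random.default_rng(2)
        targets = (rng.random((10, 4)) < 0.3).astype(float)
        outputs = rng.uniform(0.05, 0.95, (10, 4))
        expected = sum(
            focal_loss(targets[:, j], outputs[:, j]) for j in range(4)
        )
        assert multi_task_loss(targets, outputs) == pytest.approx(expected, rel=1e-12)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multi_task_loss(np.zeros((3, 4)), np.zeros((3, 2)))


class TestSplitCohort:
    @pytest.fixture
    def cohort_1000(self):
        return Cohort([make_timeline(f"P{i:04d}", 2) for i in range(1000)])

    def test_floor_rule_sizes(self, cohort_1000):
        out = split_cohort(cohort_1000, seed=0)
        sizes = {s: sum(v == s for v in out.split.values())
                 for s in ("train", "validation", "test")}
        assert sizes == {"train": 638, "validation": 112, "test": 250}

    def test_deterministic_and_partitioning(self, cohort_1000):
        a = split_cohort(cohort_1000, seed=5)
        b = split_cohort(cohort_1000, seed=5)
        assert a.split == b.split
        assert set(a.split) == set(a.patient_ids())

    def test_too_few_patients_rejected(self):
        with pytest.raises(TrainingError):
            split_cohort(Cohort([make_timeline("A", 2)]))


def small_planted_cohort(n=120, steps=16, seed=3):
    cohort = simulate_cohort(
        planted_signal_profile(n_patients=n, n_steps=steps, seed=seed)
    )
    return split_cohort(cohort, seed=seed)


class TestTrainLoop:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        cohort = small_planted_cohort(n=30, steps=8)
        spec = ModelSpec(variant="dhtm", hidden_width=4)
        from hftraj.networks import build_network

        reference = build_network(spec, seed=9)
        before = [p.data.copy() for p in reference.params()]
        model, history = train(
            spec, cohort, LossConfig(),
            TrainConfig(epochs=1, learning_rate=0.0, seed=9),
        )
        assert len(history) == 1
        for p, b in zip(model.parameters(), before):
            assert p.data == pytest.approx(b)

    def test_loss_decreases_on_planted_signal(self):
        cohort = small_planted_cohort()
        model, history = train(
            ModelSpec(variant="dhtm", hidden_width=8), cohort,
            LossConfig(), TrainConfig(epochs=4, seed=4),
        )
        assert history["total_loss"].iloc[-1] < history["total_loss"].iloc[0]

    def test_dhtmc_cm_loss_component_decreases(self):
        cohort = small_planted_cohort()
        _, history = train(
            ModelSpec(variant="dhtm_c", hidden_width=8), cohort,
            LossConfig(), TrainConfig(epochs=4, seed=4),
        )
        assert history["cm_loss"].iloc[-1] < history["cm_loss"].iloc[0]
        assert history["total_loss"].to_numpy() == pytest.approx(
            (history["hf_loss"] + history["cm_loss"]).to_numpy()
        )

    def test_deterministic_under_fixed_seed(self):
        cohort = small_planted_cohort(n=30, steps=8)
        kwargs = dict(loss_config=LossConfig(),
                      train_config=TrainConfig(epochs=2, seed=12))
        m1, h1 = train(ModelSpec(variant="dhtm", hidden_width=4), cohort, **kwargs)
        m2, h2 = train(ModelSpec(variant="dhtm", hidden_width=4), cohort, **kwargs)
        assert h1.equals(h2)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert p1.data == pytest.approx(p2.data, abs=0)


class TestStaticBaselines:
    def separable_cohort(self):
        # next-step HFH is exactly the current sepsis indicator
        rng = np.random.default_rng(6)
        patients = []
        for i in range(40):
            sepsis = (rng.random(6) < 0.4).astype(float)
            hf = np.concatenate([[0.0], sepsis[:-1]])
            patients.append(
                make_timeline(f"P{i:02d}", 6, hf=hf, cm_sepsis=sepsis)
            )
        cohort = Cohort(patients)
        return split_cohort(cohort, fractions=(1.0, 0.0, 0.0), seed=0)

    @pytest.mark.parametrize("kind", ["logreg_l2", "linear_svm"])
    def test_separable_rows_fit_perfectly(self, kind):
        cohort = self.separable_cohort()
        model = fit_static_baseline(kind, cohort)
        from hftraj.training import flatten_rows

        X, y = flatten_rows(cohort, "train")
        acc = ((model.predict_proba(X) > 0.5).astype(float) == y).mean()
        assert acc == 1.0

    def test_constant_features_predict_prevalence(self):
        rng = np.random.default_rng(7)
        patients = [
            make_timeline(f"P{i:02d}", 5, hf=(rng.random(5) < 0.3).astype(float))
            for i in range(60)
        ]
        cohort = split_cohort(Cohort(patients), fractions=(1.0, 0.0, 0.0), seed=0)
        model = fit_static_baseline("logreg_l2", cohort)
        from hftraj.training import flatten_rows

        X, y = flatten_rows(cohort, "train")
        assert model.predict_proba(X).mean() == pytest.approx(y.mean(), abs=0.02)

    def test_single_class_labels_rejected(self):
        patients = [make_timeline(f"P{i}", 4) for i in range(10)]
        cohort = split_cohort(Cohort(patients), fractions=(1.0, 0.0, 0.0), seed=0)
        with pytest.raises(TrainingError, match="one class"):
            fit_static_baseline("logreg_l2", cohort)

    def test_coefficient_recovery_on_synthetic_logistic_rows(self):
        # length-2 timelines: one (input, label) row per patient drawn from a
        # known logistic model on three co-morbidity indicators
        rng = np.random.default_rng(8)
        w = {"cm_diabetes": 1.5, "cm_kidney": -1.0, "cm_sepsis": 2.0}
        intercept = -1.0
        patients = []
        for i in range(5000):
            x = {k: float(rng.random() < 0.5) for k in w}
            logit = intercept + sum(w[k] * x[k] for k in w)
            y1 = float(rng.random() < 1 / (1 + math.exp(-logit)))
            patients.append(
                make_timeline(
                    f"P{i:05d}", 2, hf=[0.0, y1],
                    **{k: [v, v] for k, v in x.items()},
                )
            )
        cohort = split_cohort(Cohort(patients), fractions=(1.0, 0.0, 0.0), seed=0)
        model = fit_static_baseline("logreg_l2", cohort, C=100.0)
        from hftraj.cohort import INPUT_COLUMNS
        from hftraj.training import flatten_rows

        X, _ = flatten_rows(cohort, "train")
        coefs = dict(zip(INPUT_COLUMNS, model.estimator.coef_[0]))
        # asymptotic standard errors from the inverse Fisher information
        p = model.predict_proba(X)
        active = [INPUT_COLUMNS.index(k) for k in w]
        Xd = np.column_stack([np.ones(len(X)), X[:, active]])
        fisher = Xd.T @ (Xd * (p * (1 - p))[:, None])
        cov = np.linalg.inv(fisher)
        se = dict(zip(["intercept"] + list(w), np.sqrt(np.diag(cov))))
        for k, true_w in w.items():
            assert abs(coefs[k] - true_w) < 3 * se[k], k
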