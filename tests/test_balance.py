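import numpy as np
import pytest

from psqakit import (
    ShapleyReport,
    SimConfig,
    TrainConfig,
    compute_lambda,
    generate_dataset,
    shapley_oracle,
    shapley_two_modality,
    total_loss,
    value_function,
)
from psqakit.balance import SubsetValue, make_report
from psqakit.nn import BOTH, EMPTY, IMG, TAB, SubsetPredictions
from psqakit.nn.layers import Adam
from psqakit.nn.model import NetworkConfig, QAModel
from psqakit.train import fit, samples_to_arrays, train_epoch


def game(v_img, v_tab, v_both):
    return SubsetValue({EMPTY: 0.0, IMG: v_img, TAB: v_tab, BOTH: v_both})


def oracle_two(v: SubsetValue):
    table = {
        frozenset(): v[EMPTY],
        frozenset({"img"}): v[IMG],
        frozenset({"tab"}): v[TAB],
        frozenset({"img", "tab"}): v[BOTH],
    }
    return shapley_oracle(table, ("img", "tab"))


class TestValueFunction:
    def _preds(self, n, base):
        return SubsetPredictions({s: base.copy() for s in
                                  (EMPTY, IMG, TAB, BOTH)})

    def test_perfect_prediction_zero_value(self):
        targets = np.array([[90.0, 95.0, 97.0]] * 5)
        preds = self._preds(5, targets)
        v = value_function(preds, targets)
        assert v[BOTH] == 0.0

    def test_constant_offset(self):
        targets = np.array([[90.0, 95.0, 97.0]] * 4)
        by = {s: targets.copy() for s in (EMPTY, IMG, TAB, BOTH)}
        by[TAB] = targets + 2.0
        v = value_function(SubsetPredictions(by), targets)
        assert v[TAB] == pytest.approx(-2.0)

    def test_empty_subset_forced_zero(self):
        targets = np.array([[90.0, 95.0, 97.0]] * 4)
        by = {s: targets + 50.0 for s in (EMPTY, IMG, TAB, BOTH)}
        v = value_function(SubsetPredictions(by), targets)
        assert v[EMPTY] == 0.0

    def test_empty_validation_set_error(self):
        by = {s: np.zeros((0, 3)) for s in (EMPTY, IMG, TAB, BOTH)}
        with pytest.raises(ValueError):
            value_function(SubsetPredictions(by), np.zeros((0, 3)))


class TestShapley:
    def test_hand_worked_example(self):
        phi_img, phi_tab = shapley_two_modality(game(-2.0, -1.0, -0.5))
        assert phi_img == pytest.approx(-0.75)
        assert phi_tab == pytest.approx(0.25)

    def test_matches_oracle_exactly_on_random_games(self, rng):
        for _ in range(100):
            v = game(*rng.normal(0, 3, 3))
            phi = shapley_two_modality(v)
            oracle = oracle_two(v)
            assert phi[0] == pytest.approx(oracle[0], abs=1e-12)
            assert phi[1] == pytest.approx(oracle[1], abs=1e-12)

    def test_efficiency(self, rng):
        for _ in range(50):
            v = game(*rng.normal(0, 5, 3))
            phi_img, phi_tab = shapley_two_modality(v)
            assert abs(phi_img + phi_tab - (v[BOTH] - v[EMPTY])) <= 1e-12

    def test_symmetry(self):
        v = game(-1.3, -1.3, -0.4)
        phi_img, phi_tab = shapley_two_modality(v)
        assert phi_img == phi_tab

    def test_additivity(self, rng):
        for _ in range(100):
            a = rng.normal(0, 2, 3)
            b = rng.normal(0, 2, 3)
            pa = np.array(shapley_two_modality(game(*a)))
            pb = np.array(shapley_two_modality(game(*b)))
            pc = np.array(shapley_two_modality(game(*(a + b))))
            np.testing.assert_allclose(pa + pb, pc, atol=1e-12)


class TestShapleyOracle:
    def test_two_player_hand_example(self):
        phi = oracle_two(game(-2.0, -1.0, -0.5))
        np.testing.assert_allclose(phi, [-0.75, 0.25], atol=1e-12)

    def test_dummy_player(self, rng):
        # player "c" is a dummy: v(S + c) = v(S) + v({c})
        base = {frozenset(): 0.0}
        players = ("a", "b")
        r = rng.normal(0, 1, 3)
        base[frozenset({"a"})] = r[0]
        base[frozenset({"b"})] = r[1]
        base[frozenset({"a", "b"})] = r[2]
        vc = 0.7
        table = dict(base)
        for s, val in base.items():
            table[s | {"c"}] = val + vc
        phi = shapley_oracle(table, ("a", "b", "c"))
        assert phi[2] == pytest.approx(vc, abs=1e-12)

    def test_efficiency_random_three_player(self, rng):
        players = ("a", "b", "c")
        import itertools

        table = {frozenset(): 0.0}
        for k in range(1, 4):
            for combo in itertools.combinations(players, k):
                table[frozenset(combo)] = float(rng.normal())
        phi = shapley_oracle(table, players)
        assert phi.sum() == pytest.approx(table[frozenset(players)], abs=1e-12)

    def test_incomplete_table_error(self):
        with pytest.raises(ValueError, match="incomplete"):
            shapley_oracle({frozenset(): 0.0}, ("a", "b"))

    def test_player_limit(self):
        with pytest.raises(ValueError):
            shapley_oracle({}, tuple("abcdefghi"))


class TestLambdaRule:
    def test_hand_example(self):
        assert compute_lambda(-0.75, 0.25, 16.0) == pytest.approx(9.0)

    def test_clamp_branch(self):
        for r in (0.0, 8.0, 16.0, 100.0):
            assert compute_lambda(0.5, 0.2, r) == 1.0
            assert compute_lambda(0.5, 0.5, r) == 1.0

    def test_r_zero_recovers_unbalanced(self):
        for gap in (-2.0, 0.0, 0.5, 3.0):
            assert compute_lambda(0.0, gap, 0.0) == 1.0

    def test_slope(self):
        # positive branch is linear in (phi_tab - phi_img) with slope r/2
        r = 16.0
        l1 = compute_lambda(0.0, 1.0, r)
        l2 = compute_lambda(0.0, 2.0, r)
        assert l2 - l1 == pytest.approx(r / 2)

    def test_negative_r_rejected(self):
        with pytest.raises(ValueError):
            compute_lambda(0.0, 1.0, -1.0)


class TestTotalLoss:
    def test_arithmetic(self):
        assert total_loss(1.0, 2.0, 1.0) == 3.0
        assert total_loss(0.5, 0.1, 9.0) == pytest.approx(1.4)

    def test_zero_ddp(self):
        for lam in (1.0, 5.0, 100.0):
            assert total_loss(0.7, 0.0, lam) == 0.7

    def test_negative_loss_rejected(self):
        with pytest.raises(ValueError):
            total_loss(-1.0, 0.0, 1.0)


class TestShapleyReport:
    def test_efficiency_enforced(self):
        v = game(-2.0, -1.0, -0.5)
        with pytest.raises(ValueError, match="efficiency"):
            ShapleyReport(phi_img=0.0, phi_tab=0.0, lambda_ddp=1.0,
                          epoch=0, v=v)

    def test_make_report(self):
        targets = np.array([[90.0, 95.0, 97.0]] * 4)
        by = {s: targets.copy() for s in (EMPTY, IMG, TAB, BOTH)}
        by[IMG] = targets + 2.0  # image-only is worse
        rep = make_report(SubsetPredictions(by), targets, r=16.0, epoch=3)
        assert rep.epoch == 3
        assert rep.phi_tab > rep.phi_img
        assert rep.lambda_ddp > 1.0


@pytest.fixture(scope="module")
def tiny_training_setup():
    samples = generate_dataset(SimConfig(n_samples=24, grid=(32, 32), seed=3))
    net = NetworkConfig(grid=(32, 32), encoder_channels=(4, 8, 12, 16),
                        n_tab_channels=2, fused_width=16,
                        decoder_channels=(12, 8, 6, 4, 4), dropout=0.1)
    data = samples_to_arrays(samples)
    return samples, net, data


class TestTrainingLoop:
    def test_train_epoch_deterministic(self, tiny_training_setup):
        _, net, data = tiny_training_setup

        def one_epoch():
            model = QAModel(net, seed=5)
            opt = Adam(model.parameters(), lr=1e-3)
            return train_epoch(model, data, 1.0, opt,
                               np.random.default_rng(9), batch_size=8)

        assert one_epoch() == one_epoch()

    def test_lambda_below_one_rejected(self, tiny_training_setup):
        _, net, data = tiny_training_setup
        model = QAModel(net, seed=0)
        opt = Adam(model.parameters())
        with pytest.raises(ValueError):
            train_epoch(model, data, 0.5, opt, np.random.default_rng(0))

    def test_fit_history_contract(self, tiny_training_setup):
        _, net, data = tiny_training_setup
        cfg = TrainConfig(r=16.0, lr=1e-3, epochs=3, batch_size=8, seed=1)
        result = fit(data, data, net, cfg)
        assert len(result.reports) == cfg.epochs
        assert len(result.history) == cfg.epochs
        for rep in result.reports:
            total = rep.v[BOTH] - rep.v[EMPTY]
            assert abs(rep.phi_img + rep.phi_tab - total) <= 1e-9
            assert rep.lambda_ddp >= 1.0
        # lambda applied with one-epoch delay, starting at 1
        assert result.history[0]["lambda_used"] == 1.0
        assert result.history[1]["lambda_used"] == \
            result.reports[0].lambda_ddp

    def test_fit_r_zero_all_lambda_one(self, tiny_training_setup):
        _, net, data = tiny_training_setup
        cfg = TrainConfig(r=0.0, lr=1e-3, epochs=3, batch_size=8, seed=1)
        result = fit(data, data, net, cfg)
        assert all(rep.lambda_ddp == 1.0 for rep in result.reports)
        assert all(row["lambda_used"] == 1.0 for row in result.history)

    def test_loss_decreases_on_easy_data(self, tiny_training_setup):
        _, net, data = tiny_training_setup
        finals, firsts = [], []
        for seed in (0, 1, 2):
            cfg = TrainConfig(r=0.0, lr=3e-3, epochs=5, batch_size=8,
                              seed=seed)
            result = fit(data, data, net, cfg)
            firsts.append(result.history[0]["l_gpr"])
            finals.append(result.history[-1]["l_gpr"])
        assert np.median(finals) < np.median(firsts)


class TestTrainConfigDefaults:
    def test_reference_protocol_constants(self):
        cfg = TrainConfig()
        assert cfg.r == 16.0
        assert cfg.lr == 5e-4
        assert cfg.epochs == 30
        assert cfg.batch_size == 32
        assert cfg.dropout == 0.1
        assert cfg.split == (0.7, 0.1, 0.2)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(r=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(split=(0.5, 0.2, 0.2))
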