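import math

import numpy as np
import pytest

from sortseqkit.distributions import LogNormalInput, make_log_gates
from sortseqkit.infer import (
    ReadGateMatrix,
    information_footprint,
    lsq_fit_additive,
    mi_fit_montecarlo,
    mi_of_model,
)
from sortseqkit.seqmodel import (
    ActivityModel,
    activity_many,
    activity_to_mean,
    make_random_library,
    make_targeted_library,
    sample_additive_model,
)
from sortseqkit.simulate import bin_cells, sample_fluorescence


def simulate_reads(model, library, cells_per_variant, cv, gates, rng, mode="expression", nu_null=None):
    """Simulate per-read (sequence, gate) data for a library under a model."""
    seqs = np.stack([v.codes for v in library])
    g = activity_many(model, seqs)
    nus = activity_to_mean(g, mode, nu_null=nu_null)
    rows, gate_idx = [], []
    for i, nu in enumerate(nus):
        d = LogNormalInput.from_moments(float(nu), cv)
        counts = bin_cells(sample_fluorescence(d, cells_per_variant, rng), gates)
        for j, r in enumerate(counts.counts):
            rows.extend([i] * r)
            gate_idx.extend([j] * r)
    return ReadGateMatrix(
        seq_matrix=seqs[np.array(rows)], gate=np.array(gate_idx), m=gates.m
    ), nus


class TestLsqFitAdditive:
    def test_noiseless_targeted_recovery_is_exact(self, rng):
        P = 10
        truth = sample_additive_model(P, 4.0, rng)
        lib = make_targeted_library("A" * P)
        seqs = np.stack([v.codes for v in lib])
        nus = activity_to_mean(activity_many(truth, seqs), "repression", nu_null=10.0)
        fit = lsq_fit_additive(nus, lib, "A" * P, nu_null=10.0, link="repression")
        assert fit.converged
        assert fit.model.G0 == pytest.approx(truth.G0, abs=1e-6)
        np.testing.assert_allclose(fit.model.H, truth.H, atol=1e-6)

    def test_noiseless_random_library_recovery(self, rng):
        P = 10
        truth = sample_additive_model(P, 5.0, rng)
        lib = make_random_library("A" * P, 2.0, rng, n_variants=800)
        seqs = np.stack([v.codes for v in lib])
        nus = activity_to_mean(activity_many(truth, seqs), "expression")
        fit = lsq_fit_additive(nus, lib, "A" * P, link="expression")
        np.testing.assert_allclose(fit.model.H, truth.H, atol=1e-4)

    def test_shifted_data_leaves_residuals(self, rng):
        # the repression map is bounded by nu_null, so uniformly shifted
        # estimates cannot be fit exactly
        P = 6
        truth = sample_additive_model(P, 3.0, rng)
        lib = make_targeted_library("A" * P)
        seqs = np.stack([v.codes for v in lib])
        nus = activity_to_mean(activity_many(truth, seqs), "repression", nu_null=5.0)
        fit = lsq_fit_additive(nus + 2.0, lib, "A" * P, nu_null=5.0)
        assert fit.cost > 1e-4

    def test_irls_weighting_changes_nothing_on_noiseless_data(self, rng):
        P = 6
        truth = sample_additive_model(P, 3.0, rng)
        lib = make_targeted_library("A" * P)
        seqs = np.stack([v.codes for v in lib])
        nus = activity_to_mean(activity_many(truth, seqs), "expression")
        fit = lsq_fit_additive(nus, lib, "A" * P, link="expression", weighting="irls")
        np.testing.assert_allclose(fit.model.H, truth.H, atol=1e-5)


class TestInformationFootprint:
    def test_constant_position_carries_no_information(self, rng):
        seqs = np.zeros((500, 3), dtype=np.uint8)
        seqs[:, 1] = rng.integers(0, 4, 500)
        gates = rng.integers(0, 4, 500)
        fp = information_footprint(ReadGateMatrix(seq_matrix=seqs, gate=gates, m=4))
        assert fp[0] == 0.0
        assert fp[2] == 0.0

    def test_independent_product_table_has_zero_mi(self):
        # base and gate exactly independent by construction
        seqs = np.array([[q] for q in [0, 0, 1, 1, 0, 0, 1, 1]], dtype=np.uint8)
        gates = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        fp = information_footprint(ReadGateMatrix(seq_matrix=seqs, gate=gates, m=2))
        assert fp[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_correlated_binary_position_is_one_bit(self):
        seqs = np.array([[0], [1]] * 50, dtype=np.uint8)
        gates = np.array([0, 1] * 50)
        fp = information_footprint(ReadGateMatrix(seq_matrix=seqs, gate=gates, m=2))
        assert fp[0] == pytest.approx(1.0, abs=1e-12)

    def test_functional_positions_stand_out(self, rng):
        # only the first 3 positions affect activity; their MI should
        # dominate the untouched ones
        P = 8
        H = np.zeros((P, 4))
        H[:3, 1:] = -3.0
        truth = ActivityModel(reference="A" * P, G0=2.0, H=H)
        lib = make_random_library("A" * P, 2.0, rng, n_variants=400)
        gates = make_log_gates(6, 0.5, 30.0, semibounded=True)
        reads, _ = simulate_reads(truth, lib, 25, 0.3, gates, rng)
        fp = information_footprint(reads)
        assert fp[:3].min() > 5 * fp[3:].max()


class TestMiOfModel:
    @pytest.fixture
    def dataset(self, rng):
        P = 8
        truth = sample_additive_model(P, 3.0, rng)
        lib = make_random_library("A" * P, 2.0, rng, n_variants=400)
        gates = make_log_gates(6, 0.5, 60.0, semibounded=True)
        reads, _ = simulate_reads(truth, lib, 25, 0.4, gates, rng)
        return truth, reads

    def test_constant_model_has_no_rank_information(self, rng):
        seqs = rng.integers(0, 4, (5000, 4)).astype(np.uint8)
        gates = rng.integers(0, 4, 5000)
        reads = ReadGateMatrix(seq_matrix=seqs, gate=gates, m=4)
        flat = ActivityModel(reference="AAAA", G0=0.0, H=np.zeros((4, 4)))
        assert mi_of_model(reads, flat, block=100) < 0.01

    def test_scaling_H_leaves_mi_unchanged(self, dataset):
        truth, reads = dataset
        doubled = ActivityModel(reference=truth.reference, G0=truth.G0, H=2 * truth.H)
        a = mi_of_model(reads, truth, block=100, rng=np.random.default_rng(0))
        b = mi_of_model(reads, doubled, block=100, rng=np.random.default_rng(0))
        assert a == pytest.approx(b, abs=1e-12)

    def test_true_model_beats_shuffled_models(self, dataset, rng):
        truth, reads = dataset
        mi_true = mi_of_model(reads, truth, block=100)
        beaten = 0
        for _ in range(20):
            H = truth.H.copy()
            free = H[:, 1:].ravel()
            rng.shuffle(free)
            H[:, 1:] = free.reshape(H.shape[0], 3)
            shuffled = ActivityModel(reference=truth.reference, G0=truth.G0, H=H)
            beaten += mi_of_model(reads, shuffled, block=100) < mi_true
        assert beaten >= 19

    def test_requires_enough_reads_for_a_block(self, rng):
        seqs = rng.integers(0, 4, (100, 4)).astype(np.uint8)
        reads = ReadGateMatrix(seq_matrix=seqs, gate=np.zeros(100, dtype=int), m=2)
        flat = ActivityModel(reference="AAAA", G0=0.0, H=np.zeros((4, 4)))
        with pytest.raises(ValueError):
            mi_of_model(reads, flat, block=1000)


class TestMiFitMonteCarlo:
    def test_recovers_generating_model(self, rng):
        P = 8
        truth = sample_additive_model(P, 3.0, rng)
        lib = make_random_library("A" * P, 2.0, rng, n_variants=500)
        gates = make_log_gates(6, 0.5, 60.0, semibounded=True)
        reads, _ = simulate_reads(truth, lib, 20, 0.4, gates, rng)
        res = mi_fit_montecarlo(
            reads, "A" * P, rng, n_steps=8000, block=100, orient="up"
        )
        mask = truth.H != 0
        r = np.corrcoef(res.model.H[mask], truth.H[mask])[0, 1]
        assert r > 0.85

    def test_mi_trace_is_monotone_up_to_accepted_decreases(self, rng):
        # the acceptance rule only rarely lets MI drop, so the running
        # maximum should sit close to the trace tail
        P = 6
        truth = sample_additive_model(P, 3.0, rng)
        lib = make_random_library("A" * P, 2.0, rng, n_variants=300)
        gates = make_log_gates(5, 0.5, 60.0, semibounded=True)
        reads, _ = simulate_reads(truth, lib, 10, 0.4, gates, rng)
        res = mi_fit_montecarlo(reads, "A" * P, rng, n_steps=500, block=50, n_starts=1)
        assert res.mi_trace[-1] > 0.8 * res.mi_trace.max()

    def test_runs_from_different_seeds_agree(self, rng):
        P = 8
        truth = sample_additive_model(P, 3.0, rng)
        lib = make_random_library("A" * P, 2.0, rng, n_variants=500)
        gates = make_log_gates(6, 0.5, 60.0, semibounded=True)
        reads, _ = simulate_reads(truth, lib, 20, 0.4, gates, rng)
        fits = [
            mi_fit_montecarlo(
                reads, "A" * P, np.random.default_rng(seed),
                n_steps=15000, block=100, orient="up",
            )
            for seed in (101, 202)
        ]
        mask = np.zeros_like(truth.H, dtype=bool)
        mask[:, 1:] = True
        r = np.corrcoef(fits[0].model.H[mask], fits[1].model.H[mask])[0, 1]
        assert r > 0.9
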