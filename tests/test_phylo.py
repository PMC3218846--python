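import numpy as np
import pytest
from _oracles import enumeration_loglik, enumeration_posterior, gtr_q

from cpgrates.alignments import TripletAlignment, codes_to_seq
from cpgrates.phylo import (
    GTRModel,
    build_rate_matrix,
    fit_branch_lengths,
    log_likelihood,
    reconstruct_ancestor,
    transition_matrix,
)
from cpgrates.simulate import SimulationConfig, equilibrium_root_sequence, evolve_branch


def _random_model(rng):
    exch = rng.uniform(0.3, 5.0, size=6)
    pi = rng.dirichlet([8, 8, 8, 8])
    t = {"human": rng.uniform(0.005, 0.1), "rhesus": rng.uniform(0.005, 0.1),
         "mouse": rng.uniform(0.05, 0.6)}
    return GTRModel(exch, pi, t)


def _random_alignment(rng, n_cols, with_ambiguity=False):
    alphabet = "ACGTN-" if with_ambiguity else "ACGT"
    p = [0.22, 0.22, 0.22, 0.22, 0.06, 0.06] if with_ambiguity else [0.25] * 4
    seqs = ["".join(rng.choice(list(alphabet), size=n_cols, p=p)) for _ in range(3)]
    ungapped = n_cols - seqs[0].count("-")
    return TripletAlignment("I1", "chr1", 0, ungapped, "+", *seqs)


class TestRateMatrix:
    def test_detailed_balance_and_normalization(self):
        rng = np.random.default_rng(0)
        m = _random_model(rng)
        q = m.rate_matrix()
        pi = m.base_frequencies
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)
        assert np.isclose(-(pi * np.diag(q)).sum(), 1.0)

    def test_transition_matrix_rows_are_distributions(self):
        rng = np.random.default_rng(1)
        m = _random_model(rng)
        p = transition_matrix(m.rate_matrix(), m.base_frequencies, 0.3)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()


class TestLikelihoodOracle:
    def test_matches_enumeration_on_random_alignments(self):
        """Pruning likelihood equals the brute-force sum over ancestor
        states computed from scipy matrix exponentials."""
        rng = np.random.default_rng(42)
        for k in range(15):
            model = _random_model(rng)
            aln = _random_alignment(rng, int(rng.integers(5, 51)), with_ambiguity=(k % 3 == 0))
            got = log_likelihood(aln, model)
            h, r, m = aln.codes()
            want = enumeration_loglik(
                h, r, m, model.exchangeabilities, model.base_frequencies,
                model.branch_lengths["human"], model.branch_lengths["rhesus"],
                model.branch_lengths["mouse"],
            )
            assert abs(got - want) < 1e-10

    def test_zero_branch_limit_single_column(self):
        aln = TripletAlignment("I1", "chr1", 0, 1, "+", "A", "A", "A")
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        model = GTRModel(np.ones(6), pi, {"human": 0.0, "rhesus": 0.0, "mouse": 0.0})
        assert np.isclose(log_likelihood(aln, model), np.log(0.1))

    def test_reroot_invariance(self):
        """Reversibility: moving the root along the mouse branch leaves the
        likelihood unchanged (pulley principle)."""
        rng = np.random.default_rng(3)
        model = _random_model(rng)
        aln = _random_alignment(rng, 40)
        base = log_likelihood(aln, model)
        # root placed at distance x along the mouse branch: likelihood via
        # explicit two-internal-node enumeration
        t_m = model.branch_lengths["mouse"]
        q = gtr_q(model.exchangeabilities, model.base_frequencies)
        from scipy.linalg import expm

        for x in (0.25 * t_m, 0.8 * t_m):
            p_anc = expm(q * x)  # root -> human/rhesus ancestor
            p_mouse = expm(q * (t_m - x))
            p_h = expm(q * model.branch_lengths["human"])
            p_r = expm(q * model.branch_lengths["rhesus"])
            total = 0.0
            h, r, m = aln.codes()
            for hh, rr, mm in zip(h, r, m):
                site = 0.0
                for root in range(4):
                    inner = sum(
                        p_anc[root, a] * p_h[a, hh] * p_r[a, rr] for a in range(4)
                    )
                    site += model.base_frequencies[root] * inner * p_mouse[root, mm]
                total += np.log(site)
            assert abs(total - base) < 1e-10


class TestFit:
    def test_identical_sequences_give_zero_branch_lengths(self):
        seq = "ACGT" * 100
        aln = TripletAlignment("I1", "chr1", 0, 400, "+", seq, seq, seq)
        with np.errstate(all="ignore"):
            model = fit_branch_lengths(aln, fit_exchangeabilities=False)
        assert all(v <= 1e-6 for v in model.branch_lengths.values())

    def test_swapping_ingroup_leaves_swaps_their_branch_lengths(self):
        rng = np.random.default_rng(11)
        aln = _random_alignment(rng, 2000)
        m1 = fit_branch_lengths(aln, fit_exchangeabilities=False)
        swapped = TripletAlignment(
            "I1", "chr1", 0, aln.length, "+", aln.seq_rhesus, aln.seq_human, aln.seq_mouse
        )
        m2 = fit_branch_lengths(swapped, fit_exchangeabilities=False)
        assert np.isclose(m1.branch_lengths["human"], m2.branch_lengths["rhesus"], rtol=1e-3, atol=1e-6)
        assert np.isclose(m1.branch_lengths["rhesus"], m2.branch_lengths["human"], rtol=1e-3, atol=1e-6)
        assert np.isclose(m1.log_l, m2.log_l, rtol=1e-9)

    def test_parameter_recovery_on_long_neutral_simulation(self):
        """Branch lengths recovered within 5% on a 100-kb context-free
        (lambda = 1) simulated alignment."""
        cfg = SimulationConfig(
            n_introns=1, intron_length=100_000, cpg_ts_multiplier_max=1.0,
            cpg_tv_multiplier=1.0,
        )
        rng = np.random.default_rng(17)
        root = equilibrium_root_sequence(0.42, 0.0, 100_000, rng, cfg)
        params = {"gc_target": 0.42, "methylation": 0.0,
                  "cpg_ts_multiplier_max": 1.0, "cpg_tv_multiplier": 1.0}
        truth = {"human": 0.02, "rhesus": 0.025, "mouse": 0.35}
        leaves = {b: evolve_branch(root, t, params, rng, record=False)[0]
                  for b, t in truth.items()}
        aln = TripletAlignment(
            "I1", "chr1", 0, 100_000, "+",
            codes_to_seq(leaves["human"]), codes_to_seq(leaves["rhesus"]),
            codes_to_seq(leaves["mouse"]),
        )
        model = fit_branch_lengths(aln)
        assert model.converged
        for b, t in truth.items():
            assert abs(model.branch_lengths[b] - t) / t < 0.05


class TestModelIO:
    def test_yaml_round_trip(self, tmp_path):
        rng = np.random.default_rng(31)
        m = _random_model(rng)
        m.log_l = -1234.5
        path = tmp_path / "model.yaml"
        m.to_yaml(path)
        back = GTRModel.from_yaml(path)
        assert np.allclose(back.exchangeabilities, m.exchangeabilities)
        assert np.allclose(back.base_frequencies, m.base_frequencies)
        assert back.branch_lengths == pytest.approx(m.branch_lengths)
        assert back.log_l == m.log_l and back.converged == m.converged


class TestReconstruction:
    def test_posterior_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for k in range(10):
            model = _random_model(rng)
            aln = _random_alignment(rng, int(rng.integers(5, 51)), with_ambiguity=(k % 2 == 0))
            prof = reconstruct_ancestor(aln, model)
            h, r, m = aln.codes()
            want = enumeration_posterior(
                h, r, m, model.exchangeabilities, model.base_frequencies,
                model.branch_lengths["human"], model.branch_lengths["rhesus"],
                model.branch_lengths["mouse"],
            )
            ok = prof.mask
            assert np.nanmax(np.abs(prof.posterior[ok] - want[ok])) < 1e-10
            assert np.allclose(np.nansum(prof.posterior[ok], axis=1), 1.0, atol=1e-9)

    def test_zero_ingroup_branches_give_point_mass_on_shared_base(self):
        aln = TripletAlignment("I1", "chr1", 0, 4, "+", "ACGT", "ACGT", "TTTT")
        model = GTRModel(
            np.ones(6), np.full(4, 0.25), {"human": 0.0, "rhesus": 0.0, "mouse": 0.5}
        )
        prof = reconstruct_ancestor(aln, model)
        assert prof.map_sequence == "ACGT"
        assert np.allclose(prof.posterior.max(axis=1), 1.0)

    def test_ccT_column_maps_to_c_for_short_ingroup_branches(self):
        aln = TripletAlignment("I1", "chr1", 0, 1, "+", "C", "C", "T")
        model = GTRModel(
            np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0]), np.full(4, 0.25),
            {"human": 0.01, "rhesus": 0.01, "mouse": 0.4},
        )
        prof = reconstruct_ancestor(aln, model)
        assert prof.map_sequence == "C"

    def test_masked_columns_flagged_and_excluded(self):
        aln = TripletAlignment("I1", "chr1", 0, 4, "+", "ACGT", "AC-T", "ACNT")
        model = GTRModel(np.ones(6), np.full(4, 0.25),
                         {"human": 0.02, "rhesus": 0.02, "mouse": 0.3})
        prof = reconstruct_ancestor(aln, model)
        assert prof.mask.tolist() == [True, True, False, True]
        assert prof.map_codes[2] == 4
        assert np.isnan(prof.posterior[2]).all()

    def test_map_error_rate_decreases_with_branch_lengths(self, small_bundle):
        """Ancestor-call errors at non-CpG sites shrink as branches shrink."""
        rng = np.random.default_rng(23)
        cfg = SimulationConfig(n_introns=1, intron_length=4000)
        errs = []
        for scale in (1.0, 0.25):
            root = equilibrium_root_sequence(0.45, 0.7, 4000, rng, cfg)
            params = {"gc_target": 0.45, "methylation": 0.7}
            leaves = {
                b: evolve_branch(root, t * scale, params, rng, record=False)[0]
                for b, t in (("human", 0.02), ("rhesus", 0.025), ("mouse", 0.35))
            }
            aln = TripletAlignment(
                "I1", "chr1", 0, 4000, "+",
                codes_to_seq(leaves["human"]), codes_to_seq(leaves["rhesus"]),
                codes_to_seq(leaves["mouse"]),
            )
            model = fit_branch_lengths(aln, fit_exchangeabilities=False)
            prof = reconstruct_ancestor(aln, model)
            noncpg = np.ones(4000, bool)
            cg = (root[:-1] == 1) & (root[1:] == 2)
            noncpg[:-1][cg] = False
            noncpg[1:][cg] = False
            errs.append((prof.map_codes[noncpg] != root[noncpg]).mean())
        assert errs[1] < errs[0]
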