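import numpy as np
import pandas as pd
import pytest
from _oracles import total_rate_brute
from scipy import stats as sps

from cpgrates.alignments import filter_introns, read_alignments, seq_to_codes
from cpgrates.pipeline import compute_rates
from cpgrates.simulate import (
    ConfigError,
    SimulationConfig,
    cpg_oe_of_codes,
    draw_intron_parameters,
    emit_study_bundle,
    equilibrium_root_sequence,
    evolve_branch,
    replay_events,
    simulate_study,
)

EXCH = (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)


class TestConfig:
    def test_invalid_mixture_weights_rejected(self):
        with pytest.raises(ConfigError, match="mixture"):
            SimulationConfig(
                methylation_distribution={"A": [{"weight": -1.0, "a": 2, "b": 2}]}
            )

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="base_frequencies"):
            SimulationConfig(base_frequencies=(0.3, 0.3, 0.3, 0.3))

    def test_lambda_max_below_one_rejected(self):
        with pytest.raises(ConfigError, match="lambda_max"):
            SimulationConfig(cpg_ts_multiplier_max=0.5)


class TestDrawParameters:
    def test_class_c_methylation_broader_than_class_a(self):
        cfg = SimulationConfig(n_introns=1000, dataset_weights={"A": 0.5, "C": 0.5})
        df = draw_intron_parameters(cfg, np.random.default_rng(1))
        var = df.groupby("dataset_true")["methylation_true"].var()
        assert var["C"] > var["A"]

    def test_point_mass_config_gives_identical_parameters(self):
        cfg = SimulationConfig(
            n_introns=50,
            dataset_weights={"A": 1.0},
            methylation_distribution={"A": [{"weight": 1.0, "value": 0.5}]},
            gc_target_distribution={"A": {"value": 0.45}},
            rate_heterogeneity_sigma=0.0,
            gc_effect=0.0,
            expression_sd=0.0,
        )
        df = draw_intron_parameters(cfg, np.random.default_rng(2))
        for col in ("methylation_true", "gc_target", "rate_scalar", "expression_true"):
            assert df[col].nunique() == 1

    def test_fixed_seed_reproduces_table_exactly(self):
        cfg = SimulationConfig(n_introns=100)
        a = draw_intron_parameters(cfg, np.random.default_rng(3))
        b = draw_intron_parameters(cfg, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)


class TestEquilibrium:
    def test_no_hypermutability_leaves_cpg_oe_near_one(self):
        cfg = SimulationConfig(n_introns=1, intron_length=100_000,
                               cpg_ts_multiplier_max=1.0, cpg_tv_multiplier=1.0)
        seq = equilibrium_root_sequence(0.5, 0.0, 100_000, np.random.default_rng(4), cfg)
        assert abs(cpg_oe_of_codes(seq) - 1.0) < 0.05

    def test_strong_hypermutability_depletes_cpg(self):
        cfg = SimulationConfig(n_introns=1, intron_length=100_000,
                               cpg_ts_multiplier_max=20.0)
        seq = equilibrium_root_sequence(0.5, 1.0, 100_000, np.random.default_rng(5), cfg)
        assert cpg_oe_of_codes(seq) < 0.6

    def test_identical_seed_identical_sequence(self):
        cfg = SimulationConfig(n_introns=1, intron_length=2000)
        a = equilibrium_root_sequence(0.4, 0.7, 2000, np.random.default_rng(6), cfg)
        b = equilibrium_root_sequence(0.4, 0.7, 2000, np.random.default_rng(6), cfg)
        assert (a == b).all()


class TestEvolveBranch:
    PARAMS = {"gc_target": 0.5, "methylation": 0.8, "exchangeabilities": EXCH,
              "cpg_ts_multiplier_max": 12.0, "cpg_tv_multiplier": 2.0}

    def test_zero_branch_is_identity_with_empty_log(self):
        seq = "ACGTACGT" * 10
        out, events = evolve_branch(seq, 0.0, self.PARAMS, np.random.default_rng(0))
        assert (out == seq_to_codes(seq)).all()
        assert len(events) == 0

    def test_multiplier_off_control_treats_cpg_like_other_c_sites(self):
        """With lambda = 1, substitution counts at CpG-context and other C
        sites are statistically indistinguishable (chi-square)."""
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(n_introns=1, intron_length=50_000,
                               cpg_ts_multiplier_max=1.0, cpg_tv_multiplier=1.0)
        root = equilibrium_root_sequence(0.5, 1.0, 50_000, rng, cfg)
        params = dict(self.PARAMS, cpg_ts_multiplier_max=1.0, cpg_tv_multiplier=1.0)
        leaf, _ = evolve_branch(root, 0.05, params, rng)
        c_sites = root == 1
        cpg = np.zeros(root.size, bool)
        cpg[:-1] = (root[:-1] == 1) & (root[1:] == 2)
        changed = leaf != root
        table = [
            [int((changed & cpg).sum()), int((~changed & c_sites & cpg).sum())],
            [int((changed & c_sites & ~cpg).sum()), int((~changed & c_sites & ~cpg).sum())],
        ]
        _, p, _, _ = sps.chi2_contingency(table)
        assert p > 0.01

    def test_event_count_matches_analytic_total_rate(self):
        """Total event count on a 10-kb branch lies within 3 SD of the
        initial total rate x time (Poisson), with the first-event
        approximation checked at t = 0.001."""
        rng = np.random.default_rng(8)
        cfg = SimulationConfig(n_introns=1, intron_length=10_000)
        root = equilibrium_root_sequence(0.5, 0.8, 10_000, rng, cfg)
        r0 = total_rate_brute(root, EXCH, [0.25] * 4, 1 + 11 * 0.8, 2.0)
        _, events = evolve_branch(root, 0.02, self.PARAMS, rng)
        expected = r0 * 0.02
        assert abs(len(events) - expected) < 3.0 * np.sqrt(expected)
        # first-event regime: aggregate 40 short branches
        total = 0
        for _ in range(40):
            _, ev = evolve_branch(root, 0.001, self.PARAMS, rng)
            total += len(ev)
        expected_small = 40 * r0 * 0.001
        assert abs(total - expected_small) < 3.0 * np.sqrt(expected_small)

    def test_asymmetric_mode_only_elevates_written_strand(self):
        rng = np.random.default_rng(9)
        cfg = SimulationConfig(n_introns=1, intron_length=30_000, strand_symmetric=False)
        root = equilibrium_root_sequence(0.5, 1.0, 30_000, rng, cfg)
        params = dict(self.PARAMS, methylation=1.0, strand_symmetric=False)
        _, ev = evolve_branch(root, 0.02, params, rng)
        ts_coding = int(((ev.context == 1) & (ev.to_base == 3)).sum())
        ts_noncoding = int(((ev.context == 2) & (ev.to_base == 0)).sum())
        assert ts_coding > 4 * ts_noncoding


class TestStudyBundle:
    def test_replayed_event_logs_reproduce_leaves(self, small_bundle):
        seqs = {"human": 0, "rhesus": 1, "mouse": 2}
        for aln in small_bundle.alignments[:10]:
            root = small_bundle.root_sequences[aln.intron_id]
            for branch, idx in seqs.items():
                leaf = replay_events(root, small_bundle.events[aln.intron_id][branch])
                assert (leaf == aln.codes()[idx]).all()

    def test_rerun_is_byte_identical(self):
        cfg = SimulationConfig(n_introns=8, intron_length=600, seed=77)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        for x, y in zip(a.alignments, b.alignments):
            assert x == y
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(
            a.methylation_track.intervals, b.methylation_track.intervals
        )

    def test_emitted_bundle_cardinality_and_label_consistency(self, tmp_path):
        cfg = SimulationConfig(n_introns=10, intron_length=600, seed=5,
                               dataset_weights={"A": 0.3, "B": 0.3, "C": 0.4})
        out = emit_study_bundle(cfg, tmp_path / "bundle")
        alns = list(read_alignments(out / "alignments.fasta"))
        truth = pd.read_csv(out / "ground_truth.tsv", sep="\t")
        assert len(alns) == 10 and len(truth) == 10
        cgi = pd.read_csv(out / "cgi.bed", sep="\t", header=None,
                          names=["chrom", "start", "end"])
        dhs = pd.read_csv(out / "dhs.bed", sep="\t", header=None,
                          names=["chrom", "start", "end"])
        for row in truth[truth.dataset_true == "C"].itertuples():
            for track in (cgi, dhs):
                hit = track[(track.chrom == row.chrom) & (track.start < row.end)
                            & (track.end > row.start)]
                assert len(hit) > 0

    def test_mean_cpg_transition_count_monotone_in_methylation(self):
        """True per-CpG-site transition counts rise with methylation
        across quintile bins (1,000 introns, uniform methylation)."""
        cfg = SimulationConfig(
            n_introns=1000, intron_length=800, seed=55,
            dataset_weights={"A": 1.0},
            methylation_distribution={"A": [{"weight": 1.0, "a": 1.0, "b": 1.0}]},
            rate_heterogeneity_sigma=0.0, gc_effect=0.0,
        )
        b = simulate_study(cfg)
        meth, rate = [], []
        for row in b.truth.itertuples():
            root = b.root_sequences[row.intron_id]
            n_cpg = int(((root[:-1] == 1) & (root[1:] == 2)).sum())
            if n_cpg == 0:
                continue
            ev = b.events[row.intron_id]["human"]
            n_ts = int((((ev.context == 1) & (ev.to_base == 3))
                        | ((ev.context == 2) & (ev.to_base == 0))).sum())
            meth.append(row.methylation_true)
            rate.append(n_ts / n_cpg)
        df = pd.DataFrame({"m": meth, "r": rate})
        df["bin"] = pd.qcut(df["m"], 5, labels=False)
        means = df.groupby("bin")["r"].mean().to_numpy()
        assert (np.diff(means) >= 0).all()

    def test_neutral_homogeneous_cpg_and_cph_transition_rates_agree(self):
        """With lambda = 1 and homogeneous scalars, the pipeline's pooled
        per-cytosine CpG and CpH transition rates agree within 2 relative
        SE (a CpG carries a cytosine on each strand, a CpH context one)."""
        cfg = SimulationConfig(
            n_introns=150, seed=66, cpg_ts_multiplier_max=1.0, cpg_tv_multiplier=1.0,
            rate_heterogeneity_sigma=0.0, gc_effect=0.0,
        )
        b = simulate_study(cfg)
        kept, _ = filter_introns(b.alignments)
        df, _ = compute_rates(kept, fit_exchangeabilities=False)
        p_cpg = df.n_cpg_ts.sum() / (2.0 * df.n_cpg_sites.sum())
        p_cph = df.n_cph_ts.sum() / df.n_cph_sites.sum()
        se = np.sqrt(p_cpg / (2.0 * df.n_cpg_sites.sum()) + p_cph / df.n_cph_sites.sum())
        assert abs(p_cpg - p_cph) < 2.0 * se
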