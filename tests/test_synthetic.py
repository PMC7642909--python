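"""Tests for the synthetic community generator."""

import numpy as np
import pandas as pd
import pytest

from mlivirome import diversity as dv
from mlivirome import synthetic as syn
from mlivirome import triage as tr


def small_config(**kw):
    base = dict(
        n_subjects=3,
        n_viral_contigs=40,
        n_bacterial_contigs=15,
        reads_per_sample=5000,
        seed=11,
    )
    base.update(kw)
    return syn.CommunityConfig(**base)


class TestGenerateCommunity:
    def test_determinism(self):
        cfg = small_config()
        out1 = syn.generate_community(cfg)
        out2 = syn.generate_community(cfg)
        pd.testing.assert_frame_equal(out1[0], out2[0])
        pd.testing.assert_frame_equal(out1[1], out2[1])
        assert out1[0].to_csv() == out2[0].to_csv()

    def test_zero_effects_give_identical_profiles(self):
        cfg = small_config(subject_effect=0.0, site_effect=0.0)
        _, abund, _ = syn.generate_community(cfg)
        first = abund.iloc[:, 0]
        for col in abund.columns[1:]:
            np.testing.assert_allclose(abund[col], first)

    def test_within_subject_more_similar_than_between(self):
        """Planted structure: mean within-subject Bray-Curtis < between, 20 seeds."""
        within, between = [], []
        for seed in range(20):
            cfg = syn.CommunityConfig(
                n_subjects=5, n_viral_contigs=60, n_bacterial_contigs=1, seed=seed
            )
            _, abund, _ = syn.generate_community(cfg)
            dm = dv.bray_curtis_matrix(abund)
            subj = [c.split("-")[0] for c in abund.columns]
            n = len(subj)
            for i in range(n):
                for j in range(i + 1, n):
                    (within if subj[i] == subj[j] else between).append(dm[i, j])
        assert np.mean(within) < np.mean(between)

    def test_rejects_invalid_config(self):
        with pytest.raises(ValueError):
            syn.CommunityConfig(n_viral_contigs=0)
        with pytest.raises(ValueError):
            syn.CommunityConfig(subject_effect=1.5)
        with pytest.raises(ValueError):
            syn.CommunityConfig(sites=())


class TestReadCounts:
    def test_single_contig_gets_all_reads(self):
        abund = pd.DataFrame({"s1": [2.0]}, index=["c1"])
        counts = syn.simulate_read_counts(abund, pd.Series({"c1": 1000}), 500, 0)
        assert counts.loc["c1", "s1"] == 500

    def test_multinomial_expectation_weighted_by_length(self):
        """Equal abundance, lengths 1000/2000: expected counts 1e6 and 2e6."""
        abund = pd.DataFrame({"s1": [1.0, 1.0]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000, "b": 2000})
        counts = syn.simulate_read_counts(abund, lengths, 3_000_000, 123)
        sd = np.sqrt(3e6 * (1 / 3) * (2 / 3))
        assert abs(counts.loc["a", "s1"] - 1e6) < 3 * sd
        assert abs(counts.loc["b", "s1"] - 2e6) < 3 * sd
        assert counts["s1"].sum() == 3_000_000

    def test_zero_reads_gives_zero_matrix(self):
        abund = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"])
        counts = syn.simulate_read_counts(abund, pd.Series({"a": 100, "b": 100}), 0, 0)
        assert (counts == 0).all().all()

    def test_column_sums_conserved(self):
        cfg = small_config()
        contigs, abund, _ = syn.generate_community(cfg)
        counts = syn.simulate_read_counts(abund, contigs["length_bp"], 5000, 3)
        assert (counts.sum(axis=0) == 5000).all()

    def test_all_zero_sample_rejected(self):
        abund = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            syn.simulate_read_counts(abund, pd.Series({"a": 100, "b": 100}), 10, 0)


class TestDepthProfile:
    def test_zero_reads(self):
        assert syn.simulate_depth_profile(0, 1000, 200, 0) == 0

    def test_single_read_covers_exactly_read_length(self):
        assert syn.simulate_depth_profile(1, 1000, 200, 0) == 200

    def test_read_longer_than_contig_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_depth_profile(1, 100, 200, 0)

    @pytest.mark.parametrize("n_reads", [50, 100, 500])  # c = 0.5, 1, 5
    def test_lander_waterman_expectation(self, n_reads):
        """Mean breadth matches 1 - exp(-c) within Monte-Carlo error."""
        L, rl = 5000, 50
        c = n_reads * rl / L
        breadths = [
            syn.simulate_depth_profile(n_reads, L, rl, seed) / L for seed in range(200)
        ]
        assert abs(np.mean(breadths) - (1 - np.exp(-c))) < 0.02


class TestEvidence:
    def test_noiseless_evidence_gives_perfect_triage(self):
        cfg = small_config()
        contigs, _, truth = syn.generate_community(cfg)
        ev = syn.simulate_evidence(contigs, syn.EvidenceErrorRates(), seed=5)
        breadth = pd.Series(1.0, index=ev.index)  # saturating coverage
        dec = tr.triage_contigs(ev, breadth)
        retained = set(dec.index[dec["retained"]])
        assert retained == set(truth.viral_ids())

    def test_total_inclusion_failure_leaves_only_long_unknowns(self):
        cfg = small_config()
        contigs, _, _ = syn.generate_community(cfg)
        ev = syn.simulate_evidence(
            contigs, syn.EvidenceErrorRates(fn_inclusion=1.0), seed=5
        )
        dec = tr.triage_contigs(ev, pd.Series(1.0, index=ev.index))
        kept = dec[dec["retained"]]
        assert (kept["inclusion_rules_fired"] == "LONG_UNKNOWN").all()

    def test_ribosomal_false_positive_rate(self):
        """fp_ribosomal=0.05 on 1000 viral contigs: ~50 wrongly excluded."""
        cfg = syn.CommunityConfig(
            n_viral_contigs=1000, n_bacterial_contigs=1, seed=2
        )
        contigs, _, truth = syn.generate_community(cfg)
        ev = syn.simulate_evidence(
            contigs, syn.EvidenceErrorRates(fp_ribosomal=0.05), seed=9
        )
        n_excluded = int((ev.loc[truth.viral_ids(), "n_ribosomal_orfs"] >= 3).sum())
        sd = np.sqrt(1000 * 0.05 * 0.95)
        assert abs(n_excluded - 50) < 3 * sd

    def test_invariants_hold(self):
        cfg = small_config()
        contigs, _, _ = syn.generate_community(cfg)
        ev = syn.simulate_evidence(contigs, syn.EvidenceErrorRates(0.1, 0.1, 0.1, 0.1), 1)
        assert (ev["n_pvog_orfs"] <= ev["n_orfs"]).all()
        assert (ev["n_ribosomal_orfs"] <= ev["n_orfs"]).all()
        assert (ev["viral_db_min_evalue"].dropna() > 0).all()


def test_fasta_export_matches_contig_table(tmp_path):
    contigs, _, _ = syn.generate_community(small_config(n_viral_contigs=5, n_bacterial_contigs=2))
    path = tmp_path / "contigs.fasta"
    n = syn.write_contig_fasta(contigs, path, seed=1)
    assert n == 7
    from Bio import SeqIO

    records = {r.id: r for r in SeqIO.parse(str(path), "fasta")}
    assert set(records) == set(contigs.index)
    for cid, row in contigs.iterrows():
        assert len(records[cid].seq) == row["length_bp"]


class TestSpikeSimulation:
    def test_symmetric_fraction(self):
        f = syn.expected_spike_fraction(1e6, 40_000, 1e6, 40_000)
        assert f == 0.5

    def test_mass_fraction_formula(self):
        f = syn.expected_spike_fraction(1e6, 40_000, 1e9, 40_000)
        assert np.isclose(f, 1e6 / (1e6 + 1e9))  # ~9.99e-4

    def test_binomial_sampling_near_expectation(self):
        f = 1e-3
        load = 40_000 * (1 - f) / f  # parameters chosen so E[f] = 1e-3 exactly
        spikes = [
            syn.simulate_spike(1.0, 40_000, load / 40_000, 40_000, 10**6, s)[0]
            for s in range(50)
        ]
        se = np.sqrt(10**6 * f * (1 - f))
        assert abs(np.mean(spikes) - 1000) < 3 * se / np.sqrt(50)


class TestHostPairs:
    def test_perfect_correlation(self):
        from mlivirome.hostcorr import pair_correlations

        vc, host, pm = syn.simulate_host_pairs(10, 8, 1.0, seed=0)
        res = pair_correlations(vc, host, pd.Series(pm))
        np.testing.assert_allclose(res.rhos, 1.0)

    def test_null_mean_near_zero(self):
        from mlivirome.hostcorr import pair_correlations

        vc, host, pm = syn.simulate_host_pairs(500, 7, 0.0, seed=1)
        rhos = pair_correlations(vc, host, pd.Series(pm)).rhos
        se = np.std(rhos) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * se + 1e-12

    def test_planted_rho_recovered(self):
        from mlivirome.hostcorr import pair_correlations

        means = []
        for seed in range(20):
            vc, host, pm = syn.simulate_host_pairs(50, 7, 0.8, seed=seed)
            means.append(pair_correlations(vc, host, pd.Series(pm)).rhos.mean())
        assert 0.5 <= np.mean(means) <= 0.95

    def test_input_validation(self):
        with pytest.raises(ValueError):
            syn.simulate_host_pairs(5, 2, 0.5, 0)
        with pytest.raises(ValueError):
            syn.simulate_host_pairs(5, 7, 1.5, 0)
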