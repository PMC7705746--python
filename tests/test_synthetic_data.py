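"""Simulator correctness: determinism, rate structure, planted truth."""

import math

import numpy as np
import pytest

from wgdkit.codon_model import STANDARD_CODE, kimura_distance
from wgdkit.synthetic_data import (
    SimulationConfig,
    evolve_sequence_pair,
    expected_4dtv,
    random_cds,
    simulate_allopolyploid,
    simulate_anchor_genome,
    simulate_ltr_elements,
    simulate_scaffold_set,
    simulate_wgd_pairs,
    time_for_expected_4dtv,
)

TS_PAIRS = {frozenset("AG"), frozenset("CT")}


class TestEvolveSequencePair:
    def test_time_zero_is_identity(self, rng):
        anc = random_cds(100, rng)
        d1, d2 = evolve_sequence_pair(anc, 0.0, 1e-9, 1e-9, seed=4)
        assert d1 == anc and d2 == anc

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence_pair("ACGX", 1e6, 1e-9, 1e-9)

    def test_deterministic_given_seed(self, rng):
        anc = random_cds(200, rng)
        assert evolve_sequence_pair(anc, 5e6, 4e-9, 2e-9, seed=9) == \
            evolve_sequence_pair(anc, 5e6, 4e-9, 2e-9, seed=9)

    def test_equal_rates_give_1_to_2_ts_tv_ratio(self, rng):
        # alpha = beta: each site has one transition target but two
        # transversion targets, so observed changes split 1:2
        anc = "".join(rng.choice(list("ACGT"), size=200_000))
        rate = 1e-9
        d1, d2 = evolve_sequence_pair(anc, 2e7, rate, rate, seed=5)
        ts = tv = 0
        for x, y in zip(d1, d2):
            if x != y:
                if frozenset((x, y)) in TS_PAIRS:
                    ts += 1
                else:
                    tv += 1
        assert tv / ts == pytest.approx(2.0, rel=0.05)

    def test_mean_k2p_matches_planted_branch_length(self, rng):
        # d estimates 2 * mu * t with mu = alpha + 2 beta
        anc = "".join(rng.choice(list("ACGT"), size=100_000))
        alpha, beta, t = 2e-9, 1e-9, 5e6
        d1, d2 = evolve_sequence_pair(anc, t, alpha, beta, seed=6)
        d = kimura_distance(d1, d2).d
        planted = 2 * (alpha + 2 * beta) * t
        se = math.sqrt(planted / 100_000)
        assert abs(d - planted) < 3 * se


class TestWgdPairs:
    def test_planted_time_inverts_expected_4dtv(self):
        beta = 0.22e-9
        for v in (0.01, 0.08, 0.48):
            t = time_for_expected_4dtv(v, beta)
            assert expected_4dtv(beta, 2 * t) == pytest.approx(v)

    def test_truth_table_matches_cohorts(self):
        config = SimulationConfig(seed=2, expected_peaks=(0.05, 0.2),
                                  n_pairs=40, seq_len=300)
        pairs, truth = simulate_wgd_pairs(config)
        assert len(pairs) == 40 and len(truth) == 40
        assert set(truth.cohort.unique()) <= {0, 1}
        assert set(truth.expected_4dtv.unique()) <= {0.05, 0.2}
        assert all(len(p.seq_a) == 300 for p in pairs)

    def test_ancestors_are_sense_codons(self, rng):
        cds = random_cds(500, rng)
        stops = STANDARD_CODE.stop_codons
        assert all(cds[i:i + 3] not in stops for i in range(0, 1500, 3))

    def test_zero_pairs(self):
        pairs, truth = simulate_wgd_pairs(
            SimulationConfig(seed=1, n_pairs=0, seq_len=30))
        assert pairs == [] and truth.empty

    def test_bit_reproducible(self):
        config = SimulationConfig(seed=7, expected_peaks=(0.1,), n_pairs=5,
                                  seq_len=90)
        a, _ = simulate_wgd_pairs(config)
        b, _ = simulate_wgd_pairs(config)
        assert [(p.seq_a, p.seq_b) for p in a] == [(p.seq_a, p.seq_b) for p in b]


class TestLtrElements:
    def test_age_zero_identical_copies(self):
        elements, _ = simulate_ltr_elements([0.0], n_per_age=3, ltr_len=200, seed=3)
        assert all(e.ltr5_seq == e.ltr3_seq for e in elements)

    def test_small_elements_have_wide_scatter(self):
        # variance of the per-element distance scales as 1/length
        from wgdkit.chronology import ltr_insertion_age

        short, _ = simulate_ltr_elements([4.0], n_per_age=60, ltr_len=100, seed=8)
        long, _ = simulate_ltr_elements([4.0], n_per_age=60, ltr_len=4000, seed=8)
        sd_short = np.std([ltr_insertion_age(e).age_my for e in short])
        sd_long = np.std([ltr_insertion_age(e).age_my for e in long])
        assert sd_short > 3 * sd_long

    def test_truth_rows_per_element(self):
        elements, truth = simulate_ltr_elements([1.0, 2.0], n_per_age=4,
                                                ltr_len=100, seed=1)
        assert len(elements) == len(truth) == 8
        assert sorted(truth.age_my.unique()) == [1.0, 2.0]


class TestAllopolyploid:
    def test_planted_labels_recovered(self):
        from wgdkit.subgenome import identity_profile, partition_subgenomes

        table, truth = simulate_allopolyploid(92, 85, 19, seed=5)
        part = partition_subgenomes(identity_profile(table))
        planted = dict(zip(truth.chrom, truth.subgenome))
        assert part.assignment == planted

    def test_equal_levels_flagged_unseparable(self):
        _, truth = simulate_allopolyploid(90, 90, 3, seed=5)
        assert not truth.separable.any()

    def test_toy_two_chromosome_set(self):
        table, truth = simulate_allopolyploid(n_chrom_per_subgenome=1, seed=2)
        assert table.chrom.nunique() == 2 and len(truth) == 2

    def test_identities_in_range(self):
        table, _ = simulate_allopolyploid(seed=11)
        assert table.identity_pct.between(0, 100).all()


class TestScaffoldSet:
    def test_planted_lengths_give_known_n50(self):
        from wgdkit.seqio_stats import assembly_summary

        records, truth = simulate_scaffold_set(lengths=[4000, 3000, 2000, 1000],
                                               seed=1)
        summary = assembly_summary(records, min_len_bp=1)
        assert summary.n50_bp == 3000
        assert summary.total_length_bp == truth["total_length_bp"] == 10000

    def test_zero_gap_rate_means_no_ns(self):
        records, truth = simulate_scaffold_set(lengths=[500, 500], gap_rate=0.0,
                                               seed=2)
        assert truth["gap_length_bp"] == 0
        assert all("N" not in r.residues for r in records)

    def test_gap_truth_matches_sequences(self):
        records, truth = simulate_scaffold_set(lengths=[20000], gap_rate=0.01,
                                               seed=3)
        assert truth["gap_length_bp"] == sum(r.residues.count("N") for r in records)
        assert truth["gap_length_bp"] > 0

    def test_seeded_runs_byte_identical(self):
        a, _ = simulate_scaffold_set(n=5, seed=9)
        b, _ = simulate_scaffold_set(n=5, seed=9)
        assert [r.residues for r in a] == [r.residues for r in b]


class TestAnchorGenome:
    def test_truth_pairs_present_in_anchor_set(self):
        anchors_by_pair, truth = simulate_anchor_genome(seed=4)
        all_pairs = {
            (a.gene_a, a.gene_b)
            for anchors in anchors_by_pair.values() for a in anchors
        }
        assert truth <= all_pairs

    def test_reproducible(self):
        a = simulate_anchor_genome(seed=6)
        b = simulate_anchor_genome(seed=6)
        assert a[1] == b[1]
        assert list(a[0]) == list(b[0])
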