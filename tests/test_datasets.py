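"""Label derivation, identity clustering, representative rule and splitting."""

import numpy as np
import pytest

from conftest import make_window, random_window
from psadpr import (
    balance_dataset, cluster_peptides, derive_labels, peptide_identity,
    select_representatives, split_dataset,
)


class TestDeriveLabels:
    def test_set_algebra(self):
        out = derive_labels(
            pS_sites={("P1", 10), ("P1", 20)},
            SADPr_sites={("P1", 10), ("P2", 5)},
            UM_sites=set(),
        )
        assert out["pSADPr"] == {("P1", 10)}
        assert out["pS"] == {("P1", 20)}
        assert out["SADPr"] == {("P2", 5)}

    def test_disjoint_catalogs_give_empty_crosstalk(self):
        out = derive_labels({("P1", 1)}, {("P2", 2)}, set())
        assert out["pSADPr"] == set()

    def test_um_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            derive_labels({("P1", 10)}, set(), {("P1", 10)})


class TestPeptideIdentity:
    def test_identical(self):
        w = make_window()
        assert peptide_identity(w, w) == 1.0

    def test_sixteen_mismatches(self):
        a = "A" * 41
        b = "C" * 16 + "A" * 25
        assert peptide_identity(a, b) == pytest.approx(25 / 41)

    def test_completely_different(self):
        assert peptide_identity("A" * 41, "C" * 41) == 0.0

    def test_symmetric(self, rng):
        a, b = random_window(rng), random_window(rng)
        assert peptide_identity(a, b) == peptide_identity(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            peptide_identity("A" * 41, "A" * 40)

    def test_pad_pairs_count_as_match_by_default(self):
        a = "_" * 20 + "S" + "A" * 20
        b = "_" * 20 + "S" + "C" * 20
        assert peptide_identity(a, b) == pytest.approx(21 / 41)
        assert peptide_identity(a, b, count_pad=False) == pytest.approx(1 / 21)


class TestClustering:
    def test_identical_windows_one_cluster(self):
        wins = [make_window() for _ in range(5)]
        clusters = cluster_peptides(wins)
        assert len(clusters) == 1 and len(clusters[0].members) == 5

    def test_all_dissimilar_all_singletons(self):
        flank_sets = ["A" * 40, "C" * 40, "D" * 40, "E" * 40]
        wins = [make_window(f) for f in flank_sets]
        clusters = cluster_peptides(wins)
        assert len(clusters) == 4

    def test_three_window_derived_case(self):
        # w1~w2 identity 25/41 (>= 0.6), w1~w3 identity 10/41 (< 0.6)
        w1 = make_window("A" * 40)
        w2 = make_window("C" * 16 + "A" * 24)  # 16 mismatches vs w1
        w3 = make_window("C" * 31 + "A" * 9)   # 31 mismatches vs w1
        clusters = cluster_peptides([w1, w2, w3])
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]
        big = next(c for c in clusters if len(c.members) == 2)
        assert {m.peptide for m in big.members} == {w1.peptide, w2.peptide}

    def test_every_window_in_exactly_one_cluster(self, rng):
        wins = [random_window(rng) for _ in range(60)]
        clusters = cluster_peptides(wins)
        members = [m.peptide for c in clusters for m in c.members]
        assert sorted(members) == sorted(w.peptide for w in wins)

    def test_matches_brute_force_greedy_oracle(self, rng):
        # Independent re-implementation: same deterministic insertion order,
        # plain python double loop over cluster founders.
        for _ in range(10):
            wins = []
            base = random_window(rng)
            for _ in range(30):
                if rng.random() < 0.5:
                    # mutate the base at a few positions -> likely joins
                    chars = list(base.peptide)
                    for pos in rng.choice(40, size=int(rng.integers(0, 20)),
                                          replace=False):
                        i = pos if pos < 20 else pos + 1
                        chars[i] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
                    wins.append(make_window("".join(chars[:20] + chars[21:])))
                else:
                    wins.append(random_window(rng))
            order = sorted(wins, key=lambda w: (w.peptide, w.label, w.source_id,
                                                w.source_position))
            oracle: list[list[str]] = []
            founders: list[str] = []
            for w in order:
                for ci, f in enumerate(founders):
                    if sum(x == y for x, y in zip(w.peptide, f)) / 41 >= 0.6:
                        oracle[ci].append(w.peptide)
                        break
                else:
                    oracle.append([w.peptide])
                    founders.append(w.peptide)
            got = [[m.peptide for m in c.members] for c in cluster_peptides(wins)]
            assert got == oracle

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_peptides([])


class TestRepresentatives:
    def test_crosstalk_member_preferred(self):
        wins = [
            make_window("A" * 40, label="pSADPr"),
            make_window("A" * 39 + "C", label="SADPr"),
            make_window("A" * 39 + "D", label="SADPr"),
        ]
        clusters = cluster_peptides(wins)
        assert len(clusters) == 1
        reps = select_representatives(clusters, seed=0)
        assert reps[0].label == "pSADPr"
        assert clusters[0].representative.label == "pSADPr"

    def test_all_negative_cluster_returns_member(self):
        wins = [make_window("A" * 40, label="SADPr"),
                make_window("A" * 39 + "C", label="SADPr")]
        reps = select_representatives(cluster_peptides(wins), seed=1)
        assert reps[0].label == "SADPr"

    def test_rule_exhaustive_over_random_configurations(self, rng):
        # 1000 random cluster configurations: a pSADPr member always wins.
        from psadpr.datasets import PeptideCluster

        n_with_pos = 0
        clusters = []
        for i in range(1000):
            members = [
                make_window("A" * 40, label=lab)
                for lab in rng.choice(["pSADPr", "pS", "SADPr", "UM"],
                                      size=int(rng.integers(1, 10)))
            ]
            clusters.append(PeptideCluster(members=members,
                                           representative=members[0]))
            n_with_pos += any(m.label == "pSADPr" for m in members)
        reps = select_representatives(clusters, seed=2)
        chosen_pos = sum(r.label == "pSADPr" for r in reps)
        assert chosen_pos == n_with_pos

    def test_same_seed_same_representatives(self, rng):
        wins = [random_window(rng, label=("pSADPr" if i % 3 else "pS"))
                for i in range(40)]
        c1 = cluster_peptides(wins)
        c2 = cluster_peptides(wins)
        r1 = select_representatives(c1, seed=9)
        r2 = select_representatives(c2, seed=9)
        assert [w.peptide for w in r1] == [w.peptide for w in r2]


class TestSplit:
    def test_exact_divisibility(self, rng):
        wins = [random_window(rng, label="pSADPr") for _ in range(11)] + \
               [random_window(rng, label="UM") for _ in range(11)]
        plan = split_dataset(wins, seed=0)
        for g in plan.groups:
            labs = [wins[i].label for i in g]
            assert len(g) == 2 and sorted(labs) == ["UM", "pSADPr"]

    def test_determinism(self, rng):
        wins = [random_window(rng, label=("pSADPr" if i % 2 else "UM"))
                for i in range(50)]
        p1 = split_dataset(wins, seed=3)
        p2 = split_dataset(wins, seed=3)
        assert all(np.array_equal(a, b) for a, b in zip(p1.groups, p2.groups))

    def test_stratum_sizes_for_2378_positives(self):
        wins = [make_window(label="pSADPr") for _ in range(2378)]
        plan = split_dataset(wins, seed=1)
        sizes = sorted(len(g) for g in plan.groups)
        assert set(sizes) == {216, 217}
        assert sum(sizes) == 2378

    def test_partition_disjoint_and_exhaustive(self, rng):
        wins = [random_window(rng, label=("pSADPr" if i % 2 else "UM"))
                for i in range(97)]
        plan = split_dataset(wins, seed=5)
        all_idx = np.concatenate(plan.groups)
        assert sorted(all_idx) == list(range(97))
        assert plan.test_group_id not in plan.cv_group_ids

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="need"):
            split_dataset([make_window(label="pSADPr")] * 5, seed=0)


class TestBalance:
    def test_subsample_to_parity(self, rng):
        pos = [random_window(rng, "pSADPr") for _ in range(5)]
        neg = [random_window(rng, "UM") for _ in range(20)]
        out = balance_dataset(pos, neg, seed=0)
        labs = [w.label for w in out]
        assert len(out) == 10 and labs.count("pSADPr") == 5

    def test_equal_sizes_identity(self, rng):
        pos = [random_window(rng, "pSADPr") for _ in range(5)]
        neg = [random_window(rng, "UM") for _ in range(5)]
        assert len(balance_dataset(pos, neg, seed=0)) == 10

    def test_insufficient_negatives_rejected(self, rng):
        pos = [random_window(rng, "pSADPr") for _ in range(5)]
        neg = [random_window(rng, "UM") for _ in range(3)]
        with pytest.raises(ValueError):
            balance_dataset(pos, neg, seed=0)
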