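import numpy as np
import pytest

from phistruct import (
    Cluster,
    ProteinRecord,
    build_split,
    generate_sequences,
    greedy_cluster,
    pairwise_identity,
    verify_no_leakage,
)
from phistruct.synthetic_data import GeneratorConfig

from ._oracles import dp_identity

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _rec(i, seq, genus="Escherichia"):
    return ProteinRecord(
        id=f"r{i:03d}", phage_id=f"p{i}", product="tail fiber protein",
        sequence=seq, host_genus=genus,
    )


def _random_seq(rng, n):
    return "".join(rng.choice(AA, n))


def _mutant(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([a for a in AA if a != out[i]])
    return "".join(out)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKVLA", "MKVLA") == 1.0

    def test_disjoint_residue_sets(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_symmetric(self, rng):
        for _ in range(10):
            a = _random_seq(rng, int(rng.integers(5, 40)))
            b = _random_seq(rng, int(rng.integers(5, 40)))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_against_dp_oracle(self, rng):
        # exhaustive dynamic-programming oracle, same scoring convention
        for _ in range(40):
            a = _random_seq(rng, int(rng.integers(3, 25)))
            b = _random_seq(rng, int(rng.integers(3, 25)))
            assert pairwise_identity(a, b) == pytest.approx(
                dp_identity(a, b), abs=1e-12
            )

    def test_specific_pair_frozen_value(self):
        # ACDEFG vs ACDEFA: 5 positional matches, no gaps -> 5/6
        assert pairwise_identity("ACDEFG", "ACDEFA") == pytest.approx(5 / 6)
        assert dp_identity("ACDEFG", "ACDEFA") == pytest.approx(5 / 6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MK")


class TestGreedyCluster:
    def test_all_identical_one_cluster(self):
        recs = [_rec(i, "MKVLAMKVLA") for i in range(4)]
        clusters = greedy_cluster(recs, 0.9)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == [r.id for r in recs]

    def test_all_dissimilar_singletons(self, rng):
        recs = [_rec(i, _random_seq(rng, 60)) for i in range(6)]
        clusters = greedy_cluster(recs, 0.5)
        assert all(len(c.member_ids) == 1 for c in clusters)

    def test_planted_subfamilies_recovered(self, rng):
        # two 3-member subfamilies from unrelated ancestors; verify against
        # the brute-force all-pairs identity matrix
        anc1, anc2 = _random_seq(rng, 120), _random_seq(rng, 120)
        seqs = [_mutant(rng, anc1, 0.08) for _ in range(3)] + [
            _mutant(rng, anc2, 0.08) for _ in range(3)
        ]
        recs = [_rec(i, s) for i, s in enumerate(seqs)]
        s = 0.6
        matrix = {
            (a.id, b.id): pairwise_identity(a.sequence, b.sequence)
            for a in recs
            for b in recs
        }
        clusters = greedy_cluster(recs, s)
        assert len(clusters) == 2
        for cluster in clusters:
            for m in cluster.member_ids:
                assert matrix[(m, cluster.representative_id)] >= s

    def test_partition_property(self, rng):
        recs = [_rec(i, _random_seq(rng, 40)) for i in range(15)]
        clusters = greedy_cluster(recs, 0.3)
        all_members = [m for c in clusters for m in c.member_ids]
        assert sorted(all_members) == sorted(r.id for r in recs)

    def test_s_one_merges_only_exact_duplicates(self, rng):
        base = _random_seq(rng, 50)
        near = base[:-1] + ("A" if base[-1] != "A" else "C")
        recs = [_rec(0, base), _rec(1, base), _rec(2, near)]
        clusters = greedy_cluster(recs, 1.0)
        sizes = sorted(len(c.member_ids) for c in clusters)
        assert sizes == [1, 2]

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            greedy_cluster([], 0.0)


def _singleton_clusters(records, s=0.4):
    return [Cluster(r.id, [r.id], s) for r in records]


class TestBuildSplit:
    def test_seventy_thirty_per_class(self):
        recs = []
        for g in ("Escherichia", "Klebsiella"):
            recs += [_rec(len(recs) + i, "A" * (20 + i), genus=g) for i in range(10)]
        labels = {r.id: r.host_genus for r in recs}
        plan = build_split(_singleton_clusters(recs), labels, 0.4, seed=5)
        for g in ("Escherichia", "Klebsiella"):
            train_g = [i for i in plan.train_ids if labels[i] == g]
            test_g = [i for i in plan.test_ids if labels[i] == g]
            assert (len(train_g), len(test_g)) == (7, 3)

    def test_outgroup_size_matches_smallest_test_class(self):
        recs = []
        recs += [_rec(i, "A" * (20 + i), genus="Escherichia") for i in range(10)]
        recs += [_rec(100 + i, "C" * (20 + i), genus="Klebsiella") for i in range(4)]
        labels = {r.id: r.host_genus for r in recs}
        pool = [f"og{i}" for i in range(50)]
        plan = build_split(
            _singleton_clusters(recs), labels, 0.4, outgroup_pool=pool, seed=2
        )
        test_counts = {}
        for i in plan.test_ids:
            if i not in plan.outgroup_ids:
                test_counts[labels[i]] = test_counts.get(labels[i], 0) + 1
        assert len(plan.outgroup_ids) == min(test_counts.values())
        assert set(plan.outgroup_ids) <= set(pool)

    def test_single_cluster_degenerate(self):
        recs = [_rec(i, "MKVLA") for i in range(5)]
        labels = {r.id: "Escherichia" for r in recs}
        cluster = Cluster(recs[0].id, [r.id for r in recs], 0.4)
        plan = build_split([cluster], labels, 0.4, seed=1)
        assert plan.test_ids == []
        assert plan.warnings

    def test_members_follow_representative(self):
        recs = [_rec(i, "A" * 30, genus="Escherichia") for i in range(12)]
        labels = {r.id: "Escherichia" for r in recs}
        clusters = [
            Cluster(recs[i].id, [recs[i].id, recs[i + 6].id], 0.4) for i in range(6)
        ]
        plan = build_split(clusters, labels, 0.4, seed=3)
        for cluster in clusters:
            sides = {
                ("train" if m in plan.train_ids else "test")
                for m in cluster.member_ids
            }
            assert len(sides) == 1

    def test_bit_reproducible(self):
        recs = [
            _rec(i, "A" * (20 + i), genus=("Escherichia" if i % 2 else "Klebsiella"))
            for i in range(20)
        ]
        labels = {r.id: r.host_genus for r in recs}
        p1 = build_split(_singleton_clusters(recs), labels, 0.4, seed=9,
                         outgroup_pool=[f"og{i}" for i in range(9)])
        p2 = build_split(_singleton_clusters(recs), labels, 0.4, seed=9,
                         outgroup_pool=[f"og{i}" for i in range(9)])
        assert p1.train_ids == p2.train_ids
        assert p1.test_ids == p2.test_ids
        assert p1.outgroup_ids == p2.outgroup_ids


class TestVerifyNoLeakage:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_generated_families_pass(self, seed):
        config = GeneratorConfig(
            n_per_genus=5, n_outgroup=4, families_per_genus=2,
            length_median=150, length_spread=15, seed=seed,
        )
        records = generate_sequences(config)
        in_scope = [r for r in records if r.host_genus != "OUTGROUP"]
        labels = {r.id: r.host_genus for r in records}
        pool = [r.id for r in records if r.host_genus == "OUTGROUP"]
        for s in (0.6, 0.8):
            clusters = greedy_cluster(in_scope, s)
            plan = build_split(clusters, labels, s, outgroup_pool=pool, seed=seed)
            ok, violations = verify_no_leakage(plan, records, s)
            assert ok, violations

    def test_deliberate_violation_detected(self, rng):
        anc = _random_seq(rng, 100)
        seqs = [_mutant(rng, anc, 0.05) for _ in range(4)]
        seqs += [_random_seq(rng, 100) for _ in range(4)]
        recs = [_rec(i, s) for i, s in enumerate(seqs)]
        from phistruct import SplitPlan

        # put one family member on each side: guaranteed identity >= s
        plan = SplitPlan(
            s=0.6,
            train_ids=[recs[0].id] + [r.id for r in recs[4:6]],
            test_ids=[recs[1].id] + [r.id for r in recs[6:]],
            outgroup_ids=[],
            seed=0,
        )
        ok, violations = verify_no_leakage(plan, recs, 0.6)
        assert not ok
        assert any({v[0], v[1]} == {recs[0].id, recs[1].id} for v in violations)

    def test_empty_test_vacuously_true(self):
        from phistruct import SplitPlan

        recs = [_rec(0, "MKVLA")]
        plan = SplitPlan(s=0.4, train_ids=["r000"], test_ids=[], outgroup_ids=[], seed=0)
        ok, violations = verify_no_leakage(plan, recs, 0.4)
        assert ok and violations == []
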