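"""Clustering steps: hashing, fragments, greedy, set cover, cascade,
updates."""

import numpy as np
import pytest

import oracles
from conftest import random_protein
from miniclust import align as _align
from miniclust import cluster, synth
from miniclust.cluster import (
    PARAMS_30,
    PARAMS_50,
    PARAMS_90,
    cascade,
    greedy_incremental_cluster,
    greedy_set_cover,
    hash_cluster,
    merge_fragments,
    meets_fragment_rule,
    meets_thresholds,
    reassign_members,
    set_cover_cluster,
    update_clustering,
)
from miniclust.core_io import ProteinSequence, validate_partition


def seq(acc, residues):
    return ProteinSequence(accession=acc, residues=residues)


def partition_sets(clusters):
    return {frozenset(c.members) for c in clusters}


class TestHashCluster:
    def test_byte_identical_sequences_merge(self):
        s = "ACDEFGHIKLMNPQRSTVWY" * 3
        out = hash_cluster([seq("A", s), seq("B", s)])
        assert partition_sets(out) == {frozenset({"A", "B"})}

    def test_reduced_identical_but_below_identity_threshold(self):
        # I and L share a reduced-alphabet class, so both sequences hash
        # together, but full-alphabet identity is 0.85 < 0.9
        base = list("ACDEFGHIKLMNPQRSTVWY")
        other = base.copy()
        # I, L, M (positions 7, 9, 10) all belong to the hydrophobic class
        other[7], other[9], other[10] = "L", "I", "V"
        a, b = "".join(base), "".join(other)
        from miniclust.align import reduce_alphabet

        assert reduce_alphabet(a) == reduce_alphabet(b)
        assert sum(x == y for x, y in zip(a, b)) / len(a) < 0.9
        out = hash_cluster([seq("A", a), seq("B", b)])
        assert len(out) == 2

    def test_different_lengths_never_merge(self):
        s = random_protein(np.random.default_rng(0), 100)
        out = hash_cluster([seq("A", s), seq("B", s + "A")])
        assert len(out) == 2


class TestMergeFragments:
    def test_exact_prefix_fragment_absorbed(self, matrix):
        rng = np.random.default_rng(2)
        full = random_protein(rng, 100)
        clusters = hash_cluster([seq("FULL", full), seq("FRAG", full[:50])])
        assert len(clusters) == 2
        merged = merge_fragments(clusters, [seq("FULL", full), seq("FRAG", full[:50])],
                                 PARAMS_90, matrix)
        assert partition_sets(merged) == {frozenset({"FULL", "FRAG"})}
        assert merged[0].representative == "FULL"

    def test_insufficient_self_coverage_not_absorbed(self, matrix):
        # fragment whose alignable part is only ~90% of its own length
        rng = np.random.default_rng(3)
        full = random_protein(rng, 100)
        frag = full[:45] + random_protein(rng, 5)  # 5 trailing residues alien
        seqs = [seq("FULL", full), seq("FRAG", frag)]
        r = _align.align_pair(seqs[1], seqs[0], matrix)
        assert r.q_cov < 0.95
        clusters = hash_cluster(seqs)
        merged = merge_fragments(clusters, seqs, PARAMS_90, matrix)
        assert len(merged) == 2

    def test_no_eligible_pairs_identity(self, matrix):
        rng = np.random.default_rng(4)
        seqs = [seq("A", random_protein(rng, 80)), seq("B", random_protein(rng, 90))]
        clusters = hash_cluster(seqs)
        merged = merge_fragments(clusters, seqs, PARAMS_90, matrix)
        assert partition_sets(merged) == partition_sets(clusters)


class TestGreedyIncremental:
    def test_identical_pair_plus_unrelated(self, matrix):
        rng = np.random.default_rng(5)
        s = random_protein(rng, 100)
        other = random_protein(rng, 100)
        out = greedy_incremental_cluster(
            [seq("A", s), seq("B", s), seq("C", other)], PARAMS_90, matrix
        )
        assert partition_sets(out) == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_single_sequence_singleton(self, matrix):
        out = greedy_incremental_cluster([seq("A", "ACDEFGHIKL")], PARAMS_90, matrix)
        assert len(out) == 1
        assert out[0].representative == "A"

    def test_input_order_invariance(self, matrix):
        rng = np.random.default_rng(6)
        spec = synth.FamilySpec(n_families=2, members_per_family=4, seq_len=80,
                                within_identity=0.95, fragment_prob=0.0, seed=9)
        seqs, _ = synth.generate_families(spec)
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        a = greedy_incremental_cluster(seqs, PARAMS_90, matrix)
        b = greedy_incremental_cluster(shuffled, PARAMS_90, matrix)
        assert partition_sets(a) == partition_sets(b)
        assert [c.representative for c in a] == [c.representative for c in b]

    def test_representative_is_longest_member(self, matrix):
        spec = synth.FamilySpec(n_families=2, members_per_family=5, seq_len=100,
                                within_identity=0.95, fragment_prob=0.4, seed=1)
        seqs, _ = synth.generate_families(spec)
        index = {s.accession: s for s in seqs}
        out = greedy_incremental_cluster(seqs, PARAMS_90, matrix)
        for c in out:
            rep_len = len(index[c.representative].residues)
            assert all(len(index[m].residues) <= rep_len for m in c.members)


class TestSetCover:
    def test_explicit_graph_example(self):
        adjacency = {
            "1": {"2", "3"}, "2": {"1"}, "3": {"1"}, "4": {"5"}, "5": {"4"},
        }
        out = greedy_set_cover(adjacency)
        assert partition_sets(out) == {frozenset({"1", "2", "3"}),
                                       frozenset({"4", "5"})}
        reps = {c.representative for c in out}
        assert reps == {"1", "4"}

    def test_edgeless_graph_all_singletons(self):
        adjacency = {str(i): set() for i in range(7)}
        out = greedy_set_cover(adjacency)
        assert len(out) == 7

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            nodes = [f"v{i:02d}" for i in range(n)]
            adjacency = {v: set() for v in nodes}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.3:
                        adjacency[nodes[i]].add(nodes[j])
                        adjacency[nodes[j]].add(nodes[i])
            lengths = {v: int(rng.integers(10, 100)) for v in nodes}
            ours = sorted(
                (c.representative, frozenset(c.members))
                for c in greedy_set_cover(adjacency, lengths)
            )
            assert ours == oracles.greedy_cover(adjacency, lengths)

    def test_sequences_end_to_end(self, matrix):
        spec = synth.FamilySpec(n_families=3, members_per_family=3, seq_len=120,
                                within_identity=0.9, fragment_prob=0.0, seed=3)
        seqs, part = synth.generate_families(spec)
        out = set_cover_cluster(seqs, PARAMS_50, matrix)
        got = {frozenset(c.members) for c in out}
        want = {
            frozenset(a for a, f in part.items() if f == i) for i in range(3)
        }
        assert got == want


class TestReassignment:
    def test_member_moves_to_higher_scoring_representative(self, matrix):
        rng = np.random.default_rng(12)
        rep_a = random_protein(rng, 100)
        rep_b = synth.mutate_sequence(rep_a, 0.6, rng)
        # member much closer to B than to A but initially assigned to A
        member = synth.mutate_sequence(rep_b, 0.98, rng)
        seqs = [seq("A", rep_a), seq("B", rep_b), seq("M", member)]
        from miniclust.core_io import ClusterRecord

        clustering = [
            ClusterRecord(representative="A", members=["A", "M"]),
            ClusterRecord(representative="B", members=["B"]),
        ]
        out = reassign_members(clustering, seqs, PARAMS_30, matrix)
        assert partition_sets(out) == {frozenset({"A"}), frozenset({"B", "M"})}

    def test_post_state_optimality(self, matrix):
        spec = synth.FamilySpec(n_families=3, members_per_family=4, seq_len=100,
                                within_identity=0.85, fragment_prob=0.0, seed=21)
        seqs, _ = synth.generate_families(spec)
        index = {s.accession: s for s in seqs}
        out = set_cover_cluster(seqs, PARAMS_30, matrix)
        reps = [index[c.representative] for c in out]
        for c in out:
            for m in c.members:
                if m == c.representative:
                    continue
                own = _align.align_pair(index[m], index[c.representative], matrix)
                for r in reps:
                    other = _align.align_pair(index[m], r, matrix)
                    if meets_thresholds(other, PARAMS_30):
                        assert own.score_per_res >= other.score_per_res - 1e-9


class TestCascade:
    def test_three_families_three_clusters_at_every_level(
        self, canonical_families, matrix
    ):
        seqs, part = canonical_families
        u90, u50, u30 = cascade(seqs, matrix=matrix)
        want = {
            frozenset(a for a, f in part.items() if f == i) for i in range(3)
        }
        assert partition_sets(u90) == want
        assert partition_sets(u50) == want
        assert partition_sets(u30) == want

    def test_single_sequence_singleton_at_every_level(self, matrix):
        s = [seq("A", "ACDEFGHIKLMNPQRSTVWY")]
        u90, u50, u30 = cascade(s, matrix=matrix)
        for level in (u90, u50, u30):
            assert len(level) == 1
            assert level[0].members == ["A"]

    def test_coarse_clusters_are_unions_of_fine_clusters(self, matrix):
        seqs, _, _ = synth.generate_hierarchical_families(
            n_superfamilies=2, subfamilies_per=2, members_per_family=3, seed=5
        )
        u90, u50, u30 = cascade(seqs, matrix=matrix)
        fine = partition_sets(u90)
        for coarse in (u50, u30):
            for c in coarse:
                mem = set(c.members)
                covered = [f for f in fine if f <= mem]
                assert set().union(*covered) == mem

    def test_cluster_id_format(self, canonical_families, matrix):
        seqs, _ = canonical_families
        u90, u50, u30 = cascade(seqs, release="2507", matrix=matrix)
        assert [c.cluster_id for c in u90] == [
            f"uc90-2507-{i}" for i in range(1, len(u90) + 1)
        ]
        assert u50[0].cluster_id.startswith("uc50-2507-")


class TestThresholdSoundness:
    def test_every_member_satisfies_level_or_fragment_rule(
        self, canonical_families, matrix
    ):
        seqs, _ = canonical_families
        index = {s.accession: s for s in seqs}
        u90, u50, u30 = cascade(seqs, matrix=matrix)
        for clusters, params in ((u90, PARAMS_90), (u50, PARAMS_50), (u30, PARAMS_30)):
            for c in clusters:
                rep = index[c.representative]
                for m in c.members:
                    if m == c.representative:
                        continue
                    r = _align.align_pair(index[m], rep, matrix)
                    assert meets_thresholds(r, params) or meets_fragment_rule(
                        r, params
                    ), (c.cluster_id, m)


class TestUpdate:
    def test_unchanged_input_is_fixed_point(self, canonical_families, matrix):
        seqs, _ = canonical_families
        u90, _, _ = cascade(seqs, matrix=matrix)
        updated = update_clustering(u90, seqs, seqs, PARAMS_90, matrix)
        assert [(c.cluster_id, c.representative, c.members) for c in updated] == [
            (c.cluster_id, c.representative, c.members) for c in u90
        ]

    def test_duplicate_of_representative_joins_without_new_cluster(
        self, canonical_families, matrix
    ):
        seqs, _ = canonical_families
        u90, _, _ = cascade(seqs, matrix=matrix)
        rep = next(s for s in seqs if s.accession == u90[0].representative)
        dup = ProteinSequence(accession="ZZNEW", residues=rep.residues)
        updated = update_clustering(u90, seqs, list(seqs) + [dup], PARAMS_90, matrix)
        assert len(updated) == len(u90)
        target = next(c for c in updated if c.representative == rep.accession)
        assert "ZZNEW" in target.members

    def test_comparison_count_linear_in_new_times_representatives(
        self, canonical_families, matrix
    ):
        seqs, _ = canonical_families
        u90, _, _ = cascade(seqs, matrix=matrix)
        rng = np.random.default_rng(9)
        new = [
            ProteinSequence(accession=f"N{i}", residues=random_protein(rng, 150))
            for i in range(4)
        ]
        _align.reset_alignment_counter()
        update_clustering(u90, seqs, list(seqs) + new, PARAMS_90, matrix)
        n_reps = len(u90)
        # joins cost |new| x |reps|; leftovers cluster among themselves
        bound = len(new) * n_reps + len(new) * (len(new) - 1) // 2 + len(new) ** 2
        assert _align.alignment_count() <= bound

    def test_removed_member_dropped_and_representative_promoted(
        self, canonical_families, matrix
    ):
        seqs, _ = canonical_families
        u90, _, _ = cascade(seqs, matrix=matrix)
        victim = u90[0].representative
        remaining = [s for s in seqs if s.accession != victim]
        updated = update_clustering(u90, seqs, remaining, PARAMS_90, matrix)
        changed = next(c for c in updated if c.cluster_id == u90[0].cluster_id)
        assert victim not in changed.members
        index = {s.accession: s for s in remaining}
        assert len(index[changed.representative].residues) == max(
            len(index[m].residues) for m in changed.members
        )

    def test_changed_sequence_under_existing_accession_rejected(
        self, canonical_families, matrix
    ):
        seqs, _ = canonical_families
        u90, _, _ = cascade(seqs, matrix=matrix)
        mutated = [
            ProteinSequence(accession=s.accession, residues=s.residues[::-1])
            if s.accession == seqs[0].accession
            else s
            for s in seqs
        ]
        with pytest.raises(ValueError, match="immutable"):
            update_clustering(u90, seqs, mutated, PARAMS_90, matrix)


class TestPartitionInvariant:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_every_step_outputs_a_partition(self, seed, matrix):
        spec = synth.FamilySpec(n_families=2, members_per_family=4, seq_len=90,
                                within_identity=0.9, fragment_prob=0.3, seed=seed)
        seqs, _ = synth.generate_families(spec)
        accs = [s.accession for s in seqs]
        h = hash_cluster(seqs)
        validate_partition(h, accs)
        f = merge_fragments(h, seqs, PARAMS_90, matrix)
        validate_partition(f, accs)
        g = greedy_incremental_cluster(seqs, PARAMS_90, matrix)
        validate_partition(g, accs)
        s = set_cover_cluster(seqs, PARAMS_30, matrix)
        validate_partition(s, accs)
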