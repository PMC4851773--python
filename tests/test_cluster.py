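import random

import pytest

from hitcluster.align import ThresholdPolicy
from hitcluster.blast import BlastHit
from hitcluster.cluster import (ClusteringParams, SessionState, cluster_hits,
                                cluster_pass1, cluster_pass2,
                                finalize_clusters, recluster)
from hitcluster.blast import SearchParams
from hitcluster.seqio import SequenceRecord
from hitcluster.synth import FamilySpec, derive_homolog, make_family

from oracles import oracle_two_pass, partition_key, random_mixture

AA = "ACDEFGHIKLMNPQRSTVWY"


def params(cutoff=53.0, length_diff=32):
    return ClusteringParams(ThresholdPolicy(user_cutoff_pct=cutoff),
                            length_diff_limit=length_diff)


def random_seq(rng, n):
    return "".join(rng.choice(AA) for _ in range(n))


@pytest.fixture()
def abc_family(rng):
    """A (100 aa) with a close same-length homolog B and a 60 aa fragment C
    that trips the length rule but matches well over its span."""
    a = random_seq(rng, 100)
    rec_a = SequenceRecord("A", a)
    rec_b = derive_homolog(rec_a, 92.0, rng, "B")
    frag = list(a[:60])
    for i in range(len(frag)):
        if rng.random() < 0.08:
            frag[i] = rng.choice(AA)
    rec_c = SequenceRecord("C", "".join(frag))
    return rec_a, rec_b, rec_c


class TestPass1:
    def test_length_rule_excludes_fragment(self, abc_family):
        a, b, c = abc_family
        clusters = cluster_pass1([a, b, c], params())
        parts = {frozenset(cl.accessions) for cl in clusters}
        assert parts == {frozenset({"A", "B"}), frozenset({"C"})}
        rep = next(cl for cl in clusters if len(cl) == 2)
        assert rep.representative == "A"  # longest member leads

    def test_dissimilar_sequences_stay_singletons(self, rng):
        seqs = [SequenceRecord(f"S{i}", random_seq(rng, 80)) for i in range(6)]
        clusters = cluster_pass1(seqs, params())
        assert all(len(cl) == 1 for cl in clusters)

    def test_identical_duplicates_cluster_with_accession_tiebreak(self):
        seq = "MKVLLTAIARHQWE" * 5
        a, a2 = SequenceRecord("X2", seq), SequenceRecord("X1", seq)
        clusters = cluster_pass1([a, a2], params())
        assert len(clusters) == 1
        assert clusters[0].representative == "X1"

    def test_length_diff_limit_is_strict(self, rng):
        # diff of exactly 32 must fail, 31 must pass (identical overlap)
        base = random_seq(rng, 100)
        rep = SequenceRecord("R", base)
        at_limit = SequenceRecord("S32", base[:68])
        inside = SequenceRecord("S31", base[:69])
        clusters = cluster_pass1([rep, at_limit, inside], params())
        parts = {frozenset(cl.accessions) for cl in clusters}
        assert parts == {frozenset({"R", "S31"}), frozenset({"S32"})}

    def test_rejects_duplicate_accessions(self):
        s = SequenceRecord("A", "MKVLLT")
        with pytest.raises(ValueError, match="duplicate"):
            cluster_pass1([s, SequenceRecord("A", "MKVLLT")], params())

    def test_members_carry_identity_certificates(self, abc_family):
        a, b, _ = abc_family
        clusters = cluster_pass1([a, b], params())
        member = next(m for m in clusters[0].members if m.accession == "B")
        assert member.pass_no == 1
        assert member.identity_to_rep >= 53.0


class TestPass2:
    def test_fragment_rescued_with_pass2_label(self, abc_family):
        a, b, c = abc_family
        seqs = {r.accession: r for r in abc_family}
        clusters = cluster_pass2(cluster_pass1(list(abc_family), params()),
                                 seqs, params())
        assert len(clusters) == 1
        rescued = next(m for m in clusters[0].members if m.accession == "C")
        assert rescued.pass_no == 2
        assert rescued.display_label == "2:C"

    def test_poor_singleton_stays_singleton(self, abc_family, rng):
        a, b, _ = abc_family
        stranger = SequenceRecord("Z", random_seq(rng, 40))
        seqs = {r.accession: r for r in (a, b, stranger)}
        clusters = cluster_pass2(
            cluster_pass1([a, b, stranger], params()), seqs, params())
        assert {frozenset(cl.accessions) for cl in clusters} == \
            {frozenset({"A", "B"}), frozenset({"Z"})}

    def test_all_singletons_is_a_noop(self, rng):
        seqs = [SequenceRecord(f"S{i}", random_seq(rng, 80)) for i in range(4)]
        pass1 = cluster_pass1(seqs, params())
        pass2 = cluster_pass2(pass1, {s.accession: s for s in seqs}, params())
        assert [cl.accessions for cl in pass2] == [cl.accessions for cl in pass1]

    def test_no_singletons_is_a_noop(self, rng):
        fam1 = make_family(FamilySpec(3, 90, 90.0, 0, rng_seed=1, name="f1"))
        fam2 = make_family(FamilySpec(3, 90, 90.0, 0, rng_seed=2, name="f2"))
        seqs = {s.accession: s for s in fam1 + fam2}
        pass1 = cluster_pass1(list(seqs.values()), params())
        assert all(len(cl) >= 2 for cl in pass1)
        pass2 = cluster_pass2(pass1, seqs, params())
        assert [cl.accessions for cl in pass2] == [cl.accessions for cl in pass1]


class TestFinalize:
    def hits_for(self, accessions):
        return [BlastHit("Q", acc, 80.0, 100, 1e-30, 200.0 - 10 * i,
                         1, 100, 1, 100, rank=i + 1)
                for i, acc in enumerate(accessions)]

    def test_clusters_numbered_by_best_hit_rank(self, abc_family):
        a, b, c = abc_family
        seqs = {r.accession: r for r in abc_family}
        clusters = cluster_pass1([a, b, c], params(cutoff=100.0))
        # ranks: C first, then A, then B
        final = finalize_clusters(clusters, self.hits_for(["C", "A", "B"]))
        assert [cl.cluster_index for cl in final] == [1, 2, 3]
        assert final[0].representative == "C"

    def test_members_ordered_by_rank_and_query_identity_attached(self, abc_family):
        a, b, _ = abc_family
        clusters = cluster_pass1([a, b], params())
        final = finalize_clusters(clusters, self.hits_for(["B", "A"]))
        assert final[0].accessions == ["B", "A"]
        assert all(m.identity_to_query == 80.0 for m in final[0].members)

    def test_empty_inputs(self):
        assert finalize_clusters([], []) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_two_pass_oracle(self, seed):
        """Production clusterer == naive transcription of the greedy rules
        (pass markers included) on mixed random/family/fragment inputs."""
        seqs = random_mixture(seed)
        cutoff = random.Random(seed ^ 0xBEEF).choice([20.0, 53.0, 70.0, 90.0])
        produced = cluster_pass2(
            cluster_pass1(seqs, params(cutoff)),
            {s.accession: s for s in seqs}, params(cutoff))
        expected = oracle_two_pass(seqs, cutoff, 32)
        got = [{"rep": cl.representative,
                "members": {m.accession: m.pass_no for m in cl.members}}
               for cl in produced]
        assert partition_key(got) == partition_key(expected)

    def test_partition_invariant(self, three_family_hitset):
        hs = three_family_hitset
        clusters = cluster_hits(hs.records, hs.hits)
        seen = [m.accession for cl in clusters for m in cl.members]
        assert sorted(seen) == sorted(s.accession for s in hs.records)
        assert len(seen) == len(set(seen))


class TestRecluster:
    @pytest.fixture()
    def state(self, three_family_hitset):
        hs = three_family_hitset
        return SessionState(
            query=hs.query, hits=list(hs.hits),
            hit_sequences={s.accession: s for s in hs.records},
            search_params=SearchParams(),
            clustering_params=params(),
        )

    def test_idempotent(self, state):
        first = recluster(state, params())
        second = recluster(state, params())
        assert [(c.cluster_index, c.representative,
                 [(m.accession, m.pass_no) for m in c.members])
                for c in first] == \
               [(c.cluster_index, c.representative,
                 [(m.accession, m.pass_no) for m in c.members])
                for c in second]

    def test_cutoff_100_separates_distinct_sequences(self, state):
        clusters = recluster(state, params(cutoff=100.0))
        assert len(clusters) == len(state.hit_sequences)

    def test_recovers_planted_partition_at_default_cutoff(
            self, state, three_family_hitset):
        clusters = recluster(state, params())
        got = {frozenset(cl.accessions) for cl in clusters}
        truth = {}
        for acc, fam in three_family_hitset.truth.items():
            truth.setdefault(fam, set()).add(acc)
        assert got == {frozenset(v) for v in truth.values()}

    def test_session_round_trips_through_json(self, state, tmp_path):
        path = state.save(tmp_path / "state.json")
        loaded = SessionState.load(path)
        assert loaded == state
        assert loaded.to_json() == state.to_json()

    def test_incompatible_schema_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"schema_version": 99}')
        with pytest.raises(ValueError, match="schema_version"):
            SessionState.load(p)
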