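"""MID grouping, edit-distance sub-clustering, consensus building."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midseq.models import TaggingModel, frac_needing_subclustering
from midseq.preprocess import PreparedRead, PreprocessConfig, prepare_reads
from midseq.simulate import SimConfig, simulate_reads
from midseq.subcluster import (
    ClusterParams,
    MIDGroup,
    build_consensus,
    fraction_mids_with_subclusters,
    group_by_mid,
    levenshtein,
    qt_subcluster,
    subcluster_all,
)


def read(payload, mid="A" * 12, quals=None, rid="r"):
    q = np.asarray(
        quals if quals is not None else [30] * len(payload), dtype=np.uint8
    )
    return PreparedRead(id=rid, mid=mid, payload=payload, qual=q)


def dp_levenshtein(a, b):
    """Reference dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a, b, d",
        [("ACGT", "ACGT", 0), ("ACGT", "AGT", 1), ("", "ACGT", 4), ("AAAA", "TTTT", 4)],
    )
    def test_known_distances(self, a, b, d):
        assert levenshtein(a, b) == d

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(60):
            a = "".join(rng.choice(bases, size=30))
            b = "".join(rng.choice(bases, size=int(rng.integers(25, 35))))
            assert levenshtein(a, b) == dp_levenshtein(a, b)
            assert levenshtein(a, b) == levenshtein(b, a)


class TestGroupByMid:
    def test_grouping(self):
        reads = [read("AAAA", mid=m, rid=f"r{i}") for i, m in enumerate("aab")]
        groups = group_by_mid(reads)
        assert sorted((g.mid, len(g.reads)) for g in groups.values()) == [("a", 2), ("b", 1)]

    def test_empty(self):
        assert group_by_mid([]) == {}

    def test_conservation_on_simulation(self, noisy_prepared):
        _, _, prepared = noisy_prepared
        groups = group_by_mid(prepared)
        assert sum(len(g.reads) for g in groups.values()) == len(prepared)
        assert all(r.mid == g.mid for g in groups.values() for r in g.reads)


class TestQtSubcluster:
    def test_identical_reads_form_one_cluster(self):
        group = MIDGroup("A" * 12, [read("ACGT" * 30, rid=f"r{i}") for i in range(5)])
        clusters, discarded = qt_subcluster(group)
        assert len(clusters) == 1 and not discarded
        assert clusters[0].read_count == 5
        assert clusters[0].consensus == "ACGT" * 30

    def test_two_read_identity_rule(self):
        a = "ACGT" * 30
        b = a[:50] + "T" + a[51:]
        group = MIDGroup("A" * 12, [read(a, rid="r0"), read(b, rid="r1")])
        clusters, discarded = qt_subcluster(group)
        assert clusters == [] and len(discarded) == 2

    def test_singleton_group_discarded(self):
        group = MIDGroup("A" * 12, [read("ACGT" * 30)])
        clusters, discarded = qt_subcluster(group)
        assert clusters == [] and len(discarded) == 1

    def test_two_molecules_separated(self, rng):
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, size=150))
        b = list(a)
        for pos in rng.choice(150, size=60, replace=False):  # 60 substitutions
            b[pos] = "ACGT"[("ACGT".index(b[pos]) + 1) % 4]
        b = "".join(b)
        assert levenshtein(a, b) > 2 * 22  # separability regime
        reads = [read(a, rid=f"a{i}") for i in range(3)] + [
            read(b, rid=f"b{i}") for i in range(4)
        ]
        clusters, discarded = qt_subcluster(MIDGroup("A" * 12, reads))
        assert not discarded
        assert sorted(c.read_count for c in clusters) == [3, 4]
        assert {c.consensus for c in clusters} == {a, b}

    def test_partition_property(self, noisy_prepared):
        _, _, prepared = noisy_prepared
        groups = group_by_mid(prepared)
        for group in list(groups.values())[:300]:
            clusters, discarded = qt_subcluster(group)
            members = [r for c in clusters for r in c.members] + discarded
            assert sorted(r.id for r in members) == sorted(r.id for r in group.reads)

    def test_truth_partition_on_simulation(self, clean_sim):
        """Sub-cluster count per MID equals the true number of molecules
        tagged with that MID (clones are separated well beyond threshold)."""
        config, truth, sim_reads = clean_sim
        prepared = prepare_reads(
            sim_reads.reads, PreprocessConfig(anchor=config.anchor)
        ).prepared
        mids = truth.molecule_mids()
        reads_per_mol = np.bincount(sim_reads.read_molecule, minlength=truth.n_molecules)
        true_counted = {}
        for mol, mid in enumerate(mids):
            if reads_per_mol[mol] >= 2:
                true_counted[mid] = true_counted.get(mid, 0) + 1
        groups = group_by_mid(prepared)
        for mid, group in groups.items():
            clusters, _ = qt_subcluster(group)
            assert len(clusters) == true_counted.get(mid, 0)


class TestConsensus:
    def test_hand_computed_weighted_vote(self):
        # position 2: C carries 30+30=60, G carries 40 -> consensus "AC"
        r1 = read("AC", quals=[30, 30], rid="r1")
        r2 = read("AC", quals=[30, 30], rid="r2")
        r3 = read("AG", quals=[40, 40], rid="r3")
        assert build_consensus([r1, r2, r3]) == "AC"

    def test_quality_can_overrule_majority(self):
        r1 = read("AC", quals=[10, 10], rid="r1")
        r2 = read("AC", quals=[10, 10], rid="r2")
        r3 = read("AG", quals=[40, 40], rid="r3")
        assert build_consensus([r1, r2, r3]) == "AG"

    def test_tie_break_alphabetical(self):
        r1 = read("AT", quals=[30, 30], rid="r1")
        r2 = read("AG", quals=[30, 30], rid="r2")
        assert build_consensus([r1, r2]) == "AG"  # G before T

    def test_non_modal_lengths_do_not_vote(self):
        r1 = read("ACGT", rid="r1")
        r2 = read("ACGT", rid="r2")
        r3 = read("ACGTACGT", quals=[40] * 8, rid="r3")
        assert build_consensus([r1, r2, r3]) == "ACGT"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=1, max_size=40),
        n=st.integers(2, 6),
        data=st.data(),
    )
    def test_idempotence_under_any_qualities(self, seq, n, data):
        """Consensus of identical copies is that sequence, whatever the
        qualities."""
        quals = [
            data.draw(st.lists(st.integers(2, 41), min_size=len(seq), max_size=len(seq)))
            for _ in range(n)
        ]
        members = [read(seq, quals=q, rid=f"r{i}") for i, q in enumerate(quals)]
        assert build_consensus(members) == seq

    def test_error_free_cluster_matches_truth(self, clean_sim):
        config, truth, sim_reads = clean_sim
        prepared = prepare_reads(
            sim_reads.reads, PreprocessConfig(anchor=config.anchor)
        ).prepared
        clusters, _ = subcluster_all(group_by_mid(prepared))
        assert {c.consensus for c in clusters} <= truth.clone_sequences()


class TestFractionMidsWithSubclusters:
    def test_all_single_molecule(self):
        groups = {
            m: MIDGroup(m, [read("ACGT" * 30, mid=m, rid=f"{m}{i}") for i in range(3)])
            for m in ("AAAA", "CCCC")
        }
        assert fraction_mids_with_subclusters(groups) == 0.0

    def test_no_eligible_groups_is_undefined(self):
        groups = {"AAAA": MIDGroup("AAAA", [read("ACGT" * 30)])}  # singleton only
        with pytest.raises(ValueError):
            fraction_mids_with_subclusters(groups)

    def test_one_collision_among_singles(self, rng):
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, size=150)) for _ in range(4)]
        groups = {}
        for i, s in enumerate(seqs[:3]):
            mid = f"M{i}"
            groups[mid] = MIDGroup(mid, [read(s, mid=mid, rid=f"{mid}_{j}") for j in range(3)])
        collided = MIDGroup(
            "M3",
            [read(seqs[2], mid="M3", rid=f"c{j}") for j in range(3)]
            + [read(seqs[3], mid="M3", rid=f"d{j}") for j in range(3)],
        )
        groups["M3"] = collided
        assert fraction_mids_with_subclusters(groups) == pytest.approx(1 / 4)

    def test_matches_poisson_occupancy_model(self):
        """Observed sub-clustering fraction agrees with the Poisson
        occupancy prediction F(k>1) within 3 binomial standard errors."""
        config = SimConfig(
            K=700, alpha=2.5, m=3, mid_length=8, seed=33,
            pcr_error_rate=0.0, seq_error_rate=0.0,
            reads_per_molecule_mean=15.0, separation_check_max_clones=0,
        )
        truth, sim_reads = simulate_reads(config)
        prepared = prepare_reads(
            sim_reads.reads, PreprocessConfig(anchor=config.anchor, mid_length=8)
        ).prepared
        groups = group_by_mid(prepared)
        observed = fraction_mids_with_subclusters(groups)
        expected = frac_needing_subclustering(
            TaggingModel(M=4**8, N=truth.n_molecules)
        )
        n_groups = len(groups)
        se = np.sqrt(expected * (1 - expected) / n_groups)
        assert abs(observed - expected) <= 3 * se
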