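"""Clonotype merging and the three post-clustering error filters."""

import itertools

import numpy as np
import pytest
from scipy import stats

from midseq.filters import (
    Clonotype,
    ConsensusRecord,
    _distance_one_pairs,
    apply_filters,
    collapse_neighbors,
    fit_nb_mixture,
    flag_nonfunctional,
    merge_identical,
    mid_readcount_filter,
)
from midseq.subcluster import levenshtein

S1 = "ATGGCTGCTAAACCCGGGTTT"
S2 = "ATGGCTGCTAAACCCGGGTTA"  # 1 substitution from S1


def clonotype(seq, counts):
    """Clonotype with one MID entry per count."""
    return Clonotype(seq=seq, mids={(f"M{i:03d}", 0): c for i, c in enumerate(counts)})


class TestMergeIdentical:
    def test_aggregation(self):
        records = [
            ConsensusRecord("s1", "m1", 5),
            ConsensusRecord("s1", "m2", 7),
            ConsensusRecord("s2", "m3", 2),
        ]
        out = {c.seq: c for c in merge_identical(records)}
        assert out["s1"].molecule_count == 2 and out["s1"].total_reads == 12
        assert out["s2"].molecule_count == 1 and out["s2"].total_reads == 2

    def test_empty(self):
        assert merge_identical([]) == []

    def test_same_mid_twice_counts_two_molecules(self):
        records = [ConsensusRecord("s", "m", 5), ConsensusRecord("s", "m", 3)]
        (c,) = merge_identical(records)
        assert c.molecule_count == 2 and c.total_reads == 8

    def test_conservation(self):
        rng = np.random.default_rng(5)
        records = [
            ConsensusRecord(f"s{rng.integers(8)}", f"m{rng.integers(20)}", int(rng.integers(2, 50)))
            for _ in range(200)
        ]
        out = merge_identical(records)
        assert sum(c.molecule_count for c in out) == len(records)
        assert sum(c.total_reads for c in out) == sum(r.read_count for r in records)

    def test_order_independent(self):
        records = [
            ConsensusRecord("s1", "m1", 5),
            ConsensusRecord("s1", "m1", 9),
            ConsensusRecord("s2", "m2", 2),
            ConsensusRecord("s1", "m3", 4),
        ]
        baseline = merge_identical(records)
        for perm in itertools.permutations(records):
            assert merge_identical(perm) == baseline


class TestFlagNonfunctional:
    def test_in_frame_stop_flagged(self):
        c = clonotype("ATGTAAGGG", [3])
        assert flag_nonfunctional(c, 0) is True
        assert c.functional is False

    def test_open_reading_frame_not_flagged(self):
        c = clonotype("ATGGCTGCTAAA", [3])  # GCT GCT AAA: no stop
        assert flag_nonfunctional(c, 0) is False
        assert c.functional is True

    def test_frame_offset_shifts_codons(self):
        # TAA appears at offset 1 frame only
        seq = "G" + "TAA" + "GGGGGG"
        assert flag_nonfunctional(clonotype(seq, [1]), 1) is True
        assert flag_nonfunctional(clonotype(seq, [1]), 0) is False

    def test_simulated_nonproductive_clones_all_flagged(self, rng):
        from midseq.filters import merge_identical
        from midseq.pipeline import run_pipeline
        from midseq.preprocess import PreprocessConfig, prepare_reads
        from midseq.simulate import SimConfig, simulate_reads

        config = SimConfig(
            K=60, alpha=2.5, m=3, seed=77, nonproductive_fraction=0.3,
            pcr_error_rate=0.0, seq_error_rate=0.0, reads_per_molecule_mean=12.0,
        )
        truth, sim_reads = simulate_reads(config)
        prepared = prepare_reads(
            sim_reads.reads, PreprocessConfig(anchor=config.anchor)
        ).prepared
        result = run_pipeline(prepared)
        productive_truth = {c.sequence: c.productive for c in truth.clones}
        assert any(not p for p in productive_truth.values())
        for c in result.clonotypes:
            assert c.functional == productive_truth[c.seq]


class TestCollapseNeighbors:
    def test_satellite_removed(self):
        out = collapse_neighbors([clonotype(S1, [5] * 10), clonotype(S2, [2])])
        assert [c.seq for c in out] == [S1]

    def test_tie_retains_both(self):
        out = collapse_neighbors([clonotype(S1, [5, 5, 5]), clonotype(S2, [2, 2, 2])])
        assert {c.seq for c in out} == {S1, S2}

    def test_decisions_use_prefilter_state(self):
        s3 = "T" + S2[1:]  # distance 1 from S2, 2 from S1
        assert levenshtein(S2, s3) == 1 and levenshtein(S1, s3) == 2
        out = collapse_neighbors(
            [clonotype(S1, [5] * 10), clonotype(S2, [2] * 5), clonotype(s3, [1])]
        )
        # S2 removed by S1; s3 still removed by (pre-filter) S2
        assert [c.seq for c in out] == [S1]

    def test_distance_one_pairs_match_bruteforce(self, rng):
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, size=60)) for _ in range(40)]
        # plant satellites: substitution, insertion, deletion
        seqs.append(seqs[0][:30] + "A" + seqs[0][31:])
        seqs.append(seqs[1][:15] + "C" + seqs[1][15:])
        seqs.append(seqs[2][:45] + seqs[2][46:])
        seqs = list(dict.fromkeys(seqs))
        expected = {
            tuple(sorted(p))
            for p in itertools.combinations(range(len(seqs)), 2)
            if levenshtein(seqs[p[0]], seqs[p[1]]) == 1
        }
        assert len(expected) >= 3
        got = {tuple(sorted(p)) for p in _distance_one_pairs(seqs)}
        assert got == expected

    def test_order_independent(self, rng):
        clonotypes = [
            clonotype(S1, [5] * 7),
            clonotype(S2, [2]),
            clonotype("GGGCCCAAATTTGGGCCCAAA", [3, 3]),
        ]
        baseline = sorted(c.seq for c in collapse_neighbors(clonotypes))
        for perm in itertools.permutations(clonotypes):
            assert sorted(c.seq for c in collapse_neighbors(list(perm))) == baseline


class TestNBMixture:
    def test_parameter_recovery(self, rng):
        low = stats.nbinom.rvs(1, 1 / (1 + 2), size=500, random_state=rng)  # mean 2
        high = stats.nbinom.rvs(5, 5 / (5 + 60), size=500, random_state=rng)  # mean 60
        counts = np.concatenate([low, high]) + 1  # counts are >= 1 in practice
        fit = fit_nb_mixture(counts)
        assert not fit.degenerate and not fit.boundary
        assert abs(fit.mean_low - 3) / 3 < 0.25
        assert abs(fit.mean_high - 61) / 61 < 0.25
        assert 0.3 < fit.weight_low < 0.7
        assert fit.crossover_count is not None
        assert 3 < fit.crossover_count < 61

    def test_all_equal_degenerate(self):
        fit = fit_nb_mixture([7] * 30)
        assert fit.degenerate
        assert fit.mean_low == 7

    def test_single_component_hits_boundary(self, rng):
        counts = stats.nbinom.rvs(5, 5 / (5 + 30), size=600, random_state=rng) + 1
        fit = fit_nb_mixture(counts)
        # one NB cannot support two separated components: weight collapses
        # to a boundary or the two means nearly coincide
        assert fit.boundary or fit.mean_high / max(fit.mean_low, 1e-9) < 1.6

    def test_too_few_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_nb_mixture([1, 2, 3])


class TestMidReadcountFilter:
    def test_twenty_percent_rule(self):
        c = Clonotype(seq="s", mids={("m1", 0): 100, ("m2", 0): 25, ("m3", 0): 19})
        out = mid_readcount_filter(c)
        assert out is not None
        assert set(out.mids.values()) == {100, 25}
        assert out.molecule_count == 2 and out.total_reads == 125

    def test_exactly_at_threshold_kept(self):
        c = Clonotype(seq="s", mids={("m1", 0): 100, ("m2", 0): 20})
        out = mid_readcount_filter(c)
        assert out is not None and out.molecule_count == 2

    def test_single_mid_unchanged(self):
        c = Clonotype(seq="s", mids={("m1", 0): 4})
        out = mid_readcount_filter(c)
        assert out is not None and out.mids == {("m1", 0): 4}

    def test_absolute_threshold_override(self):
        c = Clonotype(seq="s", mids={("m1", 0): 100, ("m2", 0): 25, ("m3", 0): 19})
        out = mid_readcount_filter(c, threshold_count=26)
        assert out is not None and out.molecule_count == 1


class TestFilterChain:
    def test_audit_conservation(self, rng):
        records = [
            ConsensusRecord(S1, f"m{i}", int(rng.integers(10, 60))) for i in range(8)
        ] + [ConsensusRecord(S2, "mx", 2), ConsensusRecord(S1, "m0", 1)]
        clonotypes, audit = apply_filters(records, frame_offset=None)
        assert audit["merged_clonotypes"] == 2
        assert audit["removed_neighbor_collapse"] == 1
        assert audit["final_clonotypes"] == len(clonotypes) == 1

    def test_filters_only_remove(self, noisy_prepared):
        """Monotonicity: no filter creates sequence diversity."""
        from midseq.pipeline import PipelineConfig, run_pipeline

        _, _, prepared = noisy_prepared
        raw = run_pipeline(
            prepared,
            PipelineConfig(frame_offset=None, collapse=False, mid_filter=False),
        )
        filtered = run_pipeline(prepared, PipelineConfig(frame_offset=None))
        raw_seqs = {c.seq for c in raw.clonotypes}
        filt = {c.seq: c for c in filtered.clonotypes}
        assert set(filt) <= raw_seqs
        raw_by_seq = {c.seq: c for c in raw.clonotypes}
        for seq, c in filt.items():
            assert c.molecule_count <= raw_by_seq[seq].molecule_count
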