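"""Tests of WGD scoring/counting, resampling, support and region scores."""

import numpy as np
import pandas as pd
import pytest

from medphylo.genome_model import Cohort, CopyNumberProfile, GenomeLayout, diploid_profile
from medphylo.med_model import EventRecord
from medphylo.phylogeny import TreeNode
from medphylo.wgd_events import (
    branch_support,
    call_wgd_with_bootstrap,
    detect_tree_events,
    jackknife_retained_fraction,
    resample_cohort,
    score_regions,
    wgd_evidence,
)


class TestWgdEvidence:
    def test_diploid_scores_zero(self, model8):
        lay = GenomeLayout.uniform(4, 3)
        r = wgd_evidence(diploid_profile(lay), model8, lay)
        assert r.s == 0 and r.wgd_count == 0

    def test_uniformly_doubled_genome_over_22_chromosomes(self, model8):
        # 44 per-chromosome-haplotype gain runs without WGD vs one WGD
        lay = GenomeLayout.uniform(22, 10)
        t = CopyNumberProfile("t", np.full(220, 2), np.full(220, 2))
        r = wgd_evidence(t, model8, lay)
        assert r.s == 44 - 1 == 43
        assert r.wgd_count == 1

    def test_multi_wgd_counting_on_all_fours(self, model8, model8_double):
        lay = GenomeLayout.uniform(2, 2)
        t = CopyNumberProfile("t", np.full(4, 4), np.full(4, 4))
        # +1-per-WGD model: 9 > 6 > 3 = 3, so three WGDs are counted
        assert wgd_evidence(t, model8, lay).wgd_count == 3
        # doubling model: 9 > 2 = 2, two WGDs
        assert wgd_evidence(t, model8_double, lay).wgd_count == 2

    def test_score_is_never_negative(self, model8):
        rng = np.random.default_rng(30)
        lay = GenomeLayout.uniform(3, 3)
        for _ in range(20):
            p = CopyNumberProfile("p", rng.integers(0, 5, 9), rng.integers(0, 5, 9))
            assert wgd_evidence(p, model8, lay).s >= 0


class TestResampling:
    @staticmethod
    def cohort(n_chrom=4, per=3, seed=0):
        rng = np.random.default_rng(seed)
        lay = GenomeLayout.uniform(n_chrom, per)
        n = lay.n_segments
        p = CopyNumberProfile("s1", rng.integers(0, 4, n), rng.integers(0, 4, n))
        return Cohort(lay, [p])

    def test_single_chromosome_bootstrap_is_the_original(self):
        cohort = self.cohort(n_chrom=1)
        reps = resample_cohort(cohort, "chromosome_bootstrap", B=5, seed=1)
        for rep in reps:
            assert np.array_equal(rep.profiles[0].hapA, cohort.profiles[0].hapA)

    def test_jackknife_retains_about_1_minus_1_over_e(self):
        lay = GenomeLayout.uniform(22, 20)  # 440 segments
        p = diploid_profile(lay)
        cohort = Cohort(lay, [CopyNumberProfile("s", p.hapA.copy(), p.hapB.copy())])
        reps = resample_cohort(cohort, "segment_jackknife", B=300, seed=2)
        frac = jackknife_retained_fraction(cohort, reps)
        assert abs(frac - (1 - 1 / np.e)) < 0.01

    def test_fixed_seed_reproduces_replicates(self):
        cohort = self.cohort()
        a = resample_cohort(cohort, "chromosome_bootstrap", B=3, seed=7)
        b = resample_cohort(cohort, "chromosome_bootstrap", B=3, seed=7)
        for ra, rb in zip(a, b):
            assert ra.layout.chromosomes == rb.layout.chromosomes
            assert np.array_equal(ra.profiles[0].hapA, rb.profiles[0].hapA)
        c = resample_cohort(cohort, "chromosome_bootstrap", B=3, seed=8)
        assert any(
            not np.array_equal(ra.profiles[0].hapA, rc.profiles[0].hapA)
            for ra, rc in zip(a, c)
        )

    def test_jackknife_preserves_segment_order(self):
        cohort = self.cohort(seed=3)
        for rep in resample_cohort(cohort, "segment_jackknife", B=10, seed=3):
            for chrom in rep.layout.chromosomes:
                segs = rep.layout.segments[chrom]
                assert segs == sorted(segs)


class TestBootstrapCall:
    def test_diploid_is_negative(self, model8):
        lay = GenomeLayout.uniform(4, 3)
        r = call_wgd_with_bootstrap(diploid_profile(lay), model8, lay, B=20, seed=1)
        assert r.bootstrap_fraction == 0.0 and r.call is False

    def test_clean_doubled_genome_is_positive_in_every_replicate(self, model8):
        lay = GenomeLayout.uniform(6, 3)
        t = CopyNumberProfile("t", np.full(18, 2), np.full(18, 2))
        r = call_wgd_with_bootstrap(t, model8, lay, B=20, seed=1)
        assert r.bootstrap_fraction == 1.0 and r.call is True

    def test_threshold_monotonicity(self, model8):
        rng = np.random.default_rng(31)
        lay = GenomeLayout.uniform(4, 3)
        for seed in range(3):
            hap = rng.integers(1, 3, 12)
            p = CopyNumberProfile("p", hap, rng.integers(1, 3, 12))
            lo = call_wgd_with_bootstrap(p, model8, lay, B=20, threshold=0.05, seed=seed)
            hi = call_wgd_with_bootstrap(p, model8, lay, B=20, threshold=0.5, seed=seed)
            if hi.call:
                assert lo.call  # calls at 5% are a superset of calls at 50%


class TestBranchSupport:
    @staticmethod
    def quartet(split):
        (a, b), (c, d) = split
        root = TreeNode()
        left = root.add(TreeNode())
        left.add(TreeNode(name=a))
        left.add(TreeNode(name=b))
        right = root.add(TreeNode())
        right.add(TreeNode(name=c))
        right.add(TreeNode(name=d))
        return root

    def test_identical_replicates_give_full_support(self):
        t = self.quartet((("A", "B"), ("C", "D")))
        reps = [self.quartet((("A", "B"), ("C", "D"))) for _ in range(4)]
        t = branch_support(t, reps)
        supports = [n.support for n in t.postorder() if n.support is not None]
        assert supports and all(s == 100 for s in supports)

    def test_half_support_when_half_the_replicates_disagree(self):
        t = self.quartet((("A", "B"), ("C", "D")))
        reps = [
            self.quartet((("A", "B"), ("C", "D"))),
            self.quartet((("A", "C"), ("B", "D"))),
        ]
        t = branch_support(t, reps)
        supports = [n.support for n in t.postorder() if n.support is not None]
        assert set(supports) == {50}

    def test_support_invariant_to_replicate_order(self):
        reps = [
            self.quartet((("A", "B"), ("C", "D"))),
            self.quartet((("A", "C"), ("B", "D"))),
            self.quartet((("A", "D"), ("B", "C"))),
        ]
        t1 = branch_support(self.quartet((("A", "B"), ("C", "D"))), reps)
        t2 = branch_support(self.quartet((("A", "B"), ("C", "D"))), reps[::-1])
        s1 = [n.support for n in t1.postorder() if n.support is not None]
        s2 = [n.support for n in t2.postorder() if n.support is not None]
        assert s1 == s2

    def test_leaf_set_mismatch_raises(self):
        t = self.quartet((("A", "B"), ("C", "D")))
        bad = self.quartet((("A", "B"), ("C", "E")))
        with pytest.raises(ValueError):
            branch_support(t, [bad])


class TestTreeEvents:
    @staticmethod
    def build_tree(layout, model, leaf_profiles):
        """Rooted tree diploid + leaves, reconstructed ancestors."""
        from medphylo.med_model import pairwise_distances
        from medphylo.phylogeny import neighbor_joining, reconstruct_ancestors, root_at_diploid

        cohort = Cohort(layout, leaf_profiles)
        dm = pairwise_distances(cohort, model)
        tree = root_at_diploid(neighbor_joining(dm))
        return reconstruct_ancestors(tree, cohort, model), cohort

    def test_clonal_gain_is_placed_once_on_the_trunk(self, model8):
        lay = GenomeLayout.uniform(2, 3)
        base = np.array([2, 2, 2, 1, 1, 1])
        profiles = [
            CopyNumberProfile(f"s{i}", base.copy(), np.ones(6, dtype=int)) for i in range(3)
        ]
        tree, cohort = self.build_tree(lay, model8, profiles)
        events = detect_tree_events(tree, model8, cohort.layout)
        gains = [(br, e) for br, evs in events.items() for e in evs if e.kind == "gain"]
        assert len(gains) == 1
        branch_name = gains[0][0]
        node = tree.find(branch_name)
        assert not node.is_leaf  # on the trunk (an internal branch), not a leaf

    def test_parallel_gains_stay_on_separate_terminal_branches(self, model8):
        # two distinct clones share a background; the same extra gain arises
        # independently in one sample of each clade (homoplasy by construction)
        lay = GenomeLayout.uniform(2, 3)
        ones = np.ones(6, dtype=int)
        cladeA = np.array([2, 2, 2, 1, 1, 1])
        cladeB = np.array([1, 1, 1, 2, 2, 2])
        shared_gain = np.array([0, 0, 0, 0, 0, 1])
        profiles = [
            CopyNumberProfile("a1", cladeA.copy(), ones.copy()),
            CopyNumberProfile("a2", cladeA + shared_gain, ones.copy()),
            CopyNumberProfile("b1", cladeB.copy(), ones.copy()),
            CopyNumberProfile("b2", cladeB + shared_gain, ones.copy()),
        ]
        tree, cohort = self.build_tree(lay, model8, profiles)
        events = detect_tree_events(tree, model8, cohort.layout)
        hits = [
            br
            for br, evs in events.items()
            for e in evs
            if e.kind == "gain" and e.chromosome == "chr2" and e.start_segment == 2 == e.end_segment
        ]
        assert sorted(hits) == ["a2", "b2"]

    def test_leaf_identical_to_parent_has_no_events(self, model8):
        lay = GenomeLayout.uniform(1, 3)
        p = CopyNumberProfile("a", np.array([2, 1, 1]), np.ones(3, dtype=int))
        tree, cohort = self.build_tree(
            lay, model8, [p, CopyNumberProfile("b", p.hapA.copy(), p.hapB.copy())]
        )
        events = detect_tree_events(tree, model8, cohort.layout)
        assert events["a"] == [] and events["b"] == []

    def test_event_counts_sum_to_tree_length(self, model8):
        from medphylo.simulator import GenomeSimConfig, simulate_cohort
        from medphylo.med_model import pairwise_distances
        from medphylo.phylogeny import neighbor_joining, reconstruct_ancestors, root_at_diploid, tree_stats

        cfg = GenomeSimConfig(n_leaves=5, mu=0.06, n_chromosomes=4, segs_per_chrom=5, seed=33)
        cohort, _t, _l = simulate_cohort(cfg)
        dm = pairwise_distances(cohort, model8)
        tree = reconstruct_ancestors(root_at_diploid(neighbor_joining(dm)), cohort, model8)
        events = detect_tree_events(tree, model8, cohort.layout)
        assert sum(len(v) for v in events.values()) == tree_stats(tree)["tree_length"]


class TestRegionScores:
    @staticmethod
    def layout():
        return GenomeLayout.uniform(2, 4)  # 1 Mb segments

    def bed(self, chrom, start, end, name="roi"):
        return pd.DataFrame(
            [(chrom, start, end, name)], columns=["chrom", "start", "end", "name"]
        )

    def test_region_matching_a_two_segment_gain_is_counted(self):
        lay = self.layout()
        events = {"b": [EventRecord("gain", "A", "chr1", 1, 2, +1)]}
        scores = score_regions(events, self.bed("chr1", 1_000_000, 3_000_000), lay)
        assert scores[0].gains == 1 and scores[0].losses == 0

    def test_80_percent_overlap_is_not_counted(self):
        lay = self.layout()
        events = {"b": [EventRecord("loss", "A", "chr1", 0, 1, -1)]}
        # region of 2.5 Mb, event covers 2 Mb = 80%
        scores = score_regions(events, self.bed("chr1", 0, 2_500_000), lay)
        assert scores[0].losses == 0
        # 90% coverage counts
        scores = score_regions(events, self.bed("chr1", 0, 2_222_222), lay)
        assert scores[0].losses == 1

    def test_wgd_counts_as_a_gain_for_every_region(self):
        lay = self.layout()
        events = {"b": [EventRecord("wgd", "both", None, 0, 7, +1)]}
        beds = pd.concat(
            [self.bed("chr1", 0, 1_000_000, "r1"), self.bed("chr2", 2_000_000, 4_000_000, "r2")]
        )
        scores = score_regions(events, beds, lay)
        assert [s.gains for s in scores] == [1, 1]
        assert [s.net for s in scores] == [1, 1]

    def test_unknown_chromosome_is_skipped_with_warning(self, caplog):
        lay = self.layout()
        with caplog.at_level("WARNING"):
            scores = score_regions({}, self.bed("chr9", 0, 100), lay)
        assert scores == []
        assert any("unknown chromosome" in r.message for r in caplog.records)
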