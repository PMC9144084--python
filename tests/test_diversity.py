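"""p-distance, nucleotide diversity, sliding windows, HD regions, NJ."""

import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtmosaic import (
    AlignmentError,
    PlantedEvent,
    SimulationConfig,
    detect_hd_regions,
    distance_matrix,
    nj_tree,
    nucleotide_diversity,
    p_distance,
    simulate,
    sliding_profile,
)
from mtmosaic.alignio import SequenceRecord
from mtmosaic.diversity import SlidingProfile, UndefinedDistanceError
from conftest import make_aln


class TestPDistance:
    def test_identity_is_zero(self):
        a = SequenceRecord("a", "ACGTACGT")
        assert p_distance(a, SequenceRecord("b", "ACGTACGT"), n_bootstrap=50).value == 0.0
        assert p_distance(a, SequenceRecord("b", "ACGTACGT"), n_bootstrap=50).se == 0.0

    def test_one_quarter(self):
        d = p_distance(
            SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGA"), n_bootstrap=0
        )
        assert d.value == 0.25
        assert d.n_sites == 4

    def test_gaps_and_missing_excluded(self):
        d = p_distance(
            SequenceRecord("a", "AC-TN"), SequenceRecord("b", "AAG-A"), n_bootstrap=0
        )
        # comparable columns: 1 (A/A) and 2 (C/A) only
        assert d.n_sites == 2
        assert d.value == 0.5

    def test_no_comparable_sites_raises(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance(
                SequenceRecord("a", "--AA"), SequenceRecord("b", "AA--"), n_bootstrap=0
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_symmetric_bounded_zero_on_self(self, data):
        length = data.draw(st.integers(4, 30))
        mk = lambda: "".join(
            data.draw(st.sampled_from("ACGT")) for _ in range(length)
        )
        a, b = SequenceRecord("a", mk()), SequenceRecord("b", mk())
        d_ab = p_distance(a, b, n_bootstrap=0)
        d_ba = p_distance(b, a, n_bootstrap=0)
        assert d_ab.value == d_ba.value
        assert 0.0 <= d_ab.value <= 1.0
        assert p_distance(a, SequenceRecord("c", a.residues), n_bootstrap=0).value == 0


class TestDiversity:
    def test_identical_pair_zero(self):
        aln = make_aln("ACGT", "ACGT")
        assert nucleotide_diversity(aln, n_bootstrap=50).pi == 0.0

    def test_three_sequence_hand_value(self):
        # pairs: 0.25, 0.50, 0.25 -> mean 1/3
        aln = make_aln("AAAA", "AAAT", "AATT")
        est = nucleotide_diversity(aln, n_bootstrap=0)
        assert est.pi == pytest.approx(1 / 3)
        assert est.n_sequences == 3

    def test_pi_equals_matrix_off_diagonal_mean(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("ACGT-N"), 60)) for _ in range(5)]
        aln = make_aln(*rows)
        est = nucleotide_diversity(aln, n_bootstrap=0)
        dm = distance_matrix(aln, n_bootstrap=0)
        off = dm.values[np.triu_indices(5, k=1)]
        assert est.pi == pytest.approx(off.mean(), abs=1e-12)

    def test_matrix_matches_double_loop(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(4)]
        aln = make_aln(*rows)
        dm = distance_matrix(aln, n_bootstrap=0)
        for i, j in itertools.combinations(range(4), 2):
            expect = np.mean(
                [a != b for a, b in zip(rows[i], rows[j])]
            )
            assert dm.values[i, j] == pytest.approx(expect)
            assert dm.values[j, i] == dm.values[i, j]
        assert np.all(np.diag(dm.values) == 0)


class TestSlidingProfile:
    def test_constant_alignment_all_zero(self):
        aln = make_aln("A" * 200, "A" * 200)
        prof = sliding_profile(aln, "dxy", window=50, step=10)
        assert np.all(prof.values == 0)
        assert not prof.flagged.any()

    def test_midpoints_and_step_geometry(self):
        aln = make_aln("A" * 130, "A" * 130)
        prof = sliding_profile(aln, "pi", window=100, step=25)
        # full windows start at columns 1 and 26 only
        assert list(prof.midpoints) == [50, 75]
        assert np.all(np.diff(prof.midpoints) == prof.step)

    def test_matches_direct_per_window_recomputation(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT-"), 400)) for _ in range(3)]
        aln = make_aln(*rows)
        prof = sliding_profile(aln, "pi", window=60, step=20)
        from mtmosaic import RegionSpec, extract_region

        for i in range(len(prof.midpoints)):
            s = prof.window_start(i)
            sub = extract_region(aln, RegionSpec(s, s + prof.window - 1))
            try:
                expect = nucleotide_diversity(sub, n_bootstrap=0).pi
            except UndefinedDistanceError:
                continue
            assert prof.values[i] == pytest.approx(expect, abs=1e-12)

    def test_weighted_window_average_recovers_whole_distance(self):
        rng = np.random.default_rng(11)
        rows = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(2)]
        aln = make_aln(*rows)
        # step = window tiles the sequence without overlap
        prof = sliding_profile(aln, "dxy", window=50, step=50)
        total = (prof.values * prof.n_comparable).sum() / prof.n_comparable.sum()
        whole = p_distance(aln.records[0], aln.records[1], n_bootstrap=0)
        assert total == pytest.approx(whole.value, abs=1e-6)

    def test_window_larger_than_alignment_rejected(self):
        aln = make_aln("ACGT", "ACGT")
        with pytest.raises(AlignmentError):
            sliding_profile(aln, "pi", window=10, step=1)


class TestHDRegions:
    def test_flat_profile_empty(self):
        prof = SlidingProfile(
            window=100, step=25, stat="pi",
            midpoints=np.arange(50, 1050, 25),
            values=np.full(40, 0.003),
            n_comparable=np.full(40, 100),
            flagged=np.zeros(40, dtype=bool),
        )
        assert detect_hd_regions(prof) == []

    def test_isolated_window_filtered_by_run_length(self):
        values = np.full(40, 0.001)
        values[20] = 0.5
        prof = SlidingProfile(
            window=100, step=25, stat="pi",
            midpoints=np.arange(50, 1050, 25),
            values=values,
            n_comparable=np.full(40, 100),
            flagged=np.zeros(40, dtype=bool),
        )
        assert detect_hd_regions(prof, min_windows=2) == []
        regions = detect_hd_regions(prof, min_windows=1)
        assert len(regions) == 1
        assert regions[0].peak_midpoint == int(prof.midpoints[20])

    def test_recovers_planted_divergent_blocks(self):
        # one 500-column interspecific block on a conspecific background
        config = SimulationConfig(
            genome_length=6000,
            planted_events=(PlantedEvent("A2", "B", 2501, 500, 0),),
            seed=9,
        )
        aln, truth = simulate(config)
        prof = sliding_profile(aln.subset([f"A{k}" for k in range(1, 6)]), "pi")
        regions = detect_hd_regions(prof)
        assert regions, "planted block not detected"
        # every detected region lies on the block (no false regions) and the
        # union covers the block interior
        for reg in regions:
            assert reg.end >= 2501 and reg.start <= 3000
            assert reg.peak_value > reg.background
        assert min(r.start for r in regions) <= 2501 + 100
        assert max(r.end for r in regions) >= 3000 - 100


class TestNeighborJoining:
    def test_four_taxon_additive_matrix(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) gives these path lengths
        d = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        nwk = nj_tree(d, ["A", "B", "C", "D"])
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(nwk))
        sisters = {t.name for t in tree.find("A").parent.children if t.name}
        assert sisters == {"A", "B"}

    def test_random_additive_trees_recovered(self):
        from skbio import TreeNode

        rng = np.random.default_rng(17)
        for rep in range(5):
            n = 7
            # build a random additive distance matrix from a random tree by
            # sequential taxon attachment (oracle independent of NJ)
            names = [f"t{i}" for i in range(n)]
            newick = self._random_tree_newick(rng, names)
            tree = TreeNode.read(io.StringIO(newick))
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = tree.find(names[i]).distance(
                        tree.find(names[j])
                    )
            out = TreeNode.read(io.StringIO(nj_tree(d, names)))
            assert tree.compare_rfd(out) == 0.0

    @staticmethod
    def _random_tree_newick(rng, names):
        bl = lambda: round(float(rng.uniform(0.5, 3.0)), 3)
        tree = f"({names[0]}:{bl()},{names[1]}:{bl()},{names[2]}:{bl()})"
        from skbio import TreeNode

        t = TreeNode.read(io.StringIO(tree + ";"))
        for name in names[3:]:
            edges = [nd for nd in t.traverse() if nd.length is not None]
            host = edges[rng.integers(len(edges))]
            split = TreeNode(length=host.length / 2)
            leaf = TreeNode(name=name, length=bl())
            parent = host.parent
            parent.remove(host)
            host.length /= 2
            split.append(host)
            split.append(leaf)
            parent.append(split)
        return str(t)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(AlignmentError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])
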