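"""PHI, MaxChi, triplet scanning, event calling, Bonferroni."""

import itertools

import numpy as np
import pytest

from mtmosaic import (
    ConfigurationError,
    MultipleAlignment,
    RecombConfig,
    SequenceRecord,
    bonferroni,
    call_events,
    informative_sites,
    maxchi_scan,
    paper_mimic_config,
    phi_test,
    simulate,
    triplet_scan,
)
from conftest import make_aln


def columns_to_rows(cols):
    """Build an alignment whose k-th column is the string cols[k]."""
    n = len(cols[0])
    return make_aln(*("".join(c[r] for c in cols) for r in range(n)))


class TestInformativeSites:
    def test_all_identical_empty(self):
        aln = make_aln("AAAA", "AAAA", "AAAA", "AAAA")
        assert len(informative_sites(aln)) == 0

    def test_single_two_two_split(self):
        aln = columns_to_rows(["AAAA", "AACC", "ACCC"])
        sites = informative_sites(aln)
        assert list(sites.columns) == [2]

    def test_matches_brute_force_classifier(self):
        rng = np.random.default_rng(21)
        rows = ["".join(rng.choice(list("ACGTN-"), 200)) for _ in range(6)]
        aln = make_aln(*rows)
        sites = informative_sites(aln)
        expected = []
        for col in range(200):
            states = [r[col] for r in rows if r[col] in "ACGT"]
            counts = {s: states.count(s) for s in set(states)}
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                expected.append(col + 1)
        assert list(sites.columns) == expected


class TestPhi:
    def test_clonal_clade_structure_no_homoplasy(self):
        # star of 4 clades x 2 sequences; every informative site is a clean
        # clade split, so no pair of sites can violate four gametes
        cols = []
        for clade in range(4):
            for _ in range(3):
                c = ["A"] * 8
                c[2 * clade] = c[2 * clade + 1] = "C"
                cols.append("".join(c))
        aln = columns_to_rows(cols)
        res = phi_test(aln, w=100, n_permutations=200, seed=1)
        assert res.computable
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_too_few_informative_sites_flagged(self):
        aln = make_aln("AAAA", "AAAA", "AAAA", "AAAT")
        res = phi_test(aln, n_permutations=10, seed=0)
        assert not res.computable

    def test_statistic_and_p_match_exhaustive_enumeration(self):
        # two mutually incompatible splits, each repeated on three nearby
        # sites: nearby pairs are mostly compatible, permutations are not
        s1, s2 = "AACC", "ACAC"
        cols = [s1, s1, s1, s2, s2, s2]
        aln = columns_to_rows(cols)
        w = 2

        def incompatible(a, b):
            return len(set(zip(a, b))) == 4

        def stat(order):
            vals = [
                incompatible(cols[order[i]], cols[order[j]])
                for i in range(6)
                for j in range(i + 1, 6)
                if j - i <= w
            ]
            return float(np.mean(vals))

        obs = stat(list(range(6)))
        exact_p = float(
            np.mean(
                [stat(list(p)) <= obs + 1e-12 for p in itertools.permutations(range(6))]
            )
        )
        res = phi_test(aln, w=w, n_permutations=4000, seed=5)
        assert res.statistic == pytest.approx(obs)
        sd = np.sqrt(exact_p * (1 - exact_p) / 4000)
        assert abs(res.p_value - exact_p) < 3 * sd + 1 / 4000

    def test_invariant_to_row_order_and_state_relabeling(self):
        # biallelic columns: mutations flip a site to one fixed alternate base
        rng = np.random.default_rng(31)
        base = rng.choice(list("ACGT"), 120)
        alt = np.array(["ACGT"[("ACGT".index(b) + 1) % 4] for b in base])
        rows = [
            "".join(np.where(rng.random(120) < 0.25, alt, base))
            for _ in range(6)
        ]
        aln = make_aln(*rows)
        base = phi_test(aln, w=50, n_permutations=300, seed=9)

        shuffled = make_aln(*rows[::-1])
        relabeled = make_aln(
            *[r.translate(str.maketrans("ACGT", "GTAC")) for r in rows]
        )
        for variant in (shuffled, relabeled):
            res = phi_test(variant, w=50, n_permutations=300, seed=9)
            assert res.statistic == pytest.approx(base.statistic)

    def test_detects_planted_recombination(self, mimic_dataset):
        _, aln, _ = mimic_dataset
        res = phi_test(aln, w=100, n_permutations=5000, seed=2)
        assert res.computable
        assert res.p_value < 0.01
        assert res.p_value >= 1 / (res.n_permutations + 1)


class TestMaxChi:
    @staticmethod
    def step_alignment():
        cand = "A" * 60
        parent = "A" * 30 + "C" * 30
        third = "G" * 60  # keeps every column variable in the alignment
        return make_aln(cand, parent, third, ids=["cand", "par", "out"])

    def test_hand_built_step_pattern_exact(self):
        aln = self.step_alignment()
        res = maxchi_scan("cand", "par", aln, k=15, n_permutations=300, seed=1)
        assert res.computable
        assert res.max_chi == pytest.approx(30.0)
        assert res.best_breakpoint == 30
        assert res.p_value < 0.05

    def test_uniform_noise_not_significant(self):
        rng = np.random.default_rng(13)
        cand = "".join(rng.choice(list("ACGT"), 600))
        mism = rng.random(600) < 0.1
        parent = "".join(
            ("C" if c != "C" else "G") if m else c for c, m in zip(cand, mism)
        )
        aln = make_aln(cand, parent, "T" * 600, ids=["cand", "par", "out"])
        res = maxchi_scan("cand", "par", aln, k=30, n_permutations=400, seed=3)
        assert res.computable
        assert res.p_value > 0.05

    def test_too_few_variable_sites_flagged(self):
        aln = make_aln("AAAA", "AAAT", "AAAA", ids=["cand", "par", "out"])
        res = maxchi_scan("cand", "par", aln, k=30, n_permutations=10, seed=0)
        assert not res.computable

    def test_permutation_p_matches_exhaustive_on_tiny_labels(self):
        # 10 variable sites, 5 mismatches: 252 distinct label arrangements
        cand = "A" * 10
        parent = "A" * 5 + "C" * 5
        aln = make_aln(cand, parent, "G" * 10, ids=["cand", "par", "out"])
        k = 3
        res = maxchi_scan("cand", "par", aln, k=k, n_permutations=3000, seed=7)

        def max_chi_of(labels):
            y = np.array(labels, dtype=np.int64)
            cs = np.concatenate([[0], np.cumsum(y)])
            best = 0.0
            for j in range(k, 10 - k + 1):
                lm, rm = cs[j] - cs[j - k], cs[j + k] - cs[j]
                a, b, c, d = k - lm, lm, k - rm, rm
                if (a + c) == 0 or (b + d) == 0:
                    continue
                chi = 2 * k * (a * d - b * c) ** 2 / (k * k * (a + c) * (b + d))
                best = max(best, chi)
            return best

        obs = max_chi_of([0] * 5 + [1] * 5)
        assert res.max_chi == pytest.approx(obs)
        arrangements = [
            max_chi_of([1 if i in pos else 0 for i in range(10)])
            for pos in itertools.combinations(range(10), 5)
        ]
        exact_p = np.mean([m >= obs - 1e-12 for m in arrangements])
        sd = np.sqrt(exact_p * (1 - exact_p) / 3000)
        assert abs(res.p_value - exact_p) < 3 * sd + 1 / 3000


class TestTripletScan:
    def test_candidate_identical_to_parent_a(self):
        rng = np.random.default_rng(19)
        a = "".join(rng.choice(list("ACGT"), 500))
        b = "".join(
            c if rng.random() > 0.2 else "ACGT"[("ACGT".index(c) + 1) % 4] for c in a
        )
        aln = make_aln(a, a, b, ids=["cand", "pa", "pb"])
        scan = triplet_scan("cand", "pa", "pb", aln)
        assert set(scan.calls) <= {"A", "tie"}
        assert scan.segments() == []

    def test_planted_fragment_yields_single_donor_run(self, mimic_dataset):
        _, aln, truth = mimic_dataset
        scan = triplet_scan("A5", "A1", "C1", aln)
        segs = scan.segments()
        t = next(e for e in truth.events if e.recipient == "A5")
        hits = [(s, e) for s, e in segs if s <= t.end and e >= t.begin]
        assert len(hits) == 1  # exactly one run on the planted interval
        s, e = hits[0]
        assert s <= t.begin + scan.window and e >= t.end - scan.window
        # anything else is window-scale noise, not a donor-sized run
        for s, e in segs:
            if (s, e) not in hits:
                assert e - s + 1 <= 2 * scan.window

    def test_requires_distinct_ids(self, mimic_dataset):
        _, aln, _ = mimic_dataset
        with pytest.raises(ConfigurationError):
            triplet_scan("A1", "A1", "B1", aln)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expect",
        [(0.01, 1, 0.01), (0.01, 200, 1.0), (2.2e-16, 6, 1.32e-15)],
    )
    def test_values(self, p, m, expect):
        assert bonferroni(p, m) == pytest.approx(expect)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bonferroni(0.0, 3)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestCallEvents:
    def test_clean_candidates_produce_no_events(self, mimic_dataset):
        config, aln, _ = mimic_dataset
        events = call_events(
            aln, ["A1", "A2"], config.groups(),
            RecombConfig(seed=4, phi_permutations=500),
        )
        assert events == []

    def test_recovers_planted_events_with_parents(self, mimic_dataset):
        config, aln, truth = mimic_dataset
        events = call_events(
            aln, [f"A{k}" for k in range(1, 6)], config.groups(),
            RecombConfig(seed=4, phi_permutations=500),
        )
        per_genome = {}
        for ev in events:
            per_genome.setdefault(ev.recombinant_id, []).append(ev)
        assert {k: len(v) for k, v in per_genome.items()} == {"A3": 3, "A4": 1, "A5": 1}
        for ev in events:
            t = next(
                t for t in truth.events
                if t.recipient == ev.recombinant_id
                and ev.begin <= t.end and ev.end >= t.begin
            )
            assert ev.minor_parent_id == t.donor_id
            assert ev.major_parent_id in {"A1", "A2"}

    def test_events_satisfy_minor_closer_within_segment(self, mimic_dataset):
        config, aln, _ = mimic_dataset
        events = call_events(
            aln, [f"A{k}" for k in range(1, 6)], config.groups(),
            RecombConfig(seed=4, phi_permutations=500),
        )
        from mtmosaic.alignio import RegionSpec, extract_region
        from mtmosaic import p_distance

        for ev in events:
            sub = extract_region(aln, RegionSpec(ev.begin, ev.end))
            d_minor = p_distance(
                sub[ev.recombinant_id], sub[ev.minor_parent_id], n_bootstrap=0
            ).value
            d_major = p_distance(
                sub[ev.recombinant_id], sub[ev.major_parent_id], n_bootstrap=0
            ).value
            assert d_minor < d_major

    def test_missing_reference_group_is_configuration_error(self, mimic_dataset):
        config, aln, _ = mimic_dataset
        groups = {f"A{k}": "A" for k in range(1, 6)}  # no donor-group references
        with pytest.raises(ConfigurationError, match="group"):
            call_events(aln, ["A3"], groups, RecombConfig(seed=0))
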