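"""SNP calling, centroid algebra, clustering, inconsistent pairs."""

import numpy as np
import pytest

from diphase.overlap import Overlap
from diphase.phase import (
    AlleleMatrix,
    Centroid,
    GroupingParams,
    Placement,
    SnpCallParams,
    SnpSite,
    call_het_sites,
    call_read_alleles,
    centroid_sets,
    combine_subgroups,
    divide_group,
    find_inconsistent_pairs,
    map_reads_to_contigs,
    mark_inconsistent_overlaps,
    snp_agreement_counts,
    verify_correct_alleles,
)


def _matrix(H, positions=None, contig="ctg", placements=None):
    H = np.asarray(H, dtype=np.int8)
    n_reads, n_sites = H.shape
    names = [f"r{i}" for i in range(n_reads)]
    positions = positions or list(range(0, 100 * n_sites, 100))
    sites = [SnpSite(contig, p, "A", "C") for p in positions]
    return AlleleMatrix(names, sites, H, placements or {})


def _two_hap_matrix(n_per_hap=10, n_sites=10, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    H = np.zeros((2 * n_per_hap, n_sites), dtype=np.int8)
    H[:n_per_hap] = 1
    H[n_per_hap:] = 2
    if noise:
        flip = rng.random(H.shape) < noise
        H[flip] = 3 - H[flip]
    return _matrix(H)


class TestHetSiteCalling:
    def _pileup_matrix(self, cov, second):
        """A single contig column with `cov` reads, `second` of them carrying
        the alternative base."""
        contig = "A" * 200
        reads, placements = {}, {}
        for i in range(cov):
            base = "C" if i < second else "A"
            seq = "A" * 50 + base + "A" * 49
            reads[f"r{i}"] = seq
            placements[f"r{i}"] = [
                Placement(f"r{i}", "ctg", 40, 140,
                          "+", "50=1X49=" if base == "C" else "100=")
            ]
        return {"ctg": contig}, placements, reads

    @pytest.mark.parametrize(
        "cov,second,expect_site",
        [
            (10, 4, True),    # threshold 0.4*10 = 4
            (10, 3, False),
            (50, 12, True),   # threshold ~11.1
            (50, 11, False),
            (8, 4, False),    # coverage below 10
        ],
    )
    def test_piecewise_threshold(self, cov, second, expect_site):
        contigs, placements, reads = self._pileup_matrix(cov, second)
        sites = call_het_sites(contigs, placements, reads, SnpCallParams())
        at_90 = [s for s in sites if s.position == 90]
        assert bool(at_90) == expect_site

    def test_allele_order_is_frequency_order(self):
        contigs, placements, reads = self._pileup_matrix(20, 8)
        (site,) = [
            s for s in call_het_sites(contigs, placements, reads)
            if s.position == 90
        ]
        assert site.allele1 == "A" and site.allele2 == "C"


class TestReadAlleles:
    def test_h_definition(self):
        contig = "ACGT" * 50
        site = SnpSite("ctg", 100, contig[100], "T" if contig[100] != "T" else "G")
        reads = {
            "match1": contig[50:150],
            "match2": contig[50:100] + site.allele2 + contig[101:150],
            "third": contig[50:100] + ("C" if site.allele2 != "C" and contig[100] != "C" else "A") + contig[101:150],
            "away": contig[150:200],
        }
        placements = {
            "match1": [Placement("match1", "ctg", 50, 150, "+", "100=")],
            "match2": [Placement("match2", "ctg", 50, 150, "+", "50=1X49=")],
            "third": [Placement("third", "ctg", 50, 150, "+", "50=1X49=")],
            "away": [Placement("away", "ctg", 150, 200, "+", "50=")],
        }
        m = call_read_alleles(placements, [site], reads)
        assert m.H[m.row["match1"], 0] == 1
        assert m.H[m.row["match2"], 0] == 2
        assert m.H[m.row["third"], 0] == 0   # neither allele
        assert m.H[m.row["away"], 0] == 0    # not covering


class TestCentroidAlgebra:
    def test_identical_centroids_all_same(self):
        m = _two_hap_matrix()
        c = Centroid.of(m.H, np.arange(5))
        a, s, d = centroid_sets(c, c, 0.0, 1.0)
        assert d.sum() == 0
        assert a.sum() == s.sum() == m.H.shape[1]

    def test_opposite_sign_in_d(self):
        c1 = Centroid(np.array([5]), np.array([5]))
        c2 = Centroid(np.array([-5]), np.array([5]))
        a, s, d = centroid_sets(c1, c2, 0.0, 0.0)
        assert d[0] and a[0] and not s[0]

    def test_vote_threshold_excludes_weak_sites(self):
        c = Centroid(np.array([2]), np.array([10]))
        assert not c.v_ne(0.3, 0.0)[0]  # |2| < 0.3*10
        assert c.v_ne(0.1, 0.0)[0]


class TestClustering:
    def test_separated_haplotypes_split_cleanly(self):
        m = _two_hap_matrix(n_per_hap=10, n_sites=10)
        leaves = divide_group(np.arange(20), m.H, GroupingParams(),
                              np.random.default_rng(0))
        parts = [frozenset(l.tolist()) for l in leaves]
        assert frozenset(range(10)) in parts
        assert frozenset(range(10, 20)) in parts

    def test_homogeneous_group_is_leaf(self):
        H = np.ones((8, 6), dtype=np.int8)
        leaves = divide_group(np.arange(8), H, GroupingParams(),
                              np.random.default_rng(0))
        assert len(leaves) == 1

    def test_tiny_group_is_leaf(self):
        m = _two_hap_matrix(3, 5)
        leaves = divide_group(np.arange(3), m.H, GroupingParams(),
                              np.random.default_rng(0))
        assert len(leaves) == 1

    def test_combine_single_leaf(self):
        m = _two_hap_matrix()
        L = combine_subgroups([np.arange(10)], 0, m.H, GroupingParams())
        assert len(L) == 1

    def test_combine_rejoins_split_haplotype(self):
        m = _two_hap_matrix(10, 10)
        # artificially split hap-1 into two leaves; combine must rejoin them
        leaves = [np.arange(5), np.arange(5, 10), np.arange(10, 20)]
        L = combine_subgroups(leaves, 0, m.H, GroupingParams())
        assert sorted(L[0].tolist()) == list(range(10))
        assert len(L) == 2

    def test_cluster_recovery_under_noise(self):
        """>= 0.9 agreement with the truth partition at 5% allele noise."""
        m = _two_hap_matrix(n_per_hap=12, n_sites=12, noise=0.05, seed=3)
        leaves = divide_group(np.arange(24), m.H, GroupingParams(),
                              np.random.default_rng(0))
        L = combine_subgroups(leaves, 0, m.H, GroupingParams())
        got = np.zeros(24, dtype=int)
        for gi, g in enumerate(L):
            got[g] = gi
        truth = np.array([0] * 12 + [1] * 12)
        same = max(
            (got == truth).mean(), (got == 1 - truth).mean()
        )
        assert same >= 0.9


class TestVerifyCorrect:
    def test_isolated_flip_corrected(self):
        m = _two_hap_matrix(10, 10)
        m.H[0, 4] = 2  # one error in read 0
        out = verify_correct_alleles(m, GroupingParams(), seed=0)
        assert out.H[0, 4] == 1

    def test_noise_free_matrix_is_fixpoint(self):
        m = _two_hap_matrix(10, 10)
        out = verify_correct_alleles(m, GroupingParams(), seed=0)
        assert np.array_equal(out.H, m.H)

    def test_accuracy_improves_monotonically(self):
        rng = np.random.default_rng(9)
        m = _two_hap_matrix(15, 14, noise=0.08, seed=9)
        truth = np.zeros_like(m.H)
        truth[:15] = 1
        truth[15:] = 2
        accs = [np.mean(m.H == truth)]
        p = GroupingParams(verify_rounds=1)
        cur = m
        for _ in range(2):
            cur = verify_correct_alleles(cur, p, seed=0)
            accs.append(np.mean(cur.H == truth))
        assert accs[1] >= accs[0]
        assert accs[2] >= accs[1]


class TestInconsistentPairs:
    def test_cross_group_pairs_found_and_symmetric(self):
        m = _two_hap_matrix(10, 12)
        pairs = find_inconsistent_pairs(m, GroupingParams(), seed=0)
        assert pairs
        for a, b in pairs:
            ia, ib = m.row[a], m.row[b]
            assert (ia < 10) != (ib < 10)  # only cross-haplotype
            assert a < b  # canonical symmetric storage

    def test_same_haplotype_never_inconsistent(self):
        H = np.ones((12, 10), dtype=np.int8)
        m = _matrix(H)
        assert find_inconsistent_pairs(m, GroupingParams(), seed=0) == set()

    @pytest.mark.parametrize(
        "n_diff,threshold,expected",
        [(7, 8.0, False), (7, 6.0, True), (6, 6.0, True), (5, 6.0, False)],
    )
    def test_diff_threshold_rule(self, n_diff, threshold, expected):
        """Pairs must differ at >= threshold verified sites (strict=8 for
        corrected evidence, loose=6 for raw evidence)."""
        n_sites = 16
        H = np.zeros((20, n_sites), dtype=np.int8)
        H[:10] = 1
        H[10:] = 1
        H[10:, :n_diff] = 2  # second group differs at exactly n_diff sites
        m = _matrix(H)
        pairs = find_inconsistent_pairs(m, GroupingParams(), threshold, seed=0)
        assert bool(pairs) == expected


class TestOverlapMarking:
    def _placed_matrix(self):
        H = np.zeros((2, 10), dtype=np.int8)
        m = _matrix(H)
        return m

    def test_concordant_layout_marks_overlap(self):
        m = self._placed_matrix()
        m.placements = {
            "r0": [Placement("r0", "ctg", 0, 5000, "+", "")],
            "r1": [Placement("r1", "ctg", 2000, 7000, "+", "")],
        }
        ov = Overlap("r0", "r1", "+", 2000, 5000, 0, 3000, 5000, 5000)
        kept, dropped = mark_inconsistent_overlaps({("r0", "r1")}, [ov], m)
        assert dropped == [ov]

    def test_repeat_displaced_overlap_not_marked(self):
        m = self._placed_matrix()
        # layout says the reads are 5 kb further apart than the overlap implies
        m.placements = {
            "r0": [Placement("r0", "ctg", 0, 5000, "+", "")],
            "r1": [Placement("r1", "ctg", 7000, 12000, "+", "")],
        }
        ov = Overlap("r0", "r1", "+", 2000, 5000, 0, 3000, 5000, 5000)
        kept, dropped = mark_inconsistent_overlaps({("r0", "r1")}, [ov], m)
        assert kept == [ov]

    def test_strand_discordance_blocks_marking(self):
        m = self._placed_matrix()
        m.placements = {
            "r0": [Placement("r0", "ctg", 0, 5000, "+", "")],
            "r1": [Placement("r1", "ctg", 2000, 7000, "-", "")],
        }
        ov = Overlap("r0", "r1", "+", 2000, 5000, 0, 3000, 5000, 5000)
        kept, dropped = mark_inconsistent_overlaps({("r0", "r1")}, [ov], m)
        assert kept == [ov]

    def test_unplaced_reads_skip_distance_check(self):
        m = self._placed_matrix()
        ov = Overlap("r0", "r1", "+", 2000, 5000, 0, 3000, 5000, 5000)
        kept, dropped = mark_inconsistent_overlaps({("r0", "r1")}, [ov], m)
        assert dropped == [ov]


class TestAgreementCounts:
    def test_counts_shared_sites(self):
        H = np.array([[1, 1, 2, 0], [1, 2, 2, 1]], dtype=np.int8)
        m = _matrix(H)
        ov = Overlap("r0", "r1", "+", 0, 100, 0, 100, 100, 100)
        counts = snp_agreement_counts(m, [ov])
        assert counts[("r0", "r1")] == (2, 1)


class TestMapping:
    def test_secondary_placements_on_duplicated_reference(self, rng):
        seg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        contig = seg + spacer + seg  # two identical instances
        read = seg[500:1500]
        pls = map_reads_to_contigs({"q": read}, {"c": contig})
        assert len(pls["q"]) == 2
        starts = sorted(p.start for p in pls["q"])
        assert abs(starts[0] - 500) < 50
        assert abs(starts[1] - 5500) < 50


class TestRawEvidenceMerge:
    def test_absent_raw_evidence_equals_strict_corrected_pass(self):
        from diphase.phase import merge_raw_snp_evidence

        m = _two_hap_matrix(10, 12)
        p = GroupingParams()
        strict, loose = merge_raw_snp_evidence(m, None, p, seed=0)
        assert loose == set()
        assert strict == find_inconsistent_pairs(m, p, p.strict_diff, seed=0)
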