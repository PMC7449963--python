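import itertools
import warnings

import numpy as np
import pytest

from fpk.bindetect import (
    BindingSite,
    classify_bound,
    differential_binding,
    normalize_scores,
    scan_motifs,
    score_sites,
    site_log2fc,
)
from fpk.core import CutsiteTrack, GenomicInterval
from fpk.motifs import MotifModel


def brute_force_scan(motif, genome, region):
    """Oracle: score every position and strand by explicit loops, then apply
    the same keep-highest overlap resolution."""
    seq = genome[region.chrom][region.start : region.end]
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = motif.length
    hits = {"+": [], "-": []}
    for strand in "+-":
        mat = motif.logodds if strand == "+" else motif.logodds_rc()
        for i in range(len(seq) - L + 1):
            kmer = seq[i : i + L]
            if "N" in kmer:
                continue
            s = sum(mat[code[b], j] for j, b in enumerate(kmer))
            if s >= motif.threshold:
                hits[strand].append((i, s))
    out = []
    for strand, matches in hits.items():
        taken = []
        for start, s in sorted(matches, key=lambda m: (-m[1], m[0])):
            if all(start + L <= t or t + L <= start for t, _ in taken):
                taken.append((start, s))
        out.extend((region.start + t, strand) for t, _ in taken)
    return sorted(out)


class TestScanMotifs:
    def test_forward_consensus_match(self):
        m = MotifModel.from_consensus("TAAT", "TAAT")
        sites = scan_motifs([m], {"c": "GGGGTAATGGGG"}, [GenomicInterval("c", 0, 12)])
        assert [(s.interval.start, s.interval.strand) for s in sites] == [(4, "+")]

    def test_reverse_complement_match(self):
        m = MotifModel.from_consensus("TAAT", "TAAT")
        sites = scan_motifs([m], {"c": "GGGGATTAGGGG"}, [GenomicInterval("c", 0, 12)])
        assert [(s.interval.start, s.interval.strand) for s in sites] == [(4, "-")]

    def test_motif_longer_than_region_skipped(self):
        m = MotifModel.from_consensus("X", "TAATGATTAG")
        assert scan_motifs([m], {"c": "ACGTAC"}, [GenomicInterval("c", 0, 6)]) == []

    def test_matches_brute_force_oracle(self, rng):
        """Production scanner reproduces the exhaustive positional scan
        exactly for short motifs on kb-scale sequence."""
        genome = {"c": "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))}
        region = GenomicInterval("c", 0, 2000)
        for seed in range(3):
            r2 = np.random.default_rng(seed)
            pfm = r2.integers(1, 40, size=(4, 7)).astype(float)
            m = MotifModel(f"M{seed}", "M", pfm)
            got = sorted(
                (s.interval.start, s.interval.strand)
                for s in scan_motifs([m], genome, [region])
            )
            assert got == brute_force_scan(m, genome, region)

    def test_match_rate_calibrated_to_pvalue(self, rng):
        """On i.i.d. random sequence the per-position per-strand match rate
        agrees with the exhaustively enumerated tail probability within 3
        binomial standard deviations."""
        pfm = rng.integers(1, 60, size=(4, 9)).astype(float)
        m = MotifModel("M", "M", pfm)
        scores = np.array(
            [
                sum(m.logodds[b, j] for j, b in enumerate(k))
                for k in itertools.product(range(4), repeat=9)
            ]
        )
        fpr = float(np.mean(scores >= m.threshold))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000))
        sites = scan_motifs([m], {"c": seq}, [GenomicInterval("c", 0, 100_000)])
        n_pos = 2 * (100_000 - 8)
        sd = np.sqrt(fpr * (1 - fpr) / n_pos)
        assert abs(len(sites) / n_pos - fpr) < 3 * sd


class TestScoreSites:
    def _site(self, start=10, end=13):
        return BindingSite(GenomicInterval("chr1", start, end), "M", 1.0)

    def test_max_within_site(self):
        tr = CutsiteTrack(GenomicInterval("chr1", 10, 13), [0, 5, 0], kind="footprint")
        (s,) = score_sites([self._site()], {"c1": [tr]}, agg_window=0)
        assert s.scores["c1"] == 5.0

    def test_zero_track_zero_score(self):
        tr = CutsiteTrack(GenomicInterval("chr1", 0, 50), np.zeros(50), kind="footprint")
        (s,) = score_sites([self._site()], {"c1": [tr]})
        assert s.scores["c1"] == 0.0

    def test_site_outside_all_regions_flagged(self):
        tr = CutsiteTrack(GenomicInterval("chr1", 100, 150), np.ones(50), kind="footprint")
        (s,) = score_sites([self._site()], {"c1": [tr]})
        assert s.scores["c1"] == 0.0 and s.outside_scored_region

    def test_missing_condition_track_errors(self):
        t1 = CutsiteTrack(GenomicInterval("chr1", 0, 50), np.ones(50), kind="footprint")
        t2 = CutsiteTrack(GenomicInterval("chr2", 0, 50), np.ones(50), kind="footprint")
        with pytest.raises(ValueError, match="no score track"):
            score_sites([self._site()], {"c1": [t1], "c2": [t2]})


class TestNormalizeScores:
    def _sites(self, a, b):
        sites = []
        for i, (x, y) in enumerate(zip(a, b)):
            s = BindingSite(GenomicInterval("chr1", 10 * i + 1, 10 * i + 5), "M", 0.0)
            s.scores = {"c1": float(x), "c2": float(y)}
            sites.append(s)
        return sites

    def test_identical_multisets_map_to_same_values(self):
        a = [3.0, 1.0, 2.0, 5.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sites = normalize_scores(self._sites(a, a[::-1]), ["c1", "c2"])
        m1 = sorted(s.norm_scores["c1"] for s in sites)
        m2 = sorted(s.norm_scores["c2"] for s in sites)
        np.testing.assert_allclose(m1, m2)

    def test_constant_shift_removed(self):
        a = [1.0, 4.0, 2.0, 9.0]
        b = [x + 3 for x in a]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sites = normalize_scores(self._sites(a, b), ["c1", "c2"])
        for s in sites:
            assert s.norm_scores["c1"] == pytest.approx(s.norm_scores["c2"])

    def test_condition_means_equalized(self, rng):
        a, b = rng.random(2000) * 4, rng.lognormal(0, 1, 2000)
        sites = normalize_scores(self._sites(a, b), ["c1", "c2"])
        m1 = np.mean([s.norm_scores["c1"] for s in sites])
        m2 = np.mean([s.norm_scores["c2"] for s in sites])
        assert abs(m1 - m2) < 1e-9

    def test_single_condition_identity(self):
        sites = normalize_scores(self._sites([1.0, 2.0], [0.0, 0.0]), ["c1"])
        assert [s.norm_scores["c1"] for s in sites] == [1.0, 2.0]


class TestClassifyBound:
    def test_identical_scores_degenerate_all_unbound(self):
        labels, thr = classify_bound(np.full(200, 3.0))
        assert not labels.any() and thr is None

    def test_two_point_mixture_exact_split(self):
        scores = np.concatenate([np.full(700, 0.1), np.full(300, 5.0)])
        labels, thr = classify_bound(scores, random_state=0)
        assert 0.1 < thr <= 5.0
        assert labels.sum() == 300

    def test_below_min_sites_all_unbound(self):
        with pytest.warns(UserWarning, match="unbound"):
            labels, thr = classify_bound(np.arange(10.0))
        assert not labels.any()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_bound(np.array([1.0, np.nan] + [0.0] * 60))

    @pytest.mark.parametrize("bf", [0.1, 0.3, 0.5])
    def test_mixture_fraction_recovery(self, bf):
        rng = np.random.default_rng(17)
        n = 2000
        nb = rng.binomial(n, bf)
        scores = np.concatenate(
            [rng.lognormal(0, 0.4, n - nb) * 0.5, rng.lognormal(1.6, 0.4, nb)]
        )
        labels, _ = classify_bound(scores, random_state=0)
        assert abs(labels.mean() - bf) <= 0.05


def _cohort(rng, n_motifs=30, n_sites=80, shift_motif=None, shift=0.0):
    sites = []
    for m in range(n_motifs):
        mid = f"M{m:02d}"
        sc = rng.normal(5, 1.5, size=(n_sites, 2))
        if mid == shift_motif:
            sc[:, 1] += shift
        for i in range(n_sites):
            s = BindingSite(
                GenomicInterval("chr1", 1000 * m + 10 * i + 1, 1000 * m + 10 * i + 9),
                mid,
                0.0,
            )
            s.norm_scores = {"c1": float(sc[i, 0]), "c2": float(sc[i, 1])}
            sites.append(s)
    return sites


class TestDifferentialBinding:
    def test_equal_conditions_give_zero_scores(self, rng):
        sites = _cohort(rng, n_motifs=5)
        for s in sites:
            s.norm_scores["c2"] = s.norm_scores["c1"]
        with pytest.warns(UserWarning, match="zero background"):
            res = differential_binding(sites, ("c1", "c2"), seed=0)
        assert all(r.differential_score == 0 and r.p_value == 1.0 for r in res)

    def test_shifted_motif_dominates_volcano(self, rng):
        sites = _cohort(rng, shift_motif="M03", shift=4.5)
        res = differential_binding(sites, ("c1", "c2"), seed=0)
        by_id = {r.motif_id: r for r in res}
        top = max(res, key=lambda r: abs(r.differential_score))
        assert top.motif_id == "M03" and top.p_value < 0.01
        null_ps = [r.p_value for r in res if r.motif_id != "M03"]
        assert np.mean([p > 0.05 for p in null_ps]) >= 0.9

    def test_same_seed_reproducible(self, rng):
        sites = _cohort(rng, n_motifs=8)
        r1 = differential_binding(sites, ("c1", "c2"), seed=5)
        r2 = differential_binding(sites, ("c1", "c2"), seed=5)
        assert [r.p_value for r in r1] == [r.p_value for r in r2]

    def test_permuted_labels_approximately_calibrated(self):
        """With exchangeable condition labels, at most ~10% of motifs reach
        p < 0.05 across seeds."""
        rng = np.random.default_rng(99)
        fracs = []
        for rep in range(5):
            sites = _cohort(rng)
            res = differential_binding(sites, ("c1", "c2"), seed=rep)
            fracs.append(np.mean([r.p_value < 0.05 for r in res]))
        assert np.mean(fracs) <= 0.10


class TestSiteLog2FC:
    def _site(self, s1, s2):
        s = BindingSite(GenomicInterval("chr1", 1, 9), "M", 0.0)
        s.norm_scores = {"c1": s1, "c2": s2}
        return s

    @pytest.mark.parametrize(
        "s1,s2,expected", [(2, 8, np.log2(3)), (4, 4, 0.0), (0, 0, 0.0)]
    )
    def test_values(self, s1, s2, expected):
        assert site_log2fc(self._site(s1, s2), "c1", "c2") == pytest.approx(expected)
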