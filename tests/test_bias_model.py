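import numpy as np
import pytest

from fpk.bias_model import (
    BiasModel,
    calibrate_scale,
    correct_regions,
    correct_track,
    estimate_bias,
    expected_track,
    score_sequence_bias,
)
from fpk.core import CutEvent, CutsiteTrack, GenomicInterval
from fpk.formats_io import fragments_to_cutsites
from fpk.motifs import encode_sequence


def random_genome(rng, n=100_000):
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))}


class TestEstimateBias:
    def test_uniform_events_match_background(self, rng):
        """Events placed uniformly carry no sequence preference: the event
        and background dinucleotide matrices agree cell-wise."""
        genome = random_genome(rng)
        regions = [GenomicInterval("chr1", 0, 100_000)]
        events = [CutEvent("chr1", int(p)) for p in rng.integers(50, 99_950, 50_000)]
        model = estimate_bias(events, genome, regions)
        assert np.abs(model.dinuc_probs - model.background_probs).max() < 0.02

    def test_degenerate_ta_placement(self, rng):
        """Events always centered on a TA dinucleotide concentrate the
        center offset's probability mass on TA."""
        genome = random_genome(rng, 50_000)
        codes = encode_sequence(genome["chr1"])
        # TA = T then A -> codes 3,0; center offset of a k=20 window is
        # the dinucleotide starting at pos-1 (offsets 0..18, center r=9)
        ta_pos = [
            int(i) + 1
            for i in np.nonzero((codes[:-1] == 3) & (codes[1:] == 0))[0]
            if 30 < i < 49_950
        ]
        events = [CutEvent("chr1", p) for p in ta_pos[:5000]]
        model = estimate_bias(events, genome, [GenomicInterval("chr1", 0, 50_000)])
        ta_code = 4 * 3 + 0
        assert model.dinuc_probs[9, ta_code] > 0.95

    def test_no_events_in_regions_rejected(self, rng):
        genome = random_genome(rng, 1000)
        with pytest.raises(ValueError, match="no events"):
            estimate_bias(
                [CutEvent("chr1", 900)], genome, [GenomicInterval("chr1", 0, 100)]
            )

    def test_seeded_background_subsample_deterministic(self, rng):
        genome = random_genome(rng, 20_000)
        events = [CutEvent("chr1", int(p)) for p in rng.integers(50, 19_950, 2000)]
        regions = [GenomicInterval("chr1", 0, 20_000)]
        m1 = estimate_bias(events, genome, regions, bg_sample=5000, seed=7)
        m2 = estimate_bias(events, genome, regions, bg_sample=5000, seed=7)
        np.testing.assert_array_equal(m1.background_probs, m2.background_probs)

    def test_parameter_recovery_from_simulator(self, default_sim):
        """The DWM recovered from simulated events correlates with the
        implanted truth on log-ratio cells."""
        sim = default_sim
        chrom_sizes = {c: len(s) for c, s in sim.genome.items()}
        events = fragments_to_cutsites(sim.fragments["cond1"], chrom_sizes=chrom_sizes)
        model = estimate_bias(events, sim.genome, sim.peaks)
        rec = np.log(model.dinuc_probs / model.background_probs).ravel()
        true = np.log(sim.bias_model.dinuc_probs / sim.bias_model.background_probs).ravel()
        assert np.corrcoef(rec, true)[0, 1] > 0.9


class TestScoreSequenceBias:
    def test_identity_model_gives_unit_weights(self, rng):
        genome = random_genome(rng, 1000)
        track = score_sequence_bias(
            BiasModel.identity(), genome, GenomicInterval("chr1", 100, 200)
        )
        np.testing.assert_allclose(track.values, 1.0)

    def test_single_offset_hand_product(self, rng):
        """A model favoring TA 2:1 at one offset scores exactly 2 at
        TA-centered positions and 1 elsewhere (hand-computed product)."""
        k = 4
        flat = np.full((k - 1, 16), 1.0 / 16)
        dinuc = flat.copy()
        ta = 4 * 3 + 0
        # row 1 (the dinucleotide starting at the insertion point):
        # double TA's probability, renormalize the rest
        dinuc[1] = (1 - 2 / 17) / 15
        dinuc[1, ta] = 2 / 17
        bg = flat.copy()
        bg[1] = (1 - 1 / 17) / 15
        bg[1, ta] = 1 / 17
        model = BiasModel(window=k, dinuc_probs=dinuc, background_probs=bg)
        genome = {"chr1": "GGGGTAGGGG"}
        track = score_sequence_bias(model, genome, GenomicInterval("chr1", 2, 8))
        # window [p-2, p+2); offset-1 dinucleotide starts at p-1: TA at p=5.
        # Hand product: TA cell ratio (2/17)/(1/17) = 2; every other cell
        # ratio ((1-2/17)/15)/((1-1/17)/15) = 15/16 (renormalization).
        expected = np.full(6, 15 / 16)
        expected[3] = 2.0
        np.testing.assert_allclose(track.values, expected)

    def test_log_space_matches_direct_product_oracle(self, rng):
        """Vectorized log-space scoring equals a direct per-position
        probability product within 1e-10 relative."""
        k = 8
        raw = rng.random((k - 1, 16)) + 0.5
        dinuc = raw / raw.sum(axis=1, keepdims=True)
        raw2 = rng.random((k - 1, 16)) + 0.5
        bg = raw2 / raw2.sum(axis=1, keepdims=True)
        mono_raw = rng.random((k, 4)) + 0.5
        mono = mono_raw / mono_raw.sum(axis=1, keepdims=True)
        model = BiasModel(
            window=k, dinuc_probs=dinuc, background_probs=bg, mono_probs=mono
        )
        genome = random_genome(rng, 300)
        region = GenomicInterval("chr1", 50, 250)
        track = score_sequence_bias(model, genome, region)
        codes = encode_sequence(genome["chr1"])
        for i, pos in enumerate(range(region.start, region.end)):
            window = codes[pos - k // 2 : pos + k // 2]
            w = 1.0
            for r in range(k - 1):
                d = 4 * window[r] + window[r + 1]
                w *= dinuc[r, d] / bg[r, d]
            for j in range(1, k - 1):
                w /= mono[j, window[j]] / 0.25
            assert abs(track.values[i] - w) / w < 1e-10

    def test_n_window_gets_background_weight(self):
        model = BiasModel.identity(4)
        model.dinuc_probs = model.dinuc_probs * 0 + np.tile(
            np.linspace(0.01, 0.115, 16), (3, 1)
        )
        model.dinuc_probs /= model.dinuc_probs.sum(axis=1, keepdims=True)
        genome = {"chr1": "GGGNGGGG"}
        track = score_sequence_bias(model, genome, GenomicInterval("chr1", 2, 6))
        # every 4-wide window here touches the N at index 3 except pos 5
        assert track.values[0] == 1.0 and track.values[1] == 1.0


class TestExpectedAndCorrected:
    def test_proportional_allocation(self):
        region = GenomicInterval("chr1", 0, 2)
        obs = CutsiteTrack(region, [5, 3])
        bias = CutsiteTrack(region, [3, 1], kind="bias")
        exp = expected_track(obs, bias)
        np.testing.assert_allclose(exp.values, [6, 2])

    def test_flat_bias_flat_expectation(self):
        region = GenomicInterval("chr1", 0, 4)
        obs = CutsiteTrack(region, [4, 0, 0, 0])
        bias = CutsiteTrack(region, np.ones(4), kind="bias")
        np.testing.assert_allclose(expected_track(obs, bias).values, 1.0)

    def test_zero_observed_zero_expected(self):
        region = GenomicInterval("chr1", 0, 3)
        exp = expected_track(
            CutsiteTrack(region, np.zeros(3)), CutsiteTrack(region, np.ones(3), kind="bias")
        )
        assert exp.values.sum() == 0

    def test_conservation_on_random_inputs(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            region = GenomicInterval("chr1", 0, n)
            obs = CutsiteTrack(region, rng.poisson(3, n).astype(float))
            bias = CutsiteTrack(region, rng.random(n) + 0.1, kind="bias")
            exp = expected_track(obs, bias)
            assert abs(exp.total - obs.total) <= 1e-6 * max(obs.total, 1)
            corr = correct_track(obs, exp)
            assert abs(corr.total) <= 1e-6 * n

    def test_observed_equals_expected_gives_zero(self):
        region = GenomicInterval("chr1", 0, 4)
        obs = CutsiteTrack(region, [2, 2, 2, 2])
        exp = CutsiteTrack(region, np.full(4, 2.0), kind="expected")
        np.testing.assert_allclose(correct_track(obs, exp).values, 0.0)

    def test_simple_subtraction(self):
        region = GenomicInterval("chr1", 0, 2)
        corr = correct_track(
            CutsiteTrack(region, [4, 0]),
            CutsiteTrack(region, np.array([2.0, 2.0]), kind="expected"),
        )
        np.testing.assert_allclose(corr.values, [2, -2])


class TestCorrectRegions:
    def test_bundle_conservation_and_shared_region(self, default_sim):
        sim = default_sim
        chrom_sizes = {c: len(s) for c, s in sim.genome.items()}
        events = fragments_to_cutsites(sim.fragments["cond1"], chrom_sizes=chrom_sizes)
        model, bundles = correct_regions(events, sim.genome, sim.peaks, seed=0)
        for b in bundles[:20]:
            assert b.observed.region == b.corrected.region
            assert abs(b.expected.total - b.observed.total) <= 1e-6 * max(
                b.observed.total, 1
            )
            assert abs(b.corrected.total) <= 1e-6 * len(b.region)

    def test_scoring_track_restores_baseline(self, default_sim):
        sim = default_sim
        chrom_sizes = {c: len(s) for c, s in sim.genome.items()}
        events = fragments_to_cutsites(sim.fragments["cond1"], chrom_sizes=chrom_sizes)
        _, bundles = correct_regions(events, sim.genome, sim.peaks, seed=0)
        b = bundles[0]
        assert b.scoring_track().values.mean() == pytest.approx(
            b.observed.values.mean()
        )


def test_bias_model_json_roundtrip(tmp_path, rng):
    raw = rng.random((19, 16)) + 0.5
    model = BiasModel(
        window=20,
        dinuc_probs=raw / raw.sum(axis=1, keepdims=True),
        background_probs=np.full((19, 16), 1 / 16),
        scale=0.93,
    )
    p = tmp_path / "m.json"
    model.to_json(p)
    back = BiasModel.from_json(p)
    np.testing.assert_allclose(back.dinuc_probs, model.dinuc_probs)
    assert back.scale == model.scale
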