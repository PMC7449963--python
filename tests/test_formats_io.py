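import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fpk.core import CutEvent, CutsiteTrack, GenomicInterval, merge_intervals
from fpk.formats_io import (
    fragments_to_cutsites,
    pileup,
    read_bed,
    read_bedgraph,
    read_fasta,
    read_jaspar,
    write_bedgraph,
    write_jaspar,
)
from fpk.motifs import MotifModel


class TestReadFasta:
    @pytest.mark.parametrize(
        "content,expected",
        [
            (">chr1\nACGT\n", {"chr1": "ACGT"}),
            (">a\nacg\nt\n>b\nNN\n", {"a": "ACGT", "b": "NN"}),
        ],
    )
    def test_parses_records(self, tmp_path, content, expected):
        p = tmp_path / "g.fa"
        p.write_text(content)
        assert read_fasta(p) == expected

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nACGT\n>a\nTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_invalid_chars_mapped_or_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nACXT\n")
        assert read_fasta(p) == {"a": "ACNT"}
        with pytest.raises(ValueError):
            read_fasta(p, on_invalid="error")


class TestReadBed:
    def test_bed3_and_bed6(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t10\t20\nchr1\t10\t20\tx\t0\t-\n")
        ivs = read_bed(p)
        assert ivs[0] == GenomicInterval("chr1", 10, 20)
        assert ivs[1].strand == "-"

    @pytest.mark.parametrize("line", ["chr1\t20\t10", "chr1\tten\t20"])
    def test_bad_coordinates_name_the_line(self, tmp_path, line):
        p = tmp_path / "x.bed"
        p.write_text(line + "\n")
        with pytest.raises(ValueError, match=":1"):
            read_bed(p)


class TestFragmentsToCutsites:
    def test_default_shifts(self):
        events = fragments_to_cutsites([GenomicInterval("chr1", 100, 200)])
        assert [(e.pos, e.strand) for e in events] == [(104, "+"), (194, "-")]

    def test_bounds_clipping(self):
        events = fragments_to_cutsites([GenomicInterval("chr1", 0, 3)])
        assert [(e.pos, e.strand) for e in events] == [(4, "+")]  # -3 dropped

    def test_duplicates_kept(self):
        frags = [GenomicInterval("chr1", 100, 200)] * 2
        assert len(fragments_to_cutsites(frags)) == 4

    def test_length_conservation_modulo_clipping(self, rng):
        frags = [
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 500, 200), rng.integers(10, 100, 200))
        ]
        events = fragments_to_cutsites(frags, chrom_sizes={"chr1": 550})
        dropped = 2 * len(frags) - len(events)
        assert dropped >= 0
        assert len(events) + dropped == 2 * len(frags)


class TestPileup:
    def test_counts_events_at_positions(self):
        events = [CutEvent("chr1", 5), CutEvent("chr1", 5), CutEvent("chr1", 7)]
        (track,) = pileup(events, [GenomicInterval("chr1", 0, 10)])
        assert track.values.tolist() == [0, 0, 0, 0, 0, 2, 0, 1, 0, 0]

    def test_no_events_zero_track(self):
        (track,) = pileup([], [GenomicInterval("chr1", 0, 10)])
        assert track.values.sum() == 0

    def test_half_open_boundary(self):
        (track,) = pileup([CutEvent("chr1", 10)], [GenomicInterval("chr1", 0, 10)])
        assert track.values.sum() == 0

    def test_overlapping_regions_rejected(self):
        regions = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 15)]
        with pytest.raises(ValueError, match="merge"):
            pileup([], regions)

    def test_event_conservation(self, rng):
        regions = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 100, 150)]
        events = [CutEvent("chr1", int(p)) for p in rng.integers(0, 200, 500)]
        tracks = pileup(events, regions)
        inside = sum(
            1 for e in events if any(r.contains(e.chrom, e.pos) for r in regions)
        )
        assert sum(t.values.sum() for t in tracks) == inside


class TestBedgraph:
    def test_runs_merged(self, tmp_path):
        track = CutsiteTrack(GenomicInterval("chr1", 0, 3), [1, 1, 0])
        p = tmp_path / "x.bedgraph"
        write_bedgraph([track], p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("track")]
        assert lines == ["chr1\t0\t2\t1", "chr1\t2\t3\t0"]

    def test_empty_track_list(self, tmp_path):
        p = tmp_path / "x.bedgraph"
        write_bedgraph([], p)
        assert p.read_text().startswith("track")

    @settings(max_examples=20, deadline=None)
    @given(values=st.lists(st.integers(0, 9), min_size=1, max_size=60))
    def test_round_trip(self, tmp_path_factory, values):
        tmp = tmp_path_factory.mktemp("bg")
        region = GenomicInterval("chr1", 17, 17 + len(values))
        track = CutsiteTrack(region, np.array(values, dtype=float))
        path = tmp / "t.bedgraph"
        write_bedgraph([track], path)
        (back,) = read_bedgraph(path, [region])
        assert back.region == region
        np.testing.assert_array_equal(back.values, track.values)


class TestJaspar:
    JASPAR = (
        ">MA0001.1\tTOY\n"
        "A  [ 10  0 ]\n"
        "C  [  0 10 ]\n"
        "G  [  0  0 ]\n"
        "T  [  0  0 ]\n"
    )

    def test_single_motif(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(self.JASPAR)
        (m,) = read_jaspar(p)
        assert m.length == 2
        assert m.consensus == "AC"

    def test_missing_row_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text("\n".join(self.JASPAR.splitlines()[:-1]) + "\n")
        with pytest.raises(ValueError):
            read_jaspar(p)

    def test_multi_motif_order_and_roundtrip(self, tmp_path):
        motifs = [
            MotifModel.from_consensus("M1", "TTAACG"),
            MotifModel.from_consensus("M2", "GATTAG"),
        ]
        p = tmp_path / "m.jaspar"
        write_jaspar(motifs, p)
        back = read_jaspar(p)
        assert [m.motif_id for m in back] == ["M1", "M2"]
        np.testing.assert_allclose(back[0].pfm, motifs[0].pfm)


def test_merge_intervals_merges_overlaps_and_bookends():
    merged = merge_intervals(
        [
            GenomicInterval("chr1", 10, 20),
            GenomicInterval("chr1", 15, 30),
            GenomicInterval("chr1", 30, 40),
            GenomicInterval("chr2", 0, 5),
        ]
    )
    assert [(m.chrom, m.start, m.end) for m in merged] == [
        ("chr1", 10, 40),
        ("chr2", 0, 5),
    ]
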