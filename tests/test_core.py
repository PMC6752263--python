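"""Domain types, interval arithmetic, and file round-trips."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvinterp.core import (
    CnvCall,
    GenomeLayout,
    Interval,
    ParseError,
    ValidationError,
    intersection_with_union,
    merge_intervals,
    ploidy_map,
)
from cnvinterp import io as cio


class TestLayout:
    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValidationError):
            GenomeLayout.from_dict({"chr1": 0})

    def test_rejects_duplicate_names(self):
        with pytest.raises(ValidationError):
            GenomeLayout((("chr1", 100), ("chr1", 200)))

    def test_interval_bounds_enforced(self, layout):
        with pytest.raises(ValidationError):
            layout.validate_interval(Interval("chr1", 0, 500_001))
        layout.validate_interval(Interval("chr1", 0, 500_000))  # ok

    def test_ploidy_map_by_sex(self, layout):
        male = ploidy_map(layout, "male")
        female = ploidy_map(layout, "female")
        assert male == {"chr1": 2, "chr2": 2, "chrX": 1, "chrY": 1}
        assert female == {"chr1": 2, "chr2": 2, "chrX": 2, "chrY": 0}


class TestInterval:
    @pytest.mark.parametrize("start,end", [(200, 100), (100, 100), (-1, 50)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValidationError):
            Interval("chr1", start, end)

    @given(
        st.lists(
            st.tuples(st.integers(0, 9_000), st.integers(1, 1_000)),
            min_size=1, max_size=8,
        ),
        st.tuples(st.integers(0, 9_000), st.integers(1, 1_000)),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_arithmetic_matches_per_base_sets(self, regions, query):
        """Interval intersection/union agree with brute-force base sets
        on intervals shorter than 10 kb."""
        ivs = [Interval("c", s, s + l) for s, l in regions]
        q = Interval("c", query[0], query[0] + query[1])
        base_sets = [set(range(iv.start, iv.end)) for iv in ivs]
        union = set().union(*base_sets)
        merged = merge_intervals(ivs)
        assert sum(m.length for m in merged) == len(union)
        assert intersection_with_union(q, ivs) == len(
            union & set(range(q.start, q.end))
        )
        for iv in ivs:
            assert q.intersection_length(iv) == len(
                set(range(q.start, q.end)) & set(range(iv.start, iv.end))
            )

    def test_gap_between_closest_edges(self):
        a, b = Interval("c", 0, 100), Interval("c", 250, 300)
        assert a.gap_to(b) == b.gap_to(a) == 150
        assert a.gap_to(Interval("c", 50, 200)) == 0
        assert a.gap_to(Interval("d", 250, 300)) is None


class TestBedIO:
    def test_read_maps_fields(self, tmp_path, layout):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t200\tGENE_A\n")
        (iv, name), = cio.read_bed(p, layout)
        assert iv == Interval("chr1", 100, 200) and name == "GENE_A"

    def test_inverted_coordinates_rejected_not_shifted(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValidationError):
            cio.read_bed(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\toops\n")
        with pytest.raises(ParseError, match=":2"):
            cio.read_bed(p)

    def test_round_trip_identity(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tGENE_A\nchr2\t0\t50\n")
        records = cio.read_bed(p)
        q = tmp_path / "b.bed"
        cio.write_bed(records, q)
        orig = [ln.rstrip() for ln in p.read_text().splitlines()]
        new = [ln.rstrip() for ln in q.read_text().splitlines()]
        assert orig == new


class TestDepthIO:
    def test_contiguous_bins(self, tmp_path, layout):
        p = tmp_path / "d.bedgraph"
        p.write_text("chr1\t0\t1000\t98\nchr1\t1000\t2000\t101\nchr1\t2000\t3000\t100\n")
        prof = cio.read_depth_bedgraph(p, layout)
        assert prof.n_bins == 3
        assert np.mean(prof.bins["chr1"].values) == pytest.approx(99.6667, abs=1e-3)

    def test_overlapping_bins_rejected(self, tmp_path, layout):
        p = tmp_path / "d.bedgraph"
        p.write_text("chr1\t0\t1000\t10\nchr1\t500\t1500\t10\n")
        with pytest.raises(ValidationError):
            cio.read_depth_bedgraph(p, layout)

    def test_negative_depth_rejected(self, tmp_path, layout):
        p = tmp_path / "d.bedgraph"
        p.write_text("chr1\t0\t1000\t-5\n")
        with pytest.raises(ValidationError):
            cio.read_depth_bedgraph(p, layout)

    def test_empty_file_gives_empty_profile(self, tmp_path, layout, caplog):
        p = tmp_path / "d.bedgraph"
        p.write_text("")
        with caplog.at_level("WARNING"):
            prof = cio.read_depth_bedgraph(p, layout)
        assert prof.n_bins == 0
        assert any("empty" in r.message for r in caplog.records)


class TestCallIO:
    @pytest.fixture
    def loss_call(self):
        return CnvCall(Interval("chr1", 100_000, 200_000), "LOSS", 1,
                       depth_estimate=1.02, n_bins=100)

    def test_tsv_keeps_zero_based(self, tmp_path, loss_call):
        p = tmp_path / "calls.tsv"
        cio.write_calls([loss_call], p)
        (c,) = cio.read_calls(p)
        assert (c.start, c.end, c.type, c.copy_number) == (100_000, 200_000, "LOSS", 1)

    def test_vcf_like_converts_to_one_based_inclusive(self, tmp_path, loss_call):
        p = tmp_path / "calls.vcf"
        cio.write_calls([loss_call], p, fmt="vcf-like")
        row = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
        fields = row.split("\t")
        assert fields[1] == "100001"
        assert "END=200000" in fields[7] and "SVTYPE=DEL" in fields[7]

    def test_empty_call_list_header_only(self, tmp_path):
        p = tmp_path / "calls.tsv"
        cio.write_calls([], p)
        assert cio.read_calls(p) == []

    def test_annotations_round_trip(self, tmp_path, loss_call):
        c = loss_call.replace(genes=("A", "B"), population_frequency=0.05,
                              mosaic_flag=True, purity=0.5, gap_lengths=(42,),
                              het_count=3, inheritance="maternal")
        p = tmp_path / "calls.tsv"
        cio.write_calls([c], p)
        (back,) = cio.read_calls(p)
        assert back.genes == ("A", "B")
        assert back.population_frequency == pytest.approx(0.05)
        assert back.mosaic_flag and back.purity == pytest.approx(0.5)
        assert back.gap_lengths == (42,) and back.het_count == 3
        assert back.inheritance == "maternal"


class TestCallValidation:
    def test_bad_type_rejected(self):
        with pytest.raises(ValidationError):
            CnvCall(Interval("chr1", 0, 10), "DEL", 1)

    def test_frequency_range_enforced(self):
        with pytest.raises(ValidationError):
            CnvCall(Interval("chr1", 0, 10), "LOSS", 1, population_frequency=1.5)
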