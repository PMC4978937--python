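import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from footmix import (
    CutTrack,
    build_cut_matrices,
    cuts_from_alignments,
    label_instances,
    load_cut_track,
    load_model,
    make_toy_model,
    read_candidate_sites,
    read_peaks,
    save_model,
    write_bedgraph,
    write_posteriors,
)
from footmix.formats_io import FormatError, MotifInstanceSet, PeakSet


def make_sites(intervals, strand="+"):
    n = len(intervals)
    chrom = np.array([iv[0] for iv in intervals], dtype=object)
    start = np.array([iv[1] for iv in intervals], dtype=np.int64)
    end = np.array([iv[2] for iv in intervals], dtype=np.int64)
    return MotifInstanceSet(
        chrom=chrom, start=start, end=end,
        strand=np.full(n, strand, dtype=object),
        instance_id=np.array([f"m{i}" for i in range(n)], dtype=object),
        features=pd.DataFrame({"motif_score": np.zeros(n)}),
        motif_length=int(end[0] - start[0]),
    )


class TestReadCandidateSites:
    def test_basic_bed6_line(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t100\t110\tm1\t12.5\t+\n")
        sites = read_candidate_sites(p)
        assert sites.motif_length == 10
        assert sites.features.loc[0, "motif_score"] == 12.5
        assert list(sites.instance_id) == ["m1"]

    def test_mixed_widths_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t100\t110\tm1\t1\t+\nchr1\t200\t212\tm2\t1\t-\n")
        with pytest.raises(FormatError, match="inconsistent motif length.*line 2"):
            read_candidate_sites(p)

    def test_feature_tsv_join_matches_hand_built_matrix(self, tmp_path):
        bed = tmp_path / "s.bed"
        # deliberately unsorted input
        bed.write_text(
            "chr2\t50\t60\tb\t2.0\t+\n"
            "chr1\t300\t310\tc\t3.0\t-\n"
            "chr1\t100\t110\ta\t1.0\t+\n")
        tsv = tmp_path / "f.tsv"
        pd.DataFrame({"instance_id": ["a", "b", "c"],
                      "partner_score": [10.0, 20.0, 30.0]}
                     ).to_csv(tsv, sep="\t", index=False)
        sites = read_candidate_sites(bed, tsv)
        assert sites.feature_names == ["motif_score", "partner_score"]
        # sorted by (chrom, start): a, c, b
        expected = np.array([[1.0, 10.0], [3.0, 30.0], [2.0, 20.0]])
        np.testing.assert_array_equal(sites.features.to_numpy(), expected)

    def test_missing_instance_id_in_tsv_rejected(self, tmp_path):
        bed = tmp_path / "s.bed"
        bed.write_text("chr1\t100\t110\ta\t1.0\t+\n")
        tsv = tmp_path / "f.tsv"
        pd.DataFrame({"instance_id": ["zzz"], "x": [1.0]}
                     ).to_csv(tsv, sep="\t", index=False)
        with pytest.raises(FormatError, match="missing"):
            read_candidate_sites(bed, tsv)


class TestReadPeaks:
    def test_well_formed_line(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t10\t200\tpeak1\t0\t.\t7.25\t-1\t-1\t95\n")
        peaks = read_peaks(p)
        assert len(peaks) == 1
        assert peaks.signal_value[0] == 7.25

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("")
        assert len(read_peaks(p)) == 0

    def test_overlapping_peaks_retained(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        lines = [f"chr1\t{s}\t{s+100}\tpk\t0\t.\t{i}\t-1\t-1\t50\n"
                 for i, s in enumerate([10, 50, 60])]
        p.write_text("".join(lines))
        assert len(read_peaks(p)) == 3

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t10\t200\tpk\t0\t.\n")
        with pytest.raises(FormatError, match="10 columns"):
            read_peaks(p)


class TestLabelInstances:
    def make_peaks(self, intervals):
        return PeakSet(
            chrom=np.array([iv[0] for iv in intervals], dtype=object),
            start=np.array([iv[1] for iv in intervals], dtype=np.int64),
            end=np.array([iv[2] for iv in intervals], dtype=np.int64),
            signal_value=np.array([iv[3] for iv in intervals], dtype=float),
        )

    def test_one_bp_overlap_is_bound(self):
        sites = make_sites([("chr1", 100, 110)])
        labels = label_instances(sites, self.make_peaks([("chr1", 109, 200, 5.0)]))
        assert labels["bound"].iloc[0]

    def test_half_open_boundary_is_unbound(self):
        sites = make_sites([("chr1", 100, 110)])
        labels = label_instances(sites, self.make_peaks([("chr1", 110, 200, 5.0)]))
        assert not labels["bound"].iloc[0]
        assert np.isnan(labels["peak_height"].iloc[0])

    def test_max_signal_over_overlapping_peaks(self):
        sites = make_sites([("chr1", 100, 110)])
        peaks = self.make_peaks([("chr1", 90, 120, 5.0), ("chr1", 105, 130, 9.0)])
        labels = label_instances(sites, peaks)
        assert labels["peak_height"].iloc[0] == 9.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_and_is_permutation_invariant(self, data):
        n_sites = data.draw(st.integers(1, 8))
        n_peaks = data.draw(st.integers(0, 8))
        site_ivs = [("chr1", s, s + 10) for s in
                    data.draw(st.lists(st.integers(0, 200), min_size=n_sites,
                                       max_size=n_sites, unique=True))]
        peak_ivs = []
        for _ in range(n_peaks):
            a = data.draw(st.integers(0, 220))
            w = data.draw(st.integers(1, 60))
            v = data.draw(st.floats(0, 100, allow_nan=False))
            peak_ivs.append(("chr1", a, a + w, v))
        sites = make_sites(sorted(site_ivs, key=lambda iv: iv[1]))
        labels = label_instances(sites, self.make_peaks(peak_ivs))
        shuffled = label_instances(sites, self.make_peaks(peak_ivs[::-1]))
        pd.testing.assert_frame_equal(labels, shuffled)
        # base-by-base oracle
        for i in range(len(sites)):
            s, e = sites.start[i], sites.end[i]
            hits = [v for (_, a, b, v) in peak_ivs
                    if any(a <= pos < b for pos in range(s, e))]
            assert labels["bound"].iloc[i] == bool(hits)
            if hits:
                assert labels["peak_height"].iloc[i] == max(hits)


class TestCutTracks:
    def test_bedgraph_interval_expansion(self, tmp_path):
        fwd = tmp_path / "f.bg"
        rev = tmp_path / "r.bg"
        fwd.write_text("chr1\t5\t8\t2\n")
        rev.write_text("")
        track = load_cut_track(fwd, rev)
        assert [track.get("chr1", "+", p) for p in range(4, 9)] == [0, 2, 2, 2, 0]

    def test_missing_region_is_zero(self, tmp_path):
        fwd = tmp_path / "f.bg"
        rev = tmp_path / "r.bg"
        fwd.write_text("chr1\t5\t8\t2\n")
        rev.write_text("")
        assert load_cut_track(fwd, rev).get("chr2", "+", 5) == 0

    def test_negative_value_rejected(self, tmp_path):
        fwd = tmp_path / "f.bg"
        rev = tmp_path / "r.bg"
        fwd.write_text("chr1\t5\t8\t-1\n")
        rev.write_text("")
        with pytest.raises(FormatError, match="negative"):
            load_cut_track(fwd, rev)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_bedgraph_round_trip_identity(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        track = CutTrack()
        for _ in range(rng.integers(1, 30)):
            track.add("chr1", rng.choice(["+", "-"]),
                      int(rng.integers(0, 500)), int(rng.integers(1, 5)))
        d = tmp_path_factory.mktemp("bg")
        write_bedgraph(track, d / "f.bg", d / "r.bg")
        back = load_cut_track(d / "f.bg", d / "r.bg")
        for key, store in track.counts.items():
            for pos, c in store.items():
                assert back.get(key[0], key[1], pos) == c
        assert back.total() == track.total()


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:chr1\tLN:1000\n"


def write_sam(path, records):
    path.write_text(SAM_HEADER + "".join(records))


class TestCutsFromAlignments:
    def test_forward_read_counts_leftmost_base(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, ["r1\t0\tchr1\t51\t60\t36M\t*\t0\t0\t*\t*\n"])
        track = cuts_from_alignments(sam)
        assert track.get("chr1", "+", 50) == 1
        assert track.total() == 1

    def test_reverse_read_counts_rightmost_base(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, ["r1\t16\tchr1\t51\t60\t36M\t*\t0\t0\t*\t*\n"])
        track = cuts_from_alignments(sam)
        assert track.get("chr1", "-", 85) == 1

    def test_filtered_flags_skipped(self, tmp_path):
        sam = tmp_path / "a.sam"
        write_sam(sam, [
            "r1\t4\tchr1\t0\t0\t*\t*\t0\t0\t*\t*\n",      # unmapped
            "r2\t256\tchr1\t51\t60\t36M\t*\t0\t0\t*\t*\n",  # secondary
            "r3\t1024\tchr1\t51\t60\t36M\t*\t0\t0\t*\t*\n",  # duplicate
            "r4\t0\tchr1\t51\t60\t36M\t*\t0\t0\t*\t*\n",
        ])
        assert cuts_from_alignments(sam).total() == 1

    def test_bulk_tally_matches_independent_scan(self, tmp_path):
        rng = np.random.default_rng(7)
        records, expected = [], {}
        for i in range(100):
            pos = int(rng.integers(1, 900))
            flag = int(rng.choice([0, 16]))
            records.append(f"r{i}\t{flag}\tchr1\t{pos}\t60\t36M\t*\t0\t0\t*\t*\n")
            if flag == 0:
                key = ("+", pos - 1)
            else:
                key = ("-", pos - 1 + 36 - 1)
            expected[key] = expected.get(key, 0) + 1
        sam = tmp_path / "a.sam"
        write_sam(sam, records)
        track = cuts_from_alignments(sam)
        for (strand, pos), c in expected.items():
            assert track.get("chr1", strand, pos) == c
        assert track.total() == 100

    def test_bam_and_bedgraph_ingestion_agree(self, tmp_path):
        """The same synthetic fragment set via SAM and via bedGraph gives
        identical cut matrices."""
        rng = np.random.default_rng(13)
        records = []
        for i in range(60):
            pos = int(rng.integers(1, 800))
            flag = int(rng.choice([0, 16]))
            records.append(f"r{i}\t{flag}\tchr1\t{pos}\t60\t36M\t*\t0\t0\t*\t*\n")
        sam = tmp_path / "a.sam"
        write_sam(sam, records)
        track_sam = cuts_from_alignments(sam)
        write_bedgraph(track_sam, tmp_path / "f.bg", tmp_path / "r.bg")
        track_bg = load_cut_track(tmp_path / "f.bg", tmp_path / "r.bg")
        sites = make_sites([("chr1", 400, 410)])
        m1 = build_cut_matrices(track_sam, sites, margin=100)
        m2 = build_cut_matrices(track_bg, sites, margin=100)
        np.testing.assert_array_equal(m1.fwd, m2.fwd)
        np.testing.assert_array_equal(m1.rev, m2.rev)


class TestPersistence:
    def test_posterior_tsv_rows_and_roundtrip(self, tmp_path):
        sites = make_sites([("chr1", 100, 110), ("chr1", 300, 310)])
        post = np.array([[0.25, 0.75], [0.9, 0.1]])
        path = tmp_path / "post.tsv"
        write_posteriors(sites, post, path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 2
        np.testing.assert_allclose(df[["state_0", "state_1"]].sum(axis=1), 1.0)
        np.testing.assert_allclose(df["p_bound"], [0.75, 0.1], atol=1e-6)

    def test_posterior_dimension_mismatch_rejected(self, tmp_path):
        sites = make_sites([("chr1", 100, 110)])
        with pytest.raises(ValueError):
            write_posteriors(sites, np.ones((3, 2)) / 2, tmp_path / "p.tsv")

    def test_model_json_roundtrip_identity(self, tmp_path):
        model = make_toy_model(K=1, L=6, margin=40, seed=5)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.delta == model.delta
        np.testing.assert_allclose(back.prior.beta0, model.prior.beta0, atol=1e-12)
        np.testing.assert_allclose(back.prior.beta, model.prior.beta, atol=1e-12)
        for st_a, st_b in zip(model.states, back.states):
            for strand in "+-":
                assert st_a[strand].p == st_b[strand].p
                assert st_a[strand].r == st_b[strand].r
                np.testing.assert_allclose(st_a[strand].lam, st_b[strand].lam,
                                           atol=1e-12)
        for b_a, b_b in zip(model.binning, back.binning):
            np.testing.assert_array_equal(b_a.fwd_bins, b_b.fwd_bins)
            np.testing.assert_array_equal(b_a.rev_bins, b_b.rev_bins)
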