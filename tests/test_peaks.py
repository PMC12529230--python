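"""Peak ingestion, summit windows, context classification, categories,
subpeak merging, gene annotation and the width-enrichment correlation."""

import numpy as np
import pandas as pd
import pytest

from napchip import (
    GeneSet,
    Gene,
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    PeakTable,
    SummitContextClassifier,
    annotate_genes,
    classify_context,
    filter_fe,
    merge_subpeaks,
    read_peaks,
    summit_window,
    top_bottom,
    category_report,
    width_fe_correlation,
)
from napchip.peaks import PeakFormatError, SummitWindow

from conftest import make_peak_table


# --- I/O ----------------------------------------------------------------------


def test_narrowpeak_summit_offset(tmp_path):
    np_file = tmp_path / "p.narrowPeak"
    np_file.write_text("chr\t100\t200\tpk1\t0\t.\t2.5\t-1\t-1\t40\n")
    table = read_peaks(np_file, "narrowPeak")
    row = table.df.iloc[0]
    assert (row.start, row.end, row.summit, row.fold_enrichment) == (100, 200, 140, 2.5)


def test_empty_narrowpeak_is_valid(tmp_path):
    np_file = tmp_path / "p.narrowPeak"
    np_file.write_text("")
    assert len(read_peaks(np_file, "narrowPeak")) == 0


def test_negative_fe_rejected(tmp_path):
    np_file = tmp_path / "p.narrowPeak"
    np_file.write_text("chr\t100\t200\tpk1\t0\t.\t-1.0\t-1\t-1\t40\n")
    with pytest.raises(PeakFormatError):
        read_peaks(np_file, "narrowPeak")


def test_summit_outside_span_rejected(tmp_path):
    np_file = tmp_path / "p.narrowPeak"
    np_file.write_text("chr\t100\t200\tpk1\t0\t.\t2.0\t-1\t-1\t150\n")
    with pytest.raises(PeakFormatError, match="summit"):
        read_peaks(np_file, "narrowPeak")


def test_unknown_contig_rejected(tmp_path, toy_genome):
    np_file = tmp_path / "p.narrowPeak"
    np_file.write_text("chrX\t100\t200\tpk1\t0\t.\t2.0\t-1\t-1\t40\n")
    with pytest.raises(PeakFormatError, match="contig"):
        read_peaks(np_file, "narrowPeak", toy_genome)


def test_summary_tsv_round_trip(tmp_path, toy_peaks):
    out = tmp_path / "p.tsv"
    toy_peaks.to_summary_tsv(out)
    back = read_peaks(out, "summary-tsv")
    pd.testing.assert_frame_equal(
        back.df[["peak_id", "contig", "start", "end", "summit"]],
        toy_peaks.df[["peak_id", "contig", "start", "end", "summit"]])


def test_narrowpeak_round_trip(tmp_path, toy_peaks):
    out = tmp_path / "p.narrowPeak"
    toy_peaks.to_narrowpeak(out)
    back = read_peaks(out, "narrowPeak")
    assert back.df.start.tolist() == toy_peaks.df.start.tolist()
    assert back.df.summit.tolist() == toy_peaks.df.summit.tolist()


# --- summit windows -----------------------------------------------------------


def test_summit_window_interior(toy_genome):
    w = summit_window("c1", 500, "p", toy_genome)
    assert (w.start, w.end, w.width) == (470, 530, 60)


def test_summit_window_clipped_at_edge(toy_genome):
    w = summit_window("c1", 10, "p", toy_genome)
    assert (w.start, w.end, w.width) == (0, 40, 40)


def test_summit_window_inclusive_variant(toy_genome):
    w = summit_window("c1", 500, "p", toy_genome, inclusive=True)
    assert w.width == 61


# --- context classification ---------------------------------------------------


def _iset(spans, contig="c1"):
    return IntervalSet.from_intervals(
        [GenomicInterval(contig, s, e) for s, e in spans], role="intergenic")


def test_window_inside_orf_is_coding():
    call = classify_context(SummitWindow("c1", 100, 160, "p"), _iset([(500, 600)]))
    assert call.context == "coding"
    assert call.intergenic_overlap_bp == 0
    assert call.window_fully_in_context


def test_exactly_30bp_overlap_is_coding():
    """The rule is strictly 'more than 30 bp': a 30-bp tie goes to coding."""
    call = classify_context(SummitWindow("c1", 100, 160, "p"), _iset([(130, 160)]))
    assert call.intergenic_overlap_bp == 30
    assert call.context == "coding"
    assert not call.window_fully_in_context


def test_31bp_overlap_is_intergenic():
    call = classify_context(SummitWindow("c1", 100, 160, "p"), _iset([(129, 160)]))
    assert call.intergenic_overlap_bp == 31
    assert call.context == "intergenic"


def test_fully_intergenic_window_flagged():
    call = classify_context(SummitWindow("c1", 100, 160, "p"), _iset([(50, 200)]))
    assert call.context == "intergenic"
    assert call.window_fully_in_context


def test_classify_agrees_with_per_base_oracle():
    """1000 random window/interval-set instances against a per-bp membership
    count."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        length = 400
        mask = np.zeros(length, dtype=bool)
        spans = []
        for _ in range(int(rng.integers(0, 8))):
            s = int(rng.integers(0, length - 1))
            e = int(rng.integers(s + 1, min(length, s + 80) + 1))
            spans.append((s, e))
            mask[s:e] = True
        iset = _iset(spans) if spans else IntervalSet([], "intergenic")
        ws = int(rng.integers(0, length - 60))
        window = SummitWindow("c1", ws, ws + 60, "p")
        oracle_overlap = int(mask[ws:ws + 60].sum())
        call = classify_context(window, iset)
        assert call.intergenic_overlap_bp == oracle_overlap
        assert (call.context == "intergenic") == (oracle_overlap > 30)


# --- categories ---------------------------------------------------------------


def test_filter_fe_inclusive_threshold():
    table = make_peak_table([
        ("a", "c", 0, 10, 5, 1.5), ("b", "c", 20, 30, 25, 2.0),
        ("c", "c", 40, 50, 45, 2.1), ("d", "c", 60, 70, 65, 3.0),
        ("e", "c", 80, 90, 85, 0.9),
    ])
    kept = filter_fe(table, 2.0)
    assert kept.df.peak_id.tolist() == ["b", "c", "d"]
    assert len(filter_fe(table, 0.0)) == 5


def test_filter_fe_empty_table():
    table = make_peak_table([])
    assert len(filter_fe(table)) == 0


def test_top_bottom_ordering_and_k_ge_n():
    table = make_peak_table([
        (f"p{i}", "c", i * 100, i * 100 + 10, i * 100 + 5, float(i + 1))
        for i in range(5)
    ])
    top, bottom = top_bottom(table, k=2)
    assert top.df.fold_enrichment.tolist() == [5.0, 4.0]
    assert bottom.df.fold_enrichment.tolist() == [1.0, 2.0]
    top_all, bottom_all = top_bottom(table, k=20)
    assert len(top_all) == len(bottom_all) == 5


def test_category_nesting_properties():
    rng = np.random.default_rng(3)
    table = make_peak_table([
        (f"p{i}", "c", i * 100, i * 100 + 50, i * 100 + 25,
         float(rng.uniform(0.5, 5))) for i in range(50)
    ])
    top, bottom = top_bottom(table, k=20)
    all_ids = set(table.df.peak_id)
    assert set(top.df.peak_id) <= all_ids
    assert set(filter_fe(table).df.peak_id) <= all_ids
    assert not (set(top.df.peak_id) & set(bottom.df.peak_id))  # n >= 2k


def test_category_report_percentages(toy_genome):
    table = make_peak_table([
        ("a", "c1", 0, 120, 50, 1.0), ("b", "c1", 300, 500, 400, 3.0)])
    contexts = pd.DataFrame({
        "peak_id": ["a", "b"], "context": ["intergenic", "coding"],
        "window_start": [20, 370], "window_end": [80, 430],
        "intergenic_overlap_bp": [60, 0],
        "window_fully_in_context": [True, True]})
    rep = category_report(table, contexts, k=20)
    row = rep[rep.category == "all"].iloc[0]
    assert row.percent_intergenic == 50.0
    assert row.n == 2


# --- subpeak merging ----------------------------------------------------------


def test_merge_single_peak_no_letter():
    table = make_peak_table([("x", "c", 100, 200, 150, 2.0)])
    regions = merge_subpeaks(table, 100)
    assert len(regions) == 1
    assert regions[0].members == ["1"]


def test_merge_within_gap():
    table = make_peak_table([
        ("x", "c", 0, 100, 50, 2.0), ("y", "c", 150, 300, 200, 3.0)])
    regions = merge_subpeaks(table, 100)
    assert len(regions) == 1
    r = regions[0]
    assert (r.interval.start, r.interval.end) == (0, 300)
    assert r.members == ["1a", "1b"]
    assert r.max_fold_enrichment == 3.0


def test_no_merge_beyond_gap():
    table = make_peak_table([
        ("x", "c", 0, 100, 50, 2.0), ("y", "c", 250, 300, 270, 3.0)])
    assert len(merge_subpeaks(table, 100)) == 2


def test_merge_agrees_with_connected_component_oracle():
    """500 random tables against a transitive-closure clustering oracle."""
    rng = np.random.default_rng(11)
    for _ in range(500):
        n = int(rng.integers(1, 12))
        rows = []
        for i in range(n):
            s = int(rng.integers(0, 2000))
            e = s + int(rng.integers(10, 300))
            rows.append((f"p{i}", "c", s, e, s + 5, 1.0))
        table = make_peak_table(rows)
        gap = int(rng.integers(0, 300))
        regions = merge_subpeaks(table, gap)
        # oracle: union-find over pairs with span distance <= gap
        spans = [(r[2], r[3]) for r in rows]
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                d = max(spans[i][0], spans[j][0]) - min(spans[i][1], spans[j][1])
                if d <= gap:
                    parent[find(i)] = find(j)
        n_clusters = len({find(i) for i in range(n)})
        assert len(regions) == n_clusters
        # every input peak appears exactly once across regions
        members = [pid for r in regions for pid in r.member_source_ids]
        assert sorted(members) == sorted(f"p{i}" for i in range(n))
        # region spans do not overlap
        spans_out = sorted((r.interval.start, r.interval.end) for r in regions)
        for (s1, e1), (s2, e2) in zip(spans_out, spans_out[1:]):
            assert e1 <= s2


# --- gene annotation ----------------------------------------------------------


def test_annotate_single_gene(toy_genes):
    hits = annotate_genes(GenomicInterval("c1", 150, 160), toy_genes)
    assert [g.locus_tag for g in hits] == ["g001"]


def test_annotate_spanning_two_genes(toy_genes):
    hits = annotate_genes(GenomicInterval("c1", 250, 500), toy_genes)
    assert [g.locus_tag for g in hits] == ["g001", "g002"]


def test_annotate_agrees_with_overlap_oracle():
    rng = np.random.default_rng(5)
    for _ in range(500):
        n = int(rng.integers(1, 15))
        spans = []
        for i in range(n):
            s = int(rng.integers(0, 900))
            spans.append((s, s + int(rng.integers(1, 100))))
        genes = GeneSet([
            Gene(GenomicInterval("c1", s, e), f"g{i}")
            for i, (s, e) in enumerate(spans)])
        qs = int(rng.integers(0, 950))
        query = GenomicInterval("c1", qs, qs + int(rng.integers(1, 100)))
        hits = {g.locus_tag for g in annotate_genes(query, genes)}
        oracle = {f"g{i}" for i, (s, e) in enumerate(spans)
                  if min(e, query.end) - max(s, query.start) >= 1}
        assert hits == oracle


# --- correlation --------------------------------------------------------------


def test_perfect_linearity_gives_r_one():
    rows = [(f"p{i}", "c", i * 1000, i * 1000 + w, i * 1000 + 5, 1 + 0.001 * w)
            for i, w in enumerate([100, 300, 500, 800, 950])]
    res = width_fe_correlation(make_peak_table(rows))
    assert res.pearson_r == pytest.approx(1.0)
    assert res.slope == pytest.approx(0.001)
    assert res.intercept == pytest.approx(1.0)


def test_correlation_matches_closed_form():
    widths = np.array([120.0, 340.0, 510.0, 200.0, 880.0])
    fes = np.array([1.2, 2.8, 1.9, 3.3, 4.1])
    rows = [(f"p{i}", "c", i * 1000, i * 1000 + int(w), i * 1000 + 5, f)
            for i, (w, f) in enumerate(zip(widths, fes))]
    res = width_fe_correlation(make_peak_table(rows))
    x, y = widths, fes
    r_oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    slope_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    assert res.pearson_r == pytest.approx(r_oracle, abs=1e-10)
    assert res.slope == pytest.approx(slope_oracle, abs=1e-10)
    assert res.intercept == pytest.approx(y.mean() - slope_oracle * x.mean(), abs=1e-10)


def test_null_correlation_near_zero():
    rng = np.random.default_rng(99)
    rows = [(f"p{i}", "c", i * 1000, i * 1000 + int(rng.integers(100, 900)),
             i * 1000 + 5, float(rng.uniform(1, 4))) for i in range(500)]
    res = width_fe_correlation(make_peak_table(rows))
    assert abs(res.pearson_r) < 3 / np.sqrt(500)


def test_degenerate_correlation_rejected():
    rows = [(f"p{i}", "c", i * 100, i * 100 + 50, i * 100 + 5, 2.0)
            for i in range(5)]
    with pytest.raises(ValueError, match="undefined|constant"):
        width_fe_correlation(make_peak_table(rows))


# --- classifier estimator -----------------------------------------------------


def test_classifier_transform_shape(toy_genome, toy_genes, toy_peaks):
    from napchip import genic_partition

    part = genic_partition(toy_genes, toy_genome)
    clf = SummitContextClassifier().fit(part.intergenic, toy_genome)
    out = clf.transform(toy_peaks)
    assert list(out.peak_id) == list(toy_peaks.df.peak_id)
    assert set(out.context) <= {"intergenic", "coding"}
    # sklearn param plumbing
    assert clf.get_params()["flank"] == 30
    clf.set_params(flank=10)
    assert clf.flank == 10
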