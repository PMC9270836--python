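"""Retention categories, chimera detection, RBH logic, representative
selection, and the end-to-end pruning pipeline."""

import numpy as np
import pandas as pd
import pytest

from spidarch import curation
from spidarch.curation import (
    BlastHit,
    CurationParams,
    HitTable,
    classify_transcripts,
    detect_chimeras,
    parse_hit_table,
    reciprocal_best_hits,
    select_representatives,
    subject_coverage,
)
from spidarch.seq_io import parse_trinity_id
from tests.conftest import curate_fixture


def hit(q, s, bits=100.0, q_iv=(0, 100), s_iv=(0, 100), slen=100, evalue=1e-50):
    return BlastHit(
        query_id=q, subject_id=s, pct_identity=0.9, aln_len=q_iv[1] - q_iv[0],
        mismatches=0, gap_opens=0, q_start=q_iv[0], q_end=q_iv[1],
        s_start=s_iv[0], s_end=s_iv[1], evalue=evalue, bitscore=bits,
        subject_len=slen,
    )


class TestParseHitTable:
    def test_coordinates_converted(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\ts1\t90.0\t100\t10\t0\t1\t100\t1\t100\t1e-50\t200\n")
        table = parse_hit_table(p, {"s1": 200})
        h = table.hits[0]
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (0, 100, 0, 100)
        assert h.subject_len == 200
        assert h.pct_identity == pytest.approx(0.9)

    def test_evalue_ceiling_drops_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            "q1\ts1\t90.0\t100\t10\t0\t1\t100\t1\t100\t1e-5\t200\n"
            "q2\ts1\t90.0\t100\t10\t0\t1\t100\t1\t100\t1e-50\t200\n"
        )
        table = parse_hit_table(p, {"s1": 200}, evalue_max=1e-10)
        assert [h.query_id for h in table.hits] == ["q2"]
        assert table.n_dropped == 1

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("")
        with pytest.warns(UserWarning):
            table = parse_hit_table(p, {})
        assert table.hits == []

    def test_unknown_subject_and_malformed_row(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\tsX\t90.0\t100\t10\t0\t1\t100\t1\t100\t1e-50\t200\n")
        with pytest.raises(ValueError, match="unknown subject"):
            parse_hit_table(p, {"s1": 200})
        p.write_text("q1\ts1\tnot_a_number\t100\t10\t0\t1\t100\t1\t100\t1e-50\t200\n")
        with pytest.raises(ValueError, match=":1"):
            parse_hit_table(p, {"s1": 200})


class TestSubjectCoverage:
    @pytest.mark.parametrize(
        "intervals,slen,expected",
        [
            ([(0, 50), (40, 90)], 100, 0.90),
            ([(10, 20), (30, 40)], 100, 0.20),
            ([(0, 100)], 100, 1.0),
        ],
    )
    def test_union_fraction(self, intervals, slen, expected):
        hits = [hit("q", "s", s_iv=iv, slen=slen) for iv in intervals]
        assert subject_coverage(hits) == pytest.approx(expected)

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            subject_coverage([hit("q1", "s"), hit("q2", "s")])


class TestReciprocalBestHits:
    def test_mutual_best_pair(self):
        fwd = HitTable(hits=[hit("q1", "s1", 200)])
        rev = HitTable(hits=[hit("s1", "q1", 200)])
        assert reciprocal_best_hits(fwd, rev) == {("q1", "s1")}

    def test_one_sided_best_excluded(self):
        fwd = HitTable(hits=[hit("q1", "s1", 200), hit("q2", "s1", 150)])
        rev = HitTable(hits=[hit("s1", "q1", 200), hit("s1", "q2", 150)])
        assert reciprocal_best_hits(fwd, rev) == {("q1", "s1")}

    def test_bitscore_tie_breaks_lexicographically_and_deterministic(self):
        fwd = HitTable(hits=[hit("q1", "s2", 100), hit("q1", "s1", 100)])
        rev = HitTable(hits=[hit("s1", "q1", 100), hit("s2", "q1", 100)])
        for _ in range(3):
            assert reciprocal_best_hits(fwd, rev) == {("q1", "s1")}


class TestDetectChimeras:
    def test_side_by_side_subjects_flagged(self):
        hits = [
            hit("q", "s1", q_iv=(0, 300), s_iv=(0, 50), slen=100),
            hit("q", "s2", q_iv=(350, 700), s_iv=(0, 50), slen=100),
        ]
        assert detect_chimeras(HitTable(hits=hits)) == {"q"}

    def test_fully_overlapping_subjects_not_flagged(self):
        hits = [
            hit("q", "s1", q_iv=(0, 300), s_iv=(0, 50), slen=100),
            hit("q", "s2", q_iv=(0, 300), s_iv=(0, 50), slen=100),
        ]
        assert detect_chimeras(HitTable(hits=hits)) == set()

    def test_single_subject_not_flagged(self):
        assert detect_chimeras(HitTable(hits=[hit("q", "s1")])) == set()

    def test_low_coverage_subjects_ignored(self):
        hits = [
            hit("q", "s1", q_iv=(0, 300), s_iv=(0, 10), slen=100),
            hit("q", "s2", q_iv=(350, 700), s_iv=(0, 10), slen=100),
        ]
        assert detect_chimeras(HitTable(hits=hits)) == set()


def _expr(mapping, libraries=("L1", "L2")):
    return pd.DataFrame(
        {lib: {t: vals[i] for t, vals in mapping.items()} for i, lib in enumerate(libraries)}
    )


class TestClassify:
    def test_rbh_is_best(self):
        hits = HitTable(hits=[hit("q1", "s1", 200, s_iv=(0, 50), slen=100)])
        calls = classify_transcripts(
            hits, {("q1", "s1")}, _expr({"q1": (5.0, 0.0)}), {}, set(), ["q1"]
        )
        assert (calls[0].category, calls[0].reason) == ("BEST", "rbh")

    def test_second_best_sibling(self):
        # i1 holds the RBH; i2 is the top query of another database gene
        hits = HitTable(hits=[
            hit("DN1_c0_g1_i1", "s1", 400),
            hit("DN1_c0_g1_i2", "s1", 300),
            hit("DN1_c0_g1_i2", "s2", 250),
        ])
        rev = HitTable(hits=[
            hit("s1", "DN1_c0_g1_i1", 400),
            hit("s2", "DN1_c0_g1_i2", 250),
        ])
        expr = _expr({"DN1_c0_g1_i1": (5, 0), "DN1_c0_g1_i2": (5, 0)})
        calls = classify_transcripts(
            hits, {("DN1_c0_g1_i1", "s1")}, expr, {}, set(),
            ["DN1_c0_g1_i1", "DN1_c0_g1_i2"], reverse_hits=rev,
        )
        by_id = {c.transcript_id: c for c in calls}
        assert by_id["DN1_c0_g1_i1"].category == "BEST"
        assert by_id["DN1_c0_g1_i2"].category == "2BEST"
        assert by_id["DN1_c0_g1_i2"].reason == "best_to_gene"

    @pytest.mark.parametrize(
        "orf,tpm,category,reason",
        [
            (49, 10.0, "DISCARD", "no_orf"),
            (51, 10.0, "LONGORF", "longorf"),
            (51, 0.5, "DISCARD", "low_expression"),
        ],
    )
    def test_longorf_cutoffs(self, orf, tpm, category, reason):
        calls = classify_transcripts(
            HitTable(hits=[]), set(), _expr({"q": (tpm, 0.0)}), {"q": orf}, set(), ["q"]
        )
        assert (calls[0].category, calls[0].reason) == (category, reason)

    def test_structural_rna_precedes_everything(self):
        hits = HitTable(hits=[hit("q1", "s1", 200)])
        calls = classify_transcripts(
            hits, {("q1", "s1")}, _expr({"q1": (5.0, 0.0)}), {}, {"q1"}, ["q1"]
        )
        assert (calls[0].category, calls[0].reason) == ("DISCARD", "structural_rna")

    def test_missing_expression_is_error(self):
        hits = HitTable(hits=[hit("q1", "s1")])
        with pytest.raises(ValueError, match="no expression"):
            classify_transcripts(hits, set(), _expr({"other": (1, 1)}), {}, set(), ["q1"])


class TestSelectRepresentatives:
    def _call(self, tid, category, reason="rbh", bits=0.0, orf=0):
        reason = {"BEST": "rbh", "2BEST": "best_to_gene", "GOOD": "coverage_expression",
                  "LONGORF": "longorf"}.get(category, reason)
        return curation.TranscriptCall(
            transcript_id=tid, category=category, reason=reason,
            bitscore=bits, longest_orf=orf,
        )

    def test_category_rank_wins(self):
        calls = [
            self._call("DN1_c0_g1_i1", "BEST", bits=100),
            self._call("DN1_c0_g1_i2", "GOOD", bits=500),
        ]
        out = {c.transcript_id: c for c in select_representatives(calls)}
        assert out["DN1_c0_g1_i1"].category == "BEST"
        assert out["DN1_c0_g1_i2"].category == "DISCARD"
        assert out["DN1_c0_g1_i2"].reason == "not_representative"

    def test_bitscore_breaks_equal_categories(self):
        calls = [
            self._call("DN1_c0_g1_i1", "GOOD", bits=120),
            self._call("DN1_c0_g1_i2", "GOOD", bits=180),
        ]
        out = {c.transcript_id: c for c in select_representatives(calls)}
        assert out["DN1_c0_g1_i2"].category == "GOOD"
        assert out["DN1_c0_g1_i1"].category == "DISCARD"

    def test_all_discard_gene_retains_nothing(self):
        calls = [
            self._call("DN1_c0_g1_i1", "DISCARD", reason="low_coverage"),
            self._call("DN1_c0_g1_i2", "DISCARD", reason="no_orf"),
        ]
        out = select_representatives(calls)
        assert all(c.category == "DISCARD" for c in out)


def _random_instance(rng):
    """A small random but internally consistent classification instance."""
    n_genes = int(rng.integers(2, 8))
    transcripts, hits, rev_hits = [], [], []
    expr = {}
    orf_lengths = {}
    rna_ids = set()
    subjects = [f"s{k}" for k in range(6)]
    for g in range(n_genes):
        for i in range(int(rng.integers(1, 4))):
            t = f"DN{g}_c0_g1_i{i + 1}"
            transcripts.append(t)
            expr[t] = (float(rng.uniform(0, 4)), float(rng.uniform(0, 4)))
            orf_lengths[t] = int(rng.integers(0, 120))
            if rng.random() < 0.1:
                rna_ids.add(t)
            for s in subjects:
                if rng.random() < 0.25:
                    bits = float(np.round(rng.uniform(50, 500), 1))
                    cov_len = int(rng.integers(5, 100))
                    hits.append(hit(t, s, bits, q_iv=(0, 3 * cov_len),
                                    s_iv=(0, cov_len), slen=100))
    for s in subjects:
        rows = [h for h in hits if h.subject_id == s]
        for h in rng.permutation(len(rows)):
            if rng.random() < 0.6:
                src = rows[int(h)]
                rev_hits.append(hit(s, src.query_id, src.bitscore))
    return transcripts, hits, rev_hits, expr, orf_lengths, rna_ids


def _brute_force_calls(transcripts, hits, rev_hits, expr, orf_lengths, rna_ids, params):
    """Plain re-statement of the decision rules, evaluated per transcript."""
    def best(pairs):  # [(target, bits, evalue)] -> target
        return sorted(pairs, key=lambda p: (-p[1], p[2], p[0]))[0][0]

    fwd_by_q, rev_by_s = {}, {}
    for h in hits:
        fwd_by_q.setdefault(h.query_id, []).append((h.subject_id, h.bitscore, h.evalue))
    for h in rev_hits:
        rev_by_s.setdefault(h.query_id, []).append((h.subject_id, h.bitscore, h.evalue))
    rbh = set()
    for q, pairs in fwd_by_q.items():
        s = best(pairs)
        if s in rev_by_s and best(rev_by_s[s]) == q:
            rbh.add(q)
    top_of_subject = {best(pairs) for pairs in rev_by_s.values()}
    chim = detect_chimeras(HitTable(hits=list(hits)),
                           params.chimera_cov_min, params.chimera_ovl_max)

    def coverage(t):
        per = {}
        for h in hits:
            if h.query_id == t:
                per.setdefault(h.subject_id, []).append(h)
        return max((subject_coverage(v) for v in per.values()), default=0.0)

    out = {}
    for t in transcripts:
        gene = parse_trinity_id(t).gene
        t_hits = [h for h in hits if h.query_id == t]
        tpm = max(expr[t])
        sibling_rbh = any(
            q != t and parse_trinity_id(q).gene == gene for q in rbh
        )
        if t in rna_ids:
            out[t] = ("DISCARD", "structural_rna")
        elif t in chim:
            out[t] = ("DISCARD", "chimeric")
        elif t in rbh:
            out[t] = ("BEST", "rbh")
        elif t in top_of_subject and sibling_rbh:
            out[t] = ("2BEST", "best_to_gene")
        elif t_hits:
            if coverage(t) >= params.cov_min and tpm >= params.tpm_min:
                out[t] = ("GOOD", "coverage_expression")
            elif coverage(t) < params.cov_min:
                out[t] = ("DISCARD", "low_coverage")
            else:
                out[t] = ("DISCARD", "low_expression")
        else:
            if orf_lengths.get(t, 0) >= params.min_aa and tpm >= params.tpm_min:
                out[t] = ("LONGORF", "longorf")
            elif orf_lengths.get(t, 0) < params.min_aa:
                out[t] = ("DISCARD", "no_orf")
            else:
                out[t] = ("DISCARD", "low_expression")
    return out


@pytest.mark.parametrize("seed", range(12))
def test_classification_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    transcripts, hits, rev_hits, expr, orf_lengths, rna_ids = _random_instance(rng)
    params = CurationParams()
    calls = classify_transcripts(
        HitTable(hits=list(hits)),
        reciprocal_best_hits(HitTable(hits=list(hits)), HitTable(hits=list(rev_hits))),
        _expr(expr), orf_lengths, rna_ids, transcripts,
        params=params, reverse_hits=HitTable(hits=list(rev_hits)),
    )
    expected = _brute_force_calls(
        transcripts, hits, rev_hits, expr, orf_lengths, rna_ids, params
    )
    got = {c.transcript_id: (c.category, c.reason) for c in calls}
    assert got == expected


class TestEndToEnd:
    def test_reproduces_planted_truth(self, transcriptome_fixture, curation_result):
        truth = transcriptome_fixture.truth.set_index("transcript_id")
        calls = curation_result.calls_frame().set_index("transcript_id")
        merged = truth.join(calls, lsuffix="_truth")
        mismatches = merged[
            (merged.category_truth != merged.category)
            | (merged.reason_truth != merged.reason)
        ]
        assert len(mismatches) == 0

    def test_counts_and_one_per_gene(self, curation_result):
        assert curation_result.report.total == 200
        genes = {}
        for c in curation_result.calls:
            if c.category != "DISCARD":
                g = parse_trinity_id(c.transcript_id).gene
                genes[g] = genes.get(g, 0) + 1
        assert genes and max(genes.values()) == 1

    def test_no_retained_chimera_or_rna(self, transcriptome_fixture, curation_result):
        retained = {r.id for r in curation_result.retained}
        assert not retained & transcriptome_fixture.rna_ids
        chim = set(
            transcriptome_fixture.truth.query("reason == 'chimeric'").transcript_id
        )
        assert not retained & chim

    def test_idempotent_on_own_output(self, transcriptome_fixture, tmp_path, curation_result):
        retained_ids = {r.id for r in curation_result.retained}
        fix = transcriptome_fixture
        sub_records = [r for r in fix.records if r.id in retained_ids]
        import dataclasses

        sub = dataclasses.replace(
            fix,
            records=sub_records,
            forward_rows=[
                r for r in fix.forward_rows if r.split("\t")[0] in retained_ids
            ],
            reverse_rows=[
                r for r in fix.reverse_rows if r.split("\t")[1] in retained_ids
            ],
            truth=fix.truth[fix.truth.transcript_id.isin(retained_ids)],
        )
        res2 = curate_fixture(sub, tmp_path / "rerun")
        assert {r.id for r in res2.retained} == retained_ids

    def test_threshold_monotonicity(self, transcriptome_fixture, tmp_path):
        sizes = []
        for tpm_min in (1.0, 2.0, 5.0):
            res = curate_fixture(
                transcriptome_fixture, tmp_path / f"tpm{tpm_min}",
                CurationParams(tpm_min=tpm_min),
            )
            sizes.append(len(res.retained))
        assert sizes == sorted(sizes, reverse=True)
        sizes = []
        for cov_min in (0.2, 0.4, 0.8):
            res = curate_fixture(
                transcriptome_fixture, tmp_path / f"cov{cov_min}",
                CurationParams(cov_min=cov_min),
            )
            sizes.append(len(res.retained))
        assert sizes == sorted(sizes, reverse=True)
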