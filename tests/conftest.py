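import pytest

from spidarch import curation
from spidarch.synth import TranscriptomeSpec, make_transcriptome


def curate_fixture(fixture, tmpdir, params=None):
    """Run the full pruning pipeline on a written-out fixture (exercising the
    file parsers on the way)."""
    fixture.write(tmpdir)
    lengths = curation.read_subject_lengths(tmpdir / "subject_lengths.tsv")
    fwd = curation.parse_hit_table(tmpdir / "hits_fwd.tsv", lengths)
    rev_lengths = {r.id: len(r) for r in fixture.records}
    if (tmpdir / "hits_rev.tsv").read_text().strip():
        rev = curation.parse_hit_table(tmpdir / "hits_rev.tsv", rev_lengths)
    else:
        rev = curation.HitTable(hits=[])
    expr = curation.load_expression(tmpdir / "expression.tsv")
    return curation.run_curation(
        fixture.records, fwd, rev, expr, fixture.rna_ids, params
    )


@pytest.fixture(scope="session")
def transcriptome_fixture():
    return make_transcriptome(TranscriptomeSpec(seed=11))


@pytest.fixture(scope="session")
def curation_result(transcriptome_fixture, tmp_path_factory):
    tmpdir = tmp_path_factory.mktemp("trtap")
    return curate_fixture(transcriptome_fixture, tmpdir)
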