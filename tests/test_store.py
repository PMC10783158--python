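"""Corpus store: idempotent upserts, referential integrity, flow counts."""

import pytest

from nbaudit.records import (ArticleRecord, InvariantError, JournalRecord,
                             NotebookFile, OutcomeClass, OutcomeLabel,
                             ParseStatus, RepositoryRecord)
from nbaudit.store import CorpusStore, ReferentialError


def _repo(url="https://github.com/a/b", available=True):
    return RepositoryRecord(canonical_url=url, available=available,
                            local_path="/tmp/x" if available else None)


def _nb(url="https://github.com/a/b", path="a.ipynb"):
    return NotebookFile(repo_ref=url, relative_path=path, file_size=10,
                        parse_status=ParseStatus.PARSED)


def test_upserting_the_same_article_twice_keeps_one_row(fresh_store):
    article = ArticleRecord(pmc_id="PMC1", title="T")
    fresh_store.upsert_article(article)
    fresh_store.upsert_article(article)
    assert fresh_store.conn.execute(
        "SELECT COUNT(*) FROM articles").fetchone()[0] == 1


def test_journal_dedup_by_issn(fresh_store):
    a = fresh_store.upsert_journal(JournalRecord(issn="1", title="Old name"))
    b = fresh_store.upsert_journal(JournalRecord(issn="1", title="New name"))
    assert a == b


def test_notebook_requires_known_repository(fresh_store):
    with pytest.raises(ReferentialError, match="unknown repository"):
        fresh_store.upsert_notebook(_nb())
    fresh_store.upsert_repository(_repo())
    nb_id = fresh_store.upsert_notebook(_nb())
    assert fresh_store.upsert_notebook(_nb()) == nb_id  # idempotent


def test_empty_store_has_all_zero_flow_counts(fresh_store):
    flow = fresh_store.flow_counts()
    assert flow.notebooks_total == 0 and flow.notebooks_attempted == 0


def _load_stage_counts(store, install_failed, exceptions, excluded,
                       identical, different):
    """Bulk-load synthetic outcome rows mirroring corpus-scale counts."""
    store.upsert_repository(_repo())
    total = install_failed + exceptions + excluded + identical + different
    store.conn.executemany(
        "INSERT INTO notebooks (repo_url, relative_path, file_size,"
        " parse_status) VALUES ('https://github.com/a/b', ?, 1, 'parsed')",
        ((f"nb{i}.ipynb",) for i in range(total)))
    labels = (["install_failed"] * install_failed
              + ["exception"] * exceptions + ["excluded"] * excluded
              + ["finished_identical"] * identical
              + ["finished_different"] * different)
    store.conn.executemany(
        "INSERT INTO outcomes (notebook_id, label, exception_type, attempted)"
        " VALUES (?, ?, NULL, 1)",
        ((i + 1, label) for i, label in enumerate(labels)))
    store.conn.commit()


def test_corpus_scale_stage_counts_split_conservatively(fresh_store):
    """Attempted notebooks split into install failures and executions,
    and finished executions into identical and different results."""
    _load_stage_counts(fresh_store, install_failed=5429, exceptions=9100,
                       excluded=85, identical=879, different=324)
    flow = fresh_store.flow_counts()
    assert flow.notebooks_attempted == 15817
    assert flow.install_failed == 5429
    assert flow.executed == 10388
    assert flow.finished == 1203
    assert flow.finished_identical == 879
    assert flow.finished_different == 324


def test_flow_invariant_violation_names_offenders(fresh_store):
    fresh_store.upsert_repository(_repo())
    nb_id = fresh_store.upsert_notebook(_nb())
    # an unattempted label flagged attempted breaks conservation
    fresh_store.conn.execute(
        "INSERT INTO outcomes VALUES (?, 'not_target_language', NULL, 1)",
        (nb_id,))
    with pytest.raises(InvariantError, match=str(nb_id)):
        fresh_store.flow_counts()


def test_dump_and_reload_round_trip(fresh_store):
    fresh_store.upsert_repository(_repo())
    fresh_store.upsert_notebook(_nb())
    fresh_store.put_outcome(1, OutcomeClass(OutcomeLabel.EXCLUDED),
                            attempted=False)
    clone = CorpusStore.from_dump(fresh_store.dump_sql())
    for table in fresh_store.tables():
        original = fresh_store.conn.execute(
            f"SELECT * FROM {table}").fetchall()
        copied = clone.conn.execute(f"SELECT * FROM {table}").fetchall()
        assert [tuple(r) for r in original] == [tuple(r) for r in copied]


def test_export_writes_every_table(fresh_store, tmp_path):
    fresh_store.upsert_repository(_repo())
    written = fresh_store.export_tables(tmp_path, fmt="csv")
    assert {p.stem for p in written} >= {"articles", "repositories",
                                         "notebooks", "outcomes"}
    assert all(p.exists() for p in written)
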