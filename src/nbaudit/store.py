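"""Single-file relational corpus store.

Every record the pipeline produces — journals, articles, authors,
repositories, notebooks, static profiles, environments, executions,
diffs, style findings, outcomes — is persisted in one SQLite database
whose DDL ships with the package (``schema.sql``).  Upserts are
idempotent on natural keys (PMC id, canonical repository URL,
repository+path).  Flow counts are computed by queries at read time,
never cached, and their conservation invariants are asserted before
they are returned; percentages are never stored.
"""

from __future__ import annotations

import json
import sqlite3
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Optional

from .records import (ArticleRecord, DeclarationSet, DiffReport,
                    EnvironmentSpec, ExecutionTrace, FlowCounts,
                    InstallOutcome, InvariantError, JournalRecord,
                    NotebookFile, NotebookStructure, MarkdownProfile,
                    NamingProfile, ImportProfile, OutcomeClass,
                    RepositoryRecord, StyleFinding)

SCHEMA_VERSION = 1


class ReferentialError(ValueError):
    """An upsert referenced an entity that is not in the store."""


def _j(value: Any) -> Optional[str]:
    return None if value is None else json.dumps(value, sort_keys=True)


class CorpusStore:
    """Thin typed layer over the SQLite corpus database."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row
        self.conn.execute("PRAGMA foreign_keys = ON")
        ddl = resources.files("nbaudit").joinpath("schema.sql").read_text()
        self.conn.executescript(ddl)
        if not self.conn.execute("SELECT 1 FROM schema_version").fetchone():
            self.conn.execute("INSERT INTO schema_version VALUES (?)",
                              (SCHEMA_VERSION,))
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- journals / articles ------------------------------------------------

    def upsert_journal(self, journal: JournalRecord) -> int:
        key = (f"issn:{journal.issn}" if journal.issn
               else f"title:{journal.title}")
        row = self.conn.execute(
            "SELECT id FROM journals WHERE dedup_key = ?", (key,)).fetchone()
        if row:
            return row["id"]
        cur = self.conn.execute(
            "INSERT INTO journals (dedup_key, issn, title, nlm_abbrev,"
            " iso_abbrev) VALUES (?,?,?,?,?)",
            (key, journal.issn, journal.title, journal.nlm_abbrev,
             journal.iso_abbrev))
        self.conn.commit()
        return cur.lastrowid

    def upsert_article(self, article: ArticleRecord,
                       journal_id: Optional[int] = None,
                       mesh_top_level: Optional[list[str]] = None) -> str:
        self.conn.execute(
            "INSERT INTO articles (pmc_id, pubmed_id, doi, title, journal_id,"
            " publisher_id, publisher_name, date_received, date_accepted,"
            " date_published, license_text, copyright_text, keywords,"
            " mesh_terms, mesh_top_level) VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)"
            " ON CONFLICT(pmc_id) DO UPDATE SET title=excluded.title,"
            " journal_id=excluded.journal_id, mesh_terms=excluded.mesh_terms,"
            " mesh_top_level=excluded.mesh_top_level",
            (article.pmc_id, article.pubmed_id, article.doi, article.title,
             journal_id, article.publisher_id, article.publisher_name,
             article.date_received, article.date_accepted,
             article.date_published, article.license_text,
             article.copyright_text, _j(article.keywords),
             _j(article.mesh_terms), _j(mesh_top_level)))
        for link in article.repo_links:
            self.conn.execute(
                "INSERT OR IGNORE INTO article_links (article_pmc,"
                " canonical_url, owner, repo_name, source_form)"
                " VALUES (?,?,?,?,?)",
                (article.pmc_id, link.canonical_url, link.owner,
                 link.repo_name, link.source_form.value))
        for rej in article.link_rejections:
            self.conn.execute(
                "INSERT OR IGNORE INTO link_rejections (article_pmc, raw_text,"
                " reason) VALUES (?,?,?)",
                (article.pmc_id, rej.raw_text, rej.reason.value))
        for author in article.authors:
            self.conn.execute(
                "INSERT OR IGNORE INTO authors (article_pmc, surname,"
                " given_names, orcid, email) VALUES (?,?,?,?,?)",
                (article.pmc_id, author.surname, author.given_names,
                 author.orcid, author.email))
        self.conn.commit()
        return article.pmc_id

    # -- repositories / notebooks -------------------------------------------

    def upsert_repository(self, repo: RepositoryRecord) -> str:
        cols = ("canonical_url", "available", "local_path",
                "default_branch_name", "created_date", "updated_date",
                "pushed_date", "language_census", "subscribers", "forks",
                "issues", "releases", "commits_after_published",
                "commits_after_accepted", "commits_after_received",
                "license_name")
        values = [repo.canonical_url, int(repo.available), repo.local_path,
                  repo.default_branch_name, repo.created_date,
                  repo.updated_date, repo.pushed_date,
                  _j(repo.language_census), repo.subscribers, repo.forks,
                  repo.issues, repo.releases, repo.commits_after_published,
                  repo.commits_after_accepted, repo.commits_after_received,
                  repo.license_name]
        updates = ", ".join(f"{c}=excluded.{c}" for c in cols[1:])
        self.conn.execute(
            f"INSERT INTO repositories ({','.join(cols)})"
            f" VALUES ({','.join('?' * len(cols))})"
            f" ON CONFLICT(canonical_url) DO UPDATE SET {updates}", values)
        self.conn.commit()
        return repo.canonical_url

    def _require_repo(self, repo_url: str) -> None:
        if not self.conn.execute("SELECT 1 FROM repositories WHERE"
                                 " canonical_url=?", (repo_url,)).fetchone():
            raise ReferentialError(f"unknown repository {repo_url!r}")

    def upsert_notebook(self, nb: NotebookFile) -> int:
        self._require_repo(nb.repo_ref)
        self.conn.execute(
            "INSERT INTO notebooks (repo_url, relative_path, file_size,"
            " parse_status) VALUES (?,?,?,?)"
            " ON CONFLICT(repo_url, relative_path) DO UPDATE SET"
            " file_size=excluded.file_size, parse_status=excluded.parse_status",
            (nb.repo_ref, nb.relative_path, nb.file_size,
             nb.parse_status.value))
        self.conn.commit()
        row = self.conn.execute(
            "SELECT id FROM notebooks WHERE repo_url=? AND relative_path=?",
            (nb.repo_ref, nb.relative_path)).fetchone()
        return row["id"]

    def _require_notebook(self, notebook_id: int) -> None:
        if not self.conn.execute("SELECT 1 FROM notebooks WHERE id=?",
                                 (notebook_id,)).fetchone():
            raise ReferentialError(f"unknown notebook id {notebook_id}")

    # -- profiles -----------------------------------------------------------

    def put_structure(self, notebook_id: int, s: NotebookStructure) -> None:
        self._require_notebook(notebook_id)
        self.conn.execute(
            "INSERT OR REPLACE INTO structures VALUES"
            " (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (notebook_id, s.nbformat_version[0], s.nbformat_version[1],
             s.kernel_name, s.language, s.language_version_full,
             s.major_version, s.cells_total, s.code_cells, s.markdown_cells,
             s.raw_cells, s.empty_cells, s.cells_with_output,
             s.max_execution_count, int(s.has_execution_counts)))
        self.conn.commit()

    def put_markdown(self, notebook_id: int, p: MarkdownProfile) -> None:
        self._require_notebook(notebook_id)
        self.conn.execute(
            "INSERT OR REPLACE INTO markdown_profiles VALUES (?,?,?,?,?,?)",
            (notebook_id, _j(sorted(p.languages_detected)),
             int(p.english_only), p.total_lines, p.total_words,
             _j(sorted(p.elements_present))))
        self.conn.commit()

    def put_naming(self, notebook_id: int, p: NamingProfile) -> None:
        self._require_notebook(notebook_id)
        self.conn.execute(
            "INSERT OR REPLACE INTO naming_profiles VALUES (?,?,?,?,?,?,?,?,?)",
            (notebook_id, p.title, p.title_length, int(p.posix_portable),
             int(p.exceeds_14_chars), int(p.windows_disallowed),
             int(p.is_untitled), int(p.contains_copy), int(p.contains_test)))
        self.conn.commit()

    def put_imports(self, notebook_id: int, p: ImportProfile) -> None:
        self._require_notebook(notebook_id)
        self.conn.execute(
            "INSERT OR REPLACE INTO import_profiles VALUES (?,?,?,?,?,?,?)",
            (notebook_id, _j(dict(p.modules_external)),
             _j(dict(p.modules_local)), p.functions_defined,
             p.classes_defined, _j(dict(p.load_extensions)),
             int(p.syntax_ok)))
        self.conn.commit()

    def put_style_findings(self, notebook_id: int,
                           findings: Iterable[StyleFinding]) -> None:
        self._require_notebook(notebook_id)
        self.conn.executemany(
            "INSERT OR IGNORE INTO style_findings (notebook_id, code,"
            " description, cell_index, line) VALUES (?,?,?,?,?)",
            [(notebook_id, f.code, f.description, f.cell_index, f.line)
             for f in findings])
        self.conn.commit()

    # -- environments / executions -------------------------------------------

    def put_declarations(self, repo_url: str, d: DeclarationSet) -> None:
        self._require_repo(repo_url)
        self.conn.execute(
            "INSERT OR REPLACE INTO declarations VALUES (?,?,?,?,?)",
            (repo_url, int(d.has_requirements), int(d.has_setup),
             int(d.has_pipfile), _j(d.declaration_paths)))
        self.conn.commit()

    def put_environment(self, spec: EnvironmentSpec,
                        outcome: InstallOutcome) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO environments VALUES (?,?,?,?,?,?,?,?)",
            (spec.env_key, spec.interpreter_version,
             spec.dependency_source.value, _j(list(spec.declaration_paths)),
             int(outcome.success), outcome.log_excerpt, outcome.duration,
             outcome.failed_stage.value))
        self.conn.commit()

    def put_execution(self, notebook_id: int, env_key: Optional[str],
                      t: ExecutionTrace) -> None:
        self._require_notebook(notebook_id)
        self.conn.execute(
            "INSERT OR REPLACE INTO executions VALUES (?,?,?,?,?,?,?,?,?,?,?)",
            (notebook_id, env_key, t.started, t.finished, t.duration,
             int(t.completed), int(t.timed_out), int(t.kernel_start_failed),
             t.first_exception_type, t.first_exception_cell,
             t.cells_executed))
        self.conn.commit()

    def put_diff(self, notebook_id: int, d: DiffReport) -> None:
        self._require_notebook(notebook_id)
        self.conn.execute(
            "INSERT OR REPLACE INTO diffs VALUES (?,?,?,?,?)",
            (notebook_id, d.output_diff_count, d.execcount_diff_count,
             d.file_diff_count, _j(d.per_cell)))
        self.conn.commit()

    def put_outcome(self, notebook_id: int, outcome: OutcomeClass,
                    attempted: bool) -> None:
        self._require_notebook(notebook_id)
        self.conn.execute(
            "INSERT OR REPLACE INTO outcomes VALUES (?,?,?,?)",
            (notebook_id, outcome.label.value, outcome.exception_type,
             int(attempted)))
        self.conn.commit()

    # -- flow accounting ------------------------------------------------------

    def _scalar(self, sql: str, *params: Any) -> int:
        return self.conn.execute(sql, params).fetchone()[0]

    def flow_counts(self) -> FlowCounts:
        """Stage counts computed by queries; invariants asserted on exit."""
        label_count = lambda *labels: self._scalar(  # noqa: E731
            "SELECT COUNT(*) FROM outcomes WHERE label IN (%s)"
            % ",".join("?" * len(labels)), *labels)
        install_failed = label_count("install_failed")
        exceptions = label_count("exception")
        excluded = self._scalar(
            "SELECT COUNT(*) FROM outcomes WHERE label IN ('timeout',"
            " 'excluded') AND attempted = 1")
        identical = label_count("finished_identical")
        different = label_count("finished_different")
        finished = identical + different
        executed = exceptions + excluded + finished
        attempted_flagged = self._scalar(
            "SELECT COUNT(*) FROM outcomes WHERE attempted = 1")
        if attempted_flagged != install_failed + executed:
            bad = [r["notebook_id"] for r in self.conn.execute(
                "SELECT notebook_id FROM outcomes WHERE attempted = 1 AND"
                " label IN ('repo_unavailable', 'not_target_language',"
                " 'no_declared_pipeline_entry')")]
            raise InvariantError(
                "attempted = install_failed + executed violated; offending"
                f" notebooks: {bad}")
        counts = FlowCounts(
            articles=self._scalar("SELECT COUNT(*) FROM articles"),
            repos_linked=self._scalar("SELECT COUNT(*) FROM repositories"),
            repos_available=self._scalar(
                "SELECT COUNT(*) FROM repositories WHERE available = 1"),
            repos_with_notebooks=self._scalar(
                "SELECT COUNT(DISTINCT repo_url) FROM notebooks"),
            notebooks_total=self._scalar("SELECT COUNT(*) FROM notebooks"),
            notebooks_target_language=self._scalar(
                "SELECT COUNT(*) FROM structures WHERE language = 'python'"),
            notebooks_attempted=install_failed + executed,
            install_failed=install_failed,
            executed=executed,
            exceptions=exceptions,
            excluded=excluded,
            finished=finished,
            finished_identical=identical,
            finished_different=different,
        )
        return counts

    # -- export / dump ---------------------------------------------------------

    def tables(self) -> list[str]:
        return [r["name"] for r in self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'"
            " ORDER BY name")]

    def export_tables(self, out_dir: str | Path, fmt: str = "csv") -> list[Path]:
        """Write every table as CSV or JSON under *out_dir*."""
        import pandas as pd
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for table in self.tables():
            frame = pd.read_sql_query(f"SELECT * FROM {table}", self.conn)
            path = out / f"{table}.{fmt}"
            if fmt == "csv":
                frame.to_csv(path, index=False)
            else:
                frame.to_json(path, orient="records", indent=1)
            written.append(path)
        return written

    def dump_sql(self) -> str:
        return "\n".join(self.conn.iterdump())

    @classmethod
    def from_dump(cls, sql: str, path: str | Path = ":memory:") -> "CorpusStore":
        store = cls.__new__(cls)
        store.path = str(path)
        store.conn = sqlite3.connect(store.path)
        store.conn.row_factory = sqlite3.Row
        store.conn.executescript(sql)
        store.conn.execute("PRAGMA foreign_keys = ON")
        return store
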