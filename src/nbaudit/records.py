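"""Domain records shared across the audit pipeline.

Every stage of the pipeline communicates through the small, explicit
records defined here: what an article said (``ArticleRecord``), what a
repository contained (``RepositoryRecord``, ``NotebookFile``), what a
notebook looks like statically (``NotebookStructure`` and friends), what
happened when we tried to rebuild its environment and re-run it
(``InstallOutcome``, ``ExecutionTrace``, ``DiffReport``), and the single
mutually exclusive verdict per notebook (``OutcomeClass``) that drives
all flow statistics.

Records validate their own invariants in ``__post_init__`` so that a
malformed record is rejected at the point of construction, naming the
violated clause.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class InvariantError(ValueError):
    """A record violated one of its declared invariants."""


def _require(cond: bool, clause: str) -> None:
    if not cond:
        raise InvariantError(clause)


# --------------------------------------------------------------------------
# literature mining
# --------------------------------------------------------------------------

class SourceForm(str, Enum):
    """How a repository link was written in the article text."""

    PLAIN = "plain"
    BLOB_PATH = "blob_path"
    TREE_PATH = "tree_path"
    NBVIEWER = "nbviewer"
    RAW_HOST = "raw_host"
    GIT_SUFFIX = "git_suffix"
    OTHER = "other"


class RejectionReason(str, Enum):
    OWNER_ONLY = "owner_only"
    PAGES_SITE = "pages_site"
    MALFORMED = "malformed"
    NON_REPO_HOST = "non_repo_host"


@dataclass(frozen=True)
class NormalizedRepoLink:
    """A repository mention normalized to ``https://github.com/{owner}/{repo}``."""

    owner: str
    repo_name: str
    source_form: SourceForm = SourceForm.PLAIN

    def __post_init__(self) -> None:
        _require(bool(self.owner) and "/" not in self.owner,
                 "owner nonempty and contains no '/'")
        _require(bool(self.repo_name) and "/" not in self.repo_name,
                 "repo_name nonempty and contains no '/'")

    @property
    def canonical_url(self) -> str:
        return f"https://github.com/{self.owner}/{self.repo_name}"

    def dedup_key(self) -> str:
        # the hosting service routes case-insensitively
        return f"{self.owner.lower()}/{self.repo_name.lower()}"


@dataclass(frozen=True)
class LinkRejection:
    raw_text: str
    reason: RejectionReason


@dataclass
class JournalRecord:
    issn: Optional[str] = None
    title: Optional[str] = None
    nlm_abbrev: Optional[str] = None
    iso_abbrev: Optional[str] = None

    def __post_init__(self) -> None:
        _require(self.issn is not None or self.title is not None,
                 "at least one of issn/title present")


@dataclass
class AuthorRecord:
    surname: Optional[str] = None
    given_names: Optional[str] = None
    orcid: Optional[str] = None
    email: Optional[str] = None


@dataclass
class ArticleRecord:
    pmc_id: str
    title: Optional[str] = None
    pubmed_id: Optional[str] = None
    doi: Optional[str] = None
    journal_ref: Optional[int] = None
    publisher_id: Optional[str] = None
    publisher_name: Optional[str] = None
    date_received: Optional[str] = None    # ISO "YYYY-MM-DD"
    date_accepted: Optional[str] = None
    date_published: Optional[str] = None
    license_text: Optional[str] = None
    copyright_text: Optional[str] = None
    keywords: list[str] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)
    repo_links: list[NormalizedRepoLink] = field(default_factory=list)
    link_rejections: list[LinkRejection] = field(default_factory=list)
    authors: list[AuthorRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        _require(bool(self.pmc_id), "pmc_id nonempty")
        if self.date_received and self.date_published:
            _require(self.date_published >= self.date_received,
                     "published date not earlier than received date")


# --------------------------------------------------------------------------
# repository harvesting
# --------------------------------------------------------------------------

class ParseStatus(str, Enum):
    PARSED = "parsed"
    INVALID_JSON = "invalid_json"
    INVALID_SCHEMA = "invalid_schema"


@dataclass
class RepositoryRecord:
    canonical_url: str
    available: bool = False
    local_path: Optional[str] = None
    default_branch_name: Optional[str] = None
    created_date: Optional[str] = None
    updated_date: Optional[str] = None
    pushed_date: Optional[str] = None
    language_census: Optional[dict[str, int]] = None
    subscribers: Optional[int] = None
    forks: Optional[int] = None
    issues: Optional[int] = None
    releases: Optional[int] = None
    commits_after_published: Optional[int] = None
    commits_after_accepted: Optional[int] = None
    commits_after_received: Optional[int] = None
    license_name: Optional[str] = None

    def __post_init__(self) -> None:
        _require(self.available == (self.local_path is not None),
                 "available=false iff local_path absent")
        for name in ("subscribers", "forks", "issues", "releases",
                     "commits_after_published", "commits_after_accepted",
                     "commits_after_received"):
            val = getattr(self, name)
            if val is not None:
                _require(val >= 0, f"{name} nonnegative")


@dataclass(frozen=True)
class NotebookFile:
    repo_ref: str
    relative_path: str
    file_size: int
    parse_status: ParseStatus

    def __post_init__(self) -> None:
        _require(self.relative_path.endswith(".ipynb"),
                 "relative_path ends with '.ipynb'")
        _require(self.file_size >= 0, "file_size nonnegative")


# --------------------------------------------------------------------------
# notebook static census
# --------------------------------------------------------------------------

@dataclass
class NotebookStructure:
    nbformat_version: tuple[int, int]
    kernel_name: Optional[str]
    language: str
    language_version_full: Optional[str]
    major_version: Optional[int]
    cells_total: int
    code_cells: int
    markdown_cells: int
    raw_cells: int
    empty_cells: int
    cells_with_output: int
    max_execution_count: Optional[int]
    has_execution_counts: bool

    def __post_init__(self) -> None:
        _require(self.cells_total ==
                 self.code_cells + self.markdown_cells + self.raw_cells,
                 "cells_total = code + markdown + raw")
        _require(self.empty_cells <= self.cells_total,
                 "empty_cells <= cells_total")
        _require(self.cells_with_output <= self.code_cells,
                 "cells_with_output <= code_cells")
        _require((self.max_execution_count is None) ==
                 (not self.has_execution_counts),
                 "max_execution_count absent iff has_execution_counts=false")


UNDETECTED = "undetected"

MARKDOWN_ELEMENTS = ("header", "paragraph", "list", "code_block",
                     "link", "image", "table")


@dataclass
class MarkdownProfile:
    languages_detected: frozenset[str]
    english_only: bool
    total_lines: int
    total_words: int
    elements_present: frozenset[str]

    def __post_init__(self) -> None:
        if self.english_only:
            _require("en" in self.languages_detected,
                     "english_only implies 'en' detected")
        if self.total_words == 0:
            _require(self.languages_detected == frozenset({UNDETECTED}),
                     "no words implies languages {undetected}")
        _require(self.elements_present <= frozenset(MARKDOWN_ELEMENTS),
                 "elements_present within the known element set")


@dataclass
class NamingProfile:
    title: str
    title_length: int
    posix_portable: bool
    exceeds_14_chars: bool
    windows_disallowed: bool
    is_untitled: bool
    contains_copy: bool
    contains_test: bool

    def __post_init__(self) -> None:
        _require(self.title_length == len(self.title) and self.title_length >= 1,
                 "title_length = len(title) >= 1")


@dataclass
class ImportProfile:
    modules_external: Counter
    modules_local: Counter
    functions_defined: int
    classes_defined: int
    load_extensions: Counter
    directives: list[str]
    syntax_ok: bool

    def __post_init__(self) -> None:
        _require(not (set(self.modules_external) & set(self.modules_local)),
                 "local and external multisets disjoint as sets")


@dataclass(frozen=True)
class StyleFinding:
    code: str
    description: str
    cell_index: int
    line: int

    def __post_init__(self) -> None:
        _require(len(self.code) >= 2 and self.code[0].isalpha()
                 and self.code[1:].isdigit(),
                 "code matches letter+digits")


# --------------------------------------------------------------------------
# environment building
# --------------------------------------------------------------------------

@dataclass
class DeclarationSet:
    has_requirements: bool = False
    has_setup: bool = False
    has_pipfile: bool = False
    declaration_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.has_requirements or self.has_setup or self.has_pipfile):
            _require(not self.declaration_paths,
                     "all flags false implies declaration_paths empty")

    @property
    def any(self) -> bool:
        return bool(self.declaration_paths)


class DependencySource(str, Enum):
    DECLARED = "declared"
    DISTRIBUTION_BUNDLE = "distribution_bundle"


@dataclass(frozen=True)
class EnvironmentSpec:
    interpreter_version: str            # "3.7" style, or "default"
    dependency_source: DependencySource
    declaration_paths: tuple[str, ...]
    env_key: str

    def __post_init__(self) -> None:
        if self.dependency_source is DependencySource.DECLARED:
            _require(bool(self.declaration_paths),
                     "declared source implies declaration_paths nonempty")


class FailedStage(str, Enum):
    CREATE = "create"
    INSTALL = "install"
    NONE = "none"


@dataclass
class InstallOutcome:
    success: bool
    log_excerpt: str
    duration: float
    failed_stage: FailedStage
    env_path: Optional[str] = None

    def __post_init__(self) -> None:
        _require(self.success == (self.failed_stage is FailedStage.NONE),
                 "success=true iff failed_stage=none")


# --------------------------------------------------------------------------
# execution and outcome
# --------------------------------------------------------------------------

@dataclass
class ExecutionTrace:
    started: str
    finished: str
    duration: float
    completed: bool
    timed_out: bool
    kernel_start_failed: bool
    first_exception_type: Optional[str]
    first_exception_cell: Optional[int]   # position among executed code cells
    cells_executed: int

    def __post_init__(self) -> None:
        if self.completed:
            _require(self.first_exception_type is None and not self.timed_out,
                     "completed implies no exception and no timeout")
        if self.first_exception_type is not None:
            _require(self.cells_executed == self.first_exception_cell + 1,
                     "cells_executed = first_exception_cell + 1")


@dataclass
class DiffReport:
    output_diff_count: int
    execcount_diff_count: int
    file_diff_count: int
    per_cell: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        _require(self.output_diff_count ==
                 sum(1 for _, kind, _ in self.per_cell if kind == "output"),
                 "output_diff_count matches per_cell entries of kind output")
        for name in ("output_diff_count", "execcount_diff_count",
                     "file_diff_count"):
            _require(getattr(self, name) >= 0, f"{name} nonnegative")


class OutcomeLabel(str, Enum):
    REPO_UNAVAILABLE = "repo_unavailable"
    NOT_TARGET_LANGUAGE = "not_target_language"
    NO_DECLARED_PIPELINE_ENTRY = "no_declared_pipeline_entry"
    INSTALL_FAILED = "install_failed"
    EXCEPTION = "exception"
    TIMEOUT = "timeout"
    EXCLUDED = "excluded"
    FINISHED_DIFFERENT = "finished_different"
    FINISHED_IDENTICAL = "finished_identical"


@dataclass(frozen=True)
class OutcomeClass:
    label: OutcomeLabel
    exception_type: Optional[str] = None

    def __post_init__(self) -> None:
        _require((self.exception_type is not None) ==
                 (self.label is OutcomeLabel.EXCEPTION),
                 "exception_type present iff label=exception")


# --------------------------------------------------------------------------
# flow accounting
# --------------------------------------------------------------------------

@dataclass
class FlowCounts:
    articles: int = 0
    repos_linked: int = 0
    repos_available: int = 0
    repos_with_notebooks: int = 0
    notebooks_total: int = 0
    notebooks_target_language: int = 0
    notebooks_attempted: int = 0
    install_failed: int = 0
    executed: int = 0
    exceptions: int = 0
    excluded: int = 0
    finished: int = 0
    finished_identical: int = 0
    finished_different: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _require(getattr(self, f.name) >= 0, f"{f.name} nonnegative")
        _require(self.notebooks_attempted == self.install_failed + self.executed,
                 "attempted = install_failed + executed")
        _require(self.executed == self.exceptions + self.excluded + self.finished,
                 "executed = exceptions + excluded + finished")
        _require(self.finished ==
                 self.finished_identical + self.finished_different,
                 "finished = identical + different")
        _require(self.repos_with_notebooks <= self.repos_available
                 <= self.repos_linked,
                 "repos_with_notebooks <= repos_available <= repos_linked")
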