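-- nbaudit corpus store schema, version 1.
-- One row per entity; natural keys enforce idempotent upserts.

CREATE TABLE IF NOT EXISTS schema_version (
    version INTEGER NOT NULL
);

CREATE TABLE IF NOT EXISTS journals (
    id INTEGER PRIMARY KEY,
    dedup_key TEXT NOT NULL UNIQUE,
    issn TEXT,
    title TEXT,
    nlm_abbrev TEXT,
    iso_abbrev TEXT
);

CREATE TABLE IF NOT EXISTS articles (
    pmc_id TEXT PRIMARY KEY,
    pubmed_id TEXT,
    doi TEXT,
    title TEXT,
    journal_id INTEGER REFERENCES journals(id),
    publisher_id TEXT,
    publisher_name TEXT,
    date_received TEXT,
    date_accepted TEXT,
    date_published TEXT,
    license_text TEXT,
    copyright_text TEXT,
    keywords TEXT,          -- JSON array
    mesh_terms TEXT,        -- JSON array
    mesh_top_level TEXT     -- JSON array
);

CREATE TABLE IF NOT EXISTS authors (
    id INTEGER PRIMARY KEY,
    article_pmc TEXT NOT NULL REFERENCES articles(pmc_id),
    surname TEXT,
    given_names TEXT,
    orcid TEXT,
    email TEXT,
    UNIQUE (article_pmc, surname, given_names, orcid)
);

CREATE TABLE IF NOT EXISTS article_links (
    id INTEGER PRIMARY KEY,
    article_pmc TEXT NOT NULL REFERENCES articles(pmc_id),
    canonical_url TEXT NOT NULL,
    owner TEXT NOT NULL,
    repo_name TEXT NOT NULL,
    source_form TEXT NOT NULL,
    UNIQUE (article_pmc, canonical_url, source_form)
);

CREATE TABLE IF NOT EXISTS link_rejections (
    id INTEGER PRIMARY KEY,
    article_pmc TEXT NOT NULL REFERENCES articles(pmc_id),
    raw_text TEXT NOT NULL,
    reason TEXT NOT NULL,
    UNIQUE (article_pmc, raw_text, reason)
);

CREATE TABLE IF NOT EXISTS repositories (
    canonical_url TEXT PRIMARY KEY,
    available INTEGER NOT NULL,
    local_path TEXT,
    default_branch_name TEXT,
    created_date TEXT,
    updated_date TEXT,
    pushed_date TEXT,
    language_census TEXT,   -- JSON object
    subscribers INTEGER,
    forks INTEGER,
    issues INTEGER,
    releases INTEGER,
    commits_after_published INTEGER,
    commits_after_accepted INTEGER,
    commits_after_received INTEGER,
    license_name TEXT
);

CREATE TABLE IF NOT EXISTS notebooks (
    id INTEGER PRIMARY KEY,
    repo_url TEXT NOT NULL REFERENCES repositories(canonical_url),
    relative_path TEXT NOT NULL,
    file_size INTEGER NOT NULL,
    parse_status TEXT NOT NULL,
    UNIQUE (repo_url, relative_path)
);

CREATE TABLE IF NOT EXISTS structures (
    notebook_id INTEGER PRIMARY KEY REFERENCES notebooks(id),
    nbformat_major INTEGER,
    nbformat_minor INTEGER,
    kernel_name TEXT,
    language TEXT,
    language_version_full TEXT,
    major_version INTEGER,
    cells_total INTEGER,
    code_cells INTEGER,
    markdown_cells INTEGER,
    raw_cells INTEGER,
    empty_cells INTEGER,
    cells_with_output INTEGER,
    max_execution_count INTEGER,
    has_execution_counts INTEGER
);

CREATE TABLE IF NOT EXISTS markdown_profiles (
    notebook_id INTEGER PRIMARY KEY REFERENCES notebooks(id),
    languages_detected TEXT,  -- JSON array
    english_only INTEGER,
    total_lines INTEGER,
    total_words INTEGER,
    elements_present TEXT     -- JSON array
);

CREATE TABLE IF NOT EXISTS naming_profiles (
    notebook_id INTEGER PRIMARY KEY REFERENCES notebooks(id),
    title TEXT,
    title_length INTEGER,
    posix_portable INTEGER,
    exceeds_14_chars INTEGER,
    windows_disallowed INTEGER,
    is_untitled INTEGER,
    contains_copy INTEGER,
    contains_test INTEGER
);

CREATE TABLE IF NOT EXISTS import_profiles (
    notebook_id INTEGER PRIMARY KEY REFERENCES notebooks(id),
    modules_external TEXT,   -- JSON object name -> count
    modules_local TEXT,
    functions_defined INTEGER,
    classes_defined INTEGER,
    load_extensions TEXT,
    syntax_ok INTEGER
);

CREATE TABLE IF NOT EXISTS style_findings (
    id INTEGER PRIMARY KEY,
    notebook_id INTEGER NOT NULL REFERENCES notebooks(id),
    code TEXT NOT NULL,
    description TEXT NOT NULL,
    cell_index INTEGER NOT NULL,
    line INTEGER NOT NULL,
    UNIQUE (notebook_id, code, cell_index, line)
);

CREATE TABLE IF NOT EXISTS declarations (
    repo_url TEXT PRIMARY KEY REFERENCES repositories(canonical_url),
    has_requirements INTEGER,
    has_setup INTEGER,
    has_pipfile INTEGER,
    declaration_paths TEXT   -- JSON array
);

CREATE TABLE IF NOT EXISTS environments (
    env_key TEXT PRIMARY KEY,
    interpreter_version TEXT,
    dependency_source TEXT,
    declaration_paths TEXT,  -- JSON array
    success INTEGER,
    log_excerpt TEXT,
    duration REAL,
    failed_stage TEXT
);

CREATE TABLE IF NOT EXISTS executions (
    notebook_id INTEGER PRIMARY KEY REFERENCES notebooks(id),
    env_key TEXT REFERENCES environments(env_key),
    started TEXT,
    finished TEXT,
    duration REAL,
    completed INTEGER,
    timed_out INTEGER,
    kernel_start_failed INTEGER,
    first_exception_type TEXT,
    first_exception_cell INTEGER,
    cells_executed INTEGER
);

CREATE TABLE IF NOT EXISTS diffs (
    notebook_id INTEGER PRIMARY KEY REFERENCES notebooks(id),
    output_diff_count INTEGER,
    execcount_diff_count INTEGER,
    file_diff_count INTEGER,
    per_cell TEXT            -- JSON array of [cell, kind, summary]
);

CREATE TABLE IF NOT EXISTS outcomes (
    notebook_id INTEGER PRIMARY KEY REFERENCES notebooks(id),
    label TEXT NOT NULL,
    exception_type TEXT,
    attempted INTEGER NOT NULL DEFAULT 0
);
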