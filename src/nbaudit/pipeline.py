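"""End-to-end orchestration: mine -> harvest -> profile -> env -> run -> report.

Ties the stage modules together over one workspace and one corpus
store.  Every stage is resumable and idempotent at the store level; the
flow-count invariants are asserted after the run (and can be asserted
after any stage — counts are derived from stage-record presence, never
cached).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from . import harvest as harvest_mod
from . import jats
from .classify import classify_outcome
from .diffing import diff_against_original
from .envs import (EnvironmentManager, EnvironmentPolicy, NullBackend,
                   VenvBackend, detect_declarations, plan_environment)
from .execute import execute_notebook, snapshot_files
from .lang import Detector, stopword_detector
from .mesh import TreeLookup, resolve_top_level_mesh, table_lookup
from .profiles import (is_target_language, profile_imports, profile_markdown,
                       profile_name, profile_structure)
from .store import CorpusStore
from .style import profile_style
from .records import FlowCounts, OutcomeClass, OutcomeLabel, ParseStatus
from . import notebook

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs for one audit run.

    ``repo_sources`` maps canonical repository URLs to local clone
    sources (offline corpora); URLs not in the map are cloned from the
    network with the git backend.  ``package_index`` points the venv
    backend at a local wheel index.
    """
    workspace: Path = Path("workspace")
    exec_timeout: float = 30.0
    strict_counters: bool = False
    strict_files: bool = False
    mask_transients: bool = False
    policy: EnvironmentPolicy = field(default_factory=EnvironmentPolicy)
    package_index: Optional[str] = None
    backend: str = "venv"                     # venv | null
    repo_sources: dict[str, Optional[str]] = field(default_factory=dict)
    mesh_lookup: TreeLookup = staticmethod(table_lookup({}))
    lang_detector: Detector = staticmethod(stopword_detector)


def _make_backend(config: PipelineConfig):
    if config.backend == "null":
        return NullBackend()
    if config.backend == "venv":
        return VenvBackend(package_index=config.package_index)
    raise ValueError(f"unknown backend {config.backend!r}")


def _vcs_for(config: PipelineConfig, canonical_url: str):
    if canonical_url in config.repo_sources:
        source = config.repo_sources[canonical_url]
        if source is None:
            def backend(_src, _dest):
                raise harvest_mod.RepoUnavailable("not in offline source map")
            return backend, canonical_url
        return harvest_mod.copy_backend, source
    return harvest_mod.git_clone_backend, canonical_url


def mine_stage(store: CorpusStore, xml_dir: str | Path,
               config: PipelineConfig) -> list[str]:
    """Parse all article XML, persist articles/journals, return link URLs."""
    articles, registry = jats.mine_directory(xml_dir)
    journal_ids = [store.upsert_journal(j) for j in registry.records()]
    links: dict[str, str] = {}  # dedup key -> canonical url (first wins)
    for article in articles:
        jid = (journal_ids[article.journal_ref]
               if article.journal_ref is not None else None)
        top = resolve_top_level_mesh(article.mesh_terms, config.mesh_lookup)
        store.upsert_article(article, journal_id=jid, mesh_top_level=top)
        for link in article.repo_links:
            links.setdefault(link.dedup_key(), link.canonical_url)
    return list(links.values())


def harvest_stage(store: CorpusStore, canonical_urls: list[str],
                  config: PipelineConfig) -> None:
    from .records import NormalizedRepoLink
    clones = Path(config.workspace) / "clones"
    for url in canonical_urls:
        owner, name = url.rsplit("/", 2)[-2:]
        link = NormalizedRepoLink(owner=owner, repo_name=name)
        backend, source = _vcs_for(config, url)
        record = harvest_mod.acquire_repository(link, clones, backend,
                                                source=source)
        store.upsert_repository(record)
        if record.available:
            for nb in harvest_mod.enumerate_notebooks(record.local_path,
                                                      repo_ref=url):
                store.upsert_notebook(nb)
            store.put_declarations(url, detect_declarations(record.local_path))


def profile_stage(store: CorpusStore, config: PipelineConfig) -> None:
    rows = store.conn.execute(
        "SELECT n.id, n.repo_url, n.relative_path, n.parse_status,"
        " r.local_path FROM notebooks n JOIN repositories r"
        " ON r.canonical_url = n.repo_url").fetchall()
    for row in rows:
        if row["parse_status"] != ParseStatus.PARSED.value:
            continue
        nb_path = Path(row["local_path"]) / row["relative_path"]
        doc = notebook.load(nb_path)
        structure = profile_structure(doc)
        store.put_structure(row["id"], structure)
        store.put_naming(row["id"], profile_name(row["relative_path"]))
        store.put_markdown(row["id"],
                           profile_markdown(doc, config.lang_detector))
        if is_target_language(structure):
            store.put_imports(row["id"],
                              profile_imports(doc, row["local_path"]))
            store.put_style_findings(row["id"], profile_style(doc))


def run_stage(store: CorpusStore, config: PipelineConfig) -> None:
    """Environment setup, execution, diffing and classification."""
    manager = EnvironmentManager(backend=_make_backend(config),
                                 workspace=Path(config.workspace),
                                 policy=config.policy)
    results_dir = Path(config.workspace) / "results"

    rows = store.conn.execute(
        "SELECT n.id, n.repo_url, n.relative_path, n.parse_status,"
        " r.local_path, r.available FROM notebooks n JOIN repositories r"
        " ON r.canonical_url = n.repo_url ORDER BY n.repo_url,"
        " n.relative_path").fetchall()
    from .records import RepositoryRecord
    for row in rows:
        repo = RepositoryRecord(canonical_url=row["repo_url"],
                                available=bool(row["available"]),
                                local_path=row["local_path"])
        if row["parse_status"] != ParseStatus.PARSED.value:
            store.put_outcome(row["id"], classify_outcome(repo, None),
                              attempted=False)
            continue
        nb_path = Path(row["local_path"]) / row["relative_path"]
        doc = notebook.load(nb_path)
        structure = profile_structure(doc)
        if not is_target_language(structure):
            store.put_outcome(row["id"], classify_outcome(repo, structure),
                              attempted=False)
            continue

        declarations = detect_declarations(row["local_path"])
        spec = plan_environment(structure, declarations, config.policy,
                                repo_key=row["repo_url"])
        install = manager.materialize(spec, repo_root=row["local_path"])
        store.put_environment(spec, install)
        if not install.success:
            store.put_outcome(
                row["id"], classify_outcome(repo, structure, install),
                attempted=True)
            continue

        scratch = results_dir / row["repo_url"].rsplit("/", 1)[-1] \
            / Path(row["relative_path"]).parent
        before = snapshot_files(nb_path.parent)
        trace, executed_doc = execute_notebook(
            nb_path, install.env_path, config.exec_timeout, scratch)
        after = snapshot_files(nb_path.parent)
        store.put_execution(row["id"], spec.env_key, trace)

        diff = None
        if trace.completed and executed_doc is not None:
            diff = diff_against_original(doc, executed_doc, before, after,
                                         mask_transients=config.mask_transients)
            store.put_diff(row["id"], diff)
        outcome = classify_outcome(repo, structure, install, trace, diff,
                                   strict_counters=config.strict_counters,
                                   strict_files=config.strict_files)
        store.put_outcome(row["id"], outcome, attempted=True)


def run_pipeline(xml_dir: str | Path, store: CorpusStore,
                 config: PipelineConfig) -> FlowCounts:
    """Full audit over a directory of article XML; returns flow counts."""
    links = mine_stage(store, xml_dir, config)
    store.flow_counts()          # conservation holds after every stage
    harvest_stage(store, links, config)
    store.flow_counts()
    profile_stage(store, config)
    store.flow_counts()
    run_stage(store, config)
    return store.flow_counts()
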