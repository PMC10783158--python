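"""Acquiring linked repositories and enumerating their notebooks.

Only the default branch of each repository is taken — the audit never
looks at other branches.  A repository that cannot be reached is a
recorded fact (``available=False``), not an error: unavailable
repositories feed the flow statistics like any other stage.

The actual clone step is injectable.  :func:`git_clone_backend` shells
out to the ``git`` CLI (shallow, single-branch); :func:`copy_backend`
copies a local directory tree and is what tests and offline corpora use.
"""

from __future__ import annotations

import shutil
import subprocess
from pathlib import Path
from typing import Callable, Optional

from . import notebook
from .records import NormalizedRepoLink, NotebookFile, ParseStatus, RepositoryRecord

#: a clone function: (source url/path, destination) -> default branch name.
#: Raises ``RepoUnavailable`` when the remote does not exist.
VcsBackend = Callable[[str, Path], str]

HIDDEN_DIRS = {".git", ".ipynb_checkpoints", ".hg", ".svn"}
DEFAULT_PARSE_CAP = 64 * 1024 * 1024  # files above this are recorded, not parsed


class RepoUnavailable(Exception):
    """The remote repository does not exist / cannot be reached."""


def git_clone_backend(source: str, dest: Path) -> str:
    """Shallow single-branch clone of the default branch via the git CLI."""
    proc = subprocess.run(
        ["git", "clone", "--depth", "1", "--quiet", source, str(dest)],
        capture_output=True, text=True)
    if proc.returncode != 0:
        raise RepoUnavailable(proc.stderr.strip()[-500:])
    head = subprocess.run(
        ["git", "-C", str(dest), "symbolic-ref", "--short", "HEAD"],
        capture_output=True, text=True)
    return head.stdout.strip() or "HEAD"


def copy_backend(source: str, dest: Path, branch_name: str = "main") -> str:
    """Treat a local directory as the repository's default branch."""
    src = Path(source)
    if not src.is_dir():
        raise RepoUnavailable(f"no such directory: {source}")
    shutil.copytree(src, dest, symlinks=True,
                    ignore=shutil.ignore_patterns(".git"))
    return branch_name


def _workspace_slot(workspace: Path, link: NormalizedRepoLink) -> Path:
    return workspace / link.owner / link.repo_name


def acquire_repository(link: NormalizedRepoLink, workspace: Path,
                       vcs_backend: VcsBackend,
                       source: Optional[str] = None) -> RepositoryRecord:
    """Materialize the default branch of *link* under *workspace*.

    *source* overrides the clone source (offline corpora map canonical
    URLs to local directories); by default the canonical URL is used.
    Re-acquisition over an unchanged workspace is a no-op.
    """
    workspace = Path(workspace)
    workspace.mkdir(parents=True, exist_ok=True)
    dest = _workspace_slot(workspace, link)
    if dest.exists():  # idempotent harvest
        marker = dest / ".nbaudit-branch"
        branch = marker.read_text().strip() if marker.exists() else "HEAD"
        return RepositoryRecord(canonical_url=link.canonical_url,
                                available=True, local_path=str(dest),
                                default_branch_name=branch)
    try:
        branch = vcs_backend(source or link.canonical_url, dest)
    except RepoUnavailable:
        shutil.rmtree(dest, ignore_errors=True)
        return RepositoryRecord(canonical_url=link.canonical_url,
                                available=False)
    (dest / ".nbaudit-branch").write_text(branch + "\n")
    return RepositoryRecord(canonical_url=link.canonical_url, available=True,
                            local_path=str(dest), default_branch_name=branch)


def enumerate_notebooks(repo_root: str | Path, repo_ref: str = "",
                        parse_cap: int = DEFAULT_PARSE_CAP) -> list[NotebookFile]:
    """All ``*.ipynb`` files under *repo_root*, lexicographic, hidden dirs
    and checkpoint copies excluded; symbolic links are not followed."""
    root = Path(repo_root)
    if not root.exists():
        raise FileNotFoundError(repo_root)
    records = []
    for path in sorted(root.rglob("*.ipynb")):
        rel = path.relative_to(root)
        if any(part in HIDDEN_DIRS for part in rel.parts):
            continue
        if any(p.is_symlink() for p in (root / Path(*rel.parts[:i + 1])
                                        for i in range(len(rel.parts)))):
            continue
        size = path.stat().st_size
        if size > parse_cap:
            status = ParseStatus.INVALID_SCHEMA
        else:
            _, status = notebook.try_load(path)
        records.append(NotebookFile(repo_ref=repo_ref or str(root),
                                    relative_path=str(rel),
                                    file_size=size, parse_status=status))
    return records


_METADATA_KEYS = {
    "created_at": "created_date",
    "updated_at": "updated_date",
    "pushed_at": "pushed_date",
    "languages": "language_census",
    "subscribers_count": "subscribers",
    "forks_count": "forks",
    "open_issues_count": "issues",
    "releases_count": "releases",
    "commits_after_published": "commits_after_published",
    "commits_after_accepted": "commits_after_accepted",
    "commits_after_received": "commits_after_received",
    "license_name": "license_name",
}


def ingest_repo_metadata(record: RepositoryRecord,
                         api_payload: dict) -> RepositoryRecord:
    """Copy recognized hosting-API fields onto *record*.

    Unknown keys are ignored; absent keys leave the field absent.  Short
    aliases without the ``_count``/``_at`` suffix are accepted too.
    """
    aliases = dict(_METADATA_KEYS)
    aliases.update({"subscribers": "subscribers", "forks": "forks",
                    "issues": "issues", "releases": "releases"})
    for key, value in api_payload.items():
        field_name = aliases.get(key)
        if field_name is not None:
            setattr(record, field_name, value)
    record.__post_init__()  # revalidate invariants
    return record
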