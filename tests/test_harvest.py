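"""Repository acquisition and notebook enumeration."""

import json
import subprocess

import pytest

from nbaudit import notebook
from nbaudit.harvest import (acquire_repository, copy_backend,
                             enumerate_notebooks, git_clone_backend,
                             ingest_repo_metadata)
from nbaudit.records import (NormalizedRepoLink, ParseStatus,
                             RepositoryRecord)


def _link(owner="lab", name="proj"):
    return NormalizedRepoLink(owner=owner, repo_name=name)


def _write_nb(path):
    path.parent.mkdir(parents=True, exist_ok=True)
    notebook.dump(notebook.new_notebook([notebook.code_cell("1 + 1\n")]), path)


def test_copy_backend_acquires_local_tree(tmp_path):
    src = tmp_path / "src"
    _write_nb(src / "a.ipynb")
    record = acquire_repository(_link(), tmp_path / "ws", copy_backend,
                                source=str(src))
    assert record.available and record.default_branch_name == "main"
    assert (tmp_path / "ws" / "lab" / "proj" / "a.ipynb").exists()


def test_missing_remote_is_recorded_not_raised(tmp_path):
    record = acquire_repository(_link(), tmp_path / "ws", copy_backend,
                                source=str(tmp_path / "nowhere"))
    assert record.available is False and record.local_path is None


def test_reacquisition_is_a_noop(tmp_path):
    src = tmp_path / "src"
    _write_nb(src / "a.ipynb")
    first = acquire_repository(_link(), tmp_path / "ws", copy_backend,
                               source=str(src))
    _write_nb(src / "b.ipynb")  # later upstream change is not re-fetched
    second = acquire_repository(_link(), tmp_path / "ws", copy_backend,
                                source=str(src))
    assert second.local_path == first.local_path
    assert not (tmp_path / "ws" / "lab" / "proj" / "b.ipynb").exists()


def test_git_backend_clones_default_branch_only(tmp_path):
    origin = tmp_path / "origin"
    _write_nb(origin / "main_nb.ipynb")
    env = {"GIT_AUTHOR_NAME": "t", "GIT_AUTHOR_EMAIL": "t@x",
           "GIT_COMMITTER_NAME": "t", "GIT_COMMITTER_EMAIL": "t@x",
           "HOME": str(tmp_path)}
    run = lambda *args: subprocess.run(  # noqa: E731
        ["git", "-C", str(origin), *args], check=True, env=env,
        capture_output=True)
    subprocess.run(["git", "init", "-q", "-b", "main", str(origin)],
                   check=True, env=env, capture_output=True)
    run("add", "-A")
    run("commit", "-q", "-m", "init")
    run("checkout", "-q", "-b", "dev")
    _write_nb(origin / "dev_only.ipynb")
    run("add", "-A")
    run("commit", "-q", "-m", "dev nb")
    run("checkout", "-q", "main")

    record = acquire_repository(_link(), tmp_path / "ws", git_clone_backend,
                                source=str(origin))
    assert record.available and record.default_branch_name == "main"
    names = [nb.relative_path for nb in
             enumerate_notebooks(record.local_path)]
    assert names == ["main_nb.ipynb"]  # the dev-branch notebook is unseen


def test_enumeration_excludes_checkpoints_and_flags_bad_json(tmp_path):
    repo = tmp_path / "repo"
    for rel in ("top.ipynb", "deep/nested/inner.ipynb", "deep/other.ipynb"):
        _write_nb(repo / rel)
    ckpt = repo / ".ipynb_checkpoints"
    ckpt.mkdir()
    (ckpt / "top-checkpoint.ipynb").write_text("{}")
    (repo / "broken.ipynb").write_text("not json at all")
    (repo / "notnb.ipynb").write_text(json.dumps({"cells": []}))

    records = enumerate_notebooks(repo, repo_ref="r")
    by_path = {r.relative_path: r.parse_status for r in records}
    assert ".ipynb_checkpoints/top-checkpoint.ipynb" not in by_path
    assert by_path["broken.ipynb"] is ParseStatus.INVALID_JSON
    assert by_path["notnb.ipynb"] is ParseStatus.INVALID_SCHEMA
    parsed = [p for p, s in sorted(by_path.items())
              if s is ParseStatus.PARSED]
    assert parsed == ["deep/nested/inner.ipynb", "deep/other.ipynb",
                      "top.ipynb"]


def test_forged_repositories_enumerate_to_their_manifests(corpus):
    corpus_root, manifest = corpus
    for repo in manifest.repos:
        if not repo.available:
            continue
        records = enumerate_notebooks(corpus_root / repo.path,
                                      repo_ref=repo.slug)
        found = sorted(r.relative_path for r in records)
        expected = sorted(nb.path for nb in manifest.notebooks
                          if nb.repo == repo.slug)
        assert found == expected, repo.slug
        assert all(r.parse_status is ParseStatus.PARSED for r in records)


def test_metadata_ingest_copies_known_keys_only():
    record = RepositoryRecord(canonical_url="https://github.com/a/b",
                              available=False)
    ingest_repo_metadata(record, {"forks": 2, "subscribers": 5,
                                  "mystery_key": "ignored"})
    assert record.forks == 2 and record.subscribers == 5
    assert record.issues is None and record.license_name is None
    ingest_repo_metadata(record, {})
    assert record.forks == 2  # empty payload changes nothing
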