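"""Shared fixtures: one forged corpus and one full pipeline run per session.

The forged corpus is the ground-truth oracle for every round-trip test;
the pipeline run over it (lightweight venv backend, local package
index) is expensive, so it is executed once and shared.
"""

from __future__ import annotations

import shutil
from pathlib import Path

import pytest

from nbaudit.envs import EnvironmentPolicy
from nbaudit.forge import MESH_TABLE, ForgeManifest, forge_corpus
from nbaudit.mesh import table_lookup
from nbaudit.pipeline import PipelineConfig, run_pipeline
from nbaudit.store import CorpusStore

EXEC_TIMEOUT = 3.0
TIMEOUT_SLEEP = 5 * EXEC_TIMEOUT
FORGE_SEED = 1


@pytest.fixture(scope="session")
def corpus(tmp_path_factory) -> tuple[Path, ForgeManifest]:
    root = tmp_path_factory.mktemp("corpus")
    manifest = forge_corpus(root, seed=FORGE_SEED, timeout_sleep=TIMEOUT_SLEEP)
    return root, manifest


def make_config(corpus_root: Path, manifest: ForgeManifest,
                workspace: Path, **overrides) -> PipelineConfig:
    cfg = PipelineConfig(
        workspace=workspace,
        exec_timeout=EXEC_TIMEOUT,
        policy=EnvironmentPolicy(distribution_bundle=("forgelib",),
                                 install_timeout=300.0),
        package_index=str(corpus_root / "index"),
        repo_sources=manifest.repo_sources(corpus_root),
        mesh_lookup=table_lookup(MESH_TABLE),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def pipeline_run(corpus, tmp_path_factory):
    """(store, flow counts, manifest) for one full audit of the corpus."""
    corpus_root, manifest = corpus
    workspace = tmp_path_factory.mktemp("pipeline-ws")
    cfg = make_config(corpus_root, manifest, workspace)
    store = CorpusStore(workspace / "store.db")
    flow = run_pipeline(corpus_root / "articles", store, cfg)
    yield store, flow, manifest
    store.close()


@pytest.fixture()
def fresh_store() -> CorpusStore:
    return CorpusStore(":memory:")
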