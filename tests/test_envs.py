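"""Environment detection, planning and materialization."""

import pytest

from nbaudit import notebook
from nbaudit.envs import (EnvironmentManager, EnvironmentPolicy, NullBackend,
                          VenvBackend, detect_declarations, plan_environment)
from nbaudit.forge import MISSING_PACKAGE
from nbaudit.profiles import profile_structure
from nbaudit.records import DependencySource, FailedStage


def _structure(version=None):
    meta = {"kernelspec": {"name": "python3", "language": "python"}}
    if version:
        meta["language_info"] = {"name": "python", "version": version}
    return profile_structure(notebook.new_notebook([], meta))


@pytest.mark.parametrize("files,flags", [
    (["requirements.txt"], (True, False, False)),
    (["setup.py", "requirements.txt"], (True, True, False)),
    (["Pipfile"], (False, False, True)),
    (["deep/nested/REQUIREMENTS.TXT"], (True, False, False)),
    ([], (False, False, False)),
])
def test_declaration_detection_is_recursive_and_case_insensitive(
        tmp_path, files, flags):
    for rel in files:
        path = tmp_path / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("")
    decls = detect_declarations(tmp_path)
    assert (decls.has_requirements, decls.has_setup,
            decls.has_pipfile) == flags
    assert len(decls.declaration_paths) == len(files)


def test_plan_uses_declared_minor_version_and_declared_source(tmp_path):
    (tmp_path / "requirements.txt").write_text("forgelib\n")
    policy = EnvironmentPolicy(default_interpreter="3.11")
    spec = plan_environment(_structure("3.7.4"), detect_declarations(tmp_path),
                            policy, repo_key="r1")
    assert spec.interpreter_version == "3.7"
    assert spec.dependency_source is DependencySource.DECLARED


def test_plan_falls_back_to_policy_default_and_bundle(tmp_path):
    policy = EnvironmentPolicy(default_interpreter="3.11",
                               distribution_bundle=("forgelib",))
    spec = plan_environment(_structure(), detect_declarations(tmp_path),
                            policy)
    assert spec.interpreter_version == "3.11"
    assert spec.dependency_source is DependencySource.DISTRIBUTION_BUNDLE
    assert spec.declaration_paths == ()


def test_env_key_is_deterministic_and_distinguishes_repos(tmp_path):
    (tmp_path / "requirements.txt").write_text("forgelib\n")
    policy = EnvironmentPolicy()
    decls = detect_declarations(tmp_path)
    s = _structure("3.7")
    assert plan_environment(s, decls, policy, "r1").env_key == \
        plan_environment(s, decls, policy, "r1").env_key
    assert plan_environment(s, decls, policy, "r1").env_key != \
        plan_environment(s, decls, policy, "r2").env_key
    assert plan_environment(_structure("3.8"), decls, policy, "r1").env_key \
        != plan_environment(s, decls, policy, "r1").env_key


def test_null_backend_records_success_without_building(tmp_path):
    manager = EnvironmentManager(backend=NullBackend(), workspace=tmp_path)
    spec = plan_environment(_structure(), detect_declarations(tmp_path),
                            EnvironmentPolicy())
    outcome = manager.materialize(spec)
    assert outcome.success and outcome.failed_stage is FailedStage.NONE


@pytest.fixture(scope="module")
def venv_manager(corpus, tmp_path_factory):
    corpus_root, _ = corpus
    return EnvironmentManager(
        backend=VenvBackend(package_index=str(corpus_root / "index")),
        workspace=tmp_path_factory.mktemp("envs"),
        policy=EnvironmentPolicy(install_timeout=300.0))


def test_installable_requirement_from_local_index(tmp_path, venv_manager):
    (tmp_path / "requirements.txt").write_text("forgelib\n")
    spec = plan_environment(_structure("3.11"), detect_declarations(tmp_path),
                            venv_manager.policy, repo_key="ok")
    outcome = venv_manager.materialize(spec, repo_root=tmp_path)
    assert outcome.success, outcome.log_excerpt
    # the materialized interpreter can import the installed package
    import subprocess
    proc = subprocess.run([outcome.env_path, "-c",
                           "import forgelib; print(forgelib.triple(2))"],
                          capture_output=True, text=True)
    assert proc.stdout.strip() == "6"

    cached = venv_manager.materialize(spec, repo_root=tmp_path)
    assert cached.success and cached.duration == pytest.approx(0.0)


def test_unresolvable_requirement_fails_at_install_stage(tmp_path,
                                                         venv_manager):
    (tmp_path / "requirements.txt").write_text(MISSING_PACKAGE + "\n")
    spec = plan_environment(_structure("3.11"), detect_declarations(tmp_path),
                            venv_manager.policy, repo_key="bad")
    outcome = venv_manager.materialize(spec, repo_root=tmp_path)
    assert outcome.success is False
    assert outcome.failed_stage is FailedStage.INSTALL
    assert outcome.log_excerpt  # the last diagnostic lines are kept
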