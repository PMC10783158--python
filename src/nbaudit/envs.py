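"""Planning and materializing per-notebook execution environments.

A repository declares its dependencies (or not) through
``requirements.txt``, ``setup.py`` and ``Pipfile``.  The planner derives
an :class:`~nbaudit.records.EnvironmentSpec` from the notebook's declared
interpreter version (minor precision) and the repository's declaration
set, falling back to a configurable *distribution bundle* — a named
data-science package list — when nothing is declared.  Materialization
is delegated to an injectable backend:

``VenvBackend``
    lightweight virtual environments; dependencies are installed from a
    local package index, so runs are offline-reproducible.
``NullBackend``
    records the plan without building anything (dry runs).

A conda-style manager can implement the same two-method interface for
production use.  Environments are cached by ``env_key`` — the same spec
is never built twice — and an install failure is a recorded outcome,
never a crash.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import subprocess
import sys
import time
import venv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol

from .records import (DeclarationSet, DependencySource, EnvironmentSpec,
                    FailedStage, InstallOutcome, NotebookStructure)

_DECLARATION_FILES = {"requirements.txt": "has_requirements",
                      "setup.py": "has_setup",
                      "pipfile": "has_pipfile"}


def detect_declarations(repo_root: str | Path) -> DeclarationSet:
    """Find dependency declarations at any depth (case-insensitive names)."""
    root = Path(repo_root)
    if not root.exists():
        raise FileNotFoundError(repo_root)
    flags = {"has_requirements": False, "has_setup": False, "has_pipfile": False}
    paths: list[str] = []
    for path in sorted(root.rglob("*")):
        if not path.is_file():
            continue
        if any(part in (".git", ".ipynb_checkpoints") for part in path.parts):
            continue
        flag = _DECLARATION_FILES.get(path.name.lower())
        if flag:
            flags[flag] = True
            paths.append(str(path.relative_to(root)))
    return DeclarationSet(declaration_paths=paths, **flags)


@dataclass
class EnvironmentPolicy:
    """Site configuration for environment planning.

    ``default_interpreter`` is used when a notebook declares no (or an
    unparseable) interpreter version; ``distribution_bundle`` names the
    package set installed when a repository declares no dependencies.
    """
    default_interpreter: str = "3.11"
    distribution_bundle: tuple[str, ...] = (
        "numpy", "pandas", "matplotlib", "scikit-learn", "scipy")
    install_timeout: float = 1200.0


def _minor_version(full: Optional[str]) -> Optional[str]:
    if not full:
        return None
    parts = str(full).split(".")
    if parts and parts[0].isdigit():
        return ".".join(parts[:2]) if len(parts) > 1 and parts[1].isdigit() \
            else parts[0]
    return None


def compute_env_key(interpreter_version: str, source: DependencySource,
                    declaration_paths: tuple[str, ...],
                    bundle: tuple[str, ...] = ()) -> str:
    payload = json.dumps({"interpreter": interpreter_version,
                          "source": source.value,
                          "declarations": sorted(declaration_paths),
                          "bundle": sorted(bundle)},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def plan_environment(structure: NotebookStructure,
                     declarations: DeclarationSet,
                     policy: EnvironmentPolicy,
                     repo_key: str = "") -> EnvironmentSpec:
    """Derive the environment spec for one notebook.

    Declaration paths are prefixed with *repo_key* so environments are
    shared within a repository but never across repositories; with an
    empty declaration set the (interpreter, bundle) pair alone keys the
    environment, so no-dependency repositories share one build.
    """
    version = _minor_version(structure.language_version_full) \
        or policy.default_interpreter
    if declarations.any:
        source = DependencySource.DECLARED
        paths = tuple(f"{repo_key}::{p}" if repo_key else p
                      for p in declarations.declaration_paths)
    else:
        source = DependencySource.DISTRIBUTION_BUNDLE
        paths = ()
    key = compute_env_key(version, source, paths, policy.distribution_bundle)
    return EnvironmentSpec(interpreter_version=version,
                           dependency_source=source,
                           declaration_paths=paths, env_key=key)


class EnvironmentBackend(Protocol):
    def create(self, version: str, env_dir: Path) -> str: ...
    def install(self, env_dir: Path, python: str, requirements: list[str],
                project_dirs: list[str], timeout: float) -> None: ...


class InstallError(Exception):
    def __init__(self, log: str):
        super().__init__(log)
        self.log = log


def _read_pipfile_packages(path: Path) -> list[str]:
    import tomllib
    try:
        data = tomllib.loads(path.read_text(encoding="utf-8"))
    except tomllib.TOMLDecodeError as exc:
        raise InstallError(f"unparseable Pipfile: {exc}")
    specs = []
    for name, constraint in (data.get("packages") or {}).items():
        if isinstance(constraint, str) and constraint not in ("*", ""):
            specs.append(name + constraint)
        else:
            specs.append(name)
    return specs


class VenvBackend:
    """Virtual-environment backend fed from a local package index.

    Installs go into the environment's ``site-packages`` with the host
    pip, pinned to ``--no-index --find-links <index>`` so resolution is
    fully offline and a missing distribution fails fast.  Only one
    CPython is assumed to be present; the requested interpreter version
    is recorded on the spec, the running interpreter does the work.
    """

    def __init__(self, package_index: str | Path | None = None):
        self.package_index = str(package_index) if package_index else None

    def create(self, version: str, env_dir: Path) -> str:
        venv.EnvBuilder(with_pip=False, symlinks=True).create(env_dir)
        return str(env_dir / "bin" / "python")

    def _site_packages(self, env_dir: Path) -> Path:
        tag = f"python{sys.version_info.major}.{sys.version_info.minor}"
        return env_dir / "lib" / tag / "site-packages"

    def _pip(self, args: list[str], timeout: float) -> None:
        cmd = [sys.executable, "-m", "pip", "install",
               "--quiet", "--no-input", "--disable-pip-version-check",
               "--no-index"]
        if self.package_index:
            cmd += ["--find-links", self.package_index]
        cmd += args
        try:
            proc = subprocess.run(cmd, capture_output=True, text=True,
                                  timeout=timeout)
        except subprocess.TimeoutExpired:
            raise InstallError("install timed out")
        if proc.returncode != 0:
            raise InstallError((proc.stderr or proc.stdout).strip()[-2000:])

    def install(self, env_dir: Path, python: str, requirements: list[str],
                project_dirs: list[str], timeout: float) -> None:
        target = str(self._site_packages(env_dir))
        for req in requirements:
            self._pip(["--target", target, "-r", req] if req.endswith(".txt")
                      else ["--target", target, req], timeout)
        for project in project_dirs:
            self._pip(["--no-build-isolation", "--target", target, project],
                      timeout)


class NullBackend:
    """Records the plan without building; every install 'succeeds'."""

    def create(self, version: str, env_dir: Path) -> str:
        env_dir.mkdir(parents=True, exist_ok=True)
        return sys.executable

    def install(self, env_dir: Path, python: str, requirements: list[str],
                project_dirs: list[str], timeout: float) -> None:
        return None


@dataclass
class EnvironmentManager:
    """Caches materialized environments by ``env_key``."""

    backend: EnvironmentBackend
    workspace: Path
    policy: EnvironmentPolicy = field(default_factory=EnvironmentPolicy)
    _cache: dict[str, InstallOutcome] = field(default_factory=dict)

    def materialize(self, spec: EnvironmentSpec,
                    repo_root: str | Path | None = None) -> InstallOutcome:
        """Build (or fetch from cache) the environment for *spec*.

        Declaration paths carrying a repository prefix are resolved
        against *repo_root*'s parent naming; paths are taken relative
        to *repo_root* when given.
        """
        if spec.env_key in self._cache:
            cached = self._cache[spec.env_key]
            return InstallOutcome(success=cached.success,
                                  log_excerpt=cached.log_excerpt,
                                  duration=0.0,
                                  failed_stage=cached.failed_stage,
                                  env_path=cached.env_path)
        start = time.monotonic()
        env_dir = Path(self.workspace) / "envs" / spec.env_key
        requirements: list[str] = []
        projects: list[str] = []
        if repo_root is not None:
            root = Path(repo_root)
            for decl in spec.declaration_paths:
                rel = decl.split("::", 1)[1] if "::" in decl else decl
                path = root / rel
                name = path.name.lower()
                if name == "requirements.txt":
                    requirements.append(str(path))
                elif name == "setup.py":
                    projects.append(str(path.parent))
                elif name == "pipfile":
                    requirements.extend(_read_pipfile_packages(path))
        if spec.dependency_source is DependencySource.DISTRIBUTION_BUNDLE:
            requirements.extend(self.policy.distribution_bundle)

        try:
            python = self.backend.create(spec.interpreter_version, env_dir)
        except Exception as exc:  # backend misconfiguration is a hard error
            shutil.rmtree(env_dir, ignore_errors=True)
            raise RuntimeError(f"environment backend failed to create: {exc}")
        try:
            self.backend.install(env_dir, python, requirements, projects,
                                 self.policy.install_timeout)
        except InstallError as exc:
            outcome = InstallOutcome(success=False, log_excerpt=exc.log[-2000:],
                                     duration=time.monotonic() - start,
                                     failed_stage=FailedStage.INSTALL,
                                     env_path=None)
        else:
            outcome = InstallOutcome(success=True, log_excerpt="",
                                     duration=time.monotonic() - start,
                                     failed_stage=FailedStage.NONE,
                                     env_path=python)
        self._cache[spec.env_key] = outcome
        return outcome
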