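"""Single-pass re-execution of a notebook in its materialized environment.

The notebook is handed to the stdlib-only cell runner
(:mod:`nbaudit._runner`), launched as a subprocess of the environment's
interpreter with the notebook's own directory as working directory.
Cells run in document order exactly once; execution stops at the first
raised exception; a wall-clock timeout kills the whole process group
and is recorded as ``timed_out`` (only the first error of a notebook is
considered — later cells are never reached).

A failure to even start the interpreter is a distinct, recorded marker
(``kernel_start_failed``), classified downstream as *excluded*.
"""

from __future__ import annotations

import hashlib
import json
import os
import signal
import subprocess
import sys
import time
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

from . import notebook
from .records import ExecutionTrace

_RUNNER = Path(__file__).with_name("_runner.py")

# alias classes whose reported name differs from the canonical one
CANONICAL_EXCEPTIONS = {
    "IOError": "OSError",
    "EnvironmentError": "OSError",
    "WindowsError": "OSError",
}


def canonical_exception(name: Optional[str]) -> Optional[str]:
    if name is None:
        return None
    return CANONICAL_EXCEPTIONS.get(name, name)


def snapshot_files(root: str | Path) -> dict[str, str]:
    """Manifest of files under *root*: relative path -> content digest."""
    root = Path(root)
    manifest: dict[str, str] = {}
    for path in sorted(root.rglob("*")):
        if not path.is_file() or path.is_symlink():
            continue
        rel = str(path.relative_to(root))
        if rel.endswith(".ipynb") or "/.git/" in f"/{rel}":
            continue
        manifest[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
    return manifest


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def execute_notebook(nb_path: str | Path, env_python: str,
                     timeout: float, scratch_dir: str | Path
                     ) -> tuple[ExecutionTrace, Optional[dict[str, Any]]]:
    """Run *nb_path* once, top to bottom, with *env_python*.

    Returns the execution trace and the executed document (None when
    the interpreter never started or was killed before writing it).
    """
    nb_path = Path(nb_path).resolve()
    scratch = Path(scratch_dir).resolve()
    scratch.mkdir(parents=True, exist_ok=True)
    out_nb = scratch / (nb_path.stem + ".executed.ipynb")
    out_trace = scratch / (nb_path.stem + ".trace.json")
    for stale in (out_nb, out_trace):
        stale.unlink(missing_ok=True)

    started = _now()
    t0 = time.monotonic()
    timed_out = False
    start_failed = False
    try:
        proc = subprocess.Popen(
            [env_python, str(_RUNNER), str(nb_path), str(out_nb),
             str(out_trace)],
            cwd=str(nb_path.parent),
            stdout=subprocess.DEVNULL, stderr=subprocess.PIPE,
            start_new_session=True, text=True)
    except OSError:
        start_failed = True
        proc = None
    if proc is not None:
        try:
            _, stderr = proc.communicate(timeout=timeout)
        except subprocess.TimeoutExpired:
            timed_out = True
            try:
                os.killpg(os.getpgid(proc.pid), signal.SIGKILL)
            except (ProcessLookupError, PermissionError):
                proc.kill()
            proc.wait()
    duration = time.monotonic() - t0

    raw: dict[str, Any] = {}
    if out_trace.exists():
        try:
            raw = json.loads(out_trace.read_text())
        except json.JSONDecodeError:
            raw = {}
    if proc is not None and not timed_out and proc.returncode != 0 and not raw:
        start_failed = True  # interpreter died before running any cell

    completed = bool(raw.get("completed")) and not timed_out
    first_type = raw.get("first_exception_type") if not timed_out else None
    first_cell = raw.get("first_exception_cell") if not timed_out else None
    trace = ExecutionTrace(
        started=started, finished=_now(), duration=duration,
        completed=completed, timed_out=timed_out,
        kernel_start_failed=start_failed,
        first_exception_type=first_type,
        first_exception_cell=first_cell,
        cells_executed=int(raw.get("cells_executed", 0)),
    )
    executed_doc = None
    if out_nb.exists():
        try:
            executed_doc = notebook.load(out_nb)
        except (json.JSONDecodeError, notebook.NotebookSchemaError):
            executed_doc = None
    return trace, executed_doc
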