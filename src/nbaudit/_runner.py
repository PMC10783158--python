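"""Standalone notebook cell runner.

Executed as ``python _runner.py NOTEBOOK_JSON OUT_NOTEBOOK OUT_TRACE``
inside the target environment's interpreter; imports nothing beyond the
standard library so it runs in a bare virtual environment.

Runs every code cell exactly once, top to bottom, in a shared module
namespace, emulating the interactive shell: the trailing expression of
a cell (if any) becomes an ``execute_result`` output, stdout/stderr
become ``stream`` outputs, and the first raised exception stops the run
and is recorded as an ``error`` output with its type name.  Lines that
are notebook-shell directives (``%`` magics, ``!`` shell escapes,
trailing-``?`` introspection) are dropped before compilation.

The trace file is rewritten after every cell so that a supervisor
killing the process on timeout still sees how far execution got.
"""

import ast
import io
import json
import os
import sys
import time
import traceback
from contextlib import redirect_stderr, redirect_stdout


def _source(cell):
    src = cell.get("source", "")
    return "".join(src) if isinstance(src, list) else (src or "")


def _strip_directives(source):
    lines = source.splitlines()
    if lines and lines[0].lstrip().startswith("%%"):
        return ""
    kept = []
    for line in lines:
        s = line.strip()
        if s.startswith("%") or s.startswith("!"):
            continue
        if s.endswith("?") and not s.startswith("#") and "=" not in s \
                and "(" not in s:
            continue
        kept.append(line)
    return "\n".join(kept)


def _write_json(path, payload):
    tmp = path + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
    os.replace(tmp, path)


def _run_cell(code, namespace):
    """Execute one cell; returns (outputs, exception_info or None)."""
    outputs = []
    stdout, stderr = io.StringIO(), io.StringIO()
    result = _SENTINEL
    exc_info = None
    try:
        tree = ast.parse(code)
        last_expr = None
        if tree.body and isinstance(tree.body[-1], ast.Expr):
            last_expr = ast.Expression(tree.body[-1].value)
            tree.body = tree.body[:-1]
        with redirect_stdout(stdout), redirect_stderr(stderr):
            if tree.body:
                exec(compile(tree, "<cell>", "exec"), namespace)
            if last_expr is not None:
                result = eval(compile(last_expr, "<cell>", "eval"), namespace)
    except BaseException as exc:  # noqa: BLE001 - any user error ends the run
        exc_info = {
            "ename": type(exc).__name__,
            "evalue": str(exc),
            "traceback": traceback.format_exception(type(exc), exc,
                                                    exc.__traceback__),
        }
    if stdout.getvalue():
        outputs.append({"output_type": "stream", "name": "stdout",
                        "text": stdout.getvalue()})
    if stderr.getvalue():
        outputs.append({"output_type": "stream", "name": "stderr",
                        "text": stderr.getvalue()})
    if exc_info is None and result is not _SENTINEL and result is not None:
        outputs.append({"output_type": "execute_result",
                        "data": {"text/plain": repr(result)},
                        "metadata": {}, "execution_count": None})
    if exc_info is not None:
        outputs.append(dict(exc_info, output_type="error"))
    return outputs, exc_info


_SENTINEL = object()


def main(argv):
    nb_path, out_nb, out_trace = argv[1], argv[2], argv[3]
    # the kernel puts the notebook's own directory on the module path
    sys.path.insert(0, os.getcwd())
    with open(nb_path, encoding="utf-8") as fh:
        doc = json.load(fh)

    namespace = {"__name__": "__main__", "__builtins__": __builtins__}
    started = time.time()
    code_cell_pos = -1
    exc_info = None
    execution_count = 0

    for cell in doc.get("cells", []):
        if cell.get("cell_type") != "code":
            continue
        code_cell_pos += 1
        execution_count += 1
        code = _strip_directives(_source(cell))
        outputs, exc_info = _run_cell(code, namespace)
        cell["outputs"] = outputs
        cell["execution_count"] = execution_count
        for out in outputs:
            if out.get("output_type") == "execute_result":
                out["execution_count"] = execution_count
        _write_json(out_trace, {
            "completed": False,
            "cells_executed": code_cell_pos + 1,
            "first_exception_type": exc_info["ename"] if exc_info else None,
            "first_exception_cell": code_cell_pos if exc_info else None,
            "duration": time.time() - started,
        })
        if exc_info is not None:
            break

    _write_json(out_trace, {
        "completed": exc_info is None,
        "cells_executed": code_cell_pos + 1,
        "first_exception_type": exc_info["ename"] if exc_info else None,
        "first_exception_cell": code_cell_pos if exc_info else None,
        "duration": time.time() - started,
    })
    with open(out_nb, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, ensure_ascii=False, sort_keys=True)
        fh.write("\n")
    return 0


if __name__ == "__main__":
    sys.exit(main(sys.argv))
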