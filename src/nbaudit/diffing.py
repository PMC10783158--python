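"""Comparing re-executed notebook outputs against the stored originals.

Per code cell, the stored output list is compared to the re-executed
one after normalization: ANSI escape sequences are stripped, text is
compared trailing-whitespace-insensitively, consecutive stream chunks
of the same stream are merged (kernels split streams arbitrarily), and
image/binary payloads are compared by digest of the decoded bytes.
Masking of transient tokens — hexadecimal object addresses and ISO
timestamps — is off by default and enabled by flag.

Execution-count mismatches are tallied separately from output-content
differences, and files created or modified under the notebook's
directory are tallied from before/after workspace manifests; whether
those two tallies affect the identical/different verdict is a policy of
the classifier, not of the diff.
"""

from __future__ import annotations

import base64
import hashlib
import re
from typing import Any, Iterable

from .notebook import output_text, source_text
from .records import DiffReport

_ANSI_RE = re.compile(r"\x1b\[[0-9;]*[A-Za-z]")
_HEX_ADDR_RE = re.compile(r"0x[0-9a-fA-F]{6,}")
_ISO_TS_RE = re.compile(
    r"\d{4}-\d{2}-\d{2}[T ]\d{2}:\d{2}:\d{2}(?:\.\d+)?(?:Z|[+-]\d{2}:?\d{2})?")


def normalize_text(text: str, mask_transients: bool = False) -> str:
    text = _ANSI_RE.sub("", text)
    if mask_transients:
        text = _HEX_ADDR_RE.sub("0xADDR", text)
        text = _ISO_TS_RE.sub("TIMESTAMP", text)
    lines = [line.rstrip() for line in text.splitlines()]
    while lines and not lines[-1]:
        lines.pop()
    return "\n".join(lines)


def _normalize_output(output: dict[str, Any],
                      mask_transients: bool) -> tuple:
    otype = output.get("output_type")
    if otype == "stream":
        return ("stream", output.get("name", "stdout"),
                normalize_text(output_text(output), mask_transients))
    if otype in ("execute_result", "display_data"):
        data = output.get("data", {}) or {}
        items = []
        for mime in sorted(data):
            val = data[mime]
            if isinstance(val, list):
                val = "".join(val)
            if mime.startswith("image/") or mime == "application/pdf":
                try:
                    payload = base64.b64decode(val)
                except (ValueError, TypeError):
                    payload = str(val).encode()
                items.append((mime, hashlib.sha256(payload).hexdigest()))
            else:
                items.append((mime, normalize_text(str(val), mask_transients)))
        # execution counts are compared separately, not as content
        return ("rich", tuple(items))
    if otype == "error":
        return ("error", output.get("ename", ""),
                normalize_text(output_text(output, "evalue"), mask_transients))
    return (str(otype), repr(output))


def _merge_streams(outputs: Iterable[tuple]) -> list[tuple]:
    merged: list[tuple] = []
    for out in outputs:
        if (merged and out[0] == "stream" and merged[-1][0] == "stream"
                and merged[-1][1] == out[1]):
            prev = merged.pop()
            merged.append(("stream", out[1],
                           (prev[2] + "\n" + out[2]).strip("\n")))
        else:
            merged.append(out)
    return merged


def normalized_outputs(cell: dict[str, Any],
                       mask_transients: bool = False) -> list[tuple]:
    outs = [_normalize_output(o, mask_transients)
            for o in cell.get("outputs", []) or []]
    return _merge_streams([o for o in outs if o != ("stream", "stdout", "")])


def diff_against_original(original_doc: dict[str, Any],
                          executed_doc: dict[str, Any],
                          workspace_before: dict[str, str],
                          workspace_after: dict[str, str],
                          mask_transients: bool = False) -> DiffReport:
    """Cell-by-cell output diff plus workspace file tally.

    Both documents must have the same cells in the same order —
    execution never adds or removes cells.
    """
    orig_cells = original_doc["cells"]
    exec_cells = executed_doc["cells"]
    if len(orig_cells) != len(exec_cells):
        raise ValueError("documents differ in cell count; not a re-execution")

    per_cell: list[tuple[int, str, str]] = []
    execcount_diffs = 0
    for idx, (orig, ran) in enumerate(zip(orig_cells, exec_cells)):
        if orig.get("cell_type") != "code":
            continue
        before = normalized_outputs(orig, mask_transients)
        after = normalized_outputs(ran, mask_transients)
        if before != after:
            per_cell.append((idx, "output",
                             f"{len(before)} stored vs {len(after)} re-executed"))
        old_count = orig.get("execution_count")
        new_count = ran.get("execution_count")
        if old_count != new_count:
            execcount_diffs += 1

    file_diffs = 0
    for path in sorted(set(workspace_before) | set(workspace_after)):
        if workspace_before.get(path) != workspace_after.get(path):
            file_diffs += 1
            kind = ("created" if path not in workspace_before else
                    "deleted" if path not in workspace_after else "modified")
            per_cell.append((-1, "file", f"{kind}: {path}"))

    return DiffReport(
        output_diff_count=sum(1 for _, k, _ in per_cell if k == "output"),
        execcount_diff_count=execcount_diffs,
        file_diff_count=file_diffs,
        per_cell=per_cell,
    )
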