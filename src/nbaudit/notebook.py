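"""Reading and writing ipynb notebook documents.

A notebook document is a JSON object with an ordered list of cells plus
metadata (``kernelspec``, ``language_info``).  We support major versions
3 and 4; version-3 worksheets are flattened into a single cell list on
read and the document is upgraded in place to the version-4 layout so
the rest of the pipeline only ever sees one shape.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any

from .records import ParseStatus

CELL_TYPES = ("code", "markdown", "raw")


class NotebookSchemaError(ValueError):
    """Document is JSON but does not look like a notebook."""


def source_text(cell: dict[str, Any]) -> str:
    """Cell source as a single string (the format allows str or list)."""
    src = cell.get("source", cell.get("input", ""))
    if isinstance(src, list):
        return "".join(src)
    return src if isinstance(src, str) else ""


def output_text(output: dict[str, Any], key: str = "text") -> str:
    val = output.get(key, "")
    if isinstance(val, list):
        return "".join(val)
    return val if isinstance(val, str) else ""


def _upgrade_v3_cell(cell: dict[str, Any]) -> dict[str, Any]:
    c = copy.deepcopy(cell)
    ctype = c.get("cell_type", "raw")
    if ctype == "heading":
        level = int(c.get("level", 1))
        return {"cell_type": "markdown", "metadata": c.get("metadata", {}),
                "source": "#" * level + " " + source_text(c)}
    if ctype == "code":
        outs = []
        for o in c.get("outputs", []):
            o = copy.deepcopy(o)
            otype = o.pop("output_type", "stream")
            if otype == "pyout":
                otype = "execute_result"
            elif otype == "pyerr":
                otype = "error"
            o["output_type"] = otype
            outs.append(o)
        return {"cell_type": "code", "metadata": c.get("metadata", {}),
                "source": source_text(c),
                "execution_count": c.get("prompt_number"),
                "outputs": outs}
    return {"cell_type": ctype if ctype in CELL_TYPES else "raw",
            "metadata": c.get("metadata", {}), "source": source_text(c)}


def loads(text: str) -> dict[str, Any]:
    """Parse notebook JSON, upgrading v3 documents to the v4 layout.

    Raises ``json.JSONDecodeError`` for non-JSON input and
    ``NotebookSchemaError`` when the JSON is not a notebook document.
    """
    doc = json.loads(text)
    if not isinstance(doc, dict) or "nbformat" not in doc:
        raise NotebookSchemaError("document lacks an 'nbformat' field")
    major = doc.get("nbformat")
    if not isinstance(major, int) or major < 3 or major > 4:
        raise NotebookSchemaError(f"unsupported nbformat major {major!r}")
    if major == 3:
        cells: list[dict[str, Any]] = []
        for ws in doc.get("worksheets", []):
            cells.extend(_upgrade_v3_cell(c) for c in ws.get("cells", []))
        doc = {"nbformat": 4, "nbformat_minor": 0,
               "metadata": doc.get("metadata", {}), "cells": cells}
        doc["metadata"].setdefault("nbaudit_upgraded_from", 3)
    if not isinstance(doc.get("cells"), list):
        raise NotebookSchemaError("document lacks a 'cells' list")
    for i, cell in enumerate(doc["cells"]):
        if not isinstance(cell, dict) or cell.get("cell_type") not in CELL_TYPES:
            raise NotebookSchemaError(f"cell {i} has no valid cell_type")
    return doc


def load(path: str | Path) -> dict[str, Any]:
    return loads(Path(path).read_text(encoding="utf-8"))


def try_load(path: str | Path) -> tuple[dict[str, Any] | None, ParseStatus]:
    """Load a notebook, mapping failures to a parse status instead of raising."""
    try:
        text = Path(path).read_text(encoding="utf-8")
    except (OSError, UnicodeDecodeError):
        return None, ParseStatus.INVALID_JSON
    try:
        return loads(text), ParseStatus.PARSED
    except json.JSONDecodeError:
        return None, ParseStatus.INVALID_JSON
    except NotebookSchemaError:
        return None, ParseStatus.INVALID_SCHEMA


def dumps(doc: dict[str, Any]) -> str:
    return json.dumps(doc, indent=1, ensure_ascii=False, sort_keys=True)


def dump(doc: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(dumps(doc) + "\n", encoding="utf-8")


def new_notebook(cells: list[dict[str, Any]],
                 metadata: dict[str, Any] | None = None) -> dict[str, Any]:
    return {"nbformat": 4, "nbformat_minor": 5,
            "metadata": metadata or {}, "cells": cells}


def code_cell(source: str, outputs: list[dict[str, Any]] | None = None,
              execution_count: int | None = None) -> dict[str, Any]:
    return {"cell_type": "code", "metadata": {}, "source": source,
            "execution_count": execution_count, "outputs": outputs or []}


def markdown_cell(source: str) -> dict[str, Any]:
    return {"cell_type": "markdown", "metadata": {}, "source": source}


def raw_cell(source: str) -> dict[str, Any]:
    return {"cell_type": "raw", "metadata": {}, "source": source}
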