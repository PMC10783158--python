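"""Static census of a notebook: structure, Markdown, naming, imports.

Nothing here executes code.  The structure census counts cells by type
and records the declared kernel/language; the Markdown profile measures
documentation effort (element kinds, line/word volume, natural
language); the naming profile applies filename-portability rules; the
import profile walks the Python syntax tree of every code cell to
separate external from repository-local modules.
"""

from __future__ import annotations

import ast
import re
from collections import Counter
from pathlib import Path, PureWindowsPath
from typing import Any, Iterable, Optional

from .lang import Detector
from .notebook import source_text
from .records import (ImportProfile, MarkdownProfile, NamingProfile,
                    NotebookStructure, UNDETECTED)

TARGET_LANGUAGE = "python"


# --------------------------------------------------------------------------
# structure
# --------------------------------------------------------------------------

def _language_of(doc: dict[str, Any]) -> tuple[Optional[str], str, Optional[str]]:
    """(kernel name, language, full version) with kernelspec preferred."""
    meta = doc.get("metadata", {}) or {}
    kernelspec = meta.get("kernelspec", {}) or {}
    lang_info = meta.get("language_info", {}) or {}
    kernel_name = kernelspec.get("name")
    language = kernelspec.get("language") or lang_info.get("name") or "unknown"
    version = lang_info.get("version") or kernelspec.get("python_version")
    return kernel_name, str(language).lower(), version


def profile_structure(doc: dict[str, Any]) -> NotebookStructure:
    """Deterministic census over a schema-loaded notebook document."""
    kernel_name, language, version = _language_of(doc)
    major = None
    if version:
        head = str(version).split(".")[0]
        if head.isdigit():
            major = int(head)

    counts = Counter(cell.get("cell_type") for cell in doc["cells"])
    empty = sum(1 for cell in doc["cells"] if not source_text(cell).strip())
    with_output = sum(1 for cell in doc["cells"]
                      if cell.get("cell_type") == "code" and cell.get("outputs"))
    exec_counts = [cell.get("execution_count") for cell in doc["cells"]
                   if cell.get("cell_type") == "code"
                   and isinstance(cell.get("execution_count"), int)]

    return NotebookStructure(
        nbformat_version=(doc.get("nbformat", 4), doc.get("nbformat_minor", 0)),
        kernel_name=kernel_name,
        language=language,
        language_version_full=str(version) if version else None,
        major_version=major,
        cells_total=len(doc["cells"]),
        code_cells=counts.get("code", 0),
        markdown_cells=counts.get("markdown", 0),
        raw_cells=counts.get("raw", 0),
        empty_cells=empty,
        cells_with_output=with_output,
        max_execution_count=max(exec_counts) if exec_counts else None,
        has_execution_counts=bool(exec_counts),
    )


def is_target_language(structure: NotebookStructure) -> bool:
    return structure.language == TARGET_LANGUAGE


# --------------------------------------------------------------------------
# markdown
# --------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^ {0,3}#{1,6}(\s|$)")
_SETEXT_RE = re.compile(r"^ {0,3}(=+|-+)\s*$")
_LIST_RE = re.compile(r"^ {0,3}(?:[-*+]|\d+[.)])\s+")
_FENCE_RE = re.compile(r"^ {0,3}(```|~~~)")
_IMAGE_RE = re.compile(r"!\[[^\]]*\]\([^)]*\)")
_LINK_RE = re.compile(r"(?<!!)\[[^\]]*\]\([^)]*\)|<https?://[^>]+>")
_TABLE_SEP_RE = re.compile(r"^ {0,3}\|?\s*:?-{3,}:?\s*(\|\s*:?-{3,}:?\s*)+\|?\s*$")


def _markdown_elements(text: str) -> set[str]:
    elements: set[str] = set()
    lines = text.splitlines()
    in_fence = False
    prev_nonblank_plain = False
    for i, line in enumerate(lines):
        if _FENCE_RE.match(line):
            if not in_fence:
                elements.add("code_block")
            in_fence = not in_fence
            prev_nonblank_plain = False
            continue
        if in_fence:
            continue
        if _IMAGE_RE.search(line):
            elements.add("image")
        if _LINK_RE.search(line):
            elements.add("link")
        if _HEADER_RE.match(line):
            elements.add("header")
            prev_nonblank_plain = False
            continue
        if _SETEXT_RE.match(line) and prev_nonblank_plain:
            elements.add("header")
            prev_nonblank_plain = False
            continue
        if _LIST_RE.match(line):
            elements.add("list")
            prev_nonblank_plain = False
            continue
        if _TABLE_SEP_RE.match(line):
            elements.add("table")
            prev_nonblank_plain = False
            continue
        if line.startswith("    ") and line.strip():
            elements.add("code_block")
            prev_nonblank_plain = False
            continue
        if line.strip():
            elements.add("paragraph")
            prev_nonblank_plain = True
        else:
            prev_nonblank_plain = False
    return elements


def profile_markdown(doc: dict[str, Any], lang_detector: Detector) -> MarkdownProfile:
    """Markdown census; the detector is applied per Markdown cell and the
    union of detected codes is reported (``undetected`` when none)."""
    texts = [source_text(cell) for cell in doc["cells"]
             if cell.get("cell_type") == "markdown"]
    total_lines = sum(len(t.splitlines()) for t in texts)
    total_words = sum(len(t.split()) for t in texts)

    detected: set[str] = set()
    for text in texts:
        if text.strip():
            code = lang_detector(text)
            if code:
                detected.add(code)
    if total_words == 0 or not detected:
        languages = frozenset({UNDETECTED})
    else:
        languages = frozenset(detected)

    elements: set[str] = set()
    for text in texts:
        elements |= _markdown_elements(text)

    return MarkdownProfile(
        languages_detected=languages,
        english_only=(languages == frozenset({"en"})),
        total_lines=total_lines,
        total_words=total_words,
        elements_present=frozenset(elements),
    )


# --------------------------------------------------------------------------
# naming
# --------------------------------------------------------------------------

_POSIX_RE = re.compile(r"^[A-Za-z0-9._-]+$")
_WINDOWS_RESERVED = {"CON", "PRN", "AUX", "NUL",
                     *(f"COM{i}" for i in range(1, 10)),
                     *(f"LPT{i}" for i in range(1, 10))}
_WINDOWS_BAD_CHARS = set('<>:"/\\|?*')


def profile_name(relative_path: str) -> NamingProfile:
    """Portability profile of the filename stem.

    POSIX fully portable names use only ``[A-Za-z0-9._-]`` and do not
    start with a hyphen; the historic 14-character limit is reported as
    a separate flag, not a violation.
    """
    name = PureWindowsPath(relative_path).name if "\\" in relative_path \
        else Path(relative_path).name
    if not name.endswith(".ipynb"):
        raise ValueError("path does not end with the notebook extension")
    title = name[:-len(".ipynb")]
    posix = bool(_POSIX_RE.match(title)) and not title.startswith("-")
    windows_bad = (title.upper() in _WINDOWS_RESERVED
                   or name.upper().rsplit(".", 1)[0] in _WINDOWS_RESERVED
                   or any(ch in _WINDOWS_BAD_CHARS for ch in title)
                   or title.endswith((" ", ".")))
    return NamingProfile(
        title=title,
        title_length=len(title),
        posix_portable=posix,
        exceeds_14_chars=len(name) > 14,
        windows_disallowed=windows_bad,
        is_untitled=title.startswith("Untitled"),
        contains_copy="copy" in title.lower(),
        contains_test="test" in title.lower(),
    )


# --------------------------------------------------------------------------
# imports
# --------------------------------------------------------------------------

_LOAD_EXT_RE = re.compile(r"^\s*%load_ext\s+(\S+)")
_DIRECTIVE_RE = re.compile(r"^\s*(%|!)")


def strip_directives(source: str) -> tuple[str, list[str]]:
    """Remove notebook-shell directive lines (%magics, !shell, trailing ?)
    before grammar parsing; the removed lines are returned for the record."""
    kept, directives = [], []
    lines = source.splitlines()
    if lines and lines[0].lstrip().startswith("%%"):
        return "", list(lines)  # cell magic: whole cell is a directive
    for line in lines:
        stripped = line.strip()
        if _DIRECTIVE_RE.match(line):
            directives.append(stripped)
        elif (stripped.endswith("?") and not stripped.startswith("#")
              and "=" not in stripped and "(" not in stripped):
            directives.append(stripped)  # introspection request
        else:
            kept.append(line)
    return "\n".join(kept), directives


def local_module_names(repo_root: str | Path) -> set[str]:
    """Top-level module names resolvable anywhere under *repo_root*:
    stems of ``*.py`` files plus directories containing ``__init__.py``."""
    root = Path(repo_root)
    names: set[str] = set()
    for path in root.rglob("*.py"):
        if any(part in (".git", ".ipynb_checkpoints") for part in path.parts):
            continue
        if path.name == "__init__.py":
            names.add(path.parent.name)
        else:
            names.add(path.stem)
    return names


def profile_imports(doc: dict[str, Any], repo_root: str | Path) -> ImportProfile:
    """Import census via the Python abstract syntax tree.

    An import is *local* iff its top-level name resolves to a module
    file or package directory anywhere under the repository, or is a
    relative import; otherwise it is *external*.  A cell that fails to
    parse sets ``syntax_ok=False`` and is skipped (best effort).
    """
    local_names = local_module_names(repo_root)
    external: Counter = Counter()
    local: Counter = Counter()
    extensions: Counter = Counter()
    directives: list[str] = []
    functions = classes = 0
    syntax_ok = True

    for cell in doc["cells"]:
        if cell.get("cell_type") != "code":
            continue
        src = source_text(cell)
        for match in _LOAD_EXT_RE.finditer(src):
            extensions[match.group(1)] += 1
        code, cell_directives = strip_directives(src)
        directives.extend(cell_directives)
        try:
            tree = ast.parse(code)
        except SyntaxError:
            syntax_ok = False
            continue
        for node in ast.walk(tree):
            if isinstance(node, ast.Import):
                for alias in node.names:
                    top = alias.name.split(".")[0]
                    (local if top in local_names else external)[alias.name] += 1
            elif isinstance(node, ast.ImportFrom):
                if node.level and node.level > 0:
                    local[node.module or "."] += 1
                elif node.module:
                    top = node.module.split(".")[0]
                    (local if top in local_names else external)[node.module] += 1
            elif isinstance(node, (ast.FunctionDef, ast.AsyncFunctionDef)):
                functions += 1
            elif isinstance(node, ast.ClassDef):
                classes += 1

    # a dotted name is either local or external, never both: locality is
    # decided by the top-level name, so regroup any stragglers
    overlap = set(external) & set(local)
    for name in overlap:
        local[name] += external.pop(name)

    return ImportProfile(
        modules_external=external,
        modules_local=local,
        functions_defined=functions,
        classes_defined=classes,
        load_extensions=extensions,
        directives=directives,
        syntax_ok=syntax_ok,
    )
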