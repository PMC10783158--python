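"""Code-style audit of notebook code cells.

The checker enforces a subset of the PEP 8 conventions, reporting
findings under the standard pycodestyle error codes (E2xx whitespace,
E4xx imports, E7xx statements).  It is deliberately conservative: a
finding is only emitted when the rule unambiguously applies, so clean
code yields no findings.  The engine is injectable into
:func:`profile_style`; any callable with the same shape (cell source ->
``(code, description, line)`` triples) can stand in.

Notebook-shell directives are stripped before checking, and import
placement (E402) is judged across cells in document order, since a
notebook's code cells together form one module.
"""

from __future__ import annotations

import ast
import io
import tokenize
from typing import Any, Callable, Iterable

from .notebook import source_text
from .profiles import strip_directives
from .records import StyleFinding

DESCRIPTIONS = {
    "E225": "missing whitespace around operator",
    "E226": "missing whitespace around arithmetic operator",
    "E227": "missing whitespace around bitwise or shift operator",
    "E228": "missing whitespace around modulo operator",
    "E231": "missing whitespace after ',', ';', or ':'",
    "E262": "inline comment should start with '# '",
    "E265": "block comment should start with '# '",
    "E266": "too many leading '#' for block comment",
    "E401": "multiple imports on one line",
    "E402": "module level import not at top of file",
    "E701": "multiple statements on one line (colon)",
    "E702": "multiple statements on one line (semicolon)",
    "E703": "statement ends with a semicolon",
    "E741": "ambiguous variable name",
}

# operators that always require surrounding whitespace
_E225_OPS = {"==", "!=", "<", ">", "<=", ">=", "->", ":=", "<>",
             "+=", "-=", "*=", "/=", "//=", "**=", "%=", "&=", "|=",
             "^=", ">>=", "<<=", "="}
_E226_OPS = {"+", "-", "*", "/", "@"}
_E227_OPS = {"&", "|", "^", "<<", ">>", "//"}
_E228_OPS = {"%"}
_UNARY_CONTEXT = {"(", "[", "{", ",", ":", ";", "=", "+", "-", "*", "/",
                  "//", "%", "@", "**", "<", ">", "<=", ">=", "==", "!=",
                  "&", "|", "^", "<<", ">>", "~", "->", ":=", "lambda",
                  "return", "yield", "in", "not", "and", "or", "if",
                  "else", "while", "assert", "print", "is", "from"}
_COMPOUND_KEYWORDS = {"if", "elif", "else", "for", "while", "try", "except",
                      "finally", "with", "def", "class", "async"}
_AMBIGUOUS = {"l", "O", "I"}

Finding = tuple[str, str, int]  # (code, description, 1-based line)
StyleEngine = Callable[[str], list[Finding]]


def _emit(found: list[Finding], code: str, line: int) -> None:
    found.append((code, DESCRIPTIONS[code], line))


def _tokens(source: str) -> list[tokenize.TokenInfo]:
    return list(tokenize.generate_tokens(io.StringIO(source).readline))


def _check_tokens(source: str, found: list[Finding]) -> None:
    toks = [t for t in _tokens(source)
            if t.type not in (tokenize.NL, tokenize.INDENT, tokenize.DEDENT,
                              tokenize.ENCODING, tokenize.ENDMARKER)]
    lines = source.splitlines()
    bracket_stack: list[str] = []
    line_first_tok: dict[int, tokenize.TokenInfo] = {}
    for tok in toks:
        line_first_tok.setdefault(tok.start[0], tok)

    for i, tok in enumerate(toks):
        prev = toks[i - 1] if i > 0 else None
        nxt = toks[i + 1] if i + 1 < len(toks) else None
        row, col = tok.start

        if tok.type == tokenize.COMMENT:
            text = tok.string
            is_block = prev is None or prev.type == tokenize.NEWLINE \
                or prev.end[0] < row
            if is_block:
                if text.startswith("#!") and row == 1:
                    pass
                elif text.startswith("##"):
                    _emit(found, "E266", row)
                elif text != "#" and not text.startswith("# ") \
                        and not text.startswith("#!"):
                    _emit(found, "E265", row)
            else:
                if text.startswith("##") or (text != "#"
                                             and not text.startswith("# ")):
                    _emit(found, "E262", row)
            continue

        if tok.type != tokenize.OP:
            continue
        s = tok.string

        if s in "([{":
            bracket_stack.append(s)
            continue
        if s in ")]}":
            if bracket_stack:
                bracket_stack.pop()
            continue

        if s in ",;:":
            line_text = lines[row - 1] if row - 1 < len(lines) else ""
            next_ch = line_text[tok.end[1]] if tok.end[1] < len(line_text) else ""
            missing = next_ch not in ("", " ", "\t")
            if missing:
                if s == ":" and bracket_stack and bracket_stack[-1] == "[":
                    missing = False  # slice
                elif s == "," and next_ch in ")]}":
                    missing = False  # single-element tuple
                elif s == ":" and next_ch == "=":
                    missing = False  # walrus handled as one token anyway
            if missing:
                _emit(found, "E231", row)

        if s == ";":
            same_line = nxt is not None and nxt.start[0] == row \
                and nxt.type not in (tokenize.NEWLINE, tokenize.COMMENT)
            _emit(found, "E702" if same_line else "E703", row)
            continue

        if s == ":" and not bracket_stack:
            first = line_first_tok.get(row)
            if (first is not None and first.type == tokenize.NAME
                    and first.string in _COMPOUND_KEYWORDS
                    and nxt is not None and nxt.start[0] == row
                    and nxt.type not in (tokenize.NEWLINE, tokenize.COMMENT)):
                _emit(found, "E701", row)
            continue

        group = ("E225" if s in _E225_OPS else
                 "E227" if s in _E227_OPS else
                 "E228" if s in _E228_OPS else
                 "E226" if s in _E226_OPS else None)
        if group is None:
            continue
        if s == "=" and bracket_stack:
            continue  # keyword argument / default value
        if s in ("*", "**") and (prev is None or prev.type == tokenize.OP
                                 and prev.string in ("(", ",", "[", "{")):
            continue  # star-args / unpacking
        if s in ("+", "-", "~") and (
                prev is None
                or (prev.type == tokenize.OP and prev.string not in ")]}")
                or (prev.type == tokenize.NAME
                    and prev.string in _UNARY_CONTEXT)):
            continue  # unary operator
        if prev is None or nxt is None:
            continue
        space_before = prev.end != tok.start or prev.end[0] != row
        space_after = tok.end != nxt.start or nxt.start[0] != row
        if not space_before or not space_after:
            _emit(found, group, row)


def _check_ast(tree: ast.Module, found: list[Finding],
               seen_code_before: bool) -> bool:
    """Import placement (E401/E402) and ambiguous names (E741).

    Returns the updated "non-import code seen at module level" flag.
    """
    seen_code = seen_code_before

    def flag_name(name: str, line: int) -> None:
        if name in _AMBIGUOUS:
            _emit(found, "E741", line)

    for node in tree.body:
        if isinstance(node, ast.Import):
            if len(node.names) > 1:
                _emit(found, "E401", node.lineno)
            if seen_code:
                _emit(found, "E402", node.lineno)
        elif isinstance(node, ast.ImportFrom):
            if seen_code and node.module != "__future__":
                _emit(found, "E402", node.lineno)
        elif isinstance(node, ast.Expr) and isinstance(node.value, ast.Constant) \
                and isinstance(node.value.value, str):
            pass  # docstring
        elif isinstance(node, (ast.If, ast.Try)):
            seen_code = True
        else:
            seen_code = True

    for node in ast.walk(tree):
        if isinstance(node, ast.Name) and isinstance(node.ctx, ast.Store):
            flag_name(node.id, node.lineno)
        elif isinstance(node, ast.arg):
            flag_name(node.arg, node.lineno)
    return seen_code


class StyleChecker:
    """Stateful engine: one instance audits one notebook's cells in order.

    The only cross-cell state is the E402 flag (imports after earlier
    non-import code); everything else is judged per cell.
    """

    def __init__(self) -> None:
        self._seen_code = False

    def __call__(self, cell_source: str) -> list[Finding]:
        code, _ = strip_directives(cell_source)
        if not code.strip():
            return []
        found: list[Finding] = []
        try:
            _check_tokens(code, found)
        except (tokenize.TokenError, IndentationError, SyntaxError):
            raise StyleEngineError("tokenization failed")
        try:
            tree = ast.parse(code)
        except SyntaxError:
            raise StyleEngineError("parse failed")
        self._seen_code = _check_ast(tree, found, self._seen_code)
        found.sort(key=lambda f: (f[2], f[0]))
        return found


class StyleEngineError(Exception):
    """The engine could not analyze a cell; the cell is skipped."""


def profile_style(doc: dict[str, Any],
                  style_engine: StyleEngine | None = None) -> list[StyleFinding]:
    """All style findings over the notebook's code cells, none suppressed.

    Coordinates are cell-local: ``cell_index`` is the notebook cell
    index, ``line`` the 1-based line within that cell's source.  A cell
    the engine cannot analyze is skipped.
    """
    engine = style_engine or StyleChecker()
    findings: list[StyleFinding] = []
    for idx, cell in enumerate(doc["cells"]):
        if cell.get("cell_type") != "code":
            continue
        try:
            cell_findings = engine(source_text(cell))
        except StyleEngineError:
            continue
        for code, description, line in cell_findings:
            findings.append(StyleFinding(code=code, description=description,
                                         cell_index=idx, line=line))
    return findings
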