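"""Static notebook census: structure, Markdown, naming, imports."""

import json
import random

import pytest
from hypothesis import given, settings, strategies as st

from nbaudit import notebook
from nbaudit.forge import Behavior, forge_notebook
from nbaudit.lang import stub_detector
from nbaudit.profiles import (profile_imports, profile_markdown, profile_name,
                              profile_structure, strip_directives)


def recount_structure(doc):
    """Independent oracle: recount by walking the raw JSON document."""
    counts = {"code": 0, "markdown": 0, "raw": 0, "empty": 0, "with_out": 0}
    max_exec = None
    for cell in doc["cells"]:
        counts[cell["cell_type"]] += 1
        src = cell.get("source", "")
        if isinstance(src, list):
            src = "".join(src)
        if not src.strip():
            counts["empty"] += 1
        if cell["cell_type"] == "code":
            if cell.get("outputs"):
                counts["with_out"] += 1
            ec = cell.get("execution_count")
            if isinstance(ec, int):
                max_exec = ec if max_exec is None else max(max_exec, ec)
    return counts, max_exec


@pytest.mark.parametrize("behavior", list(Behavior))
def test_structure_census_matches_brute_force_recount(behavior):
    rng = random.Random(7)
    doc = forge_notebook(behavior, name="t", rng=rng, markdown_cells=3,
                         raw_cells=1)
    s = profile_structure(doc)
    counts, max_exec = recount_structure(doc)
    assert s.code_cells == counts["code"]
    assert s.markdown_cells == counts["markdown"]
    assert s.raw_cells == counts["raw"]
    assert s.cells_total == sum(counts[k] for k in ("code", "markdown", "raw"))
    assert s.empty_cells == counts["empty"]
    assert s.cells_with_output == counts["with_out"]
    assert s.max_execution_count == max_exec
    assert s.has_execution_counts is (max_exec is not None)


def test_language_resolution_prefers_kernelspec_then_language_info():
    doc = notebook.new_notebook([], {"language_info": {"name": "Python",
                                                       "version": "3.7.4"}})
    s = profile_structure(doc)
    assert s.language == "python" and s.language_version_full == "3.7.4"
    assert s.major_version == 3

    doc = notebook.new_notebook([], {})
    assert profile_structure(doc).language == "unknown"


def test_zero_cell_notebook_has_all_zero_counts():
    s = profile_structure(notebook.new_notebook([]))
    assert s.cells_total == 0 and s.max_execution_count is None
    assert not s.has_execution_counts


def test_whitespace_only_cell_counts_as_empty():
    doc = notebook.new_notebook([notebook.code_cell("   \n\t\n"),
                                 notebook.markdown_cell("text")])
    assert profile_structure(doc).empty_cells == 1


def test_v3_worksheets_are_flattened_on_read(tmp_path):
    v3 = {"nbformat": 3, "nbformat_minor": 0, "metadata": {},
          "worksheets": [{"cells": [
              {"cell_type": "heading", "level": 2, "source": "Title"},
              {"cell_type": "code", "input": "print(1)", "outputs": [
                  {"output_type": "pyout", "text": ["1"],
                   "prompt_number": 4}], "prompt_number": 4},
          ]}]}
    path = tmp_path / "old.ipynb"
    path.write_text(json.dumps(v3))
    doc = notebook.load(path)
    s = profile_structure(doc)
    assert (s.code_cells, s.markdown_cells) == (1, 1)
    assert s.max_execution_count == 4
    assert doc["cells"][0]["source"].startswith("## ")


# -- markdown ---------------------------------------------------------------

_EN = "the results of the analysis are shown in the table"
_FR = "le traitement des données est décrit dans les sections"


def test_markdown_elements_follow_the_grammar():
    doc = notebook.new_notebook([
        notebook.markdown_cell("# Title\n"),
        notebook.markdown_cell("A paragraph about methods.\n"),
        notebook.markdown_cell("- item one\n- item two\n"),
        notebook.markdown_cell("```python\nx = 1\n```\n"),
        notebook.markdown_cell("![fig](img.png) and [link](https://x.org)\n"),
        notebook.markdown_cell("|a|b|\n|---|---|\n|1|2|\n"),
        notebook.code_cell("pass"),
    ])
    profile = profile_markdown(doc, stub_detector({_EN: "en"}))
    assert profile.elements_present == frozenset(
        {"header", "paragraph", "list", "code_block", "image", "link",
         "table"})


def test_no_markdown_cells_means_undetected_language():
    doc = notebook.new_notebook([notebook.code_cell("pass")])
    profile = profile_markdown(doc, stub_detector({}))
    assert profile.total_words == 0
    assert profile.languages_detected == frozenset({"undetected"})
    assert profile.english_only is False


def test_bilingual_notebook_is_not_english_only():
    doc = notebook.new_notebook([notebook.markdown_cell(_EN),
                                 notebook.markdown_cell(_FR)])
    detector = stub_detector({_FR: "fr", _EN: "en"})
    profile = profile_markdown(doc, detector)
    assert profile.languages_detected == frozenset({"en", "fr"})
    assert profile.english_only is False

    only_en = profile_markdown(
        notebook.new_notebook([notebook.markdown_cell(_EN)]), detector)
    assert only_en.english_only is True


# -- naming -----------------------------------------------------------------

@pytest.mark.parametrize("path,checks", [
    ("Untitled3.ipynb", {"is_untitled": True, "posix_portable": True}),
    ("my analysis (copy).ipynb",
     {"posix_portable": False, "contains_copy": True}),
    ("a.ipynb", {"title_length": 1, "posix_portable": True}),
    ("dir/test_run.ipynb", {"contains_test": True}),
    ("-leading.ipynb", {"posix_portable": False}),
    ("CON.ipynb", {"windows_disallowed": True}),
    ("what?.ipynb", {"windows_disallowed": True, "posix_portable": False}),
    ("short.ipynb", {"exceeds_14_chars": False}),
    ("a_rather_long_title.ipynb", {"exceeds_14_chars": True}),
])
def test_naming_flags(path, checks):
    profile = profile_name(path)
    for attr, expected in checks.items():
        assert getattr(profile, attr) == expected, attr


def test_naming_requires_notebook_extension():
    with pytest.raises(ValueError):
        profile_name("not_a_notebook.txt")


# -- imports ----------------------------------------------------------------

def _import_doc(*cells):
    return notebook.new_notebook([notebook.code_cell(c) for c in cells])


def test_external_vs_local_resolution(tmp_path):
    (tmp_path / "utils.py").write_text("def f():\n    return 1\n")
    pkg = tmp_path / "mypkg"
    pkg.mkdir()
    (pkg / "__init__.py").write_text("")
    doc = _import_doc("import numpy as np\nimport utils\n",
                      "from mypkg import thing\nfrom . import sibling\n",
                      "import numpy.linalg\n")
    profile = profile_imports(doc, tmp_path)
    assert profile.modules_external == {"numpy": 1, "numpy.linalg": 1}
    assert profile.modules_local == {"utils": 1, "mypkg": 1, ".": 1}
    assert profile.syntax_ok


def test_directives_are_stripped_and_extensions_recorded(tmp_path):
    doc = _import_doc("%load_ext autoreload\n%autoreload 2\nimport json\n",
                      "!pip install something\nx = 1\n")
    profile = profile_imports(doc, tmp_path)
    assert profile.load_extensions == {"autoreload": 1}
    assert profile.modules_external == {"json": 1}
    assert any(d.startswith("!pip") for d in profile.directives)


def test_syntax_failure_is_best_effort_per_cell(tmp_path):
    doc = _import_doc("import os\n", "def broken(:\n")
    profile = profile_imports(doc, tmp_path)
    assert profile.syntax_ok is False
    assert profile.modules_external == {"os": 1}


def test_function_and_class_tallies(tmp_path):
    doc = _import_doc("def a():\n    pass\n\nasync def b():\n    pass\n",
                      "class C:\n    def method(self):\n        pass\n")
    profile = profile_imports(doc, tmp_path)
    assert profile.functions_defined == 3  # method counts as a function
    assert profile.classes_defined == 1


@settings(max_examples=30, derandomize=True)
@given(order=st.permutations(["import alpha\n", "import beta\n",
                              "from gamma import g\n", "import alpha\n"]))
def test_import_multisets_ignore_cell_order(order, tmp_path_factory):
    root = tmp_path_factory.getbasetemp() / "empty_repo"
    root.mkdir(exist_ok=True)
    profile = profile_imports(_import_doc(*order), root)
    assert profile.modules_external == {"alpha": 2, "beta": 1, "gamma": 1}


def test_strip_directives_drops_cell_magic_entirely():
    code, directives = strip_directives("%%bash\necho hi\n")
    assert code == "" and directives[0].startswith("%%bash")
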