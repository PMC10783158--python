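"""Single-pass re-execution, tracing and output diffing."""

import sys

import pytest

from nbaudit import notebook
from nbaudit.diffing import diff_against_original, normalize_text
from nbaudit.execute import (canonical_exception, execute_notebook,
                             snapshot_files)


def _run(tmp_path, cells, timeout=20.0, subdir="repo"):
    nb_dir = tmp_path / subdir
    nb_dir.mkdir(exist_ok=True)
    nb_path = nb_dir / "fixture.ipynb"
    doc = notebook.new_notebook([notebook.code_cell(c) for c in cells])
    notebook.dump(doc, nb_path)
    trace, executed = execute_notebook(nb_path, sys.executable, timeout,
                                       tmp_path / "scratch")
    return doc, trace, executed


def test_clean_notebook_completes_with_all_cells_executed(tmp_path):
    _, trace, executed = _run(tmp_path, ["a = 1\n", "b = a + 1\n",
                                         "print(b)\n"])
    assert trace.completed and trace.cells_executed == 3
    assert trace.first_exception_type is None
    outs = executed["cells"][2]["outputs"]
    assert outs == [{"output_type": "stream", "name": "stdout",
                     "text": "2\n"}]


def test_trailing_expression_becomes_an_execute_result(tmp_path):
    _, _, executed = _run(tmp_path, ["x = 6\nx * 7\n"])
    outs = executed["cells"][0]["outputs"]
    assert outs[0]["output_type"] == "execute_result"
    assert outs[0]["data"]["text/plain"] == "42"


def test_first_exception_stops_the_run(tmp_path):
    _, trace, executed = _run(tmp_path, [
        "a = 1\n",
        f"import nbaudit_no_such_module_xyz\n",
        "print('never')\n"])
    assert trace.completed is False
    assert trace.first_exception_type == "ModuleNotFoundError"
    assert trace.first_exception_cell == 1
    assert trace.cells_executed == 2  # invariant: failing cell included
    error = executed["cells"][1]["outputs"][-1]
    assert error["output_type"] == "error"
    assert error["ename"] == "ModuleNotFoundError"
    assert executed["cells"][2]["outputs"] == []  # never reached


def test_timeout_aborts_and_is_flagged(tmp_path):
    _, trace, _ = _run(tmp_path, ["import time\n",
                                  "time.sleep(30)\nprint('woke')\n"],
                       timeout=2.0)
    assert trace.timed_out is True and trace.completed is False
    assert trace.duration < 10.0
    assert trace.cells_executed >= 1  # partial progress was recorded


def test_working_directory_is_the_notebook_directory(tmp_path):
    (tmp_path / "repo").mkdir()
    (tmp_path / "repo" / "data.txt").write_text("payload")
    _, trace, executed = _run(
        tmp_path, ["print(open('data.txt').read())\n"])
    assert trace.completed
    assert executed["cells"][0]["outputs"][0]["text"] == "payload\n"


def test_kernel_start_failure_is_a_recorded_marker(tmp_path):
    nb_path = tmp_path / "x.ipynb"
    notebook.dump(notebook.new_notebook([notebook.code_cell("1\n")]), nb_path)
    trace, executed = execute_notebook(nb_path, "/no/such/python", 5.0,
                                       tmp_path / "scratch")
    assert trace.kernel_start_failed is True and executed is None


@pytest.mark.parametrize("alias,canonical", [
    ("IOError", "OSError"), ("OSError", "OSError"),
    ("KeyError", "KeyError"), (None, None)])
def test_exception_names_are_canonicalized(alias, canonical):
    assert canonical_exception(alias) == canonical


# -- diffing ----------------------------------------------------------------

def test_identical_documents_diff_to_zero(tmp_path):
    doc, trace, executed = _run(tmp_path, ["print('stable')\n"])
    # store the executed outputs as the "original", then compare
    report = diff_against_original(executed, executed, {}, {})
    assert (report.output_diff_count, report.execcount_diff_count,
            report.file_diff_count) == (0, 0, 0)


def test_changed_output_is_counted_per_cell(tmp_path):
    doc, _, executed = _run(tmp_path, ["print('fresh value')\n"])
    original = notebook.new_notebook([notebook.code_cell(
        "print('fresh value')\n",
        outputs=[{"output_type": "stream", "name": "stdout",
                  "text": "stale value\n"}], execution_count=1)])
    report = diff_against_original(original, executed, {}, {})
    assert report.output_diff_count == 1
    assert report.per_cell[0][:2] == (0, "output")


def test_normalization_ignores_ansi_and_trailing_whitespace():
    assert normalize_text("\x1b[31mred\x1b[0m  \n\n") == "red"
    a = {"cell_type": "code", "outputs": [
        {"output_type": "stream", "name": "stdout", "text": "x  \n"}]}
    b = {"cell_type": "code", "outputs": [
        {"output_type": "stream", "name": "stdout", "text": "x\n"}]}
    from nbaudit.diffing import normalized_outputs
    assert normalized_outputs(a) == normalized_outputs(b)


def test_transient_masking_is_off_by_default():
    from nbaudit.diffing import normalized_outputs
    mk = lambda text: {"cell_type": "code", "outputs": [  # noqa: E731
        {"output_type": "stream", "name": "stdout", "text": text}]}
    a, b = mk("<obj at 0xdeadbeef01>"), mk("<obj at 0xfeedface02>")
    assert normalized_outputs(a) != normalized_outputs(b)
    assert normalized_outputs(a, mask_transients=True) == \
        normalized_outputs(b, mask_transients=True)


def test_execution_count_differences_are_tallied_separately():
    orig = notebook.new_notebook([notebook.code_cell("1\n", outputs=[],
                                                     execution_count=9)])
    ran = notebook.new_notebook([notebook.code_cell("1\n", outputs=[],
                                                    execution_count=1)])
    report = diff_against_original(orig, ran, {}, {})
    assert report.output_diff_count == 0
    assert report.execcount_diff_count == 1


def test_workspace_file_changes_come_from_the_manifests(tmp_path):
    before_dir = tmp_path / "w"
    before_dir.mkdir()
    (before_dir / "result.csv").write_text("old")
    before = snapshot_files(before_dir)
    (before_dir / "result.csv").write_text("new")
    (before_dir / "extra.txt").write_text("created")
    after = snapshot_files(before_dir)
    doc = notebook.new_notebook([])
    report = diff_against_original(doc, doc, before, after)
    assert report.file_diff_count == 2
    kinds = sorted(summary.split(":")[0] for _, kind, summary
                   in report.per_cell if kind == "file")
    assert kinds == ["created", "modified"]


def test_cell_count_mismatch_is_rejected():
    a = notebook.new_notebook([notebook.code_cell("1\n")])
    b = notebook.new_notebook([])
    with pytest.raises(ValueError, match="cell count"):
        diff_against_original(a, b, {}, {})
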