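"""Outcome classification: precedence, policies, contract checks."""

import pytest

from nbaudit import notebook
from nbaudit.classify import InconsistentPrefixError, classify_outcome
from nbaudit.profiles import profile_structure
from nbaudit.records import (DiffReport, ExecutionTrace, FailedStage,
                             InstallOutcome, OutcomeLabel, RepositoryRecord)

REPO_OK = RepositoryRecord(canonical_url="https://github.com/a/b",
                           available=True, local_path="/tmp/x")
REPO_GONE = RepositoryRecord(canonical_url="https://github.com/a/b",
                             available=False)

PY = profile_structure(notebook.new_notebook(
    [], {"kernelspec": {"name": "python3", "language": "python"}}))
RLANG = profile_structure(notebook.new_notebook(
    [], {"kernelspec": {"name": "ir", "language": "R"}}))

INSTALL_OK = InstallOutcome(success=True, log_excerpt="", duration=1.0,
                            failed_stage=FailedStage.NONE, env_path="/py")
INSTALL_BAD = InstallOutcome(success=False, log_excerpt="boom", duration=1.0,
                             failed_stage=FailedStage.INSTALL)


def _trace(completed=True, timed_out=False, exc=None, cell=None,
           start_failed=False, cells=3):
    return ExecutionTrace(started="t0", finished="t1", duration=1.0,
                          completed=completed, timed_out=timed_out,
                          kernel_start_failed=start_failed,
                          first_exception_type=exc,
                          first_exception_cell=cell, cells_executed=cells)


def _diff(output=0, counts=0, files=0):
    per_cell = [(i, "output", "x") for i in range(output)]
    return DiffReport(output_diff_count=output, execcount_diff_count=counts,
                      file_diff_count=files, per_cell=per_cell)


def test_unavailable_repo_dominates():
    assert classify_outcome(REPO_GONE, None).label \
        is OutcomeLabel.REPO_UNAVAILABLE


def test_non_target_language_before_environment_stage():
    assert classify_outcome(REPO_OK, RLANG).label \
        is OutcomeLabel.NOT_TARGET_LANGUAGE


def test_install_failure_dominates_downstream():
    assert classify_outcome(REPO_OK, PY, INSTALL_BAD).label \
        is OutcomeLabel.INSTALL_FAILED


def test_timeout_and_kernel_failures_precede_exceptions():
    timed = classify_outcome(REPO_OK, PY, INSTALL_OK,
                             _trace(completed=False, timed_out=True))
    assert timed.label is OutcomeLabel.TIMEOUT
    excluded = classify_outcome(REPO_OK, PY, INSTALL_OK,
                                _trace(completed=False, start_failed=True))
    assert excluded.label is OutcomeLabel.EXCLUDED


def test_exception_label_carries_the_canonical_type():
    outcome = classify_outcome(
        REPO_OK, PY, INSTALL_OK,
        _trace(completed=False, exc="FileNotFoundError", cell=2, cells=3))
    assert outcome.label is OutcomeLabel.EXCEPTION
    assert outcome.exception_type == "FileNotFoundError"
    alias = classify_outcome(
        REPO_OK, PY, INSTALL_OK,
        _trace(completed=False, exc="IOError", cell=0, cells=1))
    assert alias.exception_type == "OSError"


def test_identity_requires_zero_output_differences_only_by_default():
    outcome = classify_outcome(REPO_OK, PY, INSTALL_OK, _trace(),
                               _diff(output=0, counts=3, files=1))
    assert outcome.label is OutcomeLabel.FINISHED_IDENTICAL


def test_strict_policies_flip_the_verdict():
    diff = _diff(output=0, counts=3, files=1)
    strict_counts = classify_outcome(REPO_OK, PY, INSTALL_OK, _trace(), diff,
                                     strict_counters=True)
    assert strict_counts.label is OutcomeLabel.FINISHED_DIFFERENT
    strict_files = classify_outcome(REPO_OK, PY, INSTALL_OK, _trace(), diff,
                                    strict_files=True)
    assert strict_files.label is OutcomeLabel.FINISHED_DIFFERENT


def test_any_output_difference_means_different():
    outcome = classify_outcome(REPO_OK, PY, INSTALL_OK, _trace(),
                               _diff(output=1))
    assert outcome.label is OutcomeLabel.FINISHED_DIFFERENT


def test_notebook_never_handed_to_environment_stage():
    assert classify_outcome(REPO_OK, PY).label \
        is OutcomeLabel.NO_DECLARED_PIPELINE_ENTRY


@pytest.mark.parametrize("kwargs", [
    dict(repo=REPO_GONE, structure=PY, install=INSTALL_OK),
    dict(repo=REPO_OK, structure=RLANG, install=INSTALL_OK),
    dict(repo=REPO_OK, structure=PY, install=INSTALL_BAD,
         trace=_trace()),
    dict(repo=REPO_OK, structure=PY, install=INSTALL_OK, trace=_trace(),
         diff=None),
])
def test_inconsistent_pipeline_prefixes_are_contract_violations(kwargs):
    with pytest.raises(InconsistentPrefixError):
        classify_outcome(**kwargs)
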