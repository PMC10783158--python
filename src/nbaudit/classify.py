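"""Assigning each notebook its single, mutually exclusive outcome label.

The label drives every flow statistic, so classification is a total
function over any consistent prefix of the pipeline, with a fixed
precedence: repository unavailable, then non-target language, then the
environment stage (install failure), then the execution stage (timeout
and exclusions before typed exceptions), then the diff verdict.

Identity policy: by default ``finished_identical`` requires zero
output-content differences; execution-count and workspace-file
differences are recorded but do not affect the label.  The stricter
policy — counters and files must match too — is behind explicit flags.
"""

from __future__ import annotations

from typing import Optional

from .execute import canonical_exception
from .profiles import is_target_language
from .records import (DiffReport, ExecutionTrace, InstallOutcome,
                    NotebookStructure, OutcomeClass, OutcomeLabel,
                    RepositoryRecord)


class InconsistentPrefixError(ValueError):
    """The supplied stage records cannot have come from one pipeline run."""


def classify_outcome(repo: RepositoryRecord,
                     structure: Optional[NotebookStructure],
                     install: Optional[InstallOutcome] = None,
                     trace: Optional[ExecutionTrace] = None,
                     diff: Optional[DiffReport] = None,
                     strict_counters: bool = False,
                     strict_files: bool = False) -> OutcomeClass:
    """Classify one notebook from whatever stages it reached."""
    if not repo.available:
        if install is not None or trace is not None:
            raise InconsistentPrefixError(
                "downstream records for an unavailable repository")
        return OutcomeClass(OutcomeLabel.REPO_UNAVAILABLE)

    if structure is None:
        # the document never passed the schema load; nothing was run
        if install is not None or trace is not None:
            raise InconsistentPrefixError(
                "downstream records for an unparsed notebook")
        return OutcomeClass(OutcomeLabel.EXCLUDED)

    if not is_target_language(structure):
        if install is not None or trace is not None:
            raise InconsistentPrefixError(
                "downstream records for a non-target-language notebook")
        return OutcomeClass(OutcomeLabel.NOT_TARGET_LANGUAGE)

    if install is None:
        if trace is not None:
            raise InconsistentPrefixError("trace without an install outcome")
        return OutcomeClass(OutcomeLabel.NO_DECLARED_PIPELINE_ENTRY)

    if not install.success:
        if trace is not None:
            raise InconsistentPrefixError("trace after a failed install")
        return OutcomeClass(OutcomeLabel.INSTALL_FAILED)

    if trace is None:
        return OutcomeClass(OutcomeLabel.NO_DECLARED_PIPELINE_ENTRY)

    if trace.timed_out:
        return OutcomeClass(OutcomeLabel.TIMEOUT)
    if trace.kernel_start_failed:
        return OutcomeClass(OutcomeLabel.EXCLUDED)
    if trace.first_exception_type is not None:
        return OutcomeClass(OutcomeLabel.EXCEPTION,
                            exception_type=canonical_exception(
                                trace.first_exception_type))
    if not trace.completed:
        return OutcomeClass(OutcomeLabel.EXCLUDED)

    if diff is None:
        raise InconsistentPrefixError("completed execution without a diff")
    identical = diff.output_diff_count == 0
    if strict_counters:
        identical = identical and diff.execcount_diff_count == 0
    if strict_files:
        identical = identical and diff.file_diff_count == 0
    return OutcomeClass(OutcomeLabel.FINISHED_IDENTICAL if identical
                        else OutcomeLabel.FINISHED_DIFFERENT)
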