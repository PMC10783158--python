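"""Aggregate statistics over an audited corpus.

All percentages are computed at read time from stage counts, rounded
half-away-from-zero at the requested precision and rendered as stable
decimal strings.  ``summarize`` produces the grouped tables (by
exception type, language, interpreter version, style code, ...), and
``compare_groups`` the comparison of successfully finished notebooks
whose re-executed results were identical to versus different from the
stored ones — including the reproducibility ratio
``different / (different + identical)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Optional

from .store import CorpusStore

UNDEFINED = "undefined"


def round_half_away(value: float, digits: int) -> float:
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, digits: int = 2) -> str:
    """Printed-style percentage string, half-away-from-zero rounding.

    A zero denominator yields the explicit string ``"undefined"`` rather
    than a division error.
    """
    if denominator == 0:
        return UNDEFINED
    quantum = Decimal(1).scaleb(-digits)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP)
    return f"{value:.{digits}f}" if digits > 0 else f"{value:.0f}"


def repro_ratio(different: int, identical: int) -> Optional[float]:
    """``different / (different + identical)``, full precision.

    Use :func:`round_half_away` (2 digits) for display.  Returns None
    when both counts are zero (undefined).
    """
    total = different + identical
    if total == 0:
        return None
    return different / total


class Dimension(str, Enum):
    YEAR = "year"
    JOURNAL = "journal"
    MESH_TOP_LEVEL = "mesh_top_level"
    LANGUAGE = "language"
    INTERPRETER_VERSION = "interpreter_version"
    EXCEPTION_TYPE = "exception_type"
    STYLE_CODE = "style_code"
    ARTICLE_TYPE = "article_type"


@dataclass
class SummaryTable:
    dimension: Dimension
    rows: list[tuple[str, int, Optional[float]]]
    denominator_definition: str

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows,
                            columns=["key", "count", "normalized"])


_DIMENSION_SQL = {
    Dimension.YEAR:
        "SELECT substr(date_published, 1, 4) AS k, COUNT(*) AS n"
        " FROM articles WHERE date_published IS NOT NULL GROUP BY k",
    Dimension.JOURNAL:
        "SELECT COALESCE(j.title, j.issn) AS k, COUNT(*) AS n FROM articles a"
        " JOIN journals j ON a.journal_id = j.id GROUP BY k",
    Dimension.LANGUAGE:
        "SELECT language AS k, COUNT(*) AS n FROM structures GROUP BY k",
    Dimension.INTERPRETER_VERSION:
        "SELECT COALESCE(language_version_full, 'unknown') AS k, COUNT(*) AS n"
        " FROM structures WHERE language = 'python' GROUP BY k",
    Dimension.EXCEPTION_TYPE:
        "SELECT exception_type AS k, COUNT(*) AS n FROM outcomes"
        " WHERE label = 'exception' GROUP BY k",
    Dimension.STYLE_CODE:
        "SELECT code AS k, COUNT(*) AS n FROM style_findings GROUP BY k",
}

_DENOMINATORS = {
    Dimension.YEAR: "articles with a publication date",
    Dimension.JOURNAL: "articles with a registered journal",
    Dimension.LANGUAGE: "parsed notebooks",
    Dimension.INTERPRETER_VERSION: "parsed target-language notebooks",
    Dimension.EXCEPTION_TYPE: "notebooks whose execution raised",
    Dimension.STYLE_CODE: "style findings",
}


def summarize(store: CorpusStore, dimension: Dimension,
              normalizer: Optional[int] = None) -> SummaryTable:
    """Grouped counts, ordered by descending count then key.

    *normalizer*, when given, adds ``count / normalizer`` per row (the
    caller states the denominator rule, e.g. notebooks per year).
    """
    if dimension not in _DIMENSION_SQL:
        raise ValueError(f"dimension {dimension} is not configured")
    rows = [(str(r["k"]), int(r["n"]))
            for r in store.conn.execute(_DIMENSION_SQL[dimension])]
    rows.sort(key=lambda kv: (-kv[1], kv[0]))
    out = [(k, n, (n / normalizer) if normalizer else None)
           for k, n in rows]
    denom = _DENOMINATORS[dimension]
    if normalizer:
        denom += f"; normalized by {normalizer}"
    return SummaryTable(dimension=dimension, rows=out,
                        denominator_definition=denom)


@dataclass
class GroupStats:
    notebook_count: int
    with_setup: int
    with_requirements: int
    with_pipfile: int
    mean_total_cells: Optional[float]
    mean_code_cells: Optional[float]
    mean_markdown_cells: Optional[float]
    mean_empty_cells: Optional[float]
    mean_markdown_code_ratio: Optional[float]
    mean_differences: Optional[float]
    mean_execution_time: Optional[float]
    time_per_code_cell_ratio_of_means: Optional[float]
    time_per_code_cell_mean_of_ratios: Optional[float]


@dataclass
class GroupComparison:
    different: GroupStats
    identical: GroupStats

    @property
    def ratio(self) -> Optional[float]:
        return repro_ratio(self.different.notebook_count,
                           self.identical.notebook_count)


_GROUP_SQL = """
SELECT s.cells_total, s.code_cells, s.markdown_cells, s.empty_cells,
       d.output_diff_count + d.execcount_diff_count + d.file_diff_count
           AS differences,
       e.duration,
       dec.has_setup, dec.has_requirements, dec.has_pipfile
FROM outcomes o
JOIN notebooks n ON n.id = o.notebook_id
JOIN structures s ON s.notebook_id = o.notebook_id
LEFT JOIN diffs d ON d.notebook_id = o.notebook_id
LEFT JOIN executions e ON e.notebook_id = o.notebook_id
LEFT JOIN declarations dec ON dec.repo_url = n.repo_url
WHERE o.label = ?
"""


def _group_stats(store: CorpusStore, label: str) -> GroupStats:
    rows = store.conn.execute(_GROUP_SQL, (label,)).fetchall()
    n = len(rows)

    def mean(key):
        vals = [r[key] for r in rows if r[key] is not None]
        return (sum(vals) / len(vals)) if vals else None

    ratios = [r["markdown_cells"] / r["code_cells"] if r["code_cells"]
              else 0.0 for r in rows]
    time_ratios = [r["duration"] / r["code_cells"] for r in rows
                   if r["duration"] is not None and r["code_cells"]]
    mean_time = mean("duration")
    mean_code = mean("code_cells")
    return GroupStats(
        notebook_count=n,
        with_setup=sum(1 for r in rows if r["has_setup"]),
        with_requirements=sum(1 for r in rows if r["has_requirements"]),
        with_pipfile=sum(1 for r in rows if r["has_pipfile"]),
        mean_total_cells=mean("cells_total"),
        mean_code_cells=mean_code,
        mean_markdown_cells=mean("markdown_cells"),
        mean_empty_cells=mean("empty_cells"),
        mean_markdown_code_ratio=(sum(ratios) / n) if n else None,
        mean_differences=mean("differences"),
        mean_execution_time=mean_time,
        time_per_code_cell_ratio_of_means=(
            mean_time / mean_code if mean_time and mean_code else None),
        time_per_code_cell_mean_of_ratios=(
            sum(time_ratios) / len(time_ratios) if time_ratios else None),
    )


def compare_groups(store: CorpusStore) -> GroupComparison:
    """Finished notebooks, different-results group vs identical group.

    Per-code-cell execution time is reported under both estimators —
    ratio of means and mean of ratios — since they answer different
    questions and can diverge widely; neither is privileged.
    """
    comparison = GroupComparison(
        different=_group_stats(store, "finished_different"),
        identical=_group_stats(store, "finished_identical"))
    flow = store.flow_counts()
    if (comparison.different.notebook_count != flow.finished_different
            or comparison.identical.notebook_count != flow.finished_identical):
        raise AssertionError("group sizes disagree with flow counts")
    return comparison
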