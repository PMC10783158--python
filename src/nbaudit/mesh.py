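"""Aggregation of MeSH descriptors to their top-level ancestors.

MeSH (Medical Subject Headings) is a hierarchical controlled vocabulary;
the top-level descriptor of each assigned heading serves as a proxy for
an article's research field.  Resolution goes through an injectable
descriptor -> top-level mapping so the pipeline runs offline from a
file-backed table; a network-backed adapter (e.g. a SPARQL client over
the MeSH RDF service) can implement the same one-method interface.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable

UNKNOWN = "unknown"

TreeLookup = Callable[[str], str]


def table_lookup(table: dict[str, str]) -> TreeLookup:
    """Lookup over a plain descriptor -> top-level table."""
    def lookup(term: str) -> str:
        return table.get(term, UNKNOWN)
    return lookup


def load_mesh_table(path: str | Path) -> TreeLookup:
    """File-backed lookup.  JSON object or 2-column TSV (descriptor, top)."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        return table_lookup(json.loads(p.read_text(encoding="utf-8")))
    table = {}
    for line in p.read_text(encoding="utf-8").splitlines():
        if line.strip() and not line.startswith("#"):
            term, top = line.split("\t")[:2]
            table[term] = top
    return table_lookup(table)


def resolve_top_level_mesh(terms: list[str], tree_lookup: TreeLookup) -> list[str]:
    """Deduplicated top-level ancestors, stable by first occurrence.

    A term that is itself top-level maps to itself (the lookup returns
    it unchanged); a term the lookup cannot map yields the sentinel
    ``"unknown"``.
    """
    seen: list[str] = []
    for term in terms:
        top = tree_lookup(term) or UNKNOWN
        if top not in seen:
            seen.append(top)
    return seen
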