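"""Mining article metadata and repository links from JATS full text.

JATS (Journal Article Tagging Suite) is the XML vocabulary in which
PubMed Central serves full-text articles.  This module turns one parsed
article into an :class:`~nbaudit.records.ArticleRecord` — identifiers,
title, dates, license, keywords, MeSH headings, authors — and extracts
every repository link mentioned anywhere in the text (abstract, body,
data-availability and supplementary sections, link attributes included),
normalizing each mention via :mod:`nbaudit.links`.

Fields absent from the XML are marked absent, never invented.  Journals
are deduplicated through a :class:`JournalRegistry` keyed by ISSN when
present, else by title.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

from lxml import etree

from .links import find_mentions, normalize_repo_link
from .records import (ArticleRecord, AuthorRecord, JournalRecord, LinkRejection,
                    NormalizedRepoLink)

XLINK = "{http://www.w3.org/1999/xlink}href"


class JatsParseError(ValueError):
    """Malformed XML; message names the byte offset when known."""


class JatsStructureError(ValueError):
    """Well-formed XML that is not a JATS article."""


def parse_jats(source: str | Path | bytes) -> etree._Element:
    """Parse JATS XML from a path or raw bytes, returning the article root."""
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as exc:
        # lxml positions are (line, column); report the byte offset too
        offset = getattr(exc, "position", None)
        raise JatsParseError(
            f"malformed XML at line/column {offset}: {exc}") from exc
    if root.tag == "pmc-articleset":
        articles = root.findall("article")
        if not articles:
            raise JatsStructureError("article set contains no <article>")
        root = articles[0]
    if root.tag != "article":
        raise JatsStructureError(f"root element is <{root.tag}>, not <article>")
    return root


class JournalRegistry:
    """Deduplicating journal store: one record per ISSN (else per title)."""

    def __init__(self) -> None:
        self._records: list[JournalRecord] = []
        self._index: dict[str, int] = {}

    def register(self, journal: JournalRecord) -> int:
        key = f"issn:{journal.issn}" if journal.issn else f"title:{journal.title}"
        if key in self._index:
            return self._index[key]
        self._records.append(journal)
        idx = len(self._records) - 1
        self._index[key] = idx
        return idx

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, idx: int) -> JournalRecord:
        return self._records[idx]

    def records(self) -> list[JournalRecord]:
        return list(self._records)


def _text(elem: Optional[etree._Element]) -> Optional[str]:
    if elem is None:
        return None
    joined = " ".join("".join(elem.itertext()).split())
    return joined or None


def _find_text(root: etree._Element, path: str) -> Optional[str]:
    return _text(root.find(path))


def _iso_date(elem: Optional[etree._Element]) -> Optional[str]:
    if elem is None:
        return None
    year = _find_text(elem, "year")
    if year is None:
        return None
    month = _find_text(elem, "month") or "1"
    day = _find_text(elem, "day") or "1"
    try:
        return f"{int(year):04d}-{int(month):02d}-{int(day):02d}"
    except ValueError:
        return None


def _article_id(meta: etree._Element, id_type: str) -> Optional[str]:
    for aid in meta.findall("article-id"):
        if aid.get("pub-id-type") == id_type:
            return _text(aid)
    return None


def _journal_record(root: etree._Element) -> Optional[JournalRecord]:
    jmeta = root.find("front/journal-meta")
    if jmeta is None:
        return None
    issn = _find_text(jmeta, "issn")
    title = (_find_text(jmeta, "journal-title-group/journal-title")
             or _find_text(jmeta, "journal-title"))
    nlm = iso = None
    for jid in jmeta.findall("journal-id"):
        if jid.get("journal-id-type") == "nlm-ta":
            nlm = _text(jid)
        elif jid.get("journal-id-type") == "iso-abbrev":
            iso = _text(jid)
    if issn is None and title is None:
        return None
    return JournalRecord(issn=issn, title=title, nlm_abbrev=nlm, iso_abbrev=iso)


def _authors(meta: etree._Element) -> list[AuthorRecord]:
    out = []
    for contrib in meta.findall("contrib-group/contrib"):
        if contrib.get("contrib-type") not in (None, "author"):
            continue
        orcid = None
        for cid in contrib.findall("contrib-id"):
            if cid.get("contrib-id-type") == "orcid":
                orcid = _text(cid)
        out.append(AuthorRecord(
            surname=_find_text(contrib, "name/surname"),
            given_names=_find_text(contrib, "name/given-names"),
            orcid=orcid,
            email=_find_text(contrib, "email")))
    return out


def _mesh_terms(meta: etree._Element) -> list[str]:
    terms = []
    for group in meta.findall("article-categories/subj-group"):
        if group.get("subj-group-type") == "mesh-heading":
            terms.extend(t for s in group.findall("subject")
                         if (t := _text(s)) is not None)
    return terms


def _enclosing_section(elem: etree._Element) -> str:
    node = elem
    while node is not None:
        tag = node.tag if isinstance(node.tag, str) else ""
        if tag in ("abstract", "body", "ref-list", "fig", "table-wrap"):
            return tag
        if tag == "sec" and node.get("sec-type"):
            return node.get("sec-type")
        node = node.getparent()
    return "unknown"


def extract_repo_mentions(root: etree._Element,
                          with_sections: bool = False):
    """Every candidate repository URL in document order, duplicates kept.

    Mentions are collected from all text nodes and from ``xlink:href``
    attributes; each mention's enclosing section tag is recorded so that
    section-based inclusion policies can be replayed.  Returns a list of
    raw strings, or of ``(raw, section)`` pairs if *with_sections*.
    """
    found: list[tuple[str, str]] = []
    for elem in root.iter():
        if not isinstance(elem.tag, str):
            continue
        href = elem.get(XLINK)
        if href:
            for raw in find_mentions(href):
                found.append((raw, _enclosing_section(elem)))
        for chunk in (elem.text, elem.tail):
            if chunk:
                for raw in find_mentions(chunk):
                    found.append((raw, _enclosing_section(elem)))
    return found if with_sections else [raw for raw, _ in found]


def extract_article_metadata(root: etree._Element,
                             journal_registry: JournalRegistry) -> ArticleRecord:
    """Build the article record; extractable fields populated, others absent."""
    meta = root.find("front/article-meta")
    if meta is None:
        raise JatsStructureError("article has no <front>/<article-meta>")
    pmc_id = _article_id(meta, "pmc") or _article_id(meta, "pmcid")
    if not pmc_id:
        raise JatsStructureError("article-meta carries no PMC identifier")

    journal = _journal_record(root)
    journal_ref = journal_registry.register(journal) if journal else None

    received = accepted = None
    history = meta.find("history")
    if history is not None:
        for date in history.findall("date"):
            if date.get("date-type") == "received":
                received = _iso_date(date)
            elif date.get("date-type") == "accepted":
                accepted = _iso_date(date)
    published = _iso_date(meta.find("pub-date"))

    links: list[NormalizedRepoLink] = []
    rejections: list[LinkRejection] = []
    for raw in extract_repo_mentions(root):
        result = normalize_repo_link(raw)
        if isinstance(result, LinkRejection):
            rejections.append(result)
        else:
            links.append(result)

    keywords = [t for kwd in meta.findall("kwd-group/kwd")
                if (t := _text(kwd)) is not None]

    return ArticleRecord(
        pmc_id=pmc_id,
        pubmed_id=_article_id(meta, "pmid") or _article_id(meta, "pubmed"),
        doi=_article_id(meta, "doi"),
        title=_find_text(meta, "title-group/article-title"),
        journal_ref=journal_ref,
        publisher_id=_article_id(meta, "publisher-id"),
        publisher_name=_find_text(root, "front/journal-meta/publisher/publisher-name"),
        date_received=received,
        date_accepted=accepted,
        date_published=published,
        license_text=_find_text(meta, "permissions/license"),
        copyright_text=_find_text(meta, "permissions/copyright-statement"),
        keywords=keywords,
        mesh_terms=_mesh_terms(meta),
        repo_links=links,
        link_rejections=rejections,
        authors=_authors(meta),
    )


def mine_directory(xml_dir: str | Path,
                   journal_registry: JournalRegistry | None = None
                   ) -> tuple[list[ArticleRecord], JournalRegistry]:
    """Mine every ``*.xml`` article file under *xml_dir* (sorted order)."""
    registry = journal_registry or JournalRegistry()
    articles = []
    for path in sorted(Path(xml_dir).rglob("*.xml")):
        root = parse_jats(path)
        articles.append(extract_article_metadata(root, registry))
    return articles, registry
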