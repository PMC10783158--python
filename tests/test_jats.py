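"""JATS article mining: field extraction, link recovery, journal dedup."""

import pytest
from lxml import etree

from nbaudit.jats import (JatsParseError, JatsStructureError, JournalRegistry,
                          extract_article_metadata, extract_repo_mentions,
                          parse_jats)

MINIMAL = b"""<?xml version="1.0"?>
<article>
  <front>
    <article-meta>
      <article-id pub-id-type="pmc">PMC123</article-id>
      <title-group><article-title>A minimal study</article-title></title-group>
    </article-meta>
  </front>
</article>
"""


def test_minimal_article_yields_only_present_fields():
    record = extract_article_metadata(parse_jats(MINIMAL), JournalRegistry())
    assert record.pmc_id == "PMC123"
    assert record.title == "A minimal study"
    for absent in ("pubmed_id", "doi", "journal_ref", "date_received",
                   "date_published", "license_text"):
        assert getattr(record, absent) is None, absent
    assert record.keywords == [] and record.mesh_terms == []
    assert record.repo_links == []


def test_malformed_xml_reports_position():
    with pytest.raises(JatsParseError, match="line/column"):
        parse_jats(b"<article><front>")


def test_non_article_root_is_a_structural_error():
    with pytest.raises(JatsStructureError, match="not <article>"):
        parse_jats(b"<bundle/>")


def _with_links(*chunks: str) -> bytes:
    body = "".join(chunks)
    return MINIMAL.replace(b"</article>",
                           f"<body>{body}</body></article>".encode())


def test_duplicate_mentions_are_preserved_in_document_order():
    doc = _with_links(
        "<p>code at https://github.com/a/b here</p>",
        '<sec sec-type="data-availability">'
        "<p>archived: https://github.com/a/b</p></sec>")
    mentions = extract_repo_mentions(parse_jats(doc))
    assert mentions == ["https://github.com/a/b", "https://github.com/a/b"]


def test_links_found_in_attributes_and_text_with_section_tags():
    doc = _with_links(
        '<p><ext-link xmlns:xlink="http://www.w3.org/1999/xlink" '
        'xlink:href="https://github.com/x/y/blob/main/nb.ipynb">viewer'
        "</ext-link></p>",
        '<sec sec-type="data-availability">'
        "<p>github.com/p/q</p></sec>")
    pairs = extract_repo_mentions(parse_jats(doc), with_sections=True)
    assert [raw for raw, _ in pairs] == [
        "https://github.com/x/y/blob/main/nb.ipynb", "github.com/p/q"]
    assert pairs[1][1] == "data-availability"


def test_article_without_repo_hosts_yields_no_mentions():
    doc = _with_links("<p>see https://example.org/data for data</p>")
    assert extract_repo_mentions(parse_jats(doc)) == []


def test_articles_sharing_an_issn_share_one_journal_record():
    registry = JournalRegistry()
    front = (b"<front><journal-meta>"
             b"<journal-title-group><journal-title>J%s</journal-title>"
             b"</journal-title-group><issn>1234-5678</issn></journal-meta>")
    for i, pmc in enumerate((b"PMC1", b"PMC2")):
        xml = (b"<article>" + (front % pmc) + b"<article-meta>"
               b'<article-id pub-id-type="pmc">' + pmc + b"</article-id>"
               b"</article-meta></front></article>")
        record = extract_article_metadata(parse_jats(xml), registry)
        assert record.journal_ref == 0
    assert len(registry) == 1


def test_mesh_headings_and_rejections_are_recovered(corpus):
    """Forge round trip: every planted link and rejection is recovered."""
    corpus_root, manifest = corpus
    registry = JournalRegistry()
    for spec in manifest.articles:
        record = extract_article_metadata(
            parse_jats(corpus_root / spec.xml_path), registry)
        assert record.pmc_id == spec.pmc_id
        assert record.mesh_terms == spec.mesh_terms
        assert record.keywords == spec.keywords
        recovered = sorted(link.canonical_url for link in record.repo_links)
        slug_urls = {r.slug: r.canonical_url for r in manifest.repos}
        planted = sorted(slug_urls[p.repo] for p in spec.planted_links)
        assert recovered == planted
        assert (sorted(r.reason.value for r in record.link_rejections)
                == sorted(r["reason"] for r in spec.planted_rejections))
    # journals planted from a 3-entry pool across 5 articles deduplicate
    assert len(registry) == len({a.journal_issn for a in manifest.articles})
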