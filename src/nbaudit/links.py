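"""Normalization of repository links found in article text.

Articles mention GitHub repositories in many dialects — plain repository
URLs, deep ``/blob/``/``/tree/`` paths, nbviewer renderings,
``raw.githubusercontent.com`` file links, trailing ``.git`` — all of
which identify one repository.  ``normalize_repo_link`` maps every
recognized dialect onto the canonical
``https://github.com/{owner}/{repo}`` form, and classifies
owner-only mentions, GitHub Pages sites, gists, and malformed text as
rejections (values, not errors).
"""

from __future__ import annotations

import re
from urllib.parse import urlsplit, unquote

from .records import LinkRejection, NormalizedRepoLink, RejectionReason, SourceForm

# hosts whose paths identify a github repository
_NBVIEWER_HOSTS = {"nbviewer.jupyter.org", "nbviewer.org", "nbviewer.ipython.org"}
_RAW_HOST = "raw.githubusercontent.com"

_SEGMENT_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")

# candidate link pattern used when scanning article text
MENTION_RE = re.compile(
    r"(?:https?://)?"
    r"(?:[A-Za-z0-9\-]+\.)*"
    r"(?:github\.com|github\.io|githubusercontent\.com|nbviewer\.org|"
    r"nbviewer\.jupyter\.org|nbviewer\.ipython\.org)"
    r"[^\s<>\"')\]};,]*"
)


def find_mentions(text: str) -> list[str]:
    """All candidate repository-hosting URLs in *text*, in order."""
    return [m.group(0).rstrip(".") for m in MENTION_RE.finditer(text)]


def _reject(raw: str, reason: RejectionReason) -> LinkRejection:
    return LinkRejection(raw_text=raw, reason=reason)


def _accept(raw: str, owner: str, repo: str, form: SourceForm):
    repo = repo.removesuffix(".git")
    if not (_SEGMENT_RE.match(owner or "") and _SEGMENT_RE.match(repo or "")):
        return _reject(raw, RejectionReason.MALFORMED)
    return NormalizedRepoLink(owner=owner, repo_name=repo, source_form=form)


def normalize_repo_link(raw: str) -> NormalizedRepoLink | LinkRejection:
    """Normalize one raw link string; deterministic and idempotent.

    Accepted inputs yield a ``NormalizedRepoLink`` whose ``canonical_url``
    is ``https://github.com/{owner}/{repo}``; everything else yields a
    ``LinkRejection`` with the applicable reason.
    """
    if not raw or not raw.strip():
        return _reject(raw, RejectionReason.MALFORMED)
    text = raw.strip().rstrip(").,;:]")
    # tolerate scheme-less mentions
    probe = text if "://" in text else "https://" + text
    try:
        parts = urlsplit(probe)
    except ValueError:
        return _reject(raw, RejectionReason.MALFORMED)
    host = (parts.hostname or "").lower()
    segments = [unquote(s) for s in parts.path.split("/") if s]

    if host.endswith("github.io"):
        return _reject(raw, RejectionReason.PAGES_SITE)
    if host == "gist.github.com":
        return _reject(raw, RejectionReason.NON_REPO_HOST)

    if host == "github.com" or host == "www.github.com":
        if not segments:
            return _reject(raw, RejectionReason.MALFORMED)
        if len(segments) == 1:
            return _reject(raw, RejectionReason.OWNER_ONLY)
        owner, repo = segments[0], segments[1]
        if len(segments) > 2:
            kind = segments[2]
            form = {"blob": SourceForm.BLOB_PATH,
                    "tree": SourceForm.TREE_PATH,
                    "raw": SourceForm.RAW_HOST}.get(kind, SourceForm.OTHER)
        elif repo.endswith(".git"):
            repo = repo.removesuffix(".git")
            form = SourceForm.GIT_SUFFIX
        else:
            form = SourceForm.PLAIN
        return _accept(raw, owner, repo, form)

    if host == _RAW_HOST:
        # raw.githubusercontent.com/{owner}/{repo}/{ref}/path...
        if len(segments) < 2:
            return _reject(raw, RejectionReason.MALFORMED)
        return _accept(raw, segments[0], segments[1], SourceForm.RAW_HOST)

    if host in _NBVIEWER_HOSTS:
        # nbviewer.../github/{owner}/{repo}/...  (also /gist/ and /url/ forms)
        if len(segments) >= 3 and segments[0] == "github":
            return _accept(raw, segments[1], segments[2], SourceForm.NBVIEWER)
        if segments and segments[0] == "gist":
            return _reject(raw, RejectionReason.NON_REPO_HOST)
        return _reject(raw, RejectionReason.MALFORMED)

    return _reject(raw, RejectionReason.NON_REPO_HOST)
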