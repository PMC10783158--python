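"""Natural-language detection for Markdown narrative text.

The profiler only needs a coarse signal: is the narrative English, some
other language, or too short to tell.  Detection is injectable — tests
use :func:`stub_detector` so expected outputs are exact — and the
production default is a small stopword-frequency heuristic over a few
high-volume languages.  Any callable ``text -> language code | None``
fits the interface.
"""

from __future__ import annotations

import re
from typing import Callable, Optional

Detector = Callable[[str], Optional[str]]

_MIN_WORDS = 3

_STOPWORDS: dict[str, frozenset[str]] = {
    "en": frozenset("the of and to in is that for with this are was on be as "
                    "we it by an or from which not have has".split()),
    "fr": frozenset("le la les de des du et un une est dans pour que qui sur "
                    "avec ce cette nous vous pas sont au aux".split()),
    "de": frozenset("der die das und ist nicht mit ein eine den dem für von "
                    "zu auf wir sie werden sind als auch".split()),
    "es": frozenset("el la los las de y que en un una es no con para por se "
                    "del como más pero sus este".split()),
}

_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def words(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


def stopword_detector(text: str) -> Optional[str]:
    """Pick the language whose stopwords cover the most tokens.

    Returns ``None`` (undetected) for empty/very short text or when no
    language's stopwords appear at all.
    """
    tokens = words(text)
    if len(tokens) < _MIN_WORDS:
        return None
    scores = {code: sum(1 for t in tokens if t in stops)
              for code, stops in _STOPWORDS.items()}
    best = max(scores, key=lambda c: (scores[c], c == "en"))
    return best if scores[best] > 0 else None


def stub_detector(mapping: dict[str, str],
                  default: Optional[str] = None) -> Detector:
    """Deterministic detector for tests: exact-substring trigger words.

    ``mapping`` maps a marker substring to a language code; the first
    marker found in the text wins (iteration order of the dict).
    """
    def detect(text: str) -> Optional[str]:
        for marker, code in mapping.items():
            if marker in text:
                return code
        return default
    return detect
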