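"""Shared word tokenizer.

Biomedical symbols are hyphen-rich ("IL-2", "NF-kappaB"), so a token is a
maximal run of word characters possibly joined by internal hyphens.  The
same tokenizer backs lexicon matching, keyword scanning, and the text index
so that all modules agree on token boundaries.
"""

from __future__ import annotations

import re

WORD_RE = re.compile(r"\w+(?:-\w+)*", re.UNICODE)


def tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    """Return ``(token, start, end)`` triples with half-open offsets."""
    return [(m.group(), m.start(), m.end()) for m in WORD_RE.finditer(text)]


def word_tokens(text: str) -> list[str]:
    return WORD_RE.findall(text)
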