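"""Loaders for the small word lists shipped with the package."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def _load_list(name: str) -> frozenset[str]:
    text = resources.files("bioeve.data").joinpath(name).read_text("utf-8")
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return frozenset(out)


@lru_cache(maxsize=None)
def stopwords() -> frozenset[str]:
    return _load_list("stopwords.txt")


@lru_cache(maxsize=None)
def abbreviations() -> frozenset[str]:
    return _load_list("abbreviations.txt")


@lru_cache(maxsize=None)
def greek_words() -> frozenset[str]:
    return _load_list("greek.txt")
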