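"""Descriptor text normalization shared by the taxonomy and the lexicon."""

from __future__ import annotations

import re

_PUNCT = re.compile(r"[^\w\s]|_")
_WS = re.compile(r"\s+")


def normalize_descriptor(text: str) -> str:
    """Case-fold, strip punctuation and collapse whitespace.

    ``"  Han  Chinese. "`` -> ``"han chinese"``; ``"African-American"`` ->
    ``"african american"``. Stable: normalizing twice equals normalizing once.
    """
    text = _PUNCT.sub(" ", text.casefold())
    return _WS.sub(" ", text).strip()
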