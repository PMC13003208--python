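"""Shared tokenizer for topic modeling and sentiment scoring.

Lowercase, split on whitespace and punctuation (a token is a maximal
run of word characters, underscore excluded), no stemming.  A
configurable stop-list can be supplied; it is empty by default.
"""

from __future__ import annotations

import re
from collections.abc import Iterable

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str, stop_words: Iterable[str] = ()) -> list[str]:
    """Split ``text`` into lowercase word tokens.

    Parameters
    ----------
    text : str
        Raw document text.
    stop_words : iterable of str, optional
        Tokens to drop after lowercasing.  Empty by default.
    """
    stop = frozenset(stop_words)
    tokens = [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]
    if stop:
        tokens = [t for t in tokens if t not in stop]
    return tokens
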