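"""String canonicalization shared by pair keys and reference-set matching."""

import re

_WS = re.compile(r"\s+")


def normalize_entity_string(s: str) -> str:
    """Canonicalize an entity surface string for cross-source matching.

    Lowercases and replaces every internal whitespace run with a single
    underscore, so "Heart Failure" and "heart  failure" both map to
    "heart_failure".  Idempotent by construction.

    Raises
    ------
    ValueError
        If ``s`` is empty or whitespace-only.
    """
    s = s.strip()
    if not s:
        raise ValueError("cannot normalize an empty entity string")
    return _WS.sub("_", s).lower()
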