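"""Composite mention simplification.

A composite mention is a single span denoting several concepts. Three
pattern families are expanded, each a separate rule:

* slashed/hyphen alternation on a shared numeric stem: "BRCA1/2" ->
  BRCA1, BRCA2 (full tokens on both sides, "BRCA1/BRCA2", split directly);
* pluralized stem with an enumerated number list: "SMADs 1, 5, and 8" ->
  SMAD1, SMAD5, SMAD8;
* numeric ranges on a stem: "ERK1-3" -> ERK1, ERK2, ERK3 (span <= 20).

Anything else is returned unchanged as a singleton.
"""

from __future__ import annotations

import re

MAX_RANGE = 20

# stem ending in digits, then one or more /- separated alternatives
_ALTERNATION = re.compile(
    r"^([A-Za-z][A-Za-z-]*?)(\d+)((?:\s*[/]\s*(?:\d+|[A-Za-z][A-Za-z-]*\d+))+)$"
)
_RANGE = re.compile(r"^([A-Za-z][A-Za-z-]*?)(\d+)\s*[-–]\s*(\d+)$")
_ENUM = re.compile(
    r"^([A-Za-z][A-Za-z-]*[A-Za-z])s\s+(\d+(?:\s*,\s*\d+)*"
    r"(?:\s*,?\s*(?:and|or)\s+\d+)?)$"
)


def expand(mention_text: str) -> list[str]:
    """Constituent names denoted by ``mention_text`` (singleton if none of
    the composite patterns applies)."""
    text = mention_text.strip()

    m = _ALTERNATION.match(text)
    if m:
        stem, first, rest = m.group(1), m.group(2), m.group(3)
        names = [stem + first]
        for part in re.split(r"\s*/\s*", rest.strip()):
            if not part:
                continue
            if part.isdigit():
                names.append(stem + part)
            else:
                names.append(part)  # full token after the slash
        return names

    m = _RANGE.match(text)
    if m:
        stem, a, b = m.group(1), int(m.group(2)), int(m.group(3))
        if a < b and b - a <= MAX_RANGE:
            width = len(m.group(2))
            return [f"{stem}{i:0{width}d}" for i in range(a, b + 1)]
        return [text]

    m = _ENUM.match(text)
    if m:
        stem = m.group(1)
        numbers = re.findall(r"\d+", m.group(2))
        if len(numbers) >= 2:
            return [stem + n for n in numbers]

    return [text]
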