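"""Landmark token parsing.

A token is a landmark base name plus an optional derivative-level shift,
e.g. ``"S"``, ``"c-2"`` (the APG c-wave time read on the PPG), ``"S+1"``
(the systolic-peak time read on the VPG), ``"Onext"`` (the next beat onset).

Native levels: PPG landmarks O,S,N,D (and Onext) live at level 0; VPG
landmarks w,x,y,z at level 1; APG landmarks a,b,c,d,e at level 2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

NATIVE_LEVEL = {
    "O": 0, "S": 0, "N": 0, "D": 0, "Onext": 0,
    "w": 1, "x": 1, "y": 1, "z": 1,
    "a": 2, "b": 2, "c": 2, "d": 2, "e": 2,
}

_TOKEN_RE = re.compile(r"^(Onext|[OSND]|[wxyz]|[abcde])([+-]\d)?$")


@dataclass(frozen=True)
class Token:
    base: str
    shift: int

    @property
    def level(self) -> int:
        """Absolute derivative level the token is evaluated on."""
        return NATIVE_LEVEL[self.base] + self.shift

    def __str__(self) -> str:
        if self.shift == 0:
            return self.base
        return f"{self.base}{self.shift:+d}"


def parse_token(text: str) -> Token:
    m = _TOKEN_RE.match(text)
    if m is None:
        raise ValueError(f"unparseable landmark token: {text!r}")
    base, shift = m.group(1), m.group(2)
    tok = Token(base, int(shift) if shift else 0)
    if not 0 <= tok.level <= 3:
        raise ValueError(f"token {text!r} resolves to level {tok.level}, outside 0..3")
    return tok
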