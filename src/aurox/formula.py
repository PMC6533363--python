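"""Minimal chemical-formula parser for species bookkeeping.

Handles element symbols with integer counts and nested parentheses, e.g.
``"Au(OH)4"`` -> ``{"Au": 1, "O": 4, "H": 4}``.  Only what is needed to
element-balance the reactions in the shipped database; isotopes, hydrates
and charge suffixes are out of scope (charge is a separate field).
"""

from __future__ import annotations

import re
from collections import Counter

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


class FormulaError(ValueError):
    pass


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``formula`` into an element -> count mapping.

    >>> parse_formula("Au(OH)4")
    {'Au': 1, 'O': 4, 'H': 4}
    """
    if formula is None or formula.strip() == "":
        return {}
    stack: list[Counter] = [Counter()]
    pos = 0
    s = formula.strip()
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        elem, count, open_p, close_p, group_count = m.groups()
        if elem:
            stack[-1][elem] += int(count) if count else 1
        elif open_p:
            stack.append(Counter())
        elif close_p is not None:
            if len(stack) == 1:
                raise FormulaError(f"unbalanced ')' in {formula!r}")
            group = stack.pop()
            mult = int(group_count) if group_count else 1
            for k, v in group.items():
                stack[-1][k] += v * mult
        pos = m.end()
    if len(stack) != 1:
        raise FormulaError(f"unbalanced '(' in {formula!r}")
    return dict(stack[0])
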