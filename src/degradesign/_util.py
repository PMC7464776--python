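"""Small shared helpers: report rounding and minus-sign normalization."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: Characters accepted as a leading minus sign in transcribed tables.
#: U+2212 (minus), U+2013 (en dash) and U+2014 (em dash) all occur in
#: typeset scientific tables; all are normalized to ASCII '-'.
_MINUS_VARIANTS = str.maketrans({"−": "-", "–": "-", "—": "-"})


def normalize_minus(text: str) -> str:
    """Replace typographic minus/dash characters with ASCII hyphen-minus."""
    return text.translate(_MINUS_VARIANTS)


def parse_number(text: str) -> float:
    """Parse a numeric cell, tolerating typographic minus signs and blanks.

    Raises ValueError on anything else; callers decide how to report it.
    """
    cleaned = normalize_minus(str(text)).strip().rstrip("%")
    if cleaned in ("", "-", "nan"):
        raise ValueError(f"blank or non-numeric cell: {text!r}")
    return float(cleaned)


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed tables conventionally do.

    Python's built-in round() uses banker's rounding, which disagrees with
    hand-rounded report tables on exact .5 ties.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
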