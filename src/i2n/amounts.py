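"""Exact parsing and rendering of portion amounts and nutrient cells.

Amounts entered by annotators and values read from food-composition CSVs are
kept as :class:`fractions.Fraction` so that the worked arithmetic
(``1 - 1/3 = 2/3`` cup) and all downstream sums are exact. Accepted syntax:

* plain integers and decimals (``2``, ``0.75``),
* simple fractions (``1/3``),
* mixed numbers (``2 1/2``),
* thousands separators in digit groups of three (``1,234.5``).
"""

from __future__ import annotations

import re
from fractions import Fraction

__all__ = ["parse_amount", "try_parse_amount", "format_amount", "fraction_to_str", "fraction_from_str"]

_THOUSANDS = re.compile(r"^\d{1,3}(,\d{3})+(\.\d+)?$")
_MIXED = re.compile(r"^(?P<whole>\d+)\s+(?P<num>\d+)/(?P<den>\d+)$")
_SIMPLE_FRACTION = re.compile(r"^(?P<num>\d+)\s*/\s*(?P<den>\d+)$")


def parse_amount(value: object) -> Fraction:
    """Parse an amount or nutrient cell into an exact :class:`Fraction`.

    Raises ``ValueError`` for anything that is not a non-negative number in
    one of the accepted forms.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(str(value))
    if not isinstance(value, str):
        raise ValueError(f"cannot parse amount from {value!r}")
    text = value.strip()
    if not text:
        raise ValueError("empty amount")
    negative = text.startswith("-")
    if negative:
        raise ValueError(f"negative amount {text!r}")
    if _THOUSANDS.match(text):
        text = text.replace(",", "")
    m = _MIXED.match(text)
    if m:
        return Fraction(int(m["whole"])) + Fraction(int(m["num"]), int(m["den"]))
    m = _SIMPLE_FRACTION.match(text)
    if m:
        if int(m["den"]) == 0:
            raise ValueError(f"zero denominator in {value!r}")
        return Fraction(int(m["num"]), int(m["den"]))
    try:
        return Fraction(text)
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(f"cannot parse amount from {value!r}") from exc


def try_parse_amount(value: object) -> Fraction | None:
    """Like :func:`parse_amount` but returns ``None`` on failure.

    Used by the database loader, where a non-numeric nutrient cell means
    "missing", never zero.
    """
    try:
        return parse_amount(value)
    except ValueError:
        return None


def format_amount(x: Fraction, sig: int = 4) -> str:
    """Render an exact amount as a decimal with ``sig`` significant digits."""
    return f"{float(x):.{sig}g}"


def fraction_to_str(x: Fraction) -> str:
    """Serialize a Fraction losslessly (``"2/3"``, ``"5"``)."""
    return str(x)


def fraction_from_str(s: str) -> Fraction:
    return Fraction(s)
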