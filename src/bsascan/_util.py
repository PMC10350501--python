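"""Small shared helpers."""

from __future__ import annotations

import gzip
import io
from decimal import ROUND_HALF_UP, Decimal


def open_text_write(path):
    """Text handle for writing; gzip (with zeroed mtime, so output is
    byte-reproducible) when the path ends in .gz."""
    path = str(path)
    if path.endswith(".gz"):
        raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
        return io.TextIOWrapper(gz)
    return open(path, "w")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as spreadsheet/SPSS output does.

    Python's built-in ``round`` is banker's rounding on top of binary floats
    (``round(1.935, 2) == 1.93``), which disagrees with how ratios and Mb
    lengths are conventionally printed.  Routing through ``Decimal(repr(x))``
    keeps the decimal digits the user would see.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
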