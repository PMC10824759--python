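"""Small report helpers shared across modules."""

from __future__ import annotations

from typing import Mapping


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """Percentage of ``part`` in ``whole``, rounded to ``ndigits``.

    Used by every report that prints "x of n (y%)" style quantities.
    """
    if whole == 0:
        raise ZeroDivisionError("percent undefined for whole == 0")
    return round(100.0 * part / whole, ndigits)


def partition_total(sizes: Mapping[str, int] | Mapping[int, int]) -> int:
    """Total of a partition's group sizes (bookkeeping invariant helper)."""
    return int(sum(sizes.values()))
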