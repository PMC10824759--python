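"""Single-nucleotide signal tracks and bedGraph I/O.

Nascent-RNA sequencing assigns each read to one base: the exact 3' end of
the RNA (position of the engaged polymerase) or the exact 5' end (the
transcription start position).  A :class:`SignalTrack` is a per-strand
sparse map from 0-based genomic position to read count, possibly spanning
several chromosomes.  Values may be fractional after spike normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Literal, Mapping, Tuple

import numpy as np

EndType = Literal["three_prime", "five_prime", "generic"]


class BedGraphParseError(ValueError):
    """Raised on a malformed bedGraph line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class SignalTrack:
    """Sparse per-base signal on one strand.

    Parameters
    ----------
    strand : '+' or '-'
    end_type : which read end the positions represent.
    data : mapping chrom -> {0-based position: count}.
    """

    strand: str = "+"
    end_type: EndType = "generic"
    data: Dict[str, Dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for chrom, posmap in self.data.items():
            for pos, val in posmap.items():
                if pos < 0:
                    raise ValueError(f"negative position {pos} on {chrom}")
                if val < 0:
                    raise ValueError(f"negative count {val} at {chrom}:{pos}")
        self._array_cache: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_positions(
        cls,
        chrom: str,
        positions: np.ndarray,
        strand: str = "+",
        end_type: EndType = "generic",
    ) -> "SignalTrack":
        """Build a track by tallying an array of single-base read positions."""
        track = cls(strand=strand, end_type=end_type)
        if len(positions):
            uniq, counts = np.unique(np.asarray(positions, dtype=np.int64), return_counts=True)
            track.data[chrom] = dict(zip(uniq.tolist(), counts.astype(float).tolist()))
        return track

    def add_positions(self, chrom: str, positions: np.ndarray) -> None:
        if len(positions) == 0:
            return
        uniq, counts = np.unique(np.asarray(positions, dtype=np.int64), return_counts=True)
        posmap = self.data.setdefault(chrom, {})
        for p, c in zip(uniq.tolist(), counts.tolist()):
            posmap[p] = posmap.get(p, 0.0) + float(c)
        self._array_cache.pop(chrom, None)

    # -- queries -------------------------------------------------------

    def total(self) -> float:
        return float(sum(sum(pm.values()) for pm in self.data.values()))

    def chrom_arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """Sorted position and value arrays for one chromosome (cached)."""
        cached = self._array_cache.get(chrom)
        if cached is not None:
            return cached
        posmap = self.data.get(chrom, {})
        if not posmap:
            out = np.empty(0, dtype=np.int64), np.empty(0)
        else:
            pos = np.fromiter(posmap.keys(), dtype=np.int64, count=len(posmap))
            order = np.argsort(pos)
            val = np.fromiter(posmap.values(), dtype=float, count=len(posmap))
            out = pos[order], val[order]
        self._array_cache[chrom] = out
        return out

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of counts over the half-open interval [start, end)."""
        pos, val = self.chrom_arrays(chrom)
        if len(pos) == 0 or end <= start:
            return 0.0
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return float(val[lo:hi].sum())

    def scaled(self, factor: float) -> "SignalTrack":
        """Return a copy with every count multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        out = SignalTrack(strand=self.strand, end_type=self.end_type)
        out.data = {
            chrom: {p: v * factor for p, v in pm.items()} for chrom, pm in self.data.items()
        }
        return out

    def __add__(self, other: "SignalTrack") -> "SignalTrack":
        if other.strand != self.strand:
            raise ValueError("cannot add tracks on different strands")
        out = SignalTrack(strand=self.strand, end_type=self.end_type)
        out.data = {c: dict(pm) for c, pm in self.data.items()}
        for chrom, pm in other.data.items():
            tgt = out.data.setdefault(chrom, {})
            for p, v in pm.items():
                tgt[p] = tgt.get(p, 0.0) + v
        return out


def pool_tracks(tracks: Iterable[SignalTrack]) -> SignalTrack:
    """Sum several same-strand tracks base-by-base (e.g. pooling replicates)."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks to pool")
    pooled = tracks[0]
    for t in tracks[1:]:
        pooled = pooled + t
    return pooled


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def _format_value(v: float) -> str:
    if v == int(v):
        return str(int(v))
    return format(v, ".6g")


def read_bedgraph(path, strand: str = "+", end_type: EndType = "generic") -> SignalTrack:
    """Read a 4-column bedGraph (0-based half-open) into a SignalTrack.

    Every base of an interval receives the interval's value.  Overlapping
    intervals are rejected: a single-nucleotide track has one value per base,
    and silent summation would hide upstream double counting.
    """
    intervals: Dict[str, list] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise BedGraphParseError(
                    f"expected 4 columns, got {len(parts)}", lineno
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                raise BedGraphParseError(str(exc), lineno) from exc
            if start < 0 or end <= start:
                raise BedGraphParseError(
                    f"invalid interval [{start}, {end})", lineno
                )
            if value < 0:
                raise BedGraphParseError(f"negative value {value}", lineno)
            if value != 0:
                intervals.setdefault(chrom, []).append((start, end, value, lineno))

    track = SignalTrack(strand=strand, end_type=end_type)
    for chrom, ivs in intervals.items():
        ivs.sort(key=lambda t: t[0])
        prev_end = -1
        posmap: Dict[int, float] = {}
        for start, end, value, lineno in ivs:
            if start < prev_end:
                raise BedGraphParseError(
                    f"interval [{start}, {end}) on {chrom} overlaps a previous interval",
                    lineno,
                )
            prev_end = end
            for p in range(start, end):
                posmap[p] = value
        track.data[chrom] = posmap
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a track as sorted bedGraph, merging runs of equal value."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            pos, val = track.chrom_arrays(chrom)
            run_start = None
            run_val = None
            prev = None
            for p, v in zip(pos.tolist(), val.tolist()):
                if v == 0:
                    continue
                if run_start is not None and p == prev + 1 and v == run_val:
                    prev = p
                    continue
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{_format_value(run_val)}\n")
                run_start, run_val, prev = p, v, p
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{_format_value(run_val)}\n")
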