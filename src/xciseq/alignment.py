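"""In-memory alignment records.

The pipeline consumes gapless alignment records (the simulator emits
reads with true placement coordinates, so every aligned base maps to a
reference position with no indels).  Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(slots=True)
class AlignmentRecord:
    read_id: str
    chrom: str | None
    start: int
    length: int
    sequence: str | None = None  # None when sequence-free simulation is enough
    mapq: int = 60
    mapped: bool = True
    strand: str = "+"
    mate_chrom: str | None = None
    fragment_length: int | None = None
    is_read1: bool = True
    paired: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length


ReadPair = tuple[AlignmentRecord, AlignmentRecord]


def fragment_interval(pair: ReadPair) -> tuple[str, int, int]:
    """(chrom, start, end) of the sequenced fragment of a proper pair."""
    r1, r2 = pair
    start = min(r1.start, r2.start)
    end = max(r1.end, r2.end)
    if r1.fragment_length:
        end = max(end, start + abs(r1.fragment_length))
    return r1.chrom, start, end
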