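"""Raw-read quality control.

A read pair is discarded when either mate has more than 40% low-quality
bases (Q <= 17), more than 10 Ns, or when the pair is a PCR duplicate of
an earlier retained pair (both mates' sequences identical, mate1 to mate1
and mate2 to mate2). All three thresholds are strict ">" comparisons and
configurable. No trimming or error correction is performed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional


@dataclass
class Read:
    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    read1: Read
    read2: Optional[Read] = None

    @property
    def mates(self) -> list[Read]:
        return [self.read1] if self.read2 is None else [self.read1, self.read2]


@dataclass
class QCConfig:
    low_quality_threshold: int = 17
    max_low_quality_fraction: float = 0.40
    max_n_count: int = 10
    dedupe: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_low_quality_fraction <= 1.0:
            raise ValueError("max_low_quality_fraction must be in [0,1]")
        if self.max_n_count < 0:
            raise ValueError("max_n_count must be >= 0")


@dataclass
class QCReport:
    pairs_in: int = 0
    pairs_kept: int = 0
    removed_low_quality: int = 0
    removed_n: int = 0
    removed_duplicate: int = 0

    def check(self) -> None:
        total = (self.pairs_kept + self.removed_low_quality
                 + self.removed_n + self.removed_duplicate)
        assert self.pairs_in == total, "QC counters do not conserve input"


def is_low_quality(read: Read, config: QCConfig) -> bool:
    """True iff the fraction of bases at Q <= threshold exceeds the cap
    (strictly: 40/100 low-quality bases at a 0.40 cap passes)."""
    if len(read) == 0:
        raise ValueError(f"read {read.id!r} is empty")
    low = sum(1 for q in read.qualities if q <= config.low_quality_threshold)
    return low / len(read) > config.max_low_quality_fraction


def has_excess_n(read: Read, config: QCConfig) -> bool:
    """True iff the read contains strictly more than ``max_n_count`` Ns."""
    if len(read) == 0:
        raise ValueError(f"read {read.id!r} is empty")
    return read.sequence.count("N") > config.max_n_count


def _fingerprint(pair: ReadPair) -> bytes:
    # one strong hash per retained pair keeps the duplicate set small;
    # sha1 collisions are negligible at library scale
    h = hashlib.sha1(pair.read1.sequence.encode())
    if pair.read2 is not None:
        h.update(b"/")
        h.update(pair.read2.sequence.encode())
    return h.digest()


def filter_reads(
    pairs: Iterable[ReadPair], config: Optional[QCConfig] = None
) -> tuple[list[ReadPair], QCReport]:
    """Apply the three removal rules to a stream of pairs.

    When several rules fire for one pair it is counted under the first
    failing rule, checked in the order low-quality, N-excess, duplicate,
    so the report is deterministic. The first occurrence of a duplicated
    pair is the one retained.
    """
    config = config or QCConfig()
    report = QCReport()
    kept: list[ReadPair] = []
    seen: set[bytes] = set()
    for pair in pairs:
        report.pairs_in += 1
        if any(is_low_quality(m, config) for m in pair.mates):
            report.removed_low_quality += 1
            continue
        if any(has_excess_n(m, config) for m in pair.mates):
            report.removed_n += 1
            continue
        if config.dedupe:
            fp = _fingerprint(pair)
            if fp in seen:
                report.removed_duplicate += 1
                continue
            seen.add(fp)
        kept.append(pair)
        report.pairs_kept += 1
    report.check()
    return kept, report
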