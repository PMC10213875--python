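"""Adaptor trimming and read filtering for small-RNA libraries.

Reads are 3'-adaptor-trimmed with cutadapt-like semantics (prefix-anchored
search, bounded error rate) and retained only when an adaptor was found, the
insert is 15-45 nt, and at least 80% of insert bases have Phred quality
strictly above 20.  Reads whose adaptor starts at position 0 (empty insert)
fail as too short; reads without any adaptor occurrence are discarded.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

DEFAULT_ADAPTOR = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

FAIL_NO_ADAPTOR = "no_adaptor"
FAIL_TOO_SHORT = "too_short"
FAIL_TOO_LONG = "too_long"
FAIL_LOW_QUALITY = "low_quality"


class FastqFormatError(ValueError):
    """Malformed FASTQ record; carries the 0-based record index."""

    def __init__(self, record_index: int, message: str) -> None:
        self.record_index = record_index
        super().__init__(f"record {record_index}: {message}")


@dataclass(frozen=True)
class QCConfig:
    """Trimming and filtering parameters.

    ``error_rate`` bounds adaptor mismatches at ``floor(error_rate * overlap)``;
    ``q_threshold`` is a strict inequality (Q = 20 does not count as passing).
    """

    adaptor: str = DEFAULT_ADAPTOR
    min_overlap: int = 3
    error_rate: float = 0.1
    min_len: int = 15
    max_len: int = 45
    q_threshold: int = 20
    min_q_fraction: float = 0.8
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass
class RawRead:
    read_id: str
    sequence: str
    qualities: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class CleanRead:
    read_id: str
    insert_sequence: str
    qualities: str
    sample_id: str = ""


@dataclass
class QCStats:
    sample_id: str
    raw: int = 0
    retained: int = 0
    fail_reasons: dict = field(default_factory=dict)

    @property
    def retained_fraction(self) -> Optional[float]:
        """Retained / raw; None (reported as NA) for an empty input."""
        if self.raw == 0:
            return None
        return self.retained / self.raw

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "raw": self.raw,
            "retained": self.retained,
            "retained_fraction": self.retained_fraction,
            "fail_reasons": dict(self.fail_reasons),
        }


def trim_adaptor(sequence: str, qualities: str, cfg: QCConfig) -> tuple[str, str, bool]:
    """Remove the leftmost 3' adaptor occurrence and everything after it.

    An occurrence at position ``j`` aligns a prefix of the adaptor against
    ``sequence[j:]`` with overlap >= ``min_overlap`` and at most
    ``floor(error_rate * overlap)`` mismatches.  Returns
    ``(insert, insert_qualities, adaptor_found)``; when no occurrence exists
    the read is returned unchanged with ``adaptor_found=False``.
    """
    adaptor = cfg.adaptor
    n, a = len(sequence), len(adaptor)
    for j in range(0, n - cfg.min_overlap + 1):
        overlap = min(a, n - j)
        allowed = math.floor(cfg.error_rate * overlap)
        mismatches = 0
        window = sequence[j : j + overlap]
        for x, y in zip(window, adaptor):
            if x != y:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return sequence[:j], qualities[:j], True
    return sequence, qualities, False


def filter_read(
    insert: str, qualities: str, adaptor_found: bool, cfg: QCConfig
) -> tuple[bool, Optional[str]]:
    """Apply the retention rules to a trimmed read.

    Returns ``(passed, fail_reason)`` with reason in
    ``{no_adaptor, too_short, too_long, low_quality}``.
    """
    if not adaptor_found:
        return False, FAIL_NO_ADAPTOR
    if len(insert) < cfg.min_len:
        return False, FAIL_TOO_SHORT
    if len(insert) > cfg.max_len:
        return False, FAIL_TOO_LONG
    cut = cfg.phred_offset + cfg.q_threshold
    n_good = sum(1 for c in qualities.encode() if c > cut)
    if n_good / len(insert) < cfg.min_q_fraction:
        return False, FAIL_LOW_QUALITY
    return True, None


def _open_maybe_gz(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (read_id, sequence, qualities) from a (possibly gzipped) FASTQ."""
    with _open_maybe_gz(path) as fh:
        index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqFormatError(index, "truncated record")
            header, seq, plus, qual = (
                header.rstrip("\n"),
                seq.rstrip("\n"),
                plus.rstrip("\n"),
                qual.rstrip("\n"),
            )
            if not header.startswith("@"):
                raise FastqFormatError(index, "header does not start with '@'")
            if not plus.startswith("+"):
                raise FastqFormatError(index, "separator line does not start with '+'")
            if len(seq) != len(qual):
                raise FastqFormatError(index, "sequence/quality length mismatch")
            yield header[1:].split()[0], seq, qual
            index += 1


def process_read(
    sequence: str, qualities: str, cfg: QCConfig
) -> tuple[bool, Optional[str], str, str]:
    """Trim then filter one read: (passed, reason, insert, insert_qualities)."""
    insert, tq, found = trim_adaptor(sequence, qualities, cfg)
    passed, reason = filter_read(insert, tq, found, cfg)
    return passed, reason, insert, tq


def run_qc(
    in_fastq: str | Path,
    cfg: QCConfig = QCConfig(),
    sample_id: str = "",
    out_fastq: Optional[str | Path] = None,
) -> tuple[QCStats, dict[str, int]]:
    """QC one FASTQ file.

    Returns per-sample stats and the multiset of retained insert sequences
    (sequence -> count), which downstream clustering consumes directly.
    Identical (sequence, quality) records are memoised, which makes deeply
    duplicated small-RNA libraries cheap to process.
    """
    stats = QCStats(sample_id=sample_id or Path(str(in_fastq)).stem)
    counts: dict[str, int] = {}
    memo: dict[tuple[str, str], tuple[bool, Optional[str], str, str]] = {}
    writer = _open_maybe_gz(out_fastq, "wt") if out_fastq is not None else None
    try:
        for read_id, seq, qual in iter_fastq(in_fastq):
            stats.raw += 1
            key = (seq, qual)
            result = memo.get(key)
            if result is None:
                result = process_read(seq, qual, cfg)
                memo[key] = result
            passed, reason, insert, tq = result
            if passed:
                stats.retained += 1
                counts[insert] = counts.get(insert, 0) + 1
                if writer is not None:
                    writer.write(f"@{read_id}\n{insert}\n+\n{tq}\n")
            else:
                stats.fail_reasons[reason] = stats.fail_reasons.get(reason, 0) + 1
    finally:
        if writer is not None:
            writer.close()
    return stats, counts


def write_qc_stats(stats: list[QCStats], tsv_path: str | Path, json_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("sample_id\traw\tretained\tretained_fraction\n")
        for s in stats:
            frac = "NA" if s.retained_fraction is None else f"{s.retained_fraction:.6f}"
            fh.write(f"{s.sample_id}\t{s.raw}\t{s.retained}\t{frac}\n")
    with open(json_path, "w") as fh:
        json.dump([s.as_dict() for s in stats], fh, indent=1)
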