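"""Raw FASTQ to clean, length-selected, collapsed unique tags.

The filter chain is fixed — mean-quality floor, 3' adapter trim, 18-30 nt
length window, collapse to unique tags, drop single-read tags — because the
order decides which reject bucket a read lands in, and the read-conservation
invariant (raw = clean + rejects, exactly) is checked on every run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "CleanLibrary",
    "trim_adapter",
    "clean_and_collapse",
    "length_distribution",
    "REJECT_REASONS",
    "MIN_LEN",
    "MAX_LEN",
]

MIN_LEN = 18
MAX_LEN = 30

REJECT_REASONS = ("low_quality", "empty_or_no_adapter", "out_of_length", "single_read")


@dataclass
class CleanLibrary:
    """Collapsed clean reads of one library plus full reject accounting."""

    tags: dict[str, int]
    raw_total: int
    clean_total: int
    rejects: dict[str, int] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for reason in REJECT_REASONS:
            self.rejects.setdefault(reason, 0)
        if self.raw_total != self.clean_total + sum(self.rejects.values()):
            raise ValueError(
                f"read conservation violated: raw {self.raw_total} != clean "
                f"{self.clean_total} + rejects {sum(self.rejects.values())}"
            )
        if self.clean_total != sum(self.tags.values()):
            raise ValueError("clean_total does not equal the sum of tag counts")


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> str | None:
    """Return the insert before the leftmost 3' adapter match, or None.

    A match is an exact occurrence of an adapter prefix of length
    >= ``min_overlap`` that either is the full adapter or runs to the read's 3'
    end.  An adapter-only read yields an empty insert, which the caller
    rejects as an empty adaptor; a read with no recognizable adapter returns
    None (the insert boundary cannot be delimited).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = read.upper().replace("U", "T")
    n = len(read)
    for i in range(n - min_overlap + 1):
        take = min(len(adapter), n - i)
        if read[i : i + take] == adapter[:take]:
            return read[:i]
    return None


def _mean_phred(qual: str) -> float:
    return sum(map(ord, qual)) / len(qual) - 33.0 if qual else 0.0


def clean_and_collapse(
    fastq_path: str | Path,
    adapter: str,
    quality_floor: float = 20.0,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    min_overlap: int = 6,
    keep_singletons: bool = False,
    keep_unmatched_adapter: bool = False,
    name: str = "",
) -> CleanLibrary:
    """Run the full filter chain over a FASTQ file.

    ``keep_unmatched_adapter`` retains full-length reads when no adapter is
    found instead of rejecting them; ``keep_singletons`` disables the
    single-read filter.
    """
    fastq_path = Path(fastq_path)
    rejects = dict.fromkeys(REJECT_REASONS, 0)
    tags: Counter[str] = Counter()
    raw_total = 0
    with open(fastq_path) as fh:
        for _title, seq, qual in FastqGeneralIterator(fh):
            raw_total += 1
            if _mean_phred(qual) < quality_floor:
                rejects["low_quality"] += 1
                continue
            insert = trim_adapter(seq, adapter, min_overlap=min_overlap)
            if insert is None:
                if keep_unmatched_adapter:
                    insert = seq.upper().replace("U", "T")
                else:
                    rejects["empty_or_no_adapter"] += 1
                    continue
            if not insert:
                rejects["empty_or_no_adapter"] += 1
                continue
            if not min_len <= len(insert) <= max_len:
                rejects["out_of_length"] += 1
                continue
            tags[insert] += 1
    if raw_total == 0:
        raise ValueError(f"empty FASTQ stream: {fastq_path}")
    if not keep_singletons:
        singles = [t for t, c in tags.items() if c == 1]
        rejects["single_read"] = len(singles)
        for t in singles:
            del tags[t]
    clean_total = sum(tags.values())
    return CleanLibrary(
        tags=dict(tags), raw_total=raw_total, clean_total=clean_total,
        rejects=rejects, name=name or fastq_path.stem,
    )


def length_distribution(lib: CleanLibrary) -> pd.DataFrame:
    """Per-length fractions over the 18-30 nt window, both by read abundance
    and by distinct-sequence count; each fraction column sums to 1."""
    if lib.clean_total <= 0:
        raise ValueError("length distribution of an empty library is undefined")
    lengths = range(MIN_LEN, MAX_LEN + 1)
    reads = dict.fromkeys(lengths, 0)
    distinct = dict.fromkeys(lengths, 0)
    for tag, count in lib.tags.items():
        reads[len(tag)] += count
        distinct[len(tag)] += 1
    n_distinct = sum(distinct.values())
    return pd.DataFrame(
        {
            "length": list(lengths),
            "read_count": [reads[k] for k in lengths],
            "read_fraction": [reads[k] / lib.clean_total for k in lengths],
            "distinct_count": [distinct[k] for k in lengths],
            "distinct_fraction": [distinct[k] / n_distinct for k in lengths],
        }
    )
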