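"""Demultiplexing of variable-length inline barcodes and sliding-window QC.

Reads carry their barcode inline at the 5' end, immediately followed by the
constant cutsite remnant left by restriction digestion and adaptor ligation
(``AATTC`` for EcoRI).  Assignment therefore requires an exact barcode match
*and* the remnant right after it; barcode lengths are tried longest-first so
a long barcode can never be shadowed by a shorter one that happens to share
its prefix.  Matching is exact (0 mismatches): the panel guarantees pairwise
slippage distance >= 3, so any 1-error rescue policy would be sound, but the
source protocol does not state one and exactness is the simplest defensible
choice.

Quality control mirrors a process-radtags-style sliding window: a read is
discarded (not truncated) if the mean phred score within any window of the
given width drops below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "DemuxReport",
    "read_fastq",
    "write_fastq",
    "quality_filter",
    "demultiplex",
]

DEFAULT_WINDOW = 15
DEFAULT_PHRED_THRESHOLD = 10.0
DEFAULT_REMNANT = "AATTC"


@dataclass
class ReadRecord:
    """One sequencing read with per-base phred qualities."""

    identifier: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.identifier!r}: sequence and quality lengths differ"
            )
        if self.qualities and not (0 <= min(self.qualities) <= max(self.qualities) <= 60):
            raise ValueError(f"read {self.identifier!r}: phred scores outside [0, 60]")


@dataclass
class DemuxReport:
    """Accounting of where every input read went.

    Conservation holds by construction: assigned + discarded == total.
    """

    assigned: dict[str, int] = field(default_factory=dict)
    discarded_no_barcode: int = 0
    discarded_low_quality: int = 0
    total: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def n_discarded(self) -> int:
        return self.discarded_no_barcode + self.discarded_low_quality

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for sid in sorted(self.assigned):
                fh.write(f"assigned:{sid}\t{self.assigned[sid]}\n")
            fh.write(f"discarded:no_barcode\t{self.discarded_no_barcode}\n")
            fh.write(f"discarded:low_quality\t{self.discarded_low_quality}\n")
            fh.write(f"total\t{self.total}\n")


def read_fastq(path) -> list[ReadRecord]:
    """Load a FASTQ file (Sanger phred+33) into ReadRecords."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            ReadRecord(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])
        )
    return out


def write_fastq(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.identifier}\n{read.sequence}\n+\n{qual}\n")


def quality_filter(
    read: ReadRecord,
    window: int = DEFAULT_WINDOW,
    phred_threshold: float = DEFAULT_PHRED_THRESHOLD,
) -> bool:
    """True (keep) unless some sliding window's mean phred < threshold."""
    n = len(read.qualities)
    if window > n:
        raise ValueError(f"window {window} exceeds read length {n}")
    quals = np.asarray(read.qualities, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(quals)])
    means = (csum[window:] - csum[:-window]) / window
    return bool((means >= phred_threshold).all())


def demultiplex(
    reads,
    barcode_map: dict[str, str],
    remnant: str = DEFAULT_REMNANT,
    window: int = DEFAULT_WINDOW,
    phred_threshold: float = DEFAULT_PHRED_THRESHOLD,
    truncate_to: int | None = None,
) -> tuple[dict[str, list[ReadRecord]], DemuxReport]:
    """Assign reads to samples, trim barcode + remnant, and QC-filter.

    Parameters
    ----------
    reads:
        Iterable of ReadRecord.
    barcode_map:
        ``{sample_id: barcode}``; barcodes must be unique and 7-10 bp.
    remnant:
        Constant bases expected immediately after the barcode.
    truncate_to:
        Common length to cut all trimmed reads to.  Variable-length
        barcodes leave trimmed reads of unequal length, but downstream
        locus assembly compares reads positionally, so by default every
        trimmed read is cut to the shortest trimmed length implied by the
        panel (read length minus longest barcode minus remnant).

    Returns per-sample trimmed reads plus a DemuxReport.  The QC window is
    applied to the *raw* read, before trimming, so a bad barcode region
    also disqualifies a read.
    """
    seen: dict[str, str] = {}
    for sid, barcode in barcode_map.items():
        if not (7 <= len(barcode) <= 10):
            raise ValueError(f"barcode {barcode!r} for {sid!r} has unsupported length")
        if barcode in seen:
            raise ValueError(
                f"duplicate barcode {barcode!r} for samples {seen[barcode]!r} and {sid!r}"
            )
        seen[barcode] = sid
    # longest-first: a 10-mer whose prefix is also a panel 7-mer must win
    # only when its full 10 bases + remnant match
    by_length: list[tuple[int, dict[str, str]]] = []
    for length in sorted({len(b) for b in seen}, reverse=True):
        by_length.append(
            (length, {b: sid for b, sid in seen.items() if len(b) == length})
        )
    out: dict[str, list[ReadRecord]] = {sid: [] for sid in barcode_map}
    report = DemuxReport(assigned={sid: 0 for sid in barcode_map})
    for read in reads:
        report.total += 1
        if not quality_filter(read, window=window, phred_threshold=phred_threshold):
            report.discarded_low_quality += 1
            continue
        hit_sample = None
        hit_len = 0
        for length, table in by_length:
            candidate = read.sequence[:length]
            sid = table.get(candidate)
            if sid is not None and read.sequence[length : length + len(remnant)] == remnant:
                hit_sample = sid
                hit_len = length + len(remnant)
                break
        if hit_sample is None:
            report.discarded_no_barcode += 1
            continue
        stop = len(read.sequence)
        if truncate_to is not None:
            stop = hit_len + truncate_to
        else:
            longest = by_length[0][0] + len(remnant)
            stop = hit_len + (len(read.sequence) - longest)
        out[hit_sample].append(
            ReadRecord(
                read.identifier,
                read.sequence[hit_len:stop],
                read.qualities[hit_len:stop],
            )
        )
        report.assigned[hit_sample] += 1
    return out, report
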