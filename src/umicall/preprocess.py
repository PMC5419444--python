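"""UMI extraction and primer demultiplexing.

Raw amplicon reads carry a unique molecular identifier (UMI) embedded in a
primer/adapter pattern: the pattern is written over IUPAC codes with ``N``
marking the random UMI positions, e.g. ``NNNNNNNNNNNNtgact`` for a 12-base
UMI followed by a constant anchor. This module parses such patterns, finds
the best pattern match in each read (substitutions only, no indels), pulls
out the UMI bases with their qualities, gates UMIs on minimum base quality,
and trims the matched prefix.

Rejections (no primer, ambiguous sample assignment, low UMI quality) are
data, not errors: every input read is accounted for exactly once.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .dna import is_iupac, phred_to_string, revcomp, seq_to_bits, string_to_phred

DEFAULT_MIN_UMI_QUAL = 20
DEFAULT_MAX_PRIMER_MISMATCHES = 2


class PatternError(ValueError):
    """Malformed primer/adapter pattern."""


@dataclass
class FastqRead:
    id: str
    sequence: str
    qualities: np.ndarray
    mate: Optional["FastqRead"] = None

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int32)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def reverse_complement(self) -> "FastqRead":
        return FastqRead(self.id, revcomp(self.sequence), self.qualities[::-1],
                         mate=self.mate)


@dataclass
class PrimerPattern:
    """A primer/adapter pattern with N positions marking the UMI.

    Reverse-orientation patterns are canonicalised to their reverse
    complement at parse time, so matching always works in a single
    orientation against the read and its reverse complement.
    """

    name: str
    pattern: str                    # canonical (forward) form, upper case
    orientation: str                # as given: "forward" | "reverse"
    sample_label: str
    umi_positions: np.ndarray = field(init=False)
    _bits: np.ndarray = field(init=False, repr=False)
    _fixed: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        pat = np.frombuffer(self.pattern.encode(), dtype=np.uint8)
        self.umi_positions = np.flatnonzero(pat == ord("N"))
        self._bits = seq_to_bits(self.pattern)
        self._fixed = np.flatnonzero(pat != ord("N"))

    @property
    def umi_length(self) -> int:
        return len(self.umi_positions)

    @property
    def has_umi(self) -> bool:
        return self.umi_length > 0


def parse_pattern(pattern_string: str, orientation: str = "forward",
                  name: str = "", sample_label: str = "") -> PrimerPattern:
    """Parse a primer pattern string (IUPAC codes, N = UMI position)."""
    if not pattern_string:
        raise PatternError("empty primer pattern")
    if orientation not in ("forward", "reverse"):
        raise PatternError(f"orientation must be forward|reverse, got {orientation!r}")
    for c in pattern_string:
        if c.upper() not in "ACGTRYSWKMBDHVN":
            raise PatternError(
                f"pattern {pattern_string!r}: character {c!r} is not an IUPAC code")
    canonical = pattern_string.upper()
    if orientation == "reverse":
        canonical = revcomp(canonical)
    return PrimerPattern(name=name or pattern_string, pattern=canonical,
                         orientation=orientation,
                         sample_label=sample_label or name or pattern_string)


@dataclass
class TaggedRead:
    read: FastqRead                 # primer/UMI-trimmed, pattern orientation
    umi: str
    umi_qualities: np.ndarray
    sample_label: str
    pattern_name: str = ""
    strand: str = "+"               # strand of the raw read relative to pattern

    def __post_init__(self):
        self.umi_qualities = np.asarray(self.umi_qualities, dtype=np.int32)
        if len(self.umi) != len(self.umi_qualities):
            raise ValueError("UMI sequence/quality length mismatch")


@dataclass
class Rejection:
    read_id: str
    reason: str                     # no_primer | ambiguous | low_umi_quality | empty_umi


def _best_offset(seq_bits: np.ndarray, pattern: PrimerPattern,
                 max_mm: int, window: Optional[int]) -> Optional[tuple[int, int]]:
    """Best (offset, mismatches) of `pattern` in a bit-encoded read, or None.

    Substitution-only matching: N positions always match; the remaining
    positions match per IUPAC bit overlap. Smallest offset wins ties.
    """
    plen = len(pattern._bits)
    if len(seq_bits) < plen:
        return None
    win = np.lib.stride_tricks.sliding_window_view(seq_bits, plen)
    if window is not None:
        win = win[:window]
    if len(win) == 0:
        return None
    mm = np.count_nonzero(
        (win[:, pattern._fixed] & pattern._bits[pattern._fixed]) == 0, axis=1)
    off = int(mm.argmin())
    best = int(mm[off])
    if best <= max_mm:
        return off, best
    return None


def _match_one_mate(read: FastqRead, patterns: Sequence[PrimerPattern],
                    max_mm: int, window: Optional[int]):
    """All best-scoring (pattern, strand, offset) hits for a single read."""
    fwd_bits = seq_to_bits(read.sequence)
    rc_bits = seq_to_bits(revcomp(read.sequence))
    hits = []
    for pat in patterns:
        for strand, bits in (("+", fwd_bits), ("-", rc_bits)):
            m = _best_offset(bits, pat, max_mm, window)
            if m is not None:
                hits.append((m[1], pat, strand, m[0]))
    if not hits:
        return []
    best_mm = min(h[0] for h in hits)
    return [h for h in hits if h[0] == best_mm]


def _apply_hit(read: FastqRead, pat: PrimerPattern, strand: str, off: int):
    """Extract (trimmed read, umi, umi_quals) at a pattern hit."""
    if strand == "-":
        oriented = read.reverse_complement()
    else:
        oriented = read
    seq, quals = oriented.sequence, oriented.qualities
    umi = "".join(seq[off + p] for p in pat.umi_positions)
    umi_q = quals[off + pat.umi_positions] if pat.has_umi else np.empty(0, np.int32)
    trimmed = FastqRead(read.id, seq[off + len(pat.pattern):],
                        quals[off + len(pat.pattern):])
    return trimmed, umi, umi_q


def extract_umi(read: FastqRead, patterns: Sequence[PrimerPattern],
                max_primer_mismatches: int = DEFAULT_MAX_PRIMER_MISMATCHES,
                search_window: Optional[int] = None):
    """Match a read (pair) against primer patterns and extract its UMI.

    Returns a TaggedRead on a unique best match, or a Rejection. For read
    pairs the UMI is taken from whichever mate carries an N-bearing
    pattern; if both do, the two UMIs are concatenated first-then-second
    mate. Quality gating is a separate step (`gate_umi_quality`).
    """
    hits1 = _match_one_mate(read, patterns, max_primer_mismatches, search_window)
    if read.mate is None:
        if not hits1:
            return Rejection(read.id, "no_primer")
        if len({(h[1].name, h[2]) for h in hits1}) > 1:
            # distinct patterns (or strands) tie at the best mismatch count
            if len({h[1].name for h in hits1}) > 1:
                return Rejection(read.id, "ambiguous")
            hits1.sort(key=lambda h: h[2])  # same pattern both strands: take '+'
        _, pat, strand, off = hits1[0]
        trimmed, umi, umi_q = _apply_hit(read, pat, strand, off)
        return TaggedRead(trimmed, umi, umi_q, pat.sample_label, pat.name, strand)

    hits2 = _match_one_mate(read.mate, patterns, max_primer_mismatches, search_window)
    if not hits1 and not hits2:
        return Rejection(read.id, "no_primer")
    labels = {h[1].sample_label for h in hits1} | {h[1].sample_label for h in hits2}
    if len(labels) > 1:
        return Rejection(read.id, "ambiguous")
    for hits in (hits1, hits2):
        if len({h[1].name for h in hits}) > 1:
            return Rejection(read.id, "ambiguous")

    umi_parts, qual_parts = [], []
    trimmed1, trimmed2 = read, read.mate
    pat_name, strand = "", "+"
    if hits1:
        _, pat, strand, off = min(hits1, key=lambda h: h[2])
        trimmed1, u, q = _apply_hit(read, pat, strand, off)
        pat_name = pat.name
        if pat.has_umi:
            umi_parts.append(u)
            qual_parts.append(q)
    if hits2:
        _, pat2, strand2, off2 = min(hits2, key=lambda h: h[2])
        trimmed2, u2, q2 = _apply_hit(read.mate, pat2, strand2, off2)
        pat_name = pat_name or pat2.name
        if pat2.has_umi:
            umi_parts.append(u2)
            qual_parts.append(q2)
    trimmed1.mate = trimmed2
    umi = "".join(umi_parts)
    umi_q = (np.concatenate(qual_parts) if qual_parts else np.empty(0, np.int32))
    return TaggedRead(trimmed1, umi, umi_q, labels.pop(), pat_name, strand)


def gate_umi_quality(tagged: TaggedRead,
                     min_phred: int = DEFAULT_MIN_UMI_QUAL) -> Optional[str]:
    """Return None to keep, or a rejection reason.

    A UMI is dropped iff its minimum base quality is strictly below the
    threshold; a UMI exactly at the threshold is kept. Patterns without any
    N position yield an empty UMI, dropped with its own reason.
    """
    if len(tagged.umi) == 0:
        return "empty_umi"
    if "N" in tagged.umi:
        return "low_umi_quality"
    if int(tagged.umi_qualities.min()) < min_phred:
        return "low_umi_quality"
    return None


@dataclass
class ExtractionResult:
    tagged: list
    rejections: list
    stats: "Counter"

    def summary_rows(self):
        """Per-sample summary: total matched, tagged, rejected by reason."""
        samples = sorted({t.sample_label for t in self.tagged})
        total = len(self.tagged) + len(self.rejections)
        rows = []
        for s in samples:
            n = sum(1 for t in self.tagged if t.sample_label == s)
            rows.append({"sample": s, "reads_tagged": n,
                         "tagged_fraction": n / total if total else 0.0})
        for reason in ("no_primer", "ambiguous", "low_umi_quality", "empty_umi"):
            n = sum(1 for r in self.rejections if r.reason == reason)
            rows.append({"sample": f"rejected:{reason}", "reads_tagged": n,
                         "tagged_fraction": n / total if total else 0.0})
        return rows


def extract_reads(reads: Iterable[FastqRead], patterns: Sequence[PrimerPattern],
                  max_primer_mismatches: int = DEFAULT_MAX_PRIMER_MISMATCHES,
                  min_umi_qual: int = DEFAULT_MIN_UMI_QUAL,
                  search_window: Optional[int] = None) -> ExtractionResult:
    """Run extract_umi + gate_umi_quality over a read stream."""
    tagged, rejections = [], []
    stats: Counter = Counter()
    for read in reads:
        res = extract_umi(read, patterns, max_primer_mismatches, search_window)
        if isinstance(res, Rejection):
            rejections.append(res)
            stats[res.reason] += 1
            continue
        reason = gate_umi_quality(res, min_umi_qual)
        if reason is not None:
            rejections.append(Rejection(res.read.id, reason))
            stats[reason] += 1
        else:
            tagged.append(res)
            stats["tagged"] += 1
    return ExtractionResult(tagged, rejections, stats)


# ---------------------------------------------------------------------------
# FASTQ I/O (4-line records, Phred+33, transparent gzip)

def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[FastqRead]:
    with _open_text(path) as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            yield FastqRead(rid.split()[0], seq, string_to_phred(qual))


def read_fastq_paired(path1, path2) -> Iterator[FastqRead]:
    for r1, r2 in zip(read_fastq(path1), read_fastq(path2)):
        r1.mate = r2
        yield r1


def write_fastq(reads: Iterable[FastqRead], path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{phred_to_string(r.qualities)}\n")
            n += 1
    return n


def write_tagged_fastq(tagged: Iterable[TaggedRead], path) -> int:
    """Tagged reads as FASTQ with UMI/sample encoded in the header."""
    n = 0
    with _open_text(path, "wt") as fh:
        for t in tagged:
            hdr = (f"@{t.read.id} UM:Z:{t.umi} "
                   f"UQ:Z:{phred_to_string(t.umi_qualities)} SM:Z:{t.sample_label}")
            fh.write(f"{hdr}\n{t.read.sequence}\n+\n"
                     f"{phred_to_string(t.read.qualities)}\n")
            n += 1
    return n


def read_tagged_fastq(path) -> Iterator[TaggedRead]:
    with _open_text(path) as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            fields = dict(f.split(":Z:", 1) for f in rid.split()[1:] if ":Z:" in f)
            read = FastqRead(rid.split()[0], seq, string_to_phred(qual))
            yield TaggedRead(read, fields.get("UM", ""),
                             string_to_phred(fields.get("UQ", "")),
                             fields.get("SM", ""))
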