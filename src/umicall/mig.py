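"""Molecular identifier groups (MIGs) and consensus assembly.

Reads sharing one UMI form a MIG — all descendants of one tagged template
molecule. This module groups tagged reads into MIGs, removes MIGs whose UMI
is a sequencing-error variant of a much larger neighbour (20-fold rule at
Hamming distance 1, 400-fold at distance 2), picks a read-count-weighted
MIG size threshold from the log2 size histogram (threshold = sqrt of the
histogram peak, floored at 5 reads), and assembles each surviving MIG into
a majority-vote consensus with per-position dominant-base frequency f and
consensus quality score CQS = (40/3)*(4f - 1).

Assembly anchors reads on the most frequent 30-base "core" window (taken
at offsets -5..+5 around each read's centre), drops reads that lack the
core or accumulate more than two consecutive mismatches against the
forming consensus (a signature of indel errors), and tallies "minor"
bases — high-quality within-MIG disagreements with the consensus — that
feed the PCR error model.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .dna import BASES, phred_to_string, seq_to_index
from .preprocess import FastqRead, TaggedRead

DEFAULT_SIZE_FLOOR = 5
DEFAULT_RATIO_1MM = 20.0
DEFAULT_RATIO_2MM = 400.0
CORE_LENGTH = 30
CORE_MAX_OFFSET = 5


@dataclass
class Mig:
    umi: str
    sample_label: str
    reads: List[TaggedRead]

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class Consensus:
    sequence: str
    f: np.ndarray                  # dominant-base frequency per position
    cqs_scores: np.ndarray         # (40/3)(4f-1), in [0, 40]
    reads_used: int
    reads_dropped: int
    umi: str
    sample_label: str = ""
    mate_index: int = 0            # 0 = first-mate consensus, 1 = second

    @property
    def quality_string(self) -> str:
        return phred_to_string(np.floor(self.cqs_scores).astype(int), cap=40)


class MinorCounts:
    """Tallies of within-MIG disagreements with the consensus.

    Keyed by (position, consensus_base, minor_base); positions are local to
    the consensus sequence. `pooled_by_class` collapses the tallies onto
    the six complement-collapsed substitution classes for error-model
    fitting; the accompanying per-base read-observation counts form the
    rate denominator.
    """

    def __init__(self):
        self.counts: Dict[Tuple[int, str, str], int] = defaultdict(int)
        self.observations: Dict[str, int] = defaultdict(int)  # per consensus base

    def add(self, position: int, from_base: str, to_base: str, n: int = 1):
        if to_base == from_base:
            raise ValueError("minor base equals consensus base")
        self.counts[(position, from_base, to_base)] += n

    def add_observations(self, base: str, n: int):
        self.observations[base] += n

    def update(self, other: "MinorCounts"):
        for k, v in other.counts.items():
            self.counts[k] += v
        for b, v in other.observations.items():
            self.observations[b] += v

    def total(self) -> int:
        return sum(self.counts.values())

    def pooled_by_class(self) -> Dict[str, Dict[str, int]]:
        from .error_model import collapse_substitution
        pooled: Dict[str, int] = defaultdict(int)
        for (_, frm, to), n in self.counts.items():
            pooled[collapse_substitution(frm, to)] += n
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        obs: Dict[str, int] = defaultdict(int)
        for base, n in self.observations.items():
            if base in "AC":
                key = base
            else:
                key = comp[base]
            obs[key] += n
        out = {}
        for cls, n in pooled.items():
            from_base = cls[0]  # classes are canonicalised to A>* / C>*
            out[cls] = {"minor_count": n, "observations": obs.get(from_base, 0)}
        return out


@dataclass
class AssemblyRejection:
    umi: str
    reason: str                    # below_threshold | no_core
    reads: int


def group_migs(tagged_reads: Iterable[TaggedRead]) -> List[Mig]:
    """One Mig per distinct (sample, UMI); total reads conserved."""
    groups: Dict[Tuple[str, str], List[TaggedRead]] = defaultdict(list)
    umi_lengths: Dict[str, set] = defaultdict(set)
    for t in tagged_reads:
        groups[(t.sample_label, t.umi)].append(t)
        umi_lengths[t.sample_label].add(len(t.umi))
    for sample, lengths in umi_lengths.items():
        if len(lengths) > 1:
            raise ValueError(
                f"sample {sample!r}: mixed UMI lengths {sorted(lengths)}")
    return [Mig(umi=u, sample_label=s, reads=r)
            for (s, u), r in sorted(groups.items())]


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _candidate_pairs(umis: Sequence[str]):
    """Pairs of UMIs at Hamming distance <= 2, via masked-key hashing."""
    seen = set()
    buckets: Dict[str, List[int]] = defaultdict(list)
    L = len(umis[0]) if umis else 0
    for idx, u in enumerate(umis):
        for i in range(L):
            for j in range(i + 1, L):
                key = u[:i] + "*" + u[i + 1:j] + "*" + u[j + 1:]
                buckets[key].append(idx)
    for members in buckets.values():
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                pair = (members[ai], members[bi])
                if pair not in seen:
                    seen.add(pair)
                    yield pair


def correct_umi_collisions(migs: List[Mig],
                           ratio_1mm: float = DEFAULT_RATIO_1MM,
                           ratio_2mm: float = DEFAULT_RATIO_2MM,
                           merge: bool = False):
    """Remove MIGs tagged by an erroneous variant of a larger MIG's UMI.

    A MIG is discarded when a MIG >= 20x larger exists at Hamming distance
    1 (>= 400x at distance 2). Raw (pre-threshold) sizes are compared.
    Pairs are processed largest-parent-first with lexicographic
    tie-breaks, and a discarded MIG never absorbs others, so the surviving
    set is independent of input order. With ``merge=True`` the child's
    reads are reassigned to the parent instead of being dropped.

    Returns (kept_migs, discarded) where discarded is a list of
    (child_mig, parent_umi).
    """
    by_sample: Dict[str, List[Mig]] = defaultdict(list)
    for m in migs:
        by_sample[m.sample_label].append(m)

    kept_all: List[Mig] = []
    discarded_all: List[Tuple[Mig, str]] = []
    for sample in sorted(by_sample):
        group = by_sample[sample]
        umis = [m.umi for m in group]
        rules = []
        for ai, bi in _candidate_pairs(umis):
            a, b = group[ai], group[bi]
            d = _hamming(a.umi, b.umi)
            if d == 0 or d > 2:
                continue
            big, small = (a, b) if a.size >= b.size else (b, a)
            if big.size == small.size:
                continue
            ratio = big.size / small.size
            needed = ratio_1mm if d == 1 else ratio_2mm
            if ratio >= needed:
                rules.append((big, small))
        rules.sort(key=lambda r: (-r[0].size, r[0].umi, r[1].umi))
        discarded: Dict[str, str] = {}
        for big, small in rules:
            if big.umi in discarded or small.umi in discarded:
                continue
            discarded[small.umi] = big.umi
        parents = {m.umi: m for m in group}
        for m in group:
            if m.umi in discarded:
                discarded_all.append((m, discarded[m.umi]))
                if merge:
                    parents[discarded[m.umi]].reads.extend(m.reads)
            else:
                kept_all.append(m)
    return kept_all, discarded_all


def compute_size_threshold(migs: Sequence[Mig], floor: int = DEFAULT_SIZE_FLOOR,
                           bin_width: float = 0.2) -> int:
    """Size threshold from the read-weighted log2 MIG-size histogram.

    Small MIGs dominate by count but carry few reads, so the histogram is
    weighted by read count; its mode m marks the typical true molecule.
    The threshold is sqrt of the peak size (half the log-peak), i.e.
    round(2^(m/2)), never below `floor` reads.
    """
    if not migs:
        raise ValueError("no MIGs")
    sizes = np.array([m.size for m in migs], dtype=float)
    logs = np.log2(sizes)
    nbins = max(1, int(math.ceil((logs.max() + bin_width) / bin_width)))
    hist, edges = np.histogram(logs, bins=nbins,
                               range=(0.0, nbins * bin_width), weights=sizes)
    mode = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
    return max(int(round(2.0 ** (mode / 2.0))), floor)


def cqs(f):
    """Consensus quality score (40/3)*(4f - 1) for f in [0.25, 1]."""
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0.25 - 1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError("dominant-base frequency outside [0.25, 1]")
    out = (40.0 / 3.0) * (4.0 * arr - 1.0)
    return float(out) if np.isscalar(f) else out


def _pick_core(seqs: Sequence[str], core_len: int, max_off: int) -> Optional[str]:
    counter: Counter = Counter()
    for s in seqs:
        if len(s) < core_len:
            continue
        start0 = len(s) // 2 - core_len // 2
        for off in range(-max_off, max_off + 1):
            st = start0 + off
            if 0 <= st <= len(s) - core_len:
                counter[s[st:st + core_len]] += 1
    if not counter:
        return None
    best = max(counter.values())
    return min(k for k, v in counter.items() if v == best)


def _column_consensus(mat: np.ndarray, qual: np.ndarray):
    """Majority call per column of a 0..4-encoded matrix (4 = no cover/N).

    Ties are broken by summed Phred quality, then base order A<C<G<T.
    Returns (consensus indices, majority counts, ACGT coverage).
    """
    ncol = mat.shape[1]
    counts = np.zeros((4, ncol), dtype=np.int32)
    qsums = np.zeros((4, ncol), dtype=np.int64)
    for b in range(4):
        is_b = mat == b
        counts[b] = is_b.sum(axis=0)
        qsums[b] = np.where(is_b, qual, 0).sum(axis=0)
    coverage = counts.sum(axis=0)
    # lexicographic (count, qsum, -base) argmax via stable keys
    order = counts.astype(np.int64) * (qsums.max() + 1) * 4 + qsums * 4 + (3 - np.arange(4))[:, None]
    cons = order.argmax(axis=0)
    maj = counts[cons, np.arange(ncol)]
    return cons.astype(np.int32), maj, coverage


def assemble_consensus(mig: Mig, size_threshold: int = DEFAULT_SIZE_FLOOR,
                       q_minor: int = 30, max_consecutive_mismatches: int = 2,
                       core_len: int = CORE_LENGTH,
                       core_max_offset: int = CORE_MAX_OFFSET,
                       mate_index: int = 0):
    """Assemble one MIG into a majority-vote consensus.

    Returns (Consensus, MinorCounts, dropped_reads) or an
    AssemblyRejection when fewer than `size_threshold` reads survive.
    `dropped_reads` carries the full sequences of reads discarded for
    likely indels, so a Torrent-style preset can route them to local
    re-alignment.
    """
    if mate_index == 0:
        reads = [t.read for t in mig.reads]
    else:
        reads = [t.read.mate for t in mig.reads if t.read.mate is not None]

    core = _pick_core([r.sequence for r in reads], core_len, core_max_offset)
    if core is None:
        return AssemblyRejection(mig.umi, "no_core", len(reads))

    # anchor each read at its best approximate core occurrence; reads whose
    # best offset still mismatches heavily (indels, chimeras) are dropped
    core_idx = seq_to_index(core)
    max_core_mm = core_len // 6
    anchored, dropped = [], []
    for r in reads:
        if len(r.sequence) < core_len:
            dropped.append((r, "short"))
            continue
        win = np.lib.stride_tricks.sliding_window_view(
            seq_to_index(r.sequence), core_len)
        mm = np.count_nonzero(win != core_idx, axis=1)
        pos = int(mm.argmin())
        if mm[pos] > max_core_mm:
            dropped.append((r, "no_core_match"))
        else:
            anchored.append((r, pos))
    if len(anchored) < size_threshold:
        return AssemblyRejection(mig.umi, "below_threshold", len(reads))

    # column space: column 0 == first base of the core
    left = max(pos for _, pos in anchored)
    width = max(len(r.sequence) - pos for r, pos in anchored) + left
    n = len(anchored)
    mat = np.full((n, width), 4, dtype=np.int8)
    qual = np.zeros((n, width), dtype=np.int32)
    for i, (r, pos) in enumerate(anchored):
        st = left - pos
        mat[i, st:st + len(r.sequence)] = seq_to_index(r.sequence)
        qual[i, st:st + len(r.sequence)] = r.qualities

    cons_idx, _, _ = _column_consensus(mat, qual)

    # drop reads with runs of > limit consecutive mismatches (indel signature)
    covered = mat != 4
    mism = covered & (mat != cons_idx[None, :])
    keep = np.ones(n, dtype=bool)
    lim = max_consecutive_mismatches
    for i in range(n):
        run = 0
        for j in np.flatnonzero(covered[i]):
            if mism[i, j]:
                run += 1
                if run > lim:
                    keep[i] = False
                    break
            else:
                run = 0
    for i in np.flatnonzero(~keep):
        dropped.append((anchored[i][0], "consecutive_mismatches"))
    mat, qual = mat[keep], qual[keep]
    n_used = int(keep.sum())
    if n_used < size_threshold:
        return AssemblyRejection(mig.umi, "below_threshold", len(reads))

    cons_idx, maj, coverage = _column_consensus(mat, qual)
    min_cov = max(1, (n_used + 1) // 2)   # trim ragged low-coverage edges
    cols = np.flatnonzero(coverage >= min_cov)
    lo, hi = int(cols.min()), int(cols.max()) + 1
    cons_idx, maj, coverage = cons_idx[lo:hi], maj[lo:hi], coverage[lo:hi]
    mat, qual = mat[:, lo:hi], qual[:, lo:hi]

    f = maj / np.maximum(coverage, 1)
    f = np.clip(f, 0.25, 1.0)
    sequence = "".join(BASES[i] for i in cons_idx)
    consensus = Consensus(sequence=sequence, f=f, cqs_scores=cqs(f),
                          reads_used=n_used,
                          reads_dropped=len(mig.reads) - n_used,
                          umi=mig.umi, sample_label=mig.sample_label,
                          mate_index=mate_index)

    minors = MinorCounts()
    freq_floor = 10.0 ** (-q_minor / 10.0)
    for b in range(4):
        minors.add_observations(BASES[b], int((mat == b).sum()))
    disagree = (mat != cons_idx[None, :]) & (mat != 4) & (qual >= q_minor)
    for i, j in zip(*np.nonzero(disagree)):
        b = int(mat[i, j])
        count_b = int((mat[:, j] == b).sum())
        if count_b / coverage[j] > freq_floor:
            minors.add(int(j), BASES[cons_idx[j]], BASES[b])
    # each (pos, base) tallied once per supporting read; de-duplication not
    # needed since every disagreeing read contributes one unit
    return consensus, minors, [r for r, _ in dropped]


@dataclass
class AssemblyResult:
    consensuses: List[Consensus]
    minor_counts: MinorCounts
    rejections: List[AssemblyRejection]
    realign_reads: List[FastqRead] = field(default_factory=list)

    @property
    def reads_used(self) -> int:
        return sum(c.reads_used for c in self.consensuses if c.mate_index == 0)


def assemble_all(migs: Sequence[Mig], size_threshold: int = DEFAULT_SIZE_FLOOR,
                 q_minor: int = 30, preset: str = "illumina") -> AssemblyResult:
    """Assemble every MIG at or above the size threshold.

    The 'torrent' preset tolerates one more consecutive mismatch (limit 3)
    and collects indel-suspect reads for downstream local re-alignment
    instead of discarding them silently.
    """
    if preset not in ("illumina", "torrent"):
        raise ValueError(f"unknown preset {preset!r}")
    limit = 3 if preset == "torrent" else 2
    result = AssemblyResult([], MinorCounts(), [])
    paired = any(m.reads and m.reads[0].read.mate is not None for m in migs)
    for mig in migs:
        if mig.size < size_threshold:
            result.rejections.append(
                AssemblyRejection(mig.umi, "below_threshold", mig.size))
            continue
        mates = (0, 1) if paired else (0,)
        for mate in mates:
            out = assemble_consensus(mig, size_threshold, q_minor,
                                     max_consecutive_mismatches=limit,
                                     mate_index=mate)
            if isinstance(out, AssemblyRejection):
                if mate == 0:
                    result.rejections.append(out)
                continue
            consensus, minors, dropped = out
            result.consensuses.append(consensus)
            result.minor_counts.update(minors)
            if preset == "torrent":
                result.realign_reads.extend(dropped)
    return result
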