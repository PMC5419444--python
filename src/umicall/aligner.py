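"""Two-stage consensus alignment: K-mer reference selection + Smith-Waterman.

Targeted panels contain a small set of reference amplicons, so alignment is
split into (1) picking the best reference by the total information content
of shared K-mers, I = sum over shared k-mers of -f_k * ln(f_k), where f_k is
the k-mer's frequency among all k-mer instances in the reference database
(both strands), and (2) a full affine-gap Smith-Waterman local alignment
against that reference with match +1, mismatch -3, gap open -6, gap
extend -1. The mapping quality is MAPQ = 10 * (I_best - I_nextbest), in the
spirit of BWA/bowtie MAPQ scores. Alignments with substitution-only
identity below 90% or spanning less than 70% of the query are discarded.

Shared K-mers are counted once each (distinct k-mers, not multiplicity);
the information score uses the natural logarithm — only score differences
matter, so the base fixes the MAPQ scale.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .dna import revcomp, seq_to_index

DEFAULT_K = 11
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_SPAN = 0.70
DEFAULT_SCORING = {"match": 1, "mismatch": -3, "gap_open": -6, "gap_extend": -1}


@dataclass
class ReferenceRecord:
    name: str
    sequence: str
    contig: str = ""
    genomic_start: int = 0          # 0-based (BED convention)
    strand: str = "+"


class ReferenceLibrary:
    def __init__(self, records: Sequence[ReferenceRecord]):
        names = [r.name for r in records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate reference names")
        self.records = list(records)
        self._by_name = {r.name: r for r in records}

    def __len__(self):
        return len(self.records)

    def __getitem__(self, name: str) -> ReferenceRecord:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @classmethod
    def from_fasta(cls, fasta_path, bed_path=None) -> "ReferenceLibrary":
        """Load references from FASTA, with optional BED genomic metadata.

        BED columns: contig, start, end, name, [score], [strand];
        coordinates are 0-based half-open and matched to FASTA records by
        name.
        """
        meta: Dict[str, Tuple[str, int, str]] = {}
        if bed_path is not None:
            with open(bed_path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith(("#", "track", "browser")):
                        continue
                    parts = line.split("\t")
                    contig, start, end = parts[0], int(parts[1]), int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"{contig}:{start}-{end}"
                    strand = parts[5] if len(parts) > 5 else "+"
                    if end < start:
                        raise ValueError(f"BED interval {name}: end < start")
                    meta[name] = (contig, start, strand)
        records = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            contig, start, strand = meta.get(rec.id, (rec.id, 0, "+"))
            records.append(ReferenceRecord(rec.id, str(rec.seq).upper(),
                                           contig, start, strand))
        return cls(records)


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield seq[i:i + k]


class KmerIndex:
    """K-mer frequencies over both strands of a reference database."""

    def __init__(self, k: int, f_k: Dict[str, float],
                 forward_sets: Dict[str, frozenset],
                 reverse_sets: Dict[str, frozenset]):
        self.k = k
        self.f_k = f_k
        self.forward_sets = forward_sets
        self.reverse_sets = reverse_sets

    @classmethod
    def build(cls, library: ReferenceLibrary, k: int = DEFAULT_K) -> "KmerIndex":
        if k < 5:
            raise ValueError("k must be >= 5")
        counts: Counter = Counter()
        fwd, rev = {}, {}
        for rec in library.records:
            if len(rec.sequence) < k:
                raise ValueError(
                    f"reference {rec.name!r} shorter than k={k}")
            f_kmers = list(_kmers(rec.sequence, k))
            r_kmers = list(_kmers(revcomp(rec.sequence), k))
            counts.update(f_kmers)
            counts.update(r_kmers)
            fwd[rec.name] = frozenset(f_kmers)
            rev[rec.name] = frozenset(r_kmers)
        total = sum(counts.values())
        f_k = {kmer: c / total for kmer, c in counts.items()}
        return cls(k, f_k, fwd, rev)

    def information(self, kmer: str) -> float:
        f = self.f_k.get(kmer, 0.0)
        return -f * np.log(f) if f > 0 else 0.0

    def save(self, path):
        data = {"k": self.k, "f_k": self.f_k,
                "forward_sets": {n: sorted(s) for n, s in self.forward_sets.items()},
                "reverse_sets": {n: sorted(s) for n, s in self.reverse_sets.items()}}
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def load(cls, path) -> "KmerIndex":
        with open(path) as fh:
            data = json.load(fh)
        return cls(data["k"], data["f_k"],
                   {n: frozenset(s) for n, s in data["forward_sets"].items()},
                   {n: frozenset(s) for n, s in data["reverse_sets"].items()})


@dataclass
class ReferenceSelection:
    reference: str
    strand: str                     # query strand relative to the reference
    i_best: float
    i_next: float

    @property
    def mapq(self) -> float:
        return 10.0 * (self.i_best - self.i_next)


def select_reference(query: str, index: KmerIndex) -> Optional[ReferenceSelection]:
    """Best reference by shared-K-mer information content, or None.

    I(ref) sums -f_k ln f_k over the distinct query k-mers present in the
    reference (either strand). The query strand is set by whichever strand
    of the winning reference shares more k-mers.
    """
    if len(query) < index.k:
        return None
    qk = frozenset(_kmers(query.upper(), index.k))
    scores = []
    for name in index.forward_sets:
        shared = qk & (index.forward_sets[name] | index.reverse_sets[name])
        i = sum(index.information(km) for km in shared)
        scores.append((i, name))
    scores.sort(key=lambda t: (-t[0], t[1]))
    i_best, best = scores[0]
    if i_best <= 0.0:
        return None
    i_next = scores[1][0] if len(scores) > 1 else 0.0
    n_fwd = len(qk & index.forward_sets[best])
    n_rev = len(qk & index.reverse_sets[best])
    strand = "+" if n_fwd >= n_rev else "-"
    return ReferenceSelection(best, strand, i_best, i_next)


@dataclass
class Alignment:
    score: int
    query_start: int                # 0-based half-open query interval
    query_end: int
    ref_start: int                  # 0-based half-open reference interval
    ref_end: int
    cigar: List[Tuple[str, int]]    # M/I/D ops over the aligned region only
    n_match: int
    n_mismatch: int
    query_length: int

    @property
    def identity(self) -> float:
        """Substitution-only identity: matches / non-gap aligned columns."""
        cols = self.n_match + self.n_mismatch
        return self.n_match / cols if cols else 0.0

    @property
    def span_fraction(self) -> float:
        return ((self.query_end - self.query_start) / self.query_length
                if self.query_length else 0.0)

    def cigar_string(self, with_clips: bool = True) -> str:
        parts = []
        if with_clips and self.query_start > 0:
            parts.append(f"{self.query_start}S")
        parts += [f"{n}{op}" for op, n in self.cigar]
        tail = self.query_length - self.query_end
        if with_clips and tail > 0:
            parts.append(f"{tail}S")
        return "".join(parts) if parts else "*"


_NEG = np.iinfo(np.int32).min // 4


def _sw_fill_py(q, r, ma, mi, go, ge):
    n, m = len(q), len(r)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = max(H[i, j - 1] + go + ge, E[i, j - 1] + ge)
            f = max(H[i - 1, j] + go + ge, F[i - 1, j] + ge)
            s = ma if (qi == r[j - 1] and qi != 4) else mi
            h = H[i - 1, j - 1] + s
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


try:  # JIT-compiled fill; the pure-Python version stays as a fallback
    from numba import njit as _njit

    _sw_fill = _njit(cache=True)(_sw_fill_py)
except Exception:  # pragma: no cover
    _sw_fill = _sw_fill_py


def local_align(query: str, reference: str,
                scoring: Optional[dict] = None) -> Alignment:
    """Optimal affine-gap Smith-Waterman local alignment.

    A gap of length g costs |gap_open| + g * |gap_extend| (the opening
    penalty is charged on top of the first extension). Traceback is
    deterministic: the end cell is the maximum-score cell with the
    smallest reference then query coordinate, and on ties within the
    traceback, diagonal moves are preferred over gaps in the reference
    (insertions) over gaps in the query (deletions).
    """
    sc = dict(DEFAULT_SCORING)
    if scoring:
        sc.update(scoring)
    ma, mi = sc["match"], sc["mismatch"]
    go, ge = sc["gap_open"], sc["gap_extend"]
    if not query or not reference:
        raise ValueError("sequences must be non-empty")

    q = seq_to_index(query).astype(np.int32)
    r = seq_to_index(reference).astype(np.int32)
    H, E, F = _sw_fill(q, r, np.int32(ma), np.int32(mi),
                       np.int32(go), np.int32(ge))
    return _traceback(q, r, H, E, F, sub_params=(ma, mi, go, ge),
                      query_length=len(q))


def _traceback(q, r, H, E, F, sub_params, query_length) -> Alignment:
    ma, mi, go, ge = sub_params
    n, m = len(q), len(r)
    best = int(H.max())
    if best <= 0:
        return Alignment(0, 0, 0, 0, 0, [], 0, 0, query_length)
    # end cell: max score, smallest reference then query coordinate
    cells = np.argwhere(H == best)
    j_i = cells[np.lexsort((cells[:, 0], cells[:, 1]))][0]
    i, j = int(j_i[0]), int(j_i[1])
    qe, re = i, j
    ops: List[Tuple[str, int]] = []
    n_match = n_mismatch = 0

    def push(op):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = ma if (q[i - 1] == r[j - 1] and q[i - 1] != 4) else mi
            if h == H[i - 1, j - 1] + s:
                push("M")
                if s == ma:
                    n_match += 1
                else:
                    n_mismatch += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":          # gap in reference: consume query ('I')
            push("I")
            if F[i, j] == H[i - 1, j] + go + ge:
                state = "H"
            i -= 1
        else:                       # gap in query: consume reference ('D')
            push("D")
            if E[i, j] == H[i, j - 1] + go + ge:
                state = "H"
            j -= 1
    ops.reverse()
    return Alignment(best, i, qe, j, re, ops, n_match, n_mismatch, query_length)


@dataclass
class AlignmentHit:
    query_name: str
    reference: str
    strand: str
    mapq: float
    i_best: float
    i_next: float
    alignment: Alignment
    sequence: str = ""              # query in reference orientation
    qualities: Optional[np.ndarray] = None
    tags: dict = field(default_factory=dict)


def filter_alignment(hit: AlignmentHit,
                     min_identity: float = DEFAULT_MIN_IDENTITY,
                     min_span: float = DEFAULT_MIN_SPAN) -> bool:
    """Keep iff identity >= 90% (substitutions only) and span >= 70%.

    Boundary values are kept: the filter discards strictly-below hits.
    """
    aln = hit.alignment
    if aln.score <= 0:
        return False
    return aln.identity >= min_identity and aln.span_fraction >= min_span


def align_query(name: str, sequence: str, index: KmerIndex,
                library: ReferenceLibrary,
                qualities: Optional[np.ndarray] = None,
                scoring: Optional[dict] = None,
                tags: Optional[dict] = None) -> Optional[AlignmentHit]:
    """Select a reference for one query and run the local alignment."""
    sel = select_reference(sequence, index)
    if sel is None:
        return None
    seq = sequence.upper()
    quals = qualities
    if sel.strand == "-":
        seq = revcomp(seq)
        quals = qualities[::-1] if qualities is not None else None
    aln = local_align(seq, library[sel.reference].sequence, scoring)
    return AlignmentHit(name, sel.reference, sel.strand, sel.mapq,
                        sel.i_best, sel.i_next, aln, seq, quals,
                        dict(tags or {}))


# ---------------------------------------------------------------------------
# SAM output

def write_sam(hits: Sequence[AlignmentHit], library: ReferenceLibrary, path):
    """Write mapped consensuses as SAM (1-based POS, soft-clipped flanks)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": rec.name, "LN": len(rec.sequence)}
               for rec in library.records],
    }
    tid = {rec.name: i for i, rec in enumerate(library.records)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for hit in hits:
            a = pysam.AlignedSegment(out.header)
            a.query_name = hit.query_name
            a.reference_id = tid[hit.reference]
            a.reference_start = hit.alignment.ref_start
            a.mapping_quality = min(254, max(0, int(round(hit.mapq))))
            a.cigarstring = hit.alignment.cigar_string()
            a.flag = 16 if hit.strand == "-" else 0
            a.query_sequence = hit.sequence
            if hit.qualities is not None:
                a.query_qualities = [min(40, max(0, int(qv)))
                                     for qv in hit.qualities]
            for tag, val in hit.tags.items():
                a.set_tag(tag, val)
            out.write(a)
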