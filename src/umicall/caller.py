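"""Control-free rare-variant calling on UMI consensus alignments.

Each aligned consensus is one observation of one original template
molecule, so variant calling reduces to counting consensuses per reference
position: coverage N_i is the number of consensuses whose alignment covers
position i with an M/X/= operation (positions deleted in a consensus do
not count), and n_xyi is the number carrying base y over reference base x.
Substitutions get Q = -10*log10 P(X >= n) under the class Beta-Binomial
error model, capped at 100; indels are reported with frequency and count
but no quality model (FILTER NO_QUAL). No matched normal is consulted and
no multiple-testing correction is applied — Q scores are raw.

Both sub-consensuses of a paired MIG share a UMI; a UMI contributes at
most one observation per position.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .aligner import ReferenceLibrary
from .dna import BASES, seq_to_index
from .error_model import (SubstitutionErrorModel, betabinom_tail_p,
                          collapse_substitution, q_score)

DEFAULT_Q_THRESHOLD = 20.0


@dataclass
class ReferencePileup:
    name: str
    sequence: str
    coverage: np.ndarray            # N_i per 0-based reference position
    base_counts: np.ndarray         # 4 x L counts of consensus bases
    cqs_sums: np.ndarray            # 4 x L summed consensus quality
    insertions: Dict[Tuple[int, str], int] = field(default_factory=dict)
    deletions: Dict[Tuple[int, str], int] = field(default_factory=dict)


class Pileup:
    def __init__(self, references: Dict[str, ReferencePileup],
                 variant_umis: Dict[Tuple[str, int, str], set]):
        self.references = references
        # (ref, 0-based pos, alt) -> set of supporting UMIs (for the
        # shared-UMI co-occurrence report)
        self.variant_umis = variant_umis


def build_pileup(sam_path, library: ReferenceLibrary) -> Pileup:
    """Build per-position consensus counts from a SAM stream.

    CIGAR-aware: deletions skip consensus bases and do not add coverage at
    the deleted positions; insertions are recorded between columns. Each
    UMI (read name / UM tag) contributes at most once per position.
    """
    refs: Dict[str, ReferencePileup] = {}
    ref_idx: Dict[str, np.ndarray] = {}
    for rec in library.records:
        L = len(rec.sequence)
        refs[rec.name] = ReferencePileup(
            rec.name, rec.sequence,
            coverage=np.zeros(L, dtype=np.int32),
            base_counts=np.zeros((4, L), dtype=np.int32),
            cqs_sums=np.zeros((4, L), dtype=np.float64))
        ref_idx[rec.name] = seq_to_index(rec.sequence)
    umi_cover: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
    variant_umis: Dict[Tuple[str, int, str], set] = defaultdict(set)

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if aln.reference_name not in refs:
                raise ValueError(
                    f"SAM record {aln.query_name!r} references unknown "
                    f"reference {aln.reference_name!r}")
            rp = refs[aln.reference_name]
            umi = (aln.get_tag("UM") if aln.has_tag("UM")
                   else aln.query_name)
            key = (aln.reference_name, umi)
            taken = umi_cover[key]

            def uncovered(s, e):
                spans = [(s, e)]
                for ts, te in taken:
                    spans = [piece
                             for a, b in spans
                             for piece in ((a, min(b, ts)), (max(a, te), b))
                             if piece[0] < piece[1]]
                return spans

            seq = aln.query_sequence or ""
            quals = aln.query_qualities
            qpos, rpos = 0, aln.reference_start
            for op, ln in aln.cigartuples:
                if op in (0, 7, 8):             # M / = / X
                    bases_all = seq_to_index(seq[qpos:qpos + ln])
                    for s, e in uncovered(rpos, rpos + ln):
                        rp.coverage[s:e] += 1
                        bases = bases_all[s - rpos:e - rpos]
                        pos_arr = np.arange(s, e)
                        valid = bases < 4
                        np.add.at(rp.base_counts,
                                  (bases[valid], pos_arr[valid]), 1)
                        if quals is not None:
                            qarr = np.asarray(quals[qpos + s - rpos:
                                                    qpos + e - rpos])
                            np.add.at(rp.cqs_sums,
                                      (bases[valid], pos_arr[valid]),
                                      qarr[valid])
                        mism = valid & (bases != ref_idx[rp.name][s:e])
                        for k in np.flatnonzero(mism):
                            variant_umis[(rp.name, int(pos_arr[k]),
                                          BASES[bases[k]])].add(umi)
                    qpos += ln
                    rpos += ln
                elif op == 1:                   # I: between rpos-1 and rpos
                    if not any(ts <= rpos - 1 < te for ts, te in taken):
                        ins = seq[qpos:qpos + ln]
                        k = (rpos, ins)
                        rp.insertions[k] = rp.insertions.get(k, 0) + 1
                    qpos += ln
                elif op == 2:                   # D
                    if not any(ts <= rpos < te for ts, te in taken):
                        dseq = rp.sequence[rpos:rpos + ln]
                        k = (rpos, dseq)
                        rp.deletions[k] = rp.deletions.get(k, 0) + 1
                    rpos += ln
                elif op == 4:                   # S
                    qpos += ln
                elif op == 3:                   # N
                    rpos += ln
            taken.append((aln.reference_start, rpos))
    return Pileup(refs, variant_umis)


@dataclass
class VariantCall:
    contig: str
    pos: int                        # 1-based genomic position
    ref: str
    alt: str
    kind: str                       # substitution | insertion | deletion
    frequency: float
    count: int
    coverage: int
    q: Optional[float]              # None for indels (no quality model)
    substitution_class: str = ""
    mean_cqs: float = 0.0
    empirical_p: Optional[float] = None
    filter: str = "PASS"
    reference_name: str = ""
    local_pos: int = 0              # 0-based position on the reference record


def _genomic(library: ReferenceLibrary, ref_name: str, local_pos: int):
    rec = library[ref_name]
    return rec.contig or rec.name, rec.genomic_start + local_pos + 1


def call_substitutions(pileup: Pileup, model: SubstitutionErrorModel,
                       library: ReferenceLibrary,
                       min_q: float = 0.0) -> List[VariantCall]:
    """Q-scored substitution calls for every non-reference base observed."""
    calls = []
    for name in sorted(pileup.references):
        rp = pileup.references[name]
        for pos in np.flatnonzero(rp.base_counts.sum(axis=0) > 0):
            pos = int(pos)
            x = rp.sequence[pos]
            N = int(rp.coverage[pos])
            for bi, y in enumerate(BASES):
                n = int(rp.base_counts[bi, pos])
                if n == 0 or y == x:
                    continue
                if x not in "ACGT":
                    continue        # ambiguous reference base: skip
                cls = collapse_substitution(x, y)
                a, b = model.parameters[cls]
                q = q_score(betabinom_tail_p(n, N, a, b))
                if q < min_q:
                    continue
                contig, gpos = _genomic(library, name, pos)
                calls.append(VariantCall(
                    contig=contig, pos=gpos, ref=x, alt=y,
                    kind="substitution", frequency=n / N, count=n,
                    coverage=N, q=q, substitution_class=cls,
                    mean_cqs=float(rp.cqs_sums[bi, pos] / n),
                    filter="PASS" if q >= DEFAULT_Q_THRESHOLD else "LOWQ",
                    reference_name=name, local_pos=pos))
    return calls


def _left_normalize_deletion(seq: str, start: int, length: int):
    while start > 0 and seq[start - 1] == seq[start + length - 1]:
        start -= 1
    return start


def _left_normalize_insertion(seq: str, pos: int, ins: str):
    # pos: insertion before `pos`; shift while the inserted string's last
    # base equals the reference base just before the insertion point
    while pos > 0 and ins[-1] == seq[pos - 1]:
        ins = seq[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def call_indels(pileup: Pileup, library: ReferenceLibrary) -> List[VariantCall]:
    """Indel calls with frequency and count but no quality model.

    Alleles are left-normalized with a one-base anchor per VCF
    convention and flagged NO_QUAL.
    """
    calls = []
    for name in sorted(pileup.references):
        rp = pileup.references[name]
        for (pos, dseq), n in sorted(rp.deletions.items()):
            start = _left_normalize_deletion(rp.sequence, pos, len(dseq))
            if start == 0:
                continue            # no anchor base available
            anchor = rp.sequence[start - 1]
            N = int(rp.coverage[start - 1])
            if N == 0:
                continue
            contig, gpos = _genomic(library, name, start - 1)
            calls.append(VariantCall(
                contig=contig, pos=gpos,
                ref=anchor + rp.sequence[start:start + len(dseq)], alt=anchor,
                kind="deletion", frequency=n / N, count=n, coverage=N,
                q=None, filter="NO_QUAL", reference_name=name,
                local_pos=start - 1))
        for (pos, ins), n in sorted(rp.insertions.items()):
            npos, nins = _left_normalize_insertion(rp.sequence, pos, ins)
            if npos == 0:
                continue
            anchor = rp.sequence[npos - 1]
            N = int(rp.coverage[npos - 1])
            if N == 0:
                continue
            contig, gpos = _genomic(library, name, npos - 1)
            calls.append(VariantCall(
                contig=contig, pos=gpos, ref=anchor, alt=anchor + nins,
                kind="insertion", frequency=n / N, count=n, coverage=N,
                q=None, filter="NO_QUAL", reference_name=name,
                local_pos=npos - 1))
    return calls


def empirical_pvalue(calls: Sequence[VariantCall]) -> List[VariantCall]:
    """Annotate calls with a rank-based upper-tail empirical P (diagnostic).

    Within each substitution class (indels pooled by kind), P = (number of
    calls with frequency >= own) / class total, so the single highest
    frequency among 100 calls gets P = 0.01 and a lone call gets P = 1.
    """
    groups: Dict[str, List[VariantCall]] = defaultdict(list)
    for c in calls:
        groups[c.substitution_class or c.kind].append(c)
    for group in groups.values():
        freqs = np.array([c.frequency for c in group])
        for c in group:
            c.empirical_p = float((freqs >= c.frequency).sum()) / len(group)
    return list(calls)


def shared_umi_cooccurrence(pileup: Pileup,
                            calls: Sequence[VariantCall],
                            min_shared: int = 1):
    """Pairs of called variants supported by the same UMIs.

    Reported as-is (no statistical test): co-occurrence of two variants in
    the same molecules is a capability of UMI data worth surfacing, but
    phasing inference is out of scope.
    """
    keyed = {}
    for c in calls:
        if c.kind == "substitution":
            keyed[(c.reference_name, c.local_pos, c.alt)] = c
    rows = []
    items = sorted(keyed)
    for i, k1 in enumerate(items):
        u1 = pileup.variant_umis.get(k1, set())
        for k2 in items[i + 1:]:
            shared = u1 & pileup.variant_umis.get(k2, set())
            if len(shared) >= min_shared:
                c1, c2 = keyed[k1], keyed[k2]
                rows.append({
                    "contig": c1.contig,
                    "pos1": c1.pos, "alt1": c1.alt,
                    "pos2": c2.pos, "alt2": c2.alt,
                    "shared_umis": len(shared),
                    "count1": c1.count, "count2": c2.count,
                })
    return rows


# ---------------------------------------------------------------------------
# VCF 4.2 output

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=umicall
##INFO=<ID=DP,Number=1,Type=Integer,Description="Consensus coverage N">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Consensus count supporting ALT">
##INFO=<ID=AF,Number=1,Type=Float,Description="ALT frequency AD/DP">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Complement-collapsed substitution class">
##INFO=<ID=EMPP,Number=1,Type=Float,Description="Rank-based empirical P within class (diagnostic)">
##FILTER=<ID=LOWQ,Description="Q below threshold">
##FILTER=<ID=NO_QUAL,Description="Indel call; no quality model">
##QUAL=<Description="Beta-Binomial Q score, capped at 100; raw, no multiple-testing correction">
"""


def write_vcf(calls: Sequence[VariantCall], path,
              library: Optional[ReferenceLibrary] = None):
    """Deterministic VCF 4.2: identical calls yield a byte-identical body."""
    lines = [_VCF_HEADER]
    if library is not None:
        seen = []
        for rec in library.records:
            contig = rec.contig or rec.name
            if contig not in seen:
                seen.append(contig)
                lines.append(f"##contig=<ID={contig}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for c in sorted(calls, key=lambda c: (c.contig, c.pos, c.ref, c.alt)):
        qual = "." if c.q is None else f"{c.q:.2f}"
        info = [f"DP={c.coverage}", f"AD={c.count}", f"AF={c.frequency:.6g}"]
        if c.substitution_class:
            info.append(f"CLASS={c.substitution_class.replace('>', '_')}")
        if c.empirical_p is not None:
            info.append(f"EMPP={c.empirical_p:.6g}")
        lines.append(f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{qual}\t"
                     f"{c.filter}\t{';'.join(info)}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_vcf(path) -> List[VariantCall]:
    """Parse a VCF written by `write_vcf` back into calls (round-trip)."""
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            for alt in rec.alts:
                kind = ("substitution" if len(rec.ref) == 1 and len(alt) == 1
                        else "insertion" if len(alt) > len(rec.ref)
                        else "deletion")
                cls = info.get("CLASS")
                calls.append(VariantCall(
                    contig=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    kind=kind, frequency=float(info["AF"]),
                    count=int(info["AD"]), coverage=int(info["DP"]),
                    q=rec.qual,
                    substitution_class=(cls.replace("_", ">") if cls else ""),
                    empirical_p=(float(info["EMPP"])
                                 if "EMPP" in info else None),
                    filter=list(rec.filter)[0] if rec.filter else "PASS"))
    return calls
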