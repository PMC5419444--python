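"""End-to-end driver: FASTQ -> tagged reads -> MIGs -> consensuses -> SAM -> VCF."""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

from . import aligner, caller, error_model, mig, preprocess


@dataclass
class PipelineOptions:
    max_primer_mismatches: int = 2
    min_umi_qual: int = 20
    min_mig_size: Optional[int] = None      # None = auto (sqrt of size peak)
    size_floor: int = 5
    q_minor: int = 30
    preset: str = "illumina"
    k: int = 11
    min_identity: float = 0.90
    min_span: float = 0.70
    min_q: float = 0.0                      # calls below go to LOWQ, kept
    ligation: bool = False
    pcr_efficiency: float = 1.8
    merge_collisions: bool = False


@dataclass
class PipelineResult:
    calls: List[caller.VariantCall]
    indel_calls: List[caller.VariantCall]
    pileup: caller.Pileup
    consensuses: list
    n_reads: int = 0
    n_tagged: int = 0
    n_migs: int = 0
    n_migs_discarded: int = 0
    size_threshold: int = 0
    n_consensuses: int = 0
    n_aligned: int = 0
    sam_path: str = ""

    @property
    def all_calls(self) -> List[caller.VariantCall]:
        return list(self.calls) + list(self.indel_calls)


def run_pipeline(reads: Iterable[preprocess.FastqRead],
                 patterns: Sequence[preprocess.PrimerPattern],
                 library: aligner.ReferenceLibrary,
                 options: Optional[PipelineOptions] = None,
                 model: Optional[error_model.SubstitutionErrorModel] = None,
                 workdir: Optional[str] = None) -> PipelineResult:
    """Run extraction, assembly, alignment and calling in sequence.

    `workdir` receives the intermediate SAM (a temp directory otherwise);
    the error model defaults to the shipped per-class parameters, with the
    ligation adjustment applied when requested.
    """
    opt = options or PipelineOptions()
    if model is None:
        model = error_model.SubstitutionErrorModel.default()
    if opt.ligation:
        model = error_model.adjust_for_ligation(model, opt.pcr_efficiency)

    reads = list(reads)
    extraction = preprocess.extract_reads(
        reads, patterns, opt.max_primer_mismatches, opt.min_umi_qual)

    migs = mig.group_migs(extraction.tagged)
    migs, discarded = mig.correct_umi_collisions(
        migs, merge=opt.merge_collisions)
    threshold = (opt.min_mig_size if opt.min_mig_size is not None
                 else mig.compute_size_threshold(migs, floor=opt.size_floor)
                 if migs else opt.size_floor)
    assembly = mig.assemble_all(migs, size_threshold=threshold,
                                q_minor=opt.q_minor, preset=opt.preset)

    index = aligner.KmerIndex.build(library, k=opt.k)
    hits = []
    for cons in assembly.consensuses:
        name = f"{cons.umi}" + ("" if cons.mate_index == 0 else "/2")
        hit = aligner.align_query(
            name, cons.sequence, index, library,
            qualities=cons.cqs_scores.astype(int),
            tags={"UM": cons.umi, "MS": cons.reads_used})
        if hit is None:
            continue
        if aligner.filter_alignment(hit, opt.min_identity, opt.min_span):
            hits.append(hit)

    owns_tmp = workdir is None
    tmpdir = tempfile.mkdtemp(prefix="umicall_") if owns_tmp else workdir
    sam_path = os.path.join(tmpdir, "consensus.sam")
    aligner.write_sam(hits, library, sam_path)

    pileup = caller.build_pileup(sam_path, library)
    calls = caller.call_substitutions(pileup, model, library, min_q=opt.min_q)
    indels = caller.call_indels(pileup, library)
    caller.empirical_pvalue(calls)

    return PipelineResult(
        calls=calls, indel_calls=indels, pileup=pileup,
        consensuses=assembly.consensuses,
        n_reads=len(reads), n_tagged=len(extraction.tagged),
        n_migs=len(migs) + len(discarded), n_migs_discarded=len(discarded),
        size_threshold=threshold, n_consensuses=len(assembly.consensuses),
        n_aligned=len(hits), sam_path=sam_path)
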