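"""Synthetic UMI-tagged amplicon datasets with a machine-readable truth set.

The generator emulates the full molecular history of a targeted UMI
experiment: template molecules drawn per locus (each carrying configured
variants with binomial sampling), a distinct random UMI per molecule,
branching-process PCR (each molecule duplicates per cycle with probability
efficiency - 1; each duplication introduces a substitution error with a
per-base rate, and every error's lineage is tracked), and quality-profiled
sequencing reads sampled from each molecule's amplified pool with a
log-normal reads-per-molecule (MIG size) distribution.

Reads are laid out as UMI + locus primer + template insert, matching the
pattern syntax of the preprocess module, so simulator output feeds the
pipeline end to end. What the generator does not emulate: polymerase
sequence-context effects, chimeras/primer dimers, and flow-space
(homopolymer) error structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dna import BASES
from .preprocess import FastqRead

POOL_CAP = 10 ** 7

#: Built-in toy panel: three synthetic 200-base "exon" references. The
#: first 20 bases of each act as the locus primer; the UMI is prepended
#: to the primer on every read.
TOY_PANEL: Dict[str, str] = {
    "EX1": ("TTAACTTCCGTTAGAACTATTGCGAAACTTCAAATCACAGTCTGTTCCAACGCCGCGACAGCAGGCCAAGGATGCATGGGAAGGACATAACTGCGTTCCC"
            "TAAATTTTAGCGATATACAGTGCCATCACTAAGTAGTGGCGCCCACGCAAATGGCCCACCCGCCGCGTGCATATCCCTAAATTGTTTAACCTTCTGGACC"),
    "EX2": ("CATATAAGATCTTTTTTTGACTACTTGTTCAGTGGCAAAGGGTTGGGGTTTCTGTCGCTGAGTGGGTCGGCCTCGATTTAGAGTTTTCGCCTTCGGTTAG"
            "CGGATGGGAGAACATTTAGAGCGTACTCAAGCTAATTTCTTATCTTACATTGCCTCGGTATTTTCAGTGGAGACTAAGTATTGTAATATTAGCAAACTCG"),
    "EX3": ("ATATACTCCTTAGTTTTAGACGCTCTGATGTACATCGGCCCTACCCCGTGCGGATCGCTTTGGATATAAATTCTTTTGACCCCTTCTCTTTGCCAGGGCG"
            "GGCATTTCGTATAGAAAAGGCTATGGTTTATTAGAAGATCCCTTTCCGGGTCGCAGCAGTACTAGGCGGTGGGGGTGGCAACGCGCACGATCTTCCACTC"),
}

PRIMER_LENGTH = 20


@dataclass(frozen=True)
class Variant:
    locus: str
    position: int                   # 0-based on the reference sequence
    ref: str
    alt: str
    frequency: float


@dataclass
class SimConfig:
    seed: int                       # mandatory for reproducibility
    references: Dict[str, str] = field(default_factory=lambda: dict(TOY_PANEL))
    molecules_per_locus: int = 1000
    umi_length: int = 12
    variants: Sequence[Variant] = ()
    pcr_cycles: int = 20
    pcr_efficiency: float = 1.8
    pcr_error_rate: float = 1e-5    # per base per duplication
    read_length: int = 140
    phred: int = 30                 # flat per-base quality profile
    mig_size_median: float = 10.0
    mig_size_sigma: float = 0.5
    indels: Sequence[Tuple[str, int, int, float]] = ()  # (locus, pos, del_len, freq)

    def __post_init__(self):
        if not (1.0 < self.pcr_efficiency <= 2.0):
            raise ValueError("PCR efficiency must lie in (1, 2]")
        for v in self.variants:
            if not (0.0 < v.frequency <= 1.0):
                raise ValueError(f"variant frequency {v.frequency} outside (0, 1]")
            if self.references[v.locus][v.position] != v.ref:
                raise ValueError(
                    f"variant {v}: reference base is "
                    f"{self.references[v.locus][v.position]}")

    @property
    def insert_length(self) -> int:
        return self.read_length - self.umi_length - PRIMER_LENGTH

    def patterns(self):
        """Primer patterns matching the simulated read layout."""
        from .preprocess import parse_pattern
        return [parse_pattern("N" * self.umi_length + seq[:PRIMER_LENGTH],
                              "forward", name=locus, sample_label=locus)
                for locus, seq in self.references.items()]


@dataclass
class Molecule:
    index: int
    locus: str
    umi: str
    variants: Tuple[Variant, ...]
    deletion: Optional[Tuple[int, int]] = None   # (pos, length)


def _random_umis(n: int, length: int, rng: np.random.Generator) -> List[str]:
    if 4 ** length < n:
        raise ValueError(f"UMI space 4^{length} cannot hold {n} molecules")
    umis: set = set()
    arr = np.array(list(BASES))
    while len(umis) < n:
        block = ["".join(arr[rng.integers(0, 4, length)])
                 for _ in range(n - len(umis))]
        umis.update(block)
    return sorted(umis)


def simulate_molecules(config: SimConfig,
                       rng: np.random.Generator) -> List[Molecule]:
    """Draw tagged template molecules per locus.

    Each molecule carries each configured variant independently with its
    frequency (binomial sampling across molecules); every molecule gets a
    distinct random UMI.
    """
    total = config.molecules_per_locus * len(config.references)
    umis = _random_umis(total, config.umi_length, rng)
    rng.shuffle(umis)
    molecules = []
    i = 0
    for locus in config.references:
        loc_vars = [v for v in config.variants if v.locus == locus]
        loc_dels = [d for d in config.indels if d[0] == locus]
        for _ in range(config.molecules_per_locus):
            carried = tuple(v for v in loc_vars
                            if rng.random() < v.frequency)
            deletion = None
            for _, pos, ln, freq in loc_dels:
                if rng.random() < freq:
                    deletion = (pos, ln)
                    break
            molecules.append(Molecule(i, locus, umis[i], carried, deletion))
            i += 1
    return molecules


@dataclass
class AmplifiedPool:
    """Final PCR pool of one molecule, as error-lineage classes.

    `lineages[i]` is a tuple of (position, alt_base) substitution errors
    (template coordinates) shared by `counts[i]` molecules; lineage () is
    the error-free class. Memory stays linear in the number of error
    events, not pool size.
    """
    lineages: List[Tuple[Tuple[int, str], ...]]
    counts: np.ndarray
    capped: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def pcr_branching(template_length: int, cycles: int, efficiency: float,
                  error_rate: float, rng: np.random.Generator,
                  pool_cap: int = POOL_CAP) -> AmplifiedPool:
    """Galton-Watson PCR amplification of one molecule.

    Each molecule duplicates per cycle with probability efficiency - 1;
    each duplication introduces at most one substitution error with
    probability 1 - (1 - error_rate)^template_length (multiple errors in a
    single duplication are neglected — second order in the rate). New
    error lineages inherit their parent's error list.
    """
    lam = efficiency - 1.0
    if not (0.0 < lam <= 1.0):
        raise ValueError("PCR efficiency must lie in (1, 2]")
    p_err = 1.0 - (1.0 - error_rate) ** template_length
    lineages: List[Tuple[Tuple[int, str], ...]] = [()]
    counts = [1]
    capped = False
    for _ in range(cycles):
        arr = np.array(counts, dtype=np.int64)
        dups = rng.binomial(arr, lam)
        n_err = rng.binomial(dups, p_err) if p_err > 0 else np.zeros_like(dups)
        arr = arr + dups - n_err
        counts = arr.tolist()
        for li in np.flatnonzero(n_err):
            for _ in range(int(n_err[li])):
                pos = int(rng.integers(0, template_length))
                alt = BASES[int(rng.integers(0, 3))]
                # pick among the three non-identical bases lazily: shift
                # past the template base at apply time (see _apply_errors)
                lineages.append(lineages[li] + ((pos, alt),))
                counts.append(1)
        if sum(counts) > pool_cap:
            capped = True
            break
    return AmplifiedPool(lineages, np.array(counts, dtype=np.int64), capped)


def _apply_errors(template: List[str],
                  errors: Tuple[Tuple[int, str], ...]) -> List[str]:
    if not errors:
        return template
    seq = list(template)
    for pos, alt in errors:
        cur = seq[pos]
        # `alt` is drawn from BASES[0:3]; remap so the substituted base is
        # never the current one and all three alternatives are equally
        # likely
        choices = [b for b in BASES if b != cur]
        seq[pos] = choices[BASES.index(alt) % 3]
    return seq


@dataclass
class TruthSet:
    molecules: List[dict]           # one row per molecule
    variant_truth: List[dict]       # realized per-variant molecule counts
    n_reads: int

    def molecules_to_tsv(self, path):
        import pandas as pd
        pd.DataFrame(self.molecules).to_csv(path, sep="\t", index=False)

    def variants_to_tsv(self, path):
        import pandas as pd
        pd.DataFrame(self.variant_truth).to_csv(path, sep="\t", index=False)


def _mig_size(config: SimConfig, rng: np.random.Generator) -> int:
    s = rng.lognormal(math.log(config.mig_size_median), config.mig_size_sigma)
    return max(1, int(round(s)))


def simulate_dataset(config: SimConfig,
                     molecules: Optional[List[Molecule]] = None):
    """Full generator: molecules -> PCR pools -> sequencing reads.

    Returns (reads, truth). Reads are FastqRead objects laid out as
    UMI + primer + insert; truth records every molecule (locus, UMI,
    carried variants, reads emitted) and realized variant frequencies.
    """
    rng = np.random.default_rng(config.seed)
    if molecules is None:
        molecules = simulate_molecules(config, rng)
    reads: List[FastqRead] = []
    mol_rows = []
    var_counts: Dict[Variant, int] = {v: 0 for v in config.variants}
    seq_err_p = 10.0 ** (-config.phred / 10.0)
    insert_len = config.insert_length
    if insert_len < 30:
        raise ValueError("read_length too short for UMI + primer + 30-base core")
    # flat quality profile: share one array across reads (never mutated)
    flat_quals = np.full(config.read_length, config.phred, dtype=np.int32)

    for mol in molecules:
        ref = config.references[mol.locus]
        template = list(ref)
        for v in mol.variants:
            template[v.position] = v.alt
            var_counts[v] += 1
        if mol.deletion is not None:
            dpos, dlen = mol.deletion
            template = template[:dpos] + template[dpos + dlen:]
        # insert = the sequenced window behind the primer
        insert_tpl = template[PRIMER_LENGTH:PRIMER_LENGTH + insert_len]
        pool = pcr_branching(len(insert_tpl), config.pcr_cycles,
                             config.pcr_efficiency, config.pcr_error_rate, rng)
        n_reads = _mig_size(config, rng)
        picks = rng.multinomial(n_reads, pool.counts / pool.total)
        emitted = 0
        for li in np.flatnonzero(picks):
            seq_list = _apply_errors(insert_tpl, pool.lineages[li])
            for _ in range(int(picks[li])):
                full = mol.umi + ref[:PRIMER_LENGTH] + "".join(seq_list)
                arr = list(full)
                n_seq_err = rng.binomial(len(arr), seq_err_p)
                for pos in rng.integers(0, len(arr), n_seq_err):
                    cur = arr[pos]
                    alts = [b for b in BASES if b != cur]
                    arr[pos] = alts[int(rng.integers(0, 3))]
                rid = f"mol{mol.index}:{mol.umi}:{emitted}"
                reads.append(FastqRead(rid, "".join(arr), flat_quals))
                emitted += 1
        mol_rows.append({
            "molecule": mol.index, "locus": mol.locus, "umi": mol.umi,
            "variants": ";".join(f"{v.position}{v.ref}>{v.alt}"
                                 for v in mol.variants) or ".",
            "deletion": (f"{mol.deletion[0]}-{mol.deletion[0]+mol.deletion[1]}"
                         if mol.deletion else "."),
            "n_reads": emitted,
        })
    variant_truth = []
    for v, n in var_counts.items():
        variant_truth.append({
            "locus": v.locus, "position": v.position, "ref": v.ref,
            "alt": v.alt, "configured_frequency": v.frequency,
            "molecules": n,
            "realized_frequency": n / config.molecules_per_locus,
        })
    truth = TruthSet(mol_rows, variant_truth, len(reads))
    return reads, truth


def first_cycle_error_share(lam: float, cycles: int = 20,
                            n_replicates: int = 10 ** 5,
                            rng: Optional[np.random.Generator] = None):
    """Monte-Carlo pooled share of first-cycle-error strands: oracle for g.

    A ligation-tagged molecule contributes two template strands carrying
    the same UMI. In cycle 1 a designated strand is copied with
    probability lambda and that copy carries the error; the sibling strand
    is copied independently. Every strand then duplicates per cycle with
    probability lambda. The estimator is the ratio of Monte-Carlo means
    sum(mutant strands) / sum(all strands) over replicates, whose
    expectation equals lambda / (2(1+lambda)) at every cycle count; the
    returned SE is the delta-method standard error of that ratio.
    """
    if not (0.0 < lam <= 1.0):
        raise ValueError("lambda must lie in (0, 1]")
    if cycles * math.log2(1 + lam) > 48:
        raise ValueError("cycle count would overflow the strand counters")
    rng = rng if rng is not None else np.random.default_rng()
    m = (rng.random(n_replicates) < lam).astype(np.int64)
    w = 2 + (rng.random(n_replicates) < lam).astype(np.int64)
    for _ in range(cycles - 1):
        m += rng.binomial(m, lam)
        w += rng.binomial(w, lam)
    t = m + w
    share = m.sum() / t.sum()
    resid = m - share * t
    se = math.sqrt(resid.var(ddof=1) / n_replicates) / t.mean()
    return float(share), float(se)


def write_fastq_and_truth(config: SimConfig, fastq_path, truth_prefix=None):
    """CLI entry: simulate and write FASTQ plus truth TSVs."""
    from .preprocess import write_fastq
    reads, truth = simulate_dataset(config)
    write_fastq(reads, fastq_path)
    if truth_prefix is not None:
        truth.molecules_to_tsv(f"{truth_prefix}.molecules.tsv")
        truth.variants_to_tsv(f"{truth_prefix}.variants.tsv")
    return truth
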