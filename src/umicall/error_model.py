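"""Beta-Binomial PCR substitution-error model.

After UMI consensus assembly, virtually all sequencing errors are gone
(a Phred-20 read set with a 5-read MIG threshold leaves a ~1e-5 chance of
an error dominating a consensus), so the errors that remain in consensus
sequences were introduced by the polymerase during UMI attachment. Their
per-position rate eps_xy for each of six complement-collapsed substitution
classes (A>C/T>G, A>G/T>C, A>T/T>A, C>A/G>T, C>G/G>C, C>T/G>A) is modelled
as Beta(alpha_xy, beta_xy); the observed error count n at consensus
coverage N then follows BetaBinom(N, alpha_xy, beta_xy), and a variant's
quality is Q = -10*log10 P(X >= n), capped at 100 (P = 1e-10).

For ligation-based protocols the first PCR cycle, not the tagging
reaction, introduces the heritable errors; the class error rates are then
scaled by the probability-weighted share g(lambda) = lambda / (2(1+lambda))
of the final amplified pool that descends from a first-cycle copy, with
lambda = PCR efficiency - 1 (see `simdata.first_cycle_error_share` for the
branching-process validation of this factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log10
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

SUBSTITUTION_CLASSES = (
    "A>C/T>G", "A>G/T>C", "A>T/T>A", "C>A/G>T", "C>G/G>C", "C>T/G>A",
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

MAX_Q = 100.0

#: Shipped default (alpha, beta) per class. These are placeholders chosen
#: to reproduce the qualitative ordering of polymerase error spectra
#: (C>T/G>A and A>G/T>C transitions far above transversions), not fits to
#: any particular dataset; refit with `fit_beta` for production use.
DEFAULT_PARAMETERS: Dict[str, Tuple[float, float]] = {
    "A>C/T>G": (1.0, 8.0e5),
    "A>G/T>C": (2.0, 5.0e4),
    "A>T/T>A": (1.0, 1.0e6),
    "C>A/G>T": (1.0, 4.0e5),
    "C>G/G>C": (1.0, 9.0e5),
    "C>T/G>A": (2.0, 2.0e4),
}


def collapse_substitution(from_base: str, to_base: str) -> str:
    """Map a directed substitution x>y onto its complement-collapsed class."""
    x, y = from_base.upper(), to_base.upper()
    if x not in _COMP or y not in _COMP or x == y:
        raise ValueError(f"not a substitution: {from_base}>{to_base}")
    if x in "GT":
        x, y = _COMP[x], _COMP[y]
    for cls in SUBSTITUTION_CLASSES:
        if cls.startswith(f"{x}>{y}"):
            return cls
    raise AssertionError("unreachable")


@dataclass
class SubstitutionErrorModel:
    parameters: Dict[str, Tuple[float, float]]
    provenance: str = "default"     # fitted | default | adjusted

    def __post_init__(self):
        missing = set(SUBSTITUTION_CLASSES) - set(self.parameters)
        if missing:
            raise ValueError(f"missing classes: {sorted(missing)}")
        for cls, (a, b) in self.parameters.items():
            if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
                raise ValueError(f"class {cls}: alpha/beta must be finite > 0")

    @classmethod
    def default(cls) -> "SubstitutionErrorModel":
        return cls(dict(DEFAULT_PARAMETERS), "default")

    def rate(self, substitution_class: str) -> float:
        a, b = self.parameters[substitution_class]
        return a / (a + b)

    def params_for(self, from_base: str, to_base: str) -> Tuple[float, float]:
        return self.parameters[collapse_substitution(from_base, to_base)]

    # -- TSV round trip ---------------------------------------------------
    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("class\talpha\tbeta\tprovenance\n")
            for c in SUBSTITUTION_CLASSES:
                a, b = self.parameters[c]
                fh.write(f"{c}\t{a!r}\t{b!r}\t{self.provenance}\n")

    @classmethod
    def from_tsv(cls, path) -> "SubstitutionErrorModel":
        params, prov = {}, "fitted"
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                c, a, b, p = line.rstrip("\n").split("\t")
                params[c] = (float(a), float(b))
                prov = p
        return cls(params, prov)


def fit_beta(class_frequencies: Sequence[float],
             method: str = "moments") -> Tuple[float, float]:
    """Fit Beta(alpha, beta) to per-position error frequencies.

    Method of moments by default: with sample mean m and variance v,
    alpha = m*(m(1-m)/v - 1), beta = (1-m)*(m(1-m)/v - 1). Zeros carry
    information and are included. `method="mle"` refines the moment
    estimate by maximum likelihood (requires all frequencies in (0,1)).
    """
    x = np.asarray(class_frequencies, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 observations per class")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if v <= 0:
        raise ValueError("degenerate (constant) frequencies; cannot fit Beta")
    if v >= m * (1 - m):
        raise ValueError(
            "variance exceeds Beta support (v >= m(1-m)); pool more positions")
    common = m * (1 - m) / v - 1.0
    alpha, beta = m * common, (1 - m) * common
    if method == "mle":
        if np.any(x <= 0) or np.any(x >= 1):
            raise ValueError("MLE requires frequencies strictly inside (0, 1)")
        alpha, beta, _, _ = stats.beta.fit(x, alpha, beta, floc=0, fscale=1)
    elif method != "moments":
        raise ValueError(f"unknown method {method!r}")
    return float(alpha), float(beta)


def betabinom_tail_p(n: int, N: int, alpha: float, beta: float) -> float:
    """Inclusive upper tail P(X >= n) under BetaBinom(N, alpha, beta)."""
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if n == 0:
        return 1.0
    # chunked log-space summation of the pmf: the tail stays meaningful
    # far below double underflow of the plain survival function
    log_terms = []
    chunk = 512
    running_max = -np.inf
    for lo in range(n, N + 1, chunk):
        k = np.arange(lo, min(lo + chunk, N + 1))
        lp = stats.betabinom.logpmf(k, N, alpha, beta)
        log_terms.append(lp)
        running_max = max(running_max, float(lp.max()))
        if float(lp.max()) < running_max - 45.0:  # remaining mass negligible
            break
    from scipy.special import logsumexp
    logp = float(logsumexp(np.concatenate(log_terms)))
    return float(np.exp(min(logp, 0.0)))


def q_score(p: float) -> float:
    """Q = min(-10*log10 P, 100); P <= 0 is treated as underflow (Q=100)."""
    if p > 1.0 + 1e-12:
        raise ValueError("P must be <= 1")
    if p <= 0.0:
        return MAX_Q
    return min(-10.0 * log10(p), MAX_Q)


def propagation_factor(lam: float) -> float:
    """Share of the final PCR pool descending from a first-cycle copy.

    For a double-stranded (ligation-tagged) molecule amplified at
    efficiency 1+lambda, the expected number of first-cycle copies is
    lambda against an expected pool of 2(1+lambda) strands after cycle 1;
    both grow by (1+lambda) per later cycle, so the share
    g = lambda / (2(1+lambda)) holds at every cycle. A first-cycle error
    surfaces in a consensus in proportion to this share.
    """
    if not (0 < lam <= 1):
        raise ValueError("lambda = efficiency - 1 must lie in (0, 1]")
    return lam / (2.0 * (1.0 + lam))


@dataclass
class LigationAdjustment:
    pcr_efficiency: float

    def __post_init__(self):
        if not (1.0 < self.pcr_efficiency <= 2.0):
            raise ValueError("PCR efficiency must lie in (1, 2]")

    @property
    def lam(self) -> float:
        return self.pcr_efficiency - 1.0

    @property
    def factor(self) -> float:
        return propagation_factor(self.lam)


def adjust_for_ligation(model: SubstitutionErrorModel,
                        pcr_efficiency: float) -> SubstitutionErrorModel:
    """Scale class error rates by g(lambda) for ligation-attached UMIs.

    Implemented as beta := beta / g with alpha unchanged, which scales the
    mean alpha/(alpha+beta) ~= alpha/beta by g in the rare-error regime.
    Applying the adjustment twice is an error.
    """
    if model.provenance == "adjusted":
        raise ValueError("model already ligation-adjusted")
    g = LigationAdjustment(pcr_efficiency).factor
    params = {c: (a, b / g) for c, (a, b) in model.parameters.items()}
    return SubstitutionErrorModel(params, "adjusted")


def dominance_probability(p_err: float, mig_size: int) -> float:
    """P that a strict majority of `mig_size` reads share one erroneous base.

    Binomial upper tail at j >= ceil((m+1)/2): with Phred-20 data
    (p = 0.01) and the default 5-read threshold this is ~1e-5 — the
    theoretical ceiling for sequencing errors surviving consensus
    assembly.
    """
    if not (0 < p_err < 1):
        raise ValueError("p_err must lie in (0, 1)")
    if mig_size < 1:
        raise ValueError("mig_size must be >= 1")
    j = ceil((mig_size + 1) / 2)
    return float(stats.binom.sf(j - 1, mig_size, p_err))


@dataclass
class MinorRateEstimate:
    rates: Dict[str, float]
    low_confidence: bool
    mean_mig_size: float
    n_molecules: int
    note: str = ""


def estimate_from_minors(minor_counts, mean_mig_size: float,
                         n_molecules: int) -> Optional[MinorRateEstimate]:
    """Per-class error-rate estimates from within-MIG minor tallies.

    Minor variants are reads that disagreed with their consensus: products
    of early-cycle PCR errors that did not dominate. rate(class) =
    pooled minor count / read-base observations whose consensus base
    belongs to the class. The estimate is flagged low-confidence when the
    mean MIG size < 10 or fewer than 1000 molecules are available.
    """
    pooled = minor_counts.pooled_by_class()
    obs_by_base = minor_counts.observations
    if not obs_by_base or sum(obs_by_base.values()) == 0:
        return None
    comp = _COMP
    denom = {}
    for cls in SUBSTITUTION_CLASSES:
        frm = cls[0]
        denom[cls] = obs_by_base.get(frm, 0) + obs_by_base.get(comp[frm], 0)
    rates = {}
    for cls in SUBSTITUTION_CLASSES:
        n = pooled.get(cls, {}).get("minor_count", 0)
        rates[cls] = n / denom[cls] if denom[cls] else 0.0
    low = mean_mig_size < 10 or n_molecules < 1000
    note = ("requires high sequencing quality, many molecules and large MIGs"
            if low else "")
    return MinorRateEstimate(rates, low, mean_mig_size, n_molecules, note)
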