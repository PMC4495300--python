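"""The three-cycle binomial significance model for motif over-representation.

Each candidate motif is scored by three rounds of the cumulative binomial
``f(k+; n; p)`` — the probability of ``k`` or more successes in ``n``
independent trials of probability ``p``:

1. **p1+** — per unrelated protein cluster (UPC), the probability that the
   motif occurs at least once, ``f(1+; sites; p_site)``, where ``p_site`` is
   the product over defined positions of the summed frequencies of allowed
   residues (wildcards contribute 1) and ``sites`` counts the positions in
   the cluster where the motif's footprint fits in unmasked sequence.
2. **Prob** — the probability of the observed (or greater) UPC support,
   ``f(k+; n_upc; mean p1+)``.
3. **Sig** — the probability that *any* motif in the searched space attains
   an equal or smaller Prob, ``f(1+; M; Prob) = 1 - (1 - Prob)**M``, with
   ``M`` the motif space size for the motif's defined length.

A query-restricted search pays for its reduced motif space by sacrificing
the query occurrence: support becomes ``k-1`` over ``n-1`` clusters, with
the query cluster removed from every average.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import bdtrc, gammaln

from .seqdata import AMINO_ACIDS, MaskedSequence
from .slimbuild import Motif

logger = logging.getLogger(__name__)


class ChanceError(ValueError):
    """Invalid input to a significance calculation."""


def cumulative_binomial(k: int, n: int, p: float) -> float:
    """``f(k+; n; p)``: probability of ``k`` or more successes in ``n`` trials.

    ``k <= 0`` returns 1 and ``k > n`` returns 0.  For ``k = 1`` this reduces
    to ``1 - (1 - p)**n``.  Extreme tails that underflow the direct
    computation are recovered in log space.
    """
    if not 0.0 <= p <= 1.0:
        raise ChanceError(f"success probability {p} outside [0, 1]")
    if n < 0:
        raise ChanceError("n must be >= 0")
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    value = float(bdtrc(k - 1, n, p))
    if value == 0.0 and p > 0.0:
        value = _log_space_tail(k, n, p)
    return min(1.0, max(0.0, value))


def _log_space_tail(k: int, n: int, p: float) -> float:
    log_p = math.log(p)
    log_q = math.log1p(-p) if p < 1.0 else -math.inf
    terms = []
    for i in range(k, min(n, k + 400) + 1):
        log_c = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        terms.append(log_c + i * log_p + (n - i) * log_q)
    top = max(terms)
    if top == -math.inf:
        return 0.0
    return math.exp(top) * sum(math.exp(t - top) for t in terms)


def aa_frequencies(masked_seqs: Sequence[MaskedSequence]) -> dict[str, float]:
    """Amino-acid frequencies over the unmasked residues of a dataset.

    Masked residues (``X``) are excluded and the remainder renormalised.
    """
    counts: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for m in masked_seqs:
        for c in m.masked_string:
            if c in counts:
                counts[c] += 1
                total += 1
    if total == 0:
        raise ChanceError("no unmasked residues; cannot estimate frequencies")
    return {aa: c / total for aa, c in counts.items()}


def site_probability(motif: Motif, aa_freqs: Mapping[str, float]) -> float:
    """Per-site occurrence probability: product over defined positions of the
    summed frequencies of allowed residues (wildcards contribute factor 1)."""
    p = 1.0
    for pos in motif.positions:
        factor = sum(aa_freqs.get(aa, 0.0) for aa in pos)
        if factor <= 0.0:
            logger.warning(
                "motif %s has a defined position with zero total frequency; "
                "site probability is 0", motif.pattern
            )
            return 0.0
        p *= factor
    return p


def upc_p1(p_site: float, sites: int) -> float:
    """``f(1+; sites; p_site)`` — probability of at least one occurrence."""
    if sites < 0:
        raise ChanceError("site count must be >= 0")
    if sites == 0 or p_site <= 0.0:
        return 0.0
    if p_site >= 1.0:
        return 1.0
    return -math.expm1(sites * math.log1p(-p_site))


def upc_site_count(members: Sequence[MaskedSequence], span: int) -> int:
    """Number of positions in a UPC where a motif footprint of ``span``
    residues fits within unmasked sequence.

    Per member sequence this sums ``max(0, segment - span + 1)`` over maximal
    unmasked segments; the cluster's count is the maximum over its members,
    since homologous members largely duplicate each other's content.
    """
    if span < 1:
        raise ChanceError("span must be >= 1")
    best = 0
    for m in members:
        total = sum(max(0, seg - span + 1) for seg in m.segment_lengths())
        best = max(best, total)
    return best


def support_probability(k: int, p1_list: Sequence[float]) -> float:
    """``f(k+; n; mean p1+)`` — probability of the observed (or greater)
    UPC support, with ``n`` the number of UPCs."""
    if not p1_list:
        if k >= 1:
            raise ChanceError("no UPCs but positive support required")
        return 1.0
    if k > len(p1_list):
        raise ChanceError(f"support {k} exceeds number of UPCs {len(p1_list)}")
    mean_p1 = float(np.mean(p1_list))
    return cumulative_binomial(k, len(p1_list), mean_p1)


def significance(prob: float, M: int) -> float:
    """``Sig = 1 - (1 - Prob)**M`` — the motif-space multiple-testing
    correction, computed stably for tiny ``Prob`` and huge ``M``."""
    if M < 1:
        raise ChanceError("motif space M must be >= 1")
    if not 0.0 <= prob <= 1.0:
        raise ChanceError(f"Prob {prob} outside [0, 1]")
    if prob == 0.0:
        return 0.0
    if prob == 1.0:
        return 1.0
    return min(1.0, -math.expm1(M * math.log1p(-prob)))


def query_adjust(
    k: int, n: int, query_in_support: bool = True
) -> tuple[int, int]:
    """Remove the query cluster from the support bookkeeping.

    A query-restricted candidate necessarily occurs in the query, so the
    adjusted numbers are ``k-1`` occurrences over ``n-1`` clusters (e.g.
    support 7 of 74 becomes 6 of 73).
    """
    if k < 1:
        raise ChanceError(
            "query-restricted candidates must occur in the query (k >= 1)"
        )
    if not query_in_support:
        raise ChanceError(
            "motif absent from the query cluster is not a candidate"
        )
    if n < 1:
        raise ChanceError("n must be >= 1")
    return k - 1, n - 1


@dataclass(frozen=True)
class ChanceInputs:
    """Everything the three binomial cycles need for one motif."""

    aa_freqs: Mapping[str, float]
    site_counts: tuple[int, ...]
    k: int
    n: int
    M: int

    def __post_init__(self) -> None:
        total = sum(self.aa_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ChanceError(f"amino-acid frequencies sum to {total}, not 1")
        if not 0 <= self.k <= self.n:
            raise ChanceError(f"support k={self.k} outside [0, n={self.n}]")
        if self.n != len(self.site_counts):
            raise ChanceError("one site count per UPC required")
        if self.M < 1:
            raise ChanceError("M must be >= 1")
        if any(c < 0 for c in self.site_counts):
            raise ChanceError("negative site count")


@dataclass(frozen=True)
class SignificanceResult:
    """The intermediate and final probabilities for one motif."""

    p_site: float
    p1_per_upc: tuple[float, ...]
    mean_p1: float
    prob: float
    sig: float


def score_motif(motif: Motif, inputs: ChanceInputs) -> SignificanceResult:
    """Run the full three-cycle calculation for one motif."""
    p_site = site_probability(motif, inputs.aa_freqs)
    p1 = tuple(upc_p1(p_site, c) for c in inputs.site_counts)
    mean_p1 = float(np.mean(p1)) if p1 else 0.0
    prob = support_probability(inputs.k, p1)
    sig = significance(prob, inputs.M)
    return SignificanceResult(p_site, p1, mean_p1, prob, sig)
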