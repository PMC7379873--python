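"""Hybridization detection from quartet site patterns.

For an ordered quartet (outgroup, P1, putative hybrid H, P2) the admixture
proportion γ measures how much of the hybrid genome derives from P2: a
50:50 hybrid sits near γ = 0.5, while γ near 0 (resp. 1) indicates a taxon
close to P1 (resp. P2) — a signal that can also arise from incomplete
lineage sorting or ancient gene flow rather than recent hybridization.

The estimator counts polarized biallelic site patterns.  A site is
informative when P1 and P2 carry different alleles, the outgroup matches
one of them, and H matches one of P1/P2; then

    γ̂ = n_concordant_P2 / (n_concordant_P1 + n_concordant_P2).

Significance of an admixture signal (null: γ ∈ {0, 1}, i.e. the hybrid is
effectively one of the parents) is assessed with an exact binomial test of
the minority pattern count against a small boundary proportion, Bonferroni
corrected across all tested triples.  Significant γ̂ values are then binned
into event classes: 0.4–0.6 recent hybridization, 0.1–0.4 and 0.6–0.9
older (intermediate) events; significant values below 0.1 or above 0.9 are
excluded as likely ILS/ancient signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.base import BaseEstimator

from .reduce import iupac_expand

__all__ = [
    "QuartetPatternCounts",
    "QuartetGammaResult",
    "GammaEstimator",
    "count_site_patterns",
    "estimate_gamma",
    "classify_event",
    "run_combinations",
]

NUCLEOTIDES = frozenset("ACGT")

EVENT_CLASSES = (
    "recent",
    "intermediate_low",
    "intermediate_high",
    "excluded",
    "nonsignificant",
    "undefined",
)


@dataclass
class QuartetPatternCounts:
    """Polarized biallelic site-pattern counts for one ordered quartet."""

    n_concordant_p1: int
    n_concordant_p2: int
    n_uninformative: int
    total_sites: int

    def __post_init__(self) -> None:
        if min(self.n_concordant_p1, self.n_concordant_p2, self.n_uninformative) < 0:
            raise ValueError("pattern counts must be non-negative")
        if self.n_concordant_p1 + self.n_concordant_p2 + self.n_uninformative != self.total_sites:
            raise ValueError("pattern counts do not sum to total_sites")

    @property
    def n_informative(self) -> int:
        return self.n_concordant_p1 + self.n_concordant_p2

    def __add__(self, other: "QuartetPatternCounts") -> "QuartetPatternCounts":
        return QuartetPatternCounts(
            self.n_concordant_p1 + other.n_concordant_p1,
            self.n_concordant_p2 + other.n_concordant_p2,
            self.n_uninformative + other.n_uninformative,
            self.total_sites + other.total_sites,
        )


@dataclass
class QuartetGammaResult:
    """γ̂ with its significance test and event class for one (P1, H, P2)."""

    p1: str
    hybrid: str
    p2: str
    counts: QuartetPatternCounts
    gamma: Optional[float]
    p_value: Optional[float]
    significant: Optional[bool] = None
    event_class: str = "undefined"
    reason: str = ""


def _resolve_site(bases: Sequence[str], rng: Optional[np.random.Generator]) -> Optional[Tuple[str, ...]]:
    """Resolve IUPAC codes by sampling one allele per row; None drops the site."""
    resolved = []
    for b in bases:
        b = b.upper()
        if b in NUCLEOTIDES:
            resolved.append(b)
            continue
        try:
            alleles = sorted(iupac_expand(b))
        except KeyError:
            return None
        if len(alleles) == 4 and b in "NX":
            return None  # fully ambiguous / missing
        if rng is None:
            return None
        resolved.append(alleles[rng.integers(len(alleles))])
    return tuple(resolved)


def count_site_patterns(
    out_seq: str,
    p1_seq: str,
    h_seq: str,
    p2_seq: str,
    rng: Optional[np.random.Generator] = None,
) -> QuartetPatternCounts:
    """Count polarized site patterns over four aligned sequence rows.

    A site is informative when P1 ≠ P2 (both unambiguous after resolution),
    the outgroup carries the allele of exactly one parent, and the hybrid
    carries the allele of exactly one parent.  IUPAC-coded (heterozygous)
    sites are resolved by sampling one allele uniformly per row when an
    ``rng`` is supplied, otherwise such sites are uninformative.
    """
    n = len(out_seq)
    if not (len(p1_seq) == len(h_seq) == len(p2_seq) == n):
        raise ValueError("quartet rows must have equal length")
    n_p1 = n_p2 = n_unin = 0
    for o, a, h, b in zip(out_seq, p1_seq, h_seq, p2_seq):
        site = _resolve_site((o, a, h, b), rng)
        if site is None:
            n_unin += 1
            continue
        o, a, h, b = site
        if a == b or o not in (a, b) or h not in (a, b):
            n_unin += 1
        elif h == a:
            n_p1 += 1
        else:
            n_p2 += 1
    return QuartetPatternCounts(n_p1, n_p2, n_unin, n)


def boundary_p_value(counts: QuartetPatternCounts, null_boundary: float) -> Optional[float]:
    """Exact binomial p-value for the minority pattern count exceeding the boundary null."""
    n = counts.n_informative
    if n == 0:
        return None
    k_min = min(counts.n_concordant_p1, counts.n_concordant_p2)
    return binomtest(k_min, n, null_boundary, alternative="greater").pvalue


def classify_event(gamma: Optional[float], significant: Optional[bool]) -> str:
    """Bin a γ̂ estimate into the hybridization event classes.

    Significant 0.4 ≤ γ̂ ≤ 0.6 → recent; 0.1 ≤ γ̂ < 0.4 → intermediate_low;
    0.6 < γ̂ ≤ 0.9 → intermediate_high; significant γ̂ < 0.1 or > 0.9 →
    excluded; non-significant results → nonsignificant.
    """
    if gamma is None:
        return "undefined"
    if not significant:
        return "nonsignificant"
    if 0.4 <= gamma <= 0.6:
        return "recent"
    if 0.1 <= gamma < 0.4:
        return "intermediate_low"
    if 0.6 < gamma <= 0.9:
        return "intermediate_high"
    return "excluded"


class GammaEstimator(BaseEstimator):
    """Estimate the admixture proportion γ from quartet site patterns.

    ``fit`` accepts either a :class:`QuartetPatternCounts` or four aligned
    sequence rows ``(out, p1, h, p2)``; fitted attributes are ``gamma_``,
    ``p_value_``, ``counts_`` and, after significance gating,
    ``event_class_``.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level applied after multiple-testing correction.
    null_boundary : float, default 0.02
        Null proportion for the boundary binomial test: under "no admixture
        signal" the minority pattern class is expected at most at this rate
        (sequencing noise / stray ILS).
    n_tests : int, default 1
        Bonferroni divisor; set to the number of triples tested jointly.
    seed : int or None
        Seed for resolving IUPAC-coded sites by allele sampling.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        null_boundary: float = 0.02,
        n_tests: int = 1,
        seed: Optional[int] = None,
    ):
        self.alpha = alpha
        self.null_boundary = null_boundary
        self.n_tests = n_tests
        self.seed = seed

    def fit(self, X, y=None) -> "GammaEstimator":
        if isinstance(X, QuartetPatternCounts):
            counts = X
        else:
            out_seq, p1_seq, h_seq, p2_seq = X
            rng = np.random.default_rng(self.seed)
            counts = count_site_patterns(out_seq, p1_seq, h_seq, p2_seq, rng=rng)
        self.counts_ = counts
        if counts.n_informative == 0:
            self.gamma_ = None
            self.p_value_ = None
            self.significant_ = None
            self.event_class_ = "undefined"
            self.reason_ = "zero_informative_sites"
            return self
        self.gamma_ = counts.n_concordant_p2 / counts.n_informative
        self.p_value_ = boundary_p_value(counts, self.null_boundary)
        corrected_alpha = self.alpha / max(self.n_tests, 1)
        self.significant_ = self.p_value_ <= corrected_alpha
        self.event_class_ = classify_event(self.gamma_, self.significant_)
        self.reason_ = ""
        return self

    def result(self, p1: str = "P1", hybrid: str = "H", p2: str = "P2") -> QuartetGammaResult:
        return QuartetGammaResult(
            p1=p1,
            hybrid=hybrid,
            p2=p2,
            counts=self.counts_,
            gamma=self.gamma_,
            p_value=self.p_value_,
            significant=self.significant_,
            event_class=self.event_class_,
            reason=self.reason_,
        )


def estimate_gamma(
    counts: QuartetPatternCounts,
    alpha: float = 0.05,
    null_boundary: float = 0.02,
    n_tests: int = 1,
) -> QuartetGammaResult:
    """Functional wrapper: γ̂, boundary test and event class from counts."""
    return GammaEstimator(alpha=alpha, null_boundary=null_boundary, n_tests=n_tests).fit(counts).result()


# ---------------------------------------------------------------------------
# Combination runner
# ---------------------------------------------------------------------------


def _pooled_counts(
    sequences: Mapping[str, str],
    out_ids: Sequence[str],
    p1_ids: Sequence[str],
    h_ids: Sequence[str],
    p2_ids: Sequence[str],
    rng: np.random.Generator,
) -> QuartetPatternCounts:
    """Sum pattern counts over all individual combinations of a taxon triple."""
    total = QuartetPatternCounts(0, 0, 0, 0)
    for o, a, h, b in itertools.product(out_ids, p1_ids, h_ids, p2_ids):
        total = total + count_site_patterns(
            sequences[o], sequences[a], sequences[h], sequences[b], rng=rng
        )
    return total


def run_combinations(
    sequences: Mapping[str, str],
    assignment: Mapping[str, str],
    outgroup: str,
    mode: str = "taxon",
    alpha: float = 0.05,
    null_boundary: float = 0.02,
    seed: Optional[int] = None,
    input_type: str = "sequence",
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Test every (P1, hybrid, P2) combination for admixture.

    Parameters
    ----------
    sequences
        Aligned rows per individual id (complete sequences or a
        one-character-per-site uSNP matrix rendered as strings).
    assignment
        Individual id -> taxon name; every individual must be assigned.
    outgroup
        Taxon name used to polarize site patterns; excluded from triples.
    mode
        ``"taxon"`` pools individuals per taxon before counting;
        ``"individual"`` tests every individual as its own entity.

    Returns the per-triple results table and a summary dict (counts per
    event class and mean γ̂ over significant events).  Triples are
    enumerated up to the P1 ↔ P2 symmetry (γ ↔ 1 − γ).
    """
    if mode not in ("taxon", "individual"):
        raise ValueError("mode must be 'taxon' or 'individual'")
    unknown = set(assignment) - set(sequences)
    if unknown:
        raise ValueError(f"assignment map contains unknown individuals: {sorted(unknown)}")
    unassigned = set(sequences) - set(assignment)
    if unassigned:
        raise ValueError(f"individuals without taxon assignment: {sorted(unassigned)}")

    by_taxon: Dict[str, List[str]] = {}
    for ind, taxon in assignment.items():
        by_taxon.setdefault(taxon, []).append(ind)
    for taxon in by_taxon:
        by_taxon[taxon].sort()
    if outgroup not in by_taxon:
        raise ValueError(f"outgroup taxon {outgroup!r} not in assignment map")
    out_ids = by_taxon[outgroup]

    if mode == "taxon":
        entities = {t: ids for t, ids in by_taxon.items() if t != outgroup}
    else:
        entities = {
            ind: [ind]
            for t, ids in by_taxon.items()
            if t != outgroup
            for ind in ids
        }
    names = sorted(entities)
    if len(names) < 3:
        raise ValueError("need at least 3 non-outgroup entities")

    triples = [
        (p1, h, p2)
        for h in names
        for p1, p2 in itertools.combinations([n for n in names if n != h], 2)
    ]
    n_tests = len(triples)
    rng = np.random.default_rng(seed)

    rows = []
    for p1, h, p2 in triples:
        counts = _pooled_counts(sequences, out_ids, entities[p1], entities[h], entities[p2], rng)
        res = GammaEstimator(
            alpha=alpha, null_boundary=null_boundary, n_tests=n_tests
        ).fit(counts).result(p1=p1, hybrid=h, p2=p2)
        rows.append(
            (
                p1,
                h,
                p2,
                counts.n_informative,
                res.gamma,
                res.p_value,
                bool(res.significant) if res.significant is not None else None,
                res.event_class,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["p1", "hybrid", "p2", "n_sites", "gamma", "p_value", "significant", "event_class"],
    )
    significant = table[table["significant"] == True]  # noqa: E712
    summary: Dict[str, object] = {
        "mode": mode,
        "input_type": input_type,
        "outgroup": outgroup,
        "n_tested": int(len(table)),
        "n_significant": int(len(significant)),
        "mean_gamma_significant": (
            float(significant["gamma"].mean()) if len(significant) else None
        ),
        "events_by_class": table["event_class"].value_counts().to_dict(),
        "alpha": alpha,
        "null_boundary": null_boundary,
    }
    return table, summary
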