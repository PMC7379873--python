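"""Collapse polyploid allele calls to a diploid consensus.

Genetic-structure programs written for diploids can co-analyse mixed-ploidy
samples if each polyploid genotype is reduced to the set of alleles it
carries: the tetraploid call ``AATT`` becomes ``AT``, discarding dosage.
Heterozygous positions can alternatively be encoded as a single IUPAC
ambiguity symbol for consensus-sequence output.

Missing calls are represented as ``None`` (or NaN in matrices) and propagate
unchanged.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "reduce_to_diploid",
    "iupac_consensus",
    "reduce_matrix",
    "select_usnps",
    "DiploidReducer",
]

NUCLEOTIDES = frozenset("ACGT")

#: frozenset of nucleotides -> IUPAC symbol, e.g. {A, G} -> R
_IUPAC_BY_SET: Dict[frozenset, str] = {
    frozenset(expansion): code
    for code, expansion in ambiguous_dna_values.items()
    if set(expansion) <= NUCLEOTIDES
}


def _normalize_call(call: Optional[Iterable[str] | str]) -> Optional[str]:
    """Return the call as an uppercase string of alleles, or None if missing."""
    if call is None:
        return None
    if isinstance(call, float) and np.isnan(call):
        return None
    alleles = "".join(call).upper()
    alleles = "".join(a for a in alleles if a in NUCLEOTIDES)
    return alleles or None


def reduce_to_diploid(call: Iterable[str] | str | None) -> Optional[str]:
    """Reduce an allele call of any ploidy (1-8) to a two-symbol consensus.

    One distinct allele is doubled (``AAAA -> AA``); two distinct alleles are
    reported in lexicographic order (``AATT -> AT``); with more than two
    distinct alleles the two most frequent are kept, ties broken
    lexicographically (``AAGT -> AG``).  Dosage is discarded: only allele
    presence survives the reduction.  Missing calls return ``None``.
    """
    alleles = _normalize_call(call)
    if alleles is None:
        return None
    if not 1 <= len(alleles) <= 8:
        raise ValueError(f"call size {len(alleles)} outside supported ploidy 1-8")
    counts = Counter(alleles)
    if len(counts) == 1:
        a = next(iter(counts))
        return a + a
    top = sorted(counts, key=lambda a: (-counts[a], a))[:2]
    return "".join(sorted(top))


def iupac_consensus(call: Iterable[str] | str | None) -> Optional[str]:
    """Encode the distinct alleles of a call as one IUPAC ambiguity symbol."""
    alleles = _normalize_call(call)
    if alleles is None:
        return None
    return _IUPAC_BY_SET[frozenset(alleles)]


def iupac_expand(symbol: str) -> frozenset:
    """Distinct nucleotides encoded by an IUPAC symbol (``R -> {A, G}``)."""
    return frozenset(ambiguous_dna_values[symbol.upper()])


def select_usnps(
    columns: Sequence[str],
    locus_of_column: Mapping[str, str],
    is_polymorphic: Mapping[str, bool],
) -> list:
    """Retain one SNP per locus: the first polymorphic column in coordinate order."""
    kept = []
    seen = set()
    for col in columns:
        locus = locus_of_column[col]
        if locus in seen or not is_polymorphic[col]:
            continue
        seen.add(locus)
        kept.append(col)
    return kept


class DiploidReducer(BaseEstimator, TransformerMixin):
    """Transform a mixed-ploidy genotype matrix into a diploidized SNP matrix.

    The input is a DataFrame of allele-call strings (samples x sites, e.g.
    ``"AATT"`` for a tetraploid cell, ``"AG"`` for a diploid cell, NaN/None
    for missing).  Every non-missing cell is reduced with
    :func:`reduce_to_diploid`; diploid cells pass through unchanged up to
    allele ordering.

    Parameters
    ----------
    usnp : bool, default False
        Keep only one SNP per locus (the first polymorphic site in
        coordinate order).  Requires ``locus_of_column``.
    locus_of_column : mapping or None
        Column name -> locus id, used for uSNP selection.
    reduce_before_select : bool, default True
        Whether polymorphism for uSNP selection is judged on the reduced
        matrix (True) or on the raw calls (False); the two orders can keep a
        different site when reduction collapses a rare third allele.
    """

    def __init__(
        self,
        usnp: bool = False,
        locus_of_column: Optional[Mapping[str, str]] = None,
        reduce_before_select: bool = True,
    ):
        self.usnp = usnp
        self.locus_of_column = locus_of_column
        self.reduce_before_select = reduce_before_select

    def fit(self, X: pd.DataFrame, y=None) -> "DiploidReducer":
        if self.usnp and self.locus_of_column is None:
            raise ValueError("usnp=True requires locus_of_column")
        self.n_sites_in_ = X.shape[1]
        return self

    @staticmethod
    def _column_polymorphic(col: pd.Series) -> bool:
        alleles = set()
        for cell in col:
            norm = _normalize_call(cell)
            if norm:
                alleles |= set(norm)
        return len(alleles) > 1

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        reduced = X.map(reduce_to_diploid)
        if not self.usnp:
            return reduced
        basis = reduced if self.reduce_before_select else X
        poly = {c: self._column_polymorphic(basis[c]) for c in basis.columns}
        kept = select_usnps(list(X.columns), self.locus_of_column, poly)
        return reduced[kept]


def reduce_matrix(
    matrix: pd.DataFrame,
    usnp: bool = False,
    locus_of_column: Optional[Mapping[str, str]] = None,
    reduce_before_select: bool = True,
) -> pd.DataFrame:
    """Functional wrapper around :class:`DiploidReducer`."""
    reducer = DiploidReducer(
        usnp=usnp,
        locus_of_column=locus_of_column,
        reduce_before_select=reduce_before_select,
    )
    return reducer.fit_transform(matrix)
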