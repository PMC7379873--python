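"""Five-category classification of allotetraploid SNPs.

An allotetraploid genotype called against the pseudo-reference of diploid
parent 1 is compared, site by site, with the genotype of diploid parent 2.
With ``P1`` the reference allele, ``P2`` the distinct alleles of parent 2
and ``T`` the distinct alleles of the tetraploid:

* **CAT1 / CAT2** — inter-specific SNPs: the tetraploid carries the allele
  of only one parent (CAT1 = reference parent, CAT2 = parent 2).
* **CAT34** — derived SNPs: the tetraploid carries variation not present
  between the parental genomes, i.e. an allele absent from both parents,
  attributed to mutation after the polyploidization event.  The two
  sub-cases are not distinguished and are reported as one bucket.
* **CAT5** — putative homeo-SNPs: the tetraploid is heterozygous for the
  homeologous alleles of both parents (``T = P1 ∪ P2`` with ``P1 ≠ P2``).
* **OTHER** — everything else: sites heterozygous in a parent, sites with
  more than two distinct tetraploid alleles, ambiguous reference bases.

Sites where reference, parent 2 and tetraploid all agree are invariant and
excluded from the category denominator; sites failing the depth threshold
or with missing genotypes are skipped with a reason code.

The orientation convention (CAT1 = matches the pseudo-reference parent) is
recorded in every output header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .reference import PseudoReference

__all__ = [
    "Category",
    "SiteCall",
    "CategoryTable",
    "SnpCategoryClassifier",
    "classify_site",
    "classify_all",
    "summarize_proportions",
]

NUCLEOTIDES = frozenset("ACGT")

#: documented in every output: which parent CAT1/CAT2 refer to
ORIENTATION_NOTE = (
    "CAT1 = tetraploid matches the pseudo-reference parent (parent 1) only; "
    "CAT2 = matches parent 2 only"
)


class Category(str, Enum):
    CAT1 = "CAT1"
    CAT2 = "CAT2"
    CAT34 = "CAT34"
    CAT5 = "CAT5"
    OTHER = "OTHER"
    INVARIANT = "INVARIANT"
    SKIPPED = "SKIPPED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: categories counted in the proportion denominator
CLASSIFIED = (Category.CAT1, Category.CAT2, Category.CAT34, Category.CAT5, Category.OTHER)


@dataclass
class SiteCall:
    """One genomic position of the tetraploid/parent-2 comparison.

    ``parent2_genotype`` holds the called diploid alleles (length 2),
    ``tetraploid_genotype`` the four called alleles with dosage as called;
    either may be ``None`` when the genotype is missing.
    """

    locus_id: str
    position: int  # 1-based within the pseudo-reference
    ref_base: str
    parent2_genotype: Optional[Tuple[str, ...]]
    tetraploid_genotype: Optional[Tuple[str, ...]]
    depth_parent2: int = 0
    depth_tetraploid: int = 0
    is_indel: bool = False


def classify_site(call: SiteCall, min_depth: int = 8) -> Tuple[Category, str]:
    """Assign one site to a category; returns ``(category, reason_code)``.

    ``min_depth`` defaults to 8, the base-calling depth threshold of the
    upstream assembly.  Sites failing it (in either sample), with missing
    genotypes, or at indel records are returned as SKIPPED with a reason.
    """
    if call.is_indel:
        return Category.SKIPPED, "indel"
    if call.depth_parent2 < min_depth or call.depth_tetraploid < min_depth:
        return Category.SKIPPED, "low_depth"

    ref = call.ref_base.upper()
    if ref not in NUCLEOTIDES:
        # reference parent heterozygous (IUPAC consensus) at this position
        return Category.OTHER, "ambiguous_ref"
    if call.parent2_genotype is None or call.tetraploid_genotype is None:
        return Category.SKIPPED, "missing_genotype"

    p2 = frozenset(a.upper() for a in call.parent2_genotype)
    t = frozenset(a.upper() for a in call.tetraploid_genotype)
    if not p2 or not t:
        return Category.SKIPPED, "missing_genotype"
    if not (p2 <= NUCLEOTIDES and t <= NUCLEOTIDES):
        return Category.SKIPPED, "non_nucleotide_allele"

    p1 = frozenset((ref,))
    if len(p2) != 1:
        return Category.OTHER, "heterozygous_parent2"
    if len(t) > 2:
        return Category.OTHER, "gt2_alleles"
    if t - (p1 | p2):
        return Category.CAT34, "derived_allele"
    if p1 != p2:
        if t == p1 | p2:
            return Category.CAT5, "homeo"
        if t == p1:
            return Category.CAT1, "matches_parent1"
        return Category.CAT2, "matches_parent2"
    # p1 == p2 and t ⊆ p1: nothing varies at this site
    return Category.INVARIANT, "invariant"


@dataclass
class CategoryTable:
    """Per-site category assignments plus aggregate counts and percentages."""

    sites: pd.DataFrame
    min_depth: int = 8
    orientation: str = ORIENTATION_NOTE
    metadata: Dict[str, object] = field(default_factory=dict)

    COLUMNS = (
        "locus_id",
        "position",
        "ref",
        "parent2_gt",
        "tetraploid_gt",
        "category",
        "reason",
    )

    @property
    def counts(self) -> Dict[str, int]:
        vc = self.sites["category"].value_counts()
        return {cat.value: int(vc.get(cat.value, 0)) for cat in Category}

    @property
    def n_classified(self) -> int:
        counts = self.counts
        return sum(counts[c.value] for c in CLASSIFIED)

    @property
    def n_skipped(self) -> int:
        return self.counts[Category.SKIPPED.value]

    @property
    def n_invariant(self) -> int:
        return self.counts[Category.INVARIANT.value]

    def skipped_by_reason(self) -> Dict[str, int]:
        skipped = self.sites[self.sites["category"] == Category.SKIPPED.value]
        return skipped["reason"].value_counts().to_dict()

    def percentages(self) -> Dict[str, float]:
        """Category percentages over classified polymorphic sites."""
        n = self.n_classified
        if n == 0:
            raise ValueError("no classified sites; percentages undefined")
        counts = self.counts
        return {c.value: 100.0 * counts[c.value] / n for c in CLASSIFIED}

    def summary(self) -> Dict[str, object]:
        out: Dict[str, object] = {
            "orientation": self.orientation,
            "min_depth": self.min_depth,
            "n_input_sites": int(len(self.sites)),
            "n_classified": self.n_classified,
            "n_invariant": self.n_invariant,
            "n_skipped": self.n_skipped,
            "skipped_by_reason": self.skipped_by_reason(),
            "counts": {c.value: self.counts[c.value] for c in CLASSIFIED},
        }
        if self.n_classified:
            out["percentages"] = self.percentages()
        out.update(self.metadata)
        return out

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.orientation}\n")
            self.sites.to_csv(fh, sep="\t", index=False)


class SnpCategoryClassifier(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer wrapping the category rules.

    Parameters
    ----------
    min_depth : int, default 8
        Minimum read depth required in *both* samples for a site to be
        classified; below it the site is skipped with reason ``low_depth``.
    """

    def __init__(self, min_depth: int = 8):
        self.min_depth = min_depth

    def fit(self, X: Iterable[SiteCall] | None = None, y=None) -> "SnpCategoryClassifier":
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")
        self.is_fitted_ = True
        return self

    def classify_site(self, call: SiteCall) -> Tuple[Category, str]:
        return classify_site(call, min_depth=self.min_depth)

    def transform(self, X: Iterable[SiteCall]) -> CategoryTable:
        rows: List[tuple] = []
        for call in X:
            category, reason = classify_site(call, min_depth=self.min_depth)
            rows.append(
                (
                    call.locus_id,
                    call.position,
                    call.ref_base,
                    "".join(call.parent2_genotype or ()) or ".",
                    "".join(call.tetraploid_genotype or ()) or ".",
                    category.value,
                    reason,
                )
            )
        sites = pd.DataFrame(rows, columns=list(CategoryTable.COLUMNS))
        if rows:
            sites = sites.sort_values(["position"], kind="stable").reset_index(drop=True)
        return CategoryTable(sites=sites, min_depth=self.min_depth)


def classify_all(calls: Iterable[SiteCall], min_depth: int = 8) -> CategoryTable:
    """Classify a stream of site calls into a :class:`CategoryTable`."""
    return SnpCategoryClassifier(min_depth=min_depth).fit().transform(calls)


def summarize_proportions(table: CategoryTable) -> Dict[str, float]:
    """Percentage per category over classified sites (pie-chart data)."""
    return table.percentages()


# ---------------------------------------------------------------------------
# File-level driver: VCFs + depth tables + pseudo-reference -> SiteCalls
# ---------------------------------------------------------------------------


def _read_depth_tsv(path, contig: str) -> Dict[int, int]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "pos", "depth"], comment="#"
    )
    df = df[df["contig"] == contig]
    return dict(zip(df["pos"].astype(int), df["depth"].astype(int)))


def _read_vcf_genotypes(
    path, contig: str
) -> Dict[int, Tuple[Optional[Tuple[str, ...]], int, bool]]:
    """Map 1-based position -> (allele tuple or None, DP, is_indel)."""
    import pysam

    calls: Dict[int, Tuple[Optional[Tuple[str, ...]], int, bool]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            if rec.chrom != contig:
                continue
            alleles_by_index = (rec.ref,) + tuple(rec.alts or ())
            is_indel = any(len(a) != 1 for a in alleles_by_index if a not in (None, "*"))
            sdata = rec.samples[sample]
            gt = sdata.get("GT")
            dp = sdata.get("DP") or 0
            if gt is None or all(i is None for i in gt):
                calls[rec.pos] = (None, int(dp), is_indel)
                continue
            alleles = tuple(alleles_by_index[i] for i in gt if i is not None)
            calls[rec.pos] = (alleles, int(dp), is_indel)
    return calls


def site_calls_from_files(
    reference: PseudoReference,
    parent2_vcf,
    tetraploid_vcf,
    parent2_depth,
    tetraploid_depth,
) -> List[SiteCall]:
    """Assemble :class:`SiteCall` records from the standard input files.

    The site list is the union of the two VCFs' variant positions.  A sample
    without a record at a position is taken as homozygous reference there,
    provided its depth table covers the position; a position absent from a
    depth table is treated as zero depth (and will be skipped downstream).
    """
    p2 = _read_vcf_genotypes(parent2_vcf, reference.contig)
    tet = _read_vcf_genotypes(tetraploid_vcf, reference.contig)
    d2 = _read_depth_tsv(parent2_depth, reference.contig)
    dt = _read_depth_tsv(tetraploid_depth, reference.contig)

    calls: List[SiteCall] = []
    for pos in sorted(set(p2) | set(tet)):
        locus_id, _ = reference.map_coordinate(pos)
        ref_base = reference.base_at(pos)
        gt2, _, indel2 = p2.get(pos, (None, 0, False))
        gtt, _, indelt = tet.get(pos, (None, 0, False))
        if pos not in p2 and ref_base in NUCLEOTIDES:
            gt2 = (ref_base, ref_base)
        if pos not in tet and ref_base in NUCLEOTIDES:
            gtt = (ref_base,) * 4
        calls.append(
            SiteCall(
                locus_id=locus_id,
                position=pos,
                ref_base=ref_base,
                parent2_genotype=gt2,
                tetraploid_genotype=gtt,
                depth_parent2=d2.get(pos, 0),
                depth_tetraploid=dt.get(pos, 0),
                is_indel=indel2 or indelt,
            )
        )
    return calls


def classify_files(
    reference: PseudoReference,
    parent2_vcf,
    tetraploid_vcf,
    parent2_depth,
    tetraploid_depth,
    min_depth: int = 8,
) -> CategoryTable:
    """End-to-end classification from pseudo-reference + VCFs + depth TSVs."""
    calls = site_calls_from_files(
        reference, parent2_vcf, tetraploid_vcf, parent2_depth, tetraploid_depth
    )
    table = classify_all(calls, min_depth=min_depth)
    table.metadata["inputs"] = {
        "parent2_vcf": str(parent2_vcf),
        "tetraploid_vcf": str(tetraploid_vcf),
    }
    return table
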