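"""Independent brute-force evaluator of the SNP category rules.

Restates the category definitions verbally and set-free, in a different
order and style than the package implementation, for exhaustive
equivalence checking over the finite genotype space.
"""


def oracle_classify(ref: str, p2_alleles, tet_alleles) -> str:
    distinct_p2 = sorted(set(p2_alleles))
    distinct_t = sorted(set(tet_alleles))
    parents = sorted(set(ref) | set(p2_alleles))
    # "SNPs that are heterozygous in the parental taxa" -> other
    if len(distinct_p2) > 1:
        return "OTHER"
    # "SNPs that show more than two alleles" -> other
    if len(distinct_t) > 2:
        return "OTHER"
    has_novel = any(a not in parents for a in distinct_t)
    # derived: variation in the tetraploid not identified between parents
    if has_novel:
        return "CAT34"
    if ref == distinct_p2[0]:
        # parents identical: nothing inter-specific or homeologous possible
        return "INVARIANT" if distinct_t == [ref] else "UNREACHABLE"
    # homeo-SNP: heterozygous for homeologous alleles of both parents
    if distinct_t == sorted([ref, distinct_p2[0]]):
        return "CAT5"
    # inter-specific: allele identical with only one parental species
    if distinct_t == [ref]:
        return "CAT1"
    if distinct_t == [distinct_p2[0]]:
        return "CAT2"
    return "UNREACHABLE"
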