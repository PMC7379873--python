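"""Synthetic allopolyploid RAD data with ground-truth site labels.

The generator emulates the consensus output of a de novo RAD assembly for
two diverged diploid parent lineages and an allotetraploid that combines
both parental subgenomes:

1. an ancestral genome of ``n_loci`` loci (86 bp by default, the typical
   single-end RAD read length after adapter/barcode removal) is drawn;
2. parent 1 keeps the ancestral state, parent 2 accumulates substitutions
   at ``parent_divergence`` per site (Jukes–Cantor-style: uniform choice
   among the three other bases, no indels); optional per-site parental
   heterozygosity populates the OTHER category;
3. the allotetraploid starts as an F1 carrying two haplotypes from each
   parent (unreduced-gamete union), after which ``backcross_fraction`` of
   its loci have the parent-2 subgenome replaced by parent-1 haplotypes
   (backcrossing/introgression) and post-origin mutations are applied at
   ``post_origin_rate`` per site.

Every polymorphic site receives a ground-truth category (CAT1/CAT2
inter-specific, CAT34 derived, CAT5 homeo-SNP, OTHER) and the generating
event, so downstream classification and γ estimation are testable without
real sequencing data.  Loci violating the assembly caps (at most 20 SNPs
per locus, at most 4 alleles per site) are re-drawn.

Simulation happens at the genotype level: the read-mapping/variant-calling
stage is emulated by emitting the files it would produce (pseudo-reference
FASTA, per-sample VCF with 4-allele tetraploid genotypes, per-position
depth tables with negative-binomial per-locus coverage, dropout at
``missing_rate``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .reduce import iupac_consensus, iupac_expand
from .reference import PseudoReference, RadLocusSet, build_pseudoreference

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "Tetraploid",
    "QuartetSites",
    "SimulatedFiles",
    "simulate_parents",
    "simulate_allotetraploid",
    "emit_files",
    "simulate_quartet_sites",
    "simulate_dataset",
]

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
MAX_SNPS_PER_LOCUS = 20
MAX_ALLELES_PER_SITE = 4

TRUTH_COLUMNS = ("locus_id", "offset", "true_category", "event")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    All rates are per-site probabilities; ``depth_mean`` is the mean of the
    negative-binomial per-locus coverage (52 by default, a typical RAD
    cluster depth), with ``depth_dispersion`` its shape parameter.  The
    post-origin mutation rate and backcross fraction have no empirical
    estimates to anchor them; their defaults (0) describe a plain F1
    allotetraploid and are varied explicitly by callers.
    """

    n_loci: int = 1000
    locus_length: int = 86
    parent_divergence: float = 0.01
    parental_heterozygosity: float = 0.0
    post_origin_rate: float = 0.0
    backcross_fraction: float = 0.0
    missing_rate: float = 0.0
    depth_mean: float = 52.0
    depth_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("n_loci and locus_length must be >= 1")
        for name in (
            "parent_divergence",
            "parental_heterozygosity",
            "post_origin_rate",
            "backcross_fraction",
            "missing_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} is not a probability in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independent substream of the configured seed."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


@dataclass
class TruthTable:
    """Ground-truth category and generating event per polymorphic site.

    ``offset`` is 1-based within the locus.  Events: ``divergence`` (sites
    separating the parent lineages), ``backcross`` (formerly discriminating
    sites on replaced loci), ``post_origin`` (mutations after the
    polyploid's origin), ``parental_het`` (heterozygosity within a parent).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TRUTH_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"truth table lacks columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    def counts(self) -> Dict[str, int]:
        return self.records["true_category"].value_counts().to_dict()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class Tetraploid:
    """Four haplotypes per locus for the simulated allotetraploid."""

    locus_ids: List[str]
    haplotypes: np.ndarray  # codes 0..3, shape (n_loci, 4, locus_length)

    def consensus(self) -> RadLocusSet:
        """IUPAC consensus over the four haplotypes, as assemblers report it."""
        sequences = {}
        for i, locus_id in enumerate(self.locus_ids):
            chars = []
            for j in range(self.haplotypes.shape[2]):
                alleles = {BASES[c] for c in self.haplotypes[i, :, j]}
                chars.append(iupac_consensus("".join(alleles)))
            sequences[locus_id] = "".join(chars)
        return RadLocusSet(
            sequences=sequences, presence={lid: {"tetraploid"} for lid in sequences}
        )

    def genotype(self, locus_index: int, offset0: int) -> Tuple[str, str, str, str]:
        return tuple(BASES[c] for c in self.haplotypes[locus_index, :, offset0])


def _locus_ids(n_loci: int) -> List[str]:
    width = max(6, len(str(n_loci)))
    return [f"locus_{i:0{width}d}" for i in range(1, n_loci + 1)]


def _consensus_from_haplotypes(h1: np.ndarray, h2: np.ndarray) -> List[str]:
    """Per-locus IUPAC consensus strings from a diploid haplotype pair."""
    sequences = []
    same = h1 == h2
    for i in range(h1.shape[0]):
        row1, row2 = BASES[h1[i]], BASES[h2[i]]
        if same[i].all():
            sequences.append("".join(row1))
            continue
        chars = [
            a if a == b else iupac_consensus(a + b)
            for a, b in zip(row1, row2)
        ]
        sequences.append("".join(chars))
    return sequences


def _decode_consensus(seq: str) -> Tuple[np.ndarray, np.ndarray]:
    """Inverse of the consensus encoding: two haplotype code rows.

    Heterozygous IUPAC symbols are split into their two alleles in sorted
    order; symbols encoding more than two alleles are rejected (a diploid
    consensus cannot contain them).
    """
    code_of = {b: i for i, b in enumerate(BASES)}
    h1 = np.empty(len(seq), dtype=np.int64)
    h2 = np.empty(len(seq), dtype=np.int64)
    for j, ch in enumerate(seq.upper()):
        if ch in code_of:
            h1[j] = h2[j] = code_of[ch]
            continue
        alleles = sorted(iupac_expand(ch))
        if len(alleles) != 2:
            raise ValueError(f"symbol {ch!r} does not encode a diploid site")
        h1[j], h2[j] = code_of[alleles[0]], code_of[alleles[1]]
    return h1, h2


def _mutate(codes: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute masked positions with a uniformly chosen different base."""
    out = codes.copy()
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    out[mask] = (out[mask] + shifts) % 4
    return out


def _snps_per_locus(rows: np.ndarray) -> np.ndarray:
    """Number of variable sites per locus across all haplotype rows.

    ``rows`` has shape (n_rows, n_loci, locus_length).
    """
    return (rows != rows[0]).any(axis=0).sum(axis=1)


def simulate_parents(
    config: SimulationConfig,
) -> Tuple[RadLocusSet, RadLocusSet, RadLocusSet]:
    """Draw the ancestral genome and the two diverged diploid parents.

    Parent 1 retains the ancestral state; parent 2 carries substitutions at
    ``parent_divergence`` per site.  With nonzero
    ``parental_heterozygosity`` either parent can be heterozygous at a
    site, encoded as an IUPAC symbol in its consensus.  Loci exceeding the
    20-SNPs-per-locus cap are re-drawn.
    """
    n, length = config.n_loci, config.locus_length
    rng = config.rng("parents")

    ancestral = rng.integers(0, 4, size=(n, length))
    p2_base = _mutate(ancestral, rng.random((n, length)) < config.parent_divergence, rng)

    def draw_het(base: np.ndarray) -> np.ndarray:
        mask = rng.random(base.shape) < config.parental_heterozygosity
        return _mutate(base, mask, rng)

    p1_h1, p1_h2 = ancestral, draw_het(ancestral)
    p2_h1, p2_h2 = p2_base, draw_het(p2_base)

    # re-draw loci that violate the per-locus SNP cap (the 4-alleles-per-site
    # cap holds trivially for a 4-letter alphabet)
    for _ in range(100):
        rows = np.stack([p1_h1, p1_h2, p2_h1, p2_h2])
        bad = np.flatnonzero(_snps_per_locus(rows) > MAX_SNPS_PER_LOCUS)
        if bad.size == 0:
            break
        k = bad.size
        anc_new = rng.integers(0, 4, size=(k, length))
        ancestral[bad] = anc_new
        p2_new = _mutate(anc_new, rng.random((k, length)) < config.parent_divergence, rng)
        p1_h1 = ancestral
        p1_h2 = p1_h2.copy()
        p2_h1 = p2_h1.copy()
        p2_h2 = p2_h2.copy()
        p1_h2[bad] = _mutate(
            anc_new, rng.random((k, length)) < config.parental_heterozygosity, rng
        )[np.arange(k)]
        p2_h1[bad] = p2_new
        p2_h2[bad] = _mutate(
            p2_new, rng.random((k, length)) < config.parental_heterozygosity, rng
        )
    else:  # pragma: no cover - would need extreme rates
        raise RuntimeError("could not satisfy the SNPs-per-locus cap after 100 redraws")

    ids = _locus_ids(n)

    def locus_set(h1: np.ndarray, h2: np.ndarray, sample: str) -> RadLocusSet:
        sequences = dict(zip(ids, _consensus_from_haplotypes(h1, h2)))
        return RadLocusSet(
            sequences=sequences, presence={lid: {sample} for lid in ids}
        )

    return (
        locus_set(ancestral, ancestral, "ancestral"),
        locus_set(p1_h1, p1_h2, "parent1"),
        locus_set(p2_h1, p2_h2, "parent2"),
    )


def _truth_category(
    p1: frozenset, p2: frozenset, t: frozenset
) -> Optional[str]:
    """Category implied by the allele sets of one site; None if invariant."""
    if len(p1) == 1 and p1 == p2 and t == p1:
        return None
    if len(p1) != 1 or len(p2) != 1:
        return "OTHER"
    if len(t) > 2:
        return "OTHER"
    if t - (p1 | p2):
        return "CAT34"
    if p1 != p2:
        if t == p1 | p2:
            return "CAT5"
        return "CAT1" if t == p1 else "CAT2"
    return None


def simulate_allotetraploid(
    parent1: RadLocusSet,
    parent2: RadLocusSet,
    config: SimulationConfig,
) -> Tuple[Tetraploid, TruthTable]:
    """Build the allotetraploid from the parents and label every site.

    The F1 union carries both haplotypes of each parent; then the parent-2
    subgenome of ``round(backcross_fraction * n_loci)`` loci (chosen
    uniformly) is replaced by parent-1 haplotypes, and post-origin
    mutations are applied per site at ``post_origin_rate`` to one of the
    four haplotypes.
    """
    if set(parent1.sequences) != set(parent2.sequences):
        raise ValueError("parents must share identical locus ids")
    ids = sorted(parent1.sequences)
    n = len(ids)
    length = len(parent1.sequences[ids[0]])
    rng = config.rng("tetraploid")

    p1_h1 = np.empty((n, length), dtype=np.int64)
    p1_h2 = np.empty_like(p1_h1)
    p2_h1 = np.empty_like(p1_h1)
    p2_h2 = np.empty_like(p1_h1)
    for i, lid in enumerate(ids):
        p1_h1[i], p1_h2[i] = _decode_consensus(parent1.sequences[lid])
        p2_h1[i], p2_h2[i] = _decode_consensus(parent2.sequences[lid])

    haps = np.stack([p1_h1, p1_h2, p2_h1, p2_h2], axis=1)  # (n, 4, length)

    n_backcross = int(round(config.backcross_fraction * n))
    backcrossed = np.zeros(n, dtype=bool)
    if n_backcross:
        chosen = rng.choice(n, size=n_backcross, replace=False)
        backcrossed[chosen] = True
        haps[chosen, 2] = p1_h1[chosen]
        haps[chosen, 3] = p1_h2[chosen]

    # post-origin mutations, re-drawn per locus if a locus breaks the SNP cap
    parent_rows = np.stack([p1_h1, p1_h2, p2_h1, p2_h2])
    post_mask = np.zeros((n, length), dtype=bool)
    pending = np.arange(n)
    for _ in range(100):
        mask = rng.random((pending.size, length)) < config.post_origin_rate
        hap_choice = rng.integers(0, 4, size=(pending.size, length))
        trial = haps[pending].copy()
        for r, locus in enumerate(pending):
            cols = np.flatnonzero(mask[r])
            for j in cols:
                h = hap_choice[r, j]
                trial[r, h, j] = (trial[r, h, j] + rng.integers(1, 4)) % 4
        all_rows = np.concatenate(
            [parent_rows[:, pending], np.swapaxes(trial, 0, 1)], axis=0
        )
        ok = _snps_per_locus(all_rows) <= MAX_SNPS_PER_LOCUS
        haps[pending[ok]] = trial[ok]
        post_mask[pending[ok]] = mask[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not satisfy the SNPs-per-locus cap after 100 redraws")

    # ground-truth labels for every polymorphic site
    records = []
    all_rows = np.concatenate([parent_rows, np.swapaxes(haps, 0, 1)], axis=0)
    variable = (all_rows != all_rows[0]).any(axis=0)  # (n, length)
    for i in np.argwhere(variable.any(axis=1))[:, 0]:
        for j in np.flatnonzero(variable[i]):
            p1 = frozenset({BASES[p1_h1[i, j]], BASES[p1_h2[i, j]]})
            p2 = frozenset({BASES[p2_h1[i, j]], BASES[p2_h2[i, j]]})
            t = frozenset(BASES[c] for c in haps[i, :, j])
            category = _truth_category(p1, p2, t)
            if category is None:
                continue
            if post_mask[i, j]:
                event = "post_origin"
            elif backcrossed[i] and len(p1) == 1 and len(p2) == 1 and p1 != p2:
                event = "backcross"
            elif len(p1) > 1 or len(p2) > 1:
                event = "parental_het"
            else:
                event = "divergence"
            records.append((ids[i], j + 1, category, event))

    truth = TruthTable(
        pd.DataFrame(records, columns=list(TRUTH_COLUMNS))
    )
    return Tetraploid(locus_ids=ids, haplotypes=haps), truth


# ---------------------------------------------------------------------------
# File emission (emulating the mapping/variant-calling stage outputs)
# ---------------------------------------------------------------------------


@dataclass
class SimulatedFiles:
    """Paths of one emitted synthetic dataset."""

    ref_fasta: Path
    offsets_tsv: Path
    parent1_fasta: Path
    parent2_fasta: Path
    tetraploid_fasta: Path
    parent2_vcf: Path
    tetraploid_vcf: Path
    parent2_depth: Path
    tetraploid_depth: Path
    truth_tsv: Path


def _vcf_header(contig: str, length: int, sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=radploidy-simulate")
    header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_sample(sample)
    return header


def _write_sample_vcf(
    path: Path,
    reference: PseudoReference,
    sample: str,
    haps_by_locus: Dict[str, np.ndarray],  # locus -> (ploidy, length) codes
    depth_by_locus: Dict[str, int],
) -> None:
    header = _vcf_header(reference.contig, len(reference), sample)
    code_of = {b: i for i, b in enumerate(BASES)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for locus_id in sorted(haps_by_locus):
            haps = haps_by_locus[locus_id]
            start0, _ = reference.offsets[locus_id]
            ref_seq = reference.sequence[start0 : start0 + haps.shape[1]]
            for j, ref_char in enumerate(ref_seq):
                alleles = haps[:, j]
                ref_ok = ref_char in code_of
                if ref_ok and (alleles == code_of[ref_char]).all():
                    continue
                ref_allele = ref_char if ref_ok else "N"
                sample_bases = [BASES[c] for c in alleles]
                alts = sorted(set(sample_bases) - {ref_allele})
                index_of = {ref_allele: 0}
                for k, alt in enumerate(alts, start=1):
                    index_of[alt] = k
                rec = vcf.new_record(
                    contig=reference.contig,
                    start=start0 + j,
                    alleles=tuple([ref_allele] + alts),
                )
                rec.samples[sample]["GT"] = tuple(index_of[b] for b in sample_bases)
                rec.samples[sample]["DP"] = int(depth_by_locus[locus_id])
                vcf.write(rec)


def _write_depth_tsv(
    path: Path,
    reference: PseudoReference,
    depth_by_locus: Dict[str, int],
) -> None:
    with open(path, "w") as fh:
        for locus_id in sorted(depth_by_locus):
            start0, end0 = reference.offsets[locus_id]
            depth = int(depth_by_locus[locus_id])
            for pos in range(start0 + 1, end0 + 1):
                fh.write(f"{reference.contig}\t{pos}\t{depth}\n")


def _sample_depths(
    config: SimulationConfig, sample: str, locus_ids: List[str]
) -> Dict[str, int]:
    rng = config.rng(f"depth:{sample}")
    k = config.depth_dispersion
    p = k / (k + config.depth_mean)
    draws = rng.negative_binomial(k, p, size=len(locus_ids))
    return dict(zip(locus_ids, draws.astype(int)))


def _present_loci(
    config: SimulationConfig, sample: str, locus_ids: List[str]
) -> List[str]:
    rng = config.rng(f"dropout:{sample}")
    keep = rng.random(len(locus_ids)) >= config.missing_rate
    return [lid for lid, k in zip(locus_ids, keep) if k]


def emit_files(
    parent1: RadLocusSet,
    parent2: RadLocusSet,
    tetraploid: Tetraploid,
    truth: TruthTable,
    config: SimulationConfig,
    outdir: str | Path,
) -> SimulatedFiles:
    """Write the synthetic dataset in the standard exchange formats.

    Parent 1 is the reference parent: its loci form the pseudo-reference,
    and the VCF + depth files of parent 2 and of the tetraploid are
    expressed against it.  Per-locus dropout (``missing_rate``) and
    negative-binomial depth are applied per sample.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = build_pseudoreference(parent1)

    # per-sample RNG streams are keyed by the sample's own identity (taken
    # from its presence flags) so depth/dropout draws do not depend on which
    # parent plays the reference role
    def sample_name(locus_set: RadLocusSet, default: str) -> str:
        names = set()
        for flags in locus_set.presence.values():
            names |= flags
        return next(iter(names)) if len(names) == 1 else default

    ref_name = sample_name(parent1, "parent1")
    other_name = sample_name(parent2, "parent2")

    files = SimulatedFiles(
        ref_fasta=outdir / "pseudoref.fasta",
        offsets_tsv=outdir / "pseudoref.offsets.tsv",
        parent1_fasta=outdir / "parent1.consensus.fasta",
        parent2_fasta=outdir / "parent2.consensus.fasta",
        tetraploid_fasta=outdir / "tetraploid.consensus.fasta",
        parent2_vcf=outdir / "parent2.vcf",
        tetraploid_vcf=outdir / "tetraploid.vcf",
        parent2_depth=outdir / "parent2.depth.tsv",
        tetraploid_depth=outdir / "tetraploid.depth.tsv",
        truth_tsv=outdir / "truth.tsv",
    )
    reference.write_fasta(files.ref_fasta)
    reference.write_offsets(files.offsets_tsv)
    truth.to_tsv(files.truth_tsv)

    ids = sorted(parent1.sequences)
    tet_consensus = tetraploid.consensus()
    for sample, locus_set, fasta in (
        (ref_name, parent1, files.parent1_fasta),
        (other_name, parent2, files.parent2_fasta),
        ("tetraploid", tet_consensus, files.tetraploid_fasta),
    ):
        present = _present_loci(config, sample, ids)
        subset = RadLocusSet(
            sequences={lid: locus_set.sequences[lid] for lid in present},
            presence={lid: {sample} for lid in present},
        )
        subset.to_fasta(fasta)

    index_of = {lid: i for i, lid in enumerate(tetraploid.locus_ids)}
    for sample, vcf_path, depth_path, haps_of in (
        (
            other_name,
            files.parent2_vcf,
            files.parent2_depth,
            lambda lid: np.stack(_decode_consensus(parent2.sequences[lid])),
        ),
        (
            "tetraploid",
            files.tetraploid_vcf,
            files.tetraploid_depth,
            lambda lid: tetraploid.haplotypes[index_of[lid]],
        ),
    ):
        present = _present_loci(config, sample, ids)
        depths = _sample_depths(config, sample, ids)
        depth_present = {lid: depths[lid] for lid in present}
        haps_by_locus = {lid: haps_of(lid) for lid in present}
        _write_sample_vcf(vcf_path, reference, sample, haps_by_locus, depth_present)
        _write_depth_tsv(depth_path, reference, depth_present)

    return files


# ---------------------------------------------------------------------------
# Quartet site simulation for the gamma estimator
# ---------------------------------------------------------------------------


@dataclass
class QuartetSites:
    """Aligned (outgroup, P1, hybrid, P2) rows with the true γ."""

    outgroup: str
    p1: str
    hybrid: str
    p2: str
    true_gamma: float

    def as_dict(self) -> Dict[str, str]:
        return {
            "outgroup": self.outgroup,
            "P1": self.p1,
            "H": self.hybrid,
            "P2": self.p2,
        }


def simulate_quartet_sites(
    gamma: float,
    n_sites: int,
    seed: int = 0,
    n_uninformative: int = 0,
) -> QuartetSites:
    """Simulate polarized quartet sites with a known admixture proportion.

    At each of ``n_sites`` informative sites P1 carries the ancestral
    allele (shared with the outgroup) and P2 a different, derived allele;
    the hybrid carries the P2 allele with probability ``gamma`` and the P1
    allele otherwise.  ``n_uninformative`` invariant sites can be appended
    to emulate monomorphic alignment columns.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma={gamma} outside [0, 1]")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng([seed, zlib.crc32(b"quartet")])

    anc = rng.integers(0, 4, size=n_sites)
    derived = (anc + rng.integers(1, 4, size=n_sites)) % 4
    from_p2 = rng.random(n_sites) < gamma
    hyb = np.where(from_p2, derived, anc)

    pad = rng.integers(0, 4, size=n_uninformative)
    out_row = np.concatenate([anc, pad])
    p1_row = np.concatenate([anc, pad])
    h_row = np.concatenate([hyb, pad])
    p2_row = np.concatenate([derived, pad])
    join = lambda row: "".join(BASES[row])
    return QuartetSites(
        outgroup=join(out_row),
        p1=join(p1_row),
        hybrid=join(h_row),
        p2=join(p2_row),
        true_gamma=gamma,
    )


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path
) -> Tuple[SimulatedFiles, TruthTable]:
    """Convenience: parents + tetraploid + file emission in one call."""
    _, parent1, parent2 = simulate_parents(config)
    tetraploid, truth = simulate_allotetraploid(parent1, parent2, config)
    files = emit_files(parent1, parent2, tetraploid, truth, config, outdir)
    return files, truth
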