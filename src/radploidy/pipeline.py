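"""End-to-end orchestration: simulate -> build-ref -> classify -> γ -> reduce.

The pipeline wires the stages together on a synthetic dataset, enforces
the cross-stage conservation contract (classified + skipped + invariant =
total input sites), validates input files, and serializes a structured
JSON run report with full provenance (config, seed, package version).
All randomness flows from the single configured seed through named
substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

from . import __version__
from .classify import classify_files
from .gamma import run_combinations
from .reduce import reduce_matrix
from .reference import PseudoReference
from .simulate import (
    SimulationConfig,
    emit_files,
    simulate_allotetraploid,
    simulate_parents,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "ValidationIssue"]


@dataclass
class RunConfig:
    """Parameters of one end-to-end synthetic run."""

    outdir: Path
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_depth: int = 8
    alpha: float = 0.05
    null_boundary: float = 0.02
    mode: str = "taxon"
    usnp: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(outdir=Path(outdir), simulation=sim, **raw)

    def provenance(self) -> Dict[str, object]:
        return {
            "package": "radploidy",
            "version": __version__,
            "seed": self.simulation.seed,
            "simulation": dataclasses.asdict(self.simulation),
            "min_depth": self.min_depth,
            "alpha": self.alpha,
            "null_boundary": self.null_boundary,
            "mode": self.mode,
        }


def _genotype_matrix(table_sites: pd.DataFrame) -> pd.DataFrame:
    """Genotype matrix (samples x sites) from classified site records."""
    classified = table_sites[
        table_sites["category"].isin(["CAT1", "CAT2", "CAT34", "CAT5", "OTHER"])
    ]
    columns = [f"{r.locus_id}:{r.position}" for r in classified.itertuples()]
    data = {
        "parent1": [r.ref * 2 if r.ref in "ACGT" else None for r in classified.itertuples()],
        "parent2": [r.parent2_gt if r.parent2_gt != "." else None for r in classified.itertuples()],
        "tetraploid": [r.tetraploid_gt if r.tetraploid_gt != "." else None for r in classified.itertuples()],
    }
    return pd.DataFrame(data, index=columns).T


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute all stages on a synthetic dataset and return the run report.

    Fails fast (raises) on any stage contract violation; the report is also
    written to ``<outdir>/report.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    # stage 1: simulation + file emission (includes pseudo-reference build)
    ancestral, parent1, parent2 = simulate_parents(sim)
    tetraploid, truth = simulate_allotetraploid(parent1, parent2, sim)
    files = emit_files(parent1, parent2, tetraploid, truth, sim, outdir)

    # stage 2: validation of the emitted files
    issues = validate_inputs(
        files.ref_fasta,
        files.offsets_tsv,
        {files.parent2_vcf: 2, files.tetraploid_vcf: 4},
        [files.parent2_depth, files.tetraploid_depth],
    )
    errors = [i for i in issues if i.level == "error"]
    if errors:
        raise RuntimeError(f"emitted files failed validation: {errors[:3]}")

    # stage 3: SNP categorization
    reference = PseudoReference.read(files.ref_fasta, files.offsets_tsv)
    table = classify_files(
        reference,
        files.parent2_vcf,
        files.tetraploid_vcf,
        files.parent2_depth,
        files.tetraploid_depth,
        min_depth=config.min_depth,
    )
    table.write_tsv(outdir / "categories.tsv")
    summary = table.summary()
    if summary["n_classified"] + summary["n_skipped"] + summary["n_invariant"] != summary[
        "n_input_sites"
    ]:
        raise RuntimeError("site conservation violated in classification stage")

    # stage 4: hybridization detection on the consensus sequences
    def concat(locus_set) -> str:
        return "".join(locus_set.sequences[lid] for lid in sorted(locus_set.sequences))

    sequences = {
        "ancestral": concat(ancestral),
        "parent1": concat(parent1),
        "parent2": concat(parent2),
        "tetraploid": concat(tetraploid.consensus()),
    }
    assignment = {name: name for name in sequences}
    gamma_table, gamma_summary = run_combinations(
        sequences,
        assignment,
        outgroup="ancestral",
        mode=config.mode,
        alpha=config.alpha,
        null_boundary=config.null_boundary,
        seed=sim.seed,
        input_type="sequence",
    )
    gamma_table.to_csv(outdir / "gamma.tsv", sep="\t", index=False)

    # stage 5: ploidy reduction to a structure-analysis input matrix
    matrix = _genotype_matrix(table.sites)
    locus_of_column = {c: c.split(":")[0] for c in matrix.columns}
    reduced = reduce_matrix(
        matrix, usnp=config.usnp, locus_of_column=locus_of_column
    )
    reduced.to_csv(outdir / "reduced_matrix.tsv", sep="\t")

    report: Dict[str, object] = {
        "provenance": config.provenance(),
        "simulate": {
            "n_loci": sim.n_loci,
            "n_truth_sites": int(len(truth)),
            "truth_counts": {k: int(v) for k, v in truth.counts().items()},
        },
        "classify": summary,
        "gamma": gamma_summary,
        "reduce": {
            "n_sites_in": int(matrix.shape[1]),
            "n_sites_out": int(reduced.shape[1]),
            "missing_fraction": float(reduced.isna().to_numpy().mean())
            if reduced.size
            else 0.0,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationIssue:
    file: str
    rule: str
    level: str  # "error" | "warning"
    message: str
    record: Optional[str] = None


def validate_inputs(
    ref_fasta: str | Path,
    offsets_tsv: str | Path,
    vcfs: Dict[Path, int] | Dict[str, int],
    depth_tsvs: List[Path] | List[str],
) -> List[ValidationIssue]:
    """Check well-formedness and mutual consistency of pipeline inputs.

    ``vcfs`` maps each VCF path to the expected GT ploidy of its sample
    (2 for diploids, 4 for tetraploids); a mismatching record yields a
    ploidy-mismatch warning, a position beyond the reference an error.
    """
    issues: List[ValidationIssue] = []

    records = list(SeqIO.parse(str(ref_fasta), "fasta"))
    if len(records) != 1:
        issues.append(
            ValidationIssue(
                str(ref_fasta), "single_contig", "error",
                f"expected 1 contig, found {len(records)}",
            )
        )
        return issues
    contig, ref_len = records[0].id, len(records[0].seq)

    try:
        PseudoReference.read(ref_fasta, offsets_tsv)
    except (ValueError, KeyError) as exc:
        issues.append(
            ValidationIssue(str(offsets_tsv), "offset_partition", "error", str(exc))
        )

    for vcf_path, expected_ploidy in vcfs.items():
        try:
            with pysam.VariantFile(str(vcf_path)) as vcf:
                sample = list(vcf.header.samples)[0]
                for rec in vcf:
                    tag = f"{rec.chrom}:{rec.pos}"
                    if rec.chrom != contig:
                        issues.append(
                            ValidationIssue(
                                str(vcf_path), "contig_name", "error",
                                f"unknown contig {rec.chrom!r}", tag,
                            )
                        )
                        continue
                    if not 1 <= rec.pos <= ref_len:
                        issues.append(
                            ValidationIssue(
                                str(vcf_path), "position_range", "error",
                                f"position {rec.pos} beyond reference length {ref_len}",
                                tag,
                            )
                        )
                    gt = rec.samples[sample].get("GT")
                    called = [i for i in (gt or ()) if i is not None]
                    if called and len(called) != expected_ploidy:
                        issues.append(
                            ValidationIssue(
                                str(vcf_path), "ploidy_mismatch", "warning",
                                f"GT has {len(called)} alleles, expected {expected_ploidy}",
                                tag,
                            )
                        )
        except (OSError, ValueError) as exc:
            issues.append(ValidationIssue(str(vcf_path), "vcf_parse", "error", str(exc)))

    for depth_path in depth_tsvs:
        try:
            df = pd.read_csv(
                depth_path, sep="\t", header=None,
                names=["contig", "pos", "depth"], comment="#",
            )
        except (OSError, ValueError) as exc:
            issues.append(
                ValidationIssue(str(depth_path), "depth_parse", "error", str(exc))
            )
            continue
        bad_pos = df[(df["pos"] < 1) | (df["pos"] > ref_len)]
        if len(bad_pos):
            issues.append(
                ValidationIssue(
                    str(depth_path), "position_range", "error",
                    f"{len(bad_pos)} positions outside [1, {ref_len}]",
                )
            )
        if (df["depth"] < 0).any():
            issues.append(
                ValidationIssue(
                    str(depth_path), "negative_depth", "error",
                    "negative depth values present",
                )
            )
    return issues
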