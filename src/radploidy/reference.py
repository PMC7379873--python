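"""Pseudo-reference construction from consensus RAD loci.

Without a genome assembly, reads of a polyploid and of a second diploid
parent can still be mapped if the consensus RAD loci of one diploid parent
are concatenated into a single "pseudo-reference" contig.  This module
builds that contig, keeps the bidirectional map between global coordinates
and (locus, within-locus offset), and applies the locus-sharing filter used
when assembling multi-sample RAD matrices.

Coordinates are 0-based half-open internally; the public coordinate mapping
speaks 1-based positions, matching VCF and depth-table conventions.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Set, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RadLocusSet",
    "PseudoReference",
    "build_pseudoreference",
    "filter_loci_by_coverage",
]

#: nucleotides allowed in consensus loci (IUPAC ambiguity codes included)
VALID_CONSENSUS = set("ACGTNRYSWKMBDHV")


@dataclass
class RadLocusSet:
    """Consensus RAD loci for one sample or a merged sample set.

    Parameters
    ----------
    sequences
        Mapping ``locus_id -> consensus sequence``.  Sequences may contain
        IUPAC ambiguity codes at heterozygous positions.
    presence
        Mapping ``locus_id -> set of sample ids`` in which the locus was
        recovered.  Optional; defaults to an empty set per locus, meaning
        presence information is unknown.
    """

    sequences: Dict[str, str]
    presence: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus_id, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"locus {locus_id!r} has an empty sequence")
            bad = set(seq.upper()) - VALID_CONSENSUS
            if bad:
                raise ValueError(
                    f"locus {locus_id!r} contains invalid symbols {sorted(bad)}"
                )
        for locus_id in self.presence:
            if locus_id not in self.sequences:
                raise KeyError(f"presence recorded for unknown locus {locus_id!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.sequences

    def n_samples(self) -> int:
        """Number of distinct samples recorded across all presence sets."""
        samples: Set[str] = set()
        for flags in self.presence.values():
            samples |= flags
        return len(samples)

    def presence_count(self, locus_id: str) -> int:
        return len(self.presence.get(locus_id, set()))

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.sequences[lid]), id=lid, description="")
            for lid in sorted(self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "RadLocusSet":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        if not sequences:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(sequences=sequences)


@dataclass
class PseudoReference:
    """Concatenated parent loci with the locus <-> coordinate map.

    Attributes
    ----------
    sequence
        The concatenated reference sequence.
    offsets
        Ordered mapping ``locus_id -> (start0, end0)``, half-open 0-based;
        intervals are contiguous, non-overlapping and cover the sequence.
    contig
        Name of the single reference contig.
    """

    sequence: str
    offsets: Dict[str, Tuple[int, int]]
    contig: str = "pseudoref"

    def __post_init__(self) -> None:
        expected = 0
        for locus_id, (start, end) in self.offsets.items():
            if start != expected or end <= start:
                raise ValueError(
                    f"offset table is not a contiguous partition at {locus_id!r}"
                )
            expected = end
        if expected != len(self.sequence):
            raise ValueError("offset table does not cover the reference sequence")
        self._locus_ids = list(self.offsets)
        self._starts = [self.offsets[lid][0] for lid in self._locus_ids]

    def __len__(self) -> int:
        return len(self.sequence)

    def map_coordinate(self, global_pos: int) -> Tuple[str, int]:
        """Map a 1-based global position to ``(locus_id, 1-based offset)``."""
        if not 1 <= global_pos <= len(self.sequence):
            raise ValueError(
                f"position {global_pos} outside reference [1, {len(self.sequence)}]"
            )
        idx = bisect_right(self._starts, global_pos - 1) - 1
        locus_id = self._locus_ids[idx]
        start, _ = self.offsets[locus_id]
        return locus_id, global_pos - start

    def to_global(self, locus_id: str, offset: int) -> int:
        """Inverse of :meth:`map_coordinate`: 1-based offset -> 1-based position."""
        start, end = self.offsets[locus_id]
        if not 1 <= offset <= end - start:
            raise ValueError(f"offset {offset} outside locus {locus_id!r}")
        return start + offset

    def base_at(self, global_pos: int) -> str:
        return self.sequence[global_pos - 1]

    # ---- I/O ----------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.sequence), id=self.contig, description="")
        SeqIO.write([rec], str(path), "fasta")

    def write_offsets(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(lid, s, e) for lid, (s, e) in self.offsets.items()],
            columns=["locus_id", "start0", "end0"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta: str | Path, offsets_tsv: str | Path) -> "PseudoReference":
        records = list(SeqIO.parse(str(fasta), "fasta"))
        if len(records) != 1:
            raise ValueError("pseudo-reference FASTA must contain a single contig")
        df = pd.read_csv(offsets_tsv, sep="\t")
        offsets = {
            str(r.locus_id): (int(r.start0), int(r.end0)) for r in df.itertuples()
        }
        return cls(
            sequence=str(records[0].seq).upper(), offsets=offsets, contig=records[0].id
        )


def build_pseudoreference(
    loci: RadLocusSet | Mapping[str, str] | Iterable[Tuple[str, str]],
    contig: str = "pseudoref",
) -> PseudoReference:
    """Concatenate consensus loci (sorted by locus id) into a pseudo-reference.

    Accepts a :class:`RadLocusSet`, a mapping, or an iterable of
    ``(locus_id, sequence)`` pairs; the latter raises on duplicate ids.
    """
    if isinstance(loci, RadLocusSet):
        sequences = loci.sequences
    elif isinstance(loci, Mapping):
        sequences = dict(loci)
    else:
        sequences = {}
        for locus_id, seq in loci:
            if locus_id in sequences:
                raise ValueError(f"duplicate locus id {locus_id!r}")
            sequences[locus_id] = seq
    if not sequences:
        raise ValueError("cannot build a pseudo-reference from zero loci")

    offsets: Dict[str, Tuple[int, int]] = {}
    parts = []
    cursor = 0
    for locus_id in sorted(sequences):
        seq = sequences[locus_id].upper()
        if not seq:
            raise ValueError(f"locus {locus_id!r} has an empty sequence")
        offsets[locus_id] = (cursor, cursor + len(seq))
        parts.append(seq)
        cursor += len(seq)
    return PseudoReference(sequence="".join(parts), offsets=offsets, contig=contig)


def filter_loci_by_coverage(loci: RadLocusSet, m: int) -> RadLocusSet:
    """Retain loci present in at least ``m`` samples (the RAD ``m`` threshold).

    Emits a warning and returns an empty set when ``m`` exceeds the number of
    samples recorded in the presence flags.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n_samples = loci.n_samples()
    if n_samples and m > n_samples:
        warnings.warn(
            f"m={m} exceeds the {n_samples} recorded samples; no locus can pass",
            stacklevel=2,
        )
    kept = {lid for lid in loci.sequences if loci.presence_count(lid) >= m}
    return RadLocusSet(
        sequences={lid: loci.sequences[lid] for lid in kept},
        presence={lid: set(loci.presence[lid]) for lid in kept if lid in loci.presence},
    )
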