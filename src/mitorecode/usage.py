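"""Codon counting, family occupancy, and liberated-codon detection.

A codon family that a genome has stopped using altogether is "liberated": it
can later be captured with a new amino-acid identity without disturbing any
existing protein.  A+T-rich organellar genomes liberate codons readily —
third-position C/G codons go first — which is why this module reports, next
to raw counts, the set of unused sense codons broken down by third-position
base and a per-box occupancy table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

from Bio import SeqIO

from mitorecode.codes import (
    ALL_CODONS,
    RNA_BASES,
    FramePolicy,
    GeneticCode,
    transcribe,
)


@dataclass
class CodonUsageTable:
    counts: Dict[str, int]
    per_gene: Dict[str, Dict[str, int]]
    total_codons: int
    include_stops: bool = False

    def count(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def _iter_cds(cds_set) -> Iterable[Tuple[str, str]]:
    """Yield (gene id, sequence) from a FASTA path, SeqRecord iterable, or mapping."""
    if isinstance(cds_set, Mapping):
        yield from cds_set.items()
        return
    if isinstance(cds_set, (str, bytes)) or hasattr(cds_set, "read"):
        for rec in SeqIO.parse(cds_set, "fasta"):
            yield rec.id, str(rec.seq)
        return
    for rec in cds_set:
        yield rec.id, str(rec.seq)


def count_codons(
    cds_set,
    code: GeneticCode,
    include_stops: bool = False,
    frame_policy: FramePolicy = FramePolicy.STRICT,
) -> CodonUsageTable:
    """Count codon usage over a set of CDS.

    ``cds_set`` may be a FASTA path, an iterable of SeqRecords, or a mapping
    of gene id -> sequence.  Genes with internal stop codons are rejected
    (an internal stop signals a wrong code or frame, which would silently
    corrupt every downstream liberation call).  The terminal stop codon is
    excluded from ``counts`` unless ``include_stops`` is set.
    """
    counts: Counter = Counter()
    per_gene: Dict[str, Dict[str, int]] = {}
    for gene_id, seq in _iter_cds(cds_set):
        rna = transcribe(seq)
        if len(rna) % 3:
            if frame_policy is FramePolicy.STRICT:
                raise ValueError(
                    f"gene {gene_id!r}: length {len(rna)} is not a multiple of 3"
                )
            rna = rna[: len(rna) - len(rna) % 3]
        codons = [rna[i : i + 3] for i in range(0, len(rna), 3)]
        for i, codon in enumerate(codons[:-1]):
            if code.is_stop(codon):
                raise ValueError(
                    f"gene {gene_id!r}: internal stop codon {codon} at codon {i}"
                )
        gene_counts = Counter(codons)
        if codons and code.is_stop(codons[-1]) and not include_stops:
            gene_counts[codons[-1]] -= 1
            if gene_counts[codons[-1]] == 0:
                del gene_counts[codons[-1]]
        per_gene[gene_id] = dict(gene_counts)
        counts.update(gene_counts)
    return CodonUsageTable(
        counts=dict(counts),
        per_gene=per_gene,
        total_codons=sum(counts.values()),
        include_stops=include_stops,
    )


@dataclass
class UnusedCodonReport:
    unused: frozenset
    third_position_breakdown: Dict[str, int] = field(default_factory=dict)

    @property
    def n_unused(self) -> int:
        return len(self.unused)


def unused_codons(table: CodonUsageTable, code: GeneticCode) -> UnusedCodonReport:
    """Sense codons with zero usage, with a third-position base breakdown."""
    unused = frozenset(
        c for c in code.sense_codons if table.count(c) == 0
    )
    breakdown = Counter(c[2] for c in unused)
    return UnusedCodonReport(unused, {b: breakdown.get(b, 0) for b in RNA_BASES if breakdown.get(b, 0)})


@dataclass
class FamilyOccupancy:
    box: str                       # codon prefix, e.g. "CU"
    amino_acids: Dict[str, str]    # codon -> amino acid under the code
    used: Tuple[str, ...]
    unused: Tuple[str, ...]
    fraction_third_AU: float       # among used occurrences, weighted by count

    @property
    def codons(self):
        return tuple(sorted(self.amino_acids))


def family_occupancy(table: CodonUsageTable, code: GeneticCode):
    """Per-box occupancy report over the 16 codon boxes (sense codons only)."""
    reports = []
    for p1 in RNA_BASES:
        for p2 in RNA_BASES:
            box = p1 + p2
            codons = [box + b for b in RNA_BASES if (box + b) in code.sense_codons]
            if not codons:
                continue
            used = tuple(c for c in codons if table.count(c) > 0)
            unused = tuple(c for c in codons if table.count(c) == 0)
            total = sum(table.count(c) for c in codons)
            au = sum(table.count(c) for c in codons if c[2] in "AU")
            reports.append(
                FamilyOccupancy(
                    box=box,
                    amino_acids={c: code.amino_acid(c) for c in codons},
                    used=used,
                    unused=unused,
                    fraction_third_AU=(au / total) if total else float("nan"),
                )
            )
    return reports


def usage_to_tsv(table: CodonUsageTable, code: GeneticCode, path) -> None:
    """Write a 16-box-ordered TSV (codon, amino_acid, count)."""
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tcount\n")
        for codon in ALL_CODONS:
            aa = code.amino_acid(codon)
            if aa == "*" and not table.include_stops:
                continue
            fh.write(f"{codon}\t{aa}\t{table.count(codon)}\n")
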