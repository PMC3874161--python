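"""Conservation-based codon identity calls from ortholog protein alignments.

The idea: if a codon family has been reassigned in a target genome, the
residues that family encodes will sit, in ortholog alignments, in columns
where the *other* species show a different — often invariant — amino acid.
Reading the modal residue of well-conserved columns at the target's family
codon positions therefore reveals what the family encodes, without any
knowledge of the target's tRNA complement.

This module turns that by-eye argument into a score: for every site where
the target uses a codon of the assessed family, take the column's residue
frequencies over the other species (target excluded, to avoid circularity),
weight each site by the column's conservation (its modal frequency), keep
sites above a conservation floor, and average.  The winning amino acid must
beat the runner-up by a margin, otherwise the call is AMBIGUOUS.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO

from mitorecode.codes import GeneticCode, transcribe

GAP = "-"

NO_SIGNAL = "NO-SIGNAL"
AMBIGUOUS = "AMBIGUOUS"
ABSENT = "ABSENT"


@dataclass
class OrthologAlignment:
    """One gene's aligned proteins across species, tied to the target CDS.

    ``column_map[i]`` is the alignment column holding the target's i-th codon
    (0-based both ways); it covers exactly the non-gap positions of the
    target row, strictly increasing.
    """

    gene_id: str
    rows: Dict[str, str]          # species -> gapped residue string
    target: str                   # species id of the assessed genome
    cds: str                      # target CDS (RNA), stop already trimmed
    column_map: List[int]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"gene {self.gene_id}: unequal row lengths {lengths}")
        if self.target not in self.rows:
            raise ValueError(f"gene {self.gene_id}: target {self.target!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def codon(self, i: int) -> str:
        return self.cds[3 * i : 3 * i + 3]


def map_codons_to_columns(cds: str, target_row: str) -> List[int]:
    """Pair each codon of ``cds`` with the alignment column of its residue.

    ``target_row`` is the gapped residue string of the target species.  The
    ungapped row must have exactly one residue per codon (terminal stop
    already trimmed from the CDS).
    """
    rna = transcribe(cds)
    if len(rna) % 3:
        raise ValueError(f"CDS length {len(rna)} not a multiple of 3")
    n_codons = len(rna) // 3
    columns = [i for i, ch in enumerate(target_row) if ch != GAP]
    if len(columns) != n_codons:
        raise ValueError(
            f"target row has {len(columns)} residues but CDS encodes {n_codons} codons"
        )
    return columns


@dataclass
class ColumnProfile:
    frequencies: Dict[str, float]   # residue -> frequency over non-gap, non-excluded rows
    weight: float                   # conservation weight = modal frequency
    n_rows: int                     # rows contributing

    @property
    def empty(self) -> bool:
        return self.n_rows == 0

    def frequency(self, residue: str) -> float:
        return self.frequencies.get(residue, 0.0)


def column_profile(
    alignment: OrthologAlignment,
    column: int,
    exclude: Sequence[str] = (),
) -> ColumnProfile:
    """Residue frequencies at one column over non-excluded species.

    The target species is always excluded in scoring; pass it in ``exclude``
    (plus any species suspected to share the reassignment).  An all-gap
    column after exclusion yields an empty, zero-weight profile.
    """
    if not 0 <= column < alignment.n_columns:
        raise IndexError(f"column {column} out of range")
    excluded = set(exclude)
    residues = [
        row[column]
        for sp, row in alignment.rows.items()
        if sp not in excluded and row[column] != GAP
    ]
    if not residues:
        return ColumnProfile({}, 0.0, 0)
    counts = Counter(residues)
    n = len(residues)
    freqs = {aa: c / n for aa, c in counts.items()}
    return ColumnProfile(freqs, max(freqs.values()), n)


@dataclass
class SiteEvidence:
    gene_id: str
    codon_index: int
    codon: str
    column: int
    weight: float
    frequencies: Dict[str, float]


@dataclass
class ReassignmentCall:
    family: Tuple[str, ...]
    n_sites: int                  # usable sites (weight >= min_weight)
    support: Dict[str, float]
    call: str                     # amino acid, AMBIGUOUS, NO-SIGNAL or ABSENT
    sites: List[SiteEvidence] = field(default_factory=list)
    margin: float = 0.2


def _decide(support: Dict[str, float], margin: float) -> str:
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    if not ranked:
        return NO_SIGNAL
    best, best_score = ranked[0]
    runner = ranked[1][1] if len(ranked) > 1 else 0.0
    return best if best_score - runner >= margin else AMBIGUOUS


def score_codon_family(
    alignments: Sequence[OrthologAlignment],
    family: Sequence[str],
    code_for_others: GeneticCode,
    min_weight: float = 0.5,
    margin: float = 0.2,
    exclude: Sequence[str] = (),
) -> ReassignmentCall:
    """Score the amino-acid identity of a codon family in the target genome.

    support(a) = sum_i w_i * f_i(a) / sum_i w_i over sites i where the target
    uses a family codon and the column's conservation weight w_i (modal
    frequency over the other species) is >= ``min_weight``.  The call is the
    argmax when it beats the runner-up by ``margin``; with zero family usage
    the result is ABSENT (a codon-capture candidate); with usage but no site
    passing the conservation floor it is NO-SIGNAL.
    """
    fam = {transcribe(c) for c in family}
    sites: List[SiteEvidence] = []
    any_usage = False
    for aln in alignments:
        excl = set(exclude) | {aln.target}
        n_codons = len(aln.column_map)
        for i in range(n_codons):
            if aln.codon(i) not in fam:
                continue
            any_usage = True
            col = aln.column_map[i]
            prof = column_profile(aln, col, exclude=excl)
            if prof.empty or prof.weight < min_weight:
                continue
            sites.append(
                SiteEvidence(aln.gene_id, i, aln.codon(i), col, prof.weight, prof.frequencies)
            )
    fam_sorted = tuple(sorted(fam))
    if not any_usage:
        return ReassignmentCall(fam_sorted, 0, {}, ABSENT, [], margin)
    if not sites:
        return ReassignmentCall(fam_sorted, 0, {}, NO_SIGNAL, [], margin)
    wsum = sum(s.weight for s in sites)
    support: Dict[str, float] = {}
    for s in sites:
        for aa, f in s.frequencies.items():
            support[aa] = support.get(aa, 0.0) + s.weight * f
    support = {aa: v / wsum for aa, v in support.items()}
    return ReassignmentCall(fam_sorted, len(sites), support, _decide(support, margin), sites, margin)


def codon_families(code: GeneticCode) -> List[Tuple[str, ...]]:
    """Partition each codon box's sense codons by amino acid under ``code``.

    This yields the synonymous codon groups a single tRNA box-cover could
    serve (e.g. the full CUN family under codes where the box is uniform,
    or the UUU/UUC vs UUA/UUG split of the UUN box).
    """
    from mitorecode.codes import RNA_BASES

    fams: List[Tuple[str, ...]] = []
    for p1 in RNA_BASES:
        for p2 in RNA_BASES:
            box = p1 + p2
            by_aa: Dict[str, List[str]] = {}
            for b in RNA_BASES:
                codon = box + b
                if codon in code.sense_codons:
                    by_aa.setdefault(code.amino_acid(codon), []).append(codon)
            for group in by_aa.values():
                fams.append(tuple(sorted(group)))
    return fams


def call_all_families(
    alignments: Sequence[OrthologAlignment],
    code_for_others: GeneticCode,
    min_weight: float = 0.5,
    margin: float = 0.2,
    exclude: Sequence[str] = (),
    per_codon: bool = True,
) -> List[ReassignmentCall]:
    """Genome-wide sweep: one call per synonymous codon family, plus
    per-single-codon calls when ``per_codon`` is set (only the CUA member of
    a family may carry experimental confirmation, say)."""
    calls = []
    for fam in codon_families(code_for_others):
        calls.append(
            score_codon_family(alignments, fam, code_for_others, min_weight, margin, exclude)
        )
        if per_codon and len(fam) > 1:
            for codon in fam:
                calls.append(
                    score_codon_family(
                        alignments, (codon,), code_for_others, min_weight, margin, exclude
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# IO


def read_ortholog_set(
    alignment_dir,
    cds_fasta,
    target: str,
    stop_trimmed: bool = False,
    code: Optional[GeneticCode] = None,
) -> List[OrthologAlignment]:
    """Load aligned FASTA files (one per gene, ids = species) plus the target
    CDS multi-FASTA keyed by gene id; gene id = alignment file stem."""
    cds = {rec.id: str(rec.seq) for rec in SeqIO.parse(cds_fasta, "fasta")}
    alignments = []
    for fname in sorted(os.listdir(alignment_dir)):
        stem, ext = os.path.splitext(fname)
        if ext.lower() not in (".fa", ".fasta", ".faa", ".afa"):
            continue
        rows = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(os.path.join(alignment_dir, fname), "fasta")
        }
        if stem not in cds:
            raise ValueError(f"alignment {fname} has no CDS entry {stem!r}")
        rna = transcribe(cds[stem])
        if code is not None and len(rna) % 3 == 0 and rna[-3:] in code.stop_codons:
            rna = rna[:-3]
        cmap = map_codons_to_columns(rna, rows[target])
        alignments.append(OrthologAlignment(stem, rows, target, rna, cmap))
    return alignments


def calls_to_tsv(calls: Sequence[ReassignmentCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tn_sites\tcall\ttop_support\tsecond_support\n")
        for c in calls:
            ranked = sorted(c.support.items(), key=lambda kv: (-kv[1], kv[0]))
            top = f"{ranked[0][0]}:{ranked[0][1]:.3f}" if ranked else "."
            second = f"{ranked[1][0]}:{ranked[1][1]:.3f}" if len(ranked) > 1 else "."
            fh.write(f"{'/'.join(c.family)}\t{c.n_sites}\t{c.call}\t{top}\t{second}\n")


def calls_to_audit(calls: Sequence[ReassignmentCall]) -> list:
    """JSON-serializable per-site evidence (columns reported 1-based)."""
    out = []
    for c in calls:
        out.append(
            {
                "family": list(c.family),
                "call": c.call,
                "n_sites": c.n_sites,
                "support": {k: round(v, 6) for k, v in sorted(c.support.items())},
                "sites": [
                    {
                        "gene": s.gene_id,
                        "codon_index": s.codon_index + 1,
                        "codon": s.codon,
                        "column": s.column + 1,
                        "weight": round(s.weight, 6),
                        "profile": {k: round(v, 6) for k, v in sorted(s.frequencies.items())},
                    }
                    for s in c.sites
                ],
            }
        )
    return out
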