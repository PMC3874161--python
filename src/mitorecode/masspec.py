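"""Variant proteomes, tryptic digestion, and peptide-level mass matching.

To decide experimentally what a candidate codon family encodes, the target's
proteome is inferred three ways — every family codon translated as each
candidate amino acid — and observed peptides are matched against all
variants.  A tryptic peptide that covers a family codon position
("discriminating") is compatible only with the variant whose residue it
carries; identifying it pins the codon's meaning at the protein level.

Digestion and monoisotopic masses go through pyteomics; matching is at the
peptide level (sequence identity, or monoisotopic mass within a ppm
tolerance), which is the level at which the codon-identity verdict is
decided.  Fragment-ion scoring is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from pyteomics import mass as _pmass

from mitorecode.codes import (
    FramePolicy,
    GeneticCode,
    InternalStopPolicy,
    translate_cds,
    transcribe,
)
from mitorecode.usage import _iter_cds

WATER = 18.0105646863
CARBAMIDOMETHYL = 57.02146
DEFAULT_FIXED_MODS = {"C": CARBAMIDOMETHYL}

RESIDUE_MONO = dict(_pmass.std_aa_mass)


def peptide_mass(seq: str, fixed_mods: Optional[Dict[str, float]] = None) -> float:
    """Monoisotopic peptide mass in Da (water included, fixed mods added).

    The default fixed modification is carbamidomethyl-Cys (+57.02146),
    matching standard reduction/alkylation sample prep.  An empty sequence
    returns the water mass alone (degenerate but defined).
    """
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    total = WATER
    for aa in seq:
        try:
            total += RESIDUE_MONO[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
        total += fixed_mods.get(aa, 0.0)
    return total


# ---------------------------------------------------------------------------
# variant proteomes


@dataclass
class VariantProteome:
    variant: str                                   # candidate amino acid, e.g. "A"
    proteins: Dict[str, str]
    variant_positions: Dict[str, List[Tuple[int, str]]]   # gene -> (residue idx, codon)


def variant_proteomes(
    cds_set,
    family: Sequence[str],
    candidates: Sequence[str],
    code: GeneticCode,
) -> List[VariantProteome]:
    """One inferred proteome per candidate amino acid for the assessed family.

    All variants share identical ``variant_positions`` and differ only
    there.  ``code`` supplies the translation of every non-family codon.
    """
    fam = {transcribe(c) for c in family}
    base: Dict[str, List[str]] = {}
    positions: Dict[str, List[Tuple[int, str]]] = {}
    for gene_id, seq in _iter_cds(cds_set):
        rna = transcribe(seq)
        if len(rna) % 3:
            raise ValueError(f"gene {gene_id!r}: CDS not triplet-clean")
        codons = [rna[i : i + 3] for i in range(0, len(rna), 3)]
        if codons and code.is_stop(codons[-1]):
            codons = codons[:-1]
        residues, pos = [], []
        for i, codon in enumerate(codons):
            if codon in fam:
                pos.append((i, codon))
                residues.append("?")      # filled per variant
            else:
                aa = code.amino_acid(codon)
                if aa == "*":
                    raise ValueError(f"gene {gene_id!r}: internal stop {codon}")
                residues.append(aa)
        base[gene_id] = residues
        positions[gene_id] = pos
    out = []
    for aa in candidates:
        proteins = {
            g: "".join(aa if r == "?" else r for r in residues)
            for g, residues in base.items()
        }
        out.append(VariantProteome(aa, proteins, positions))
    return out


# ---------------------------------------------------------------------------
# tryptic digestion


@dataclass
class PeptideRecord:
    gene: str
    start: int                 # 0-based residue coords, half-open
    end: int
    sequence: str
    mass: float
    missed_cleavages: int
    discriminating: bool = False
    variants_separated: Tuple[str, ...] = ()


def _cleavage_sites(protein: str) -> List[int]:
    """Positions after which trypsin cuts: K/R not followed by P."""
    return [
        i + 1
        for i, aa in enumerate(protein[:-1])
        if aa in "KR" and protein[i + 1] != "P"
    ]


def tryptic_digest(
    protein: str,
    missed_cleavages: int = 0,
    gene: str = "protein",
    fixed_mods: Optional[Dict[str, float]] = None,
) -> List[PeptideRecord]:
    """In-silico trypsin digest with spans and monoisotopic masses.

    Cleaves after K or R except before P; peptides with up to
    ``missed_cleavages`` internal uncut sites are appended.  The 0-missed
    peptides concatenate back to the protein.
    """
    bounds = [0] + _cleavage_sites(protein) + [len(protein)]
    records = []
    for mc in range(missed_cleavages + 1):
        for i in range(len(bounds) - 1 - mc):
            s, e = bounds[i], bounds[i + 1 + mc]
            seq = protein[s:e]
            if seq:
                records.append(
                    PeptideRecord(gene, s, e, seq, peptide_mass(seq, fixed_mods), mc)
                )
    return records


def digest_proteome(
    proteome: VariantProteome,
    missed_cleavages: int = 0,
    fixed_mods: Optional[Dict[str, float]] = None,
) -> List[PeptideRecord]:
    """Digest every protein of a variant, flagging discriminating peptides
    (those overlapping >=1 family codon position)."""
    records = []
    for gene, protein in proteome.proteins.items():
        var_pos = {i for i, _ in proteome.variant_positions.get(gene, [])}
        for rec in tryptic_digest(protein, missed_cleavages, gene, fixed_mods):
            overlap = {i for i in var_pos if rec.start <= i < rec.end}
            rec.discriminating = bool(overlap)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# matching


@dataclass
class ObservationMatch:
    observation: str                    # the sequence, or the mass rendered as text
    mode: str                           # "sequence" or "mass"
    per_variant: Dict[str, List[PeptideRecord]] = field(default_factory=dict)
    consistent_variants: Tuple[str, ...] = ()
    discriminating: bool = False


@dataclass
class MatchReport:
    matches: List[ObservationMatch]
    unmatched: List[str]
    verdict: Tuple[str, ...]            # variants consistent with ALL discriminating evidence


def match_observed(
    observed: Sequence,
    proteomes: Sequence[VariantProteome],
    tolerance_ppm: float = 10.0,
    missed_cleavages: int = 1,
    fixed_mods: Optional[Dict[str, float]] = None,
) -> MatchReport:
    """Assign observed peptides (sequences or masses) to variant digests.

    Sequence observations match by identity; numeric observations match any
    peptide whose monoisotopic mass lies within ``tolerance_ppm``.  For each
    observation the consistent variants are those whose digest contains a
    matching peptide; a match to a non-discriminating peptide is consistent
    with every variant.  The overall verdict intersects the consistent sets
    of all discriminating observations (order-independent).
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    digests = {
        p.variant: digest_proteome(p, missed_cleavages, fixed_mods) for p in proteomes
    }
    all_variants = tuple(p.variant for p in proteomes)
    matches, unmatched = [], []
    verdict = set(all_variants)
    for obs in observed:
        is_mass = isinstance(obs, (int, float))
        per_variant: Dict[str, List[PeptideRecord]] = {}
        for variant, records in digests.items():
            if is_mass:
                hits = [
                    r
                    for r in records
                    if abs(r.mass - obs) / obs * 1e6 <= tolerance_ppm
                ]
            else:
                hits = [r for r in records if r.sequence == obs]
            if hits:
                per_variant[variant] = hits
        if not per_variant:
            unmatched.append(str(obs))
            continue
        discriminating = any(r.discriminating for recs in per_variant.values() for r in recs)
        consistent = (
            tuple(sorted(per_variant)) if discriminating else all_variants
        )
        if discriminating:
            verdict &= set(consistent)
        matches.append(
            ObservationMatch(
                str(obs),
                "mass" if is_mass else "sequence",
                per_variant,
                consistent,
                discriminating,
            )
        )
    return MatchReport(matches, unmatched, tuple(sorted(verdict)))


def infer_protein(cds: str, code: GeneticCode) -> str:
    """Plain translation helper (terminal stop trimmed)."""
    return translate_cds(cds, code, FramePolicy.STRICT, InternalStopPolicy.ERROR)
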