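"""Genetic-code tables, translation, and wobble decoding arithmetic.

The central objects are :class:`GeneticCode` (a 64-codon table plus a set of
codons an organism avoids in practice) and :class:`WobbleClass` (what a tRNA
anticodon's position-34 base can read at the codon third position).  On top of
these the module computes, per codon box, the exact minimum number of distinct
anticodons needed to read every sense codon — the arithmetic behind the
observation that an organellar genome can decode its proteome with ~25 or
fewer tRNA species when unmodified U34 "superwobbles" across all four third
positions.

All codons are handled in the RNA alphabet; DNA input is transcribed on entry.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Data import CodonTable as _NCBICodonTable

STOP = "*"
RNA_BASES = "UCAG"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

ALL_CODONS = tuple(
    a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES
)


def transcribe(seq: str) -> str:
    """Uppercase and convert T to U; validate the alphabet."""
    rna = seq.upper().replace("T", "U")
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return rna


def reverse_complement(rna: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(rna))


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table with an organism-level set of avoided codons.

    Parameters
    ----------
    name : str
        Short identifier (e.g. ``"yeast-mito"``).
    table : mapping
        RNA codon -> one-letter amino acid, or ``"*"`` for stop.  Must cover
        all 64 codons.
    avoided : frozenset of str
        Sense codons the genome is observed (or predicted) to avoid.  They
        still translate; the flag records usage, not chemistry.
    """

    name: str
    table: Mapping[str, str]
    avoided: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        keys = set(self.table)
        if keys != set(ALL_CODONS):
            missing = set(ALL_CODONS) - keys
            extra = keys - set(ALL_CODONS)
            raise ValueError(
                f"codon table must have exactly the 64 RNA codons "
                f"(missing {sorted(missing)[:4]}, extra {sorted(extra)[:4]})"
            )
        bad = {aa for aa in self.table.values() if aa != STOP and aa not in AMINO_ACIDS}
        if bad:
            raise ValueError(f"non-canonical amino acid value(s): {sorted(bad)}")
        if not set(self.avoided) <= self.sense_codons:
            raise ValueError("avoided codons must be sense codons")

    @property
    def sense_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.table.items() if aa != STOP)

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.table.items() if aa == STOP)

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == STOP

    def amino_acid(self, codon: str) -> str:
        return self.table[codon]


def _from_ncbi(name: str, ncbi_id: int, avoided: Iterable[str] = ()) -> GeneticCode:
    t = _NCBICodonTable.unambiguous_rna_by_id[ncbi_id]
    table = dict(t.forward_table)
    for stop in t.stop_codons:
        table[stop] = STOP
    return GeneticCode(name, table, frozenset(avoided))


def _ashbya_mito() -> GeneticCode:
    """Yeast-mito table with the whole CUN family reassigned to Ala.

    CUC and CUG are flagged avoided: the genome uses only CUA/CUU, but the
    U34 tRNA would superwobble-read all four family members, so the table
    encodes the Ala prediction for the unused pair as well.
    """
    base = _from_ncbi("ashbya-mito", 3)
    table = dict(base.table)
    for codon in ("CUU", "CUC", "CUA", "CUG"):
        table[codon] = "A"
    return GeneticCode("ashbya-mito", table, frozenset({"CUC", "CUG"}))


BUILTIN_CODES = {
    "standard": lambda: _from_ncbi("standard", 1),
    "yeast-mito": lambda: _from_ncbi("yeast-mito", 3),
    "vertebrate-mito": lambda: _from_ncbi("vertebrate-mito", 2),
    "ashbya-mito": _ashbya_mito,
}


def get_code(name: str) -> GeneticCode:
    """Return a built-in genetic code by name."""
    try:
        return BUILTIN_CODES[name]()
    except KeyError:
        raise KeyError(
            f"unknown code {name!r}; built-ins: {sorted(BUILTIN_CODES)}"
        ) from None


def load_code_tsv(path, name: str = "custom", avoided: Iterable[str] = ()) -> GeneticCode:
    """Load a custom code from a two-column TSV (codon, amino-acid/STOP)."""
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, aa = line.split("\t")[:2]
            aa = aa.strip().upper()
            table[transcribe(codon)] = STOP if aa in (STOP, "STOP") else aa
    return GeneticCode(name, table, frozenset(avoided))


class FramePolicy(enum.Enum):
    STRICT = "strict"          # non-triplet length is an error
    TRIM = "trim"              # drop trailing 1-2 bases


class InternalStopPolicy(enum.Enum):
    ERROR = "error"
    MARK = "mark"              # internal stops rendered as '*'


def translate_cds(
    cds: str,
    code: GeneticCode,
    frame_policy: FramePolicy = FramePolicy.STRICT,
    internal_stop: InternalStopPolicy = InternalStopPolicy.ERROR,
) -> str:
    """Translate a coding sequence; the terminal stop codon is trimmed.

    Accepts DNA or RNA.  Raises on non-triplet length under the strict frame
    policy and on internal stops under the error policy.
    """
    rna = transcribe(cds)
    if len(rna) % 3:
        if frame_policy is FramePolicy.STRICT:
            raise ValueError(f"CDS length {len(rna)} is not a multiple of 3")
        rna = rna[: len(rna) - len(rna) % 3]
    codons = [rna[i : i + 3] for i in range(0, len(rna), 3)]
    if codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
    out = []
    for i, codon in enumerate(codons):
        aa = code.amino_acid(codon)
        if aa == STOP and internal_stop is InternalStopPolicy.ERROR:
            raise ValueError(f"internal stop codon {codon} at codon index {i}")
        out.append(aa)
    return "".join(out)


class WobbleClass(enum.Enum):
    """Decoding capacity of the anticodon position-34 base.

    The value is (required base 34, frozenset of readable codon third bases).
    An unmodified U34 superwobbles across all four; a modified U34 is
    restricted to purine-ending codons; G34 reads the pyrimidines; C34 and
    A34 read a single codon each.
    """

    U_UNMODIFIED = ("U", frozenset("ACGU"))
    U_MODIFIED = ("U", frozenset("AG"))
    G = ("G", frozenset("CU"))
    C = ("C", frozenset("G"))
    A = ("A", frozenset("U"))

    @property
    def base34(self) -> str:
        return self.value[0]

    @property
    def reads(self) -> frozenset:
        return self.value[1]


DEFAULT_WOBBLE_CLASSES = (
    WobbleClass.U_UNMODIFIED,
    WobbleClass.U_MODIFIED,
    WobbleClass.G,
    WobbleClass.C,
    WobbleClass.A,
)


def anticodon_read_set(anticodon: str, wobble: WobbleClass) -> frozenset:
    """Codons read by an anticodon (5'->3') under a wobble class.

    Positions 35/36 of the anticodon Watson-Crick pair codon positions 2/1;
    position 34 (the anticodon's first base) pairs the codon third position
    according to the wobble class.
    """
    ac = transcribe(anticodon)
    if len(ac) != 3:
        raise ValueError("anticodon must be a 3-mer")
    if ac[0] != wobble.base34:
        raise ValueError(
            f"wobble class {wobble.name} requires base 34 = {wobble.base34}, "
            f"got {ac[0]} in {ac}"
        )
    prefix = _COMPLEMENT[ac[2]] + _COMPLEMENT[ac[1]]
    return frozenset(prefix + third for third in wobble.reads)


def anticodon_for(box_prefix: str, wobble: WobbleClass) -> str:
    """The anticodon whose read set sits in the codon box ``box_prefix``."""
    return wobble.base34 + _COMPLEMENT[box_prefix[1]] + _COMPLEMENT[box_prefix[0]]


class UncoverableCodonError(ValueError):
    def __init__(self, codon: str):
        self.codon = codon
        super().__init__(f"sense codon {codon} cannot be covered under the wobble class table")


def _box_candidates(prefix: str, code: GeneticCode, classes):
    """Valid (anticodon, class, read set) triples for one codon box.

    A candidate is valid when its read set neither touches a stop codon nor
    mixes amino acids.
    """
    out = []
    for wc in classes:
        ac = anticodon_for(prefix, wc)
        reads = anticodon_read_set(ac, wc)
        aas = {code.table[c] for c in reads}
        if STOP in aas or len(aas) != 1:
            continue
        out.append((ac, wc, reads))
    return out


def minimal_anticodon_set(code: GeneticCode, classes=DEFAULT_WOBBLE_CLASSES):
    """Exact minimum anticodon set reading every sense codon of ``code``.

    Codon positions 1-2 fix the box, so the set cover decouples into 16
    independent per-box covers, each solved by exhaustive subset enumeration
    over the <=5 admissible anticodons.  Returns ``(count, chosen)`` with
    ``chosen`` a list of (anticodon, WobbleClass) pairs.
    """
    chosen = []
    for p1, p2 in itertools.product(RNA_BASES, repeat=2):
        prefix = p1 + p2
        targets = {prefix + b for b in RNA_BASES} & code.sense_codons
        if not targets:
            continue
        cands = _box_candidates(prefix, code, classes)
        best = None
        for r in range(1, len(cands) + 1):
            for subset in itertools.combinations(cands, r):
                covered = frozenset().union(*(c[2] for c in subset))
                if targets <= covered:
                    best = subset
                    break
            if best is not None:
                break
        if best is None:
            uncovered = targets - frozenset().union(
                frozenset(), *(c[2] for c in cands)
            )
            raise UncoverableCodonError(sorted(uncovered)[0])
        chosen.extend((ac, wc) for ac, wc, _ in best)
    return len(chosen), chosen
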