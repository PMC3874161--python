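"""tRNA cloverleaf parsing, identity elements, and synthetase recognition.

Aminoacyl-tRNA synthetases pick their substrates by a handful of sequence
and structure landmarks rather than the anticodon alone: AlaRS keys on the
G3:U70 wobble pair in the acceptor stem; HisRS on the extra G at position −1
pairing the C73 discriminator (plus the GUG anticodon); the yeast
mitochondrial ThrRS (MST1) on an enlarged 8-nt anticodon loop; LeuRS on an
A73 discriminator.  A tRNA matched by exactly one synthetase is orthogonal —
the prerequisite for an unambiguous codon reassignment.

This module parses a tRNA gene into numbered landmarks (conventional tRNA
numbering: acceptor pairs 1:72 … 7:66, anticodon 34–36, discriminator 73,
optional genomic −1 base), reads the identity elements off the landmarks,
evaluates a small editable rule table per synthetase, and supports landmark-
coordinate point mutations and insertions/deletions with automatic re-parse.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from mitorecode.codes import transcribe

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _paired(a: str, b: str) -> bool:
    """Watson-Crick or G:U wobble."""
    return (a, b) in _PAIRS


class CloverleafParseError(ValueError):
    pass


@dataclass
class TRNAGene:
    """A parsed tRNA with landmark indices into ``body``.

    ``body`` runs from position 1 through the discriminator (73); the −1 base
    and the 3' CCA, when present, are held separately so landmark numbering
    is stable under maturation state.
    """

    id: str
    body: str
    minus_one: Optional[str] = None
    cca_present: bool = False
    cca_encoded: bool = False
    structure: Optional[str] = None
    # landmarks (indices into body)
    acceptor_pairs: List[Tuple[int, int]] = field(default_factory=list)  # pair k = entry k-1
    loop_start: int = 0
    loop_len: int = 0
    anticodon_index: int = 0

    @property
    def sequence(self) -> str:
        """Full 5'->3' sequence as given (−1 base and CCA included)."""
        return (self.minus_one or "") + self.body + ("CCA" if self.cca_present else "")

    @property
    def discriminator(self) -> str:
        return self.body[-1]

    @property
    def anticodon(self) -> str:
        return self.body[self.anticodon_index : self.anticodon_index + 3]

    @property
    def anticodon_loop(self) -> str:
        return self.body[self.loop_start : self.loop_start + self.loop_len]

    def pair(self, n: int) -> Tuple[str, str]:
        """Bases of acceptor-stem pair n:(73-n), n in 1..7."""
        i, j = self.acceptor_pairs[n - 1]
        return self.body[i], self.body[j]

    def index_of(self, position: int) -> int:
        """Map a canonical landmark number to a ``body`` index.

        Supported: 1–7 (acceptor 5'), 31 (last 5' anticodon-stem base),
        34–36 (anticodon), 66–72 (acceptor 3'), 73 (discriminator).
        """
        n = len(self.body)
        if 1 <= position <= 7:
            return position - 1
        if 66 <= position <= 72:
            return n - 1 - (73 - position)
        if position == 73:
            return n - 1
        if position == 31:
            return self.loop_start - 1
        if 34 <= position <= 36:
            return self.anticodon_index + (position - 34)
        raise KeyError(f"position {position} is not a mapped landmark")


def _stem_score(body: str, i: int, j_end: int, stem_len: int) -> int:
    """Complementarity of body[i:i+stem_len] with the strand closing at
    j_end (exclusive): Watson-Crick pairs score 2, G:U wobbles 1."""
    score = 0
    for t in range(stem_len):
        a, b = body[i + t], body[j_end - 1 - t]
        if (a, b) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
            score += 2
        elif (a, b) in (("G", "U"), ("U", "G")):
            score += 1
    return score


def _best_hairpin_score(body: str, lo: int, hi: int, stem_len: int,
                        loop_lens) -> int:
    """Best hairpin (stem + loop + stem) score inside body[lo:hi]."""
    best = 0
    for loop_len in loop_lens:
        arm = 2 * stem_len + loop_len
        for i in range(lo, hi - arm + 1):
            best = max(best, _stem_score(body, i, i + arm, stem_len))
    return best


def _find_anticodon_arm(body: str) -> Tuple[int, int, int]:
    """Locate the anticodon hairpin heuristically.

    Each candidate 5-bp-stem/7-9-nt-loop window in the central region is
    scored together with the best 4-bp D-arm hairpin that fits before it and
    the best 5-bp T-arm hairpin after it — a chance stem in the wrong place
    leaves no room for well-paired flanking arms, so scoring the whole
    cloverleaf decomposition discriminates far better than the anticodon
    stem alone.  Ties prefer the canonical 7-nt loop, then centrality.
    Returns (loop_start, loop_len, anticodon-stem score).
    """
    n = len(body)
    center = n / 2
    best = None
    for loop_len in (7, 8, 9):
        for i in range(8, n - 8 - (10 + loop_len) + 1):
            arm_center = i + (10 + loop_len) / 2
            if abs(arm_center - center) > 10:
                continue
            ac = _stem_score(body, i, i + 10 + loop_len, 5)
            if ac < 8:
                continue
            d = _best_hairpin_score(body, 8, i, 4, range(4, 13))
            t = _best_hairpin_score(body, i + 10 + loop_len, n - 8, 5, (7,))
            key = (ac + d + t, -loop_len, -abs(arm_center - center))
            if best is None or key > best[0]:
                best = (key, i + 5, loop_len, ac)
    if best is None:
        raise CloverleafParseError(
            "no viable anticodon hairpin (no central 5-bp stem with a 7-9 nt loop)"
        )
    return best[1], best[2], best[3]


def _hairpins_from_structure(structure: str) -> List[Tuple[int, int]]:
    """(loop_start, loop_len) of each hairpin loop in a dot-bracket string."""
    stack, pairs = [], {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise CloverleafParseError("unbalanced dot-bracket structure")
            pairs[stack.pop()] = i
    if stack:
        raise CloverleafParseError("unbalanced dot-bracket structure")
    paired_positions = set(pairs) | set(pairs.values())
    hairpins = []
    for i, j in sorted(pairs.items()):
        if not any(k in paired_positions for k in range(i + 1, j)):
            hairpins.append((i + 1, j - i - 1))
    return hairpins


def parse_cloverleaf(
    seq: str,
    structure: Optional[str] = None,
    id: str = "trna",
    has_minus_one: bool = False,
    cca: Optional[bool] = None,
    cca_encoded: bool = False,
) -> TRNAGene:
    """Parse a tRNA sequence (DNA or RNA, 5'->3') into numbered landmarks.

    ``has_minus_one`` marks the first base as the genomic −1 position (the
    histidine-type 5' extension).  ``cca=None`` auto-detects a 3'-terminal
    CCA; pass an explicit bool when the gene body genuinely ends in CCA.
    When a dot-bracket ``structure`` is given, the anticodon loop is taken
    from its central hairpin; otherwise a complementarity heuristic is used.
    """
    rna = transcribe(seq)
    if not 60 <= len(rna) <= 95:
        raise CloverleafParseError(f"sequence length {len(rna)} outside 60-95 nt")
    minus_one = None
    struct = structure
    if has_minus_one:
        minus_one, rna = rna[0], rna[1:]
        if struct is not None:
            struct = struct[1:]
    cca_present = rna.endswith("CCA") if cca is None else cca
    body = rna[:-3] if cca_present else rna
    if struct is not None and cca_present:
        struct = struct[: len(body)]
    if struct is not None and len(struct) != len(body):
        raise CloverleafParseError("structure length does not match sequence body")

    # acceptor stem: pair k = (k-1) with (len-1-k); position 73 unpaired at the end
    n = len(body)
    pairs = [(k, n - 2 - k) for k in range(7)]
    n_comp = sum(_paired(body[i], body[j]) for i, j in pairs)
    if n_comp < 5:
        raise CloverleafParseError(
            f"acceptor stem only {n_comp}/7 complementary — not a cloverleaf 5'/3' anchoring"
        )

    if struct is not None:
        hairpins = _hairpins_from_structure(struct)
        if not hairpins:
            raise CloverleafParseError("structure contains no hairpin loop")
        mid = [(ls, ll) for ls, ll in hairpins]
        # central hairpin: closest to the sequence centre
        loop_start, loop_len = min(
            mid, key=lambda h: abs((h[0] + h[1] / 2) - n / 2)
        )
        if loop_len not in (7, 8, 9):
            raise CloverleafParseError(
                f"anticodon loop length {loop_len} outside 7-9 nt"
            )
    else:
        loop_start, loop_len, _ = _find_anticodon_arm(body)

    # anticodon: centred in a 7-nt loop (34-36); in enlarged loops the extra
    # base sits on the 31/32 side, so the triplet shifts one slot 3'
    anticodon_index = loop_start + (2 if loop_len == 7 else 3)

    return TRNAGene(
        id=id,
        body=body,
        minus_one=minus_one,
        cca_present=cca_present,
        cca_encoded=cca_encoded,
        structure=struct,
        acceptor_pairs=pairs,
        loop_start=loop_start,
        loop_len=loop_len,
        anticodon_index=anticodon_index,
    )


# ---------------------------------------------------------------------------
# identity elements


@dataclass
class IdentityElements:
    pair_3_70: str                 # e.g. "G:U"
    minus_one: Optional[str]       # None = not provided in the input
    discriminator: str
    anticodon: str
    loop_len: int
    inserted_31: Optional[str]     # base in the extra 31-side slot of an 8-nt loop
    minus1_73_pair: Optional[bool]  # None = unknown (no −1 base in input)

    def get(self, name: str):
        return getattr(self, name)


def extract_identity_elements(g: TRNAGene) -> IdentityElements:
    b5, b3 = g.pair(3)
    minus1_73 = None if g.minus_one is None else _paired(g.minus_one, g.discriminator)
    return IdentityElements(
        pair_3_70=f"{b5}:{b3}",
        minus_one=g.minus_one,
        discriminator=g.discriminator,
        anticodon=g.anticodon,
        loop_len=g.loop_len,
        inserted_31=g.body[g.loop_start] if g.loop_len == 8 else None,
        minus1_73_pair=minus1_73,
    )


# ---------------------------------------------------------------------------
# synthetase rules

MATCH = "match"
NO_MATCH = "no-match"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class SynthetaseRule:
    synthetase: str
    conditions: Tuple[Tuple[str, str], ...]   # (element name, required value)


DEFAULT_RULES: Tuple[SynthetaseRule, ...] = (
    SynthetaseRule("AlaRS", (("pair_3_70", "G:U"),)),
    SynthetaseRule(
        "HisRS",
        (("minus_one", "G"), ("discriminator", "C"), ("anticodon", "GUG")),
    ),
    SynthetaseRule(
        "ThrRS-MST1",
        (("loop_len", "8"), ("inserted_31", "U"), ("anticodon", "UAG")),
    ),
    SynthetaseRule("LeuRS-candidate", (("discriminator", "A"),)),
)


def load_rules_tsv(path) -> Tuple[SynthetaseRule, ...]:
    """Rules are data: TSV columns (synthetase, element, required_value)."""
    grouped: Dict[str, List[Tuple[str, str]]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "synthetase":
                continue
            name, element, value = row[0], row[1], row[2]
            grouped.setdefault(name, []).append((element, value))
    return tuple(SynthetaseRule(n, tuple(c)) for n, c in grouped.items())


def write_rules_tsv(path, rules: Sequence[SynthetaseRule] = DEFAULT_RULES) -> None:
    with open(path, "w") as fh:
        fh.write("synthetase\telement\trequired_value\n")
        for r in rules:
            for element, value in r.conditions:
                fh.write(f"{r.synthetase}\t{element}\t{value}\n")


@dataclass
class SynthetasePrediction:
    synthetase: str
    status: str                       # match / no-match / undetermined
    matched: List[str] = field(default_factory=list)
    violated: List[str] = field(default_factory=list)
    unknown: List[str] = field(default_factory=list)


@dataclass
class IdentityCall:
    elements: IdentityElements
    predictions: Dict[str, SynthetasePrediction]

    @property
    def matching(self) -> List[str]:
        return sorted(n for n, p in self.predictions.items() if p.status == MATCH)

    @property
    def orthogonal(self) -> bool:
        return len(self.matching) == 1


def classify_synthetase(
    g: TRNAGene,
    rules: Sequence[SynthetaseRule] = DEFAULT_RULES,
    his_anticodon_required: bool = True,
) -> IdentityCall:
    """Evaluate each synthetase rule against the tRNA's identity elements.

    A rule matches when every condition holds; a missing element (e.g. the
    −1 base when the input did not carry genomic context) makes the rule
    UNDETERMINED rather than violated.  ``his_anticodon_required=False``
    drops anticodon conditions from the HisRS rule, to score candidates
    where a synthetase specificity change at the anticodon is hypothesised.
    """
    elements = extract_identity_elements(g)
    predictions: Dict[str, SynthetasePrediction] = {}
    for rule in rules:
        conditions = rule.conditions
        if rule.synthetase == "HisRS" and not his_anticodon_required:
            conditions = tuple(c for c in conditions if c[0] != "anticodon")
        pred = SynthetasePrediction(rule.synthetase, MATCH)
        for element, required in conditions:
            value = elements.get(element)
            label = f"{element}={required}"
            if value is None:
                pred.unknown.append(label)
            elif str(value) == required:
                pred.matched.append(label)
            else:
                pred.violated.append(f"{element}={value}!={required}")
        if pred.violated:
            pred.status = NO_MATCH
        elif pred.unknown:
            pred.status = UNDETERMINED
        predictions[rule.synthetase] = pred
    return IdentityCall(elements, predictions)


# ---------------------------------------------------------------------------
# mutations


def apply_mutation(g: TRNAGene, edits: Sequence[dict]) -> TRNAGene:
    """Apply landmark-coordinate edits and re-parse.

    Each edit is ``{"position": int, "op": "substitute"|"insert"|"delete",
    "base": str}``.  Position −1 substitutes/sets the genomic −1 base.
    ``insert`` places the base immediately 3' of the landmark (so
    ``insert at 31`` creates the enlarged 8-nt anticodon loop);
    ``delete`` removes the base immediately 3' of the landmark for position
    31 (its exact inverse) and the landmark base itself elsewhere.
    """
    for edit in edits:
        pos, op = edit["position"], edit["op"]
        base = transcribe(edit["base"]) if edit.get("base") else None
        body, minus_one = g.body, g.minus_one
        if pos == -1:
            if op in ("substitute", "insert"):
                minus_one = base
            elif op == "delete":
                minus_one = None
            else:
                raise ValueError(f"unknown edit op {op!r}")
        else:
            idx = g.index_of(pos)
            if op == "substitute":
                body = body[:idx] + base + body[idx + 1 :]
            elif op == "insert":
                body = body[: idx + 1] + base + body[idx + 1 :]
            elif op == "delete":
                at = idx + 1 if pos == 31 else idx
                body = body[:at] + body[at + 1 :]
            else:
                raise ValueError(f"unknown edit op {op!r}")
        # re-parse after every edit: inserts/deletes shift landmark indices
        g = parse_cloverleaf(
            (minus_one or "") + body,
            id=g.id,
            has_minus_one=minus_one is not None,
            cca=False,
            cca_encoded=g.cca_encoded,
        )
    return g


def mutation_from_name(name: str) -> dict:
    """Parse shorthand like ``G3A`` (substitute), ``InsU31``, ``dU31``."""
    name = name.strip()
    if name.lower().startswith("ins"):
        return {"position": int(name[4:]), "op": "insert", "base": name[3]}
    if name.startswith("d"):
        return {"position": int(name[2:]), "op": "delete", "base": None}
    return {"position": int(name[1:-1]), "op": "substitute", "base": name[-1]}
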