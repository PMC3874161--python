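"""Seeded synthetic-data generator for every pipeline input, with ground truth.

The generator emulates the data situation of a codon-reassignment study on a
small organellar genome without any downloads:

* ortholog protein families over a star phylogeny, with per-site
  conservation classes (invariant / conserved-with-retention-p / variable)
  and one lineage carrying a planted codon-family reassignment;
* an A+T-biased back-translation of the target genome with avoided codons;
* a tRNA gene built from a chosen identity-element specification, with
  genomic flanks, dot-bracket structure, and small-RNA reads drawn from
  precursor and mature(+CCA) forms at chosen depths;
* Michaelis–Menten velocity tables at chosen kinetic constants.

Everything is driven by a single integer seed through one RNG stream;
regenerating with the same truth object reproduces identical outputs.  A
star phylogeny (independent divergence of every species from the ancestor)
is deliberate: the conservation-profile inference ignores tree structure, so
tree realism would add nothing the pipeline can see.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from mitorecode.codes import GeneticCode, get_code, reverse_complement
from mitorecode.infer import OrthologAlignment, map_codons_to_columns
from mitorecode.trna import TRNAGene, parse_cloverleaf

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# truth specification


@dataclass
class SyntheticTruth:
    """Planted parameters for one synthetic study; fully serializable."""

    seed: int = 1
    # ortholog set
    species: Tuple[str, ...] = tuple(f"sp{i:02d}" for i in range(1, 10))
    target: str = "target"
    n_genes: int = 8
    gene_length: int = 120                    # codons per gene
    p_invariant: float = 0.30
    p_conserved: float = 0.50                 # remainder is variable
    conserved_retention: float = 0.90         # P(keep ancestral residue) at conserved sites
    gap_rate: float = 0.0
    # planted reassignment
    reassigned_family: Optional[Tuple[str, ...]] = ("CUU", "CUC", "CUA", "CUG")
    planted_aa: Optional[str] = "A"
    planted_codon_counts: Dict[str, int] = field(
        default_factory=lambda: {"CUA": 49, "CUU": 32}
    )
    # codon bias of the target genome
    code_name: str = "ashbya-mito"
    third_AU_prob: float = 0.90
    avoided: Tuple[str, ...] = ("CUC", "CUG")
    # tRNA fixture
    trna_elements: Dict[str, str] = field(
        default_factory=lambda: {
            "pair_3_70": "G:U",
            "anticodon": "UAG",
            "loop_len": "7",
            "discriminator": "G",
        }
    )
    trna_flank: int = 30
    cca_encoded: bool = False
    # reads
    read_depth: Dict[str, int] = field(
        default_factory=lambda: {"precursor": 100, "mature": 100}
    )
    read_length: Tuple[int, int] = (20, 50)
    read_error_rate: float = 0.0
    # kinetics
    kinetics_kcat: float = 2.1                # min^-1
    kinetics_km: float = 0.53                 # µM
    kinetics_noise: float = 0.0               # relative s.d. on velocities

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @property
    def code(self) -> GeneticCode:
        return get_code(self.code_name)


def preset(name: str, seed: int = 1, **overrides) -> SyntheticTruth:
    """Shipped study conditions: ashbya-like, klactis-like, standard-null."""
    if name == "ashbya-like":
        truth = SyntheticTruth(seed=seed)
    elif name == "klactis-like":
        # the codon family has vanished: nothing planted, family fully avoided
        truth = SyntheticTruth(
            seed=seed,
            reassigned_family=("CUU", "CUC", "CUA", "CUG"),
            planted_aa=None,
            planted_codon_counts={},
            code_name="yeast-mito",
            avoided=("CUU", "CUC", "CUA", "CUG"),
        )
    elif name == "standard-null":
        truth = SyntheticTruth(
            seed=seed,
            reassigned_family=None,
            planted_aa=None,
            planted_codon_counts={},
            code_name="standard",
            avoided=(),
            third_AU_prob=0.60,
        )
    else:
        raise KeyError(f"unknown preset {name!r}")
    return dataclasses.replace(truth, **overrides) if overrides else truth


# ---------------------------------------------------------------------------
# ortholog families


def _synonym_weights(
    residue: str, code: GeneticCode, forbidden: frozenset, third_AU_prob: float
) -> Tuple[List[str], List[float]]:
    syn = [
        c
        for c in code.sense_codons
        if code.amino_acid(c) == residue and c not in forbidden
    ]
    if not syn:
        raise ValueError(f"no usable codon for residue {residue!r}")
    au = [c for c in syn if c[2] in "AU"]
    cg = [c for c in syn if c[2] in "CG"]
    weights = []
    for c in syn:
        if au and cg:
            w = third_AU_prob / len(au) if c[2] in "AU" else (1 - third_AU_prob) / len(cg)
        else:
            w = 1.0 / len(syn)
        weights.append(w)
    total = sum(weights)
    return syn, [w / total for w in weights]


def simulate_ortholog_set(
    truth: SyntheticTruth, rng: Optional[np.random.Generator] = None
) -> List[OrthologAlignment]:
    """Generate gapless-target ortholog alignments plus the target CDS.

    Planted reassignment sites are invariant columns whose ancestral residue
    is the planted amino acid; the target writes a family codon there.  All
    other target sites never use family codons, so the planted usage count
    is exact.  Non-target species diverge independently from the ancestor at
    class-dependent rates.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    code = truth.code
    if truth.planted_codon_counts and truth.planted_aa not in AA_ALPHABET:
        raise ValueError(
            f"planted amino acid {truth.planted_aa!r} is not a canonical residue"
        )
    forbidden = frozenset(truth.avoided) | (
        frozenset(truth.reassigned_family) if truth.reassigned_family else frozenset()
    )
    # distribute planted codons across genes, round-robin over a shuffled list
    planted_codons: List[str] = []
    for codon, n in sorted(truth.planted_codon_counts.items()):
        planted_codons += [codon] * n
    rng.shuffle(planted_codons)
    per_gene_sites: List[List[str]] = [[] for _ in range(truth.n_genes)]
    for i, codon in enumerate(planted_codons):
        per_gene_sites[i % truth.n_genes].append(codon)

    alignments = []
    aa_list = list(AA_ALPHABET)
    for g in range(truth.n_genes):
        gene_id = f"gene{g + 1:02d}"
        L = truth.gene_length
        classes = rng.choice(
            3,
            size=L,
            p=[
                truth.p_invariant,
                truth.p_conserved,
                1 - truth.p_invariant - truth.p_conserved,
            ],
        )
        ancestor = [aa_list[i] for i in rng.integers(0, len(aa_list), size=L)]
        planted_here = per_gene_sites[g]
        site_idx = rng.choice(L, size=len(planted_here), replace=False)
        planted_map = {}                      # site -> family codon
        for s, codon in zip(site_idx, planted_here):
            classes[s] = 0                    # invariant column
            ancestor[s] = truth.planted_aa
            planted_map[int(s)] = codon
        rows: Dict[str, str] = {}
        for sp in truth.species:
            residues = []
            for s in range(L):
                if classes[s] == 0:
                    residues.append(ancestor[s])
                elif classes[s] == 1:
                    if rng.random() < truth.conserved_retention:
                        residues.append(ancestor[s])
                    else:
                        residues.append(aa_list[int(rng.integers(0, len(aa_list)))])
                else:
                    residues.append(aa_list[int(rng.integers(0, len(aa_list)))])
                if truth.gap_rate and rng.random() < truth.gap_rate:
                    residues[-1] = "-"
            rows[sp] = "".join(residues)
        # target protein: ancestral residues (planted sites carry planted_aa)
        target_protein = "".join(ancestor)
        codons = []
        for s in range(L):
            if s in planted_map:
                codons.append(planted_map[s])
            else:
                syn, w = _synonym_weights(ancestor[s], code, forbidden, truth.third_AU_prob)
                codons.append(syn[int(rng.choice(len(syn), p=w))])
        cds = "".join(codons)
        rows[truth.target] = target_protein
        cmap = map_codons_to_columns(cds, rows[truth.target])
        alignments.append(
            OrthologAlignment(gene_id, rows, truth.target, cds, cmap)
        )
    return alignments


# ---------------------------------------------------------------------------
# tRNA construction


def _random_bases(rng, n: int) -> str:
    return "".join("ACGU"[int(i)] for i in rng.integers(0, 4, size=n))


def _random_stem(rng, n: int) -> Tuple[str, str]:
    five = _random_bases(rng, n)
    three = "".join(_WC[b] for b in reversed(five))
    return five, three


def build_trna(
    elements: Dict[str, str],
    rng: Optional[np.random.Generator] = None,
    id: str = "trna",
    minus_one: Optional[str] = None,
) -> Tuple[str, str]:
    """Construct a cloverleaf sequence and dot-bracket from identity elements.

    Layout (body coordinates): 7-bp acceptor stem, 2-nt link, 4-bp D stem
    with 8-nt loop, 1-nt link, 5-bp anticodon stem with a 7/8-nt loop, 5-nt
    variable region, 5-bp T stem with 7-nt loop, 3' acceptor strand,
    discriminator.  Stems are Watson-Crick except where an element (the
    G3:U70 pair) says otherwise.  Returns (sequence, dot_bracket); the
    sequence includes the −1 base when given.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    for _ in range(25):
        seq, structure = _build_trna_once(elements, rng)
        # reject molecules with a chance competing decomposition: a real tRNA
        # folds one way, so the structure-free parse must recover the design
        from mitorecode.trna import CloverleafParseError, parse_cloverleaf

        try:
            g = parse_cloverleaf(seq, cca=False)
        except CloverleafParseError:
            continue
        loop_len = int(elements.get("loop_len", "7"))
        if (
            g.loop_len == loop_len
            and g.anticodon == elements.get("anticodon", "UAG")
            and ":".join(g.pair(3)) == elements.get("pair_3_70", "G:C")
            and g.loop_start == 31
        ):
            if minus_one:
                return minus_one + seq, "." + structure
            return seq, structure
    raise ValueError("could not realise the element spec as an unambiguous cloverleaf")


def _build_trna_once(elements, rng) -> Tuple[str, str]:
    acc5 = _random_bases(rng, 7)
    pair = elements.get("pair_3_70", "G:C").split(":")
    acc5 = acc5[:2] + pair[0] + acc5[3:]
    # 3' strand runs 66..72; position k pairs 73-k, so index j pairs acc5[6-j];
    # the partner of position 3 (acc5[2]) is position 70 = index 4
    acc3 = "".join(
        pair[1] if j == 4 else _WC[acc5[6 - j]] for j in range(7)
    )
    d5, d3 = _random_stem(rng, 4)
    dloop = _random_bases(rng, 8)
    ac5, ac3 = _random_stem(rng, 5)
    loop_len = int(elements.get("loop_len", "7"))
    anticodon = elements.get("anticodon", "UAG")
    flank5 = _random_bases(rng, 2)
    flank3 = _random_bases(rng, 2)
    if loop_len == 7:
        loop = flank5 + anticodon + flank3
    elif loop_len == 8:
        inserted = elements.get("inserted_31", "U")
        loop = inserted + flank5 + anticodon + flank3
    else:
        raise ValueError("loop_len must be 7 or 8")
    var = _random_bases(rng, 5)
    t5, t3 = _random_stem(rng, 5)
    tloop = _random_bases(rng, 7)
    disc = elements.get("discriminator", "G")
    body = (
        acc5 + _random_bases(rng, 2) + d5 + dloop + d3 + _random_bases(rng, 1)
        + ac5 + loop + ac3 + var + t5 + tloop + t3 + acc3 + disc
    )
    structure = (
        "(((((((" + ".." + "((((" + "." * 8 + "))))" + "."
        + "(((((" + "." * loop_len + ")))))" + "." * 5
        + "(((((" + "." * 7 + ")))))" + ")))))))" + "."
    )
    return body, structure


@dataclass
class TRNAFixture:
    gene: TRNAGene
    sequence: str                 # gene body (no CCA unless encoded)
    structure: str
    flank5: str
    flank3: str

    @property
    def gene_with_flanks(self) -> str:
        return self.flank5 + self.sequence + self.flank3

    @property
    def gene_start(self) -> int:
        return len(self.flank5)

    @property
    def gene_end(self) -> int:
        return len(self.flank5) + len(self.sequence)


def simulate_trna_and_reads(
    truth: SyntheticTruth, rng: Optional[np.random.Generator] = None
) -> Tuple[TRNAFixture, List[str]]:
    """Build the tRNA fixture and sample reads from its expression forms.

    Reads are drawn from the unprocessed precursor (5' leader + gene + 3'
    trailer) and the mature form (gene + CCA when not genome-encoded) at the
    depths in ``truth.read_depth``, with uniform substitution errors at
    ``truth.read_error_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1)
    seq, structure = build_trna(truth.trna_elements, rng, id="trna-fixture")
    gene = parse_cloverleaf(seq, structure=structure, id="trna-fixture", cca=False,
                            cca_encoded=truth.cca_encoded)
    flank5 = _random_bases(rng, truth.trna_flank)
    flank3 = _random_bases(rng, truth.trna_flank)
    while flank3.startswith("C"):
        # a trailer beginning with C mimics the post-transcriptional CCA and
        # would make maturation invisible to exact-window counting
        flank3 = _random_bases(rng, truth.trna_flank)
    body = seq + ("CCA" if truth.cca_encoded else "")
    fixture = TRNAFixture(gene, body, structure, flank5, flank3)
    forms = {
        "precursor": flank5 + body + flank3,
        "mature": body + ("" if truth.cca_encoded else "CCA"),
    }
    reads: List[str] = []
    lo, hi = truth.read_length
    for form_name in sorted(truth.read_depth):
        source = forms[form_name]
        for _ in range(truth.read_depth[form_name]):
            n = int(rng.integers(lo, hi + 1))
            n = min(n, len(source))
            start = int(rng.integers(0, len(source) - n + 1))
            read = list(source[start : start + n])
            if truth.read_error_rate:
                for i in range(len(read)):
                    if rng.random() < truth.read_error_rate:
                        read[i] = "ACGU"[int(rng.integers(0, 4))]
            reads.append("".join(read))
    return fixture, reads


# ---------------------------------------------------------------------------
# kinetics


def simulate_kinetics(
    kcat: float,
    km: float,
    substrate: Sequence[float] = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0),
    enzyme_conc: float = 1.0,
    noise: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Velocity table v = kcat·E·S/(Km+S)·(1 + noise·N(0,1)), clipped at 0."""
    if rng is None:
        rng = np.random.default_rng(0)
    s = np.asarray(substrate, dtype=float)
    v = kcat * enzyme_conc * s / (km + s)
    if noise:
        v = v * (1.0 + noise * rng.standard_normal(len(s)))
        v = np.clip(v, 0.0, None)
    return s, v


# ---------------------------------------------------------------------------
# on-disk emission


def write_ortholog_set(alignments: Sequence[OrthologAlignment], outdir) -> None:
    aln_dir = os.path.join(outdir, "alignments")
    os.makedirs(aln_dir, exist_ok=True)
    with open(os.path.join(outdir, "cds.fasta"), "w") as cds_fh:
        for aln in alignments:
            with open(os.path.join(aln_dir, f"{aln.gene_id}.fasta"), "w") as fh:
                for sp, row in sorted(aln.rows.items()):
                    fh.write(f">{sp}\n{row}\n")
            cds_fh.write(f">{aln.gene_id}\n{aln.cds}\n")


def write_trna_and_reads(fixture: TRNAFixture, reads: Sequence[str], outdir) -> None:
    trna_dir = os.path.join(outdir, "trna")
    os.makedirs(trna_dir, exist_ok=True)
    with open(os.path.join(trna_dir, "trna.fasta"), "w") as fh:
        fh.write(f">{fixture.gene.id}\n{fixture.sequence}\n")
    with open(os.path.join(trna_dir, "trna.dotbracket"), "w") as fh:
        fh.write(fixture.structure + "\n")
    # genomic locus (gene + flanks) with a BED sidecar for the read scan
    with open(os.path.join(trna_dir, "locus.fasta"), "w") as fh:
        fh.write(f">{fixture.gene.id}\n{fixture.gene_with_flanks}\n")
    with open(os.path.join(trna_dir, "trna.bed"), "w") as fh:
        fh.write(f"{fixture.gene.id}\t{fixture.gene_start}\t{fixture.gene_end}\n")
    with open(os.path.join(outdir, "reads.fastq"), "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read{i + 1}\n{r}\n+\n{'I' * len(r)}\n")


def simulate_to_dir(truth: SyntheticTruth, outdir) -> None:
    """Emit the full directory tree consumed by the CLI subcommands."""
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    alignments = simulate_ortholog_set(truth, rng)
    write_ortholog_set(alignments, outdir)
    fixture, reads = simulate_trna_and_reads(truth, rng)
    write_trna_and_reads(fixture, reads, outdir)
    s, v = simulate_kinetics(
        truth.kinetics_kcat,
        truth.kinetics_km,
        noise=truth.kinetics_noise,
        rng=rng,
    )
    with open(os.path.join(outdir, "kinetics.tsv"), "w") as fh:
        fh.write("substrate\tvelocity\n")
        for si, vi in zip(s, v):
            fh.write(f"{si:.6g}\t{vi:.9g}\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(truth.to_json() + "\n")
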