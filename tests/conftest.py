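import numpy as np
import pytest

from mitorecode import codes, simulate, trna

# simple one-codon-per-residue back-translation (valid under the standard and
# yeast-mito codes; Leu deliberately via UUA so CUN stays free for planting)
BACKTRANSLATE = {
    "A": "GCU", "C": "UGU", "D": "GAU", "E": "GAA", "F": "UUU", "G": "GGU",
    "H": "CAU", "I": "AUU", "K": "AAA", "L": "UUA", "M": "AUG", "N": "AAU",
    "P": "CCU", "Q": "CAA", "R": "CGU", "S": "UCU", "T": "ACU", "V": "GUU",
    "W": "UGG", "Y": "UAU",
}


def back_translate(protein: str) -> str:
    return "".join(BACKTRANSLATE[aa] for aa in protein)


@pytest.fixture(scope="session")
def standard_code():
    return codes.get_code("standard")


@pytest.fixture(scope="session")
def yeast_mito():
    return codes.get_code("yeast-mito")


@pytest.fixture(scope="session")
def ashbya_mito():
    return codes.get_code("ashbya-mito")


def make_trna(elements, seed=0, minus_one=None):
    """Constructed-truth tRNA: (parsed gene, sequence, dot-bracket)."""
    rng = np.random.default_rng(seed)
    seq, struct = simulate.build_trna(elements, rng, minus_one=minus_one)
    gene = trna.parse_cloverleaf(
        seq, structure=struct, has_minus_one=minus_one is not None, cca=False
    )
    return gene, seq, struct


@pytest.fixture
def ala_trna():
    """AlaRS-orthogonal fixture: G3:U70, 7-nt loop, UAG anticodon, non-A 73."""
    gene, _, _ = make_trna(
        {"pair_3_70": "G:U", "anticodon": "UAG", "loop_len": "7", "discriminator": "G"},
        seed=3,
    )
    return gene


@pytest.fixture
def thr_trna():
    """MST1-type fixture: A3:U70, enlarged 8-nt loop with inserted U, UAG."""
    gene, _, _ = make_trna(
        {
            "pair_3_70": "A:U",
            "anticodon": "UAG",
            "loop_len": "8",
            "inserted_31": "U",
            "discriminator": "G",
        },
        seed=7,
    )
    return gene


@pytest.fixture
def his_trna():
    """HisRS fixture: genomic G at −1 pairing the C73 discriminator, GUG."""
    gene, _, _ = make_trna(
        {"pair_3_70": "G:C", "anticodon": "GUG", "loop_len": "7", "discriminator": "C"},
        seed=11,
        minus_one="G",
    )
    return gene
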