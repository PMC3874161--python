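"""Exact k-mer window scans of small-RNA reads over tRNA precursor coordinates.

Whether a tRNA gene is transcribed, end-processed and CCA-matured can be read
off untargeted small-RNA data with nothing more than exact substring counts:
a k-mer spanning the 5'-leader/gene junction can only come from an
unprocessed precursor; a k-mer running off the gene 3' end into a CCA that is
not genome-encoded can only come from the matured tRNA.  This module builds
the labeled window set for a gene with genomic flanks, counts exact window
hits in reads, and summarizes the counts per processing state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from Bio import SeqIO

from mitorecode.codes import reverse_complement, transcribe

PRECURSOR_5P = "precursor-5p-junction"
PRECURSOR_3P = "precursor-3p-junction"
MATURE_BODY = "mature-body"
MATURE_5P_END = "mature-5p-end"
MATURE_3P_CCA = "mature-3p-cca"
AMBIGUOUS = "ambiguous"            # flank-only windows: uninformative


@dataclass(frozen=True)
class ScanConfig:
    k: int = 15
    flank: int = 30
    count_reverse_complement: bool = False

    def __post_init__(self):
        if self.k < 8:
            raise ValueError("window length k must be >= 8")
        if self.flank < self.k - 1:
            raise ValueError("flank must be >= k-1 so junction windows exist")


@dataclass(frozen=True)
class Window:
    sequence: str
    label: str
    start: int            # 0-based start in precursor coordinates (mature-3p-cca
                          # windows index into the mature+CCA form instead)


@dataclass
class WindowSet:
    trna_id: str
    windows: Tuple[Window, ...]
    cfg: ScanConfig

    def by_label(self, label: str) -> List[Window]:
        return [w for w in self.windows if w.label == label]


def build_windows(
    gene_with_flanks: str,
    gene_start: int,
    gene_end: int,
    cca_encoded: bool,
    cfg: ScanConfig = ScanConfig(),
    trna_id: str = "trna",
) -> WindowSet:
    """Label every k-mer of the flanked gene, plus mature+CCA k-mers.

    ``gene_start``/``gene_end`` are 0-based half-open coordinates of the gene
    within ``gene_with_flanks``.  Labels partition the windows:

    * windows overlapping the 5' or 3' gene/flank boundary — precursor-only
      junction evidence;
    * windows fully inside the gene — mature body (shared by all forms; the
      single window starting at the gene 5' end is sub-labeled separately as
      mature-5p-end);
    * windows of the mature form (gene + CCA) that run past the gene 3' end
      into an appended CCA — mature-3p-cca, absent when the CCA is
      genome-encoded (those k-mers match the genome anyway);
    * windows fully inside a flank — ambiguous (present in the precursor but
      carrying no processing information).
    """
    precursor = transcribe(gene_with_flanks).upper()
    k = cfg.k
    if not (0 <= gene_start < gene_end <= len(precursor)):
        raise ValueError("gene coordinates outside the flanked sequence")
    if gene_end - gene_start < k:
        raise ValueError(f"gene shorter than window length {k}")
    mature = precursor[gene_start:gene_end] + ("" if cca_encoded else "CCA")
    windows: List[Window] = []
    for s in range(0, len(precursor) - k + 1):
        e = s + k
        if s < gene_start < e:
            label = PRECURSOR_5P
        elif s < gene_end < e:
            label = PRECURSOR_3P
        elif gene_start <= s and e <= gene_end:
            label = MATURE_5P_END if s == gene_start else MATURE_BODY
        else:
            label = AMBIGUOUS
        if label in (PRECURSOR_5P, PRECURSOR_3P) and precursor[s:e] in mature:
            # a trailer starting with C/CC/CCA (or a leader ending like the
            # gene) makes this junction k-mer occur in the mature form too —
            # it carries no processing information
            label = AMBIGUOUS
        windows.append(Window(precursor[s:e], label, s))
    if not cca_encoded:
        gene_len = gene_end - gene_start
        for s in range(max(0, gene_len - k + 1), len(mature) - k + 1):
            # windows reaching past the gene 3' end into the appended CCA;
            # those that also occur in the genomic precursor are uninformative
            if s + k > gene_len:
                seq = mature[s : s + k]
                label = AMBIGUOUS if seq in precursor else MATURE_3P_CCA
                windows.append(Window(seq, label, s))
    return WindowSet(trna_id, tuple(windows), cfg)


@dataclass
class ProcessingSummary:
    trna_id: str
    per_window: Dict[Tuple[str, int], int]   # (label, start) -> read count
    n_reads: int
    derived: Dict[str, int] = field(default_factory=dict)

    def count(self, label: str) -> int:
        return self.derived.get(label, 0)


def _iter_reads(reads) -> List[str]:
    if isinstance(reads, (list, tuple)):
        return [transcribe(r) for r in reads]
    fmt = "fastq" if str(reads).lower().endswith(("fastq", "fq")) else "fasta"
    return [transcribe(str(rec.seq)) for rec in SeqIO.parse(reads, fmt)]


def scan_reads(reads, window_set: WindowSet) -> ProcessingSummary:
    """Count, per labeled window, the reads containing it as an exact substring.

    A read containing a window several times still counts once for that
    window (grep -c semantics over reads).  Reverse-complement matches are
    added when the config asks for them.
    """
    seqs = _iter_reads(reads)
    cfg = window_set.cfg
    per_window: Dict[Tuple[str, int], int] = {}
    for w in window_set.windows:
        rc = reverse_complement(w.sequence) if cfg.count_reverse_complement else None
        c = 0
        for s in seqs:
            if w.sequence in s or (rc is not None and rc in s):
                c += 1
        per_window[(w.label, w.start)] = c
    derived = {
        label: sum(c for (lab, _), c in per_window.items() if lab == label)
        for label in (PRECURSOR_5P, PRECURSOR_3P, MATURE_BODY, MATURE_5P_END, MATURE_3P_CCA, AMBIGUOUS)
    }
    return ProcessingSummary(window_set.trna_id, per_window, len(seqs), derived)


@dataclass
class ExpressionRow:
    trna_id: str
    mean_mature_body: float
    ratio_to_median: float


def expression_report(summaries: Sequence[ProcessingSummary]) -> List[ExpressionRow]:
    """Relative expression: mean mature-body window count per tRNA, as a
    ratio to the median tRNA (a single tRNA is its own median, ratio 1)."""
    means = []
    for s in summaries:
        body = [c for (lab, _), c in s.per_window.items() if lab in (MATURE_BODY, MATURE_5P_END)]
        means.append(sum(body) / len(body) if body else 0.0)
    sorted_means = sorted(means)
    m = len(sorted_means)
    median = (
        sorted_means[m // 2]
        if m % 2
        else (sorted_means[m // 2 - 1] + sorted_means[m // 2]) / 2
    )
    return [
        ExpressionRow(s.trna_id, mu, mu / median if median else float("nan"))
        for s, mu in zip(summaries, means)
    ]


@dataclass
class EditingReport:
    identical: bool
    n_differences: int
    positions: Tuple[int, ...]


def editing_report(genomic_gene: str, observed_mature: str) -> EditingReport:
    """Sequence-equality check: a mature tRNA identical to its gene (CCA
    excluded) indicates no post-transcriptional editing."""
    g = transcribe(genomic_gene)
    o = transcribe(observed_mature)
    if o.endswith("CCA") and len(o) == len(g) + 3:
        o = o[:-3]
    if len(g) != len(o):
        return EditingReport(False, abs(len(g) - len(o)), ())
    diffs = tuple(i for i, (a, b) in enumerate(zip(g, o)) if a != b)
    return EditingReport(not diffs, len(diffs), diffs)


def summary_to_tsv(summary: ProcessingSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tstart\tcount\n")
        for (label, start), c in sorted(summary.per_window.items(), key=lambda x: (x[0][0], x[0][1])):
            fh.write(f"{label}\t{start}\t{c}\n")
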