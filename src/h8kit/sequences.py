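"""Pairwise global alignment and region-wise sequence comparison.

Built for the receptor-vs-receptor question this package grew out of:
where exactly do two GPCR paralogues differ, loop by loop?  A global
alignment (Needleman-Wunsch with affine gaps, BLOSUM62, computed by
Biopython's PairwiseAligner) is combined with a region annotation in
UniProt numbering to report per-region gap lengths and percent identity.

Reference sequences for the two human C5a receptors (UniProt P21730 and
Q9P296) and a matching region annotation ship with the package for
offline use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

VALID_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

REGION_NAMES = (
    ["N-term"]
    + [f"TM{i}" for i in range(1, 8)]
    + [f"ICL{i}" for i in range(1, 5)]
    + [f"ECL{i}" for i in range(1, 4)]
    + ["H8", "C-term"]
)


@dataclass
class SequenceRecord:
    id: str
    residues: str
    numbering_offset: int = 1  # UniProt position of the first residue

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - VALID_ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id}: invalid letters {sorted(bad)}")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)

    def truncated(self, first_kept: int) -> "SequenceRecord":
        """Drop residues before UniProt position ``first_kept``."""
        cut = first_kept - self.numbering_offset
        if not 0 <= cut < len(self.residues):
            raise ValueError(f"truncation point {first_kept} outside sequence")
        return SequenceRecord(
            id=self.id,
            residues=self.residues[cut:],
            numbering_offset=first_kept,
        )


@dataclass
class RegionAnnotation:
    name: str
    start: int  # UniProt numbering, inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PairwiseAlignment:
    record_a: SequenceRecord
    record_b: SequenceRecord
    aligned_a: str
    aligned_b: str
    score: float
    # per column: (UniProt position in a or None, position in b or None)
    column_map: list[tuple[int | None, int | None]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")
        if self.aligned_a.replace("-", "") != self.record_a.residues:
            raise ValueError("aligned_a does not recover sequence a")
        if self.aligned_b.replace("-", "") != self.record_b.residues:
            raise ValueError("aligned_b does not recover sequence b")
        if not self.column_map:
            self.column_map = self._build_column_map()

    def _build_column_map(self) -> list[tuple[int | None, int | None]]:
        pa = self.record_a.numbering_offset - 1
        pb = self.record_b.numbering_offset - 1
        out = []
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-":
                pa += 1
            if cb != "-":
                pb += 1
            out.append((pa if ca != "-" else None, pb if cb != "-" else None))
        return out


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def bundled_c5ar_sequences() -> dict[str, SequenceRecord]:
    """The two human C5a receptor sequences shipped with the package."""
    ref = resources.files("h8kit.data") / "c5ar_sequences.fasta"
    with resources.as_file(ref) as path:
        return {r.id: r for r in read_fasta(path)}


def load_regions(path: str | Path | None = None) -> dict[str, list[RegionAnnotation]]:
    """Region annotations keyed by sequence id; bundled C5aR file by default."""
    if path is None:
        ref = resources.files("h8kit.data") / "c5ar_regions.yaml"
        with resources.as_file(ref) as p:
            raw = yaml.safe_load(Path(p).read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    out: dict[str, list[RegionAnnotation]] = {}
    for seq_id, regions in raw.items():
        anns = [RegionAnnotation(name, int(lo), int(hi))
                for name, (lo, hi) in regions.items()]
        spans = sorted((a.start, a.end, a.name) for a in anns)
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"regions {n1} and {n2} overlap in {seq_id}")
        out[seq_id] = anns
    return out


def align_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps.

    Defaults (BLOSUM62, open 10, extend 0.5) are the EMBOSS-needle
    conventions.  When several traceback paths are optimal the aligner's
    first path is taken, which prefers aligning residues over opening
    gaps; the choice is deterministic.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    return PairwiseAlignment(
        record_a=a,
        record_b=b,
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=float(aln.score),
    )


def _region_columns(
    alignment: PairwiseAlignment, region: RegionAnnotation, on: str
) -> range:
    """Contiguous alignment-column span of a region annotated on one sequence.

    Columns are selected by the numbering of sequence ``on``; interior gap
    columns of either sequence are included (a gap column carries no
    coordinate of its own, so the span runs from the first to the last
    column whose ``on``-position falls inside the region).
    """
    which = 0 if on == "a" else 1
    hits = [
        i for i, pos in enumerate(alignment.column_map)
        if pos[which] is not None and region.start <= pos[which] <= region.end
    ]
    if not hits:
        raise ValueError(
            f"region {region.name} [{region.start}, {region.end}] lies outside "
            f"sequence {'ab'[which]}'s coordinate range"
        )
    return range(hits[0], hits[-1] + 1)


def region_gap_length(
    alignment: PairwiseAlignment,
    region: RegionAnnotation,
    in_sequence: str,
    region_on: str = "a",
) -> int:
    """Number of gap columns of one sequence inside an annotated region.

    ``in_sequence`` ("a" or "b") names the sequence whose gaps are counted;
    ``region_on`` names the sequence whose numbering locates the region
    (default "a").  For two receptor paralogues, a region annotated on
    receptor a with gaps counted in b answers "how many residues of this
    loop are deleted in the other receptor".
    """
    if in_sequence not in ("a", "b"):
        raise ValueError("in_sequence must be 'a' or 'b'")
    cols = _region_columns(alignment, region, region_on)
    gapped = alignment.aligned_a if in_sequence == "a" else alignment.aligned_b
    return sum(gapped[i] == "-" for i in cols)


def region_length(
    alignment: PairwiseAlignment,
    region: RegionAnnotation,
    of_sequence: str,
    region_on: str = "a",
) -> int:
    """Residue count of one sequence inside a region annotated on ``region_on``."""
    cols = _region_columns(alignment, region, region_on)
    seq = alignment.aligned_a if of_sequence == "a" else alignment.aligned_b
    return sum(seq[i] != "-" for i in cols)


def region_identity(
    alignment: PairwiseAlignment,
    region: RegionAnnotation,
    on: str = "a",
) -> float:
    """Percent identity restricted to a region (located on sequence ``on``).

    Identity = 100 x identical columns / columns where at least one
    sequence has a residue.
    """
    cols = _region_columns(alignment, region, on)
    ident = denom = 0
    for i in cols:
        ca, cb = alignment.aligned_a[i], alignment.aligned_b[i]
        if ca == "-" and cb == "-":
            continue
        denom += 1
        if ca == cb:
            ident += 1
    if denom == 0:
        raise ValueError(f"region {region.name} is empty after mapping")
    return 100.0 * ident / denom


def region_report(
    alignment: PairwiseAlignment,
    regions: list[RegionAnnotation],
    on: str = "a",
) -> pd.DataFrame:
    """Per-region table: span, gaps in each sequence, percent identity."""
    rows = []
    for region in regions:
        rows.append(
            {
                "region": region.name,
                "start": region.start,
                "end": region.end,
                "gap_len_a": region_gap_length(alignment, region, "a", on),
                "gap_len_b": region_gap_length(alignment, region, "b", on),
                "len_a": region_length(alignment, region, "a", on),
                "len_b": region_length(alignment, region, "b", on),
                "identity_pct": region_identity(alignment, region, on),
            }
        )
    return pd.DataFrame(rows)


def compare_c5ar_receptors(
    truncate_n_term: bool = False,
) -> tuple[PairwiseAlignment, pd.DataFrame]:
    """Align the bundled C5aR1/C5aR2 sequences and build the region report.

    ``truncate_n_term`` drops the extracellular residues 1-29 of C5aR1 and
    1-27 of C5aR2 before aligning (the receptors' disordered N-termini).
    """
    seqs = bundled_c5ar_sequences()
    a, b = seqs["P21730"], seqs["Q9P296"]
    if truncate_n_term:
        a, b = a.truncated(30), b.truncated(28)
    alignment = align_pair(a, b)
    regions = load_regions()["P21730"]
    if truncate_n_term:
        regions = [r for r in regions if r.end >= 30]
    return alignment, region_report(alignment, regions)
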