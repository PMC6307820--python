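"""Panmolecule construction: a union coordinate system over two parental haplotypes.

Pollen-typing amplicons are sequenced from F1 hybrids between two diverged
accessions (e.g. Col and Ler), whose alleles differ by SNPs and indels. To place
crossover events from either parent on a common axis we build a *panmolecule*:
an ordered coordinate system containing every base present in either allele, so
that bases inserted in only one parent still occupy coordinates. Each panmolecule
position records the cognate 1-based coordinate in each parent (where present),
the bases, whether the position is a SNP, and an insertion code (1 = base present
only in parent B, 2 = only in parent A) matching the published key-table dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from Bio import Align

VALID_BASES = frozenset("ACGT")

#: sentinel used on the A/B side of an alignment column where that parent has no base
GAP = "-"


class InputError(ValueError):
    """Invalid user-supplied sequence or table."""


class RangeError(IndexError):
    """Coordinate outside the valid parental or panmolecule range."""


@dataclass(frozen=True)
class Haplotype:
    """One parental allele of the amplicon.

    ``role`` distinguishes the two parents of the cross; by convention parent A
    is the reference-like accession (Col in the published tables) and parent B
    the diverged one (Ler, Wl or Mh).
    """

    accession_id: str
    sequence: str
    role: Literal["parentA", "parentB"]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"haplotype {self.accession_id!r}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise InputError(
                f"haplotype {self.accession_id!r}: ambiguous/invalid bases {sorted(bad)}; "
                "only unambiguous A/C/G/T templates are accepted"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedPair:
    """Global alignment of the two parental alleles as explicit columns.

    Each column is a ``(baseA, baseB)`` pair where one side may be :data:`GAP`
    (never both). The ungapped concatenation of each side reproduces the
    corresponding haplotype sequence exactly.
    """

    haplotypeA: Haplotype
    haplotypeB: Haplotype
    columns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        a = "".join(c[0] for c in self.columns if c[0] != GAP)
        b = "".join(c[1] for c in self.columns if c[1] != GAP)
        if any(c == (GAP, GAP) for c in self.columns):
            raise InputError("alignment contains an all-gap column")
        if a != self.haplotypeA.sequence or b != self.haplotypeB.sequence:
            raise InputError("alignment columns do not reproduce the input sequences")

    @property
    def score_matrix_free_length(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class PanPosition:
    pan_coord: int
    coordA: Optional[int]
    coordB: Optional[int]
    baseA: Optional[str]
    baseB: Optional[str]
    is_snp: bool
    insertion_code: int  # 0 = shared column, 1 = B-only base, 2 = A-only base


@dataclass
class Panmolecule:
    """Union coordinate system over the two parental alleles.

    ``length_bp = len(A) + (# B-only bases) = len(B) + (# A-only bases)``.
    Pan coordinates are 1-based and contiguous.
    """

    haplotypeA_id: str
    haplotypeB_id: str
    positions: list[PanPosition]
    # liftover indexes, filled in __post_init__
    _panA: dict[int, int] = field(default_factory=dict, repr=False)
    _panB: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._panA = {p.coordA: p.pan_coord for p in self.positions if p.coordA is not None}
        self._panB = {p.coordB: p.pan_coord for p in self.positions if p.coordB is not None}

    @property
    def length_bp(self) -> int:
        return len(self.positions)

    @property
    def length_A(self) -> int:
        return len(self._panA)

    @property
    def length_B(self) -> int:
        return len(self._panB)

    @property
    def n_snps(self) -> int:
        return sum(p.is_snp for p in self.positions)

    def insertion_bases(self, code: int) -> int:
        """Number of positions carrying the given insertion code (1=B-only, 2=A-only)."""
        return sum(p.insertion_code == code for p in self.positions)

    def snp_pan_positions(self) -> list[int]:
        return [p.pan_coord for p in self.positions if p.is_snp]

    def parental_sequence(self, parent: Literal["A", "B"]) -> str:
        attr = "baseA" if parent == "A" else "baseB"
        return "".join(
            getattr(p, attr) for p in self.positions if getattr(p, attr) is not None
        )


@dataclass(frozen=True)
class PolymorphismRecord:
    pan_start: int
    pan_end: int
    kind: Literal["SNP", "insertionA", "insertionB"]
    weight_bp: int


@dataclass(frozen=True)
class PolymorphismTrack:
    """Interhomolog polymorphisms with the divergence weighting used throughout:
    a SNP counts 1 and an indel counts its length in base pairs."""

    records: tuple[PolymorphismRecord, ...]

    def total_weight(self, kind: Optional[str] = None) -> int:
        return sum(r.weight_bp for r in self.records if kind is None or r.kind == kind)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def align_haplotypes(
    seqA: Haplotype,
    seqB: Haplotype,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
    match: float = 1.0,
    mismatch: float = -2.0,
) -> AlignedPair:
    """Optimal global alignment of the two alleles with deterministic tie-breaking.

    Gap cost convention: a gap of length L costs ``gap_open + L * gap_extend``.
    Among co-optimal alignments the one placing gaps rightmost in parent A is
    returned (implemented by aligning the reversed sequences, whose first
    enumerated optimum prefers leftmost gaps, and reversing the columns).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython charges open for the first gap base (open + (L-1)*extend)
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend

    ra, rb = seqA.sequence[::-1], seqB.sequence[::-1]
    aln = aligner.align(ra, rb)[0]
    a_rows = str(aln[0])
    b_rows = str(aln[1])
    columns = tuple((ca, cb) for ca, cb in zip(a_rows[::-1], b_rows[::-1]))
    return AlignedPair(haplotypeA=seqA, haplotypeB=seqB, columns=columns)


def build_panmolecule(ap: AlignedPair) -> Panmolecule:
    """One panmolecule position per alignment column, 1-based and contiguous."""
    positions: list[PanPosition] = []
    ca = cb = 0
    for i, (a, b) in enumerate(ap.columns, start=1):
        coordA = coordB = None
        if a != GAP:
            ca += 1
            coordA = ca
        if b != GAP:
            cb += 1
            coordB = cb
        if a == GAP:
            code = 1  # base present only in parent B
        elif b == GAP:
            code = 2  # base present only in parent A
        else:
            code = 0
        is_snp = code == 0 and a != b
        positions.append(
            PanPosition(
                pan_coord=i,
                coordA=coordA,
                coordB=coordB,
                baseA=None if a == GAP else a,
                baseB=None if b == GAP else b,
                is_snp=is_snp,
                insertion_code=code,
            )
        )
    return Panmolecule(
        haplotypeA_id=ap.haplotypeA.accession_id,
        haplotypeB_id=ap.haplotypeB.accession_id,
        positions=positions,
    )


def lift_to_pan(coord: int, parent: Literal["A", "B"], pm: Panmolecule) -> int:
    """Convert a 1-based parental coordinate to its panmolecule coordinate."""
    index = pm._panA if parent == "A" else pm._panB
    try:
        return index[coord]
    except KeyError:
        n = pm.length_A if parent == "A" else pm.length_B
        raise RangeError(
            f"coordinate {coord} outside parent {parent} range 1..{n}"
        ) from None


def lift_from_pan(pan_coord: int, parent: Literal["A", "B"], pm: Panmolecule) -> Optional[int]:
    """Parental coordinate stored at a panmolecule position, or None for an
    insertion belonging to the other parent."""
    if not 1 <= pan_coord <= pm.length_bp:
        raise RangeError(f"pan coordinate {pan_coord} outside 1..{pm.length_bp}")
    p = pm.positions[pan_coord - 1]
    return p.coordA if parent == "A" else p.coordB


def polymorphism_track(pm: Panmolecule) -> PolymorphismTrack:
    """SNPs as weight-1 records; maximal runs of one-parent bases as single indel
    records weighted by their length in bp."""
    records: list[PolymorphismRecord] = []
    run_code = 0
    run_start = 0
    for p in pm.positions:
        code = p.insertion_code
        if code != run_code:
            if run_code in (1, 2):
                kind = "insertionB" if run_code == 1 else "insertionA"
                end = p.pan_coord - 1
                records.append(
                    PolymorphismRecord(run_start, end, kind, end - run_start + 1)
                )
            run_code = code
            run_start = p.pan_coord
        if code == 0 and p.is_snp:
            records.append(PolymorphismRecord(p.pan_coord, p.pan_coord, "SNP", 1))
    if run_code in (1, 2):
        kind = "insertionB" if run_code == 1 else "insertionA"
        end = pm.positions[-1].pan_coord
        records.append(PolymorphismRecord(run_start, end, kind, end - run_start + 1))
    records.sort(key=lambda r: r.pan_start)
    return PolymorphismTrack(records=tuple(records))


# ---------------------------------------------------------------------------
# key-table CSV I/O (published S2/S5-style dialect)
# ---------------------------------------------------------------------------

_KEY_COLUMNS = [
    "pan_coordinate",
    "coordA",
    "coordB",
    "SNP",
    "B_insertion",
    "A_insertion",
    "baseA",
    "baseB",
]


def write_key_table(pm: Panmolecule, path) -> None:
    """Write the key-table CSV: pan coordinate, cognate parental coordinates,
    SNP flag (1/blank), B-insertion flag (1/blank), A-insertion flag (2/blank)."""
    rows = []
    for p in pm.positions:
        rows.append(
            {
                "pan_coordinate": p.pan_coord,
                "coordA": p.coordA if p.coordA is not None else "",
                "coordB": p.coordB if p.coordB is not None else "",
                "SNP": 1 if p.is_snp else "",
                "B_insertion": 1 if p.insertion_code == 1 else "",
                "A_insertion": 2 if p.insertion_code == 2 else "",
                "baseA": p.baseA or "",
                "baseB": p.baseB or "",
            }
        )
    pd.DataFrame(rows, columns=_KEY_COLUMNS).to_csv(path, index=False)


class KeyTableParseError(InputError):
    """Malformed key table; message names the offending row."""


def read_key_table(path) -> Panmolecule:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_KEY_COLUMNS) - set(df.columns)
    if missing:
        raise KeyTableParseError(f"key table missing columns: {sorted(missing)}")
    positions: list[PanPosition] = []
    prev_a = prev_b = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pan = int(row.pan_coordinate)
        if pan != i:
            raise KeyTableParseError(f"row {i}: pan coordinate {pan} not contiguous")
        coordA = int(row.coordA) if row.coordA != "" else None
        coordB = int(row.coordB) if row.coordB != "" else None
        b_ins = row.B_insertion != ""
        a_ins = row.A_insertion != ""
        if b_ins and a_ins:
            raise KeyTableParseError(f"row {i}: both insertion flags set")
        if coordA is None and coordB is None:
            raise KeyTableParseError(f"row {i}: no parental coordinate")
        if coordA is not None:
            if coordA <= prev_a:
                raise KeyTableParseError(f"row {i}: non-monotone parent-A coordinate")
            prev_a = coordA
        if coordB is not None:
            if coordB <= prev_b:
                raise KeyTableParseError(f"row {i}: non-monotone parent-B coordinate")
            prev_b = coordB
        code = 1 if b_ins else 2 if a_ins else 0
        if code == 1 and coordA is not None:
            raise KeyTableParseError(f"row {i}: B-insertion flag on a shared position")
        if code == 2 and coordB is not None:
            raise KeyTableParseError(f"row {i}: A-insertion flag on a shared position")
        positions.append(
            PanPosition(
                pan_coord=pan,
                coordA=coordA,
                coordB=coordB,
                baseA=row.baseA or None,
                baseB=row.baseB or None,
                is_snp=row.SNP != "",
                insertion_code=code,
            )
        )
    return Panmolecule(haplotypeA_id="A", haplotypeB_id="B", positions=positions)


def read_fasta_haplotype(path, role: Literal["parentA", "parentB"]) -> Haplotype:
    """Load a single-record FASTA template as one parental haplotype."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise InputError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return Haplotype(accession_id=rec.id, sequence=str(rec.seq), role=role)
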