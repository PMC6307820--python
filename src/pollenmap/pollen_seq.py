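"""Crossover read-pair classification from pooled crossover-molecule sequencing.

Mass-amplified crossover molecules are sonicated, size-selected (300-400 bp)
and sequenced as 2x75 bp read pairs. Because the selecting primers force each
crossover molecule to run parent A on one side and parent B on the other, a
read pair that straddles the breakpoint has one end matching only template A
and the other only template B. Classification is a filter cascade with a
per-stage ledger:

    Total -> Mapped -> Unique -> Matched -> Orientate -> Strand

Mapped: each end has at least one zero-mismatch match to either template.
Unique: each end matches exactly one template at exactly one location.
Matched: the two ends match different templates.
Orientate: the parent-B end has the lower panmolecule coordinate (configurable).
Strand: the two ends lie on opposite strands, as sequencing of a physical
fragment requires.

Accepted pairs carry a breakpoint span (the open pan interval between the
inner read ends, where the crossover must lie) which is accumulated into a
per-base profile, normalized by the number of crossover pairs and weighted by
the titration-measured genetic distance in cM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .molecule_quant import GeneticDistance
from .panmolecule import VALID_BASES, Panmolecule, lift_to_pan

_COMP = str.maketrans("ACGT", "TGCA")

STAGES = ("Total", "Mapped", "Unique", "Matched", "Orientate", "Strand")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    seq1: str
    seq2: str


@dataclass(frozen=True)
class AlignmentHit:
    template: Literal["A", "B"]
    strand: Literal["+", "-"]
    start: int  # 1-based template coordinate of the leftmost matched base
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class CrossoverReadPair:
    pair_id: str
    hit_low: AlignmentHit  # end on the lower-pan-coordinate parent (B by default)
    hit_high: AlignmentHit
    breakpoint_span: tuple[int, int]  # open pan interval between inner read ends, inclusive
    fragment_span: tuple[int, int]  # outer end to outer end in pan coordinates


@dataclass
class FilterLedger:
    """Read pairs surviving each sequential filter; counts are non-increasing."""

    counts: dict[str, int]

    @classmethod
    def empty(cls) -> "FilterLedger":
        return cls(counts={s: 0 for s in STAGES})

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, name="read_pairs")


@dataclass(frozen=True)
class CoverageProfile:
    raw: np.ndarray  # integer counts per pan position (index 0 = pan 1)
    normalized: np.ndarray
    weighted: np.ndarray
    n_pairs: int
    cM: float


def align_exact(read: str, templateA: str, templateB: str) -> list[AlignmentHit]:
    """All zero-mismatch occurrences of the read (or its reverse complement) on
    both strands of both templates. Reads containing ambiguous bases never match."""
    read = read.upper()
    if not read or set(read) - VALID_BASES:
        return []
    hits: list[AlignmentHit] = []
    rc = revcomp(read)
    for name, template in (("A", templateA), ("B", templateB)):
        for strand, query in (("+", read), ("-", rc)):
            start = template.find(query)
            while start != -1:
                hits.append(AlignmentHit(name, strand, start + 1, len(query)))
                start = template.find(query, start + 1)
    return hits


def _pan_interval(hit: AlignmentHit, pm: Panmolecule) -> tuple[int, int]:
    return (
        lift_to_pan(hit.start, hit.template, pm),
        lift_to_pan(hit.end, hit.template, pm),
    )


def classify_pairs(
    pairs: Iterable[ReadPair],
    pm: Panmolecule,
    lower_parent: Literal["A", "B"] = "B",
) -> tuple[list[CrossoverReadPair], FilterLedger]:
    """Run the exact-match dual-template filter cascade.

    ``lower_parent`` sets which parent must occupy the lower pan coordinates in
    an accepted pair (default B, the published Ler-lower coordinate rule).
    Every rejected pair is attributed to exactly the first stage it fails.
    """
    templateA = pm.parental_sequence("A")
    templateB = pm.parental_sequence("B")
    ledger = FilterLedger.empty()
    accepted: list[CrossoverReadPair] = []
    for pair in pairs:
        ledger.counts["Total"] += 1
        hits1 = align_exact(pair.seq1, templateA, templateB)
        hits2 = align_exact(pair.seq2, templateA, templateB)
        if not hits1 or not hits2:
            continue
        ledger.counts["Mapped"] += 1
        if len(hits1) != 1 or len(hits2) != 1:
            continue
        ledger.counts["Unique"] += 1
        h1, h2 = hits1[0], hits2[0]
        if h1.template == h2.template:
            continue
        ledger.counts["Matched"] += 1
        low_hit = h1 if h1.template == lower_parent else h2
        high_hit = h2 if low_hit is h1 else h1
        low_iv = _pan_interval(low_hit, pm)
        high_iv = _pan_interval(high_hit, pm)
        if low_iv[1] >= high_iv[0]:
            continue
        ledger.counts["Orientate"] += 1
        if low_hit.strand == high_hit.strand:
            continue
        ledger.counts["Strand"] += 1
        accepted.append(
            CrossoverReadPair(
                pair_id=pair.pair_id,
                hit_low=low_hit,
                hit_high=high_hit,
                breakpoint_span=(low_iv[1] + 1, high_iv[0] - 1),
                fragment_span=(low_iv[0], high_iv[1]),
            )
        )
    return accepted, ledger


def accumulate_coverage(
    xos: Sequence[CrossoverReadPair], pm: Panmolecule
) -> np.ndarray:
    """Add 1 to every pan position in each pair's breakpoint span (difference-
    array accumulation); returns integer counts indexed from pan position 1."""
    diff = np.zeros(pm.length_bp + 1, dtype=np.int64)
    for xo in xos:
        start, end = xo.breakpoint_span
        if end < start:  # abutting reads: empty open interval
            continue
        diff[start - 1] += 1
        diff[end] -= 1
    return np.cumsum(diff[:-1])


def normalize_profile(
    raw: np.ndarray, n_crossover_pairs: int, cm: GeneticDistance | float
) -> CoverageProfile:
    """normalized = raw / n pairs; weighted = normalized * cM."""
    if n_crossover_pairs < 1:
        raise ValueError("need at least one crossover read pair to normalize")
    cm_value = cm.cM if isinstance(cm, GeneticDistance) else float(cm)
    normalized = raw.astype(float) / n_crossover_pairs
    return CoverageProfile(
        raw=np.asarray(raw),
        normalized=normalized,
        weighted=normalized * cm_value,
        n_pairs=n_crossover_pairs,
        cM=cm_value,
    )


@dataclass(frozen=True)
class FragmentLengthSummary:
    lengths: np.ndarray
    mean: float
    counts: np.ndarray  # histogram counts
    bin_edges: np.ndarray


def fragment_length_histogram(
    xos: Sequence[CrossoverReadPair], bins: int | Sequence[float] = 20
) -> FragmentLengthSummary:
    """Distribution of outer-end-to-outer-end fragment spans of accepted pairs."""
    if not xos:
        raise ValueError("no crossover read pairs")
    lengths = np.array([x.fragment_span[1] - x.fragment_span[0] + 1 for x in xos])
    counts, edges = np.histogram(lengths, bins=bins)
    return FragmentLengthSummary(
        lengths=lengths, mean=float(lengths.mean()), counts=counts, bin_edges=edges
    )


# ---------------------------------------------------------------------------
# tabular output on pancoordinates
# ---------------------------------------------------------------------------


def crossover_pairs_table(xos: Sequence[CrossoverReadPair]) -> pd.DataFrame:
    """BED-like table of accepted pairs on pancoordinates."""
    return pd.DataFrame(
        [
            {
                "pair_id": x.pair_id,
                "breakpoint_start": x.breakpoint_span[0],
                "breakpoint_end": x.breakpoint_span[1],
                "fragment_start": x.fragment_span[0],
                "fragment_end": x.fragment_span[1],
                "low_parent": x.hit_low.template,
                "high_parent": x.hit_high.template,
                "low_strand": x.hit_low.strand,
                "high_strand": x.hit_high.strand,
            }
            for x in xos
        ]
    )


def profile_table(profile: CoverageProfile) -> pd.DataFrame:
    """bedGraph-style per-position table (pan position, raw, normalized, weighted)."""
    n = len(profile.raw)
    return pd.DataFrame(
        {
            "pan_position": np.arange(1, n + 1),
            "raw": profile.raw,
            "normalized": profile.normalized,
            "weighted": profile.weighted,
        }
    )


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Load paired FASTQ files (read n of file 1 pairs with read n of file 2)."""
    from Bio import SeqIO

    reads1 = list(SeqIO.parse(str(path1), "fastq"))
    reads2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(reads1) != len(reads2):
        raise ValueError("FASTQ files have different read counts")
    return [
        ReadPair(pair_id=r1.id, seq1=str(r1.seq), seq2=str(r2.seq))
        for r1, r2 in zip(reads1, reads2)
    ]
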