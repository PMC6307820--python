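"""Crossover breakpoint calling from Sanger-genotyped single molecules.

Each amplified crossover molecule is genotyped at every polymorphism between
the selecting allele-specific primers, giving an ordered series of A/B allele
calls on panmolecule coordinates. A molecule with exactly one A->B transition
is a simple crossover whose breakpoint lies strictly between the last A-side
marker and the first B-side marker; zero transitions means a parental
(non-recombinant) molecule and more than one a complex molecule, which is
reported but excluded from rate tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import pandas as pd

from .molecule_quant import GeneticDistance
from .panmolecule import Panmolecule


class UninformativeMoleculeError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleCall:
    pan_position: int
    allele: Literal["A", "B", "unknown"]


@dataclass(frozen=True)
class MoleculeGenotype:
    molecule_id: str
    calls: tuple[AlleleCall, ...]

    def __post_init__(self) -> None:
        pos = [c.pan_position for c in self.calls]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"molecule {self.molecule_id}: positions not strictly increasing")

    def informative(self) -> list[AlleleCall]:
        return [c for c in self.calls if c.allele != "unknown"]


@dataclass(frozen=True)
class CrossoverCall:
    molecule_id: str
    status: Literal["simple", "complex", "parental"]
    n_transitions: int
    # closed on the flanking markers; the breakpoint lies strictly between them
    pan_start: Optional[int] = None  # last A-side marker (simple calls only)
    pan_end: Optional[int] = None  # first B-side marker


@dataclass(frozen=True)
class IntervalRateRow:
    pan_start: int
    pan_end: int
    length_bp: int  # open span on the panmolecule (bases strictly between markers)
    n_crossovers: int
    cM: float
    cM_per_Mb: float


@dataclass(frozen=True)
class IntervalRateTable:
    rows: tuple[IntervalRateRow, ...]
    total_cM: float
    n_simple: int
    n_complex_excluded: int


def call_breakpoint(mg: MoleculeGenotype) -> CrossoverCall:
    """Classify one molecule from its ordered informative allele calls.

    Unknown calls are skipped when counting transitions, so the call is
    invariant to inserting unknowns anywhere. Exactly one transition in the
    A->B (ASO selection) orientation makes a simple crossover; a lone B->A
    transition cannot come from the selected amplicon configuration and is
    classed complex.
    """
    inf = mg.informative()
    if len(inf) < 2:
        raise UninformativeMoleculeError(
            f"molecule {mg.molecule_id}: fewer than 2 informative calls"
        )
    transitions = [
        (prev, cur)
        for prev, cur in zip(inf, inf[1:])
        if prev.allele != cur.allele
    ]
    n = len(transitions)
    if n == 0:
        return CrossoverCall(mg.molecule_id, "parental", 0)
    if n == 1 and transitions[0][0].allele == "A":
        prev, cur = transitions[0]
        return CrossoverCall(
            mg.molecule_id,
            "simple",
            1,
            pan_start=prev.pan_position,
            pan_end=cur.pan_position,
        )
    return CrossoverCall(mg.molecule_id, "complex", n)


def interval_rates(
    calls: Sequence[CrossoverCall],
    total_cm: GeneticDistance | float,
    pm: Panmolecule | None = None,
    marker_positions: Sequence[int] | None = None,
) -> IntervalRateTable:
    """Per-interval crossover counts and cM/Mb on panmolecule coordinates.

    Interval cM = (crossovers in interval / total simple calls) * total cM;
    interval length is the open panmolecule span between the flanking markers.
    ``marker_positions`` (defaults to the panmolecule SNP positions) adds
    zero-crossover rows for every adjacent marker pair, mirroring the published
    interval tables; complex molecules are counted and excluded.
    """
    total_cm_value = total_cm.cM if isinstance(total_cm, GeneticDistance) else float(total_cm)
    simple = [c for c in calls if c.status == "simple"]
    n_complex = sum(1 for c in calls if c.status == "complex")
    if not simple:
        raise UninformativeMoleculeError("no simple crossover calls; rate table undefined")

    counts: dict[tuple[int, int], int] = {}
    for c in simple:
        key = (c.pan_start, c.pan_end)
        counts[key] = counts.get(key, 0) + 1

    if marker_positions is None and pm is not None:
        marker_positions = pm.snp_pan_positions()
    if marker_positions is not None:
        for a, b in zip(marker_positions, list(marker_positions)[1:]):
            counts.setdefault((a, b), 0)

    n_simple = len(simple)
    rows = []
    for (start, end), k in sorted(counts.items()):
        length = end - start - 1
        cm = k / n_simple * total_cm_value
        rate = cm / (length * 1e-6) if length > 0 else float("nan")
        rows.append(
            IntervalRateRow(
                pan_start=start,
                pan_end=end,
                length_bp=length,
                n_crossovers=k,
                cM=cm,
                cM_per_Mb=round(rate, 2) if length > 0 else rate,
            )
        )
    return IntervalRateTable(
        rows=tuple(rows),
        total_cM=total_cm_value,
        n_simple=n_simple,
        n_complex_excluded=n_complex,
    )


# ---------------------------------------------------------------------------
# CSV I/O: molecule_id, pan_position, allele
# ---------------------------------------------------------------------------


def read_genotype_csv(path) -> list[MoleculeGenotype]:
    df = pd.read_csv(path)
    out = []
    for mid, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("pan_position")
        calls = tuple(
            AlleleCall(int(r.pan_position), str(r.allele)) for r in grp.itertuples(index=False)
        )
        out.append(MoleculeGenotype(molecule_id=str(mid), calls=calls))
    return out


def write_interval_table(table: IntervalRateTable, path) -> None:
    """TSV mirroring the published interval-rate layout."""
    pd.DataFrame(
        [
            {
                "pan_start": r.pan_start,
                "pan_end": r.pan_end,
                "length_bp": r.length_bp,
                "n_crossovers": r.n_crossovers,
                "cM": r.cM,
                "cM_per_Mb": r.cM_per_Mb,
            }
            for r in table.rows
        ]
    ).to_csv(path, sep="\t", index=False)
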