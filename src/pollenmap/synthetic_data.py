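"""Seeded generators for every input the hotspot-mapping pipeline consumes.

The generator emulates a pollen-typing experiment on a disease-resistance-gene
amplicon from an F1 hybrid between two diverged accessions: a polymorphic
haplotype pair (~20-35 SNPs/kb plus indels, the divergence reported for the
Col/Ler and Col/Mh amplicons), single-breakpoint recombinant molecules drawn
from a configurable crossover landscape, sonication fragments of 300-400 bp
sequenced as 2x75 bp read pairs, and limiting-dilution titration outcomes with
known concentrations. Everything is deterministic under a fixed seed, and a
:class:`TruthSet` retains enough ground truth to score every pipeline output.

Because haplotype B is derived from A by explicit edits, the true alignment is
known by construction and the truth panmolecule is built from it directly —
no realignment is involved, so generator truth stays independent of the
alignment code it is used to test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .panmolecule import (
    GAP,
    AlignedPair,
    Haplotype,
    Panmolecule,
    build_panmolecule,
)
from .molecule_quant import TitrationLevel, TitrationSeries
from .pollen_seq import ReadPair, revcomp
from .sanger_xo import AlleleCall, MoleculeGenotype

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LandscapeSpec:
    """Per-interval crossover intensity.

    ``uniform``: every valid breakpoint position equally likely.
    ``table``: explicit per-window weights.
    ``inverse_divergence``: window intensity y = log(a) + b * x^(-c) from the
    window's polymorphism weight x (clipped at 0), spread uniformly over the
    window's valid breakpoint positions.
    """

    kind: Literal["uniform", "table", "inverse_divergence"] = "uniform"
    window_bp: int = 500
    weights: Optional[Sequence[float]] = None  # for kind == "table"
    a: float = 2.0
    b: float = 5.0
    c: float = 1.0


@dataclass(frozen=True)
class TitrationConfig:
    true_lambda: float  # molecules per reaction at dilution factor 1
    dilution_factors: tuple[float, ...] = (1.0, 3.0, 9.0, 27.0, 81.0)
    n_reactions: int = 24


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    length_bp: int = 6000
    snp_rate: float = 0.030  # per bp; the studied amplicons run 20-35 SNPs/kb
    indel_rate: float = 0.002  # events per bp
    indel_mean_len: float = 3.0  # geometric mean length
    landscape: LandscapeSpec = field(default_factory=LandscapeSpec)
    n_molecules: int = 1000
    fragment_min: int = 300
    fragment_max: int = 400
    read_len: int = 75
    seq_error_rate: float = 0.0
    titration_crossover: TitrationConfig = field(
        default_factory=lambda: TitrationConfig(true_lambda=0.8)
    )
    titration_parental: TitrationConfig = field(
        default_factory=lambda: TitrationConfig(
            true_lambda=800.0, dilution_factors=(243.0, 729.0, 2187.0, 6561.0)
        )
    )

    def __post_init__(self) -> None:
        if not (0 <= self.snp_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.length_bp <= 0 or self.read_len <= 0:
            raise ValueError("lengths must be positive")
        if self.fragment_min > self.fragment_max:
            raise ValueError("fragment_min must be <= fragment_max")


@dataclass
class SimMolecule:
    molecule_id: str
    sequence: str
    breakpoint_pan: Optional[int]  # last parent-A pan position; None = parental
    n_prefix_bases: int  # molecule bases drawn from parent A


@dataclass
class ReadPairTruth:
    pair_id: str
    molecule_id: str
    frag_start: int  # 1-based on the molecule
    frag_end: int
    read1_span: tuple[int, int]  # molecule coordinates
    read2_span: tuple[int, int]


@dataclass
class TruthSet:
    haplotypeA: Haplotype
    haplotypeB: Haplotype
    aligned: AlignedPair
    panmolecule: Panmolecule
    molecules: list[SimMolecule] = field(default_factory=list)
    read_pairs: list[ReadPairTruth] = field(default_factory=list)
    true_lambda: dict[str, float] = field(default_factory=dict)

    def molecule(self, molecule_id: str) -> SimMolecule:
        return next(m for m in self.molecules if m.molecule_id == molecule_id)

    def read_avoids_breakpoint(self, truth: ReadPairTruth, which: int) -> bool:
        """True when the given read (1 or 2) does not cross the crossover
        junction of its source molecule."""
        mol = self.molecule(truth.molecule_id)
        if mol.breakpoint_pan is None:
            return True
        span = truth.read1_span if which == 1 else truth.read2_span
        return span[1] <= mol.n_prefix_bases or span[0] > mol.n_prefix_bases


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_haplotypes(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> tuple[Haplotype, Haplotype, TruthSet]:
    """Ancestral sequence as parent A; parent B derived by Bernoulli SNPs and
    geometric-length indels (insertions in B and deletions from B with equal
    probability). The true alignment is recorded edit by edit."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    seq_a = _random_dna(rng, cfg.length_bp)
    columns: list[tuple[str, str]] = []
    i = 0
    while i < len(seq_a):
        if rng.random() < cfg.indel_rate:
            length = int(rng.geometric(1.0 / cfg.indel_mean_len))
            if rng.random() < 0.5:
                # insertion in B: B-only bases before the current A base
                for base in _random_dna(rng, length):
                    columns.append((GAP, base))
                continue  # current A base still to be emitted
            else:
                # deletion from B: A-only bases
                for j in range(min(length, len(seq_a) - i)):
                    columns.append((seq_a[i + j], GAP))
                i += min(length, len(seq_a) - i)
                continue
        base = seq_a[i]
        if rng.random() < cfg.snp_rate:
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            columns.append((base, alt))
        else:
            columns.append((base, base))
        i += 1
    hap_a = Haplotype("simA", "".join(c[0] for c in columns if c[0] != GAP), "parentA")
    hap_b = Haplotype("simB", "".join(c[1] for c in columns if c[1] != GAP), "parentB")
    aligned = AlignedPair(hap_a, hap_b, tuple(columns))
    pm = build_panmolecule(aligned)
    return hap_a, hap_b, TruthSet(hap_a, hap_b, aligned, pm)


def make_haplotypes_exact(
    rng: np.random.Generator,
    length_a: int,
    n_snps: int = 0,
    insertions_b: Sequence[int] = (),
    insertions_a: Sequence[int] = (),
    min_separation: int = 25,
) -> tuple[Haplotype, Haplotype, TruthSet]:
    """Haplotype pair with an exact polymorphism budget: ``n_snps`` SNPs plus
    indels of the given lengths (``insertions_b`` = B-only bases, i.e. bases
    absent from parent A; ``insertions_a`` = A-only). Events are placed at
    well-separated random positions so the edit script is unambiguous."""
    n_events = n_snps + len(insertions_b) + len(insertions_a)
    n_a_only = int(sum(insertions_a))
    slack = length_a - n_a_only - n_snps - (n_events + 1) * min_separation
    if slack < 0:
        raise ValueError("parent A too short for the requested events and separation")
    seq_a = _random_dna(rng, length_a)
    # anchor positions on parent A, strictly increasing with min separation
    gaps = rng.multinomial(slack, np.ones(n_events + 1) / (n_events + 1))
    kinds = (
        ["snp"] * n_snps
        + [("insB", l) for l in insertions_b]
        + [("insA", l) for l in insertions_a]
    )
    order = rng.permutation(len(kinds))
    columns: list[tuple[str, str]] = []
    pos = 0

    def emit_identical(n: int) -> None:
        nonlocal pos
        for k in range(n):
            columns.append((seq_a[pos + k], seq_a[pos + k]))
        pos += n

    for idx, g in zip(order, gaps[:-1]):
        emit_identical(int(g) + min_separation)
        ev = kinds[idx]
        if ev == "snp":
            base = seq_a[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            columns.append((base, alt))
            pos += 1
        elif ev[0] == "insB":
            for base in _random_dna(rng, ev[1]):
                columns.append((GAP, base))
        else:  # insA: consume A bases with no B counterpart
            for k in range(ev[1]):
                columns.append((seq_a[pos + k], GAP))
            pos += ev[1]
    emit_identical(length_a - pos)
    hap_a = Haplotype("simA", seq_a, "parentA")
    hap_b = Haplotype("simB", "".join(c[1] for c in columns if c[1] != GAP), "parentB")
    aligned = AlignedPair(hap_a, hap_b, tuple(columns))
    pm = build_panmolecule(aligned)
    return hap_a, hap_b, TruthSet(hap_a, hap_b, aligned, pm)


# ---------------------------------------------------------------------------
# recombinant molecules
# ---------------------------------------------------------------------------


def _valid_breakpoints(pm: Panmolecule) -> np.ndarray:
    """Pan positions b such that cutting between b and b+1 lies strictly
    between polymorphisms (never inside or adjacent to an indel or SNP)."""
    poly = np.array(
        [p.is_snp or p.insertion_code != 0 for p in pm.positions], dtype=bool
    )
    ok = ~poly.copy()
    ok[:-1] &= ~poly[1:]  # position b+1 must also be non-polymorphic
    ok[-1] = False  # need at least one B base to the right
    # require at least one polymorphism on each side, else the molecule is
    # indistinguishable from parental
    first = int(np.argmax(poly)) if poly.any() else 0
    last = len(poly) - 1 - int(np.argmax(poly[::-1])) if poly.any() else 0
    ok[: first + 1] = False
    ok[last:] = False
    return np.flatnonzero(ok) + 1  # 1-based pan coordinates


def _breakpoint_probabilities(
    pm: Panmolecule, candidates: np.ndarray, spec: LandscapeSpec
) -> np.ndarray:
    if spec.kind == "uniform":
        w = np.ones(len(candidates))
    else:
        win = (candidates - 1) // spec.window_bp
        if spec.kind == "table":
            weights = np.asarray(spec.weights, dtype=float)
            w = weights[np.minimum(win, len(weights) - 1)]
        elif spec.kind == "inverse_divergence":
            from .landscape_stats import _polymorphism_weights, _window_bounds
            from .panmolecule import polymorphism_track

            bounds = _window_bounds(pm.length_bp, spec.window_bp)
            x = _polymorphism_weights(polymorphism_track(pm), bounds)
            y = np.where(x > 0, np.log(spec.a) + spec.b * np.maximum(x, 1e-9) ** (-spec.c), 0.0)
            y = np.maximum(y, 0.0)
            # per-window intensity spread over that window's candidates
            n_cand = np.bincount(win, minlength=len(bounds)).astype(float)
            per_cand = np.where(n_cand > 0, y / np.maximum(n_cand, 1), 0.0)
            w = per_cand[win]
        else:
            raise ValueError(f"unknown landscape kind {spec.kind!r}")
    total = w.sum()
    if total <= 0:
        raise ValueError("crossover landscape has zero total intensity")
    return w / total


def sample_crossover_molecules(
    cfg: SimConfig,
    truth: TruthSet,
    rng: Optional[np.random.Generator] = None,
    n_molecules: Optional[int] = None,
) -> list[SimMolecule]:
    """Single-breakpoint recombinants: parent-A sequence left of the breakpoint
    joined to parent-B sequence right of it, in pan space."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = cfg.n_molecules if n_molecules is None else n_molecules
    pm = truth.panmolecule
    candidates = _valid_breakpoints(pm)
    if len(candidates) == 0:
        raise ValueError("no valid breakpoint positions (haplotypes too divergent?)")
    probs = _breakpoint_probabilities(pm, candidates, cfg.landscape)
    draws = rng.choice(candidates, size=n, p=probs)
    seq_a = pm.parental_sequence("A")
    seq_b = pm.parental_sequence("B")
    # cumulative parental base counts up to each pan position -> O(1) joins
    cum_a = np.cumsum([p.baseA is not None for p in pm.positions])
    cum_b = np.cumsum([p.baseB is not None for p in pm.positions])
    molecules = []
    for k, b in enumerate(sorted(draws.tolist())):
        prefix = seq_a[: cum_a[b - 1]]
        suffix = seq_b[cum_b[b - 1] :]
        molecules.append(
            SimMolecule(
                molecule_id=f"xo{k:05d}",
                sequence=prefix + suffix,
                breakpoint_pan=int(b),
                n_prefix_bases=len(prefix),
            )
        )
    truth.molecules.extend(molecules)
    return molecules


def make_parental_molecules(truth: TruthSet, parent: Literal["A", "B"], n: int) -> list[SimMolecule]:
    """Non-recombinant molecules carrying one parental haplotype end to end."""
    seq = truth.panmolecule.parental_sequence(parent)
    n_prefix = len(seq) if parent == "A" else 0
    mols = [
        SimMolecule(f"par{parent}{k:05d}", seq, None, n_prefix) for k in range(n)
    ]
    truth.molecules.extend(mols)
    return mols


def molecule_genotype(mol: SimMolecule, truth: TruthSet) -> MoleculeGenotype:
    """Perfect Sanger genotype of a simulated molecule at every SNP marker."""
    pm = truth.panmolecule
    calls = []
    for pos in pm.snp_pan_positions():
        if mol.breakpoint_pan is None:
            allele = "A" if mol.n_prefix_bases > 0 else "B"
        else:
            allele = "A" if pos <= mol.breakpoint_pan else "B"
        calls.append(AlleleCall(pan_position=pos, allele=allele))
    return MoleculeGenotype(molecule_id=mol.molecule_id, calls=tuple(calls))


# ---------------------------------------------------------------------------
# sequencing reads
# ---------------------------------------------------------------------------


def make_read_pairs(
    molecules: Sequence[SimMolecule],
    cfg: SimConfig,
    truth: TruthSet,
    rng: Optional[np.random.Generator] = None,
    pairs_per_molecule: int = 10,
) -> list[ReadPair]:
    """Sonication-fragment read pairs: fragment length uniform on
    [fragment_min, fragment_max], position uniform on the molecule; read 1 is
    the first ``read_len`` bases of the fragment, read 2 the reverse
    complement of the last. Which physical end yields read 1 is random, as in
    real library prep. Optional per-base substitution errors."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    pairs: list[ReadPair] = []
    n_resampled = 0
    for mol in molecules:
        mol_len = len(mol.sequence)
        for k in range(pairs_per_molecule):
            frag_len = int(rng.integers(cfg.fragment_min, cfg.fragment_max + 1))
            if frag_len > mol_len:
                n_resampled += 1
                frag_len = mol_len
            start = int(rng.integers(1, mol_len - frag_len + 2))
            end = start + frag_len - 1
            frag = mol.sequence[start - 1 : end]
            fwd = frag[: cfg.read_len]
            rev = revcomp(frag[-cfg.read_len :])
            fwd_span = (start, start + cfg.read_len - 1)
            rev_span = (end - cfg.read_len + 1, end)
            if rng.random() < 0.5:
                seq1, seq2, span1, span2 = fwd, rev, fwd_span, rev_span
            else:
                seq1, seq2, span1, span2 = rev, fwd, rev_span, fwd_span
            if cfg.seq_error_rate > 0:
                seq1 = _add_errors(seq1, cfg.seq_error_rate, rng)
                seq2 = _add_errors(seq2, cfg.seq_error_rate, rng)
            pair_id = f"{mol.molecule_id}.f{k}"
            pairs.append(ReadPair(pair_id=pair_id, seq1=seq1, seq2=seq2))
            truth.read_pairs.append(
                ReadPairTruth(
                    pair_id=pair_id,
                    molecule_id=mol.molecule_id,
                    frag_start=start,
                    frag_end=end,
                    read1_span=span1,
                    read2_span=span2,
                )
            )
    return pairs


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
    return "".join(out)


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------


def simulate_titration(
    tc: TitrationConfig,
    molecule_class: Literal["crossover", "parental"],
    rng: np.random.Generator,
) -> TitrationSeries:
    """Per level, positives ~ Binomial(n, 1 - exp(-lambda / dilution))."""
    levels = []
    for d in tc.dilution_factors:
        p = 1.0 - np.exp(-tc.true_lambda / d)
        k = int(rng.binomial(tc.n_reactions, p))
        levels.append(TitrationLevel(dilution_factor=d, n_reactions=tc.n_reactions, n_positive=k))
    return TitrationSeries(molecule_class=molecule_class, levels=tuple(levels))


# ---------------------------------------------------------------------------
# file emission (FASTA, FASTQ, CSV, JSON truth)
# ---------------------------------------------------------------------------


def write_fasta(haplotypes: Sequence[Haplotype], path) -> None:
    with open(path, "w") as fh:
        for hap in haplotypes:
            fh.write(f">{hap.accession_id}\n{hap.sequence}\n")


def write_fastq_pairs(pairs: Sequence[ReadPair], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "I" * len(p.seq1)
            q2 = "I" * len(p.seq2)
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{q2}\n")


def write_genotype_csv(genotypes: Sequence[MoleculeGenotype], path) -> None:
    import pandas as pd

    rows = [
        {"molecule_id": g.molecule_id, "pan_position": c.pan_position, "allele": c.allele}
        for g in genotypes
        for c in g.calls
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truth_json(truth: TruthSet, path) -> None:
    payload = {
        "length_bp": truth.panmolecule.length_bp,
        "n_snps": truth.panmolecule.n_snps,
        "insertion_bases_B_only": truth.panmolecule.insertion_bases(1),
        "insertion_bases_A_only": truth.panmolecule.insertion_bases(2),
        "breakpoints": {
            m.molecule_id: m.breakpoint_pan for m in truth.molecules
        },
        "true_lambda": truth.true_lambda,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
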