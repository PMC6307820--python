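"""Single-molecule quantification from limiting-dilution (titration) PCR.

Pollen-typing estimates crossover and parental amplifiable-molecule
concentrations by serial dilution: template is diluted until reactions contain
roughly zero-to-a-few molecules, and the fraction of positive reactions at each
dilution level carries Poisson information about the stock concentration. The
zero-class estimator per level is

    lambda_hat = -ln(1 - k/n)   molecules per reaction,

scaled by the fold-dilution back to the stock, with levels combined by
inverse-variance weighting. Genetic distance follows the pollen-typing formula
cM = 100 * crossovers / (crossovers + parentals), with uncertainty propagated
by the delta method, and genotypes are compared with 2x2 chi-square tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd
from scipy.stats import chi2_contingency


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class TitrationLevel:
    dilution_factor: float  # fold-dilution relative to stock (>0)
    n_reactions: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be > 0")
        if not 0 <= self.n_positive <= self.n_reactions:
            raise ValueError("need 0 <= n_positive <= n_reactions")


@dataclass(frozen=True)
class TitrationSeries:
    molecule_class: Literal["crossover", "parental"]
    levels: tuple[TitrationLevel, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("titration series needs at least one level")


@dataclass(frozen=True)
class MoleculeEstimate:
    concentration: float  # molecules per ul of stock
    variance: float
    n_levels_used: int


@dataclass(frozen=True)
class GeneticDistance:
    cM: float
    sd: float
    crossover_conc: float
    parental_conc: float


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p_value: float


def _level_estimate(level: TitrationLevel) -> tuple[float, float]:
    """Stock-scale (lambda_hat, variance) for one informative level.

    Delta method on p_hat = k/n: var(lambda_hat per reaction) = p / ((1-p) n).
    """
    p = level.n_positive / level.n_reactions
    lam = -math.log1p(-p) * level.dilution_factor
    var = p / ((1.0 - p) * level.n_reactions) * level.dilution_factor**2
    return lam, var


def estimate_concentration(
    ts: TitrationSeries, method: str = "inverse_variance"
) -> MoleculeEstimate:
    """Combine Poisson zero-class estimates across informative dilution levels.

    A level is informative when 0 < n_positive < n_reactions. ``method`` is
    ``inverse_variance`` (default) or ``best_level`` (the single level with the
    smallest variance).
    """
    informative = [
        lv for lv in ts.levels if 0 < lv.n_positive < lv.n_reactions
    ]
    if not informative:
        all_pos = all(lv.n_positive == lv.n_reactions for lv in ts.levels)
        state = "saturated (all reactions positive)" if all_pos else "empty (no positive reactions)"
        raise EstimationError(
            f"no informative titration level: series is {state}; "
            "re-dilute the template and repeat"
        )
    ests = [_level_estimate(lv) for lv in informative]
    if method == "best_level":
        lam, var = min(ests, key=lambda e: e[1])
        return MoleculeEstimate(lam, var, 1)
    if method != "inverse_variance":
        raise ValueError(f"unknown combination method {method!r}")
    weights = [1.0 / var for _, var in ests]
    wsum = sum(weights)
    lam = sum(w * e for w, (e, _) in zip(weights, ests)) / wsum
    return MoleculeEstimate(lam, 1.0 / wsum, len(ests))


def genetic_distance(xo: MoleculeEstimate, par: MoleculeEstimate) -> GeneticDistance:
    """cM = 100 * xo / (xo + par), SD by the delta method from both variances."""
    x, p = xo.concentration, par.concentration
    total = x + p
    if total <= 0:
        raise EstimationError("both concentrations are zero; genetic distance undefined")
    cm = 100.0 * x / total
    dx = 100.0 * p / total**2
    dp = -100.0 * x / total**2
    var = dx**2 * xo.variance + dp**2 * par.variance
    return GeneticDistance(cM=cm, sd=math.sqrt(var), crossover_conc=x, parental_conc=p)


def cm_per_mb(gd_or_cm, length_bp: int) -> float:
    """Recombination rate in cM/Mb over a panmolecule span, to 2 decimals."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    cm = gd_or_cm.cM if isinstance(gd_or_cm, GeneticDistance) else float(gd_or_cm)
    return round(cm / (length_bp * 1e-6), 2)


def compare_genetic_distance(a: GeneticDistance, b: GeneticDistance) -> ContingencyResult:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2 table of
    integer-rounded per-ul crossover/parental means of the two genotypes."""
    table = [
        [round(a.crossover_conc), round(a.parental_conc)],
        [round(b.crossover_conc), round(b.parental_conc)],
    ]
    if any(sum(row) == 0 for row in table) or any(
        table[0][j] + table[1][j] == 0 for j in (0, 1)
    ):
        raise EstimationError("zero marginal in 2x2 table; chi-square undefined")
    chi2, p, df, _ = chi2_contingency(table, correction=False)
    return ContingencyResult(chi2=float(chi2), df=int(df), p_value=float(p))


# ---------------------------------------------------------------------------
# CSV I/O: columns class,dilution_factor,n_reactions,n_positive
# ---------------------------------------------------------------------------


def read_titration_csv(path) -> dict[str, TitrationSeries]:
    df = pd.read_csv(path)
    out: dict[str, TitrationSeries] = {}
    for cls, grp in df.groupby("class"):
        levels = tuple(
            TitrationLevel(float(r.dilution_factor), int(r.n_reactions), int(r.n_positive))
            for r in grp.itertuples(index=False)
        )
        out[str(cls)] = TitrationSeries(molecule_class=str(cls), levels=levels)
    return out


def write_titration_csv(series: Sequence[TitrationSeries], path) -> None:
    rows = [
        {
            "class": ts.molecule_class,
            "dilution_factor": lv.dilution_factor,
            "n_reactions": lv.n_reactions,
            "n_positive": lv.n_positive,
        }
        for ts in series
        for lv in ts.levels
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
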