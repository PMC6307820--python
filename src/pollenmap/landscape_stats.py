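"""Windowed crossover/polymorphism statistics and the divergence model.

Crossovers and interhomolog polymorphism are tallied in adjacent fixed-size
windows along the panmolecule (500 bp for Sanger-resolution crossovers, 250 bp
for sequencing profiles). A crossover whose marker interval straddles a window
boundary is split fractionally by the proportion of the interval in each
window, so totals are conserved exactly. Polymorphism per window counts each
SNP as 1 and each indel as its length in bp, split per base across boundaries.
The final partial window is flagged and excluded from correlation and model
fitting.

The negative, non-linear relationship between local polymorphism x and
crossovers y is modelled as

    y = log(a) + b * x^(-c),        a > 0, c > 0,

fitted by bounded nonlinear least squares from a deterministic multi-start
grid. Monotone association is assessed with Spearman's rank correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panmolecule import Panmolecule, PolymorphismTrack
from .pollen_seq import CoverageProfile
from .sanger_xo import CrossoverCall


@dataclass(frozen=True)
class WindowRow:
    window_index: int
    pan_start: int
    pan_end: int
    crossover_value: float  # fractional count (sanger) or mean reads/cM (profile)
    polymorphism_weight: float  # bp-equivalents: SNP=1, indel=length
    included: bool  # False for the trailing partial window
    crossover_percent: Optional[float] = None


@dataclass(frozen=True)
class WindowTable:
    rows: tuple[WindowRow, ...]
    window_bp: int
    mode: str  # "sanger" | "profile"

    def included_rows(self) -> list[WindowRow]:
        return [r for r in self.rows if r.included]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


@dataclass(frozen=True)
class ModelFit:
    a: float
    b: float
    c: float
    residual_ss: float
    converged: bool
    n_windows: int
    n_zero_poly_excluded: int
    c_identifiable: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        return math.log(self.a) + self.b * np.asarray(x, dtype=float) ** (-self.c)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float


def _window_bounds(length_bp: int, window_bp: int) -> list[tuple[int, int, bool]]:
    """(pan_start, pan_end, included) per adjacent window; trailing partial
    window flagged excluded."""
    bounds = []
    start = 1
    idx = 0
    while start <= length_bp:
        end = min(start + window_bp - 1, length_bp)
        full = end - start + 1 == window_bp
        bounds.append((start, end, full))
        start = end + 1
        idx += 1
    return bounds


def _polymorphism_weights(
    track: PolymorphismTrack, bounds: Sequence[tuple[int, int, bool]]
) -> np.ndarray:
    w = np.zeros(len(bounds))
    for rec in track.records:
        for i, (ws, we, _) in enumerate(bounds):
            overlap = min(rec.pan_end, we) - max(rec.pan_start, ws) + 1
            if overlap > 0:
                # SNP records span 1 bp; indel weight splits per base
                w[i] += overlap if rec.kind != "SNP" else 1
    return w


def _fractional_counts(
    calls: Sequence[CrossoverCall], bounds: Sequence[tuple[int, int, bool]]
) -> np.ndarray:
    counts = np.zeros(len(bounds))
    for call in calls:
        if call.status != "simple":
            continue
        lo, hi = call.pan_start + 1, call.pan_end - 1  # open span between markers
        if hi < lo:
            # adjacent markers: split the point breakpoint across the two
            # windows holding the flanking markers
            for pos, frac in ((call.pan_start, 0.5), (call.pan_end, 0.5)):
                for i, (ws, we, _) in enumerate(bounds):
                    if ws <= pos <= we:
                        counts[i] += frac
                        break
            continue
        total = hi - lo + 1
        for i, (ws, we, _) in enumerate(bounds):
            overlap = min(hi, we) - max(lo, ws) + 1
            if overlap > 0:
                counts[i] += overlap / total
    return counts


def window_counts(
    data: Sequence[CrossoverCall] | CoverageProfile,
    track: PolymorphismTrack,
    pm: Panmolecule,
    window_bp: int = 500,
) -> WindowTable:
    """Build the per-window crossover / polymorphism table.

    Sanger mode (``data`` is a list of crossover calls): each simple crossover
    contributes to each window the fraction of its open marker interval that
    the window covers. Profile mode (``data`` is a :class:`CoverageProfile`):
    the crossover value is the mean cM-weighted profile over the window.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    bounds = _window_bounds(pm.length_bp, window_bp)
    if isinstance(data, CoverageProfile):
        mode = "profile"
        values = np.array(
            [data.weighted[ws - 1 : we].mean() for ws, we, _ in bounds]
        )
    else:
        mode = "sanger"
        values = _fractional_counts(data, bounds)
    poly = _polymorphism_weights(track, bounds)
    rows = tuple(
        WindowRow(
            window_index=i,
            pan_start=ws,
            pan_end=we,
            crossover_value=float(values[i]),
            polymorphism_weight=float(poly[i]),
            included=full,
        )
        for i, (ws, we, full) in enumerate(bounds)
    )
    return WindowTable(rows=rows, window_bp=window_bp, mode=mode)


def percent_normalize(wt: WindowTable) -> WindowTable:
    """Express each included window's crossover value as a percent of the total
    over included windows, making landscapes comparable across hybrids."""
    included = wt.included_rows()
    total = sum(r.crossover_value for r in included)
    if total <= 0:
        raise ValueError("all-zero window table; percent normalization undefined")
    rows = tuple(
        WindowRow(
            window_index=r.window_index,
            pan_start=r.pan_start,
            pan_end=r.pan_end,
            crossover_value=r.crossover_value,
            polymorphism_weight=r.polymorphism_weight,
            included=r.included,
            crossover_percent=(100.0 * r.crossover_value / total) if r.included else None,
        )
        for r in wt.rows
    )
    return WindowTable(rows=rows, window_bp=wt.window_bp, mode=wt.mode)


class FitError(RuntimeError):
    pass


_START_GRID = {
    "a": (0.1, 1.0, 10.0),
    "b": (0.1, 1.0, 10.0, 100.0),
    "c": (0.25, 0.5, 1.0, 2.0),
}


def fit_divergence_model(
    wt: WindowTable | tuple[np.ndarray, np.ndarray]
) -> ModelFit:
    """Fit y = log(a) + b*x^(-c) to included windows by least squares.

    Multi-start over a fixed grid of (a, b, c) initial values in deterministic
    order; a and c are bounded positive. Windows with zero polymorphism weight
    are excluded (x^(-c) is undefined at 0) and their count reported. When the
    data are flat in x, b collapses to ~0 and c is flagged unidentifiable.
    """
    if isinstance(wt, WindowTable):
        rows = [r for r in wt.included_rows()]
        x = np.array([r.polymorphism_weight for r in rows], dtype=float)
        y = np.array([r.crossover_value for r in rows], dtype=float)
    else:
        x = np.asarray(wt[0], dtype=float)
        y = np.asarray(wt[1], dtype=float)
    keep = x > 0
    n_excluded = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise FitError("need at least 4 windows with positive polymorphism weight")

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, c = theta
        return np.log(a) + b * x ** (-c) - y

    lo = [1e-12, -np.inf, 1e-12]
    hi = [np.inf, np.inf, np.inf]
    best = None
    for a0, b0, c0 in itertools.product(
        _START_GRID["a"], _START_GRID["b"], _START_GRID["c"]
    ):
        try:
            res = optimize.least_squares(
                residuals, x0=[a0, b0, c0], bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost - 1e-15):
            best = res
    if best is None:
        raise FitError("divergence-model fit failed to converge from every start")
    a, b, c = best.x
    rss = float(2 * best.cost)
    # flat data: the b*x^(-c) term is negligible everywhere, c means nothing
    term_range = float(np.ptp(b * x ** (-c)))
    scale = max(1.0, float(np.ptp(y)))
    c_ident = term_range > 1e-6 * scale
    return ModelFit(
        a=float(a),
        b=float(b),
        c=float(c),
        residual_ss=rss,
        converged=True,
        n_windows=len(x),
        n_zero_poly_excluded=n_excluded,
        c_identifiable=bool(c_ident),
    )


def spearman_windows(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Spearman rank correlation (mid-rank ties) with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p))


def window_table_tsv(wt: WindowTable, path) -> None:
    wt.to_frame().to_csv(path, sep="\t", index=False)
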