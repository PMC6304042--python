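"""Contrast-response function (CRF) fitting and supra-baseline selection.

The saturating dependence of steady-state amplitude on stimulus contrast is
modelled with the Naka-Rushton (hyperbolic ratio) function

    R(C) = baseline + r_max * C^n / (C^n + c50^n)

with semi-saturation contrast ``c50`` (% Michelson), exponent ``n`` and an
additive noise-floor ``baseline``.  Fits are ordinary (optionally weighted)
least squares from a small fixed multi-start grid, so results are
deterministic.

``select_supra_baseline`` identifies the contrast conditions whose
first-harmonic amplitude is statistically above the 0%-contrast (blank)
response; only those conditions later enter the frequency-ratio index, so
that the index is not dominated by noise-floor measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ContrastResponseFunction",
    "SupraBaselineSet",
    "naka_rushton",
    "fit_crf",
    "select_supra_baseline",
]


def naka_rushton(
    contrast, r_max: float, c50: float, exponent: float, baseline: float = 0.0
):
    """Hyperbolic-ratio CRF; accepts scalar or array contrast in percent."""
    c = np.asarray(contrast, dtype=float)
    cn = np.power(c, exponent)
    out = baseline + r_max * cn / (cn + c50**exponent)
    return float(out) if np.isscalar(contrast) else out


@dataclass(frozen=True)
class ContrastResponseFunction:
    """Fitted Naka-Rushton parameters for one group x harmonic."""

    r_max: float         # saturating amplitude, uV
    c50: float           # semi-saturation contrast, %
    exponent: float      # dimensionless
    baseline: float      # response at 0% contrast, uV
    residual_rms: float  # uV

    def predict(self, contrast):
        return naka_rushton(contrast, self.r_max, self.c50, self.exponent,
                            self.baseline)


# Fixed multi-start grid over (c50, exponent); deterministic fits.
_C50_STARTS = (3.0, 10.0, 30.0, 60.0, 120.0)
_EXP_STARTS = (0.5, 1.0, 2.0, 4.0)


def fit_crf(
    contrasts: Sequence[float],
    amplitudes: Sequence[float],
    weights: Sequence[float] | None = None,
) -> ContrastResponseFunction:
    """Least-squares Naka-Rushton fit to amplitude-vs-contrast data.

    Bounds: r_max in [0, 10 x max amplitude], c50 in (0, 200],
    exponent in (0, 5], baseline in [0, max amplitude].  The best of the
    multi-start solutions is returned; ties in residual are broken by the
    lower c50.
    """
    c = np.asarray(contrasts, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("contrasts and amplitudes must be 1-D and equal length")
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    if np.any(y < 0) or np.any(c < 0):
        raise ValueError("contrasts and amplitudes must be non-negative")
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct contrasts to fit 4 parameters")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))

    ymax = max(float(y.max()), 1e-12)
    lb = np.array([0.0, 1e-3, 1e-3, 0.0])
    ub = np.array([10.0 * ymax, 200.0, 5.0, ymax + 1e-12])

    def residual(theta):
        r_max, c50, n, b = theta
        return w * (naka_rushton(c, r_max, c50, n, b) - y)

    r0 = max(float(y.max() - y.min()), 1e-6)
    b0 = float(y.min())
    best = None
    for c50_0 in _C50_STARTS:
        for n0 in _EXP_STARTS:
            x0 = np.clip([r0, c50_0, n0, b0], lb, ub)
            sol = optimize.least_squares(
                residual, x0, bounds=(lb, ub), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            key = (sol.cost, sol.x[1])
            if best is None or _better(key, best[0]):
                best = (key, sol)
    sol = best[1]
    r_max, c50, n, b = sol.x
    rms = float(np.sqrt(np.mean((naka_rushton(c, r_max, c50, n, b) - y) ** 2)))
    return ContrastResponseFunction(
        r_max=float(r_max), c50=float(c50), exponent=float(n),
        baseline=float(b), residual_rms=rms,
    )


def _better(key, ref, rtol: float = 1e-9) -> bool:
    """Lower cost wins; near-ties (relative rtol) go to the lower c50."""
    cost, c50 = key
    cost_ref, c50_ref = ref
    if cost < cost_ref - rtol * (1.0 + cost_ref):
        return True
    if cost <= cost_ref + rtol * (1.0 + cost_ref):
        return c50 < c50_ref
    return False


@dataclass(frozen=True)
class SupraBaselineSet:
    """Contrast conditions whose 1F amplitude exceeds the blank response."""

    harmonic: int
    selected_contrasts: tuple[float, ...]
    alpha: float
    stats: Mapping[float, Mapping[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "harmonic": self.harmonic,
            "selected_contrasts": list(self.selected_contrasts),
            "alpha": self.alpha,
            "stats": {str(k): dict(v) for k, v in self.stats.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SupraBaselineSet":
        return cls(
            harmonic=int(d["harmonic"]),
            selected_contrasts=tuple(float(c) for c in d["selected_contrasts"]),
            alpha=float(d["alpha"]),
            stats={float(k): v for k, v in d.get("stats", {}).items()},
        )


def select_supra_baseline(
    responses: pd.DataFrame,
    harmonic: int = 1,
    alpha: float = 0.05,
) -> SupraBaselineSet:
    """Select contrasts with 1F amplitude significantly above baseline.

    For each nonzero contrast a one-sided paired t-test compares subjects'
    amplitude at that contrast against their 0%-contrast amplitude; the
    contrast is selected iff p < alpha (uncorrected).  Subjects are pooled
    across groups so one condition set is produced per dataset.

    ``responses`` is a long table with columns subject_id, contrast,
    harmonic, amplitude (the per-subject coherent averages).
    """
    sub = responses[responses["harmonic"] == harmonic]
    if sub.empty:
        raise ValueError(f"no rows for harmonic {harmonic}")
    pivot = sub.pivot_table(index="subject_id", columns="contrast",
                            values="amplitude", aggfunc="mean")
    if 0.0 not in pivot.columns:
        raise ValueError("responses lack a 0% (baseline) contrast condition")
    if len(pivot) < 2:
        raise ValueError("need at least two subjects")
    baseline = pivot[0.0]
    selected = []
    stat_table: dict[float, dict[str, float]] = {}
    for contrast in sorted(col for col in pivot.columns if col > 0.0):
        paired = pd.concat([pivot[contrast], baseline], axis=1).dropna()
        t, p = stats.ttest_rel(paired.iloc[:, 0], paired.iloc[:, 1],
                               alternative="greater")
        stat_table[float(contrast)] = {"t": float(t), "p": float(p),
                                       "n": int(len(paired))}
        if p < alpha:
            selected.append(float(contrast))
    if not selected:
        # degenerate but legal: nothing rises above the noise floor
        pass
    return SupraBaselineSet(
        harmonic=harmonic,
        selected_contrasts=tuple(selected),
        alpha=alpha,
        stats=stat_table,
    )
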