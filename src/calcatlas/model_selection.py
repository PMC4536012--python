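"""SPHARM model-order selection (MDL) and population coefficient reduction.

The truncation degree L is chosen by Rissanen's Minimum Description Length
criterion in its standard Gaussian linear-model form,

    MDL(L) = (D/2) ln(RSS_L / D) + ((L+1)^2 / 2) ln D,

with RSS_L the residual sum of squares of the least-squares fit at order L
and D the number of radius samples.  The penalty grows strictly with L, so
noiseless data of true order L0 select L0 exactly.

After order selection the coefficient set is reduced across the population:
each coefficient is tested for zero mean over bones (one-sample t test) and
the Benjamini–Hochberg procedure controls the false discovery rate; the
retained coefficients are the rejected nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spharm import SphericalSamples, fit_coefficients

__all__ = ["MDLResult", "ReductionResult", "mdl_select", "reduce_coefficients"]

# keeps ln(RSS/D) finite on degenerate noiseless fits
RSS_FLOOR_PER_SAMPLE = 1e-12


@dataclass(frozen=True)
class MDLResult:
    orders: np.ndarray
    criteria: np.ndarray
    rss: np.ndarray
    selected_order: int


@dataclass(frozen=True)
class ReductionResult:
    """Per-coefficient zero-mean test outcome across a bone population."""

    p_values: np.ndarray
    retained: np.ndarray
    level: float

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def mdl_select(samples: SphericalSamples, max_order: int) -> MDLResult:
    """Evaluate MDL(L) for L = 0..max_order and return the minimizing order.

    Requires more samples than the largest model's coefficient count.  Ties
    resolve to the smallest order (np.argmin convention), favouring the more
    parsimonious model.
    """
    if samples.n_samples <= (max_order + 1) ** 2:
        raise ValueError("need more samples than coefficients at max_order")
    d = samples.n_samples
    orders = np.arange(max_order + 1)
    rss = np.empty(max_order + 1)
    crit = np.empty(max_order + 1)
    floor = RSS_FLOOR_PER_SAMPLE * d
    for L in orders:
        fit = fit_coefficients(samples, int(L))
        rss[L] = fit.rss
        k = (L + 1) ** 2
        crit[L] = 0.5 * d * np.log(max(fit.rss, floor) / d) + 0.5 * k * np.log(d)
    return MDLResult(
        orders=orders, criteria=crit, rss=rss, selected_order=int(np.argmin(crit))
    )


def reduce_coefficients(matrix: np.ndarray, level: float = 0.05) -> ReductionResult:
    """Benjamini–Hochberg reduction of a (bones x Q) coefficient matrix.

    Each column gets a one-sample t test of mean zero; BH-adjusted p-values
    below ``level`` mark the coefficient as retained (representative).
    Zero-variance columns bypass the t test: an identically-zero column is
    excluded (it carries no shape information), a constant nonzero column is
    retained with p = 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 3:
        raise ValueError("need a (bones x Q) matrix with at least 3 bones")
    if not 0.0 < level < 1.0:
        raise ValueError("FDR level must be in (0, 1)")
    n_coeff = matrix.shape[1]
    sd = matrix.std(axis=0, ddof=1)
    mean = matrix.mean(axis=0)
    degenerate = sd == 0.0

    p_raw = np.ones(n_coeff)
    testable = ~degenerate
    if testable.any():
        res = stats.ttest_1samp(matrix[:, testable], popmean=0.0, axis=0)
        p_raw[testable] = res.pvalue
    p_raw[degenerate & (mean != 0.0)] = 0.0
    p_raw[degenerate & (mean == 0.0)] = 1.0

    adjusted = np.ones(n_coeff)
    adjusted[testable] = stats.false_discovery_control(p_raw[testable], method="bh")
    adjusted[degenerate & (mean != 0.0)] = 0.0
    retained = adjusted < level
    retained[degenerate & (mean == 0.0)] = False
    return ReductionResult(p_values=adjusted, retained=retained, level=level)
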