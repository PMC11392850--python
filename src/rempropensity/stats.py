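"""Correlation and proportion analyses linking propensity to REM features.

Reproduces the pipeline's report tables: Pearson correlations (two-tailed
t-test p-values) between the propensity at REM onset and (a) the duration of
the next REM bout, (b) the number |S| of consecutive sequential cycles
following a single cycle, (c) the presence of at least one sequential cycle
(point-biserial), and (d) |S| restricted to anchors with |S| >= 1; a
companion logistic regression for (c); and Welch comparisons of the
proportion of sleep spent in REM between single cycles, sequential cycles
and sequential chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .classify import Chain, SEQUENTIAL, SINGLE
from .cycles import RemCycle
from .propensity import PropensityCurve

__all__ = [
    "StatsError",
    "CorrelationResult",
    "LogisticResult",
    "ProportionResult",
    "propensity_at_onset",
    "onset_propensities",
    "pearson_r_p",
    "correlate_rempost",
    "correlate_chains",
    "logistic_seq_presence",
    "rem_fraction_compare",
]

ALPHA = 0.05


class StatsError(ValueError):
    """A statistical contract violation (too few pairs, zero variance, ...)."""


@dataclass(frozen=True)
class CorrelationResult:
    subset: tuple[str, ...]
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class LogisticResult:
    slope: float
    p: float
    n: int
    separated: bool  # perfect separation flagged, not fatal


@dataclass(frozen=True)
class ProportionResult:
    phase: str
    frac_single: float
    frac_sequential: float
    frac_chain: float
    p_single_vs_seq: float
    p_single_vs_chain: float
    n_single: int
    n_sequential: int
    n_chains: int


def propensity_at_onset(cycle: RemCycle, curve: PropensityCurve) -> float:
    """p30 at the cycle's realized |N| — the propensity when REMpost begins.

    Evaluated at the nearest grid second; beyond the grid the direct formula
    is used.
    """
    return curve.at(cycle.n_s)


def onset_propensities(
    cycles: Sequence[RemCycle], curves: Mapping[int, PropensityCurve]
) -> np.ndarray:
    """Vector of onset propensities, resolving each cycle's bin curve."""
    out = np.empty(len(cycles))
    for i, c in enumerate(cycles):
        if c.bin_index not in curves:
            raise KeyError(f"no propensity curve for bin {c.bin_index}")
        out[i] = curves[c.bin_index].at(c.n_s)
    return out


def pearson_r_p(
    x: Sequence[float], y: Sequence[float], subset: tuple[str, ...] = ()
) -> CorrelationResult:
    """Sample Pearson r with the two-tailed t-test p-value.

    p is derived from t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom
    (what :func:`scipy.stats.pearsonr` computes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-d and equal length")
    if x.size < 3:
        raise StatsError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(subset=subset, r=float(r), p=float(p), n=int(x.size))


def correlate_rempost(
    cycles: Sequence[RemCycle],
    curves: Mapping[int, PropensityCurve],
    subset: tuple[str, ...] = (),
) -> CorrelationResult:
    """Correlation between onset propensity and |REMpost| over a cycle group.

    The caller selects the group (one phase, before- or after-peak cycles
    lumped across |REMpre| bins); this computes the correlation.
    """
    if len(cycles) == 0:
        raise StatsError("empty cycle group")
    p30 = onset_propensities(cycles, curves)
    rempost = np.array([c.rempost_s for c in cycles])
    return pearson_r_p(p30, rempost, subset=subset)


def correlate_chains(
    chains: Sequence[Chain],
    anchor_p30: Sequence[float],
    subset: tuple[str, ...] = (),
) -> dict[str, CorrelationResult]:
    """The three |S| correlations for a group of single-cycle anchors.

    Returns keys ``n_sequential`` (propensity vs |S|), ``seq_presence``
    (propensity vs the 0/1 indicator |S| >= 1, point-biserial via the plain
    Pearson formula) and ``n_sequential_in_chains`` (propensity vs |S|
    restricted to anchors with |S| >= 1).
    """
    if len(chains) != len(anchor_p30):
        raise StatsError("chains and anchor propensities must align")
    p30 = np.asarray(anchor_p30, dtype=float)
    s = np.array([c.length_S for c in chains], dtype=float)
    out: dict[str, CorrelationResult] = {}
    out["n_sequential"] = pearson_r_p(p30, s, subset=subset + ("n_sequential",))
    out["seq_presence"] = pearson_r_p(
        p30, (s >= 1).astype(float), subset=subset + ("seq_presence",)
    )
    mask = s >= 1
    out["n_sequential_in_chains"] = pearson_r_p(
        p30[mask], s[mask], subset=subset + ("n_sequential_in_chains",)
    )
    return out


def logistic_seq_presence(
    p30: Sequence[float], indicator: Sequence[int]
) -> LogisticResult:
    """Maximum-likelihood logistic slope and Wald p for P(sequential follows).

    Companion to the point-biserial correlation. Perfect separation is
    flagged in the result rather than raised.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    x = np.asarray(p30, dtype=float)
    y = np.asarray(indicator, dtype=float)
    if x.shape != y.shape:
        raise StatsError("propensity and indicator must align")
    classes = np.unique(y)
    if classes.size < 2:
        raise StatsError("both outcome classes must be present")
    design = sm.add_constant(x)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0)
            slope = float(fit.params[1])
            p = float(fit.pvalues[1])
        except Exception:
            separated = True
            slope = float("inf") if np.corrcoef(x, y)[0, 1] > 0 else float("-inf")
            p = float("nan")
    return LogisticResult(slope=slope, p=p, n=int(x.size), separated=separated)


def _rem_fraction(c: RemCycle) -> float:
    # sleep only: the cycle's own REM bout over REM + inter-REM NREM
    return c.rempre_s / (c.rempre_s + c.n_s)


def rem_fraction_compare(
    cycles: Sequence[RemCycle],
    labels: Sequence[str],
    chains: Sequence[Chain],
    phase_name: str = "",
) -> ProportionResult:
    """Welch comparisons of the proportion of sleep spent in REM.

    Per cycle the fraction is rempre / (rempre + n); wake is excluded so the
    ratio reflects sleep composition. A chain's fraction pools the epochs of
    its sequential members (sum of REM over sum of REM + NREM). Welch's
    unequal-variance two-tailed t-test compares single cycles against
    sequential cycles and against chains.
    """
    if len(cycles) != len(labels):
        raise StatsError("cycles and labels must align")
    fr_single = [
        _rem_fraction(c) for c, lab in zip(cycles, labels) if lab == SINGLE
    ]
    fr_seq = [
        _rem_fraction(c) for c, lab in zip(cycles, labels) if lab == SEQUENTIAL
    ]
    if not fr_single or not fr_seq:
        raise StatsError("both single and sequential cycles are required")
    fr_chain: list[float] = []
    for ch in chains:
        if ch.length_S < 1:
            continue
        members = [cycles[i] for i in ch.member_indices]
        rem = sum(c.rempre_s for c in members)
        total = sum(c.rempre_s + c.n_s for c in members)
        fr_chain.append(rem / total)
    if not fr_chain:
        raise StatsError("no sequential chains with |S| >= 1")
    t_seq = sps.ttest_ind(fr_single, fr_seq, equal_var=False)
    t_chain = sps.ttest_ind(fr_single, fr_chain, equal_var=False)
    return ProportionResult(
        phase=phase_name,
        frac_single=float(np.mean(fr_single)),
        frac_sequential=float(np.mean(fr_seq)),
        frac_chain=float(np.mean(fr_chain)),
        p_single_vs_seq=float(t_seq.pvalue),
        p_single_vs_chain=float(t_chain.pvalue),
        n_single=len(fr_single),
        n_sequential=len(fr_seq),
        n_chains=len(fr_chain),
    )
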