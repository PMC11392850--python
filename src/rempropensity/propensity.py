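"""The predictive REM propensity p_delta(|N|) and its peak structure.

The propensity is the probability that the transition to REM occurs before
another delta seconds of NREM accumulate, given |N| seconds already have:

    p_delta(n) = (F(n + delta) - F(n)) / (1 - F(n)),

a discrete-horizon hazard of the inter-REM |N| distribution. With F the
lognormal-mixture CDF fitted per |REMpre| bin, every such curve rises to at
least one strict local maximum and decays to zero as |N| grows; the largest
local maximum on the 1..3000 s grid splits cycles into before-peak and
after-peak groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence, Union

import numpy as np

from .cycles import RemCycle
from .gmm import GmmParams, mixture_cdf, mixture_sf

__all__ = [
    "PropensityCurve",
    "NoPeakError",
    "DEFAULT_DELTA_S",
    "DEFAULT_GRID_MAX_S",
    "cdf_of_n",
    "survival_of_n",
    "propensity_at",
    "mixture_propensity",
    "evaluate_curve",
    "find_peak",
    "split_before_after",
]

logger = logging.getLogger(__name__)

DEFAULT_DELTA_S = 30.0
DEFAULT_GRID_MAX_S = 3000

#: A plain CDF this close to 1 is treated as 1 (event certain) to avoid 0/0.
_CDF_ONE_TOL = 1e-12


class NoPeakError(RuntimeError):
    """The curve has no interior strict local maximum."""


def cdf_of_n(
    params: GmmParams, n_s: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Probability that REM is entered after at most *n_s* seconds of NREM.

    The mixture is fitted on log(|N|), so this is the mixture CDF at log(n).
    """
    n = np.asarray(n_s, dtype=float)
    if np.any(n <= 0):
        raise ValueError("n_s must be positive")
    return mixture_cdf(params, np.log(n))


def survival_of_n(
    params: GmmParams, n_s: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """1 - cdf_of_n, computed via normal survival functions (tail-accurate)."""
    n = np.asarray(n_s, dtype=float)
    if np.any(n <= 0):
        raise ValueError("n_s must be positive")
    return mixture_sf(params, np.log(n))


def propensity_at(
    cdf: Callable[[float], float],
    n_s: float,
    delta_s: float = DEFAULT_DELTA_S,
) -> float:
    """p_delta(n) for an arbitrary monotone CDF over seconds.

    Clamped to [0, 1] against rounding; where the CDF is numerically 1 the
    transition has almost surely already occurred and the propensity is
    defined as 1 (with a warning).
    """
    f_n = float(cdf(n_s))
    if f_n >= 1.0 - _CDF_ONE_TOL:
        logger.warning(
            "CDF numerically 1 at n=%g s; propensity defined as 1", n_s
        )
        return 1.0
    f_next = float(cdf(n_s + delta_s))
    p = (f_next - f_n) / (1.0 - f_n)
    return min(max(p, 0.0), 1.0)


def mixture_propensity(
    params: GmmParams,
    n_s: Union[float, np.ndarray],
    delta_s: float = DEFAULT_DELTA_S,
) -> Union[float, np.ndarray]:
    """p_delta(n) for a fitted mixture, via survival functions.

    Using p = 1 - S(n + delta)/S(n) keeps the far tail exact (S underflows
    only around z ~ 39), so the decay of the propensity to zero at very
    large |N| is represented faithfully rather than being clipped by
    double-precision loss in 1 - CDF.
    """
    n = np.asarray(n_s, dtype=float)
    s_now = np.asarray(survival_of_n(params, n))
    s_next = np.asarray(survival_of_n(params, n + delta_s))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - s_next / s_now
    dead = s_now == 0.0
    if np.any(dead):
        logger.warning("survival underflowed to 0; propensity defined as 1")
        p = np.where(dead, 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class PropensityCurve:
    """p_delta evaluated on an integer-second grid, with its peak location."""

    delta_s: float
    grid_s: np.ndarray
    values: np.ndarray
    peak_n_s: float
    params: GmmParams
    label: str = ""

    def at(self, n_s: float) -> float:
        """Propensity at a realized |N|: nearest grid second, or the direct
        formula beyond the grid."""
        if n_s < 1.0:
            n_s = 1.0
        idx = int(round(n_s)) - int(self.grid_s[0])
        if 0 <= idx < self.grid_s.size:
            return float(self.values[idx])
        return float(mixture_propensity(self.params, n_s, self.delta_s))


def find_peak(
    values: Sequence[float], grid_s: Sequence[float] | None = None
) -> float:
    """Largest grid point at a strict local maximum.

    A plateau (exact ties over consecutive points) counts as one candidate
    maximum at its rightmost point, provided the values immediately before
    and after the plateau are strictly lower. Grid endpoints are not
    eligible. Raises :class:`NoPeakError` when no interior strict maximum
    exists.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 grid points")
    g = (
        np.arange(1, v.size + 1, dtype=float)
        if grid_s is None
        else np.asarray(grid_s, dtype=float)
    )
    if g.size != v.size:
        raise ValueError("grid and values must align")

    # Compress runs of equal values; a run is a maximum iff strictly above
    # both neighbouring runs and interior.
    change = np.flatnonzero(np.diff(v) != 0.0)
    run_ends = np.concatenate([change, [v.size - 1]])  # rightmost idx per run
    run_vals = v[run_ends]
    peaks: list[float] = []
    for j in range(1, run_vals.size - 1):
        if run_vals[j] > run_vals[j - 1] and run_vals[j] > run_vals[j + 1]:
            peaks.append(float(g[run_ends[j]]))
    if not peaks:
        raise NoPeakError("no interior strict local maximum on the grid")
    return max(peaks)


def evaluate_curve(
    params: GmmParams,
    delta_s: float = DEFAULT_DELTA_S,
    grid_max_s: int = DEFAULT_GRID_MAX_S,
    label: str = "",
) -> PropensityCurve:
    """Evaluate p_delta at |N| = 1, 2, ..., grid_max_s and locate the peak."""
    grid = np.arange(1, grid_max_s + 1, dtype=float)
    vals = np.asarray(mixture_propensity(params, grid, delta_s))
    try:
        peak = find_peak(vals, grid)
    except NoPeakError as err:
        raise NoPeakError(
            f"propensity curve {label or '<unlabelled>'} has no interior "
            f"strict local maximum on [1, {grid_max_s}] s"
        ) from err
    return PropensityCurve(
        delta_s=delta_s,
        grid_s=grid,
        values=vals,
        peak_n_s=peak,
        params=params,
        label=label,
    )


def split_before_after(
    cycles: Iterable[RemCycle], peaks: Mapping[int, float]
) -> tuple[list[RemCycle], list[RemCycle]]:
    """Partition cycles into before-peak / after-peak groups.

    A cycle is BEFORE iff its realized n_s is strictly less than its
    |REMpre| bin's peak; ties go to AFTER. *peaks* maps bin_index ->
    peak_n_s and must cover every cycle's bin.
    """
    before: list[RemCycle] = []
    after: list[RemCycle] = []
    for c in cycles:
        if c.bin_index not in peaks:
            raise KeyError(f"no propensity peak for bin {c.bin_index}")
        (before if c.n_s < peaks[c.bin_index] else after).append(c)
    return before, after
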