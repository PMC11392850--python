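"""Validation of the propensity measure: empirical hazard and surrogate |N|.

Two independent checks that the mixture-based propensity describes the data
it was fitted to:

* a train/test comparison — fit on 80% of cycles, then compute a purely
  empirical propensity on the held-out 20% as, at each second t of |N|,
  (# cycles transitioning to REM within the next 30 s) / (# cycles that
  have yet to transition), averaged over 30 s bins to tame sparse-data
  noise;
* surrogate |N| generation — walk 30 s intervals starting at t = 1 s,
  firing each interval with probability p30 at its start and drawing |N|
  uniformly within the interval that fires; the surrogate distribution
  should match the fitted mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .cycles import RemCycle
from .gmm import GmmParams
from .propensity import DEFAULT_DELTA_S, mixture_propensity

__all__ = [
    "EmpiricalPropensity",
    "train_test_split",
    "empirical_propensity",
    "generate_surrogate_N",
    "surrogate_sample",
]

DEFAULT_CAP_S = 1_000_000.0


@dataclass(frozen=True)
class EmpiricalPropensity:
    """Per-second hazard estimates with 30 s bin averages."""

    t_s: np.ndarray  # seconds at which the estimate is defined
    values: np.ndarray  # hazard estimate at each second
    survivors: np.ndarray  # denominator (cycles yet to transition)
    horizon_s: float

    def binned(self, bin_s: float = 30.0) -> pd.DataFrame:
        """Average the per-second values within consecutive bins of t.

        Bins start at t = 1 s ([1, 31), [31, 61), ...), matching the
        surrogate walk; seconds where the estimate is undefined are simply
        absent and do not drag the average.
        """
        idx = ((self.t_s - 1.0) // bin_s).astype(int)
        df = pd.DataFrame(
            {"bin": idx, "value": self.values, "survivors": self.survivors}
        )
        out = df.groupby("bin").agg(
            value=("value", "mean"),
            survivors=("survivors", "max"),
            n_seconds=("value", "size"),
        )
        out["t_bin_start"] = out.index * bin_s + 1.0
        return out.reset_index(drop=True)[
            ["t_bin_start", "value", "survivors", "n_seconds"]
        ]


def train_test_split(
    cycles: Sequence[RemCycle],
    train_frac: float = 0.8,
    seed: Union[int, np.random.Generator, None] = None,
) -> tuple[list[RemCycle], list[RemCycle]]:
    """Seeded uniform split at cycle level: disjoint, exhaustive."""
    if len(cycles) < 5:
        raise ValueError("need at least 5 cycles to split")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cycles))
    n_train = int(round(train_frac * len(cycles)))
    train_idx = set(perm[:n_train].tolist())
    train = [c for i, c in enumerate(cycles) if i in train_idx]
    test = [c for i, c in enumerate(cycles) if i not in train_idx]
    return train, test


def empirical_propensity(
    n_values_s: Union[Sequence[float], Sequence[RemCycle]],
    horizon_s: float = DEFAULT_DELTA_S,
) -> EmpiricalPropensity:
    """Empirical hazard of the |N| distribution at each integer second.

    Accepts either raw |N| values (seconds) or cycles (their n_s is used).
    At second t the numerator counts cycles with n in [t, t+horizon) and the
    denominator those with n >= t; seconds with an empty denominator are
    omitted.
    """
    if len(n_values_s) == 0:
        raise ValueError("empty test set")
    first = n_values_s[0]
    if isinstance(first, RemCycle):
        n = np.array([c.n_s for c in n_values_s], dtype=float)
    else:
        n = np.asarray(n_values_s, dtype=float)
    n = np.sort(n)
    t_max = int(np.floor(n[-1]))
    t = np.arange(1, t_max + 1, dtype=float)
    # survivors(t) = #(n >= t); transitions within [t, t + horizon)
    survivors = n.size - np.searchsorted(n, t, side="left")
    upper = np.searchsorted(n, t + horizon_s, side="left")
    lower = np.searchsorted(n, t, side="left")
    numer = upper - lower
    defined = survivors > 0
    return EmpiricalPropensity(
        t_s=t[defined],
        values=(numer[defined] / survivors[defined]).astype(float),
        survivors=survivors[defined].astype(int),
        horizon_s=horizon_s,
    )


def generate_surrogate_N(
    params: GmmParams,
    delta_s: float = DEFAULT_DELTA_S,
    seed: Union[int, np.random.Generator, None] = None,
    cap_s: float = DEFAULT_CAP_S,
) -> tuple[float, bool]:
    """One surrogate |N| draw; returns ``(n_s, capped)``.

    Walks intervals [1, 1+delta), [1+delta, 1+2*delta), ...; at each
    interval start the propensity is compared with a fresh uniform draw, and
    the first interval whose propensity exceeds the draw yields |N| uniform
    within it. Walks reaching *cap_s* are flagged (capped=True) so callers
    can exclude and count them.
    """
    draws, capped = surrogate_sample(params, 1, delta_s=delta_s, seed=seed, cap_s=cap_s)
    return float(draws[0]), bool(capped[0])


def surrogate_sample(
    params: Union[GmmParams, "callable"],
    size: int,
    delta_s: float = DEFAULT_DELTA_S,
    seed: Union[int, np.random.Generator, None] = None,
    cap_s: float = DEFAULT_CAP_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized surrogate draws; returns ``(n_s, capped)`` arrays.

    *params* may also be a callable ``p(n_s) -> probability`` (e.g. a
    constant hazard for closed-form checks). Capped walks carry n_s = cap_s
    and capped=True; exclude them (their frequency is the caller's to
    report).
    """
    rng = np.random.default_rng(seed)
    if isinstance(params, GmmParams):
        prop = lambda s: float(mixture_propensity(params, s, delta_s))  # noqa: E731
    else:
        prop = params
    n_out = np.full(size, cap_s, dtype=float)
    capped = np.ones(size, dtype=bool)
    active = np.arange(size)
    start = 1.0
    while active.size and start < cap_s:
        p = prop(start)
        u = rng.random(active.size)
        fired = u < p
        if np.any(fired):
            hit = active[fired]
            n_out[hit] = start + delta_s * rng.random(hit.size)
            capped[hit] = False
            active = active[~fired]
        start += delta_s
    return n_out, capped
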