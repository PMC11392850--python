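"""Single vs sequential cycle labelling and sequential-chain counting.

A cycle is labelled sequential when its |N| falls below the point where the
weighted short component (1-k_l)*N_s of the bin's mixture stops dominating
the weighted long component k_l*N_l — the responsibility crossover between
the two classes. Two bins get special rules mirroring the degeneracies seen
in the mouse data: the light-phase |REMpre|>180 s bin is labelled all-single
(its two components nearly coincide), and the dark-phase >180 s and
[90,120) s bins borrow the cutoff of the neighbouring bin ([150,180) and
[120,150) respectively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .cycles import RemCycle
from .gmm import FitResult, GmmParams
from .hypnogram import Phase

__all__ = [
    "SINGLE",
    "SEQUENTIAL",
    "CutoffRule",
    "CutoffTable",
    "Chain",
    "compute_cutoff",
    "build_cutoff_table",
    "label_cycles",
    "count_chains",
]

SINGLE = "single"
SEQUENTIAL = "sequential"


class RuleKind(Enum):
    NUMERIC = "numeric"
    ALL_SINGLE = "all_single"
    BORROW = "borrow"


@dataclass(frozen=True)
class CutoffRule:
    kind: RuleKind
    cutoff_n_s: float | None = None  # resolved value (NUMERIC and BORROW)
    borrow_from: int | None = None


@dataclass(frozen=True)
class CutoffTable:
    """Resolved per-bin cutoff rules for one phase."""

    phase: int
    rules: Mapping[int, CutoffRule]

    def cutoff(self, bin_index: int) -> CutoffRule:
        if bin_index not in self.rules:
            raise KeyError(f"no cutoff rule for bin {bin_index}")
        return self.rules[bin_index]


@dataclass(frozen=True)
class Chain:
    """A single (anchor) cycle and the consecutive sequential cycles after it."""

    anchor: int  # index into the cycle sequence passed to count_chains
    length_S: int
    member_indices: tuple[int, ...]  # the sequential members (may be empty)


def compute_cutoff(params: GmmParams) -> float | None:
    """|N| (seconds) where k_l*N_l and (1-k_l)*N_s intersect, or None.

    Solving k_l*phi(x; mu_l, sigma_l) = (1-k_l)*phi(x; mu_s, sigma_s) in
    log-seconds is a quadratic in x when the sigmas differ and linear when
    they are equal; the root lying in (mu_s, mu_l) — the decision boundary
    between the classes — is returned as exp(x*). Degenerate weights
    (k_l in {0, 1}) or no root between the means yield ``None``
    (NO_INTERSECTION).
    """
    k, mul, sl, mus, ss = (
        params.k_l,
        params.mu_l,
        params.sigma_l,
        params.mu_s,
        params.sigma_s,
    )
    if k <= 0.0 or k >= 1.0:
        return None
    # log(k/sl) - (x-mul)^2/(2 sl^2) = log((1-k)/ss) - (x-mus)^2/(2 ss^2)
    c0 = math.log(k / sl) - math.log((1.0 - k) / ss)
    a = 1.0 / (2.0 * ss * ss) - 1.0 / (2.0 * sl * sl)
    b = mul / (sl * sl) - mus / (ss * ss)
    c = c0 - mul * mul / (2.0 * sl * sl) + mus * mus / (2.0 * ss * ss)
    if abs(a) < 1e-300:  # equal sigmas: linear equation b*x + c = 0
        if b == 0.0:
            return None
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            return None
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    inside = sorted(x for x in roots if mus < x < mul)
    if not inside:
        return None
    if len(inside) > 1:
        # keep the crossing where the short class dominates below and the
        # long class above (the responsibility crossover)
        def _gap(x: float) -> float:
            lw = math.log(k / sl) - (x - mul) ** 2 / (2 * sl * sl)
            sw = math.log((1 - k) / ss) - (x - mus) ** 2 / (2 * ss * ss)
            return lw - sw

        eps = 1e-9 * max(1.0, abs(inside[0]))
        inside = [x for x in inside if _gap(x - eps) < 0 < _gap(x + eps)] or inside
    return math.exp(inside[0])


def build_cutoff_table(
    fits: Mapping[int, FitResult],
    phase: int,
    n_bins: int = 7,
) -> CutoffTable:
    """Numeric cutoffs per bin, overridden by the fixed special-case rules.

    Light phase: the >180 s bin is ALL_SINGLE. Dark phase: the >180 s bin
    borrows the [150,180) cutoff and the [90,120) bin borrows the [120,150)
    cutoff. A bin whose components never intersect (no crossover between the
    means) is treated as ALL_SINGLE with a warning-free fallback, since one
    class dominates everywhere.
    """
    if set(fits.keys()) < set(range(n_bins)):
        missing = sorted(set(range(n_bins)) - set(fits.keys()))
        raise ValueError(f"missing fits for bins {missing}")
    last = n_bins - 1
    borrow_map: dict[int, int] = {}
    all_single: set[int] = set()
    if phase == Phase.LIGHT.value:
        all_single.add(last)
    else:
        borrow_map[last] = last - 1  # >180 s  <- [150,180)
        borrow_map[3] = 4  # [90,120) <- [120,150)

    rules: dict[int, CutoffRule] = {}
    for b in range(n_bins):
        if b in all_single:
            rules[b] = CutoffRule(kind=RuleKind.ALL_SINGLE)
        elif b in borrow_map:
            continue  # resolved below once the source bin exists
        else:
            cut = compute_cutoff(fits[b].params)
            if cut is None:
                rules[b] = CutoffRule(kind=RuleKind.ALL_SINGLE)
            else:
                rules[b] = CutoffRule(kind=RuleKind.NUMERIC, cutoff_n_s=cut)
    numeric = {
        b: r.cutoff_n_s
        for b, r in rules.items()
        if r.kind is RuleKind.NUMERIC
    }
    for b, src in borrow_map.items():
        if src not in numeric:
            # the named source bin is itself degenerate; generalize the
            # nearby-bin approximation to the nearest bin with a numeric
            # cutoff (lower bin preferred on ties)
            if not numeric:
                raise ValueError(
                    f"bin {b} borrows its cutoff from bin {src}, which has "
                    "no numeric cutoff, and no other bin provides one"
                )
            src = min(numeric, key=lambda j: (abs(j - src), j))
        rules[b] = CutoffRule(
            kind=RuleKind.BORROW,
            cutoff_n_s=numeric[src],
            borrow_from=src,
        )
    return CutoffTable(phase=phase, rules=rules)


def label_cycles(
    cycles: Iterable[RemCycle], table: CutoffTable
) -> list[str]:
    """SEQUENTIAL iff n_s is strictly below the bin's cutoff; ties are SINGLE.

    ALL_SINGLE bins label everything single regardless of n_s.
    """
    labels: list[str] = []
    for c in cycles:
        rule = table.cutoff(c.bin_index)
        if rule.kind is RuleKind.ALL_SINGLE:
            labels.append(SINGLE)
        else:
            labels.append(SEQUENTIAL if c.n_s < rule.cutoff_n_s else SINGLE)
    return labels


def count_chains(
    cycles: Sequence[RemCycle],
    labels: Sequence[str],
    include_terminal: bool = False,
) -> list[Chain]:
    """Chains of consecutive sequential cycles following each single cycle.

    Cycles must be supplied with their labels; chains are counted within one
    recording only, in temporal order. For each single cycle with at least
    one following cycle in the same recording, |S| is the number of
    immediately following consecutive sequential cycles (|S| = 0 when the
    next cycle is again single). Terminal singles — the last cycle of a
    recording — are censored and excluded unless *include_terminal* is set,
    in which case they contribute |S| = 0.
    """
    if len(cycles) != len(labels):
        raise ValueError("cycles and labels must align")
    # group indices per recording, preserving temporal order
    order = sorted(
        range(len(cycles)), key=lambda i: (cycles[i].recording_id, cycles[i].order)
    )
    chains: list[Chain] = []
    by_rec: dict[str, list[int]] = {}
    for i in order:
        by_rec.setdefault(cycles[i].recording_id, []).append(i)
    for rec_indices in by_rec.values():
        for pos, i in enumerate(rec_indices):
            if labels[i] != SINGLE:
                continue
            followers = rec_indices[pos + 1 :]
            if not followers:
                if include_terminal:
                    chains.append(Chain(anchor=i, length_S=0, member_indices=()))
                continue
            members: list[int] = []
            for j in followers:
                if labels[j] == SEQUENTIAL:
                    members.append(j)
                else:
                    break
            chains.append(
                Chain(anchor=i, length_S=len(members), member_indices=tuple(members))
            )
    return chains
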