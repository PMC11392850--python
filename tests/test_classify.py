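import math

import numpy as np
import pytest

from rempropensity.classify import (
    SEQUENTIAL,
    SINGLE,
    build_cutoff_table,
    compute_cutoff,
    count_chains,
    label_cycles,
)
from rempropensity.cycles import RemCycle
from rempropensity.gmm import FitResult, GmmParams
from rempropensity.hypnogram import Phase


def _grid_crossing(p: GmmParams) -> float:
    """Brute-force density-crossing oracle at 1e-4 log-second resolution."""
    from scipy.stats import norm

    x = np.arange(p.mu_s, p.mu_l, 1e-4)
    wl = p.k_l * norm.pdf(x, p.mu_l, p.sigma_l)
    ws = (1 - p.k_l) * norm.pdf(x, p.mu_s, p.sigma_s)
    diff = ws - wl  # positive where the short class dominates
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if sign_change.size == 0:
        return math.nan
    # crossing where dominance passes from short to long
    for i in sign_change:
        if diff[i] > 0 > diff[i + 1]:
            return float(x[i])
    return float(x[sign_change[0]])


class TestComputeCutoff:
    def test_symmetric_case_closed_form(self):
        p = GmmParams(0.5, 6.0, 0.5, 4.0, 0.5)
        assert compute_cutoff(p) == pytest.approx(math.exp(5.0), rel=1e-12)

    def test_degenerate_weights_no_intersection(self):
        assert compute_cutoff(GmmParams(1.0, 6.0, 0.5, 4.0, 0.5)) is None
        assert compute_cutoff(GmmParams(0.0, 6.0, 0.5, 4.0, 0.5)) is None

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 20:
            p = GmmParams(
                k_l=float(rng.uniform(0.2, 0.95)),
                mu_l=float(rng.uniform(6.0, 7.2)),
                sigma_l=float(rng.uniform(0.3, 0.8)),
                mu_s=float(rng.uniform(4.0, 5.5)),
                sigma_s=float(rng.uniform(0.3, 0.8)),
            )
            expected = _grid_crossing(p)
            got = compute_cutoff(p)
            if math.isnan(expected):
                assert got is None
            else:
                assert math.log(got) == pytest.approx(expected, abs=1e-3)
            checked += 1

    def test_dominance_flips_at_cutoff(self):
        from scipy.stats import norm

        p = GmmParams(0.7, 6.8, 0.5, 4.7, 0.45)
        x_star = math.log(compute_cutoff(p))
        for x, short_dominates in ((x_star - 0.05, True), (x_star + 0.05, False)):
            wl = p.k_l * norm.pdf(x, p.mu_l, p.sigma_l)
            ws = (1 - p.k_l) * norm.pdf(x, p.mu_s, p.sigma_s)
            assert bool(ws > wl) == short_dominates


def _fits(params_by_bin):
    return {
        b: FitResult(
            params=p, ks_stat=0.02, ks_p=None, n=100,
            n_restarts_used=20, converged=True, iterations=50,
        )
        for b, p in params_by_bin.items()
    }


GOOD = GmmParams(0.7, 6.8, 0.5, 4.7, 0.45)


class TestCutoffTable:
    def test_light_top_bin_all_single(self):
        table = build_cutoff_table(_fits({b: GOOD for b in range(7)}),
                                   Phase.LIGHT.value)
        assert table.cutoff(6).cutoff_n_s is None
        assert table.cutoff(6).kind.value == "all_single"
        # ordinary bins carry the numeric intersection
        assert table.cutoff(0).cutoff_n_s == pytest.approx(compute_cutoff(GOOD))

    def test_dark_borrow_rules(self):
        table = build_cutoff_table(_fits({b: GOOD for b in range(7)}),
                                   Phase.DARK.value)
        assert table.cutoff(6).borrow_from == 5
        assert table.cutoff(6).cutoff_n_s == table.cutoff(5).cutoff_n_s
        assert table.cutoff(3).borrow_from == 4
        assert table.cutoff(3).cutoff_n_s == table.cutoff(4).cutoff_n_s

    def test_degenerate_borrow_source_falls_back_to_nearest_bin(self):
        degenerate = GmmParams(1.0, 6.8, 0.5, 4.7, 0.45)  # no intersection
        params = {b: GOOD for b in range(7)}
        params[5] = degenerate  # dark bin 6 borrows from bin 5
        table = build_cutoff_table(_fits(params), Phase.DARK.value)
        assert table.cutoff(6).borrow_from == 4
        assert table.cutoff(6).cutoff_n_s == pytest.approx(compute_cutoff(GOOD))

    def test_no_numeric_cutoff_anywhere_raises(self):
        degenerate = GmmParams(1.0, 6.8, 0.5, 4.7, 0.45)
        with pytest.raises(ValueError, match="borrow"):
            build_cutoff_table(
                _fits({b: degenerate for b in range(7)}), Phase.DARK.value
            )

    def test_missing_bins_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_cutoff_table(_fits({0: GOOD}), Phase.LIGHT.value)


def _cycle(n_s, bin_index=1, rec="r0", order=0):
    return RemCycle(
        rempre_s=45.0 if bin_index == 1 else 200.0,
        n_s=n_s, wake_s=0.0, max_wake_bout_s=0.0, rempost_s=30.0,
        phase=0, bin_index=bin_index, onset_epoch=0,
        recording_id=rec, order=order,
    )


class TestLabelling:
    def setup_method(self):
        self.table = build_cutoff_table(
            _fits({b: GOOD for b in range(7)}), Phase.LIGHT.value
        )
        self.cut = compute_cutoff(GOOD)

    def test_below_cutoff_sequential(self):
        assert label_cycles([_cycle(self.cut - 1)], self.table) == [SEQUENTIAL]

    def test_at_cutoff_single(self):
        assert label_cycles([_cycle(self.cut)], self.table) == [SINGLE]

    def test_all_single_bin_ignores_n(self):
        assert label_cycles([_cycle(10.0, bin_index=6)], self.table) == [SINGLE]

    def test_monotone_in_n(self):
        n_vals = np.linspace(50, 2000, 40)
        labels = label_cycles([_cycle(float(n)) for n in n_vals], self.table)
        seq = [lab == SEQUENTIAL for lab in labels]
        assert seq == sorted(seq, reverse=True)


class TestChains:
    def _mk(self, labels, rec="r0"):
        cycles = [_cycle(100.0, rec=rec, order=i) for i in range(len(labels))]
        return cycles, list(labels)

    def test_example_chain_counts(self):
        cycles, labels = self._mk(
            [SINGLE, SEQUENTIAL, SEQUENTIAL, SINGLE, SEQUENTIAL, SINGLE]
        )
        chains = count_chains(cycles, labels)
        assert [c.length_S for c in chains] == [2, 1]  # last single censored

    def test_include_terminal_as_zero(self):
        cycles, labels = self._mk([SINGLE, SINGLE])
        chains = count_chains(cycles, labels, include_terminal=True)
        assert [c.length_S for c in chains] == [0, 0]

    def test_all_singles(self):
        cycles, labels = self._mk([SINGLE] * 4)
        chains = count_chains(cycles, labels)
        assert [c.length_S for c in chains] == [0, 0, 0]

    def test_chains_never_span_recordings(self):
        c1, l1 = self._mk([SINGLE], rec="a")
        c2, l2 = self._mk([SEQUENTIAL, SINGLE], rec="b")
        chains = count_chains(c1 + c2, l1 + l2)
        # the singles in "a" and "b" are both terminal within their
        # recordings -> censored, so no chain may borrow b's sequential cycle
        assert chains == []

    def test_accounting_identity(self):
        labels = [SINGLE, SEQUENTIAL, SINGLE, SEQUENTIAL, SEQUENTIAL, SINGLE,
                  SINGLE, SEQUENTIAL]
        cycles, labels = self._mk(labels)
        chains = count_chains(cycles, labels)
        # every cycle is a chain anchor or a chain member here (the sequence
        # opens with a single and its last single is non-terminal)
        assert sum(1 + c.length_S for c in chains) == len(cycles)
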