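"""Synthetic hypnogram cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: per
|REMpre|-bin two-component lognormal mixtures of accumulated NREM duration
|N| (the short component playing "sequential" cycles, the long one
"single"), REM-bout durations chained so one cycle's REMpost is the next
cycle's REMpre, wake bouts interspersed in the inter-REM interval (including
occasional extended bouts that trigger the 5-min discard rule), a 12:12
light:dark schedule, and two configurable couplings gated to light-phase
before-peak cycles: the propensity at REM onset can shift (a) the duration
of the next REM bout and (b) the log-odds that the next cycle is sequential.

Every latent truth (component fired, true propensity, real-valued and
epoch-rounded durations) is recorded so each pipeline stage can be tested
against the generating parameters. Default parameter values are
plausible-scale inventions for testing, not estimates from any recorded
data set.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .cycles import BinSpec, DEFAULT_BINS, assign_bin
from .gmm import GmmParams
from .hypnogram import Hypnogram, Phase, State, label_phase
from .propensity import evaluate_curve, mixture_propensity

__all__ = [
    "GeneratorConfig",
    "CycleRecord",
    "default_bin_params",
    "sample_cycles",
    "render_hypnogram",
    "generate_cohort",
]


def default_bin_params(n_bins: int = 7) -> tuple[GmmParams, ...]:
    """Plausible-scale true mixtures per |REMpre| bin.

    Short component around 150 s, long around 900 s, with the long-component
    weight k_l rising with |REMpre| (longer pre-bouts make sequential cycles
    rarer), mirroring the qualitative structure of scored mouse sleep.
    """
    k_ls = np.linspace(0.60, 0.90, n_bins)
    return tuple(
        GmmParams(
            k_l=float(k),
            mu_l=math.log(800.0),
            sigma_l=0.50,
            mu_s=math.log(150.0),
            sigma_s=0.45,
        )
        for k in k_ls
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters and couplings of the synthetic cohort."""

    bin_params_light: tuple[GmmParams, ...] = field(
        default_factory=default_bin_params
    )
    bin_params_dark: tuple[GmmParams, ...] = field(
        default_factory=default_bin_params
    )
    bins: BinSpec = DEFAULT_BINS
    epoch_s: float = 2.5
    # REM-bout duration model: lognormal, chained through the couplings
    rempre_meanlog: float = math.log(90.0)
    rempre_sdlog: float = 0.55
    #: linear effect (log-seconds per unit propensity) of p30-at-onset on the
    #: next REM bout's duration; active only for light-phase before-peak
    #: cycles
    b_rempost: float = 0.0
    #: logistic effect (log-odds per unit propensity) of p30-at-onset on the
    #: probability that the next cycle is sequential; same gating
    b_seq: float = 0.0
    #: propensity value the couplings are centred on
    p_ref: float = 0.05
    #: couplings act only while |N| is below this fraction of the true peak;
    #: the margin keeps the coupled region strictly inside the before-peak
    #: group even under estimation noise in the recovered peak location
    peak_gate_frac: float = 0.8
    # wake model: bouts per inter-REM interval and their durations
    wake_rate: float = 1.5
    wake_meanlog: float = math.log(20.0)
    wake_sdlog: float = 0.75
    p_extended_wake: float = 0.03
    extended_wake_scale_s: float = 120.0
    # cohort layout
    cycles_per_recording: int = 40
    max_recording_s: float = 41_400.0  # stay inside one 12 h phase
    delta_s: float = 30.0
    grid_max_s: int = 3000

    def bin_params(self, phase: int) -> tuple[GmmParams, ...]:
        return (
            self.bin_params_light
            if phase == Phase.LIGHT.value
            else self.bin_params_dark
        )


@dataclass(frozen=True)
class CycleRecord:
    """One generated cycle with all latent truth attached.

    Real-valued durations are the draws; ``*_r`` fields are their
    epoch-rounded counterparts (round half up), which are what rendering
    realizes and extraction recovers.
    """

    recording_id: str
    order: int
    phase: int
    rempre_s: float
    rempre_r_s: float
    n_s: float
    n_r_s: float
    rempost_s: float
    rempost_r_s: float
    wake_bouts_s: tuple[float, ...]  # rounded bout durations
    bin_index: int
    component: str  # "long" (single) or "short" (sequential)
    p30_onset: float  # true propensity at the real-valued |N|
    before_peak: bool  # |N| below the true peak of its bin's curve
    coupled: bool  # couplings were active for this cycle


def _round_epochs(x_s: float, epoch_s: float, minimum: int = 1) -> float:
    return max(int(math.floor(x_s / epoch_s + 0.5)), minimum) * epoch_s


def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def _true_peaks(
    params: Sequence[GmmParams], delta_s: float, grid_max_s: int
) -> list[float]:
    return [
        evaluate_curve(p, delta_s=delta_s, grid_max_s=grid_max_s).peak_n_s
        for p in params
    ]


def _draw_wake_bouts(
    cfg: GeneratorConfig, rng: np.random.Generator, n_epochs_nrem: int
) -> tuple[float, ...]:
    n_bouts = int(rng.poisson(cfg.wake_rate))
    bouts = [
        _round_epochs(d, cfg.epoch_s)
        for d in np.exp(rng.normal(cfg.wake_meanlog, cfg.wake_sdlog, n_bouts))
    ]
    if rng.random() < cfg.p_extended_wake:
        extra = 300.0 + rng.exponential(cfg.extended_wake_scale_s)
        # an "extended" bout must exceed the 5-min rule even after rounding
        bouts.append(
            max(_round_epochs(extra, cfg.epoch_s), 121 * cfg.epoch_s)
        )
    # wake bouts sit strictly between NREM epochs, so at most n_nrem - 1 fit
    max_bouts = max(n_epochs_nrem - 1, 0)
    return tuple(bouts[:max_bouts])


def sample_cycles(
    config: GeneratorConfig,
    n: int,
    seed: Union[int, np.random.Generator, None],
    phase: int = Phase.LIGHT.value,
    recording_prefix: str | None = None,
) -> list[CycleRecord]:
    """Draw *n* ground-truth cycles for one phase, chained into recordings.

    Within a recording, cycle i's REMpost duration becomes cycle i+1's
    REMpre, and the couplings let cycle i's propensity at onset shift that
    duration and the component (sequential/single) of cycle i+1 — both only
    when cycle i is light-phase and before its bin's propensity peak.
    """
    rng = np.random.default_rng(seed)
    params = config.bin_params(phase)
    peaks = _true_peaks(params, config.delta_s, config.grid_max_s)
    prefix = (
        recording_prefix
        if recording_prefix is not None
        else ("light" if phase == Phase.LIGHT.value else "dark")
    )

    records: list[CycleRecord] = []
    rec_idx = 0
    while len(records) < n:
        rec_id = f"{prefix}-{rec_idx:03d}"
        rec_idx += 1
        elapsed = 0.0
        order = 0
        rempre = float(
            np.exp(rng.normal(config.rempre_meanlog, config.rempre_sdlog))
        )
        prev_gate = False
        prev_p30 = config.p_ref
        while (
            len(records) < n
            and order < config.cycles_per_recording
            and elapsed < config.max_recording_s
        ):
            rempre_r = _round_epochs(rempre, config.epoch_s)
            b = assign_bin(rempre_r, config.bins)
            pars = params[b]
            # component of THIS cycle, coupled to the previous cycle's onset
            # propensity when that cycle was gated
            base_logit = math.log((1.0 - pars.k_l) / pars.k_l)
            shift = config.b_seq * (prev_p30 - config.p_ref) if prev_gate else 0.0
            p_short = _sigmoid(base_logit + shift)
            component = "short" if rng.random() < p_short else "long"
            if component == "short":
                n_real = float(np.exp(rng.normal(pars.mu_s, pars.sigma_s)))
            else:
                n_real = float(np.exp(rng.normal(pars.mu_l, pars.sigma_l)))
            n_r = _round_epochs(n_real, config.epoch_s)
            p30 = float(
                mixture_propensity(pars, n_real, config.delta_s)
            )
            gate = (
                phase == Phase.LIGHT.value
                and n_real < config.peak_gate_frac * peaks[b]
            )
            b_eff = config.b_rempost if gate else 0.0
            rempost = float(
                np.exp(
                    config.rempre_meanlog
                    + b_eff * (p30 - config.p_ref)
                    + config.rempre_sdlog * rng.normal()
                )
            )
            rempost_r = _round_epochs(rempost, config.epoch_s)
            wake = _draw_wake_bouts(config, rng, int(round(n_r / config.epoch_s)))
            records.append(
                CycleRecord(
                    recording_id=rec_id,
                    order=order,
                    phase=phase,
                    rempre_s=rempre,
                    rempre_r_s=rempre_r,
                    n_s=n_real,
                    n_r_s=n_r,
                    rempost_s=rempost,
                    rempost_r_s=rempost_r,
                    wake_bouts_s=wake,
                    bin_index=b,
                    component=component,
                    p30_onset=p30,
                    before_peak=n_real < peaks[b],
                    coupled=gate,
                )
            )
            elapsed += rempre_r + n_r + sum(wake)
            rempre = rempost
            prev_gate = gate
            prev_p30 = p30
            order += 1
    return records


def render_hypnogram(
    records: Sequence[CycleRecord],
    config: GeneratorConfig,
    seed: Union[int, np.random.Generator, None] = None,
) -> Hypnogram:
    """Epochize the cycles of one recording into a phase-labelled hypnogram.

    Realizes each cycle as its (rounded) REMpre epochs followed by NREM
    epochs totalling |N| with the drawn wake bouts interleaved (each bout a
    maximal wake run separated from its neighbours by at least one NREM
    epoch), and closes the recording with the final cycle's REMpost bout.
    """
    if not records:
        raise ValueError("no cycle records to render")
    rec_ids = {r.recording_id for r in records}
    if len(rec_ids) != 1:
        raise ValueError("render_hypnogram expects records of one recording")
    rng = np.random.default_rng(seed)
    recs = sorted(records, key=lambda r: r.order)
    epoch = config.epoch_s
    chunks: list[np.ndarray] = []
    for r in recs:
        chunks.append(
            np.full(int(round(r.rempre_r_s / epoch)), State.REM.value, np.int8)
        )
        n_nrem = int(round(r.n_r_s / epoch))
        bouts = [int(round(w / epoch)) for w in r.wake_bouts_s]
        n_slots = len(bouts) + 1
        # random composition of the NREM epochs into n_slots positive parts
        if n_slots == 1:
            parts = [n_nrem]
        else:
            cuts = np.sort(
                rng.choice(np.arange(1, n_nrem), size=n_slots - 1, replace=False)
            )
            parts = np.diff(np.concatenate([[0], cuts, [n_nrem]])).tolist()
        interval: list[np.ndarray] = []
        for i, part in enumerate(parts):
            interval.append(np.full(part, State.NREM.value, np.int8))
            if i < len(bouts):
                interval.append(np.full(bouts[i], State.WAKE.value, np.int8))
        chunks.extend(interval)
    chunks.append(
        np.full(int(round(recs[-1].rempost_r_s / epoch)), State.REM.value, np.int8)
    )
    start = (
        _dt.time(7, 0, 0)
        if recs[0].phase == Phase.LIGHT.value
        else _dt.time(19, 0, 0)
    )
    h = Hypnogram(
        states=np.concatenate(chunks),
        epoch_s=epoch,
        start_clock=start,
        recording_id=recs[0].recording_id,
    )
    return label_phase(h)


def generate_cohort(
    config: GeneratorConfig,
    n_light: int,
    n_dark: int,
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> tuple[list[CycleRecord], list[Hypnogram]]:
    """Sample and render a two-phase cohort; returns (records, hypnograms)."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_light, s_dark, s_render = ss.spawn(3)
    records: list[CycleRecord] = []
    if n_light:
        records += sample_cycles(
            config, n_light, np.random.default_rng(s_light), Phase.LIGHT.value
        )
    if n_dark:
        records += sample_cycles(
            config, n_dark, np.random.default_rng(s_dark), Phase.DARK.value
        )
    render_rng = np.random.default_rng(s_render)
    by_rec: dict[str, list[CycleRecord]] = {}
    for r in records:
        by_rec.setdefault(r.recording_id, []).append(r)
    hypnograms = [
        render_hypnogram(recs, config, render_rng) for recs in by_rec.values()
    ]
    return records, hypnograms
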