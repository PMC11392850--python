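"""End-to-end orchestration: ingest -> extract -> fit -> propensity ->
classify -> stats -> validate, with per-stage seeds and TSV outputs.

Light and dark phases are analyzed fully separately. Per-stage seeds are
spawned from a master seed via :class:`numpy.random.SeedSequence`, so every
stage is independently reproducible and a rerun with the same seeds yields
byte-identical numeric tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import stats as _stats
from .cycles import (
    BinSpec,
    DEFAULT_BINS,
    DEFAULT_MAX_WAKE_BOUT_S,
    RemCycle,
    build_cycles,
    cycles_to_frame,
    filter_extended_wake,
    find_rem_bouts,
)
from .gmm import FitResult, fit_with_restarts, lilliefors_p
from .hypnogram import (
    DEFAULT_STAGE_MAP,
    Hypnogram,
    Phase,
    label_phase,
    read_hypnogram,
)
from .propensity import (
    DEFAULT_DELTA_S,
    DEFAULT_GRID_MAX_S,
    PropensityCurve,
    evaluate_curve,
    split_before_after,
)
from .stats import StatsError
from .validate import empirical_propensity, train_test_split

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_all", "analyze_cycles"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Settings of one full analysis run."""

    input_dir: Union[str, Path, None] = None  # canonical hypnogram TSVs
    output_dir: Union[str, Path] = "rempropensity_out"
    epoch_s: float = 2.5
    start_clock: str = "07:00:00"
    light_on: str = "07:00:00"
    light_off: str = "19:00:00"
    bins: BinSpec = DEFAULT_BINS
    delta_s: float = DEFAULT_DELTA_S
    grid_max_s: int = DEFAULT_GRID_MAX_S
    n_restarts: int = 20
    em_tol: float = 1e-10
    max_wake_bout_s: float = DEFAULT_MAX_WAKE_BOUT_S
    wake_filter_mode: str = "single"
    min_fit_n: int = 10
    lilliefors_replicates: int = 0  # 0 disables the (costly) corrected KS p
    run_validation: bool = False
    train_frac: float = 0.8
    seed: int = 0

    @staticmethod
    def from_yaml(path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bins" in raw:
            raw["bins"] = BinSpec(tuple(raw["bins"]))
        return RunConfig(**raw)


@dataclass
class RunReport:
    """All tables produced by one run, plus bookkeeping counts."""

    cycles: pd.DataFrame
    fits: dict[tuple[int, int], FitResult]  # (phase, bin) -> fit
    curves: dict[tuple[int, int], PropensityCurve]
    peaks: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    validation: pd.DataFrame | None
    counts: dict[str, int] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"[{name}] {err}") from err

        return inner

    return wrap


@_stage("ingest")
def _ingest(config: RunConfig) -> list[Hypnogram]:
    if config.input_dir is None:
        raise ValueError("no input_dir configured and no hypnograms supplied")
    d = Path(config.input_dir)
    paths = sorted(d.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no hypnogram TSV files in {d}")
    out = []
    for p in paths:
        h = read_hypnogram(
            p,
            stage_map=DEFAULT_STAGE_MAP,
            epoch_s=config.epoch_s,
            start_clock=config.start_clock,
        )
        out.append(label_phase(h, config.light_on, config.light_off))
    return out


@_stage("extract")
def _extract(
    config: RunConfig, hypnograms: Sequence[Hypnogram]
) -> tuple[list[RemCycle], dict[str, int]]:
    cycles: list[RemCycle] = []
    for h in hypnograms:
        hh = h if h.phase is not None else label_phase(
            h, config.light_on, config.light_off
        )
        cycles.extend(build_cycles(hh, find_rem_bouts(hh), config.bins))
    kept = filter_extended_wake(
        cycles, config.max_wake_bout_s, mode=config.wake_filter_mode
    )
    counts = {
        "cycles_extracted": len(cycles),
        "cycles_dropped_wake_filter": len(cycles) - len(kept),
        "cycles_kept": len(kept),
    }
    logger.info("extraction: %s", counts)
    return kept, counts


@_stage("fit")
def _fit_phase(
    config: RunConfig,
    cycles: Sequence[RemCycle],
    phase: int,
    seed_seq: np.random.SeedSequence,
) -> dict[int, FitResult]:
    fits: dict[int, FitResult] = {}
    children = seed_seq.spawn(config.bins.n_bins)
    for b in range(config.bins.n_bins):
        sample = np.log([c.n_s for c in cycles if c.bin_index == b])
        if sample.size < config.min_fit_n:
            raise ValueError(
                f"bin {config.bins.label(b)} ({Phase(phase).name}) has only "
                f"{sample.size} cycles (< {config.min_fit_n})"
            )
        rng = np.random.default_rng(children[b])
        if config.lilliefors_replicates > 0:
            _, fit = lilliefors_p(
                sample,
                n_restarts=config.n_restarts,
                n_mc=config.lilliefors_replicates,
                seed=rng,
                tol=config.em_tol,
            )
        else:
            fit = fit_with_restarts(
                sample, n_restarts=config.n_restarts, seed=rng, tol=config.em_tol
            )
        fits[b] = fit
    return fits


@_stage("propensity")
def _curves(
    config: RunConfig, fits: Mapping[int, FitResult], phase: int
) -> dict[int, PropensityCurve]:
    return {
        b: evaluate_curve(
            fit.params,
            delta_s=config.delta_s,
            grid_max_s=config.grid_max_s,
            label=f"{Phase(phase).name}:{config.bins.label(b)}",
        )
        for b, fit in fits.items()
    }


@_stage("stats")
def _phase_stats(
    config: RunConfig,
    cycles: Sequence[RemCycle],
    fits: Mapping[int, FitResult],
    curves: Mapping[int, PropensityCurve],
    phase: int,
) -> tuple[list[dict], dict | None]:
    phase_name = Phase(phase).name
    peaks = {b: c.peak_n_s for b, c in curves.items()}
    before, after = split_before_after(cycles, peaks)
    groups = {"Before": before, "After": after}

    rows: list[dict] = []

    def add_row(target: str, group: str, res) -> None:
        rows.append(
            {
                "correlation_target": target,
                "phase": phase_name,
                "group": group,
                "r": res.r if res is not None else np.nan,
                "p": res.p if res is not None else np.nan,
                "n": res.n if res is not None else 0,
            }
        )

    for gname, group in groups.items():
        try:
            res = _stats.correlate_rempost(
                group, curves, subset=(phase_name, gname, "REMpost")
            )
        except StatsError as err:
            logger.info("REMpost %s/%s: %s", phase_name, gname, err)
            res = None
        add_row("REMpost", gname, res)

    # sequential-cycle analyses need labels and chains over the whole phase
    table = _classify.build_cutoff_table(fits, phase, config.bins.n_bins)
    labels = _classify.label_cycles(cycles, table)
    chains = _classify.count_chains(cycles, labels)

    chain_groups: dict[str, list] = {"Both": chains}
    chain_groups["Before"] = [
        c for c in chains if cycles[c.anchor].n_s < peaks[cycles[c.anchor].bin_index]
    ]
    chain_groups["After"] = [
        c
        for c in chains
        if cycles[c.anchor].n_s >= peaks[cycles[c.anchor].bin_index]
    ]
    key_to_target = {
        "n_sequential": "# of consecutive sequential cycles",
        "seq_presence": "Probability of a sequential cycle",
        "n_sequential_in_chains": "# of consecutive sequential cycles in chains",
    }
    for gname, group in chain_groups.items():
        anchor_p30 = [
            curves[cycles[c.anchor].bin_index].at(cycles[c.anchor].n_s)
            for c in group
        ]
        try:
            res = _stats.correlate_chains(group, anchor_p30, subset=(phase_name, gname))
        except StatsError as err:
            logger.info("chains %s/%s: %s", phase_name, gname, err)
            res = {k: None for k in key_to_target}
        for key, target in key_to_target.items():
            add_row(target, gname, res.get(key))
        # companion logistic regression for the presence indicator
        s_vals = np.array([c.length_S for c in group], dtype=float)
        try:
            logit = _stats.logistic_seq_presence(
                anchor_p30, (s_vals >= 1).astype(int)
            )
            rows.append(
                {
                    "correlation_target": "Probability of a sequential cycle"
                    " (logistic slope)",
                    "phase": phase_name,
                    "group": gname,
                    "r": logit.slope,
                    "p": logit.p,
                    "n": logit.n,
                }
            )
        except StatsError as err:
            logger.info("logistic %s/%s: %s", phase_name, gname, err)

    try:
        prop = _stats.rem_fraction_compare(cycles, labels, chains, phase_name)
        table2_row = {
            "phase": phase_name,
            "frac_single": prop.frac_single,
            "frac_sequential": prop.frac_sequential,
            "frac_chain": prop.frac_chain,
            "p_single_vs_seq": prop.p_single_vs_seq,
            "p_single_vs_chain": prop.p_single_vs_chain,
        }
    except StatsError as err:
        logger.info("REM fractions %s: %s", phase_name, err)
        table2_row = None
    return rows, table2_row


@_stage("validate")
def _validation(
    config: RunConfig,
    cycles: Sequence[RemCycle],
    phase: int,
    seed_seq: np.random.SeedSequence,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed_seq)
    train, test = train_test_split(cycles, config.train_frac, rng)
    frames = []
    for b in range(config.bins.n_bins):
        sample = np.log([c.n_s for c in train if c.bin_index == b])
        if sample.size < config.min_fit_n:
            continue
        fit = fit_with_restarts(
            sample, n_restarts=config.n_restarts, seed=rng, tol=config.em_tol
        )
        curve = evaluate_curve(fit.params, config.delta_s, config.grid_max_s)
        test_n = [c.n_s for c in test if c.bin_index == b]
        if not test_n:
            continue
        emp = empirical_propensity(test_n, config.delta_s).binned(config.delta_s)
        emp["model_p30"] = [curve.at(t) for t in emp["t_bin_start"]]
        emp.insert(0, "bin_label", config.bins.label(b))
        emp.insert(0, "phase", Phase(phase).name)
        frames.append(emp)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def analyze_cycles(
    config: RunConfig,
    cycles: Sequence[RemCycle],
    seed_seq: np.random.SeedSequence | None = None,
) -> RunReport:
    """Run every stage downstream of extraction on an existing cycle list."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    fit_seed, val_seed = seed_seq.spawn(2)
    fit_children = fit_seed.spawn(2)
    val_children = val_seed.spawn(2)

    fits: dict[tuple[int, int], FitResult] = {}
    curves: dict[tuple[int, int], PropensityCurve] = {}
    table1_rows: list[dict] = []
    table2_rows: list[dict] = []
    val_frames: list[pd.DataFrame] = []
    peak_rows: list[dict] = []

    for phase in (Phase.LIGHT.value, Phase.DARK.value):
        phase_cycles = [c for c in cycles if c.phase == phase]
        if not phase_cycles:
            logger.info("no cycles in phase %s; skipped", Phase(phase).name)
            continue
        phase_fits = _fit_phase(config, phase_cycles, phase, fit_children[phase])
        phase_curves = _curves(config, phase_fits, phase)
        for b, f in phase_fits.items():
            fits[(phase, b)] = f
        for b, c in phase_curves.items():
            curves[(phase, b)] = c
            peak_rows.append(
                {
                    "phase": Phase(phase).name,
                    "bin_label": config.bins.label(b),
                    "peak_n_s": c.peak_n_s,
                }
            )
        rows, t2 = _phase_stats(
            config, phase_cycles, phase_fits, phase_curves, phase
        )
        table1_rows.extend(rows)
        if t2 is not None:
            table2_rows.append(t2)
        if config.run_validation:
            val_frames.append(
                _validation(config, phase_cycles, phase, val_children[phase])
            )

    report = RunReport(
        cycles=cycles_to_frame(cycles, config.bins),
        fits=fits,
        curves=curves,
        peaks=pd.DataFrame(peak_rows),
        table1=pd.DataFrame(table1_rows),
        table2=pd.DataFrame(table2_rows),
        validation=(
            pd.concat(val_frames, ignore_index=True) if val_frames else None
        ),
    )
    return report


def _write_outputs(config: RunConfig, report: RunReport) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.cycles.to_csv(out / "cycles.tsv", sep="\t", index=False)
    fit_rows = [
        {
            "phase": Phase(phase).name,
            "bin_label": config.bins.label(b),
            "n": f.n,
            "k_l": f.params.k_l,
            "mu_l": f.params.mu_l,
            "sigma_l": f.params.sigma_l,
            "mu_s": f.params.mu_s,
            "sigma_s": f.params.sigma_s,
            "ks_stat": f.ks_stat,
            "ks_p": f.ks_p if f.ks_p is not None else np.nan,
            "converged": f.converged,
        }
        for (phase, b), f in sorted(report.fits.items())
    ]
    pd.DataFrame(fit_rows).to_csv(out / "fits.tsv", sep="\t", index=False)
    report.peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    report.table1.to_csv(out / "table1.tsv", sep="\t", index=False)
    report.table2.to_csv(out / "table2.tsv", sep="\t", index=False)
    if report.validation is not None:
        report.validation.to_csv(out / "validation.tsv", sep="\t", index=False)
    curve_rows = []
    for (phase, b), c in sorted(report.curves.items()):
        curve_rows.append(
            pd.DataFrame(
                {
                    "phase": Phase(phase).name,
                    "bin_label": config.bins.label(b),
                    "n_s": c.grid_s.astype(int),
                    "p30": c.values,
                }
            )
        )
    if curve_rows:
        pd.concat(curve_rows, ignore_index=True).to_csv(
            out / "curves.tsv", sep="\t", index=False
        )


def run_all(
    config: RunConfig,
    hypnograms: Sequence[Hypnogram] | None = None,
    write: bool = True,
) -> RunReport:
    """Run the full analysis and (optionally) write all output tables.

    *hypnograms* may be supplied directly (e.g. from the synthetic
    generator); otherwise they are read from ``config.input_dir``.
    """
    if hypnograms is None:
        hypnograms = _ingest(config)
    cycles, counts = _extract(config, hypnograms)
    report = analyze_cycles(config, cycles)
    report.counts = counts
    for phase in (Phase.LIGHT, Phase.DARK):
        report.counts[f"cycles_{phase.name.lower()}"] = sum(
            1 for c in cycles if c.phase == phase.value
        )
    if write:
        _write_outputs(config, report)
    return report
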