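"""Benchmark experiment grids: fuzzy-fraction sweep and coverage sweep.

Each condition is replicated with seeds spawned deterministically from a
master seed (``numpy.random.SeedSequence(master, spawn_key=(condition,
replicate))``), so any single replicate can be re-run in isolation.
Summaries (mean ± sd of raw and tight-pair-filtered call counts, mean
positioning error) are always recomputable from the per-replicate values
stored on the result objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import call_nucleosomes
from .io import FragmentRecord
from .profiles import ProfileConfig
from .synthetic import (
    adjacent_distance_distribution,
    filter_close_nucleosomes,
    positioning_error,
    subsample_fragments,
    synthetic_nuc_map,
)

log = logging.getLogger(__name__)


def spawn_seed(master_seed: int, condition: int, replicate: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(condition, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentResult:
    """Per-condition record of a sweep: one entry per replicate."""

    label: str
    seeds: list[int]
    raw_counts: list[int]
    filtered_counts: list[int]
    error_means: list[float]
    n_matched: list[int] = field(default_factory=list)
    n_truth: list[int] = field(default_factory=list)
    distance_hist: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.seeds)

    def summary(self) -> dict:
        def ms(v):
            a = np.asarray(v, dtype=float)
            if a.size == 0:
                return float("nan"), float("nan")
            return float(a.mean()), float(a.std(ddof=0))
        raw_m, raw_s = ms(self.raw_counts)
        fil_m, fil_s = ms(self.filtered_counts)
        err_m, err_s = ms([e for e in self.error_means if np.isfinite(e)])
        return dict(
            label=self.label, n_replicates=self.n_replicates,
            raw_mean=raw_m, raw_sd=raw_s,
            filtered_mean=fil_m, filtered_sd=fil_s,
            error_mean=err_m, error_sd=err_s,
        )


def run_fuzzy_sweep(
    r_values: Sequence[float],
    replicates: int = 10,
    scale: float = 1.0,
    max_cover: int = 70,
    master_seed: int = 0,
    config: ProfileConfig | None = None,
) -> list[ExperimentResult]:
    """Sweep the fuzzy-nucleosome fraction r over replicated synthetic maps.

    At full scale the r condition generates maps with wp_num=1100,
    wp_del=100 + r·1000 and fuz_num=r·1000 (so r=0 keeps exactly 1000
    well-positioned nucleosomes); ``scale`` shrinks every count
    proportionally for desk-sized runs.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    results: list[ExperimentResult] = []
    for ci, r in enumerate(r_values):
        wp_num = int(round(1100 * scale))
        wp_del = int(round((100 + r * 1000) * scale))
        fuz_num = int(round(r * 1000 * scale))
        res = ExperimentResult(label=f"r={r:g}", seeds=[], raw_counts=[],
                               filtered_counts=[], error_means=[])
        all_dists: list[np.ndarray] = []
        for ri in range(replicates):
            seed = spawn_seed(master_seed, ci, ri)
            truth, frags = synthetic_nuc_map(
                wp_num=wp_num, wp_del=wp_del, fuz_num=fuz_num,
                max_cover=max_cover, seed=seed,
            )
            nmap = call_nucleosomes(frags, config=config)
            match = positioning_error(truth, nmap)
            res.seeds.append(seed)
            res.raw_counts.append(len(nmap))
            res.filtered_counts.append(filter_close_nucleosomes(nmap))
            res.error_means.append(
                float(match.distances.mean()) if match.n_matched else float("nan")
            )
            res.n_matched.append(match.n_matched)
            res.n_truth.append(len(truth))
            from .synthetic import adjacent_distances
            all_dists.append(adjacent_distances(nmap))
            log.info("fuzzy sweep %s rep %d: %d calls", res.label, ri,
                     res.raw_counts[-1])
        d = np.concatenate(all_dists) if all_dists else np.array([])
        if len(d):
            edges = np.arange(0.0, d.max() + 10.0, 5.0)
            res.distance_hist = tuple(np.histogram(d, bins=edges))  # type: ignore[assignment]
        results.append(res)
    return results


def run_coverage_sweep(
    fractions: Sequence[float],
    fragments: Sequence[FragmentRecord],
    master_seed: int = 0,
    truth=None,
    config: ProfileConfig | None = None,
) -> list[ExperimentResult]:
    """Subsample a fragment set at several fractions and call each subset."""
    results: list[ExperimentResult] = []
    for ci, frac in enumerate(fractions):
        if not 0 < frac <= 1:
            raise ValueError("fractions must be in (0, 1]")
        seed = spawn_seed(master_seed, ci, 0)
        sub = subsample_fragments(fragments, frac, seed=seed)
        nmap = call_nucleosomes(sub, config=config)
        err = float("nan")
        matched, n_truth = 0, 0
        if truth is not None:
            match = positioning_error(truth, nmap)
            err = float(match.distances.mean()) if match.n_matched else float("nan")
            matched, n_truth = match.n_matched, len(truth)
        res = ExperimentResult(
            label=f"fraction={frac:g}", seeds=[seed],
            raw_counts=[len(nmap)],
            filtered_counts=[filter_close_nucleosomes(nmap)],
            error_means=[err], n_matched=[matched], n_truth=[n_truth],
            distance_hist=adjacent_distance_distribution(nmap),
        )
        log.info("coverage sweep %s: %d fragments -> %d calls",
                 res.label, len(sub), len(nmap))
        results.append(res)
    return results


def summarize(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """One summary row per condition (means and sds over replicates)."""
    cols = ["label", "n_replicates", "raw_mean", "raw_sd",
            "filtered_mean", "filtered_sd", "error_mean", "error_sd"]
    if not results:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.summary() for r in results], columns=cols)


def write_summary(results: Sequence[ExperimentResult], path: str) -> None:
    summarize(results).to_csv(path, sep="\t", index=False)
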