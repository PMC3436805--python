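"""Benchmark harness: score call sets against truth and drive parameter grids.

Sensitivity S = TP/(TP+FN) and positive predictive value PPV = TP/(TP+FP)
are computed per SV type by greedy one-to-one matching of same-type calls
to truth events at >= 80% reciprocal overlap (translocations instead
require the insertion point and both segment boundaries within the
insert-size cutoff).  Each grid cell is simulated in replicate and the
median over replicates is reported, separately for the paired-end-only
call set and the split-read-refined calls.
"""

from __future__ import annotations

import os
import shutil
import tempfile
from dataclasses import replace

import numpy as np
import pandas as pd

from ._util import reciprocal_overlap
from .callset import FinalCall, assemble_final
from .pipeline import CallerParams, discover
from .simulate import SimConfig, TruthRecord, simulate_dataset


def derive_seed(seed: int, *key: int) -> int:
    """Stable sub-seed below 2**31 for one replicate of one cell."""
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % (2**31))


def match_calls(calls: list[FinalCall], truth: list[TruthRecord], sv_type: str,
                insert_max: float, min_reciprocal: float = 0.8) -> dict[str, int]:
    """Greedy one-to-one TP/FP/FN assignment for one SV type.

    Intrachromosomal pairs are ranked by descending reciprocal overlap;
    each truth event is matched at most once, so a second call on the same
    event counts as a false positive.  A translocation truth is recovered
    only when a merged call places the insertion point and both segment
    boundaries within ``insert_max`` of the truth.
    """
    cands = [c for c in calls if c.sv_type == sv_type]
    trues = [t for t in truth if t.sv_type == sv_type]
    pairs = []
    if sv_type == "TRA":
        for ci, c in enumerate(cands):
            if c.pos2_end is None:
                continue  # unmerged junction: only one partner breakpoint known
            for ti, t in enumerate(trues):
                if c.chrom != t.chrom or c.chrom2 != t.chrom2:
                    continue
                d_ins = abs(c.start - t.start)
                d_lo = abs(c.pos2 - t.start2)
                d_hi = abs(c.pos2_end - t.end2)
                if d_ins <= insert_max and d_lo <= insert_max and d_hi <= insert_max:
                    pairs.append((-(d_ins + d_lo + d_hi), ci, ti))
    else:
        for ci, c in enumerate(cands):
            for ti, t in enumerate(trues):
                if c.chrom != t.chrom:
                    continue
                ro = reciprocal_overlap(c.start, c.end, t.start, t.end)
                if ro >= min_reciprocal:
                    pairs.append((ro, ci, ti))
    pairs.sort(reverse=True)
    used_c: set[int] = set()
    used_t: set[int] = set()
    for _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
    tp = len(used_t)
    return {"TP": tp, "FP": len(cands) - tp, "FN": len(trues) - tp}


def _rates(counts: dict[str, int]) -> tuple[float, float]:
    tp, fp, fn = counts["TP"], counts["FP"], counts["FN"]
    s = tp / (tp + fn) if tp + fn else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    return s, ppv


def run_cell(cfg: SimConfig, replicates: int, seed: int, cell: str = "default",
             workdir: str | None = None, params: CallerParams | None = None,
             keep: bool = False) -> pd.DataFrame:
    """Simulate -> project -> call -> score one parameter cell in replicate.

    Returns one row per (replicate, caller mode, SV type) with TP/FP/FN,
    sensitivity and PPV.  Intermediate BAMs live in a scratch directory and
    are removed unless ``keep``.
    """
    rows = []
    sv_types = [t for t, n in cfg.counts().items() if n > 0]
    for rep in range(replicates):
        # replicate r of every cell runs at seed + r, so a base seed of 1
        # reproduces the same five simulations (seeds 1-5) in each cell
        rep_cfg = replace(cfg, seed=int(seed) + rep)
        tmp = tempfile.mkdtemp(prefix=f"svdelver_{cell}_r{rep}_", dir=workdir)
        try:
            ds = simulate_dataset(rep_cfg, tmp)
            result = discover([ds.bam], ds.fasta, params)
            imax = max(p.insert_max for p in result.profiles.values())
            pe_final = assemble_final(result.pe_calls)
            sr_final = [c for c in result.final if c.precise]
            for mode, callset in (("PE", pe_final), ("SR", sr_final)):
                for sv_type in sv_types:
                    counts = match_calls(callset, ds.truth, sv_type, imax)
                    s, ppv = _rates(counts)
                    rows.append(dict(cell=cell, replicate=rep, mode=mode,
                                     sv_type=sv_type, **counts,
                                     sensitivity=s, ppv=ppv))
        finally:
            if not keep:
                shutil.rmtree(tmp, ignore_errors=True)
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Median sensitivity/PPV over replicates per (cell, mode, SV type)."""
    return (results.groupby(["cell", "mode", "sv_type"], as_index=False)
            .agg(sensitivity=("sensitivity", "median"), ppv=("ppv", "median"),
                 replicates=("replicate", "nunique")))


def run_benchmark(cells: dict[str, SimConfig], replicates: int, seed: int,
                  workdir: str | None = None,
                  params: CallerParams | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every grid cell; returns (per-replicate rows, median summary)."""
    frames = [run_cell(cfg, replicates, seed, name, workdir, params)
              for name, cfg in sorted(cells.items())]
    results = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return results, summarize(results) if len(results) else results


def default_grid(scale: float = 1.0) -> dict[str, SimConfig]:
    """The benchmark's coverage grid for deletions at the default cell settings."""
    base = SimConfig(n_del=int(50 * scale), genome_length=int(5_000_000 * scale))
    return {f"cov{c}": replace(base, coverage=float(c)) for c in (5, 10, 15, 30)}
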