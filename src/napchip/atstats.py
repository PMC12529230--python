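"""AT-content comparison of peak summit windows against genomic backgrounds.

Peak windows are partitioned by genic context and their AT fractions are
compared with the AT fractions of the matching genomic background set
(per-interval values of the intergenic or merged-coding complement, or
length-matched random windows drawn from it) using an unpaired t test
(Welch by default) with a permutation companion. Significance is flagged at
p < 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    at_fraction,
    per_region_at,
)
from .peaks import PeakTable, SummitWindow, summit_windows, top_bottom, filter_fe

__all__ = [
    "TTestResult",
    "AtComparison",
    "collect_at",
    "unpaired_t",
    "permutation_test",
    "sample_background_windows",
    "at_report",
]

SIGNIFICANCE_THRESHOLD = 1e-3


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    variant: str


def unpaired_t(
    sample_a: np.ndarray, sample_b: np.ndarray, variant: str = "welch"
) -> TTestResult:
    """Two-sided unpaired t test; ``variant`` is "welch" (unequal variances,
    Welch-Satterthwaite df) or "student" (pooled variance)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        # identical constant samples: t = 0 by convention
        return TTestResult(0.0, 1.0, float(len(a) + len(b) - 2), variant)
    if variant == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif variant == "student":
        res = stats.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return TTestResult(float(res.statistic), float(res.pvalue),
                       float(res.df), variant)


def permutation_test(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Two-sided label-permutation p-value for the difference in means,
    with the add-one estimator p = (1 + #{|d_perm| >= |d_obs|}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    d_obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[:n_a].mean() - perm[n_a:].mean())
        if d >= d_obs - 1e-15:  # tolerate float noise on exact ties
            count += 1
    return (1 + count) / (n_perm + 1)


def collect_at(
    windows: list[SummitWindow],
    contexts: pd.DataFrame,
    genome: GenomeAssembly,
) -> dict[str, np.ndarray]:
    """Partition summit windows by called context and return one AT-fraction
    vector per context. All-N windows are excluded with a warning."""
    ctx = contexts.set_index("peak_id")["context"]
    out: dict[str, list[float]] = {"intergenic": [], "coding": []}
    for w in windows:
        at = at_fraction(genome, w.interval())
        if np.isnan(at):
            warnings.warn(f"window of peak {w.peak_id!r} is all-N; excluded")
            continue
        out[ctx.loc[w.peak_id]].append(at)
    return {k: np.asarray(v) for k, v in out.items()}


def sample_background_windows(
    background: IntervalSet,
    genome: GenomeAssembly,
    n: int,
    width: int = 60,
    seed: int | None = None,
) -> np.ndarray:
    """AT fractions of ``n`` random ``width``-bp windows drawn (with
    replacement, length-weighted) from a background interval set. Intervals
    shorter than ``width`` contribute their full span."""
    rng = np.random.default_rng(seed)
    lengths = np.array([iv.width for iv in background], dtype=float)
    probs = lengths / lengths.sum()
    values = []
    intervals = list(background)
    for idx in rng.choice(len(intervals), size=n, p=probs):
        iv = intervals[idx]
        if iv.width <= width:
            win = iv
        else:
            start = iv.start + int(rng.integers(0, iv.width - width + 1))
            win = GenomicInterval(iv.contig, start, start + width)
        values.append(at_fraction(genome, win))
    return np.asarray(values)


@dataclass
class AtComparison:
    category: str
    context: str
    n_peaks: int
    n_background: int
    mean_at_peaks: float
    mean_at_background: float
    t: float
    df: float
    p: float
    significant: bool
    computable: bool
    method: str


def at_report(
    table: PeakTable,
    contexts: pd.DataFrame,
    genome: GenomeAssembly,
    intergenic: IntervalSet,
    coding: IntervalSet,
    k: int = 20,
    fe_threshold: float = 2.0,
    variant: str = "welch",
    background: str = "per_region",
    flank: int = 30,
    seed: int | None = None,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> pd.DataFrame:
    """One AT comparison per (category x context): peak-window AT fractions
    versus the matching genomic background.

    ``background`` is "per_region" (one AT value per genomic interval of the
    matching set) or "matched_windows" (length-matched random windows drawn
    from it). Categories with fewer than 2 windows in a context are marked
    not computable.
    """
    backgrounds: dict[str, np.ndarray] = {}
    for name, iset in (("intergenic", intergenic), ("coding", coding)):
        if background == "per_region":
            vals = per_region_at(genome, iset)
        elif background == "matched_windows":
            vals = sample_background_windows(
                iset, genome, n=max(200, len(iset)), width=2 * flank, seed=seed)
        else:
            raise ValueError(f"unknown background mode {background!r}")
        backgrounds[name] = vals[~np.isnan(vals)]

    top, bottom = top_bottom(table, k=k)
    categories = {
        "all": table,
        f"FE>={fe_threshold:g}": filter_fe(table, fe_threshold),
        f"top-{k}": top,
        f"bottom-{k}": bottom,
    }
    rows = []
    for cat_name, sub in categories.items():
        windows = summit_windows(sub, genome, flank=flank)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            by_ctx = collect_at(windows, contexts, genome)
        for ctx_name, peak_vals in by_ctx.items():
            bg = backgrounds[ctx_name]
            if len(peak_vals) < 2 or len(bg) < 2:
                rows.append(AtComparison(
                    cat_name, ctx_name, len(peak_vals), len(bg),
                    float(np.mean(peak_vals)) if len(peak_vals) else float("nan"),
                    float(np.mean(bg)) if len(bg) else float("nan"),
                    float("nan"), float("nan"), float("nan"),
                    False, False, f"{variant}/{background}"))
                continue
            res = unpaired_t(peak_vals, bg, variant=variant)
            rows.append(AtComparison(
                cat_name, ctx_name, len(peak_vals), len(bg),
                float(peak_vals.mean()), float(bg.mean()),
                res.t, res.df, res.p, bool(res.p < threshold), True,
                f"{variant}/{background}"))
    return pd.DataFrame([vars(r) for r in rows])
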