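"""ChIP peak tables: ingestion, summit windows, genic-context classification,
fold-enrichment categories, subpeak merging, gene annotation and the
width-enrichment correlation.

The classification rule operates on the enrichment-summit window spanning
30 bp upstream through 30 bp downstream of the peak summit (60 bp, clipped
at contig edges): a peak is called intergenic iff strictly more than 30 bp
of that window lie in intergenic sequence, otherwise coding.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .genome import (
    Gene,
    GeneSet,
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
)

__all__ = [
    "PEAK_COLUMNS",
    "PeakTable",
    "SummitWindow",
    "ContextCall",
    "ParentRegion",
    "read_peaks",
    "summit_window",
    "summit_windows",
    "classify_context",
    "SummitContextClassifier",
    "filter_fe",
    "top_bottom",
    "category_report",
    "merge_subpeaks",
    "annotate_genes",
    "width_fe_correlation",
]

PEAK_COLUMNS = [
    "peak_id", "contig", "start", "end", "summit",
    "fold_enrichment", "q_value", "replicate_support",
]


class PeakFormatError(ValueError):
    """Raised when a peak table violates its dialect or bounds contract."""


@dataclass
class PeakTable:
    """Peak rows with internal 0-based half-open coordinates.

    Columns: peak_id, contig, start, end, summit, fold_enrichment,
    q_value (nan allowed), replicate_support.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.df.columns]
        if missing:
            raise PeakFormatError(f"peak table missing columns {missing}")
        self.df = self.df.loc[:, PEAK_COLUMNS].reset_index(drop=True)
        if len(self.df):
            bad = self.df[
                ~(
                    (self.df.start <= self.df.summit)
                    & (self.df.summit < self.df.end)
                    & (self.df.start < self.df.end)
                )
            ]
            if len(bad):
                raise PeakFormatError(
                    f"summit outside [start, end) for peaks "
                    f"{bad.peak_id.tolist()[:5]}"
                )
            fe = self.df.fold_enrichment
            if not np.all(np.isfinite(fe)) or (fe < 0).any():
                raise PeakFormatError("fold_enrichment must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return (row for _, row in self.df.iterrows())

    @property
    def widths(self) -> np.ndarray:
        return (self.df.end - self.df.start).to_numpy()

    def validate_against(self, genome: GenomeAssembly) -> "PeakTable":
        for _, row in self.df.iterrows():
            if row.contig not in genome:
                raise PeakFormatError(f"peak {row.peak_id!r}: unknown contig {row.contig!r}")
            if row.end > genome.lengths[row.contig]:
                raise PeakFormatError(f"peak {row.peak_id!r} exceeds contig bounds")
        return self

    # --- I/O -----------------------------------------------------------------

    @classmethod
    def from_narrowpeak(cls, path: str | Path) -> "PeakTable":
        """MACS-style narrowPeak (BED6+4): 0-based half-open on disk, summit
        given as an offset from start in column 10; signalValue is the fold
        enrichment."""
        names = ["contig", "start", "end", "peak_id", "score", "strand",
                 "signal", "p", "q", "offset"]
        try:
            raw = pd.read_csv(path, sep="\t", header=None, names=names,
                              comment="#", dtype={"contig": str})
        except pd.errors.EmptyDataError:
            raw = pd.DataFrame(columns=names)
        df = pd.DataFrame({
            "peak_id": raw.peak_id.astype(str),
            "contig": raw.contig,
            "start": raw.start.astype(int) if len(raw) else pd.Series(dtype=int),
            "end": raw.end.astype(int) if len(raw) else pd.Series(dtype=int),
            "summit": (raw.start + raw.offset).astype(int) if len(raw) else pd.Series(dtype=int),
            "fold_enrichment": raw.signal.astype(float) if len(raw) else pd.Series(dtype=float),
            "q_value": raw.q.astype(float) if len(raw) else pd.Series(dtype=float),
            "replicate_support": 1,
        })
        return cls(df)

    @classmethod
    def from_summary_tsv(cls, path: str | Path) -> "PeakTable":
        """Tab-separated summary dialect with 1-based inclusive coordinates
        on disk (columns: peak_id, contig, start, end, summit, width,
        fold_enrichment, q_value); converted to 0-based half-open on read."""
        try:
            raw = pd.read_csv(path, sep="\t", dtype={"contig": str, "peak_id": str})
        except pd.errors.EmptyDataError:
            raw = pd.DataFrame(
                columns=["peak_id", "contig", "start", "end", "summit",
                         "width", "fold_enrichment", "q_value"])
        df = pd.DataFrame({
            "peak_id": raw.peak_id.astype(str),
            "contig": raw.contig,
            "start": raw.start.astype(int) - 1 if len(raw) else pd.Series(dtype=int),
            "end": raw.end.astype(int) if len(raw) else pd.Series(dtype=int),
            "summit": raw.summit.astype(int) - 1 if len(raw) else pd.Series(dtype=int),
            "fold_enrichment": raw.fold_enrichment.astype(float) if len(raw) else pd.Series(dtype=float),
            "q_value": raw.get("q_value", pd.Series(np.nan, index=raw.index)).astype(float)
            if len(raw) else pd.Series(dtype=float),
            "replicate_support": 1,
        })
        return cls(df)

    def to_summary_tsv(self, path: str | Path) -> None:
        """Write the 1-based inclusive summary dialect (round-trips exactly)."""
        out = pd.DataFrame({
            "peak_id": self.df.peak_id,
            "contig": self.df.contig,
            "start": self.df.start + 1,
            "end": self.df.end,
            "summit": self.df.summit + 1,
            "width": self.df.end - self.df.start,
            "fold_enrichment": self.df.fold_enrichment,
            "q_value": self.df.q_value,
        })
        out.to_csv(path, sep="\t", index=False)

    def to_narrowpeak(self, path: str | Path) -> None:
        out = pd.DataFrame({
            "contig": self.df.contig,
            "start": self.df.start,
            "end": self.df.end,
            "peak_id": self.df.peak_id,
            "score": 0,
            "strand": ".",
            "signal": self.df.fold_enrichment,
            "p": -1.0,
            "q": self.df.q_value.fillna(-1.0),
            "offset": self.df.summit - self.df.start,
        })
        out.to_csv(path, sep="\t", index=False, header=False)


def read_peaks(
    path: str | Path, dialect: str, genome: GenomeAssembly | None = None
) -> PeakTable:
    """Read a peak table in the named dialect ("narrowPeak" or "summary-tsv"),
    bounds-checking against ``genome`` when given."""
    if dialect == "narrowPeak":
        table = PeakTable.from_narrowpeak(path)
    elif dialect == "summary-tsv":
        table = PeakTable.from_summary_tsv(path)
    else:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    if genome is not None:
        table.validate_against(genome)
    return table


# --- summit windows and context ----------------------------------------------


@dataclass(frozen=True)
class SummitWindow:
    contig: str
    start: int
    end: int
    peak_id: str

    @property
    def width(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end)


def summit_window(
    contig: str,
    summit: int,
    peak_id: str,
    genome: GenomeAssembly,
    flank: int = 30,
    inclusive: bool = False,
) -> SummitWindow:
    """Window spanning ``flank`` bp upstream through ``flank`` bp downstream
    of the summit, clipped to contig bounds.

    Default half-open ``[summit-flank, summit+flank)`` = 2*flank bp (the
    "60-bp region around the summit"); ``inclusive=True`` adds the final
    base for a 2*flank+1 bp window.
    """
    length = genome.lengths[contig]
    start = max(0, summit - flank)
    end = min(length, summit + flank + (1 if inclusive else 0))
    return SummitWindow(contig, start, end, peak_id)


def summit_windows(
    table: PeakTable, genome: GenomeAssembly, flank: int = 30, inclusive: bool = False
) -> list[SummitWindow]:
    return [
        summit_window(row.contig, int(row.summit), str(row.peak_id), genome,
                      flank=flank, inclusive=inclusive)
        for row in table
    ]


@dataclass(frozen=True)
class ContextCall:
    peak_id: str
    context: str  # "intergenic" or "coding"
    intergenic_overlap_bp: int
    window_fully_in_context: bool


def classify_context(
    window: SummitWindow, intergenic: IntervalSet, min_intergenic_bp: int = 30
) -> ContextCall:
    """Call a summit window intergenic iff strictly more than
    ``min_intergenic_bp`` bases overlap the intergenic set; exactly
    ``min_intergenic_bp`` (or fewer) is coding.

    ``window_fully_in_context`` is true when the window lies entirely in its
    called context (overlap equal to the window width for intergenic calls,
    zero for coding calls).
    """
    overlap = intergenic.overlap_bp(window.interval())
    intergenic_call = overlap > min_intergenic_bp
    fully = overlap == window.width if intergenic_call else overlap == 0
    return ContextCall(
        peak_id=window.peak_id,
        context="intergenic" if intergenic_call else "coding",
        intergenic_overlap_bp=overlap,
        window_fully_in_context=fully,
    )


class SummitContextClassifier(BaseEstimator, TransformerMixin):
    """Genic-context classifier for peak summit windows.

    Parameters
    ----------
    flank : int
        Bases upstream and downstream of the summit (window = 2*flank bp).
    min_intergenic_bp : int
        Strict threshold: intergenic overlap must exceed this for an
        intergenic call.
    inclusive_window : bool
        Use the 2*flank+1 bp closed window instead of the half-open default.

    After ``fit(intergenic, genome)`` the fitted attributes are
    ``intergenic_`` and ``genome_``; ``transform(peak_table)`` returns one
    row per peak with the context call.
    """

    def __init__(self, flank: int = 30, min_intergenic_bp: int = 30,
                 inclusive_window: bool = False):
        self.flank = flank
        self.min_intergenic_bp = min_intergenic_bp
        self.inclusive_window = inclusive_window

    def fit(self, intergenic: IntervalSet, genome: GenomeAssembly):
        self.intergenic_ = intergenic
        self.genome_ = genome
        return self

    def transform(self, table: PeakTable) -> pd.DataFrame:
        if not hasattr(self, "intergenic_"):
            raise RuntimeError("SummitContextClassifier is not fitted")
        rows = []
        for w in summit_windows(table, self.genome_, flank=self.flank,
                                inclusive=self.inclusive_window):
            call = classify_context(w, self.intergenic_, self.min_intergenic_bp)
            rows.append({
                "peak_id": call.peak_id,
                "window_start": w.start,
                "window_end": w.end,
                "context": call.context,
                "intergenic_overlap_bp": call.intergenic_overlap_bp,
                "window_fully_in_context": call.window_fully_in_context,
            })
        return pd.DataFrame(
            rows, columns=["peak_id", "window_start", "window_end", "context",
                           "intergenic_overlap_bp", "window_fully_in_context"])


# --- categories ---------------------------------------------------------------


def filter_fe(table: PeakTable, threshold: float = 2.0) -> PeakTable:
    """Peaks with fold enrichment >= ``threshold`` (inclusive), order preserved."""
    return PeakTable(table.df[table.df.fold_enrichment >= threshold].copy())


def top_bottom(table: PeakTable, k: int = 20) -> tuple[PeakTable, PeakTable]:
    """(top-k, bottom-k) by fold enrichment; ties broken by (contig, start)
    for determinism. If n <= k both equal the whole table."""
    df = table.df.sort_values(
        ["fold_enrichment", "contig", "start"],
        ascending=[False, True, True], kind="mergesort",
    )
    if len(df) <= k:
        return PeakTable(df.copy()), PeakTable(df.copy())
    return PeakTable(df.head(k).copy()), PeakTable(df.tail(k).iloc[::-1].copy())


def category_report(
    table: PeakTable,
    contexts: pd.DataFrame,
    genome: GenomeAssembly | None = None,
    k: int = 20,
    fe_threshold: float = 2.0,
) -> pd.DataFrame:
    """Aggregate context statistics for the four standard peak categories:
    all, FE>=threshold, top-k and bottom-k by fold enrichment.

    ``contexts`` is the output of :class:`SummitContextClassifier.transform`.
    Returns one row per category: n, percent_intergenic, mean_width_bp,
    mean fold enrichment, optional mean window AT, and member peak ids.
    """
    ctx = contexts.set_index("peak_id")["context"]
    top, bottom = top_bottom(table, k=k)
    categories = {
        "all": table,
        f"FE>={fe_threshold:g}": filter_fe(table, fe_threshold),
        f"top-{k}": top,
        f"bottom-{k}": bottom,
    }
    rows = []
    for name, sub in categories.items():
        ids = sub.df.peak_id.astype(str).tolist()
        if ids:
            calls = ctx.loc[ids]
            pct = 100.0 * (calls == "intergenic").mean()
            mean_w = float(sub.widths.mean())
            mean_fe = float(sub.df.fold_enrichment.mean())
        else:
            pct = mean_w = mean_fe = float("nan")
        mean_at = float("nan")
        if genome is not None and ids:
            from .genome import at_fraction
            ats = [at_fraction(genome, w.interval())
                   for w in summit_windows(sub, genome)]
            mean_at = float(np.nanmean(ats)) if ats else float("nan")
        rows.append({
            "category": name,
            "n": len(ids),
            "percent_intergenic": pct,
            "mean_width_bp": mean_w,
            "mean_fold_enrichment": mean_fe,
            "mean_window_at": mean_at,
            "peak_ids": ",".join(ids),
        })
    return pd.DataFrame(rows)


# --- subpeak merging and annotation -------------------------------------------


def _letters(i: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa, ... (spreadsheet-style lettering)."""
    out = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        out = string.ascii_lowercase[rem] + out
    return out


@dataclass
class ParentRegion:
    region_id: str
    interval: GenomicInterval
    members: list[str]           # lettered member ids, by start
    member_source_ids: list[str]  # original peak ids, same order
    max_fold_enrichment: float
    covered_genes: list[Gene] = field(default_factory=list)

    @property
    def n_subpeaks(self) -> int:
        return len(self.members)


def merge_subpeaks(table: PeakTable, max_gap_bp: int = 200) -> list[ParentRegion]:
    """Group peaks whose spans are separated by <= ``max_gap_bp`` on the same
    contig into parent regions; members are lettered a, b, c, ... by start.
    A single-member region keeps its bare region id (no letter suffix).
    Region fold enrichment is the max over members.
    """
    df = table.df.sort_values(["contig", "start", "end"], kind="mergesort")
    regions: list[ParentRegion] = []
    cluster: list[pd.Series] = []

    def flush(idx: int) -> None:
        if not cluster:
            return
        contig = cluster[0].contig
        start = int(min(r.start for r in cluster))
        end = int(max(r.end for r in cluster))
        region_id = str(idx + 1)
        if len(cluster) == 1:
            members = [region_id]
        else:
            members = [f"{region_id}{_letters(i)}" for i in range(len(cluster))]
        regions.append(ParentRegion(
            region_id=region_id,
            interval=GenomicInterval(contig, start, end),
            members=members,
            member_source_ids=[str(r.peak_id) for r in cluster],
            max_fold_enrichment=float(max(r.fold_enrichment for r in cluster)),
        ))

    for _, row in df.iterrows():
        if cluster and (
            row.contig != cluster[-1].contig
            or row.start - max(int(r.end) for r in cluster) > max_gap_bp
        ):
            flush(len(regions))
            cluster = []
        cluster.append(row)
    flush(len(regions))
    return regions


def annotate_genes(span: GenomicInterval, genes: GeneSet) -> list[Gene]:
    """All genes overlapping ``span`` by >= 1 bp, in genomic order."""
    hits = [g for g in genes if span.overlap(g.interval) >= 1]
    hits.sort(key=lambda g: (g.interval.contig, g.interval.start))
    return hits


# --- correlation --------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    slope: float
    intercept: float
    p_value: float
    n: int


def width_fe_correlation(table: PeakTable) -> CorrelationResult:
    """Pearson correlation and least-squares line of fold enrichment as a
    function of peak width. Degenerate inputs (n < 3 or zero variance in
    either variable) raise ``ValueError``."""
    widths = table.widths.astype(float)
    fe = table.df.fold_enrichment.to_numpy(dtype=float)
    if len(widths) < 3:
        raise ValueError("need at least 3 peaks for a correlation")
    if np.ptp(widths) == 0 or np.ptp(fe) == 0:
        raise ValueError("undefined correlation: constant widths or enrichments")
    res = stats.linregress(widths, fe)
    return CorrelationResult(
        pearson_r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n=len(widths),
    )
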