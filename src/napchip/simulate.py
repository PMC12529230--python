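"""Seeded synthetic-data generators for every input the pipeline consumes.

The genome generator draws bases independently with contrasting AT targets
for coding (default 53%) and intergenic (default 62%) sequence, matching the
compositional contrast of a small thermoacidophile genome. Occupancy of a
non-sequence-specific, AT-favouring DNA-binding protein is modelled as a
bounded logistic function of the local (moving-window) AT fraction; read
coverage is Poisson around the expected fold-enrichment track, in
independent replicates. EMSA titrations and AFM topographs are generated
with known ground truth.

Randomness: every generator takes a seed (or Generator); the master seed is
split into independent child streams with ``numpy.random.SeedSequence.spawn``
so adding a replicate never perturbs earlier streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emsa import EmsaTitration
from .afm import HeightMap
from .genome import Gene, GeneSet, GenomeAssembly, GenomicInterval
from .peaks import PEAK_COLUMNS, PeakTable

__all__ = [
    "GenomeSpec",
    "OccupancySpec",
    "CoverageTrack",
    "simulate_genome",
    "occupancy_track",
    "sample_coverage",
    "call_toy_peaks",
    "simulate_emsa",
    "simulate_afm",
]

_BASES = np.array(list("ATGC"))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class GenomeSpec:
    """Study conditions for the synthetic genome.

    Defaults give a 400-kb single-contig genome, 240 genes of 600-1400 bp,
    coding AT 53% and intergenic AT 62%. Composition is
    heterogeneous: each gene gets its own AT target drawn around the coding
    mean (truncated normal with the class sd), and intergenic sequence
    varies at the sub-kilobase scale (one AT target per
    ``intergenic_at_block`` bp), so gaps contain AT-rich islands the
    occupancy model can center on while genome-wide class averages stay on
    target; coding sequence is more homogeneous, as codon constraints make
    it in real genomes. Gap lengths follow a symmetric Dirichlet
    partition of the non-coding space; the small concentration parameter
    produces a heavy-tailed gap distribution with occasional kilobase-scale
    intergenic islands, the substrate for broad enrichment zones.
    """

    contig_length: int = 400_000
    n_genes: int = 240
    gene_length: tuple[int, int] = (600, 1400)
    coding_at: float = 0.53
    intergenic_at: float = 0.62
    coding_at_sd: float = 0.02
    intergenic_at_sd: float = 0.05
    intergenic_at_block: int = 500
    gap_concentration: float = 0.3
    min_gap: int = 30
    contig_id: str = "sim_1"

    def __post_init__(self) -> None:
        if not (0 < self.coding_at < 1 and 0 < self.intergenic_at < 1):
            raise ValueError("AT targets must lie in (0, 1)")
        if self.gene_length[0] > self.gene_length[1] or self.gene_length[0] < 1:
            raise ValueError("invalid gene length range")


def _random_bases(n: int, at: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _region_at(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Per-region AT target: truncated normal around the class mean."""
    if sd == 0:
        return mean
    return float(np.clip(rng.normal(mean, sd), 0.02, 0.98))


def simulate_genome(spec: GenomeSpec, seed=0) -> tuple[GenomeAssembly, GeneSet]:
    """Generate a genome and non-overlapping gene set under ``spec``.

    Bases are drawn independently with P(A or T) equal to the class target.
    Raises if the requested genes cannot be packed with positive gaps.
    """
    rng = _rng(seed)

    def draw_intergenic(n: int) -> np.ndarray:
        # sub-kilobase compositional blocks, each with its own AT target
        chunks = []
        for off in range(0, n, spec.intergenic_at_block):
            size = min(spec.intergenic_at_block, n - off)
            at = _region_at(spec.intergenic_at, spec.intergenic_at_sd, rng)
            chunks.append(_random_bases(size, at, rng))
        return np.concatenate(chunks) if chunks else np.empty(0, dtype="<U1")

    def draw_coding(n: int) -> np.ndarray:
        at = _region_at(spec.coding_at, spec.coding_at_sd, rng)
        return _random_bases(n, at, rng)

    if spec.n_genes == 0:
        seq = "".join(draw_intergenic(spec.contig_length))
        return GenomeAssembly({spec.contig_id: seq}), GeneSet([])

    lengths = rng.integers(spec.gene_length[0], spec.gene_length[1] + 1,
                           size=spec.n_genes)
    n_gaps = spec.n_genes + 1
    leftover = spec.contig_length - int(lengths.sum()) - n_gaps * spec.min_gap
    if leftover < 0:
        raise ValueError(
            f"cannot pack {spec.n_genes} genes into {spec.contig_length} bp "
            f"with positive gaps")
    weights = rng.dirichlet(np.full(n_gaps, spec.gap_concentration))
    gaps = spec.min_gap + np.floor(weights * leftover).astype(int)
    # distribute the rounding remainder over the first gaps
    short = spec.contig_length - int(lengths.sum()) - int(gaps.sum())
    gaps[: short] += 1

    base_arr = np.empty(spec.contig_length, dtype="<U1")
    genes: list[Gene] = []
    pos = 0
    for i in range(spec.n_genes):
        gap = int(gaps[i])
        base_arr[pos : pos + gap] = draw_intergenic(gap)
        pos += gap
        glen = int(lengths[i])
        base_arr[pos : pos + glen] = draw_coding(glen)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(
            GenomicInterval(spec.contig_id, pos, pos + glen, strand),
            locus_tag=f"sim_{i + 1:04d}",
            product="simulated protein",
        ))
        pos += glen
    base_arr[pos:] = draw_intergenic(spec.contig_length - pos)
    return GenomeAssembly({spec.contig_id: "".join(base_arr)}), GeneSet(genes)


@dataclass(frozen=True)
class OccupancySpec:
    """AT-biased nonspecific occupancy model.

    Expected fold enrichment at position x is
    ``baseline + bias_alpha * logistic((AT_w(x) - at_midpoint) / at_scale)``
    where AT_w is the centered moving AT fraction over ``window_w`` bp. The
    logistic link bounds enrichment at ``baseline + bias_alpha``; defaults
    put simulated maxima in the 3-5x fold-enrichment range over AT-rich
    intergenic islands. ``bias_alpha = 0`` gives a flat track (the null).
    """

    window_w: int = 500
    bias_alpha: float = 3.5
    baseline: float = 1.0
    at_midpoint: float = 0.65
    at_scale: float = 0.02

    def __post_init__(self) -> None:
        if self.window_w < 1:
            raise ValueError("window_w must be >= 1")
        if self.bias_alpha < 0:
            raise ValueError("bias_alpha must be >= 0")


def _moving_at(seq: str, window: int) -> np.ndarray:
    is_at = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_at = ((is_at == ord("A")) | (is_at == ord("T"))).astype(float)
    kernel = np.ones(window) / window
    smoothed = np.convolve(is_at, kernel, mode="same")
    # renormalize the edges where the kernel is truncated
    norm = np.convolve(np.ones_like(is_at), kernel, mode="same")
    return smoothed / norm


def occupancy_track(genome: GenomeAssembly, spec: OccupancySpec) -> dict[str, np.ndarray]:
    """Deterministic expected fold-enrichment track per contig."""
    tracks = {}
    for contig, seq in genome.contigs.items():
        if spec.bias_alpha == 0:
            tracks[contig] = np.full(len(seq), spec.baseline)
            continue
        at_w = _moving_at(seq, spec.window_w)
        z = (at_w - spec.at_midpoint) / spec.at_scale
        tracks[contig] = spec.baseline + spec.bias_alpha / (1.0 + np.exp(-z))
    return tracks


@dataclass
class CoverageTrack:
    """Per-bp IP and input read depth, per replicate."""

    contig: str
    ip: list[np.ndarray]
    input: list[np.ndarray]
    depth: float

    @property
    def n_replicates(self) -> int:
        return len(self.ip)


def sample_coverage(
    expected: np.ndarray,
    depth: float,
    n_replicates: int = 3,
    seed=0,
    contig: str = "sim_1",
) -> CoverageTrack:
    """Poisson coverage around the expected enrichment track.

    IP depth at x ~ Poisson(depth * E(x) / mean(E)); input ~ Poisson(depth).
    Replicates use independent child streams of the master seed.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    expected = np.asarray(expected, dtype=float)
    lam_ip = depth * expected / expected.mean()
    master = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else seed.entropy)
    children = master.spawn(2 * n_replicates)
    ip, inp = [], []
    for r in range(n_replicates):
        ip.append(np.random.default_rng(children[2 * r]).poisson(lam_ip))
        inp.append(np.random.default_rng(children[2 * r + 1]).poisson(depth, size=len(expected)))
    return CoverageTrack(contig=contig, ip=ip, input=inp, depth=depth)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    norm = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return np.convolve(x.astype(float), kernel, mode="same") / norm


def call_toy_peaks(
    coverage: CoverageTrack,
    smoothing_bp: int = 300,
    fe_cutoff: float = 1.5,
    min_width_bp: int = 100,
    merge_gap_bp: int = 200,
) -> PeakTable:
    """Segment a replicate-averaged smoothed fold-enrichment track into
    peaks: maximal runs with FE >= cutoff and width >= min_width, nearby
    runs (gaps <= merge_gap) merged first. Summit = leftmost argmax of FE in
    the peak; peak fold enrichment = mean FE over the peak.

    This is a deliberately simple segmenter for simulated tracks, not a
    peak caller for real read data.
    """
    n = len(coverage.ip[0])
    fe_reps = []
    for ip, inp in zip(coverage.ip, coverage.input):
        ratio = (ip + 1.0) / (inp + 1.0)
        ratio *= (inp.mean() + 1.0) / (ip.mean() + 1.0)  # depth normalization
        fe_reps.append(_smooth(ratio, smoothing_bp))
    fe = np.mean(fe_reps, axis=0)

    above = fe >= fe_cutoff
    # run-length encode
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))
    # merge runs separated by <= merge_gap_bp
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap_bp:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    rows = []
    idx = 0
    for s, e in merged:
        if e - s < min_width_bp:
            continue
        idx += 1
        summit = s + int(np.argmax(fe[s:e]))
        rows.append({
            "peak_id": f"toy_{idx:04d}",
            "contig": coverage.contig,
            "start": int(s),
            "end": int(e),
            "summit": summit,
            "fold_enrichment": float(fe[s:e].mean()),
            "q_value": np.nan,
            "replicate_support": coverage.n_replicates,
        })
    return PeakTable(pd.DataFrame(rows, columns=PEAK_COLUMNS))


def simulate_emsa(
    kd_nM: float,
    concentrations: np.ndarray,
    noise_sd: float = 0.0,
    seed=0,
    probe_id: str = "sim_probe",
) -> EmsaTitration:
    """Hyperbolic titration theta = c/(kd + c) with optional Gaussian noise,
    clipped to [0, 1]."""
    if kd_nM <= 0:
        raise ValueError("kd must be > 0")
    rng = _rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    theta = conc / (kd_nM + conc)
    if noise_sd > 0:
        theta = np.clip(theta + rng.normal(0, noise_sd, size=len(conc)), 0, 1)
    return EmsaTitration(probe_id, conc, theta)


def simulate_afm(
    n_complexes: int,
    height_choices: np.ndarray = (1.5, 3.0, 5.0, 8.0),
    foci_choices: np.ndarray = (1, 2, 3, 4),
    map_size: tuple[int, int] = (256, 256),
    seed=0,
    sigma_px: float = 2.5,
    foci_spacing_sigma: float = 3.1,
    max_tries: int = 2000,
) -> tuple[HeightMap, pd.DataFrame]:
    """Topograph of Gaussian-bump complexes with known ground truth.

    Each complex is a chain of equal-amplitude Gaussian bumps (one per
    focus) spaced ``foci_spacing_sigma * sigma_px`` apart along a random
    direction; collinear spacing guarantees every pair of foci is at least
    that far apart while the inter-bump valley stays above ~0.6x the bump
    amplitude, so a complex remains one connected component for any
    segmentation threshold below ~0.6x its height. Complex centers keep a
    mutual clearance so complexes never merge; raises if the requested
    number cannot be packed.

    Returns (HeightMap, ground-truth table with columns complex_id,
    center_y, center_x, max_height_nm, foci_count).
    """
    rng = _rng(seed)
    ny, nx = map_size
    values = np.zeros((ny, nx))
    spacing = foci_spacing_sigma * sigma_px
    max_foci = int(np.max(foci_choices))
    half_span = (max_foci - 1) * spacing / 2
    margin = half_span + 4 * sigma_px
    clearance = 2 * half_span + 8 * sigma_px
    if 2 * margin >= min(ny, nx):
        raise ValueError("map too small for the requested foci geometry")
    centers: list[tuple[float, float]] = []
    truth = []
    yy, xx = np.mgrid[0:ny, 0:nx]
    for i in range(n_complexes):
        for attempt in range(max_tries):
            cy = rng.uniform(margin, ny - margin)
            cx = rng.uniform(margin, nx - margin)
            if all(np.hypot(cy - y, cx - x) >= clearance for y, x in centers):
                break
        else:
            raise ValueError(
                f"could not place complex {i + 1} of {n_complexes}: map too crowded")
        centers.append((cy, cx))
        height = float(rng.choice(np.asarray(height_choices, dtype=float)))
        n_foci = int(rng.choice(np.asarray(foci_choices)))
        theta = rng.uniform(0, 2 * np.pi)
        dy, dx = np.sin(theta), np.cos(theta)
        offsets = (np.arange(n_foci) - (n_foci - 1) / 2) * spacing
        for off in offsets:
            fy, fx = cy + off * dy, cx + off * dx
            values += height * np.exp(
                -((yy - fy) ** 2 + (xx - fx) ** 2) / (2 * sigma_px**2))
        truth.append({
            "complex_id": i + 1,
            "center_y": cy,
            "center_x": cx,
            "max_height_nm": height,
            "foci_count": n_foci,
        })
    truth_df = pd.DataFrame(
        truth, columns=["complex_id", "center_y", "center_x",
                        "max_height_nm", "foci_count"])
    return HeightMap(values), truth_df
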