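"""Synthetic fixture generators with the statistical structure the analysis assumes.

Every generator is a pure function of its parameters and seed (bit-identical
reruns) and returns a :class:`SyntheticTruth` carrying the planted ground
truth, so downstream recovery can be scored without re-deriving it.

The enhancer landscape emulates the hockey-stick rank-signal geometry of
real cofactor occupancy: many isolated typical enhancers with exponential
signals against a few dense, high-signal clusters that stitch into
super-enhancers.  TF peak sets emulate multi-factor co-occupancy at shared
sites; time-course expression draws from four archetype curves (biphasic,
down, up, flat); case/control sets plant up/down-dysregulated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigurationError
from .expression import archetype_templates
from .io import GeneModel, GenomicInterval, Peak, PeakSet

__all__ = [
    "SyntheticLandscapeSpec",
    "SyntheticTruth",
    "generate_annotation",
    "generate_enhancer_landscape",
    "generate_tf_peaksets",
    "generate_timecourse_expression",
    "generate_case_control_datasets",
    "generate_condition_pair",
    "generate_read_placements",
]

_MAX_TRIES = 1000


@dataclass
class SyntheticLandscapeSpec:
    """Parameters of the planted enhancer landscape.

    Defaults reproduce the standing study conditions: 200 isolated typical
    enhancers (exponential signal, mean 5) and 10 planted clusters of 8
    peaks (mean 50) whose spans are well below the stitch distance, on two
    20-Mb chromosomes carrying 200 genes.
    """

    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 200
    n_typical: int = 200
    typical_signal_mean: float = 5.0
    n_se_clusters: int = 10
    peaks_per_cluster: int = 8
    cluster_span: int = 10_000
    se_signal_mean: float = 50.0
    stitch_distance: int = 12_500
    tss_exclusion: int = 2_500
    seed: int = 0

    def __post_init__(self):
        if self.se_signal_mean <= self.typical_signal_mean:
            raise ConfigurationError("se_signal_mean must exceed typical_signal_mean")
        if self.cluster_span >= self.stitch_distance:
            raise ConfigurationError("cluster_span must be < stitch_distance")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    planted_se_intervals: list[GenomicInterval] = field(default_factory=list)
    class_labels: dict[str, int] = field(default_factory=dict)
    dysregulated_genes: dict[str, str] = field(default_factory=dict)
    cooccupancy_rate: float | Sequence[float] | None = None
    site_factor_matrix: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(spec: SyntheticLandscapeSpec) -> list[GeneModel]:
    """Place non-overlapping genes with 2–6 exons, uniformly, strands random.

    Raises :class:`CapacityError` when the genes cannot fit.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = spec.chrom_names()
    genes: list[GeneModel] = []
    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1
    min_gap = 1_000
    idx = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(3_000, 12_001, size=k)
        free = spec.chrom_length - int(lengths.sum()) - (k + 1) * min_gap
        if free < 0:
            raise CapacityError(
                f"{k} genes (total {lengths.sum()} bp) exceed {chrom} "
                f"({spec.chrom_length} bp)"
            )
        extra = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for j in range(k):
            pos += min_gap + int(extra[j])
            start, end = pos, pos + int(lengths[j])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    symbol=f"gene{idx:04d}",
                    tx_name=f"tx{idx:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=_make_exons(rng, chrom, start, end),
                )
            )
            idx += 1
    return genes


def _make_exons(rng, chrom: str, start: int, end: int) -> tuple[GenomicInterval, ...]:
    m = int(rng.integers(2, 7))
    # 2(m-1) interior cuts -> alternate exon/intron segments, exons at even slots
    cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * (m - 1), replace=False))
    bounds = [start, *cuts.tolist(), end]
    return tuple(
        GenomicInterval(chrom, bounds[i], bounds[i + 1])
        for i in range(0, len(bounds) - 1, 2)
    )


# ---------------------------------------------------------------------------
# enhancer landscape
# ---------------------------------------------------------------------------

def generate_enhancer_landscape(
    spec: SyntheticLandscapeSpec, genes: Sequence[GeneModel]
) -> tuple[PeakSet, SyntheticTruth]:
    """Plant isolated typical peaks and dense high-signal clusters.

    Typical peaks are pairwise separated by more than the stitch distance;
    each cluster's peaks fit within ``cluster_span``; clusters sit more
    than the stitch distance from any other peak and more than the TSS
    exclusion zone from every TSS, so planted extents survive SE calling
    intact.  Truth lists each cluster's stitched extent.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = spec.chrom_names()
    tss = {c: np.sort([g.tss for g in genes if g.chrom == c]) for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def blocked(chrom: str, lo: int, hi: int) -> bool:
        pad = spec.stitch_distance + 1
        for s, e in occupied[chrom]:
            if lo - pad < e and s < hi + pad:
                return True
        sites = tss[chrom]
        z = spec.tss_exclusion
        i = np.searchsorted(sites, lo - z, side="left")
        return bool(i < len(sites) and sites[i] <= hi + z)

    def place(span: int) -> tuple[str, int]:
        for _ in range(_MAX_TRIES):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, spec.chrom_length - span))
            if not blocked(chrom, start, start + span):
                occupied[chrom].append((start, start + span))
                return chrom, start
        raise CapacityError("placement failed; landscape too dense for the genome size")

    peaks: list[Peak] = []
    truth_intervals: list[GenomicInterval] = []

    for ci in range(spec.n_se_clusters):
        width = 600
        chrom, base = place(spec.cluster_span)
        offsets = np.sort(
            rng.choice(spec.cluster_span - width, size=spec.peaks_per_cluster, replace=False)
        )
        signals = rng.exponential(spec.se_signal_mean, size=spec.peaks_per_cluster)
        cluster_peaks = [
            Peak(
                GenomicInterval(chrom, base + int(o), base + int(o) + width),
                float(s),
                factor="p300",
                cell_state="TSC",
                name=f"se{ci}_{j}",
            )
            for j, (o, s) in enumerate(zip(offsets, signals))
        ]
        peaks.extend(cluster_peaks)
        truth_intervals.append(
            GenomicInterval(
                chrom,
                min(p.start for p in cluster_peaks),
                max(p.end for p in cluster_peaks),
            )
        )

    for ti in range(spec.n_typical):
        width = int(rng.integers(300, 1_000))
        chrom, start = place(width)
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, start + width),
                float(rng.exponential(spec.typical_signal_mean)),
                factor="p300",
                cell_state="TSC",
                name=f"typ{ti}",
            )
        )

    peakset = PeakSet("p300", "TSC", sorted(peaks, key=lambda p: (p.chrom, p.start)))
    return peakset, SyntheticTruth(planted_se_intervals=truth_intervals)


# ---------------------------------------------------------------------------
# TF peak sets
# ---------------------------------------------------------------------------

def generate_tf_peaksets(
    n_factors: int,
    shared_sites: int,
    cooccupancy_rate: float | Sequence[float],
    private_sites_per_factor: int,
    seed: int,
    anchors: Sequence[tuple[str, int]] | None = None,
    cell_state: str = "TSC",
    private_chrom: str = "chrU",
) -> tuple[list[PeakSet], SyntheticTruth]:
    """Multi-factor peak sets with controllable co-occupancy at shared sites.

    Each factor binds each shared site independently with its co-occupancy
    rate (a scalar broadcast to all factors, or one rate per factor); bound
    peaks get centers jittered within ±100 bp of the site anchor.  Each
    factor additionally receives ``private_sites_per_factor`` sites of its
    own.  Truth carries the site-by-factor indicator matrix for the shared
    universe.

    ``anchors`` optionally pins the shared-site anchors to given (chrom,
    position) pairs — e.g. inside planted super-enhancers; by default
    anchors are spaced 5 kb apart on "chrU".
    """
    rates = np.broadcast_to(np.asarray(cooccupancy_rate, dtype=float), (n_factors,))
    if ((rates < 0) | (rates > 1)).any():
        raise ConfigurationError("cooccupancy_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    factors = [f"TF{i + 1:02d}" for i in range(n_factors)]

    if anchors is None:
        anchors = [("chrU", 10_000 + 5_000 * i) for i in range(shared_sites)]
    else:
        anchors = list(anchors)[:shared_sites]
        if len(anchors) != shared_sites:
            raise ConfigurationError("fewer anchors than shared_sites")

    bound = rng.random((shared_sites, n_factors)) < rates[None, :]
    jitter = rng.integers(-100, 101, size=(shared_sites, n_factors))

    half = 250
    peaksets: list[PeakSet] = []
    private_base = 10_000_000
    for j, factor in enumerate(factors):
        plist: list[Peak] = []
        for i, (chrom, pos) in enumerate(anchors):
            if bound[i, j]:
                c = int(pos + jitter[i, j])
                plist.append(
                    Peak(
                        GenomicInterval(chrom, c - half, c + half),
                        float(rng.exponential(10.0)),
                        factor,
                        cell_state,
                        name=f"{factor}_s{i}",
                    )
                )
        for k in range(private_sites_per_factor):
            c = private_base + j * private_sites_per_factor * 5_000 + k * 5_000
            plist.append(
                Peak(
                    GenomicInterval(private_chrom, c - half, c + half),
                    float(rng.exponential(10.0)),
                    factor,
                    cell_state,
                    name=f"{factor}_p{k}",
                )
            )
        peaksets.append(PeakSet(factor, cell_state, plist))

    matrix = pd.DataFrame(
        bound.astype(int),
        index=[f"{c}:{p}" for c, p in anchors],
        columns=factors,
    )
    truth = SyntheticTruth(
        cooccupancy_rate=cooccupancy_rate, site_factor_matrix=matrix
    )
    return peaksets, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_timecourse_expression(
    n_genes_per_class: int,
    n_timepoints: int = 7,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Time-course table drawn from the four archetype mean curves.

    Gene ``g`` in class ``c`` follows ``baseline * 2**template_c(t)`` with
    multiplicative lognormal noise of log-scale s.d. ``noise_sd``
    (``noise_sd=0`` gives the exact archetype curve).
    """
    if n_timepoints < 4:
        raise ConfigurationError("need >= 4 timepoints")
    rng = np.random.default_rng(seed)
    templates = archetype_templates(n_timepoints)
    rows, index, labels = [], [], {}
    for c in (1, 2, 3, 4):
        for g in range(n_genes_per_class):
            name = f"g_c{c}_{g:03d}"
            baseline = 2.0 ** rng.uniform(5.0, 9.0)
            mean_curve = baseline * 2.0 ** templates[c]
            noise = np.exp(rng.normal(0.0, noise_sd, n_timepoints)) if noise_sd > 0 else 1.0
            rows.append(mean_curve * noise)
            index.append(name)
            labels[name] = c
    table = pd.DataFrame(
        rows, index=index, columns=[f"t{i}" for i in range(n_timepoints)]
    )
    return table, SyntheticTruth(class_labels=labels)


def generate_case_control_datasets(
    n_datasets: int,
    n_genes: int,
    n_planted_up: int,
    n_planted_down: int,
    effect_log2fc: float,
    noise_sd: float,
    seed: int,
    n_samples_per_group: int = 5,
    extreme_fraction: float = 0.10,
):
    """Case/control expression sets with planted dysregulated genes.

    Per dataset, each sample's log2 expression is a gene baseline plus
    N(0, noise_sd) noise; planted genes get their case mean shifted by
    ±``effect_log2fc``.  The planted count must fit inside one extreme
    tail (``n_planted_up + n_planted_down < extreme_fraction * n_genes``).

    Returns ``(datasets, truth)`` where each dataset is an
    ``expression.CaseControlDataset``.
    """
    from .expression import CaseControlDataset

    if n_planted_up + n_planted_down >= extreme_fraction * n_genes:
        raise ConfigurationError(
            "planted genes must be fewer than one extreme tail "
            f"({n_planted_up + n_planted_down} >= {extreme_fraction * n_genes:g})"
        )
    rng = np.random.default_rng(seed)
    gene_names = [f"gene{i:05d}" for i in range(n_genes)]
    planted_idx = rng.choice(n_genes, size=n_planted_up + n_planted_down, replace=False)
    direction = {gene_names[i]: "up" for i in planted_idx[:n_planted_up]}
    direction.update({gene_names[i]: "down" for i in planted_idx[n_planted_up:]})
    shift = np.zeros(n_genes)
    shift[planted_idx[:n_planted_up]] = effect_log2fc
    shift[planted_idx[n_planted_up:]] = -effect_log2fc

    datasets = []
    for d in range(n_datasets):
        baseline = rng.normal(6.0, 2.0, n_genes)
        case = baseline[:, None] + shift[:, None] + rng.normal(
            0.0, noise_sd, (n_genes, n_samples_per_group)
        )
        ctrl = baseline[:, None] + rng.normal(
            0.0, noise_sd, (n_genes, n_samples_per_group)
        )
        cols_case = [f"case{j}" for j in range(n_samples_per_group)]
        cols_ctrl = [f"ctrl{j}" for j in range(n_samples_per_group)]
        expr = pd.DataFrame(
            np.hstack([2.0 ** case, 2.0 ** ctrl]),
            index=gene_names,
            columns=cols_case + cols_ctrl,
        )
        datasets.append(
            CaseControlDataset(f"ds{d + 1}", expr, cols_case, cols_ctrl)
        )
    return datasets, SyntheticTruth(dysregulated_genes=direction)


def generate_condition_pair(
    counts: Mapping[str, int],
    seed: int,
    effect_per_enhancer: float = 0.4,
    noise_sd: float = 0.3,
    n_samples: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition tables whose log-ratio increases with enhancer count.

    Emulates the enhancer-dosage relationship: genes with more condition-A
    enhancers are expressed relatively higher in condition A.  Used by the
    demo to exercise the moving-average analysis.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(counts)
    c = np.array([counts[g] for g in genes], dtype=float)
    c_std = (c - c.mean()) / (c.std() or 1.0)
    base = rng.uniform(4.0, 8.0, len(genes))
    ratio = effect_per_enhancer * c_std + rng.normal(0.0, noise_sd, len(genes))
    log_a = base + ratio / 2
    log_b = base - ratio / 2
    noise = lambda: rng.normal(0.0, 0.05, (len(genes), n_samples))
    a = pd.DataFrame(
        2.0 ** (log_a[:, None] + noise()),
        index=genes,
        columns=[f"a{j}" for j in range(n_samples)],
    )
    b = pd.DataFrame(
        2.0 ** (log_b[:, None] + noise()),
        index=genes,
        columns=[f"b{j}" for j in range(n_samples)],
    )
    return a, b


def generate_read_placements(
    centers: Sequence[tuple[str, int]],
    n_reads_per_center: int,
    spread_sd: float,
    seed: int,
    background: int = 0,
    background_span: tuple[str, int, int] | None = None,
) -> pd.DataFrame:
    """Fragment positions scattered normally around centers, plus background."""
    rng = np.random.default_rng(seed)
    chroms, pos = [], []
    for chrom, center in centers:
        offs = rng.normal(0.0, spread_sd, n_reads_per_center).astype(np.int64)
        chroms.extend([chrom] * n_reads_per_center)
        pos.extend(np.maximum(center + offs, 0).tolist())
    if background and background_span is not None:
        bchrom, lo, hi = background_span
        chroms.extend([bchrom] * background)
        pos.extend(rng.integers(lo, hi, background).tolist())
    return pd.DataFrame({"chrom": chroms, "position": pos})
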