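"""End-to-end orchestration: staged runs from a YAML config, plus a demo
mode that generates the full synthetic fixture suite, runs every stage,
and scores the outputs against the planted truth.

Stages execute in dependency order (io → se_calling → feature_annotation →
cooccupancy → network → expression_analysis → signal_profiling), each
reading its predecessors' TSV outputs from ``out_dir`` so partial reruns
are possible.  A :class:`RunManifest` records the config snapshot, input
and output digests, and stage timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import classify_peakset, map_enhancers_to_genes
from .config import PipelineConfig
from .cooccupancy import build_union_sites, count_factors_per_region, pairwise_correlation
from .errors import ConfigurationError
from .expression import (
    CaseControlDataset,
    classify_timecourse,
    crossdataset_dysregulated,
    moving_average_enhancer_counts,
    relative_timecourse,
)
from .io import (
    GenomicInterval,
    read_expression_table,
    read_intervals_bed,
    read_ortholog_map,
    read_peaks,
    read_read_placements,
    read_refflat,
    filter_repeat_regions,
    write_expression_table,
    write_peaks,
    write_refflat,
)
from .network import build_trn, coregulated_gene_set, export_edge_list, find_circuitry
from .profiling import profile_around_centers, region_occupancy_score, relative_occupancy
from .se_calling import associate_se_genes, exclude_tss_peaks, rank_and_cutoff, stitch_peaks

logger = logging.getLogger(__name__)

STAGES = (
    "io",
    "se_calling",
    "feature_annotation",
    "cooccupancy",
    "network",
    "expression_analysis",
    "signal_profiling",
)

__all__ = ["RunManifest", "run_pipeline", "demo", "STAGES"]


@dataclass
class RunManifest:
    config_snapshot: dict
    rng_seed: int
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    stage_timings: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Holds per-run state and implements one method per stage."""

    def __init__(self, cfg: dict, out_dir: Path):
        self.raw = cfg
        self.out = out_dir
        self.out.mkdir(parents=True, exist_ok=True)
        self.params = PipelineConfig.from_dict(cfg.get("params", {}))
        self.inputs = cfg.get("inputs", {})
        self.manifest = RunManifest(
            config_snapshot=cfg, rng_seed=self.params.rng_seed
        )
        # cross-stage state
        self.se_peaks = None
        self.genes = None
        self.se_result = None
        self.se_gene_map = None
        self.tf_peaksets = None

    # -- helpers ---------------------------------------------------------

    def _need(self, key: str, stage: str):
        if key not in self.inputs:
            raise ConfigurationError(f"stage {stage!r}: missing input {key!r}")
        return self.inputs[key]

    def _register(self, path: Path):
        self.manifest.outputs[str(path)] = _sha256(path)

    def _digest_input(self, path):
        p = Path(path)
        if p.exists():
            self.manifest.input_digests[str(p)] = _sha256(p)
        return p

    def _load_genes(self):
        if self.genes is None:
            self.genes = read_refflat(self._digest_input(self._need("refflat", "io")))
        return self.genes

    def _load_se_peaks(self):
        if self.se_peaks is None:
            filtered = self.out / "filtered_peaks.bed"
            spec = self._need("se_peaks", "io")
            src = filtered if filtered.exists() else self._digest_input(spec["path"])
            self.se_peaks = read_peaks(
                src, factor=spec.get("factor", "p300"), cell_state=spec.get("cell_state", "")
            )
        return self.se_peaks

    def _load_tf_peaksets(self):
        if self.tf_peaksets is None:
            specs = self._need("tf_peaks", "cooccupancy")
            self.tf_peaksets = [
                read_peaks(
                    self._digest_input(s["path"]),
                    factor=s["factor"],
                    cell_state=s.get("cell_state", ""),
                )
                for s in specs
            ]
        return self.tf_peaksets

    def _se_result(self):
        if self.se_result is None:
            peaks = exclude_tss_peaks(
                self._load_se_peaks(), self._load_genes(), self.params.tss_exclusion
            )
            if self.params.min_peak_signal > 0:
                peaks = peaks.replace_peaks(
                    [p for p in peaks if p.signal >= self.params.min_peak_signal]
                )
            regions = stitch_peaks(peaks, self.params.stitch_distance)
            self.se_result = rank_and_cutoff(regions)
        return self.se_result

    # -- stages ----------------------------------------------------------

    def stage_io(self):
        peaks = self._load_se_peaks()
        repeats_path = self.inputs.get("repeats")
        if repeats_path:
            repeats = read_intervals_bed(self._digest_input(repeats_path))
            peaks = filter_repeat_regions(peaks, repeats)
        self.se_peaks = peaks
        dest = self.out / "filtered_peaks.bed"
        write_peaks(peaks, dest)
        self._register(dest)
        logger.info("io: %d peaks ready", len(peaks))

    def stage_se_calling(self):
        result = self._se_result()
        genes = self._load_genes()
        rows = []
        for r in result.regions:
            rows.append(
                (
                    r.interval.chrom, r.interval.start, r.interval.end,
                    f"region_{r.rank}", r.total_signal, r.rank,
                    int(r.total_signal > result.cutoff_signal),
                )
            )
        regions_df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "total_signal", "rank", "is_SE"]
        )
        dest = self.out / "stitched_regions.tsv"
        regions_df.to_csv(dest, sep="\t", index=False)
        self._register(dest)

        n = len(result.regions)
        sig = regions_df["total_signal"].to_numpy()
        curve = pd.DataFrame(
            {
                "rank": regions_df["rank"],
                "total_signal": sig,
                "x": np.arange(n) / (n - 1),
                "y": (sig - sig[0]) / (sig[-1] - sig[0]),
            }
        )
        dest = self.out / "rank_curve.tsv"
        curve.to_csv(dest, sep="\t", index=False)
        self._register(dest)

        self.se_gene_map = associate_se_genes(result, genes, self.params.network_window)
        dest = self.out / "se_genes.tsv"
        with open(dest, "w") as fh:
            fh.write("chrom\tstart\tend\tgenes\n")
            for iv in sorted(self.se_gene_map):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    + ",".join(sorted(self.se_gene_map[iv]))
                    + "\n"
                )
        self._register(dest)
        logger.info(
            "se_calling: %d regions, %d super-enhancers, %d SE-associated genes",
            n, len(result.superenhancers),
            len(set().union(*self.se_gene_map.values())) if self.se_gene_map else 0,
        )

    def stage_feature_annotation(self):
        genes = self._load_genes()
        peaks = self._load_se_peaks()
        calls = classify_peakset(peaks, genes, self.params)
        dest = self.out / "feature_calls.tsv"
        with open(dest, "w") as fh:
            fh.write("chrom\tstart\tend\tfactor\tfeature\tgene\n")
            for c in calls:
                fh.write(
                    f"{c.peak.chrom}\t{c.peak.start}\t{c.peak.end}\t"
                    f"{c.peak.factor}\t{c.feature!s}\t"
                    f"{c.gene.symbol if c.gene else ''}\n"
                )
        self._register(dest)

        counts = map_enhancers_to_genes(peaks, genes, self.params)
        dest = self.out / "enhancer_counts.tsv"
        with open(dest, "w") as fh:
            fh.write("gene\tenhancer_count\n")
            for g in sorted(counts):
                fh.write(f"{g}\t{counts[g]}\n")
        self._register(dest)
        logger.info("feature_annotation: %d calls, %d genes counted", len(calls), len(counts))

    def stage_cooccupancy(self):
        peaksets = self._load_tf_peaksets()
        matrix = build_union_sites(peaksets, self.params.overlap_window)
        dest = self.out / "occupancy_matrix.tsv"
        matrix.to_frame().to_csv(dest, sep="\t", index_label="site")
        self._register(dest)

        corr = pairwise_correlation(matrix)
        dest = self.out / "correlation.tsv"
        corr.table.to_csv(dest, sep="\t", index_label="factor")
        self._register(dest)
        dest = self.out / "correlation_order.txt"
        dest.write_text("\n".join(corr.order) + "\n")
        self._register(dest)

        # factors per SE, using the SE calls when available
        se_file = self.out / "stitched_regions.tsv"
        if se_file.exists():
            df = pd.read_csv(se_file, sep="\t")
            ses = [
                GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in df[df["is_SE"] == 1].itertuples()
            ]
            counts = count_factors_per_region(ses, peaksets)
            dest = self.out / "se_tf_counts.tsv"
            with open(dest, "w") as fh:
                fh.write("chrom\tstart\tend\tn_factors\n")
                for iv in sorted(counts):
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{counts[iv]}\n")
            self._register(dest)
        logger.info("cooccupancy: %d union sites x %d factors", len(matrix.sites), len(matrix.factors))

    def stage_network(self):
        peaksets = self._load_tf_peaksets()
        genes = self._load_genes()
        tf_map_path = self._need("tf_gene_map", "network")
        tf_map = dict(
            pd.read_csv(self._digest_input(tf_map_path), sep="\t")
            .iloc[:, :2]
            .itertuples(index=False, name=None)
        )
        trn = build_trn(peaksets, genes, tf_map, self.params)
        dest = self.out / "edges.tsv"
        export_edge_list(trn, dest)
        self._register(dest)

        circuitry = find_circuitry(trn)
        dest = self.out / "circuitry.tsv"
        with open(dest, "w") as fh:
            fh.write("motif\tmembers\n")
            for tf in sorted(circuitry.autoregulators):
                fh.write(f"autoregulation\t{tf}\n")
            for pair in sorted(tuple(sorted(p)) for p in circuitry.feedback_pairs):
                fh.write(f"feedback\t{','.join(pair)}\n")
            for triad in sorted(circuitry.feedforward_triads):
                fh.write(f"feedforward\t{','.join(triad)}\n")
        self._register(dest)

        threshold = min(self.params.cooccupancy_gene_threshold, len(peaksets) - 1)
        coreg = coregulated_gene_set(peaksets, genes, threshold, self.params, network=trn)
        dest = self.out / "coregulated_genes.txt"
        dest.write_text("".join(f"{g}\n" for g in sorted(coreg)))
        self._register(dest)
        logger.info(
            "network: %d edges, %d autoregulators, %d coregulated genes (> %d TFs)",
            len(trn.edges), len(circuitry.autoregulators), len(coreg), threshold,
        )

    def stage_expression_analysis(self):
        p = self.params
        if "expression_a" in self.inputs and "expression_b" in self.inputs:
            counts_file = self.out / "enhancer_counts.tsv"
            if not counts_file.exists():
                raise ConfigurationError(
                    "stage 'expression_analysis': enhancer_counts.tsv missing "
                    "(run feature_annotation first)"
                )
            counts = dict(
                pd.read_csv(counts_file, sep="\t").itertuples(index=False, name=None)
            )
            a = read_expression_table(self._digest_input(self.inputs["expression_a"]))
            b = read_expression_table(self._digest_input(self.inputs["expression_b"]))
            ma = moving_average_enhancer_counts(a, b, counts, p.ma_window, p.pseudocount)
            dest = self.out / "moving_average.tsv"
            ma.to_csv(dest, sep="\t", index=False)
            self._register(dest)

        if "timecourse" in self.inputs:
            tc = read_expression_table(self._digest_input(self.inputs["timecourse"]))
            classing = classify_timecourse(
                tc, p.n_classes, p.pseudocount, p.timecourse_metric
            )
            dest = self.out / "timecourse_classes.tsv"
            with open(dest, "w") as fh:
                fh.write("gene\tclass\n")
                for g in tc.index:
                    fh.write(f"{g}\t{classing.class_of[g]}\n")
            self._register(dest)
            dest = self.out / "relative_timecourse.tsv"
            write_expression_table(relative_timecourse(tc), dest)
            self._register(dest)

        if "case_control" in self.inputs:
            specs = self.inputs["case_control"]
            datasets = [
                CaseControlDataset(
                    s["name"],
                    read_expression_table(self._digest_input(s["expression"])),
                    list(s["case_samples"]),
                    list(s["control_samples"]),
                )
                for s in specs
            ]
            se_genes = self._resolve_se_genes()
            orthologs = (
                read_ortholog_map(self._digest_input(self.inputs["orthologs"]))
                if "orthologs" in self.inputs
                else None
            )
            result = crossdataset_dysregulated(
                datasets, se_genes, orthologs, p.extreme_fraction,
                p.min_dataset_hits, p.pseudocount,
            )
            dest = self.out / "dysregulated.tsv"
            result.to_csv(dest, sep="\t")
            self._register(dest)
            logger.info("expression_analysis: %d dysregulated genes", len(result))

    def _resolve_se_genes(self) -> set[str]:
        if "se_genes" in self.inputs:
            return set(Path(self.inputs["se_genes"]).read_text().split())
        se_file = self.out / "se_genes.tsv"
        if se_file.exists():
            genes: set[str] = set()
            for line in se_file.read_text().splitlines()[1:]:
                genes |= set(line.split("\t")[3].split(","))
            return genes - {""}
        raise ConfigurationError(
            "stage 'expression_analysis': no SE-associated gene set "
            "(provide inputs.se_genes or run se_calling first)"
        )

    def stage_signal_profiling(self):
        if "reads" not in self.inputs:
            return
        p = self.params
        read_sets = {
            s["name"]: read_read_placements(self._digest_input(s["path"]))
            for s in self.inputs["reads"]
        }
        centers = [(pk.chrom, pk.center) for pk in self._load_se_peaks()]
        scores: dict[str, dict[str, float]] = {}
        for name, reads in read_sets.items():
            profile = profile_around_centers(reads, centers, p)
            dest = self.out / f"profile_{name}.tsv"
            profile.to_frame().to_csv(dest, sep="\t", index=False)
            self._register(dest)
            se_file = self.out / "stitched_regions.tsv"
            if se_file.exists():
                df = pd.read_csv(se_file, sep="\t")
                scores[name] = {
                    f"{r.chrom}:{r.start}-{r.end}": region_occupancy_score(
                        reads, GenomicInterval(r.chrom, int(r.start), int(r.end))
                    )
                    for r in df[df["is_SE"] == 1].itertuples()
                }
        if len(scores) >= 2:
            names = sorted(scores)
            a, b = names[0], names[1]
            dest = self.out / "relative_occupancy.tsv"
            with open(dest, "w") as fh:
                fh.write(f"region\tscore_{a}\tscore_{b}\tlog2_ratio\n")
                for region in sorted(scores[a]):
                    sa, sb = scores[a][region], scores[b][region]
                    fh.write(
                        f"{region}\t{sa:.6g}\t{sb:.6g}\t"
                        f"{relative_occupancy(sa, sb, p.pseudocount):.6g}\n"
                    )
            self._register(dest)


def run_pipeline(config_path: str | Path, stages: list[str] | None = None) -> RunManifest:
    """Execute the selected stages in dependency order and write a manifest.

    ``stages=None`` runs everything.  Missing inputs for a selected stage
    fail fast with the stage name; a stage exception is recorded in the
    manifest before propagating.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    out_dir = Path(cfg.get("out_dir", config_path.parent / "results"))
    selected = list(stages) if stages else list(STAGES)
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    selected = [s for s in STAGES if s in selected]

    run = _Run(cfg, out_dir)
    # fail fast on missing inputs before any stage executes
    requirements = {
        "io": ["se_peaks"],
        "se_calling": ["se_peaks", "refflat"],
        "feature_annotation": ["se_peaks", "refflat"],
        "cooccupancy": ["tf_peaks"],
        "network": ["tf_peaks", "refflat", "tf_gene_map"],
        "expression_analysis": [],
        "signal_profiling": ["se_peaks"],
    }
    for stage in selected:
        for key in requirements[stage]:
            run._need(key, stage)
    if "expression_analysis" in selected and not (
        {"expression_a", "timecourse", "case_control"} & set(run.inputs)
    ):
        raise ConfigurationError(
            "stage 'expression_analysis': no expression inputs configured"
        )

    for stage in selected:
        t0 = time.perf_counter()
        try:
            getattr(run, f"stage_{stage}")()
        except Exception:
            run.manifest.failed_stage = stage
            run.manifest.write(out_dir / "manifest.json")
            raise
        run.manifest.stage_timings[stage] = round(time.perf_counter() - t0, 4)
    run.manifest.write(out_dir / "manifest.json")
    return run.manifest


# ---------------------------------------------------------------------------
# demo
# ---------------------------------------------------------------------------

def demo(seed: int, out_dir: str | Path, scale: float = 1.0) -> RunManifest:
    """Generate the synthetic fixture suite, run all stages, score recovery.

    ``scale`` shrinks the landscape/expression sizes for quick smoke runs
    (1.0 = the standing study conditions).  Writes ``recovery_report.json``
    with planted-SE recall/exactness, time-course class accuracy, and
    dysregulation precision/recall; two runs with the same seed produce
    byte-identical stage outputs.
    """
    from .synthetic import (
        SyntheticLandscapeSpec,
        generate_annotation,
        generate_case_control_datasets,
        generate_condition_pair,
        generate_enhancer_landscape,
        generate_read_placements,
        generate_tf_peaksets,
        generate_timecourse_expression,
    )

    out_dir = Path(out_dir)
    fixtures = out_dir / "fixtures"
    fixtures.mkdir(parents=True, exist_ok=True)
    results = out_dir / "results"

    n = lambda x: max(int(round(x * scale)), 1)
    spec = SyntheticLandscapeSpec(
        n_genes=n(200), n_typical=n(200), n_se_clusters=max(n(10), 3), seed=seed
    )
    genes = generate_annotation(spec)
    write_refflat(genes, fixtures / "genes.refflat")
    landscape, land_truth = generate_enhancer_landscape(spec, genes)
    write_peaks(landscape, fixtures / "p300_TSC.bed")

    # TF peak sets anchored inside the planted SEs plus a shared background
    anchors = []
    for iv in land_truth.planted_se_intervals:
        third = len(iv) // 3
        anchors += [(iv.chrom, iv.start + third), (iv.chrom, iv.start + 2 * third)]
    n_factors = 27
    tf_sets, tf_truth = generate_tf_peaksets(
        n_factors=n_factors,
        shared_sites=len(anchors),
        cooccupancy_rate=0.85,
        private_sites_per_factor=n(40),
        seed=seed + 1,
        anchors=anchors,
    )
    tf_specs = []
    for ps in tf_sets:
        path = fixtures / f"{ps.factor}.bed"
        write_peaks(ps, path)
        tf_specs.append({"path": str(path), "factor": ps.factor, "cell_state": "TSC"})
    tf_map_path = fixtures / "tf_gene_map.tsv"
    with open(tf_map_path, "w") as fh:
        fh.write("factor\tgene\n")
        for i, ps in enumerate(tf_sets):
            fh.write(f"{ps.factor}\t{genes[i].symbol}\n")

    # expression fixtures
    from .annotation import map_enhancers_to_genes as _map_counts

    params = PipelineConfig(rng_seed=seed)
    counts = _map_counts(landscape, genes, params)
    expr_a, expr_b = generate_condition_pair(counts, seed=seed + 2)
    write_expression_table(expr_a, fixtures / "expr_TSC.tsv")
    write_expression_table(expr_b, fixtures / "expr_ESC.tsv")

    tc, tc_truth = generate_timecourse_expression(
        n_genes_per_class=n(50), n_timepoints=7, noise_sd=0.1, seed=seed + 3
    )
    write_expression_table(tc, fixtures / "timecourse.tsv")

    cc_sets, cc_truth = generate_case_control_datasets(
        n_datasets=5, n_genes=n(1000), n_planted_up=n(20), n_planted_down=n(20),
        effect_log2fc=2.0, noise_sd=0.2, seed=seed + 4,
    )
    cc_specs = []
    for ds in cc_sets:
        path = fixtures / f"{ds.name}.tsv"
        write_expression_table(ds.expression, path)
        cc_specs.append(
            {
                "name": ds.name,
                "expression": str(path),
                "case_samples": ds.case_samples,
                "control_samples": ds.control_samples,
            }
        )
    # the screen is restricted to SE-associated orthologs; in the demo the
    # planted dysregulated genes play that role (identity orthology)
    se_gene_file = fixtures / "screen_genes.txt"
    se_gene_file.write_text(
        "".join(f"{g}\n" for g in sorted(cc_truth.dysregulated_genes))
    )

    # read placements: dense over SE constituent centers in "TSC", sparse in "dTSC"
    se_centers = [
        (iv.chrom, (iv.start + iv.end) // 2) for iv in land_truth.planted_se_intervals
    ]
    span = ("chr1", 0, spec.chrom_length)
    reads_a = generate_read_placements(se_centers, n(2000), 800.0, seed + 5, n(20000), span)
    reads_b = generate_read_placements(se_centers, n(500), 800.0, seed + 6, n(20000), span)
    for name, df in (("TSC", reads_a), ("dTSC", reads_b)):
        path = fixtures / f"reads_{name}.bed"
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.position}\t{row.position + 1}\n")

    cfg = {
        "out_dir": str(results),
        "params": {"rng_seed": seed, "ma_window": min(100, max(n(200) // 2, 2))},
        "inputs": {
            "se_peaks": {"path": str(fixtures / "p300_TSC.bed"), "factor": "p300", "cell_state": "TSC"},
            "refflat": str(fixtures / "genes.refflat"),
            "tf_peaks": tf_specs,
            "tf_gene_map": str(tf_map_path),
            "expression_a": str(fixtures / "expr_TSC.tsv"),
            "expression_b": str(fixtures / "expr_ESC.tsv"),
            "timecourse": str(fixtures / "timecourse.tsv"),
            "case_control": cc_specs,
            "se_genes": str(se_gene_file),
            "reads": [
                {"name": "TSC", "path": str(fixtures / "reads_TSC.bed")},
                {"name": "dTSC", "path": str(fixtures / "reads_dTSC.bed")},
            ],
        },
    }
    config_path = out_dir / "demo_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    manifest = run_pipeline(config_path)
    report = _score_recovery(results, land_truth, tc_truth, cc_truth)
    report_path = out_dir / "recovery_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.outputs[str(report_path)] = _sha256(report_path)
    manifest.write(results / "manifest.json")
    return manifest


def _score_recovery(results: Path, land_truth, tc_truth, cc_truth) -> dict:
    df = pd.read_csv(results / "stitched_regions.tsv", sep="\t")
    called = {
        (r.chrom, int(r.start), int(r.end))
        for r in df[df["is_SE"] == 1].itertuples()
    }
    planted = {
        (iv.chrom, iv.start, iv.end) for iv in land_truth.planted_se_intervals
    }
    recall = len(called & planted) / len(planted) if planted else float("nan")

    classes = pd.read_csv(results / "timecourse_classes.tsv", sep="\t")
    acc = float(
        np.mean([tc_truth.class_labels[g] == c for g, c in classes.itertuples(index=False)])
    )

    dys = pd.read_csv(results / "dysregulated.tsv", sep="\t").set_index("gene")
    truth_dir = cc_truth.dysregulated_genes
    tp = sum(
        1 for g, row in dys.iterrows()
        if truth_dir.get(g) == row["direction"]
    )
    precision = tp / len(dys) if len(dys) else float("nan")
    d_recall = tp / len(truth_dir) if truth_dir else float("nan")

    tf_counts = pd.read_csv(results / "se_tf_counts.tsv", sep="\t")
    frac_gt8 = float((tf_counts["n_factors"] > 8).mean()) if len(tf_counts) else float("nan")

    return {
        "n_superenhancers_called": int(len(called)),
        "planted_se_recall": recall,
        "planted_se_exact": bool(called == planted),
        "timecourse_class_accuracy": acc,
        "dysregulation_precision": precision,
        "dysregulation_recall": d_recall,
        "fraction_se_cooccupied_gt8_tfs": frac_gt8,
    }
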