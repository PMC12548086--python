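"""End-to-end orchestration: simulate -> call -> annotate -> integrate ->
intersect -> rhythm, driven by a single YAML-serialisable config.

Each stage reads its inputs from, and writes its outputs to, the run
directory, so stages can be re-run individually and a full run is just
the fixed stage sequence. Everything is deterministic under the master
seed; the run summary (JSON) collects per-assay call counts, pair
tallies, intersection results and rhythm comparisons, plus sha256
checksums of every artifact.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann_mod
from . import diffcall, integrate, intersect, io, rhythm
from .simulate import SimulationConfig, make_genome, simulate_omics, simulate_rhythm_series

log = logging.getLogger("cistrans")

STAGES = ("simulate", "call", "integrate", "intersect", "rhythm")


@dataclass
class RunConfig:
    """Validated pipeline parameters; every default is echoed on write."""

    seed: int = 0
    outdir: str = "runs/demo"
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    # differential calling
    bin_bp: int = 100
    min_cov: int = 10
    delta_min: float = 0.10
    merge_gap: int = 100
    alpha: float = 0.05
    # annotation
    promoter_bp: int = 2_000
    max_target_distance: float = 1_000_000.0
    bin_edges: tuple[float, ...] = ann_mod.DEFAULT_BIN_EDGES
    # integration
    n_components: int | None = 1
    n_permutations: int = 200
    pair_alpha: float = 0.05
    # rhythm
    period: float = 24.0
    group_labels: tuple[str, str] = ("FA", "PM")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = {
            "bin_bp": self.bin_bp > 0,
            "min_cov": self.min_cov >= 0,
            "delta_min": 0 <= self.delta_min <= 1,
            "merge_gap": self.merge_gap >= 0,
            "alpha": 0 < self.alpha < 1,
            "promoter_bp": self.promoter_bp > 0,
            "n_permutations": self.n_permutations >= 50,
            "pair_alpha": 0 < self.pair_alpha <= 1,
            "period": self.period > 0,
            "bin_edges": all(b > a for a, b in zip(self.bin_edges, self.bin_edges[1:])),
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid RunConfig field(s): {', '.join(bad)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulate"] = self.simulate.to_dict()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "simulate" in d and not isinstance(d["simulate"], SimulationConfig):
            d["simulate"] = SimulationConfig.from_dict(d["simulate"] or {})
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.read_yaml(path) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    """Generate the genome, the three assays, truth and the rhythm series."""
    sim = config.simulate
    annotation = make_genome(sim, seed=config.seed)
    meth, atac, rna, truth = simulate_omics(annotation, sim, seed=config.seed)
    series, rhythm_truth = simulate_rhythm_series(sim, seed=config.seed)
    data = outdir / "data"
    io.write_annotation(annotation, data / "annotation")
    io.write_methylation_coverage(meth, data / "methylation")
    meth.samples.to_csv(data / "methylation_samples.tsv", sep="\t", index=False)
    io.write_count_table(atac, data / "atac_counts.tsv", data / "atac_regions.tsv")
    atac.samples.to_csv(data / "atac_samples.tsv", sep="\t", index=False)
    io.write_count_table(rna, data / "rna_counts.tsv")
    rna.samples.to_csv(data / "rna_samples.tsv", sep="\t", index=False)
    io.write_table(truth.dmrs, data / "truth_dmrs.tsv")
    io.write_table(truth.dars, data / "truth_dars.tsv")
    io.write_table(truth.degs, data / "truth_degs.tsv")
    io.write_table(truth.couplings, data / "truth_couplings.tsv")
    io.write_table(series, data / "rhythm_series.tsv")
    io.write_table(rhythm_truth, data / "rhythm_truth.tsv")
    log.info("simulate: %d genes, %d CpG sites, %d peaks", len(annotation.genes),
             len(meth.sites), len(atac.counts))


def _load_data(config: RunConfig, outdir: Path):
    data = outdir / "data"
    annotation = io.read_annotation(data / "annotation")
    meth_sheet = pd.read_csv(data / "methylation_samples.tsv", sep="\t")
    paths = {s: data / "methylation" / f"{s}.cov.tsv" for s in meth_sheet["sample_id"]}
    meth = io.read_methylation_coverage(paths, meth_sheet)
    atac_sheet = pd.read_csv(data / "atac_samples.tsv", sep="\t")
    atac = io.read_count_table(data / "atac_counts.tsv", atac_sheet, data / "atac_regions.tsv")
    rna_sheet = pd.read_csv(data / "rna_samples.tsv", sep="\t")
    rna = io.read_count_table(data / "rna_counts.tsv", rna_sheet)
    return annotation, meth, atac, rna


def stage_call(config: RunConfig, outdir: Path) -> None:
    """Differential calling plus annotation and curation for both region assays."""
    annotation, meth, atac, rna = _load_data(config, outdir)
    g = config.group_labels
    binned = diffcall.bin_methylation(meth, bin_bp=config.bin_bp, min_cov=config.min_cov)
    dmrs = diffcall.call_dmrs(
        binned, group_labels=g, alpha=config.alpha,
        delta_min=config.delta_min, merge_gap=config.merge_gap,
    )
    dars = diffcall.call_dars(atac, group_labels=g, alpha=config.alpha)
    degs = diffcall.call_degs(rna, group_labels=g, alpha=config.alpha)
    calls = outdir / "calls"
    for name, tab in (("dmrs", dmrs), ("dars", dars)):
        annotated = ann_mod.annotate_regions(
            tab, annotation, promoter_bp=config.promoter_bp,
            max_target_distance=config.max_target_distance, bin_edges=config.bin_edges,
        )
        curated = diffcall.curate_annotated(annotated)
        io.write_regions(annotated, calls / name)
        io.write_table(curated, calls / f"{name}_curated.tsv")
        log.info("call: %d %s (%d curated)", len(tab), name.upper(), len(curated))
    io.write_table(degs, calls / "degs.tsv")
    log.info("call: %d DEGs", len(degs))


def _integration_inputs(config, outdir, which, annotation, meth, atac, rna):
    calls = outdir / "calls"
    regions = io.read_table(calls / f"{which}_curated.tsv")
    degs = io.read_table(calls / "degs.tsv")
    omics = meth if which == "dmrs" else atac
    shared = integrate.shared_samples(omics.samples, rna.samples)
    X = integrate.region_signal_matrix(regions, omics, samples=shared)
    Y = integrate.gene_signal_matrix(degs, rna, samples=shared)
    return regions, degs, X, Y


def stage_integrate(config: RunConfig, outdir: Path) -> None:
    """Correlation + PLS pairing for DMR-DEG and DAR-DEG."""
    annotation, meth, atac, rna = _load_data(config, outdir)
    pairs_dir = outdir / "pairs"
    for which in ("dmrs", "dars"):
        regions, degs, X, Y = _integration_inputs(
            config, outdir, which, annotation, meth, atac, rna
        )
        if X.shape[1] == 0 or Y.shape[1] == 0:
            io.write_table(
                pd.DataFrame(columns=integrate.PAIR_COLUMNS),
                pairs_dir / f"{which[:-1]}_deg_pairs.tsv",
            )
            continue
        beta = integrate.fit_mpls(X, Y, K=config.n_components)
        thresholds = integrate.permutation_thresholds(
            X, Y, alpha=config.pair_alpha, B=config.n_permutations,
            seed=config.seed, K=config.n_components,
        )
        pairs = integrate.classify_pairs(
            X, Y, beta, thresholds, annotation, regions, degs,
            promoter_bp=config.promoter_bp,
        )
        io.write_table(pairs, pairs_dir / f"{which[:-1]}_deg_pairs.tsv")
        io.write_json(
            {
                "thresholds": thresholds.__dict__,
                "tallies": integrate.pair_category_tallies(pairs),
            },
            pairs_dir / f"{which[:-1]}_deg_tallies.json",
        )
        log.info(
            "integrate %s: %d significant of %d pairs (r*=%.3f, beta*=%.3f)",
            which, int(pairs["significant"].sum()) if len(pairs) else 0, len(pairs),
            thresholds.r_star, thresholds.beta_star,
        )


def stage_intersect(config: RunConfig, outdir: Path) -> None:
    """Venn intersection, direction-dependence chi-square, binned overlap tests."""
    calls, pairs_dir = outdir / "calls", outdir / "pairs"
    dmr_cur = io.read_table(calls / "dmrs_curated.tsv")
    dar_cur = io.read_table(calls / "dars_curated.tsv")
    degs = io.read_table(calls / "degs.tsv")
    venn = intersect.venn_genes(
        dmr_cur["target_gene"].dropna(), dar_cur["target_gene"].dropna(), degs["gene_id"]
    )
    results: dict = {"venn_cells": venn.cells, "triple_genes": venn.triple}
    labels = ann_mod.distance_bin_labels(config.bin_edges)
    for which in ("dmr", "dar"):
        path = pairs_dir / f"{which}_deg_pairs.tsv"
        pairs = io.read_table(path) if path.exists() else pd.DataFrame()
        key = f"{which}_deg"
        if not len(pairs):
            results[key] = {"n_pairs": 0}
            continue
        try:
            dep = intersect.dependence_chi2(pairs, proximal_bp=config.promoter_bp)
            results[key] = {
                "n_pairs": int(pairs["significant"].sum()),
                "chi2": dep.chi2,
                "df": dep.df,
                "p": dep.p,
                "odds_ratio": dep.odds_ratio,
                "table": dep.table.to_numpy().tolist(),
            }
        except ValueError as err:
            results[key] = {"n_pairs": int(pairs["significant"].sum()), "chi2_error": str(err)}
        # overlap of the PLS pairing with a nearest-gene distance predictor
        finite = pairs[np.isfinite(pairs["tss_distance"])].copy()
        finite["bin"] = [
            labels[ann_mod.distance_bin(d, config.bin_edges)] for d in finite["tss_distance"]
        ]
        pred_a = set(
            zip(finite.loc[finite["significant"], "region_id"],
                finite.loc[finite["significant"], "gene_id"])
        )
        cur = dmr_cur if which == "dmr" else dar_cur
        nearest = set(zip(cur["region_id"], cur["nearest_gene"].astype(str)))
        pred_b = set(zip(finite["region_id"], finite["gene_id"])) & nearest
        overlap = intersect.binned_overlap_test(pred_a, pred_b, finite)
        results[f"{key}_overlap"] = overlap.to_dict(orient="records")
    io.write_json(results, outdir / "intersect" / "results.json")
    log.info("intersect: triple genes = %s", venn.triple)


def stage_rhythm(config: RunConfig, outdir: Path) -> None:
    series = io.read_timeseries(outdir / "data" / "rhythm_series.tsv", period=config.period)
    fits = rhythm.fit_rhythms(series, period=config.period)
    comparison = rhythm.compare_cosinor(series, config.group_labels, period=config.period)
    io.write_table(fits, outdir / "rhythm" / "cosinor_fits.tsv")
    io.write_table(comparison, outdir / "rhythm" / "cosinor_comparison.tsv")
    log.info("rhythm: %d genes compared", len(comparison))


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run all stages in order and write the machine-readable summary."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_yaml(config.to_dict(), outdir / "config.yaml")
    for stage in STAGES:
        log.info("stage: %s", stage)
        globals()[f"stage_{stage}"](config, outdir)
    summary = build_summary(config, outdir)
    io.write_json(summary, outdir / "summary.json")
    return summary


def build_summary(config: RunConfig, outdir: Path) -> dict:
    outdir = Path(outdir)
    calls = outdir / "calls"
    summary: dict = {"seed": config.seed}
    for name, path, status_col in (
        ("dmrs", calls / "dmrs.tsv", "status"),
        ("dars", calls / "dars.tsv", "status"),
        ("degs", calls / "degs.tsv", "status"),
    ):
        tab = io.read_table(path) if path.exists() else pd.DataFrame()
        entry = {"n": len(tab)}
        if len(tab) and status_col in tab.columns:
            entry.update(tab[status_col].value_counts().to_dict())
        summary[name] = entry
    for which in ("dmr", "dar"):
        path = outdir / "pairs" / f"{which}_deg_tallies.json"
        if path.exists():
            import json

            summary[f"{which}_deg_pairs"] = json.loads(path.read_text())
    inter = outdir / "intersect" / "results.json"
    if inter.exists():
        import json

        summary["intersect"] = json.loads(inter.read_text())
    comp_path = outdir / "rhythm" / "cosinor_comparison.tsv"
    if comp_path.exists():
        comp = io.read_table(comp_path)
        summary["rhythm"] = {
            "n_genes": len(comp),
            "mesor_sig": int((comp["q_mesor"] < config.alpha).sum()),
            "amplitude_sig": int((comp["q_amplitude"] < config.alpha).sum()),
            "acrophase_sig": int((comp["q_acrophase"] < config.alpha).sum()),
        }
    checksums = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "summary.json":
            checksums[str(path.relative_to(outdir))] = _sha256(path)
    summary["checksums"] = checksums
    return summary
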