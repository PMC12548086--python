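"""Readers and writers for the tabular formats the pipeline touches.

Methylation comes in the Bismark coverage dialect: six tab-separated
columns (chrom, start, end, percent methylated, count methylated, count
unmethylated), one file per sample, no header. Counts are plain TSV
tables with the feature id in the first column and one column per
sample. Counts are authoritative everywhere: percent columns are
recomputed from counts and discrepancies above 0.5 percentage points are
reported as warnings. Gzip is handled transparently by file extension.
All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .annotate import GenomeAnnotation

COVERAGE_COLUMNS = ["chrom", "start", "end", "pct_meth", "count_meth", "count_unmeth"]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class MethylSiteMatrix:
    """Site-level methylation counts across samples.

    ``sites`` holds (chrom, start, end) sorted by position; ``meth`` and
    ``total`` are sites x samples count frames sharing the row index of
    ``sites``; ``samples`` is the sample sheet (sample_id, group, ...).
    """

    sites: pd.DataFrame
    meth: pd.DataFrame
    total: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        ids = list(self.samples["sample_id"])
        if list(self.meth.columns) != ids or list(self.total.columns) != ids:
            raise ValueError("count columns do not match sample sheet order")
        if (self.meth.to_numpy() < 0).any() or (self.total.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.meth.to_numpy() > self.total.to_numpy()).any():
            raise ValueError("methylated counts exceed total coverage")
        key = self.sites[["chrom", "start"]]
        if not key.equals(key.sort_values(["chrom", "start"], ignore_index=True)):
            raise ValueError("sites are not sorted by (chrom, start)")

    @property
    def levels(self) -> pd.DataFrame:
        """Per-site methylation fraction (NaN where coverage is zero)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.meth / self.total.replace(0, np.nan)


@dataclass
class CountMatrix:
    """Nonnegative integer counts, features x samples.

    Used for both peak (accessibility) and gene (expression) counts;
    ``regions`` optionally maps peak feature ids to genomic intervals.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    regions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("count columns do not match sample sheet order")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("non-integer counts")
        if self.regions is not None and not self.regions.index.equals(self.counts.index):
            raise ValueError("regions index does not match count features")


def validate_timeseries(series: pd.DataFrame, period: float = 24.0) -> pd.DataFrame:
    """Validate a long-format time series (gene, group, zt, replicate, value)."""
    required = {"gene", "group", "zt", "replicate", "value"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"time series is missing columns: {sorted(missing)}")
    if ((series["zt"] < 0) | (series["zt"] >= period)).any():
        raise ValueError(f"ZT values must lie in [0, {period})")
    counts = series.groupby(["gene", "group", "zt"])["replicate"].nunique()
    for (gene, group), sub in counts.groupby(level=["gene", "group"]):
        if sub.nunique() != 1:
            raise ValueError(
                f"unequal replicate counts across ZT for gene {gene!r}, group {group!r}"
            )
    return series


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_methylation_coverage(
    paths: Mapping[str, str | Path], sample_sheet: pd.DataFrame
) -> MethylSiteMatrix:
    """Read Bismark-coverage files (one per sample) into a site matrix.

    Sites are the union across samples; a site absent from a sample gets
    coverage 0 there. The percent column is recomputed from the counts;
    rows off by more than 0.5 percentage points are reported in a single
    warning per file. A methylated count exceeding total coverage is a
    hard error naming the file and line.
    """
    missing = set(sample_sheet["sample_id"]) - set(paths)
    if missing:
        raise ValueError(f"no coverage path given for samples: {sorted(missing)}")
    per_sample: dict[str, pd.DataFrame] = {}
    for sample_id in sample_sheet["sample_id"]:
        path = Path(paths[sample_id])
        tab = pd.read_csv(path, sep="\t", header=None, names=COVERAGE_COLUMNS)
        if tab[["start", "end", "count_meth", "count_unmeth"]].isna().any().any():
            raise FormatError(f"{path}: missing values in coverage columns")
        total = tab["count_meth"] + tab["count_unmeth"]
        # methylated > total is equivalent to a negative unmethylated count here
        if (tab[["count_meth", "count_unmeth"]] < 0).any().any():
            line = int(np.where((tab[["count_meth", "count_unmeth"]] < 0).any(axis=1))[0][0]) + 1
            raise FormatError(f"{path}, line {line}: methylated count exceeds total coverage")
        recomputed = np.where(total > 0, 100.0 * tab["count_meth"] / total.replace(0, np.nan), 0.0)
        off = np.abs(recomputed - tab["pct_meth"].to_numpy()) > 0.5
        if off.any():
            warnings.warn(
                f"{path}: {int(off.sum())} rows with percent-methylation column off by "
                ">0.5 percentage points; counts are authoritative",
                stacklevel=2,
            )
        if not tab[["chrom", "start"]].equals(
            tab[["chrom", "start"]].sort_values(["chrom", "start"], ignore_index=True)
        ):
            warnings.warn(f"{path}: unsorted input; sorting by (chrom, start)", stacklevel=2)
            tab = tab.sort_values(["chrom", "start"], ignore_index=True)
        if tab.duplicated(["chrom", "start", "end"]).any():
            raise FormatError(f"{path}: duplicate site rows")
        tab = tab.assign(total=total)
        per_sample[sample_id] = tab.set_index(["chrom", "start", "end"])[["count_meth", "total"]]

    meth = pd.concat({s: t["count_meth"] for s, t in per_sample.items()}, axis=1)
    total = pd.concat({s: t["total"] for s, t in per_sample.items()}, axis=1)
    meth = meth.fillna(0).astype(int)
    total = total.fillna(0).astype(int)
    meth = meth.sort_index()
    total = total.reindex(meth.index)
    sites = meth.index.to_frame(index=False)
    order = list(sample_sheet["sample_id"])
    return MethylSiteMatrix(
        sites=sites,
        meth=meth[order].reset_index(drop=True),
        total=total[order].reset_index(drop=True),
        samples=sample_sheet.reset_index(drop=True),
    )


def read_count_table(
    path: str | Path,
    sample_sheet: pd.DataFrame,
    regions_path: str | Path | None = None,
) -> CountMatrix:
    """Read a TSV count table (header row; first column = feature id)."""
    path = Path(path)
    tab = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(sample_sheet["sample_id"]) - set(tab.columns)
    if missing:
        raise FormatError(f"{path}: samples in sheet missing from table: {sorted(missing)}")
    if tab.index.duplicated().any():
        dup = tab.index[tab.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    tab = tab[list(sample_sheet["sample_id"])]
    vals = tab.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.allclose(vals, np.round(vals)):
        raise FormatError(f"{path}: non-integer count values")
    regions = None
    if regions_path is not None:
        regions = pd.read_csv(regions_path, sep="\t", index_col=0)
        regions = regions.reindex(tab.index)
        if regions[["chrom", "start", "end"]].isna().any().any():
            raise FormatError(f"{regions_path}: missing region coordinates for some features")
        regions["start"] = regions["start"].astype(int)
        regions["end"] = regions["end"].astype(int)
    return CountMatrix(
        counts=tab.astype(int), samples=sample_sheet.reset_index(drop=True), regions=regions
    )


def read_timeseries(path: str | Path, period: float = 24.0) -> pd.DataFrame:
    return validate_timeseries(pd.read_csv(path, sep="\t"), period=period)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_methylation_coverage(m: MethylSiteMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write one Bismark-coverage file per sample; returns sample -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample_id in m.samples["sample_id"]:
        meth = m.meth[sample_id].to_numpy()
        total = m.total[sample_id].to_numpy()
        keep = total > 0  # a site unobserved in this sample has no row
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(total > 0, 100.0 * meth / np.where(total > 0, total, 1), 0.0)
        tab = pd.DataFrame(
            {
                "chrom": m.sites["chrom"][keep],
                "start": m.sites["start"][keep],
                "end": m.sites["end"][keep],
                "pct_meth": np.round(pct[keep], 6),
                "count_meth": meth[keep],
                "count_unmeth": (total - meth)[keep],
            }
        )
        path = outdir / f"{sample_id}.cov.tsv"
        tab.to_csv(path, sep="\t", header=False, index=False)
        paths[sample_id] = path
    return paths


def write_count_table(cm: CountMatrix, path: str | Path, regions_path: str | Path | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cm.counts.rename_axis("feature_id").to_csv(path, sep="\t")
    if regions_path is not None and cm.regions is not None:
        cm.regions.rename_axis("feature_id").to_csv(regions_path, sep="\t")
    return path


def bed_score(q: float) -> int:
    """BED score column: min(1000, round(-10*log10 q)), clamped for q=0."""
    if not np.isfinite(q) or q <= 0:
        return 1000
    return int(min(1000, round(-10 * np.log10(q))))


def write_regions(calls: pd.DataFrame, prefix: str | Path) -> tuple[Path, Path]:
    """Write called regions as BED6 plus a TSV sidecar with all statistics."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")
    if len(calls):
        bed = pd.DataFrame(
            {
                "chrom": calls["chrom"],
                "start": calls["start"].astype(int),
                "end": calls["end"].astype(int),
                "name": calls["region_id"],
                "score": [bed_score(q) for q in calls["q"]],
                "strand": ".",
            }
        )
    else:
        bed = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    calls.to_csv(tsv_path, sep="\t", index=False)
    return bed_path, tsv_path


def write_table(tab: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tab.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray,)):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def write_yaml(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def read_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())


# ---------------------------------------------------------------------------
# Genome annotation round trip
# ---------------------------------------------------------------------------


def write_annotation(ann: GenomeAnnotation, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom_sizes.tsv",
        "genes": outdir / "genes.tsv",
        "partitions": outdir / "partitions.bed",
        "enhancers": outdir / "enhancers.bed",
    }
    pd.DataFrame(
        {"chrom": list(ann.chrom_sizes), "size": list(ann.chrom_sizes.values())}
    ).to_csv(paths["chrom_sizes"], sep="\t", index=False)
    ann.genes.to_csv(paths["genes"], sep="\t", index=False)
    part = ann.partitions
    pd.DataFrame(
        {
            "chrom": part["chrom"],
            "start": part["start"],
            "end": part["end"],
            "name": part["label"],
            "score": 0,
            "strand": ".",
        }
    ).to_csv(paths["partitions"], sep="\t", header=False, index=False)
    enh = ann.enhancers
    pd.DataFrame(
        {
            "chrom": enh["chrom"],
            "start": enh["start"],
            "end": enh["end"],
            "name": enh["target"],
            "score": 0,
            "strand": ".",
        }
    ).to_csv(paths["enhancers"], sep="\t", header=False, index=False)
    return paths


def read_annotation(outdir: str | Path) -> GenomeAnnotation:
    outdir = Path(outdir)
    sizes_tab = pd.read_csv(outdir / "chrom_sizes.tsv", sep="\t")
    chrom_sizes = dict(zip(sizes_tab["chrom"], sizes_tab["size"].astype(int)))
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")
    bed_names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        part = pd.read_csv(outdir / "partitions.bed", sep="\t", header=None, names=bed_names)
    except pd.errors.EmptyDataError:
        part = pd.DataFrame(columns=bed_names)
    try:
        enh = pd.read_csv(outdir / "enhancers.bed", sep="\t", header=None, names=bed_names)
    except pd.errors.EmptyDataError:
        enh = pd.DataFrame(columns=bed_names)
    partitions = part.rename(columns={"name": "label"})[["chrom", "start", "end", "label"]]
    enhancers = enh.rename(columns={"name": "target"})[["chrom", "start", "end", "target"]]
    return GenomeAnnotation(
        chrom_sizes=chrom_sizes, genes=genes, partitions=partitions, enhancers=enhancers
    )
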