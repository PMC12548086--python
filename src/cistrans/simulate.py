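"""Synthetic genomes and two-group multi-omics datasets with planted truth.

The generator emulates a two-group exposure design (filtered air "FA"
versus particulate exposure "PM"): a small annotated genome, site-level
bisulfite counts, accessibility peak counts, gene expression counts and
a 6-timepoint circadian expression series. Effects are planted only in
the PM group and recorded in a :class:`TruthTable` so every downstream
stage can be scored against ground truth.

Count models
------------
* Methylation: per-CpG coverage is 1 + Poisson(mean-1); methylated reads
  are Binomial(coverage, beta) with beta logit-shifted inside planted
  regions (PM samples only).
* Accessibility / expression: negative binomial with a log-link group
  effect and per-sample library factors.
* Region-gene couplings: a per-animal latent Gaussian factor is added
  (with the planted sign) to both the region's logit-methylation (or
  log-counts) and the gene's log-expression, inducing the sample-wise
  correlation that the pairing stage measures. The same animals underlie
  all assays, so the latent factor is shared across them.

One RNG stream per assay is derived from the master seed by fixed
offsets, so changing one assay's parameters never perturbs the others.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotate import GenomeAnnotation
from .io import CountMatrix, MethylSiteMatrix, validate_timeseries

# Fixed sub-stream offsets from the master seed.
_STREAM_GENOME = 0
_STREAM_METH = 1
_STREAM_ATAC = 2
_STREAM_RNA = 3
_STREAM_RHYTHM = 4
_STREAM_TRUTH = 5


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the emulated design as defaults."""

    # genome layout
    n_chroms: int = 2
    n_genes: int = 400
    gene_spacing: int = 10_000
    gene_length_range: tuple[int, int] = (2_000, 5_000)
    enhancer_fraction: float = 0.15
    enhancer_distance_range: tuple[int, int] = (20_000, 80_000)
    # samples (two groups; epigenome assays n=3/group, transcriptome n=4/group)
    groups: tuple[str, str] = ("FA", "PM")
    n_meth_per_group: int = 3
    n_atac_per_group: int = 3
    n_rna_per_group: int = 4
    # methylome
    cpg_spacing: int = 25
    coverage_mean: float = 30.0
    beta0: float = 0.5
    bin_logit_sd: float = 0.5
    bin_bp: int = 100
    n_dmrs: int = 100
    dmr_delta: float = 0.3
    dmr_width: int = 200
    # accessibility / expression counts
    n_peaks: int = 2_000
    peak_width: int = 500
    count_mu: float = 200.0
    count_mu_sdlog: float = 1.0
    nb_dispersion: float = 0.05
    library_sdlog: float = 0.1
    n_dars: int = 100
    dar_lfc: float = 1.5
    n_degs: int = 200
    deg_lfc: float = 1.5
    # region-gene couplings (latent-factor model)
    n_cis_meth: int = 30
    n_trans_meth: int = 30
    n_cis_atac: int = 30
    n_trans_atac: int = 30
    cis_meth_sign: int | None = -1  # promoter methylation is repressive by default
    cis_atac_sign: int | None = +1  # promoter accessibility is activating by default
    coupling_kappa_meth: float = 0.25  # logit units per latent SD
    coupling_kappa_count: float = 0.35  # log2 units per latent SD
    # circadian series
    n_rhythm_genes: int = 12
    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_rhythm_reps: int = 3
    mesor: float = 10.0
    amplitude: float = 3.0
    acrophase: float = 8.0
    period: float = 24.0
    rhythm_noise_sd: float = 0.5
    rhythm_dmesor: float = -2.0
    rhythm_damp: float = -1.0
    rhythm_dphase: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_chroms < 1 or self.n_genes < 1:
            raise ValueError("need at least one chromosome and one gene")
        if not (0.0 < self.beta0 < 1.0):
            raise ValueError("beta0 must lie in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("negative-binomial dispersion must be > 0")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        for name in ("bin_logit_sd", "library_sdlog", "rhythm_noise_sd", "count_mu_sdlog"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if self.bin_bp <= 0 or self.cpg_spacing <= 0:
            raise ValueError("bin_bp and cpg_spacing must be positive")
        if self.gene_length_range[1] + 4_000 > self.gene_spacing:
            raise ValueError("gene_spacing too small for gene_length_range plus flanks")
        if not (0 < self.beta0 + abs(self.dmr_delta) < 1) and self.n_dmrs:
            raise ValueError("beta0 + |dmr_delta| must stay inside (0, 1)")
        n_coupled = self.n_cis_meth + self.n_trans_meth + self.n_cis_atac + self.n_trans_atac
        if n_coupled > self.n_degs:
            raise ValueError("more couplings requested than planted DEGs to carry them")
        if self.n_cis_meth + self.n_trans_meth > self.n_dmrs:
            raise ValueError("more methylation couplings than planted DMRs")
        if self.n_cis_atac + self.n_trans_atac > self.n_dars:
            raise ValueError("more accessibility couplings than planted DARs")
        if self.n_degs > self.n_genes:
            raise ValueError("more planted DEGs than genes")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulate config keys: {sorted(unknown)}")
        d = dict(d)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class TruthTable:
    """What was planted: effect tables plus region-gene couplings.

    ``couplings`` columns: assay (meth|atac), chrom, start, end, feature_id
    (peak id or empty for methylation windows), gene_id, type (cis|trans),
    sign (+1/-1, the planted correlation sign).
    """

    dmrs: pd.DataFrame
    dars: pd.DataFrame
    degs: pd.DataFrame
    couplings: pd.DataFrame

    def validate(self, annotation: GenomeAnnotation, promoter_bp: int = 2_000) -> None:
        genes = annotation.genes.set_index("gene_id")
        for row in self.couplings.itertuples(index=False):
            tss = int(genes.loc[row.gene_id, "tss"])
            mid = (int(row.start) + int(row.end)) // 2
            inside = genes.loc[row.gene_id, "chrom"] == row.chrom and abs(mid - tss) < promoter_bp
            if row.type == "cis" and not inside:
                raise ValueError(f"cis coupling {row} lies outside the promoter window")
            if row.type == "trans" and inside:
                raise ValueError(f"trans coupling {row} lies inside the promoter window")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def make_genome(config: SimulationConfig, seed: int | None = None) -> GenomeAnnotation:
    """Build a deterministic annotated genome from the config.

    Genes occupy regular slots of ``gene_spacing`` bp with >=2 kb flanks;
    each gene gets a TSS window (+-100 bp), a promoter (+-1 kb minus the
    TSS window), alternating exons/introns, a 300-bp 3'UTR at the distal
    end, and intergenic space sprinkled with LINE/SINE/LTR repeats.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_GENOME])
    per_chrom = math.ceil(config.n_genes / config.n_chroms)
    chrom_size = per_chrom * config.gene_spacing + config.gene_spacing
    chrom_sizes = {f"chr{i + 1}": chrom_size for i in range(config.n_chroms)}

    genes, partitions, enhancers = [], [], []
    lo, hi = config.gene_length_range
    gid = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        for slot in range(per_chrom):
            if gid >= config.n_genes:
                break
            slot_start = slot * config.gene_spacing
            length = int(rng.integers(lo, hi + 1))
            margin_max = config.gene_spacing - length - 2_000
            start = slot_start + int(rng.integers(2_000, margin_max + 1))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            gene_id = f"G{gid + 1:04d}"
            genes.append((gene_id, chrom, strand, tss, start, end))
            partitions.extend(_gene_partitions(chrom, start, end, strand, tss))
            # repeats in the downstream intergenic stretch of the slot
            gap_lo, gap_hi = end + 1_200, slot_start + config.gene_spacing - 200
            if rng.random() < 0.7 and gap_hi - gap_lo > 900:
                w = int(rng.integers(300, 801))
                s = int(rng.integers(gap_lo, gap_hi - w))
                label = rng.choice(["LINE", "SINE", "LTR"], p=[0.5, 0.25, 0.25])
                partitions.append((chrom, s, s + w, str(label)))
            gid += 1

    gene_tab = pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "tss", "start", "end"])
    # distal enhancers for a subset of genes
    n_enh = int(round(config.enhancer_fraction * len(gene_tab)))
    if n_enh:
        chosen = rng.choice(len(gene_tab), size=n_enh, replace=False)
        d_lo, d_hi = config.enhancer_distance_range
        for row in gene_tab.iloc[np.sort(chosen)].itertuples(index=False):
            dist = int(rng.integers(d_lo, d_hi + 1)) * (1 if rng.random() < 0.5 else -1)
            s = int(np.clip(row.tss + dist - 250, 0, chrom_sizes[row.chrom] - 500))
            enhancers.append((row.chrom, s, s + 500, row.gene_id))

    return GenomeAnnotation(
        chrom_sizes=chrom_sizes,
        genes=gene_tab,
        partitions=pd.DataFrame(partitions, columns=["chrom", "start", "end", "label"]),
        enhancers=pd.DataFrame(enhancers, columns=["chrom", "start", "end", "target"]),
    )


def _gene_partitions(chrom, start, end, strand, tss):
    """TSS/Promoter windows plus exon/intron/3UTR tiling of the gene body."""
    out = [
        (chrom, tss - 100, tss + 100, "TSS"),
        (chrom, tss - 1_000, tss - 100, "Promoter"),
        (chrom, tss + 100, tss + 1_000, "Promoter"),
    ]
    # tile the body from the TSS-proximal end in transcription order
    utr = 300
    if strand == "+":
        body_lo, body_hi, utr_lo, utr_hi = start, end - utr, end - utr, end
    else:
        body_lo, body_hi, utr_lo, utr_hi = start + utr, end, start, start + utr
    out.append((chrom, utr_lo, utr_hi, "3UTR"))
    lengths = [200, 800]  # exon, intron alternation
    labels = ["Exon", "Intron"]
    i = 0
    remaining = body_hi - body_lo
    cursor = body_lo if strand == "+" else body_hi
    while remaining > 0:
        w = min(lengths[i % 2], remaining)
        if strand == "+":
            out.append((chrom, cursor, cursor + w, labels[i % 2]))
            cursor += w
        else:
            out.append((chrom, cursor - w, cursor, labels[i % 2]))
            cursor -= w
        remaining -= w
        i += 1
    return out


# ---------------------------------------------------------------------------
# Omics simulation
# ---------------------------------------------------------------------------


def _sample_sheet(groups, n_per_group) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{g}_{i + 1}", "group": g} for g in groups for i in range(n_per_group)
    ]
    return pd.DataFrame(rows)


def _overlaps(a, intervals) -> bool:
    return any(not (a[2] <= s or e <= a[1]) for (c, s, e) in intervals if c == a[0])


def simulate_omics(
    annotation: GenomeAnnotation, config: SimulationConfig, seed: int | None = None
) -> tuple[MethylSiteMatrix, CountMatrix, CountMatrix, TruthTable]:
    """Simulate the three assays plus the planted-truth table."""
    seed = config.seed if seed is None else seed
    rng_truth = np.random.default_rng([seed, _STREAM_TRUTH])
    g1, g2 = config.groups
    n_animals = max(config.n_meth_per_group, config.n_atac_per_group, config.n_rna_per_group)
    animals = [f"{g}_{i + 1}" for g in config.groups for i in range(n_animals)]
    pm_animal = np.array([a.startswith(g2) for a in animals])

    genes = annotation.genes
    gene_order = rng_truth.permutation(len(genes))
    deg_rows = gene_order[: config.n_degs]
    deg_ids = genes["gene_id"].to_numpy()[deg_rows]

    # coupling gene assignment: disjoint slices of the planted DEGs
    n_cm, n_tm = config.n_cis_meth, config.n_trans_meth
    n_ca, n_ta = config.n_cis_atac, config.n_trans_atac
    cis_meth_genes = deg_ids[:n_cm]
    trans_meth_genes = deg_ids[n_cm : n_cm + n_tm]
    cis_atac_genes = deg_ids[n_cm + n_tm : n_cm + n_tm + n_ca]
    trans_atac_genes = deg_ids[n_cm + n_tm + n_ca : n_cm + n_tm + n_ca + n_ta]

    gene_by_id = genes.set_index("gene_id")
    enh_intervals = [
        (r.chrom, int(r.start), int(r.end)) for r in annotation.enhancers.itertuples(index=False)
    ]
    used: list[tuple[str, int, int]] = []

    def place_distal(width: int) -> tuple[str, int, int]:
        """A window >2 kb (plus slack) from every TSS, avoiding enhancers."""
        tss_by_chrom = {c: pos for c, (pos, _) in annotation.tss_index().items()}
        chroms = list(annotation.chrom_sizes)
        for _ in range(10_000):
            chrom = chroms[int(rng_truth.integers(len(chroms)))]
            size = annotation.chrom_sizes[chrom]
            start = int(rng_truth.integers(0, size - width))
            mid = start + width // 2
            pos = tss_by_chrom.get(chrom, np.array([]))
            if len(pos) and np.min(np.abs(pos - mid)) <= 2_000 + width:
                continue
            cand = (chrom, start, start + width)
            if _overlaps(cand, enh_intervals) or _overlaps(cand, used):
                continue
            used.append(cand)
            return cand
        raise ValueError("could not place a distal region; genome too crowded")

    def promoter_region(gene_id: str, width: int) -> tuple[str, int, int]:
        g = gene_by_id.loc[gene_id]
        region = (g["chrom"], int(g["tss"]) - width // 2, int(g["tss"]) + width - width // 2)
        used.append(region)
        return region

    # --- planted methylation regions -----------------------------------------
    couplings = []
    dmr_rows = []
    s_fixed = config.cis_meth_sign

    def coupling_signs(sign_fixed):
        s = int(sign_fixed) if sign_fixed is not None else (1 if rng_truth.random() < 0.5 else -1)
        u_region = 1 if rng_truth.random() < 0.5 else -1
        return s, u_region, s * u_region

    for gid in cis_meth_genes:
        region = promoter_region(gid, config.dmr_width)
        s, u_r, u_g = coupling_signs(s_fixed)
        dmr_rows.append((*region, u_r * abs(config.dmr_delta), u_r, len(couplings)))
        couplings.append(("meth", *region, "", gid, "cis", s, u_r, u_g))
    for gid in trans_meth_genes:
        region = place_distal(config.dmr_width)
        s, u_r, u_g = coupling_signs(None)
        dmr_rows.append((*region, u_r * abs(config.dmr_delta), u_r, len(couplings)))
        couplings.append(("meth", *region, "", gid, "trans", s, u_r, u_g))
    n_plain_dmrs = config.n_dmrs - len(dmr_rows)
    chroms = list(annotation.chrom_sizes)
    for _ in range(n_plain_dmrs):
        for _try in range(10_000):
            chrom = chroms[int(rng_truth.integers(len(chroms)))]
            size = annotation.chrom_sizes[chrom]
            start = int(rng_truth.integers(0, (size - config.dmr_width) // config.bin_bp))
            start *= config.bin_bp
            cand = (chrom, start, start + config.dmr_width)
            if not _overlaps(cand, used):
                used.append(cand)
                break
        else:
            raise ValueError("requested planted-region count exceeds available windows")
        direction = 1 if rng_truth.random() < 0.5 else -1
        dmr_rows.append((*cand, direction * abs(config.dmr_delta), direction, -1))
    truth_dmrs = pd.DataFrame(
        dmr_rows, columns=["chrom", "start", "end", "delta", "direction", "coupling"]
    )

    # --- peak set and planted accessibility ----------------------------------
    peak_rows = []
    for row in genes.itertuples(index=False):
        s = int(row.tss) - config.peak_width // 2
        peak_rows.append((row.chrom, s, s + config.peak_width, row.gene_id))
    n_distal_peaks = max(0, config.n_peaks - len(peak_rows))
    for _ in range(n_distal_peaks):
        region = place_distal(config.peak_width)
        peak_rows.append((*region, ""))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "promoter_of"])
    peaks.index = [f"peak_{c}_{s}" for c, s in zip(peaks["chrom"], peaks["start"])]

    promoter_peak = {g: i for i, g in enumerate(peaks["promoter_of"]) if g}
    distal_peak_idx = [i for i, g in enumerate(peaks["promoter_of"]) if not g]
    rng_truth.shuffle(distal_peak_idx)
    dar_rows = []
    s_fixed_a = config.cis_atac_sign
    for gid in cis_atac_genes:
        pi = promoter_peak[gid]
        s, u_r, u_g = coupling_signs(s_fixed_a)
        dar_rows.append((pi, u_r * abs(config.dar_lfc), u_r, len(couplings)))
        couplings.append(
            ("atac", *peaks.iloc[pi][["chrom", "start", "end"]], peaks.index[pi], gid, "cis", s, u_r, u_g)
        )
    if len(trans_atac_genes) > len(distal_peak_idx):
        raise ValueError("not enough distal peaks for the requested trans couplings")
    for k, gid in enumerate(trans_atac_genes):
        pi = distal_peak_idx[k]
        s, u_r, u_g = coupling_signs(None)
        dar_rows.append((pi, u_r * abs(config.dar_lfc), u_r, len(couplings)))
        couplings.append(
            ("atac", *peaks.iloc[pi][["chrom", "start", "end"]], peaks.index[pi], gid, "trans", s, u_r, u_g)
        )
    taken = {pi for pi, *_ in dar_rows}
    free = [i for i in range(len(peaks)) if i not in taken]
    rng_truth.shuffle(free)
    n_plain_dars = config.n_dars - len(dar_rows)
    if n_plain_dars > len(free):
        raise ValueError("requested planted-region count exceeds available peaks")
    for pi in free[:n_plain_dars]:
        direction = 1 if rng_truth.random() < 0.5 else -1
        dar_rows.append((pi, direction * abs(config.dar_lfc), direction, -1))
    truth_dars = pd.DataFrame(dar_rows, columns=["peak_idx", "lfc", "direction", "coupling"])
    truth_dars["feature_id"] = peaks.index.to_numpy()[truth_dars["peak_idx"]]

    couplings_tab = pd.DataFrame(
        couplings,
        columns=["assay", "chrom", "start", "end", "feature_id", "gene_id", "type", "sign", "u_region", "u_gene"],
    )

    # --- planted DEG directions ----------------------------------------------
    deg_dir = {}
    for gid in deg_ids:
        deg_dir[gid] = 1 if rng_truth.random() < 0.5 else -1
    for row in couplings_tab.itertuples(index=False):
        deg_dir[row.gene_id] = int(row.u_gene)  # aligned with the coupling
    truth_degs = pd.DataFrame(
        {
            "gene_id": deg_ids,
            "lfc": [deg_dir[g] * abs(config.deg_lfc) for g in deg_ids],
        }
    )

    # latent factors, one per coupling, per animal
    z = rng_truth.standard_normal((len(couplings_tab), len(animals)))

    meth = _simulate_methylome(annotation, config, seed, truth_dmrs, couplings_tab, z, animals, pm_animal)
    atac = _simulate_counts(
        peaks, config, [seed, _STREAM_ATAC], truth_dars, couplings_tab, z, animals, pm_animal,
        n_per_group=config.n_atac_per_group, assay="atac",
    )
    rna = _simulate_rna(genes, config, seed, truth_degs, couplings_tab, z, animals, pm_animal)

    truth = TruthTable(
        dmrs=truth_dmrs.drop(columns=["coupling"]),
        dars=truth_dars[["feature_id", "lfc", "direction"]],
        degs=truth_degs,
        couplings=couplings_tab[
            ["assay", "chrom", "start", "end", "feature_id", "gene_id", "type", "sign"]
        ],
    )
    return meth, atac, rna, truth


def _assay_samples(animals, pm_animal, n_per_group, groups):
    """First n animals of each group, preserving FA-then-PM order."""
    fa = [a for a, pm in zip(animals, pm_animal) if not pm][:n_per_group]
    pm = [a for a, pm in zip(animals, pm_animal) if pm][:n_per_group]
    ids = fa + pm
    sheet = pd.DataFrame(
        {"sample_id": ids, "group": [groups[0]] * len(fa) + [groups[1]] * len(pm)}
    )
    cols = [animals.index(a) for a in ids]
    return sheet, np.array(cols)


def _simulate_methylome(annotation, config, seed, truth_dmrs, couplings, z, animals, pm_animal):
    rng = np.random.default_rng([seed, _STREAM_METH])
    sheet, cols = _assay_samples(animals, pm_animal, config.n_meth_per_group, config.groups)
    pm = pm_animal[cols]

    site_chrom, site_start = [], []
    for chrom, size in annotation.chrom_sizes.items():
        pos = np.arange(config.cpg_spacing // 2, size, config.cpg_spacing)
        site_chrom.append(np.full(len(pos), chrom, dtype=object))
        site_start.append(pos)
    chrom_arr = np.concatenate(site_chrom)
    start_arr = np.concatenate(site_start).astype(int)
    n_sites, n_samp = len(start_arr), len(sheet)

    # per-bin baseline heterogeneity on the logit scale (shared across samples)
    bin_key = pd.factorize(
        pd.Series(chrom_arr).astype(str) + ":" + (start_arr // config.bin_bp).astype(str)
    )[0]
    n_bins = bin_key.max() + 1
    base_logit = logit(config.beta0) + config.bin_logit_sd * rng.standard_normal(n_bins)
    logits = np.repeat(base_logit[bin_key][:, None], n_samp, axis=1)

    site_index = {c: np.flatnonzero(chrom_arr == c) for c in annotation.chrom_sizes}

    def sites_in(chrom, start, end):
        idx = site_index[chrom]
        sub = start_arr[idx]
        return idx[(sub >= start) & (sub < end)]

    shift = logit(config.beta0 + config.dmr_delta) - logit(config.beta0)
    for row in truth_dmrs.itertuples(index=False):
        sel = sites_in(row.chrom, row.start, row.end)
        logits[np.ix_(sel, np.flatnonzero(pm))] += row.direction * abs(shift)
        if row.coupling >= 0:
            kappa = config.coupling_kappa_meth * couplings.iloc[row.coupling]["u_region"]
            logits[sel, :] += kappa * z[row.coupling, cols][None, :]

    coverage = 1 + rng.poisson(config.coverage_mean - 1.0, size=(n_sites, n_samp))
    meth_counts = rng.binomial(coverage, expit(logits))

    sites = pd.DataFrame(
        {"chrom": chrom_arr, "start": start_arr, "end": start_arr + 1}
    ).sort_values(["chrom", "start"], ignore_index=True)
    order = (
        pd.DataFrame({"chrom": chrom_arr, "start": start_arr})
        .sort_values(["chrom", "start"])
        .index.to_numpy()
    )
    ids = list(sheet["sample_id"])
    return MethylSiteMatrix(
        sites=sites,
        meth=pd.DataFrame(meth_counts[order], columns=ids),
        total=pd.DataFrame(coverage[order], columns=ids),
        samples=sheet,
    )


def _nb_draw(rng, mean, dispersion):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def _simulate_counts(features, config, rng_key, truth, couplings, z, animals, pm_animal,
                     n_per_group, assay):
    rng = np.random.default_rng(rng_key)
    sheet, cols = _assay_samples(animals, pm_animal, n_per_group, config.groups)
    pm = pm_animal[cols]
    n_feat, n_samp = len(features), len(sheet)
    mu = config.count_mu * np.exp(config.count_mu_sdlog * rng.standard_normal(n_feat))
    lib = np.exp(config.library_sdlog * rng.standard_normal(n_samp))
    log2_mean = np.log2(mu)[:, None] + np.log2(lib)[None, :]
    for row in truth.itertuples(index=False):
        log2_mean[row.peak_idx, pm] += row.lfc
        if row.coupling >= 0:
            kappa = config.coupling_kappa_count * couplings.iloc[row.coupling]["u_region"]
            log2_mean[row.peak_idx, :] += kappa * z[row.coupling, cols]
    counts = _nb_draw(rng, 2.0 ** log2_mean, config.nb_dispersion)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=features.index, columns=list(sheet["sample_id"])),
        samples=sheet,
        regions=features[["chrom", "start", "end"]].copy(),
    )


def _simulate_rna(genes, config, seed, truth_degs, couplings, z, animals, pm_animal):
    rng = np.random.default_rng([seed, _STREAM_RNA])
    sheet, cols = _assay_samples(animals, pm_animal, config.n_rna_per_group, config.groups)
    pm = pm_animal[cols]
    n_feat, n_samp = len(genes), len(sheet)
    mu = config.count_mu * np.exp(config.count_mu_sdlog * rng.standard_normal(n_feat))
    lib = np.exp(config.library_sdlog * rng.standard_normal(n_samp))
    log2_mean = np.log2(mu)[:, None] + np.log2(lib)[None, :]
    gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}
    for row in truth_degs.itertuples(index=False):
        log2_mean[gene_pos[row.gene_id], pm] += row.lfc
    for ci, row in enumerate(couplings.itertuples(index=False)):
        kappa = config.coupling_kappa_count * row.u_gene
        log2_mean[gene_pos[row.gene_id], :] += kappa * z[ci, cols]
    counts = _nb_draw(rng, 2.0 ** log2_mean, config.nb_dispersion)
    return CountMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(genes["gene_id"], name="feature_id"),
            columns=list(sheet["sample_id"]),
        ),
        samples=sheet,
    )


# ---------------------------------------------------------------------------
# Circadian series
# ---------------------------------------------------------------------------


def simulate_rhythm_series(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cosinor-structured expression series for both groups.

    value(g, t, rep) = M_g + A_g * cos(2*pi*(t - phi_g)/period) + noise.
    Group 2 carries the configured mesor/amplitude/acrophase deltas.
    Returns (long-format series, per-gene truth).
    """
    if config.period <= 0:
        raise ValueError("period must be > 0")
    if config.n_rhythm_reps < 1:
        raise ValueError("need at least one replicate")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, _STREAM_RHYTHM])
    rows, truth_rows = [], []
    times = np.asarray(config.timepoints, dtype=float)
    for gi in range(config.n_rhythm_genes):
        gene = f"R{gi + 1:03d}"
        for group_i, group in enumerate(config.groups):
            m = config.mesor + (config.rhythm_dmesor if group_i else 0.0)
            a = max(0.0, config.amplitude + (config.rhythm_damp if group_i else 0.0))
            phi = (config.acrophase + (config.rhythm_dphase if group_i else 0.0)) % config.period
            truth_rows.append(
                {"gene": gene, "group": group, "mesor": m, "amplitude": a, "acrophase": phi}
            )
            mean = m + a * np.cos(2 * np.pi * (times - phi) / config.period)
            for rep in range(config.n_rhythm_reps):
                noise = config.rhythm_noise_sd * rng.standard_normal(len(times))
                for t, v in zip(times, mean + noise):
                    rows.append(
                        {"gene": gene, "group": group, "zt": t, "replicate": rep + 1, "value": v}
                    )
    series = validate_timeseries(pd.DataFrame(rows), period=config.period)
    return series, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Truth-matching helpers for recovery scoring
# ---------------------------------------------------------------------------


def match_regions(called: pd.DataFrame, truth_regions: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(recovered flag per truth region, true flag per called region) by overlap."""
    recovered = np.zeros(len(truth_regions), dtype=bool)
    is_true = np.zeros(len(called), dtype=bool)
    for ti, t in enumerate(truth_regions.itertuples(index=False)):
        for ci, c in enumerate(called.itertuples(index=False)):
            if c.chrom == t.chrom and c.start < t.end and t.start < c.end:
                recovered[ti] = True
                is_true[ci] = True
    return recovered, is_true


def match_couplings(
    pairs: pd.DataFrame, truth_couplings: pd.DataFrame, assay: str
) -> pd.Series:
    """Per planted coupling: is there a significant pair with the right gene,
    an overlapping region, and the matching cis/trans (homologous/heterologous)
    label?"""
    sig = pairs[pairs["significant"]]
    want_type = {"cis": "homologous", "trans": "heterologous"}
    out = []
    for t in truth_couplings[truth_couplings["assay"] == assay].itertuples(index=False):
        sub = sig[(sig["gene_id"] == t.gene_id) & (sig["type"] == want_type[t.type])]
        hit = False
        for p in sub.itertuples(index=False):
            if p.region_chrom == t.chrom and p.region_start < t.end and t.start < p.region_end:
                hit = True
                break
        out.append(hit)
    return pd.Series(out, dtype=bool)
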