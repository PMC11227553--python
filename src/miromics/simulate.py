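"""Synthetic multi-omics cohorts with the joint structure the pipeline assumes.

The generator plants ground truth at every level the analysis touches:

* a toy genome with miRNA TSS/locus annotations and 450K-style probes placed
  in known positional categories (TSS200 / TSS2000 / body / outside) plus an
  unassigned background;
* per-sample piecewise-constant copy-number segment tracks (segment means
  ~ Normal(0, 0.3), the log2(CN/2) scale of SNP-array segmentation);
* probe-level beta-values built from a logit-normal latent promoter
  methylation signal plus probe noise, with type II probes compressed toward
  0.5 by a known monotone logistic map (so the bias-correction step has a
  checkable target);
* miRNA expression linearly coupled to copy number (positive) and promoter
  methylation (negative) with effect sizes parameterized as target Pearson
  correlations — driver classes cnv / dnam / both / null are planted by
  fraction;
* marker-gene expression coupled to latent immune-cell infiltration, plus
  nine synthetic signature gene sets allocated to T/I/S factors;
* proportional-hazards survival with hazard proportional to
  exp(log_hr * risk score) of the eight-miRNA panel, under independent
  uniform censoring.

Everything is deterministic given (config, seed); the truth object records
planted classes, targets and generative parameters for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .immune import CTL_PANEL, MHC_PANEL, GeneSet
from .risk import DEFAULT_COEFFICIENTS, DEFAULT_PANEL, RiskModel, risk_score

CELL_TYPES = ("B_cell", "CD4_T_cell", "CD8_T_cell", "Neutrophil", "Macrophage", "Dendritic")

DEFAULT_PLANTED_FRACTIONS = {"cnv": 0.10, "dnam": 0.10, "both": 0.05}
DEFAULT_EFFECT_SIZES = {"cnv": 0.5, "dnam": 0.5}


@dataclass
class AnnotationBundle:
    mirnas: pd.DataFrame  # mirna_id, chrom, tss, strand, locus_start, locus_end
    probes: pd.DataFrame  # probe_id, chrom, pos, design_type, island_relation
    probe_truth: pd.DataFrame  # probe_id, mirna_id, category (planted positional class)
    chrom_length: int


@dataclass
class SyntheticTruth:
    driver_class: pd.Series  # per miRNA: cnv / dnam / both / null
    target_r_cnv: pd.Series
    target_r_dnam: pd.Series
    infiltration: pd.DataFrame  # latent cell-type levels, cell types x samples
    risk_scores: pd.Series  # planted per-sample risk score driving the hazard
    log_hr: float
    baseline_hazard: float
    censoring_rate: float
    compression_gamma: float
    seed: int


@dataclass
class Cohort:
    annotation: AnnotationBundle
    segments: pd.DataFrame  # SEG: sample, chrom, start, end, segment_mean
    beta: pd.DataFrame  # probes x samples, with injected missing cells
    design_types: pd.Series
    cnv: pd.DataFrame  # miRNA x samples (truth-level, matches segment lookup)
    meth: pd.DataFrame  # miRNA x samples latent promoter methylation
    expression: pd.DataFrame  # miRNA x samples, log2-RPM-like
    gene_expression: pd.DataFrame  # genes x samples, linear non-negative
    gene_sets: list[GeneSet]
    allocation: dict[str, str]
    infiltration_estimates: pd.DataFrame  # cell types x samples (noisy observed)
    tide: pd.DataFrame  # score x samples
    survival: pd.DataFrame  # index sample, columns time, event
    truth: SyntheticTruth


def compress_type2(beta: np.ndarray, gamma: float) -> np.ndarray:
    """The planted type-II bias: logistic shrinkage toward 0.5 (monotone,
    invertible; gamma > 1 compresses)."""
    b = np.clip(beta, 1e-6, 1 - 1e-6)
    return expit(logit(b) / gamma)


def generate_annotation(
    n_mirnas: int,
    n_chroms: int = 5,
    mean_extra_probes: float = 4.0,
    chrom_length: int = 10_000_000,
    n_background_probes: int | None = None,
    seed: int = 0,
) -> AnnotationBundle:
    """Toy genome annotation: miRNA TSS placed uniformly, probes scattered
    across known positional zones, design types ~30% I / 70% II.

    Each promoter gets ``1 + Poisson(mean_extra_probes)`` probes; background
    probes land far from any promoter (planted category ``Background``).
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    if n_mirnas * 2501 > n_chroms * chrom_length:
        raise ValueError("infeasible density: promoters exceed total chromosome length")
    rng = np.random.default_rng(seed)
    if n_background_probes is None:
        n_background_probes = 3 * n_mirnas

    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    recs = []
    for i in range(n_mirnas):
        mirna_id = DEFAULT_PANEL[i] if i < len(DEFAULT_PANEL) else f"syn-mir-{i + 1:04d}"
        chrom = chroms[int(rng.integers(n_chroms))]
        tss = int(rng.integers(5000, chrom_length - 5000))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            locus_start = tss + int(rng.integers(20, 120))
            locus_end = locus_start + 21
        else:
            locus_end = tss - int(rng.integers(20, 120))
            locus_start = locus_end - 21
        recs.append((mirna_id, chrom, tss, strand, locus_start, locus_end))
    mirnas = pd.DataFrame(
        recs, columns=["mirna_id", "chrom", "tss", "strand", "locus_start", "locus_end"]
    )

    probe_rows = []
    truth_rows = []
    zones = ("TSS200", "TSS2000", "Body", "Outside")
    zone_probs = (0.35, 0.35, 0.20, 0.10)
    counter = 0

    def _new_probe(chrom, pos, category, mirna_id=None):
        nonlocal counter
        counter += 1
        pid = f"cg{counter:08d}"
        design = "I" if rng.random() < 0.30 else "II"
        island = ("Island", "N_Shore", "S_Shore", "OpenSea")[
            int(rng.choice(4, p=[0.3, 0.25, 0.15, 0.3]))
        ]
        probe_rows.append((pid, chrom, max(int(pos), 1), design, island))
        truth_rows.append((pid, mirna_id, category))

    for rec in mirnas.itertuples(index=False):
        n_probes = 1 + int(rng.poisson(mean_extra_probes))
        sign = 1 if rec.strand == "+" else -1
        for _ in range(n_probes):
            zone = zones[int(rng.choice(4, p=zone_probs))]
            if zone == "TSS200":
                d = int(rng.integers(1, 201))
                pos = rec.tss - sign * d
            elif zone == "TSS2000":
                d = int(rng.integers(201, 2001))
                pos = rec.tss - sign * d
            elif zone == "Body":
                pos = int(rng.integers(rec.locus_start, rec.locus_end + 1))
            else:  # downstream of TSS, inside the promoter but outside the locus
                pos = rec.tss + sign * int(rng.integers(1, 15))
            _new_probe(rec.chrom, pos, zone, rec.mirna_id)

    for _ in range(n_background_probes):
        chrom = chroms[int(rng.integers(n_chroms))]
        pos = int(rng.integers(1, chrom_length))
        _new_probe(chrom, pos, "Background")

    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos", "design_type", "island_relation"]
    )
    probe_truth = pd.DataFrame(truth_rows, columns=["probe_id", "mirna_id", "category"])
    return AnnotationBundle(mirnas, probes, probe_truth, chrom_length)


def _segment_tracks(
    rng: np.random.Generator,
    samples: list[str],
    chroms: list[str],
    chrom_length: int,
    mean_breaks: float = 5.0,
    segment_sd: float = 0.3,
) -> pd.DataFrame:
    rows = []
    for sample in samples:
        for chrom in chroms:
            n_breaks = int(rng.poisson(mean_breaks))
            cuts = np.sort(rng.integers(2, chrom_length, size=n_breaks))
            bounds = np.concatenate([[0], cuts, [chrom_length]])
            # 1-based inclusive, disjoint: (prev+1 .. cut)
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b <= a:
                    continue
                rows.append((sample, chrom, int(a) + 1, int(b), float(rng.normal(0.0, segment_sd))))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "segment_mean"])


def _lookup_segment_means(
    segments: pd.DataFrame, mirnas: pd.DataFrame, samples: list[str]
) -> pd.DataFrame:
    """Fast truth-level CNV assignment: segment mean at each locus midpoint."""
    mids = ((mirnas["locus_start"] + mirnas["locus_end"]) // 2).to_numpy()
    out = np.full((len(mirnas), len(samples)), np.nan)
    grouped = {k: v for k, v in segments.groupby(["sample", "chrom"])}
    for j, sample in enumerate(samples):
        for chrom, idx in mirnas.groupby("chrom").groups.items():
            sub = grouped.get((sample, chrom))
            if sub is None:
                continue
            starts = sub["start"].to_numpy()
            means = sub["segment_mean"].to_numpy()
            ends = sub["end"].to_numpy()
            pos = mids[mirnas.index.get_indexer(idx)]
            k = np.searchsorted(starts, pos, side="right") - 1
            ok = (k >= 0) & (pos <= ends[np.clip(k, 0, len(ends) - 1)])
            vals = np.where(ok, means[np.clip(k, 0, len(means) - 1)], np.nan)
            out[mirnas.index.get_indexer(idx), j] = vals
    return pd.DataFrame(out, index=mirnas["mirna_id"].to_numpy(), columns=samples)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_cohort(
    n_samples: int = 200,
    n_mirnas: int = 500,
    planted_fractions: dict[str, float] | None = None,
    effect_sizes: dict[str, float] | None = None,
    probe_noise_sd: float = 0.05,
    compression_gamma: float = 1.8,
    missing_rate: float = 0.02,
    high_missing_probe_fraction: float = 0.02,
    log_hr: float = 1.0,
    baseline_hazard: float = np.log(2) / 730.0,
    censoring_rate: float = 0.30,
    n_chroms: int = 5,
    seed: int = 0,
) -> Cohort:
    """Generate a full synthetic cohort plus ground truth.

    Defaults mirror a reduced-scale glioma-like study: a few hundred samples,
    ~10% of miRNAs CNV-driven and ~10% DNAm-driven at target |r| = 0.5, 5%
    driven by both, median survival around two years (hazard in 1/days) with
    ~30% censoring.
    """
    if n_samples < 30:
        raise ValueError("n_samples must be >= 30")
    planted_fractions = dict(DEFAULT_PLANTED_FRACTIONS if planted_fractions is None else planted_fractions)
    effect_sizes = dict(DEFAULT_EFFECT_SIZES if effect_sizes is None else effect_sizes)
    if sum(planted_fractions.values()) > 1:
        raise ValueError("planted class fractions must sum to <= 1")
    r_c = float(effect_sizes["cnv"])
    r_d = float(effect_sizes["dnam"])
    if not (0 < r_c < 1 and 0 < r_d < 1):
        raise ValueError("target correlations must lie in (0, 1)")
    if r_c**2 + r_d**2 >= 1:
        bound = float(np.sqrt(1 - r_c**2))
        raise ValueError(
            f"unachievable joint targets: with r_cnv={r_c} the feasible |r_dnam| bound is {bound:.3f}"
        )

    if n_mirnas < len(DEFAULT_PANEL):
        raise ValueError(f"n_mirnas must be >= {len(DEFAULT_PANEL)} (the risk panel size)")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(6)
    rng_cnv, rng_meth, rng_expr, rng_imm, rng_surv = (
        np.random.default_rng(s) for s in children[1:]
    )

    ann = generate_annotation(n_mirnas, n_chroms=n_chroms, seed=children[0])
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    mirna_ids = ann.mirnas["mirna_id"].tolist()
    chroms = sorted(ann.mirnas["chrom"].unique())

    # --- copy number -------------------------------------------------------
    segments = _segment_tracks(rng_cnv, samples, chroms, ann.chrom_length)
    cnv = _lookup_segment_means(segments, ann.mirnas, samples)

    # --- driver classes ----------------------------------------------------
    classes = np.array(["null"] * n_mirnas, dtype=object)
    order = rng_expr.permutation(n_mirnas)
    k = 0
    for cls in ("cnv", "dnam", "both"):
        n_cls = int(round(planted_fractions.get(cls, 0.0) * n_mirnas))
        classes[order[k : k + n_cls]] = cls
        k += n_cls
    driver_class = pd.Series(classes, index=mirna_ids, name="driver_class")

    # --- latent promoter methylation and probe betas -----------------------
    # bimodal per-miRNA baseline, unmethylated-heavy as promoter CpGs are
    low = rng_meth.random(n_mirnas) < 0.6
    mu = np.where(
        low, rng_meth.normal(-2.2, 0.5, n_mirnas), rng_meth.normal(1.8, 0.5, n_mirnas)
    )
    M_logit = mu[:, None] + rng_meth.normal(0.0, 0.8, size=(n_mirnas, n_samples))
    M = expit(M_logit)
    meth = pd.DataFrame(M, index=mirna_ids, columns=samples)

    promoter_probes = ann.probe_truth.dropna(subset=["mirna_id"])
    probe_ids = ann.probes["probe_id"].tolist()
    probe_to_mirna = dict(zip(promoter_probes["probe_id"], promoter_probes["mirna_id"]))
    mirna_pos = {m: i for i, m in enumerate(mirna_ids)}
    beta_vals = np.empty((len(probe_ids), n_samples))
    for i, pid in enumerate(probe_ids):
        mid = probe_to_mirna.get(pid)
        if mid is None:  # background probe: its own latent level, same landscape
            center = rng_meth.normal(-2.2, 0.5) if rng_meth.random() < 0.6 else rng_meth.normal(1.8, 0.5)
            base = expit(center + rng_meth.normal(0.0, 0.5, n_samples))
        else:
            base = M[mirna_pos[mid]]
        beta_vals[i] = np.clip(base + rng_meth.normal(0.0, probe_noise_sd, n_samples), 0.0, 1.0)
    design = ann.probes.set_index("probe_id")["design_type"]
    is_two = (design == "II").to_numpy()
    beta_vals[is_two] = compress_type2(beta_vals[is_two], compression_gamma)

    # missing cells: a base rate everywhere plus a few high-missingness probes
    miss = rng_meth.random(beta_vals.shape) < missing_rate
    n_high = int(round(high_missing_probe_fraction * len(probe_ids)))
    if n_high:
        high_idx = rng_meth.choice(len(probe_ids), size=n_high, replace=False)
        miss[high_idx] |= rng_meth.random((n_high, n_samples)) < 0.5
    beta_vals = np.where(miss, np.nan, beta_vals)
    beta = pd.DataFrame(beta_vals, index=probe_ids, columns=samples)

    # --- expression coupled to CNV (+) and methylation (-) -----------------
    N = cnv.to_numpy()
    Y = np.empty((n_mirnas, n_samples))
    tgt_c = pd.Series(0.0, index=mirna_ids)
    tgt_d = pd.Series(0.0, index=mirna_ids)
    for i, mid in enumerate(mirna_ids):
        eps = rng_expr.normal(0.0, 1.0, n_samples)
        cls = driver_class.iloc[i]
        if cls == "cnv":
            Y[i] = r_c * _standardize(N[i]) + np.sqrt(1 - r_c**2) * eps
            tgt_c[mid] = r_c
        elif cls == "dnam":
            Y[i] = -r_d * _standardize(M[i]) + np.sqrt(1 - r_d**2) * eps
            tgt_d[mid] = -r_d
        elif cls == "both":
            Y[i] = (
                r_c * _standardize(N[i])
                - r_d * _standardize(M[i])
                + np.sqrt(1 - r_c**2 - r_d**2) * eps
            )
            tgt_c[mid], tgt_d[mid] = r_c, -r_d
        else:
            Y[i] = eps
    expression = pd.DataFrame(5.0 + 1.5 * Y, index=mirna_ids, columns=samples)

    # --- immune layer ------------------------------------------------------
    infiltration = pd.DataFrame(
        rng_imm.normal(0.0, 1.0, size=(len(CELL_TYPES), n_samples)),
        index=list(CELL_TYPES),
        columns=samples,
    )
    infiltration_estimates = infiltration + rng_imm.normal(0.0, 0.3, infiltration.shape)

    t_lat = rng_imm.normal(0.0, 1.0, n_samples)
    i_lat = infiltration.loc[["CD8_T_cell", "B_cell", "Dendritic"]].mean(axis=0).to_numpy()
    s_lat = rng_imm.normal(0.0, 1.0, n_samples)

    gene_rows: dict[str, np.ndarray] = {}

    def _marker(latent: np.ndarray, loading: float = 0.8, scale: float = 0.4) -> np.ndarray:
        return np.exp(1.0 + loading * latent + rng_imm.normal(0.0, scale, n_samples))

    for g in dict.fromkeys(("GZMA", "PRF1") + CTL_PANEL):
        gene_rows[g] = _marker(infiltration.loc["CD8_T_cell"].to_numpy())
    for g in MHC_PANEL:
        gene_rows[g] = _marker(infiltration.loc["Dendritic"].to_numpy())

    allocation: dict[str, str] = {}
    gene_sets: list[GeneSet] = []
    factor_latents = {"T": t_lat, "I": i_lat, "S": s_lat}
    set_plan = [("T", 2), ("I", 3), ("S", 4)]
    for factor, n_sets in set_plan:
        for s_i in range(n_sets):
            name = f"SYN_{factor}_SET_{s_i + 1}"
            members = []
            for g_i in range(10):
                gname = f"{name}_G{g_i + 1}"
                gene_rows[gname] = _marker(factor_latents[factor], loading=0.6, scale=0.6)
                members.append(gname)
            gene_sets.append(GeneSet(name, frozenset(members), factor))
            allocation[name] = factor
    for g_i in range(30):
        gene_rows[f"FILLER_G{g_i + 1}"] = np.exp(rng_imm.normal(1.0, 0.8, n_samples))
    gene_expression = pd.DataFrame(gene_rows, index=samples).T
    gene_expression.index.name = "gene"

    # --- TIDE-like evasion score, weakly coupled to one panel miRNA --------
    mir10b = _standardize(expression.loc["hsa-miR-10b-5p"].to_numpy())
    tide_vals = 0.6 * s_lat - 0.3 * i_lat + 0.3 * mir10b + rng_imm.normal(0.0, 0.5, n_samples)
    tide = pd.DataFrame([tide_vals], index=pd.Index(["TIDE"], name="score"), columns=samples)

    # --- survival tied to the eight-miRNA risk score -----------------------
    model = RiskModel()
    scores = risk_score(expression, model)
    lin = log_hr * (scores - scores.mean()).to_numpy()
    hazard = baseline_hazard * np.exp(lin)
    t_event = rng_surv.exponential(1.0 / hazard)
    mean_h = float(hazard.mean())

    def _cens_gap(u):  # expected censoring fraction under U(0, u) censoring
        x = mean_h * u
        return (1 - np.exp(-x)) / x - censoring_rate

    u_max = brentq(_cens_gap, 1e-6 / mean_h, 1e4 / mean_h)
    c_time = rng_surv.uniform(0.0, u_max, n_samples)
    time = np.minimum(t_event, c_time)
    event = (t_event <= c_time).astype(int)
    time = np.maximum(time, 1e-3)
    survival = pd.DataFrame({"time": time, "event": event}, index=pd.Index(samples, name="sample"))

    truth = SyntheticTruth(
        driver_class=driver_class,
        target_r_cnv=tgt_c,
        target_r_dnam=tgt_d,
        infiltration=infiltration,
        risk_scores=scores,
        log_hr=log_hr,
        baseline_hazard=baseline_hazard,
        censoring_rate=censoring_rate,
        compression_gamma=compression_gamma,
        seed=seed,
    )
    return Cohort(
        annotation=ann,
        segments=segments,
        beta=beta,
        design_types=design,
        cnv=cnv,
        meth=meth,
        expression=expression,
        gene_expression=gene_expression,
        gene_sets=gene_sets,
        allocation=allocation,
        infiltration_estimates=infiltration_estimates,
        tide=tide,
        survival=survival,
        truth=truth,
    )


def write_fixture_bundle(cohort: Cohort, directory: str | Path, force: bool = False) -> dict[str, Path]:
    """Write the cohort in exactly the plain-text formats the pipeline reads.

    Emits SEG, BED6 (TSS), GFF3 (mature loci), manifest CSV, beta /
    expression / gene-expression / infiltration / TIDE TSV matrices, a GMT
    with the factor allocation encoded in set names, a survival TSV and a
    truth JSON.  Refuses a non-empty existing directory unless ``force``.
    """
    from . import io as mio

    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"output directory {directory} is not empty (use force=True)")
    directory.mkdir(parents=True, exist_ok=True)

    paths = {
        "seg": directory / "segments.seg",
        "tss_bed": directory / "mirna_tss.bed",
        "loci_gff3": directory / "mirna_loci.gff3",
        "manifest": directory / "probe_manifest.csv",
        "beta": directory / "beta.tsv",
        "expression": directory / "mirna_expression.tsv",
        "gene_expression": directory / "gene_expression.tsv",
        "infiltration": directory / "infiltration.tsv",
        "tide": directory / "tide.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "allocation": directory / "factor_allocation.json",
        "survival": directory / "survival.tsv",
        "truth": directory / "truth.json",
    }
    mio.write_seg(cohort.segments, paths["seg"])
    mio.write_tss_bed(cohort.annotation.mirnas, paths["tss_bed"])
    mio.write_loci_gff3(cohort.annotation.mirnas, paths["loci_gff3"])
    mio.write_manifest(cohort.annotation.probes, paths["manifest"])
    mio.write_matrix(cohort.beta, paths["beta"])
    mio.write_matrix(cohort.expression, paths["expression"])
    mio.write_matrix(cohort.gene_expression, paths["gene_expression"])
    mio.write_matrix(cohort.infiltration_estimates, paths["infiltration"])
    mio.write_matrix(cohort.tide, paths["tide"])
    mio.write_gmt(cohort.gene_sets, paths["gene_sets"])
    paths["allocation"].write_text(json.dumps(cohort.allocation, indent=1))
    mio.write_survival(cohort.survival, paths["survival"])

    truth = cohort.truth
    truth_json = {
        "seed": truth.seed,
        "driver_class": truth.driver_class.to_dict(),
        "target_r_cnv": truth.target_r_cnv.to_dict(),
        "target_r_dnam": truth.target_r_dnam.to_dict(),
        "log_hr": truth.log_hr,
        "baseline_hazard": truth.baseline_hazard,
        "censoring_rate": truth.censoring_rate,
        "compression_gamma": truth.compression_gamma,
        "risk_scores": truth.risk_scores.round(6).to_dict(),
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1))
    return paths
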