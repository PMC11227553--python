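"""Promoter interval models for miRNAs and mapping of array probes / CNV segments.

miRNAs are transcribed from their own promoters (CAGE-defined TSS), so the
promoter of a miRNA is modelled as a fixed window around its TSS: 2000 bp
upstream to 500 bp downstream, strand-aware.  450K methylation-array probes
falling inside that window are re-annotated to the miRNA, and the miRNA's
promoter methylation level is the arithmetic mean of its probes' beta-values.
Copy-number values are assigned to a miRNA from the segment that contains the
midpoint of its mature locus (mature miRNAs are ~22 nt, effectively a point).

All genomic coordinates in this package are 1-based inclusive, the convention
of GFF3 and of the 450K manifest (``MAPINFO``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

TSS_CATEGORIES = ("TSS200", "TSS2000", "Body", "Outside")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "OpenSea")
DESIGN_TYPES = ("I", "II")

DEFAULT_UPSTREAM = 2000
DEFAULT_DOWNSTREAM = 500


@dataclass(frozen=True)
class MirnaAnnotation:
    """A miRNA with its genomic locus, TSS and derived promoter interval.

    ``promoter`` is 1-based inclusive; its length is ``upstream + downstream + 1``
    unless clipped at the chromosome start.
    """

    mirna_id: str
    chrom: str
    tss: int
    strand: str
    locus_start: int
    locus_end: int
    promoter: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.mirna_id}")
        if self.locus_start > self.locus_end:
            raise ValueError(f"locus_start > locus_end for {self.mirna_id}")


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    chrom: str
    pos: int
    design_type: str
    island_relation: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"probe {self.probe_id}: position must be >= 1")
        if self.design_type not in DESIGN_TYPES:
            raise ValueError(f"probe {self.probe_id}: bad design type {self.design_type!r}")
        if self.island_relation not in ISLAND_RELATIONS:
            raise ValueError(
                f"probe {self.probe_id}: bad island relation {self.island_relation!r}"
            )


@dataclass(frozen=True)
class ProbeAssignment:
    probe_id: str
    mirna_id: str
    tss_category: str


def build_promoters(
    annotations: pd.DataFrame,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[MirnaAnnotation]:
    """Derive strand-aware promoter windows around each miRNA TSS.

    Parameters
    ----------
    annotations
        One row per miRNA with columns ``mirna_id, chrom, tss, strand,
        locus_start, locus_end``.  Records with missing TSS are dropped and
        counted; records with an unknown strand symbol are rejected with a
        warning.  Duplicate TSS records for one miRNA are deduplicated to the
        first after sorting by (chrom, tss), with a warning.
    upstream, downstream
        Promoter extent in bp on the 5' and 3' side of the TSS.

    Returns
    -------
    list of :class:`MirnaAnnotation` with the ``promoter`` field populated,
    clipped at position 1.
    """
    required = {"mirna_id", "chrom", "tss", "strand", "locus_start", "locus_end"}
    missing_cols = required - set(annotations.columns)
    if missing_cols:
        raise ValueError(f"annotation table missing columns: {sorted(missing_cols)}")

    n_missing_tss = int(annotations["tss"].isna().sum())
    if n_missing_tss:
        logger.warning("excluded %d miRNA records with missing TSS", n_missing_tss)
    ann = annotations.dropna(subset=["tss"]).copy()

    bad_strand = ~ann["strand"].isin(["+", "-"])
    if bad_strand.any():
        for rec in ann.loc[bad_strand, "mirna_id"]:
            logger.warning("rejected miRNA %s: unknown strand symbol", rec)
        ann = ann.loc[~bad_strand]

    ann = ann.sort_values(["chrom", "tss"], kind="stable")
    dups = ann.duplicated(subset="mirna_id", keep="first")
    if dups.any():
        logger.warning(
            "deduplicated %d duplicate TSS records (kept first by chrom, tss)",
            int(dups.sum()),
        )
        ann = ann.loc[~dups]

    out: list[MirnaAnnotation] = []
    for rec in ann.itertuples(index=False):
        tss = int(rec.tss)
        if rec.strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        out.append(
            MirnaAnnotation(
                mirna_id=str(rec.mirna_id),
                chrom=str(rec.chrom),
                tss=tss,
                strand=rec.strand,
                locus_start=int(rec.locus_start),
                locus_end=int(rec.locus_end),
                promoter=(max(start, 1), end),
            )
        )
    return out


def _check_chrom_style(a: set[str], b: set[str]) -> None:
    a_pref = {c.startswith("chr") for c in a}
    b_pref = {c.startswith("chr") for c in b}
    if a and b and a_pref != b_pref and not (a & b):
        raise ValueError(
            "chromosome naming mismatch between inputs (e.g. 'chr1' vs '1'); "
            "harmonize naming before mapping"
        )


def tss_category(probe_pos: int, mirna: MirnaAnnotation) -> str:
    """Strand-aware positional category of a probe relative to a miRNA TSS.

    Upstream distance in (0, 200] -> TSS200, in (200, 2000] -> TSS2000; on the
    TSS or downstream of it, probes inside the mature locus -> Body, otherwise
    Outside.  A probe exactly on the TSS counts as downstream (distance 0), so
    it never belongs to both windows.
    """
    if mirna.strand == "+":
        upstream_dist = mirna.tss - probe_pos
    else:
        upstream_dist = probe_pos - mirna.tss
    if 0 < upstream_dist <= 200:
        return "TSS200"
    if 200 < upstream_dist <= 2000:
        return "TSS2000"
    if mirna.locus_start <= probe_pos <= mirna.locus_end:
        return "Body"
    return "Outside"


def map_probes_to_promoters(
    probes: list[ProbeAnnotation] | pd.DataFrame,
    promoters: list[MirnaAnnotation],
) -> list[ProbeAssignment]:
    """Assign each probe to every miRNA promoter interval that contains it.

    A probe shared by overlapping promoters is assigned to each of them (its
    beta later contributes to each miRNA's mean).  The assignment is
    order-independent: output is sorted by (mirna_id, probe_id).
    """
    if isinstance(probes, pd.DataFrame):
        probes = [
            ProbeAnnotation(
                probe_id=str(r.probe_id),
                chrom=str(r.chrom),
                pos=int(r.pos),
                design_type=str(r.design_type),
                island_relation=str(r.island_relation),
            )
            for r in probes.itertuples(index=False)
        ]
    _check_chrom_style({p.chrom for p in probes}, {m.chrom for m in promoters})

    trees: dict[str, IntervalTree] = {}
    for m in promoters:
        start, end = m.promoter
        # IntervalTree is half-open; +1 makes the 1-based inclusive end queryable
        trees.setdefault(m.chrom, IntervalTree()).addi(start, end + 1, m)

    out: list[ProbeAssignment] = []
    for p in probes:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for iv in tree.at(p.pos):
            m: MirnaAnnotation = iv.data
            out.append(ProbeAssignment(p.probe_id, m.mirna_id, tss_category(p.pos, m)))
    out.sort(key=lambda a: (a.mirna_id, a.probe_id))
    return out


def assignments_to_frame(assignments: list[ProbeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.probe_id, a.mirna_id, a.tss_category) for a in assignments],
        columns=["probe_id", "mirna_id", "tss_category"],
    )


def summarize_promoter_methylation(
    beta: pd.DataFrame, assignments: list[ProbeAssignment]
) -> pd.DataFrame:
    """Per-miRNA promoter methylation: mean beta of assigned probes, per sample.

    Missing betas are ignored in the mean; a cell is missing only when every
    assigned probe is missing for that sample.  miRNAs with no assigned probe
    present in ``beta`` are absent from the output.
    """
    if not assignments:
        raise ValueError("no probes mapped: empty assignment")
    table = assignments_to_frame(assignments)
    present = table[table["probe_id"].isin(beta.index)]
    missing_probes = set(table["probe_id"]) - set(beta.index)
    if missing_probes:
        logger.warning(
            "%d assigned probes absent from the beta matrix", len(missing_probes)
        )
    if present.empty:
        raise ValueError("no probes mapped: no assigned probe present in beta matrix")
    stacked = beta.loc[present["probe_id"]].set_index(present["mirna_id"].values)
    result = stacked.groupby(level=0).mean()
    result.index.name = "mirna_id"
    return result


def map_cnv_to_mirnas(
    segments: pd.DataFrame, annotations: list[MirnaAnnotation]
) -> pd.DataFrame:
    """miRNA x sample copy-number matrix from segmented calls.

    The value for a miRNA in a sample is the ``segment_mean`` (log2(CN/2)) of
    the segment containing the midpoint of the mature locus; NaN when no
    segment covers it.  Segments must be non-overlapping within one sample and
    chromosome.

    ``segments`` columns: sample, chrom, start, end, segment_mean.
    """
    _check_chrom_style(set(segments["chrom"].astype(str)), {m.chrom for m in annotations})
    samples = sorted(segments["sample"].unique())
    mirnas = [m.mirna_id for m in annotations]
    mids = {m.mirna_id: (m.chrom, (m.locus_start + m.locus_end) // 2) for m in annotations}

    values = np.full((len(mirnas), len(samples)), np.nan)
    for j, sample in enumerate(samples):
        sub = segments[segments["sample"] == sample]
        trees: dict[str, IntervalTree] = {}
        for rec in sub.itertuples(index=False):
            if rec.start > rec.end:
                raise ValueError(f"segment with start > end in sample {sample}")
            tree = trees.setdefault(str(rec.chrom), IntervalTree())
            if tree.overlap(rec.start, rec.end + 1):
                raise ValueError(
                    f"overlapping segments in sample {sample}, chromosome {rec.chrom}"
                )
            tree.addi(rec.start, rec.end + 1, float(rec.segment_mean))
        for i, mid in enumerate(mirnas):
            chrom, pos = mids[mid]
            tree = trees.get(chrom)
            if tree is None:
                continue
            hits = tree.at(pos)
            if hits:
                values[i, j] = next(iter(hits)).data
    return pd.DataFrame(values, index=pd.Index(mirnas, name="mirna_id"), columns=samples)


def category_frequency_test(
    assigned: pd.Series | list[str],
    background: pd.Series | list[str],
    categories: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Chi-square goodness-of-fit of assigned category counts vs background.

    Tests whether probes assigned to miRNA promoters distribute across
    positional (or island-relation) categories the way the background probe
    universe does.  Pearson chi-square with k-1 degrees of freedom against the
    background proportions.

    Returns (counts table, statistic, p).
    """
    assigned = pd.Series(list(assigned), dtype=object)
    background = pd.Series(list(background), dtype=object)
    if categories is None:
        categories = tuple(sorted(set(background)))
    obs = assigned.value_counts().reindex(categories, fill_value=0)
    bg = background.value_counts().reindex(categories, fill_value=0)
    nonzero = int((bg > 0).sum())
    if nonzero < 2 or (obs > 0).sum() < 2:
        raise ValueError("need at least 2 non-empty categories for the frequency test")
    if ((bg == 0) & (obs > 0)).any():
        bad = obs.index[(bg == 0) & (obs > 0)].tolist()
        raise ValueError(f"assigned counts in categories absent from background: {bad}")
    keep = bg > 0
    props = bg[keep] / bg[keep].sum()
    expected = props * obs[keep].sum()
    stat, p = stats.chisquare(obs[keep].to_numpy(), expected.to_numpy())
    table = pd.DataFrame(
        {"assigned": obs, "background": bg, "expected": expected.reindex(obs.index)}
    )
    return table, float(stat), float(p)
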