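"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: TSV matrices are features x samples with the feature id in the
first column; genomic inputs are interpreted 1-based inclusive (GFF3 /
manifest ``MAPINFO``) except BED, whose half-open 0-based starts are converted
on read; chromosome names are normalized to the "chr"-prefixed style at read
time (toggle with ``chr_prefix=False``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .immune import GeneSet

logger = logging.getLogger(__name__)


def _norm_chrom(series: pd.Series, chr_prefix: bool = True) -> pd.Series:
    s = series.astype(str)
    if chr_prefix:
        return s.where(s.str.startswith("chr"), "chr" + s)
    return s.str.replace("^chr", "", regex=True)


def _nonempty(path: str | Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    return path


# --- SEG -------------------------------------------------------------------

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Segment_Mean"]


def read_seg(path: str | Path, chr_prefix: bool = True) -> pd.DataFrame:
    """Segmented copy-number calls (SEG dialect, tab-separated, headered).

    Returns columns sample, chrom, start, end, segment_mean with start <= end
    validated per line.
    """
    path = _nonempty(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: SEG header missing columns {missing}")
    df = df.rename(
        columns={
            "Sample": "sample",
            "Chromosome": "chrom",
            "Start": "start",
            "End": "end",
            "Segment_Mean": "segment_mean",
        }
    )
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start > end on data line(s) {[i + 2 for i in bad[:5]]}")
    df["chrom"] = _norm_chrom(df["chrom"], chr_prefix)
    return df[["sample", "chrom", "start", "end", "segment_mean"]]


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    out = segments.rename(
        columns={
            "sample": "Sample",
            "chrom": "Chromosome",
            "start": "Start",
            "end": "End",
            "segment_mean": "Segment_Mean",
        }
    )
    out[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


# --- BED (miRNA TSS) -------------------------------------------------------


def read_tss_bed(path: str | Path, chr_prefix: bool = True) -> pd.DataFrame:
    """BED6 of single-base miRNA TSS records -> mirna_id, chrom, tss, strand.

    BED is 0-based half-open; the 1-based TSS is ``start + 1``.
    """
    path = _nonempty(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if df["strand"].isna().any() or not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: BED6 strand column required with +/- values")
    if (df["end"] - df["start"] != 1).any():
        raise ValueError(f"{path}: TSS BED records must be single-base intervals")
    return pd.DataFrame(
        {
            "mirna_id": df["name"],
            "chrom": _norm_chrom(df["chrom"], chr_prefix),
            "tss": df["start"] + 1,
            "strand": df["strand"],
        }
    )


def write_tss_bed(mirnas: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": mirnas["chrom"],
            "start": mirnas["tss"] - 1,
            "end": mirnas["tss"],
            "name": mirnas["mirna_id"],
            "score": 0,
            "strand": mirnas["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# --- GFF3 (mature loci) ----------------------------------------------------


def read_loci_gff3(path: str | Path, chr_prefix: bool = True) -> pd.DataFrame:
    """Mature-miRNA loci from a miRBase-style GFF3 (1-based inclusive).

    Records are matched to miRNAs by the ``Name=`` attribute.
    """
    path = _nonempty(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
        ],
    )
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]][:5]
        raise ValueError(f"{path}: start > end on GFF3 record(s) {list(bad)}")
    names = df["attributes"].str.extract(r"Name=([^;]+)")[0]
    if names.isna().any():
        raise ValueError(f"{path}: GFF3 records missing a Name= attribute")
    return pd.DataFrame(
        {
            "mirna_id": names,
            "chrom": _norm_chrom(df["chrom"], chr_prefix),
            "locus_start": df["start"],
            "locus_end": df["end"],
            "strand": df["strand"],
        }
    )


def write_loci_gff3(mirnas: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in mirnas.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\tmiromics\tmiRNA\t{rec.locus_start}\t{rec.locus_end}"
                f"\t.\t{rec.strand}\t.\tID={rec.mirna_id};Name={rec.mirna_id}\n"
            )


def read_mirna_annotation(
    tss_bed: str | Path, loci_gff3: str | Path, chr_prefix: bool = True
) -> pd.DataFrame:
    """Join TSS (BED) and mature-locus (GFF3) records into one annotation table."""
    tss = read_tss_bed(tss_bed, chr_prefix)
    loci = read_loci_gff3(loci_gff3, chr_prefix)
    merged = tss.merge(
        loci[["mirna_id", "locus_start", "locus_end"]], on="mirna_id", how="inner"
    )
    dropped = set(tss["mirna_id"]) - set(merged["mirna_id"])
    if dropped:
        logger.warning("%d TSS records had no mature locus and were dropped", len(dropped))
    return merged


# --- 450K-style manifest ---------------------------------------------------

MANIFEST_COLUMNS = {"probe_id": "probe_id", "CHR": "chrom", "MAPINFO": "pos",
                    "design_type": "design_type", "island_relation": "island_relation"}


def read_manifest(path: str | Path, chr_prefix: bool = True) -> pd.DataFrame:
    """Probe manifest CSV with columns probe_id, CHR, MAPINFO, design_type,
    island_relation (MAPINFO is the 1-based probe coordinate)."""
    path = _nonempty(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    df = df.rename(columns=MANIFEST_COLUMNS)
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: MAPINFO positions must be >= 1")
    df["chrom"] = _norm_chrom(df["chrom"], chr_prefix)
    return df[list(MANIFEST_COLUMNS.values())]


def write_manifest(probes: pd.DataFrame, path: str | Path) -> None:
    out = probes.rename(columns={"chrom": "CHR", "pos": "MAPINFO"})
    out[["probe_id", "CHR", "MAPINFO", "design_type", "island_relation"]].to_csv(
        path, index=False
    )


# --- matrices --------------------------------------------------------------


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Feature x sample TSV matrix; first column is the feature id."""
    path = _nonempty(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()][:5].tolist()
        raise ValueError(f"{path}: duplicated feature ids, e.g. {dups}")
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    matrix.to_csv(path, sep="\t", float_format=float_format,
                  index_label=matrix.index.name or "feature")


# --- GMT -------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT gene sets: name <tab> description <tab> member genes...

    A description field of ``T``, ``I`` or ``S`` is picked up as the factor
    allocation of the set.
    """
    path = _nonempty(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, desc, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        allocation = desc if desc in ("T", "I", "S") else None
        sets.append(GeneSet(name, frozenset(genes), allocation))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            desc = gs.factor_allocation or "na"
            fh.write("\t".join([gs.name, desc, *sorted(gs.members)]) + "\n")


# --- survival --------------------------------------------------------------


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival TSV with columns sample, time, event -> indexed by sample."""
    path = _nonempty(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: survival table missing column {col!r}")
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: non-positive survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0 or 1")
    return df.set_index("sample")[["time", "event"]]


def write_survival(survival: pd.DataFrame, path: str | Path) -> None:
    out = survival.reset_index()
    out.columns = ["sample", "time", "event"]
    out.to_csv(path, sep="\t", index=False)
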