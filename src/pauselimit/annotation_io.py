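"""Transcription units, stranded coverage and count tables.

This module defines the genomic coordinate contract shared by every stage of
the pipeline:

* all intervals are 0-based, half-open ``[start, end)`` (GTF's 1-based closed
  convention is converted on read);
* TU-local coordinates place position 0 at the TSS and increase in the
  direction of transcription, regardless of strand — every downstream window
  (response window, pause window) is expressed TU-locally.

A transcription unit (TU) is the per-gene union of all annotated transcript
isoforms.  Length/TSS filters used by downstream estimators (>10 kbp,
>35 kbp, unique TSS, ...) are parameters of those estimators, not of the TU
builder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# interval primitives
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals, returned sorted and non-overlapping."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def intersect_interval_sets(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Base-wise intersection of two merged interval sets."""
    out: list[Interval] = []
    i = j = 0
    a = merge_intervals(a)
    b = merge_intervals(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_interval(intervals: Sequence[Interval], cut: Interval) -> list[Interval]:
    """Remove a single half-open interval from a merged interval set."""
    cs, ce = cut
    out: list[Interval] = []
    for s, e in intervals:
        if e <= cs or s >= ce:
            out.append((s, e))
            continue
        if s < cs:
            out.append((s, cs))
        if e > ce:
            out.append((ce, e))
    return out


def interval_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


# ---------------------------------------------------------------------------
# gene models and transcription units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Raw per-gene annotation: one exon list per transcript isoform."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    isoforms: tuple[tuple[Interval, ...], ...]


@dataclass
class TranscriptionUnit:
    """Union of a gene's transcript isoforms with derived windows.

    ``first_exon_end`` is the genomic coordinate at which the first exon (the
    exon containing the TSS) ends in transcription direction; use
    :meth:`first_exon_end_offset` for its TU-local equivalent.
    """

    tu_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval]
    unique_tss: bool
    nonfirst_constitutive_exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.tu_id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"{self.tu_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def first_exon(self) -> Interval:
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def first_exon_end(self) -> int:
        s, e = self.first_exon
        return e if self.strand == "+" else s

    def first_exon_end_offset(self) -> int:
        """TU-local position one past the last base of the first exon."""
        s, e = self.first_exon
        return e - s

    @property
    def first_intron_length(self) -> int:
        if len(self.exons) < 2:
            return 0
        if self.strand == "+":
            return self.exons[1][0] - self.exons[0][1]
        return self.exons[-1][0] - self.exons[-2][1]

    @property
    def nonfirst_constitutive_length(self) -> int:
        return interval_length(self.nonfirst_constitutive_exons)

    def to_local(self, genomic: int) -> int:
        """Genomic coordinate -> TU-local offset (0 at TSS, 5'->3')."""
        return genomic - self.start if self.strand == "+" else self.end - 1 - genomic

    def local_intervals(self, genomic_intervals: Sequence[Interval]) -> list[Interval]:
        """Genomic intervals -> TU-local half-open intervals, 5'->3' sorted."""
        out = []
        for s, e in genomic_intervals:
            if self.strand == "+":
                out.append((s - self.start, e - self.start))
            else:
                out.append((self.end - e, self.end - s))
        return sorted(out)


def build_tus(genes: Iterable[GeneModel]) -> list[TranscriptionUnit]:
    """One TU per gene: span/exon union of all isoforms.

    ``unique_tss`` is true iff every isoform starts at exactly the same TSS
    (exact coordinate equality; annotation fuzz is not absorbed).  The
    non-first constitutive exon set is the base-wise intersection of all
    isoforms' exons, with the first merged exon removed; it is the region
    over which initiation frequencies are integrated downstream.

    Genes without exons are rejected with a logged reason.
    """
    tus: list[TranscriptionUnit] = []
    for gene in genes:
        isoforms = [merge_intervals(iso) for iso in gene.isoforms if iso]
        if not isoforms:
            logger.warning("gene %s rejected: no exons", gene.gene_id)
            continue
        exons = merge_intervals(iv for iso in isoforms for iv in iso)
        start, end = exons[0][0], exons[-1][1]
        if gene.strand == "+":
            tss_set = {iso[0][0] for iso in isoforms}
        else:
            tss_set = {iso[-1][1] - 1 for iso in isoforms}
        constitutive = isoforms[0]
        for iso in isoforms[1:]:
            constitutive = intersect_interval_sets(constitutive, iso)
        first = exons[0] if gene.strand == "+" else exons[-1]
        tu = TranscriptionUnit(
            tu_id=gene.gene_id,
            chrom=gene.chrom,
            strand=gene.strand,
            start=start,
            end=end,
            exons=exons,
            unique_tss=len(tss_set) == 1,
            nonfirst_constitutive_exons=subtract_interval(constitutive, first),
        )
        tus.append(tu)
    return tus


# ---------------------------------------------------------------------------
# GTF input / output
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF file (exon features grouped by
    gene_id/transcript_id).  Coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    genes: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes["gene_id"][0]
        tid = exon.attributes["transcript_id"][0]
        rec = genes.setdefault(gid, {"chrom": exon.seqid, "strand": exon.strand, "tx": {}})
        rec["tx"].setdefault(tid, []).append((exon.start - 1, exon.end))
    out = []
    for gid, rec in genes.items():
        isoforms = tuple(tuple(sorted(ex)) for _, ex in sorted(rec["tx"].items()))
        out.append(GeneModel(gid, rec["chrom"], rec["strand"], isoforms))
    return out


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            span_s = min(iv[0] for iso in gene.isoforms for iv in iso)
            span_e = max(iv[1] for iso in gene.isoforms for iv in iso)
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\tpauselimit\tgene\t{span_s + 1}\t{span_e}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for k, iso in enumerate(gene.isoforms):
                tid = f"{gene.gene_id}.t{k + 1}"
                tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
                fh.write(
                    f"{gene.chrom}\tpauselimit\ttranscript\t{iso[0][0] + 1}\t{iso[-1][1]}\t.\t{gene.strand}\t.\t{tattrs}\n"
                )
                for s, e in iso:
                    fh.write(
                        f"{gene.chrom}\tpauselimit\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{tattrs}\n"
                    )


def write_tu_table(tus: Sequence[TranscriptionUnit], path: str | Path) -> None:
    rows = [
        dict(
            tu_id=t.tu_id, chrom=t.chrom, strand=t.strand, start=t.start, end=t.end,
            tss=t.tss, length=t.length, unique_tss=t.unique_tss, n_exons=len(t.exons),
        )
        for t in tus
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stranded coverage
# ---------------------------------------------------------------------------

@dataclass
class StrandedCoverage:
    """Per-base, per-strand signal for one sample.

    ``plus``/``minus`` map chromosome name to a vector whose length equals
    the declared chromosome length.  Raw loaded values are non-negative;
    antisense-corrected tracks may be clamped to 0 but never negative.
    """

    sample_id: str
    assay: str  # ttseq | mnet | dms_invivo | dms_denatured
    condition: str  # control | inhibited
    replicate: int
    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]

    def track(self, strand: str) -> dict[str, np.ndarray]:
        return self.plus if strand == "+" else self.minus


def _expand_bedgraph(df: pd.DataFrame, chrom_sizes: Mapping[str, int], path: str) -> dict[str, np.ndarray]:
    tracks = {c: np.zeros(int(n), dtype=np.float64) for c, n in chrom_sizes.items()}
    if df.empty:
        return tracks
    if (df["value"] < 0).any():
        bad = df[df["value"] < 0].iloc[0]
        raise ValueError(f"{path}: negative coverage at {bad['chrom']}:{bad['start']}")
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in tracks:
            raise ValueError(f"{path}: chromosome {chrom!r} not in chrom sizes")
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        vals = grp["value"].to_numpy(dtype=np.float64)
        if (ends <= starts).any():
            k = int(np.argmax(ends <= starts))
            raise ValueError(f"{path}: empty interval {chrom}:{starts[k]}-{ends[k]}")
        overlap = starts[1:] < ends[:-1]
        if overlap.any():
            k = int(np.argmax(overlap)) + 1
            raise ValueError(
                f"{path}: overlapping intervals at {chrom}:{starts[k]}-{ends[k]}"
            )
        n = tracks[chrom].size
        if ends[-1] > n:
            raise ValueError(f"{path}: interval beyond chromosome end on {chrom}")
        diff = np.zeros(n + 1)
        np.add.at(diff, starts, vals)
        np.add.at(diff, ends, -vals)
        tracks[chrom] = np.cumsum(diff[:-1])
    return tracks


def _load_track(path: str | Path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    path = str(path)
    if path.endswith((".bw", ".bigwig", ".bigWig")):
        import pyBigWig

        bw = pyBigWig.open(path)
        out = {}
        for chrom, n in chrom_sizes.items():
            if chrom in bw.chroms():
                vals = np.nan_to_num(np.asarray(bw.values(chrom, 0, int(n)), dtype=np.float64))
            else:
                vals = np.zeros(int(n))
            if (vals < 0).any():
                raise ValueError(f"{path}: negative coverage on {chrom}")
            out[chrom] = vals
        bw.close()
        return out
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="t",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str}, engine="python",
    )
    return _expand_bedgraph(df, chrom_sizes, path)


def load_coverage(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_sizes: Mapping[str, int],
    sample_id: str,
    assay: str,
    condition: str,
    replicate: int = 1,
) -> StrandedCoverage:
    """Load a plus/minus bedGraph (or bigWig) pair into per-base vectors.

    bedGraph intervals are expanded; regions without intervals are zero.
    Overlapping intervals or negative values raise ``ValueError``.
    """
    return StrandedCoverage(
        sample_id=sample_id, assay=assay, condition=condition, replicate=replicate,
        plus=_load_track(plus_path, chrom_sizes),
        minus=_load_track(minus_path, chrom_sizes),
    )


def write_bedgraph(track: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length encode per-base vectors as 4-column bedGraph (zero runs
    are omitted)."""
    with open(path, "w") as fh:
        for chrom in track:
            vals = np.asarray(track[chrom])
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    v_out = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{s}\t{e}\t{v_out}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, n in chrom_sizes.items():
            fh.write(f"{chrom}\t{int(n)}\n")


def tu_local_view(
    cov: StrandedCoverage,
    tu: TranscriptionUnit,
    window: Interval,
    antisense: bool = False,
) -> np.ndarray:
    """Signal over a TU-local window, oriented 5'->3'.

    ``window`` is half-open in TU-local coordinates (0 = TSS, increasing
    downstream).  The sense strand of a minus-strand TU is the minus track,
    reversed.  Windows extending past the chromosome are truncated with a
    warning.
    """
    a, b = window
    if b <= a:
        raise ValueError("empty window")
    sense_strand = tu.strand if not antisense else ("-" if tu.strand == "+" else "+")
    arr = cov.track(sense_strand)[tu.chrom]
    n = arr.size
    if tu.strand == "+":
        gs, ge = tu.tss + a, tu.tss + b
    else:
        gs, ge = tu.tss - b + 1, tu.tss - a + 1
    cs, ce = max(gs, 0), min(ge, n)
    if (cs, ce) != (gs, ge):
        logger.warning(
            "%s: window [%d,%d) truncated to chromosome bounds", tu.tu_id, a, b
        )
    if ce <= cs:
        return np.zeros(0)
    out = arr[cs:ce].astype(np.float64)
    return out if tu.strand == "+" else out[::-1]


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Sense/antisense counts: features (TUs or spike-ins) x samples."""

    sense: pd.DataFrame
    antisense: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.sense.index.equals(self.antisense.index) or not self.sense.columns.equals(
            self.antisense.columns
        ):
            raise ValueError("sense and antisense tables must be aligned")
        if (self.sense.to_numpy() < 0).any() or (self.antisense.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.sense.columns)

    def to_tsv(self, path: str | Path) -> None:
        s = self.sense.add_suffix(":sense")
        a = self.antisense.add_suffix(":antisense")
        pd.concat([s, a], axis=1).rename_axis("feature").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        sense = df[[c for c in df.columns if c.endswith(":sense")]]
        anti = df[[c for c in df.columns if c.endswith(":antisense")]]
        sense.columns = [c[: -len(":sense")] for c in sense.columns]
        anti.columns = [c[: -len(":antisense")] for c in anti.columns]
        return cls(sense=sense, antisense=anti[sense.columns])


def expression_filter(
    tus: Sequence[TranscriptionUnit],
    corrected_counts: pd.DataFrame,
    rpk_threshold: float = 100.0,
) -> list[TranscriptionUnit]:
    """Keep TUs whose antisense-bias-corrected RPK, summed over the provided
    (control) replicate columns, reaches ``rpk_threshold``.

    TUs missing from the count table are excluded with a log message.
    """
    kept = []
    for tu in tus:
        if tu.tu_id not in corrected_counts.index:
            logger.warning("TU %s absent from count table; excluded", tu.tu_id)
            continue
        total = float(corrected_counts.loc[tu.tu_id].sum())
        rpk = total / (tu.length / 1000.0)
        if rpk >= rpk_threshold:
            kept.append(tu)
    return kept
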