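"""Readers, writers and coordinate conventions for every external file format.

All interval files (BED, bedGraph, ibed) are 0-based half-open per UCSC
convention. Probe manifest positions are 1-based single-bp positions (the
convention of EPIC-style array manifests). The two conventions meet in exactly
one place: :func:`pos1_in_interval`, which every downstream containment test
must use. Strand is parsed but ignored by overlap operations, since CpG
methylation is strand-symmetric.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .exceptions import (
    MalformedDataError,
    MalformedIntervalError,
    MetadataError,
    ParseError,
)

TIMEPOINTS_H = (0, 3, 12, 24, 48, 72, 168)
CONDITIONS = ("transdiff", "negative_control", "positive_control")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise MalformedIntervalError("interval has empty chromosome name")
        if self.start < 0:
            raise MalformedIntervalError(
                f"negative start {self.start} on {self.chrom}"
            )
        if self.end <= self.start:
            raise MalformedIntervalError(
                f"end {self.end} <= start {self.start} on {self.chrom}"
            )
        if self.strand not in {"+", "-", "."}:
            raise MalformedIntervalError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def __len__(self) -> int:
        return self.end - self.start


def pos1_in_interval(chrom: str, pos: int, interval: GenomicInterval) -> bool:
    """Is a 1-based single-bp position inside a 0-based half-open interval?

    The 1-based position ``p`` lies inside ``[start, end)`` iff
    ``start <= p - 1 < end``. This is the single point where the manifest
    (1-based) and interval (0-based half-open) conventions meet.
    """
    return chrom == interval.chrom and interval.start <= pos - 1 < interval.end


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: where in the timecourse a column belongs."""

    sample_id: str
    timepoint_h: Optional[int]
    replicate: int
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise MetadataError(
                f"sample {self.sample_id}: unknown condition {self.condition!r}"
            )
        if self.condition == "transdiff":
            if self.timepoint_h is None:
                raise MetadataError(
                    f"transdiff sample {self.sample_id} lacks a timepoint"
                )
            if self.timepoint_h not in TIMEPOINTS_H:
                raise MetadataError(
                    f"sample {self.sample_id}: timepoint {self.timepoint_h} h "
                    f"not in {TIMEPOINTS_H}"
                )
        if self.replicate < 1:
            raise MetadataError(f"sample {self.sample_id}: replicate < 1")


class SampleMatrix:
    """A features x samples matrix with per-column :class:`SampleMeta`."""

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta]):
        by_id = {s.sample_id: s for s in samples}
        if len(by_id) != len(samples):
            raise MetadataError("duplicate sample_id in metadata")
        missing = [c for c in values.columns if c not in by_id]
        if missing:
            raise MetadataError(f"columns without metadata: {missing}")
        self.values = values
        self.samples = [by_id[c] for c in values.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def columns_for(
        self, condition: str, timepoint_h: Optional[int] = None
    ) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.condition == condition
            and (timepoint_h is None or s.timepoint_h == timepoint_h)
        ]

    def timepoints(self) -> list[int]:
        """Sorted transdifferentiation timepoints present in the matrix."""
        return sorted(
            {s.timepoint_h for s in self.samples if s.condition == "transdiff"}
        )

    def timepoint_means(self, feature_id: str) -> "pd.Series":
        """Mean value per transdiff timepoint for one feature (sorted by time)."""
        row = self.values.loc[feature_id]
        return pd.Series(
            {
                t: float(row[self.columns_for("transdiff", t)].mean())
                for t in self.timepoints()
            }
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SampleMatrix)
            and self.values.equals(other.values)
            and self.samples == other.samples
        )


class BetaMatrix(SampleMatrix):
    """Probes x samples methylation beta values, all finite and in [0, 1]."""

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta]):
        arr = values.to_numpy()
        bad = ~((arr >= 0.0) & (arr <= 1.0))  # catches NaN too
        if bad.any():
            i, j = [int(x[0]) for x in bad.nonzero()]
            raise MalformedDataError(
                f"beta value {arr[i, j]!r} outside [0,1] at probe "
                f"{values.index[i]!r}, sample {values.columns[j]!r}"
            )
        super().__init__(values, samples)


class ExpressionMatrix(SampleMatrix):
    """Genes x samples expression values (log2 scale, as provided)."""


# ---------------------------------------------------------------------------
# sample metadata TSV
# ---------------------------------------------------------------------------

def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    out = []
    for row in df.itertuples(index=False):
        tp = row.timepoint_h
        tp = None if pd.isna(tp) else int(tp)
        out.append(
            SampleMeta(str(row.sample_id), tp, int(row.replicate), str(row.condition))
        )
    return out


def write_sample_meta(samples: Sequence[SampleMeta], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "timepoint_h": [s.timepoint_h for s in samples],
            "replicate": [s.replicate for s in samples],
            "condition": [s.condition for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# beta / expression matrices
# ---------------------------------------------------------------------------

def _read_matrix(path, meta_path, index_name: str) -> tuple[pd.DataFrame, list[SampleMeta]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = index_name
    samples = read_sample_meta(meta_path)
    return df, samples


def read_beta_matrix(path, meta_path) -> BetaMatrix:
    """Read a probes x samples beta TSV plus its sample-metadata table.

    First column is ``probe_id``; every remaining column must match exactly
    one metadata row. Values are validated to be finite and in [0, 1].
    """
    df, samples = _read_matrix(path, meta_path, "probe_id")
    return BetaMatrix(df, samples)


def write_beta_matrix(bm: BetaMatrix, path, meta_path) -> None:
    bm.values.to_csv(path, sep="\t", index=True, index_label="probe_id")
    write_sample_meta(bm.samples, meta_path)


def read_expression_matrix(path, meta_path) -> ExpressionMatrix:
    df, samples = _read_matrix(path, meta_path, "gene")
    return ExpressionMatrix(df, samples)


def write_expression_matrix(em: ExpressionMatrix, path, meta_path) -> None:
    em.values.to_csv(path, sep="\t", index=True, index_label="gene")
    write_sample_meta(em.samples, meta_path)


# ---------------------------------------------------------------------------
# PCHi-C interactions (ibed dialect)
# ---------------------------------------------------------------------------

IBED_COLUMNS = [
    "bait_chr", "bait_start", "bait_end", "bait_name",
    "otherEnd_chr", "otherEnd_start", "otherEnd_end", "otherEnd_name",
    "N_reads", "score",
]


@dataclass(frozen=True)
class Interaction:
    """One PCHi-C interaction call: bait promoter fragment <-> other end."""

    bait: GenomicInterval
    bait_genes: tuple[str, ...]
    other_end: GenomicInterval
    other_end_name: str
    n_reads: int
    score: float
    id: str

    @property
    def unannotated(self) -> bool:
        return len(self.bait_genes) == 0


class InteractionSet:
    """An ordered collection of :class:`Interaction` records."""

    def __init__(self, interactions: Sequence[Interaction]):
        self.interactions = list(interactions)
        self._by_id = {i.id: i for i in self.interactions}
        if len(self._by_id) != len(self.interactions):
            raise MalformedDataError("duplicate interaction ids")

    def __iter__(self) -> Iterator[Interaction]:
        return iter(self.interactions)

    def __len__(self) -> int:
        return len(self.interactions)

    def __getitem__(self, interaction_id: str) -> Interaction:
        return self._by_id[interaction_id]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, InteractionSet)
            and self.interactions == other.interactions
        )


def read_interactions(path) -> InteractionSet:
    """Read an ibed-dialect interaction table (0-based half-open intervals).

    ``bait_name`` carries semicolon-separated bait gene symbols; records with
    an empty bait_name are retained and flagged unannotated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in IBED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"ibed file missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            score = float(row.score)
        except (TypeError, ValueError):
            raise ParseError(f"non-numeric score {row.score!r} at record {i}")
        if not math.isfinite(score):
            raise ParseError(f"non-finite score at record {i}")
        bait = GenomicInterval(row.bait_chr, int(row.bait_start), int(row.bait_end))
        other = GenomicInterval(
            row.otherEnd_chr, int(row.otherEnd_start), int(row.otherEnd_end)
        )
        name = "" if pd.isna(row.bait_name) else str(row.bait_name)
        genes = tuple(g for g in name.split(";") if g)
        oe_name = "" if pd.isna(row.otherEnd_name) else str(row.otherEnd_name)
        records.append(
            Interaction(
                bait=bait,
                bait_genes=genes,
                other_end=other,
                other_end_name=oe_name,
                n_reads=int(row.N_reads),
                score=score,
                id=f"int{i:06d}",
            )
        )
    return InteractionSet(records)


def write_interactions(iset: InteractionSet, path) -> None:
    rows = []
    for rec in iset:
        rows.append(
            {
                "bait_chr": rec.bait.chrom,
                "bait_start": rec.bait.start,
                "bait_end": rec.bait.end,
                "bait_name": ";".join(rec.bait_genes),
                "otherEnd_chr": rec.other_end.chrom,
                "otherEnd_start": rec.other_end.start,
                "otherEnd_end": rec.other_end.end,
                "otherEnd_name": rec.other_end_name,
                "N_reads": rec.n_reads,
                "score": rec.score,
            }
        )
    pd.DataFrame(rows, columns=IBED_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ (0-based half-open); intervals are sorted by (chrom, start)."""
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{line_no}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, name, strand))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def write_bedgraph(profile, path, values: Optional[Sequence[float]] = None) -> None:
    """Write one value per restriction fragment of a contact profile.

    ``values`` defaults to the profile's depth-normalized UMI counts.
    """
    fragments = profile.fragments
    if values is None:
        total = profile.total_umis or 1
        values = [count / total for _, count in fragments]
    if len(values) != len(fragments):
        raise MalformedDataError("one bedGraph value required per fragment")
    with open(path, "w") as fh:
        for (iv, _), v in zip(fragments, values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


def read_contact_counts(path) -> list[tuple[GenomicInterval, int]]:
    """Read a per-fragment UMI count TSV (chrom, start, end, umi_count)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        count = int(row.umi_count)
        if count < 0:
            raise MalformedDataError(f"negative umi_count at {iv}")
        out.append((iv, count))
    return out


def write_contact_counts(fragments: Sequence[tuple[GenomicInterval, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tumi_count\n")
        for iv, count in fragments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{count}\n")
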