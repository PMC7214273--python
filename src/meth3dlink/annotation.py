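"""Genomic-context annotation of CpG probes from an EPIC-style manifest.

The manifest is the annotation ground truth: per probe a 1-based genomic
position, zero or more gene symbols, and one feature class per gene. A CpG is
"promoter" for a gene when its feature class is one of TSS1500, TSS200, 5UTR
or FirstExon — the standard EPIC-manifest promoter set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import AnnotationError, InputError, MalformedDataError

FEATURE_CLASSES = ("TSS1500", "TSS200", "5UTR", "FirstExon", "Body", "3UTR")
PROMOTER_CLASSES = frozenset({"TSS1500", "TSS200", "5UTR", "FirstExon"})


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    chrom: str
    pos: int  # 1-based bp of the interrogated CpG
    gene_symbols: tuple[str, ...]
    feature_classes: tuple[str, ...]  # aligned with gene_symbols

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MalformedDataError(f"probe {self.probe_id}: pos {self.pos} < 1")
        if len(self.gene_symbols) != len(self.feature_classes):
            raise MalformedDataError(
                f"probe {self.probe_id}: gene/feature lists misaligned"
            )
        for fc in self.feature_classes:
            if fc not in FEATURE_CLASSES:
                raise MalformedDataError(
                    f"probe {self.probe_id}: unknown feature class {fc!r}"
                )

    def feature_for(self, gene: str) -> str:
        for g, fc in zip(self.gene_symbols, self.feature_classes):
            if g == gene:
                return fc
        raise InputError(f"probe {self.probe_id} not annotated to gene {gene}")


class ProbeManifest:
    """Mapping of probe_id to :class:`ProbeAnnotation`."""

    def __init__(self, annotations: Sequence[ProbeAnnotation]):
        self._by_id = {a.probe_id: a for a in annotations}
        if len(self._by_id) != len(annotations):
            raise MalformedDataError("duplicate probe_id in manifest")

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_id

    def __getitem__(self, probe_id: str) -> ProbeAnnotation:
        try:
            return self._by_id[probe_id]
        except KeyError:
            raise AnnotationError(f"probe {probe_id!r} absent from manifest")

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProbeManifest) and self._by_id == other._by_id


def read_manifest(path) -> ProbeManifest:
    """Read a manifest TSV: probe_id, chrom, pos, gene_symbols, feature_classes.

    ``gene_symbols`` and ``feature_classes`` are ';'-joined, aligned by
    position; both empty for probes without an annotated gene.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        genes = tuple(
            g for g in ("" if pd.isna(row.gene_symbols) else row.gene_symbols).split(";") if g
        )
        feats = tuple(
            f
            for f in ("" if pd.isna(row.feature_classes) else row.feature_classes).split(";")
            if f
        )
        out.append(
            ProbeAnnotation(str(row.probe_id), str(row.chrom), int(row.pos), genes, feats)
        )
    return ProbeManifest(out)


def write_manifest(manifest: ProbeManifest, path) -> None:
    rows = [
        {
            "probe_id": a.probe_id,
            "chrom": a.chrom,
            "pos": a.pos,
            "gene_symbols": ";".join(a.gene_symbols),
            "feature_classes": ";".join(a.feature_classes),
        }
        for a in manifest
    ]
    pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "gene_symbols", "feature_classes"]
    ).to_csv(path, sep="\t", index=False)


def partition_by_gene(
    probes: Iterable[str], manifest: ProbeManifest
) -> tuple[set[str], set[str]]:
    """Split probes into (gene-associated, non-gene) sets.

    A probe is gene-associated iff its manifest gene list is non-empty. The
    two sets are disjoint and their union is the input; a probe annotated to
    several genes is counted once.
    """
    gene_associated, non_gene = set(), set()
    for pid in probes:
        ann = manifest[pid]
        (gene_associated if ann.gene_symbols else non_gene).add(pid)
    return gene_associated, non_gene


def promoter_status(probe_id: str, gene: str, manifest: ProbeManifest) -> str:
    """'promoter' iff the probe's feature class for *gene* is TSS1500/TSS200/
    5UTR/FirstExon, else 'nonpromoter'."""
    fc = manifest[probe_id].feature_for(gene)
    return "promoter" if fc in PROMOTER_CLASSES else "nonpromoter"


def format_fraction(k: int, n: int) -> str:
    """Percentage string to one decimal, e.g. format_fraction(141, 251) == '56.2%'."""
    if n == 0:
        return "0.0%"
    return f"{100.0 * k / n:.1f}%"
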