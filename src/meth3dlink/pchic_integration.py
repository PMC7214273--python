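"""Long-range regulatory integration of DMCs with Promoter Capture Hi-C.

Significant CpGs are placed into the *other-end* fragments of PCHi-C
interaction calls (the distal side of a promoter-anchored loop); each hit
nominates the bait's gene(s) as candidate long-range targets. Methylation of
the CpG is then correlated with target-gene expression across the timecourse,
and the element is classified: for a hypomethylated CpG, expression gain with
methylation loss marks a candidate *enhancer*, expression loss a candidate
*silencer* (signs invert for hypermethylated CpGs).

Gene-associated CpGs are eligible alongside intergenic ones — a CpG inside a
gene body can still act as a long-range interactor for another promoter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement
from intervaltree import IntervalTree

from .annotation import ProbeManifest, promoter_status
from .dmc_calling import DMCRecord
from .exceptions import ConfigError, InputError
from .io_formats import (
    BetaMatrix,
    ExpressionMatrix,
    GenomicInterval,
    InteractionSet,
)
from .local_linkage import DEFAULT_LINK_P_THRESHOLD, classify_link, correlate_series

CTCF_CONSENSUS = "CCGCGNGGNGGCAG"  # core CTCF binding consensus (IUPAC)


@dataclass(frozen=True)
class DistalLink:
    probe_id: str
    interaction_id: str
    target_gene: str
    r: float
    p_perm: float
    reg_class: str  # enhancer | silencer | uncorrelated
    cpg_context: str  # non_gene | gene_promoter | gene_nonpromoter


def map_cpgs_to_other_ends(
    probe_ids: Iterable[str],
    interactions: InteractionSet,
    manifest: ProbeManifest,
    include_bait_side: bool = False,
    min_score: Optional[float] = None,
) -> dict[str, list[str]]:
    """Map each probe to every interaction whose other-end contains it.

    Probes with >= 1 hit form the "distal regulatory" subset. Interaction
    calls are assumed pre-filtered; ``min_score`` optionally re-filters.
    ``include_bait_side`` additionally admits probes inside bait fragments.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in interactions:
        if min_score is not None and rec.score < min_score:
            continue
        trees.setdefault(rec.other_end.chrom, IntervalTree()).addi(
            rec.other_end.start, rec.other_end.end, rec.id
        )
        if include_bait_side:
            trees.setdefault(rec.bait.chrom, IntervalTree()).addi(
                rec.bait.start, rec.bait.end, rec.id
            )
    mapping: dict[str, list[str]] = {}
    for pid in probe_ids:
        ann = manifest[pid]
        tree = trees.get(ann.chrom)
        hits = sorted(h.data for h in tree.at(ann.pos - 1)) if tree else []
        if hits:
            mapping[pid] = hits
    return mapping


def _cpg_context(probe_id: str, manifest: ProbeManifest) -> str:
    ann = manifest[probe_id]
    if not ann.gene_symbols:
        return "non_gene"
    # promoter if the probe is promoter-class for any of its annotated genes
    for gene in ann.gene_symbols:
        if promoter_status(probe_id, gene, manifest) == "promoter":
            return "gene_promoter"
    return "gene_nonpromoter"


def build_distal_links(
    mapping: Mapping[str, Sequence[str]],
    interactions: InteractionSet,
    dmcs: Sequence[DMCRecord],
    manifest: ProbeManifest,
    beta: BetaMatrix,
    expr: ExpressionMatrix,
    link_p_threshold: float = DEFAULT_LINK_P_THRESHOLD,
) -> list[DistalLink]:
    """One candidate link per (probe, interaction, bait gene) with expression.

    An interaction with two bait genes yields two candidate links — genes are
    counted, not interactions. Target genes without expression rows are
    silently uncovered (no link).
    """
    by_probe = {d.probe_id: d for d in dmcs}
    links = []
    for pid in sorted(mapping):
        direction = by_probe[pid].direction
        x = beta.timepoint_means(pid).to_numpy()
        ctx = _cpg_context(pid, manifest)
        for iid in mapping[pid]:
            rec = interactions[iid]
            for gene in rec.bait_genes:
                if gene not in expr.values.index:
                    continue
                y = expr.timepoint_means(gene).to_numpy()
                r, p = correlate_series(x, y)
                cls = classify_link(direction, r, p < link_p_threshold)
                reg = {"activation": "enhancer", "repression": "silencer", "none": "uncorrelated"}[cls]
                links.append(DistalLink(pid, iid, gene, r, p, reg, ctx))
    return links


def correlated(links: Sequence[DistalLink]) -> list[DistalLink]:
    return [l for l in links if l.reg_class != "uncorrelated"]


def multiplicity_classes(links: Sequence[DistalLink]) -> dict[str, int]:
    """Partition classified probes by number of distinct correlated target
    genes: 1 -> unique, 2 -> dual, >=3 -> complex."""
    genes_per_probe: dict[str, set[str]] = {}
    for l in correlated(links):
        genes_per_probe.setdefault(l.probe_id, set()).add(l.target_gene)
    counts = Counter()
    for genes in genes_per_probe.values():
        n = len(genes)
        counts["unique" if n == 1 else "dual" if n == 2 else "complex"] += 1
    return {"unique": counts["unique"], "dual": counts["dual"], "complex": counts["complex"]}


def gene_class_split(links: Sequence[DistalLink]) -> dict[str, int]:
    """Partition correlated target genes into enhancer vs silencer genes.

    A gene linked by both signs (possible across probes) is assigned the
    class of its most significant link (lowest p_perm; ties by |r| then
    probe_id), so the two counts always partition the distinct gene set.
    """
    best: dict[str, DistalLink] = {}
    for l in correlated(links):
        cur = best.get(l.target_gene)
        if cur is None or (l.p_perm, -abs(l.r), l.probe_id) < (
            cur.p_perm,
            -abs(cur.r),
            cur.probe_id,
        ):
            best[l.target_gene] = l
    enh = sum(l.reg_class == "enhancer" for l in best.values())
    sil = sum(l.reg_class == "silencer" for l in best.values())
    return {"enhancer_genes": enh, "silencer_genes": sil, "total_genes": len(best)}


def distal_summary(mapping: Mapping[str, Sequence[str]], links: Sequence[DistalLink]) -> dict:
    corr = correlated(links)
    return {
        "n_distal_probes": len(mapping),
        "n_correlated_probes": len({l.probe_id for l in corr}),
        "n_target_genes": len({l.target_gene for l in corr}),
        **gene_class_split(links),
        "multiplicity": multiplicity_classes(links),
    }


# ---------------------------------------------------------------------------
# CTCF motif overlap
# ---------------------------------------------------------------------------

def _iupac_scan(sequence: str, pattern: str) -> list[int]:
    """0-based start positions where the IUPAC pattern matches either strand."""
    seq = sequence.upper()
    hits = set()
    for pat in {pattern.upper(), reverse_complement(pattern.upper())}:
        allowed = [set(ambiguous_dna_values[c]) for c in pat]
        m = len(pat)
        for i in range(len(seq) - m + 1):
            if all(seq[i + j] in allowed[j] for j in range(m)):
                hits.add(i)
    return sorted(hits)


def scan_motif_sites(
    sequence: str, chrom: str, pattern: str = CTCF_CONSENSUS, offset: int = 0
) -> list[GenomicInterval]:
    """Scan a supplied sequence for an IUPAC motif on either strand; returns
    0-based half-open intervals named after the pattern."""
    return [
        GenomicInterval(chrom, offset + i, offset + i + len(pattern), "CTCF")
        for i in _iupac_scan(sequence, pattern)
    ]


def ctcf_overlap(
    probe_ids: Iterable[str],
    manifest: ProbeManifest,
    motif_sites: Optional[Sequence[GenomicInterval]] = None,
    sequence: Optional[str] = None,
    sequence_chrom: Optional[str] = None,
    pattern: str = CTCF_CONSENSUS,
) -> set[str]:
    """Probes whose CpG position lies inside a CTCF motif site.

    Supply either a motif-site interval track, or a sequence (+ its
    chromosome name) to scan for ``pattern`` on both strands.
    """
    if motif_sites is None:
        if sequence is None or sequence_chrom is None:
            raise ConfigError("supply motif_sites, or sequence + sequence_chrom")
        motif_sites = scan_motif_sites(sequence, sequence_chrom, pattern)
    trees: dict[str, IntervalTree] = {}
    for iv in motif_sites:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    out = set()
    for pid in probe_ids:
        ann = manifest[pid]
        tree = trees.get(ann.chrom)
        if tree is not None and tree.at(ann.pos - 1):
            out.add(pid)
    return out
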