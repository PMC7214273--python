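"""Transcription-factor binding-site overlap and category enrichment.

Correlated CpGs are intersected with a named TF binding-site interval track
(any BED4 resource the user trusts); the resulting TF set is tested for
category overrepresentation with an upper-tail hypergeometric test and BH
adjustment across categories. The TF universe defaults to all TFs present in
the supplied track; categories come from a TF -> category TSV so the analysis
stays hermetic (no live ontology queries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .io_formats import GenomicInterval


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int  # selected items in category
    K: int  # universe items in category
    n: int  # selected-set size
    N: int  # universe size
    p_hyper: float
    q: float


def build_interval_index(track: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over a named track (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    for iv in track:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    return trees


def overlap_tf_sites(
    cpg_positions: Mapping[str, tuple[str, int]],
    tf_track: Sequence[GenomicInterval],
) -> tuple[dict[str, set[str]], set[str]]:
    """Map each CpG to the TFs whose binding sites contain it.

    ``cpg_positions`` maps probe_id -> (chrom, 1-based pos). A probe maps to
    TF t iff its 0-based converted position lies in at least one interval
    named t. Returns (per-probe mapping, union TF set); empty overlaps are
    allowed and yield empty sets.
    """
    trees = build_interval_index(tf_track)
    mapping: dict[str, set[str]] = {}
    union: set[str] = set()
    for pid, (chrom, pos) in cpg_positions.items():
        hits = set()
        tree = trees.get(chrom)
        if tree is not None:
            # intervaltree queries are half-open, matching BED
            hits = {h.data for h in tree.at(pos - 1)}
        mapping[pid] = hits
        union |= hits
    return mapping, union


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed via the stable
    survival function; by convention k = 0 gives exactly 1."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise InputError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_categories(
    selected: Iterable[str],
    universe: Iterable[str],
    category_map: Mapping[str, set[str]],
    adjust: str = "bh",
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of categories in a selected TF set.

    ``category_map`` maps TF -> categories; TFs without categories count in N
    but belong to no category. One result per category hit by at least one
    selected TF; BH q-values are computed over all tested categories. Results
    are sorted by ascending p, ties broken by category name.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise InputError(f"selected TFs outside universe: {sorted(selected - universe)}")
    N, n = len(universe), len(selected)

    members: dict[str, set[str]] = {}
    for tf in universe:
        for cat in category_map.get(tf, ()):  # uncovered TFs: no category
            members.setdefault(cat, set()).add(tf)

    rows = []
    for cat, tfs in members.items():
        k = len(tfs & selected)
        if k < 1:
            continue
        K = len(tfs)
        rows.append((cat, k, K, hypergeom_upper_tail(k, K, n, N)))
    if not rows:
        return []

    pvals = np.array([r[3] for r in rows])
    if adjust == "bh":
        q = multipletests(pvals, method="fdr_bh")[1]
    elif adjust == "none":
        q = pvals
    else:
        raise InputError(f"unknown adjustment {adjust!r}")

    results = [
        EnrichmentResult(cat, k, K, n, N, float(p), float(qv))
        for (cat, k, K, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_hyper, r.category))
    return results


def read_category_map(path) -> dict[str, set[str]]:
    """TSV with columns tf, categories (';'-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        cats = "" if pd.isna(row.categories) else row.categories
        out[str(row.tf)] = {c for c in cats.split(";") if c}
    return out


def write_category_map(category_map: Mapping[str, set[str]], path) -> None:
    rows = [
        {"tf": tf, "categories": ";".join(sorted(cats))}
        for tf, cats in sorted(category_map.items())
    ]
    pd.DataFrame(rows, columns=["tf", "categories"]).to_csv(path, sep="\t", index=False)
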