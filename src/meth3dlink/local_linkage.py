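"""Methylation-expression linkage for gene-associated CpGs.

For each passing DMC annotated to a gene, the per-timepoint mean beta series
is correlated (Pearson) with the gene's per-timepoint mean expression series
across the transdifferentiation course. With only seven timepoints the
t-approximation for the correlation p-value is poor, so significance comes
from an exact two-sided permutation test: the fraction of all n! pairings
(identity included) whose |r| reaches the observed |r|, enumerated in full for
n <= 8 and approximated by seeded Monte-Carlo sampling above that.

Link classes follow the sign logic of a repressive methylation mark: for a
hypomethylated probe, negative r (expression rises as beta falls) is
demethylation-linked *activation*; positive r is demethylation-linked
*repression*. Signs invert for hypermethylated probes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import ProbeManifest
from .dmc_calling import DMCRecord
from .exceptions import InputError
from .io_formats import BetaMatrix, ExpressionMatrix

DEFAULT_LINK_P_THRESHOLD = 0.05
ENUMERATION_LIMIT = 8  # full n! enumeration up to this series length
N_MONTE_CARLO = 10_000
_R_TOL = 1e-12  # float tolerance when comparing |r| against the observed value


@dataclass(frozen=True)
class LocalLink:
    probe_id: str
    gene: str
    r: float
    p_perm: float
    link_class: str  # activation | repression | none


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise InputError("correlation undefined for a constant series")
    return float(xc @ yc) / denom


def correlate_series(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
    rng: Optional[np.random.Generator] = None,
    force_monte_carlo: bool = False,
) -> tuple[float, float]:
    """Correlation and exact two-sided permutation p-value for two series.

    For n <= 8 the p-value is exact: the count of all n! pairings (including
    the identity) with |r_perm| >= |r_obs|, divided by n!. For longer series
    10,000 Monte-Carlo permutations are drawn from ``rng`` (a fresh
    deterministic generator when None) and p = (1 + #{|r_perm| >= |r_obs|
    among non-identity draws}) / (1 + n_perm), which stays in (0, 1] and
    converges to the enumerated value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("series must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise InputError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for a constant series")

    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise InputError(f"unknown correlation method {method!r}")

    r_obs = _pearson(x, y)

    # |r| under permutation depends on y only through its permuted centering,
    # so compute r for every permutation of y against fixed x.
    xc = x - x.mean()
    yc = y - y.mean()
    norm = math.sqrt(float(xc @ xc) * float(yc @ yc))

    if n <= ENUMERATION_LIMIT and not force_monte_carlo:
        perms = np.array(list(itertools.permutations(range(n))))
        r_all = (yc[perms] @ xc) / norm
        hits = int(np.sum(np.abs(r_all) >= abs(r_obs) - _R_TOL))
        return r_obs, hits / math.factorial(n)

    if rng is None:
        rng = np.random.default_rng(0)
    hits = 0
    for _ in range(N_MONTE_CARLO):
        r_p = float(xc @ yc[rng.permutation(n)]) / norm
        if abs(r_p) >= abs(r_obs) - _R_TOL:
            hits += 1
    return r_obs, (1 + hits) / (1 + N_MONTE_CARLO)


def classify_link(direction: str, r: float, significant: bool) -> str:
    """Map DMC direction and correlation sign to a link class.

    hypo + r<0 -> activation (expression gains as methylation is lost);
    hypo + r>0 -> repression; signs invert for hyper probes. Non-significant
    or exactly-zero correlations are 'none'.
    """
    if not significant or r == 0.0:
        return "none"
    falls_with_meth_loss = r > 0
    if direction == "hypo":
        return "repression" if falls_with_meth_loss else "activation"
    return "activation" if falls_with_meth_loss else "repression"


def build_local_links(
    dmcs: Sequence[DMCRecord],
    manifest: ProbeManifest,
    beta: BetaMatrix,
    expr: ExpressionMatrix,
    link_p_threshold: float = DEFAULT_LINK_P_THRESHOLD,
    method: Literal["pearson", "spearman"] = "pearson",
    adjust: Literal["none", "bh"] = "none",
) -> tuple[list[LocalLink], list[tuple[str, str]]]:
    """Correlate each gene-associated passing DMC with its annotated gene(s).

    Returns (links, uncovered) where ``uncovered`` lists (probe_id, gene)
    pairs whose gene has no expression row — reported, not an error. A probe
    annotated to k genes yields up to k links, each tested independently;
    BH adjustment across all tested links is available via ``adjust``.
    """
    candidates: list[tuple[str, str, float, float]] = []
    uncovered: list[tuple[str, str]] = []
    tps = beta.timepoints()
    for d in dmcs:
        if not d.passes:
            continue
        ann = manifest[d.probe_id]
        if not ann.gene_symbols:
            continue
        x = beta.timepoint_means(d.probe_id).to_numpy()
        for gene in ann.gene_symbols:
            if gene not in expr.values.index:
                uncovered.append((d.probe_id, gene))
                continue
            y = expr.timepoint_means(gene).to_numpy()
            if len(y) != len(tps):
                raise InputError(f"expression does not cover all timepoints for {gene}")
            r, p = correlate_series(x, y, method=method)
            candidates.append((d.probe_id, gene, r, p))

    pvals = np.array([c[3] for c in candidates]) if candidates else np.array([])
    if adjust == "bh" and len(pvals):
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]

    by_probe = {d.probe_id: d for d in dmcs}
    links = []
    for (pid, gene, r, p_raw), p_eff in zip(candidates, pvals):
        cls = classify_link(by_probe[pid].direction, r, p_eff < link_p_threshold)
        links.append(LocalLink(pid, gene, r, float(p_raw), cls))
    return links, uncovered


def link_summary(links: Sequence[LocalLink]) -> dict:
    """Counts of significant links / probes / genes by class."""
    sig = [l for l in links if l.link_class != "none"]
    return {
        "n_links": len(sig),
        "n_probes": len({l.probe_id for l in sig}),
        "n_genes": len({l.gene for l in sig}),
        "n_activation_genes": len(
            {l.gene for l in sig if l.link_class == "activation"}
        ),
        "n_repression_genes": len(
            {l.gene for l in sig if l.link_class == "repression"}
        ),
    }
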