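"""Seeded synthetic study generator with planted ground truth.

Emulates the structure of a B-ALL-to-macrophage transdifferentiation
methylome study: a probes x samples beta matrix over seven timepoints (0, 3,
12, 24, 48, 72, 168 h) with replicates plus negative- (untransdifferentiated
pre-B-ALL-like) and positive- (macrophage-like) control profiles; a matched
expression matrix; an EPIC-style probe manifest on a single synthetic
chromosome tiled into equal restriction fragments; promoter-capture
interaction calls (bait promoter <-> other-end fragment); TF binding-site,
category and CTCF-motif tracks; and two UMI-4C contact profiles around one
bait with a planted loop gain in one condition.

Planted differential probes follow a logistic demethylation (or methylation,
for hyper probes) trajectory between a high plateau drawn in [0.7, 0.95] and
a low plateau drawn in [0.05, 0.25]; the plateau pair is drawn conditioned on
a gap >= 0.72 so the planted endpoint effect clears the 0.66 delta-beta
filter under the default noise. Null probes hold a constant expected beta
drawn in [0.15, 0.85] (>= 5 sd from the [0,1] bounds at the default noise, so
truncation is negligible). Noise is truncated-Gaussian by default; a
Beta-distributed alternative with matched mean and variance is available via
``noise_model='beta'``. All randomness flows from a single seed; a fixed
config and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .annotation import (
    FEATURE_CLASSES,
    ProbeAnnotation,
    ProbeManifest,
    write_manifest,
)
from .exceptions import ConfigError
from .io_formats import (
    TIMEPOINTS_H,
    BetaMatrix,
    ExpressionMatrix,
    GenomicInterval,
    Interaction,
    InteractionSet,
    SampleMeta,
    write_bed,
    write_beta_matrix,
    write_contact_counts,
    write_expression_matrix,
    write_interactions,
)
from .tf_enrichment import write_category_map
from .umi4c_lite import ContactProfile

CHROM = "chrS"
MIN_PLATEAU_GAP = 0.72  # keeps planted |delta beta| above the 0.66 filter

TF_POOL = (
    "SPI1", "GATA2", "FOXC1", "MEIS1", "HOXA2", "HOXC11", "CEBPA", "RUNX1",
    "IRF8", "EGR1", "KLF4", "STAT5A", "PAX5", "EBF1", "TCF3", "IKZF1",
    "MYB", "ETS1", "ELK1", "SP1", "NRF1", "YY1", "E2F1", "MAX",
    "USF1", "CREB1", "ATF2", "JUN", "FOS", "NFYA",
)
IMMUNE_TFS = TF_POOL[:16]
CATEGORIES = {
    "immune_system_development": IMMUNE_TFS,
    "cell_fate_commitment": IMMUNE_TFS[:10],
    "leukocyte_differentiation": IMMUNE_TFS[4:14],
    "generic_transcription": TF_POOL[16:],
    "cell_cycle": TF_POOL[20:28],
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study; the seed fixes every random draw."""

    n_probes: int = 2000
    n_planted_hypo: int = 100
    n_planted_hyper: int = 1
    replicates_per_timepoint: int = 3
    beta_noise_sd: float = 0.03
    expr_noise_sd: float = 0.1
    n_genes: int = 200
    n_interactions: int = 150
    fragment_size_bp: int = 4000
    umi4c_mean_depth: float = 2000.0
    distance_decay_exponent: float = 1.0
    loop_gain_factor: float = 5.0
    noise_model: str = "truncnorm"  # or 'beta'
    n_local_activation: int = 20
    n_local_repression: int = 5
    n_distal_enhancer_genes: int = 12
    n_distal_silencer_genes: int = 8
    n_dual_probes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_probes, self.n_genes, self.n_interactions,
            self.replicates_per_timepoint, self.fragment_size_bp,
        ]
        if any(c <= 0 for c in counts):
            raise ConfigError("all counts must be positive")
        if self.beta_noise_sd < 0 or self.expr_noise_sd < 0:
            raise ConfigError("noise sds must be >= 0")
        if self.n_planted_hypo + self.n_planted_hyper > self.n_probes:
            raise ConfigError("more planted probes than probes")
        n_distal_genes = self.n_distal_enhancer_genes + self.n_distal_silencer_genes
        n_distal_probes = n_distal_genes - self.n_dual_probes
        n_link_probes = self.n_local_activation + self.n_local_repression + n_distal_probes
        if n_link_probes > self.n_planted_hypo:
            raise ConfigError("planted links exceed planted hypo probes")
        n_link_genes = self.n_local_activation + self.n_local_repression + n_distal_genes
        if n_link_genes > self.n_genes:
            raise ConfigError("planted link genes exceed n_genes")
        if self.n_dual_probes * 2 > n_distal_genes:
            raise ConfigError("too many dual probes for the distal gene count")
        if self.noise_model not in {"truncnorm", "beta"}:
            raise ConfigError(f"unknown noise model {self.noise_model!r}")

    @property
    def n_fragments(self) -> int:
        return max(2 * self.n_genes, 250)

    @property
    def chrom_length(self) -> int:
        return self.n_fragments * self.fragment_size_bp

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """A configuration with no planted signal of any kind (for
        type-I-error calibration runs)."""
        base = dict(
            n_planted_hypo=0, n_planted_hyper=0,
            n_local_activation=0, n_local_repression=0,
            n_distal_enhancer_genes=0, n_distal_silencer_genes=0,
            n_dual_probes=0,
        )
        base.update(overrides)
        return cls(**base)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimConfig(**raw)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for every downstream stage."""

    dmc_direction: dict[str, str]  # probe -> 'hypo' | 'hyper'
    local_links: dict[str, tuple[str, str]]  # probe -> (gene, activation|repression)
    distal_links: dict[str, tuple[tuple[str, str], ...]]  # probe -> ((gene, enhancer|silencer), ...)
    loop_target: Optional[tuple[str, int, str]]  # (bait gene, fragment idx, boosted condition)

    @property
    def dmc_probe_ids(self) -> set[str]:
        return set(self.dmc_direction)


@dataclass
class SyntheticDataset:
    beta: BetaMatrix
    expression: ExpressionMatrix
    manifest: ProbeManifest
    interactions: InteractionSet
    tf_track: list[GenomicInterval]
    category_map: dict[str, set[str]]
    motif_track: list[GenomicInterval]
    contact_t0: ContactProfile
    contact_t168: ContactProfile
    truth: SyntheticTruth
    config: SimConfig


def _logistic_trajectories(
    rng: np.random.Generator, n: int, direction: str
) -> np.ndarray:
    """Expected beta per timepoint for n planted probes (n x 7).

    Plateau pairs are rejection-sampled within [0.7, 0.95] x [0.05, 0.25]
    conditioned on gap >= MIN_PLATEAU_GAP; the logistic midpoint is uniform in
    [12, 72] h with a steepness keeping both endpoints within ~1% of their
    plateaus, so planted endpoint effects clear the delta-beta filter.
    """
    high = np.empty(n)
    low = np.empty(n)
    filled = 0
    while filled < n:
        h = rng.uniform(0.7, 0.95, size=n - filled)
        l = rng.uniform(0.05, 0.25, size=n - filled)
        ok = (h - l) >= MIN_PLATEAU_GAP
        m = int(ok.sum())
        high[filled : filled + m] = h[ok]
        low[filled : filled + m] = l[ok]
        filled += m
    t_mid = rng.uniform(12.0, 72.0, size=n)
    tau = np.minimum(t_mid, 168.0 - t_mid) / 5.0
    t = np.asarray(TIMEPOINTS_H, dtype=float)
    z = (t[None, :] - t_mid[:, None]) / tau[:, None]
    falling = low[:, None] + (high - low)[:, None] / (1.0 + np.exp(z))
    if direction == "hypo":
        return falling
    return (high + low)[:, None] - falling  # mirrored rising trajectory


def _add_noise(
    rng: np.random.Generator, expected: np.ndarray, sd: float, model: str
) -> np.ndarray:
    if sd == 0:
        return expected.copy()
    if model == "truncnorm":
        a = (0.0 - expected) / sd
        b = (1.0 - expected) / sd
        return stats.truncnorm.rvs(a, b, loc=expected, scale=sd, random_state=rng)
    # Beta noise with matched mean and (approximate) variance
    mu = np.clip(expected, 1e-3, 1 - 1e-3)
    nu = np.maximum(mu * (1 - mu) / sd**2 - 1.0, 2.0)
    return rng.beta(mu * nu, (1 - mu) * nu)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic study. Deterministic for a fixed config."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    probe_ids = [f"cg{i:05d}" for i in range(cfg.n_probes)]
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    n_frag = cfg.n_fragments
    frag_size = cfg.fragment_size_bp

    # --- planted probe roles -------------------------------------------------
    planted_total = cfg.n_planted_hypo + cfg.n_planted_hyper
    planted_idx = rng.choice(cfg.n_probes, size=planted_total, replace=False)
    hypo_idx = np.sort(planted_idx[: cfg.n_planted_hypo])
    hyper_idx = np.sort(planted_idx[cfg.n_planted_hypo :])
    hypo_ids = [probe_ids[i] for i in hypo_idx]
    hyper_ids = [probe_ids[i] for i in hyper_idx]

    n_distal_genes = cfg.n_distal_enhancer_genes + cfg.n_distal_silencer_genes
    n_distal_probes = n_distal_genes - cfg.n_dual_probes
    n_local = cfg.n_local_activation + cfg.n_local_repression
    link_probes = hypo_ids[: n_local + n_distal_probes]
    local_probes = link_probes[:n_local]
    distal_probes = link_probes[n_local:]

    # --- gene layout: promoter of gene g sits in fragment 2g -----------------
    gene_frag = {g: 2 * gi for gi, g in enumerate(gene_ids)}
    gene_tss = {g: gene_frag[g] * frag_size + frag_size // 2 + 1 for g in gene_ids}  # 1-based

    link_genes = gene_ids[: n_local + n_distal_genes]
    local_genes = link_genes[:n_local]
    distal_genes = link_genes[n_local:]
    local_signs = ["activation"] * cfg.n_local_activation + [
        "repression"
    ] * cfg.n_local_repression
    distal_signs = ["enhancer"] * cfg.n_distal_enhancer_genes + [
        "silencer"
    ] * cfg.n_distal_silencer_genes

    # distal (gene, sign) pairs -> probes; the first n_dual_probes probes
    # carry two target genes each, the rest one
    pairs = list(zip(distal_genes, distal_signs))
    distal_assignment: dict[str, list[tuple[str, str]]] = {}
    cursor = 0
    for j, pid in enumerate(distal_probes):
        take = 2 if j < cfg.n_dual_probes else 1
        distal_assignment[pid] = pairs[cursor : cursor + take]
        cursor += take
    assert cursor == len(pairs)

    # --- expected beta trajectories ------------------------------------------
    expected = np.empty((cfg.n_probes, len(TIMEPOINTS_H)))
    null_mask = np.ones(cfg.n_probes, dtype=bool)
    null_mask[planted_idx] = False
    expected[null_mask] = rng.uniform(0.15, 0.85, size=int(null_mask.sum()))[:, None]
    expected[hypo_idx] = _logistic_trajectories(rng, len(hypo_idx), "hypo")
    if len(hyper_idx):
        expected[hyper_idx] = _logistic_trajectories(rng, len(hyper_idx), "hyper")

    # --- beta samples ---------------------------------------------------------
    reps = cfg.replicates_per_timepoint
    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    for ti, t in enumerate(TIMEPOINTS_H):
        for r in range(1, reps + 1):
            sid = f"t{t:03d}_r{r}"
            samples.append(SampleMeta(sid, t, r, "transdiff"))
            columns[sid] = _add_noise(
                rng, expected[:, ti], cfg.beta_noise_sd, cfg.noise_model
            )
    for cond, short, exp_col in (
        ("negative_control", "neg", expected[:, 0]),
        ("positive_control", "pos", expected[:, -1]),
    ):
        for r in range(1, reps + 1):
            sid = f"{short}_r{r}"
            samples.append(SampleMeta(sid, None, r, cond))
            columns[sid] = _add_noise(rng, exp_col, cfg.beta_noise_sd, cfg.noise_model)
    beta = BetaMatrix(
        pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id")), samples
    )

    # --- expression -----------------------------------------------------------
    idx_of = {pid: i for i, pid in enumerate(probe_ids)}
    expr_expected = np.empty((cfg.n_genes, len(TIMEPOINTS_H)))
    baseline = rng.uniform(2.0, 8.0, size=cfg.n_genes)
    expr_expected[:] = baseline[:, None]
    planted_expr: dict[str, tuple[str, int]] = {}  # gene -> (probe, +-1)
    for pid, gene, sign in zip(local_probes, local_genes, local_signs):
        planted_expr[gene] = (pid, +1 if sign == "activation" else -1)
    for pid, gene_sign_list in distal_assignment.items():
        for gene, sign in gene_sign_list:
            planted_expr[gene] = (pid, +1 if sign == "enhancer" else -1)
    slope = rng.uniform(2.0, 4.0, size=cfg.n_genes)
    for gi, gene in enumerate(gene_ids):
        if gene in planted_expr:
            pid, s = planted_expr[gene]
            expr_expected[gi] = baseline[gi] + s * slope[gi] * (
                1.0 - expected[idx_of[pid]]
            )
    transdiff_samples = [s for s in samples if s.condition == "transdiff"]
    expr_cols = {}
    for s in transdiff_samples:
        ti = TIMEPOINTS_H.index(s.timepoint_h)
        expr_cols[s.sample_id] = expr_expected[:, ti] + rng.normal(
            0.0, cfg.expr_noise_sd, size=cfg.n_genes
        )
    expression = ExpressionMatrix(
        pd.DataFrame(expr_cols, index=pd.Index(gene_ids, name="gene")),
        transdiff_samples,
    )

    # --- distal probe placement & interactions -------------------------------
    odd_frags = [f for f in range(1, n_frag, 2)]  # never promoter fragments
    probe_frag: dict[str, int] = {}
    taken: set[int] = set()
    planted_interactions: list[tuple[str, str]] = []  # (bait gene, probe)
    loop_probe = next(
        (pid for pid in distal_probes if distal_assignment[pid][0][1] == "enhancer"),
        None,
    )
    for pid in distal_probes:
        # keep the other end within UMI-4C range of its first bait; one
        # fragment per planted probe keeps the planted mapping unambiguous.
        # The loop that the UMI-4C assay targets is planted at an
        # assay-typical enhancer-promoter distance (<= ~0.5 Mb); the
        # remaining distal elements span the full quantifiable band.
        first_gene = distal_assignment[pid][0][0]
        fb = gene_frag[first_gene]
        reach = 120 if pid == loop_probe else 240
        lo, hi = max(0, fb - reach), min(n_frag - 1, fb + reach)
        candidates = [
            f
            for f in range(lo, hi + 1)
            if f % 2 == 1 and abs(f - fb) >= 3 and f not in taken
        ]
        ft = candidates[int(rng.integers(len(candidates)))]
        taken.add(ft)
        probe_frag[pid] = ft
        for gene, _sign in distal_assignment[pid]:
            planted_interactions.append((gene, pid))

    positions = rng.integers(1, cfg.chrom_length + 1, size=cfg.n_probes)
    for pid, ft in probe_frag.items():
        positions[idx_of[pid]] = ft * frag_size + frag_size // 2 + 1  # 1-based mid

    records: list[Interaction] = []
    used_other_ends = set(probe_frag.values())
    for k, (gene, pid) in enumerate(planted_interactions):
        ft = probe_frag[pid]
        fb = gene_frag[gene]
        records.append(
            Interaction(
                bait=GenomicInterval(CHROM, fb * frag_size, (fb + 1) * frag_size),
                bait_genes=(gene,),
                other_end=GenomicInterval(CHROM, ft * frag_size, (ft + 1) * frag_size),
                other_end_name=".",
                n_reads=int(rng.poisson(50)) + 1,
                score=float(rng.uniform(5.0, 15.0)),
                id=f"int{k:06d}",
            )
        )
    n_filler = max(0, cfg.n_interactions - len(records))
    free_frags = [f for f in odd_frags if f not in used_other_ends]
    for k in range(n_filler):
        gene = gene_ids[int(rng.integers(cfg.n_genes))]
        ft = free_frags[int(rng.integers(len(free_frags)))]
        fb = gene_frag[gene]
        if ft == fb:
            ft = (ft + 2) % n_frag
        records.append(
            Interaction(
                bait=GenomicInterval(CHROM, fb * frag_size, (fb + 1) * frag_size),
                bait_genes=(gene,),
                other_end=GenomicInterval(CHROM, ft * frag_size, (ft + 1) * frag_size),
                other_end_name=".",
                n_reads=int(rng.poisson(50)) + 1,
                score=float(rng.uniform(5.0, 15.0)),
                id=f"int{len(records):06d}",
            )
        )
    interactions = InteractionSet(records)

    # --- manifest -------------------------------------------------------------
    promoter_like = ("TSS1500", "TSS200", "5UTR", "FirstExon")
    nonpromoter_like = ("Body", "3UTR")
    filler_genes = gene_ids[len(link_genes) :] or gene_ids
    annotations = []
    local_by_probe = dict(zip(local_probes, zip(local_genes, local_signs)))
    distal_set = set(distal_probes)
    for i, pid in enumerate(probe_ids):
        genes: tuple[str, ...] = ()
        feats: tuple[str, ...] = ()
        if pid in local_by_probe:
            gene = local_by_probe[pid][0]
            pool = promoter_like if rng.random() < 0.7 else nonpromoter_like
            genes, feats = (gene,), (pool[int(rng.integers(len(pool)))],)
        elif pid in distal_set:
            # roughly half the distal CpGs sit inside (unrelated) genes,
            # mostly in non-promoter context
            if rng.random() < 0.5:
                gene = filler_genes[int(rng.integers(len(filler_genes)))]
                pool = nonpromoter_like if rng.random() < 0.7 else promoter_like
                genes, feats = (gene,), (pool[int(rng.integers(len(pool)))],)
        else:
            if rng.random() < 0.5:
                gene = filler_genes[int(rng.integers(len(filler_genes)))]
                feats_pool = FEATURE_CLASSES
                genes, feats = (gene,), (feats_pool[int(rng.integers(len(feats_pool)))],)
        annotations.append(
            ProbeAnnotation(pid, CHROM, int(positions[i]), genes, feats)
        )
    manifest = ProbeManifest(annotations)

    # --- TF binding-site track and category map -------------------------------
    tf_track: list[GenomicInterval] = []
    for pid in local_probes:
        pos0 = int(positions[idx_of[pid]]) - 1
        n_tfs = int(rng.integers(1, 4))
        tf_idx = rng.choice(len(IMMUNE_TFS), size=n_tfs, replace=False)
        for k in tf_idx:
            pad_l = int(rng.integers(5, 40))
            pad_r = int(rng.integers(5, 40))
            tf_track.append(
                GenomicInterval(
                    CHROM, max(0, pos0 - pad_l), pos0 + pad_r, IMMUNE_TFS[int(k)]
                )
            )
    for _ in range(200):  # background sites away from any planted signal
        start = int(rng.integers(0, cfg.chrom_length - 60))
        tf = TF_POOL[int(rng.integers(len(TF_POOL)))]
        tf_track.append(GenomicInterval(CHROM, start, start + int(rng.integers(20, 60)), tf))
    tf_track.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))
    category_map = {tf: set() for tf in TF_POOL}
    for cat, tfs in CATEGORIES.items():
        for tf in tfs:
            category_map[tf].add(cat)

    # --- CTCF motif track: four planted distal CpGs in motif sites ------------
    motif_track: list[GenomicInterval] = []
    ctcf_probes = distal_probes[: min(4, len(distal_probes))]
    for pid in ctcf_probes:
        pos0 = int(positions[idx_of[pid]]) - 1
        motif_track.append(GenomicInterval(CHROM, pos0 - 7, pos0 + 7, "CTCF"))
    for _ in range(5):  # decoys away from probes
        start = int(rng.integers(0, cfg.chrom_length - 20))
        motif_track.append(GenomicInterval(CHROM, start, start + 14, "CTCF"))
    motif_track.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))

    # --- UMI-4C profiles around the planted enhancer loop (or, with nothing
    # planted, a null bait at the first gene's promoter) ------------------------
    if loop_probe is not None:
        loop_gene = distal_assignment[loop_probe][0][0]
        loop_frag: Optional[int] = probe_frag[loop_probe]
    else:
        loop_gene = gene_ids[0]
        loop_frag = None
    bait_frag = gene_frag[loop_gene]
    bait_pos = gene_tss[loop_gene]
    d = np.abs(np.arange(n_frag) - bait_frag).astype(float)
    d[bait_frag] = 1.0
    mean = cfg.umi4c_mean_depth * d ** (-cfg.distance_decay_exponent)
    mean_boost = mean.copy()
    if loop_frag is not None:
        mean_boost[loop_frag] *= cfg.loop_gain_factor
    grid = [
        GenomicInterval(CHROM, f * frag_size, (f + 1) * frag_size)
        for f in range(n_frag)
    ]
    counts_a = rng.poisson(mean)
    counts_b = rng.poisson(mean_boost)
    contact_t0 = ContactProfile(bait_pos, list(zip(grid, map(int, counts_a))), "t0")
    contact_t168 = ContactProfile(bait_pos, list(zip(grid, map(int, counts_b))), "t168")

    # --- truth ----------------------------------------------------------------
    truth = SyntheticTruth(
        dmc_direction={
            **{pid: "hypo" for pid in hypo_ids},
            **{pid: "hyper" for pid in hyper_ids},
        },
        local_links={
            pid: (gene, sign)
            for pid, gene, sign in zip(local_probes, local_genes, local_signs)
        },
        distal_links={pid: tuple(v) for pid, v in distal_assignment.items()},
        loop_target=(loop_gene, loop_frag, "t168") if loop_frag is not None else None,
    )
    return SyntheticDataset(
        beta=beta,
        expression=expression,
        manifest=manifest,
        interactions=interactions,
        tf_track=tf_track,
        category_map=category_map,
        motif_track=motif_track,
        contact_t0=contact_t0,
        contact_t168=contact_t168,
        truth=truth,
        config=cfg,
    )


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Flat table of planted facts: one row per planted DMC, link and loop."""
    rows = []
    for pid in sorted(truth.dmc_direction):
        rows.append(
            {"kind": "dmc", "probe_id": pid, "gene": "", "detail": truth.dmc_direction[pid]}
        )
    for pid in sorted(truth.local_links):
        gene, sign = truth.local_links[pid]
        rows.append({"kind": "local_link", "probe_id": pid, "gene": gene, "detail": sign})
    for pid in sorted(truth.distal_links):
        for gene, sign in truth.distal_links[pid]:
            rows.append(
                {"kind": "distal_link", "probe_id": pid, "gene": gene, "detail": sign}
            )
    if truth.loop_target is not None:
        gene, frag, cond = truth.loop_target
        rows.append(
            {"kind": "loop", "probe_id": "", "gene": gene, "detail": f"{frag}:{cond}"}
        )
    return pd.DataFrame(rows, columns=["kind", "probe_id", "gene", "detail"])


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the full fixture set in the io_formats dialects."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / "beta.tsv",
        "beta_meta": out / "beta_meta.tsv",
        "expression": out / "expression.tsv",
        "expression_meta": out / "expression_meta.tsv",
        "manifest": out / "manifest.tsv",
        "interactions": out / "interactions.ibed",
        "tf_track": out / "tf_sites.bed",
        "categories": out / "tf_categories.tsv",
        "motifs": out / "ctcf_motifs.bed",
        "umi4c_t0": out / "umi4c_t0.tsv",
        "umi4c_t168": out / "umi4c_t168.tsv",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.yaml",
    }
    write_beta_matrix(ds.beta, paths["beta"], paths["beta_meta"])
    write_expression_matrix(ds.expression, paths["expression"], paths["expression_meta"])
    write_manifest(ds.manifest, paths["manifest"])
    write_interactions(ds.interactions, paths["interactions"])
    write_bed(ds.tf_track, paths["tf_track"])
    write_category_map(ds.category_map, paths["categories"])
    write_bed(ds.motif_track, paths["motifs"])
    write_contact_counts(ds.contact_t0.fragments, paths["umi4c_t0"])
    write_contact_counts(ds.contact_t168.fragments, paths["umi4c_t168"])
    truth_report(ds.truth).to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(ds.config), fh, sort_keys=False)
    return paths
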