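"""End-to-end orchestration: simulate -> dmc -> annotate -> link-local ->
enrich -> link-distal -> umi4c, under one YAML config and one seed.

Every stage output is written to the run directory in the io_formats
dialects, and the run report's counts are all recomputable from those files.
Percentages in the human-readable report are printed to one decimal place.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import annotation as ann
from . import dmc_calling as dmc
from . import local_linkage as ll
from . import pchic_integration as pchic
from . import synthetic_data as synth
from . import tf_enrichment as tfe
from . import umi4c_lite as u4c
from .exceptions import ConfigError
from .io_formats import write_bedgraph

logger = logging.getLogger("meth3dlink")


DEFAULT_CONFIG: dict[str, Any] = {
    "sim": {},  # SimConfig fields; seed is injected
    "dmc": {"p_threshold": 0.05, "delta_threshold": 0.66, "adjust": "none",
            "method": "welch_t"},
    "linkage": {"link_p_threshold": 0.05},
    "enrich": {"adjust": "bh", "q_threshold": 0.05},
    "umi4c": {"min_bp": 500, "max_bp": 1_000_000, "smooth_window": 5,
              "scales": [1, 3, 5, 9, 15], "target_window_frags": 1},
}


def load_config(path=None) -> dict[str, Any]:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section not in cfg:
                raise ConfigError(f"unknown config section {section!r}")
            cfg[section].update(values or {})
    return cfg


@dataclass
class RunReport:
    seed: int
    counts: dict[str, Any]
    paths: dict[str, str]
    config: dict[str, Any]

    def lines(self) -> list[str]:
        c = self.counts
        pct = ann.format_fraction
        n_sig = c["n_significant"]
        out = [
            f"significant CpGs: {n_sig} ({c['n_hypo']} hypo, {c['n_hyper']} hyper)",
            f"macrophage-like at endpoint: {c['n_macrophage_like']} of {n_sig} "
            f"({pct(c['n_macrophage_like'], n_sig)})",
            f"gene-associated: {c['n_gene_associated']} ({pct(c['n_gene_associated'], n_sig)}); "
            f"non-gene: {c['n_non_gene']} ({pct(c['n_non_gene'], n_sig)})",
            f"correlated local CpGs: {c['n_local_probes']} over {c['n_local_genes']} genes "
            f"({c['n_activation_genes']} activation, {c['n_repression_genes']} repression)",
            f"TFs overlapping correlated CpGs: {c['n_tfs']}",
            f"enriched TF categories (q < {self.config['enrich']['q_threshold']}): "
            f"{c['n_enriched_categories']}",
            f"distal (other-end) CpGs: {c['n_distal_probes']} ({pct(c['n_distal_probes'], n_sig)})",
            f"correlated distal CpGs: {c['n_correlated_distal']} targeting "
            f"{c['n_target_genes']} genes ({c['enhancer_genes']} enhancer, "
            f"{c['silencer_genes']} silencer)",
            f"multiplicity (unique/dual/complex): {c['multiplicity_unique']}/"
            f"{c['multiplicity_dual']}/{c['multiplicity_complex']}",
            f"distal CpGs in CTCF motifs: {c['n_ctcf']}",
            f"loop contact test: chi2 = {c['loop_chi2']:.2f}, "
            f"adjusted p = {c['loop_p_adjusted']:.3g}",
        ]
        return out


def run_all(config_path=None, out_dir="meth3dlink_run", seed: int = 0) -> RunReport:
    """Execute the full synthetic-study pipeline and write all stage outputs."""
    t_start = time.time()
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage %s (t+%.1fs)", name, time.time() - t_start)

    # simulate ---------------------------------------------------------------
    stage("simulate")
    sim_cfg = synth.SimConfig(**{**cfg["sim"], "seed": seed})
    ds = synth.generate_dataset(sim_cfg)
    paths = {k: str(v) for k, v in synth.write_dataset(ds, out / "data").items()}

    # dmc --------------------------------------------------------------------
    stage("dmc")
    d = cfg["dmc"]
    dmcs = dmc.call_dmcs(
        ds.beta,
        p_threshold=d["p_threshold"],
        delta_threshold=d["delta_threshold"],
        adjust=d["adjust"],
        method=d["method"],
    )
    passing = dmc.passing(dmcs)
    summary = dmc.summarize(dmcs)
    conc = dmc.control_concordance(ds.beta, dmcs)
    dmc_path = out / "dmc.tsv"
    dmc.dmc_table(dmcs).to_csv(dmc_path, sep="\t", index=False)
    paths["dmc"] = str(dmc_path)

    # annotate ---------------------------------------------------------------
    stage("annotate")
    pass_ids = [r.probe_id for r in passing]
    gene_assoc, non_gene = ann.partition_by_gene(pass_ids, ds.manifest)

    # link-local -------------------------------------------------------------
    stage("link-local")
    links, _uncovered = ll.build_local_links(
        dmcs, ds.manifest, ds.beta, ds.expression,
        link_p_threshold=cfg["linkage"]["link_p_threshold"],
    )
    lsum = ll.link_summary(links)
    links_path = out / "local_links.tsv"
    _write_tsv(
        links_path,
        ["probe_id", "gene", "r", "p_perm", "link_class"],
        [(l.probe_id, l.gene, f"{l.r:.6g}", f"{l.p_perm:.6g}", l.link_class) for l in links],
    )
    paths["local_links"] = str(links_path)

    # enrich -----------------------------------------------------------------
    stage("enrich")
    sig_probes = sorted({l.probe_id for l in links if l.link_class != "none"})
    cpg_pos = {p: (ds.manifest[p].chrom, ds.manifest[p].pos) for p in sig_probes}
    _, tf_union = tfe.overlap_tf_sites(cpg_pos, ds.tf_track)
    universe = sorted({iv.name for iv in ds.tf_track})
    enr = tfe.enrich_categories(tf_union, universe, ds.category_map,
                                adjust=cfg["enrich"]["adjust"])
    q_thr = cfg["enrich"]["q_threshold"]
    enr_path = out / "enrichment.tsv"
    _write_tsv(
        enr_path,
        ["category", "k", "K", "n", "N", "p_hyper", "q"],
        [(e.category, e.k, e.K, e.n, e.N, f"{e.p_hyper:.6g}", f"{e.q:.6g}") for e in enr],
    )
    paths["enrichment"] = str(enr_path)

    # link-distal ------------------------------------------------------------
    stage("link-distal")
    mapping = pchic.map_cpgs_to_other_ends(pass_ids, ds.interactions, ds.manifest)
    dlinks = pchic.build_distal_links(
        mapping, ds.interactions, dmcs, ds.manifest, ds.beta, ds.expression,
        link_p_threshold=cfg["linkage"]["link_p_threshold"],
    )
    dsum = pchic.distal_summary(mapping, dlinks)
    ctcf = pchic.ctcf_overlap(sorted(mapping), ds.manifest, motif_sites=ds.motif_track)
    distal_path = out / "distal_links.tsv"
    _write_tsv(
        distal_path,
        ["probe_id", "interaction_id", "target_gene", "r", "p_perm", "reg_class",
         "cpg_context"],
        [(l.probe_id, l.interaction_id, l.target_gene, f"{l.r:.6g}",
          f"{l.p_perm:.6g}", l.reg_class, l.cpg_context) for l in dlinks],
    )
    paths["distal_links"] = str(distal_path)

    # umi4c ------------------------------------------------------------------
    stage("umi4c")
    u = cfg["umi4c"]
    prof_a = u4c.distance_filter(ds.contact_t0, u["min_bp"], u["max_bp"])
    prof_b = u4c.distance_filter(ds.contact_t168, u["min_bp"], u["max_bp"])
    dgram = u4c.domainogram(prof_a, prof_b, tuple(u["scales"]))
    # target the strongest differential contact (variance-stabilized z)
    center = int(np.argmax(np.abs(u4c.per_fragment_z(prof_a, prof_b))))
    half = int(u["target_window_frags"]) // 2
    window = (max(0, center - half), min(len(prof_a.fragments) - 1, center + half))
    test = u4c.contact_test(prof_a, prof_b, window)
    write_bedgraph(prof_a, out / "umi4c_t0_smoothed.bedgraph",
                   u4c.smooth_profile(prof_a, u["smooth_window"]))
    write_bedgraph(prof_b, out / "umi4c_t168_smoothed.bedgraph",
                   u4c.smooth_profile(prof_b, u["smooth_window"]))
    np.savetxt(out / "domainogram.tsv", dgram.values, delimiter="\t", fmt="%.6g")
    paths["domainogram"] = str(out / "domainogram.tsv")

    counts = {
        "n_probes": summary.n_probes,
        "n_significant": summary.n_pass,
        "n_hypo": summary.n_hypo,
        "n_hyper": summary.n_hyper,
        "n_macrophage_like": sum(r.macrophage_like for r in conc),
        "n_gene_associated": len(gene_assoc),
        "n_non_gene": len(non_gene),
        "n_local_links": lsum["n_links"],
        "n_local_probes": lsum["n_probes"],
        "n_local_genes": lsum["n_genes"],
        "n_activation_genes": lsum["n_activation_genes"],
        "n_repression_genes": lsum["n_repression_genes"],
        "n_tfs": len(tf_union),
        "n_enriched_categories": sum(e.q < q_thr for e in enr),
        "n_distal_probes": dsum["n_distal_probes"],
        "n_correlated_distal": dsum["n_correlated_probes"],
        "n_target_genes": dsum["n_target_genes"],
        "enhancer_genes": dsum["enhancer_genes"],
        "silencer_genes": dsum["silencer_genes"],
        "multiplicity_unique": dsum["multiplicity"]["unique"],
        "multiplicity_dual": dsum["multiplicity"]["dual"],
        "multiplicity_complex": dsum["multiplicity"]["complex"],
        "n_ctcf": len(ctcf),
        "loop_window": list(window),
        "loop_chi2": test.chi2,
        "loop_p": test.p,
        "loop_p_adjusted": test.p_adjusted,
    }

    report = RunReport(seed=seed, counts=counts, paths=paths, config=cfg)

    # machine-readable manifest + human-readable summary
    with open(out / "run_report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2, sort_keys=True)
    _write_tsv(out / "run_report.tsv", ["key", "value"],
               [(k, v) for k, v in counts.items()])
    with open(out / "run_report.txt", "w") as fh:
        fh.write("\n".join(report.lines()) + "\n")
    stage("done")
    return report


def _write_tsv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
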