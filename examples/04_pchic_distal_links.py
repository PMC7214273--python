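"""Classify distal CpGs as candidate enhancers or silencers via PCHi-C loops.

Significant CpGs are placed into the other-end fragments of promoter-capture
interaction calls; each hit nominates the bait's gene as a long-range target.
A hypomethylated CpG whose methylation anti-correlates with target expression
is a candidate enhancer; positive correlation marks a candidate silencer.
"""

from meth3dlink import SimConfig, generate_dataset
from meth3dlink.dmc_calling import call_dmcs
from meth3dlink.pchic_integration import (
    build_distal_links, ctcf_overlap, distal_summary, map_cpgs_to_other_ends,
)

ds = generate_dataset(SimConfig(seed=1))
dmcs = call_dmcs(ds.beta)
pass_ids = [r.probe_id for r in dmcs if r.passes]

mapping = map_cpgs_to_other_ends(pass_ids, ds.interactions, ds.manifest)
links = build_distal_links(mapping, ds.interactions, dmcs, ds.manifest,
                           ds.beta, ds.expression)
s = distal_summary(mapping, links)
print(f"{s['n_distal_probes']} of {len(pass_ids)} significant CpGs fall in "
      f"PCHi-C other-end fragments (candidate distant regulatory regions)")
print(f"{s['n_correlated_probes']} of them correlate with looped target-gene "
      f"expression, over {s['n_target_genes']} genes: "
      f"{s['enhancer_genes']} enhancer-like, {s['silencer_genes']} silencer-like")
m = s["multiplicity"]
print(f"interaction multiplicity: {m['unique']} CpGs touch one gene, "
      f"{m['dual']} touch two, {m['complex']} touch three or more")

ctcf = ctcf_overlap(sorted(mapping), ds.manifest, motif_sites=ds.motif_track)
print(f"{len(ctcf)} distal CpGs sit inside CTCF motif sites "
      f"(candidate architectural, loop-anchoring positions)")
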