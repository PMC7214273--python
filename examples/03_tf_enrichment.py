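"""Overlap correlated CpGs with TF binding sites and test category enrichment.

CpGs whose methylation tracks expression are intersected with a named TF
binding-site track; the resulting TF set is tested for category
overrepresentation with an upper-tail hypergeometric test (BH-adjusted).
"""

from meth3dlink import SimConfig, generate_dataset
from meth3dlink.dmc_calling import call_dmcs
from meth3dlink.local_linkage import build_local_links
from meth3dlink.tf_enrichment import enrich_categories, overlap_tf_sites

ds = generate_dataset(SimConfig(seed=1))
dmcs = call_dmcs(ds.beta)
links, _ = build_local_links(dmcs, ds.manifest, ds.beta, ds.expression)
correlated = sorted({l.probe_id for l in links if l.link_class != "none"})

positions = {p: (ds.manifest[p].chrom, ds.manifest[p].pos) for p in correlated}
mapping, tf_set = overlap_tf_sites(positions, ds.tf_track)
print(f"{len(correlated)} correlated CpGs sit in binding sites of {len(tf_set)} TFs")

universe = sorted({iv.name for iv in ds.tf_track})
results = enrich_categories(tf_set, universe, ds.category_map)
print("top categories (k/K = selected/universe members, q = BH-adjusted p):")
for r in results[:3]:
    print(f"  {r.category}: k={r.k}/K={r.K}, p={r.p_hyper:.2e}, q={r.q:.2e}")
print("small q means the category is overrepresented among TFs whose sites "
      "host the correlated CpGs")
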