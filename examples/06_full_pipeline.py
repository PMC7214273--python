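"""Run every stage end to end and print the run report.

Equivalent to `meth3dlink run --out runs/demo --seed 1`: simulate, call DMCs,
annotate, link locally, enrich TFs, integrate PCHi-C, test the loop, and
write all stage outputs plus a reproducible report under the output
directory.
"""

from meth3dlink.pipeline import run_all

report = run_all(out_dir="runs/demo", seed=1)
for line in report.lines():
    print(line)
print("\nstage outputs:", ", ".join(sorted(report.paths)))
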