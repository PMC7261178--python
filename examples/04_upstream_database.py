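"""Infer the cohort database of upstream sequences (5'UTR + leader).

Upstream fragments are split off at the V-REGION start, right-anchored at
position -1, trimmed (95%-N rule), length-filtered, clustered at 99.9%
identity per allele and individual, and summarised as 60%-majority
consensuses; identical consensuses across individuals collapse into one
record per upstream variant.
"""

import ighvkit as ik
from ighvkit.simulate import upstream_benchmark
from ighvkit.upstream import upstream_db_to_frame
from ighvkit.usage import CollapseMap

config = upstream_benchmark(seed=5)
db = config.germline_db
table, truth = ik.simulate_cohort(config)

cmap = CollapseMap.for_database(db)
analysis = ik.select_analysis_reads(ik.collapse_vcalls(table, cmap), db, cmap=cmap)
records, per_sample = ik.infer_upstream_db(analysis, db)

frame = upstream_db_to_frame(records)
frame["sequence"] = frame["sequence"].str[:24] + "..."
print(frame.to_string(index=False))
print("\nAlleles with more than one record carry a variant suffix (_1, _2);")
print("n_individuals counts the carriers of each variant, and")
print("start_coordinate is the 5'-most base relative to the V-REGION")
print("start (position -1 = last L-PART2 base).")
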