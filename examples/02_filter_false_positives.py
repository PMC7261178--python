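"""Filter false-positive novel-allele candidates by mismatch frequency.

Simulates a cohort with a planted heterozygous novel allele under an
A->C-biased sequencing-error model, detects positional candidates, and
classifies each by the per-carrier mismatch frequency (threshold 0.35),
the batch rule and the substitution blacklist.
"""

import ighvkit as ik
from ighvkit.simulate import novel_allele_benchmark

config = novel_allele_benchmark(seed=3, n_individuals=8, depth=2000)
db = config.germline_db
table, truth = ik.simulate_cohort(config)

candidates = ik.detect_candidates_naive(table, db)
classified, report = ik.classify_candidates(candidates, table, db)

print(f"cohort: {len(table)} reads, {config.n_individuals} individuals")
print(f"candidates evaluated: {len(classified)}\n")
print(report[["candidate", "verdict", "carrier_frequencies"]].to_string(index=False))
print("\nA genuine heterozygous germline variant sits near 0.5 mismatch")
print("frequency in its carriers; amplification artifacts sit below the")
print("0.35 threshold in all carriers and are called false positives.")
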