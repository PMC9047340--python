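"""Desk-scale spike-in benchmark across all five SV classes.

Runs ten seeded cases (two per SV class), each spiked into two fresh
neutral 100-variant backgrounds, and reports the median rank of the
causal variant per case.
"""

import tempfile

from svprio.synthetic import run_spike_in_suite

with tempfile.TemporaryDirectory() as tmp:
    results = run_spike_in_suite(
        tmp, n_cases=10, n_backgrounds=2, background_size=100, seed=1
    )

print("case                     class  median rank  per-background ranks")
for case, median, ranks in results:
    print(f"{case.case_id:24s} {case.sv_class:5s}  {median:11g}  {ranks}")

top1 = sum(1 for _c, m, _r in results if m == 1)
print(f"\n{top1}/{len(results)} cases recovered at rank 1.")
print(
    "Backgrounds are neutral by construction (deep-intronic, intergenic, "
    "or common-panel variants), so a deleterious variant in the single "
    "phenotype-matched gene should always rank first; ties would be "
    "reported at the middle of their tied group."
)
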