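"""Time the auto-layout engine across synthetic model sizes.

Models keep the fixed 4:1 species-to-reaction ratio; each size is laid out
with 50 relaxation iterations on one core and the median wall-clock time is
reported.  Timings depend on your hardware — they describe scaling, not a
pass/fail criterion.
"""

import sbmlviz as sv

rows = sv.run_benchmark(sizes=[20, 100, 500], iterations=50, reps=3, seed=0)

print(f"{'n_species':>9}  {'n_reactions':>11}  {'median_s':>9}  {'reps':>4}")
for row in rows:
    print(f"{row.n_species:>9}  {row.n_reactions:>11}  "
          f"{row.median_seconds:>9.4f}  {row.reps:>4}")
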