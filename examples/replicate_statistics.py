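"""Reproduce the replicate-statistics analysis from the packaged AP table.

Each training condition has three replicate test AP@0.5 values.  Normality
of each triple is checked with the exact n=3 Shapiro-Wilk form; each
proposed augmentation method is then compared against its baseline condition
with a paired two-sided t-test (replicates paired by index, df = 2).
"""

from wormsynth.selflabel import estimate_time_saved
from wormsynth.stats import (
    compare_methods,
    dataset_split_total,
    reference_table,
    relative_drop_percent,
    shapiro_wilk_n3,
    stylized_image_count,
)

table = reference_table()
print("replicate AP@0.5 triples and their Shapiro-Wilk normality p:")
for label, row in table.rows.items():
    p = shapiro_wilk_n3(row["test"]).p
    print(f"  {label:<26} {row['test']}  p={p:.3f}")

print("\npaired t-tests (method vs its baseline condition):")
for r in compare_methods(table):
    print(f"  {r.method:<15} t={r.t:6.3f}  df={r.df}  p={r.p:.4f}")
print("smaller p = stronger evidence the augmentation method improved AP.")

print("\nbookkeeping around the experiments:")
print(f"  strain-change AP drop, default weights:    "
      f"{relative_drop_percent(0.995, 0.814):.1f} %")
print(f"  strain-change AP drop, generalist weights: "
      f"{relative_drop_percent(0.995, 0.968):.1f} %")
print(f"  dataset total: {dataset_split_total(10_612, 3_773, 2_828)} images; "
      f"style transfer adds {stylized_image_count(10_612)} stylized images")
print(f"  hand-labeling 10,468 worms at 5 s each: "
      f"{estimate_time_saved(10_468)} h")
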