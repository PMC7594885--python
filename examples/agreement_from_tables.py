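"""Agreement statistics on the packaged observer measurements.

Computes ICC(A,k) on the 12-item x 4-observer matrix (six distances, each
measured on the real radiograph and on the DRR), the per-measurement
summary, and Bland–Altman limits of agreement on the published
per-measurement means.
"""
from isodrr import (bland_altman, format_summary, icc_a_k, load_mean_pairs,
                    load_observer_table, summarize_measurements)

matrix = load_observer_table()
icc, lo, hi = icc_a_k(matrix)
print(f"ICC(A,k) over {matrix.n_items} items x {matrix.n_raters} observers: "
      f"{icc:.3f} (95% CI {lo:.3f}-{hi:.3f})")
print("values above 0.9 count as excellent inter-observer agreement\n")

summary, _ = summarize_measurements(matrix)
print("per-measurement summary (mm, observer means and SDs):")
print(format_summary(summary).to_string())

names, pairs = load_mean_pairs()
r = bland_altman(pairs)
print(f"\nBland-Altman on the {len(pairs)} published mean pairs (real - DRR):")
print(f"  bias {r.bias_mm:.2f} mm, SD {r.sd_mm:.2f}, "
      f"95% limits of agreement {r.loa_high_mm:.2f} to {r.loa_low_mm:.2f} mm")
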