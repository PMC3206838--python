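"""Gene-list stability (POG) between two studies, against their IR.

Two pairs of studies: one shares a low-IR subspace signature (like two
tumor/control cohorts), one carries independent residual-space signal (like
two relapse cohorts).  Stability is the percentage of overlapping genes in
the two top-5% Welch-ranked lists.
"""

from irstab import SimConfig, simulate_study_pair
from irstab.stability import pair_stability

for mode, shared, label in (
        ("subspace", True, "shared low-IR signature"),
        ("residual", False, "independent high-IR signal")):
    cfg = SimConfig(signal_mode=mode, seed=1000)
    (sa, ca, _), (sb, cb, _) = simulate_study_pair(cfg, shared, 11, 12)
    row = pair_stability(sa, sb, ca, cb, n=4)
    print(f"{label:32s}  mean IR = {row['mean_ir']:.3f}   POG = {row['pog']:.0f}%")

print("\nLow-IR phenotypes yield reproducible biomarker lists across studies;")
print("high-IR phenotypes give near-chance overlap (5% lists ~ 5% baseline).")
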