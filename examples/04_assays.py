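"""Copy-number and growth assays.

qPCR delta-Ct chain: a strain's plasmid copy number is its marker/reference
ratio scaled through an internal control of known copy number (~11 copies
for the lab-strain 2-micron plasmid).  Growth: doubling times from
log-linear OD600 fits, relative growth, and a paired t-test.
"""

import numpy as np

from ampfit import assays, simdata

# qPCR: strain carrying ~6 copies, control at 11 copies, noisy Cts
strain, control = simdata.simulate_qpcr(6.0, 11.0, noise_sd_ct=0.15, seed=2)
ratio_s, ratio_c = assays.qpcr_ratio(strain), assays.qpcr_ratio(control)
copies = assays.copy_number(ratio_s, ratio_c, control_copy=11.0)
print(f"qPCR ratios strain={ratio_s:.2f} control={ratio_c:.2f} -> "
      f"{copies:.1f} copies per haploid genome (true 6.0)")

# RPKM for a sequencing-based copy estimate
print(f"RPKM(1000 reads, 2 kb, 10M total) = "
      f"{assays.rpkm(1000, 2000, 10_000_000):.1f}")

# doubling times: vector strain vs empty-vector control, 3 replicate pairs
tests = [simdata.simulate_growth(1.95, noise=0.02, seed=10 + i)
         for i in range(3)]
ctrls = [simdata.simulate_growth(1.5, noise=0.02, seed=20 + i)
         for i in range(3)]
dt_test = [assays.doubling_time(c) for c in tests]
dt_ctrl = [assays.doubling_time(c) for c in ctrls]
rel = assays.relative_growth(tests, ctrls)
print(f"doubling times test={np.round(dt_test, 2)} h, "
      f"control={np.round(dt_ctrl, 2)} h")
print(f"relative growth {rel['mean']:.2f} +/- {rel['sd']:.2f} (true 1.30)")
res = assays.paired_ttest(dt_test, dt_ctrl, sides="one", direction="greater")
print(f"one-tailed paired t-test (test slower): t={res.t:.2f}, "
      f"p={res.p_value:.4f}")
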