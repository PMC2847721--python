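"""Melt-curve QC for a multi-product (pooled-repeat) assay.

Pooled Alu amplification legitimately melts at several temperatures, so
the QC rule is replicate concordance: technical replicates of one sample
must share their -dF/dT peak pattern, while different samples may differ.
"""

from earnorm import (MeltComponent, curve_peaks, replicate_concordance,
                     simulate_melt)

mix_s1 = [MeltComponent(69.0, 0.6, 0.8), MeltComponent(88.69, 0.5, 1.0)]
mix_s2 = [MeltComponent(80.0, 0.6, 0.9), MeltComponent(88.69, 0.5, 1.0)]

reps_s1 = [curve_peaks(simulate_melt(mix_s1, noise_sd=0.002, seed=s,
                                     well_id=f"S1-rep{s}")) for s in (1, 2)]
reps_s2 = [curve_peaks(simulate_melt(mix_s2, noise_sd=0.002, seed=s,
                                     well_id=f"S2-rep{s}")) for s in (3, 4)]

for peaks in reps_s1 + reps_s2:
    temps = ", ".join(f"{t:.1f}" for t in peaks.peak_temperatures)
    print(f"{peaks.well_id}: peaks at {temps} degC")

print("sample 1 replicates:", replicate_concordance(reps_s1).status)
print("sample 2 replicates:", replicate_concordance(reps_s2).status)
print("cross-sample check :", replicate_concordance([reps_s1[0],
                                                     reps_s2[0]]).status)
print()
print("Replicates of each sample pass; the cross-sample comparison fails")
print("because the two samples amplified different repeat mixtures.")
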