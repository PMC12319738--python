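"""Aggregate g-ratio from MWF and the intra-axonal signal fraction.

Chains the ex vivo calibration MVF = 0.859·MWF/(0.384·MWF + 0.475), the
axon volume fraction AVF = (1−MVF)·f_ia, and g = (1 + MVF/AVF)^(−1/2) for
a few representative white-matter states.  Well-myelinated voxels land in
the 0.7–0.8 range; g → 1 as myelin vanishes.
"""

from axomyelin import avf_from_mvf, gratio_from_fractions, mvf_from_mwf

print(" MWF    f_ia   MVF     AVF     g")
for mwf, f_ia in [(0.00, 0.70), (0.10, 0.80), (0.20, 0.60), (0.30, 0.80)]:
    mvf = mvf_from_mwf(mwf)
    avf = avf_from_mvf(mvf, f_ia)
    g = gratio_from_fractions(mvf, avf)
    print(f" {mwf:.2f}   {f_ia:.2f}   {mvf:.4f}  {avf:.4f}  {g:.4f}")
print("\nzero myelin gives g = 1; increasing MWF at fixed f_ia lowers g.")
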