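"""Translate ex vivo attenuation thresholds to the in vivo intensity scale.

The bench calibration expresses aeration thresholds as signal attenuation
relative to a fully deflated lung (0.70 for non-aerated, 0.28 for poorly
aerated tissue).  A patient has no deflated-lung reference, but collapsed
(atelectatic) tissue plays the same role: multiplying its muscle-normalized
intensity (canonically 0.92) by the attenuation thresholds yields the
intensity thresholds applied to patient scans.
"""

from lungaerate import reference_data
from lungaerate.invivo import translate_thresholds

thr = translate_thresholds(
    mri_atel=reference_data.MRI_ATEL_REFERENCE,           # 0.92
    threshold_nonaerated=reference_data.EXVIVO_THRESHOLD_NONAERATED,  # 0.70
    threshold_poor=reference_data.EXVIVO_THRESHOLD_POOR,              # 0.28
)

full = thr.provenance["full_precision"]
rounded = thr.provenance["rounded_values"]
print(f"non-aerated threshold: {full[0]:.4f}  (reported as {rounded[0]})")
print(f"poorly aerated threshold: {full[1]:.4f}  (reported as {rounded[1]})")
# A lung voxel with muscle-normalized intensity >= 0.64 is counted as
# non-aerated; between 0.26 and 0.64 as poorly aerated; below 0.26 as
# normally or hyper-aerated.
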