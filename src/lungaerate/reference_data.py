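"""Reference values from the original ex vivo porcine calibration experiment.

These are the printed study inputs the package's worked examples and the
``reproduce-paper`` workflow operate on: the per-sample lung masses
(airways removed, grams) of the 11 bench samples, the retained
extravascular-lung-water fractions of the three saline-instilled samples,
the attenuation thresholds the calibration produced, and the canonical
atelectasis reference intensity measured in patients.
"""

from __future__ import annotations

#: per-sample lung tissue mass (g) after surgical removal of the large
#: airways, 8 healthy followed by 3 injured samples
SAMPLE_MASSES_G = (
    93.6, 123.0, 120.3, 152.4, 183.4, 114.1, 92.7, 77.7,   # healthy
    185.6, 152.5, 149.7,                                   # injured
)

#: retained extravascular lung water per gram of tissue (g/g) for the
#: three saline-instilled samples, as reported in the sample table
EVLW_FRACTIONS = (0.31, 0.33, 0.36)

#: ex vivo attenuation thresholds (MRI_CPAP/MRI_0) at the gas-fraction
#: cut-offs 0.1 and 0.5, with 95% CIs
EXVIVO_THRESHOLD_NONAERATED = 0.70
EXVIVO_THRESHOLD_NONAERATED_CI = (0.65, 0.74)
EXVIVO_THRESHOLD_POOR = 0.28
EXVIVO_THRESHOLD_POOR_CI = (0.27, 0.30)

#: mean muscle-normalized intensity of atelectatic tissue in patient scans
MRI_ATEL_REFERENCE = 0.92

#: two-decimal in vivo intensity thresholds derived from the above
INVIVO_THRESHOLD_NONAERATED = 0.64
INVIVO_THRESHOLD_POOR = 0.26
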