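"""Quantify aeration compartments in a synthetic thorax scan.

Generates a supine thorax phantom (two breath-hold blocks with different
scanner gains, ventro-dorsal gradient, dorsal atelectasis), samples the
muscle reference per block, merges the blocks into a muscle-normalized
volume, anchors the thresholds on the atelectasis ROI, and reports
compartment volumes against the generator's ground truth.
"""

from lungaerate.pipeline import quantify_blocks
from lungaerate.synthetic import InvivoConfig, generate_invivo_scan

scan = generate_invivo_scan(InvivoConfig(noise_sigma=0.05), seed=1)
result = quantify_blocks(scan.blocks, scan.mask, scan.muscle_rois,
                         scan.atelectasis_roi)

rep = result["report"]
print(f"MRI_ATEL (atelectasis reference): {result['mri_atel']:.3f}")
print(f"thresholds: {rep['thresholds']['t_nonaerated']:.3f} / "
      f"{rep['thresholds']['t_poor']:.3f}")
print(f"total lung volume: {rep['total_lung_volume_ml']:.0f} mL "
      f"(truth {scan.truth['tlv_ml']:.0f} mL)")
for cls in ("non_aerated", "poorly_aerated", "normal_hyper_aerated"):
    print(f"  {cls:21s} {rep['volumes_ml'][cls]:7.1f} mL "
          f"({rep['percent_of_tlv'][cls]:5.2f} % TLV)")
print(f"truth: non-aerated {scan.truth['non_aerated_pct']:.2f} %, "
      f"poorly aerated {scan.truth['poorly_aerated_pct']:.2f} %")
print(f"ventral mean {rep['ventral_mean_signal']:.3f} < "
      f"dorsal mean {rep['dorsal_mean_signal']:.3f} (supine gradient)")

worst = max(r["max_abs_delta_percent_tlv"]
            for r in result["threshold_sensitivity"])
print(f"max compartment shift under +/-5% threshold perturbation: "
      f"{worst:.2f} % TLV")
# The recovered compartments track the painted truth to within the noise
# level, and the dorsal region is brighter, as in supine subjects.
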