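"""In vivo aeration quantification on muscle-normalized thorax scans.

The ex vivo calibration yields attenuation thresholds (relative to a fully
deflated lung) at the gas-fraction cut-offs 0.1 and 0.5.  In a patient the
deflated-lung reference is unavailable, but collapsed (atelectatic) tissue
plays the same role: its muscle-normalized intensity ``MRI_ATEL`` anchors
the scale, and in vivo intensity thresholds follow as
``t = MRI_ATEL * MRI_ATT_threshold``.  Voxels under the lung mask are then
classified into non-aerated, poorly aerated, and normally-or-hyper-aerated
compartments, reported as mL and % of total lung volume (TLV), with the
ventro-dorsal gradient assessed in two equally spaced anterior-posterior
regions.  Paired pre-/post-operative comparisons use the Wilcoxon
signed-rank test; the ROI x time design uses a classical two-way
repeated-measures ANOVA with Sidak-adjusted pairwise contrasts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .imaging import Mask, RoiSpec, Volume, mask_volume_ml, mean_signal, roi_mask, sample_roi

logger = logging.getLogger(__name__)

LABEL_NORMAL = 0      # normally or hyper-aerated (merged class)
LABEL_POOR = 1
LABEL_NONAERATED = 2

CLASS_NAMES = {LABEL_NONAERATED: "non_aerated", LABEL_POOR: "poorly_aerated",
               LABEL_NORMAL: "normal_hyper_aerated"}


@dataclass
class ThresholdSet:
    """Aeration thresholds on a declared intensity scale.

    ``scale`` is ``"attenuation"`` (ex vivo, relative to the deflated lung)
    or ``"muscle-normalized-intensity"`` (in vivo).  Provenance records how
    in vivo values were obtained (atelectasis reference, ex vivo thresholds,
    rounding applied).
    """

    scale: str
    t_nonaerated: float
    t_poor: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("attenuation", "muscle-normalized-intensity"):
            raise ValueError(f"unknown threshold scale {self.scale!r}")
        if not (self.t_nonaerated > self.t_poor > 0):
            raise ValueError(
                f"need t_nonaerated > t_poor > 0, got "
                f"{self.t_nonaerated} / {self.t_poor}"
            )

    def scaled(self, factor_non: float = 1.0, factor_poor: float = 1.0
               ) -> "ThresholdSet":
        return ThresholdSet(
            scale=self.scale,
            t_nonaerated=self.t_nonaerated * factor_non,
            t_poor=self.t_poor * factor_poor,
            provenance={**self.provenance,
                        "perturbation": (factor_non, factor_poor)},
        )


@dataclass
class AerationReport:
    """Per-scan compartment volumes and ROI statistics (one table row)."""

    scan_label: str
    total_lung_volume_ml: float
    volumes_ml: dict            # class name -> mL
    percent_of_tlv: dict        # class name -> %
    mean_normalized_signal: float
    ventral_mean_signal: float | None
    dorsal_mean_signal: float | None
    thresholds: ThresholdSet

    def __post_init__(self) -> None:
        total = sum(self.volumes_ml.values())
        if self.total_lung_volume_ml > 0 and not math.isclose(
                total, self.total_lung_volume_ml, rel_tol=1e-6):
            raise ValueError(
                f"class volumes sum to {total} mL != TLV "
                f"{self.total_lung_volume_ml} mL"
            )
        if abs(sum(self.percent_of_tlv.values()) - 100.0) > 1e-4 \
                and self.total_lung_volume_ml > 0:
            raise ValueError("class percentages do not sum to 100")

    def to_dict(self) -> dict:
        return {
            "scan_label": self.scan_label,
            "total_lung_volume_ml": self.total_lung_volume_ml,
            "volumes_ml": self.volumes_ml,
            "percent_of_tlv": self.percent_of_tlv,
            "mean_normalized_signal": self.mean_normalized_signal,
            "ventral_mean_signal": self.ventral_mean_signal,
            "dorsal_mean_signal": self.dorsal_mean_signal,
            "thresholds": {
                "scale": self.thresholds.scale,
                "t_nonaerated": self.thresholds.t_nonaerated,
                "t_poor": self.thresholds.t_poor,
                "provenance": self.thresholds.provenance,
            },
        }


# ---------------------------------------------------------------------------
# threshold translation
# ---------------------------------------------------------------------------

def atelectasis_reference(volume_normalized: Volume, roi: RoiSpec,
                          mask: Mask | None = None) -> float:
    """Mean muscle-normalized signal of a cubic ROI inside collapsed tissue.

    When a lung mask is given, the ROI must lie fully inside it; an ROI that
    leaks into aerated voxels biases the reference low, so partial coverage
    is rejected rather than silently averaged.
    """
    if volume_normalized.units != "muscle-normalized":
        raise ValueError("atelectasis reference requires a muscle-normalized volume")
    rmask = roi_mask(volume_normalized, roi)
    if mask is not None:
        mask.check_paired(volume_normalized)
        outside = rmask.data & ~mask.data
        if outside.any():
            raise ValueError(
                f"atelectasis ROI has {int(outside.sum())} voxel(s) outside "
                f"the lung mask"
            )
    return mean_signal(volume_normalized, rmask)


def translate_thresholds(mri_atel: float, threshold_nonaerated: float,
                         threshold_poor: float, rounded: bool = False
                         ) -> ThresholdSet:
    """Map ex vivo attenuation thresholds onto the in vivo intensity scale.

    ``t = MRI_ATEL * MRI_ATT_threshold`` per class.  With ``rounded=True``
    the two-decimal convenience values are applied (the presentation used
    in clinical reports); full-precision values are always recorded in the
    provenance.
    """
    if mri_atel <= 0:
        raise ValueError(f"MRI_ATEL must be > 0, got {mri_atel}")
    t_non = mri_atel * threshold_nonaerated
    t_poor = mri_atel * threshold_poor
    prov = {
        "mri_atel": mri_atel,
        "exvivo_thresholds": (threshold_nonaerated, threshold_poor),
        "full_precision": (t_non, t_poor),
        "rounded_values": (round(t_non, 2), round(t_poor, 2)),
        "rounding_applied": rounded,
    }
    if rounded:
        t_non, t_poor = round(t_non, 2), round(t_poor, 2)
    return ThresholdSet(scale="muscle-normalized-intensity",
                        t_nonaerated=t_non, t_poor=t_poor, provenance=prov)


# ---------------------------------------------------------------------------
# voxel classification and reporting
# ---------------------------------------------------------------------------

def classify_voxels(volume_normalized: Volume, mask: Mask,
                    thresholds: ThresholdSet) -> np.ndarray:
    """Label lung voxels by aeration class.

    ``s >= t_nonaerated`` -> non-aerated; ``t_poor <= s < t_nonaerated`` ->
    poorly aerated; ``s < t_poor`` -> normally/hyper-aerated.  Returns an
    int array matching the grid, with -1 outside the mask.
    """
    if thresholds.scale != "muscle-normalized-intensity":
        raise ValueError(
            "attenuation-scale thresholds cannot be applied to an intensity "
            "volume; translate them via an atelectasis reference first"
        )
    if volume_normalized.units != "muscle-normalized":
        raise ValueError("classification requires a muscle-normalized volume")
    mask.check_paired(volume_normalized)
    s = volume_normalized.data
    labels = np.full(s.shape, -1, dtype=np.int8)
    m = mask.data
    labels[m] = LABEL_NORMAL
    labels[m & (s >= thresholds.t_poor)] = LABEL_POOR
    labels[m & (s >= thresholds.t_nonaerated)] = LABEL_NONAERATED
    return labels


def compartment_report(labels: np.ndarray, mask: Mask,
                       thresholds: ThresholdSet,
                       volume_normalized: Volume | None = None,
                       scan_label: str = "scan") -> AerationReport:
    """Compartment volumes (mL) and % of TLV from a label map."""
    voxel_ml = mask.voxel_volume_mm3 / 1000.0
    tlv = mask_volume_ml(mask)
    volumes = {}
    for code, name in CLASS_NAMES.items():
        volumes[name] = float(np.count_nonzero(labels[mask.data] == code)) * voxel_ml
    pct = {name: (100.0 * v / tlv if tlv > 0 else 0.0)
           for name, v in volumes.items()}

    mean_sig = ventral = dorsal = None
    if volume_normalized is not None:
        mean_sig = mean_signal(volume_normalized, mask)
        try:
            vmask, dmask = ventro_dorsal_split(mask)
            if vmask.data.any():
                ventral = mean_signal(volume_normalized, vmask)
            if dmask.data.any():
                dorsal = mean_signal(volume_normalized, dmask)
        except ValueError:
            logger.warning("no anterior-posterior axis label; skipping V/D ROIs")
    return AerationReport(
        scan_label=scan_label, total_lung_volume_ml=tlv, volumes_ml=volumes,
        percent_of_tlv=pct,
        mean_normalized_signal=float("nan") if mean_sig is None else mean_sig,
        ventral_mean_signal=ventral, dorsal_mean_signal=dorsal,
        thresholds=thresholds,
    )


def quantify_scan(volume_normalized: Volume, mask: Mask,
                  thresholds: ThresholdSet, scan_label: str = "scan"
                  ) -> AerationReport:
    """Classify and report in one call (the per-scan pipeline stage)."""
    labels = classify_voxels(volume_normalized, mask, thresholds)
    return compartment_report(labels, mask, thresholds, volume_normalized,
                              scan_label)


def ventro_dorsal_split(mask: Mask) -> tuple[Mask, Mask]:
    """Partition the lung mask into ventral and dorsal halves.

    The split plane bisects the anterior-posterior bounding-box extent of
    the mask (equal geometric extent, not equal voxel count).  Every lung
    voxel lands in exactly one half.
    """
    if not mask.data.any():
        raise ValueError("cannot split an empty mask")
    ap_axis = None
    for i, lab in enumerate(mask.axis_labels):
        if frozenset(lab.upper()) == frozenset("AP"):
            ap_axis = i
            break
    if ap_axis is None:
        raise ValueError(
            f"no anterior-posterior axis label in {mask.axis_labels}"
        )
    idx = np.where(mask.data.any(axis=tuple(a for a in range(3) if a != ap_axis)))[0]
    lo, hi = idx.min(), idx.max()
    mid = (lo + hi + 1) / 2.0          # bounding-box midpoint in index units
    coords = np.arange(mask.data.shape[ap_axis])
    anterior_side = mask.axis_labels[ap_axis].upper().index("A")  # 0 or 1
    first_half = coords < mid
    sel = np.ones(mask.data.shape, dtype=bool)
    shape = [1, 1, 1]
    shape[ap_axis] = -1
    first = first_half.reshape(shape)
    if anterior_side == 0:      # label like "AP": anterior at low indices
        ventral_sel, dorsal_sel = first, ~first
    else:                        # label like "PA": anterior at high indices
        ventral_sel, dorsal_sel = ~first, first
    ventral = Mask(data=mask.data & ventral_sel, spacing=mask.spacing,
                   origin=mask.origin, axis_labels=mask.axis_labels)
    dorsal = Mask(data=mask.data & dorsal_sel, spacing=mask.spacing,
                  origin=mask.origin, axis_labels=mask.axis_labels)
    return ventral, dorsal


def threshold_sensitivity(volume_normalized: Volume, mask: Mask,
                          thresholds: ThresholdSet,
                          perturbation: float = 0.05) -> list[dict]:
    """Compartment %TLV deltas under +/- perturbation of each threshold.

    Each threshold is perturbed independently and jointly; rows report the
    absolute change in %TLV per class against the baseline report.
    """
    base = quantify_scan(volume_normalized, mask, thresholds)
    rows = []
    factors = (1.0 - perturbation, 1.0 + perturbation)
    scenarios = [("t_nonaerated", (f, 1.0)) for f in factors]
    scenarios += [("t_poor", (1.0, f)) for f in factors]
    scenarios += [("both", (f, f)) for f in factors]
    for name, (fn, fp) in scenarios:
        rep = quantify_scan(volume_normalized, mask, thresholds.scaled(fn, fp))
        deltas = {
            cls: rep.percent_of_tlv[cls] - base.percent_of_tlv[cls]
            for cls in base.percent_of_tlv
        }
        rows.append({
            "perturbed": name,
            "factor_nonaerated": fn,
            "factor_poor": fp,
            "delta_percent_tlv": deltas,
            "max_abs_delta_percent_tlv": max(abs(d) for d in deltas.values()),
        })
    return rows


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------

def paired_wilcoxon(pre_values: Sequence[float], post_values: Sequence[float]
                    ) -> float:
    """Two-sided Wilcoxon signed-rank p via the normal approximation.

    Zero differences are dropped; no continuity correction (this convention
    yields p = 0.028 for six uniformly signed pairs, the value clinical
    reports print for n = 6).
    """
    from scipy.stats import wilcoxon

    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired lists must have equal length")
    if pre.size < 4:
        raise ValueError(f"need at least 4 pairs, got {pre.size}")
    diffs = post - pre
    if np.all(diffs == 0):
        raise ValueError("all paired differences are zero; test undefined")
    res = wilcoxon(pre, post, zero_method="wilcox", correction=False,
                   method="approx")
    return float(res.pvalue)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity adjustment 1 - (1 - p)^m for m contrasts."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return 1.0 - (1.0 - p) ** m


def _paired_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """p-value of the within-subject contrast a - b (F = t^2, df (1, n-1))."""
    from scipy.stats import f as f_dist

    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            logger.warning("zero-variance contrast; returning p = 1")
            return 1.0
        return 0.0
    t = d.mean() / (sd / math.sqrt(n))
    return float(f_dist.sf(t ** 2, 1, n - 1))


def rm_anova_roi_time(ventral_pre: Sequence[float], dorsal_pre: Sequence[float],
                      ventral_post: Sequence[float], dorsal_post: Sequence[float]
                      ) -> dict:
    """Two-way repeated-measures ANOVA on the 2x2 ROI x time design.

    Subjects are the blocking factor; with two levels per factor each main
    effect and the interaction reduce to a within-subject contrast tested
    with F(1, n-1) = t^2 — the classical univariate RM-ANOVA for a 2x2
    design.  Pairwise contrasts (each factor within each level of the
    other) are Sidak-adjusted with m = 2 per family.
    """
    cells = [np.asarray(v, dtype=float) for v in
             (ventral_pre, dorsal_pre, ventral_post, dorsal_post)]
    n = cells[0].size
    if any(c.size != n for c in cells):
        raise ValueError("all four cells must contain one value per subject")
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    vpre, dpre, vpost, dpost = cells

    roi_p = _paired_f_test((dpre + dpost) / 2, (vpre + vpost) / 2)
    time_p = _paired_f_test((vpost + dpost) / 2, (vpre + dpre) / 2)
    inter_p = _paired_f_test(dpost - vpost, dpre - vpre)

    contrasts = {
        "dorsal_vs_ventral_pre": _paired_f_test(dpre, vpre),
        "dorsal_vs_ventral_post": _paired_f_test(dpost, vpost),
        "post_vs_pre_ventral": _paired_f_test(vpost, vpre),
        "post_vs_pre_dorsal": _paired_f_test(dpost, dpre),
    }
    adjusted = {k: sidak_adjust(p, 2) for k, p in contrasts.items()}
    return {
        "p_roi": roi_p,
        "p_time": time_p,
        "p_interaction": inter_p,
        "pairwise_raw": contrasts,
        "pairwise_sidak": adjusted,
        "n_subjects": n,
    }
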