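"""Digital phantoms with known ground truth for every pipeline stage.

Two experiments are emulated:

* **Ex vivo bench**: isolated lungs of known mass scanned at CPAP levels
  0, 40, 10 and 2 cmH2O beside sealed water and muscle reference tubes.
  Signal is painted as the exact inverse of the analysis-direction model
  ``density = a * s^2 + b`` (or proportionally to density in the linear
  mode), so the calibration fits are closed-loop recoverable.

* **In vivo thorax**: a body with two lung ellipsoids, a ventro-dorsal
  normalized-signal gradient, an anterior muscle band, and an optional
  dorsal atelectasis blob with a poorly-aerated shell.  The scan is
  emitted as 2-3 contiguous axial blocks with distinct scanner gains, as
  acquired over consecutive breath-holds.

Noise is Rician (magnitude MRI): each voxel ``v`` becomes
``sqrt((v + n1)^2 + n2^2)`` with independent zero-mean Gaussians; in
signal-free air this reduces to a Rayleigh floor with mean
``sigma * sqrt(pi/2)``, which is what makes the measured SNR finite.

All generation is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import LPS_LABELS, Mask, RAS_LABELS, RoiSpec, Volume

# default inflation factors V_CPAP / V_0 per pressure level (cmH2O)
DEFAULT_INFLATION = {0: 1.0, 40: 3.3, 10: 2.0, 2: 1.35}


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_rician_noise(volume: Volume, sigma: float,
                     seed: int | np.random.Generator = 0) -> Volume:
    """Rician-corrupt a magnitude image; ``sigma = 0`` is the identity."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return Volume(data=volume.data.copy(), spacing=volume.spacing,
                      origin=volume.origin, axis_labels=volume.axis_labels,
                      units=volume.units)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=volume.data.shape)
    n2 = rng.normal(0.0, sigma, size=volume.data.shape)
    noisy = np.sqrt((volume.data + n1) ** 2 + n2 ** 2)
    return Volume(data=noisy, spacing=volume.spacing, origin=volume.origin,
                  axis_labels=volume.axis_labels, units=volume.units)


def _rician_array(data: np.ndarray, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return data.copy()
    n1 = rng.normal(0.0, sigma, size=data.shape)
    n2 = rng.normal(0.0, sigma, size=data.shape)
    return np.sqrt((data + n1) ** 2 + n2 ** 2)


# ---------------------------------------------------------------------------
# ex vivo
# ---------------------------------------------------------------------------

@dataclass
class ExvivoConfig:
    """Study conditions for the ex vivo bench phantom.

    Defaults mirror the calibration experiment: 8 healthy + 3 saline-
    instilled lungs with masses 131.4 +/- 34.6 g, scanned at CPAP
    {0, 40, 10, 2} cmH2O.  The signal model is ``density = a * s^2 + b``
    in raw GU at unit gain (``signal_mode="quadratic"``); the linear mode
    paints signal strictly proportional to density, the closed-form limit
    in which the attenuation line is exactly ``1 - GAS_F``.
    """

    n_healthy: int = 8
    n_injured: int = 3
    mass_mean_g: float = 131.4
    mass_sd_g: float = 34.6
    specific_volume_ml_per_g: float = 0.96    # deflated lung, ~1.04 g/mL
    inflation_factors: dict = field(
        default_factory=lambda: dict(DEFAULT_INFLATION))
    inflation_jitter_sd: float = 0.05         # lognormal jitter on factors >1
    signal_mode: str = "quadratic"            # "quadratic" | "linear"
    coef_a: float = 1e-4                      # g/mL per GU^2 (quadratic mode)
    coef_b: float = 0.05                      # g/mL
    linear_gain_gu_per_density: float = 100.0  # GU per g/mL (linear mode)
    injury_density_offset: float = 0.0        # g/mL added for injured lungs
    evlw_mean: float = 0.33                   # g fluid per g tissue (injured)
    evlw_sd: float = 0.02
    sample_gain_sd: float = 0.02              # per-sample scanner gain spread
    water_gu: float = 300.0
    muscle_gu: float = 200.0
    air_floor_gu: float = 1.5                 # painted background level
    signal_noise_frac: float = 0.02           # sd of measured mean signal
    volume_noise_frac: float = 0.01           # sd of measured volume
    noise_sigma_gu: float = 1.5               # Rician sigma for images
    spacing_mm: tuple = (2.5, 2.5, 5.0)

    def pressures(self) -> list[int]:
        return sorted(self.inflation_factors, key=[0, 40, 10, 2].index)


def _true_signal(cfg: ExvivoConfig, density: float, injured: bool) -> float:
    """Raw-GU signal at unit gain for a given tissue density."""
    rho = density - (cfg.injury_density_offset if injured else 0.0)
    if cfg.signal_mode == "linear":
        s = rho * cfg.linear_gain_gu_per_density
        if s <= 0:
            raise ValueError(f"density {density} outside linear signal range")
        return s
    arg = (rho - cfg.coef_b) / cfg.coef_a
    if arg <= 0:
        raise ValueError(
            f"density {density:.3f} g/mL outside the invertible range of the "
            f"quadratic signal model (b = {cfg.coef_b})"
        )
    return math.sqrt(arg)


def generate_exvivo_table(config: ExvivoConfig | None = None, seed: int = 0
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-table realization of the ex vivo experiment (no images).

    Returns ``(records, truth)``: the measured per-(sample, CPAP) table in
    the calibration input schema, and the exactly consistent ground truth
    (mass = density * volume to 1e-9 by construction).
    """
    cfg = config or ExvivoConfig()
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    groups = ["healthy"] * cfg.n_healthy + ["injured"] * cfg.n_injured
    for i, group in enumerate(groups):
        sid = f"S{i + 1:02d}"
        injured = group == "injured"
        mass = max(30.0, rng.normal(cfg.mass_mean_g, cfg.mass_sd_g))
        evlw = rng.normal(cfg.evlw_mean, cfg.evlw_sd) if injured else np.nan
        gain = rng.normal(1.0, cfg.sample_gain_sd)
        v0 = mass * cfg.specific_volume_ml_per_g
        for p in cfg.pressures():
            f = cfg.inflation_factors[p]
            if f > 1.0 and cfg.inflation_jitter_sd > 0:
                f = 1.0 + (f - 1.0) * rng.lognormal(0.0, cfg.inflation_jitter_sd)
            v_true = v0 * f
            density = mass / v_true
            s_true = _true_signal(cfg, density, injured) * gain
            v_meas = v_true * (1.0 + rng.normal(0.0, cfg.volume_noise_frac))
            s_meas = s_true * (1.0 + rng.normal(0.0, cfg.signal_noise_frac))
            rows.append({
                "sample_id": sid, "group": group, "mass_g": mass,
                "evlw_fraction": evlw, "cpap_cmh2o": p,
                "volume_ml": v_meas, "mean_signal_gu": s_meas,
                "water_ref_gu": cfg.water_gu * gain,
                "muscle_ref_gu": cfg.muscle_gu * gain,
                "air_ref_gu": cfg.air_floor_gu,
            })
            truth_rows.append({
                "sample_id": sid, "group": group, "cpap_cmh2o": p,
                "mass_g": mass, "volume_ml": v_true,
                "density_g_per_ml": density,
                "gas_fraction": (v_true - v0) / v_true,
                "signal_gu": s_true, "gain": gain, "seed": seed,
            })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


@dataclass
class ExvivoScan:
    """One rasterized bench scan: image, lung mask and reference ROIs."""

    sample_id: str
    cpap_cmh2o: int
    volume: Volume
    mask: Mask
    water_roi: RoiSpec
    muscle_roi: RoiSpec
    air_roi: RoiSpec


def _ellipsoid_mask(shape: tuple, spacing: Sequence[float],
                    center_mm: Sequence[float],
                    semi_mm: Sequence[float]) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    d = [(coords[i] - center_mm[i]) / semi_mm[i] for i in range(3)]
    return (d[0][:, None, None] ** 2 + d[1][None, :, None] ** 2
            + d[2][None, None, :] ** 2) <= 1.0


def generate_exvivo_dataset(config: ExvivoConfig | None = None, seed: int = 0,
                            n_samples: int | None = None
                            ) -> tuple[list[ExvivoScan], pd.DataFrame, pd.DataFrame]:
    """Rasterized ex vivo scans plus the sample table and truth table.

    Each scan paints a lung ellipsoid of the true inflated volume at the
    true signal level, beside water/muscle tubes and an air background
    floor, then applies Rician noise.  ``n_samples`` truncates the sample
    list for fast image-based tests; the returned tables always match the
    rasterized scans.
    """
    cfg = config or ExvivoConfig()
    records, truth = generate_exvivo_table(cfg, seed)
    if n_samples is not None:
        keep = records["sample_id"].unique()[:n_samples]
        records = records[records["sample_id"].isin(keep)].reset_index(drop=True)
        truth = truth[truth["sample_id"].isin(keep)].reset_index(drop=True)
    rng = np.random.default_rng(seed + 1)

    sx, sy, sz = cfg.spacing_mm
    # grid sized for the largest inflated lung plus reference tubes
    vmax_ml = float(truth["volume_ml"].max())
    t = (vmax_ml * 1000.0 * 3 / (4 * math.pi * 1.0 * 0.8 * 1.4)) ** (1 / 3)
    semi_max = (t, 0.8 * t, 1.4 * t)
    margin = 30.0
    extent = (2 * semi_max[0] + 2 * margin + 60.0,   # room for tubes in x
              2 * semi_max[1] + 2 * margin,
              2 * semi_max[2] + 2 * margin)
    shape = tuple(int(math.ceil(e / s)) for e, s in zip(extent, (sx, sy, sz)))

    scans = []
    for (sid, p), sub in truth.groupby(["sample_id", "cpap_cmh2o"], sort=False):
        row = sub.iloc[0]
        rec = records[(records["sample_id"] == sid)
                      & (records["cpap_cmh2o"] == p)].iloc[0]
        tt = (row["volume_ml"] * 1000.0 * 3
              / (4 * math.pi * 1.0 * 0.8 * 1.4)) ** (1 / 3)
        semi = (tt, 0.8 * tt, 1.4 * tt)
        center = (semi_max[0] + margin + 60.0,
                  extent[1] / 2.0, extent[2] / 2.0)
        grid = np.full(shape, cfg.air_floor_gu)
        lung = _ellipsoid_mask(shape, (sx, sy, sz), center, semi)
        grid[lung] = row["signal_gu"]

        # reference tubes: vertical cylinders left of the lung
        tube_r, tube_len = 12.0, 80.0
        z0, z1 = center[2] - tube_len / 2, center[2] + tube_len / 2
        xs = np.arange(shape[0]) * sx
        ys = np.arange(shape[1]) * sy
        zs = np.arange(shape[2]) * sz
        in_z = (zs >= z0) & (zs <= z1)
        tubes = {}
        for name, cx, value in (
                ("water", 18.0, cfg.water_gu * row["gain"]),
                ("muscle", 46.0, cfg.muscle_gu * row["gain"])):
            cy = extent[1] / 2.0
            in_plane = ((xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2
                        <= tube_r ** 2)
            tube = in_plane[:, :, None] & in_z[None, None, :]
            grid[tube] = value
            tubes[name] = RoiSpec(shape="sphere", center_mm=(cx, cy, center[2]),
                                  size_cm3=2.03)
        air_roi = RoiSpec(
            shape="sphere",
            center_mm=(extent[0] - 15.0, 15.0, center[2]), size_cm3=2.03,
        )
        noisy = _rician_array(grid, cfg.noise_sigma_gu, rng)
        vol = Volume(data=noisy, spacing=(sx, sy, sz), axis_labels=RAS_LABELS)
        scans.append(ExvivoScan(
            sample_id=sid, cpap_cmh2o=int(p), volume=vol,
            mask=Mask.from_volume(vol, lung),
            water_roi=tubes["water"], muscle_roi=tubes["muscle"],
            air_roi=air_roi,
        ))
    return scans, records, truth


def generate_attenuation_records(n_samples: int = 11, slope: float = -1.05,
                                 intercept: float = 0.805,
                                 gas_f_levels: Sequence[float] = (0.02, 0.25, 0.5, 0.7),
                                 gasf_jitter_sd: float = 0.02,
                                 sample_intercept_sd: float = 0.02,
                                 noise_sd: float = 0.03,
                                 seed: int = 0) -> pd.DataFrame:
    """Attenuation observations drawn from a known line.

    Statistical test bed for the attenuation fit and threshold bootstrap:
    per sample, one gas fraction near each configured level (4 pressures)
    and ``mri_att = intercept + slope * gas_f + b_i + eps`` with a random
    per-sample intercept ``b_i`` and residual noise ``eps``.  The defaults
    place the true thresholds at 0.70 (cut-off 0.1) and 0.28 (cut-off 0.5).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        b_i = rng.normal(0.0, sample_intercept_sd)
        for level in gas_f_levels:
            g = float(np.clip(level + rng.normal(0.0, gasf_jitter_sd), 0.0, 0.95))
            att = intercept + slope * g + b_i + rng.normal(0.0, noise_sd)
            rows.append({"sample_id": f"S{i + 1:02d}", "gas_fraction": g,
                         "mri_att": att})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# in vivo
# ---------------------------------------------------------------------------

@dataclass
class InvivoConfig:
    """Study conditions for the supine thorax phantom.

    The painted field is in muscle-normalized units (muscle band = 1.0);
    raw blocks are obtained by multiplying with ``muscle_gu`` and a
    per-block scanner gain.  The ventro-dorsal gradient runs from
    ``ventral_mean`` (anterior) to ``dorsal_mean`` (posterior), matching
    the gravitational density gradient of a supine subject.  The optional
    dorsal atelectasis blob is painted at ``atelectasis_intensity`` with a
    surrounding poorly-aerated shell.
    """

    shape: tuple = (64, 64, 60)
    spacing_mm: tuple = (3.0, 3.0, 5.0)
    body_semi_mm: tuple = (92.0, 86.0)        # elliptic trunk cross-section
    lung_semi_mm: tuple = (32.0, 55.0, 110.0)
    lung_offset_x_mm: float = 45.0
    soft_tissue_intensity: float = 0.75       # non-muscle trunk tissue
    muscle_intensity: float = 1.0
    muscle_band_halfwidth_mm: float = 7.0
    ventral_mean: float = 0.08
    dorsal_mean: float = 0.18
    atelectasis: bool = True
    atelectasis_intensity: float = 0.92
    poor_intensity: float = 0.40
    fraction_nonaerated: float = 0.10         # of TLV, painted blob target
    fraction_poor: float = 0.16
    thresholds: tuple = (0.64, 0.26)          # used for the truth labelling
    n_blocks: int = 2
    block_gains: tuple = (1.0, 1.2, 0.9)
    muscle_gu: float = 180.0
    noise_sigma: float = 0.05                 # Rician sigma, normalized units
    axis_labels: tuple = RAS_LABELS           # axis 1 runs posterior->anterior


@dataclass
class InvivoScan:
    """A generated thorax acquisition with ground truth."""

    blocks: list                  # raw-GU Volume per breath-hold block
    mask: Mask                    # lung mask on the merged grid
    muscle_rois: list             # per-block RoiSpec (disc, block-local coords)
    atelectasis_roi: RoiSpec | None
    normalized_truth: Volume      # painted pre-noise muscle-normalized field
    truth: dict


def generate_invivo_scan(config: InvivoConfig | None = None, seed: int = 0
                         ) -> InvivoScan:
    cfg = config or InvivoConfig()
    if cfg.n_blocks not in (2, 3):
        raise ValueError(f"block count must be 2 or 3, got {cfg.n_blocks}")
    rng = np.random.default_rng(seed)
    nx, ny, nz = cfg.shape
    sx, sy, sz = cfg.spacing_mm
    xs = (np.arange(nx) - (nx - 1) / 2.0) * sx
    ys = (np.arange(ny) - (ny - 1) / 2.0) * sy
    zs = np.arange(nz) * sz

    field_ = np.zeros(cfg.shape)
    body = ((xs[:, None] / cfg.body_semi_mm[0]) ** 2
            + (ys[None, :] / cfg.body_semi_mm[1]) ** 2) <= 1.0
    field_[body] = cfg.soft_tissue_intensity

    # anterior muscle band: thin elliptic annulus segment, full z extent
    # anterior = +y (axis labels "PA": posterior at index 0)
    r2 = ((xs[:, None] / (cfg.body_semi_mm[0] - cfg.muscle_band_halfwidth_mm)) ** 2
          + (ys[None, :] / (cfg.body_semi_mm[1] - cfg.muscle_band_halfwidth_mm)) ** 2)
    band = body & (r2 > 1.0) & (ys[None, :] > 0.3 * cfg.body_semi_mm[1])
    field_[band] = cfg.muscle_intensity
    # solid muscle pad where the reference discs sit (guarantees coverage)
    pad_cy = cfg.body_semi_mm[1] - cfg.muscle_band_halfwidth_mm - 4.0
    pad = (np.abs(xs[:, None]) <= 20.0) & (np.abs(ys[None, :] - pad_cy) <= 10.0)
    field_[pad & body] = cfg.muscle_intensity

    zc = (zs[0] + zs[-1]) / 2.0
    lungs = np.zeros(cfg.shape, dtype=bool)
    for sign in (-1.0, 1.0):
        d = ((xs[:, None, None] - sign * cfg.lung_offset_x_mm)
             / cfg.lung_semi_mm[0]) ** 2 \
            + (ys[None, :, None] / cfg.lung_semi_mm[1]) ** 2 \
            + ((zs[None, None, :] - zc) / cfg.lung_semi_mm[2]) ** 2
        lungs |= d <= 1.0
    lungs &= body[:, :, None]

    # ventro-dorsal gradient across the lung's anterior-posterior extent
    y_lo, y_hi = ys.min(), ys.max()
    frac_anterior = (ys - y_lo) / (y_hi - y_lo)
    grad = cfg.dorsal_mean + (cfg.ventral_mean - cfg.dorsal_mean) * frac_anterior
    field_[lungs] = np.broadcast_to(grad[None, :, None], cfg.shape)[lungs]

    atel_roi = None
    if cfg.atelectasis:
        tlv_vox = int(lungs.sum())
        voxel_ml = sx * sy * sz / 1000.0
        # dorsal blob in the right lung (patient right = -x in RAS)
        target_non = cfg.fraction_nonaerated * tlv_vox
        target_outer = (cfg.fraction_nonaerated + cfg.fraction_poor) * tlv_vox
        base_semi = np.array([1.0, 0.65, 2.2])
        center = (-cfg.lung_offset_x_mm, y_lo + 0.32 * (y_hi - y_lo), zc)
        if center[1] > 0:
            raise ValueError("atelectasis blob does not fit in the dorsal half")

        def blob(scale: float) -> np.ndarray:
            semi = base_semi * scale
            d = ((xs[:, None, None] - center[0]) / semi[0]) ** 2 \
                + ((ys[None, :, None] - center[1]) / semi[1]) ** 2 \
                + ((zs[None, None, :] - center[2]) / semi[2]) ** 2
            return (d <= 1.0) & lungs

        def solve(target_vox: float) -> tuple[float, np.ndarray]:
            lo_s, hi_s = 5.0, 90.0
            for _ in range(40):
                mid = (lo_s + hi_s) / 2.0
                if blob(mid).sum() < target_vox:
                    lo_s = mid
                else:
                    hi_s = mid
            return hi_s, blob(hi_s)

        s_non, non_mask = solve(target_non)
        s_out, outer_mask = solve(target_outer)
        if not non_mask.any():
            raise ValueError("atelectasis blob target volume too small for grid")
        field_[outer_mask] = cfg.poor_intensity
        field_[non_mask] = cfg.atelectasis_intensity
        atel_roi = RoiSpec(shape="cube", center_mm=(center[0], center[1], center[2]),
                           size_cm3=2.03)

    origin = (float(xs[0]), float(ys[0]), 0.0)
    normalized_truth = Volume(data=field_, spacing=cfg.spacing_mm, origin=origin,
                              axis_labels=cfg.axis_labels,
                              units="muscle-normalized")
    mask = Mask(data=lungs, spacing=cfg.spacing_mm, origin=origin,
                axis_labels=cfg.axis_labels)

    # truth compartments from the painted field against the config thresholds
    t_non, t_poor = cfg.thresholds
    under = field_[lungs]
    voxel_ml = sx * sy * sz / 1000.0
    n_non = int((under >= t_non).sum())
    n_poor = int(((under >= t_poor) & (under < t_non)).sum())
    n_all = int(lungs.sum())
    truth = {
        "tlv_ml": n_all * voxel_ml,
        "non_aerated_ml": n_non * voxel_ml,
        "poorly_aerated_ml": n_poor * voxel_ml,
        "normal_hyper_aerated_ml": (n_all - n_non - n_poor) * voxel_ml,
        "non_aerated_pct": 100.0 * n_non / n_all,
        "poorly_aerated_pct": 100.0 * n_poor / n_all,
        "thresholds": (t_non, t_poor),
        "atelectasis_intensity": cfg.atelectasis_intensity if cfg.atelectasis else None,
        "seed": seed,
    }

    # split into contiguous axial blocks with per-block gain and noise
    edges = np.linspace(0, nz, cfg.n_blocks + 1).astype(int)
    blocks, muscle_rois = [], []
    for b in range(cfg.n_blocks):
        z0, z1 = edges[b], edges[b + 1]
        gain = cfg.block_gains[b]
        raw = field_[:, :, z0:z1] * cfg.muscle_gu * gain
        sigma_gu = cfg.noise_sigma * cfg.muscle_gu * gain
        raw = _rician_array(raw, sigma_gu, rng)
        vol = Volume(data=raw, spacing=cfg.spacing_mm,
                     origin=(origin[0], origin[1], float(zs[z0])),
                     axis_labels=cfg.axis_labels, units="gu")
        blocks.append(vol)
        mid = (z1 - z0) // 2
        muscle_rois.append(RoiSpec(
            shape="disc", center_mm=(0.0, pad_cy, float(zs[z0] + mid * sz)),
            size_cm2=0.46, slice_index=mid,
        ))
    return InvivoScan(blocks=blocks, mask=mask, muscle_rois=muscle_rois,
                      atelectasis_roi=atel_roi,
                      normalized_truth=normalized_truth, truth=truth)
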