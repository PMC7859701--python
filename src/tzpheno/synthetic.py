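"""Synthetic microscopy scenes and behavioural cohorts with known ground truth.

The generator emulates the data this pipeline is built to quantify:
phasmid-cilium transition zones (TZ, ~0.8 um hollow-shell signal with
optional axial periodicity and proximal enrichment), a pan-ciliary marker
channel spanning TZ + ~3 um middle + ~3 um distal segments, optional
periciliary "leakage" signal along the cilium, and behavioural assay
cohorts (dye-filling categories 0-4, roaming square counts, escape times
right-censored at 10 min).  Every scene carries its generating parameters
so each estimator can be validated by parameter recovery.

Rendering strategy: emitters are laid out on a fine 3D grid, blurred with
a separable Gaussian PSF, then integrated onto the detector grid
(projected along z for wide-field; binned to the z step for the
super-resolution modality).  All randomness comes from
``numpy.random.default_rng(seed)``, so identical parameters give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import PlaneImage, Polyline, VolumeStack

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SceneGroundTruth:
    """Generating parameters for one simulated phasmid-cilium scene.

    Lengths are in micrometres, amplitudes in photons per emitting voxel
    of the rendering grid, backgrounds in photons per detector pixel.
    """

    seed: int = 0
    modality: str = "widefield"  # or "superres"
    tz_length_um: float = 0.8
    tz_shell_radius_um: float = 0.125
    tz_shell_thickness_um: float = 0.05
    axial_peak_count: int = 0
    modulation_depth: float = 0.5
    asymmetry_decay_um: Optional[float] = None
    tz_amplitude: float = 50.0
    middle_segment_um: float = 3.0
    distal_segment_um: float = 3.0
    marker_amplitude: float = 20.0
    marker_radius_um: float = 0.1
    leakage_amplitude: float = 0.0
    background_level: float = 10.0
    background_gradient: float = 0.0
    psf_fwhm_um: float = 0.25
    pixel_size_um: float = 0.08
    z_step_um: float = 0.2
    read_noise_sd: float = 1.0
    shot_noise: bool = True
    n_cilia: int = 2
    pair_separation_um: float = 1.0
    # Super-res stacks emulate the deconvolved output that 3D modelling
    # consumes, so the default PSF is isotropic at the stated resolution;
    # raise this factor to model raw (axially elongated) confocal data.
    psf_axial_factor: float = 1.0

    def validate(self) -> None:
        positive = [
            "tz_length_um", "tz_shell_radius_um", "tz_shell_thickness_um",
            "middle_segment_um", "distal_segment_um", "marker_radius_um",
            "psf_fwhm_um", "pixel_size_um", "z_step_um",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        nonneg = [
            "tz_amplitude", "marker_amplitude", "leakage_amplitude",
            "background_level", "read_noise_sd", "modulation_depth",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.modality not in ("widefield", "superres"):
            raise ValueError("modality must be 'widefield' or 'superres'")
        if self.axial_peak_count < 0:
            raise ValueError("axial_peak_count must be >= 0")
        if self.asymmetry_decay_um is not None and not self.asymmetry_decay_um > 0:
            raise ValueError("asymmetry_decay_um must be > 0 or None")
        if self.n_cilia < 1:
            raise ValueError("n_cilia must be >= 1")
        if self.modulation_depth > 1:
            raise ValueError("modulation_depth must be <= 1")

    # -- presets ------------------------------------------------------------
    @staticmethod
    def widefield(**overrides) -> "SceneGroundTruth":
        """Wide-field defaults: 0.08 um pixels (20 px = 1.6 um), 0.25 um PSF."""
        return replace(SceneGroundTruth(), modality="widefield", **overrides)

    @staticmethod
    def superres(**overrides) -> "SceneGroundTruth":
        """Super-resolution confocal defaults: 26.7 nm pixels, 148.6 nm
        lateral resolution, 0.2 um z steps, a single TZ with 3 axial peaks."""
        base = SceneGroundTruth(
            modality="superres",
            pixel_size_um=0.0267,
            psf_fwhm_um=0.1486,
            z_step_um=0.2,
            n_cilia=1,
            axial_peak_count=3,
            tz_amplitude=200.0,
            marker_amplitude=0.0,
            background_level=5.0,
        )
        return replace(base, **overrides)

    @staticmethod
    def widefield_g155s(**overrides) -> "SceneGroundTruth":
        """G155S-like wide-field condition: 4-fold lower TZ amplitude,
        proximally enriched (0.3 um decay), 2 axial peaks."""
        base = SceneGroundTruth.widefield(
            tz_amplitude=12.5, asymmetry_decay_um=1.2, axial_peak_count=2
        )
        return replace(base, **overrides)

    @staticmethod
    def superres_g155s(**overrides) -> "SceneGroundTruth":
        """G155S-like super-resolution condition: amplitude x0.25, two axial
        peaks, proximal decay."""
        base = SceneGroundTruth.superres(
            tz_amplitude=50.0, axial_peak_count=2, asymmetry_decay_um=1.2
        )
        return replace(base, **overrides)


@dataclass
class SimulatedScene:
    """A rendered scene: channels, the echoed ground truth, and the
    annotations/true photon counts recovery tests need."""

    channels: dict
    truth: SceneGroundTruth
    info: dict = field(default_factory=dict)


def _axial_weight(x_um: np.ndarray, truth: SceneGroundTruth) -> np.ndarray:
    """Axial intensity modulation over the TZ, on [0, L] relative coords.

    ``1 - m*cos(2*pi*P*u)`` places exactly P interior maxima on the TZ;
    an optional exponential proximal->distal decay is applied on top.
    """
    u = x_um / truth.tz_length_um
    w = np.ones_like(x_um)
    if truth.axial_peak_count > 0:
        w = 1.0 - truth.modulation_depth * np.cos(2 * np.pi * truth.axial_peak_count * u)
    if truth.asymmetry_decay_um is not None:
        w = w * np.exp(-x_um / truth.asymmetry_decay_um)
    return w


def simulate_phasmid_scene(truth: SceneGroundTruth) -> SimulatedScene:
    """Render one phasmid scene (wide-field 2D plane or super-res z-stack).

    Returns channels ``"tz"`` (shell signal), ``"marker"`` (pan-ciliary
    axoneme signal, if ``marker_amplitude > 0``) and ``"leakage"`` (uniform
    along the cilium, if ``leakage_amplitude > 0``).  ``info`` carries the
    annotations a user would normally draw (TZ box centre, axis polylines,
    the 20-pixel line-scan) plus true photon totals for recovery tests.
    """
    truth.validate()
    wf = truth.modality == "widefield"
    psz = truth.pixel_size_um

    # Rendering grid: supersample xy twofold for wide-field (pixels are
    # coarse relative to the shell), native xy for super-res; fine z always.
    sub = 2 if wf else 1
    dxy = psz / sub
    zsub = 4
    dz = dxy if wf else truth.z_step_um / zsub

    cilium_len = truth.tz_length_um + truth.middle_segment_um + truth.distal_segment_um
    if wf:
        margin_x = 1.6
        nx_out = int(np.ceil((cilium_len + 2 * margin_x) / psz))
        half_y = max(2.0, truth.pair_separation_um / 2 + 1.5)
        ny_out = int(np.ceil(2 * half_y / psz))
        z_half = truth.tz_shell_radius_um + 0.25
        nz_f = int(np.ceil(2 * z_half / dz))
        nz_out = 1
    else:
        margin_x = 0.6
        nx_out = int(np.ceil((truth.tz_length_um + 2 * margin_x) / psz))
        ny_out = int(np.ceil(1.4 / psz))
        z_extent = max(1.6, 2 * truth.tz_shell_radius_um + 1.2)
        nz_out = max(int(round(z_extent / truth.z_step_um)), 3)
        nz_f = nz_out * zsub

    nx_f, ny_f = nx_out * sub, ny_out * sub

    xs = (np.arange(nx_f) + 0.5) * dxy
    ys = (np.arange(ny_f) + 0.5) * dxy
    zs = (np.arange(nz_f) + 0.5) * dz

    x0 = margin_x
    yc = ny_out * psz / 2.0
    zc = nz_f * dz / 2.0
    if not wf:
        # place the cilium axis on an acquisition plane so the central
        # z slice cuts through the shell axis
        plane_z = (np.arange(zsub // 2, nz_f, zsub) + 0.5) * dz
        zc = float(plane_z[np.argmin(np.abs(plane_z - zc))])
    if truth.n_cilia == 1:
        y_axes = [yc]
    else:
        sep = truth.pair_separation_um
        y_axes = [yc + (i - (truth.n_cilia - 1) / 2.0) * sep for i in range(truth.n_cilia)]

    X = xs[None, None, :]
    Y = ys[None, :, None]
    Z = zs[:, None, None]

    tz = np.zeros((nz_f, ny_f, nx_f))
    marker = np.zeros_like(tz)
    leak = np.zeros_like(tz)

    in_tz_x = (X >= x0) & (X <= x0 + truth.tz_length_um)
    in_cil_x = (X >= x0) & (X <= x0 + cilium_len)
    w_axial = np.where(
        in_tz_x, _axial_weight(np.clip(X - x0, 0, truth.tz_length_um), truth), 0.0
    )

    for y0 in y_axes:
        r = np.sqrt((Y - y0) ** 2 + (Z - zc) ** 2)
        shell = (
            (r >= truth.tz_shell_radius_um - truth.tz_shell_thickness_um / 2)
            & (r <= truth.tz_shell_radius_um + truth.tz_shell_thickness_um / 2)
        )
        core = r <= truth.marker_radius_um
        tz += truth.tz_amplitude * w_axial * (shell & in_tz_x)
        marker += truth.marker_amplitude * (core & in_cil_x)
        leak += truth.leakage_amplitude * (core & in_cil_x)

    channels_fine = {"tz": tz}
    if truth.marker_amplitude > 0:
        channels_fine["marker"] = marker
    if truth.leakage_amplitude > 0:
        channels_fine["leakage"] = leak
    true_photons = {name: float(ch.sum()) for name, ch in channels_fine.items()}

    sigma_xy = truth.psf_fwhm_um * _FWHM_TO_SIGMA / dxy
    sigma_z = truth.psf_fwhm_um * truth.psf_axial_factor * _FWHM_TO_SIGMA / dz

    rng = np.random.default_rng(truth.seed)
    out_channels: dict = {}
    bg_x = truth.background_level + truth.background_gradient * (np.arange(nx_out) + 0.5) * psz

    for name in ("tz", "marker", "leakage"):
        if name not in channels_fine:
            continue
        ch = channels_fine[name]
        if wf:
            plane = ch.sum(axis=0)  # project z first; z-blur commutes with the sum
            plane = ndimage.gaussian_filter(
                plane, sigma=sigma_xy, mode="constant", truncate=4.0
            )
            # bin the supersampled grid onto detector pixels (mass-conserving)
            plane = plane.reshape(ny_out, sub, nx_out, sub).sum(axis=(1, 3))
            img = plane + bg_x[None, :]
            img = _apply_noise(img, truth, rng)
            out_channels[name] = PlaneImage(img, psz, channel_name=name)
        else:
            vol = ndimage.gaussian_filter(
                ch, sigma=(sigma_z, sigma_xy, sigma_xy), mode="constant", truncate=4.0
            )
            # confocal z acquisition samples the blurred field at discrete
            # planes (it does not integrate over the slab); scale by the
            # plane spacing so stack totals stay on the photon scale
            vol = vol[zsub // 2 :: zsub] * zsub
            img = vol + bg_x[None, None, :]
            img = _apply_noise(img, truth, rng)
            out_channels[name] = VolumeStack(
                img, psz, truth.z_step_um, channel_name=name
            )

    tz_mid_um = x0 + truth.tz_length_um / 2.0
    axis_lines = []
    profile_lines = []
    for y0 in y_axes:
        y_px = y0 / psz - 0.5
        a = max((x0 - 0.6), 0.0) / psz - 0.5
        b = min(x0 + cilium_len + 0.6, nx_out * psz) / psz - 0.5
        axis_lines.append(Polyline([[a, y_px], [min(b, nx_out - 1.0), y_px]]))
        half_scan = 0.8  # 20 wide-field pixels = 1.6 um total
        profile_lines.append(
            Polyline(
                [
                    [(tz_mid_um - half_scan) / psz - 0.5, y_px],
                    [(tz_mid_um + half_scan) / psz - 0.5, y_px],
                ]
            )
        )

    info = {
        "tz_interval_um": (x0, x0 + truth.tz_length_um),
        "cilium_y_um": list(y_axes),
        "box_center_px": (tz_mid_um / psz - 0.5, yc / psz - 0.5),
        "axis_lines": axis_lines,
        "profile_lines": profile_lines,
        "true_photons": true_photons,
    }
    return SimulatedScene(out_channels, truth, info)


def _apply_noise(img: np.ndarray, truth: SceneGroundTruth, rng: np.random.Generator) -> np.ndarray:
    if truth.shot_noise:
        img = rng.poisson(img).astype(float)
    if truth.read_noise_sd > 0:
        img = img + rng.normal(0.0, truth.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# Allele-competition model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompetitionModel:
    """Two-allele competition for a saturable pool of TZ docking sites.

    ``k_tagged``/``k_untagged`` are the incorporation efficiencies of the
    fluorescently tagged and untagged alleles' proteins; ``site_capacity``
    is the total TZ fluorescence of the tagged homozygote.  In a
    heterozygote the two gene products compete for the same sites, so the
    tagged (visible) share is ``k_tagged / (k_tagged + k_untagged)`` —
    one half when both alleles are recruited equally well.
    """

    k_tagged: float
    k_untagged: float
    site_capacity: float = 100.0

    def __post_init__(self) -> None:
        if self.k_tagged < 0 or self.k_untagged < 0:
            raise ValueError("incorporation rates must be >= 0")
        if not self.site_capacity > 0:
            raise ValueError("site_capacity must be > 0")


def predict_het_fraction(model: CompetitionModel) -> float:
    """Predicted heterozygote fluorescence as a fraction of the homozygote."""
    total = model.k_tagged + model.k_untagged
    if total == 0:
        raise ValueError("degenerate competition: both rates are zero")
    return model.k_tagged / total


def simulate_het_cohort(
    model: CompetitionModel, n: int, noise_cv: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw matched heterozygote and homozygote fluorescence samples.

    Homozygote draws centre on ``site_capacity``; heterozygote draws on
    ``predict_het_fraction(model) * site_capacity``.  Biological scatter is
    multiplicative lognormal with the stated coefficient of variation.
    Returns ``(het, homo)`` arrays of length ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    frac = predict_het_fraction(model)
    rng = np.random.default_rng(seed)
    if noise_cv == 0:
        mult_het = np.ones(n)
        mult_homo = np.ones(n)
    else:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        mu = -sigma ** 2 / 2.0  # unit-mean lognormal
        mult_het = rng.lognormal(mu, sigma, size=n)
        mult_homo = rng.lognormal(mu, sigma, size=n)
    het = frac * model.site_capacity * mult_het
    homo = model.site_capacity * mult_homo
    return het, homo


# ---------------------------------------------------------------------------
# Behavioural cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorSimParams:
    """Parameters for one simulated behavioural cohort.

    ``dye_category_probs`` are the probabilities of a worm showing dye
    uptake in 0..4 phasmid neurons; roaming square counts are negative
    binomial (mean, dispersion); escape from the osmotic ring is an
    exponential hazard right-censored at ``censor_time_min``.
    """

    n_worms: int = 45
    dye_category_probs: tuple = (0.02, 0.02, 0.03, 0.08, 0.85)
    roaming_mean: float = 60.0
    roaming_dispersion: float = 8.0
    escape_rate: float = 0.05
    censor_time_min: float = 10.0
    seed: int = 0
    genotype: str = "WT"
    n_trials: int = 3

    def validate(self) -> None:
        if self.n_worms < 1:
            raise ValueError("n_worms must be >= 1")
        probs = np.asarray(self.dye_category_probs, dtype=float)
        if probs.size != 5 or np.any(probs < 0):
            raise ValueError("dye_category_probs must be 5 nonnegative values")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("dye_category_probs must sum to 1")
        if not self.censor_time_min > 0:
            raise ValueError("censor_time_min must be > 0")
        if not self.roaming_dispersion > 0:
            raise ValueError("roaming_dispersion must be > 0")
        if self.escape_rate < 0:
            raise ValueError("escape_rate must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


COHORT_COLUMNS = [
    "worm_id", "genotype", "trial", "dye_filled_count",
    "squares_entered", "escape_time_min", "censored",
]


def simulate_behavior_cohort(params: BehaviorSimParams) -> pd.DataFrame:
    """Simulate one per-worm behavioural cohort as a tidy DataFrame."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_worms
    probs = np.asarray(params.dye_category_probs, dtype=float)
    dye = rng.choice(5, size=n, p=probs / probs.sum())
    # negative binomial parametrised by mean m and dispersion k: p = k/(k+m)
    k = params.roaming_dispersion
    p = k / (k + params.roaming_mean)
    squares = rng.negative_binomial(k, p, size=n)
    if params.escape_rate > 0:
        t = rng.exponential(1.0 / params.escape_rate, size=n)
    else:
        t = np.full(n, np.inf)
    censored = t >= params.censor_time_min
    t = np.where(censored, params.censor_time_min, t)
    trial = 1 + (np.arange(n) % params.n_trials)
    return pd.DataFrame(
        {
            "worm_id": [f"{params.genotype}_{i:03d}" for i in range(n)],
            "genotype": params.genotype,
            "trial": trial,
            "dye_filled_count": dye.astype(int),
            "squares_entered": squares.astype(int),
            "escape_time_min": t,
            "censored": censored,
        },
        columns=COHORT_COLUMNS,
    )
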