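"""Synthetic data generation with known ground truth.

Three kinds of inputs are emulated so every downstream stage can be
tested without clinical data:

* a *phantom series*: one fixed texture (standing in for a physical
  breast phantom) imaged repeatedly under varied acquisition physics
  (contrast gain as a kV proxy, signal-proportional noise as an mAs
  proxy, Gaussian blur as a sharpness proxy);
* a *bilateral cohort*: left/right image pairs per woman, generated from
  a shared latent texture parameter vector with a small bilateral
  perturbation;
* a *matched case-control feature table*: 1 case + m matched controls
  per stratum, with a known effect planted in designated features.

Textures are band-limited power-law (1/f^beta) Gaussian random fields;
per-woman beta, amplitude and offset are the latent parameters.  All
randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .catalog import FeatureCatalog
from .records import ImageRecord

__all__ = [
    "PhysicsSetting",
    "SyntheticGroundTruth",
    "default_phantom_settings",
    "half_ellipse_mask",
    "power_law_field",
    "simulate_phantom_series",
    "simulate_bilateral_cohort",
    "simulate_case_control_features",
    "simulate_robustness_tables",
]

#: Default synthetic image geometry: 6.3 mm windows at 0.2 mm spacing
#: give 32 px windows, so a 256 px image holds an 8x8 lattice.
DEFAULT_SIZE_PX = (256, 256)
DEFAULT_SPACING_MM = 0.2

_OFFSET = 1000.0  # baseline intensity, detector-like units
_AMPLITUDE = 200.0  # texture SD
_PHANTOM_BETA = 3.0  # power-law exponent of the phantom texture


@dataclass(frozen=True)
class PhysicsSetting:
    """One simulated acquisition condition.

    ``contrast_gain`` is a multiplicative factor (kV proxy);
    ``noise_scale`` the additive-noise SD as a fraction of the local
    signal (mAs proxy; noise scales like 1/sqrt(mAs));
    ``blur_sigma`` a Gaussian blur in pixels (sharpness proxy);
    ``replicate_seed`` separates the noise streams of repeat exposures.
    """

    contrast_gain: float = 1.0
    noise_scale: float = 0.0
    blur_sigma: float = 0.0
    replicate_seed: int = 0
    kv: float = float("nan")
    mas: float = float("nan")

    def __post_init__(self) -> None:
        if self.contrast_gain <= 0:
            raise ValueError("contrast_gain must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be nonnegative")


@dataclass
class SyntheticGroundTruth:
    """What the generator knows and the pipeline should recover."""

    #: per-feature true physics sensitivity (table-level generator) or
    #: None when the truth lives in the physics settings themselves.
    sensitivity: pd.Series | None = None
    #: per-woman latent texture parameters.
    latents: pd.DataFrame | None = None
    #: planted case effect size per feature (0 for null features).
    case_effects: pd.Series | None = None
    #: physics settings of a phantom series.
    settings: list[PhysicsSetting] = field(default_factory=list)


def default_phantom_settings(
    base_noise: float = 0.03, blur_sigma: float = 0.5, n_replicates: int = 2
) -> list[PhysicsSetting]:
    """The six clinically plausible (kV, mAs) conditions, each replicated.

    kV drives contrast (gain = kV / 31); mAs drives relative noise
    (noise ~ 1/sqrt(mAs), anchored at 120 mAs).  With two replicates per
    condition the series has 12 acquisitions.
    """
    conditions = [
        (28.0, 160.0),
        (29.0, 140.0),
        (30.0, 120.0),
        (31.0, 120.0),
        (31.0, 140.0),
        (31.0, 180.0),
    ]
    settings = []
    rep_seed = 0
    for kv, mas in conditions:
        for _ in range(n_replicates):
            settings.append(
                PhysicsSetting(
                    contrast_gain=kv / 31.0,
                    noise_scale=base_noise * np.sqrt(120.0 / mas),
                    blur_sigma=blur_sigma,
                    replicate_seed=rep_seed,
                    kv=kv,
                    mas=mas,
                )
            )
            rep_seed += 1
    return settings


def half_ellipse_mask(shape: tuple[int, int]) -> np.ndarray:
    """Half-ellipse breast outline touching the left image edge (CC-like)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    a = 0.85 * w  # horizontal semi-axis, centred on the left edge
    b = 0.45 * h
    cy = h / 2.0
    return (xx / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def power_law_field(
    shape: tuple[int, int],
    beta: float,
    rng: np.random.Generator | None = None,
    white: np.ndarray | None = None,
) -> np.ndarray:
    """Zero-mean, unit-SD Gaussian random field with power spectrum 1/f^beta.

    Pass ``white`` (a fixed white-noise array) to realise fields with
    different ``beta`` from the same underlying randomness.
    """
    if white is None:
        if rng is None:
            raise ValueError("need rng or white noise array")
        white = rng.standard_normal(shape)
    ky = np.fft.fftfreq(shape[0])
    kx = np.fft.fftfreq(shape[1])
    k = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    filt = np.zeros(shape)
    nonzero = k > 0
    filt[nonzero] = k[nonzero] ** (-beta / 2.0)
    fld = np.real(np.fft.ifft2(np.fft.fft2(white) * filt))
    fld -= fld.mean()
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def _apply_physics(
    signal: np.ndarray,
    setting: PhysicsSetting,
    noise_rng: np.random.Generator,
) -> np.ndarray:
    """Blur -> contrast gain -> signal-proportional additive noise."""
    out = signal
    if setting.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, setting.blur_sigma)
    out = out * setting.contrast_gain
    if setting.noise_scale > 0:
        sd = setting.noise_scale * np.clip(out, 0.0, None)
        out = out + noise_rng.standard_normal(out.shape) * sd
    return np.clip(out, 0.0, None)


def simulate_phantom_series(
    base_texture_seed: int,
    settings: list[PhysicsSetting],
    size_px: tuple[int, int] = DEFAULT_SIZE_PX,
    pixel_spacing_mm: float = DEFAULT_SPACING_MM,
) -> list[ImageRecord]:
    """Image one fixed texture under each physics setting.

    The noiseless texture is identical across all outputs (fixed by
    ``base_texture_seed``); only contrast, noise and blur differ.  Each
    record carries the setting's kV/mAs labels and a constant 50 mm
    thickness.  List one setting per intended replicate (with distinct
    ``replicate_seed``).
    """
    if not settings:
        raise ValueError("need at least one physics setting")
    h, w = int(size_px[0]), int(size_px[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"image size must be positive, got {size_px}")
    rng = np.random.default_rng(np.random.SeedSequence([int(base_texture_seed), 0]))
    mask = half_ellipse_mask((h, w))
    base = mask * (_OFFSET + _AMPLITUDE * power_law_field((h, w), _PHANTOM_BETA, rng))
    base = np.clip(base, 0.0, None)
    records = []
    for setting in settings:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(
                [int(base_texture_seed), 1, int(setting.replicate_seed)]
            )
        )
        pixels = _apply_physics(base, setting, noise_rng)
        records.append(
            ImageRecord(
                pixels=pixels,
                pixel_spacing_mm=pixel_spacing_mm,
                mask=mask,
                subject_id="phantom",
                laterality="",
                view="CC",
                thickness_mm=50.0,
                kv=setting.kv,
                mas=setting.mas,
            )
        )
    return records


def simulate_bilateral_cohort(
    n_women: int,
    bilateral_jitter: float = 0.05,
    thickness_range_mm: tuple[float, float] = (35.0, 65.0),
    seed: int = 0,
    size_px: tuple[int, int] = DEFAULT_SIZE_PX,
    pixel_spacing_mm: float = DEFAULT_SPACING_MM,
    acquisition_noise: float = 0.02,
    share_side_noise: bool = False,
) -> tuple[list[ImageRecord], SyntheticGroundTruth]:
    """Left/right image pairs per woman from a shared latent texture.

    Each woman draws latent parameters (power-law exponent beta, texture
    amplitude, intensity offset); her two sides realise the *same*
    underlying white noise with parameters perturbed multiplicatively by
    ``bilateral_jitter``, mimicking the similarity of parenchymal
    patterns across a woman's breasts.  With ``bilateral_jitter=0`` and
    ``share_side_noise=True`` the two sides are identical.
    """
    if n_women < 2:
        raise ValueError("n_women must be >= 2")
    if bilateral_jitter < 0:
        raise ValueError("bilateral_jitter must be nonnegative")
    t_lo, t_hi = thickness_range_mm
    if t_hi < t_lo:
        raise ValueError("invalid thickness range")
    h, w = int(size_px[0]), int(size_px[1])
    mask = half_ellipse_mask((h, w))
    records: list[ImageRecord] = []
    latents = []
    ss = np.random.SeedSequence([int(seed), 2])
    for j, child in enumerate(ss.spawn(n_women)):
        rng = np.random.default_rng(child)
        beta = rng.uniform(2.2, 3.4)
        offset = rng.uniform(800.0, 1200.0)
        amp = rng.uniform(150.0, 300.0)
        thickness = rng.uniform(t_lo, t_hi)
        white = rng.standard_normal((h, w))
        # per-side multiplicative perturbations, fixed draws scaled by jitter
        deltas = rng.standard_normal((2, 3))
        side_thick = np.clip(
            thickness + rng.uniform(-3.0, 3.0, size=2), t_lo, t_hi
        )
        subject = f"W{j:05d}"
        latents.append(
            {"subject_id": subject, "beta": beta, "offset": offset,
             "amplitude": amp, "thickness_mm": thickness}
        )
        for s_idx, side in enumerate(("L", "R")):
            d_beta, d_off, d_amp = deltas[s_idx]
            beta_s = beta * (1.0 + bilateral_jitter * 0.1 * d_beta)
            off_s = offset * (1.0 + bilateral_jitter * d_off)
            amp_s = amp * (1.0 + bilateral_jitter * d_amp)
            fld = power_law_field((h, w), beta_s, white=white)
            signal = mask * np.clip(off_s + amp_s * fld, 0.0, None)
            noise_key = 0 if share_side_noise else s_idx
            noise_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 3, j, noise_key])
            )
            if acquisition_noise > 0:
                sd = acquisition_noise * signal
                signal = np.clip(
                    signal + noise_rng.standard_normal(signal.shape) * sd,
                    0.0,
                    None,
                )
            records.append(
                ImageRecord(
                    pixels=signal,
                    pixel_spacing_mm=pixel_spacing_mm,
                    mask=mask,
                    subject_id=subject,
                    laterality=side,
                    view="CC",
                    thickness_mm=float(side_thick[s_idx]),
                    kv=31.0,
                    mas=140.0,
                )
            )
    truth = SyntheticGroundTruth(latents=pd.DataFrame(latents))
    return records, truth


def simulate_case_control_features(
    n_cases: int,
    controls_per_case: int,
    catalog: FeatureCatalog | list[str],
    signal_features: set[str] | list[str],
    effect_size: float,
    seed: int = 0,
    stratum_sd: float = 0.0,
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Matched case-control feature table with a planted effect.

    Each stratum holds one case and ``controls_per_case`` matched
    controls.  Features are unit-variance Gaussian; cases are shifted by
    ``effect_size`` (in SD units) on the designated signal features,
    null features are exchangeable between cases and controls.
    ``stratum_sd`` adds a shared within-stratum random effect
    (off by default so the binormal AUC relation is exact marginally).
    """
    names = catalog.names if isinstance(catalog, FeatureCatalog) else list(catalog)
    signal_features = set(signal_features)
    missing = signal_features - set(names)
    if missing:
        raise ValueError(
            f"signal features not in catalog: {sorted(missing)[:5]}"
        )
    if n_cases < 1 or controls_per_case < 1:
        raise ValueError("need n_cases >= 1 and controls_per_case >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    n_feat = len(names)
    effects = np.array(
        [effect_size if n in signal_features else 0.0 for n in names]
    )
    rows = []
    values = []
    group = 1 + controls_per_case
    for s in range(n_cases):
        u = rng.standard_normal(n_feat) * stratum_sd
        for member in range(group):
            is_case = int(member == 0)
            x = u + rng.standard_normal(n_feat) + is_case * effects
            rows.append({"stratum": s, "is_case": is_case})
            values.append(x)
    table = pd.concat(
        [pd.DataFrame(rows), pd.DataFrame(np.array(values), columns=names)],
        axis=1,
    )
    truth = SyntheticGroundTruth(
        case_effects=pd.Series(effects, index=names)
    )
    return table, truth


def simulate_robustness_tables(
    n_features: int = 60,
    n_acquisitions: int = 12,
    n_women: int = 100,
    sensitivity_range: tuple[float, float] = (0.0, 2.0),
    bilateral_sd: float = 0.2,
    replicate_sd: float = 0.05,
    thickness_range_mm: tuple[float, float] = (35.0, 65.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticGroundTruth]:
    """Feature-level generator with known per-feature physics sensitivity.

    Bypasses image synthesis: phantom acquisition values respond to a
    common physics axis ``g_i`` with per-feature slope ``s_k`` (the true
    sensitivity), plus small replicate noise; cohort values share a
    per-woman latent with a bilateral perturbation.  Used for
    parameter-recovery tests of the robustness metrics.

    Returns ``(phantom_df, cohort_df, truth)`` where ``phantom_df`` has
    columns kV/mAs/replicate + features and ``cohort_df`` has columns
    subject_id/laterality/thickness_mm + features.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    names = [f"f{k:03d}" for k in range(n_features)]
    mu = rng.uniform(-5.0, 5.0, size=n_features)
    sens = rng.uniform(*sensitivity_range, size=n_features)
    # physics axis: evenly spread severity across acquisitions
    g = np.linspace(-0.5, 0.5, n_acquisitions)
    phantom_rows = []
    for i in range(n_acquisitions):
        vals = mu + sens * g[i] + rng.standard_normal(n_features) * replicate_sd
        phantom_rows.append(
            {"kV": 28.0 + i % 4, "mAs": 120.0 + 10 * (i % 3), "replicate": i % 2}
            | dict(zip(names, vals))
        )
    phantom_df = pd.DataFrame(phantom_rows)
    t_lo, t_hi = thickness_range_mm
    cohort_rows = []
    for j in range(n_women):
        latent = mu + rng.standard_normal(n_features)
        thickness = rng.uniform(t_lo, t_hi)
        for side in ("L", "R"):
            vals = latent + rng.standard_normal(n_features) * bilateral_sd
            cohort_rows.append(
                {
                    "subject_id": f"W{j:05d}",
                    "laterality": side,
                    "thickness_mm": float(
                        np.clip(thickness + rng.uniform(-3, 3), t_lo, t_hi)
                    ),
                }
                | dict(zip(names, vals))
            )
    cohort_df = pd.DataFrame(cohort_rows)
    truth = SyntheticGroundTruth(sensitivity=pd.Series(sens, index=names))
    return phantom_df, cohort_df, truth
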