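"""Synthetic multi-organ cohort with known ground-truth aging.

Stands in for population-scale MRI/OCT data: each subject carries a
chronological age (CA) drawn from a truncated normal on [44, 83] years, a
vector of true per-organ age gaps with a systemic + bilateral-pair factor
structure, proportional-hazards disease and death outcomes driven by those
gaps, and phantom images that encode each organ's biological age
(CA + gap) as the radius of a dark inner cavity.

Because the generator knows every latent quantity, each downstream stage
(regression, bias correction, stratification, survival) can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import (
    ORGANS,
    ORGANS_2D,
    AgingFactorConfig,
    ConfigurationError,
    DemographicConfig,
    HazardConfig,
    PhantomConfig,
    hash2,
)
from .preprocess import OrganImage

#: age before which the outcome hazards are zero (cohort enters at 44+)
HAZARD_ONSET_AGE = 40.0


@dataclass
class SubjectRecord:
    """One participant of the synthetic cohort."""

    subject_id: str
    sex: str  # {"female", "male"}
    ca_at_imaging: float
    bmi: float
    true_pag: dict[str, float] = field(default_factory=dict)
    outcome_ages: dict[str, float] = field(default_factory=dict)  # observed diagnoses
    death_age: float | None = None
    retrieval_age: float = float("nan")

    @staticmethod
    def from_row(row: pd.Series) -> "SubjectRecord":
        pag = {c[4:]: float(row[c]) for c in row.index if c.startswith("pag_")}
        ages = {c[4:]: float(row[c]) for c in row.index
                if c.startswith("age_") and pd.notna(row[c])}
        death = float(row["death_age"]) if pd.notna(row.get("death_age")) else None
        return SubjectRecord(
            subject_id=str(row["subject_id"]), sex=str(row["sex"]),
            ca_at_imaging=float(row["ca_at_imaging"]), bmi=float(row["bmi"]),
            true_pag=pag, outcome_ages=ages, death_age=death,
            retrieval_age=float(row["retrieval_age"]))


def sample_organ_pags(n: int, factors: AgingFactorConfig | None = None,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw an (n, n_organs) matrix of true age gaps in years.

    Gap_o = pag_sd_o * (s_o * Z + g_o * W_pair(o)) + e_o with shared factor Z,
    one factor per bilateral pair, and independent residuals scaled so every
    organ's marginal SD equals pag_sd_o.  Zero mean by construction.
    """
    factors = factors or AgingFactorConfig()
    factors.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    organs = factors.organs
    z = rng.standard_normal(n)
    pair_names = sorted({p for o in organs
                         for p in [_pair_of(o)] if p is not None})
    w = {p: rng.standard_normal(n) for p in pair_names}
    out = np.empty((n, len(organs)))
    for j, organ in enumerate(organs):
        s, g = factors.loadings(organ)
        sd = factors.pag_sd[organ]
        common = sd * s * z
        pair = _pair_of(organ)
        if pair is not None and g != 0.0:
            common = common + sd * g * w[pair]
        out[:, j] = common + factors.noise_sd(organ) * rng.standard_normal(n)
    return out


def _pair_of(organ: str) -> str | None:
    from .config import BILATERAL_PAIRS

    for pair, members in BILATERAL_PAIRS.items():
        if organ in members:
            return pair
    return None


def generate_cohort(n: int, demo: DemographicConfig | None = None,
                    factors: AgingFactorConfig | None = None,
                    hazards: HazardConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Generate the cohort table: demographics, true PAGs, outcomes.

    Columns: subject_id, sex, ca_at_imaging, bmi, retrieval_age, pag_<organ>
    for each organ, age_<outcome> (NaN = never observed) and death_age.
    Deterministic under a fixed seed.
    """
    if n < 0:
        raise ConfigurationError("cohort size must be nonnegative")
    demo = demo or DemographicConfig()
    factors = factors or AgingFactorConfig()
    hazards = hazards or HazardConfig()
    demo.validate()
    factors.validate()
    hazards.validate(factors.organs)

    rng = np.random.default_rng(seed)
    a = (demo.ca_min - demo.ca_mean) / demo.ca_sd
    b = (demo.ca_max - demo.ca_mean) / demo.ca_sd
    ca = stats.truncnorm.rvs(a, b, loc=demo.ca_mean, scale=demo.ca_sd,
                             size=n, random_state=rng)
    sex = np.where(rng.random(n) < demo.female_fraction, "female", "male")
    bmi = np.clip(rng.normal(demo.bmi_mean, demo.bmi_sd, size=n), 16.0, 55.0)
    retrieval = ca + rng.uniform(0.0, demo.followup_max, size=n)

    df = pd.DataFrame({
        "subject_id": [f"S{i:06d}" for i in range(n)],
        "sex": sex,
        "ca_at_imaging": ca,
        "bmi": bmi,
        "retrieval_age": retrieval,
    })
    pags = sample_organ_pags(n, factors, rng)
    for j, organ in enumerate(factors.organs):
        df[f"pag_{organ}"] = pags[:, j]
    return assign_outcomes(df, hazards, rng, organs=factors.organs)


def assign_outcomes(cohort: pd.DataFrame, hazards: HazardConfig | None = None,
                    seed: int | np.random.Generator = 0,
                    organs: tuple[str, ...] = ORGANS) -> pd.DataFrame:
    """Sample diagnosis/death ages from exponential proportional hazards.

    The age at outcome k is ``40 + Exp(rate)`` with rate
    ``baseline_rate_k * exp(log_hr_k * true_pag[source_organ])``; only events
    occurring before the end of observation (data retrieval, or earlier death)
    are recorded.  Subjects who are ever diagnosed get the outcome's
    ``disease_acceleration`` added to the true PAG of the affected organ(s),
    so disease groups are separable only through the rendered images.
    """
    hazards = hazards or HazardConfig()
    hazards.validate(organs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = cohort.copy()
    n = len(df)

    raw_times: dict[str, np.ndarray] = {}
    for name in sorted(hazards.outcomes):
        hz = hazards.outcomes[name]
        pag = df[f"pag_{hz.source_organ}"].to_numpy()
        rate = hz.baseline_rate * np.exp(hz.log_hr_per_pag_year * pag)
        with np.errstate(divide="ignore"):
            scale = np.where(rate > 0, 1.0 / np.where(rate > 0, rate, 1.0), np.inf)
        draws = rng.exponential(size=n)
        raw_times[name] = hz.onset_age + draws * scale

    window_end = df["retrieval_age"].to_numpy().copy()
    if "death" in raw_times:
        death_t = raw_times.pop("death")
        observed = death_t <= window_end
        df["death_age"] = np.where(observed, death_t, np.nan)
        window_end = np.minimum(window_end, np.where(observed, death_t, np.inf))
    else:
        df["death_age"] = np.nan

    for name, t in raw_times.items():
        observed = t <= window_end
        df[f"age_{name}"] = np.where(observed, t, np.nan)
        hz = hazards.outcomes[name]
        if hz.disease_acceleration != 0.0:
            for organ in hz.affected():
                df[f"pag_{organ}"] = (df[f"pag_{organ}"].to_numpy()
                                      + hz.disease_acceleration * observed)
    return df


# ---------------------------------------------------------------------------
# Phantom rendering
# ---------------------------------------------------------------------------

#: organ ellipsoid semi-axes as fractions of the grid size per axis
_ELLIPSOID_FRACTIONS_3D = (0.42, 0.38, 0.35)
_ELLIPSE_FRACTIONS_2D = (0.42, 0.38)
_CHANNEL_GAINS_2D = (1.0, 0.8, 0.6)
_TISSUE, _CAVITY, _BACKGROUND = 0.95, 0.15, 0.05
_EDGE_SOFTNESS = 0.6  # voxels; sub-voxel anti-aliasing of the cavity wall


def render_organ_image(subject: SubjectRecord | pd.Series, organ: str,
                       phantom: PhantomConfig | None = None,
                       seed: int = 0) -> OrganImage:
    """Render one phantom: an organ ellipsoid with an age-encoding cavity.

    The cavity radius is ``r0 + slope_b * (CA + true_pag[organ])`` plus a
    jitter whose SD scales with the subject's texture blur level; a small
    random translation acts as nuisance.  Fundus organs are rendered as a
    single 2D 3-channel slice, all others as a 3D volume.
    """
    phantom = phantom or PhantomConfig()
    phantom.validate()
    if isinstance(subject, pd.Series):
        subject = SubjectRecord.from_row(subject)
    if organ not in subject.true_pag:
        raise ConfigurationError(f"organ {organ!r} not present in subject record")
    rng = np.random.default_rng(seed)

    is_2d = organ in ORGANS_2D
    shape = phantom.fundus_shape if is_2d else phantom.grid_shape
    nd = len(shape)
    shift = rng.uniform(-phantom.nuisance_shift_max, phantom.nuisance_shift_max, nd)
    blur = float(rng.choice(phantom.texture_blur_levels))
    ba = subject.ca_at_imaging + subject.true_pag[organ]
    radius = (phantom.r0 + phantom.slope_b * ba
              + rng.normal(0.0, phantom.radius_noise_sd * blur))
    fractions = _ELLIPSE_FRACTIONS_2D if is_2d else _ELLIPSOID_FRACTIONS_3D
    semi_axes = [f * s for f, s in zip(fractions, shape)]
    if radius >= min(semi_axes) - 1.0:
        raise ConfigurationError(
            f"cavity radius {radius:.1f} exceeds the organ extent "
            f"{min(semi_axes):.1f} on grid {shape}")

    center = [(s - 1) / 2.0 + d for s, d in zip(shape, shift)]
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    organ_d2 = sum(((g - c) / ax) ** 2
                   for g, c, ax in zip(grids, center, semi_axes))
    mask = (organ_d2 <= 1.0).astype(np.uint8)
    cavity_d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    # smooth cavity wall so the radius is encoded with sub-voxel precision
    wall = 1.0 / (1.0 + np.exp(-(cavity_d - radius) / _EDGE_SOFTNESS))
    base = _BACKGROUND + mask * (_CAVITY - _BACKGROUND + (_TISSUE - _CAVITY) * wall)

    if is_2d:
        channels = []
        for gain in _CHANNEL_GAINS_2D:
            chan = ndimage.gaussian_filter(gain * base, blur)
            chan += rng.normal(0.0, phantom.intensity_noise_sd, shape)
            channels.append(chan)
        voxels = np.stack(channels)
        spacing: tuple[float, ...] = (1.0, 1.0)
    else:
        voxels = ndimage.gaussian_filter(base, blur)
        voxels += rng.normal(0.0, phantom.intensity_noise_sd, shape)
        spacing = (1.0, 1.0, 1.0)
    return OrganImage(voxels=voxels, mask=mask, organ=organ, spacing=spacing)


def measure_cavity_radius(img: OrganImage, threshold: float = 0.5) -> float:
    """Model-free cavity radius estimate from the thresholded dark core.

    Independent of the regression model: counts in-mask voxels darker than
    `threshold` (relative to the in-mask intensity range) and inverts the
    sphere/disc volume formula.
    """
    vox = img.voxels if not img.has_channels else img.voxels[0]
    inside = img.mask > 0
    vals = vox[inside]
    lo, hi = vals.min(), vals.max()
    dark = inside & (vox < lo + threshold * (hi - lo))
    v = float(dark.sum())
    if img.mask.ndim == 2:
        return float(np.sqrt(v / np.pi))
    return float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0))


def render_seed(base_seed: int, subject_index: int, organ: str) -> int:
    """Deterministic per-(subject, organ) rendering seed below 2**31."""
    ss = np.random.SeedSequence([base_seed, subject_index, hash2(organ)])
    return int(ss.generate_state(1)[0] % (2**31))


def render_cohort(cohort: pd.DataFrame, organ: str,
                  phantom: PhantomConfig | None = None,
                  base_seed: int = 0) -> list[OrganImage]:
    """Render every subject's phantom for one organ (deterministic order)."""
    return [render_organ_image(row, organ, phantom,
                               seed=render_seed(base_seed, i, organ))
            for i, (_, row) in enumerate(cohort.iterrows())]


# ---------------------------------------------------------------------------
# Cohort and image I/O
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """One row per subject; empty cells encode absent diagnosis/death ages."""
    cohort.to_csv(path, index=False, float_format="%.6f")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_images(cohort: pd.DataFrame, organs, out_dir,
                 phantom: PhantomConfig | None = None, base_seed: int = 0) -> None:
    """Write ``<subject>_<organ>.nii.gz`` / ``..._mask.nii.gz`` pairs."""
    from pathlib import Path

    from .preprocess import save_nifti

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for organ in organs:
        for i, (_, row) in enumerate(cohort.iterrows()):
            img = render_organ_image(row, organ, phantom,
                                     seed=render_seed(base_seed, i, organ))
            sid = row["subject_id"]
            save_nifti(img, out / f"{sid}_{organ}.nii.gz",
                       out / f"{sid}_{organ}_mask.nii.gz")
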