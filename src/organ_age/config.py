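"""Configuration objects for the synthetic cohort, phantoms, training and
experiment orchestration.

The defaults define the study conditions emulated throughout the package: a
UK-Biobank-like age window (44-83 y, mean ~64.2), nine organ systems with
bilateral kidney/fundus pairs, factor-structured organ age gaps whose
implied correlations match the reported cross-organ pattern (kidney pair
r~0.43, fundus pair r~0.74, weak liver-abdominal coupling), and
proportional-hazards outcomes with left truncation at the imaging age.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

ORGANS: tuple[str, ...] = (
    "brain",
    "heart",
    "kidney_left",
    "kidney_right",
    "liver",
    "pancreas",
    "spleen",
    "fundus_left",
    "fundus_right",
)

#: organs rendered on the 2D (channel, y, x) path instead of the 3D volume path
ORGANS_2D: frozenset[str] = frozenset({"fundus_left", "fundus_right"})

BILATERAL_PAIRS: dict[str, tuple[str, str]] = {
    "kidney": ("kidney_left", "kidney_right"),
    "fundus": ("fundus_left", "fundus_right"),
}

#: outcomes whose pre-imaging diagnosis excludes a subject from the healthy
#: training set of the given organ
ORGAN_EXCLUSIONS: dict[str, tuple[str, ...]] = {
    "brain": ("alzheimers",),
    "heart": ("myocardial_infarction",),
    "pancreas": ("t2dm",),
    "kidney_left": ("ckd",),
    "kidney_right": ("ckd",),
    "liver": (),
    "spleen": (),
    "fundus_left": (),
    "fundus_right": (),
}


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


class DataError(ValueError):
    """Raised for malformed data (NaN/Inf intensities, shape mismatches)."""


class QCFailure(ValueError):
    """Raised when an image fails quality control (e.g. empty mask)."""


def _organ_pair(organ: str) -> str | None:
    for pair, members in BILATERAL_PAIRS.items():
        if organ in members:
            return pair
    return None


@dataclass
class AgingFactorConfig:
    """Factor structure of the per-organ true age gaps.

    Each organ's gap is ``pag_sd * (systemic*Z + pair*W) + noise`` with a
    shared systemic factor Z, one factor W per bilateral pair, and
    independent organ noise.  The implied correlation between organs o, p is
    ``s_o*s_p + g_o*g_p*[same pair]``.
    """

    organs: tuple[str, ...] = ORGANS
    systemic_loading: dict[str, float] = field(default_factory=lambda: {
        "brain": 0.15, "heart": 0.29, "kidney_left": 0.45, "kidney_right": 0.45,
        "liver": 0.55, "pancreas": 0.45, "spleen": 0.50,
        "fundus_left": 0.05, "fundus_right": 0.05,
    })
    pair_loading: dict[str, float] = field(default_factory=lambda: {
        # chosen so the implied pair correlations are 0.43 (kidney), 0.74 (fundus)
        "kidney": math.sqrt(0.43 - 0.45**2),
        "fundus": math.sqrt(0.74 - 0.05**2),
    })
    pag_sd: dict[str, float] = field(
        default_factory=lambda: {o: 2.5 for o in ORGANS})
    organ_noise_sd: dict[str, float] | None = None

    def loadings(self, organ: str) -> tuple[float, float]:
        s = self.systemic_loading[organ]
        pair = _organ_pair(organ)
        g = self.pair_loading.get(pair, 0.0) if pair else 0.0
        return s, g

    def noise_sd(self, organ: str) -> float:
        """Residual SD in years; derived so Var(PAG) = pag_sd**2."""
        if self.organ_noise_sd is not None:
            return self.organ_noise_sd[organ]
        s, g = self.loadings(organ)
        return self.pag_sd[organ] * math.sqrt(1.0 - s * s - g * g)

    def validate(self) -> None:
        for organ in self.organs:
            if organ not in self.systemic_loading or organ not in self.pag_sd:
                raise ConfigurationError(f"organ {organ!r} missing loadings or pag_sd")
            s, g = self.loadings(organ)
            if s * s + g * g > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"loadings of {organ!r} imply negative residual variance "
                    f"(s^2+g^2 = {s*s+g*g:.3f} > 1): factor structure not PSD")
            if self.pag_sd[organ] < 0:
                raise ConfigurationError(f"pag_sd of {organ!r} is negative")
            if self.organ_noise_sd is not None:
                expected = self.pag_sd[organ] ** 2 * (1.0 - s * s - g * g)
                if not math.isclose(self.organ_noise_sd[organ] ** 2, expected,
                                    rel_tol=1e-6, abs_tol=1e-9):
                    raise ConfigurationError(
                        f"organ_noise_sd of {organ!r} inconsistent with pag_sd "
                        "(implied covariance diagonal must equal pag_sd^2)")

    def implied_correlation(self) -> np.ndarray:
        """Analytic correlation matrix of the organ age gaps."""
        self.validate()
        k = len(self.organs)
        corr = np.eye(k)
        for i, oi in enumerate(self.organs):
            si, gi = self.loadings(oi)
            for j in range(i + 1, k):
                oj = self.organs[j]
                sj, gj = self.loadings(oj)
                r = si * sj
                if _organ_pair(oi) is not None and _organ_pair(oi) == _organ_pair(oj):
                    r += gi * gj
                corr[i, j] = corr[j, i] = r
        return corr


@dataclass
class OutcomeHazard:
    """Constant-rate proportional hazard for one outcome, acting beyond age 40."""

    baseline_rate: float  # events / year
    log_hr_per_pag_year: float
    source_organ: str
    disease_acceleration: float = 0.0  # years added to affected organs' true PAG
    affected_organs: tuple[str, ...] | None = None  # default: (source_organ,)
    onset_age: float = 40.0  # age before which the hazard is zero

    def affected(self) -> tuple[str, ...]:
        return self.affected_organs if self.affected_organs is not None else (self.source_organ,)


@dataclass
class HazardConfig:
    outcomes: dict[str, OutcomeHazard] = field(default_factory=lambda: {
        "death": OutcomeHazard(0.006, 0.12, "heart", 0.0),
        "alzheimers": OutcomeHazard(0.0012, 0.40, "brain", 3.0),
        "t2dm": OutcomeHazard(0.005, 0.11, "pancreas", 3.0),
        "ckd": OutcomeHazard(0.004, 0.17, "kidney_left", 3.0,
                             ("kidney_left", "kidney_right")),
        "myocardial_infarction": OutcomeHazard(0.003, 0.12, "heart", 2.0),
    })

    def validate(self, organs: tuple[str, ...] = ORGANS) -> None:
        for name, hz in self.outcomes.items():
            if hz.baseline_rate < 0:
                raise ConfigurationError(f"baseline_rate of {name!r} is negative")
            for organ in (hz.source_organ, *hz.affected()):
                if organ not in organs:
                    raise ConfigurationError(
                        f"outcome {name!r} references unknown organ {organ!r}")


@dataclass
class DemographicConfig:
    """Truncated-normal chronological ages on [44, 83] with mean ~64.2 y."""

    ca_mean: float = 64.23
    ca_sd: float = 7.8
    ca_min: float = 44.0
    ca_max: float = 83.0
    female_fraction: float = 0.53
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    followup_max: float = 10.0  # retrieval_age = ca + U(0, followup_max)

    def validate(self) -> None:
        if not (self.ca_min < self.ca_max):
            raise ConfigurationError("ca_min must be below ca_max")
        if self.ca_sd <= 0 or self.bmi_sd <= 0:
            raise ConfigurationError("age/BMI SDs must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must be in [0, 1]")
        if self.followup_max <= 0:
            raise ConfigurationError("followup_max must be positive")


@dataclass
class PhantomConfig:
    """Geometry of the rendered phantoms.

    An organ ellipsoid carries an inner dark cavity whose radius grows
    linearly with the organ's biological age (``r0 + slope_b * BA``), the
    image-level counterpart of ventricles enlarging with age.  A per-subject
    texture blur level both smooths the image and scales the radius jitter,
    so predictive uncertainty is learnable from texture.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    fundus_shape: tuple[int, int] = (64, 64)
    r0: float = 2.0  # base cavity radius, voxels
    slope_b: float = 0.08  # voxels per year of biological age
    texture_blur_levels: tuple[float, ...] = (0.5, 1.0, 1.5)
    radius_noise_sd: float = 0.12  # voxels, scaled by the blur level
    intensity_noise_sd: float = 0.05
    nuisance_shift_max: float = 1.5  # voxels, per-axis uniform translation

    def validate(self) -> None:
        for shape in (self.grid_shape, self.fundus_shape):
            if any(s <= 0 for s in shape):
                raise ConfigurationError("grid dimensions must be positive")
            if self.r0 + self.slope_b * 95.0 >= min(shape) / 2.0:
                raise ConfigurationError(
                    "cavity does not fit the grid: r0 + slope_b*95 must be "
                    f"below min(grid)/2 = {min(shape)/2}")
        if self.slope_b < 0 or self.r0 <= 0:
            raise ConfigurationError("r0 must be positive and slope_b nonnegative")
        if not self.texture_blur_levels:
            raise ConfigurationError("texture_blur_levels must be nonempty")


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 3e-3
    seed: int = 0
    sigma_clamp: tuple[float, float] = (-2.0, 3.0)  # log-years
    split_ratio: float = 0.8
    channels: tuple[int, ...] = (8, 16, 32)  # one residual block per entry

    def validate(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigurationError("split_ratio must be in (0, 1)")
        if self.epochs < 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ConfigurationError("invalid training hyperparameters")
        if self.sigma_clamp[0] >= self.sigma_clamp[1]:
            raise ConfigurationError("sigma_clamp must be an increasing interval")


@dataclass
class ExperimentConfig:
    """One end-to-end run: generate, preprocess, train, predict, analyze."""

    seed: int = 0
    n_subjects: int = 150
    organs: tuple[str, ...] = ("brain", "kidney_left", "kidney_right")
    margin: int = 4
    target_grid: tuple[int, int, int] = (32, 32, 32)
    qc_k: float = 5.0
    demographics: DemographicConfig = field(default_factory=DemographicConfig)
    factors: AgingFactorConfig = field(default_factory=AgingFactorConfig)
    hazards: HazardConfig = field(default_factory=HazardConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=8))
    survival_outcomes: tuple[str, ...] = ("death", "ckd")
    make_figures: bool = True
    schema_version: int = 1

    @staticmethod
    def from_dict(doc: dict) -> "ExperimentConfig":
        doc = dict(doc)
        kwargs: dict = {}
        simple = {f.name for f in dataclasses.fields(ExperimentConfig)
                  if f.name not in {"demographics", "factors", "hazards", "phantom", "train"}}
        for key in list(doc):
            if key in simple:
                value = doc.pop(key)
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[key] = value
        for key, cls in (("demographics", DemographicConfig), ("phantom", PhantomConfig),
                         ("train", TrainConfig), ("factors", AgingFactorConfig)):
            if key in doc:
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in doc.pop(key).items()}
                kwargs[key] = cls(**sub)
        if "hazards" in doc:
            outcomes = {name: OutcomeHazard(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in spec.items()})
                for name, spec in doc.pop("hazards").items()}
            kwargs["hazards"] = HazardConfig(outcomes=outcomes)
        if doc:
            raise ConfigurationError(f"unknown configuration keys: {sorted(doc)}")
        return ExperimentConfig(**kwargs)

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigurationError("configuration document must be a mapping")
        return ExperimentConfig.from_dict(doc)


def validate_config(config: ExperimentConfig) -> list[str]:
    """Return a list of problems (empty iff the configuration is valid)."""
    problems: list[str] = []

    def _collect(fn, *args) -> None:
        try:
            fn(*args)
        except ConfigurationError as exc:
            problems.append(str(exc))

    if config.n_subjects < 0:
        problems.append("n_subjects: cohort size must be nonnegative")
    for organ in config.organs:
        if organ not in config.factors.organs:
            problems.append(f"organs: {organ!r} not defined in factor config")
    _collect(config.demographics.validate)
    _collect(config.factors.validate)
    _collect(config.hazards.validate, config.factors.organs)
    _collect(config.phantom.validate)
    _collect(config.train.validate)
    if config.margin < 0:
        problems.append("margin: must be nonnegative")
    return problems


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the root seed."""
    ss = np.random.SeedSequence([root_seed, abs(hash2(stage))])
    return int(ss.generate_state(1)[0] % (2**31))


def hash2(text: str) -> int:
    """Stable (non-salted) string hash for seed derivation."""
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h
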