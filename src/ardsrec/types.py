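"""Core domain types.

The study population is mechanically ventilated ICU patients with acute
hypoxemic respiratory failure (PaO2/FiO2 <= 300), split into an ARDS cohort
(Berlin-definition positive) and a non-ARDS hypoxemic control cohort.  The
central behavioural readout is the lowest *standardized* tidal volume a
patient received, in mL per kg of predicted body weight (PBW).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, InvalidInputError


class Cohort(str, enum.Enum):
    ARDS = "ARDS"
    CONTROL = "control"


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Severity(str, enum.Enum):
    """Berlin hypoxemia strata on the lowest PaO2/FiO2 ratio."""

    MILD = "mild"          # 200 < P/F <= 300
    MODERATE = "moderate"  # 100 < P/F <= 200
    SEVERE = "severe"      # P/F <= 100


SEVERITY_ORDER = (Severity.MILD, Severity.MODERATE, Severity.SEVERE)


class Subgroup(str, enum.Enum):
    """The three analysis subgroups used by both recognition models."""

    ARDS_NONDOC = "ards_nondocumented"
    CONTROL_NONDOC = "control_nondocumented"
    POOLED_DOC = "pooled_documented"


class Method(str, enum.Enum):
    NAIVE_BAYES = "naive_bayes"
    MIXTURE = "mixture"


@dataclass
class PatientRecord:
    """One ventilated patient.

    ``latent_recognized`` is synthetic-only ground truth (did the simulated
    physician recognise ARDS); analysis stages never read it.
    """

    patient_id: str
    cohort: Cohort
    gender: Gender
    height_in: float
    pbw_kg: float
    admit_weight_kg: float
    pf_first: float
    pf_lowest: float
    pplat_highest: Optional[float]
    vt_lowest_ml: float
    vt_std: float
    documented: bool
    study_duration_h: float
    bilateral_infiltrates: Optional[bool] = None
    admitting_icu: Optional[str] = None
    latent_recognized: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.pbw_kg < 25:
            raise InvalidInputError(
                f"{self.patient_id}: PBW {self.pbw_kg} kg below the 25 kg inclusion floor")
        if self.study_duration_h < 5.67:
            raise InvalidInputError(
                f"{self.patient_id}: study duration {self.study_duration_h} h "
                "below the 5.67 h inclusion floor")
        if self.pf_lowest > 300:
            raise InvalidInputError(
                f"{self.patient_id}: lowest P/F {self.pf_lowest} exceeds 300")
        if self.pf_lowest > self.pf_first:
            raise InvalidInputError(
                f"{self.patient_id}: lowest P/F exceeds first P/F")
        if abs(self.vt_std - self.vt_lowest_ml / self.pbw_kg) > 1e-9:
            raise InvalidInputError(
                f"{self.patient_id}: vt_std inconsistent with vt_lowest_ml / pbw_kg")
        if self.documented and self.latent_recognized is False:
            raise InvalidInputError(
                f"{self.patient_id}: documented implies recognized")

    @property
    def severity(self) -> Severity:
        from .synthetic import assign_severity

        return assign_severity(self.pf_lowest)

    @property
    def subgroup(self) -> Subgroup:
        if self.documented:
            return Subgroup.POOLED_DOC
        if self.cohort is Cohort.ARDS:
            return Subgroup.ARDS_NONDOC
        return Subgroup.CONTROL_NONDOC


@dataclass
class Density2D:
    """A normalised density over the (PBW, standardized tidal volume) plane.

    For ``kind == "kde"`` the axes are grid *nodes* and ``values`` holds the
    density evaluated at each node (trapezoidal integral ~ 1).  For
    ``kind == "histogram"`` the axes are bin *edges* and ``values`` holds the
    probability mass per cell (sums to 1).
    """

    axis_pbw: np.ndarray
    axis_vt: np.ndarray
    values: np.ndarray
    kind: str  # "kde" | "histogram"
    bandwidths: Optional[tuple[float, float]] = None  # kde only
    bin_widths: Optional[tuple[float, float]] = None  # histogram only

    def __post_init__(self) -> None:
        self.axis_pbw = np.asarray(self.axis_pbw, dtype=float)
        self.axis_vt = np.asarray(self.axis_vt, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise InvalidInputError("density values must be non-negative")
        if self.kind == "kde":
            if self.values.shape != (self.axis_pbw.size, self.axis_vt.size):
                raise InvalidInputError("kde values shape must match the node grid")
            total = np.trapezoid(np.trapezoid(self.values, self.axis_vt, axis=1),
                                 self.axis_pbw)
            if abs(total - 1.0) > 1e-2:
                raise InvalidInputError(
                    f"kde grid integral {total:.4f} deviates from 1 by more than 1e-2")
        elif self.kind == "histogram":
            if self.values.shape != (self.axis_pbw.size - 1, self.axis_vt.size - 1):
                raise InvalidInputError("histogram values shape must match the bin edges")
            if abs(self.values.sum() - 1.0) > 1e-12:
                raise InvalidInputError("histogram cell masses must sum to 1")
        else:
            raise InvalidInputError(f"unknown density kind {self.kind!r}")

    def same_bins(self, other: "Density2D") -> bool:
        return (self.kind == other.kind == "histogram"
                and self.axis_pbw.size == other.axis_pbw.size
                and self.axis_vt.size == other.axis_vt.size
                and np.allclose(self.axis_pbw, other.axis_pbw)
                and np.allclose(self.axis_vt, other.axis_vt))


@dataclass
class RegressionResult:
    """One factor(s) -> outcome fit: coefficients, 99% CIs, p-values, IC."""

    outcome: str
    factors: list[str]
    betas: np.ndarray
    ci99: np.ndarray          # shape (k, 2)
    p_values: np.ndarray
    n: int
    aic: float
    bic: float
    significant: Optional[bool] = None
    status: str = "ok"        # "ok" | "separation" | "skipped"
    intercept: float = float("nan")
    messages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.betas = np.atleast_1d(np.asarray(self.betas, dtype=float))
        self.ci99 = np.asarray(self.ci99, dtype=float).reshape(-1, 2)
        self.p_values = np.atleast_1d(np.asarray(self.p_values, dtype=float))
        if self.status == "ok":
            ok = np.isfinite(self.betas)
            if np.any(self.ci99[ok, 0] - self.betas[ok] > 1e-9) or \
               np.any(self.betas[ok] - self.ci99[ok, 1] > 1e-9):
                raise InvalidInputError("confidence interval must bracket the estimate")
            p = self.p_values[np.isfinite(self.p_values)]
            if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
                raise InvalidInputError("p-values must lie in [0, 1]")


@dataclass
class RecognitionEstimate:
    """Per-severity recognition fraction from one method."""

    severity: Severity
    method: Method
    fraction: float
    n: int
    uncertainty: Optional[tuple[float, float]] = None
    level: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise InvalidInputError("recognition fraction must lie in [0, 1]")
        if self.uncertainty is not None:
            low, high = self.uncertainty
            if not low - 1e-12 <= self.fraction <= high + 1e-12:
                raise InvalidInputError("uncertainty interval must bracket the fraction")


@dataclass
class MixtureFit:
    """L1 mixture decomposition result for one severity stratum."""

    severity: Optional[Severity]
    f_hat: float
    delta: float
    non_unique: bool = False
    bootstrap_fractions: Optional[np.ndarray] = None
    ci99: Optional[tuple[float, float]] = None
    mean: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.f_hat <= 1 + 1e-12:
            raise InvalidInputError("mixture fraction must lie in [0, 1]")
        self.f_hat = float(min(max(self.f_hat, 0.0), 1.0))
        if self.delta < -1e-12:
            raise InvalidInputError("L1 objective must be non-negative")
        if self.ci99 is not None and self.mean is not None:
            if not self.ci99[0] - 1e-12 <= self.mean <= self.ci99[1] + 1e-12:
                raise InvalidInputError("bootstrap CI must bracket the bootstrap mean")


@dataclass
class AnalysisConfig:
    """Analysis-wide constants: significance thresholds, priors, grids.

    Every threshold used anywhere in the pipeline is sourced from here, so
    a single override propagates consistently.
    """

    alpha: float = 0.01
    bonferroni_regression: int = 33   # V^T-outcome regression comparisons
    bonferroni_covariate: int = 2     # documentation covariate fits
    bonferroni_ks: int = 3            # pairwise severity KS tests
    priors: tuple[float, float] = (0.5, 0.5)
    nb_bootstrap_iters: int = 100
    mixture_bootstrap_iters: int = 1000
    ltvv_threshold: float = 6.5       # mL/kg PBW
    severity_cutpoints: tuple[float, float, float] = (100.0, 200.0, 300.0)
    # KDE evaluation grid; wide enough that edge kernels keep their mass
    # even for small bootstrap resamples (larger bandwidths)
    kde_pbw_range: tuple[float, float, float] = (15.0, 115.0, 0.5)
    kde_vt_range: tuple[float, float, float] = (0.0, 18.0, 0.05)
    # histogram bins for the mixture model; calibrated by parameter-recovery
    # simulation (see docs/methods.md) — finer bins bias the L1 fit away from
    # the sparser reference when the references hold only ~60 patients
    hist_pbw_range: tuple[float, float, float] = (25.0, 105.0, 10.0)
    hist_vt_range: tuple[float, float, float] = (2.0, 14.0, 1.0)
    # conventions that the source analysis leaves open
    nb_include_documented: bool = True
    nb_bootstrap_match_documented_size: bool = True
    mixture_include_documented: bool = True
    mixture_resample_references: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if abs(sum(self.priors) - 1.0) > 1e-12:
            raise ConfigError("priors must sum to 1")
        for m in (self.bonferroni_regression, self.bonferroni_covariate,
                  self.bonferroni_ks):
            if m < 1:
                raise ConfigError("Bonferroni denominators must be positive")

    @property
    def regression_threshold(self) -> float:
        return self.alpha / self.bonferroni_regression

    @property
    def covariate_threshold(self) -> float:
        return self.alpha / self.bonferroni_covariate

    @property
    def ks_threshold(self) -> float:
        return self.alpha / self.bonferroni_ks

    @staticmethod
    def _grid(rng: tuple[float, float, float]) -> np.ndarray:
        lo, hi, step = rng
        n = (hi - lo) / step
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(f"grid range {rng} is not divisible by its step")
        return lo + step * np.arange(int(round(n)) + 1)

    def kde_pbw_grid(self) -> np.ndarray:
        return self._grid(self.kde_pbw_range)

    def kde_vt_grid(self) -> np.ndarray:
        return self._grid(self.kde_vt_range)

    def hist_pbw_edges(self) -> np.ndarray:
        return self._grid(self.hist_pbw_range)

    def hist_vt_edges(self) -> np.ndarray:
        return self._grid(self.hist_vt_range)


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort generator.

    Defaults emulate the study conditions: cohort sizes 361 ARDS / 388
    control, a tidal-volume menu dominated by 450/500/600 mL, per-severity
    recognition probabilities, and documentation conditional on recognition.
    """

    n_ards: int = 361
    n_control: int = 388
    gender_fraction_male: float = 0.55
    height_mean_in: dict = field(default_factory=lambda: {"male": 69.0, "female": 64.0})
    height_sd_in: dict = field(default_factory=lambda: {"male": 3.0, "female": 2.8})
    vt_menu: tuple[float, ...] = (400.0, 450.0, 500.0, 550.0, 600.0, 650.0, 700.0)
    vt_menu_weights_male: tuple[float, ...] = (0.02, 0.13, 0.25, 0.10, 0.33, 0.10, 0.07)
    vt_menu_weights_female: tuple[float, ...] = (0.08, 0.30, 0.30, 0.12, 0.15, 0.03, 0.02)
    recognition_prob_by_severity: tuple[float, float, float] = (0.22, 0.34, 0.67)
    documentation_prob_given_recognized: float = 0.30
    documentation_prob_control: float = 0.042
    recognized_vt_target_mean: float = 6.0   # mL/kg PBW
    recognized_vt_target_sd: float = 0.7
    pf_median: dict = field(default_factory=lambda: {"ARDS": 140.0, "control": 180.0})
    pf_sigma: dict = field(default_factory=lambda: {"ARDS": 0.55, "control": 0.50})
    pf_first_inflation_scale: float = 0.35
    pplat_missing_prob: float = 0.40
    bilateral_infiltrate_prob: float = 0.35
    admitting_icus: tuple[str, ...] = ("MICU", "CCU", "SICU", "NICU")
    admitting_icu_weights: tuple[float, ...] = (0.45, 0.20, 0.20, 0.15)
    duration_log_mean: float = 3.2   # study_duration_h = 5.67 + lognormal
    duration_log_sd: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ards <= 0 or self.n_control <= 0:
            raise ConfigError("cohort sizes must be positive")
        probs = (self.gender_fraction_male,
                 *self.recognition_prob_by_severity,
                 self.documentation_prob_given_recognized,
                 self.documentation_prob_control,
                 self.pplat_missing_prob,
                 self.bilateral_infiltrate_prob)
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        for v in self.vt_menu:
            if v <= 0 or abs(v / 25.0 - round(v / 25.0)) > 1e-9:
                raise ConfigError("menu tidal volumes must be positive multiples of 25 mL")
        for w in (self.vt_menu_weights_male, self.vt_menu_weights_female):
            if len(w) != len(self.vt_menu):
                raise ConfigError("menu weights must match the menu length")
            if any(x < 0 for x in w) or sum(w) <= 0:
                raise ConfigError("menu weights must be non-negative with positive sum")
        if len(self.admitting_icu_weights) != len(self.admitting_icus) or \
                sum(self.admitting_icu_weights) <= 0:
            raise ConfigError("admitting-ICU weights must match the labels")


def severity_probs(config: CohortConfig) -> dict[Severity, float]:
    """Map the configured (mild, moderate, severe) recognition triple."""
    mild, moderate, severe = config.recognition_prob_by_severity
    return {Severity.MILD: mild, Severity.MODERATE: moderate, Severity.SEVERE: severe}
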