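"""KDE / Naive Bayes recognition classifier.

Two reference clusters are characterised in the (PBW, V^T) plane by 2D
kernel density estimates: the pooled documented subgroup (physicians who
charted ARDS — "recognised behaviour") and the control non-documented
subgroup ("unrecognised behaviour").  Each non-documented ARDS patient is
classified by the posterior odds

    P(documented | PBW, V^T) / P(control | PBW, V^T)
        = [ dens_doc(PBW, V^T) * p_doc ] / [ dens_ctrl(PBW, V^T) * p_ctrl ]

with flat priors (0.5, 0.5) by default.  Odds > 1 (the patient sits in the
documented-behaviour region, i.e. low standardized tidal volume) means
"recognised"; ties and undefined 0/0 odds count as unrecognised, the
conservative choice.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (InsufficientDataError, InvalidInputError,
                     SubgroupViolationError, UndefinedOddsError)
from .types import (AnalysisConfig, Cohort, Density2D, Method, PatientRecord,
                    RecognitionEstimate, Severity, SEVERITY_ORDER)

logger = logging.getLogger(__name__)


def scott_bandwidths(points: np.ndarray) -> tuple[float, float]:
    """Per-axis Scott's rule: sd * n^(-1/6) for a 2D product kernel."""
    n = points.shape[0]
    sds = points.std(axis=0, ddof=1)
    return tuple(float(s) * n ** (-1.0 / 6.0) for s in sds)


def fit_kde2d(points: Sequence[tuple[float, float]],
              config: Optional[AnalysisConfig] = None,
              bandwidths: Optional[tuple[float, float]] = None) -> Density2D:
    """Gaussian product-kernel KDE evaluated on the configured grid.

    The evaluation is separable: the full grid is the outer product of the
    per-axis kernel matrices, so cost is O(n * (g1 + g2)) rather than
    O(n * g1 * g2).
    """
    cfg = config or AnalysisConfig()
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 5:
        raise InsufficientDataError(
            f"KDE needs at least 5 points, got {pts.shape[0]}")
    if not np.isfinite(pts).all():
        raise InvalidInputError("KDE points must be finite")
    if bandwidths is None:
        bandwidths = scott_bandwidths(pts)
    grid1, grid2 = cfg.kde_pbw_grid(), cfg.kde_vt_grid()
    bw = []
    # floor at the grid step: narrower kernels cannot be resolved by the
    # trapezoidal grid and would break normalisation
    for b, floor in zip(bandwidths, (cfg.kde_pbw_range[2], cfg.kde_vt_range[2])):
        if b < floor:
            warnings.warn("near-zero-variance axis: bandwidth floored to the "
                          "grid step", RuntimeWarning, stacklevel=2)
            b = floor
        bw.append(float(b))
    k1 = _gauss(grid1[:, None], pts[None, :, 0], bw[0])   # (g1, n)
    k2 = _gauss(grid2[:, None], pts[None, :, 1], bw[1])   # (g2, n)
    values = (k1 @ k2.T) / pts.shape[0]
    return Density2D(axis_pbw=grid1, axis_vt=grid2, values=values,
                     kind="kde", bandwidths=(bw[0], bw[1]))


def _gauss(x, mu, bw):
    return np.exp(-0.5 * ((x - mu) / bw) ** 2) / (bw * np.sqrt(2.0 * np.pi))


def density_at(density: Density2D, points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a KDE grid; zero outside the grid."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    g1, g2 = density.axis_pbw, density.axis_vt
    out = np.zeros(pts.shape[0])
    inside = ((pts[:, 0] >= g1[0]) & (pts[:, 0] <= g1[-1])
              & (pts[:, 1] >= g2[0]) & (pts[:, 1] <= g2[-1]))
    if not inside.any():
        return out
    p = pts[inside]
    i = np.clip(np.searchsorted(g1, p[:, 0]) - 1, 0, g1.size - 2)
    j = np.clip(np.searchsorted(g2, p[:, 1]) - 1, 0, g2.size - 2)
    t = (p[:, 0] - g1[i]) / (g1[i + 1] - g1[i])
    u = (p[:, 1] - g2[j]) / (g2[j + 1] - g2[j])
    v = density.values
    out[inside] = ((1 - t) * (1 - u) * v[i, j] + t * (1 - u) * v[i + 1, j]
                   + (1 - t) * u * v[i, j + 1] + t * u * v[i + 1, j + 1])
    return out


def posterior_odds(point: tuple[float, float], dens_doc: Density2D,
                   dens_ctrl: Density2D,
                   priors: tuple[float, float] = (0.5, 0.5)) -> float:
    """Posterior odds of documented-like vs control-like behaviour.

    Raises :class:`UndefinedOddsError` where both densities vanish.
    """
    if abs(sum(priors) - 1.0) > 1e-12:
        raise InvalidInputError("priors must sum to 1")
    num = float(density_at(dens_doc, np.array([point]))[0]) * priors[0]
    den = float(density_at(dens_ctrl, np.array([point]))[0]) * priors[1]
    if den == 0.0:
        if num == 0.0:
            raise UndefinedOddsError(f"both densities vanish at {point}")
        return np.inf
    return num / den


def classify_recognized(patient: PatientRecord, dens_doc: Density2D,
                        dens_ctrl: Density2D,
                        priors: tuple[float, float] = (0.5, 0.5)) -> bool:
    """Recognised iff posterior odds > 1; ties and 0/0 are unrecognised."""
    if patient.documented or patient.cohort is not Cohort.ARDS:
        raise SubgroupViolationError(
            f"{patient.patient_id}: classifier applies to the "
            "non-documented ARDS subgroup only")
    try:
        odds = posterior_odds((patient.pbw_kg, patient.vt_std),
                              dens_doc, dens_ctrl, priors)
    except UndefinedOddsError:
        return False
    return bool(odds > 1.0)


def nb_recognition_by_severity(ards_records: Sequence[PatientRecord],
                               dens_doc: Density2D, dens_ctrl: Density2D,
                               config: Optional[AnalysisConfig] = None
                               ) -> list[RecognitionEstimate]:
    """Per-severity recognition fraction over the whole ARDS cohort.

    Documented patients count as recognised (documentation implies
    recognition); non-documented patients contribute their classification.
    """
    cfg = config or AnalysisConfig()
    estimates = []
    for severity in SEVERITY_ORDER:
        stratum = [r for r in ards_records if r.severity is severity]
        if not stratum:
            warnings.warn(f"empty {severity.value} stratum: estimate omitted",
                          RuntimeWarning, stacklevel=2)
            continue
        recognized = 0
        for r in stratum:
            if r.documented:
                recognized += int(cfg.nb_include_documented)
            elif classify_recognized(r, dens_doc, dens_ctrl, cfg.priors):
                recognized += 1
        estimates.append(RecognitionEstimate(
            severity=severity, method=Method.NAIVE_BAYES,
            fraction=recognized / len(stratum), n=len(stratum)))
    return estimates


# --------------------------------------------------------------------------
# decision boundary and its bootstrap band


def boundary_curve(dens_doc: Density2D, dens_ctrl: Density2D,
                   priors: tuple[float, float] = (0.5, 0.5)) -> np.ndarray:
    """V^T of the odds = 1 contour at each PBW grid node (NaN if absent).

    At each PBW the signed score doc*p_doc - ctrl*p_ctrl is scanned upward
    in V^T within the region of non-negligible total density; the boundary
    is the first crossing from documented-dominant to control-dominant.
    """
    s = dens_doc.values * priors[0] - dens_ctrl.values * priors[1]
    total = dens_doc.values + dens_ctrl.values
    support = total > 1e-9 * total.max()
    vt = dens_ctrl.axis_vt
    curve = np.full(dens_ctrl.axis_pbw.size, np.nan)
    for i in range(curve.size):
        idx = np.nonzero(support[i])[0]
        if idx.size < 2:
            continue
        si = s[i, idx]
        sign = si > 0
        if not sign[0]:
            continue  # control dominates even at the lowest tidal volumes
        crossings = np.nonzero(sign[:-1] & ~sign[1:])[0]
        if crossings.size == 0:
            continue  # documented dominates everywhere in support
        k = crossings[0]
        j0, j1 = idx[k], idx[k + 1]
        a, b = s[i, j0], s[i, j1]
        frac = a / (a - b) if a != b else 0.5
        curve[i] = vt[j0] + frac * (vt[j1] - vt[j0])
    return curve


@dataclass
class BoundaryBand:
    """Recognition boundary with pointwise bootstrap confidence band."""

    pbw: np.ndarray
    vt_boundary: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n_iter: int
    n_redrawn: int = 0


def bootstrap_boundary(ctrl_records: Sequence[PatientRecord],
                       doc_records: Sequence[PatientRecord],
                       n_iter: Optional[int] = None,
                       seed: Optional[int] = None,
                       config: Optional[AnalysisConfig] = None) -> BoundaryBand:
    """Bootstrap the control-non-documented subgroup and re-derive the
    odds = 1 contour; band = pointwise 2.5-97.5 percentiles of boundary V^T.

    By default each resample has the pooled-documented size, addressing the
    size imbalance between the two reference subgroups.
    """
    cfg = config or AnalysisConfig()
    n_iter = cfg.nb_bootstrap_iters if n_iter is None else n_iter
    if n_iter < 1:
        raise InvalidInputError("need at least 1 bootstrap iteration")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ctrl_pts = np.asarray([(r.pbw_kg, r.vt_std) for r in ctrl_records])
    doc_pts = np.asarray([(r.pbw_kg, r.vt_std) for r in doc_records])
    dens_doc = fit_kde2d(doc_pts, cfg)
    dens_ctrl = fit_kde2d(ctrl_pts, cfg)
    base = boundary_curve(dens_doc, dens_ctrl, cfg.priors)
    m = len(doc_records) if cfg.nb_bootstrap_match_documented_size \
        else len(ctrl_records)
    curves = np.empty((n_iter, base.size))
    n_redrawn = 0
    for it in range(n_iter):
        while True:
            sample = ctrl_pts[rng.integers(0, len(ctrl_pts), size=m)]
            if np.unique(sample, axis=0).shape[0] > 1:
                break
            n_redrawn += 1
            logger.info("degenerate bootstrap resample redrawn (iteration %d)", it)
        dens_b = fit_kde2d(sample, cfg)
        curves[it] = boundary_curve(dens_doc, dens_b, cfg.priors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        low = np.nanpercentile(curves, 2.5, axis=0)
        high = np.nanpercentile(curves, 97.5, axis=0)
    return BoundaryBand(pbw=dens_ctrl.axis_pbw, vt_boundary=base,
                        band_low=low, band_high=high,
                        n_iter=n_iter, n_redrawn=n_redrawn)
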