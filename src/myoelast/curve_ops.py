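"""Single force-curve processing.

The per-curve chain is: least-squares baseline correction, contact-point
detection (noise-threshold or variance-ratio), conversion to
force-indentation, and a Sneddon cone fit for the Young's modulus with
optional continuous refinement of the contact point. Every failure mode is
an explicit QC status, never a silent drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .config import FitConfig
from .curves import ForceCurve
from .sneddon import (BOLTZMANN_J_PER_K, modulus_from_prefactor_Pa)

# QC statuses -----------------------------------------------------------------
STATUS_OK = "ok"
STATUS_LOW_INDENTATION = "low_indentation"
STATUS_POOR_FIT = "poor_fit"
STATUS_NO_CONTACT = "no_contact"
STATUS_EXCLUDED = "excluded"


class ContactNotFoundError(RuntimeError):
    """No sample of the curve satisfies the contact criterion."""


@dataclass
class IndentationFit:
    """Per-curve fit result with full diagnostics."""

    youngs_modulus_Pa: float
    contact_z_nm: float
    baseline_offset_nm: float
    nu: float
    half_angle_deg: float
    fit_rmse_pN: float
    n_points_fit: int
    status: str
    baseline_sd_nm: float = float("nan")
    max_indentation_nm: float = float("nan")
    pixel_coords: Optional[Tuple[int, int]] = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def baseline_correct(curve: ForceCurve, baseline_fraction: float = 0.3
                     ) -> Tuple[ForceCurve, float]:
    """Remove a linear baseline fitted to the pre-contact start of the ramp.

    A straight line is fitted by least squares to the first
    ``baseline_fraction`` of the approach and subtracted from the whole
    deflection record. Returns the corrected curve and the residual standard
    deviation of the baseline region (the curve's noise estimate).
    """
    if not (0.0 < baseline_fraction <= 0.8):
        raise ValueError("baseline_fraction must be in (0, 0.8]")
    n = int(round(baseline_fraction * len(curve)))
    if n < 8:
        raise ValueError(f"baseline region has {n} points; need >= 8")
    z, d = curve.z_nm, curve.deflection_nm
    coef = np.polyfit(z[:n], d[:n], 1)
    corrected = d - np.polyval(coef, z)
    sd = float(np.std(corrected[:n], ddof=2))
    return curve.replace_deflection(corrected), sd


def select_baseline_fraction(curve: ForceCurve, max_fraction: float = 0.3,
                             n_candidates: int = 12) -> float:
    """Choose a contact-free baseline fraction for a curve.

    Fits a line to a ladder of candidate prefixes and returns the largest
    fraction whose residual sd stays close to the smallest observed (within
    25%, plus a small absolute allowance for float dust on noiseless data).
    A prefix that reaches into the contact region inflates its residual sd
    above the curve's high-frequency noise level, so the rule stops just
    short of contact without knowing where it is. The noise reference is a
    MAD estimate on first differences (immune to smooth trends and to the
    gentle contact onset), and candidate prefixes hold at least 32 samples
    so their residual sd is stable.
    """
    n = len(curve)
    d = curve.deflection_nm
    half = max(16, n // 2)
    dd = np.diff(d[:half])
    sigma_hf = float(np.median(np.abs(dd - np.median(dd)))) / 0.6745 / np.sqrt(2)
    min_pts = min(max(8, 32), max(8, n // 4))
    fractions = np.linspace(min_pts / n, max_fraction, n_candidates)
    sds = []
    for f in fractions:
        m = max(8, int(round(f * n)))
        coef = np.polyfit(curve.z_nm[:m], d[:m], 1)
        resid = d[:m] - np.polyval(coef, curve.z_nm[:m])
        sds.append(np.std(resid, ddof=2))
    sds = np.asarray(sds)
    cap = max(1.35 * sigma_hf, sigma_hf + 1e-4)
    good = np.flatnonzero(sds <= cap)
    if good.size == 0:
        return float(fractions[int(np.argmin(sds))])
    return float(fractions[good[-1]])


def _threshold_contact(z: np.ndarray, d: np.ndarray, threshold: float,
                       min_run: int) -> Tuple[float, int]:
    above = d > threshold
    if min_run > 1:
        run = np.convolve(above.astype(int), np.ones(min_run, int), "valid")
        hits = np.flatnonzero(run == min_run)
    else:
        hits = np.flatnonzero(above)
    if hits.size == 0:
        raise ContactNotFoundError("deflection never exceeds the contact threshold")
    i = int(hits[0])
    if i == 0:
        return float(z[0]), 0
    # interpolate the crossing of the threshold between the bracketing samples
    d0, d1 = d[i - 1], d[i]
    frac = 0.0 if d1 == d0 else np.clip((threshold - d0) / (d1 - d0), 0.0, 1.0)
    return float(z[i - 1] + frac * (z[i] - z[i - 1])), i


def _variance_ratio_contact(z: np.ndarray, d: np.ndarray, window: int,
                            noise_var: float) -> Tuple[float, int]:
    n = d.size
    w = int(min(window, n // 4))
    if w < 4:
        raise ContactNotFoundError("curve too short for a variance-ratio scan")
    c2 = np.concatenate([[0.0], np.cumsum(d * d)])

    def _win_msq(i0: np.ndarray, i1: np.ndarray) -> np.ndarray:
        # second moment about the corrected baseline level (zero), so a
        # flat post-contact plateau still scores as signal
        return (c2[i1] - c2[i0]) / (i1 - i0).astype(float)

    # split index i compares the w samples before against the w after
    idx = np.arange(w, n - w)
    var_b = _win_msq(idx - w, idx)
    var_a = _win_msq(idx, idx + w)
    score = var_a / (var_b + 1e-30)
    best = int(idx[np.argmax(score)])
    if var_a[best - w] <= noise_var:
        raise ContactNotFoundError("no variance increase beyond the noise level")
    return float(0.5 * (z[best - 1] + z[best])), best


def detect_contact_point(curve: ForceCurve, method: str = "threshold",
                         baseline_sd_nm: Optional[float] = None,
                         n_sigma: float = 3.0, min_run: int = 5
                         ) -> Tuple[float, int]:
    """Locate the tip-sample contact point on a baseline-corrected curve.

    ``threshold``: first index whose deflection exceeds
    ``n_sigma * baseline_sd`` and stays above it for ``min_run`` samples;
    z0 is interpolated linearly at the threshold crossing.
    ``ratio_of_variances``: the split index maximizing
    var(after) / var(before).

    Raises :class:`ContactNotFoundError` when the criterion is never met.
    """
    z, d = curve.z_nm, curve.deflection_nm
    if baseline_sd_nm is None:
        _, baseline_sd_nm = baseline_correct(curve)
    # absolute floor keeps exact-zero noiseless baselines from triggering on
    # float dust
    threshold = max(n_sigma * baseline_sd_nm, 1e-9)
    if method == "threshold":
        return _threshold_contact(z, d, threshold, min_run)
    if method == "ratio_of_variances":
        return _variance_ratio_contact(z, d, 25, threshold ** 2)
    raise ValueError(f"unknown contact method {method!r}")


def to_force_indentation(curve: ForceCurve, z0_nm: float, d0_nm: float = 0.0
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Convert (z, deflection) to (indentation, force) past contact.

    F = k (d - d0); delta = (z - z0) - (d - d0). Only samples with
    delta >= 0 are returned, in ramp order.
    """
    z, d = curve.z_nm, curve.deflection_nm
    if not (z.min() <= z0_nm <= z.max()):
        raise ValueError("contact point lies outside the recorded z range")
    rel = d - d0_nm
    delta = (z - z0_nm) - rel
    force = curve.spring_constant_pN_per_nm * rel
    keep = delta >= 0
    return delta[keep], force[keep]


class SneddonModel(BaseEstimator, RegressorMixin):
    """Sneddon cone fit of a force-indentation record.

    Fits F = c * (delta - t)^2 with c the cone prefactor of the Young's
    modulus and t an optional contact-point offset. With
    ``refine_contact=False`` the contact is taken at delta = 0 and the
    modulus is the closed-form least-squares slope of F on delta^2. With
    ``refine_contact=True`` the offset t is found by coarse grid search plus
    bounded scalar minimization of the full-range force RMSE, and the
    modulus is re-estimated at the optimum. The reported fit is restricted
    to the relative force window ``force_window`` of the peak force.

    Attributes (after ``fit``)
    --------------------------
    youngs_modulus_Pa_ : float
    contact_offset_nm_ : float
        Offset of the refined contact relative to the delta = 0 origin.
    rmse_pN_ : float
        Force RMSE over the fitted window.
    n_points_ : int
    status_ : str
        One of the QC statuses (``ok``, ``low_indentation``, ``poor_fit``).
    """

    def __init__(self, nu: float = 0.5, half_angle_deg: float = 45.0,
                 refine_contact: bool = False, refine_span_nm: float = 900.0,
                 force_window: Tuple[float, float] = (0.1, 0.9),
                 min_points: int = 8, min_indentation_nm: float = 20.0):
        self.nu = nu
        self.half_angle_deg = half_angle_deg
        self.refine_contact = refine_contact
        self.refine_span_nm = refine_span_nm
        self.force_window = force_window
        self.min_points = min_points
        self.min_indentation_nm = min_indentation_nm

    # -- internals ------------------------------------------------------
    @staticmethod
    def _slope(delta2: np.ndarray, force: np.ndarray) -> float:
        denom = float(np.dot(delta2, delta2))
        if denom == 0.0:
            return 0.0
        return float(np.dot(force, delta2) / denom)

    def _full_rmse(self, delta: np.ndarray, force: np.ndarray,
                   t: float) -> float:
        d = delta - t
        m = d > 0
        if int(m.sum()) < self.min_points:
            return np.inf
        d2 = d[m] ** 2
        a = max(self._slope(d2, force[m]), 0.0)
        resid = np.where(m, force - a * np.clip(delta - t, 0, None) ** 2, force)
        return float(np.sqrt(np.mean(resid ** 2)))

    def _window_fit(self, delta: np.ndarray, force: np.ndarray, t: float):
        d = delta - t
        m = d > 0
        d, f = d[m], force[m]
        if d.size < self.min_points:
            return np.nan, np.nan, 0, STATUS_LOW_INDENTATION, 0.0
        fmax = float(f.max())
        lo, hi = self.force_window
        w = (f >= lo * fmax) & (f <= hi * fmax)
        if int(w.sum()) < self.min_points:
            w = np.ones_like(f, bool)
        a = self._slope(d[w] ** 2, f[w])
        rmse = float(np.sqrt(np.mean((f[w] - a * d[w] ** 2) ** 2)))
        max_delta = float(d.max())
        if a <= 0 or fmax <= 0:
            return np.nan, rmse, int(w.sum()), STATUS_POOR_FIT, max_delta
        status = STATUS_OK
        if max_delta < self.min_indentation_nm:
            status = STATUS_LOW_INDENTATION
        E = modulus_from_prefactor_Pa(a, self.nu, self.half_angle_deg)
        return E, rmse, int(w.sum()), status, max_delta

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y):
        """Fit the cone law. X: indentation (nm), y: force (pN)."""
        delta = np.asarray(X, dtype=float).reshape(-1)
        force = np.asarray(y, dtype=float).reshape(-1)
        if delta.shape != force.shape:
            raise ValueError("indentation and force must have equal length")
        order = np.argsort(delta, kind="stable")
        delta, force = delta[order], force[order]

        t_opt = 0.0
        if self.refine_contact and delta.size >= self.min_points:
            t_max = min(self.refine_span_nm,
                        float(delta.max()) - 1e-9)
            if t_max > 0:
                spacing = max(np.median(np.diff(delta[delta > 0])) if
                              (delta > 0).sum() > 1 else 1.0, 1e-3)
                step = max(spacing, t_max / 400.0)
                grid = np.arange(0.0, t_max, step)
                scores = np.array([self._full_rmse(delta, force, t)
                                   for t in grid])
                if np.isfinite(scores).any():
                    t0 = float(grid[int(np.nanargmin(scores))])
                    lo = max(0.0, t0 - step)
                    hi = min(t_max, t0 + step)
                    res = minimize_scalar(
                        lambda t: self._full_rmse(delta, force, t),
                        bounds=(lo, hi), method="bounded",
                        options={"xatol": 1e-6})
                    t_opt = float(res.x) if res.fun <= scores.min() else t0

        E, rmse, n, status, max_delta = self._window_fit(delta, force, t_opt)
        self.youngs_modulus_Pa_ = E
        self.contact_offset_nm_ = t_opt
        self.rmse_pN_ = rmse
        self.n_points_ = n
        self.status_ = status
        self.max_indentation_nm_ = max_delta
        return self

    def predict(self, X):
        """Predicted force (pN) at the fitted modulus and contact offset."""
        from .sneddon import sneddon_force_pN
        delta = np.asarray(X, dtype=float).reshape(-1) - self.contact_offset_nm_
        return sneddon_force_pN(delta, self.youngs_modulus_Pa_, self.nu,
                                self.half_angle_deg)


def fit_sneddon(indentation_nm, force_pN, nu: float = 0.5,
                half_angle_deg: float = 45.0, refine_contact: bool = False,
                refine_span_nm: float = 900.0,
                force_window: Tuple[float, float] = (0.1, 0.9),
                min_points: int = 8,
                min_indentation_nm: float = 20.0) -> IndentationFit:
    """Functional wrapper over :class:`SneddonModel`.

    Returns an :class:`IndentationFit`; ``contact_z_nm`` holds the refined
    contact offset on the indentation axis (0 when unrefined).
    """
    model = SneddonModel(nu, half_angle_deg, refine_contact, refine_span_nm,
                         force_window, min_points, min_indentation_nm)
    model.fit(indentation_nm, force_pN)
    return IndentationFit(
        youngs_modulus_Pa=model.youngs_modulus_Pa_,
        contact_z_nm=model.contact_offset_nm_,
        baseline_offset_nm=0.0, nu=nu, half_angle_deg=half_angle_deg,
        fit_rmse_pN=model.rmse_pN_, n_points_fit=model.n_points_,
        status=model.status_, max_indentation_nm=model.max_indentation_nm_)


def analyze_curve(curve: ForceCurve, fit_config: Optional[FitConfig] = None
                  ) -> IndentationFit:
    """Run the full per-curve chain and return an auditable fit record.

    Baseline-corrects, detects contact, backs the provisional contact off by
    ``refine_back_nm`` so the refinement window brackets the true contact,
    fits the Sneddon model, and applies the QC rules. When the fitted
    contact point shows that the baseline region was chosen too short or
    reached into contact, the baseline is re-fitted on the strictly
    pre-contact samples and the chain re-run once. The returned
    ``contact_z_nm`` is on the absolute piezo axis of the input curve.
    """
    cfg = fit_config or FitConfig()
    fraction = cfg.baseline_fraction
    if cfg.adaptive_baseline:
        fraction = select_baseline_fraction(curve, cfg.baseline_fraction)
    fit = _analyze_once(curve, cfg, fraction)
    if np.isfinite(fit.contact_z_nm):
        dz = float(np.median(np.diff(curve.z_nm)))
        n_pre = int(np.sum(curve.z_nm < fit.contact_z_nm - 5.0 * abs(dz)))
        fraction2 = min(max(n_pre / len(curve), 8.0 / len(curve)), 0.8)
        if n_pre >= 8 and abs(fraction2 - fraction) > 0.02:
            second = _analyze_once(curve, cfg, fraction2)
            if second.status != STATUS_NO_CONTACT:
                fit = second
    return fit


def _analyze_once(curve: ForceCurve, cfg: FitConfig,
                  fraction: float) -> IndentationFit:
    corrected, baseline_sd = baseline_correct(curve, fraction)

    def _failed(status: str) -> IndentationFit:
        return IndentationFit(np.nan, np.nan, 0.0, cfg.nu, cfg.half_angle_deg,
                              np.nan, 0, status, baseline_sd_nm=baseline_sd,
                              pixel_coords=curve.pixel_coords)

    try:
        z0_det, _ = detect_contact_point(corrected, cfg.contact_method,
                                         baseline_sd, cfg.n_sigma, cfg.min_run)
    except ContactNotFoundError:
        return _failed(STATUS_NO_CONTACT)

    back = cfg.refine_back_nm if cfg.refine_contact else 0.0
    z0_early = max(float(corrected.z_nm[0]), z0_det - back)
    delta, force = to_force_indentation(corrected, z0_early, 0.0)
    if delta.size < cfg.min_points:
        return _failed(STATUS_LOW_INDENTATION)

    span = (z0_det - z0_early) + cfg.refine_forward_nm
    fit = fit_sneddon(delta, force, cfg.nu, cfg.half_angle_deg,
                      cfg.refine_contact, span, cfg.force_window,
                      cfg.min_points, cfg.min_indentation_nm)
    contact_z = z0_early + fit.contact_z_nm if cfg.refine_contact else z0_det

    status = fit.status
    if status == STATUS_OK:
        rmse_cap = max(cfg.rmse_cap_pN,
                       cfg.rmse_cap_noise_factor *
                       curve.spring_constant_pN_per_nm * baseline_sd)
        if fit.fit_rmse_pN > rmse_cap:
            status = STATUS_POOR_FIT
    return IndentationFit(
        youngs_modulus_Pa=fit.youngs_modulus_Pa if status == STATUS_OK else np.nan,
        contact_z_nm=contact_z, baseline_offset_nm=0.0, nu=cfg.nu,
        half_angle_deg=cfg.half_angle_deg, fit_rmse_pN=fit.fit_rmse_pN,
        n_points_fit=fit.n_points_fit, status=status,
        baseline_sd_nm=baseline_sd,
        max_indentation_nm=fit.max_indentation_nm,
        pixel_coords=curve.pixel_coords)


@dataclass
class CalibrationResult:
    """Thermal-noise spring-constant calibration output."""

    spring_constant_pN_per_nm: float
    method: str
    temperature_K: float
    mean_square_deflection_nm2: float

    def __post_init__(self) -> None:
        if self.spring_constant_pN_per_nm <= 0:
            raise ValueError("calibrated spring constant must be > 0")


def calibrate_spring_constant_thermal(deflection_fluctuation_nm,
                                      temperature_K: float,
                                      correction_factor: float = 1.0
                                      ) -> CalibrationResult:
    """Equipartition spring-constant estimate from a thermal deflection record.

    k = correction_factor * k_B T / <d^2>, with <d^2> the variance of the
    fluctuation record. The default correction factor 1.0 is the plain
    equipartition estimate; 0.817 applies the first-mode optical-lever
    correction.
    """
    d = np.asarray(deflection_fluctuation_nm, dtype=float).reshape(-1)
    if d.size < 1000:
        raise ValueError("need at least 1000 fluctuation samples")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    var_nm2 = float(np.var(d, ddof=1))
    if var_nm2 == 0.0:
        raise ValueError("fluctuation record has zero variance")
    k_N_per_m = correction_factor * BOLTZMANN_J_PER_K * temperature_K \
        / (var_nm2 * 1e-18)
    return CalibrationResult(k_N_per_m * 1000.0, "thermal", temperature_K,
                             var_nm2)
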