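"""Curve fitting for the four binding-curve families.

* equilibrium titration:  R = Fmax / (1 + KD_app / x) + Fmin
* biphasic wash decay:    R = R1 e^(-kd1 (t-t0)) + (R0 - R1) e^(-kd2 (t-t0))
* 1:1 bio-layer interferometry association/dissociation with KD = kd / ka
* four-parameter logistic inhibition (log IC50)

All fits are unweighted least squares on the raw signal.  Rate and
equilibrium constants are optimized in log10 space, which enforces
positivity and conditions the problem across the pM-uM range; reported
parameters are back-transformed.  Non-convergent or unidentifiable inputs
are flagged, never raised.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

logger = logging.getLogger(__name__)


@dataclass
class EquilibriumFit:
    kd_app: float      # molar
    fmax: float        # FI; saturating amplitude above fmin
    fmin: float        # FI
    residual_norm: float
    converged: bool

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.fmax / (1.0 + self.kd_app / conc) + self.fmin


@dataclass
class DissocFit:
    kd1: float         # 1/s, fast phase (kd1 >= kd2 by label ordering)
    kd2: float         # 1/s
    r0: float          # FI at t0
    r1: float          # FI in the fast phase
    t0: float
    residual_norm: float
    converged: bool

    def predict(self, t):
        dt = np.asarray(t, dtype=float) - self.t0
        return self.r1 * np.exp(-self.kd1 * dt) + (self.r0 - self.r1) * np.exp(-self.kd2 * dt)


@dataclass
class BliFit:
    ka: float          # 1/(M s)
    kd: float          # 1/s
    rmax: float
    conc: float        # molar analyte concentration
    y0: float          # response at the association/dissociation boundary
    residual_norm: float
    converged: bool

    @property
    def kd_over_ka(self) -> float:
        """Equilibrium constant K_D = k_d / k_a in molar."""
        return self.kd / self.ka


@dataclass
class Ic50Fit:
    top: float
    bottom: float
    log_ic50: float    # log10 molar
    hill_slope: float
    residual_norm: float
    converged: bool

    def predict(self, log_conc):
        x = np.asarray(log_conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10 ** ((self.log_ic50 - x) * self.hill_slope))


def _drop_nonfinite(*arrays):
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    mask = np.all([np.isfinite(a) for a in arrays], axis=0)
    return [a[mask] for a in arrays]


def fit_equilibrium(concs, fis) -> EquilibriumFit:
    """Fit the saturation-binding curve to a titration series.

    Initialization: fmin = min(FI), fmax = max - min, KD at the geometric
    mean of the concentration range.  Flat series are unidentifiable and
    returned with converged=False.
    """
    concs, fis = _drop_nonfinite(concs, fis)
    if len(concs) < 3:
        raise ValueError("need at least 3 (concentration, FI) pairs")
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive")
    span = float(np.ptp(fis))
    if span == 0:
        return EquilibriumFit(kd_app=float(np.sqrt(concs.min() * concs.max())),
                              fmax=0.0, fmin=float(fis[0]),
                              residual_norm=0.0, converged=False)

    def model(x, log_kd, fmax, fmin):
        return fmax / (1.0 + 10 ** log_kd / x) + fmin

    p0 = [float(np.log10(np.sqrt(concs.min() * concs.max()))),
          span, float(fis.min())]
    try:
        popt, _ = curve_fit(model, concs, fis, p0=p0,
                            bounds=([-15.0, 0.0, -np.inf], [3.0, np.inf, np.inf]),
                            maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    resid = float(np.linalg.norm(model(concs, *popt) - fis))
    # KD pinned at the search bound means the series carried no information
    if popt[0] <= -14.5 or popt[0] >= 2.5:
        converged = False
    return EquilibriumFit(kd_app=float(10 ** popt[0]), fmax=float(popt[1]),
                          fmin=float(popt[2]), residual_norm=resid,
                          converged=converged)


def fit_dissociation(times, fis, t0: float = 0.0) -> DissocFit:
    """Fit the biphasic wash decay; labels swapped post-fit so kd1 >= kd2.

    Parameters are (r0, fast fraction, log10 rates); initial rates 1e-2 and
    1e-4 / s with half the amplitude in the fast phase.  A constant signal is
    fit exactly by kd1 = kd2 = 0 (both rates at the lower search bound).
    """
    times, fis = _drop_nonfinite(times, fis)
    if np.any(times < t0):
        raise ValueError("all times must be >= t0")
    if len(times) < 4:
        raise ValueError("need at least 4 time points")

    def model(t, r0, frac, log_k1, log_k2):
        dt = t - t0
        r1 = frac * r0
        return r1 * np.exp(-(10 ** log_k1) * dt) + (r0 - r1) * np.exp(-(10 ** log_k2) * dt)

    p0 = [float(fis.max()), 0.5, -2.0, -4.0]
    try:
        popt, _ = curve_fit(model, times, fis, p0=p0,
                            bounds=([0.0, 0.0, -12.0, -12.0],
                                    [np.inf, 1.0, 2.0, 2.0]),
                            maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    resid = float(np.linalg.norm(model(times, *popt) - fis))
    r0, frac = float(popt[0]), float(popt[1])
    k1, k2 = float(10 ** popt[2]), float(10 ** popt[3])
    # rates at the floor of the log search window mean "no measurable decay"
    if popt[2] <= -11.5:
        k1 = 0.0
    if popt[3] <= -11.5:
        k2 = 0.0
    r1 = frac * r0
    if k2 > k1:
        k1, k2 = k2, k1
        r1 = r0 - r1
    return DissocFit(kd1=k1, kd2=k2, r0=r0, r1=r1, t0=t0,
                     residual_norm=resid, converged=converged)


def fit_bli(assoc_t, assoc_r, dissoc_t, dissoc_r, conc: float) -> BliFit:
    """Joint 1:1 bio-layer interferometry fit with Y0 continuity.

    Association follows R = Rmax / (1 + kd/(ka C)) (1 - e^(-k_obs t)) with
    the observed rate k_obs = ka C + kd; dissociation continues from the
    association end point Y0 as a single exponential Y0 e^(-kd (t - t0)).
    Both phases share (ka, kd, Rmax) and are fit jointly.
    """
    if conc <= 0:
        raise ValueError("analyte concentration must be positive")
    assoc_t, assoc_r = _drop_nonfinite(assoc_t, assoc_r)
    dissoc_t, dissoc_r = _drop_nonfinite(dissoc_t, dissoc_r)
    t_end = float(assoc_t.max())

    def curves(params):
        log_ka, log_kd, rmax = params
        ka, kd = 10 ** log_ka, 10 ** log_kd
        kobs = ka * conc + kd
        plateau = rmax / (1.0 + kd / (ka * conc))
        ra = plateau * (1.0 - np.exp(-kobs * assoc_t))
        y0 = plateau * (1.0 - np.exp(-kobs * t_end))
        rd = y0 * np.exp(-kd * (dissoc_t - t_end))
        return ra, rd, y0

    def resid(params):
        ra, rd, _ = curves(params)
        return np.concatenate([ra - assoc_r, rd - dissoc_r])

    p0 = [5.0, -3.0, float(max(assoc_r.max(), 1e-6))]
    sol = least_squares(resid, p0, bounds=([0.0, -8.0, 0.0], [9.0, 1.0, np.inf]),
                        max_nfev=20000)
    log_ka, log_kd, rmax = sol.x
    _, _, y0 = curves(sol.x)
    return BliFit(ka=float(10 ** log_ka), kd=float(10 ** log_kd),
                  rmax=float(rmax), conc=float(conc), y0=float(y0),
                  residual_norm=float(np.linalg.norm(sol.fun)),
                  converged=bool(sol.success))


def fit_ic50(log_conc, response) -> Ic50Fit:
    """Four-parameter logistic fit: Y = bottom + (top-bottom)/(1+10^((logIC50-X) h)).

    The response at X = logIC50 is (top + bottom)/2 by construction.  A flat
    response is unidentifiable and flagged; non-monotone data beyond noise
    emits a warning.
    """
    x, y = _drop_nonfinite(log_conc, response)
    if len(x) < 5:
        raise ValueError("need at least 5 points for a 4PL fit")
    if np.ptp(y) == 0:
        return Ic50Fit(top=float(y[0]), bottom=float(y[0]),
                       log_ic50=float(np.median(x)), hill_slope=1.0,
                       residual_norm=0.0, converged=False)
    order = np.argsort(x)
    ys = y[order]
    diffs = np.diff(ys)
    if (diffs > 0).any() and (diffs < 0).any():
        noise = 0.05 * np.ptp(y)
        if min(diffs.max(), -diffs.min()) > noise:
            warnings.warn("response is not monotone beyond noise", stacklevel=2)

    def model(X, top, bottom, log_ic50, slope):
        return bottom + (top - bottom) / (1.0 + 10 ** ((log_ic50 - X) * slope))

    p0 = [float(y.max()), float(y.min()), float(np.median(x)), 1.0]
    try:
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    resid = float(np.linalg.norm(model(x, *popt) - y))
    top, bottom = float(popt[0]), float(popt[1])
    if top < bottom:  # orient so top >= bottom; slope sign flips accordingly
        top, bottom = bottom, top
    return Ic50Fit(top=top, bottom=bottom, log_ic50=float(popt[2]),
                   hill_slope=float(popt[3]), residual_norm=resid,
                   converged=converged)


def fit_table(table: pd.DataFrame, concentrations, wash_times,
              binding_channel: str = "T", stat: str = "mean") -> pd.DataFrame:
    """Fit equilibrium and dissociation curves for every row of a
    genotype-phenotype table (wide format from :mod:`deepscreen.clusterstats`).

    Appends kd_app / fmax / fmin / eq_converged and kd1 / kd2 /
    dissoc_converged columns.  Missing conditions are dropped pairwise.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    wash_times = np.asarray(wash_times, dtype=float)
    eq_cols = [f"eq_{c:.3g}M__{binding_channel}__{stat}" for c in concentrations]
    wash_cols = [f"wash_{int(t)}s__{binding_channel}__{stat}" for t in wash_times]
    out = table.copy()
    kd_app = np.full(len(table), np.nan)
    fmax = np.full(len(table), np.nan)
    fmin = np.full(len(table), np.nan)
    eq_ok = np.zeros(len(table), dtype=bool)
    kd1 = np.full(len(table), np.nan)
    kd2 = np.full(len(table), np.nan)
    dis_ok = np.zeros(len(table), dtype=bool)
    for i, (_, row) in enumerate(table.iterrows()):
        fis = row.reindex(eq_cols).to_numpy(dtype=float)
        ok = np.isfinite(fis)
        if ok.sum() >= 3:
            fit = fit_equilibrium(concentrations[ok], fis[ok])
            kd_app[i], fmax[i], fmin[i] = fit.kd_app, fit.fmax, fit.fmin
            eq_ok[i] = fit.converged
        wfis = row.reindex(wash_cols).to_numpy(dtype=float)
        ok = np.isfinite(wfis)
        if ok.sum() >= 4:
            dfit = fit_dissociation(wash_times[ok], wfis[ok], t0=0.0)
            kd1[i], kd2[i] = dfit.kd1, dfit.kd2
            dis_ok[i] = dfit.converged
    out["kd_app"] = kd_app
    out["fmax"] = fmax
    out["fmin"] = fmin
    out["eq_converged"] = eq_ok
    out["kd1"] = kd1
    out["kd2"] = kd2
    out["dissoc_converged"] = dis_ok
    return out
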