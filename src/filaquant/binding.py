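"""Allosteric binding and activity models for a SAM-regulated enzyme.

Forward models and least-squares fitters for the quantitative biophysics of
an allosterically activated, filament-forming enzyme:

* a linear H2S-rate calibration (fluorogenic-probe standard curve),
* Michaelis–Menten substrate kinetics,
* Hill-type activation by an allosteric ligand (basal -> activated rate),
* thermal-activation sigmoid with a melting-style midpoint ``Tm``,
* a two-sets-of-sites isothermal titration calorimetry (ITC) model with
  displacement dilution, and
* size-exclusion-chromatography molecular-weight estimation from the
  partition coefficient ``Kav``.

All fits are unweighted nonlinear least squares (``scipy.optimize``) with a
fixed multi-start policy so fitted outputs are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

R_KCAL = 1.987204259e-3  # gas constant, kcal / (mol K)

__all__ = [
    "MMParams",
    "HillActivationParams",
    "ThermalParams",
    "ITCExperiment",
    "ITCSiteClass",
    "ITCTwoSetsParams",
    "SECCalibration",
    "LinearCalibration",
    "michaelis_menten",
    "hill_activation",
    "thermal_sigmoid",
    "calibrate_h2s",
    "fit_michaelis_menten",
    "fit_hill_activation",
    "fit_thermal_sigmoid",
    "itc_model_heats",
    "fit_itc_two_sets",
    "sec_mw_estimate",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class MMParams:
    """Michaelis–Menten parameters: ``v = Vmax * S / (Km + S)``."""

    vmax: float
    km: float
    vmax_se: float | None = None
    km_se: float | None = None

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be positive")


@dataclass
class HillActivationParams:
    """Hill activation from a basal to a maximal rate.

    ``v(S) = v_basal + (v_max - v_basal) * S^n / (K_act^n + S^n)``
    """

    v_basal: float
    v_max: float
    k_act: float
    n_hill: float
    k_act_se: float | None = None
    n_hill_se: float | None = None
    in_range: bool = True

    def __post_init__(self) -> None:
        if self.v_basal <= 0 or self.v_max < self.v_basal:
            raise ValueError("require v_max >= v_basal > 0")
        if self.k_act <= 0 or self.n_hill <= 0:
            raise ValueError("k_act and n_hill must be positive")

    @property
    def fold_activation(self) -> float:
        return self.v_max / self.v_basal


@dataclass
class ThermalParams:
    """Logistic thermal-activation curve between two plateaus.

    ``v(T) = low + (high - low) / (1 + exp(-(T - tm) / slope))``
    """

    low: float
    high: float
    tm: float
    slope: float
    tm_se: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")


@dataclass
class ITCExperiment:
    """An ITC titration design (and optionally its measured heats).

    Parameters
    ----------
    cell_volume_ul : active cell volume in microlitres.
    cell_conc_uM : macromolecule (monomer) concentration in the cell, µM.
    syringe_conc_uM : ligand concentration in the syringe, µM.
    injection_volumes_ul : per-injection volumes in µl.  The conventional
        schedule is one small pre-injection followed by equal injections,
        e.g. ``[0.4] + 44 * [0.8]``.
    temperature_C : experiment temperature in Celsius.
    heats_ucal : measured (or simulated) integrated heats per injection, µcal.
    """

    cell_volume_ul: float
    cell_conc_uM: float
    syringe_conc_uM: float
    injection_volumes_ul: list[float] = field(default_factory=list)
    temperature_C: float = 25.0
    heats_ucal: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cell_volume_ul <= 0:
            raise ValueError("cell volume must be positive")
        vols = np.asarray(self.injection_volumes_ul, dtype=float)
        if vols.size and np.any(vols <= 0):
            raise ValueError("injection volumes must be positive")
        if self.heats_ucal is not None:
            self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
            if self.heats_ucal.size != vols.size:
                raise ValueError("heats list length must equal injections")

    @classmethod
    def standard_schedule(
        cls,
        cell_conc_uM: float = 40.0,
        syringe_conc_uM: float = 500.0,
        n_injections: int = 44,
        first_ul: float = 0.4,
        main_ul: float = 0.8,
        cell_volume_ul: float = 200.0,
        temperature_C: float = 25.0,
    ) -> "ITCExperiment":
        """The conventional schedule: 0.4 µl then ``n`` × 0.8 µl."""
        return cls(
            cell_volume_ul=cell_volume_ul,
            cell_conc_uM=cell_conc_uM,
            syringe_conc_uM=syringe_conc_uM,
            injection_volumes_ul=[first_ul] + [main_ul] * n_injections,
            temperature_C=temperature_C,
        )


@dataclass
class ITCSiteClass:
    """One independent class of binding sites."""

    n: float          # sites per monomer
    k: float          # association constant, 1/M
    dh: float         # kcal/mol

    @property
    def kd(self) -> float:
        """Dissociation constant in M."""
        return 1.0 / self.k

    def dg(self, temperature_C: float) -> float:
        return -R_KCAL * (temperature_C + 273.15) * np.log(self.k)

    def minus_tds(self, temperature_C: float) -> float:
        return self.dg(temperature_C) - self.dh


@dataclass
class ITCTwoSetsParams:
    """Two independent sets of sites; class 1 is the tighter (smaller Kd)."""

    sites: tuple[ITCSiteClass, ITCSiteClass]
    temperature_C: float = 25.0
    rss: float | None = None
    identifiable: bool = True

    def __post_init__(self) -> None:
        for s in self.sites:
            if s.n < 0 or s.k <= 0:
                raise ValueError("require N_i >= 0 and K_i > 0")

    def summary(self) -> dict:
        out = {}
        for i, s in enumerate(self.sites, start=1):
            out[f"N{i}"] = s.n
            out[f"Kd{i}_M"] = s.kd
            out[f"dH{i}_kcal_mol"] = s.dh
            out[f"dG{i}_kcal_mol"] = s.dg(self.temperature_C)
            out[f"minus_TdS{i}_kcal_mol"] = s.minus_tds(self.temperature_C)
        return out


@dataclass
class LinearCalibration:
    """Ordinary least-squares line ``y = slope * x + intercept``."""

    slope: float
    intercept: float
    r2: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def invert(self, y):
        """Map a response back to the concentration axis."""
        return (np.asarray(y, dtype=float) - self.intercept) / self.slope


@dataclass
class SECCalibration:
    """Size-exclusion column calibration: log10(MW) linear in Kav."""

    v0_ml: float
    vt_ml: float
    standards: list[tuple[float, float]]  # (MW, Ve_ml)
    line: LinearCalibration | None = None

    def __post_init__(self) -> None:
        if not self.v0_ml < self.vt_ml:
            raise ValueError("require V0 < Vt")
        for mw, ve in self.standards:
            if not (self.v0_ml < ve < self.vt_ml):
                raise ValueError(f"standard Ve={ve} outside (V0, Vt)")
        if self.line is None and len(self.standards) >= 2:
            mws = np.array([m for m, _ in self.standards], dtype=float)
            kavs = np.array([self.kav(v) for _, v in self.standards])
            res = stats.linregress(kavs, np.log10(mws))
            self.line = LinearCalibration(res.slope, res.intercept, res.rvalue**2)

    def kav(self, ve_ml: float) -> float:
        """Partition coefficient ``Kav = (Ve - V0) / (Vt - V0)``."""
        return (ve_ml - self.v0_ml) / (self.vt_ml - self.v0_ml)


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------


def michaelis_menten(s, vmax: float, km: float):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def hill_activation(s, v_basal: float, v_max: float, k_act: float, n_hill: float):
    s = np.asarray(s, dtype=float)
    sn = np.power(s, n_hill, where=s > 0, out=np.zeros_like(s))
    return v_basal + (v_max - v_basal) * sn / (k_act**n_hill + sn)


def thermal_sigmoid(t, low: float, high: float, tm: float, slope: float):
    t = np.asarray(t, dtype=float)
    return low + (high - low) / (1.0 + np.exp(-(t - tm) / slope))


# ---------------------------------------------------------------------------
# simple calibrations
# ---------------------------------------------------------------------------


def calibrate_h2s(concentrations, rates) -> LinearCalibration:
    """Fit the H2S standard curve (fluorescence rate vs known concentration).

    Returns the OLS line mapping concentration to raw rate; use
    :meth:`LinearCalibration.invert` to convert measured rates into µM/min.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 standard points")
    if np.unique(x).size < 2:
        raise ValueError("singular design: concentrations are not distinct")
    res = stats.linregress(x, y)
    return LinearCalibration(res.slope, res.intercept, res.rvalue**2)


def sec_mw_estimate(calibration: SECCalibration, ve_sample_ml: float) -> dict:
    """Estimate molecular weight from a sample's elution volume.

    Returns a dict with ``kav``, ``mw`` (same units as the standards) and an
    ``extrapolated`` flag when Kav falls outside the standards' range.  A
    sample eluting at or before the void volume is flagged ``void`` with no
    estimate.
    """
    if len(calibration.standards) < 3:
        raise ValueError("need at least 3 standards")
    if ve_sample_ml <= calibration.v0_ml:
        return {"kav": None, "mw": None, "void": True, "extrapolated": False}
    kav = calibration.kav(ve_sample_ml)
    std_kavs = [calibration.kav(v) for _, v in calibration.standards]
    extrapolated = not (min(std_kavs) <= kav <= max(std_kavs))
    mw = 10.0 ** calibration.line.predict(kav)
    return {"kav": kav, "mw": float(mw), "void": False, "extrapolated": extrapolated}


# ---------------------------------------------------------------------------
# nonlinear fitters
# ---------------------------------------------------------------------------


def _curve_fit(f, x, y, p0, bounds):
    popt, pcov = optimize.curve_fit(
        f, x, y, p0=p0, bounds=bounds, maxfev=20000, method="trf"
    )
    perr = np.sqrt(np.diag(pcov))
    return popt, perr


def fit_michaelis_menten(s, v) -> MMParams:
    """Nonlinear least-squares Michaelis–Menten fit."""
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.unique(s).size < 4:
        raise ValueError("need >= 4 distinct substrate levels")
    vmax0 = float(np.max(v)) or 1.0
    km0 = float(np.median(s[s > 0])) if np.any(s > 0) else 1.0
    try:
        popt, perr = _curve_fit(
            michaelis_menten, s, v, p0=[vmax0, km0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    return MMParams(vmax=popt[0], km=popt[1], vmax_se=perr[0], km_se=perr[1])


def fit_hill_activation(s, v) -> HillActivationParams:
    """Fit the Hill activation model; multi-start over the Hill exponent.

    The exponent is bounded to (0.2, 10].  If the fitted ``K_act`` lies
    outside the assayed ligand range the result is flagged via
    ``in_range=False``.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.unique(s).size < 5 or not np.any(s == 0):
        raise ValueError("need >= 5 activator levels including 0")
    vb0 = float(np.mean(v[s == 0]))
    vm0 = float(np.max(v))
    pos = s[s > 0]
    k0 = float(np.median(pos))
    best = None
    for n0 in (0.5, 1.0, 2.0, 3.0, 5.0):
        try:
            popt, perr = _curve_fit(
                hill_activation, s, v,
                p0=[max(vb0, 1e-9), max(vm0, vb0 + 1e-9), k0, n0],
                bounds=([1e-12, 1e-12, 1e-12, 0.2], [np.inf, np.inf, np.inf, 10.0]),
            )
        except RuntimeError:
            continue
        rss = float(np.sum((hill_activation(s, *popt) - v) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, perr)
    if best is None:
        raise RuntimeError("Hill activation fit did not converge from any start")
    _, popt, perr = best
    in_range = bool(pos.min() <= popt[2] <= pos.max())
    if not in_range:
        warnings.warn("fitted K_act lies outside the assayed ligand range")
    return HillActivationParams(
        v_basal=popt[0], v_max=popt[1], k_act=popt[2], n_hill=popt[3],
        k_act_se=perr[2], n_hill_se=perr[3], in_range=in_range,
    )


def fit_thermal_sigmoid(t, v) -> ThermalParams:
    """Fit a logistic between plateaus; ``Tm`` is the inflection point."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.unique(t).size < 6:
        raise ValueError("need >= 6 temperatures bracketing the transition")
    lo0, hi0 = float(np.min(v)), float(np.max(v))
    tm0 = float(t[np.argmin(np.abs(v - (lo0 + hi0) / 2))])
    best = None
    for slope0 in (0.5, 1.0, 2.0, 5.0):
        try:
            popt, perr = _curve_fit(
                thermal_sigmoid, t, v,
                p0=[lo0, hi0, tm0, slope0],
                bounds=([-np.inf, -np.inf, -np.inf, 1e-6],
                        [np.inf, np.inf, np.inf, np.inf]),
            )
        except RuntimeError:
            continue
        rss = float(np.sum((thermal_sigmoid(t, *popt) - v) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, perr)
    if best is None:
        raise RuntimeError("thermal sigmoid fit did not converge")
    _, popt, perr = best
    if not (t.min() <= popt[2] <= t.max()):
        raise ValueError(
            "no inflection within the assayed temperature range "
            f"(fitted Tm={popt[2]:.1f})"
        )
    # a logistic whose 10-90% transition (~4.4 * slope) exceeds the assayed
    # span is indistinguishable from a line: no resolvable inflection
    if 4.394 * popt[3] > np.ptp(t):
        raise ValueError(
            "monotone data without a resolvable inflection in range "
            f"(fitted transition width {4.394 * popt[3]:.1f} exceeds the "
            f"assayed span {np.ptp(t):.1f})"
        )
    return ThermalParams(low=popt[0], high=popt[1], tm=popt[2],
                         slope=popt[3], tm_se=perr[2])


# ---------------------------------------------------------------------------
# ITC two-sets-of-sites model
# ---------------------------------------------------------------------------


def _free_ligand(x_total: float, m_total: float, sites) -> float:
    """Solve free ligand x from total-ligand conservation by bracketed root.

    ``X_total = x + M_total * sum_i N_i K_i x / (1 + K_i x)``
    """
    if x_total <= 0:
        return 0.0

    def f(x):
        bound = sum(m_total * s.n * s.k * x / (1.0 + s.k * x) for s in sites)
        return x + bound - x_total

    # f(0) = -x_total < 0, f(x_total) >= 0: root is bracketed.
    sol = optimize.brentq(f, 0.0, x_total, rtol=1e-14, xtol=1e-30, maxiter=200)
    return float(sol)


def itc_model_heats(params: ITCTwoSetsParams, design: ITCExperiment) -> np.ndarray:
    """Per-injection heats (µcal) for a two-sets-of-sites titration.

    Each injection of volume ``dV`` expels a fraction ``dV/V0`` of the cell
    content (displacement dilution) before delivering ligand.  After each
    injection the free-ligand concentration is solved from mass conservation
    and the cell heat content is

    ``Q = V0 * M_total * sum_i N_i * dH_i * K_i x / (1 + K_i x)``.

    The observed heat of injection j is
    ``dQ_j = Q_j - Q_{j-1} + (dV_j / V0) * (Q_j + Q_{j-1}) / 2``,
    the last term compensating for heat content expelled with the displaced
    volume.
    """
    v0 = design.cell_volume_ul * 1e-6           # litres
    m_tot = design.cell_conc_uM * 1e-6          # molar
    x_syr = design.syringe_conc_uM * 1e-6
    sites = params.sites

    x_tot = 0.0
    q_prev = 0.0
    heats = []
    for dv_ul in design.injection_volumes_ul:
        dv = dv_ul * 1e-6
        frac = dv / v0
        # displacement: expel frac of current cell content, add ligand
        m_tot = m_tot * (1.0 - frac)
        x_tot = x_tot * (1.0 - frac) + x_syr * frac
        x_free = _free_ligand(x_tot, m_tot, sites)
        q = v0 * m_tot * sum(
            s.n * s.dh * (s.k * x_free / (1.0 + s.k * x_free)) for s in sites
        )  # kcal
        dq = q - q_prev + frac * (q + q_prev) / 2.0
        heats.append(dq * 1e9)  # kcal -> µcal
        q_prev = q
    return np.asarray(heats)


def itc_mass_balance(params: ITCTwoSetsParams, design: ITCExperiment) -> np.ndarray:
    """Relative mass-balance residual |x + bound - X_total| / X_total per injection."""
    v0 = design.cell_volume_ul * 1e-6
    m_tot = design.cell_conc_uM * 1e-6
    x_syr = design.syringe_conc_uM * 1e-6
    x_tot = 0.0
    out = []
    for dv_ul in design.injection_volumes_ul:
        frac = dv_ul * 1e-6 / v0
        m_tot *= 1.0 - frac
        x_tot = x_tot * (1.0 - frac) + x_syr * frac
        x = _free_ligand(x_tot, m_tot, params.sites)
        bound = sum(m_tot * s.n * s.k * x / (1.0 + s.k * x) for s in params.sites)
        out.append(abs(x + bound - x_tot) / x_tot)
    return np.asarray(out)


def _itc_theta_to_sites(theta, share_n):
    if share_n:
        return (
            ITCSiteClass(n=theta[0], k=10.0 ** theta[1], dh=theta[2]),
            ITCSiteClass(n=theta[0], k=10.0 ** theta[3], dh=theta[4]),
        )
    return (
        ITCSiteClass(n=theta[0], k=10.0 ** theta[1], dh=theta[2]),
        ITCSiteClass(n=theta[3], k=10.0 ** theta[4], dh=theta[5]),
    )


def _itc_residuals(theta, design, observed, use, share_n):
    sites = _itc_theta_to_sites(theta, share_n)
    model = itc_model_heats(
        ITCTwoSetsParams(sites=sites, temperature_C=design.temperature_C), design
    )
    return model[use] - observed[use]


def fit_itc_two_sets(
    design: ITCExperiment,
    blank_heats=None,
    discard_first: bool = True,
    dilution: str = "auto",
    share_n: bool = False,
) -> ITCTwoSetsParams:
    """Fit a two-sets-of-sites model to the observed injection heats.

    Parameters
    ----------
    design : titration with ``heats_ucal`` populated.
    blank_heats : optional ligand-into-buffer blank titration heats (µcal);
        their mean is subtracted as the heat of dilution.
    discard_first : drop the small pre-injection from the fit (standard
        calorimetry practice); it is still simulated in the forward model.
    dilution : ``"auto"`` subtracts the blank mean if given, otherwise the
        mean of the final 3 injection heats; ``"none"`` subtracts nothing.
    share_n : constrain both site classes to the same stoichiometry
        (one N fitted instead of two).  With two overlapping binding events
        the unconstrained six-parameter model is often weakly identified;
        sharing N markedly tightens the association constants.

    Classes are reported sorted by Kd ascending (class 1 = tighter site).
    When both site classes are weakly populated (c-value << 1) the result is
    flagged non-identifiable and a single-class fallback is compared by RSS.
    """
    if design.heats_ucal is None:
        raise ValueError("design carries no observed heats")
    heats = np.asarray(design.heats_ucal, dtype=float).copy()
    n_inj = heats.size
    if n_inj < 15:
        raise ValueError("need >= 15 informative injections")

    if dilution == "auto":
        if blank_heats is not None:
            heats = heats - float(np.mean(blank_heats))
        else:
            heats = heats - float(np.mean(heats[-3:]))
    elif dilution != "none":
        raise ValueError("dilution must be 'auto' or 'none'")

    use = np.ones(n_inj, dtype=bool)
    if discard_first:
        use[0] = False

    # data-driven enthalpy scale for the starting grid
    v0 = design.cell_volume_ul * 1e-6
    m0 = design.cell_conc_uM * 1e-6
    total_kcal = float(np.sum(heats[use])) * 1e-9
    h_scale = total_kcal / (v0 * m0) if m0 > 0 else 1.0  # ~ sum N_i dH_i
    h_first = float(heats[1] if n_inj > 1 else heats[0]) * 1e-9 / (
        v0 * m0 * 0.05 + 1e-30
    )

    starts = []
    for lk1 in (6.0, 7.0):
        for lk2 in (5.0, 6.0):
            for h1, h2 in (
                (h_scale, h_scale),
                (h_first, h_scale - h_first / 2),
                (-abs(h_scale), abs(h_scale)),
                (abs(h_scale), -abs(h_scale)),
            ):
                if share_n:
                    starts.append([0.5, lk1, h1, lk2, h2])
                else:
                    starts.append([0.5, lk1, h1, 0.5, lk2, h2])

    if share_n:
        lb = [0.0, 3.0, -100.0, 3.0, -100.0]
        ub = [4.0, 11.0, 100.0, 11.0, 100.0]
    else:
        lb = [0.0, 3.0, -100.0, 0.0, 3.0, -100.0]
        ub = [4.0, 11.0, 100.0, 4.0, 11.0, 100.0]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        try:
            res = optimize.least_squares(
                _itc_residuals, p0, bounds=(lb, ub),
                args=(design, heats, use, share_n),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("two-sets-of-sites fit failed from all starts")

    sites = list(_itc_theta_to_sites(best.x, share_n))
    sites.sort(key=lambda s: s.kd)  # class 1 = tighter
    c_values = [m0 * s.n * s.k for s in sites]
    identifiable = any(c > 1.0 for c in c_values)
    params = ITCTwoSetsParams(
        sites=(sites[0], sites[1]),
        temperature_C=design.temperature_C,
        rss=float(2 * best.cost),
        identifiable=identifiable,
    )
    if not identifiable:
        warnings.warn(
            "both site classes have c-value << 1; fit flagged non-identifiable "
            "(single-class fallback compared by RSS)"
        )
    return params
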