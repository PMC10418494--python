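"""Multi-detector size-exclusion chromatography quantification.

A tetra-detector SEC run records, on a common retention-volume grid, signals
proportional to concentration-weighted optical properties of the eluting
species:

    RI   = k_RI  * c * dn/dc
    UV   = k_UV  * c * dA/dc
    LS   = k_LS  * c * Mw * (dn/dc)^2      (RALS and LALS)
    VIS  = k_VIS * c * [eta]

with c the local mass concentration.  Calibrating the detector constants on
a single standard of known mass, molar mass and dn/dc then gives, per
deconvolved peak: the injected mass (RI), the absolute molar mass (LS/RI)
and the specific absorbance dA/dc (UV/RI) — no column calibration needed.

Peak deconvolution fits the RI trace with Gaussian (optionally
exponentially-modified Gaussian) components and transfers the fitted shapes
to the other detectors, where component areas are re-estimated by
non-negative linear least squares.

The module also carries the Stokes-Einstein conversion between diffusion
coefficient and hydrodynamic radius and the Gill-von Hippel extinction
coefficient at 280 nm.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.optimize import least_squares, nnls
from scipy.special import erfc

from .errors import CalibrationError, FitError, ValidationError

BOLTZMANN = 1.380649e-23          # J/K
DEFAULT_VISCOSITY = 7.0e-4        # Pa s, aqueous buffer near 36 C
DEFAULT_DN_DC = 0.185             # mL/g, protein in aqueous buffer
DETECTORS = ("RI", "UV", "RALS", "LALS", "VIS")

# log-linear retention calibration V = a - b*log10(M/kDa), anchored on the
# antibody/complex family (147 kDa -> 17.3 mL, 234 -> 15.4, 320 -> 14.1)
RETENTION_A = 38.05
RETENTION_B = 9.56

GILL_VON_HIPPEL = {"trp": 5690.0, "tyr": 1280.0, "cystine": 120.0}  # M^-1 cm^-1


@dataclass
class Chromatogram:
    volume: np.ndarray                       # mL, uniform increasing grid
    traces: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.ndim != 1 or len(self.volume) < 2:
            raise ValidationError("volume grid must be a 1-D array")
        if not np.all(np.diff(self.volume) > 0):
            raise ValidationError("volume grid must be strictly increasing")
        for name, tr in self.traces.items():
            tr = np.asarray(tr, dtype=float)
            if tr.shape != self.volume.shape:
                raise ValidationError(f"trace {name!r} does not share the volume grid")
            self.traces[name] = tr

    def to_csv(self, path: str | Path | None = None) -> str:
        lines = [f"# {k}={v}" for k, v in self.metadata.items()]
        df = pd.DataFrame({"volume_mL": self.volume, **self.traces})
        text = "\n".join(lines) + ("\n" if lines else "") + df.to_csv(index=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, path_or_text: str | Path) -> "Chromatogram":
        p = Path(path_or_text) if "\n" not in str(path_or_text) else None
        text = p.read_text() if p is not None and p.exists() else str(path_or_text)
        meta: dict = {}
        body = []
        for line in text.splitlines():
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition("=")
                try:
                    meta[k] = float(v)
                except ValueError:
                    meta[k] = v
            elif line.strip():
                body.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body)))
        volume = df.pop("volume_mL").to_numpy()
        return cls(volume, {c: df[c].to_numpy() for c in df.columns}, meta)


@dataclass
class DetectorCalibration:
    k_ri: float
    k_uv: float
    k_ls: float
    k_vis: float | None = None
    standard: str = "BSA"
    standard_mw_kDa: float = 66.4
    standard_dn_dc: float = DEFAULT_DN_DC

    def __post_init__(self):
        for name in ("k_ri", "k_uv", "k_ls"):
            if getattr(self, name) <= 0:
                raise CalibrationError(f"{name} must be positive")


@dataclass
class Peak:
    center: float                    # mL
    sigma: float                     # mL
    tau: float                       # mL; 0 => pure Gaussian
    areas: dict[str, float]          # signal * mL per detector
    fraction_ct: float               # share of total RI mass
    mass_mg: float | None = None     # needs calibration
    conc_gL: float | None = None
    species: str = ""


@dataclass
class DeconvolutionResult:
    peaks: list[Peak]
    rms_residual: float
    converged: bool
    shape: str
    model_ri: np.ndarray


@dataclass
class OpticalProperties:
    epsilon_280: float               # M^-1 cm^-1
    dA_dc: float                     # mL g^-1 cm^-1
    dn_dc: float = DEFAULT_DN_DC     # mL/g


@dataclass
class HydroParams:
    d_s: float                       # m^2/s
    r_h: float                       # m
    temperature: float               # K
    viscosity: float                 # Pa s

    @property
    def r_h_nm(self) -> float:
        return self.r_h * 1e9


def retention_volume(mass_kDa: float) -> float:
    """Log-linear retention model for the antibody/antigen size family."""
    return RETENTION_A - RETENTION_B * math.log10(mass_kDa)


def _gauss(v: np.ndarray, area: float, mu: float, sigma: float) -> np.ndarray:
    return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
        -0.5 * ((v - mu) / sigma) ** 2
    )


def _emg(v: np.ndarray, area: float, mu: float, sigma: float, tau: float) -> np.ndarray:
    if tau <= 1e-9:
        return _gauss(v, area, mu, sigma)
    lam = 1.0 / tau
    arg = lam / 2.0 * (2 * mu + lam * sigma ** 2 - 2 * v)
    # clip to avoid overflow; erfc term kills the tail anyway
    return area * lam / 2.0 * np.exp(np.clip(arg, -700, 700)) * erfc(
        (mu + lam * sigma ** 2 - v) / (math.sqrt(2) * sigma)
    )


def _component(v, area, mu, sigma, tau, shape):
    return _emg(v, area, mu, sigma, tau) if shape == "emg" else _gauss(v, area, mu, sigma)


def simulate_chromatogram(
    species: list[dict],
    k_ri: float = 1.0,
    k_uv: float = 1.0,
    k_ls: float = 1.0,
    k_vis: float = 1.0,
    grid: np.ndarray | None = None,
    sigma_mL: float = 0.25,
    shape: str = "gaussian",
    noise_sigma_rel: float = 0.01,
    baseline_drift: float = 0.0,
    injection_volume_uL: float = 100.0,
    flow_rate_mL_min: float = 0.5,
    temperature: float = 309.0,
    seed: int | None = None,
) -> Chromatogram:
    """Synthesize an aligned tetra-detector chromatogram.

    Each species dict carries ``name``, ``mass_kDa``, ``conc_gL`` (mass
    concentration in the injected sample), optional ``dn_dc``, ``dA_dc``,
    ``intrinsic_visc``, ``center_mL``, ``sigma_mL``, ``tau_mL``.  Noise is
    multiplicative Gaussian per grid point (sigma relative to the local
    signal) plus an optional linear baseline drift; ``seed`` makes the run
    bit-reproducible.
    """
    if grid is None:
        grid = np.arange(10.0, 22.0, 0.01)
    v = np.asarray(grid, dtype=float)
    inj_mL = injection_volume_uL * 1e-3
    traces = {d: np.zeros_like(v) for d in DETECTORS}
    for sp in species:
        mass = sp["mass_kDa"]
        conc = sp["conc_gL"]
        if conc < 0:
            raise ValidationError("species concentration must be non-negative")
        dn_dc = sp.get("dn_dc", DEFAULT_DN_DC)
        dA_dc = sp.get("dA_dc", 1.0)
        ivisc = sp.get("intrinsic_visc", 6.5)
        mu = sp.get("center_mL", retention_volume(mass))
        sig = sp.get("sigma_mL", sigma_mL)
        tau = sp.get("tau_mL", 0.0)
        m_mg = conc * inj_mL  # injected mass, mg
        profile = _component(v, m_mg, mu, sig, tau if shape == "emg" else 0.0, shape)
        traces["RI"] += k_ri * dn_dc * profile
        traces["UV"] += k_uv * dA_dc * profile
        traces["RALS"] += k_ls * mass * dn_dc ** 2 * profile
        traces["LALS"] += k_ls * mass * dn_dc ** 2 * profile
        traces["VIS"] += k_vis * ivisc * profile
    rng = np.random.default_rng(seed)
    for d in DETECTORS:
        tr = traces[d]
        if noise_sigma_rel > 0:
            tr = tr * (1.0 + noise_sigma_rel * rng.standard_normal(tr.shape))
        if baseline_drift:
            tr = tr + baseline_drift * (v - v[0]) / (v[-1] - v[0])
        traces[d] = tr
    meta = {
        "flow_rate_mL_min": flow_rate_mL_min,
        "injection_volume_uL": injection_volume_uL,
        "temperature_K": temperature,
    }
    return Chromatogram(v, traces, meta)


def _detect_peaks(trace: np.ndarray, min_prominence_rel: float = 0.05) -> np.ndarray:
    top = float(np.max(trace)) if len(trace) else 0.0
    if top <= 0:
        return np.array([], dtype=int)
    idx, _ = _signal.find_peaks(trace, prominence=min_prominence_rel * top)
    return idx


def calibrate(
    standard_chromatogram: Chromatogram,
    standard_mw_kDa: float,
    standard_conc_gL: float,
    standard_dn_dc: float = DEFAULT_DN_DC,
    standard_dA_dc: float = 0.66,
    standard_intrinsic_visc: float | None = None,
) -> DetectorCalibration:
    """Derive per-detector response constants from a single-standard run."""
    chrom = standard_chromatogram
    ri = chrom.traces["RI"]
    n_peaks = len(_detect_peaks(ri))
    if n_peaks == 0:
        raise CalibrationError("standard run shows no RI peak")
    if n_peaks > 1:
        raise CalibrationError(
            f"standard run must contain a single resolved peak, found {n_peaks}"
        )
    inj_mL = float(chrom.metadata.get("injection_volume_uL", 100.0)) * 1e-3
    m_mg = standard_conc_gL * inj_mL
    if m_mg <= 0:
        raise CalibrationError("standard injected mass must be positive")
    area = {d: float(np.trapezoid(chrom.traces[d], chrom.volume)) for d in chrom.traces}
    k_ri = area["RI"] / (m_mg * standard_dn_dc)
    k_uv = area["UV"] / (m_mg * standard_dA_dc)
    ls_area = area.get("RALS", area.get("LALS"))
    k_ls = ls_area / (m_mg * standard_mw_kDa * standard_dn_dc ** 2)
    k_vis = None
    if standard_intrinsic_visc and "VIS" in area:
        k_vis = area["VIS"] / (m_mg * standard_intrinsic_visc)
    return DetectorCalibration(
        k_ri, k_uv, k_ls, k_vis,
        standard_mw_kDa=standard_mw_kDa, standard_dn_dc=standard_dn_dc,
    )


def deconvolve(
    chromatogram: Chromatogram,
    n_peaks: int,
    initial_centers: list[float] | None = None,
    shape: str = "gaussian",
    sigma_guess: float = 0.25,
    max_nfev: int = 5000,
) -> DeconvolutionResult:
    """Fit the RI trace with ``n_peaks`` components; transfer shapes to the
    other detectors and re-estimate their component areas linearly.

    Nonlinear least squares on (area, center, sigma[, tau]) per peak with
    non-negativity on areas; tolerance 1e-10.  Raises :class:`FitError`
    with diagnostics when the optimiser does not converge.
    """
    if n_peaks < 1:
        raise ValidationError("n_peaks must be >= 1")
    if shape not in ("gaussian", "emg"):
        raise ValidationError(f"unknown peak shape {shape!r}")
    v = chromatogram.volume
    ri = chromatogram.traces["RI"]
    if initial_centers is None:
        sm = ri if len(ri) < 11 else _signal.savgol_filter(ri, 11, 3)
        top = float(np.max(sm))
        if top <= 0:
            raise FitError("RI trace carries no signal to deconvolve")
        idx, props = np.array([], dtype=int), {"prominences": np.array([])}
        for prom in (0.05, 0.01, 0.002, 0.0005):
            idx, props = _signal.find_peaks(sm, prominence=prom * top)
            if len(idx) >= n_peaks:
                break
        if len(idx) >= n_peaks:
            keep = np.sort(idx[np.argsort(props["prominences"])[::-1][:n_peaks]])
            initial_centers = [float(v[i]) for i in keep]
        else:
            # pad detected maxima with centers spread over the signal support
            centers = [float(v[i]) for i in idx]
            support = v[sm > 0.01 * top]
            extra = np.linspace(support[0], support[-1], n_peaks - len(centers) + 2)
            initial_centers = sorted(centers + list(extra[1:-1]))
    if len(initial_centers) != n_peaks or not np.all(np.isfinite(initial_centers)):
        raise ValidationError("need one finite initial center per peak")

    dv = float(v[1] - v[0])
    area0 = max(float(np.trapezoid(np.clip(ri, 0, None), v)) / n_peaks, dv)
    per = 4 if shape == "emg" else 3

    def unpack(theta):
        th = theta.reshape(n_peaks, per)
        return th[:, 0], th[:, 1], th[:, 2], (th[:, 3] if per == 4 else np.zeros(n_peaks))

    def model(theta):
        areas, mus, sigmas, taus = unpack(theta)
        out = np.zeros_like(v)
        for a, m, s, t in zip(areas, mus, sigmas, taus):
            out += _component(v, a, m, s, t, shape)
        return out

    theta0, lo, hi = [], [], []
    for mu in initial_centers:
        theta0 += [area0, mu, sigma_guess] + ([0.05] if per == 4 else [])
        lo += [0.0, v[0], dv / 2] + ([1e-6] if per == 4 else [])
        hi += [np.inf, v[-1], (v[-1] - v[0])] + ([2.0] if per == 4 else [])
    res = least_squares(
        lambda th: model(th) - ri,
        np.array(theta0), bounds=(np.array(lo), np.array(hi)),
        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=max_nfev,
    )
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    scale = float(np.max(np.abs(ri))) or 1.0
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitError(
            f"deconvolution did not converge (status {res.status})",
            diagnostics={"rms_residual": rms, "status": res.status},
        )
    areas_ri, mus, sigmas, taus = unpack(res.x)
    order = np.argsort(mus)
    areas_ri, mus, sigmas, taus = (arr[order] for arr in (areas_ri, mus, sigmas, taus))

    # unit-area component shapes, reused across detectors
    shapes = np.stack(
        [_component(v, 1.0, m, s, t, shape) for m, s, t in zip(mus, sigmas, taus)]
    ).T
    total_ri = float(areas_ri.sum())
    peaks = []
    for i in range(n_peaks):
        areas = {"RI": float(areas_ri[i])}
        peaks.append(
            Peak(
                center=float(mus[i]), sigma=float(sigmas[i]), tau=float(taus[i]),
                areas=areas,
                fraction_ct=float(areas_ri[i] / total_ri) if total_ri > 0 else 0.0,
            )
        )
    for det, trace in chromatogram.traces.items():
        if det == "RI":
            continue
        coef, _ = nnls(shapes, trace)
        for i, pk in enumerate(peaks):
            pk.areas[det] = float(coef[i])
    return DeconvolutionResult(
        peaks=peaks, rms_residual=rms, converged=bool(res.success),
        shape=shape, model_ri=model(res.x),
    )


def quantify_peaks(
    result: DeconvolutionResult,
    calibration: DetectorCalibration,
    injection_volume_uL: float = 100.0,
    dn_dc: float = DEFAULT_DN_DC,
) -> DeconvolutionResult:
    """Attach injected mass and sample mass concentration to each peak."""
    inj_mL = injection_volume_uL * 1e-3
    for pk in result.peaks:
        pk.mass_mg = pk.areas["RI"] / (calibration.k_ri * dn_dc)
        pk.conc_gL = pk.mass_mg / inj_mL
    return result


def molar_mass(
    peak: Peak, calibration: DetectorCalibration, dn_dc: float = DEFAULT_DN_DC,
    ls_detector: str = "RALS",
) -> float:
    """Absolute molar mass (kDa) of a peak from the LS/RI area ratio."""
    a_ri = peak.areas.get("RI", 0.0)
    if a_ri <= 0:
        raise FitError("vanishing RI area; molar mass undefined")
    a_ls = peak.areas[ls_detector]
    return (a_ls / calibration.k_ls) / ((a_ri / calibration.k_ri) * dn_dc)


def absorption_coefficient(
    peak: Peak, calibration: DetectorCalibration, dn_dc: float = DEFAULT_DN_DC
) -> float:
    """Specific absorbance dA/dc (mL g^-1 cm^-1) from the UV/RI area ratio."""
    a_ri = peak.areas.get("RI", 0.0)
    if a_ri <= 0:
        raise FitError("vanishing RI area; dA/dc undefined")
    mass = (a_ri / calibration.k_ri) / dn_dc
    return (peak.areas["UV"] / calibration.k_uv) / mass


def stokes_einstein(
    d_s: float | None = None,
    r_h: float | None = None,
    temperature: float = 309.0,
    viscosity: float = DEFAULT_VISCOSITY,
) -> HydroParams:
    """Relate diffusion coefficient (m^2/s) and hydrodynamic radius (m).

    Exactly one of ``d_s``/``r_h`` must be given; the other is returned in
    the resulting :class:`HydroParams` via D = k_B T / (6 pi eta r_h).
    """
    if (d_s is None) == (r_h is None):
        raise ValidationError("give exactly one of d_s or r_h")
    if temperature <= 0 or viscosity <= 0:
        raise ValidationError("temperature and viscosity must be positive")
    known = d_s if d_s is not None else r_h
    if known is None or known <= 0:
        raise ValidationError("d_s / r_h must be positive")
    factor = BOLTZMANN * temperature / (6.0 * math.pi * viscosity)
    if d_s is not None:
        r_h = factor / d_s
    else:
        d_s = factor / r_h
    return HydroParams(d_s, r_h, temperature, viscosity)


def extinction_from_sequence(
    n_trp: int, n_tyr: int, n_cystine: int, mw: float,
    dn_dc: float = DEFAULT_DN_DC,
) -> OpticalProperties:
    """Gill-von Hippel extinction at 280 nm and the implied dA/dc.

    ``mw`` in g/mol.  The specific absorbance is numerically eps/Mw — the
    absorbance of a 1 mg/mL solution in a 1 cm cell (the convention under
    which an IgG sits near 1.4 and serum albumin near 0.66).
    """
    if min(n_trp, n_tyr, n_cystine) < 0 or mw <= 0:
        raise ValidationError("counts must be >= 0 and Mw positive")
    eps = (
        GILL_VON_HIPPEL["trp"] * n_trp
        + GILL_VON_HIPPEL["tyr"] * n_tyr
        + GILL_VON_HIPPEL["cystine"] * n_cystine
    )
    return OpticalProperties(eps, eps / mw, dn_dc)
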