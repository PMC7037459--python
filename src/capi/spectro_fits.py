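"""CD spectral descriptors, thermal-melt fitting and fluorescence normalization.

For an all-alpha-helix calcium sensor the far-UV CD spectrum has its two
characteristic minima at 208 and 222 nm; the ratio theta_222/theta_208 is a
compact spectral-shape descriptor and Delta-theta_222/theta_222 =
(theta_222^ion - theta_222^EGTA)/theta_222^EGTA reports the gain in
ellipticity on cation binding.  Near-UV spectra are baselined by
subtracting the mean ellipticity over 310-320 nm, where no protein signal
is expected.  Thermal denaturation followed at 222 nm over a 20-96 C scan
is fit with a four-parameter Hill sigmoid in Celsius,

    theta(T) = theta_folded + (theta_unfolded - theta_folded) * T^h / (T_m^h + T^h),

whose midpoint is T_m; melts with no detectable transition in the scan
range are reported censored ("> 96 C" style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import lmfit


@dataclass
class CDSpectrum:
    """Wavelength-indexed ellipticity (nm, mdeg); wavelengths strictly monotone."""

    wavelengths: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise ValueError("wavelengths and ellipticity lengths differ")
        d = np.diff(self.wavelengths)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelengths must be strictly monotone")

    def at(self, wavelength: float) -> float:
        """Ellipticity at an exact wavelength by linear interpolation."""
        w, e = self.wavelengths, self.ellipticity
        if w[0] > w[-1]:
            w, e = w[::-1], e[::-1]
        if not (w[0] <= wavelength <= w[-1]):
            raise ValueError(f"{wavelength} nm outside spectrum range [{w[0]}, {w[-1]}]")
        return float(np.interp(wavelength, w, e))


@dataclass
class MeltCurve:
    """Temperature-indexed ellipticity at 222 nm (C, mdeg); strictly increasing T."""

    temperature: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.temperature.shape != self.ellipticity.shape:
            raise ValueError("temperature and ellipticity lengths differ")
        if self.temperature.size > 1 and not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperature must be strictly increasing")


@dataclass
class MeltFit:
    """Result of :func:`fit_melt`.

    ``censored`` marks melts whose midpoint lies beyond the scan maximum or
    that show no transition; their T_m is reported as "> {scan max}".
    """

    theta_folded: float  # mdeg
    theta_unfolded: float  # mdeg
    tm: float  # C
    h: float  # Hill exponent, > 0
    converged: bool
    censored: bool
    scan_max: float
    tm_stderr: float = float("nan")

    @property
    def tm_report(self) -> str:
        return f"> {self.scan_max:g}" if self.censored else f"{self.tm:.1f}"


def hill_sigmoid(t: np.ndarray, theta_folded: float, theta_unfolded: float,
                 tm: float, h: float) -> np.ndarray:
    """Four-parameter Hill sigmoid in Celsius; theta(T_m) is the baseline midpoint."""
    t = np.asarray(t, dtype=float)
    ratio = np.power(t / tm, h)  # numerically safer than t^h / (tm^h + t^h)
    return theta_folded + (theta_unfolded - theta_folded) * ratio / (1.0 + ratio)


def theta_ratio(spectrum: CDSpectrum) -> float:
    """theta_222/theta_208, each read by interpolation at exactly 222.0/208.0 nm."""
    t208 = spectrum.at(208.0)
    t222 = spectrum.at(222.0)
    if t208 == 0:
        raise ZeroDivisionError("theta_208 is zero")
    return t222 / t208


def delta_theta(theta222_ion: float, theta222_egta: float) -> float:
    """(theta_222^ion - theta_222^EGTA) / theta_222^EGTA."""
    if theta222_egta == 0:
        raise ZeroDivisionError("theta_222^EGTA is zero")
    return (theta222_ion - theta222_egta) / theta222_egta


def normalize_near_uv(spectrum: CDSpectrum, band: tuple[float, float] = (310.0, 320.0)) -> CDSpectrum:
    """Subtract the mean ellipticity over the signal-free band (default 310-320 nm)."""
    lo, hi = band
    w = spectrum.wavelengths
    mask = (w >= lo) & (w <= hi)
    if not np.any(mask):
        raise ValueError(f"spectrum does not cover the {lo}-{hi} nm baseline band")
    offset = float(spectrum.ellipticity[mask].mean())
    return CDSpectrum(w.copy(), spectrum.ellipticity - offset)


def fit_melt(curve: MeltCurve, amplitude_sd_factor: float = 3.0) -> MeltFit:
    """Fit a four-parameter Hill sigmoid to a thermal denaturation profile.

    Multi-start over a T_m grid spanning the scan (plus one beyond-scan
    start so censored melts converge cleanly) and Hill exponents
    {10, 25, 50}.  A melt is censored when the fitted T_m exceeds the scan
    maximum or the fitted transition amplitude is below
    ``amplitude_sd_factor`` times the residual SD (no detectable
    transition).
    """
    t = curve.temperature
    y = curve.ellipticity
    if t.size < 8 or (t[-1] - t[0]) < 20.0:
        raise ValueError("need >= 8 points spanning >= 20 C")
    scan_max = float(t[-1])
    span = float(y.max() - y.min())

    params = lmfit.Parameters()
    params.add("theta_folded", value=float(y[0]), min=y.min() - 2 * span - 1, max=y.max() + 2 * span + 1)
    params.add("theta_unfolded", value=float(y[-1]), min=y.min() - 2 * span - 1, max=y.max() + 2 * span + 1)
    params.add("tm", value=0.5 * (t[0] + t[-1]), min=max(t[0], 1.0), max=scan_max + 60.0)
    params.add("h", value=25.0, min=0.5, max=500.0)

    def resid(p):
        return hill_sigmoid(t, p["theta_folded"].value, p["theta_unfolded"].value,
                            p["tm"].value, p["h"].value) - y

    best = None
    tm_starts = list(np.linspace(t[0] + 2, scan_max - 2, 8)) + [scan_max + 20.0]
    for tm0 in tm_starts:
        for h0 in (10.0, 25.0, 50.0):
            params["tm"].value = tm0
            params["h"].value = h0
            try:
                res = lmfit.minimize(resid, params, method="leastsq")
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
    if best is None:
        raise RuntimeError("melt fit failed from every start")

    p = best.params
    amplitude = abs(p["theta_unfolded"].value - p["theta_folded"].value)
    residual_sd = float(np.std(best.residual))
    censored = (p["tm"].value > scan_max) or (amplitude < amplitude_sd_factor * residual_sd)
    tm_err = p["tm"].stderr if p["tm"].stderr is not None else float("nan")
    return MeltFit(
        theta_folded=float(p["theta_folded"].value),
        theta_unfolded=float(p["theta_unfolded"].value),
        tm=float(p["tm"].value),
        h=float(p["h"].value),
        converged=bool(best.success),
        censored=bool(censored),
        scan_max=scan_max,
        tm_stderr=float(tm_err),
    )


def normalize_fluorescence(titration: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Normalize a (free Ca2+, F_332) titration to the lowest-calcium intensity.

    The series is sorted by free calcium; every intensity is divided by the
    intensity at the lowest calcium point, so the first value is 1.
    """
    if not len(titration):
        raise ValueError("empty titration")
    pts = sorted((float(c), float(f)) for c, f in titration)
    f0 = pts[0][1]
    if f0 == 0:
        raise ZeroDivisionError("reference intensity at lowest calcium is zero")
    return [(c, f / f0) for c, f in pts]
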