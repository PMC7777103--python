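"""Absorbance-spectrum algebra and damped-harmonic-oscillator decomposition.

The experimental THz analysis represents a low-frequency water absorbance
spectrum as a sum of three damped harmonic oscillators — a relaxational mode
below 100 cm⁻¹, the intermolecular hydrogen-bond stretching band near
180 cm⁻¹, and the librational band centered near 650 cm⁻¹ (outside the
measured window, so its center is conventionally held fixed). The canonical
absorbance lineshape used throughout is

    I(ν) = Σ_modes A · ν² · w0 / [(ν0² − ν²)² + (ν·w0)²]

whose single-mode maximum lies exactly at ν0. Center frequencies track the
hydrogen-bond strength; linewidths track the diversity and lifetime of the
HB environments.

Also here: the double-difference construction ΔΔα = Δα(host+water) −
Δα(host+guest) that isolates the displaced water cluster's fingerprint,
estimation of the number of confined waters by scaling a bulk reference
spectrum, and band-ratio diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import lmfit

__all__ = [
    "Spectrum",
    "DifferenceSpectrum",
    "Oscillator",
    "OscillatorParams",
    "OscillatorFitResult",
    "STRETCH_BANDS",
    "default_oscillator_params",
    "oscillator_model",
    "fit_oscillators",
    "double_difference",
    "estimate_water_count",
    "band_ratio",
    "read_spectrum",
    "write_spectrum",
]

#: measured intermolecular-stretch band (center, width) in cm⁻¹ for water in
#: the Ga4L6 cage and for bulk water at several thermodynamic state points
STRETCH_BANDS: dict[str, tuple[float, float]] = {
    "cage": (180.0, 249.0),
    "bulk_293K": (181.0, 537.0),
    "bulk_273K": (193.0, 557.0),
    "bulk_10kbar": (216.0, 542.0),
}

MODE_NAMES = ("relaxational", "stretch", "librational")

#: conventional librational band center of liquid water, cm⁻¹
LIBRATIONAL_CENTER = 650.0


@dataclass
class Spectrum:
    """Frequency grid (cm⁻¹) with intensity values and provenance metadata."""

    frequency: np.ndarray
    intensity: np.ndarray
    normalization: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.frequency.shape != self.intensity.shape:
            raise ValueError("frequency and intensity must have equal length")
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequency grid must be monotone increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    def interp(self, nu: float | np.ndarray) -> float | np.ndarray:
        return np.interp(nu, self.frequency, self.intensity)

    def normalized(self) -> "Spectrum":
        """Copy rescaled to unit maximum (the comparison convention)."""
        peak = float(np.max(np.abs(self.intensity)))
        if peak == 0:
            return replace(self, normalization="max1")
        return replace(self, intensity=self.intensity / peak,
                       normalization="max1")


@dataclass
class DifferenceSpectrum(Spectrum):
    """A (double-)difference absorbance spectrum, optionally per-concentration."""

    concentration_mM: float | None = None


@dataclass
class Oscillator:
    """One damped harmonic mode: amplitude A, center ν0, width w0 (cm⁻¹)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.center < 0 or self.width <= 0 or self.amplitude < 0:
            raise ValueError("need center >= 0, width > 0, amplitude >= 0")


@dataclass
class OscillatorParams:
    """The three-mode decomposition with per-parameter 2σ uncertainties."""

    relaxational: Oscillator
    stretch: Oscillator
    librational: Oscillator
    two_sigma: dict = field(default_factory=dict)

    def modes(self) -> dict[str, Oscillator]:
        return {"relaxational": self.relaxational, "stretch": self.stretch,
                "librational": self.librational}


def default_oscillator_params(kind: str = "cage") -> OscillatorParams:
    """Default three-mode parameters for a named environment.

    The stretch mode takes the measured (center, width) for ``kind`` from
    :data:`STRETCH_BANDS`; the relaxational mode defaults to (50, 220) cm⁻¹
    and the librational mode to (650, 400) cm⁻¹, all with unit amplitude.
    """
    nu0, w0 = STRETCH_BANDS[kind]
    return OscillatorParams(
        relaxational=Oscillator(1.0, 50.0, 220.0),
        stretch=Oscillator(1.0, nu0, w0),
        librational=Oscillator(1.0, LIBRATIONAL_CENTER, 400.0),
    )


def _single_mode(nu: np.ndarray, A: float, nu0: float, w0: float) -> np.ndarray:
    return A * nu**2 * w0 / ((nu0**2 - nu**2) ** 2 + (nu * w0) ** 2)


def oscillator_model(params: OscillatorParams, grid) -> np.ndarray:
    """Evaluate the sum-of-damped-oscillators absorbance model on a grid."""
    nu = np.asarray(grid, dtype=float)
    out = np.zeros_like(nu)
    for osc in params.modes().values():
        out += _single_mode(nu, osc.amplitude, osc.center, osc.width)
    return out


@dataclass
class OscillatorFitResult:
    params: OscillatorParams
    success: bool
    redchi: float
    message: str
    residual_rms: float


def fit_oscillators(spectrum: Spectrum, init: OscillatorParams | None = None,
                    fix_librational_center: bool = True,
                    fixed: dict[str, tuple[str, ...]] | None = None,
                    relaxational_max_center: float = 100.0,
                    multistart: bool = True) -> OscillatorFitResult:
    """Nonlinear least-squares fit of the three-mode model.

    ``fixed`` maps mode name to the parameter fields to hold at their init
    values, e.g. ``{"librational": ("center",)}``; the librational center is
    fixed by default (it lies outside the measured window) and the
    relaxational center is constrained below ``relaxational_max_center``.
    The stretch center is bounded to the measured frequency window (the band
    it describes lies inside the data). With ``multistart`` (default) a small
    grid of stretch-band starting points is tried and the best residual kept
    — the broad, overlapping bands otherwise admit poor local minima.
    2σ uncertainties are taken from the covariance diagonal.
    Non-convergence is flagged in the result, never silently ignored.
    """
    if init is None and multistart:
        starts = [OscillatorParams(
            relaxational=Oscillator(1.0, 50.0, 220.0),
            stretch=Oscillator(1.0, c0, w0),
            librational=Oscillator(1.0, LIBRATIONAL_CENTER, 400.0))
            for c0 in (140.0, 190.0, 260.0) for w0 in (150.0, 350.0, 550.0)]
        best: OscillatorFitResult | None = None
        for start in starts:
            res = fit_oscillators(spectrum, init=start,
                                  fix_librational_center=fix_librational_center,
                                  fixed=fixed,
                                  relaxational_max_center=relaxational_max_center,
                                  multistart=False)
            if best is None or (res.success and res.residual_rms <
                                best.residual_rms):
                best = res
        return best
    if init is None:
        init = OscillatorParams(
            relaxational=Oscillator(1.0, 50.0, 220.0),
            stretch=Oscillator(1.0, 190.0, 350.0),
            librational=Oscillator(1.0, LIBRATIONAL_CENTER, 400.0),
        )
    fixed = dict(fixed or {})
    if fix_librational_center:
        fixed.setdefault("librational", ())
        if "center" not in fixed["librational"]:
            fixed["librational"] = tuple(fixed["librational"]) + ("center",)

    p = lmfit.Parameters()
    for name, osc in init.modes().items():
        frozen = fixed.get(name, ())
        p.add(f"{name}_amplitude", value=osc.amplitude, min=0.0,
              vary="amplitude" not in frozen)
        if name == "relaxational":
            cmin, cmax = 0.0, relaxational_max_center
        elif name == "stretch":
            cmin = float(spectrum.frequency.min())
            cmax = float(spectrum.frequency.max())
        else:
            cmin, cmax = 0.0, np.inf
        p.add(f"{name}_center", value=min(max(osc.center, cmin), cmax),
              min=cmin, max=cmax, vary="center" not in frozen)
        p.add(f"{name}_width", value=osc.width, min=1e-6,
              vary="width" not in frozen)

    nu = spectrum.frequency
    y = spectrum.intensity

    def resid(pars):
        model = np.zeros_like(nu)
        for name in MODE_NAMES:
            model += _single_mode(nu, pars[f"{name}_amplitude"].value,
                                  pars[f"{name}_center"].value,
                                  pars[f"{name}_width"].value)
        return model - y

    result = lmfit.minimize(resid, p, method="leastsq")
    two_sigma = {}
    modes = {}
    for name in MODE_NAMES:
        vals = {}
        for fieldname in ("amplitude", "center", "width"):
            par = result.params[f"{name}_{fieldname}"]
            vals[fieldname] = float(par.value)
            if par.stderr is not None:
                two_sigma[f"{name}_{fieldname}"] = 2.0 * float(par.stderr)
        modes[name] = Oscillator(**vals)
    out = OscillatorParams(relaxational=modes["relaxational"],
                           stretch=modes["stretch"],
                           librational=modes["librational"],
                           two_sigma=two_sigma)
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return OscillatorFitResult(params=out, success=bool(result.success),
                               redchi=float(getattr(result, "redchi", np.nan)),
                               message=str(result.message), residual_rms=rms)


# ---------------------------------------------------------------------------
# spectrum algebra

def moving_average(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; edges use the available shorter window."""
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def double_difference(d1: Spectrum, d2: Spectrum,
                      smooth: bool = False, window: int = 5) -> DifferenceSpectrum:
    """ΔΔα(ν) = Δα(1)(ν) − Δα(2)(ν), pointwise on identical grids.

    Optional moving-average smoothing (default 5-point, matching a 2 cm⁻¹
    wide window on a 0.5 cm⁻¹ grid convention).
    """
    if d1.frequency.shape != d2.frequency.shape or not np.allclose(
            d1.frequency, d2.frequency):
        raise ValueError("frequency grids differ; resample explicitly first")
    vals = d1.intensity - d2.intensity
    if smooth:
        vals = moving_average(vals, window)
    conc = getattr(d1, "concentration_mM", None)
    return DifferenceSpectrum(frequency=d1.frequency.copy(), intensity=vals,
                              concentration_mM=conc,
                              metadata={"operation": "double_difference",
                                        "smoothed": bool(smooth)})


def estimate_water_count(dd: Spectrum, bulk_reference: Spectrum,
                         host_concentration_mM: float,
                         fit_band: tuple[float, float] = (100.0, 270.0),
                         n_max: int = 30,
                         bulk_molarity: float | None = None) -> dict:
    """Estimate how many waters the difference spectrum accounts for.

    The bulk reference is scaled by n·(c_host/c_bulk) for integer candidate
    n and the n minimizing the squared deviation over ``fit_band`` is
    selected. Returns ``{"count", "residuals", "scale_per_molecule"}`` where
    ``residuals`` maps each candidate n to its sum of squared deviations
    (so near-degenerate neighbors, e.g. a ±1 uncertainty, stay visible).
    """
    from .units import BULK_WATER_MOLARITY

    if host_concentration_mM <= 0:
        raise ValueError("host concentration must be positive")
    if bulk_molarity is None:
        bulk_molarity = BULK_WATER_MOLARITY
    lo, hi = fit_band
    mask = (dd.frequency >= lo) & (dd.frequency <= hi)
    if not np.any(mask):
        raise ValueError("fit band contains no data points")
    if dd.frequency[mask].min() < bulk_reference.frequency.min() or \
            dd.frequency[mask].max() > bulk_reference.frequency.max():
        raise ValueError("bulk reference does not cover the fit band")
    nu = dd.frequency[mask]
    target = dd.intensity[mask]
    scale = host_concentration_mM / (bulk_molarity * 1000.0)
    per_molecule = scale * bulk_reference.interp(nu)
    residuals = {n: float(np.sum((target - n * per_molecule) ** 2))
                 for n in range(n_max + 1)}
    best = min(residuals, key=residuals.get)
    return {"count": best, "residuals": residuals,
            "scale_per_molecule": scale}


def band_ratio(spectrum: Spectrum, nu_a: float = 400.0,
               nu_b: float = 180.0) -> float:
    """Ratio of linearly interpolated intensities I(ν_a)/I(ν_b).

    Returns NaN (flagged undefined) when the denominator is ≤ 0.
    """
    f = spectrum.frequency
    for nu in (nu_a, nu_b):
        if not (f.min() <= nu <= f.max()):
            raise ValueError(f"{nu} cm^-1 outside the spectrum grid")
    num = float(spectrum.interp(nu_a))
    den = float(spectrum.interp(nu_b))
    if den <= 0:
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# I/O: two-column text with # metadata header

def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: frequency_cm-1 intensity\n")
        fh.write(f"# normalization: {spec.normalization}\n")
        for key, val in spec.metadata.items():
            fh.write(f"# {key}: {val}\n")
        for nu, i in zip(spec.frequency, spec.intensity):
            fh.write(f"{nu:.6f} {i:.10g}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    meta: dict = {}
    freq, inten = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            freq.append(float(parts[0]))
            inten.append(float(parts[1]))
    norm = meta.pop("normalization", "raw")
    meta.pop("columns", None)
    return Spectrum(frequency=np.array(freq), intensity=np.array(inten),
                    normalization=norm, metadata=meta)
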