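"""Synthetic SERS spectrum generator for chlorpyrifos, pyrimethanil and
their mixtures.

The generator emulates the statistical structure of surface-enhanced Raman
spectra of the two pesticides measured on AuNP colloids: each analyte
contributes a set of Lorentzian (optionally Gaussian) characteristic bands
whose common amplitude follows a log-linear concentration response,
``amplitude = max(0, intercept + slope * log10(c))``; acetonitrile solvent
bands, a smooth quadratic fluorescence baseline, per-spectrum multiplicative
gain jitter and additive Gaussian noise are superimposed.  Mixtures are the
sum of the two analyte signals with effective concentrations scaled by the
mixing volume fractions (one baseline and one solvent contribution, not
doubled).

Class coding follows the study design: 1 = mixture, 2 = pyrimethanil,
3 = chlorpyrifos.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "PeakSpec",
    "AnalyteModel",
    "GeneratorConfig",
    "Spectrum",
    "LabeledSpectrumSet",
    "CHLORPYRIFOS",
    "PYRIMETHANIL",
    "DEFAULT_SOLVENT_PEAKS",
    "generate_pure_spectrum",
    "generate_mixture_spectrum",
    "generate_dataset",
]

#: Class codes used throughout the package.
CLASS_MIXTURE = 1
CLASS_PYRIMETHANIL = 2
CLASS_CHLORPYRIFOS = 3


@dataclass(frozen=True)
class PeakSpec:
    """A single vibrational band.

    Parameters
    ----------
    center : float
        Band position in cm^-1.
    width : float
        Half-width at half-maximum in cm^-1.
    relative_amplitude : float
        Dimensionless weight in (0, 1] multiplying the analyte's
        concentration-dependent amplitude scale (or, for solvent peaks,
        the absolute peak height in intensity units).
    """

    center: float
    width: float = 6.0
    relative_amplitude: float = 1.0

    def __post_init__(self):
        if self.width <= 0:
            raise ConfigurationError(f"peak at {self.center} cm^-1: width must be > 0")
        if self.relative_amplitude <= 0:
            raise ConfigurationError(
                f"peak at {self.center} cm^-1: relative_amplitude must be > 0"
            )


@dataclass(frozen=True)
class AnalyteModel:
    """An analyte's band set and its log-linear concentration response.

    The common amplitude scale of all bands at molar concentration ``c`` is
    ``max(0, response_intercept + response_slope * log10(c))`` in intensity
    units; individual bands are scaled by their ``relative_amplitude``.
    """

    name: str
    peaks: tuple[PeakSpec, ...]
    response_slope: float = 1.0
    response_intercept: float = 8.0

    def __post_init__(self):
        if not self.peaks:
            raise ConfigurationError(f"analyte {self.name!r} must have at least one peak")
        if self.response_slope <= 0:
            raise ConfigurationError(
                f"analyte {self.name!r}: response_slope must be > 0"
            )

    def amplitude(self, concentration: float) -> float:
        """Amplitude scale (intensity units) at a molar concentration."""
        if concentration <= 0:
            return 0.0
        return max(
            0.0, self.response_intercept + self.response_slope * np.log10(concentration)
        )


# SERS band positions (cm^-1) of the two analytes with qualitative relative
# prominence: the 609/675 cm^-1 P=S bands dominate for chlorpyrifos, the
# 558 cm^-1 antisymmetric stretch and the 990 cm^-1 ring-breathing mode for
# pyrimethanil.
CHLORPYRIFOS = AnalyteModel(
    name="chlorpyrifos",
    peaks=(
        PeakSpec(609.0, 6.0, 1.00),   # P=S
        PeakSpec(675.0, 6.0, 0.90),   # P=S
        PeakSpec(1092.0, 6.0, 0.60),  # P-O-C stretch
        PeakSpec(1166.0, 6.0, 0.45),  # Cl-ring, delta(C_H)
        PeakSpec(1567.0, 7.0, 0.35),  # ring stretching
    ),
    response_slope=1.0,
    response_intercept=8.0,
)

PYRIMETHANIL = AnalyteModel(
    name="pyrimethanil",
    peaks=(
        PeakSpec(558.0, 6.0, 1.00),   # antisymmetric stretching
        PeakSpec(608.0, 6.0, 0.50),   # aromatic ring in-plane deformation
        PeakSpec(990.0, 6.0, 0.90),   # ring breathing
        PeakSpec(1294.0, 6.0, 0.50),  # antisymmetric stretching
        PeakSpec(1600.0, 7.0, 0.45),  # CH_ring antisymmetric stretching
    ),
    response_slope=0.9,
    response_intercept=7.5,
)

#: Acetonitrile solvent bands; relative_amplitude is the absolute height in
#: intensity units (no concentration dependence).
DEFAULT_SOLVENT_PEAKS = (
    PeakSpec(740.0, 6.0, 0.80),
    PeakSpec(910.0, 6.0, 0.60),
    PeakSpec(1040.0, 6.0, 1.00),
    PeakSpec(1370.0, 6.0, 0.60),
)

#: Mixing volume ratios pyrimethanil:chlorpyrifos of the study design.
DEFAULT_RATIO_LEVELS = ((1, 1), (1, 2), (1, 3), (1, 4), (4, 1), (3, 1), (2, 1))

#: Molar concentration levels spanned by the dataset.
DEFAULT_CONCENTRATION_LEVELS = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic dataset.

    Defaults encode the study conditions: a 200-1700 cm^-1 grid at 2 cm^-1
    spacing (751 points), 78 spectra split 38/20/20 over classes
    mixture/pyrimethanil/chlorpyrifos, concentrations 1e-3..1e-7 M, seven
    mixing ratios, a gentle quadratic fluorescence baseline, additive noise
    with sd ~2% of the strongest noiseless band and +/-5% gain jitter.
    """

    grid_start: float = 200.0
    grid_end: float = 1700.0
    grid_step: float = 2.0
    solvent_peaks: tuple[PeakSpec, ...] = DEFAULT_SOLVENT_PEAKS
    # baseline(nu) = c0 + c1*nu + c2*nu^2 (intensity units; nu in cm^-1)
    baseline_coefficients: tuple[float, ...] = (3.0, 1.0e-3, 2.0e-7)
    noise_sd: float = 0.12
    gain_jitter_sd: float = 0.05
    seed: int = 0
    # counts per class code {1: mixtures, 2: pyrimethanil, 3: chlorpyrifos}
    class_composition: dict[int, int] = field(
        default_factory=lambda: {CLASS_MIXTURE: 38, CLASS_PYRIMETHANIL: 20, CLASS_CHLORPYRIFOS: 20}
    )
    concentration_levels: tuple[float, ...] = DEFAULT_CONCENTRATION_LEVELS
    ratio_levels: tuple[tuple[float, float], ...] = DEFAULT_RATIO_LEVELS
    peak_shape: str = "lorentzian"
    concentration_range: tuple[float, float] = (1e-8, 1e-2)

    def __post_init__(self):
        if self.grid_start >= self.grid_end:
            raise ConfigurationError("grid_start must be < grid_end")
        if self.grid_step <= 0:
            raise ConfigurationError("grid_step must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.gain_jitter_sd < 0:
            raise ConfigurationError("gain_jitter_sd must be >= 0")
        if self.peak_shape not in ("lorentzian", "gaussian"):
            raise ConfigurationError(f"unknown peak_shape {self.peak_shape!r}")
        if any(n < 1 for n in self.class_composition.values()):
            raise ConfigurationError("class_composition counts must all be >= 1")

    @property
    def wavenumbers(self) -> np.ndarray:
        """The shared wavenumber grid (inclusive of both ends)."""
        n = int(round((self.grid_end - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    @property
    def size(self) -> int:
        return sum(self.class_composition.values())


@dataclass
class Spectrum:
    """One spectrum: a wavenumber grid, intensities, class label, metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must have equal length")
        if self.wavenumbers.ndim != 1:
            raise ValueError("spectrum vectors must be one-dimensional")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy with new intensities on the same grid."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float),
                        self.label, dict(self.metadata))


class LabeledSpectrumSet:
    """An ordered collection of spectra sharing one wavenumber grid."""

    def __init__(self, spectra: list[Spectrum]):
        if not spectra:
            raise ValueError("LabeledSpectrumSet requires at least one spectrum")
        grid = spectra[0].wavenumbers
        for i, s in enumerate(spectra):
            if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
                raise ValueError(f"spectrum {i} is not on the shared wavenumber grid")
        self.spectra = list(spectra)
        self.wavenumbers = grid

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label if s.label is not None else -1 for s in self.spectra])

    @property
    def intensities(self) -> np.ndarray:
        """(n_spectra, n_points) intensity matrix."""
        return np.vstack([s.intensities for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def __iter__(self):
        return iter(self.spectra)

    def map(self, fn) -> "LabeledSpectrumSet":
        """Apply a Spectrum -> Spectrum function to every member."""
        return LabeledSpectrumSet([fn(s) for s in self.spectra])


def _profile(grid: np.ndarray, peak: PeakSpec, shape: str) -> np.ndarray:
    """Unit-height band profile on the grid."""
    d = grid - peak.center
    if shape == "lorentzian":
        w2 = peak.width**2
        return w2 / (d * d + w2)
    # gaussian: width is HWHM -> sigma = w / sqrt(2 ln 2)
    sigma = peak.width / np.sqrt(2.0 * np.log(2.0))
    return np.exp(-0.5 * (d / sigma) ** 2)


def _check_peaks_on_grid(peaks, config: GeneratorConfig, owner: str):
    for p in peaks:
        if not (config.grid_start <= p.center <= config.grid_end):
            raise ConfigurationError(
                f"{owner} peak at {p.center} cm^-1 lies outside the grid "
                f"[{config.grid_start}, {config.grid_end}]"
            )


def analyte_signal(model: AnalyteModel, concentration: float,
                   config: GeneratorConfig) -> np.ndarray:
    """Noiseless analyte contribution (no solvent, no baseline)."""
    _check_peaks_on_grid(model.peaks, config, model.name)
    grid = config.wavenumbers
    amp = model.amplitude(concentration)
    signal = np.zeros_like(grid)
    if amp > 0:
        for p in model.peaks:
            signal += amp * p.relative_amplitude * _profile(grid, p, config.peak_shape)
    return signal


def solvent_signal(config: GeneratorConfig) -> np.ndarray:
    """Noiseless solvent contribution."""
    _check_peaks_on_grid(config.solvent_peaks, config, "solvent")
    grid = config.wavenumbers
    signal = np.zeros_like(grid)
    for p in config.solvent_peaks:
        signal += p.relative_amplitude * _profile(grid, p, config.peak_shape)
    return signal


def baseline_signal(config: GeneratorConfig) -> np.ndarray:
    """Quadratic fluorescence baseline evaluated on the grid."""
    grid = config.wavenumbers
    return np.polynomial.polynomial.polyval(grid, list(config.baseline_coefficients))


def _assemble(chemical: np.ndarray, config: GeneratorConfig,
              rng: np.random.Generator | None) -> np.ndarray:
    """chemical (analyte+solvent) signal -> gain jitter, baseline, noise."""
    gain = 1.0
    if rng is not None and config.gain_jitter_sd > 0:
        gain = 1.0 + config.gain_jitter_sd * rng.standard_normal()
    y = gain * chemical + baseline_signal(config)
    if rng is not None and config.noise_sd > 0:
        y = y + config.noise_sd * rng.standard_normal(y.size)
    return y


def _check_concentration(concentration: float, config: GeneratorConfig):
    if concentration <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    lo, hi = config.concentration_range
    if not (lo <= concentration <= hi):
        raise ValueError(
            f"concentration {concentration} M outside the validity range [{lo}, {hi}] M"
        )


def generate_pure_spectrum(model: AnalyteModel, concentration: float,
                           config: GeneratorConfig,
                           rng: np.random.Generator | None = None) -> Spectrum:
    """Generate one single-analyte spectrum.

    With ``rng=None`` the spectrum is noiseless (no additive noise, unit
    gain), which is the deterministic signal used by the additivity and
    monotonicity guarantees.
    """
    _check_concentration(concentration, config)
    chemical = analyte_signal(model, concentration, config) + solvent_signal(config)
    y = _assemble(chemical, config, rng)
    label = CLASS_PYRIMETHANIL if model.name == "pyrimethanil" else CLASS_CHLORPYRIFOS
    return Spectrum(config.wavenumbers, y, label=label,
                    metadata={"analyte": model.name, "concentration": concentration})


def generate_mixture_spectrum(model_a: AnalyteModel, model_b: AnalyteModel,
                              conc_a: float, conc_b: float,
                              ratio: tuple[float, float],
                              config: GeneratorConfig,
                              rng: np.random.Generator | None = None) -> Spectrum:
    """Generate one two-analyte mixture spectrum.

    ``ratio = (ra, rb)`` are mixing volumes of the a- and b-solutions; the
    effective concentration of each analyte in the mixture is its stock
    concentration scaled by its volume fraction.  The mixture signal is the
    sum of the two analyte signals plus exactly one solvent and one baseline
    contribution.
    """
    if conc_a <= 0 or conc_b <= 0:
        raise ValueError("mixture concentrations must both be > 0")
    ra, rb = ratio
    if ra <= 0 or rb <= 0:
        raise ValueError(f"ratio components must be > 0, got {ratio}")
    fa, fb = ra / (ra + rb), rb / (ra + rb)
    chemical = (
        analyte_signal(model_a, conc_a * fa, config)
        + analyte_signal(model_b, conc_b * fb, config)
        + solvent_signal(config)
    )
    y = _assemble(chemical, config, rng)
    return Spectrum(config.wavenumbers, y, label=CLASS_MIXTURE,
                    metadata={"analyte": f"{model_a.name}+{model_b.name}",
                              "concentration_a": conc_a, "concentration_b": conc_b,
                              "ratio": (float(ra), float(rb))})


def generate_dataset(config: GeneratorConfig | None = None,
                     size: int | None = None,
                     model_a: AnalyteModel = PYRIMETHANIL,
                     model_b: AnalyteModel = CHLORPYRIFOS) -> LabeledSpectrumSet:
    """Generate the labeled dataset defined by the configuration.

    Pure-analyte spectra cycle through ``concentration_levels``; mixtures
    cycle through the (ratio, concentration) product with both stocks at the
    same molarity.  Deterministic given ``config.seed``.
    """
    config = config or GeneratorConfig()
    if size is None:
        size = config.size
    if size != config.size:
        raise ConfigurationError(
            f"class_composition sums to {config.size} but size {size} was requested"
        )
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []

    n_chl = config.class_composition.get(CLASS_CHLORPYRIFOS, 0)
    n_pyr = config.class_composition.get(CLASS_PYRIMETHANIL, 0)
    n_mix = config.class_composition.get(CLASS_MIXTURE, 0)

    conc_cycle = itertools.cycle(config.concentration_levels)
    for _ in range(n_chl):
        spectra.append(generate_pure_spectrum(model_b, next(conc_cycle), config, rng))
    conc_cycle = itertools.cycle(config.concentration_levels)
    for _ in range(n_pyr):
        spectra.append(generate_pure_spectrum(model_a, next(conc_cycle), config, rng))
    mix_cycle = itertools.cycle(
        itertools.product(config.ratio_levels, config.concentration_levels)
    )
    for _ in range(n_mix):
        ratio, conc = next(mix_cycle)
        spectra.append(
            generate_mixture_spectrum(model_a, model_b, conc, conc, ratio, config, rng)
        )
    return LabeledSpectrumSet(spectra)


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
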