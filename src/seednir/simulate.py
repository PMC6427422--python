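"""Synthetic FT-NIR seed-spectra generator.

Emulates the statistical structure of single-seed absorbance spectra from a
naturally aged triploid watermelon lot of three varieties:

* broad Gaussian absorption bands (C-H / N-H / O-H overtone and combination
  regions) shared by both viability classes, centred near 4536, 4744, 4987,
  5174, 5376 and 6929 cm^-1;
* class-discriminative bands near 4079, 5261 and 7416 cm^-1 whose amplitude
  is larger for nonviable seeds, plus a global additive offset so nonviable
  spectra sit uniformly above viable ones;
* per-variety baseline offset and slope (varietal seed-coat differences);
* per-seed compositional variability (random band-amplitude multipliers), so
  the class signal is comparable to biological variation rather than
  deterministic;
* per-sample affine scatter corruption x' = offset + slope * x with
  slope ~ N(1, sd) and offset ~ N(0, sd) — the generative model that MSC and
  SNV are designed to invert;
* per-sample linear drift and smooth baseline wander (random low-frequency
  sin/cos harmonics with a 1/f coefficient spectrum), the high-dimensional
  nuisance that motivates derivative preprocessing;
* heteroscedastic instrument noise, with the information-free tail above
  9000 cm^-1 much noisier than the informative region.

Every draw flows from a single :class:`numpy.random.Generator`, so identical
config + seed gives bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import SpectraSet, VIABLE, NONVIABLE
from .errors import ConfigurationError

VARIETIES = ("V1", "V2", "V3")

# center (cm^-1), sigma (cm^-1), amplitude viable, amplitude nonviable (AU).
# Amplitudes differ only at the discriminative centers 4079/5261/7416.
_DEFAULT_BANDS = (
    (4079.0, 55.0, 0.07, 0.10),
    (4536.0, 90.0, 0.30, 0.30),
    (4744.0, 60.0, 0.12, 0.12),
    (4987.0, 80.0, 0.28, 0.28),
    (5174.0, 70.0, 0.22, 0.22),
    (5261.0, 65.0, 0.07, 0.10),
    (5376.0, 70.0, 0.24, 0.24),
    (6929.0, 160.0, 0.35, 0.35),
    (7416.0, 75.0, 0.05, 0.08),
)


def _col(i):
    return tuple(b[i] for b in _DEFAULT_BANDS)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic lot.

    Defaults describe the emulated study conditions: 4000-10000 cm^-1 grid at
    4 cm^-1 (1501 points), three varieties with germination rates 0.87, 0.89
    and 0.84, nonviable absorbance uniformly above viable.
    """

    wn_min: float = 4000.0
    wn_max: float = 10000.0
    wn_step: float = 4.0
    band_centers: tuple = field(default_factory=lambda: _col(0))
    band_widths: tuple = field(default_factory=lambda: _col(1))
    band_amplitudes_viable: tuple = field(default_factory=lambda: _col(2))
    band_amplitudes_nonviable: tuple = field(default_factory=lambda: _col(3))
    class_offset: float = 0.03
    discriminative_centers: tuple = (4079.0, 5261.0, 7416.0)
    #: relative SD of the per-seed, per-band amplitude multiplier
    #: (seed-to-seed compositional variability; 0 for deterministic bands)
    band_amplitude_sd: float = 0.2
    #: variety -> (additive offset in AU, slope in AU per cm^-1 from wn_min)
    variety_baselines: dict = field(default_factory=lambda: {
        "V1": (0.00, 0.0),
        "V2": (0.06, 8e-6),
        "V3": (0.12, 1.5e-5),
    })
    scatter_slope_sd: float = 0.10
    scatter_offset_sd: float = 0.05
    #: per-sample baseline tilt, AU per cm^-1 (linear-in-wavenumber
    #: instrument drift; centered mid-axis so it is offset-free)
    drift_slope_sd: float = 3e-5
    #: smooth per-sample baseline wander (scatter curvature / fringing):
    #: sum of the first K sin/cos harmonics over the axis with coefficient
    #: SD = wander_amplitude / harmonic -- a high-dimensional, low-frequency
    #: nuisance that derivative preprocessing suppresses
    wander_amplitude: float = 0.2
    wander_harmonics: int = 24
    noise_sd_base: float = 0.004
    noise_sd_tail: float = 0.04
    tail_start: float = 9000.0
    germination_rates: dict = field(default_factory=lambda: {
        "V1": 0.87, "V2": 0.89, "V3": 0.84,
    })
    rng_seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if not self.wn_min < self.wn_max:
            raise ConfigurationError("wn_min must be < wn_max")
        if self.wn_step <= 0:
            raise ConfigurationError("wn_step must be > 0")
        m = (self.wn_max - self.wn_min) / self.wn_step
        if abs(m - round(m)) > 1e-9:
            raise ConfigurationError(
                f"(wn_max - wn_min)/wn_step = {m} is not an integer grid length"
            )
        k = len(self.band_centers)
        for name in ("band_widths", "band_amplitudes_viable",
                     "band_amplitudes_nonviable"):
            if len(getattr(self, name)) != k:
                raise ConfigurationError(f"{name} length != band_centers length")
        amps = tuple(self.band_amplitudes_viable) + tuple(self.band_amplitudes_nonviable)
        if any(a < 0 for a in amps):
            raise ConfigurationError("band amplitudes must be non-negative")
        if any(w <= 0 for w in self.band_widths):
            raise ConfigurationError("band widths must be positive")
        if not self.class_offset > 0:
            raise ConfigurationError("class_offset must be > 0")
        for v, r in self.germination_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"germination rate for {v} outside [0,1]")
        for sd in (self.scatter_slope_sd, self.scatter_offset_sd,
                   self.noise_sd_base, self.noise_sd_tail,
                   self.band_amplitude_sd, self.drift_slope_sd,
                   self.wander_amplitude):
            if sd < 0:
                raise ConfigurationError("dispersion parameters must be >= 0")
        if self.wander_harmonics < 1:
            raise ConfigurationError("wander_harmonics must be >= 1")

    def grid(self) -> np.ndarray:
        self.validate()
        n = int(round((self.wn_max - self.wn_min) / self.wn_step)) + 1
        return self.wn_min + self.wn_step * np.arange(n)

    def varieties(self) -> tuple:
        return tuple(self.variety_baselines)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


# ----------------------------------------------------------------------
def _synthesize(config: SimulationConfig, varieties: np.ndarray,
                labels: np.ndarray, rng: np.random.Generator) -> SpectraSet:
    wn = config.grid()
    n = len(labels)
    k = len(config.band_centers)
    # Gaussian band basis, one row per band
    basis = np.stack([np.exp(-0.5 * ((wn - c) / s) ** 2)
                      for c, s in zip(config.band_centers, config.band_widths)])
    amp_v = np.asarray(config.band_amplitudes_viable, dtype=float)
    amp_nv = np.asarray(config.band_amplitudes_nonviable, dtype=float)
    is_viable = np.array([l == VIABLE for l in labels])
    amps = np.where(is_viable[:, None], amp_v, amp_nv)
    # seed-to-seed compositional variability: per-band multiplier around 1
    mult = rng.normal(1.0, config.band_amplitude_sd, size=(n, k))
    clean = (amps * mult) @ basis
    clean[~is_viable] += config.class_offset
    base = np.array([config.variety_baselines[v] for v in varieties])
    clean += base[:, [0]] + base[:, [1]] * (wn - config.wn_min)
    slope = rng.normal(1.0, config.scatter_slope_sd, size=n)
    offset = rng.normal(0.0, config.scatter_offset_sd, size=n)
    drift = rng.normal(0.0, config.drift_slope_sd, size=n)
    # smooth baseline wander: 1/f-weighted random sin/cos harmonics
    K = config.wander_harmonics
    u = (wn - wn[0]) / max(wn[-1] - wn[0], 1.0)
    karr = np.arange(1, K + 1)
    wander_basis = np.concatenate([np.sin(np.pi * np.outer(karr, u)),
                                   np.cos(np.pi * np.outer(karr, u))])
    wander_sd = np.concatenate([config.wander_amplitude / karr] * 2)
    wander = (rng.normal(0.0, 1.0, (n, 2 * K)) * wander_sd) @ wander_basis
    sd = np.where(wn >= config.tail_start, config.noise_sd_tail, config.noise_sd_base)
    noise = rng.standard_normal((n, wn.size)) * sd
    X = (offset[:, None] + slope[:, None] * clean
         + drift[:, None] * (wn - wn.mean()) + wander + noise)
    ids = np.array([f"{v}-{l[:3]}-{i:05d}"
                    for i, (v, l) in enumerate(zip(varieties, labels))], dtype=object)
    return SpectraSet(wavenumbers=wn, absorbance=X, sample_ids=ids,
                      variety=np.asarray(varieties, dtype=object),
                      label=np.asarray(labels, dtype=object))


def simulate_spectra(config: SimulationConfig,
                     n_per_variety_per_class: int,
                     seed: int | None = None) -> SpectraSet:
    """Balanced lot: ``n_per_variety_per_class`` seeds per variety per class.

    Returns ``2 * n_varieties * n`` samples.  ``seed`` overrides
    ``config.rng_seed``.
    """
    config.validate()
    if n_per_variety_per_class < 1:
        raise ConfigurationError("n_per_variety_per_class must be >= 1")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    varieties, labels = [], []
    for v in config.varieties():
        for l in (VIABLE, NONVIABLE):
            varieties += [v] * n_per_variety_per_class
            labels += [l] * n_per_variety_per_class
    return _synthesize(config, np.array(varieties, dtype=object),
                       np.array(labels, dtype=object), rng)


def simulate_labelled_lot(config: SimulationConfig, n_per_variety: int,
                          seed: int | None = None) -> SpectraSet:
    """Field-lot simulation: each seed's viability is Bernoulli with its
    variety's germination rate, then its spectrum is synthesized.

    Emulates the unbalanced external-test situation where a random bunch of
    seeds is drawn from mixed varieties.
    """
    config.validate()
    if n_per_variety < 1:
        raise ConfigurationError("n_per_variety must be >= 1")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    varieties, labels = [], []
    for v in config.varieties():
        rate = config.germination_rates.get(v)
        if rate is None:
            raise ConfigurationError(f"no germination rate configured for {v}")
        draws = rng.random(n_per_variety) < rate
        varieties += [v] * n_per_variety
        labels += [VIABLE if d else NONVIABLE for d in draws]
    return _synthesize(config, np.array(varieties, dtype=object),
                       np.array(labels, dtype=object), rng)
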