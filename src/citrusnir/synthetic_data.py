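"""Synthetic navel-orange NIR spectra with the structure the analysis assumes.

The generator emulates a hand-held short-wave NIR instrument (650-950 nm,
2 nm grid): Gaussian absorption bands linked to constituents, per-spectrum
multiplicative scatter, polynomial baselines, population-level batch
effects (gain drift, wavelength shift, structured interferents) and white
measurement noise.  Band centers follow the instrument's characteristic
peaks — 680 nm (chlorophyll), 740/840 nm (water O-H), 815 nm (N-H),
840/880/920 nm (sugar C-H) — so the sugar signal is linear in absorbance
by construction and a PLSR oracle on clean spectra succeeds.

Two fruit varieties are emulated: populations 1-6 carry reference SSC and
TA statistics of a first-variety harvest series, 7-12 a second variety
bought months later, with batch effects that separate the two groups in
PCA score space and defeat an un-updated calibration.

Titratable acidity ground truth is defined through the titration formula
``TA = c (V1 - V2) k F / m × 1000`` (NaOH concentration c in mol/L,
titre volumes in mL, citric-acid conversion k = 0.064, dilution F,
juice volume m in mL); the generator can simulate the titration itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import CitrusNIRError, ParameterError, ValidationError
from .spectra_io import AnalysisSet, ReferenceTable, SpectraSet, WavelengthGrid

__all__ = [
    "Band",
    "PopulationSpec",
    "BatchEffectSpec",
    "GeneratorConfig",
    "generate",
    "compute_titratable_acidity",
    "simulate_titration",
    "default_bands",
    "table_populations",
    "two_variety_batch_effects",
    "default_config",
]


@dataclass
class Band:
    """One Gaussian absorption band and the constituent it loads on."""

    center: float  # nm
    width: float  # Gaussian sigma, nm
    constituent: str  # "sugar" | "water" | "chlorophyll" | "acid" | "fixed"
    amplitude: float  # absorbance per unit of the constituent driver


@dataclass
class PopulationSpec:
    population_id: str
    n_fruit: int
    ssc_mean: float  # °Brix
    ssc_sd: float  # °Brix
    replicates_per_fruit: int = 3
    ta_mean: Optional[float] = None  # g/L
    ta_sd: Optional[float] = None
    chlorophyll_level: float = 1.0
    variety: str = "Newhall"

    def __post_init__(self):
        if self.n_fruit < 1:
            raise ParameterError("n_fruit must be >= 1")
        if self.ssc_sd <= 0:
            raise ParameterError("ssc_sd must be > 0")


@dataclass
class BatchEffectSpec:
    """Systematic distortion applied to every spectrum of a population."""

    wavelength_shift: float = 0.0  # nm
    gain: float = 1.0  # multiplicative on the clean spectrum
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    baseline_curvature: float = 0.0
    interferent_direction: Optional[np.ndarray] = None  # unit norm, length p
    interferent_scale_sd: float = 0.0  # per-spectrum random loading SD
    interferent_mean: float = 0.0  # deterministic mean loading

    def __post_init__(self):
        if self.interferent_direction is not None:
            d = np.asarray(self.interferent_direction, dtype=float)
            nrm = np.linalg.norm(d)
            if not np.isclose(nrm, 1.0, atol=1e-8):
                raise ValidationError("interferent_direction must have unit norm")
            self.interferent_direction = d


@dataclass
class GeneratorConfig:
    grid: WavelengthGrid
    populations: List[PopulationSpec]
    batch_effects: Dict[str, BatchEffectSpec] = field(default_factory=dict)
    bands: List[Band] = field(default_factory=lambda: default_bands())
    noise_sd: float = 0.002  # absorbance, per wavelength
    within_fruit_ssc_sd: float = 0.15  # °Brix, replicate-to-replicate
    gain_sd: float = 0.05  # per-spectrum multiplicative scatter SD
    ta_signal_scale: float = 1.0  # multiplies acid-band amplitudes
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        lo, hi = self.grid.values[0], self.grid.values[-1]
        for b in self.bands:
            if not (lo <= b.center <= hi):
                raise ParameterError(f"band center {b.center} nm outside grid span")


def default_bands() -> List[Band]:
    """Band table for the instrument's characteristic peaks.

    Sugar bands carry absorbance proportional to SSC (°Brix); water and
    the N-H band have fixed mean loading; the chlorophyll band scales
    with the population's chlorophyll level; the acid band's default
    amplitude sits near the noise floor (TA is spectroscopically weak in
    this wavelength range).
    """
    return [
        Band(680.0, 12.0, "chlorophyll", 0.30),
        Band(740.0, 20.0, "water", 0.50),
        Band(815.0, 18.0, "fixed", 0.10),
        Band(840.0, 25.0, "water", 0.35),
        Band(840.0, 18.0, "sugar", 0.020),  # per °Brix
        Band(880.0, 20.0, "sugar", 0.025),
        Band(920.0, 16.0, "sugar", 0.018),
        Band(770.0, 22.0, "acid", 2.0e-5),  # per g/L; near noise floor
    ]


def clean_spectrum(grid: WavelengthGrid, bands: List[Band], ssc: float,
                   ta: float = 0.0, chlorophyll: float = 1.0,
                   ta_signal_scale: float = 1.0) -> np.ndarray:
    """Closed-form noise-free spectrum: sum of constituent-scaled Gaussians."""
    lam = grid.values
    out = np.zeros_like(lam)
    drivers = {"sugar": ssc, "water": 1.0, "chlorophyll": chlorophyll,
               "acid": ta * ta_signal_scale, "fixed": 1.0}
    for b in bands:
        out = out + b.amplitude * drivers[b.constituent] * np.exp(
            -0.5 * ((lam - b.center) / b.width) ** 2
        )
    return out


def gaussian_direction(grid: WavelengthGrid, center: float, width: float) -> np.ndarray:
    """Unit-norm Gaussian bump, convenient as an interferent direction."""
    d = np.exp(-0.5 * ((grid.values - center) / width) ** 2)
    return d / np.linalg.norm(d)


def _population_rng(seed: int, pop_index: int, fruit_index: int) -> np.random.Generator:
    # counter-style keying: each fruit gets its own reproducible substream,
    # so generating a subset of populations reproduces the full run's draws
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(pop_index, fruit_index))
    return np.random.default_rng(ss)


def generate(config: GeneratorConfig) -> AnalysisSet:
    """Generate spectra + reference values for every configured population.

    Deterministic given ``config.seed``; each (population, fruit) pair
    draws from its own keyed substream.
    """
    grid = config.grid
    lam = grid.values
    p = len(grid)
    u = (lam - lam.mean()) / ((lam[-1] - lam[0]) / 2)  # [-1, 1] baseline axis
    rows_meta, rows_ref, spectra = [], [], []
    for pop_index, pop in enumerate(config.populations):
        eff = config.batch_effects.get(pop.population_id, BatchEffectSpec())
        if eff.interferent_direction is not None and eff.interferent_direction.shape[0] != p:
            raise ValidationError(
                f"interferent direction length {eff.interferent_direction.shape[0]} != grid {p}"
            )
        baseline = (eff.baseline_offset + eff.baseline_slope * u
                    + eff.baseline_curvature * u**2)
        for fruit_index in range(pop.n_fruit):
            rng = _population_rng(config.seed, pop_index, fruit_index)
            ssc_fruit = max(0.1, pop.ssc_mean + pop.ssc_sd * rng.standard_normal())
            ta_fruit = np.nan
            if pop.ta_mean is not None:
                ta_sd = pop.ta_sd if pop.ta_sd is not None else 0.0
                ta_fruit = max(0.0, pop.ta_mean + ta_sd * rng.standard_normal())
            fruit_id = f"P{pop.population_id}_F{fruit_index + 1:03d}"
            for rep in range(1, pop.replicates_per_fruit + 1):
                ssc_rep = max(0.1, ssc_fruit
                              + config.within_fruit_ssc_sd * rng.standard_normal())
                clean = clean_spectrum(grid, config.bands, ssc_rep,
                                       ta=0.0 if np.isnan(ta_fruit) else ta_fruit,
                                       chlorophyll=pop.chlorophyll_level,
                                       ta_signal_scale=config.ta_signal_scale)
                if eff.wavelength_shift != 0.0:
                    clean = np.interp(lam + eff.wavelength_shift, lam, clean)
                gain_i = eff.gain + config.gain_sd * rng.standard_normal()
                obs = gain_i * clean + baseline
                if eff.interferent_direction is not None:
                    s_i = eff.interferent_mean + eff.interferent_scale_sd * rng.standard_normal()
                    obs = obs + s_i * eff.interferent_direction
                if config.noise_sd > 0:
                    obs = obs + config.noise_sd * rng.standard_normal(p)
                sid = f"{fruit_id}_R{rep}"
                rows_meta.append({"spectrum_id": sid, "fruit_id": fruit_id,
                                  "population_id": str(pop.population_id),
                                  "replicate_index": rep, "variety": pop.variety})
                rows_ref.append({"spectrum_id": sid, "ssc": ssc_rep, "ta": ta_fruit})
                spectra.append(obs)
    sset = SpectraSet(grid, np.vstack(spectra), pd.DataFrame(rows_meta))
    ref = ReferenceTable(pd.DataFrame(rows_ref))
    return AnalysisSet(sset, ref)


# ---------------------------------------------------------------------------
# titration


def compute_titratable_acidity(c: float, V1: float, V2: float, k: float,
                               F: float, m: float) -> float:
    """TA in g/L from a NaOH titration: ``c (V1 - V2) k F / m × 1000``."""
    if m <= 0:
        raise CitrusNIRError("juice volume m must be > 0")
    if V2 < 0 or V1 < V2:
        raise CitrusNIRError("titre volumes must satisfy V1 >= V2 >= 0")
    return c * (V1 - V2) * k * F / m * 1000.0


def simulate_titration(ta: float, c: float = 0.1, k: float = 0.064, F: float = 5.0,
                       m: float = 10.0, noise_sd_mL: float = 0.0,
                       seed: int | np.random.Generator = 0):
    """Inverse titration: titre volumes (V1, V2) that realise a given TA.

    With ``noise_sd_mL = 0`` the round trip through
    :func:`compute_titratable_acidity` is exact.
    """
    if ta < 0:
        raise CitrusNIRError("ta must be >= 0")
    if min(c, k, F, m) <= 0:
        raise CitrusNIRError("c, k, F, m must all be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V2 = abs(0.2 + noise_sd_mL * rng.standard_normal()) if noise_sd_mL > 0 else 0.2
    V1 = V2 + ta * m / (c * k * F * 1000.0)
    if noise_sd_mL > 0:
        V1 += noise_sd_mL * rng.standard_normal()
    return V1, V2


# ---------------------------------------------------------------------------
# default study configuration


_POPULATION_TABLE = [
    # (id, variety, n_fruit, ssc_mean, ssc_sd, ta_mean, ta_sd)
    ("1", "Newhall", 22, 11.3, 0.77, 101.1, 22.64),
    ("2", "Newhall", 29, 11.2, 0.92, 88.8, 14.56),
    ("3", "Newhall", 29, 12.1, 1.02, 18.4, 6.00),
    ("4", "Newhall", 29, 11.9, 1.07, 17.4, 6.65),
    ("5", "Newhall", 30, 12.6, 1.14, 17.8, 7.21),
    ("6", "Newhall", 40, 12.5, 0.87, 16.0, 4.38),
    ("7", "Lunwan", 30, 11.7, 1.84, None, None),
    ("8", "Lunwan", 30, 11.8, 1.27, None, None),
    ("9", "Lunwan", 30, 11.0, 1.03, None, None),
    ("10", "Lunwan", 30, 11.3, 1.22, None, None),
    ("11", "Lunwan", 30, 11.1, 1.15, None, None),
    ("12", "Lunwan", 30, 11.2, 1.10, None, None),
]


def table_populations(n_fruit: Optional[int] = None) -> List[PopulationSpec]:
    """The 12-population study design; ``n_fruit`` overrides every count
    (used for scaled-down runs)."""
    pops = []
    for pid, variety, nf, sm, ssd, tam, tasd in _POPULATION_TABLE:
        pops.append(PopulationSpec(
            population_id=pid, n_fruit=n_fruit or nf, ssc_mean=sm, ssc_sd=ssd,
            ta_mean=tam, ta_sd=tasd,
            chlorophyll_level=1.0 if variety == "Newhall" else 0.7,
            variety=variety,
        ))
    return pops


# Second-variety batch effects: each population's structured interferent is
# a population-specific combination of two bands, one near the chlorophyll
# shoulder (710 nm) and one inside the sugar-information region (880 nm),
# so the variety shift spans a 2-dimensional subspace that overlaps the
# calibration's active coefficients.  Populations 9-10 load on the 710 nm
# direction only, in a tight cluster whose mean effect differs from the
# other populations': an update set drawn from them leaves the 880 nm
# direction unseen and its corrections mis-centered — the "negative group"
# design.  The two covering splits (update {7,8} and {9,12}) have mean
# effects matched to their prediction sets.
_LUNWAN_EFFECTS = {
    # pop: (gain, loading on d1 (710 nm), loading on d2 (880 nm), scale_sd)
    "7": (1.04, 0.096, 0.107, 0.040),
    "8": (1.08, 0.160, 0.220, 0.040),
    "9": (1.06, 0.133, 0.000, 0.012),
    "10": (1.06, 0.133, 0.000, 0.012),
    "11": (1.04, 0.107, 0.133, 0.040),
    "12": (1.08, 0.170, 0.250, 0.040),
}


def two_variety_batch_effects(grid: WavelengthGrid) -> Dict[str, BatchEffectSpec]:
    d1 = gaussian_direction(grid, 710.0, 9.0)
    d2 = gaussian_direction(grid, 880.0, 20.0)
    effects = {}
    for pid, (gain, a1, a2, sd) in _LUNWAN_EFFECTS.items():
        combo = a1 * d1 + a2 * d2
        mean = float(np.linalg.norm(combo))
        effects[pid] = BatchEffectSpec(gain=gain, interferent_direction=combo / mean,
                                       interferent_mean=mean, interferent_scale_sd=sd)
    return effects


def default_config(seed: int = 0, n_fruit: Optional[int] = None) -> GeneratorConfig:
    """Full study configuration: 12 populations, two varieties, batch effects."""
    grid = WavelengthGrid.default()
    return GeneratorConfig(
        grid=grid,
        populations=table_populations(n_fruit=n_fruit),
        batch_effects=two_variety_batch_effects(grid),
        seed=seed,
    )
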