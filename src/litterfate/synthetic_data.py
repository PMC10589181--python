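"""Synthetic two-year jar-incubation experiment.

Generates the full statistical structure the downstream analysis assumes:
true carbon-pool trajectories for every jar (first-order decay of four
pools with particulate-to-mineral transfer and a C:N-dependent priming
multiplier on the native pools), a measurement layer that turns true
states into noisy observations (concentrations, fraction masses, delta13C
by isotope mass balance), and mid-infrared litter spectra whose compound
band ratios track litter C:N.

The experiment emulated is a C4-grass (*Miscanthus*) root-litter addition
to a C3-dominated agricultural topsoil: 16 g soil at 11.2 g C kg-1 plus
0.4 g litter per jar, six treatments (an unamended control, litter C:N
50/65/85/124, and C:N 124 plus mineral N) x five replicates, destructively
sampled at 6, 12 and 24 months, with a 20 um particle-size split into a
coarse (POC) and a fine (MAOC) fraction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LitterBatch",
    "NoiseModel",
    "ExperimentDesign",
    "SimulationConfig",
    "JarState",
    "SyntheticDataset",
    "default_design",
    "default_config",
    "simulate_pools",
    "observe",
    "generate_spectrum",
    "generate_experiment",
]

OBSERVATION_COLUMNS = [
    "treatment",
    "replicate",
    "month",
    "coarse_mass_g",
    "fine_mass_g",
    "input_mass_g",
    "coarse_c_gkg",
    "fine_c_gkg",
    "bulk_c_gkg",
    "coarse_d13c",
    "fine_d13c",
    "bulk_d13c",
]


@dataclass(frozen=True)
class LitterBatch:
    """One root-litter quality treatment.

    ``cn_ratio`` is the mass C:N ratio of the *litter itself*; a mineral-N
    supplement (``mineral_n_g``, grams N per jar) lowers the C:N of the
    total amendment without changing the litter.
    """

    label: str
    c_pct: float
    n_pct: float
    delta13c: float = -14.2
    mineral_n_g: float = 0.0

    def __post_init__(self) -> None:
        if self.c_pct <= 0 or self.n_pct <= 0:
            raise ValueError(f"litter C%/N% must be > 0 for {self.label!r}")
        if self.mineral_n_g < 0:
            raise ValueError("mineral_n_g must be >= 0")

    @property
    def cn_ratio(self) -> float:
        return self.c_pct / self.n_pct


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters.

    cv_concentration : relative SD on measured C concentrations.
    sd_delta         : additive SD on delta13C (per mil).
    mass_recovery_mean/sd : multiplicative fraction of the input mass
        recovered after fractionation (applied to both size fractions).
    """

    cv_concentration: float = 0.03
    sd_delta: float = 0.2
    mass_recovery_mean: float = 0.982
    mass_recovery_sd: float = 0.007

    def __post_init__(self) -> None:
        if min(self.cv_concentration, self.sd_delta, self.mass_recovery_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 < self.mass_recovery_mean <= 1.05:
            raise ValueError("mass_recovery_mean must be in (0, 1.05]")

    @classmethod
    def zero(cls) -> "NoiseModel":
        """Noise-free model (recovery still at its mean)."""
        return cls(cv_concentration=0.0, sd_delta=0.0, mass_recovery_sd=0.0)


def _default_treatments() -> tuple[LitterBatch, ...]:
    # Elemental-analyser values for the four pooled root-litter batches;
    # CN124N re-uses the C:N 124 litter plus ammonium-nitrate N bringing
    # the amendment C:N down to ~50.
    cn124 = dict(c_pct=43.43, n_pct=0.35)
    litter_c_g = 0.4 * 43.43 / 100.0
    n_to_cn50 = litter_c_g / 50.0 - 0.4 * 0.35 / 100.0
    return (
        LitterBatch("CON", c_pct=44.17, n_pct=0.89),  # c/n unused: no litter added
        LitterBatch("CN50", c_pct=44.17, n_pct=0.89),
        LitterBatch("CN65", c_pct=43.64, n_pct=0.67),
        LitterBatch("CN85", c_pct=44.39, n_pct=0.52),
        LitterBatch("CN124", **cn124),
        LitterBatch("CN124N", **cn124, mineral_n_g=round(n_to_cn50, 6)),
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """Physical design constants of the jar experiment."""

    soil_mass_g: float = 16.0
    soil_c_gkg: float = 11.2
    soil_n_gkg: float = 0.88
    litter_mass_g: float = 0.4
    treatments: tuple[LitterBatch, ...] = field(default_factory=_default_treatments)
    replicates: int = 5
    delta_litter: float = -14.2
    delta_old_maoc: float = -26.2
    delta_old_poc: float = -26.7  # ~0.5 per mil more negative than MAOC
    initial_old_split: float = 0.30  # share of native SOC that is POC at t0
    coarse_mass_fraction: float = 0.775  # >20 um share of the mineral mass
    control_label: str = "CON"
    aliquot_mass_g: float = 7.5  # dry mass taken per destructive sampling

    def __post_init__(self) -> None:
        if self.delta_litter <= self.delta_old_maoc:
            raise ValueError("C4 litter must be isotopically heavier than native SOC")
        if min(self.soil_mass_g, self.soil_c_gkg, self.litter_mass_g) <= 0:
            raise ValueError("masses and concentrations must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.initial_old_split < 1:
            raise ValueError("initial_old_split must be in (0, 1)")
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate treatment labels")

    def litter_c_g(self, batch: LitterBatch) -> float:
        """Grams litter C added per jar (0 for the control)."""
        if batch.label == self.control_label:
            return 0.0
        return self.litter_mass_g * batch.c_pct / 100.0

    def amendment_cn(self, batch: LitterBatch) -> float:
        """C:N of the total amendment (litter + mineral N)."""
        c = self.litter_mass_g * batch.c_pct / 100.0
        n = self.litter_mass_g * batch.n_pct / 100.0 + batch.mineral_n_g
        return c / n


@dataclass(frozen=True)
class SimulationConfig:
    """First-order decay rates (per month) and priming parameters.

    The native (old) pool rates are multiplied per treatment by
    ``1 + alpha * (CN - cn_reference) / cn_reference`` (clamped at 0);
    the unamended control's multiplier is pinned at 1. ``h_transfer`` is
    the fraction of decomposed POC routed to MAOC of the same isotopic
    source; the remainder is respired.

    Defaults emulate the observed two-year dynamics: ~80% of added litter
    C lost from coarse POC, ~9% of it recovered as new MAOC, ~33% of
    native POC and ~20% of native MAOC lost, with native-MAOC loss
    increasing with litter C:N (priming for N mining).
    """

    k_poc_new: float = 0.0677
    k_poc_old: float = 0.019
    k_maoc_old: float = 0.0088
    k_maoc_new: float = 0.005
    h_transfer: float = 0.125
    alpha_priming: float = 0.066
    alpha_priming_poc: float = -0.05
    cn_reference: float = 25.0
    n_amended_priming_offset: float = 0.15
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    months: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0)

    def __post_init__(self) -> None:
        for name in ("k_poc_new", "k_poc_old", "k_maoc_old", "k_maoc_new"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.h_transfer <= 1:
            raise ValueError("h_transfer must be in [0, 1]")
        if self.cn_reference <= 0:
            raise ValueError("cn_reference must be > 0")
        m = tuple(self.months)
        if m[0] != 0 or any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError("months must be strictly increasing and start at 0")

    def priming_multiplier(self, cn: float, alpha: float, *, control: bool = False,
                           n_amended: bool = False) -> float:
        if control:
            return 1.0
        m = 1.0 + alpha * (cn - self.cn_reference) / self.cn_reference
        if n_amended:
            m += self.n_amended_priming_offset
        return max(m, 0.0)


@dataclass(frozen=True)
class JarState:
    """True state of one jar at one time (grams C per jar)."""

    time_months: float
    poc_new: float
    poc_old: float
    maoc_new: float
    maoc_old: float
    respired_new: float
    respired_old: float

    @property
    def total(self) -> float:
        return self.poc_new + self.poc_old + self.maoc_new + self.maoc_old

    @property
    def respired_total(self) -> float:
        return self.respired_new + self.respired_old


def _decay_with_transfer(p0: float, m0: float, kp: float, km: float,
                         h: float, t: float) -> tuple[float, float]:
    """Exact solution of  P' = -kp P,  M' = -km M + h kp P  on [0, t]."""
    p = p0 * np.exp(-kp * t)
    if abs(km - kp) < 1e-12:
        m = m0 * np.exp(-km * t) + h * kp * p0 * t * np.exp(-kp * t)
    else:
        m = m0 * np.exp(-km * t) + h * kp * p0 * (
            np.exp(-kp * t) - np.exp(-km * t)
        ) / (km - kp)
    return float(p), float(m)


def simulate_pools(design: ExperimentDesign, config: SimulationConfig,
                   batch: LitterBatch) -> list[JarState]:
    """True pool trajectory for one treatment (noise-free, per jar).

    Uses the exact exponential solution of the linear two-pool-per-source
    system on each inter-sampling interval; source identity (litter-derived
    vs native) is preserved through the POC->MAOC transfer. Respiration is
    the closed-system mass-balance residual, tracked per source.
    """
    is_control = batch.label == design.control_label
    n_amended = batch.mineral_n_g > 0
    cn = batch.cn_ratio
    m_old = config.priming_multiplier(cn, config.alpha_priming,
                                      control=is_control, n_amended=n_amended)
    m_old_poc = config.priming_multiplier(cn, config.alpha_priming_poc,
                                          control=is_control, n_amended=n_amended)

    soil_c = design.soil_mass_g * design.soil_c_gkg / 1000.0
    litter_c = design.litter_c_g(batch)
    pn = litter_c
    po = soil_c * design.initial_old_split
    mn = 0.0
    mo = soil_c * (1.0 - design.initial_old_split)
    new0, old0 = pn + mn, po + mo

    states = [JarState(0.0, pn, po, mn, mo, 0.0, 0.0)]
    for t_prev, t in zip(config.months, config.months[1:]):
        dt = t - t_prev
        pn, mn = _decay_with_transfer(pn, mn, config.k_poc_new,
                                      config.k_maoc_new, config.h_transfer, dt)
        po, mo = _decay_with_transfer(po, mo, config.k_poc_old * m_old_poc,
                                      config.k_maoc_old * m_old,
                                      config.h_transfer, dt)
        states.append(JarState(t, pn, po, mn, mo,
                               new0 - (pn + mn), old0 - (po + mo)))
    return states


def _fraction_delta(new_c: float, old_c: float, delta_new: float,
                    delta_old: float) -> float:
    """C-weighted linear delta13C mixing of the two sources in a fraction."""
    total = new_c + old_c
    if total <= 0:
        return delta_old
    return (new_c * delta_new + old_c * delta_old) / total


def observe(state: JarState, design: ExperimentDesign, noise: NoiseModel,
            rng: np.random.Generator, *, batch: LitterBatch,
            replicate: int) -> dict:
    """One noisy laboratory observation of a jar state.

    Concentrations are on a g C per kg dry mineral soil basis (the 16 g of
    soil every jar starts from), so control and amended jars share one
    basis; fraction masses are the recovered masses after fractionation of
    an aliquot, scaled by a drawn mass-recovery factor. Bulk C and bulk
    delta13C are measured on a separate milled aliquot, independently of
    the fractions, so summed-pool C recovery is not exactly 100% once
    noise is on.
    """
    m_total_kg = design.soil_mass_g / 1000.0
    p_c = design.coarse_mass_fraction
    p_f = 1.0 - p_c

    coarse_c = (state.poc_new + state.poc_old) / (m_total_kg * p_c)
    fine_c = (state.maoc_new + state.maoc_old) / (m_total_kg * p_f)
    bulk_c = state.total / m_total_kg
    d_coarse = _fraction_delta(state.poc_new, state.poc_old,
                               design.delta_litter, design.delta_old_poc)
    d_fine = _fraction_delta(state.maoc_new, state.maoc_old,
                             design.delta_litter, design.delta_old_maoc)
    d_bulk = _fraction_delta(
        state.poc_new + state.maoc_new,
        state.poc_old + state.maoc_old,
        design.delta_litter,
        _fraction_delta(state.maoc_old, state.poc_old,  # old-pool mixture
                        design.delta_old_maoc, design.delta_old_poc)
        if (state.poc_old + state.maoc_old) > 0 else design.delta_old_maoc,
    )

    recovery = noise.mass_recovery_mean + noise.mass_recovery_sd * rng.standard_normal()
    recovery = max(recovery, 0.0)
    cv, sd = noise.cv_concentration, noise.sd_delta
    conc_noise = 1.0 + cv * rng.standard_normal(3)
    delta_noise = sd * rng.standard_normal(3)
    input_mass = design.aliquot_mass_g

    return {
        "treatment": batch.label,
        "replicate": replicate,
        "month": state.time_months,
        "coarse_mass_g": input_mass * p_c * recovery,
        "fine_mass_g": input_mass * p_f * recovery,
        "input_mass_g": input_mass,
        "coarse_c_gkg": coarse_c * conc_noise[0],
        "fine_c_gkg": fine_c * conc_noise[1],
        "bulk_c_gkg": bulk_c * conc_noise[2],
        "coarse_d13c": d_coarse + delta_noise[0],
        "fine_d13c": d_fine + delta_noise[1],
        "bulk_d13c": d_bulk + delta_noise[2],
    }


# --- mid-infrared litter spectra -------------------------------------------

#: Diagnostic band windows (cm-1) for the litter-quality compound ratios.
BAND_WINDOWS: dict[str, tuple[float, float]] = {
    "Aliphatic": (2915.0, 2990.0),
    "Aromatic": (1600.0, 1660.0),
    "AmideI": (1652.0, 1658.0),
    "AmideII": (1540.0, 1548.0),
    "Lignin": (1504.0, 1512.0),
    "AmideIII": (1230.0, 1320.0),
    "Polysaccharides": (1140.0, 1180.0),
}

# Gaussian peak shape per band: (centre cm-1, sigma cm-1). Centres sit on
# the 4 cm-1 instrument grid so the sampled maximum equals the peak value.
_BAND_PEAKS: dict[str, tuple[float, float]] = {
    "Aliphatic": (2952.0, 14.0),
    "Aromatic": (1628.0, 11.0),
    "AmideI": (1656.0, 4.0),
    "AmideII": (1544.0, 5.0),
    "Lignin": (1508.0, 5.0),
    "AmideIII": (1276.0, 16.0),
    "Polysaccharides": (1160.0, 8.0),
}

# Cosmetic peaks outside every diagnostic window (O-H/N-H stretch, C-H
# stretch shoulder, carbonyl): keep the spectra looking like plant litter
# without touching the band maxima.
_EXTRA_PEAKS: tuple[tuple[float, float, float], ...] = (
    (3400.0, 120.0, 1.10),
    (2852.0, 10.0, 0.45),
    (1732.0, 9.0, 0.55),
    (1050.0, 40.0, 0.85),
)

# Peak amplitude = a + b * cn_ratio. Calibrated numerically (including
# baseline and band-overlap contributions, minimax over the four litter
# batches) against the observed compound ratios: the lowest- and
# highest-C:N batches land within ~4%; the strictly affine form cannot
# reproduce the convex progression of the amide ratios at the two
# intermediate batches (up to ~16% off for Aliphatic:AmideII there).
_AMP_COEFS: dict[str, tuple[float, float]] = {
    "Aliphatic": (0.550000, 0.0045000),
    "Aromatic": (1.024323, -0.0013399),
    "AmideI": (0.915640, -0.0013188),
    "AmideII": (0.535943, -0.0023676),
    "Lignin": (0.800000, 0.0000000),
    "AmideIII": (0.792263, 0.0018452),
    "Polysaccharides": (0.552250, 0.0089657),
}


def spectrum_grid() -> np.ndarray:
    """Instrument wavenumber grid, 4000 -> 400 cm-1 at 4 cm-1 resolution."""
    return np.arange(4000.0, 399.0, -4.0)


def generate_spectrum(cn_ratio: float, rng: np.random.Generator | None = None,
                      *, noise_sd: float = 0.002):
    """Synthetic litter DRIFT spectrum for a litter of given C:N ratio.

    Gaussian peaks centred inside each diagnostic band window, with
    amplitudes affine in C:N, on a smooth baseline; additive Gaussian
    absorbance noise unless ``rng`` is None or ``noise_sd`` is 0.
    """
    if not 20.0 <= cn_ratio <= 200.0:
        raise ValueError("cn_ratio must be within [20, 200]")
    from .drift_spectra import Spectrum

    wn = spectrum_grid()
    absorb = 0.02 + 0.008 * (4000.0 - wn) / 3600.0  # gentle sloping baseline
    for band, (centre, sigma) in _BAND_PEAKS.items():
        a, b = _AMP_COEFS[band]
        amp = max(a + b * cn_ratio, 0.0)
        absorb = absorb + amp * np.exp(-0.5 * ((wn - centre) / sigma) ** 2)
    for centre, sigma, amp in _EXTRA_PEAKS:
        absorb = absorb + amp * np.exp(-0.5 * ((wn - centre) / sigma) ** 2)
    if rng is not None and noise_sd > 0:
        absorb = absorb + noise_sd * rng.standard_normal(wn.size)
    return Spectrum(wavenumbers=wn, absorbance=absorb)


# --- whole-experiment generation -------------------------------------------


def _jar_rng(seed: int, treatment: str, replicate: int) -> np.random.Generator:
    """Per-jar substream, stable under iteration-order changes."""
    key = zlib.crc32(treatment.encode("utf8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence(entropy=seed & 0x7FFFFFFF,
                                spawn_key=(key, replicate))
    return np.random.default_rng(ss)


@dataclass
class SyntheticDataset:
    """Observations table, litter spectra and true per-jar states."""

    observations: pd.DataFrame
    spectra: dict[str, list]
    true_states: pd.DataFrame
    design: ExperimentDesign
    config: SimulationConfig

    def write(self, outdir) -> None:
        """Write delimited-text tables (byte-identical for a given seed)."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        obs = self.observations.copy()
        obs.to_csv(out / "observations.csv", index=False, float_format="%.10g")
        self.true_states.to_csv(out / "true_states.csv", index=False,
                                float_format="%.10g")
        for label, specs in self.spectra.items():
            for i, spec in enumerate(specs, start=1):
                df = pd.DataFrame({"wavenumber_cm1": spec.wavenumbers,
                                   "absorbance": spec.absorbance})
                df.to_csv(out / f"spectrum_{label}_rep{i}.csv", index=False,
                          float_format="%.10g")


def generate_experiment(design: ExperimentDesign | None = None,
                        config: SimulationConfig | None = None,
                        *, spectrum_replicates: int = 4) -> SyntheticDataset:
    """Generate the full synthetic incubation dataset.

    Emits one observation per treatment x replicate x sampling occasion
    (including time zero, which downstream code uses for the control
    reference signature), four spectra per litter batch, and the true
    states behind every observation.
    """
    design = design or ExperimentDesign()
    config = config or SimulationConfig()

    rows, truth = [], []
    for batch in design.treatments:
        states = simulate_pools(design, config, batch)
        for rep in range(1, design.replicates + 1):
            rng = _jar_rng(config.seed, batch.label, rep)
            for state in states:
                rows.append(observe(state, design, config.noise, rng,
                                    batch=batch, replicate=rep))
                truth.append({
                    "treatment": batch.label, "replicate": rep,
                    "month": state.time_months,
                    "poc_new_g": state.poc_new, "poc_old_g": state.poc_old,
                    "maoc_new_g": state.maoc_new, "maoc_old_g": state.maoc_old,
                    "respired_new_g": state.respired_new,
                    "respired_old_g": state.respired_old,
                })

    spectra: dict[str, list] = {}
    for batch in design.treatments:
        if batch.label == design.control_label:
            continue
        srng = _jar_rng(config.seed ^ 0x5EC7, batch.label, 0)
        spectra[batch.label] = [
            generate_spectrum(batch.cn_ratio, srng)
            for _ in range(spectrum_replicates)
        ]

    obs = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    return SyntheticDataset(observations=obs, spectra=spectra,
                            true_states=pd.DataFrame(truth),
                            design=design, config=config)


def default_design() -> ExperimentDesign:
    return ExperimentDesign()


def default_config(seed: int = 0, *, noise: NoiseModel | None = None) -> SimulationConfig:
    cfg = SimulationConfig(seed=seed)
    if noise is not None:
        cfg = replace(cfg, noise=noise)
    return cfg
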