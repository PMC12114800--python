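"""Synthetic datasets with the statistical structure of a flow-channel
intrinsic-dissolution study.

The generator draws IDR values on the master curve

    IDR = c_s(T) * D(T) * A * Re^m * eps,   eps ~ lognormal(0, sigma)

for a panel of substances, temperatures, Reynolds numbers and replicates,
so that every downstream stage (master-curve fitting, solubility
back-fitting, layer-curve fitting, mechanism reading) can be exercised
against known ground truth.  The default panel emulates the scale of the
study the model targets: eight small-molecule drugs, 25-50 degC,
Re in [25, 1000], a few replicates per operating point
(8 substances x 3 temperatures x 8 Re x 4 replicates = 768 experiments).

The default solubility tables are synthetic: plausible aqueous
solubilities on the scale reported in the pharmaceutical literature for
these drugs, chosen once to span ~3 orders of magnitude and to increase
with temperature.  They are inputs of the simulated study, not measured
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .experiment_io import ConcentrationSeries, DissolutionMeasurement, TopographyProfile
from .hydrodynamics import ChannelGeometry
from .substances import (
    DiffusionSpec,
    Substance,
    diffusion_coefficient,
    parse_formula,
    water_properties,
)

__all__ = [
    "GeneratorSpec",
    "default_registry",
    "generate_concentration_series",
    "generate_idr_dataset",
    "generate_topography",
]

# (formula, bonds, aromatic rings, non-aromatic rings,
#  synthetic c_s [kg/m^3] at 25/37/50 degC)
_DEFAULT_PANEL: dict[str, tuple[str, int, int, int, dict[float, float]]] = {
    "theophylline_monohydrate": ("C7H10N4O3", 24, 2, 0,
                                 {25.0: 7.5, 37.0: 12.0, 50.0: 20.0}),
    "benzocaine": ("C9H11NO2", 23, 1, 0,
                   {25.0: 1.0, 37.0: 1.7, 50.0: 3.0}),
    "carbamazepine": ("C15H12N2O", 31, 2, 1,
                      {25.0: 0.13, 37.0: 0.23, 50.0: 0.42}),
    "griseofulvin": ("C17H17ClO6", 43, 1, 2,
                     {25.0: 0.010, 37.0: 0.015, 50.0: 0.025}),
    "ibuprofen": ("C13H18O2", 33, 1, 0,
                  {25.0: 0.049, 37.0: 0.085, 50.0: 0.16}),
    "naproxen": ("C14H14O3", 32, 2, 0,
                 {25.0: 0.027, 37.0: 0.052, 50.0: 0.10}),
    "phenytoin": ("C15H12N2O2", 32, 2, 1,
                  {25.0: 0.026, 37.0: 0.042, 50.0: 0.075}),
    "trimethoprim": ("C14H18N4O3", 40, 2, 0,
                     {25.0: 0.40, 37.0: 0.62, 50.0: 1.0}),
}


def default_registry() -> dict[str, Substance]:
    """Synthetic eight-substance panel with formulas and solubility tables."""
    registry: dict[str, Substance] = {}
    for name, (formula, bonds, arom, nonarom, sol) in _DEFAULT_PANEL.items():
        registry[name] = Substance(
            name=name,
            composition=parse_formula(formula),
            bonds=bonds,
            aromatic_rings=arom,
            nonaromatic_rings=nonarom,
            solubilities=dict(sol),
        )
    return registry


@dataclass
class GeneratorSpec:
    """Study design of a synthetic IDR dataset.

    ``master_prefactor`` (A, m^-1) and ``master_exponent`` (m) define the
    generating master curve; ``noise_sigma`` is the lognormal sigma of the
    multiplicative measurement noise.  ``exponent_override`` maps a
    substance name to an alternative (A, m) pair, emulating a
    surface-reaction-influenced substance whose normalized rate depends
    only weakly on Re.  ``seed`` is mandatory whenever ``noise_sigma > 0``.
    """

    substances: dict[str, Substance] = field(default_factory=default_registry)
    re_grid: tuple[float, ...] = tuple(np.geomspace(25.0, 1000.0, 8))
    temperatures_C: tuple[float, ...] = (25.0, 37.0, 50.0)
    replicates: int = 4
    master_prefactor: float = 2.125  # m^-1
    master_exponent: float = 0.3
    noise_sigma: float = 0.05
    seed: int | None = None
    sample_diameter_mm: float = 8.0
    diffusion: DiffusionSpec = field(default_factory=DiffusionSpec)
    exponent_override: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(25.0 <= re <= 1000.0 for re in self.re_grid):
            raise ValueError("re_grid must lie within [25, 1000]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sigma > 0 and self.seed is None:
            raise ValueError("seed is mandatory for stochastic generation")

    @property
    def n_experiments(self) -> int:
        return (len(self.substances) * len(self.temperatures_C)
                * len(self.re_grid) * self.replicates)


def generate_idr_dataset(spec: GeneratorSpec) -> list[DissolutionMeasurement]:
    """Draw a full IDR dataset on the master curve (deterministic in seed).

    Loop order (substance, temperature, Re, replicate) is fixed so the
    noise stream is reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[DissolutionMeasurement] = []
    for name in spec.substances:
        sub = spec.substances[name]
        A, m = spec.exponent_override.get(
            name, (spec.master_prefactor, spec.master_exponent)
        )
        for T in spec.temperatures_C:
            cs = sub.solubility_at(T)
            D = diffusion_coefficient(sub, water_properties(T), spec.diffusion)
            for re in spec.re_grid:
                mean_idr = cs * D * A * re**m
                for rep in range(1, spec.replicates + 1):
                    eps = (
                        float(np.exp(spec.noise_sigma * rng.standard_normal()))
                        if spec.noise_sigma > 0 else 1.0
                    )
                    out.append(DissolutionMeasurement(
                        substance=name,
                        temperature_C=T,
                        reynolds=float(re),
                        sample_diameter_mm=spec.sample_diameter_mm,
                        replicate=rep,
                        idr=mean_idr * eps,
                    ))
    return out


def generate_concentration_series(
    idr: float,
    geometry: ChannelGeometry = ChannelGeometry(),
    duration_s: float = 240.0,
    dt_s: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[ConcentrationSeries, float]:
    """Closed-loop series c(t) = (IDR*A/V) * t + Gaussian noise.

    Returns (series, ground-truth IDR).
    """
    if noise_sd > 0 and seed is None:
        raise ValueError("seed is mandatory for stochastic generation")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    volume_m3 = geometry.medium_volume_ml * 1e-6
    slope = idr * geometry.tablet_area_m2 / volume_m3
    c = slope * t
    if noise_sd > 0:
        c = np.clip(c + noise_sd * rng.standard_normal(t.shape), 0.0, None)
    series = ConcentrationSeries(
        time_s=t,
        concentration_kg_m3=c,
        medium_volume_ml=geometry.medium_volume_ml,
        tablet_area_m2=geometry.tablet_area_m2,
    )
    return series, idr


def generate_topography(
    edge_erosion_um: float = 110.0,
    protrusion_um: float = 60.0,
    roughness_sd_um: float = 0.0,
    seed: int | None = None,
    n_points: int = 300,
    line_length_mm: float = 10.0,
    tablet_start_mm: float = 1.0,
    tablet_length_mm: float = 8.0,
) -> dict[str, TopographyProfile]:
    """Three-state synthetic line profiles (dry, t1, t2).

    dry: flat baseline with a smooth dome-shaped protrusion over the
    tablet (elastic recovery after compaction); t1: dry plus a further
    uniform swell of 20% of the protrusion after water contact; t2: t1
    minus a leading-edge erosion ramp of depth ``edge_erosion_um``
    (constant over the first 0.5 mm of the tablet, tapering to zero by
    2 mm).  Seeded roughness is added independently per state.
    """
    if roughness_sd_um > 0 and seed is None:
        raise ValueError("seed is mandatory for stochastic generation")
    rng = np.random.default_rng(seed)
    pos = np.linspace(0.0, line_length_mm, n_points)
    on_tablet = (pos >= tablet_start_mm) & (pos <= tablet_start_mm + tablet_length_mm)
    s = np.zeros_like(pos)
    s[on_tablet] = (pos[on_tablet] - tablet_start_mm) / tablet_length_mm
    dome = np.where(on_tablet, np.sin(np.pi * s) ** 2, 0.0)

    dry = protrusion_um * dome
    t1 = dry + 0.2 * protrusion_um * dome

    x_edge = pos - tablet_start_mm
    ramp = np.zeros_like(pos)
    ramp[on_tablet & (x_edge <= 0.5)] = 1.0
    taper = on_tablet & (x_edge > 0.5) & (x_edge < 2.0)
    ramp[taper] = (2.0 - x_edge[taper]) / 1.5
    t2 = t1 - edge_erosion_um * ramp

    profiles = {}
    for state, height in (("dry", dry), ("t1", t1), ("t2", t2)):
        noisy = height + (
            roughness_sd_um * rng.standard_normal(pos.shape)
            if roughness_sd_um > 0 else 0.0
        )
        profiles[state] = TopographyProfile(
            position_mm=pos.copy(), height_um=noisy, state=state,
            tablet_start_mm=tablet_start_mm,
        )
    return profiles
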