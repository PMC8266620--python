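"""Photochemistry of light-directed synthesis: dose, photolysis, stray light.

Removal of the 5'-photolabile protecting group (BzNPPOC at 365 nm) follows
first-order kinetics in radiant exposure E (J/cm^2):

    yield(E) = 1 - exp(-k * E)

with k calibrated so that the standard 3 J/cm^2 exposure gives ~95%
photodeprotection.  Features not scheduled for exposure still receive stray
dose from three channels:

* global scatter -- proportional to the fraction of ON mirrors on the current
  mask (light scattered anywhere on the optical path, not imaged),
* local leakage -- diffraction/edge scatter into side- and corner-adjacent
  features (about 0.5% and 0.05% of the nominal dose per fully exposed
  neighbor),
* internal reflection -- an optional extra dose over a configurable rectangle,
  modelling a region where the UV-absorbing back-chamber fluid is missing.

Illumination is not perfectly uniform: intensity falls off toward the edges
and corners of the DMD (imperfect beam homogenization), modelled as
1 - a * r^b with r the normalized radial distance from the array center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .layout import ArrayLayout, MaskStack


def calibrate_photolysis_rate(yield_: float, exposure: float) -> float:
    """Rate constant k with 1 - exp(-k*E) = yield at exposure E.

    >>> round(calibrate_photolysis_rate(0.95, 3.0), 4)
    0.9986
    """
    if not 0.0 < yield_ < 1.0:
        raise ValueError("yield must be in (0, 1)")
    if exposure <= 0:
        raise ValueError("exposure must be > 0")
    return -math.log(1.0 - yield_) / exposure


def photolysis_yield(exposure: float, k_rate: float) -> float:
    """Fraction of protecting groups removed by a dose of *exposure* J/cm^2."""
    if exposure < 0:
        raise ValueError("exposure must be >= 0")
    return 1.0 - math.exp(-k_rate * exposure)


def calibrate_global_scatter(
    target_insertion_rate: float,
    oligo_len: int = 67,
    total_cycles: int = 185,
    active_fraction: float = 4.0 / 9.0,
    k_rate: float | None = None,
    nominal_exposure: float = 3.0,
) -> float:
    """Global-scatter coefficient g yielding a target per-bp insertion rate.

    Inverts the (approximate) insertion budget: a feature spends about
    ``total_cycles - oligo_len`` cycles OFF; each OFF exposure deprotects a
    protected terminus with probability 1 - exp(-k * E_nominal * g * f_ON),
    and an unintended deprotection is followed by one inserted coupling.
    Per reference base,

        insertions/bp ~= p_stray * (total_cycles - oligo_len) / oligo_len.

    *target_insertion_rate* is a fraction (0.006 for 0.6%/bp).
    """
    if not 0.0 < target_insertion_rate < 1.0:
        raise ValueError("target insertion rate must be in (0, 1)")
    if total_cycles <= oligo_len:
        raise ValueError("total_cycles must exceed oligo_len")
    if k_rate is None:
        k_rate = calibrate_photolysis_rate(0.95, 3.0)
    p_stray = target_insertion_rate * oligo_len / (total_cycles - oligo_len)
    dose = -math.log(1.0 - p_stray) / k_rate
    return dose / (nominal_exposure * active_fraction)


#: Default global scatter coefficient, from calibrate_global_scatter(0.006)
#: at the standard 2SZ conditions (0.6%/bp insertions, 44% density, 67-mers,
#: ~185 cycles).
DEFAULT_GLOBAL_SCATTER = calibrate_global_scatter(0.006)


@dataclass(frozen=True)
class PhotochemParams:
    """Optical and kinetic parameters of one synthesis run.

    k_rate                first-order photolysis rate constant, per J/cm^2
                          (default: calibrated to 95% yield at 3 J/cm^2)
    nominal_exposure      radiant exposure per intended exposure event, J/cm^2
    global_scatter_coeff  stray dose per unit ON-mirror fraction, as a fraction
                          of the nominal dose (default from
                          :func:`calibrate_global_scatter` at 2SZ conditions:
                          0.6%/bp insertions, 44% density, 67-mers)
    side_leak             fraction of nominal dose leaked into a side-adjacent
                          feature per full exposure
    corner_leak           same for corner-adjacent features
    edge_falloff_amplitude/exponent   illumination profile 1 - a * r^b
    reflection_*          optional uniform extra stray dose over a mirror-
                          coordinate rectangle (row0, col0, row1, col1),
                          half-open, active once the cycle fraction passes
                          ``reflection_onset_fraction``
    numerical_aperture, wavelength_nm  informational only
    """

    k_rate: float = -math.log(0.05) / 3.0
    nominal_exposure: float = 3.0
    global_scatter_coeff: float = DEFAULT_GLOBAL_SCATTER
    side_leak: float = 0.005
    corner_leak: float = 0.0005
    edge_falloff_amplitude: float = 0.1
    edge_falloff_exponent: float = 4.0
    reflection_enabled: bool = False
    reflection_extra_dose: float = 0.0
    reflection_region: tuple[int, int, int, int] | None = None
    reflection_onset_fraction: float = 0.0
    numerical_aperture: float = 0.08
    wavelength_nm: float = 365.0

    def __post_init__(self) -> None:
        if self.k_rate <= 0:
            raise ValueError("k_rate must be > 0")
        for name in ("global_scatter_coeff", "side_leak", "corner_leak",
                     "edge_falloff_amplitude", "reflection_extra_dose",
                     "reflection_onset_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def illumination_factor(layout: ArrayLayout, feature_id: str,
                        params: PhotochemParams) -> float:
    """Relative illumination intensity at a feature, in (0, 1].

    1 at the array center, decreasing radially; the corners (r = 1) receive
    the least light, edge midpoints (r ~ 0.71) an intermediate amount.
    """
    a = params.edge_falloff_amplitude
    if a == 0.0:
        return 1.0
    r = layout.normalized_center_distance(feature_id, norm="euclid")
    return 1.0 - a * r**params.edge_falloff_exponent


def _in_region(layout: ArrayLayout, feature_id: str,
               region: tuple[int, int, int, int]) -> bool:
    fr, fc = layout.feature(feature_id).center
    r0, c0, r1, c1 = region
    return r0 <= fr < r1 and c0 <= fc < c1


def reflection_dose(layout: ArrayLayout, feature_id: str,
                    params: PhotochemParams,
                    cycle_fraction: float = 1.0) -> float:
    """Extra stray dose (fraction of nominal) from internal reflection."""
    if not params.reflection_enabled or params.reflection_region is None:
        return 0.0
    if cycle_fraction < params.reflection_onset_fraction:
        return 0.0
    if _in_region(layout, feature_id, params.reflection_region):
        return params.reflection_extra_dose
    return 0.0


def stray_dose(
    layout: ArrayLayout,
    mask: MaskStack,
    cycle: int,
    feature_id: str,
    params: PhotochemParams,
    cycle_fraction: float | None = None,
) -> float:
    """Unintended dose (J/cm^2) received by an OFF feature in one exposure.

    dose = nominal * [ g * f_ON
                       + side_leak   * (#ON side neighbors)   / 4
                       + corner_leak * (#ON corner neighbors) / 4
                       + reflection term ]

    where f_ON is the ON-mirror fraction of the current mask.  Raises if the
    feature is ON in this cycle (the intended dose applies there).
    """
    _, _, on = mask.cycles[cycle]
    if feature_id in on:
        raise ValueError(f"feature {feature_id} is ON in cycle {cycle}; "
                         "stray dose is undefined")
    f_on = mask.on_mirror_fraction(cycle)
    n_side = sum(1 for fid in layout.neighbor_ids(feature_id, diagonal=False)
                 if fid in on)
    n_corner = sum(1 for fid in layout.neighbor_ids(feature_id, diagonal=True)
                   if fid in on)
    if cycle_fraction is None:
        cycle_fraction = cycle / max(len(mask) - 1, 1)
    frac = (params.global_scatter_coeff * f_on
            + params.side_leak * n_side / 4.0
            + params.corner_leak * n_corner / 4.0
            + reflection_dose(layout, feature_id, params, cycle_fraction))
    return params.nominal_exposure * frac


def scale_insertion_rate(rate: float, from_density: float,
                         to_density: float) -> float:
    """Linear scaling of a global-scatter insertion rate with mirror density.

    Global scatter is proportional to the total light sent to the surface,
    i.e. to the active-mirror fraction; so is the insertion pressure it
    causes.  E.g. 0.6%/bp at 44% density extrapolates to ~0.68%/bp at 50%.
    """
    if from_density <= 0:
        raise ValueError("from_density must be > 0")
    return rate * to_density / from_density
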