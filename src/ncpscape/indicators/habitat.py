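"""Habitat preservation (HAB): protection-level supply, degradation demand.

Supply maps protection levels (0..4, adapted IUCN-style) to values in [0, 1]
and averages them per municipality. Demand is a distance-decayed threat
exposure: each threat's intensity is averaged through its decay kernel,
weighted by the exposed pixel's class sensitivity, summed over threats,
rescaled by the regional maximum, and averaged per municipality.
"""

from __future__ import annotations

import numpy as np

from ..types import (
    LAND_COVER_CLASSES,
    ConfigurationError,
    KernelParams,
    LandscapeStack,
)
from ..zonal import zone_mean
from .kernels import (
    exponential_decay_kernel,
    kernel_average,
    linear_decay_kernel,
)

DEFAULT_PROTECTION_VALUES: dict[int, float] = {0: 0.0, 1: 0.25, 2: 0.5, 3: 0.75, 4: 1.0}


def habitat_supply(
    stack: LandscapeStack,
    t: int = 0,
    protection_values: dict[int, float] | None = None,
) -> np.ndarray:
    """Mean protection value per municipality.

    ``t`` is accepted for interface symmetry; the protection raster is
    timestep-invariant in this data model.
    """
    values = protection_values or DEFAULT_PROTECTION_VALUES
    levels = np.unique(stack.protection)
    unknown = [int(v) for v in levels if int(v) not in values]
    if unknown:
        raise ConfigurationError(f"unknown protection levels {unknown}")
    lut = np.zeros(max(values) + 1)
    for level, value in values.items():
        lut[level] = value
    return zone_mean(lut[stack.protection], stack.zones, stack.n_zones)


def habitat_degradation(
    stack: LandscapeStack, t: int, params: KernelParams
) -> np.ndarray:
    """Per-pixel degradation before rescaling (weighted threat exposure)."""
    lc = stack.land_cover[t]
    pixel_size = stack.pixel_size
    degradation = np.zeros(stack.grid_shape)
    if not stack.threat_layers:
        raise ConfigurationError("habitat demand requires at least one threat layer")
    for name, layer in stack.threat_layers.items():
        decay = params.threat_decay.get(name)
        d_max = params.threat_max_distance.get(name)
        weight = params.threat_weight.get(name)
        sens_table = params.habitat_sensitivity.get(name)
        if None in (decay, d_max, weight) or sens_table is None:
            raise ConfigurationError(f"threat {name!r} lacks kernel parameters")
        missing = [c for c in LAND_COVER_CLASSES if c not in sens_table]
        if missing:
            raise ConfigurationError(
                f"threat {name!r} sensitivity missing classes {missing}"
            )
        if decay == "linear":
            kernel = linear_decay_kernel(d_max, pixel_size)
        else:
            kernel = exponential_decay_kernel(d_max, pixel_size)
        exposure = kernel_average(layer[t], kernel)
        sens = np.array([sens_table[c] for c in LAND_COVER_CLASSES])[lc]
        degradation += weight * exposure * sens
    return degradation


def run_degradation_max(stack: LandscapeStack, params: KernelParams) -> float:
    """Regional degradation maximum pooled over all timesteps of the run.

    Pooling across timesteps keeps the rescaled index comparable in time
    (per-timestep rescaling would erase temporal trends).
    """
    return max(
        float(habitat_degradation(stack, t, params).max())
        for t in range(stack.n_timesteps)
    )


def habitat_demand(
    stack: LandscapeStack,
    t: int,
    params: KernelParams | None = None,
    rescale_max: float | None = None,
) -> np.ndarray:
    """Mean rescaled habitat degradation per municipality, in [0, 1].

    Degradation is rescaled by the regional maximum of the current run
    (pooled over timesteps), or by an explicit ``rescale_max`` — passing a
    fixed denominator makes the index pointwise monotone in the threat
    layers. An all-zero threat field yields 0 everywhere (not an error).
    """
    params = params or KernelParams()
    degradation = habitat_degradation(stack, t, params)
    peak = run_degradation_max(stack, params) if rescale_max is None else rescale_max
    if peak > 0:
        degradation = np.clip(degradation / peak, 0.0, 1.0)
    return zone_mean(degradation, stack.zones, stack.n_zones)
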