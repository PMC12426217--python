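"""Planted socio-ecological archetypes for the synthetic region generator.

Each archetype is a starting land-cover composition plus a per-decade Markov
transition of class fractions. The four canonical templates mirror the broad
municipality types of an urbanizing temperate region: a densifying urban
core, stable forested highlands, intensifying agricultural patches, and a
mixed blue-green (lake/park) belt. Fraction trajectories, not maps, are
defined here; spatial allocation happens in :mod:`ncpscape.synth.region`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import LAND_COVER_CLASSES, LC_CODE, ConfigurationError

N_CLASSES = len(LAND_COVER_CLASSES)


@dataclass(frozen=True)
class ArchetypeTemplate:
    name: str
    initial_fractions: np.ndarray  # (n_classes,) sums to 1
    transition: np.ndarray  # (n_classes, n_classes) row-stochastic, per decade
    protected_fraction: float  # share of zone pixels under any protection

    def fractions_over_time(self, n_timesteps: int) -> np.ndarray:
        """Class-fraction trajectory, shape (n_timesteps, n_classes)."""
        out = np.empty((n_timesteps, N_CLASSES))
        f = self.initial_fractions.copy()
        for t in range(n_timesteps):
            out[t] = f
            f = f @ self.transition
        return out


def _fractions(**shares: float) -> np.ndarray:
    f = np.zeros(N_CLASSES)
    for name, share in shares.items():
        f[LC_CODE[name]] = share
    if abs(f.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"archetype class fractions sum to {f.sum():.4f}, expected 1"
        )
    return f


def _transition(moves: dict[tuple[str, str], float]) -> np.ndarray:
    """Row-stochastic matrix from {(from, to): per-decade rate} moves."""
    p = np.eye(N_CLASSES)
    for (src, dst), rate in moves.items():
        i, j = LC_CODE[src], LC_CODE[dst]
        p[i, i] -= rate
        p[i, j] += rate
    if (np.diag(p) < 0).any():
        raise ConfigurationError("transition rates out of a class exceed 1")
    return p


def canonical_templates() -> list[ArchetypeTemplate]:
    """The four canonical archetypes, in planted-label order."""
    urbanizing_core = ArchetypeTemplate(
        name="urbanizing_core",
        initial_fractions=_fractions(
            settlement=0.25,
            cropland=0.20,
            horticulture=0.05,
            forest=0.15,
            meadow_pasture=0.20,
            water=0.03,
            park_public=0.07,
            other=0.05,
        ),
        transition=_transition(
            {
                ("cropland", "settlement"): 0.18,
                ("meadow_pasture", "settlement"): 0.12,
                ("horticulture", "settlement"): 0.10,
                ("forest", "settlement"): 0.02,
                ("meadow_pasture", "park_public"): 0.03,
            }
        ),
        protected_fraction=0.12,
    )
    stable_highlands = ArchetypeTemplate(
        name="stable_highlands",
        initial_fractions=_fractions(
            settlement=0.05,
            cropland=0.05,
            horticulture=0.01,
            forest=0.45,
            meadow_pasture=0.35,
            water=0.02,
            park_public=0.01,
            other=0.06,
        ),
        transition=_transition(
            {
                ("meadow_pasture", "forest"): 0.02,
                ("cropland", "meadow_pasture"): 0.02,
                ("meadow_pasture", "settlement"): 0.01,
            }
        ),
        protected_fraction=0.35,
    )
    agro_patches = ArchetypeTemplate(
        name="agro_patches",
        initial_fractions=_fractions(
            settlement=0.08,
            cropland=0.45,
            horticulture=0.10,
            forest=0.15,
            meadow_pasture=0.15,
            water=0.01,
            park_public=0.01,
            other=0.05,
        ),
        transition=_transition(
            {
                ("meadow_pasture", "cropland"): 0.08,
                ("forest", "cropland"): 0.02,
                ("cropland", "settlement"): 0.03,
                ("meadow_pasture", "horticulture"): 0.02,
            }
        ),
        protected_fraction=0.08,
    )
    blue_green_belt = ArchetypeTemplate(
        name="blue_green_belt",
        initial_fractions=_fractions(
            settlement=0.12,
            cropland=0.12,
            horticulture=0.03,
            forest=0.18,
            meadow_pasture=0.24,
            water=0.15,
            park_public=0.11,
            other=0.05,
        ),
        transition=_transition(
            {
                ("cropland", "park_public"): 0.08,
                ("meadow_pasture", "park_public"): 0.06,
                ("cropland", "meadow_pasture"): 0.04,
            }
        ),
        protected_fraction=0.28,
    )
    return [urbanizing_core, stable_highlands, agro_patches, blue_green_belt]


def make_templates(n_archetypes: int, rng: np.random.Generator) -> list[ArchetypeTemplate]:
    """Return ``n_archetypes`` templates.

    The first four are canonical; additional ones recycle the canonical
    compositions with a deterministic multiplicative perturbation so every
    planted archetype stays distinct.
    """
    base = canonical_templates()
    out: list[ArchetypeTemplate] = []
    for i in range(n_archetypes):
        template = base[i % len(base)]
        if i < len(base):
            out.append(template)
            continue
        jitter = np.exp(0.35 * rng.standard_normal(N_CLASSES))
        f = template.initial_fractions * jitter
        f /= f.sum()
        out.append(
            ArchetypeTemplate(
                name=f"{template.name}_v{i // len(base) + 1}",
                initial_fractions=f,
                transition=template.transition,
                protected_fraction=template.protected_fraction,
            )
        )
    return out
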