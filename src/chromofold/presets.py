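"""Named parameter presets for the two cell states under study.

The log (exponentially growing) and quiescent fiber presets mirror the
study conditions: the quiescent fiber carries linker histone at 0.29
LH/nucleosome and almost no acetylation (3 of 228 nucleosomes), the log
fiber carries 0.05 LH/nucleosome and extensive acetylation (61 of 222).
The contact-pair presets encode the corresponding local-contact
signatures: a next-neighbour (n+1) dominated distance mixture for log
versus a flatter short-range mixture with elevated 500--1000 bp mass for
quiescence.

Desk-scale simulations use a reduced-resolution force field (fewer core
surface-charge beads) so that a 12-nucleosome fiber samples hundreds of
thousands of Monte Carlo steps in minutes.
"""

from __future__ import annotations

from dataclasses import replace

from .fiber_model import ForceFieldParams
from .synthetic_data import SyntheticContactSpec, SyntheticFiberSpec

__all__ = [
    "LOG_ACETYLATION_DENSITY",
    "Q_ACETYLATION_DENSITY",
    "LOG_LH_DENSITY",
    "Q_LH_DENSITY",
    "log_fiber_spec",
    "quiescent_fiber_spec",
    "log_contact_spec",
    "quiescent_contact_spec",
    "desk_force_field",
]

# per-nucleosome densities of the two modelled fibers
LOG_ACETYLATION_DENSITY = 61 / 222
Q_ACETYLATION_DENSITY = 3 / 228
LOG_LH_DENSITY = 0.05
Q_LH_DENSITY = 0.29


def log_fiber_spec(n_nucleosomes: int = 222, seed: int = 0) -> SyntheticFiberSpec:
    """Log-state nucleosome track: high acetylation, low LH occupancy."""
    return SyntheticFiberSpec(
        n_nucleosomes=n_nucleosomes,
        acetylation_density=LOG_ACETYLATION_DENSITY,
        lh_density=LOG_LH_DENSITY,
        seed=seed,
    )


def quiescent_fiber_spec(n_nucleosomes: int = 228,
                         seed: int = 0) -> SyntheticFiberSpec:
    """Quiescent-state nucleosome track: low acetylation, high LH."""
    return SyntheticFiberSpec(
        n_nucleosomes=n_nucleosomes,
        acetylation_density=Q_ACETYLATION_DENSITY,
        lh_density=Q_LH_DENSITY,
        seed=seed,
    )


def log_contact_spec(n_pairs: int = 100_000, seed: int = 0,
                     **overrides) -> SyntheticContactSpec:
    """n+1-dominated contact mixture with modest long-range mass."""
    kw = dict(
        n_pairs=n_pairs,
        neighbor_weights={1: 0.55, 2: 0.20, 3: 0.08},
        long_range_weight=0.10,
        background_weight=0.07,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticContactSpec(**kw)


def quiescent_contact_spec(n_pairs: int = 100_000, seed: int = 0,
                           **overrides) -> SyntheticContactSpec:
    """Flattened n+1/n+2 mixture with elevated 500--1000 bp mass."""
    kw = dict(
        n_pairs=n_pairs,
        neighbor_weights={1: 0.18, 2: 0.18, 3: 0.12},
        long_range_weight=0.38,
        background_weight=0.07,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticContactSpec(**kw)


def desk_force_field(**overrides) -> ForceFieldParams:
    """Reduced-resolution force field for desk-scale runs: 16 core
    surface-charge beads (total core charge unchanged)."""
    return replace(ForceFieldParams(n_core_charge_beads=16), **overrides)
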