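"""Canned demographic models for the simulator's validation experiments.

``model1`` is the workhorse: a single constant-size population. ``model2`` and
``model3`` are piecewise-constant renderings of the three-population human
out-of-Africa demography of Gravel et al. (2011) — externally sourced
parameter values, included as editable presets, with exponential growth
approximated by constant-size stages. ``model3`` adds the published migration
fractions; ``model2`` is the same history without gene flow. Generation time
25 years; sampling targets the African deme.
"""

from __future__ import annotations

from .wf import DemographyEpoch, SimulationConfig

__all__ = ["model1", "model2", "model3", "bottleneck_model"]

# Gravel et al. (2011) point estimates (externally sourced):
#   N_A = 7310, N_AF = 14474 (T_AF = 5920 gen), OOA bottleneck N_B = 1861
#   (T_B = 2040 gen), EU/AS split at 920 gen with N_EU0 = 1032, N_AS0 = 554
#   growing at 0.38% / 0.48% per generation; migration (x1e-5 per gen):
#   AF<->B 15, AF<->EU 2.5, AF<->AS 0.78, EU<->AS 3.11.
_M_NONE = None
_M_GRAVEL = (
    (0.0, 2.5e-5, 0.78e-5),
    (2.5e-5, 0.0, 3.11e-5),
    (0.78e-5, 3.11e-5, 0.0),
)


def model1(
    n_diploid: int = 10_000, duration: int = 100_000, **overrides
) -> SimulationConfig:
    """Constant population size; burn-in then ``duration`` extra generations.

    The default matches a 10,000-individual population run for 100,000
    generations; pass ``scaling_factor`` to rescale it to desk size.
    """
    overrides.setdefault("burn_in_factor", 0.0)
    return SimulationConfig(
        epochs=(DemographyEpoch(duration=duration, sizes=(n_diploid,)),),
        **overrides,
    )


def _gravel_epochs(migration: bool) -> tuple[DemographyEpoch, ...]:
    m = _M_GRAVEL if migration else None
    # growth rendered as two constant stages per growing deme (geometric-mean
    # split); demes: AF, EU, AS (EU doubles as the pre-split OOA deme).
    return (
        DemographyEpoch(duration=3880, sizes=(14474, 1861, 550)),
        DemographyEpoch(duration=1120, sizes=(14474, 1861, 550), migration=m),
        DemographyEpoch(duration=460, sizes=(14474, 2488, 1666), migration=m),
        DemographyEpoch(duration=460, sizes=(14474, 5999, 5011), migration=m),
    )


def model2(**overrides) -> SimulationConfig:
    """Human expansion demography without migration (approximate preset)."""
    return SimulationConfig(epochs=_gravel_epochs(migration=False), **overrides)


def model3(**overrides) -> SimulationConfig:
    """Human expansion demography with migration (approximate preset)."""
    return SimulationConfig(epochs=_gravel_epochs(migration=True), **overrides)


def bottleneck_model(
    n_before: int = 10_000,
    n_bottleneck: int = 1_000,
    duration: int = 10,
    **overrides,
) -> SimulationConfig:
    """Equilibrium at ``n_before`` then ``duration`` generations at the
    reduced size; duration 0 is the no-bottleneck control."""
    return SimulationConfig(
        epochs=(
            DemographyEpoch(duration=0, sizes=(n_before,)),
            DemographyEpoch(duration=duration, sizes=(n_bottleneck,)),
        ),
        **overrides,
    )
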