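"""Canonical, fully-specified reference scenarios.

Each fixture reproduces one of the standard model experiments at desk
scale, with the reference parameterization; nothing is downloaded and no
state is read from disk.  Shapes differ by fixture kind:

* ``fig4_branch``       -> dict: equilibrium-continuation job (switch level)
* ``fig5_deprivation``  -> dict: glucose-withdrawal protocol (switch level)
* ``fig7_periodic``     -> ScenarioConfig: periodic far-field injections
* ``fig9_twin``         -> (pulsed ScenarioConfig, constant-supply twin)
* ``fig10_alpha_sweep`` -> list of (alpha, ScenarioConfig), control last
* ``fig11_beta_sweep``  -> list of (beta, ScenarioConfig), control first
* ``fig12_grid``        -> dict {(tau, g_in): ScenarioConfig} on {10,50}x{5,30}
"""

from __future__ import annotations

from glioswitch.simulator import ScenarioConfig, run_constant_supply_twin
from glioswitch.spatial_model import InjectionSchedule, PDEParams
from glioswitch.switch_network import SwitchParams

__all__ = ["fixture", "FIXTURE_NAMES", "ALPHA_SWEEP", "BETA_SWEEP"]

ALPHA_SWEEP = (1.0, 1.2, 1.4, 1.6)  # control alpha = 1.6 (last)
BETA_SWEEP = (1.0, 2.0, 3.0, 4.0)  # control beta = 1.0 (first)


def _periodic(tau: float = 10.0, g_in: float = 5.0, **overrides) -> ScenarioConfig:
    params = overrides.pop("params", PDEParams())
    return ScenarioConfig(
        name="default",
        params=params,
        schedule=InjectionSchedule(tau=tau, g_in=g_in),
        t_end=100.0,
        output_dt=1.0,
        **overrides,
    )


def _fig7(**kw):
    return _periodic(tau=10.0, g_in=5.0, **kw)


def _fig9():
    pulsed = _fig7()
    return pulsed, run_constant_supply_twin(pulsed)


def _fig10():
    return [(a, _fig7(params=PDEParams(switch=SwitchParams(alpha=a)))) for a in ALPHA_SWEEP]


def _fig11():
    return [(b, _fig7(params=PDEParams(switch=SwitchParams(beta=b)))) for b in BETA_SWEEP]


def _fig12():
    return {(tau, g): _periodic(tau=tau, g_in=g) for tau in (10.0, 50.0) for g in (5.0, 30.0)}


_FIXTURES = {
    "fig4_branch": lambda: {"kind": "branch", "params": SwitchParams(),
                            "G_range": (0.0, 1.0), "G_resolution": 0.002},
    "fig5_deprivation": lambda: {"kind": "deprivation", "params": SwitchParams(),
                                 "G_high": 0.7, "glucose_ratio": 0.3 / 4.5},
    "fig7_periodic": _fig7,
    "fig9_twin": _fig9,
    "fig10_alpha_sweep": _fig10,
    "fig11_beta_sweep": _fig11,
    "fig12_grid": _fig12,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str):
    """Return the canonical configuration for a named reference experiment."""
    try:
        maker = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available fixtures: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return maker()
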