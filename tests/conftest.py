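"""Shared fixtures: desk-scale stimuli, simulators, and a symbolic oracle."""

from __future__ import annotations

import numpy as np
import pytest

from zwuisdp import (
    DesignConstraints,
    SimConfig,
    ZwuisStimulus,
    design_zwuis,
)


def quadratic_dp_oracle(multipliers, amplitudes, phases_cycles, c1, c2, polarity):
    """Brute-force symbolic expansion of ``c1 u + polarity c2 u^2``.

    Expands the trigonometric products with sympy's product-to-sum rules and
    returns ``{frequency multiple: complex cosine amplitude}`` including DC.
    Independent of the package's time-domain simulation and DFT path.
    """
    import sympy as sp
    from sympy.simplify.fu import TR8

    x = sp.Symbol("x", real=True)  # x = 2*pi*base_frequency*t
    u = sum(
        sp.nsimplify(a, rational=True)
        * sp.cos(int(n) * x + 2 * sp.pi * sp.nsimplify(p, rational=True))
        for a, n, p in zip(amplitudes, multipliers, phases_cycles)
    )
    expr = sp.expand(
        TR8(sp.expand(sp.nsimplify(c1, rational=True) * u
                      + polarity * sp.nsimplify(c2, rational=True) * u * u))
    )
    comps: dict[int, complex] = {}
    for term in sp.Add.make_args(expr):
        coeff, rest = term.as_coeff_Mul()
        if rest == sp.S.One:
            comps[0] = comps.get(0, 0) + complex(coeff)
            continue
        assert isinstance(rest, (sp.cos, sp.sin)), f"unexpected term {term}"
        arg = sp.expand(rest.args[0])
        n = int(arg.coeff(x))
        phi = arg - n * x
        if isinstance(rest, sp.sin):  # sin(t) = cos(t - pi/2)
            phi = phi - sp.pi / 2
        if n < 0:
            n, phi = -n, -phi
        comps[n] = comps.get(n, 0) + complex(
            (coeff * sp.exp(sp.I * phi)).evalf()
        )
    return comps


@pytest.fixture(scope="session")
def desk_constraints():
    """10 components in 2-8 kHz (CF 16 kHz), 1.2-s records, 10-Hz base."""
    return DesignConstraints(
        n_components=10,
        f_min_hz=2000.0,
        f_max_hz=8000.0,
        cf_hz=16000.0,
        seed=7,
        base_frequency_hz=10.0,
        duration_s=1.2,
        level_db_spl=60.0,
    )


@pytest.fixture(scope="session")
def desk_stimulus(desk_constraints) -> ZwuisStimulus:
    return design_zwuis(desk_constraints)


@pytest.fixture
def noiseless_config() -> SimConfig:
    return SimConfig(noise_density_pm_per_rthz=0.0, duration_s=1.2)


@pytest.fixture(scope="session")
def two_tone_stimulus() -> ZwuisStimulus:
    """The classic 4600 + 5400 Hz two-tone pair (base 200 Hz)."""
    return ZwuisStimulus(
        base_frequency_hz=200.0,
        multipliers=[23, 27],
        levels_db_spl=[70.0, 70.0],
        phases_cycles=[0.0, 0.0],
        duration_s=1.2,
        sample_rate_hz=111600.0,
    )


def measured_dp_table(record, stimulus, **kw):
    from zwuisdp import correct_combinatorial, measure_dp2

    return correct_combinatorial(measure_dp2(record, stimulus, **kw))
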