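import numpy as np
import pytest
import sympy as sp

from teaps.models import ODESystem, build_builtin_model
from teaps.objective import BSRSpec


@pytest.fixture(scope="session")
def t1():
    return build_builtin_model("T1")


@pytest.fixture(scope="session")
def spec():
    return BSRSpec()


def make_linear_model(k: float = 1.0, n: int = 1, name: str = "linear") -> ODESystem:
    """dx_i/dt = -k_i (x_i - 1): globally attracting fixed point at 1."""
    species = tuple(f"x{i+1}" for i in range(n))
    params = tuple(f"k{i+1}" for i in range(n))
    rhs = tuple(
        -sp.Symbol(p) * (sp.Symbol(s) - 1) for s, p in zip(species, params)
    )
    return ODESystem(
        name=name,
        species_names=species,
        parameter_names=params,
        reactions={f"re{i+1}": rhs[i] for i in range(n)},
        rhs=rhs,
    )


def make_repeller_model() -> ODESystem:
    """dx/dt = +k (x - 1): unstable fixed point at 1."""
    x, k = sp.Symbol("x1"), sp.Symbol("k1")
    return ODESystem(
        name="repeller",
        species_names=("x1",),
        parameter_names=("k1",),
        reactions={"re1": k * (x - 1)},
        rhs=(k * (x - 1),),
    )


def make_rotation_model() -> ODESystem:
    """Planar rotation about (1, 1): antisymmetric Jacobian, M identically 0."""
    x1, x2 = sp.Symbol("x1"), sp.Symbol("x2")
    w = sp.Symbol("w")
    return ODESystem(
        name="rotation",
        species_names=("x1", "x2"),
        parameter_names=("w",),
        reactions={"re1": -w * (x2 - 1), "re2": w * (x1 - 1)},
        rhs=(-w * (x2 - 1), w * (x1 - 1)),
    )


def make_limit_cycle_model() -> ODESystem:
    """Hopf normal form shifted to (1, 1): for mu > 0 the fixed point is an
    unstable focus enclosed by a stable limit cycle of radius sqrt(mu)."""
    x1, x2, mu = sp.Symbol("x1"), sp.Symbol("x2"), sp.Symbol("mu")
    u, v = x1 - 1, x2 - 1
    r2 = u**2 + v**2
    return ODESystem(
        name="limit-cycle",
        species_names=("x1", "x2"),
        parameter_names=("mu",),
        reactions={"re1": u * (mu - r2) - v, "re2": v * (mu - r2) + u},
        rhs=(sp.expand(u * (mu - r2) - v), sp.expand(v * (mu - r2) + u)),
    )
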