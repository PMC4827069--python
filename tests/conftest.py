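import numpy as np
import pytest

from actsim import (CancerParams, CytokineParams, ModelParams, PopulationState,
                    TCellParams, TraitSpace)


@pytest.fixture(scope="session")
def single_type():
    """One cancer trait, no interactions: a linear birth-death process."""
    def make(b=2.0, d=1.0, K=100, **cancer_kw):
        space = TraitSpace(genotypes=("g",), phenotypes_of={"g": ("p",)})
        return ModelParams(space=space,
                           cancer=CancerParams(b={"p": b}, d={"p": d}, **cancer_kw),
                           K=K)
    return make


@pytest.fixture
def full_params():
    """A small complete parameter set exercising every kernel."""
    space = TraitSpace(genotypes=("g", "h"),
                       phenotypes_of={"g": ("x", "y"), "h": ("u",)},
                       tcell_types=("z",), cytokine_types=("w",))
    cancer = CancerParams(
        b={"x": 3.0, "y": 2.0, "u": 2.5},
        d={"x": 1.0, "y": 0.5, "u": 1.0},
        c={("x", "x"): 1.0, ("x", "y"): 0.5, ("y", "x"): 0.5,
           ("y", "y"): 1.0, ("u", "u"): 1.0},
        c_b={("x", "x"): 0.2, ("u", "x"): 4.0},
        t_kill={("x", "z"): 5.0},
        kill_burst={("x", "z", "w"): 2},
        s_nat={("x", "y"): 0.1, ("y", "x"): 0.05},
        s_cyt={("w", "x", "y"): 2.0},
        mu={"g": 0.1},
        m_law={("g", "x"): {("h", "u"): 1.0},
               ("g", "y"): {("h", "u"): 1.0}},
    )
    tcells = TCellParams(b_T={"z": 1.0}, d_T={"z": 3.0},
                         t_prod={("z", "x"): 8.0}, rep_burst={("z", "w"): 1})
    return ModelParams(space=space, cancer=cancer, tcells=tcells,
                       cytokines=CytokineParams(d_W={"w": 10.0}), K=200)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def state_of(params, **counts):
    return PopulationState(time=0.0, counts=dict(counts))
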