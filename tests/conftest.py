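import numpy as np
import pytest

import msjoint as mj


@pytest.fixture(scope="session")
def fig1_graph():
    """Five-state progressive scheme with eight permitted transitions."""
    return mj.five_state_progressive_graph()


@pytest.fixture(scope="session")
def model2_graph():
    return mj.five_state_extended_graph()


@pytest.fixture(scope="session")
def m1_config():
    return mj.model1_preset(40, seed=7)


@pytest.fixture(scope="session")
def m1_subjects(m1_config):
    """Small simulated joint dataset with latent truth attached."""
    subjects, latent = mj.simulate_dataset(m1_config, seed=7, return_latent=True)
    return subjects, latent


@pytest.fixture()
def one_subject(fig1_graph):
    """Hand-built subject: 0 -> 2 at t=4, 2 -> 4 at t=8, visits 1,3,5,7."""
    return mj.SubjectRecord(
        id="s1",
        obs_times=[1.0, 3.0, 5.0, 7.0],
        obs_values=[0.1, 0.2, 0.3, 0.4],
        covariates=[0.5],
        path=[(0, 0.0), (2, 4.0), (4, 8.0)],
        censor_time=8.0,
    ).validate_against(fig1_graph)


def constant_hazard_spec(graph, rates, timescale="clock_reset"):
    """Weibull shape=1 (constant intensity) spec with no covariates and no
    association: the multistate likelihood has a closed form."""
    lm = mj.intercept_slope_submodel(beta=(0.0, 0.0), sigma_e2=1.0,
                                     Sigma_b=np.eye(2))
    trans = {
        key: mj.TransitionModel(
            transition=key,
            baseline=mj.WeibullBaseline(1.0, rates[key]),
            timescale=timescale,
            gamma=np.zeros(1),
            association=mj.AssociationStructure("none"),
        )
        for key in graph.transitions
    }
    return mj.JointModelSpec(graph=graph, longitudinal=lm, transitions=trans)
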