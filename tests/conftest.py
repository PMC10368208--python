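import numpy as np
import pandas as pd
import pytest

from ssdmodels.categorical import CategoricalObserverParams, lapse_scaled_curve


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def make_categorical_session(
    seed: int,
    n_per: int = 2000,
    priors=(0.2, 0.5, 0.8),
    noise_levels=(0.5, 1.25, 2.0),
    sigma_jump: float = 2.5,
    sigma_nojump: float = 0.2,
    lower_bound: float = 0.02,
    lapse: float = 0.05,
) -> pd.DataFrame:
    """Synthetic binary-response session generated from a known ideal observer."""
    rng = np.random.default_rng(seed)
    frames = []
    for prior in priors:
        for sigma_t in noise_levels:
            params = CategoricalObserverParams(
                p_jump=prior, sigma_jump=sigma_jump, sigma_nojump=sigma_nojump,
                sigma_t=sigma_t, lower_bound=lower_bound, lapse=lapse,
            )
            jumped = rng.random(n_per) < prior
            disp = np.where(
                jumped,
                sigma_jump * rng.standard_normal(n_per),
                sigma_nojump * rng.standard_normal(n_per),
            )
            p = lapse_scaled_curve(disp, params)
            resp = (rng.random(n_per) < p).astype(float)
            frames.append(
                pd.DataFrame(
                    {
                        "displacement_deg": disp,
                        "prior_label": prior,
                        "noise_sigma_deg": sigma_t,
                        "jumped": jumped,
                        "response": resp,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
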