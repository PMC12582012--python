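import numpy as np
import pytest

import tracekin as tk


@pytest.fixture(scope="session")
def mac_scheme():
    return tk.reference_scheme()


@pytest.fixture(scope="session")
def cond15():
    return tk.Condition("mac", 15.0, 0.0)


@pytest.fixture(scope="session")
def small_ensemble(mac_scheme, cond15):
    """A modest 15 mM ensemble shared across unit tests (40 x 300 frames)."""
    cfg = tk.SimulationConfig(n_traces=40, n_frames=300, rng_seed=7)
    return tk.generate_ensemble(mac_scheme, [cond15], cfg), cfg


@pytest.fixture(scope="session")
def small_fit(small_ensemble):
    """Fitted/decoded bundle on the small ensemble."""
    traces, cfg = small_ensemble
    fit = tk.fit_hmm(traces, 3, tk.HmmOptions(init_seed=1))
    model = tk.label_states(fit.model)
    label_map = {i: model.label_of(i) for i in range(3)}
    decoded = tk.decode_ensemble(model, traces)
    dwells = tk.extract_dwells_ensemble(decoded, cfg.frame_period, label_map)
    return {
        "traces": traces,
        "cfg": cfg,
        "fit": fit,
        "model": model,
        "decoded": decoded,
        "label_map": label_map,
        "dwells": dwells,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
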