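import numpy as np
import pytest

import somnohrv as sh


@pytest.fixture(scope="session")
def control_sim():
    """Default control-like 30-min synthetic recording, seed 0."""
    return sh.generate_recording(sh.control_preset(), seed=0)


@pytest.fixture(scope="session")
def control_bundle(control_sim):
    """Full pipeline result on the control recording."""
    return sh.run_pipeline(control_sim.recording)


@pytest.fixture(scope="session")
def control_features(control_bundle):
    return control_bundle["features"]


def random_labels(rng, n, p_err=0.1):
    """Random AW/QS/PS/ERR label sequence for run-length oracles."""
    return rng.choice(
        np.array(["AW", "QS", "PS", "ERR"]),
        size=n,
        p=[(1 - p_err) / 3] * 3 + [p_err],
    )


def rle_oracle(labels, min_run):
    """Brute-force run-length encoding into (bouts, interruptions)."""
    bouts, inter = [], []
    cur = []
    start = 0
    for i, lab in enumerate(list(labels) + [None]):
        if cur and lab != cur[-1]:
            run = (cur[-1], start, len(cur))
            if cur[-1] != "ERR":
                (bouts if len(cur) >= min_run else inter).append(run)
            cur = []
        if lab is not None:
            if not cur:
                start = i
            cur.append(lab)
    return bouts, inter
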