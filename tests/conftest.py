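import warnings

import numpy as np
import pytest

from carrgo.fitting import fit_logistic
from carrgo.rtca import select_fit_window
from carrgo.synthetic import default_plate_config, generate_plate

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", message=".*lsoda.*")


@pytest.fixture(scope="session")
def zero_noise_plate():
    """Default study-condition plate with noise and spike switched off."""
    cfg = default_plate_config(
        seed=11, noise_mult_sd=0.0, noise_add_sd=0.0, spike_amplitude=0.0
    )
    wells, truth = generate_plate(cfg)
    return cfg, wells, truth


@pytest.fixture(scope="session")
def noisy_plate():
    """Default study-condition plate (2% multiplicative + 0.01 CI additive)."""
    cfg = default_plate_config(seed=7)
    wells, truth = generate_plate(cfg)
    return cfg, wells, truth


def line_growth(wells):
    """Per-line (rho, K) from the untreated replicates, as the pipeline does."""
    out = {}
    for line in {w.meta.cell_line for w in wells}:
        fits = [
            fit_logistic(w, select_fit_window(w))
            for w in wells
            if not w.meta.treated and w.meta.cell_line == line
        ]
        out[line] = (
            float(np.mean([f.params.rho for f in fits])),
            float(np.mean([f.params.K for f in fits])),
        )
    return out


def line_ci_max(wells):
    """Per-line untreated-plateau CI, the confluency-cutoff reference."""
    out = {}
    for w in wells:
        if not w.meta.treated:
            out[w.meta.cell_line] = max(
                out.get(w.meta.cell_line, 0.0), float(w.ci.max())
            )
    return out
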