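import numpy as np
import pandas as pd
import pytest

import exoscreen as xs
from exoscreen.datatypes import FeatureMatrix


@pytest.fixture(scope="session")
def small_screen():
    """A compact noisy screen (full panel, 120 ions) shared by read-only tests."""
    cfg = xs.paper_like_config(seed=7, noise_cv=0.05, n_ions=120)
    design, truth, curves, masses, features = xs.generate_screen(cfg)
    return {"config": cfg, "design": design, "truth": truth,
            "curves": curves, "masses": masses, "features": features}


@pytest.fixture(scope="session")
def noiseless_screen():
    """Zero-noise screen: planted truth is exactly recoverable."""
    cfg = xs.paper_like_config(seed=11, noise_cv=0.0, n_ions=80)
    design, truth, curves, masses, features = xs.generate_screen(cfg)
    return {"config": cfg, "design": design, "truth": truth,
            "curves": curves, "masses": masses, "features": features}


def tiny_feature_matrix(intensities, sample_classes, condition_ids, mz=None,
                        replicates=None):
    """Hand-build a FeatureMatrix from a 2-D array for worked examples."""
    intensities = np.asarray(intensities, dtype=float)
    n_ions, n_samples = intensities.shape
    ion_ids = [f"i{k}" for k in range(n_ions)]
    sample_ids = [f"s{k}" for k in range(n_samples)]
    if mz is None:
        mz = 100.0 + 10.0 * np.arange(n_ions)
    if replicates is None:
        replicates = list(range(1, n_samples + 1))
    return FeatureMatrix(
        pd.DataFrame(intensities, index=pd.Index(ion_ids, name="ion_id"),
                     columns=sample_ids),
        pd.DataFrame({"ion_id": ion_ids, "mz": mz, "polarity": "negative"}),
        pd.DataFrame({"sample_id": sample_ids, "condition_id": condition_ids,
                      "replicate": replicates,
                      "sample_class": sample_classes}),
    )
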