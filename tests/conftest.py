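import numpy as np
import pytest

import matmotion as mm


@pytest.fixture(scope="session")
def small_cohort():
    """10 infants x 6 snippets: enough for 5 grouped folds, fast to build."""
    cfg = mm.CohortConfig(n_infants=10, snippets_per_infant=6, rng_seed=7)
    snippets, manifest = mm.generate_cohort(cfg)
    return cfg, snippets, manifest


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """Encoded + featurised version of the small cohort."""
    from matmotion.pipeline import featurize
    _, snippets, manifest = small_cohort
    signals = mm.encode_cohort(snippets)
    f12, f24 = featurize(signals)
    return mm.Dataset(manifest=manifest, features12=f12, features24=f24,
                      signals=signals)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def quiet_body():
    """Blob geometry well inside each area, so split-boundary truncation
    of the Gaussian tails stays negligible."""
    return mm.BodyModel(top_center=(7.0, 15.0), bottom_center=(21.0, 15.0),
                        blob_sd_top=1.5, blob_sd_bottom=2.0)
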