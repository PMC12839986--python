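import numpy as np
import pytest

from hrdfuse import synthdata


def cohort_views(patients):
    """Stack per-patient modality features into aligned matrices."""
    morph = np.vstack([p.bag.mean(axis=0) for p in patients])
    tx = np.vstack([p.inferred_expression for p in patients])
    mol = np.column_stack(
        [
            [p.clinical.ge_burden for p in patients],
            [p.clinical.aneuploidy_score for p in patients],
        ]
        + [np.vstack([p.clinical.sig_hrd for p in patients])]
        + [np.vstack([p.clinical.timex for p in patients])]
    )
    return {"morphology": morph, "molecular": mol, "transcriptomic": tx}


def labels01(patients):
    return np.array([p.hrd_label == synthdata.HRD_HIGH for p in patients], dtype=int)


@pytest.fixture(scope="session")
def small_cohort():
    spec = synthdata.CohortSpec(
        n_patients=120, n_genes=80, latent_dim=6, n_de_genes=10, de_effect=2.0,
        n_synergy_pairs=1, seed=42,
    )
    return synthdata.generate_cohort(spec)


@pytest.fixture(scope="session")
def shared_factor_cohort():
    spec = synthdata.CohortSpec(
        n_patients=200, n_genes=300, latent_dim=8, seed=5
    )
    return synthdata.generate_cohort(spec)
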