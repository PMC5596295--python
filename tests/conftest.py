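import numpy as np
import pytest

from graicar.synthetic import CohortSpec, SubjectDataset, generate_cohort, make_blob_sources


@pytest.fixture(scope="session")
def small_cohort():
    """8+8 subjects, 1 shared + 1 A-only + 1 B-only blob source, snr=10."""
    sources = make_blob_sources(
        ["shared", "group_A_only", "group_B_only"], n_voxels=1000, seed=2000)
    spec = CohortSpec(n_subjects_per_group=8, n_timepoints=120,
                      sources=sources, snr=10.0, seed=2000)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_subject():
    """One subject mixing 3 shared sources with no noise (exact rank 3)."""
    sources = make_blob_sources(["shared"] * 3, n_voxels=800, seed=5)
    spec = CohortSpec(n_subjects_per_group=1, n_timepoints=60,
                      sources=sources, snr=float("inf"), seed=5)
    datasets, truth = generate_cohort(spec)
    return datasets[0], truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def noise_datasets(n_subjects: int, t: int = 40, v: int = 400, seed: int = 0):
    """Structureless Gaussian cohort, half labeled A, half B."""
    gen = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        out.append(SubjectDataset(
            subject_id=f"sub-{i:03d}",
            group="A" if i < n_subjects // 2 else "B",
            data=gen.standard_normal((t, v)),
        ))
    return out
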