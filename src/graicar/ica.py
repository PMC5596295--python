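"""Per-subject spatial ICA realizations (stage 1).

Each subject's ``t x v`` matrix is decomposed ``d`` times with FastICA from
distinct random initial values. A single run is a *realization* (RE): ``c``
variance-normalized spatial maps (independent over voxels) and the matching
``t x c`` mixing time courses. Running ICA repeatedly from random starts is
what makes reproducibility measurable downstream: components that reappear
across realizations and subjects are the stable ones.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .synthetic import SubjectDataset

logger = logging.getLogger(__name__)

__all__ = ["Realization", "decompose_subject", "estimate_dimension"]


@dataclass
class Realization:
    """One ICA decomposition (RE) of one subject.

    ``spatial_maps`` is ``c x v`` with unit-variance rows; ``mixing`` is
    ``t x c`` so that ``mixing @ spatial_maps`` reconstructs the retained
    signal subspace.
    """

    subject_index: int
    realization_index: int
    spatial_maps: np.ndarray
    mixing: np.ndarray
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]


def _normalize_realization(maps: np.ndarray, mixing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance maps, non-negative skewness sign convention.

    ICA leaves scale and sign of each component arbitrary; fixing both (and
    folding the scale into the time course) keeps outputs comparable across
    runs without changing the reconstruction ``mixing @ maps``.
    """
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = maps / sd
    mixing = mixing * sd.T
    sk = stats.skew(maps, axis=1)
    flip = np.where(sk < 0, -1.0, 1.0)
    return maps * flip[:, None], mixing * flip[None, :]


def decompose_subject(
    dataset: SubjectDataset,
    n_components: int,
    n_realizations: int,
    seed: int = 0,
    subject_index: int = 0,
    max_retries: int = 3,
    max_iter: int = 1000,
    tol: float = 1e-3,
) -> list[Realization]:
    """Run spatial FastICA ``n_realizations`` times with distinct random starts.

    Voxels are treated as samples and time points as features, so the
    recovered sources are spatial maps. A run that fails to converge is
    retried with a fresh initialization up to ``max_retries`` times; if it
    still fails, the realization is returned flagged ``converged=False`` and a
    warning is logged (downstream callers may exclude it), never silently.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    t, v = dataset.data.shape
    if n_components > min(t, v):
        raise ValueError(f"n_components={n_components} exceeds min(t, v)={min(t, v)}")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")

    child_seeds = np.random.SeedSequence(seed).generate_state(n_realizations * (max_retries + 1))
    X = dataset.data.T  # voxels as samples -> spatial ICA
    out: list[Realization] = []
    for j in range(n_realizations):
        maps = mixing = None
        converged = False
        for attempt in range(max_retries + 1):
            rs = int(child_seeds[j * (max_retries + 1) + attempt] % (2**31 - 1))
            ica = FastICA(
                n_components=n_components,
                random_state=rs,
                max_iter=max_iter,
                tol=tol,
                whiten="unit-variance",
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                sources = ica.fit_transform(X)  # (v, c)
                bad = any(issubclass(w.category, ConvergenceWarning) for w in caught)
            maps = sources.T
            mixing = ica.mixing_  # (t, c)
            if not bad:
                converged = True
                break
        if not converged:
            logger.warning(
                "FastICA did not converge for subject %s realization %d after %d retries; "
                "realization flagged non-converged",
                dataset.subject_id, j, max_retries,
            )
        maps, mixing = _normalize_realization(maps, mixing)
        out.append(
            Realization(
                subject_index=subject_index,
                realization_index=j,
                spatial_maps=maps,
                mixing=mixing,
                converged=converged,
            )
        )
    return out


def estimate_dimension(dataset: SubjectDataset, variance_fraction: float = 0.9) -> int:
    """Smallest number of principal components explaining >= ``variance_fraction``.

    A PCA-based model-order stand-in: on data with ``k`` strong sources above
    the noise floor the eigen-spectrum has ``k`` dominant values, so moderate
    fractions recover the source count.
    """
    if not (0 < variance_fraction < 1):
        raise ValueError("variance_fraction must be in (0, 1)")
    X = dataset.data
    if not np.any(X):
        raise ValueError("degenerate (rank-0) data: no variance to decompose")
    # uncentered SVD: the mixing model has no intercept, so the singular
    # spectrum of the raw matrix is the right notion of dimensionality
    s = np.linalg.svd(X, compute_uv=False)
    cum = np.cumsum(s**2) / np.sum(s**2)
    return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)


def write_realizations(realizations: list[Realization], out_dir: str,
                       grid_shape: tuple[int, int, int] | None = None) -> None:
    """Archive REs: per realization one NIfTI (maps, 4th dim = component) when a
    grid shape is known, else a TSV; plus a mixing TSV. Layout: version 1,
    files ``re-<subject>-<realization>_{maps,mixing}.{nii|tsv}``."""
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    for re in realizations:
        stem = os.path.join(out_dir, f"re-{re.subject_index:03d}-{re.realization_index:03d}")
        if grid_shape is not None:
            vol = re.spatial_maps.T.reshape(*grid_shape, re.n_components)
            nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), stem + "_maps.nii")
        else:
            np.savetxt(stem + "_maps.tsv", re.spatial_maps, delimiter="\t")
        np.savetxt(stem + "_mixing.tsv", re.mixing, delimiter="\t")
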