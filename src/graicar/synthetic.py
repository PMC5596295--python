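"""Synthetic multi-subject resting-state-like cohorts with planted spatial sources.

Each subject's dataset is a ``t x v`` matrix built from the linear mixing model
``M = A S + E``: a small number of spatial source maps (rows of ``S``, length
``v``) mixed by band-limited time courses (columns of ``A``, length ``t``) plus
i.i.d. Gaussian noise ``E`` scaled to a requested signal-to-noise ratio. Sources
carry a group membership tag so that some networks are shared by the whole
cohort while others exist in only one diagnostic group — the structure the
discover-confirm scheme is designed to detect.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = [
    "SourceSpec",
    "CohortSpec",
    "SubjectDataset",
    "GroundTruth",
    "make_blob_sources",
    "generate_cohort",
    "write_cohort",
    "scenario_features",
]

MEMBERSHIPS = ("shared", "group_A_only", "group_B_only")


@dataclass
class SourceSpec:
    """One planted spatial source.

    Parameters
    ----------
    spatial_map : ndarray, shape (v,)
        The planted network map, arbitrary units, non-constant.
    membership : str
        One of ``shared``, ``group_A_only``, ``group_B_only``.
    amplitude_jitter : float
        Spread of the per-subject multiplicative amplitude (lognormal sigma).
    """

    spatial_map: np.ndarray
    membership: str = "shared"
    amplitude_jitter: float = 0.1

    def __post_init__(self) -> None:
        self.spatial_map = np.asarray(self.spatial_map, dtype=float)
        if self.membership not in MEMBERSHIPS:
            raise ValueError(f"membership must be one of {MEMBERSHIPS}")
        if np.ptp(self.spatial_map) == 0:
            raise ValueError("spatial_map must have non-zero variance")


@dataclass
class CohortSpec:
    """Specification of a two-group synthetic cohort."""

    n_subjects_per_group: int
    n_timepoints: int
    sources: list[SourceSpec]
    snr: float = 10.0
    seed: int = 0
    grid_shape: tuple[int, int, int] | None = None
    tr: float = 2.0  # repetition time in seconds, sets the band-pass grid
    passband: tuple[float, float] = (0.01, 0.1)  # Hz, emulates preprocessing

    @property
    def n_voxels(self) -> int:
        if self.grid_shape is not None:
            return int(np.prod(self.grid_shape))
        return int(self.sources[0].spatial_map.size)

    def validate(self) -> None:
        if not self.sources:
            raise ValueError("at least one source is required")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        n_per_subject = max(
            sum(1 for s in self.sources if s.membership in ("shared", tag))
            for tag in ("group_A_only", "group_B_only")
        )
        if self.n_timepoints < n_per_subject:
            raise ValueError("n_timepoints must be >= number of sources per subject")
        v = self.n_voxels
        for s in self.sources:
            if s.spatial_map.size != v:
                raise ValueError("all spatial maps must have length n_voxels")
        # planted maps must be mutually distinguishable
        for a in range(len(self.sources)):
            for b in range(a + 1, len(self.sources)):
                r = np.corrcoef(self.sources[a].spatial_map, self.sources[b].spatial_map)[0, 1]
                if abs(r) >= 0.3:
                    raise ValueError(
                        f"sources {a} and {b} have |r| = {abs(r):.2f} >= 0.3; "
                        "planted maps must be near-orthogonal"
                    )


@dataclass
class SubjectDataset:
    """One subject's time x voxel data matrix plus metadata."""

    subject_id: str
    group: str  # "A" or "B"
    data: np.ndarray  # (t, v)
    grid_shape: tuple[int, int, int] | None = None

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class GroundTruth:
    """The planted structure of a generated cohort."""

    source_membership: list[str]
    spatial_maps: np.ndarray  # (n_sources, v)
    # per subject: dict source index -> mixing time course (t,); absent sources omitted
    mixing: list[dict[int, np.ndarray]] = field(default_factory=list)

    def sources_of(self, group: str) -> list[int]:
        tag = f"group_{group}_only"
        return [i for i, m in enumerate(self.source_membership) if m in ("shared", tag)]


def _smooth_blob_map(
    grid: tuple[int, ...],
    rng: np.random.Generator,
    n_blobs: int = 3,
    region: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """A sparse, spatially smooth bump pattern on a voxel grid.

    Blob centers are confined to a fractional ``region`` of the first grid
    axis so that distinct sources can be given largely disjoint territory,
    the way distinct resting-state networks occupy different cortex.
    """
    vol = np.zeros(grid)
    coords = np.indices(grid).astype(float)
    lo, hi = region[0] * (grid[0] - 1), region[1] * (grid[0] - 1)
    for _ in range(n_blobs):
        center = np.array([rng.uniform(lo, hi)] +
                          [rng.uniform(0, g - 1) for g in grid[1:]])
        width = np.array([rng.uniform(0.05, 0.12) * (hi - lo + 1)] +
                         [rng.uniform(0.08, 0.2) * g for g in grid[1:]])
        d2 = sum(((coords[k] - center[k]) / width[k]) ** 2 for k in range(len(grid)))
        vol += rng.choice([1.0, 1.0, -0.5]) * np.exp(-d2 / 2)
    return vol.ravel()


def make_blob_sources(
    memberships: list[str],
    n_voxels: int | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    seed: int = 0,
    amplitude_jitter: float = 0.1,
    max_tries: int = 200,
    max_abs_r: float = 0.15,
) -> list[SourceSpec]:
    """Generate smooth blob source maps with pairwise |Pearson r| < ``max_abs_r``.

    Maps are drawn on a 3D grid (``grid_shape``) or, for flat-vector cohorts,
    on an internal 1D grid of length ``n_voxels``. Each source's blobs are
    confined to its own stripe of the first grid axis (spill-over allowed),
    and candidates still too correlated with accepted maps are redrawn. The
    default ceiling of 0.15 is well inside the 0.3 the cohort spec enforces,
    which keeps ICA separation and spatial matching unambiguous.
    """
    rng = np.random.default_rng(seed)
    grid = grid_shape if grid_shape is not None else (int(n_voxels),)
    k = len(memberships)
    maps: list[np.ndarray] = []
    for s in range(k):
        region = (s / k, (s + 1) / k)
        for _ in range(max_tries):
            cand = _smooth_blob_map(grid, rng, region=region)
            if np.ptp(cand) == 0:
                continue
            # enforce sparseness from both sides: a near-empty map carries too
            # little mutual information to be matched, and a diffuse one is
            # too Gaussian for a negentropy ICA contrast to isolate
            active = np.mean(np.abs(cand) > 0.25 * np.abs(cand).max())
            if not (0.05 <= active <= 0.20):
                continue
            if all(abs(np.corrcoef(cand, m)[0, 1]) < max_abs_r for m in maps):
                maps.append(cand)
                break
        else:
            raise RuntimeError("could not draw a sufficiently uncorrelated blob map")
    return [
        SourceSpec(m, membership=tag, amplitude_jitter=amplitude_jitter)
        for m, tag in zip(maps, memberships)
    ]


def _band_limited_course(n_t: int, tr: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian time course band-passed to the resting-state band."""
    x = rng.standard_normal(n_t)
    nyq = 0.5 / tr
    lo = max(band[0] / nyq, 1e-4)
    hi = min(band[1] / nyq, 0.99)
    b, a = sp_signal.butter(3, [lo, hi], btype="band")
    padlen = min(3 * max(len(a), len(b)), n_t - 1)  # filtfilt needs padlen < n_t
    y = sp_signal.filtfilt(b, a, x, padlen=padlen)
    sd = y.std()
    if sd < 1e-12:  # pathological short series; fall back to white noise
        y = x
        sd = y.std()
    return y / sd


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectDataset], GroundTruth]:
    """Generate a two-group cohort under the linear mixing model.

    Each subject's matrix is ``mixing @ maps + noise`` where the rows of
    ``maps`` are that subject's sources (all shared ones plus its group's
    exclusive ones) and the noise standard deviation is set so that
    ``var(signal) / var(noise) == spec.snr``. ``snr=math.inf`` produces
    noiseless data. Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth(
        source_membership=[s.membership for s in spec.sources],
        spatial_maps=np.vstack([s.spatial_map for s in spec.sources]),
    )
    datasets: list[SubjectDataset] = []
    for group in ("A", "B"):
        source_ids = truth.sources_of(group)
        for k in range(spec.n_subjects_per_group):
            mixing: dict[int, np.ndarray] = {}
            sig = np.zeros((spec.n_timepoints, spec.n_voxels))
            for sid in source_ids:
                src = spec.sources[sid]
                course = _band_limited_course(spec.n_timepoints, spec.tr, spec.passband, rng)
                amp = float(np.exp(rng.normal(0.0, src.amplitude_jitter)))
                course = amp * course
                mixing[sid] = course
                sig += np.outer(course, src.spatial_map)
            if math.isinf(spec.snr):
                data = sig
            else:
                noise_sd = math.sqrt(sig.var() / spec.snr)
                data = sig + rng.normal(0.0, noise_sd, size=sig.shape)
            truth.mixing.append(mixing)
            datasets.append(
                SubjectDataset(
                    subject_id=f"sub-{group}{k:03d}",
                    group=group,
                    data=data,
                    grid_shape=spec.grid_shape,
                )
            )
    return datasets, truth


def write_cohort(datasets: list[SubjectDataset], out_dir: str) -> dict[str, str]:
    """Write a cohort to disk: NIfTI (when a grid shape is known) or TSV matrices,
    plus a subject/group manifest TSV. Returns a mapping subject_id -> path."""
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    rows = []
    for ds in datasets:
        if ds.grid_shape is not None:
            # time as the 4th dimension, per NIfTI-1 convention
            vol = ds.data.T.reshape(*ds.grid_shape, ds.n_timepoints)
            path = os.path.join(out_dir, f"{ds.subject_id}.nii")
            nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), path)
        else:
            path = os.path.join(out_dir, f"{ds.subject_id}.tsv")
            np.savetxt(path, ds.data, delimiter="\t")
        paths[ds.subject_id] = path
        rows.append({"subject_id": ds.subject_id, "group": ds.group})
    manifest = os.path.join(out_dir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    paths["__manifest__"] = manifest
    return paths


def read_cohort(in_dir: str) -> list[SubjectDataset]:
    """Read a cohort previously written by :func:`write_cohort`."""
    import nibabel as nib

    manifest = pd.read_csv(os.path.join(in_dir, "manifest.tsv"), sep="\t")
    datasets = []
    for _, row in manifest.iterrows():
        sid, group = str(row["subject_id"]), str(row["group"])
        nii = os.path.join(in_dir, f"{sid}.nii")
        if os.path.exists(nii):
            img = nib.load(nii)
            vol = np.asarray(img.dataobj, dtype=float)
            grid = vol.shape[:3]
            data = vol.reshape(-1, vol.shape[3]).T
            datasets.append(SubjectDataset(sid, group, data, grid_shape=grid))
        else:
            data = np.loadtxt(os.path.join(in_dir, f"{sid}.tsv"), delimiter="\t")
            datasets.append(SubjectDataset(sid, group, np.atleast_2d(data)))
    return datasets


def scenario_features(
    n_per_group: int,
    mean_separation: float,
    within_scatter: float,
    dim: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature-space toy model of group separability.

    Two groups with means ``mean_separation`` apart along the first axis and
    isotropic within-group standard deviation ``within_scatter``. Holding the
    separation fixed while increasing the scatter reproduces the qualitative
    regimes of interest: well-separated means with poor within-group
    reproducibility versus tight, reproducible clusters.

    Returns (features, labels) with labels in {"A", "B"}.
    """
    rng = np.random.default_rng(seed)
    mean_a = np.zeros(dim)
    mean_b = np.zeros(dim)
    mean_b[0] = mean_separation
    xa = rng.normal(mean_a, within_scatter, size=(n_per_group, dim))
    xb = rng.normal(mean_b, within_scatter, size=(n_per_group, dim))
    labels = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    return np.vstack([xa, xb]), labels
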