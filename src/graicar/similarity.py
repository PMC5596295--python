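"""Normalized mutual information and the full similarity matrix (stage 2).

Similarity between two spatial maps x and y is

    NMI(x, y) = (H(x) + H(y)) / H(x, y) - 1,

which is 1 for identical maps and 0 for statistically independent ones, and —
unlike correlation — captures higher-order dependence. The default estimator
is a plug-in histogram with ``ceil(sqrt(v))`` equal-width bins capped at 64,
which is deterministic and bounded; a Kraskov-style kNN estimator is available
as an option.

The full similarity matrix (FSM) collects NMI between every pair of
components across all realizations of all subjects. It is block-structured:
subject blocks (SB) partition it by subject pair, realization blocks (RB) by
realization pair. Within each off-diagonal RB the NMI values are standardized
(SNMI) by the mean/std of the row-union-column multiset, which turns absolute
similarity into specificity of a match relative to its competitors. Diagonal
RBs (a realization against itself) are identity-like and are zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ica import Realization

logger = logging.getLogger(__name__)

__all__ = [
    "normalized_mutual_information",
    "build_fsm",
    "standardize_block",
    "FullSimilarityMatrix",
]

MAX_BINS = 64


def _n_bins(v: int) -> int:
    return min(MAX_BINS, int(np.ceil(np.sqrt(v))))


def _digitize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin indices over [min, max]; rightmost edge closed."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant map: entropy undefined for the histogram estimator")
    idx = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64)
    idx[idx == n_bins] = n_bins - 1
    return idx


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def _hist_nmi_from_indices(ix: np.ndarray, iy: np.ndarray, n_bins: int,
                           hx: float, hy: float) -> float:
    joint = np.bincount(ix * n_bins + iy, minlength=n_bins * n_bins)
    hxy = _entropy_from_counts(joint)
    if hxy <= 0:
        return 1.0
    return float(np.clip((hx + hy) / hxy - 1.0, 0.0, 1.0))


def _ksg_nmi(x: np.ndarray, y: np.ndarray, n_neighbors: int = 3) -> float:
    """Kraskov kNN mutual information, normalized by a joint-entropy estimate.

    Differential entropies can make the normalization ill-behaved for
    near-deterministic pairs; the result is clamped to [0, 1].
    """
    from scipy.stats import differential_entropy
    from sklearn.feature_selection import mutual_info_regression

    mi = float(mutual_info_regression(x[:, None], y, n_neighbors=n_neighbors,
                                      random_state=0)[0])
    hx = float(differential_entropy(x))
    hy = float(differential_entropy(y))
    hxy = hx + hy - mi
    if hxy <= 1e-9:
        return 1.0
    return float(np.clip((hx + hy) / hxy - 1.0, 0.0, 1.0))


def normalized_mutual_information(x: np.ndarray, y: np.ndarray,
                                  estimator: str = "hist") -> float:
    """NMI between two equal-length, non-constant spatial maps, in [0, 1].

    Symmetric in its arguments. ``estimator`` is ``"hist"`` (default plug-in
    histogram) or ``"ksg"`` (Kraskov k-nearest-neighbor).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("maps must have the same length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant map: entropy undefined for the histogram estimator")
    if estimator == "ksg":
        return _ksg_nmi(x, y)
    if estimator != "hist":
        raise ValueError(f"unknown estimator {estimator!r}")
    b = _n_bins(x.size)
    ix, iy = _digitize(x, b), _digitize(y, b)
    hx = _entropy_from_counts(np.bincount(ix, minlength=b))
    hy = _entropy_from_counts(np.bincount(iy, minlength=b))
    return _hist_nmi_from_indices(ix, iy, b, hx, hy)


@dataclass
class FullSimilarityMatrix:
    """Block-structured NMI/SNMI matrix over all components of all REs.

    Components are flattened into a single axis of length P; bookkeeping
    arrays record each column's (subject, realization, component) origin.
    ``alive`` supports FSM-wide row/column elimination during alignment.
    """

    raw: np.ndarray       # (P, P) NMI; diagonal RBs zeroed
    snmi: np.ndarray      # (P, P) standardized NMI
    subjects: np.ndarray  # (P,) subject index per column
    realizations: np.ndarray  # (P,) realization index per column
    components: np.ndarray    # (P,) within-RE component index per column
    alive: np.ndarray = field(default=None)  # (P,) bool

    def __post_init__(self):
        if self.alive is None:
            self.alive = np.ones(self.raw.shape[0], dtype=bool)

    @property
    def n_total(self) -> int:
        return self.raw.shape[0]

    @property
    def n_subjects(self) -> int:
        return int(self.subjects.max()) + 1

    def index_of(self, subject: int, realization: int, component: int) -> int:
        mask = (
            (self.subjects == subject)
            & (self.realizations == realization)
            & (self.components == component)
        )
        idx = np.nonzero(mask)[0]
        if idx.size != 1:
            raise KeyError((subject, realization, component))
        return int(idx[0])

    def triple_of(self, index: int) -> tuple[int, int, int]:
        return (
            int(self.subjects[index]),
            int(self.realizations[index]),
            int(self.components[index]),
        )

    def realization_pairs(self):
        """Distinct (subject, realization) labels in lexicographic order."""
        labels = sorted({(int(s), int(r)) for s, r in zip(self.subjects, self.realizations)})
        return labels

    def block_slice(self, subject: int, realization: int) -> np.ndarray:
        return np.nonzero((self.subjects == subject) & (self.realizations == realization))[0]


def subset_fsm(fsm: "FullSimilarityMatrix", subjects_keep: list[int]) -> "FullSimilarityMatrix":
    """Restrict an FSM to a subset of subjects, remapping subject indices to
    0..k-1 in sorted order.

    Exact by construction: raw NMI is pairwise and SNMI standardization is
    local to each realization block, so slicing a built FSM equals building
    one from the subset's realizations.
    """
    keep = sorted(int(s) for s in subjects_keep)
    mask = np.isin(fsm.subjects, keep)
    idx = np.nonzero(mask)[0]
    remap = {s: i for i, s in enumerate(keep)}
    return FullSimilarityMatrix(
        raw=fsm.raw[np.ix_(idx, idx)].copy(),
        snmi=fsm.snmi[np.ix_(idx, idx)].copy(),
        subjects=np.array([remap[int(s)] for s in fsm.subjects[idx]]),
        realizations=fsm.realizations[idx].copy(),
        components=fsm.components[idx].copy(),
    )


def standardize_block(raw_block: np.ndarray, count_intersection_twice: bool = False) -> np.ndarray:
    """Standardize one realization block of NMI values into SNMI.

    Entry [y, z] is centered and scaled by the mean/std of the multiset
    ``row y ∪ column z``; by default the intersecting entry raw[y, z] is
    counted once (set ``count_intersection_twice`` for the alternative
    reading). A zero-variance union yields 0 with a logged warning.
    """
    raw_block = np.asarray(raw_block, dtype=float)
    ny, nz = raw_block.shape
    out = np.zeros_like(raw_block)
    warned = False
    for y in range(ny):
        row = raw_block[y, :]
        for z in range(nz):
            col = raw_block[:, z]
            if count_intersection_twice:
                union = np.concatenate([row, col])
            else:
                # the intersecting entry raw[y, z] appears exactly once
                union = np.concatenate([row, np.delete(col, y)])
            mu = union.mean()
            sd = union.std()
            if sd == 0:
                if not warned:
                    logger.warning("constant realization block: SNMI set to 0")
                    warned = True
                out[y, z] = 0.0
            else:
                out[y, z] = (raw_block[y, z] - mu) / sd
    return out


def build_fsm(
    realizations: list[Realization],
    estimator: str = "hist",
    count_intersection_twice: bool = False,
) -> FullSimilarityMatrix:
    """Assemble the FSM from all realizations of all subjects.

    Every off-diagonal realization block is filled with pairwise NMI and
    standardized; diagonal RBs (same subject, same realization) are zeroed.
    The result is symmetric under block transpose.
    """
    if not realizations:
        raise ValueError("empty realization list")
    n_subj = len({re.subject_index for re in realizations})
    if n_subj < 2:
        raise ValueError("FSM requires at least 2 subjects")

    res = sorted(realizations, key=lambda r: (r.subject_index, r.realization_index))
    subj, real, comp, maps = [], [], [], []
    for re in res:
        for p in range(re.n_components):
            subj.append(re.subject_index)
            real.append(re.realization_index)
            comp.append(p)
            maps.append(re.spatial_maps[p])
    subjects = np.array(subj)
    reals = np.array(real)
    comps = np.array(comp)
    P = len(maps)
    v = maps[0].size

    if estimator == "hist":
        b = _n_bins(v)
        idx = np.empty((P, v), dtype=np.int64)
        hmarg = np.empty(P)
        for p, m in enumerate(maps):
            idx[p] = _digitize(np.asarray(m, dtype=float), b)
            hmarg[p] = _entropy_from_counts(np.bincount(idx[p], minlength=b))

        def nmi_pair(p, q):
            return _hist_nmi_from_indices(idx[p], idx[q], b, hmarg[p], hmarg[q])
    else:
        def nmi_pair(p, q):
            return normalized_mutual_information(maps[p], maps[q], estimator=estimator)

    raw = np.zeros((P, P))
    same_re = [(s, r) for s, r in zip(subjects, reals)]
    for p in range(P):
        for q in range(p + 1, P):
            if same_re[p] == same_re[q]:
                continue  # diagonal RB stays zero
            val = nmi_pair(p, q)
            raw[p, q] = raw[q, p] = val

    snmi = np.zeros((P, P))
    labels = sorted({(int(s), int(r)) for s, r in zip(subjects, reals)})
    slices = {lab: np.nonzero((subjects == lab[0]) & (reals == lab[1]))[0] for lab in labels}
    for a_i, a in enumerate(labels):
        for b_lab in labels[a_i + 1:]:
            ra, rb = slices[a], slices[b_lab]
            block = raw[np.ix_(ra, rb)]
            sblock = standardize_block(block, count_intersection_twice)
            snmi[np.ix_(ra, rb)] = sblock
            snmi[np.ix_(rb, ra)] = sblock.T

    return FullSimilarityMatrix(raw=raw, snmi=snmi, subjects=subjects,
                                realizations=reals, components=comps)
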