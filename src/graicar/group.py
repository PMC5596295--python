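"""Group-level component metrics, weighted maps, and significance (stage 4).

For an aligned component (AC) the reproducibility matrix is summarized by:

* inter-subject consistency ``alpha[i, m]`` — the mean NMI between subject
  i's and subject m's member components;
* subject centrality ``tau[i]`` — the mean of subject i's consistencies with
  every other subject, i.e. that subject's load on the AC;
* intra-subject reliability ``beta[i]`` — the mean NMI among subject i's own
  member components across realizations (1 by convention for a single member).

The group map is the ``beta * tau``-weighted average of per-subject mean
member maps, after harmonizing each member's sign with the seed map (ICA sign
indeterminacy would otherwise cancel contributions).

Significance is non-parametric: pseudo-ACs are built by sampling one
component per realization with replacement, their mean consistencies form a
null distribution, and its 95th percentile is the threshold an AC's mean
consistency must exceed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignedComponent
from .ica import Realization
from .similarity import FullSimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComponent",
    "inter_subject_consistency",
    "subject_centrality",
    "intra_subject_reliability",
    "group_map",
    "consistency_null",
    "select_significant",
    "summarize_component",
]


@dataclass
class GroupComponent:
    """A group-level component with its consistency metrics."""

    ac: AlignedComponent
    map: np.ndarray                 # (v,) weighted group map (gIC)
    alpha: np.ndarray               # (n, n) inter-subject consistency, zero diagonal
    tau: np.ndarray                 # (n,) subject centrality
    beta: np.ndarray                # (n,) intra-subject reliability
    mean_consistency: float
    min_consistency: float = 0.0
    mixing_mean: np.ndarray | None = None
    significant: bool = False
    representative_subjects: list[int] = field(default_factory=list)


def _member_indices_by_subject(ac: AlignedComponent) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {}
    for pos, (s, _, _) in enumerate(ac.members):
        out.setdefault(s, []).append(pos)
    return out


def inter_subject_consistency(ac: AlignedComponent, i: int, m: int) -> float:
    """Mean NMI between every member of subject i and every member of subject m
    (the i-m inter-subject block of the reproducibility matrix). A subject
    with no member yields 0 with a logged notice."""
    if i == m:
        raise ValueError("inter-subject consistency requires i != m")
    by_subj = _member_indices_by_subject(ac)
    if i not in by_subj or m not in by_subj:
        logger.info("subject %d or %d absent from AC; consistency defined as 0",
                    i, m)
        return 0.0
    block = ac.reproducibility_matrix[np.ix_(by_subj[i], by_subj[m])]
    return float(block.mean())


def subject_centrality(alpha: np.ndarray, i: int) -> float:
    """tau_i: mean of subject i's consistencies with all other subjects."""
    n = alpha.shape[0]
    if n < 2:
        raise ValueError("centrality requires at least 2 subjects")
    others = np.delete(alpha[i], i)
    return float(others.mean())


def intra_subject_reliability(ac: AlignedComponent, i: int) -> float:
    """beta_i: mean NMI over subject i's within-subject member pairs.

    A subject with fewer than two member realizations has reliability 1 by
    convention (a single observation cannot disagree with itself).
    """
    by_subj = _member_indices_by_subject(ac)
    pos = by_subj.get(i, [])
    if len(pos) < 2:
        return 1.0
    block = ac.reproducibility_matrix[np.ix_(pos, pos)]
    iu = np.triu_indices(len(pos), k=1)
    return float(block[iu].mean())


def _member_map(realizations_by_key: dict, member) -> np.ndarray:
    s, j, p = member
    return realizations_by_key[(s, j)].spatial_maps[p]


def _harmonize_sign(map_: np.ndarray, reference: np.ndarray) -> np.ndarray:
    r = np.corrcoef(map_, reference)[0, 1]
    return -map_ if r < 0 else map_


def group_map(
    ac: AlignedComponent,
    realizations: list[Realization],
    beta: np.ndarray,
    tau: np.ndarray,
) -> np.ndarray:
    """gIC: the beta*tau-weighted average over subjects of each subject's mean
    member map, sign-harmonized to the seed-pair map. All-zero weights fall
    back to an unweighted mean with a logged warning."""
    if not ac.members:
        raise ValueError("empty aligned component")
    by_key = {(re.subject_index, re.realization_index): re for re in realizations}
    ref = _member_map(by_key, ac.seed_pair[0])
    by_subj: dict[int, list[np.ndarray]] = {}
    for member in ac.members:
        by_subj.setdefault(member[0], []).append(
            _harmonize_sign(_member_map(by_key, member), ref)
        )
    subj_ids = sorted(by_subj)
    subj_means = np.vstack([np.mean(by_subj[s], axis=0) for s in subj_ids])
    w = np.array([beta[s] * tau[s] for s in subj_ids], dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        logger.warning("all beta*tau weights are zero; using unweighted mean map")
        return subj_means.mean(axis=0)
    return (w[:, None] * subj_means).sum(axis=0) / w.sum()


def summarize_component(
    ac: AlignedComponent,
    realizations: list[Realization],
    n_subjects: int,
) -> GroupComponent:
    """Compute alpha/tau/beta, the weighted map, and the mean consistency."""
    alpha = np.zeros((n_subjects, n_subjects))
    for i in range(n_subjects):
        for m in range(i + 1, n_subjects):
            alpha[i, m] = alpha[m, i] = inter_subject_consistency(ac, i, m)
    tau = np.array([subject_centrality(alpha, i) for i in range(n_subjects)])
    beta = np.array([intra_subject_reliability(ac, i) for i in range(n_subjects)])
    iu = np.triu_indices(n_subjects, k=1)
    mean_cons = float(alpha[iu].mean())
    min_cons = float(alpha[iu].min())
    gmap = group_map(ac, realizations, beta, tau)
    by_key = {(re.subject_index, re.realization_index): re for re in realizations}
    courses = []
    for (s, j, p) in ac.members:
        re = by_key[(s, j)]
        if re.mixing.shape[0] == realizations[0].mixing.shape[0]:
            courses.append(re.mixing[:, p])
    mixing_mean = np.mean(courses, axis=0) if courses else None
    return GroupComponent(ac=ac, map=gmap, alpha=alpha, tau=tau, beta=beta,
                          mean_consistency=mean_cons, min_consistency=min_cons,
                          mixing_mean=mixing_mean)


def _pseudo_pair_consistencies(fsm: FullSimilarityMatrix, member_idx: np.ndarray,
                               member_subj: np.ndarray) -> np.ndarray:
    """Inter-subject consistencies (one per subject pair) of a pseudo-AC."""
    sub = fsm.raw[np.ix_(member_idx, member_idx)]
    subjects = np.unique(member_subj)
    vals = []
    for a_i, a in enumerate(subjects):
        ra = member_subj == a
        for b in subjects[a_i + 1:]:
            rb = member_subj == b
            vals.append(sub[np.ix_(ra, rb)].mean())
    return np.asarray(vals)


def consistency_null(
    fsm: FullSimilarityMatrix,
    n_resamples: int = 500,
    seed: int = 0,
    percentile: float = 95.0,
    return_distribution: bool = False,
):
    """Null distribution of mean inter-subject consistency.

    Each resample draws one component per (subject, realization) with
    replacement — an artificial aligned component with no preferred
    structure — and records its mean inter-subject consistency. The
    ``percentile`` (default 95th, p = 0.05) of the ``n_resamples`` (default
    500) values is the significance threshold.
    """
    if fsm.n_subjects < 2:
        raise ValueError("null distribution requires at least 2 subjects")
    if n_resamples < 20:
        logger.warning("n_resamples=%d is small; the percentile estimate is unstable",
                       n_resamples)
    rng = np.random.default_rng(seed)
    labels = fsm.realization_pairs()
    slices = [fsm.block_slice(s, r) for (s, r) in labels]
    member_subj = np.array([s for (s, _) in labels])
    draws = np.empty(n_resamples)
    for b in range(n_resamples):
        member_idx = np.array([int(rng.choice(sl)) for sl in slices])
        draws[b] = _pseudo_pair_consistencies(fsm, member_idx, member_subj).mean()
    threshold = float(np.percentile(draws, percentile))
    if return_distribution:
        return threshold, draws
    return threshold


def null_thresholds(
    fsm: FullSimilarityMatrix,
    n_resamples: int = 500,
    seed: int = 0,
    percentile: float = 95.0,
) -> tuple[float, float]:
    """AC-level and pair-level null thresholds from one set of resamples.

    Returns ``(mean_threshold, pair_threshold)``: the percentile of the
    pseudo-AC mean consistencies (the significance threshold) and the same
    percentile of the pooled per-subject-pair consistencies. The pair-level
    value is the floor a genuinely cohort-wide component clears for *every*
    subject pair, whereas a component reproducible in only part of the
    cohort has cross-block pairs at chance level.
    """
    if fsm.n_subjects < 2:
        raise ValueError("null distribution requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    labels = fsm.realization_pairs()
    slices = [fsm.block_slice(s, r) for (s, r) in labels]
    member_subj = np.array([s for (s, _) in labels])
    means = np.empty(n_resamples)
    pair_draws = []
    for b in range(n_resamples):
        member_idx = np.array([int(rng.choice(sl)) for sl in slices])
        pairs = _pseudo_pair_consistencies(fsm, member_idx, member_subj)
        means[b] = pairs.mean()
        pair_draws.append(pairs)
    return (
        float(np.percentile(means, percentile)),
        float(np.percentile(np.concatenate(pair_draws), percentile)),
    )


def _subject_level_thresholds(
    gc: GroupComponent,
    n_resamples: int,
    rng: np.random.Generator,
    percentile: float = 95.0,
) -> tuple[float, float]:
    """Null 95th percentiles of tau and beta by randomly reassigning the AC's
    member components (with replacement) to artificial subjects with the same
    per-subject member counts."""
    ac = gc.ac
    n_members = len(ac.members)
    counts = [len(ac.members_of_subject(s)) for s in ac.subjects]
    taus, betas = [], []
    for _ in range(n_resamples):
        assign = rng.integers(0, n_members, size=n_members)
        groups: list[np.ndarray] = []
        start = 0
        for c in counts:
            groups.append(assign[start:start + c])
            start += c
        m = gc.ac.reproducibility_matrix
        a = np.zeros((len(groups), len(groups)))
        for i in range(len(groups)):
            for k in range(i + 1, len(groups)):
                a[i, k] = a[k, i] = m[np.ix_(groups[i], groups[k])].mean()
        for i, g in enumerate(groups):
            taus.append(np.delete(a[i], i).mean())
            if len(g) >= 2:
                iu = np.triu_indices(len(g), k=1)
                betas.append(m[np.ix_(g, g)][iu].mean())
            else:
                betas.append(1.0)
    return float(np.percentile(taus, percentile)), float(np.percentile(betas, percentile))


def select_significant(
    components: list[GroupComponent],
    threshold: float,
    subject_level: bool = False,
    n_resamples: int = 500,
    seed: int = 0,
) -> list[GroupComponent]:
    """Flag components whose mean consistency exceeds the null threshold.

    With ``subject_level``, per-component null distributions of tau and beta
    gate which subjects are representative of each significant component.
    """
    rng = np.random.default_rng(seed)
    for gc in components:
        gc.significant = bool(gc.mean_consistency > threshold)
        if subject_level and gc.significant:
            t_thr, b_thr = _subject_level_thresholds(gc, n_resamples, rng)
            gc.representative_subjects = [
                s for s in gc.ac.subjects
                if gc.tau[s] > t_thr and gc.beta[s] > b_thr
            ]
    return [gc for gc in components if gc.significant]
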