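"""Discover-confirm workflow: three-way gRAICAR runs, exclusion, clustering.

The scheme looks for independent components that are highly reproducible
within each of two diagnostic groups but *not* in the merged cohort — those
are the candidates that carry group-discriminative information. It then
confirms discriminability without using the labels: subject-level spatial
maps under a (group-A component, group-B component) pairing are stacked into
one matrix, clustered with k-means (k = 2), and scored against the diagnosis
by cluster purity, sensitivity and specificity.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .alignment import extract_all_acs
from .group import GroupComponent, null_thresholds, select_significant, summarize_component
from .ica import Realization, decompose_subject
from .similarity import FullSimilarityMatrix, build_fsm, subset_fsm
from .synthetic import SubjectDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GraicarConfig",
    "GraicarResult",
    "ClusterEvaluation",
    "PairingResult",
    "run_group_graicar",
    "exclude_shared_components",
    "stack_subject_maps",
    "kmeans_two",
    "cluster_purity",
    "sensitivity_specificity",
    "best_spatial_match",
    "pairing_sweep",
    "discover",
    "confirm",
]


@dataclass
class GraicarConfig:
    """Tunables for one gRAICAR run."""

    n_components: int = 3
    n_realizations: int = 10
    seed: int = 0
    estimator: str = "hist"
    n_resamples: int = 500
    subject_level: bool = False
    exclusion_r_threshold: float = 0.5
    kmeans_restarts: int = 10
    # fraction of subject pairs that must individually exceed the pair-level
    # null for an AC to count as reproducible across the cohort; must exceed
    # the within-group pair fraction of a balanced two-group cohort (~0.47)
    # while tolerating a minority of poorly decomposed subjects
    consistency_coverage: float = 0.6


@dataclass
class GraicarResult:
    """Everything one gRAICAR run produced, significant components first-class.

    ``significant`` holds components whose mean inter-subject consistency
    exceeds the null threshold; ``reproducible`` further requires a clear
    majority of subject pairs to individually clear the pair-level null —
    the operational reading of "consistent across all subjects" used when
    selecting group-level components. A component carried by only one of
    two balanced groups has chance-level consistency for every cross-group
    pair (over half of all pairs) and is rejected there even when its
    overall mean is elevated, while a genuine cohort-wide component
    tolerates a minority of poorly decomposed subjects.
    """

    datasets: list[SubjectDataset]
    realizations: list[Realization]
    components: list[GroupComponent]       # all extracted, by discovery rank
    significant: list[GroupComponent]
    threshold: float
    pair_threshold: float = 0.0
    reproducible: list[GroupComponent] = field(default_factory=list)

    def subject_map(self, gc: GroupComponent, subject_index: int) -> np.ndarray | None:
        """Subject-level map under a group component: sign-harmonized mean over
        the subject's member realizations; None if the subject has no member."""
        members = gc.ac.members_of_subject(subject_index)
        if not members:
            return None
        by_key = {(re.subject_index, re.realization_index): re for re in self.realizations}
        maps = []
        for (s, j, p) in members:
            m = by_key[(s, j)].spatial_maps[p]
            r = np.corrcoef(m, gc.map)[0, 1]
            maps.append(-m if r < 0 else m)
        return np.mean(maps, axis=0)

    def fallback_subject_map(self, gc: GroupComponent, subject_index: int) -> np.ndarray | None:
        """Best |r|-matching component from the subject's first realization."""
        for re in self.realizations:
            if re.subject_index == subject_index:
                rs = [abs(np.corrcoef(m, gc.map)[0, 1]) for m in re.spatial_maps]
                p = int(np.argmax(rs))
                m = re.spatial_maps[p]
                r = np.corrcoef(m, gc.map)[0, 1]
                return -m if r < 0 else m
        return None


def decompose_all(datasets: list[SubjectDataset], config: GraicarConfig) -> list[Realization]:
    """Per-subject ICA realizations for a set of subjects, seeds derived from
    the config seed. Non-converged realizations are dropped unless a subject
    would be left with none (then kept flagged, with a warning)."""
    seeds = np.random.SeedSequence(config.seed).generate_state(len(datasets))
    realizations: list[Realization] = []
    for i, ds in enumerate(datasets):
        res = decompose_subject(
            ds,
            n_components=config.n_components,
            n_realizations=config.n_realizations,
            seed=int(seeds[i] % (2**31 - 1)),
            subject_index=i,
        )
        kept = [r for r in res if r.converged]
        if not kept:  # never drop a subject entirely
            logger.warning("subject %s: no converged realization; keeping flagged ones",
                           ds.subject_id)
            kept = res
        realizations.extend(kept)
    return realizations


def analyze_fsm(
    fsm: FullSimilarityMatrix,
    realizations: list[Realization],
    datasets: list[SubjectDataset],
    config: GraicarConfig,
    null_seed: int,
) -> GraicarResult:
    """AC extraction + metrics + significance on an already-built FSM."""
    threshold, pair_threshold = null_thresholds(
        fsm, n_resamples=config.n_resamples, seed=null_seed)
    acs = extract_all_acs(fsm)
    components = [summarize_component(ac, realizations, len(datasets)) for ac in acs]
    significant = select_significant(
        components, threshold,
        subject_level=config.subject_level,
        n_resamples=config.n_resamples,
        seed=null_seed + 1,
    )
    def pair_coverage(gc: GroupComponent) -> float:
        iu = np.triu_indices(gc.alpha.shape[0], k=1)
        return float((gc.alpha[iu] > pair_threshold).mean())

    reproducible = [gc for gc in significant
                    if pair_coverage(gc) >= config.consistency_coverage]
    return GraicarResult(datasets=datasets, realizations=realizations,
                         components=components, significant=significant,
                         threshold=threshold, pair_threshold=pair_threshold,
                         reproducible=reproducible)


def run_group_graicar(datasets: list[SubjectDataset], config: GraicarConfig) -> GraicarResult:
    """Full gRAICAR on one set of subjects: per-subject ICA realizations, FSM,
    AC extraction, consistency metrics, and the 500-resample null test.
    Returns all components with the significant subset flagged and listed."""
    if len(datasets) < 2:
        raise ValueError("gRAICAR requires at least 2 subjects")
    seeds = np.random.SeedSequence(config.seed).generate_state(2)
    from dataclasses import replace
    realizations = decompose_all(datasets, replace(config, seed=int(seeds[0] % (2**31 - 1))))
    fsm = build_fsm(realizations, estimator=config.estimator)
    return analyze_fsm(fsm, realizations, datasets, config,
                       null_seed=int(seeds[1] % (2**31 - 1)))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def exclude_shared_components(
    group_components: list[GroupComponent],
    combined_components: list[GroupComponent],
    r_threshold: float = 0.5,
) -> list[GroupComponent]:
    """Drop group components spatially matching any combined-run component.

    A component reproducible in the merged cohort carries no group-specific
    information; the match rule is |Pearson r| >= ``r_threshold`` between
    group maps (an automated stand-in for visual examination).
    """
    kept = []
    for gc in group_components:
        rs = [abs(_pearson(gc.map, cc.map)) for cc in combined_components]
        if rs and max(rs) >= r_threshold:
            logger.info("excluding group component (rank %d): |r|=%.2f with a "
                        "combined-run component", gc.ac.rank, max(rs))
            continue
        kept.append(gc)
    return kept


def stack_subject_maps(
    gc_a: GroupComponent,
    gc_b: GroupComponent,
    result_a: GraicarResult,
    result_b: GraicarResult,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One row per subject: group-A subjects contribute their subject-level map
    under ``gc_a``, group-B subjects under ``gc_b``.

    Subjects without a member in the component fall back to their
    best-matching single-realization map (logged); a subject unmappable under
    both rules is excluded with a warning. Returns (matrix, labels, ids).
    """
    rows, labels, ids = [], [], []
    for gc, result in ((gc_a, result_a), (gc_b, result_b)):
        for i, ds in enumerate(result.datasets):
            m = result.subject_map(gc, i)
            if m is None:
                logger.info("subject %s has no member in the component; using "
                            "best-matching fallback map", ds.subject_id)
                m = result.fallback_subject_map(gc, i)
            if m is None:
                logger.warning("subject %s unmappable; excluded from the stack",
                               ds.subject_id)
                continue
            rows.append(m)
            labels.append(ds.group)
            ids.append(ds.subject_id)
    return np.vstack(rows), np.array(labels), ids


def kmeans_two(matrix: np.ndarray, seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """k-means with k = 2; best of ``n_restarts`` by within-cluster sum of
    squares; deterministic given the seed. Degenerate input (fewer than two
    distinct rows) is retried with fresh seeds, then raises."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("k-means with k=2 needs at least 2 rows")
    for attempt in range(3):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed + attempt)
            labels = km.fit_predict(matrix)
        if len(np.unique(labels)) == 2:
            return labels
    raise RuntimeError("k-means produced an empty cluster (identical rows?)")


def cluster_purity(labels: np.ndarray, truth: np.ndarray) -> float:
    """Purity: (1/N) sum over clusters of the majority-group count."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape[0] != truth.shape[0]:
        raise ValueError("labels and truth must have the same length")
    total = 0
    for c in np.unique(labels):
        members = truth[labels == c]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return total / labels.shape[0]


def _majority_mapping(labels: np.ndarray, truth: np.ndarray) -> dict:
    """Cluster -> group by majority vote; ties map cluster 0 to group A."""
    groups = sorted(np.unique(truth))
    mapping = {}
    for c in sorted(np.unique(labels)):
        members = truth[labels == c]
        counts = {g: int((members == g).sum()) for g in groups}
        best = max(counts.values())
        winners = [g for g in groups if counts[g] == best]
        if len(winners) > 1:
            mapping[c] = groups[0] if c == sorted(np.unique(labels))[0] else groups[-1]
        else:
            mapping[c] = winners[0]
    return mapping


def sensitivity_specificity(labels: np.ndarray, truth: np.ndarray,
                            positive: str = "A") -> tuple[float, float]:
    """SEN = TP/(TP+FN), SPC = TN/(TN+FP) with the positive class being group
    ``positive`` and clusters mapped to groups by majority vote."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    groups = np.unique(truth)
    if len(groups) < 2:
        raise ValueError("both groups must be present in truth")
    mapping = _majority_mapping(labels, truth)
    predicted = np.array([mapping[c] for c in labels])
    tp = int(((predicted == positive) & (truth == positive)).sum())
    fn = int(((predicted != positive) & (truth == positive)).sum())
    tn = int(((predicted != positive) & (truth != positive)).sum())
    fp = int(((predicted == positive) & (truth != positive)).sum())
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spc = tn / (tn + fp) if (tn + fp) else float("nan")
    return sen, spc


@dataclass
class ClusterEvaluation:
    labels: np.ndarray
    truth: np.ndarray
    purity: float
    sensitivity: float
    specificity: float


def evaluate_clustering(matrix: np.ndarray, truth: np.ndarray, seed: int = 0,
                        n_restarts: int = 10) -> ClusterEvaluation:
    labels = kmeans_two(matrix, seed=seed, n_restarts=n_restarts)
    sen, spc = sensitivity_specificity(labels, truth)
    return ClusterEvaluation(labels=labels, truth=truth,
                             purity=cluster_purity(labels, truth),
                             sensitivity=sen, specificity=spc)


def best_spatial_match(component: np.ndarray, candidates: list[np.ndarray]) -> tuple[int, float]:
    """Candidate with the highest Pearson correlation to ``component`` (signed:
    a sign-flipped copy does not beat the original). Returns (index, r)."""
    if not candidates:
        raise ValueError("empty candidate list")
    rs = [_pearson(component, c) for c in candidates]
    idx = int(np.argmax(rs))
    return idx, float(rs[idx])


@dataclass
class PairingResult:
    index_a: int
    index_b: int
    evaluation: ClusterEvaluation


def pairing_sweep(
    components_a: list[GroupComponent],
    components_b: list[GroupComponent],
    result_a: GraicarResult,
    result_b: GraicarResult,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[list[PairingResult], pd.DataFrame]:
    """Cluster every (A-component, B-component) pairing and tabulate purity,
    sensitivity and specificity; |A| x |B| evaluations in total."""
    if not components_a or not components_b:
        raise ValueError("both component lists must be non-empty")
    results = []
    rows = []
    for ia, ib in itertools.product(range(len(components_a)), range(len(components_b))):
        matrix, truth, _ = stack_subject_maps(components_a[ia], components_b[ib],
                                              result_a, result_b)
        ev = evaluate_clustering(matrix, truth, seed=seed, n_restarts=n_restarts)
        results.append(PairingResult(ia, ib, ev))
        rows.append({"component_a": ia, "component_b": ib, "purity": ev.purity,
                     "sensitivity": ev.sensitivity, "specificity": ev.specificity})
    table = pd.DataFrame(rows)
    return results, table


@dataclass
class DiscoverResult:
    result_a: GraicarResult
    result_b: GraicarResult
    result_combined: GraicarResult
    exclusive_a: list[GroupComponent] = field(default_factory=list)
    exclusive_b: list[GroupComponent] = field(default_factory=list)


def _remap_realizations(realizations: list[Realization], keep: list[int]) -> list[Realization]:
    from dataclasses import replace as dc_replace

    remap = {s: i for i, s in enumerate(sorted(keep))}
    return [dc_replace(re, subject_index=remap[re.subject_index])
            for re in realizations if re.subject_index in remap]


def discover(
    datasets: list[SubjectDataset],
    config: GraicarConfig,
) -> DiscoverResult:
    """Run gRAICAR on group A, group B, and the merged cohort, then exclude
    from each group's reproducible components those also reproducible in the
    merged cohort.

    Per-subject ICA realizations are computed once and shared by the three
    analyses (a subject's decomposition does not depend on which cohort it
    is analyzed in); the group similarity matrices are exact sub-blocks of
    the combined one and are sliced rather than recomputed.
    """
    idx_a = [i for i, d in enumerate(datasets) if d.group == "A"]
    idx_b = [i for i, d in enumerate(datasets) if d.group == "B"]
    if not idx_a or not idx_b:
        raise ValueError("both groups must be present")
    seeds = np.random.SeedSequence(config.seed).generate_state(4)
    from dataclasses import replace
    realizations = decompose_all(datasets, replace(config, seed=int(seeds[0] % (2**31 - 1))))
    fsm_c = build_fsm(realizations, estimator=config.estimator)
    fsm_a = subset_fsm(fsm_c, idx_a)
    fsm_b = subset_fsm(fsm_c, idx_b)
    res_a = analyze_fsm(fsm_a, _remap_realizations(realizations, idx_a),
                        [datasets[i] for i in idx_a], config,
                        null_seed=int(seeds[1] % (2**31 - 1)))
    res_b = analyze_fsm(fsm_b, _remap_realizations(realizations, idx_b),
                        [datasets[i] for i in idx_b], config,
                        null_seed=int(seeds[2] % (2**31 - 1)))
    res_c = analyze_fsm(fsm_c, realizations, datasets, config,
                        null_seed=int(seeds[3] % (2**31 - 1)))
    excl_a = exclude_shared_components(res_a.reproducible, res_c.reproducible,
                                       config.exclusion_r_threshold)
    excl_b = exclude_shared_components(res_b.reproducible, res_c.reproducible,
                                       config.exclusion_r_threshold)
    return DiscoverResult(res_a, res_b, res_c, excl_a, excl_b)


def confirm(
    discovery: DiscoverResult,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[list[PairingResult], pd.DataFrame, pd.DataFrame]:
    """Pairing sweep over the discovered exclusive components plus a summary
    (min/max/mean/sd of purity). Returns (results, table, summary)."""
    results, table = pairing_sweep(
        discovery.exclusive_a, discovery.exclusive_b,
        discovery.result_a, discovery.result_b,
        seed=seed, n_restarts=n_restarts,
    )
    summary = pd.DataFrame([{
        "n_pairings": len(results),
        "purity_min": table["purity"].min(),
        "purity_max": table["purity"].max(),
        "purity_mean": table["purity"].mean(),
        "purity_sd": table["purity"].std(ddof=1) if len(table) > 1 else 0.0,
    }])
    return results, table, summary
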