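"""Greedy extraction and alignment of reproducible components (stage 3).

The search repeatedly takes the global SNMI maximum over cross-subject
entries as the seed of a new aligned component (AC), then walks every other
realization looking for the component most similar to the two seeds: the
row candidate (vs the first seed) and the column candidate (vs the second).
When the two candidates agree the component joins outright; when they
disagree, a vote — mean NMI to the members agreed so far — picks one. All
member rows/columns are then eliminated from the FSM before the next AC is
seeded, so each component can belong to at most one AC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .similarity import FullSimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["AlignedComponent", "find_global_maximum", "collect_aligned_component", "extract_all_acs"]

Triple = tuple[int, int, int]  # (subject, realization, component)


@dataclass
class AlignedComponent:
    """A group-level aligned component: one member component per (subject,
    realization) at most, with the NMI reproducibility matrix over members."""

    members: list[Triple]
    seed_pair: tuple[Triple, Triple]
    reproducibility_matrix: np.ndarray
    rank: int = 0
    member_indices: list[int] = field(default_factory=list)  # FSM column indices

    def members_of_subject(self, subject: int) -> list[Triple]:
        return [m for m in self.members if m[0] == subject]

    @property
    def subjects(self) -> list[int]:
        return sorted({m[0] for m in self.members})


def find_global_maximum(fsm: FullSimilarityMatrix) -> tuple[Triple, Triple] | None:
    """Argmax SNMI over alive entries in off-diagonal subject blocks.

    Ties break to the lexicographically smallest (i, m, j, k, y, z) tuple.
    Returns None when every cross-subject entry has been eliminated.
    """
    alive = fsm.alive
    mask = np.outer(alive, alive) & (fsm.subjects[:, None] != fsm.subjects[None, :])
    if not mask.any():
        return None
    vals = np.where(mask, fsm.snmi, -np.inf)
    best = vals.max()
    if not np.isfinite(best):
        return None
    rows, cols = np.nonzero(vals == best)
    keys = []
    for r, c in zip(rows, cols):
        i, j, y = fsm.triple_of(int(r))
        m, k, z = fsm.triple_of(int(c))
        keys.append(((i, m, j, k, y, z), (i, j, y), (m, k, z)))
    keys.sort(key=lambda item: item[0])
    return keys[0][1], keys[0][2]


def collect_aligned_component(
    fsm: FullSimilarityMatrix,
    seed_pair: tuple[Triple, Triple],
    eliminate: bool = True,
) -> AlignedComponent:
    """Grow an AC from a seed pair and (by default) eliminate its members.

    For every other realization the row-maximum candidate u (most similar to
    the first seed) and the column-maximum candidate v (most similar to the
    second seed) are located among the realization's surviving components.
    ``u == v`` joins directly; otherwise the candidate with the higher mean
    NMI to all already-agreed members wins, ties going to the row candidate.
    A realization whose components are all eliminated contributes no member.
    """
    (i, j, y), (m, k, z) = seed_pair
    seed_row = fsm.index_of(i, j, y)
    seed_col = fsm.index_of(m, k, z)
    members: list[Triple] = [(i, j, y), (m, k, z)]
    member_idx: list[int] = [seed_row, seed_col]

    for (a, b) in fsm.realization_pairs():
        if (a, b) in ((i, j), (m, k)):
            continue
        cols = fsm.block_slice(a, b)
        cols = cols[fsm.alive[cols]]
        if cols.size == 0:
            continue
        u = int(cols[np.argmax(fsm.snmi[seed_row, cols])])
        v = int(cols[np.argmax(fsm.snmi[cols, seed_col])])
        if u == v:
            chosen = u
        else:
            mean_u = fsm.raw[u, member_idx].mean()
            mean_v = fsm.raw[v, member_idx].mean()
            chosen = u if mean_u >= mean_v else v
        members.append(fsm.triple_of(chosen))
        member_idx.append(chosen)

    mrep = fsm.raw[np.ix_(member_idx, member_idx)].copy()
    np.fill_diagonal(mrep, 1.0)
    if eliminate:
        fsm.alive[member_idx] = False
    return AlignedComponent(
        members=members,
        seed_pair=seed_pair,
        reproducibility_matrix=mrep,
        member_indices=member_idx,
    )


def extract_all_acs(fsm: FullSimilarityMatrix, c_max: int | None = None) -> list[AlignedComponent]:
    """Repeat seed-search and collection until ``c_max`` ACs exist.

    ``c_max`` defaults to the maximum per-subject component count. If the FSM
    is exhausted earlier, the shorter list is returned with a logged notice.
    Discovery order is recorded as each AC's rank (1 = first found, i.e. the
    strongest cross-subject match).
    """
    if c_max is None:
        counts = {}
        for s, r, c in zip(fsm.subjects, fsm.realizations, fsm.components):
            counts[(int(s), int(r))] = max(counts.get((int(s), int(r)), 0), int(c) + 1)
        per_subject = {}
        for (s, _), c in counts.items():
            per_subject[s] = max(per_subject.get(s, 0), c)
        c_max = max(per_subject.values())

    acs: list[AlignedComponent] = []
    for rank in range(1, c_max + 1):
        seed = find_global_maximum(fsm)
        if seed is None:
            logger.info("FSM exhausted after %d of %d aligned components", len(acs), c_max)
            break
        ac = collect_aligned_component(fsm, seed)
        ac.rank = rank
        acs.append(ac)
    return acs
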