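"""Shape-group modulation profiles and the curved-vs-straight contrast.

A group profile summarizes an RDM by six mean distances (each over the 8
column pairs): within-pair distances for R, IC, ISC and ISS, plus the two
cross-group curved-vs-straight contrasts ISCa-vs-ISSa and ISCb-vs-ISSb
(column-wise distances between corresponding members of the ISC and ISS
groups). Profiles from different response sources (neurons, model layers,
pixels, human judgments) are compared by Pearson correlation over the matched
means; human sorting data provides 5 entries (one collapsed curved-vs-straight
contrast), so a model profile's two cross contrasts are averaged for that
comparison.

The curved-vs-straight test asks whether the curved-vs-straight distances
exceed the Regular-pair distances, the signature that distinguishes human
shape judgments from neural modulations. It is an exact two-sided Wilcoxon
signed-rank test on the 8 paired column differences, computed by full
enumeration of the 2^8 sign assignments; with untied, non-zero differences
its achievable p-values are multiples of 1/256 (e.g. 10/256 = 0.0390625 and
6/256 = 0.0234375).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.stats import rankdata

from .rdm import RDM
from .stimuli import GROUPS, ShapeSet, stimulus_id

PROFILE_CONTRASTS = ("R", "IC", "ISC", "ISS", "ISCa_vs_ISSa", "ISCb_vs_ISSb")
HUMAN_CONTRASTS = ("R", "IC", "ISC", "ISS", "ISC_vs_ISS")


@dataclass
class GroupProfile:
    """Six mean within/cross-group distances with SEMs over the 8 column pairs."""

    means: np.ndarray  # (6,)
    sems: np.ndarray  # (6,)
    per_pair_distances: np.ndarray  # (6, 8)
    source_tag: str = ""

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sems = np.asarray(self.sems, dtype=float)
        self.per_pair_distances = np.asarray(self.per_pair_distances, dtype=float)
        if self.per_pair_distances.shape != (6, 8):
            raise ValueError("per_pair_distances must be 6 x 8")
        if not np.allclose(self.means, self.per_pair_distances.mean(axis=1)):
            raise ValueError("means must equal the mean of their 8 per-pair distances")

    def as_dict(self) -> dict:
        return {c: float(m) for c, m in zip(PROFILE_CONTRASTS, self.means)}


@dataclass
class HumanProfile:
    """Five-entry profile of sorting dissimilarities (collapsed ISC-vs-ISS)."""

    means: np.ndarray
    sems: np.ndarray
    per_pair_distances: np.ndarray  # (5, 8)
    source_tag: str = "human"

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        if self.per_pair_distances.shape != (5, 8):
            raise ValueError("per_pair_distances must be 5 x 8")


def _lookup(rdm: RDM) -> dict:
    return {sid: k for k, sid in enumerate(rdm.stimulus_ids)}


def _dist(rdm: RDM, idx: dict, id_a: str, id_b: str) -> float:
    try:
        return float(rdm.values[idx[id_a], idx[id_b]])
    except KeyError as e:
        raise KeyError(f"stimulus {e.args[0]!r} missing from RDM") from None


def group_pair_distances(rdm: RDM, shape_set: ShapeSet | list[str] | None = None,
                         source_tag: str = "") -> GroupProfile:
    """Extract the 6 x 8 pair-distance table and its means/SEMs from an RDM.

    Within-group entries use the a-b distance of each column pair; the two
    cross entries use the column-wise ISC-ISS distances of the a members and
    of the b members. SEM = sd / sqrt(8) per contrast.
    """
    idx = _lookup(rdm)
    table = np.empty((6, 8))
    for j in range(1, 9):
        for g_i, g in enumerate(GROUPS):
            table[g_i, j - 1] = _dist(rdm, idx, stimulus_id(g, j, "a"),
                                      stimulus_id(g, j, "b"))
        table[4, j - 1] = _dist(rdm, idx, stimulus_id("ISC", j, "a"),
                                stimulus_id("ISS", j, "a"))
        table[5, j - 1] = _dist(rdm, idx, stimulus_id("ISC", j, "b"),
                                stimulus_id("ISS", j, "b"))
    means = table.mean(axis=1)
    sems = table.std(axis=1, ddof=1) / np.sqrt(8)
    return GroupProfile(means, sems, table, source_tag=source_tag)


def human_profile_from_rdm(rdm: RDM, source_tag: str = "human") -> HumanProfile:
    """Five-entry sorting profile: the ISC-vs-ISS contrast is the per-column
    average of the a-member and b-member cross distances."""
    g6 = group_pair_distances(rdm, source_tag=source_tag)
    table = np.vstack([g6.per_pair_distances[:4],
                       g6.per_pair_distances[4:6].mean(axis=0)])
    means = table.mean(axis=1)
    sems = table.std(axis=1, ddof=1) / np.sqrt(8)
    return HumanProfile(means, sems, table, source_tag=source_tag)


def _collapse_to_human(profile: GroupProfile) -> np.ndarray:
    return np.concatenate([profile.means[:4], [profile.means[4:6].mean()]])


def profile_correlation(profile_a, profile_b, mode: str = "neural_6") -> float:
    """Pearson correlation between two profiles' matched means.

    ``neural_6``: all six contrasts of two GroupProfiles. ``human_5``: five
    contrasts; a GroupProfile side is collapsed by averaging its two
    ISC-vs-ISS entries to match the human profile structure.
    """
    if mode == "neural_6":
        a = np.asarray(profile_a.means if isinstance(profile_a, GroupProfile) else profile_a)
        b = np.asarray(profile_b.means if isinstance(profile_b, GroupProfile) else profile_b)
        if a.shape != (6,) or b.shape != (6,):
            raise ValueError("neural_6 mode requires 6-entry profiles")
    elif mode == "human_5":
        def five(p):
            if isinstance(p, GroupProfile):
                return _collapse_to_human(p)
            if isinstance(p, HumanProfile):
                return np.asarray(p.means)
            v = np.asarray(p, dtype=float)
            if v.shape == (6,):
                return np.concatenate([v[:4], [v[4:6].mean()]])
            return v
        a, b = five(profile_a), five(profile_b)
        if a.shape != (5,) or b.shape != (5,):
            raise ValueError("human_5 mode requires 5-entry profiles")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("profile with zero variance: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def exact_signed_rank_p(diffs, alternative: str = "two-sided") -> float:
    """Exact Wilcoxon signed-rank p by enumeration of all sign assignments.

    Zeros are dropped (standard exact convention; all-zero input gives p = 1);
    ties among |d| get average ranks, with enumeration kept exact. Two-sided
    p is 2 * min(P(W+ <= w), P(W+ >= w)) over the 2^m equiprobable sign
    patterns, capped at 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    if m > 20:
        raise ValueError("exact enumeration limited to 20 non-zero differences")
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array([
        np.dot(signs, ranks) for signs in product((0.0, 1.0), repeat=m)
    ])
    total = w_all.size
    p_ge = np.count_nonzero(w_all >= w_obs - 1e-12) / total
    p_le = np.count_nonzero(w_all <= w_obs + 1e-12) / total
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    if alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(1.0, 2.0 * min(p_ge, p_le))


def curved_straight_test(profile: GroupProfile,
                         alternative: str = "two-sided") -> float:
    """Are curved-vs-straight distances larger than Regular-pair distances?

    Per column j, d_j = mean(ISCa-vs-ISSa_j, ISCb-vs-ISSb_j) - R_j; the 8
    paired differences go into the exact signed-rank enumeration. All-zero
    differences give p = 1 by convention.
    """
    t = profile.per_pair_distances
    d = t[4:6].mean(axis=0) - t[0]
    return exact_signed_rank_p(d, alternative=alternative)
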