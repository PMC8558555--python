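"""Clonality analysis: normalized VAFs, shared/private partition, CCF,
and clone clustering.

Clonal status uses the normalized-VAF rule: each mutation's VAF is
divided by the maximum VAF in the same specimen, and mutations with a
normalized VAF >= 0.5 are called clonal (ties inclusive).  This removes
the frequency bias between components with very different tumor-cell
content.

Clone clustering groups mutations that plausibly share one
cancer-cell-fraction trajectory.  It is a seeded finite binomial-mixture
model over alt-read counts, fitted by EM with BIC model selection over
1..max_clusters, followed by a greedy hard-assignment polish that
maximizes the classification likelihood.  The highest-prevalence
cluster is the trunk candidate.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .calls import MutationCall, SpecimenProfile, MutationTableError

logger = logging.getLogger(__name__)

Key = tuple[str, int, str, str]

CLONAL_THRESHOLD = 0.5


@dataclass(frozen=True)
class NormalizedMutation:
    """A mutation with its within-specimen normalized VAF and clonality."""

    key: Key
    gene: str
    vaf: float
    normalized_vaf: float

    @property
    def clonal(self) -> bool:
        return self.normalized_vaf >= CLONAL_THRESHOLD


@dataclass(frozen=True)
class SharedPartition:
    """Shared / stroma-specific / neoplasm-specific variant keys of one patient."""

    patient_id: str
    shared: frozenset[Key]
    stroma_specific: frozenset[Key]
    neoplasm_specific: frozenset[Key]

    def __post_init__(self) -> None:
        if self.shared & self.stroma_specific or self.shared & self.neoplasm_specific:
            raise ValueError("partition classes must be disjoint")
        if self.stroma_specific & self.neoplasm_specific:
            raise ValueError("partition classes must be disjoint")


@dataclass
class CloneCluster:
    """A set of mutations inferred to share a CCF trajectory."""

    cluster_id: int
    member_keys: list[Key]
    mean_ccf: float
    rank: int = 0
    contains_driver: bool = False
    mean_ccf_stroma: Optional[float] = None

    def __len__(self) -> int:
        return len(self.member_keys)


def normalize_vafs(profile: SpecimenProfile) -> list[NormalizedMutation]:
    """Normalize each mutation's VAF by the specimen maximum.

    The maximum-VAF carrier(s) get normalized VAF 1.0 by construction;
    an empty profile yields an empty list.
    """
    if not profile.mutations:
        return []
    max_vaf = profile.max_vaf
    if max_vaf <= 0:
        raise MutationTableError(
            f"specimen {profile.patient_id}/{profile.component} has max VAF 0"
        )
    return [
        NormalizedMutation(
            key=m.key, gene=m.gene, vaf=m.vaf, normalized_vaf=m.vaf / max_vaf
        )
        for m in profile.mutations
    ]


def partition_mutations(
    stroma: SpecimenProfile, neoplasm: SpecimenProfile
) -> SharedPartition:
    """Partition one patient's retained mutations by component sharing.

    Keys on exact (chrom, pos, ref, alt).  Raises when the two profiles
    belong to different patients.
    """
    if stroma.patient_id != neoplasm.patient_id:
        raise MutationTableError(
            f"patient mismatch: {stroma.patient_id} vs {neoplasm.patient_id}"
        )
    s_keys = stroma.keys()
    n_keys = neoplasm.keys()
    return SharedPartition(
        patient_id=stroma.patient_id,
        shared=frozenset(s_keys & n_keys),
        stroma_specific=frozenset(s_keys - n_keys),
        neoplasm_specific=frozenset(n_keys - s_keys),
    )


def ccf_vaf_factor(copy_number: int, purity: float, mutant_copies: int = 1) -> float:
    """Expected VAF per unit CCF for a variant at the given local copy number."""
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if copy_number < 1:
        raise ValueError(f"copy number must be >= 1, got {copy_number}")
    return purity * mutant_copies / (purity * copy_number + (1.0 - purity) * 2.0)


def compute_ccf(
    mutation: MutationCall, purity: float, mutant_copies: int = 1
) -> float:
    """Cancer cell fraction from VAF, purity and local copy number.

    CCF = VAF * (purity*CN + (1-purity)*2) / (purity * m) with m mutant
    copies (one by default), clipped to [0, 1] with a warning when the
    raw value exceeds 1.
    """
    raw = mutation.vaf / ccf_vaf_factor(mutation.copy_number, purity, mutant_copies)
    if raw > 1.0:
        logger.warning(
            "CCF %.3f > 1 at %s:%d (vaf=%.3f, purity=%.2f, CN=%d); clipped",
            raw,
            mutation.chrom,
            mutation.pos,
            mutation.vaf,
            purity,
            mutation.copy_number,
        )
        return 1.0
    return max(raw, 0.0)


# ---------------------------------------------------------------------------
# Binomial-mixture clone clustering

_CCF_EPS = 1e-4


def _log_binom_pmf(alt: np.ndarray, depth: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-pmf with the combinatorial constant included."""
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    const = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    return const + alt * np.log(p) + (depth - alt) * np.log1p(-p)


def _mixture_loglik(
    alt: np.ndarray,
    depth: np.ndarray,
    factor: np.ndarray,
    weights: np.ndarray,
    ccfs: np.ndarray,
) -> float:
    log_p = _log_binom_pmf(
        alt[:, None], depth[:, None], ccfs[None, :] * factor[:, None]
    )
    log_w = np.log(np.clip(weights, 1e-12, None))
    return float(np.logaddexp.reduce(log_p + log_w[None, :], axis=1).sum())


def _em_fit(
    alt: np.ndarray,
    depth: np.ndarray,
    factor: np.ndarray,
    init_ccfs: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit a K-component binomial mixture by EM from given CCF centers."""
    k = len(init_ccfs)
    ccfs = np.clip(init_ccfs.astype(float), _CCF_EPS, 1.0)
    weights = np.full(k, 1.0 / k)
    prev = -np.inf
    for _ in range(max_iter):
        log_p = _log_binom_pmf(
            alt[:, None], depth[:, None], ccfs[None, :] * factor[:, None]
        )
        log_joint = log_p + np.log(np.clip(weights, 1e-12, None))[None, :]
        log_norm = np.logaddexp.reduce(log_joint, axis=1)
        resp = np.exp(log_joint - log_norm[:, None])
        loglik = float(log_norm.sum())
        if loglik - prev < tol:
            break
        prev = loglik
        weights = resp.mean(axis=0)
        denom = resp.T @ (depth * factor)
        numer = resp.T @ alt
        with np.errstate(invalid="ignore", divide="ignore"):
            new = np.where(denom > 0, numer / np.maximum(denom, 1e-12), ccfs)
        ccfs = np.clip(new, _CCF_EPS, 1.0)
    return weights, ccfs, prev


def map_partition_loglik(
    assignment: Sequence[int],
    alt: np.ndarray,
    depth: np.ndarray,
    factor: np.ndarray,
) -> float:
    """Classification log-likelihood of a hard partition with per-cluster MLE CCFs.

    For each cluster the CCF maximizing the binomial likelihood is
    sum(alt) / sum(depth * factor), clipped to (0, 1].  This is the
    objective shared with the exhaustive small-instance oracle.
    """
    assignment = np.asarray(assignment)
    total = 0.0
    for label in np.unique(assignment):
        mask = assignment == label
        denom = float((depth[mask] * factor[mask]).sum())
        ccf = np.clip(alt[mask].sum() / max(denom, 1e-12), _CCF_EPS, 1.0)
        total += float(
            _log_binom_pmf(alt[mask], depth[mask], ccf * factor[mask]).sum()
        )
    return total


def _greedy_polish(
    assignment: np.ndarray,
    alt: np.ndarray,
    depth: np.ndarray,
    factor: np.ndarray,
    max_labels: int,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Greedy single-point reassignment ascent on the classification likelihood."""
    assignment = assignment.copy()
    n = len(alt)
    best = map_partition_loglik(assignment, alt, depth, factor)
    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            current = assignment[i]
            for label in range(max_labels):
                if label == current:
                    continue
                assignment[i] = label
                trial = map_partition_loglik(assignment, alt, depth, factor)
                if trial > best + 1e-12:
                    best = trial
                    current = label
                    improved = True
                else:
                    assignment[i] = current
        if not improved:
            break
    return assignment


def best_partition(
    alt: np.ndarray,
    depth: np.ndarray,
    factor: np.ndarray,
    max_labels: int,
    seed: int = 0,
    n_restarts: int = 20,
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood hard partition with at most ``max_labels`` clusters.

    EM restarts at K = ``max_labels`` followed by the greedy polish;
    returns the assignment and its classification log-likelihood (the
    same objective :func:`brute_force_partition` maximizes exhaustively).
    Labels may collapse: fewer than ``max_labels`` clusters can remain.
    """
    n = len(alt)
    k = min(max_labels, n)
    naive = np.clip(alt / np.maximum(depth * factor, 1e-12), _CCF_EPS, 1.0)
    rng = np.random.default_rng(seed)
    best_ll = -np.inf
    best_assign = np.zeros(n, dtype=int)

    def consider(assignment: np.ndarray) -> None:
        nonlocal best_ll, best_assign
        ll = map_partition_loglik(assignment, alt, depth, factor)
        if ll > best_ll:
            best_ll = ll
            best_assign = assignment.copy()

    # with equal CCF->VAF factors the optimal hard partition is contiguous
    # in VAF order, so enumerate contiguous segmentations exactly when cheap
    if n <= 40:
        order = np.argsort(naive, kind="stable")
        for kk in range(1, k + 1):
            for bounds in combinations(range(1, n), kk - 1):
                assignment = np.zeros(n, dtype=int)
                edges = (0, *bounds, n)
                for label in range(kk):
                    assignment[order[edges[label] : edges[label + 1]]] = label
                consider(assignment)

    inits = [np.quantile(naive, (np.arange(k) + 0.5) / k)]
    for _ in range(n_restarts - 1):
        inits.append(rng.choice(naive, size=k, replace=True))
    for init in inits:
        weights, ccfs, _ = _em_fit(alt, depth, factor, np.asarray(init))
        log_p = _log_binom_pmf(
            alt[:, None], depth[:, None], ccfs[None, :] * factor[:, None]
        ) + np.log(np.clip(weights, 1e-12, None))[None, :]
        consider(_greedy_polish(np.asarray(log_p.argmax(axis=1)), alt, depth, factor, k))
    final = _greedy_polish(best_assign, alt, depth, factor, k)
    return final, map_partition_loglik(final, alt, depth, factor)


def cluster_clones(
    profile: SpecimenProfile,
    purity: float = 1.0,
    max_clusters: int = 6,
    seed: int = 0,
    n_restarts: int = 20,
) -> list[CloneCluster]:
    """Cluster a specimen's mutations into clones by CCF.

    A seeded binomial-mixture EM over alt-read counts with BIC model
    selection over 1..max_clusters (ties favor fewer clusters).  After
    model selection, mutations are hard-assigned and the partition is
    polished by greedy reassignment.  Clusters are ranked by mean CCF
    descending; ties favor the larger cluster, then lexicographically
    smallest membership.  The rank-1 cluster is the trunk candidate.
    """
    muts = list(profile.mutations)
    if not muts:
        return []
    alt = np.array([m.hq_alt_reads for m in muts], dtype=float)
    depth = np.array([m.depth for m in muts], dtype=float)
    factor = np.array(
        [ccf_vaf_factor(max(m.copy_number, 1), purity) for m in muts], dtype=float
    )
    n = len(muts)
    naive = np.clip(alt / np.maximum(depth * factor, 1e-12), _CCF_EPS, 1.0)
    rng = np.random.default_rng(seed)

    best_bic = np.inf
    best_k = 1
    best_fit: tuple[np.ndarray, np.ndarray] | None = None
    for k in range(1, min(max_clusters, n) + 1):
        quantiles = np.quantile(naive, (np.arange(k) + 0.5) / k)
        inits = [quantiles]
        for _ in range(n_restarts - 1):
            inits.append(rng.choice(naive, size=k, replace=True))
        k_best_ll = -np.inf
        k_best = None
        for init in inits:
            weights, ccfs, ll = _em_fit(alt, depth, factor, np.asarray(init))
            if ll > k_best_ll:
                k_best_ll = ll
                k_best = (weights, ccfs)
        bic = -2.0 * k_best_ll + (2 * k - 1) * math.log(n)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best_k = k
            best_fit = k_best

    weights, ccfs = best_fit  # type: ignore[misc]
    log_p = _log_binom_pmf(
        alt[:, None], depth[:, None], ccfs[None, :] * factor[:, None]
    ) + np.log(np.clip(weights, 1e-12, None))[None, :]
    assignment = np.asarray(log_p.argmax(axis=1))
    assignment = _greedy_polish(assignment, alt, depth, factor, best_k)

    clusters: list[CloneCluster] = []
    for label in np.unique(assignment):
        mask = assignment == label
        denom = float((depth[mask] * factor[mask]).sum())
        ccf = float(np.clip(alt[mask].sum() / max(denom, 1e-12), _CCF_EPS, 1.0))
        members = sorted(m.key for m, keep in zip(muts, mask) if keep)
        clusters.append(
            CloneCluster(cluster_id=int(label), member_keys=members, mean_ccf=ccf)
        )
    clusters.sort(key=lambda c: (-c.mean_ccf, -len(c), c.member_keys))
    for rank, cluster in enumerate(clusters, start=1):
        cluster.rank = rank
        cluster.cluster_id = rank
    return clusters


def brute_force_partition(
    alt: np.ndarray,
    depth: np.ndarray,
    factor: np.ndarray,
    max_labels: int,
) -> tuple[np.ndarray, float]:
    """Exhaustively maximize the classification likelihood over assignments.

    Small-instance oracle: enumerates every assignment of n mutations to
    at most ``max_labels`` clusters and returns the best partition and
    its log-likelihood.  Exponential in n — intended for n <= ~10.
    """
    n = len(alt)
    best_ll = -np.inf
    best_assign = np.zeros(n, dtype=int)
    assignment = np.zeros(n, dtype=int)

    def recurse(i: int, used: int) -> None:
        nonlocal best_ll, best_assign
        if i == n:
            ll = map_partition_loglik(assignment, alt, depth, factor)
            if ll > best_ll:
                best_ll = ll
                best_assign = assignment.copy()
            return
        # canonical labelings only: next label is at most one past those used
        for label in range(min(used + 1, max_labels)):
            assignment[i] = label
            recurse(i + 1, max(used, label + 1))

    recurse(0, 0)
    return best_assign, best_ll
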