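"""Consensus meta-clustering over repeated stochastic trainings.

Each training run yields a hard labeling of the same events; runs differ
by seed.  The consensus procedure picks the run most in agreement with
the others (highest mean NMI) as the reference, greedily relabels every
other run's clusters onto the reference clusters by descending event
overlap, and takes a per-event majority vote (ties resolved in favour of
the reference run, making the output deterministic).  Agreement of each
run with the consensus is reported as pairwise F-score and NMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix, pair_confusion_matrix


@dataclass
class RunSet:
    """Hard labelings from R repeated trainings of the same events."""

    labelings: np.ndarray               # (R, n_events) integer labels
    run_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labelings = np.atleast_2d(np.asarray(self.labelings))
        if self.labelings.size == 0:
            raise ValueError("empty RunSet")

    @property
    def n_runs(self) -> int:
        return self.labelings.shape[0]

    @property
    def n_events(self) -> int:
        return self.labelings.shape[1]


@dataclass
class ConsensusResult:
    consensus_labels: np.ndarray
    per_run_fscore: np.ndarray
    per_run_nmi: np.ndarray
    reference_run: int
    n_clusters: int

    @property
    def mean_fscore(self) -> float:
        return float(np.mean(self.per_run_fscore))

    @property
    def mean_nmi(self) -> float:
        return float(np.mean(self.per_run_nmi))


def nmi(a, b) -> float:
    """Normalised mutual information (arithmetic-mean normalisation), in [0, 1]."""
    a, b = _check_pair(a, b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def pairwise_fscore(a, b) -> float:
    """F1 over co-clustered event pairs, with `a` the prediction.

    precision = shared pairs / pairs in `a`; recall = shared pairs /
    pairs in `b`.  Two all-singleton partitions agree perfectly (F = 1);
    a partition without any pair scores 0 against one that has pairs.
    """
    a, b = _check_pair(a, b)
    (n00, n01), (n10, n11) = pair_confusion_matrix(b, a)  # rows: b, cols: a
    pairs_a = (n01 + n11) // 2          # pair_confusion counts ordered pairs
    pairs_b = (n10 + n11) // 2
    shared = n11 // 2
    if pairs_a == 0 and pairs_b == 0:
        return 1.0
    if shared == 0:
        return 0.0
    precision = shared / pairs_a
    recall = shared / pairs_b
    return float(2.0 * precision * recall / (precision + recall))


def best_match_fscore(a, b) -> float:
    """Cluster-level F-measure: weighted best-match F1 of `b`'s clusters in `a`."""
    a, b = _check_pair(a, b)
    cont = contingency_matrix(b, a)      # rows: clusters of b, cols: of a
    n = len(a)
    row_sums = cont.sum(axis=1, keepdims=True)
    col_sums = cont.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 2.0 * cont / (row_sums + col_sums)
    return float((row_sums[:, 0] / n * f.max(axis=1)).sum())


def greedy_consensus(runs: RunSet, k: int | None = None) -> ConsensusResult:
    """Combine R labelings into one partition by greedy cluster matching.

    `k` is accepted for interface symmetry with the training stage; the
    consensus cluster count is determined by the vote itself.
    """
    L = runs.labelings
    R, n = L.shape
    if R == 1:
        labels = L[0].copy()
        return ConsensusResult(
            consensus_labels=labels,
            per_run_fscore=np.ones(1),
            per_run_nmi=np.ones(1),
            reference_run=0,
            n_clusters=len(np.unique(labels)),
        )

    mean_nmi = np.zeros(R)
    for i in range(R):
        mean_nmi[i] = np.mean([nmi(L[i], L[j]) for j in range(R) if j != i])
    ref = int(np.argmax(mean_nmi))       # first max -> deterministic

    ref_labels = L[ref]
    ref_values = np.unique(ref_labels)
    relabeled = np.empty_like(L)
    relabeled[ref] = ref_labels
    for r in range(R):
        if r == ref:
            continue
        relabeled[r] = _relabel_to_reference(L[r], ref_labels, ref_values)

    # per-event majority vote; ties favour the reference run's label
    counts = np.zeros((len(ref_values), n), dtype=np.int32)
    value_index = {v: i for i, v in enumerate(ref_values)}
    for r in range(R):
        rows = np.fromiter((value_index[v] for v in relabeled[r]), dtype=np.int64, count=n)
        np.add.at(counts, (rows, np.arange(n)), 1)
    winner = np.argmax(counts, axis=0)
    best_count = counts[winner, np.arange(n)]
    ref_idx = np.fromiter((value_index[v] for v in ref_labels), dtype=np.int64, count=n)
    ref_count = counts[ref_idx, np.arange(n)]
    tie_with_ref = ref_count == best_count
    winner = np.where(tie_with_ref, ref_idx, winner)
    consensus = ref_values[winner]

    fs = np.array([pairwise_fscore(L[r], consensus) for r in range(R)])
    nm = np.array([nmi(L[r], consensus) for r in range(R)])
    return ConsensusResult(
        consensus_labels=consensus,
        per_run_fscore=fs,
        per_run_nmi=nm,
        reference_run=ref,
        n_clusters=len(np.unique(consensus)),
    )


def _relabel_to_reference(labels, ref_labels, ref_values) -> np.ndarray:
    """Greedy overlap matching of one run's clusters onto reference clusters."""
    cont = contingency_matrix(labels, ref_labels)  # rows: run clusters
    run_values = np.unique(labels)
    mapping: dict = {}
    work = cont.astype(np.int64).copy()
    n_rounds = min(len(run_values), len(ref_values))
    for _ in range(n_rounds):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        if work[i, j] < 0:
            break
        mapping[run_values[i]] = ref_values[j]
        work[i, :] = -1
        work[:, j] = -1
    # any leftover run clusters go to their best-overlap reference cluster
    for i, v in enumerate(run_values):
        if v not in mapping:
            mapping[v] = ref_values[int(np.argmax(cont[i]))]
    out = np.empty_like(ref_labels)
    for v, tgt in mapping.items():
        out[labels == v] = tgt
    return out


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if a.size == 0:
        raise ValueError("empty label vectors")
    return a, b
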