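"""Species-differentiation evaluation: clustering ARI, metagenomic binning,
and few-shot classification.

Three protocols, run on any embedding (trained encoder or TNF baseline):

* **Clustering** -- K-means with K set to the true species count, scored by the
  Adjusted Rand Index against the species labels, averaged over independent
  seeded runs.
* **Binning** -- a modified K-medoid algorithm: repeatedly find the densest
  remaining point (the point with most neighbours within a learned cosine
  distance threshold), carve out its neighbourhood as a bin, and stop when no
  neighbourhood reaches the minimum bin size.  A species counts as identified
  when its best per-bin F1 exceeds 0.5; species are reported by F1 band.
* **Few-shot classification** -- per class, hold out a fixed test set, train an
  L2-regularized multinomial logistic regression on k labelled embeddings per
  class, and report macro-F1 across shot counts and runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.special import comb
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score

from .records import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledEmbeddingSet",
    "BinResult",
    "RecoveryReport",
    "adjusted_rand_index",
    "kmeans_ari",
    "filter_binning_input",
    "learn_threshold",
    "modified_kmedoid_bin",
    "species_recovery",
    "fewshot_eval",
]

F1_BANDS = [(0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 1.0)]


@dataclass
class LabeledEmbeddingSet:
    ids: list[str]
    X: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.ids)
        if self.X.shape[0] != n or len(self.labels) != n:
            raise ValueError("ids, X and labels must align")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in embedding set")


@dataclass
class BinResult:
    """Disjoint clusters from the binning algorithm, in discovery order."""

    assignments: dict[str, int]   # seq_id -> bin index; unbinned ids absent
    bins: list[set[str]]
    threshold: float
    iterations: int


@dataclass
class RecoveryReport:
    best_f1: dict[str, float]
    band_counts: dict[str, int]   # e.g. "0.5-0.6" -> count
    identified: int               # species with best F1 > 0.5


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-adjusted Rand index from the contingency table, in [-1, 1]."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must have equal length")
    n = labels_a.size
    if n < 2:
        raise ValueError("need at least two items")
    _, ia = np.unique(labels_a, return_inverse=True)
    _, ib = np.unique(labels_b, return_inverse=True)
    table = np.zeros((ia.max() + 1, ib.max() + 1), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # only happens when both partitions are all-singletons or both are a
        # single cluster -- identical partitions, perfect agreement
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def kmeans_ari(
    embeddings: LabeledEmbeddingSet,
    runs: int = 5,
    seed: int = 0,
    normalize: bool = False,
) -> tuple[float, list[float]]:
    """K-means (K = number of species) ARI against labels, over seeded runs."""
    labels = np.asarray(embeddings.labels)
    k = len(set(embeddings.labels))
    if k < 2:
        raise ValueError("need at least two species for clustering")
    X = embeddings.X
    if X.shape[0] < k:
        raise ValueError("fewer points than clusters")
    if normalize:
        X = X / np.linalg.norm(X, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    aris = []
    for _ in range(runs):
        km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                    random_state=int(rng.integers(2**31 - 1)))
        pred = km.fit_predict(X)
        aris.append(adjusted_rand_index(labels, pred))
    return float(np.mean(aris)), aris


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def filter_binning_input(
    records: list[SequenceRecord],
    labels: dict[str, str],
    min_length: int = 2500,
    min_species_size: int = 10,
) -> tuple[list[SequenceRecord], dict[str, str], dict[str, int]]:
    """Keep sequences strictly longer than ``min_length`` bp, then drop species
    with fewer than ``min_species_size`` surviving sequences.

    Returns (kept records, kept labels, drop counts).  An empty result is
    signalled explicitly through the counts, never silently.
    """
    missing = [r.seq_id for r in records if r.seq_id not in labels]
    if missing:
        raise ValueError(f"records without labels: {missing[:3]}...")
    long_enough = [r for r in records if r.length > min_length]
    n_short = len(records) - len(long_enough)
    sizes: dict[str, int] = {}
    for r in long_enough:
        sizes[labels[r.seq_id]] = sizes.get(labels[r.seq_id], 0) + 1
    kept = [r for r in long_enough if sizes[labels[r.seq_id]] >= min_species_size]
    n_rare = len(long_enough) - len(kept)
    counts = {"dropped_short": n_short, "dropped_rare_species": n_rare,
              "kept": len(kept)}
    logger.info("binning filter: %s", counts)
    return kept, {r.seq_id: labels[r.seq_id] for r in kept}, counts


def learn_threshold(X: np.ndarray, seed: int = 0, max_points: int = 2000,
                    bins: int = 256) -> float:
    """Learn the within/between-cluster cosine-distance cut-off.

    Pairwise cosine distances of a seeded subsample are split by Otsu's
    between-class-variance criterion over ``bins`` histogram bins; the returned
    threshold sits in the valley between the intra- and inter-cluster distance
    modes.  Degenerate (constant-distance) inputs return that distance.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 points to learn a threshold")
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_points:
        idx = rng.choice(X.shape[0], size=max_points, replace=False)
        X = X[idx]
    d = pdist(X, metric="cosine")
    if np.ptp(d) < 1e-12:
        logger.warning("degenerate pairwise distances; threshold = %g", d[0])
        return float(d[0])
    return float(threshold_otsu(d, nbins=bins))


def modified_kmedoid_bin(
    X: np.ndarray,
    threshold: float,
    min_bin_size: int = 10,
    ids: list[str] | None = None,
) -> BinResult:
    """Iterative densest-point binning in cosine-distance space.

    Repeat: count, for every remaining point, the remaining points within
    ``threshold`` (inclusive, self included); take the maximum-density point
    (ties broken toward the lowest index); stop if its density is below
    ``min_bin_size``; otherwise its neighbourhood becomes the next bin and is
    removed.  Bins are disjoint by construction.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids must align with embedding rows")
    if n == 0:
        return BinResult({}, [], threshold, 0)

    close = cdist(X, X, metric="cosine") <= threshold
    remaining = np.ones(n, dtype=bool)
    bins: list[set[str]] = []
    assignments: dict[str, int] = {}
    iterations = 0
    while remaining.any():
        density = (close & remaining[None, :])[remaining].sum(axis=1)
        rem_idx = np.flatnonzero(remaining)
        best_local = int(np.argmax(density))  # argmax takes first maximum
        if density[best_local] < min_bin_size:
            break
        medoid = rem_idx[best_local]
        members = np.flatnonzero(close[medoid] & remaining)
        bin_ids = {ids[j] for j in members}
        for j in members:
            assignments[ids[j]] = len(bins)
        bins.append(bin_ids)
        remaining[members] = False
        iterations += 1
    return BinResult(assignments, bins, float(threshold), iterations)


def species_recovery(bins: BinResult, labels: dict[str, str]) -> RecoveryReport:
    """Best per-species F1 over bins, with unbinned sequences counting against
    recall (never against precision), plus F1-band counts."""
    unlabeled = set(bins.assignments) - set(labels)
    if unlabeled:
        raise ValueError(f"binned ids without labels: {sorted(unlabeled)[:3]}...")
    species_sizes: dict[str, int] = {}
    for sp in labels.values():
        species_sizes[sp] = species_sizes.get(sp, 0) + 1
    best_f1 = {sp: 0.0 for sp in species_sizes}
    for members in bins.bins:
        bin_species: dict[str, int] = {}
        for sid in members:
            sp = labels[sid]
            bin_species[sp] = bin_species.get(sp, 0) + 1
        for sp, hits in bin_species.items():
            precision = hits / len(members)
            recall = hits / species_sizes[sp]
            f1 = 2 * precision * recall / (precision + recall)
            best_f1[sp] = max(best_f1[sp], f1)
    band_counts = {
        f"{lo}-{hi}": sum(1 for f in best_f1.values() if lo < f <= hi)
        for lo, hi in F1_BANDS
    }
    identified = sum(1 for f in best_f1.values() if f > 0.5)
    return RecoveryReport(best_f1=best_f1, band_counts=band_counts,
                          identified=identified)


# ---------------------------------------------------------------------------
# Few-shot classification
# ---------------------------------------------------------------------------


def fewshot_eval(
    embeddings: LabeledEmbeddingSet,
    shots: list[int] = (1, 2, 5, 10, 20),
    test_per_class: int = 80,
    runs: int = 5,
    seed: int = 0,
    l2_c: float = 1.0,
) -> pd.DataFrame:
    """Macro-F1 of logistic regression at several shot counts.

    Per run and per class: a seeded shuffle holds out ``test_per_class``
    embeddings for testing and draws the training shots (nested across shot
    counts) from the remainder.  Returns a table indexed by shots with one
    column per run plus their mean.
    """
    shots = sorted(int(s) for s in shots)
    labels = np.asarray(embeddings.labels)
    classes, counts = np.unique(labels, return_counts=True)
    need = max(shots) + test_per_class
    too_small = classes[counts < need]
    if too_small.size:
        raise ValueError(
            f"class {too_small[0]!r} has fewer than {need} members"
        )
    rng = np.random.default_rng(seed)
    results = np.zeros((len(shots), runs))
    for run in range(runs):
        test_idx, pool_idx = [], []
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            idx = rng.permutation(idx)
            test_idx.append(idx[:test_per_class])
            pool_idx.append(idx[test_per_class : test_per_class + max(shots)])
        test_idx = np.concatenate(test_idx)
        for si, k in enumerate(shots):
            train_idx = np.concatenate([p[:k] for p in pool_idx])
            clf = LogisticRegression(max_iter=2000, C=l2_c)
            clf.fit(embeddings.X[train_idx], labels[train_idx])
            pred = clf.predict(embeddings.X[test_idx])
            results[si, run] = f1_score(labels[test_idx], pred, average="macro")
    df = pd.DataFrame(results, index=pd.Index(shots, name="shots"),
                      columns=[f"run{r}" for r in range(runs)])
    df["mean"] = df.mean(axis=1)
    return df
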