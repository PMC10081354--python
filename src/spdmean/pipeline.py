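"""Group-level connectome analyses built on geodesic mean estimation.

Stages, each reusable on its own:

- :func:`correlation_connectome` — Pearson correlation of ROI time series,
  shrunk toward the identity so the matrix is full rank (SPD);
- :func:`bootstrap_group_distance` — bootstrap distribution of the geodesic
  distance between two groups' mean connectomes, tested against matched
  within-group (split-half) distances with a one-sided Wilcoxon signed-rank
  test;
- :func:`permutation_edge_selection` — per-edge group differences of the
  mean connectomes tested by label permutation with Benjamini-Hochberg FDR;
- :func:`classify_with_selected_features` — off-the-shelf classification on
  the selected edges (thin glue around scikit-learn);
- :class:`GeodesicEM` — EM-style clustering whose E-step assigns subjects to
  the geodesically nearest centroid and whose M-step re-estimates centroids
  with a geodesic mean estimator (mSPD-NN by default);
- :func:`cluster_purity` — majority-vote purity of a clustering against
  known labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .collection import ConnectomeCollection
from .estimators import make_mean_estimator
from .geometry import check_spd, geodesic_distance, sym

__all__ = [
    "GroupedCohort",
    "EdgeSelection",
    "EMState",
    "BootstrapDistanceResult",
    "correlation_connectome",
    "bootstrap_group_distance",
    "permutation_edge_selection",
    "classify_with_selected_features",
    "GeodesicEM",
    "mspd_em_cluster",
    "cluster_purity",
    "split_cohort",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupedCohort:
    """A labelled collection plus its distinct group set."""

    collection: ConnectomeCollection

    def __post_init__(self):
        if self.collection.labels is None:
            raise ValueError("cohort requires a labelled collection")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.collection.labels))

    def group(self, label) -> ConnectomeCollection:
        return self.collection.group(label)


@dataclass
class EdgeSelection:
    """Result of permutation-based edge selection.

    ``p_values`` is a symmetric P x P matrix (diagonal 1), ``selected`` the
    symmetric FDR-controlled mask (diagonal never selected).
    """

    p_values: np.ndarray
    selected: np.ndarray
    alpha: float
    n_permutations: int
    observed: np.ndarray = field(default=None, repr=False)


@dataclass
class EMState:
    """Geodesic EM clustering state."""

    centroids: np.ndarray
    assignments: np.ndarray
    iteration: int
    converged: bool


@dataclass
class BootstrapDistanceResult:
    """Bootstrap group-separation distances and the paired signed-rank test."""

    between: np.ndarray
    within: np.ndarray
    p_value: float | None
    group_pair: tuple


def _mean_fitter(method: str, P: int, config: dict | None):
    """Estimator factory used by pipeline stages.

    Pipeline stages need accurate means rather than tolerance-matched
    comparisons, so the estimator's own (tight) defaults are used;
    ``config`` overrides them.
    """
    base = dict(config) if config else {}

    def fit(matrices) -> np.ndarray:
        return make_mean_estimator(method, **base).fit(matrices).mean_

    return fit


def correlation_connectome(timeseries, shrinkage: float = 0.05) -> np.ndarray:
    """Regularized Pearson correlation connectome from a T x P time series.

    Computes the Pearson correlation matrix ``C`` of the columns and shrinks
    it toward the identity, ``(1 - shrinkage) C + shrinkage I``, so the
    result is full rank. Constant columns are rejected by name; a
    rank-deficient result at ``shrinkage=0`` raises with advice to shrink.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError(f"expected a T x P series with T >= 2, got {ts.shape}")
    if not 0 <= shrinkage < 1:
        raise ValueError("shrinkage must lie in [0, 1)")
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant column(s) {constant.tolist()}: correlation undefined")
    C = np.corrcoef(ts, rowvar=False)
    C = (1.0 - shrinkage) * sym(C) + shrinkage * np.eye(ts.shape[1])
    try:
        return check_spd(C, name="correlation connectome")
    except ValueError as exc:
        raise ValueError(
            f"{exc}; increase shrinkage above {shrinkage} to restore full rank"
        ) from None


def bootstrap_group_distance(
    cohort: GroupedCohort,
    group_pair,
    n_boot: int = 10,
    subjects_per_boot: int = 25,
    method: str = "mspdnn",
    config: dict | None = None,
    seed: int = 0,
) -> BootstrapDistanceResult:
    """Bootstrap separation between two groups' geodesic mean connectomes.

    Per trial, ``subjects_per_boot`` subjects are subsampled without
    replacement from each group, group means are estimated, and the geodesic
    distance between the two means is one "between" draw. The matched
    "within" draw is the mean of the two groups' split-half distances
    (disjoint half-samples of the same trial's subjects). A one-sided
    Wilcoxon signed-rank test of between > within is reported
    (``None`` when ``n_boot < 2``: no distribution to test).
    """
    g1, g2 = group_pair
    coll1, coll2 = cohort.group(g1), cohort.group(g2)
    for lab, coll in ((g1, coll1), (g2, coll2)):
        if len(coll) < subjects_per_boot:
            raise ValueError(
                f"group {lab!r} has {len(coll)} subjects < subjects_per_boot={subjects_per_boot}"
            )
    P = cohort.collection.dim
    fit = _mean_fitter(method, P, config)
    rng = np.random.default_rng([seed, 3])
    half = max(subjects_per_boot // 2, 1)
    between, within = [], []
    for _ in range(n_boot):
        sub1 = rng.choice(len(coll1), size=subjects_per_boot, replace=False)
        sub2 = rng.choice(len(coll2), size=subjects_per_boot, replace=False)
        m1 = fit(coll1.matrices[sub1])
        m2 = fit(coll2.matrices[sub2])
        between.append(geodesic_distance(m1, m2))
        w = []
        for coll, sub in ((coll1, sub1), (coll2, sub2)):
            halves = rng.permutation(sub)
            a = fit(coll.matrices[halves[:half]])
            b = fit(coll.matrices[halves[half : 2 * half]])
            w.append(geodesic_distance(a, b))
        within.append(float(np.mean(w)))
    between = np.asarray(between)
    within = np.asarray(within)
    if n_boot < 2:
        p_value = None
    else:
        p_value = float(
            stats.wilcoxon(between, within, alternative="greater").pvalue
        )
    return BootstrapDistanceResult(
        between=between, within=within, p_value=p_value, group_pair=(g1, g2)
    )


def _group_mean_difference(matrices, labels_mask, fit):
    """|difference| of group geodesic means for a boolean group-1 mask."""
    m1 = fit(matrices[labels_mask])
    m2 = fit(matrices[~labels_mask])
    return np.abs(m1 - m2)


def permutation_edge_selection(
    cohort: GroupedCohort,
    group_pair,
    n_permutations: int = 100,
    alpha: float = 0.001,
    method: str = "mspdnn",
    config: dict | None = None,
    seed: int = 0,
) -> EdgeSelection:
    """Permutation test of per-edge differences between group mean connectomes.

    The observed statistic per edge is the absolute entrywise difference of
    the two groups' geodesic means. The null is built by permuting group
    labels and re-estimating both means per shuffle. Per-edge p-values use
    the add-one estimator ``(1 + #{null >= observed}) / (1 + n_permutations)``
    and are Benjamini-Hochberg corrected at ``alpha`` over the strict upper
    triangle (the mask is mirrored; the diagonal is never selected).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    g1, g2 = group_pair
    idx = [i for i, lab in enumerate(cohort.collection.labels) if lab in (g1, g2)]
    sub = cohort.collection.subset(idx)
    mask = np.array([lab == g1 for lab in sub.labels])
    if mask.all() or not mask.any():
        raise ValueError("both groups must be nonempty")
    P = sub.dim
    fit = _mean_fitter(method, P, config)
    observed = _group_mean_difference(sub.matrices, mask, fit)
    rng = np.random.default_rng([seed, 5])
    exceed = np.zeros((P, P))
    for _ in range(n_permutations):
        perm = rng.permutation(mask)
        null = _group_mean_difference(sub.matrices, perm, fit)
        exceed += null >= observed
    p = (1.0 + exceed) / (1.0 + n_permutations)
    p = sym(p)  # statistic and permutations are symmetric; enforce exactly
    iu = np.triu_indices(P, k=1)
    rejected, _, _, _ = multipletests(p[iu], alpha=alpha, method="fdr_bh")[:4]
    selected = np.zeros((P, P), dtype=bool)
    selected[iu] = rejected
    selected = selected | selected.T
    np.fill_diagonal(p, 1.0)
    np.fill_diagonal(selected, False)
    return EdgeSelection(
        p_values=p,
        selected=selected,
        alpha=alpha,
        n_permutations=n_permutations,
        observed=observed,
    )


def _edge_features(collection: ConnectomeCollection, selected: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(collection.dim, k=1)
    keep = selected[iu]
    return collection.matrices[:, iu[0], iu[1]][:, keep]


def classify_with_selected_features(
    train: GroupedCohort,
    test: GroupedCohort,
    selection: EdgeSelection,
    classifier=None,
    seed: int = 0,
) -> dict:
    """Train a classifier on the selected connectome edges and score held-out data.

    Subjects are vectorized over the selected (upper-triangle) edges; the
    default classifier is a 100-tree random forest. Returns held-out accuracy
    and AUROC (AUROC ``None`` for more than two classes).
    """
    if not selection.selected.any():
        raise ValueError(
            "empty edge selection; relax alpha or increase permutations"
        )
    X_train = _edge_features(train.collection, selection.selected)
    X_test = _edge_features(test.collection, selection.selected)
    y_train = np.asarray(train.collection.labels)
    y_test = np.asarray(test.collection.labels)
    clf = classifier or RandomForestClassifier(n_estimators=100, random_state=seed)
    clf.fit(X_train, y_train)
    y_pred = clf.predict(X_test)
    out = {"accuracy": float(accuracy_score(y_test, y_pred)), "auroc": None}
    if len(clf.classes_) == 2 and hasattr(clf, "predict_proba"):
        scores = clf.predict_proba(X_test)[:, 1]
        out["auroc"] = float(roc_auc_score(y_test == clf.classes_[1], scores))
    return out


class GeodesicEM(BaseEstimator, ClusterMixin):
    """EM-style geodesic clustering of SPD matrices.

    The E-step assigns each subject to the geodesically nearest centroid
    (ties to the lowest cluster index); the M-step re-estimates each
    centroid as the geodesic mean of its members (mSPD-NN by default).
    Iteration stops when assignments no longer change or at ``max_iter``.
    An emptied cluster keeps its previous centroid (logged).

    Parameters
    ----------
    n_clusters : int, default 2
        Number of clusters when no explicit ``init_centroids`` are given
        (initialization then takes the first ``n_clusters`` distinct
        subjects spread by a seeded farthest-point heuristic).
    init_centroids : ndarray (K, P, P), optional
        Explicit SPD initialization; overrides ``n_clusters``.
    max_iter : int, default 20
    method : str, default "mspdnn"
        Mean estimator for the M-step.
    config : dict, optional
        Estimator config overrides.
    random_state : int, default 0

    Attributes
    ----------
    centroids_ : ndarray (K, P, P)
    labels_ : ndarray (N,)
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_clusters: int = 2,
        init_centroids=None,
        max_iter: int = 20,
        method: str = "mspdnn",
        config: dict | None = None,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.init_centroids = init_centroids
        self.max_iter = max_iter
        self.method = method
        self.config = config
        self.random_state = random_state

    def _init(self, matrices) -> np.ndarray:
        if self.init_centroids is not None:
            cents = np.asarray(self.init_centroids, dtype=float)
            if cents.ndim != 3 or cents.shape[-1] != matrices.shape[-1]:
                raise ValueError(
                    f"init_centroids shape {cents.shape} does not match data "
                    f"dimension {matrices.shape[-1]}"
                )
            return cents.copy()
        # farthest-point seeding in geodesic distance
        rng = np.random.default_rng([self.random_state, 7])
        first = int(rng.integers(len(matrices)))
        chosen = [first]
        while len(chosen) < self.n_clusters:
            dists = [
                min(geodesic_distance(m, matrices[c]) for c in chosen)
                for m in matrices
            ]
            chosen.append(int(np.argmax(dists)))
        return matrices[chosen].copy()

    def _assign(self, matrices, centroids) -> np.ndarray:
        d = np.array(
            [[geodesic_distance(m, c) for c in centroids] for m in matrices]
        )
        return d.argmin(axis=1)  # argmin takes the lowest index on ties

    def fit(self, X, y=None):
        if self.max_iter <= 0:
            raise ValueError("max_iter must be positive")
        matrices = (
            X.matrices if isinstance(X, ConnectomeCollection) else np.asarray(X, float)
        )
        centroids = self._init(matrices)
        K = len(centroids)
        P = matrices.shape[-1]
        fit_mean = _mean_fitter(self.method, P, self.config)
        assignments = self._assign(matrices, centroids)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            for k in range(K):
                members = matrices[assignments == k]
                if len(members) == 0:
                    logger.info("cluster %d empty at iteration %d; centroid kept", k, it)
                    continue
                centroids[k] = fit_mean(members)
            new_assignments = self._assign(matrices, centroids)
            if np.array_equal(new_assignments, assignments):
                converged = True
                break
            assignments = new_assignments
        self.centroids_ = centroids
        self.labels_ = assignments
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def predict(self, X):
        matrices = (
            X.matrices if isinstance(X, ConnectomeCollection) else np.asarray(X, float)
        )
        return self._assign(matrices, self.centroids_)


def mspd_em_cluster(
    collection,
    init_centroids=None,
    n_clusters: int = 2,
    max_iter: int = 20,
    method: str = "mspdnn",
    config: dict | None = None,
    random_state: int = 0,
) -> EMState:
    """Run :class:`GeodesicEM` and return an :class:`EMState`."""
    em = GeodesicEM(
        n_clusters=n_clusters,
        init_centroids=init_centroids,
        max_iter=max_iter,
        method=method,
        config=config,
        random_state=random_state,
    ).fit(collection)
    return EMState(
        centroids=em.centroids_,
        assignments=em.labels_,
        iteration=em.n_iter_,
        converged=em.converged_,
    )


def cluster_purity(assignments, labels) -> tuple[dict, float]:
    """Majority-vote purity per cluster and size-weighted overall purity.

    A cluster's purity is the fraction of its members carrying the cluster's
    modal true label. Empty clusters have undefined purity and are excluded
    from the overall average with a warning.
    """
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if assignments.shape != labels.shape:
        raise ValueError("assignments and labels must have equal length")
    per_cluster: dict = {}
    total = 0
    weighted = 0.0
    for k in np.unique(assignments):
        members = labels[assignments == k]
        values, counts = np.unique(members, return_counts=True)
        purity = counts.max() / len(members)
        per_cluster[int(k)] = float(purity)
        weighted += purity * len(members)
        total += len(members)
    n_clusters_seen = len(per_cluster)
    if n_clusters_seen == 0:
        warnings.warn("no nonempty clusters; purity undefined")
        return per_cluster, float("nan")
    return per_cluster, float(weighted / total)


def split_cohort(
    cohort: GroupedCohort, test_size: float = 0.9, seed: int = 0
) -> tuple[GroupedCohort, GroupedCohort]:
    """Seeded stratified train/test split of a labelled cohort."""
    if not 0 < test_size < 1:
        raise ValueError("test_size must lie in (0, 1)")
    rng = np.random.default_rng([seed, 13])
    labels = np.asarray(cohort.collection.labels)
    train_idx, test_idx = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_size * len(idx))))
        n_test = min(n_test, len(idx) - 1)
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return (
        GroupedCohort(cohort.collection.subset(sorted(train_idx))),
        GroupedCohort(cohort.collection.subset(sorted(test_idx))),
    )
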