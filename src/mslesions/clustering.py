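"""Stability-validated two-type lesion clustering.

The typing scheme is deliberately conservative: a candidate feature set is
accepted only if the 2-means partition it induces replicates in new data.
Replication is measured by the *prediction strength* of Tibshirani &
Walther: split the lesions into two random halves, cluster each half with
k-means (k=2), classify the test half by the training half's centroids, and
take the worst-case fraction of within-cluster pairs (in the test half's own
clustering) that the training classifier keeps together.  This is averaged
over 500 random splits, and significance is assessed against a permutation
null in which each feature column is shuffled independently across lesions
(destroying the multivariate cluster structure while preserving marginals).

Feature sets whose averaged prediction strength exceeds 0.8 in every lesion
location stratum are considered replicated; lesions are then labelled A/B by
nearest centroid, with the convention that B is the cluster with the lower
intra-neurite volume fraction centroid (lower FA as tie-break) — the more
damaged tissue type.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmeans import assign_nearest, lloyd_kmeans

__all__ = [
    "ClusterModel",
    "PSResult",
    "ScreenReport",
    "kmeans2",
    "assign_types",
    "prediction_strength",
    "ps_null_pvalue",
    "screen_metrics",
    "select_feature_sets",
    "labeling_agreement",
    "patient_burden",
]


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-derived child generator: reproducible and collision-free."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if feature_names is None else list(feature_names)
        return X[names].to_numpy(dtype=float), names
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j}" for j in range(X.shape[1])]
    )
    return X, names


def _standardize(X: np.ndarray, names: list[str]):
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    for j, s in enumerate(sds):
        if s == 0:
            raise ValueError(f"feature {names[j]!r} is constant (zero SD)")
    return (X - means) / sds, means, sds


@dataclass
class ClusterModel:
    """Standardization + k=2 centroids with the A/B label convention."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    centroids: np.ndarray  # (2, p), standardized space
    label_map: dict[int, str]  # cluster index -> "A"/"B"

    def centroids_raw(self) -> np.ndarray:
        return self.centroids * self.sds + self.means


@dataclass
class PSResult:
    """Replication evidence: per-split prediction strengths and summary."""

    splits: np.ndarray
    n_splits: int
    p_value: float | None = None
    null_ps: np.ndarray | None = None
    strata: dict = field(default_factory=dict)

    @property
    def mean_ps(self) -> float:
        return float(np.mean(self.splits))


def _ab_label_map(centroids_raw: np.ndarray, names: list[str]) -> dict[int, str]:
    # B = lower f_in centroid; tie-break lower FA; fall back to first feature
    for key in ("f_in", "FA", names[0]):
        if key in names:
            j = names.index(key)
            c0, c1 = centroids_raw[0, j], centroids_raw[1, j]
            if not np.isclose(c0, c1):
                b_idx = 0 if c0 < c1 else 1
                return {b_idx: "B", 1 - b_idx: "A"}
    return {0: "B", 1: "A"}  # fully degenerate: arbitrary but deterministic


def kmeans2(X, seed: int = 0, feature_names=None, n_restarts: int = 10) -> ClusterModel:
    """z-score the features and fit k-means with k=2 and multiple restarts."""
    M, names = _as_matrix(X, feature_names)
    if M.shape[0] < 4:
        raise ValueError("need at least 4 lesions to cluster")
    Z, means, sds = _standardize(M, names)
    centers, _, _ = lloyd_kmeans(Z, 2, rng=_child_rng(seed, 0), n_init=n_restarts)
    model = ClusterModel(names, means, sds, centers, {})
    model.label_map = _ab_label_map(model.centroids_raw(), names)
    return model


def assign_types(X, model: ClusterModel) -> np.ndarray:
    """Nearest-centroid A/B labels using the stored standardization.

    Deterministic; an exactly equidistant point goes to the lower-index
    centroid.
    """
    if isinstance(X, pd.DataFrame):
        missing = set(model.feature_names) - set(X.columns)
        if missing:
            raise ValueError(f"missing feature column(s): {sorted(missing)}")
    M, _ = _as_matrix(X, model.feature_names)
    Z = (M - model.means) / model.sds
    idx = assign_nearest(Z, model.centroids)
    return np.asarray([model.label_map[i] for i in idx])


# --------------------------------------------------------------------------
# prediction strength
# --------------------------------------------------------------------------

def _min_pair_agreement(own: np.ndarray, other: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Worst-case over own-clusters of the fraction of (ordered) pairs that
    ``other`` keeps co-assigned; clusters with <= 1 member contribute 1."""
    if mask is None:
        mask = np.ones(own.shape[0], dtype=bool)
    ps = 1.0
    for j in np.unique(own[mask]):
        members = mask & (own == j)
        n_j = int(members.sum())
        if n_j < 2:
            continue
        counts = np.bincount(other[members])
        agree = float(np.sum(counts * (counts - 1)))
        ps = min(ps, agree / (n_j * (n_j - 1)))
    return ps


def prediction_strength(
    X,
    n_splits: int = 500,
    seed: int = 0,
    n_restarts: int = 10,
    strata=None,
    feature_names=None,
    standardize: bool = True,
) -> PSResult:
    """Averaged prediction strength of the k=2 clustering over random
    half-splits.

    Each split randomly halves the lesions, clusters both halves, and
    evaluates pair-agreement in both train/test role assignments (averaged).
    Split-specific seeds are derived from ``seed`` by a counter scheme, so
    the result is reproducible and row-order invariant up to RNG pairing.

    With ``strata`` (a label per lesion), per-stratum prediction strengths
    are computed from the same pooled half-clusterings by restricting the
    pair-counting to the stratum's members.
    """
    M, names = _as_matrix(X, feature_names)
    n = M.shape[0]
    if n < 8:
        raise ValueError("need at least 8 lesions for half-splitting")
    if standardize:
        M, _, _ = _standardize(M, names)
    strata = None if strata is None else np.asarray(strata)
    stratum_names = [] if strata is None else list(pd.unique(strata))
    ps = np.empty(n_splits)
    ps_strat = {s: np.full(n_splits, np.nan) for s in stratum_names}
    for s in range(n_splits):
        rng = _child_rng(seed, s)
        perm = rng.permutation(n)
        halves = (perm[: n // 2], perm[n // 2:])
        fits = [
            lloyd_kmeans(M[h], 2, rng=rng, n_init=n_restarts) for h in halves
        ]
        vals = []
        strat_vals = {name: [] for name in stratum_names}
        for (train, test) in ((0, 1), (1, 0)):
            own = fits[test][1]
            other = assign_nearest(M[halves[test]], fits[train][0])
            vals.append(_min_pair_agreement(own, other))
            if strata is not None:
                labels_test = strata[halves[test]]
                for name in stratum_names:
                    strat_vals[name].append(
                        _min_pair_agreement(own, other, mask=labels_test == name)
                    )
        ps[s] = np.mean(vals)
        for name in stratum_names:
            ps_strat[name][s] = np.mean(strat_vals[name])
    result = PSResult(ps, n_splits)
    if strata is not None:
        result.strata = {
            name: PSResult(ps_strat[name], n_splits) for name in stratum_names
        }
    return result


def ps_null_pvalue(
    X,
    n_perms: int = 100,
    n_splits_null: int = 50,
    seed: int = 0,
    n_restarts: int = 10,
    feature_names=None,
) -> PSResult:
    """Permutation-null p-value for the observed mean prediction strength.

    Each permutation shuffles every feature column independently across
    lesions and recomputes the averaged prediction strength with
    ``n_splits_null`` splits; ``p = (1 + #{null >= observed}) / (1 + n_perms)``
    (add-one estimator, so p is bounded below by 1/(n_perms+1)).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    M, names = _as_matrix(X, feature_names)
    obs = prediction_strength(
        M, n_splits_null, seed=_child_seed(seed, 0), n_restarts=n_restarts,
        feature_names=names,
    )
    null = np.empty(n_perms)
    for p in range(n_perms):
        rng = _child_rng(seed, 1, p)
        Mp = np.column_stack(
            [M[rng.permutation(M.shape[0]), j] for j in range(M.shape[1])]
        )
        null[p] = prediction_strength(
            Mp, n_splits_null, seed=_child_seed(seed, 2, p),
            n_restarts=n_restarts, feature_names=names,
        ).mean_ps
    pval = (1.0 + float(np.sum(null >= obs.mean_ps))) / (1.0 + n_perms)
    return PSResult(obs.splits, n_splits_null, p_value=pval, null_ps=null)


# --------------------------------------------------------------------------
# metric screening and feature-set selection
# --------------------------------------------------------------------------

@dataclass
class ScreenReport:
    retained: list[str]
    discarded: list[str]
    ceiling_fraction: dict[str, float]
    cv: dict[str, float]
    correlations: pd.DataFrame


def screen_metrics(
    X: pd.DataFrame,
    fit_bounds: dict[str, float] | None = None,
    ceiling_frac: float = 0.30,
    cv_floor: float = 0.01,
    bound_atol: float = 1e-8,
) -> ScreenReport:
    """Discard near-degenerate metrics before clustering.

    A metric is discarded if more than ``ceiling_frac`` of its values sit at
    its fit upper bound (the boundary pile-up that makes a metric carry no
    contrast), or if its coefficient of variation falls below ``cv_floor``
    (constants included).  Also reports the pairwise correlation matrix.
    """
    fit_bounds = fit_bounds or {}
    ceil_f, cvs, retained, discarded = {}, {}, [], []
    for name in X.columns:
        v = X[name].to_numpy(dtype=float)
        bound = fit_bounds.get(name)
        frac = float(np.mean(v >= bound - bound_atol)) if bound is not None else 0.0
        mean = v.mean()
        cv = float(v.std(ddof=0) / abs(mean)) if mean != 0 else float(v.std(ddof=0))
        ceil_f[name], cvs[name] = frac, cv
        if frac > ceiling_frac or cv < cv_floor:
            discarded.append(name)
        else:
            retained.append(name)
    return ScreenReport(retained, discarded, ceil_f, cvs, X.corr())


def labeling_agreement(labels1, labels2) -> float:
    """Fraction of identical assignments, maximized over a label swap."""
    a = np.asarray(labels1)
    b = np.asarray(labels2)
    same = float(np.mean(a == b))
    return max(same, 1.0 - same)


def select_feature_sets(
    X: pd.DataFrame,
    candidate_sets=None,
    strata=None,
    ps_threshold: float = 0.8,
    n_splits: int = 100,
    seed: int = 0,
    min_stratum: int = 16,
    set_sizes: tuple[int, ...] = (3, 4, 5),
) -> pd.DataFrame:
    """Rank candidate feature sets by replicated clustering quality.

    For each set, the averaged prediction strength is computed overall and
    within each location stratum (pooled clustering, stratum-restricted pair
    counting; strata with fewer than ``min_stratum`` lesions are skipped
    with a warning column).  A set passes if the overall value and every
    evaluated stratum exceed ``ps_threshold``; passing sets are ranked by
    overall mean prediction strength, ties broken by smaller set size.
    """
    if candidate_sets is None:
        cols = list(X.columns)
        candidate_sets = [
            c for k in set_sizes for c in itertools.combinations(cols, k)
        ]
    if len(candidate_sets) == 0:
        raise ValueError("candidate_sets is empty")
    strata_arr = None if strata is None else np.asarray(strata)
    skipped = []
    if strata_arr is not None:
        counts = pd.Series(strata_arr).value_counts()
        skipped = [s for s in counts.index if counts[s] < min_stratum]
        eval_strata = np.where(np.isin(strata_arr, skipped), "_skipped", strata_arr)
    rows = []
    for i, fset in enumerate(candidate_sets):
        fset = list(fset)
        res = prediction_strength(
            X[fset], n_splits=n_splits, seed=_child_seed(seed, i),
            strata=None if strata_arr is None else eval_strata,
        )
        strat_ps = {
            f"ps_{name}": r.mean_ps
            for name, r in res.strata.items()
            if name != "_skipped"
        }
        passed = res.mean_ps > ps_threshold and all(
            v > ps_threshold for v in strat_ps.values()
        )
        rows.append(
            {
                "features": ",".join(fset),
                "n_features": len(fset),
                "mean_ps": res.mean_ps,
                **strat_ps,
                "passed": passed,
                "skipped_strata": ",".join(map(str, skipped)),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["passed", "mean_ps", "n_features"], ascending=[False, False, True]
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# patient-level burden
# --------------------------------------------------------------------------

def patient_burden(
    lesion_table: pd.DataFrame, patient_ids=None
) -> pd.DataFrame:
    """Per-patient, per-stratum burden of each lesion type.

    Expects columns ``patient_id``, ``location``, ``volume_mm3`` and
    ``type`` (A/B).  Returns one row per patient and stratum ("overall" plus
    each location present) with counts, volumes and B-type percentages by
    count and by volume; percentages are NaN (missing, not zero) when the
    patient has no lesions in the stratum.
    """
    if "type" not in lesion_table.columns:
        raise ValueError("lesion table lacks a 'type' column")
    if patient_ids is None:
        patient_ids = list(pd.unique(lesion_table["patient_id"]))
    strata = ["overall", *pd.unique(lesion_table["location"])]
    rows = []
    for pid in patient_ids:
        sub_p = lesion_table[lesion_table["patient_id"] == pid]
        for stratum in strata:
            sub = sub_p if stratum == "overall" else sub_p[sub_p["location"] == stratum]
            ca = int((sub["type"] == "A").sum())
            cb = int((sub["type"] == "B").sum())
            va = float(sub.loc[sub["type"] == "A", "volume_mm3"].sum())
            vb = float(sub.loc[sub["type"] == "B", "volume_mm3"].sum())
            rows.append(
                {
                    "patient_id": pid,
                    "stratum": stratum,
                    "count_A": ca,
                    "count_B": cb,
                    "volume_A_mm3": va,
                    "volume_B_mm3": vb,
                    "percent_B_count": 100.0 * cb / (ca + cb) if ca + cb else np.nan,
                    "percent_B_volume": 100.0 * vb / (va + vb) if va + vb else np.nan,
                }
            )
    return pd.DataFrame(rows)
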