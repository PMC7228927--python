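"""Unsupervised tissue segmentation: ICA + GMM with rule-based labelling.

The pipeline pools the normalized feature images of a cohort into an
observation matrix (rows = in-mask voxels of all subjects, columns = image
types), unmixes it with FastICA, orders the independent components by
normalized mutual information against the mean protocol image, clusters
the component scores with a full-covariance Gaussian mixture, and assigns
tissue labels to the clusters with a three-rule ruleset:

1. the cluster most extreme on the anchor component(s) is blood/edema;
2. each IC axis is reflected (sign-flipped) as needed so the blood/edema
   mean is component-wise non-negative — ICA does not fix source signs;
3. the remaining clusters are ranked by their (reflected) means on the
   ranking component: smallest = muscle, then muscle/connective, then
   necrosis/apoptosis, largest = active tumour.

The in-vivo formulation anchors on IC1 and ranks on IC2 (the default of
:func:`assign_cluster_labels`); the pipeline-level
:class:`TissueSegmenter` defaults to an adaptive variant that ranks on
the most mean-image-correlated component, where the tissue-graded axis
lands on synthetic cohorts (see the methods note).

The estimators follow scikit-learn conventions (`fit`/`transform`/
`predict`, `get_params`, fitted attributes with trailing underscores) and
compose with sklearn tooling; the module-level functions are thin wrappers
over them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.metrics import normalized_mutual_info_score
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_array, check_is_fitted

from .phantom import LABELS
from .preprocess import PreprocessedStudy, feature_name
from . import validation

__all__ = [
    "ObservationMatrix",
    "OrderedICA",
    "TissueSegmenter",
    "ClusterAssignment",
    "PROTOCOLS",
    "protocol_image_names",
    "build_observation_matrix",
    "fit_ica",
    "order_components",
    "select_n_clusters_bic",
    "fit_gmm",
    "assign_cluster_labels",
    "segment_cohort",
    "CohortSegmentation",
    "leave_one_out",
    "optimize_protocol",
    "feature_select",
]

#: Ranking of the four non-blood clusters by ascending (reflected) IC2 mean.
_IC2_RANK_LABELS = (
    LABELS["muscle"],
    LABELS["muscle_connective"],
    LABELS["necrosis_apoptosis"],
    LABELS["active_tumour"],
)


# ---------------------------------------------------------------------------
# observation matrix and protocols

PROTOCOLS = {
    "t1t2": ("maps",),
    "all_zspec": ("low_b1", "high_b1"),
    "low_b1": ("low_b1",),
    "high_b1": ("high_b1",),
    "t1t2_high_b1": ("maps", "high_b1"),
    "t1t2_low_b1": ("maps", "low_b1"),
    "t1t2_all": ("maps", "low_b1", "high_b1"),
}


def protocol_image_names(schedule, protocol: str) -> list[str]:
    """Feature-image names for one of the named imaging protocols."""
    if protocol not in PROTOCOLS:
        raise KeyError(f"unknown protocol {protocol!r}; options: {sorted(PROTOCOLS)}")
    names: list[str] = []
    parts = PROTOCOLS[protocol]
    if "maps" in parts:
        names += ["t1_norm", "t2_norm"]
    for role in ("low_b1", "high_b1"):
        if role in parts:
            for bi in schedule.blocks_with_role(role):
                blk = schedule.blocks[bi]
                names += [feature_name(blk.b1_uT, off) for off in blk.offsets_ppm]
    return names


@dataclass
class ObservationMatrix:
    """Voxels-by-image-types data matrix pooled over a cohort.

    Rows are in-mask voxels concatenated subject-by-subject (subjects in
    lexicographic subject_id order so the matrix is independent of input
    ordering); m equals the sum of per-subject voxel counts.
    """

    values: np.ndarray
    row_index: list  # of (subject_id, (iy, ix))
    column_names: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        if self.values.shape[0] != len(self.row_index):
            raise ValueError("row_index length mismatch")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observation matrix contains non-finite values")

    @property
    def subjects(self) -> list:
        seen = dict.fromkeys(sid for sid, _ in self.row_index)
        return list(seen)

    def rows_for(self, subject_id) -> np.ndarray:
        return np.array([i for i, (sid, _) in enumerate(self.row_index)
                         if sid == subject_id], dtype=int)


def build_observation_matrix(studies: list[PreprocessedStudy],
                             image_names: list[str]) -> ObservationMatrix:
    """Pool the named feature images of all studies into one matrix."""
    ids = [s.subject_id for s in studies]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in cohort")
    blocks, row_index = [], []
    for s in sorted(studies, key=lambda s: s.subject_id):
        if not s.eroded_mask.any():
            raise ValueError(f"empty eroded mask for subject {s.subject_id}")
        blocks.append(s.feature_matrix(image_names))
        coords = np.argwhere(s.eroded_mask)
        row_index += [(s.subject_id, (int(iy), int(ix))) for iy, ix in coords]
    return ObservationMatrix(np.vstack(blocks), row_index, list(image_names))


# ---------------------------------------------------------------------------
# ICA with NMI ordering


def _binned(signal: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(signal.min()), float(signal.max())
    if hi <= lo:
        return np.zeros(signal.shape, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(signal, edges[1:-1]), 0, n_bins - 1)


def _nmi(a: np.ndarray, b: np.ndarray, n_bins: int) -> float:
    """NMI between two continuous signals after equal-width binning,
    normalized by the arithmetic mean of the entropies; 0 when either
    signal is constant."""
    ba, bb = _binned(a, n_bins), _binned(b, n_bins)
    if len(np.unique(ba)) < 2 or len(np.unique(bb)) < 2:
        return 0.0
    return float(normalized_mutual_info_score(ba, bb, average_method="arithmetic"))


class OrderedICA(TransformerMixin, BaseEstimator):
    """FastICA whose components are ordered by mutual information.

    After the fixed-point (parallel, log-cosh) FastICA fit, each component
    is scored by normalized mutual information against the voxel-wise mean
    of the input images and the components are re-labelled IC1..ICk in
    ascending NMI, so IC1 is the component least related to overall image
    intensity.

    Parameters
    ----------
    n_components : int
        Number of independent components; must not exceed the number of
        input images.
    n_bins : int
        Equal-width bins used to discretize signals for the NMI score.

    Attributes
    ----------
    ica_ : fitted ``sklearn.decomposition.FastICA``
    order_ : ndarray — permutation applied to the raw components
    mi_scores_ : ndarray — NMI scores, ascending
    components_ : ndarray (k, n) — ordered unmixing matrix (of the whitened
        pipeline, as exposed by FastICA)
    mixing_ : ndarray (n, k) — ordered mixing matrix
    """

    def __init__(self, n_components: int = 3, n_bins: int = 32,
                 max_iter: int = 500, tol: float = 1e-6, random_state: int = 0):
        self.n_components = n_components
        self.n_bins = n_bins
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        if self.n_components > X.shape[1]:
            raise ValueError(
                f"n_components={self.n_components} exceeds the number of "
                f"image types ({X.shape[1]}): the number of unique image "
                "types must be at least the number of ICs"
            )
        if X.shape[0] < 10 * self.n_components:
            raise ValueError("too few voxels for a stable ICA fit")
        self.ica_ = FastICA(
            n_components=self.n_components, algorithm="parallel", fun="logcosh",
            whiten="unit-variance", max_iter=self.max_iter, tol=self.tol,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # occasional convergence warnings
            scores = self.ica_.fit_transform(X)
        mean_image = X.mean(axis=1)
        mi = np.array([_nmi(scores[:, j], mean_image, self.n_bins)
                       for j in range(self.n_components)])
        self.order_ = np.argsort(mi, kind="stable")
        self.mi_scores_ = mi[self.order_]
        self.components_ = self.ica_.components_[self.order_]
        self.mixing_ = self.ica_.mixing_[:, self.order_]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "order_")
        X = check_array(X)
        return self.ica_.transform(X)[:, self.order_]


# ---------------------------------------------------------------------------
# GMM and model selection


def fit_gmm(ic_scores: np.ndarray, k: int = 5, seed: int = 0,
            n_init: int = 10, reg_covar: float = 1e-6, tol: float = 1e-6,
            max_iter: int = 500) -> GaussianMixture:
    """EM-fitted full-covariance Gaussian mixture (best of seeded restarts)."""
    gm = GaussianMixture(
        n_components=k, covariance_type="full", n_init=n_init,
        init_params="k-means++", reg_covar=reg_covar, tol=tol,
        max_iter=max_iter, random_state=seed,
    )
    with warnings.catch_warnings():
        # the tight EM tolerance occasionally trips sklearn's convergence
        # warning without affecting the selected restart
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(ic_scores)
    return gm


def select_n_clusters_bic(ic_scores: np.ndarray, k_max: int = 10, seed: int = 0,
                          f: float = 0.05, n_init: int = 3):
    """Optimal cluster count from the gradient of the BIC.

    GMMs are fit for k = 1..k_max; the BIC gradient dBIC(k) = BIC(k) -
    BIC(k-1) falls sharply until the optimal k and is then relatively
    flat.  The rule returns the smallest k such that every later gradient
    is below ``f`` times the maximum gradient magnitude.

    Returns ``(k_star, bic_values)``.
    """
    ic_scores = np.asarray(ic_scores)
    if ic_scores.shape[0] < 20 * k_max:
        raise ValueError("need at least 20*k_max samples for BIC selection")
    bics = np.array([
        fit_gmm(ic_scores, k, seed=seed, n_init=n_init).bic(ic_scores)
        for k in range(1, k_max + 1)
    ])
    # improvement from adding the k-th cluster; positive gradients (pure
    # penalty growth on structureless data) count as zero improvement
    drops = np.maximum(-np.diff(bics), 0.0)
    if drops.max() <= 0.0:
        return 1, bics
    thresh = f * drops.max()
    k_star = k_max
    for k in range(1, k_max + 1):
        if np.all(drops[k - 1:] < thresh):
            k_star = k
            break
    else:
        warnings.warn("BIC gradient never flattens; returning k_max")
    return int(k_star), bics


# ---------------------------------------------------------------------------
# label assignment


@dataclass
class ClusterAssignment:
    """Record of the rule-based cluster -> tissue-label assignment."""

    cluster_to_label: dict
    reflections: np.ndarray  # +/-1 per IC axis
    reflected_means: np.ndarray
    tie_warnings: list = field(default_factory=list)

    def labels_for(self, cluster_indices: np.ndarray) -> np.ndarray:
        lut = np.zeros(max(self.cluster_to_label) + 1, dtype=np.int32)
        for c, l in self.cluster_to_label.items():
            lut[c] = l
        return lut[cluster_indices]


def assign_cluster_labels(gmm: GaussianMixture, n_labels: int = 5,
                          ranking_component: int = 1,
                          anchor_components=None) -> ClusterAssignment:
    """Apply the labelling ruleset to a 5-cluster mixture in IC space.

    The ruleset has three steps: (1) the cluster most extreme (largest
    absolute GMM mean) on the anchor component(s) is blood/edema; (2) IC
    axes are reflected (sign-flipped) as needed so the blood/edema mean is
    component-wise non-negative — ICA does not identify source signs; (3)
    the remaining clusters are ranked by their reflected means on the
    ranking component: smallest = muscle, second = muscle/connective,
    second-largest = necrosis/apoptosis, largest = active tumour.

    With the defaults (anchor on IC1, rank on IC2) this reproduces the
    ruleset as published for the in-vivo cohort.  The pipeline-level
    segmenter instead anchors on all non-ranking components and ranks on
    the last (most mean-image-correlated) component, which is where the
    tissue-graded axis consistently lands on synthetic cohorts (see the
    methods note).

    Reflections flip whole IC axes (data, means, and the corresponding
    covariance rows/columns together), which leaves cluster membership
    unchanged; they only orient the axes so the ranking is well-defined.
    """
    means = np.asarray(gmm.means_)
    k, n_ics = means.shape
    if k != n_labels:
        raise ValueError(f"label ruleset requires exactly {n_labels} clusters, got {k}")
    if n_ics < 2:
        raise ValueError("label ruleset requires at least 2 ICs")
    ranking_component = range(n_ics)[ranking_component]  # normalize negatives
    if anchor_components is None:
        anchor_components = (0,)
    anchor_components = [range(n_ics)[a] for a in anchor_components]
    if ranking_component in anchor_components:
        raise ValueError("ranking component cannot also anchor blood/edema")
    ties = []

    anchor_extreme = np.abs(means[:, anchor_components]).max(axis=1)
    blood = int(np.argmax(anchor_extreme))
    if np.sum(anchor_extreme == anchor_extreme[blood]) > 1:
        ties.append("tie in blood/edema anchor extremity; broken by cluster index")
        warnings.warn(ties[-1])

    signs = np.where(means[blood] < 0, -1.0, 1.0)
    reflected = means * signs

    rest = [c for c in range(k) if c != blood]
    rank_vals = reflected[rest, ranking_component]
    if len(np.unique(rank_vals)) < len(rank_vals):
        ties.append("tie in ranking-component means; broken by cluster index")
        warnings.warn(ties[-1])
    ranked = [rest[i] for i in np.argsort(rank_vals, kind="stable")]

    mapping = {blood: LABELS["blood_edema"]}
    for cluster, label in zip(ranked, _IC2_RANK_LABELS):
        mapping[cluster] = label
    return ClusterAssignment(mapping, signs, reflected, ties)


# ---------------------------------------------------------------------------
# the end-to-end estimator


class TissueSegmenter(BaseEstimator):
    """ICA + GMM tissue segmenter with rule-based label assignment.

    ``fit`` learns the ICA basis, the component order, the Gaussian
    mixture, and the cluster -> tissue-label mapping from pooled cohort
    voxels; ``predict`` labels new voxels (e.g. a held-out subject) with
    the trained model.

    Attributes
    ----------
    ica_ : fitted :class:`OrderedICA`
    gmm_ : fitted ``GaussianMixture``
    assignment_ : :class:`ClusterAssignment`
    labels_ : tissue labels of the training voxels
    """

    def __init__(self, n_components: int = 3, n_clusters: int = 5,
                 n_bins: int = 32, n_init: int = 10, reg_covar: float = 1e-6,
                 label_mode: str = "adaptive", tol: float = 1e-6,
                 max_iter: int = 500, ica_max_iter: int = 500,
                 ica_tol: float = 1e-6, random_state: int = 0):
        self.n_components = n_components
        self.n_clusters = n_clusters
        self.n_bins = n_bins
        self.n_init = n_init
        self.reg_covar = reg_covar
        self.label_mode = label_mode
        self.tol = tol
        self.max_iter = max_iter
        self.ica_max_iter = ica_max_iter
        self.ica_tol = ica_tol
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.label_mode not in ("adaptive", "published"):
            raise ValueError("label_mode must be 'adaptive' or 'published'")
        self.ica_ = OrderedICA(
            n_components=self.n_components, n_bins=self.n_bins,
            max_iter=self.ica_max_iter, tol=self.ica_tol,
            random_state=self.random_state,
        ).fit(X)
        scores = self.ica_.transform(X)
        self.gmm_ = fit_gmm(scores, self.n_clusters, seed=self.random_state,
                            n_init=self.n_init, reg_covar=self.reg_covar,
                            tol=self.tol, max_iter=self.max_iter)
        if self.label_mode == "adaptive":
            # rank on the most mean-correlated IC (last after NMI ordering);
            # anchor blood/edema on the remaining components
            ranking = self.n_components - 1
            anchors = tuple(range(self.n_components - 1))
        else:
            ranking, anchors = 1, (0,)
        self.assignment_ = assign_cluster_labels(
            self.gmm_, self.n_clusters, ranking_component=ranking,
            anchor_components=anchors)
        self.labels_ = self.assignment_.labels_for(self.gmm_.predict(scores))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "assignment_")
        scores = self.ica_.transform(X)
        return self.assignment_.labels_for(self.gmm_.predict(scores))

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def fit_ica(matrix: ObservationMatrix | np.ndarray, k: int, seed: int = 0) -> OrderedICA:
    """Fit the NMI-ordered ICA on an observation matrix."""
    X = matrix.values if isinstance(matrix, ObservationMatrix) else matrix
    return OrderedICA(n_components=k, random_state=seed).fit(X)


def order_components(transform: OrderedICA, matrix: ObservationMatrix | np.ndarray) -> OrderedICA:
    """Recompute the NMI ordering of a fitted transform on given data."""
    X = matrix.values if isinstance(matrix, ObservationMatrix) else matrix
    scores = transform.ica_.transform(X)
    mean_image = X.mean(axis=1)
    mi = np.array([_nmi(scores[:, j], mean_image, transform.n_bins)
                   for j in range(scores.shape[1])])
    transform.order_ = np.argsort(mi, kind="stable")
    transform.mi_scores_ = mi[transform.order_]
    transform.components_ = transform.ica_.components_[transform.order_]
    transform.mixing_ = transform.ica_.mixing_[:, transform.order_]
    return transform


# ---------------------------------------------------------------------------
# cohort-level operations


@dataclass
class CohortSegmentation:
    """Per-subject label maps plus the trained model that produced them."""

    segmenter: TissueSegmenter
    matrix: ObservationMatrix
    label_maps: dict  # subject_id -> 2D int array (0 = background)

    def necrosis_fractions(self) -> dict:
        return {sid: validation.necrosis_fraction(lm)
                for sid, lm in self.label_maps.items()}


def _row_flat_indices(matrix: ObservationMatrix, shapes: dict) -> dict:
    """Per-subject (row slice, flat voxel indices) lookup, computed once."""
    out = {}
    sids = np.array([sid for sid, _ in matrix.row_index])
    coords = np.array([c for _, c in matrix.row_index])
    for sid, shape in shapes.items():
        rows = np.flatnonzero(sids == sid)
        flat = coords[rows, 0] * shape[1] + coords[rows, 1]
        out[sid] = (rows, flat)
    return out


def _labels_to_maps(matrix: ObservationMatrix, labels: np.ndarray,
                    shapes: dict, lookup: dict | None = None) -> dict:
    if lookup is None:
        lookup = _row_flat_indices(matrix, shapes)
    maps = {}
    for sid, shape in shapes.items():
        rows, flat = lookup[sid]
        lm = np.zeros(shape[0] * shape[1], dtype=np.int32)
        lm[flat] = labels[rows]
        maps[sid] = lm.reshape(shape)
    return maps


def segment_cohort(studies: list[PreprocessedStudy], protocol,
                   k_ics: int = 3, k_clusters: int = 5, seed: int = 0,
                   n_init: int = 10) -> CohortSegmentation:
    """Run the full segmentation pipeline on a preprocessed cohort.

    ``protocol`` is either one of the named protocols (see ``PROTOCOLS``)
    or an explicit list of feature-image names.
    """
    if isinstance(protocol, str):
        image_names = protocol_image_names(studies[0].schedule, protocol)
    else:
        image_names = list(protocol)
    if len(image_names) < k_ics:
        raise ValueError(
            f"protocol has {len(image_names)} images but {k_ics} ICs requested: "
            "the number of unique image types must be at least the number of ICs"
        )
    matrix = build_observation_matrix(studies, image_names)
    seg = TissueSegmenter(n_components=k_ics, n_clusters=k_clusters,
                          n_init=n_init, random_state=seed)
    labels = seg.fit_predict(matrix.values)
    shapes = {s.subject_id: s.eroded_mask.shape for s in studies}
    return CohortSegmentation(seg, matrix, _labels_to_maps(matrix, labels, shapes))


def leave_one_out(studies: list[PreprocessedStudy], protocol, k_ics: int = 3,
                  k_clusters: int = 5, seed: int = 0, n_init: int = 10,
                  reference: CohortSegmentation | None = None):
    """Leave-one-out robustness of the segmentation pipeline.

    For each subject the model (ICA basis, IC order, GMM, label
    assignment) is trained on the remaining subjects and applied to the
    held-out one; the resulting label map is compared with the
    whole-cohort segmentation by multi-class Dice.

    Returns a DataFrame with one row per subject (subject_id, dice,
    flagged) — flagged marks training runs whose label assignment emitted
    tie warnings (degenerate cluster geometry).
    """
    if len(studies) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    if reference is None:
        reference = segment_cohort(studies, protocol, k_ics, k_clusters, seed,
                                   n_init=n_init)
    image_names = reference.matrix.column_names
    rows = []
    for held in sorted(studies, key=lambda s: s.subject_id):
        train = [s for s in studies if s.subject_id != held.subject_id]
        train_matrix = build_observation_matrix(train, image_names)
        seg = TissueSegmenter(n_components=k_ics, n_clusters=k_clusters,
                              n_init=n_init, random_state=seed)
        seg.fit(train_matrix.values)
        labels = seg.predict(held.feature_matrix(image_names))
        lo_map = np.zeros(held.eroded_mask.shape, dtype=np.int32)
        lo_map[held.eroded_mask] = labels
        _, mean_dice = validation.dice(lo_map, reference.label_maps[held.subject_id])
        rows.append({
            "subject_id": held.subject_id,
            "dice": mean_dice,
            "flagged": bool(seg.assignment_.tie_warnings),
        })
    return pd.DataFrame(rows)


def optimize_protocol(studies: list[PreprocessedStudy], reference_fractions: dict,
                      candidate_protocols=None, ics_range=(2, 3, 4), seed: int = 0,
                      k_clusters: int = 5, n_init: int = 10):
    """Select the imaging protocol whose necrosis fraction best tracks the
    reference (histology or phantom truth) fractions.

    Returns ``(best_protocol, best_k_ics, table)`` where the table has one
    row per feasible (protocol, k_ics) with the Pearson correlation
    between machine-learning and reference necrosis fractions.
    """
    protocols = list(candidate_protocols or PROTOCOLS)
    subjects = sorted(reference_fractions)
    ref = np.array([reference_fractions[s] for s in subjects], dtype=float)
    rows = []
    for prot in protocols:
        names = protocol_image_names(studies[0].schedule, prot) \
            if isinstance(prot, str) else list(prot)
        for k_ics in ics_range:
            if len(names) < k_ics:
                continue  # infeasible: fewer images than ICs
            seg = segment_cohort(studies, names, k_ics, k_clusters, seed,
                                 n_init=n_init)
            ml = np.array([validation.necrosis_fraction(seg.label_maps[s])
                           for s in subjects])
            ok = np.isfinite(ml) & np.isfinite(ref)
            rho, p = (validation.pearson_r(ml[ok], ref[ok])
                      if ok.sum() >= 3 else (float("nan"), float("nan")))
            rows.append({"protocol": prot, "k_ics": k_ics, "rho": rho, "p": p})
    table = pd.DataFrame(rows)
    if table.empty or table["rho"].isna().all():
        raise ValueError("no feasible (protocol, k_ics) combination produced a "
                         "necrosis-fraction correlation")
    best = table.loc[table["rho"].idxmax()]
    return best["protocol"], int(best["k_ics"]), table


def feature_select(studies: list[PreprocessedStudy], reference: CohortSegmentation,
                   subset_sizes=range(3, 10), pool=None, seed: int = 0,
                   budget: int = 100_000, max_fit_rows: int | None = None,
                   n_init: int = 2, rank_ics: int = 3):
    """Search image subsets that reproduce the full-protocol segmentation.

    For each subset size an exhaustive search over combinations from
    ``pool`` is performed (greedy forward search past ``budget``
    candidates); each subset is scored by the mean multi-class Dice of its
    segmentation against the reference label maps.  ``max_fit_rows``
    subsamples the voxels used for model fitting (all voxels are still
    labelled and scored).

    Returns ``(scores, summary)``: ``scores`` maps size -> DataFrame of
    (subset, dice) for every evaluated candidate; ``summary`` has one row
    per size with the best subset and its PPV/NPV for the active-tumour
    and necrosis/apoptosis labels.
    """
    pool = list(pool or reference.matrix.column_names)
    matrix = build_observation_matrix(sorted(studies, key=lambda s: s.subject_id), pool)
    col = {name: j for j, name in enumerate(pool)}
    shapes = {s.subject_id: s.eroded_mask.shape for s in studies}
    lookup = _row_flat_indices(matrix, shapes)
    # reference labels as per-subject row vectors, aligned with the matrix
    ref_vecs = {sid: reference.label_maps[sid].ravel()[flat]
                for sid, (_rows, flat) in lookup.items()}
    rng = np.random.default_rng(seed)
    m = matrix.values.shape[0]
    fit_rows = (np.sort(rng.choice(m, size=max_fit_rows, replace=False))
                if max_fit_rows and max_fit_rows < m else slice(None))

    def score(names) -> float:
        idx = [col[n] for n in names]
        X = matrix.values[:, idx]
        # search-grade solver budget: uninformative subsets otherwise run
        # EM/ICA to their iteration caps without changing the ranking
        seg = TissueSegmenter(n_components=rank_ics, n_clusters=5,
                              n_init=n_init, tol=1e-3, max_iter=100,
                              ica_max_iter=200, ica_tol=1e-4,
                              random_state=seed)
        seg.fit(X[fit_rows])
        labels = seg.predict(X)
        ds = []
        for sid, (rows, _flat) in lookup.items():
            pred = labels[rows]
            ref = ref_vecs[sid]
            per = []
            for lab in np.union1d(np.unique(pred), np.unique(ref)):
                if lab == 0:
                    continue
                a = pred == lab
                b = ref == lab
                per.append(2.0 * np.sum(a & b) / (a.sum() + b.sum()))
            ds.append(np.mean(per) if per else np.nan)
        return float(np.nanmean(ds))

    scores, summary_rows = {}, []
    for size in subset_sizes:
        if size < rank_ics:
            raise ValueError("subset size below the number of ICs is infeasible")
        n_combos = _n_combinations(len(pool), size)
        if n_combos <= budget:
            candidates = itertools.combinations(pool, size)
        else:
            candidates = _greedy_candidates(pool, size, score)
        rows = [{"subset": tuple(c), "dice": score(c)} for c in candidates]
        df = pd.DataFrame(rows).sort_values("dice", ascending=False,
                                            ignore_index=True)
        scores[size] = df
        best = df.iloc[0]
        maps = _best_maps(matrix, col, best["subset"], shapes, reference, seed,
                          n_init, rank_ics, fit_rows)
        pv = {}
        for tissue in ("active_tumour", "necrosis_apoptosis"):
            lab = LABELS[tissue]
            ppv, npv = _pooled_predictive_values(maps, reference.label_maps, lab)
            pv[f"ppv_{tissue}"] = ppv
            pv[f"npv_{tissue}"] = npv
        summary_rows.append({"n_images": size, "subset": best["subset"],
                             "dice": best["dice"], **pv})
    return scores, pd.DataFrame(summary_rows)


def _n_combinations(n: int, k: int) -> int:
    import math
    return math.comb(n, k)


def _greedy_candidates(pool, size, score):
    """Greedy forward selection: returns the single best-growing chain."""
    chosen: list = []
    while len(chosen) < size:
        best_name, best_val = None, -np.inf
        for name in pool:
            if name in chosen:
                continue
            cand = chosen + [name]
            if len(cand) < 3:
                # cannot segment with fewer images than ICs; defer scoring
                val = 0.0
            else:
                val = score(cand)
            if val > best_val:
                best_name, best_val = name, val
        chosen.append(best_name)
    return [tuple(chosen)]


def _best_maps(matrix, col, subset, shapes, reference, seed, n_init, rank_ics,
               fit_rows):
    idx = [col[n] for n in subset]
    X = matrix.values[:, idx]
    seg = TissueSegmenter(n_components=rank_ics, n_clusters=5, n_init=n_init,
                          tol=1e-3, max_iter=100, ica_max_iter=200,
                          ica_tol=1e-4, random_state=seed)
    seg.fit(X[fit_rows])
    return _labels_to_maps(matrix, seg.predict(X), shapes)


def _pooled_predictive_values(pred_maps: dict, ref_maps: dict, label: int):
    tp = fp = tn = fn = 0
    for sid in pred_maps:
        c = validation.confusion_counts(pred_maps[sid], ref_maps[sid], label)
        tp += c.tp
        fp += c.fp
        tn += c.tn
        fn += c.fn
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return ppv, npv
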