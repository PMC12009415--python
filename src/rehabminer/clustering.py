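"""Cluster relation-dictionary entries: TF-IDF -> PCA -> kmeans++ -> silhouette.

Each disease becomes one document — the list of its value phrases (symptoms
or measures).  By default every whole phrase is a term ("phrase" mode; the
values are short curated phrases, so splitting them into words is an
opt-in).  TF-IDF down-weights phrases that occur for most diseases (a
ubiquitous term like "treatment" carries little cluster signal), PCA
removes noise dimensions, and seeded kmeans++ with Lloyd refinement
partitions the diseases.  Partitions are scored by the silhouette
coefficient s = (b - a) / max(a, b), averaged over points; per cluster
count k the clustering is repeated (default 5 times), the mean silhouette
recorded and the lowest-inertia run kept.

Default cluster counts per dictionary kind are DS=15, SFD=20, NSFD=6; a
k-grid scan maximising mean silhouette is available instead, with the
caveat that silhouette tends to grow with k so a cap is advisable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.feature_extraction.text import TfidfVectorizer

from .knowledge_base import RelationDictionary

__all__ = [
    "DEFAULT_K",
    "DocVectors",
    "ClusterReport",
    "vectorize",
    "reduce",
    "kmeans_plus_plus_init",
    "lloyd",
    "kmeanspp_cluster",
    "silhouette",
    "select_k_and_report",
]

DEFAULT_K = {"DS": 15, "SFD": 20, "NSFD": 6}


@dataclass
class DocVectors:
    diseases: list[str]
    matrix: np.ndarray            # (n_docs, n_terms), L2-normalised rows
    terms: list[str]


@dataclass
class ClusterReport:
    k: int
    assignments: dict[str, int]
    centers: np.ndarray
    inertia: float
    silhouette_mean: float
    per_k_trace: dict[int, float] = field(default_factory=dict)
    summaries: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# vectorization and reduction


def vectorize(dictionary: RelationDictionary, term_mode: str = "phrase") -> DocVectors:
    """TF-IDF document vectors, one document per disease.

    tf = raw count, idf = ln((1+N)/(1+df)) + 1 (smoothed), rows
    L2-normalised.  ``term_mode="phrase"`` treats each whole value phrase as
    one term; ``"word"`` splits phrases on whitespace.
    """
    if len(dictionary.entries) < 2:
        raise ValueError("need at least two diseases to vectorize")
    diseases = list(dictionary.entries)
    if term_mode == "phrase":
        docs = [list(dictionary.entries[d]) for d in diseases]
        analyzer = lambda doc: doc  # noqa: E731
    elif term_mode == "word":
        docs = [
            [w for phrase in dictionary.entries[d] for w in phrase.split()]
            for d in diseases
        ]
        analyzer = lambda doc: doc  # noqa: E731
    else:
        raise ValueError(f"unknown term_mode {term_mode!r}")
    vec = TfidfVectorizer(analyzer=analyzer, norm="l2", smooth_idf=True,
                          sublinear_tf=False)
    matrix = vec.fit_transform(docs).toarray()
    return DocVectors(diseases=diseases, matrix=matrix,
                      terms=list(vec.get_feature_names_out()))


def reduce(
    matrix: np.ndarray,
    n_components: int | None = None,
    variance_target: float = 0.95,
) -> np.ndarray:
    """Mean-centred PCA.

    Default: the smallest component count explaining >= ``variance_target``
    of the variance, capped at min(50, n-1).  Zero-variance input is
    returned unchanged with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least two vectors")
    centered = matrix - matrix.mean(axis=0)
    if not np.any(centered):
        warnings.warn("zero-variance input: PCA skipped, identity mapping")
        return matrix.copy()
    cap = min(50, n - 1, matrix.shape[1])
    if n_components is None:
        pca = PCA(n_components=cap, svd_solver="full")
        reduced = pca.fit_transform(matrix)
        cum = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, variance_target) + 1)
        return reduced[:, :keep]
    pca = PCA(n_components=min(n_components, matrix.shape[1], n), svd_solver="full")
    return pca.fit_transform(matrix)


# ---------------------------------------------------------------------------
# kmeans++ / Lloyd


def kmeans_plus_plus_init(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """D^2 seeding: each next centre sampled with probability proportional
    to its squared distance from the nearest centre chosen so far."""
    n = X.shape[0]
    centers = [X[int(rng.integers(n))]]
    for _ in range(1, k):
        d2 = cdist(X, np.array(centers), metric="sqeuclidean").min(axis=1)
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centres
            centers.append(X[int(rng.integers(n))])
            continue
        centers.append(X[int(rng.choice(n, p=d2 / total))])
    return np.array(centers)


def lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd refinement to convergence; inertia never increases.

    An emptied cluster is re-seeded at the point farthest from its centre
    assignment.
    """
    centers = centers.copy()
    prev_inertia = np.inf
    for _ in range(max_iter):
        d2 = cdist(X, centers, metric="sqeuclidean")
        assign = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(X)), assign].sum())
        assert inertia <= prev_inertia + 1e-9, "Lloyd inertia increased"
        for j in range(len(centers)):
            members = X[assign == j]
            if len(members) == 0:
                farthest = int(d2[np.arange(len(X)), assign].argmax())
                centers[j] = X[farthest]
                assign[farthest] = j
            else:
                centers[j] = members.mean(axis=0)
        if prev_inertia - inertia <= tol:
            prev_inertia = inertia
            break
        prev_inertia = inertia
    d2 = cdist(X, centers, metric="sqeuclidean")
    assign = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(X)), assign].sum())
    return assign, centers, inertia


def silhouette(X: np.ndarray, assignments: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-point silhouette s = (b - a)/max(a, b) and the mean.

    a = mean distance to the other members of the point's cluster; b = the
    smallest mean distance to the members of any other cluster.  Points in
    singleton clusters score 0.
    """
    X = np.asarray(X, dtype=float)
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if len(labels) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    dist = cdist(X, X)
    s = np.zeros(len(X))
    for i in range(len(X)):
        own = assignments[i]
        same = (assignments == own) & (np.arange(len(X)) != i)
        if not same.any():
            s[i] = 0.0  # singleton convention
            continue
        a = dist[i, same].mean()
        b = min(
            dist[i, assignments == other].mean()
            for other in labels
            if other != own
        )
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s, float(s.mean())


def kmeanspp_cluster(
    vectors: DocVectors | np.ndarray,
    k: int,
    n_repeats: int = 5,
    seed: int = 0,
) -> ClusterReport:
    """Best-of-``n_repeats`` kmeans++ runs (lowest inertia kept).

    The reported ``silhouette_mean`` is the across-repeat average for this
    k — the evaluation protocol of repeating each setting five times and
    averaging the silhouette coefficient.
    """
    if isinstance(vectors, DocVectors):
        X = vectors.matrix
        names = vectors.diseases
    else:
        X = np.asarray(vectors, dtype=float)
        names = [str(i) for i in range(len(X))]
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n (k={k}, n={n})")
    rng = np.random.default_rng(seed)
    best = None
    sils = []
    for _ in range(n_repeats):
        centers0 = kmeans_plus_plus_init(X, k, rng)
        assign, centers, inertia = lloyd(X, centers0)
        if len(np.unique(assign)) >= 2 and k < n:
            sils.append(silhouette(X, assign)[1])
        elif k == n:
            sils.append(0.0)  # all singletons
        if best is None or inertia < best[2] - 1e-12:
            best = (assign, centers, inertia)
    assign, centers, inertia = best
    return ClusterReport(
        k=k,
        assignments={name: int(c) for name, c in zip(names, assign)},
        centers=centers,
        inertia=inertia,
        silhouette_mean=float(np.mean(sils)) if sils else 0.0,
    )


# ---------------------------------------------------------------------------
# model selection and reporting


def _summaries(
    vectors: DocVectors, reduced_assign: np.ndarray, k: int
) -> list[dict]:
    """Per-cluster disease lists and the terms they share most strongly."""
    out = []
    mat = vectors.matrix
    for j in range(k):
        member_idx = np.where(reduced_assign == j)[0]
        diseases = [vectors.diseases[i] for i in member_idx]
        if len(member_idx):
            mean_w = mat[member_idx].mean(axis=0)
            top = np.argsort(mean_w)[::-1][:5]
            shared = [vectors.terms[t] for t in top if mean_w[t] > 0]
        else:
            shared = []
        out.append({"cluster": j, "n_diseases": len(diseases),
                    "diseases": diseases, "shared_terms": shared})
    return out


def select_k_and_report(
    dictionary: RelationDictionary,
    fixed_k: int | None = None,
    k_grid: list[int] | None = None,
    n_repeats: int = 5,
    seed: int = 0,
    term_mode: str = "phrase",
) -> ClusterReport:
    """Cluster one dictionary end to end and build its report.

    Without ``fixed_k`` or ``k_grid`` the kind-specific default cluster
    count (DS=15, SFD=20, NSFD=6) is used.  With a grid, the k with the
    highest mean silhouette wins.  The largest cluster is marked
    "residual" in the summaries when its mean silhouette is negative.
    """
    vectors = vectorize(dictionary, term_mode=term_mode)
    X = reduce(vectors.matrix)
    n = X.shape[0]
    trace: dict[int, float] = {}
    if k_grid:
        grid = [k for k in k_grid if 2 <= k <= n - 1]
        if not grid:
            raise ValueError("no feasible k in grid")
        best_k, best_sil = None, -np.inf
        for k in grid:
            rep = kmeanspp_cluster(X, k, n_repeats=n_repeats, seed=seed)
            trace[k] = rep.silhouette_mean
            if rep.silhouette_mean > best_sil:
                best_k, best_sil = k, rep.silhouette_mean
        k = best_k
    else:
        k = fixed_k if fixed_k is not None else DEFAULT_K[dictionary.kind]
        if k > n:
            raise ValueError(
                f"k={k} exceeds the {dictionary.kind} dictionary size n={n}"
            )
    report = kmeanspp_cluster(X, k, n_repeats=n_repeats, seed=seed)
    report.per_k_trace = trace
    assign = np.array([report.assignments[str(i)] for i in range(n)])
    report.assignments = {d: int(a) for d, a in zip(vectors.diseases, assign)}
    report.summaries = _summaries(vectors, assign, k)
    if len(np.unique(assign)) >= 2 and k < n:
        per_point, _ = silhouette(X, assign)
        sizes = [(s["n_diseases"], s["cluster"]) for s in report.summaries]
        largest = max(sizes)[1]
        members = assign == largest
        if members.any() and per_point[members].mean() < 0:
            report.summaries[largest]["residual"] = True
    return report


def report_to_rows(report: ClusterReport) -> list[dict]:
    """Flatten a report into CSV-ready rows (category, count, names, terms)."""
    rows = []
    for s in report.summaries:
        rows.append(
            {
                "category": s["cluster"],
                "n_diseases": s["n_diseases"],
                "diseases": "; ".join(s["diseases"]),
                "shared_terms": "; ".join(s["shared_terms"]),
                "residual": bool(s.get("residual", False)),
            }
        )
    return rows
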