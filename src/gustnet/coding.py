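"""Breadth of tuning, chemosensitive clustering, and ensemble analysis.

Three breadth-of-tuning measures are computed per neuron and condition: the
number of stimuli passing the response criterion; the noise:signal (N:S)
ratio, i.e. second-best over best net response (umami cocktail excluded via
the panel); and the entropy

    H = -1.43 * sum_i P_i * log10(P_i)

where P_i is the proportion of the summed responses arising from stimulus i.
With K = 1.43 ~ 1/log10(5), a perfectly uniform five-stimulus profile gives
H ~ 1 and a one-stimulus profile gives H ~ 0. Because the measure cannot
accommodate zeros or negative numbers, responses <= 0 are replaced by a very
small positive value before forming the proportions.

Profile similarity uses Pearson correlation: hierarchical clustering on
1 - r distances with average linkage, per-neuron cross-condition profile
correlations, and across-neuron stimulus correlations embedded by classical
(Torgerson) multidimensional scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .core import StimulusPanel, ValidationError
from .responses import ResponseProfile

__all__ = [
    "TuningMetrics",
    "ClusterResult",
    "EnsemblePattern",
    "ENTROPY_K",
    "tuning_metrics",
    "cluster_profiles",
    "profile_stability",
    "ensemble_mds",
    "classical_mds",
]

ENTROPY_K = 1.43


@dataclass
class TuningMetrics:
    unit_id: str
    light_condition: str
    n_significant: int
    ns_ratio: float  # NaN when undefined (best response <= 0)
    entropy_h: float  # NaN when the cell is entirely unresponsive
    proportions: np.ndarray  # the P_i entering H, in panel order

    @property
    def defined(self) -> bool:
        return not math.isnan(self.entropy_h)


def entropy_h(responses, eps_factor: float = 1e-6) -> tuple[float, np.ndarray]:
    """Breadth-of-tuning entropy of a net-response vector.

    Responses <= 0 are substituted with ``eps_factor`` times the sum of the
    positive responses (a documented reading of "a very small value"); the
    vector is then renormalized to proportions. Returns (H, P).
    """
    r = np.asarray(responses, dtype=float)
    if r.size < 2:
        raise ValidationError("entropy needs >= 2 responses")
    pos_sum = r[r > 0].sum()
    if pos_sum <= 0:
        return float("nan"), np.full(r.size, np.nan)
    r = np.where(r > 0, r, eps_factor * pos_sum)
    p = r / r.sum()
    h = -ENTROPY_K * float(np.sum(p * np.log10(p)))
    return h, p


def noise_signal_ratio(responses) -> float:
    """Second-best over best response, negatives floored at zero.

    NaN when the best response is not positive (ratio undefined).
    """
    r = np.maximum(np.asarray(responses, dtype=float), 0.0)
    if r.size < 2:
        raise ValidationError("N:S ratio needs >= 2 responses")
    order = np.sort(r)[::-1]
    if order[0] <= 0:
        return float("nan")
    return float(order[1] / order[0])


def tuning_metrics(
    profile: ResponseProfile,
    condition: str,
    panel: StimulusPanel | None = None,
    eps_factor: float = 1e-6,
) -> TuningMetrics:
    """All three breadth-of-tuning measures for one neuron and condition."""
    panel = panel or profile.panel
    vec = profile.vector(condition, panel.labels)
    if np.isnan(vec).any():
        raise ValidationError(
            f"{profile.unit_id}: missing responses for {condition!r}"
        )
    h, p = entropy_h(vec, eps_factor)
    ns_vec = profile.vector(condition, panel.ns_labels)
    ns = noise_signal_ratio(ns_vec)
    return TuningMetrics(
        unit_id=profile.unit_id,
        light_condition=condition,
        n_significant=profile.n_significant(condition),
        ns_ratio=ns,
        entropy_h=h,
        proportions=p,
    )


@dataclass
class ClusterResult:
    unit_ids: list[str]
    excluded_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix; heights in 1 - r units
    condition: str

    @property
    def scree(self) -> np.ndarray:
        """Amalgamation distances, in merge order (consult to choose k)."""
        return self.linkage[:, 2]

    def labels(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.unit_ids, (int(x) for x in flat)))

    def largest_gap_k(self) -> int:
        """Optional heuristic: cut at the largest jump in the scree."""
        heights = self.scree
        if heights.size < 2:
            return 1
        gap = np.diff(heights)
        return int(heights.size - np.argmax(gap))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.unit_ids[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def cluster_profiles(
    profiles: list[ResponseProfile],
    condition: str = "control",
) -> ClusterResult:
    """Average-linkage hierarchical clustering on 1 - Pearson-r distances.

    Zero-variance (constant) profiles have no defined correlation and are
    excluded with a warning entry, mirroring the documented handling of a
    single outlying neuron omitted from the clustering process.
    """
    if len(profiles) < 3:
        raise ValidationError("clustering needs >= 3 profiles")
    rows, ids, excluded = [], [], []
    for p in profiles:
        vec = p.vector(condition)
        if np.isnan(vec).any() or np.std(vec) == 0:
            excluded.append(p.unit_id)
            continue
        rows.append(vec)
        ids.append(p.unit_id)
    if len(rows) < 3:
        raise ValidationError("fewer than 3 usable (nonconstant) profiles")
    X = np.vstack(rows)
    dist = pdist(X, metric="correlation")  # 1 - Pearson r
    Z = hierarchy.linkage(dist, method="average")
    return ClusterResult(unit_ids=ids, excluded_ids=excluded, linkage=Z, condition=condition)


def cluster_mean_profiles(
    profiles: list[ResponseProfile],
    labels: dict[str, int],
    condition: str = "control",
) -> dict[int, np.ndarray]:
    """Mean net-response profile of each flat cluster, in panel order."""
    by_label: dict[int, list[np.ndarray]] = {}
    for p in profiles:
        if p.unit_id in labels:
            by_label.setdefault(labels[p.unit_id], []).append(p.vector(condition))
    return {k: np.mean(np.vstack(v), axis=0) for k, v in sorted(by_label.items())}


def profile_stability(
    profiles: list[ResponseProfile],
    cond_a: str = "control",
    cond_b: str = "light_br",
) -> dict[str, float]:
    """Per-unit Pearson r between response profiles in the two conditions.

    A zero-variance vector leaves r undefined; such units map to NaN.
    """
    out: dict[str, float] = {}
    for p in profiles:
        a, b = p.vector(cond_a), p.vector(cond_b)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
            out[p.unit_id] = float("nan")
            continue
        out[p.unit_id] = float(pearsonr(a, b)[0])
    return out


def classical_mds(distances: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS by eigendecomposition.

    Double-centers the squared distance matrix and embeds on the leading
    eigenvectors. Coordinates are centered; each axis's sign is fixed so the
    first point has a nonnegative coordinate. Deterministic.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be square and symmetric")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    for ax in range(coords.shape[1]):
        if coords[0, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    return coords


@dataclass
class EnsemblePattern:
    """Across-neuron stimulus correlations and their MDS embedding."""

    stimuli: tuple[str, ...]
    conditions: tuple[str, ...]
    correlations: np.ndarray  # (s*c) x (s*c) symmetric, unit diagonal
    coordinates: np.ndarray  # (s*c) x dims
    index: list[tuple[str, str]] = field(default_factory=list)  # (stimulus, condition)

    def corr(self, pair_a: tuple[str, str], pair_b: tuple[str, str]) -> float:
        i, j = self.index.index(pair_a), self.index.index(pair_b)
        return float(self.correlations[i, j])

    def cross_condition(self) -> dict[str, float]:
        """Within-stimulus correlation between the two conditions."""
        if len(self.conditions) != 2:
            raise ValidationError("cross-condition correlations need exactly 2 conditions")
        a, b = self.conditions
        return {s: self.corr((s, a), (s, b)) for s in self.stimuli}

    def coords_for(self, stimulus: str, condition: str) -> np.ndarray:
        return self.coordinates[self.index.index((stimulus, condition))]


def ensemble_mds(
    profiles: list[ResponseProfile],
    conditions=("control", "light_br"),
    dims: int = 2,
) -> EnsemblePattern:
    """Across-neuron taste-space analysis.

    Each stimulus x condition defines a vector of net responses across
    neurons; Pearson correlations between these vectors give the ensemble
    similarity structure, embedded by classical MDS on 1 - r distances.
    """
    if len(profiles) < 3:
        raise ValidationError("ensemble analysis needs >= 3 neurons")
    panel = profiles[0].panel
    stimuli = panel.labels
    vectors, index = [], []
    for cond in conditions:
        mat = np.vstack([p.vector(cond) for p in profiles])  # neurons x stimuli
        if np.isnan(mat).any():
            raise ValidationError(f"missing responses under {cond!r}")
        for j, s in enumerate(stimuli):
            vectors.append(mat[:, j])
            index.append((s, cond))
    V = np.vstack(vectors)
    sd = V.std(axis=1)
    if np.any(sd == 0):
        flat = [index[i] for i in np.nonzero(sd == 0)[0]]
        raise ValidationError(f"zero-variance across-neuron vectors: {flat}")
    R = np.corrcoef(V)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    coords = classical_mds(D, dims=dims)
    return EnsemblePattern(
        stimuli=stimuli,
        conditions=tuple(conditions),
        correlations=R,
        coordinates=coords,
        index=index,
    )
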