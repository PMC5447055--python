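"""Cluster-validity indices and the optimal-k report.

Three families of criteria for choosing the number of subregions k:

* consistency across parcellations -- Cramer's V, Dice coefficient,
  normalized mutual information (NMI) and variation of information (VI),
  evaluated over resampled pairs of parcellations (split-half, pairwise,
  leave-one-out);
* consistency within a parcellation -- mean silhouette value under the
  cosine distance on native connectivity profiles, and the continuity
  index (mean fraction of each cluster occupied by its largest connected
  component, for 6/18/26-connectivity);
* consistency of topology -- the hierarchy index (mean probability that a
  cluster at k descends from a single cluster at k-1) and the topological
  distance (cosine distance between row-normalized 26-neighbor contact
  matrices, e.g. between hemispheres).

All entropies use the natural logarithm; NMI is base-invariant and VI is
reported in nats.  The suggested k is the majority vote over each index's
favorable local extrema (interior points of the k range only, since an
endpoint has an unobserved neighbor), with VI contributing the k values
flagged by its stability rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .group import match_labels
from .maps import maximum_probability_map, probability_maps
from .parcellate import Parcellation

__all__ = [
    "FrequencyTable",
    "InformationSummary",
    "SilhouetteBreakdown",
    "ContactMatrix",
    "ValidityReport",
    "SuggestedK",
    "overlap_table",
    "cramers_v",
    "dice",
    "information_summary",
    "nmi",
    "vi",
    "silhouette",
    "continuity_index",
    "hierarchy_index",
    "contact_matrix",
    "topological_distance",
    "split_half",
    "pairwise",
    "leave_one_out",
    "stability_profile",
    "validity_report",
    "suggest_k",
]


# ---------------------------------------------------------------------------
# frequency table and across-parcellation indices


@dataclass
class FrequencyTable:
    """Cluster-overlap counts between two labelings on a common domain.

    ``t[i, j]`` counts voxels with label ``a_labels[i]`` in A and
    ``b_labels[j]`` in B, over voxels labeled (nonzero) in both.
    """

    t: np.ndarray  # (m, n) int64
    a_labels: np.ndarray
    b_labels: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.t.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.t.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.t.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.t.shape


def _labels_of(x) -> np.ndarray:
    if isinstance(x, Parcellation):
        return x.to_volume().data
    return np.asarray(x)


def overlap_table(a, b) -> FrequencyTable:
    """Frequency table of two labelings restricted to their common domain."""
    a = _labels_of(a).ravel()
    b = _labels_of(b).ravel()
    if a.shape != b.shape:
        raise ValueError("labelings must live on the same voxel grid")
    domain = (a > 0) & (b > 0)
    if not domain.any():
        raise ValueError("labelings have no common labeled voxels")
    a, b = a[domain], b[domain]
    a_labels, ai = np.unique(a, return_inverse=True)
    b_labels, bi = np.unique(b, return_inverse=True)
    t = np.zeros((len(a_labels), len(b_labels)), dtype=np.int64)
    np.add.at(t, (ai, bi), 1)
    return FrequencyTable(t, a_labels, b_labels)


def cramers_v(table: FrequencyTable) -> float:
    """Cramer's V: sqrt(chi^2 / (N * min(m - 1, n - 1))), in [0, 1].

    1 indicates a perfect match.  Cells with zero expected count are
    skipped in chi^2.  Two single-cluster labelings on the same domain
    get V = 1; a single-cluster labeling against a multi-cluster one has
    no defined association strength and raises.
    """
    t = table.t.astype(np.float64)
    m, n = t.shape
    if m == 1 or n == 1:
        if m == n == 1:
            return 1.0
        raise ValueError("Cramer's V undefined when one labeling has a "
                         "single cluster and the other does not")
    big_n = t.sum()
    expected = np.outer(table.row_sums, table.col_sums) / big_n
    mask = expected > 0
    chi2 = (((t - expected) ** 2)[mask] / expected[mask]).sum()
    v2 = chi2 / (big_n * min(m - 1, n - 1))
    return float(np.sqrt(min(v2, 1.0)))


def dice(a, b, k: int | None = None) -> float:
    """Mean per-cluster Dice overlap, assuming corresponding labels.

    2|A_i ∩ B_i| / (|A_i| + |B_i|) averaged over clusters 1..k; a cluster
    empty in both parcellations contributes 1, empty in exactly one
    contributes 0.  1 indicates the same parcellation.  Label-sensitive
    by design: parcellations must be relabeled consistently first.
    """
    av = _labels_of(a).ravel()
    bv = _labels_of(b).ravel()
    if av.shape != bv.shape:
        raise ValueError("labelings must live on the same voxel grid")
    ka = int(av.max(initial=0))
    kb = int(bv.max(initial=0))
    if k is None:
        if isinstance(a, Parcellation) and isinstance(b, Parcellation):
            if a.k != b.k:
                raise ValueError(f"cluster counts differ: {a.k} vs {b.k}")
            k = a.k
        else:
            k = max(ka, kb)
    total = 0.0
    for c in range(1, k + 1):
        in_a = av == c
        in_b = bv == c
        na, nb = int(in_a.sum()), int(in_b.sum())
        if na + nb == 0:
            total += 1.0
        else:
            total += 2.0 * int((in_a & in_b).sum()) / (na + nb)
    return total / k


@dataclass
class InformationSummary:
    """Entropies and mutual information of a frequency table (nats)."""

    h_a: float
    h_b: float
    mi: float


def information_summary(table: FrequencyTable) -> InformationSummary:
    """Plug-in entropies and mutual information (natural log, 0 log 0 = 0)."""
    p = table.t / table.n_total
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def _ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    nz = p > 0
    mi = float(
        (p[nz] * np.log(p[nz] / np.outer(pa, pb)[nz])).sum()
    )
    return InformationSummary(_ent(pa), _ent(pb), max(mi, 0.0))


def nmi(table: FrequencyTable) -> float:
    """Normalized mutual information 2 I / (H(A) + H(B)) in [0, 1].

    The (H(A)+H(B))/2 normalizer is a tight upper bound on I.  Two
    single-cluster labelings (zero entropy on both sides) get 1.
    """
    s = information_summary(table)
    denom = s.h_a + s.h_b
    if denom == 0:
        return 1.0
    return 2.0 * s.mi / denom


def vi(table: FrequencyTable) -> float:
    """Variation of information H(A) + H(B) - 2 I, in nats (>= 0);
    0 means identical partitions, lower is more stable."""
    s = information_summary(table)
    return max(s.h_a + s.h_b - 2.0 * s.mi, 0.0)


# ---------------------------------------------------------------------------
# within-parcellation indices


@dataclass
class SilhouetteBreakdown:
    a: np.ndarray  # mean cosine distance to own cluster (excluding self)
    b: np.ndarray  # min mean cosine distance to another cluster
    s: np.ndarray  # per-voxel silhouette values in [-1, 1]
    mean: float


def silhouette(native: np.ndarray, labels: np.ndarray) -> SilhouetteBreakdown:
    """Mean silhouette of a parcellation under cosine distance.

    s_i = (b_i - a_i) / max(a_i, b_i) from the cosine distances between
    native connectivity rows; voxels in singleton clusters get s_i = 0,
    and distances involving an all-zero row are 1 by convention.
    """
    x = np.asarray(native, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    if x.shape[0] != labels.size:
        raise ValueError("one native row per labeled voxel required")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    norms = np.linalg.norm(x, axis=1)
    zero = norms <= 0
    xn = np.where(zero[:, None], 0.0, x / np.where(zero, 1.0, norms)[:, None])
    d = 1.0 - xn @ xn.T
    d[zero, :] = 1.0
    d[:, zero] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)

    n = len(labels)
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in clusters}
    for i in range(n):
        own = members[labels[i]]
        others = [c for c in clusters if c != labels[i]]
        b[i] = min(d[i, members[c]].mean() for c in others)
        if len(own) == 1:
            s[i] = 0.0  # singleton convention
            continue
        a[i] = d[i, own[own != i]].mean()
        denom = max(a[i], b[i])
        s[i] = 0.0 if denom == 0 else (b[i] - a[i]) / denom
    return SilhouetteBreakdown(a, b, s, float(s.mean()))


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def continuity_index(p, connectivity: int = 26) -> float:
    """Mean, over clusters, of (largest connected component) / (cluster
    size); 1 means every cluster is a single spatial continuum."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    vol = _labels_of(p)
    if vol.ndim != 3:
        raise ValueError("continuity needs a 3D label volume")
    structure = _STRUCTURES[connectivity]
    fractions = []
    for c in np.unique(vol[vol > 0]):
        mask = vol == c
        comp, n_comp = ndimage.label(mask, structure=structure)
        sizes = np.bincount(comp.ravel())[1:]
        fractions.append(sizes.max() / mask.sum())
    if not fractions:
        raise ValueError("no labeled voxels")
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# topology indices


def hierarchy_index(pk, pkm1) -> float:
    """Mean over clusters of the k solution of the fraction of its voxels
    inherited from its single largest parent in the k-1 solution; 1 means
    a perfect hierarchy (strict refinement)."""
    table = overlap_table(pk, pkm1)
    x = table.t.astype(np.float64)
    row = x.sum(axis=1)
    return float((x.max(axis=1) / row).mean())


@dataclass
class ContactMatrix:
    """26-neighbor region adjacency counts and their row-normalized form.

    ``raw[i, j]`` = number of voxels of region i+1 with at least one
    26-neighbor in region j+1 (diagonal excluded); rows of ``normalized``
    sum to 1 unless the region touches nothing (all-zero row kept).
    """

    raw: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.int64)
        sums = self.raw.sum(axis=1, keepdims=True).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(sums > 0, self.raw / np.where(sums > 0, sums, 1.0), 0.0)
        self.normalized = norm


def contact_matrix(p, k: int | None = None) -> ContactMatrix:
    """Region-contact counts under the 26-neighborhood."""
    from .maps import _shift  # same zero-padded shift used for MPM neighbors

    vol = _labels_of(p)
    if k is None:
        k = int(vol.max(initial=0))
    touch = np.zeros((k,) + vol.shape, dtype=bool)
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        shifted = _shift(vol, off)
        for j in range(1, k + 1):
            touch[j - 1] |= shifted == j
    raw = np.zeros((k, k), dtype=np.int64)
    for i in range(1, k + 1):
        region = vol == i
        for j in range(1, k + 1):
            if i == j:
                continue
            raw[i - 1, j - 1] = int((region & touch[j - 1]).sum())
    return ContactMatrix(raw)


def topological_distance(left, right) -> float:
    """Cosine distance of the vectorized row-normalized contact matrices.

    0 means identical topological arrangement; if either contact pattern
    is empty the distance is 1 by convention.  Labels must already be
    harmonized across the two parcellations.
    """
    cl = left if isinstance(left, ContactMatrix) else contact_matrix(left)
    cr = right if isinstance(right, ContactMatrix) else contact_matrix(right)
    if cl.normalized.shape != cr.normalized.shape:
        raise ValueError("contact matrices must have the same cluster count")
    u = cl.normalized.ravel()
    v = cr.normalized.ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 1.0
    return float(np.clip(1.0 - u @ v / (nu * nv), 0.0, 1.0))


# ---------------------------------------------------------------------------
# resampling drivers

_ACROSS = ("cv", "dice", "nmi", "vi")


def _across_indices(a_vol: np.ndarray, b_vol: np.ndarray, k: int
                    ) -> dict[str, float]:
    table = overlap_table(a_vol, b_vol)
    try:
        cv = cramers_v(table)
    except ValueError:
        # one side collapsed to a single cluster on the common domain
        # (possible for unstable k in resampled MPMs): no association
        cv = 0.0
    return {
        "cv": cv,
        "dice": dice(a_vol, b_vol, k=k),
        "nmi": nmi(table),
        "vi": vi(table),
    }


def _half_mpm(parcellations: list[Parcellation]) -> np.ndarray:
    return maximum_probability_map(probability_maps(parcellations)).volume.data


def split_half(
    parcellations: list[Parcellation],
    n_reps: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Reproducibility indices between MPMs of random half-cohorts.

    Each repetition splits the subjects into two random halves (odd n:
    the first half takes the extra subject), builds an MPM per half,
    aligns the second MPM's labels to the first by optimal assignment,
    and evaluates CV, Dice, NMI and VI between the two MPMs.
    """
    n = len(parcellations)
    if n < 4:
        raise ValueError("split-half needs at least 4 subjects")
    k = parcellations[0].k
    rng = np.random.default_rng(seed)
    out: dict[str, list[float]] = {name: [] for name in _ACROSS}
    n_first = (n + 1) // 2
    for _ in range(n_reps):
        order = rng.permutation(n)
        half1 = [parcellations[i] for i in order[:n_first]]
        half2 = [parcellations[i] for i in order[n_first:]]
        m1 = _half_mpm(half1)
        m2 = _half_mpm(half2)
        both = (m1 > 0) & (m2 > 0)
        if both.any():
            perm = match_labels(m1[both], m2[both], k=k)
            relabeled = np.zeros_like(m2)
            mask = m2 > 0
            relabeled[mask] = perm[m2[mask] - 1]
            m2 = relabeled
        for name, value in _across_indices(m1, m2, k).items():
            out[name].append(value)
    return {name: np.asarray(vals) for name, vals in out.items()}


def pairwise(parcellations: list[Parcellation]) -> dict[str, np.ndarray]:
    """Indices over all n(n-1)/2 subject pairs, parcellations compared
    directly (labels assumed already consistent)."""
    n = len(parcellations)
    if n < 2:
        raise ValueError("pairwise needs at least 2 subjects")
    k = parcellations[0].k
    vols = [p.to_volume().data for p in parcellations]
    out: dict[str, list[float]] = {name: [] for name in _ACROSS}
    for i in range(n):
        for j in range(i + 1, n):
            for name, value in _across_indices(vols[i], vols[j], k).items():
                out[name].append(value)
    return {name: np.asarray(vals) for name, vals in out.items()}


def leave_one_out(parcellations: list[Parcellation]) -> dict[str, np.ndarray]:
    """Indices between each subject and the MPM of the remaining subjects."""
    n = len(parcellations)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    k = parcellations[0].k
    out: dict[str, list[float]] = {name: [] for name in _ACROSS}
    for s in range(n):
        rest = parcellations[:s] + parcellations[s + 1:]
        mpm = _half_mpm(rest)
        subj = parcellations[s].to_volume().data
        for name, value in _across_indices(subj, mpm, k).items():
            out[name].append(value)
    return {name: np.asarray(vals) for name, vals in out.items()}


# ---------------------------------------------------------------------------
# optimal-k report


def stability_profile(
    ks: list[int], vi_means: np.ndarray, sd_factor: float = 1.0
) -> tuple[list[int], np.ndarray]:
    """VI stability rule over a contiguous k range.

    A solution k is flagged stable when the VI increase from k to k+1 is
    considerable (above mean + sd_factor * sd of all increments) while
    the increase from k-1 to k is not above the mean.  Returns the
    flagged k values and the increment series dVI(k) = VI(k+1) - VI(k).
    """
    vi_means = np.asarray(vi_means, dtype=np.float64)
    if len(ks) < 3 or len(vi_means) != len(ks):
        raise ValueError("need VI means over at least 3 contiguous k values")
    dvi = np.diff(vi_means)
    mean = dvi.mean()
    sd = dvi.std(ddof=1)
    flags = []
    for idx, k in enumerate(ks[:-1]):
        considerable = dvi[idx] > mean + sd_factor * sd
        previous_ok = idx == 0 or dvi[idx - 1] <= mean
        if considerable and previous_ok:
            flags.append(k)
    return flags, dvi


def _local_extrema(ks: list[int], values: np.ndarray, maximize: bool
                   ) -> list[int]:
    """Interior local extrema (endpoints excluded: a k with an unobserved
    neighbor cannot be called a peak)."""
    v = np.asarray(values, dtype=np.float64)
    if not maximize:
        v = -v
    out = []
    for i in range(1, len(v) - 1):
        left, mid, right = v[i - 1], v[i], v[i + 1]
        if (mid > left and mid >= right) or (mid >= left and mid > right):
            out.append(ks[i])
    return out


@dataclass
class ValidityReport:
    """Summary table (index, k, scheme, mean, sd, n) plus raw replicates."""

    table: pd.DataFrame
    replicates: dict = field(default_factory=dict)

    def series(self, index: str, scheme: str | None = None
               ) -> tuple[list[int], np.ndarray]:
        sub = self.table[self.table["index"] == index]
        if scheme is not None:
            sub = sub[sub["scheme"] == scheme]
        elif sub["scheme"].nunique() > 1:
            order = ["split_half", "pairwise", "leave_one_out", "subjects",
                     "group"]
            for sch in order:
                if (sub["scheme"] == sch).any():
                    sub = sub[sub["scheme"] == sch]
                    break
        sub = sub.sort_values("k")
        return list(sub["k"]), sub["mean"].to_numpy()


@dataclass
class SuggestedK:
    k: int | None
    votes: dict[str, list[int]]


_VOTE_DIRECTION = {
    "cv": True,
    "dice": True,
    "nmi": True,
    "silhouette": True,
    "continuity_26": True,
    "hi": True,
    "tpd": False,
}


def suggest_k(report: ValidityReport, vi_sd_factor: float = 1.0) -> SuggestedK:
    """Majority vote over each index's favorable k values.

    Peaked indices vote with their interior local maxima (minima for
    TpD); VI votes with the k values flagged by :func:`stability_profile`.
    The suggestion is the mode of all votes (smallest k on ties) and is
    advisory only -- the full vote table is returned alongside.
    """
    votes: dict[str, list[int]] = {}
    indices = report.table["index"].unique()
    for name, maximize in _VOTE_DIRECTION.items():
        if name not in indices:
            continue
        ks, means = report.series(name)
        if len(ks) >= 3:
            votes[name] = _local_extrema(ks, means, maximize)
    if "vi" in indices:
        ks, means = report.series("vi")
        if len(ks) >= 3:
            flags, _ = stability_profile(ks, means, sd_factor=vi_sd_factor)
            votes["vi"] = flags
    pool = [k for vs in votes.values() for k in vs]
    if not pool:
        return SuggestedK(None, votes)
    counts: dict[int, int] = {}
    for k in pool:
        counts[k] = counts.get(k, 0) + 1
    best = max(counts.values())
    suggested = min(k for k, c in counts.items() if c == best)
    return SuggestedK(suggested, votes)


def validity_report(
    relabeled_by_k: dict[int, list[Parcellation]],
    natives: list[np.ndarray] | None = None,
    schemes: tuple[str, ...] = ("split_half", "pairwise", "leave_one_out"),
    n_reps: int = 100,
    seed: int = 0,
) -> ValidityReport:
    """Evaluate the full index suite over a range of k.

    ``relabeled_by_k[k]`` holds one consistently-labeled parcellation per
    subject; ``natives`` (one native connectivity matrix per subject)
    enables the silhouette rows.  Resampling schemes whose subject-count
    preconditions are not met are silently omitted.
    """
    ks = sorted(relabeled_by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k values must form a contiguous range")
    drivers = {
        "split_half": lambda ps: split_half(ps, n_reps=n_reps, seed=seed),
        "pairwise": pairwise,
        "leave_one_out": leave_one_out,
    }
    minimum = {"split_half": 4, "pairwise": 2, "leave_one_out": 3}
    rows = []
    replicates: dict = {}
    mpm_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        parcs = relabeled_by_k[k]
        n = len(parcs)
        for scheme in schemes:
            if n < minimum[scheme]:
                continue
            values = drivers[scheme](parcs)
            for name, vals in values.items():
                replicates[(name, k, scheme)] = vals
                rows.append(
                    dict(index=name, k=k, scheme=scheme, mean=vals.mean(),
                         sd=vals.std(ddof=1) if len(vals) > 1 else 0.0,
                         n=len(vals))
                )
        if natives is not None:
            sil = np.array(
                [silhouette(natives[s], parcs[s].labels).mean
                 for s in range(n)]
            )
            replicates[("silhouette", k, "subjects")] = sil
            rows.append(
                dict(index="silhouette", k=k, scheme="subjects",
                     mean=sil.mean(),
                     sd=sil.std(ddof=1) if n > 1 else 0.0, n=n)
            )
        for conn in (6, 18, 26):
            cont = np.array(
                [continuity_index(p, connectivity=conn) for p in parcs]
            )
            replicates[(f"continuity_{conn}", k, "subjects")] = cont
            rows.append(
                dict(index=f"continuity_{conn}", k=k, scheme="subjects",
                     mean=cont.mean(),
                     sd=cont.std(ddof=1) if n > 1 else 0.0, n=n)
            )
        mpm_by_k[k] = _half_mpm(parcs)
        if k - 1 in mpm_by_k:
            hi = hierarchy_index(mpm_by_k[k], mpm_by_k[k - 1])
            replicates[("hi", k, "group")] = np.array([hi])
            rows.append(
                dict(index="hi", k=k, scheme="group", mean=hi, sd=0.0, n=1)
            )
    return ValidityReport(pd.DataFrame(rows), replicates)
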