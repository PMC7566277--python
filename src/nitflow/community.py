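"""Succession analytics on ASV count tables.

Rarefied alpha diversity (richness, Shannon, Pielou), Bray-Curtis beta
diversity, non-metric multidimensional scaling, Ward+elbow successional
staging, indicator-taxon analysis with a point-biserial association
index, and dissimilarity structure over sampling time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

__all__ = [
    "CommunityTable",
    "StageAssignment",
    "OrdinationResult",
    "rarefy_diversity",
    "rarefied_mean_table",
    "bray_curtis",
    "nmds",
    "cluster_stages",
    "indicator_taxa",
    "dissimilarity_structure",
    "aggregate_taxa",
]


@dataclass
class CommunityTable:
    """Samples-by-taxa count table with taxonomy and sampling days.

    ``counts``: DataFrame, rows = samples (index = day), columns = taxa,
    non-negative integers.  ``taxonomy``: DataFrame indexed by taxon with
    ``genus`` and ``phylum`` columns; taxa without an entry get
    "unclassified".
    """

    counts: pd.DataFrame
    sample_days: np.ndarray
    taxonomy: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.sample_days = np.asarray(self.sample_days, dtype=float)
        if self.sample_days.shape[0] != counts.shape[0]:
            raise ValueError("sample_days length != number of samples")
        if np.any(np.diff(self.sample_days) <= 0):
            raise ValueError("sample_days must be strictly increasing")
        if self.taxonomy is None:
            self.taxonomy = pd.DataFrame(index=pd.Index([], name="taxon_id"),
                                         columns=["genus", "phylum"])
        missing = [t for t in counts.columns if t not in self.taxonomy.index]
        if missing:
            extra = pd.DataFrame(
                {"genus": "unclassified", "phylum": "unclassified"},
                index=pd.Index(missing, name="taxon_id"))
            self.taxonomy = pd.concat([self.taxonomy, extra])

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def relative(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("sample with zero total reads")
        return self.counts.div(totals, axis=0)


@dataclass
class StageAssignment:
    """Successional-stage labels chosen by Ward clustering + elbow rule."""

    k: int
    labels: np.ndarray  # per sample, 1..k, renumbered in temporal order
    within_dispersion: dict[int, float]  # candidate k -> total W(k)


@dataclass
class OrdinationResult:
    """NMDS configuration (samples x k_dims) and its Kruskal stress-1."""

    coordinates: np.ndarray
    stress: float


def rarefy_diversity(
    table: CommunityTable, depth: int = 30000, reps: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Rarefied alpha-diversity profile.

    Each replicate subsamples ``depth`` reads per sample without
    replacement; richness S (taxa observed), Shannon H' (nats) and Pielou
    J = H'/ln S are computed per replicate and averaged over replicates.
    J is defined as 0 for single-taxon samples (the no-diversity limit of
    the 0/0 form).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    counts = table.counts.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    for i, tot in enumerate(totals):
        if tot < depth:
            raise ValueError(
                f"sample at day {table.sample_days[i]} has {tot} reads, "
                f"fewer than rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    n = counts.shape[0]
    rich = np.zeros((reps, n))
    shan = np.zeros((reps, n))
    piel = np.zeros((reps, n))
    for r in range(reps):
        for i in range(n):
            if totals[i] == depth:
                sub = counts[i]
            else:
                sub = rng.multivariate_hypergeometric(counts[i], depth)
            pos = sub[sub > 0]
            s = pos.size
            p = pos / depth
            h = float(-(p * np.log(p)).sum())
            rich[r, i] = s
            shan[r, i] = h
            piel[r, i] = h / np.log(s) if s > 1 else 0.0
    return pd.DataFrame({
        "day": table.sample_days,
        "richness": rich.mean(axis=0),
        "shannon": shan.mean(axis=0),
        "pielou": piel.mean(axis=0),
    })


def rarefied_mean_table(
    table: CommunityTable, depth: int = 30000, reps: int = 20, seed: int = 0
) -> CommunityTable:
    """Average of ``reps`` rarefied tables (counts become non-integer).

    Composition metrics downstream (Bray-Curtis, staging, indicators) use
    this depth-equalized table so deep and shallow samples are compared
    fairly.
    """
    counts = table.counts.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    for i, tot in enumerate(totals):
        if tot < depth:
            raise ValueError(
                f"sample at day {table.sample_days[i]} has {tot} reads, "
                f"fewer than rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(counts, dtype=float)
    for _ in range(reps):
        for i in range(counts.shape[0]):
            if totals[i] == depth:
                acc[i] += counts[i]
            else:
                acc[i] += rng.multivariate_hypergeometric(counts[i], depth)
    mean = pd.DataFrame(acc / reps, index=table.counts.index,
                        columns=table.counts.columns)
    return CommunityTable(counts=mean, sample_days=table.sample_days.copy(),
                          taxonomy=table.taxonomy)


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = 1 - 2*sum(min)/sum(totals)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = table.counts.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        raise ValueError("sample with zero total reads")
    d = squareform(pdist(x, metric="braycurtis"))
    ids = [f"{day:g}" for day in table.sample_days]
    return DistanceMatrix(d, ids=ids)


def _as_square(dist) -> np.ndarray:
    if isinstance(dist, DistanceMatrix):
        return dist.data.copy()
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("need a square dissimilarity matrix")
    return d


def nmds(
    dist, k: int = 3, restarts: int = 50, seed: int = 0
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Runs SMACOF with monotone (isotonic) regression from ``restarts``
    random initializations and keeps the lowest Kruskal stress-1
    configuration.  Zero-dissimilarity duplicates are collapsed before
    embedding and share coordinates afterwards.  The configuration is
    centered at the origin; each axis's sign is fixed so its correlation
    with sample order is non-negative (for time-ordered tables this makes
    axes reproducible against sampling day).
    """
    d = _as_square(dist)
    n = d.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    # collapse exact duplicates (zero dissimilarity) to one representative
    rep = np.arange(n)
    for i in range(n):
        for j in range(i):
            if d[i, j] <= 0 and rep[i] == i:
                rep[i] = rep[j]
    uniq = np.flatnonzero(rep == np.arange(n))
    du = d[np.ix_(uniq, uniq)]
    if uniq.size <= k:
        coords_u = np.zeros((uniq.size, k))
        stress = 0.0
    else:
        mds = MDS(n_components=k, metric=False, dissimilarity="precomputed",
                  n_init=restarts, random_state=seed, max_iter=500,
                  eps=1e-9, normalized_stress=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords_u = mds.fit_transform(du)
        stress = float(mds.stress_)
    coords = np.zeros((n, k))
    pos = {int(u): idx for idx, u in enumerate(uniq)}
    for i in range(n):
        coords[i] = coords_u[pos[int(rep[i])]]
    coords -= coords.mean(axis=0)
    order = np.arange(n, dtype=float)
    for j in range(k):
        axis = coords[:, j]
        if axis.std() > 0 and np.corrcoef(order, axis)[0, 1] < 0:
            coords[:, j] = -axis
    return OrdinationResult(coordinates=coords, stress=stress)


def _within_dispersion(d: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster dispersion: sum over clusters of
    sum_{i<j in c} d_ij^2 / n_c (the distance form of within variance)."""
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        total += float((sub ** 2).sum()) / (2.0 * idx.size)
    return total


def _temporal_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..k in order of first appearance."""
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_stages(dist, k_max: int = 8, k: int | None = None) -> StageAssignment:
    """Ward-linkage staging with an explicit elbow rule.

    Agglomerates on the dissimilarities (scipy's ward on a distance
    matrix, i.e. the Ward.D2 convention, applied directly to Bray-Curtis
    despite its non-Euclideanity — standard ecological practice).  The
    number of stages is the k in 2..k_max maximizing the second
    difference W(k-1) - 2 W(k) + W(k+1) of total within-cluster
    dispersion.  Pass ``k`` to force a cluster count.
    """
    d = _as_square(dist)
    n = d.shape[0]
    if k is None and k_max < 2:
        raise ValueError("k_max must be >= 2")
    if k_max >= n:
        warnings.warn(f"k_max={k_max} >= n_samples={n}; clipped to {n - 1}")
        k_max = n - 1
    z = linkage(squareform(d, checks=False), method="ward")
    dispersion: dict[int, float] = {}
    for kk in range(1, min(k_max + 1, n) + 1):
        labels = fcluster(z, t=kk, criterion="maxclust")
        dispersion[kk] = _within_dispersion(d, labels)
    if k is None:
        candidates = [kk for kk in range(2, k_max + 1)
                      if kk - 1 in dispersion and kk + 1 in dispersion]
        if not candidates:
            k = 1
        else:
            curvature = {
                kk: dispersion[kk - 1] - 2 * dispersion[kk] + dispersion[kk + 1]
                for kk in candidates
            }
            k = max(candidates, key=lambda kk: (curvature[kk], -kk))
    labels = _temporal_relabel(fcluster(z, t=k, criterion="maxclust"))
    return StageAssignment(k=int(k), labels=labels,
                           within_dispersion=dispersion)


def indicator_taxa(
    table: CommunityTable,
    stages: StageAssignment,
    permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Indicator-taxon analysis with the point-biserial association index.

    For every (taxon, stage) pair, r_pb is the Pearson correlation
    between the taxon's relative abundance across samples and the 0/1
    stage-membership vector; the p-value is the permutation fraction
    (with +1 smoothing) of |r_perm| >= |r_obs| under shuffled sample
    labels.  Constant abundance vectors get r_pb = 0 and p = 1.  No
    multiple-testing correction is applied.
    """
    uniq = np.unique(stages.labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 stages")
    x = table.relative().to_numpy()  # n x t
    n, t = x.shape
    rng = np.random.default_rng(seed)
    xc = x - x.mean(axis=0)
    xs = xc.std(axis=0, ddof=0)
    constant = xs <= 0
    xs_safe = np.where(constant, 1.0, xs)
    xz = xc / xs_safe  # standardized columns (population sd)

    perms = np.empty((permutations + 1, n), dtype=np.intp)
    perms[0] = np.arange(n)
    for b in range(1, permutations + 1):
        perms[b] = rng.permutation(n)

    rows = []
    for stage in uniq:
        member = (stages.labels == stage).astype(float)
        mz = member - member.mean()
        ms = mz.std(ddof=0)
        if ms <= 0:
            continue
        mz /= ms
        # r for all permutations x all taxa in one product
        mperm = mz[perms]  # (B+1) x n
        r_all = (mperm @ xz) / n  # (B+1) x t
        r_obs = r_all[0]
        exceed = (np.abs(r_all[1:]) >= np.abs(r_obs)[None, :] - 1e-12).sum(axis=0)
        p = (exceed + 1.0) / (permutations + 1.0)
        r_obs = np.where(constant, 0.0, r_obs)
        p = np.where(constant, 1.0, p)
        for j, taxon in enumerate(table.counts.columns):
            rows.append((taxon, int(stage), float(r_obs[j]), float(p[j])))
    return pd.DataFrame(rows, columns=["taxon", "stage", "r_pb", "p_value"])


def dissimilarity_structure(
    dist, sample_days: np.ndarray, stages: StageAssignment | None = None
) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Dissimilarity as a function of sampling-time gap, plus the
    within-stage pairwise dissimilarity distributions.

    Returns (gap curve: DataFrame with gap, mean_dissimilarity, n_pairs;
    stage -> array of within-stage pairwise dissimilarities).
    """
    d = _as_square(dist)
    days = np.asarray(sample_days, dtype=float)
    n = d.shape[0]
    if days.size != n:
        raise ValueError("sample_days length mismatch")
    gaps: dict[float, list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            gaps.setdefault(abs(days[j] - days[i]), []).append(d[i, j])
    gap_df = pd.DataFrame(
        [(g, float(np.mean(v)), len(v)) for g, v in sorted(gaps.items())],
        columns=["gap", "mean_dissimilarity", "n_pairs"])
    within: dict[int, np.ndarray] = {}
    if stages is not None:
        for lab in np.unique(stages.labels):
            idx = np.flatnonzero(stages.labels == lab)
            vals = [d[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]]
            within[int(lab)] = np.asarray(vals)
    return gap_df, within


def aggregate_taxa(table: CommunityTable, rank: str) -> CommunityTable:
    """Sum counts within taxonomy groups at ``rank`` ('genus' or 'phylum').

    Per-sample read totals are preserved.
    """
    if rank not in ("genus", "phylum"):
        raise ValueError(f"unknown rank {rank!r}; use 'genus' or 'phylum'")
    groups = table.taxonomy.loc[table.counts.columns, rank]
    agg = table.counts.T.groupby(groups.values).sum().T
    tax = pd.DataFrame(index=pd.Index(agg.columns, name="taxon_id"))
    tax["genus"] = agg.columns if rank == "genus" else "aggregated"
    tax["phylum"] = (
        agg.columns if rank == "phylum"
        else [table.taxonomy.loc[table.taxonomy[rank] == g, "phylum"].iloc[0]
              if (table.taxonomy[rank] == g).any() else "unclassified"
              for g in agg.columns])
    return CommunityTable(counts=agg, sample_days=table.sample_days.copy(),
                          taxonomy=tax)
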