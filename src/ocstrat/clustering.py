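"""Cohort feature matrix, grouped normalization, and ward.D clustering.

The feature matrix per sample holds the six substitution-class counts, a
total DBS count, collapsed indel-family counts, the 10-kb-split SV
category counts, and the three ploidy fractions.  Dependent feature
blocks (the SNV six, the indel families, the SV categories) are centred
and scaled by their pooled mean/SD so that within-block differences are
preserved; singleton columns are z-scored.

Distances are 1 - Pearson correlation between normalized sample rows.
Agglomeration uses the classic "ward.D" convention: the Lance-Williams
Ward update applied to the distances as given, without squaring (as
distinct from ward.D2).  Trees are cut by merge order (R cutree
semantics), which is robust to the height inversions ward.D can produce
on non-Euclidean dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_features import INDEL_FAMILIES, SV10_KEYS, SUBSTITUTION_CLASSES

SNV_GROUP = "SNV6"
INDEL_GROUP = "INDEL"
SV_GROUP = "SV"


@dataclass
class FeatureMatrix:
    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (n_samples, n_features)
    groups: dict[str, str]  # feature -> normalization group

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids/names")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing values")
        missing = [f for f in self.feature_names if f not in self.groups]
        if missing:
            raise ValueError(f"features without a normalization group: {missing}")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)


def feature_columns() -> tuple[list[str], dict[str, str]]:
    """Default clustering feature names and their normalization groups."""
    names, groups = [], {}
    for sub in SUBSTITUTION_CLASSES:
        names.append(f"snv.{sub}")
        groups[f"snv.{sub}"] = SNV_GROUP
    names.append("dbs.total")
    groups["dbs.total"] = "singleton:dbs.total"
    for fam in INDEL_FAMILIES:
        names.append(f"indel.{fam}")
        groups[f"indel.{fam}"] = INDEL_GROUP
    for key in SV10_KEYS:
        names.append(f"sv.{key}")
        groups[f"sv.{key}"] = SV_GROUP
    for p in ("frac_haploid", "frac_diploid", "frac_polyploid"):
        names.append(f"ploidy.{p}")
        groups[f"ploidy.{p}"] = f"singleton:ploidy.{p}"
    return names, groups


def build_feature_matrix(cohort_features: dict[str, tuple]) -> FeatureMatrix:
    """Assemble the clustering matrix from per-sample feature blocks.

    ``cohort_features`` maps sample_id -> (ContextCounts, PloidyProfile);
    row order follows input order.  A sample missing either block raises
    an error naming the sample.
    """
    names, groups = feature_columns()
    rows = []
    for sid, blocks in cohort_features.items():
        if blocks is None or len(blocks) != 2 or any(b is None for b in blocks):
            raise ValueError(f"sample {sid}: missing context or ploidy block")
        cc, pp = blocks
        row = np.concatenate(
            [
                cc.snv6().astype(float),
                [float(cc.dbs_total())],
                cc.indel_families().astype(float),
                cc.sv10.astype(float),
                [pp.frac_haploid, pp.frac_diploid, pp.frac_polyploid],
            ]
        )
        rows.append(row)
    return FeatureMatrix(list(cohort_features), names, np.vstack(rows), groups)


def normalize_grouped(m: FeatureMatrix) -> FeatureMatrix:
    """Grouped z-normalization.

    Columns in a shared group are centred and scaled with the pooled mean
    and pooled SD of all values in the group, preserving within-block
    contrasts; singleton columns are z-scored individually.  Zero-variance
    columns/groups map to zeros.
    """
    if len(m.sample_ids) < 2:
        raise ValueError("normalization requires at least 2 samples")
    values = m.values.copy()
    by_group: dict[str, list[int]] = {}
    for i, name in enumerate(m.feature_names):
        by_group.setdefault(m.groups[name], []).append(i)
    for _, cols in by_group.items():
        block = values[:, cols]
        mu = block.mean()
        sd = block.std(ddof=0)
        if sd == 0:
            values[:, cols] = 0.0
        else:
            values[:, cols] = (block - mu) / sd
    return FeatureMatrix(m.sample_ids, m.feature_names, values, dict(m.groups))


def sample_distance(m: FeatureMatrix) -> np.ndarray:
    """Pairwise d(i, j) = 1 - Pearson(row_i, row_j); zero diagonal."""
    values = m.values
    sds = values.std(axis=1)
    bad = [m.sample_ids[i] for i in np.flatnonzero(sds == 0)]
    if bad:
        raise ValueError(f"zero-variance feature rows for samples: {bad}")
    corr = np.corrcoef(values)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # (n-1, 4) scipy-style merge table, ward.D heights
    labels: np.ndarray  # 1..k per sample
    k: int
    bootstrap_p: dict[int, float] = field(default_factory=dict)
    pca_cumvar: np.ndarray | None = None


def ward_linkage(d: np.ndarray) -> np.ndarray:
    """Agglomerate with the ward.D Lance-Williams update on raw distances.

    Ties are broken by the lowest (i, j) pair in row-major order.  Returns
    a scipy-style merge table; heights are the ward.D merge costs and may
    contain inversions on non-Euclidean input.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))  # positions map to cluster ids
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = work[np.ix_(active, active)]
        flat = np.argmin(sub)
        i_pos, j_pos = divmod(int(flat), len(active))
        if i_pos > j_pos:
            i_pos, j_pos = j_pos, i_pos
        ci, cj = ids[active[i_pos]], ids[active[j_pos]]
        ai, aj = active[i_pos], active[j_pos]
        height = work[ai, aj]
        ni, nj = sizes[ci], sizes[cj]
        new_id = n + step
        # Lance-Williams ward.D update against every other active cluster
        for pos in active:
            if pos in (ai, aj):
                continue
            no = sizes[ids[pos]]
            upd = (
                (ni + no) * work[ai, pos]
                + (nj + no) * work[aj, pos]
                - no * height
            ) / (ni + nj + no)
            work[ai, pos] = work[pos, ai] = upd
        ids[ai] = new_id
        sizes[new_id] = ni + nj
        active.remove(aj)
        lo, hi = sorted((ci, cj))
        Z[step] = (lo, hi, height, ni + nj)
    return Z


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Labels 1..k by applying the first n-k merges (merge-order cut)."""
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    parent = list(range(n + max(n - 1, 0)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, int] = {}
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[i] = roots[r]
    return labels


def ward_cluster(d: np.ndarray, k: int) -> ClusterResult:
    """(1 - Pearson)/ward.D clustering cut to k clusters."""
    n = d.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    Z = ward_linkage(d)
    labels = cut_tree(Z, k) if n > 1 else np.ones(1, dtype=int)
    return ClusterResult(Z, labels, k)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def bootstrap_stability(
    m: FeatureMatrix,
    k: int,
    B: int = 200,
    seed: int = 0,
    jaccard_threshold: float = 0.75,
) -> dict[int, float]:
    """Per-cluster bootstrap recovery probability.

    Features (columns) are resampled with replacement B times and the
    clustering repeated; a cluster counts as recovered in a replicate when
    some replicate cluster reaches Jaccard >= ``jaccard_threshold`` with
    it.  This is the plain bootstrap-probability simplification of
    pvclust's multiscale procedure.
    """
    if B < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    base = ward_cluster(sample_distance(m), k)
    orig = {
        c: set(np.flatnonzero(base.labels == c)) for c in range(1, k + 1)
    }
    hits = {c: 0 for c in orig}
    p = m.values.shape[1]
    for _ in range(B):
        cols = rng.integers(0, p, size=p)
        boot = FeatureMatrix(
            m.sample_ids,
            [f"b{i}" for i in range(p)],
            m.values[:, cols],
            {f"b{i}": "singleton:b" for i in range(p)},
        )
        try:
            dist = _safe_distance(boot)
        except ValueError:
            continue
        labels = ward_cluster(dist, k).labels
        reps = [set(np.flatnonzero(labels == c)) for c in range(1, k + 1)]
        for c, members in orig.items():
            if max(_jaccard(members, r) for r in reps) >= jaccard_threshold:
                hits[c] += 1
    return {c: hits[c] / B for c in orig}


def _safe_distance(m: FeatureMatrix) -> np.ndarray:
    """Distance that tolerates zero-variance rows (treated as r = 0)."""
    values = m.values
    sds = values.std(axis=1)
    if np.all(sds > 0):
        return sample_distance(m)
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    norms[norms == 0] = 1.0
    corr = (centred / norms[:, None]) @ (centred / norms[:, None]).T
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def pca_cumvar(m: FeatureMatrix) -> np.ndarray:
    """Cumulative fraction of variance explained by principal components."""
    from sklearn.decomposition import PCA

    pca = PCA()
    pca.fit(m.values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    if len(cum):
        cum[-1] = min(max(cum[-1], cum[-1]), 1.0)
    return cum


def suggest_k(
    m: FeatureMatrix,
    k_range=range(2, 11),
    B: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability and dimensionality diagnostics per candidate k.

    Reports the minimum and mean bootstrap recovery probability for each
    k together with the PCA cumulative variance curve; it never chooses k.
    """
    cum = pca_cumvar(m)
    rows = []
    for k in k_range:
        stab = bootstrap_stability(m, k, B=B, seed=seed)
        rows.append(
            {
                "k": k,
                "min_stability": min(stab.values()),
                "mean_stability": float(np.mean(list(stab.values()))),
                "pca_cumvar_k": cum[k - 1] if k - 1 < len(cum) else 1.0,
            }
        )
    return pd.DataFrame(rows)


def linkage_table(Z: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(Z, columns=["child1", "child2", "height", "size"])


def to_newick(Z: np.ndarray, leaf_names: list[str] | None = None) -> str:
    """Dendrogram as a Newick string with branch lengths from merge heights.

    Branch lengths are parent height minus child height, clipped at 0 so
    that ward.D height inversions still yield a valid tree.
    """
    n = Z.shape[0] + 1
    if leaf_names is None:
        leaf_names = [str(i) for i in range(n)]
    if len(leaf_names) != n:
        raise ValueError("leaf_names length does not match tree size")
    height = {i: 0.0 for i in range(n)}
    node = {i: str(leaf_names[i]) for i in range(n)}
    for step in range(n - 1):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        h = float(Z[step, 2])
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + step] = h
    return node[2 * n - 2] + ";"
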