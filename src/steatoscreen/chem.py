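"""Compound clustering and target-activity profiling.

Confirmed hits are compared by 2048-bit circular fingerprints (ECFP4-style;
computed from SMILES via RDKit when available, or supplied precomputed),
clustered with Ward's minimum-variance agglomeration on Tanimoto distances,
and profiled against a compound x target matrix of pXC50 potencies with a
configurable activity cutoff (7.0 by default, the conventional boundary for
potent drug-like activity).

Ward agglomeration is implemented directly (squared-dissimilarity
Lance-Williams update, lexicographic tie-break on cluster ids) so merges are
fully deterministic; note the usual caveat that Ward's objective is derived
for Euclidean distances and is applied to Tanimoto dissimilarities by
convention. The linkage is emitted in the standard (n-1, 4) merge-table
layout so downstream cutting and dendrogram utilities apply unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list

__all__ = [
    "FingerprintSet",
    "fingerprints_from_smiles",
    "tanimoto_distance",
    "pairwise_tanimoto",
    "Linkage",
    "ward_cluster",
    "cut_clusters",
    "linkage_to_newick",
    "ActivityMatrix",
    "build_activity_matrix",
    "rank_target_classes",
]


@dataclass
class FingerprintSet:
    """Binary fingerprints for a set of compounds (equal bit length)."""

    ids: list[str]
    bits: np.ndarray  # (n_compounds, n_bits) bool
    provenance: str = "precomputed"  # or "computed-from-SMILES"

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("compound ids must be unique")
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.ids):
            raise ValueError("bits must be (n_compounds, n_bits)")

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    @classmethod
    def from_csv(cls, path) -> "FingerprintSet":
        """Read (id, bitstring) rows, bitstring as '0'/'1' characters."""
        df = pd.read_csv(path, dtype=str)
        ids = df.iloc[:, 0].tolist()
        bits = np.array([[ch == "1" for ch in s] for s in df.iloc[:, 1]], dtype=bool)
        return cls(ids=ids, bits=bits, provenance="precomputed")

    def to_csv(self, path) -> None:
        rows = ["".join("1" if b else "0" for b in row) for row in self.bits]
        pd.DataFrame({"compound": self.ids, "fingerprint": rows}).to_csv(path, index=False)


def fingerprints_from_smiles(
    smiles: dict[str, str], n_bits: int = 2048, radius: int = 2
) -> FingerprintSet:
    """Radius-2 circular (ECFP4-equivalent) fingerprints from SMILES via RDKit."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ids, rows = [], []
    for cid, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES for {cid}: {smi!r}")
        fp = gen.GetFingerprint(mol)
        rows.append(np.array(fp, dtype=bool))
        ids.append(cid)
    return FingerprintSet(ids=ids, bits=np.array(rows), provenance="computed-from-SMILES")


def tanimoto_distance(fp_a, fp_b) -> float:
    """1 - |a AND b| / |a OR b|; two empty fingerprints have distance 0."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return 1.0 - np.count_nonzero(a & b) / union


def pairwise_tanimoto(fps: FingerprintSet) -> np.ndarray:
    """Square symmetric Tanimoto distance matrix for a fingerprint set."""
    n = len(fps.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tanimoto_distance(fps.bits[i], fps.bits[j])
    return d


@dataclass
class Linkage:
    """Agglomerative merge table in the standard (n-1, 4) layout.

    Each row is (cluster_a, cluster_b, height, size): leaves are clusters
    0..n-1, the merge in row i creates cluster n+i. ``leaf_order`` is the
    left-to-right dendrogram order.
    """

    merges: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return leaves_list(self.merges)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        )
        df[["cluster_a", "cluster_b", "size"]] = df[
            ["cluster_a", "cluster_b", "size"]
        ].astype(int)
        return df


def _validate_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return d


def ward_cluster(distance_matrix, labels: list[str] | None = None) -> Linkage:
    """Ward's minimum-variance agglomeration of a dissimilarity matrix.

    Greedy agglomeration with the Lance-Williams update on squared
    dissimilarities,

        d(k, i+j)^2 = [(n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2 - n_k d_ij^2]
                      / (n_i+n_j+n_k),

    merging the pair of minimal dissimilarity at each step; among tied pairs
    the lexicographically smallest (id_a, id_b) wins. Heights are the merge
    dissimilarities (for two singletons at distance d, the merge height is
    d), which are non-decreasing because Ward is reducible.
    """
    d = _validate_distance_matrix(distance_matrix)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two items to cluster")
    d2 = {}  # squared dissimilarity between active cluster ids
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = d[i, j] ** 2

    def key(a, b):
        return (a, b) if a < b else (b, a)

    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = key(active[ii], active[jj])
                v = d2[(a, b)]
                if best is None or v < best[0] - 1e-15 or (
                    abs(v - best[0]) <= 1e-15 and (a, b) < (best[1], best[2])
                ):
                    best = (v, a, b)
        v, a, b = best
        na, nb = sizes[a], sizes[b]
        merges[step] = (a, b, np.sqrt(max(v, 0.0)), na + nb)
        for k in active:
            if k in (a, b):
                continue
            nk = sizes[k]
            dak = d2[key(a, k)]
            dbk = d2[key(b, k)]
            d2[key(next_id, k)] = (
                (na + nk) * dak + (nb + nk) * dbk - nk * v
            ) / (na + nb + nk)
        active = [k for k in active if k not in (a, b)] + [next_id]
        sizes[next_id] = na + nb
        next_id += 1
    return Linkage(merges=merges, labels=labels or [str(i) for i in range(n)])


def cut_clusters(
    linkage: Linkage, k: int | None = None, height: float | None = None
) -> np.ndarray:
    """Flat cluster labels by count (k) or by merge height.

    Labels are renumbered 0.. in order of first appearance along the leaf
    index so repeated runs give identical labelings.
    """
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    n = linkage.n_leaves
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must lie in [1, {n}]")
        raw = fcluster(linkage.merges, t=k, criterion="maxclust")
    else:
        raw = fcluster(linkage.merges, t=height, criterion="distance")
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        out[i] = remap[r]
    return out


def linkage_to_newick(linkage: Linkage) -> str:
    """Render the dendrogram as a Newick string with branch heights."""
    n = linkage.n_leaves
    labels = linkage.labels
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: labels[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(linkage.merges):
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        nid = n + step
        node[nid] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
        height[nid] = h
    return node[2 * n - 2] + ";"


@dataclass
class ActivityMatrix:
    """Compound x target pXC50 grid with an activity cutoff view.

    ``values`` holds all finite potencies (NaN where unmeasured); ``masked``
    hides entries below the cutoff — the sub-threshold potencies a profile
    heatmap grays out.
    """

    values: pd.DataFrame
    cutoff: float = 7.0

    @property
    def masked(self) -> pd.DataFrame:
        return self.values.where(self.values >= self.cutoff)

    def above_cutoff_pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for compound in self.values.index:
            for target in self.values.columns:
                v = self.values.loc[compound, target]
                if np.isfinite(v) and v >= self.cutoff:
                    out.append((compound, target, float(v)))
        return out


def build_activity_matrix(
    records: pd.DataFrame, cutoff: float = 7.0, aggregation: str = "max"
) -> ActivityMatrix:
    """Pivot (compound, target, value) records into an ActivityMatrix.

    Repeated measurements for one pair are aggregated by the median within
    each source and then, across sources, by ``aggregation`` ("max" reports
    the highest activity, the usual library-annotation convention;
    "median" pools everything by median). A missing ``source`` column is
    treated as a single source.
    """
    df = records.copy()
    for col in ("compound", "target", "value"):
        if col not in df.columns:
            raise ValueError(f"activity records missing column {col!r}")
    bad = df[~df["value"].apply(lambda v: isinstance(v, (int, float, np.number)))]
    if len(bad):
        rec = bad.iloc[0]
        raise ValueError(
            f"non-numeric activity value {rec['value']!r} for "
            f"({rec['compound']}, {rec['target']})"
        )
    if "source" not in df.columns:
        df = df.assign(source="default")
    per_source = (
        df.groupby(["compound", "target", "source"])["value"].median().reset_index()
    )
    if aggregation == "max":
        pooled = per_source.groupby(["compound", "target"])["value"].max()
    elif aggregation == "median":
        pooled = per_source.groupby(["compound", "target"])["value"].median()
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    matrix = pooled.unstack("target")
    return ActivityMatrix(values=matrix, cutoff=cutoff)


def rank_target_classes(
    matrix: ActivityMatrix, class_map: dict[str, str]
) -> pd.DataFrame:
    """Order target classes by their count of above-cutoff compound-target pairs.

    Unmapped targets fall into "unclassified"; ties are broken
    alphabetically. Returns columns (target_class, n_active_pairs).
    """
    pairs = matrix.above_cutoff_pairs()
    if not pairs:
        return pd.DataFrame(columns=["target_class", "n_active_pairs"])
    counts: dict[str, int] = {}
    for _, target, _ in pairs:
        cls = class_map.get(target, "unclassified")
        counts[cls] = counts.get(cls, 0) + 1
    out = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["target_class", "n_active_pairs"],
    )
    return out
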