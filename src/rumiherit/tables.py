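"""ASV count-table handling: I/O, filtering, transformation, diversity and
group-comparison statistics.

The central container is :class:`AsvTable`, a thin wrapper around a pandas
DataFrame of non-negative integer counts (samples as rows, ASVs as columns)
plus an optional taxonomy map (ASV id -> semicolon-separated 7-rank lineage).
All downstream stages (heritability screening, networks, associations,
prediction) consume this object or matrices derived from it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
import scipy.stats as sstats
from skbio import TreeNode
from skbio.diversity.alpha import chao1
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class AsvTable:
    """Samples x ASVs integer count table with optional taxonomy.

    Invariants: unique sample and ASV ids, finite non-negative counts.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise ValueError("no samples in ASV table")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate ASV ids: {dup}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric counts in ASV table")
        if not np.isfinite(arr).all():
            raise ValueError("non-finite counts in ASV table")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"ASV {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "AsvTable":
        return AsvTable(self.counts.loc[list(sample_ids)].copy(), self.taxonomy)

    def subset_asvs(self, asv_ids) -> "AsvTable":
        asv_ids = list(asv_ids)
        tax = {a: self.taxonomy[a] for a in asv_ids if a in self.taxonomy}
        return AsvTable(self.counts[asv_ids].copy(), tax)


def read_asv_table(path, taxonomy_path=None) -> AsvTable:
    """Read a TSV count table (samples as rows, header row of ASV ids).

    An optional two-column taxonomy TSV (ASV id, lineage) may accompany it.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ValueError(
                f"non-numeric count at sample {df.index[bad.argmax()]!r}, ASV {col!r}"
            )
    taxonomy = {}
    if taxonomy_path is not None:
        tx = pd.read_csv(taxonomy_path, sep="\t", header=None, names=["asv", "lineage"])
        taxonomy = dict(zip(tx["asv"].astype(str), tx["lineage"].astype(str)))
    return AsvTable(df, taxonomy)


def write_asv_table(table: AsvTable, path, taxonomy_path=None) -> None:
    """Write the canonical TSV form (and optionally the taxonomy TSV)."""
    table.counts.to_csv(path, sep="\t", index_label="sample")
    if taxonomy_path is not None:
        with open(taxonomy_path, "w") as fh:
            for asv in table.asv_ids:
                fh.write(f"{asv}\t{table.taxonomy.get(asv, '')}\n")


def filter_prevalence(table: AsvTable, min_fraction: float = 0.05) -> AsvTable:
    """Drop rare ASVs: keep those detected (count > 0) in >= ``min_fraction``
    of all samples.  The boundary is inclusive: an ASV present in exactly the
    threshold fraction is retained (only strictly rarer ASVs are removed)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    prev = (table.counts > 0).mean(axis=0)
    keep = prev[prev >= min_fraction].index
    return table.subset_asvs(keep)


def rarefy(table: AsvTable, depth: int = 10_000, seed=None) -> AsvTable:
    """Subsample every sample to ``depth`` sequences without replacement.

    Samples with fewer than ``depth`` total counts are dropped with a warning.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
        warnings.warn(f"rarefy: dropped {len(dropped)} samples below depth {depth}",
                      stacklevel=2)
    if len(keep) == 0:
        raise ValueError(f"all samples below rarefaction depth {depth}")
    sub = table.counts.loc[keep]
    out = np.empty_like(sub.to_numpy())
    for i, row in enumerate(sub.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return AsvTable(pd.DataFrame(out, index=sub.index, columns=sub.columns),
                    table.taxonomy)


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Per-sample proportions (rows sum to 1)."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        zero = totals[totals == 0].index.tolist()
        raise ValueError(f"zero-total samples: {zero}")
    return table.counts.div(totals, axis=0)


def log_transform(proportions: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Natural log of (proportion + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log(proportions + pseudocount)


def alpha_diversity(table: AsvTable) -> pd.DataFrame:
    """Per-sample Chao1 (bias-corrected), Shannon (natural log) and Pielou
    evenness.  Evenness is NaN for samples with a single observed taxon."""
    rows = []
    for sid, row in table.counts.iterrows():
        c = row.to_numpy()
        c = c[c > 0]
        if c.size == 0:
            rows.append((sid, 0.0, 0.0, np.nan))
            continue
        p = c / c.sum()
        h = float(-(p * np.log(p)).sum())
        s_obs = c.size
        even = h / np.log(s_obs) if s_obs > 1 else np.nan
        rows.append((sid, float(chao1(c)), h, even))
    return pd.DataFrame(rows, columns=["sample", "chao1", "shannon", "evenness"]
                        ).set_index("sample")


def _check_tree_covers(tree: TreeNode, asv_ids) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [a for a in asv_ids if a not in tips]
    if missing:
        raise ValueError(f"tree is missing leaves for ASVs: {missing}")


def beta_dissimilarity(table: AsvTable, metric: str = "bray_curtis",
                       tree: TreeNode | None = None) -> pd.DataFrame:
    """Pairwise sample dissimilarity.

    Metrics: ``bray_curtis``, ``binary_jaccard`` (1 - |A∩B|/|A∪B| on
    presence/absence) and ``weighted_unifrac`` (normalized form, requires a
    tree covering all ASVs).
    """
    x = table.counts.to_numpy(dtype=float)
    ids = table.sample_ids
    if metric == "bray_curtis":
        d = ssd.squareform(ssd.pdist(x, metric="braycurtis"))
    elif metric == "binary_jaccard":
        d = ssd.squareform(ssd.pdist(x > 0, metric="jaccard"))
    elif metric == "weighted_unifrac":
        if tree is None:
            raise ValueError("weighted_unifrac requires a tree")
        _check_tree_covers(tree, table.asv_ids)
        from skbio.diversity import beta_diversity as _bd
        dm = _bd("weighted_unifrac", table.counts.to_numpy(), ids=ids,
                 taxa=table.asv_ids, tree=tree, normalized=True)
        d = dm.data
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame          # samples x retained axes
    eigenvalues: np.ndarray            # positive eigenvalues, descending
    proportion_explained: np.ndarray   # over positive eigenvalues


def pcoa(distance: pd.DataFrame) -> PcoaResult:
    """Classical metric scaling of a square symmetric distance matrix.

    Axes with non-positive eigenvalues are excluded; proportion explained is
    reported over the positive eigenvalues only.
    """
    d = np.asarray(distance, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(d, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = eig > max(1e-12, 1e-10 * abs(eig).max() if eig.size else 0)
    eig_pos = eig[pos]
    coords = res.samples.to_numpy()[:, pos]
    prop = eig_pos / eig_pos.sum() if eig_pos.sum() > 0 else np.zeros_like(eig_pos)
    ids = list(distance.index) if isinstance(distance, pd.DataFrame) else None
    cols = [f"PCo{i+1}" for i in range(coords.shape[1])]
    return PcoaResult(pd.DataFrame(coords, index=ids, columns=cols), eig_pos, prop)


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances (Anderson's formulation)."""
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ssa = sst - ssw
    a = groups.size
    return (ssa / (a - 1)) / (ssw / (n - a))


def permanova(distance: pd.DataFrame, labels, n_perm: int = 999, seed=None):
    """PERMANOVA pseudo-F and permutation p-value.

    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1), so the smallest attainable
    p at 999 permutations is 0.001.
    """
    d = np.asarray(distance, dtype=float)
    labels = np.asarray(labels)
    if d.shape[0] != labels.size:
        raise ValueError("labels length must match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = d ** 2
    f_obs = _permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_f(d2, perm) >= f_obs:
            hits += 1
    return f_obs, (hits + 1) / (n_perm + 1)


def rank_sum_test(values_a, values_b) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value.

    Exact for small samples without ties; normal approximation with tie
    correction otherwise.  Constant pooled data yields p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(min(res.pvalue, 1.0))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="holm")[1]


def group_presence_summary(table: AsvTable, groups: pd.Series) -> dict:
    """Shared/unique ASV counts between the two cohorts (dam vs lamb)."""
    groups = groups.reindex(table.sample_ids)
    out = {}
    present = {}
    for g in sorted(groups.dropna().unique()):
        sub = table.counts.loc[groups == g]
        present[g] = set(sub.columns[(sub > 0).any(axis=0)])
    names = sorted(present)
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    g1, g2 = names
    out[f"{g1}_only"] = len(present[g1] - present[g2])
    out[f"{g2}_only"] = len(present[g2] - present[g1])
    out["shared"] = len(present[g1] & present[g2])
    return out


def aggregate_taxonomy(table: AsvTable, rank: str) -> pd.DataFrame:
    """Sum per-sample relative abundances into the named taxonomic rank.

    ASVs whose lineage does not resolve at that rank are pooled as
    ``unclassified``.  Row sums are preserved (equal to 1).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    level = RANKS.index(rank)
    props = relative_abundance(table)
    labels = {}
    for asv in table.asv_ids:
        lineage = [t.strip() for t in table.taxonomy.get(asv, "").split(";")]
        name = lineage[level] if level < len(lineage) else ""
        labels[asv] = name if name else "unclassified"
    return props.T.groupby(pd.Series(labels)).sum().T
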