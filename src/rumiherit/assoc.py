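"""Rank-correlation screening of ASVs against lamb growth traits and rumen
fermentation parameters, with Benjamini-Hochberg multiplicity control.

ASVs prevalent in at least half of the dams or half of the lambs are
correlated (Spearman, midrank ties; exact permutation p for n <= 9) with
each lamb's BW, WW, PWG and fermentation variables.  A dam's abundances are
paired with each of her lambs, so a dam with three lambs contributes three
paired rows; this duplication is deliberate and recorded in the output.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sstats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROWTH_TRAITS = ("BW", "WW", "PWG")


def select_assoc_asvs(table, metadata: pd.DataFrame,
                      prevalence_min: float = 0.5) -> list[str]:
    """ASVs present (count > 0) in >= ``prevalence_min`` of dams OR of lambs
    (boundary inclusive)."""
    counts = table.counts if hasattr(table, "counts") else table
    groups = metadata.loc[counts.index, "group"]
    keep = []
    prev = {}
    for g in ("dam", "lamb"):
        sub = counts.loc[groups == g]
        prev[g] = (sub > 0).mean(axis=0) if len(sub) else pd.Series(0.0, index=counts.columns)
    for asv in counts.columns:
        if prev["dam"][asv] >= prevalence_min or prev["lamb"][asv] >= prevalence_min:
            keep.append(asv)
    return keep


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 9, full
    enumeration of orderings of one margin)."""
    n = x.size
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (ry_c[perms] @ rx_c) / denom
    return float((np.abs(rhos) >= abs(rho_obs) - 1e-12).mean())


def spearman_with_p(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho (midrank ties) and two-sided p (exact for small n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector")
    rho, p_t = sstats.spearmanr(x, y)
    if x.size <= exact_max_n:
        return float(rho), float(_spearman_exact_p(x, y, rho))
    return float(rho), float(p_t)


@dataclass
class AssociationEdge:
    asv: str
    cohort: str       # "lamb" or "dam"
    variable: str
    rho: float
    p: float
    p_adj: float = np.nan
    sign: int = 0

    def __post_init__(self) -> None:
        if self.sign == 0:
            self.sign = 1 if self.rho > 0 else (-1 if self.rho < 0 else 0)


def _paired_frames(log_abund: pd.DataFrame, metadata: pd.DataFrame):
    """Per-lamb rows for lamb and dam abundances, aligned to lamb variables."""
    lamb_meta = metadata[metadata["group"] == "lamb"]
    animal_to_sample = {a: s for s, a in metadata["animal"].items()}
    lamb_rows, dam_rows, kept = [], [], []
    for sid, row in lamb_meta.iterrows():
        dam_sid = animal_to_sample.get(row["dam_id"])
        if sid not in log_abund.index:
            continue
        if dam_sid is None or dam_sid not in log_abund.index:
            logger.warning("assoc: lamb %s has no dam sample; dam pairing skipped", sid)
            dam_rows.append(None)
        else:
            dam_rows.append(dam_sid)
        lamb_rows.append(sid)
        kept.append(sid)
    return lamb_rows, dam_rows, lamb_meta.loc[kept]


def spearman_matrix(log_abund: pd.DataFrame, metadata: pd.DataFrame,
                    asvs=None, variables=None) -> list[AssociationEdge]:
    """Spearman rho and raw p for every (cohort, ASV, variable) pair.

    Lamb abundances and dam abundances (duplicated across littermates) are
    both correlated with the lamb's variables.  Constant vectors are skipped
    with a log entry.
    """
    if asvs is None:
        asvs = list(log_abund.columns)
    if variables is None:
        variables = [v for v in metadata.columns
                     if v in GROWTH_TRAITS or v not in
                     ("animal", "group", "age", "year_season", "litter_id",
                      "dam_id", "litter_size", "library_size")]
        variables = [v for v in variables
                     if pd.api.types.is_numeric_dtype(metadata[v])]
    lamb_rows, dam_rows, lamb_meta = _paired_frames(log_abund, metadata)
    edges = []
    for var in variables:
        yv = lamb_meta[var].to_numpy(float)
        ok = np.isfinite(yv)
        for cohort in ("lamb", "dam"):
            rows = lamb_rows if cohort == "lamb" else dam_rows
            mask = ok & np.array([r is not None for r in rows])
            if mask.sum() < 4:
                continue
            sel = [r for r, m in zip(rows, mask) if m]
            sub = log_abund.loc[sel, asvs].to_numpy(float)
            yy = yv[mask]
            for j, asv in enumerate(asvs):
                xj = sub[:, j]
                try:
                    rho, p = spearman_with_p(xj, yy)
                except ValueError:
                    logger.info("assoc: skipped constant pair %s/%s/%s",
                                cohort, asv, var)
                    continue
                edges.append(AssociationEdge(asv, cohort, var, rho, p,
                                             sign=1 if rho > 0 else -1))
    return edges


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_edges(edges: list[AssociationEdge],
                 alpha: float = 0.05) -> list[AssociationEdge]:
    """BH-adjust jointly over the whole ASV x variable matrix and return the
    edges retained at adjusted p < alpha."""
    if not edges:
        return []
    adj = bh_adjust([e.p for e in edges])
    for e, q in zip(edges, adj):
        e.p_adj = float(q)
    return [e for e in edges if e.p_adj < alpha]


def assoc_summary(significant: list[AssociationEdge],
                  heritable_asvs=None) -> dict:
    """Per-variable positive/negative counts by cohort, plus the overlap of
    trait-associated ASVs with the heritable set."""
    summary: dict = {"by_variable": {}, "heritable_overlap": {}}
    for e in significant:
        key = e.variable
        d = summary["by_variable"].setdefault(
            key, {"positive": 0, "negative": 0, "lamb": 0, "dam": 0})
        d["positive" if e.sign > 0 else "negative"] += 1
        d[e.cohort] += 1
    if heritable_asvs is not None:
        hset = set(heritable_asvs)
        for cohort in ("lamb", "dam"):
            assoc_set = {e.asv for e in significant if e.cohort == cohort}
            summary["heritable_overlap"][cohort] = sorted(assoc_set & hset)
    return summary


def edges_to_frame(edges: list[AssociationEdge],
                   heritable_asvs=None) -> pd.DataFrame:
    hset = set(heritable_asvs or [])
    rows = [{**e.__dict__, "heritable": e.asv in hset} for e in edges]
    return pd.DataFrame(rows)
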