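"""Pedigree-based heritability of per-ASV log relative abundances.

The model is the classical animal model with a maternal effect:

    y = Xb + Za + Wm + e,
    a ~ N(0, A * sigma_a2),  m ~ N(0, I * sigma_m2),  e ~ N(0, I * sigma_e2)

where y is the log-transformed relative abundance of one ASV across samples,
X carries the fixed effects (year-season, group dam/lamb, age as a covariate),
A is the pedigree numerator relationship matrix, Z maps samples to animals and
W maps samples to the dam of the sampled animal.  Variance components are
estimated by restricted maximum likelihood with average-information updates
(expectation-maximization fallback), and heritability is

    h2 = sigma_a2 / (sigma_a2 + sigma_m2 + sigma_e2)

with a first-order (delta-method) standard error and a two-tailed Student t
p-value on h2 / SE at df = n - rank(X).  An ASV is screened as heritable when
h2 > 0.2 and p < 0.05 (both strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.stats as sstats

logger = logging.getLogger(__name__)

VARIANCE_FLOOR_REL = 1e-8  # floor relative to the phenotypic variance scale


# ---------------------------------------------------------------------------
# Pedigree


@dataclass
class Pedigree:
    """Validated, topologically sorted pedigree records.

    ``animals`` lists ids with parents preceding offspring; ``sire``/``dam``
    map each animal to its parent id or None.  Inbreeding coefficients F are
    filled in by :func:`a_matrix`.
    """

    animals: list[str]
    sire: dict[str, str | None]
    dam: dict[str, str | None]
    inbreeding: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.animals)

    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.animals)}


def _toposort(records: list[tuple[str, str | None, str | None]]) -> list[str]:
    parents = {a: [p for p in (s, d) if p is not None] for a, s, d in records}
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(a: str, stack: list[str]) -> None:
        st = state.get(a, 0)
        if st == 2:
            return
        if st == 1:
            cyc = stack[stack.index(a):] + [a]
            raise ValueError(f"pedigree cycle involving: {' -> '.join(cyc)}")
        state[a] = 1
        stack.append(a)
        for p in parents.get(a, []):
            visit(p, stack)
        stack.pop()
        state[a] = 2
        order.append(a)

    for a, _, _ in records:
        visit(a, [])
    return order


def make_pedigree(records: list[tuple[str, str | None, str | None]]) -> Pedigree:
    """Validate raw (animal, sire, dam) records and sort parents-first."""
    seen = set()
    for a, _, _ in records:
        if a in seen:
            raise ValueError(f"duplicate animal id: {a!r}")
        seen.add(a)
    sire = {a: s for a, s, _ in records}
    dam = {a: d for a, _, d in records}
    # parents referenced but not listed become founders
    for a, s, d in list(records):
        for p in (s, d):
            if p is not None and p not in seen:
                records.append((p, None, None))
                sire[p] = None
                dam[p] = None
                seen.add(p)
    as_sire = {s for s in sire.values() if s is not None}
    as_dam = {d for d in dam.values() if d is not None}
    both = as_sire & as_dam
    if both:
        raise ValueError(f"ids appear as both sire and dam: {sorted(both)}")
    for a in seen:
        if sire.get(a) == a or dam.get(a) == a:
            raise ValueError(f"animal {a!r} is its own parent")
    order = _toposort(records)
    ped = Pedigree(order, {a: sire[a] for a in order}, {a: dam[a] for a in order})
    A = a_matrix(ped)  # fills inbreeding
    del A
    return ped


def load_pedigree(path) -> Pedigree:
    """Read an animal,sire,dam CSV; 0 or empty encodes an unknown parent."""
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = [c.lower() for c in df.columns]
    if cols[:3] != ["animal", "sire", "dam"]:
        raise ValueError("pedigree CSV must have columns animal,sire,dam")
    records = []
    for _, row in df.iterrows():
        a = row.iloc[0].strip()
        s = row.iloc[1].strip()
        d = row.iloc[2].strip()
        records.append((a, None if s in ("", "0") else s,
                        None if d in ("", "0") else d))
    return make_pedigree(records)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal,sire,dam\n")
        for a in ped.animals:
            fh.write(f"{a},{ped.sire[a] or 0},{ped.dam[a] or 0}\n")


def a_matrix(ped: Pedigree) -> pd.DataFrame:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + 0.5 * a(sire, dam); a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))
    for j preceding i; unknown parents contribute zero.  Also fills the
    pedigree's inbreeding coefficients F_i = a_ii - 1.
    """
    n = len(ped)
    idx = ped.index()
    A = np.zeros((n, n))
    for i, animal in enumerate(ped.animals):
        s, d = ped.sire[animal], ped.dam[animal]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    ped.inbreeding = {a: float(A[idx[a], idx[a]] - 1.0) for a in ped.animals}
    return pd.DataFrame(A, index=ped.animals, columns=ped.animals)


def a_inverse(ped: Pedigree) -> pd.DataFrame:
    """Direct construction of A^-1 (Henderson/Quaas, inbreeding-aware).

    Uses the Mendelian-sampling variances d_i derived from parental
    inbreeding coefficients; requires F (computed as a side effect of
    :func:`a_matrix` / :func:`make_pedigree`).
    """
    if not ped.inbreeding:
        a_matrix(ped)
    n = len(ped)
    idx = ped.index()
    Ainv = np.zeros((n, n))
    F = ped.inbreeding
    for animal in ped.animals:
        i = idx[animal]
        s, d = ped.sire[animal], ped.dam[animal]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        if si is not None and di is not None:
            dii = 0.5 - 0.25 * (F[s] + F[d])
        elif si is not None:
            dii = 0.75 - 0.25 * F[s]
        elif di is not None:
            dii = 0.75 - 0.25 * F[d]
        else:
            dii = 1.0
        alpha = 1.0 / dii
        Ainv[i, i] += alpha
        for pi in (si, di):
            if pi is not None:
                Ainv[pi, i] -= alpha / 2
                Ainv[i, pi] -= alpha / 2
        for pi in (si, di):
            for qi in (si, di):
                if pi is not None and qi is not None:
                    Ainv[pi, qi] += alpha / 4
    return pd.DataFrame(Ainv, index=ped.animals, columns=ped.animals)


# ---------------------------------------------------------------------------
# Model design


@dataclass
class ModelDesign:
    """Design matrices for one fit: fixed effects X (full column rank),
    additive incidence Z (samples -> pedigree animals) and maternal incidence
    W (samples -> dam levels; all-zero row when the dam is unknown)."""

    X: np.ndarray
    Z: np.ndarray
    W: np.ndarray
    sample_ids: list[str]
    fixed_names: list[str]
    dropped_fixed: list[str]
    maternal_levels: list[str]
    animal_order: list[str]


def build_design(metadata: pd.DataFrame, ped: Pedigree) -> ModelDesign:
    """Build X, Z, W from sample metadata.

    X = intercept + year-season dummies + group dummy + centered age, with
    aliased columns dropped to full rank (reference level = lexicographically
    first).  Every sampled animal must be in the pedigree; W maps each sample
    to the pedigree dam of the sampled animal.
    """
    idx = ped.index()
    missing = [a for a in metadata["animal"] if a not in idx]
    if missing:
        raise ValueError(f"sample animals missing from pedigree: {sorted(set(missing))}")
    n = len(metadata)
    cols = [np.ones(n)]
    names = ["intercept"]
    ys = metadata["year_season"].astype(str)
    for lev in sorted(ys.unique())[1:]:
        cols.append((ys == lev).to_numpy(float))
        names.append(f"year_season[{lev}]")
    grp = metadata["group"].astype(str)
    for lev in sorted(grp.unique())[1:]:
        cols.append((grp == lev).to_numpy(float))
        names.append(f"group[{lev}]")
    age = metadata["age"].to_numpy(float)
    cols.append(age - age.mean())
    names.append("age")
    X = np.column_stack(cols)
    # drop aliased columns to full rank via pivoted QR
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.warning("build_design: dropped aliased fixed-effect columns: %s", dropped)
    X = X[:, keep]
    names = [names[j] for j in keep]

    Z = np.zeros((n, len(ped)))
    for i, a in enumerate(metadata["animal"]):
        Z[i, idx[a]] = 1.0
    dams = []
    for a in metadata["animal"]:
        dams.append(ped.dam[a])
    levels = sorted({d for d in dams if d is not None})
    lev_idx = {d: j for j, d in enumerate(levels)}
    W = np.zeros((n, len(levels)))
    for i, d in enumerate(dams):
        if d is not None:
            W[i, lev_idx[d]] = 1.0
    return ModelDesign(X, Z, W, list(metadata.index.astype(str)), names, dropped,
                       levels, list(ped.animals))


# ---------------------------------------------------------------------------
# REML


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_m2: float
    sigma_e2: float
    loglik: float
    covariance: np.ndarray          # asymptotic covariance of (a2, m2, e2)
    converged: bool
    n_iter: int
    boundary: tuple[bool, bool, bool]
    n_samples: int
    rank_x: int

    @property
    def total(self) -> float:
        return self.sigma_a2 + self.sigma_m2 + self.sigma_e2


def _reml_pieces(theta, y, X, Va, Vm):
    """Restricted log-likelihood and projection quantities at theta."""
    n = y.size
    V = theta[0] * Va + theta[1] * Vm + theta[2] * np.eye(n)
    try:
        c, low = sla.cho_factor(V, lower=True, check_finite=False)
    except sla.LinAlgError:
        return None
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    Vinv_X = sla.cho_solve((c, low), X, check_finite=False)
    Vinv_y = sla.cho_solve((c, low), y, check_finite=False)
    XtVX = X.T @ Vinv_X
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return None
    beta = np.linalg.solve(XtVX, Vinv_X.T @ y)
    Py = Vinv_y - Vinv_X @ beta
    yPy = float(y @ Py)
    ll = -0.5 * (logdet_v + logdet_x + yPy)
    # P = Vinv - Vinv X (X'VinvX)^-1 X'Vinv, needed for traces
    Vinv = sla.cho_solve((c, low), np.eye(n), check_finite=False)
    P = Vinv - Vinv_X @ np.linalg.solve(XtVX, Vinv_X.T)
    return ll, P, Py, yPy


def reml_fit(design: ModelDesign, A: pd.DataFrame, y,
             max_iter: int = 200, tol_param: float = 1e-8,
             tol_loglik: float = 1e-10, theta0=None) -> VarianceComponents:
    """AI-REML fit of (sigma_a2, sigma_m2, sigma_e2).

    Average-information updates with expectation-maximization fallback when
    an AI step proposes out-of-bounds variances or decreases the restricted
    likelihood.  Variances are floored at 1e-8 times the phenotypic variance
    scale (boundary-flagged); the asymptotic covariance is the inverse of the
    final average-information matrix.
    """
    y = np.asarray(y, dtype=float)
    X, Z, W = design.X, design.Z, design.W
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("need n_samples > rank(X) + 2")
    Amat = A.to_numpy() if isinstance(A, pd.DataFrame) else np.asarray(A)
    Va = Z @ Amat @ Z.T
    Vm = W @ W.T
    s2 = float(np.var(y - X @ np.linalg.lstsq(X, y, rcond=None)[0], ddof=p))
    if s2 <= 0:
        s2 = max(float(np.var(y)), 1e-12)
    floor = VARIANCE_FLOOR_REL * s2
    theta = np.array(theta0, float) if theta0 is not None else \
        np.array([0.3 * s2, 0.2 * s2, 0.5 * s2])
    theta = np.maximum(theta, floor)
    Vs = (Va, Vm, np.eye(n))
    # effective level counts for EM denominators
    q = np.array([len(design.animal_order), max(1, W.shape[1]), n], float)

    pieces = _reml_pieces(theta, y, X, Va, Vm)
    if pieces is None:
        raise ValueError("singular covariance at starting values; "
                         "check design condition number")
    ll, P, Py, yPy = pieces
    converged = False
    it = 0
    AI = np.eye(3)
    for it in range(1, max_iter + 1):
        PVs = [Vi @ Py for Vi in Vs]           # V_i P y
        score = np.array([
            -0.5 * (np.einsum("ij,ji->", P, Vi) - Py @ (Vi @ Py))
            for Vi in Vs
        ])
        PViPy = [P @ v for v in PVs]
        AI = 0.5 * np.array([[PVs[i] @ PViPy[j] for j in range(3)]
                             for i in range(3)])
        step_ok = False
        try:
            delta = np.linalg.solve(AI, score)
            cand = theta + delta
            if np.any(cand < floor):
                # active-set step: pin out-of-bounds components at the floor
                # and re-solve the reduced AI system for the rest
                for _ in range(3):
                    active = cand < floor
                    if not active.any():
                        break
                    free = ~active
                    cand = np.where(active, floor, theta)
                    if free.any():
                        rhs = score[free] - AI[np.ix_(free, active)] @ \
                            (floor - theta[active])
                        sub = AI[np.ix_(free, free)]
                        cand[free] = theta[free] + np.linalg.solve(sub, rhs)
                cand = np.maximum(cand, floor)
            full = cand.copy()
            for frac in (1.0, 0.5, 0.25, 0.1):
                cand = np.maximum(theta + frac * (full - theta), floor)
                cand_p = _reml_pieces(cand, y, X, Va, Vm)
                if cand_p is not None and cand_p[0] >= ll - 1e-12:
                    step_ok = True
                    break
        except np.linalg.LinAlgError:
            pass
        if not step_ok:
            # EM-style update (Johnson & Thompson): always increases L
            cand = theta + (theta ** 2 / q) * (2.0 * score)
            cand = np.maximum(cand, floor)
            cand_p = _reml_pieces(cand, y, X, Va, Vm)
            if cand_p is None or cand_p[0] < ll - 1e-8:
                # halve toward current point
                ok = False
                for _ in range(20):
                    cand = 0.5 * (cand + theta)
                    cand_p = _reml_pieces(cand, y, X, Va, Vm)
                    if cand_p is not None and cand_p[0] >= ll - 1e-8:
                        ok = True
                        break
                if not ok:
                    break
        new_ll, P, Py, yPy = cand_p
        # relative change on the phenotypic-variance scale so that a
        # component pinned near the floor cannot stall convergence
        rel = np.max(np.abs(cand - theta)) / max(float(cand.sum()), floor)
        dll = abs(new_ll - ll)
        theta, ll = cand, new_ll
        if rel < tol_param or dll < tol_loglik:
            converged = True
            break
    if not converged:
        logger.warning("reml_fit: not converged after %d iterations", it)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
    boundary = tuple(bool(t <= floor * (1 + 1e-6)) for t in theta)
    return VarianceComponents(float(theta[0]), float(theta[1]), float(theta[2]),
                              float(ll), cov, converged, it, boundary, n, p)


def heritability(vc: VarianceComponents) -> float:
    """h2 = sigma_a2 / (sigma_a2 + sigma_m2 + sigma_e2)."""
    t = vc.total
    if not np.isfinite(t) or t <= 0:
        raise ValueError("non-positive total variance")
    return vc.sigma_a2 / t


def heritability_se_p(vc: VarianceComponents) -> tuple[float, float]:
    """Delta-method SE of h2 and two-tailed Student t p-value.

    Gradient of h2 w.r.t. (a2, m2, e2) is ((m2+e2)/T^2, -a2/T^2, -a2/T^2);
    SE = sqrt(g' V g) with V the variance-component covariance; t = h2/SE at
    df = n_samples - rank(X).
    """
    t = vc.total
    g = np.array([(vc.sigma_m2 + vc.sigma_e2) / t ** 2,
                  -vc.sigma_a2 / t ** 2,
                  -vc.sigma_a2 / t ** 2])
    V = vc.covariance
    if not np.all(np.isfinite(V)):
        return np.nan, np.nan
    var = float(g @ V @ g)
    if var < 0:
        var = 0.0
    se = np.sqrt(var)
    h2 = heritability(vc)
    df = vc.n_samples - vc.rank_x
    if se == 0:
        p = 0.0 if h2 > 0 else 1.0
    else:
        p = float(2.0 * sstats.t.sf(abs(h2 / se), df))
    return float(se), p


@dataclass
class HeritabilityResult:
    asv: str
    h2: float
    se: float
    p: float
    heritable: bool
    sigma_a2: float
    sigma_m2: float
    sigma_e2: float
    converged: bool
    boundary: bool


def fit_asv_heritability(log_abund: pd.DataFrame, metadata: pd.DataFrame,
                         ped: Pedigree, h2_min: float = 0.2,
                         p_max: float = 0.05) -> pd.DataFrame:
    """Fit the animal model for every ASV column of ``log_abund``.

    Rows of ``log_abund`` and ``metadata`` must align (one sample per row);
    returns one result row per ASV.
    """
    design = build_design(metadata, ped)
    A = a_matrix(ped)
    rows = []
    for asv in log_abund.columns:
        y = log_abund[asv].to_numpy(float)
        vc = reml_fit(design, A, y)
        h2 = heritability(vc)
        se, p = heritability_se_p(vc)
        flag = bool(h2 > h2_min and np.isfinite(p) and p < p_max)
        rows.append(HeritabilityResult(asv, h2, se, p, flag, vc.sigma_a2,
                                       vc.sigma_m2, vc.sigma_e2, vc.converged,
                                       any(vc.boundary)))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("asv")


def screen_heritable(results: pd.DataFrame, table, metadata: pd.DataFrame,
                     h2_min: float = 0.2, p_max: float = 0.05) -> dict:
    """Apply the heritability screen (h2 > h2_min and p < p_max, both strict)
    and summarize: count, percent of prevalent ASVs, and the per-cohort
    combined relative abundance (mean +/- SD across samples) of the
    heritable set."""
    from .tables import relative_abundance
    flagged = results[(results["h2"] > h2_min) & (results["p"] < p_max)]
    heritable = list(flagged.index)
    n_prev = len(results)
    summary = {
        "n_prevalent": n_prev,
        "n_heritable": len(heritable),
        "pct_heritable": round(100.0 * len(heritable) / n_prev, 1) if n_prev else 0.0,
        "combined_abundance": {},
    }
    props = relative_abundance(table)
    groups = metadata.set_index(metadata.index.astype(str))["group"] \
        if "group" in metadata else None
    if groups is not None:
        for g in sorted(groups.unique()):
            sids = [s for s in props.index if groups.get(s) == g]
            if not sids:
                continue
            comb = props.loc[sids, [a for a in heritable if a in props.columns]] \
                .sum(axis=1) * 100.0
            summary["combined_abundance"][g] = {
                "mean_pct": float(comb.mean()) if len(comb) else 0.0,
                "sd_pct": float(comb.std(ddof=1)) if len(comb) > 1 else 0.0,
            }
    summary["heritable_asvs"] = heritable
    return summary
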