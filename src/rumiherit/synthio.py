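"""Synthetic dam-lamb populations with known genetic architecture.

Emulates a flock of ~128 ewes, each with a litter of 1-4 lambs sired from a
finite ram pool (so littermates are full sibs and some lambs across litters
are paternal half sibs).  Per-ASV latent log-abundances are generated under
the additive + maternal animal model (y = Xb + Za + Wm + e) with the additive
effects drawn jointly from N(0, A*sigma_a2); latent values are mapped to
per-sample compositions by a softmax and to counts by a multinomial draw at a
negative-binomial library size (mean ~35,000 to mimic typical amplicon
depth).  Growth traits (BW, WW; PWG = WW - BW) are linear in designated
causal ASVs' latent values plus a litter-size effect and Gaussian noise.

Everything is driven by a single integer seed, so identical parameters give
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .heritability import Pedigree, a_matrix, make_pedigree, write_pedigree
from .tables import AsvTable


@dataclass
class SynthParams:
    """Generator settings; defaults emulate the study flock.

    Variances are on the latent log-abundance scale and may be scalars
    (shared by all ASVs) or per-ASV arrays.
    """

    n_dams: int = 128
    litter_size_probs: tuple = (0.65, 0.30, 0.04, 0.01)  # sizes 1..4, mean 1.41
    n_sires: int = 12
    n_asvs: int = 100
    sigma_a2: float | np.ndarray = 0.3
    sigma_m2: float | np.ndarray = 0.1
    sigma_e2: float | np.ndarray = 0.6
    base_log_mean_sd: float = 2.0     # spread of per-ASV baseline abundances
    year_season_levels: tuple = ("2019-spring", "2019-summer")
    year_season_effects: tuple = (0.0, 0.15)
    group_effect: float = 0.4         # lamb minus dam shift on latent scale
    age_slope: float = 0.0002         # per day of age
    library_size_mean: float = 35_000.0
    library_size_shape: float = 13.5  # negative-binomial size parameter
    n_trait_asvs: int = 5
    trait_effect_size: float = 1.0    # kg per unit latent value (on WW)
    trait_noise_sd: float = 0.5       # kg
    litter_size_effect: float = -0.4  # kg per extra littermate (on BW and WW)
    bw_mean: float = 4.5              # kg
    ww_mean: float = 22.0             # kg
    dam_age_mean: float = 1033.0      # days
    dam_age_sd: float = 425.0
    lamb_age_mean: float = 60.0
    lamb_age_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.litter_size_probs, float)
        if p.size != 4 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("litter_size_probs must be 4 non-negative values summing to 1")
        for name in ("sigma_a2", "sigma_m2", "sigma_e2"):
            v = np.asarray(getattr(self, name), float)
            if (v < 0).any():
                raise ValueError(f"{name} must be >= 0")
        if self.n_dams < 1:
            raise ValueError("n_dams must be >= 1")
        if self.n_trait_asvs > self.n_asvs:
            raise ValueError("n_trait_asvs must be <= n_asvs")

    def variance_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        out = []
        for name in ("sigma_a2", "sigma_m2", "sigma_e2"):
            v = np.asarray(getattr(self, name), float)
            out.append(np.broadcast_to(v, (self.n_asvs,)).copy())
        return tuple(out)


def simulate_pedigree(params: SynthParams, seed=None):
    """Simulate the flock pedigree.

    Dams and sires are founders; each dam has one litter whose size is drawn
    from ``litter_size_probs`` and whose lambs share a sire drawn from the
    ram pool (littermates are full sibs).  Returns the validated pedigree
    plus a litter table (lamb, dam, sire, litter id, litter size).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    dams = [f"D{i+1:04d}" for i in range(params.n_dams)]
    sires = [f"S{i+1:03d}" for i in range(params.n_sires)]
    records = [(s, None, None) for s in sires] + [(d, None, None) for d in dams]
    sizes = rng.choice([1, 2, 3, 4], size=params.n_dams,
                       p=np.asarray(params.litter_size_probs, float))
    litters = []
    k = 0
    for d, size in zip(dams, sizes):
        sire = sires[rng.integers(0, params.n_sires)]
        litter_id = f"L{d[1:]}"
        for _ in range(int(size)):
            k += 1
            lamb = f"P{k:04d}"
            records.append((lamb, sire, d))
            litters.append({"lamb": lamb, "dam": d, "sire": sire,
                            "litter_id": litter_id, "litter_size": int(size)})
    ped = make_pedigree(records)
    return ped, pd.DataFrame(litters)


def _sample_frame(ped: Pedigree, litters: pd.DataFrame, params: SynthParams,
                  rng: np.random.Generator) -> pd.DataFrame:
    """One rumen sample per dam and per lamb (sires are unsampled)."""
    rows = []
    lamb_info = litters.set_index("lamb")
    dam_sizes = litters.drop_duplicates("dam").set_index("dam")["litter_size"]
    for a in ped.animals:
        if a.startswith("S"):
            continue
        if a.startswith("D"):
            rows.append({"sample": f"smp_{a}", "animal": a, "group": "dam",
                         "age": float(np.round(rng.normal(params.dam_age_mean,
                                                          params.dam_age_sd))),
                         "litter_id": f"L{a[1:]}", "dam_id": "",
                         "litter_size": int(dam_sizes.get(a, 1))})
        else:
            info = lamb_info.loc[a]
            rows.append({"sample": f"smp_{a}", "animal": a, "group": "lamb",
                         "age": float(np.round(rng.normal(params.lamb_age_mean,
                                                          params.lamb_age_sd))),
                         "litter_id": info["litter_id"], "dam_id": info["dam"],
                         "litter_size": int(info["litter_size"])})
    df = pd.DataFrame(rows).set_index("sample")
    df["age"] = df["age"].clip(lower=1.0)
    levels = list(params.year_season_levels)
    df["year_season"] = rng.choice(levels, size=len(df))
    return df


def simulate_asv_table(ped: Pedigree, litters: pd.DataFrame,
                       params: SynthParams, seed=None):
    """Latent log-abundances under the animal model, then compositional counts.

    Per ASV: y = mu + Xb + Za + Wm + e with a ~ N(0, A*sigma_a2) jointly over
    the pedigree, m i.i.d. per dam, e i.i.d. per sample.  Softmax across ASVs
    gives each sample's composition (summing to 1); counts are multinomial at
    a negative-binomial library size.

    Returns (AsvTable, metadata DataFrame, latent DataFrame samples x ASVs).
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    meta = _sample_frame(ped, litters, params, rng)
    n = len(meta)
    d = params.n_asvs
    asv_ids = [f"ASV{j+1}" for j in range(d)]
    A = a_matrix(ped).to_numpy()
    try:
        L = np.linalg.cholesky(A + 1e-10 * np.eye(A.shape[0]))
    except np.linalg.LinAlgError as err:
        raise ValueError("relationship matrix not positive definite; "
                         "pedigree invalid") from err
    idx = ped.index()
    zi = np.array([idx[a] for a in meta["animal"]])
    dam_levels = sorted({dm for dm in meta["dam_id"] if dm})
    dam_pos = {dm: j for j, dm in enumerate(dam_levels)}
    wi = np.array([dam_pos.get(dm, -1) for dm in meta["dam_id"]])

    sa2, sm2, se2 = params.variance_arrays()
    mu = rng.normal(0.0, params.base_log_mean_sd, size=d)
    ys_eff = dict(zip(params.year_season_levels, params.year_season_effects))
    fixed = (meta["year_season"].map(ys_eff).to_numpy(float)
             + np.where(meta["group"] == "lamb", params.group_effect, 0.0)
             + params.age_slope * meta["age"].to_numpy(float))

    # additive values for all pedigree animals, one draw per ASV
    u = rng.standard_normal((A.shape[0], d))
    a_vals = (L @ u) * np.sqrt(sa2)[None, :]
    m_vals = rng.standard_normal((len(dam_levels), d)) * np.sqrt(sm2)[None, :]
    e_vals = rng.standard_normal((n, d)) * np.sqrt(se2)[None, :]

    latent = mu[None, :] + fixed[:, None] + a_vals[zi, :] + e_vals
    has_dam = wi >= 0
    latent[has_dam] += m_vals[wi[has_dam], :]

    # softmax -> composition, multinomial -> counts
    z = latent - latent.max(axis=1, keepdims=True)
    props = np.exp(z)
    props /= props.sum(axis=1, keepdims=True)
    p_nb = params.library_size_shape / (params.library_size_shape
                                        + params.library_size_mean)
    lib = rng.negative_binomial(params.library_size_shape, p_nb, size=n) + 1
    counts = np.empty((n, d), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(lib[i], props[i])
    meta = meta.copy()
    meta["library_size"] = lib

    taxonomy = _synthetic_taxonomy(asv_ids, rng)
    table = AsvTable(pd.DataFrame(counts, index=meta.index, columns=asv_ids),
                     taxonomy)
    latent_df = pd.DataFrame(latent, index=meta.index, columns=asv_ids)
    return table, meta, latent_df


_FAMILIES = ("Prevotellaceae", "Lachnospiraceae", "Ruminococcaceae",
             "Rikenellaceae", "Christensenellaceae", "Atopobiaceae",
             "Succinivibrionaceae", "Anaerovoracaceae")


def _synthetic_taxonomy(asv_ids, rng) -> dict[str, str]:
    """Toy 7-rank lineage strings over a few common rumen families."""
    tax = {}
    for asv in asv_ids:
        fam = _FAMILIES[rng.integers(0, len(_FAMILIES))]
        genus = f"{fam[:-4]}_{rng.integers(1, 4)}"
        tax[asv] = (f"Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;"
                    f"{fam};{genus};{asv}_sp")
    return tax


def simulate_traits(meta: pd.DataFrame, latent: pd.DataFrame,
                    params: SynthParams, seed=None):
    """Lamb growth traits linear in the causal ASVs' latent values.

    BW and WW each get a litter-size effect and Gaussian noise; the causal
    effect enters WW (and hence PWG = WW - BW exactly).  Returns the metadata
    with BW/WW/PWG columns added (NaN for dams) plus the causal ASV list.
    """
    rng = np.random.default_rng(params.seed + 2 if seed is None else seed)
    causal = list(latent.columns[:params.n_trait_asvs])
    meta = meta.copy()
    lambs = meta.index[meta["group"] == "lamb"]
    z = latent.loc[lambs, causal].to_numpy() if causal else np.zeros((len(lambs), 0))
    z = (z - z.mean(axis=0)) if z.size else z
    effect = z.sum(axis=1) * params.trait_effect_size if causal else 0.0
    ls = meta.loc[lambs, "litter_size"].to_numpy(float)
    bw = (params.bw_mean + params.litter_size_effect * (ls - 1)
          + 0.1 * effect
          + rng.normal(0, params.trait_noise_sd, size=len(lambs)))
    ww = (params.ww_mean + 2 * params.litter_size_effect * (ls - 1)
          + effect
          + bw - params.bw_mean
          + rng.normal(0, params.trait_noise_sd, size=len(lambs)))
    for col in ("BW", "WW", "PWG"):
        meta[col] = np.nan
    meta.loc[lambs, "BW"] = bw
    meta.loc[lambs, "WW"] = ww
    meta.loc[lambs, "PWG"] = ww - bw
    return meta, causal


_FERMENTATION = ("NH3-N", "acetate", "propionate", "butyrate",
                 "isobutyrate", "valerate", "isovalerate")


def simulate_fermentation(meta: pd.DataFrame, latent: pd.DataFrame,
                          params: SynthParams, seed=None) -> pd.DataFrame:
    """Rumen fermentation parameters loosely coupled to the causal ASVs."""
    rng = np.random.default_rng(params.seed + 3 if seed is None else seed)
    causal = list(latent.columns[:params.n_trait_asvs])
    meta = meta.copy()
    base = {"NH3-N": 8.0, "acetate": 55.0, "propionate": 18.0, "butyrate": 10.0,
            "isobutyrate": 1.0, "valerate": 1.2, "isovalerate": 1.5}
    for k, var in enumerate(_FERMENTATION):
        drv = latent[causal[k % len(causal)]] if causal else 0.0
        drv = (drv - np.mean(drv)) if causal else 0.0
        vals = base[var] * (1.0 + 0.05 * drv) \
            + rng.normal(0, 0.1 * base[var], size=len(meta))
        meta[var] = np.maximum(np.asarray(vals, float), 0.01)
    return meta


def simulate_tree(asv_ids, seed=0) -> str:
    """Random rooted bifurcating tree over the ASV ids, as a newick string.

    Built by repeated random joins with exponential branch lengths; the same
    seed always yields the byte-identical string.
    """
    asv_ids = list(asv_ids)
    if len(asv_ids) < 2:
        raise ValueError("need at least 2 ASV ids")
    if len(set(asv_ids)) != len(asv_ids):
        raise ValueError("duplicate ASV ids")
    rng = np.random.default_rng(seed)
    nodes = [(aid, 0.0) for aid in asv_ids]  # (newick fragment, height)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        h = max(ha, hb) + float(rng.exponential(0.1)) + 1e-3
        frag = f"({na}:{h - ha:.6f},{nb}:{h - hb:.6f})"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((frag, h))
    return nodes[0][0] + ";"


def simulate_population(params: SynthParams, seed=None):
    """Full synthetic data set: pedigree, ASV table, metadata with traits and
    fermentation parameters, latent matrix, causal ASVs and a newick tree."""
    base = params.seed if seed is None else seed
    ped, litters = simulate_pedigree(params, seed=base)
    table, meta, latent = simulate_asv_table(ped, litters, params, seed=base + 1)
    meta, causal = simulate_traits(meta, latent, params, seed=base + 2)
    meta = simulate_fermentation(meta, latent, params, seed=base + 3)
    tree = simulate_tree(table.asv_ids, seed=base + 4)
    return {"pedigree": ped, "litters": litters, "table": table,
            "metadata": meta, "latent": latent, "causal_asvs": causal,
            "tree_newick": tree}


def write_population(pop: dict, params: SynthParams, outdir) -> None:
    """Serialize a simulated population: counts TSV, metadata TSV, pedigree
    CSV, newick tree and a ground-truth JSON (variances, causal ASVs)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from .tables import write_asv_table
    write_asv_table(pop["table"], out / "asv_table.tsv",
                    taxonomy_path=out / "taxonomy.tsv")
    pop["metadata"].to_csv(out / "metadata.tsv", sep="\t", index_label="sample")
    write_pedigree(pop["pedigree"], out / "pedigree.csv")
    (out / "tree.nwk").write_text(pop["tree_newick"])
    sa2, sm2, se2 = params.variance_arrays()
    truth = {"sigma_a2": sa2.tolist(), "sigma_m2": sm2.tolist(),
             "sigma_e2": se2.tolist(), "causal_asvs": pop["causal_asvs"],
             "seed": params.seed}
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
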