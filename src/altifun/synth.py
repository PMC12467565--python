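"""Synthetic data with the statistical structure each pipeline stage assumes.

Every generator is a pure function of (parameters, seed): the same call
returns bit-identical output. The default scale mirrors the study design —
4 altitude groups × 5 replicate plots, 300 taxa, sequencing depth 10,000 —
small enough for desk-scale null models while leaving each downstream
statistic enough signal to recover the planted truth.

Community regimes
-----------------
``simulate_communities`` draws multinomial count vectors whose expected
composition encodes one of the five assembly processes:

* ``heterogeneous_selection`` / ``homogeneous_selection`` — Gaussian
  environmental filtering of a Brownian-motion trait evolved on the
  phylogeny (so niche conservatism holds and the phylogenetic null model
  has power), with divergent versus common environments across samples;
* ``drift`` — Dirichlet-multinomial resampling around a shared
  metacommunity (demographic noise, no phylogenetic or spatial structure);
* ``dispersal_limitation`` — each sample draws from its own independent
  regional pool;
* ``homogenizing_dispersal`` — every sample drawn straight from the common
  metacommunity pool.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .config import substream
from .exceptions import UsageError
from .io import RANKS, FunctionMatrix, OtuTable, write_function_matrix, write_newick, write_otu_table

REGIMES = [
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
]

DEFAULT_GROUPS = {"HB1": 896.0, "HB2": 1407.0, "HB3": 1597.0, "HB4": 1805.0}

#: 17 ecosystem-function indicators in four groups (4 + 4 + 5 + 4)
DEFAULT_INDICATOR_GROUPS = {
    "soil_TC": "EF-C", "stem_TC": "EF-C", "leaf_TC": "EF-C", "sucrase": "EF-C",
    "soil_TN": "EF-N", "stem_TN": "EF-N", "leaf_TN": "EF-N", "urease": "EF-N",
    "soil_TP": "EF-P", "stem_TP": "EF-P", "leaf_TP": "EF-P",
    "alkaline_phosphatase": "EF-P", "acid_phosphatase": "EF-P",
    "plant_height": "EF-Prod", "stem_biomass": "EF-Prod",
    "leaf_biomass": "EF-Prod", "crown_width": "EF-Prod",
}

__all__ = [
    "REGIMES",
    "DEFAULT_GROUPS",
    "DEFAULT_INDICATOR_GROUPS",
    "SynthTruth",
    "simulate_tree",
    "brownian_traits",
    "simulate_communities",
    "simulate_function_panel",
    "simulate_correlated_taxa",
    "default_path_blocks",
    "default_true_paths",
    "make_study_bundle",
    "write_bundle",
]


@dataclass
class SynthTruth:
    """Ground truth planted by the generators, for recovery tests."""

    regimes: dict[str, str] | None = None
    modules: list[dict] | None = None  # planted network modules
    true_paths: pd.DataFrame | None = None  # [target, source] coefficients
    optima: pd.Series | None = None  # taxon → environmental optimum (trait)
    latents: pd.DataFrame | None = None  # plot × latent block scores
    manifest_panel: pd.DataFrame | None = None  # plot × single-manifest columns
    env_values: dict[str, np.ndarray] | None = None


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int = 0) -> skbio.TreeNode:
    """Random ultrametric pure-birth tree with ``n_tips`` labeled tips.

    Built by successive random joins with exponentially distributed waiting
    times between join events, so every branch length is positive and all
    root-to-tip distances are equal.
    """
    if n_tips < 3:
        raise UsageError("n_tips must be >= 3")
    rng = substream(seed, "simulate_tree")
    names = [f"t{i+1:04d}" for i in range(n_tips)]
    subtrees: list[tuple[str, float]] = [(n, 0.0) for n in names]
    height = 0.0
    while len(subtrees) > 1:
        k = len(subtrees)
        height += rng.exponential(1.0 / k)
        i, j = rng.choice(k, size=2, replace=False)
        (na, ha), (nb, hb) = subtrees[i], subtrees[j]
        merged = f"({na}:{height - ha:.10f},{nb}:{height - hb:.10f})"
        subtrees = [s for idx, s in enumerate(subtrees) if idx not in (i, j)]
        subtrees.append((merged, height))
    newick = subtrees[0][0] + ";"
    return skbio.TreeNode.read([newick], format="newick")


def brownian_traits(tree: skbio.TreeNode, seed: int = 0, sigma: float = 1.0) -> pd.Series:
    """Brownian-motion trait evolved along the tree, standardized across tips."""
    rng = substream(seed, "brownian_traits")
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        bl = node.length or 0.0
        values[id(node)] = values[id(node.parent)] + rng.normal(0.0, sigma * np.sqrt(bl))
    tips = {t.name: values[id(t)] for t in tree.tips()}
    s = pd.Series(tips)
    sd = s.std(ddof=0)
    return (s - s.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _metacommunity(rng: np.random.Generator, n_taxa: int, sigma: float = 1.5) -> np.ndarray:
    logab = rng.normal(0.0, sigma, size=n_taxa)
    p = np.exp(logab)
    return p / p.sum()


def simulate_communities(
    tree: skbio.TreeNode,
    regime: str,
    n_samples: int = 5,
    depth: int = 10_000,
    env_values=None,
    seed: int = 0,
    sample_prefix: str = "S",
    group: str = "G1",
    selection_width: float = 0.5,
    meta_sigma: float = 2.0,
    drift_theta: float = 3.0,
    selection_theta: float = 10.0,
) -> tuple[OtuTable, SynthTruth]:
    """Simulate one group of communities under an assembly regime.

    ``selection_width`` is the Gaussian niche breadth of the environmental
    filter (smaller = stronger selection); ``drift_theta`` the Dirichlet
    concentration of demographic drift around the metacommunity (smaller =
    more drift); ``selection_theta`` adds the same demographic noise inside
    the selection regimes so replicate communities are not carbon copies.
    ``env_values`` defaults to a divergent spread in [−2, 2] for
    heterogeneous selection, and to a common non-central optimum (+1.5
    trait units, which selects a coherent clade tail) for homogeneous
    selection; a Brownian trait has many unrelated lineages near its
    center, so filtering toward the center would not produce the
    phylogenetic clustering the regime is meant to plant.
    """
    if regime not in REGIMES:
        raise UsageError(f"unknown regime {regime!r}; one of {REGIMES}")
    if depth < 1000:
        raise UsageError("depth must be >= 1000")
    rng = substream(seed, f"simulate_communities-{regime}-{group}")
    taxa = sorted(t.name for t in tree.tips())
    n_taxa = len(taxa)
    traits = brownian_traits(tree, seed=seed).loc[taxa].to_numpy()
    meta = _metacommunity(rng, n_taxa, meta_sigma)
    if env_values is None:
        if regime == "heterogeneous_selection":
            env_values = np.linspace(-2.0, 2.0, n_samples)
        elif regime == "homogeneous_selection":
            env_values = np.full(n_samples, 1.5)
        else:
            env_values = np.zeros(n_samples)
    env_values = np.asarray(env_values, dtype=float)
    if len(env_values) != n_samples:
        raise UsageError("env_values length must equal n_samples")
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        if regime in ("heterogeneous_selection", "homogeneous_selection"):
            base = rng.dirichlet(selection_theta * n_taxa * meta + 1e-9)
            fitness = -((traits - env_values[s]) ** 2) / (2.0 * selection_width**2)
            p = base * np.exp(fitness)
            p = p / p.sum()
        elif regime == "drift":
            p = rng.dirichlet(drift_theta * n_taxa * meta + 1e-9)
        elif regime == "dispersal_limitation":
            p = _metacommunity(rng, n_taxa, meta_sigma)  # own regional pool
        else:  # homogenizing_dispersal
            p = meta
        counts[:, s] = rng.multinomial(depth, p)
    sample_ids = [f"{sample_prefix}{s+1}" for s in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=taxa, columns=sample_ids)
    taxonomy = _synthetic_taxonomy(tree, taxa)
    metadata = pd.DataFrame(
        {"group": group, "altitude_m": np.nan, "replicate": np.arange(1, n_samples + 1)},
        index=sample_ids,
    )
    truth = SynthTruth(
        regimes={group: regime},
        optima=pd.Series(traits, index=taxa),
        env_values={group: env_values},
    )
    return OtuTable(counts_df, taxonomy, metadata), truth


def _synthetic_taxonomy(tree: skbio.TreeNode, taxa: list[str],
                        kingdom: str = "Bacteria", n_phyla: int = 6) -> pd.DataFrame:
    """Phyla assigned as contiguous clades in tree tip order; genus = OTU."""
    tip_order = [t.name for t in tree.tips()]
    chunk = int(np.ceil(len(tip_order) / n_phyla))
    phylum_of = {
        name: f"Phylum{i // chunk + 1}" for i, name in enumerate(tip_order)
    }
    df = pd.DataFrame(index=taxa, columns=RANKS, dtype=object)
    df["kingdom"] = kingdom
    df["phylum"] = [phylum_of[t] for t in taxa]
    df["class"] = df["phylum"] + "_c"
    df["order"] = df["phylum"] + "_o"
    df["family"] = df["phylum"] + "_f"
    df["genus"] = ["g_" + t for t in taxa]
    return df


# ---------------------------------------------------------------------------
# planted co-occurrence structure
# ---------------------------------------------------------------------------

def simulate_correlated_taxa(
    module_sizes=(10, 10),
    n_background: int = 30,
    n_samples: int = 20,
    depth: int = 10_000,
    neg_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[OtuTable, SynthTruth]:
    """Taxa with planted co-occurrence modules driven by shared latent factors.

    Each module has one latent log-abundance factor per sample; member taxa
    load on it with sign +1 (the first ``1−neg_fraction``) or −1, so the
    expected edge sign inside a module is the product of the loadings.
    Background taxa are independent noise and carry most of the community
    mass, which keeps the compositional (closure-induced) correlations
    between unrelated taxa well below any sensible edge cutoff.
    """
    rng = substream(seed, "simulate_correlated_taxa")
    rows = []
    names = []
    modules = []
    # module factors are orthogonalized across samples so planted modules
    # are independent by construction, not just in expectation
    raw = rng.normal(0.0, 1.0, size=(n_samples, len(module_sizes)))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    factors = q * np.sqrt(n_samples)
    for m, size in enumerate(module_sizes):
        factor = factors[:, m]
        n_neg = int(round(neg_fraction * size))
        loadings = np.array([1.0] * (size - n_neg) + [-1.0] * n_neg)
        members = []
        for t in range(size):
            name = f"m{m+1}_t{t+1:03d}"
            base = rng.normal(-2.0, 0.3)
            logab = base + 1.2 * loadings[t] * factor + 0.3 * rng.normal(size=n_samples)
            rows.append(logab)
            names.append(name)
            members.append({"taxon": name, "loading": float(loadings[t])})
        modules.append({"module": m + 1, "members": members})
    for t in range(n_background):
        names.append(f"bg_t{t+1:03d}")
        rows.append(rng.normal(2.0, 0.3) + 0.8 * rng.normal(size=n_samples))
    logab = np.array(rows)
    p = np.exp(logab)
    p = p / p.sum(axis=0)
    counts = np.column_stack(
        [rng.multinomial(depth, p[:, s]) for s in range(n_samples)]
    )
    sample_ids = [f"S{s+1}" for s in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=names, columns=sample_ids)
    taxonomy = pd.DataFrame(index=names, columns=RANKS, dtype=object)
    taxonomy["kingdom"] = "Bacteria"
    taxonomy["phylum"] = ["Module" + n.split("_")[0][1:] if n.startswith("m") else "Background" for n in names]
    taxonomy["genus"] = ["g_" + n for n in names]
    taxonomy = taxonomy.fillna("Unclassified")
    metadata = pd.DataFrame({"group": "G1", "replicate": range(1, n_samples + 1)},
                            index=sample_ids)
    return OtuTable(counts_df, taxonomy, metadata), SynthTruth(modules=modules)


# ---------------------------------------------------------------------------
# function panel with known path structure
# ---------------------------------------------------------------------------

PATH_BLOCK_ORDER = [
    "altitude", "pH", "bacteria", "fungi", "EF-C", "EF-N", "EF-P", "EF-Prod", "EMF",
]


def default_true_paths() -> pd.DataFrame:
    """Plausible default inner model over the ordered latent blocks.

    Signs echo the study system: altitude raises N/P nutrient functions,
    pH helps nitrogen but hurts carbon cycling, bacteria promote and fungi
    suppress nutrient functions and multifunctionality.
    """
    pm = pd.DataFrame(0.0, index=PATH_BLOCK_ORDER, columns=PATH_BLOCK_ORDER)
    edges = {
        ("pH", "altitude"): -0.5,
        ("bacteria", "altitude"): 0.3,
        ("fungi", "altitude"): 0.4,
        ("EF-C", "pH"): -0.4,
        ("EF-C", "bacteria"): 0.5,
        ("EF-C", "fungi"): -0.35,
        ("EF-N", "altitude"): 0.5,
        ("EF-N", "pH"): 0.4,
        ("EF-N", "fungi"): -0.3,
        ("EF-P", "altitude"): 0.4,
        ("EF-P", "fungi"): -0.3,
        ("EF-Prod", "altitude"): 0.45,
        ("EMF", "EF-C"): 0.4,
        ("EMF", "EF-N"): 0.25,
        ("EMF", "EF-P"): 0.3,
        ("EMF", "fungi"): -0.25,
    }
    for (t, s), v in edges.items():
        pm.loc[t, s] = v
    return pm


def default_path_blocks(single_manifest: bool = False) -> dict[str, list[str]]:
    """Block → manifest map matching the synthetic panel's column names."""
    if single_manifest:
        return {b: [f"{b}_m"] for b in PATH_BLOCK_ORDER}
    blocks: dict[str, list[str]] = {
        "altitude": ["altitude_m"],
        "pH": ["pH_m"],
        "bacteria": ["bacteria_ax1", "bacteria_ax2"],
        "fungi": ["fungi_ax1", "fungi_ax2"],
        "EMF": ["EMF_m"],
    }
    for g in ("EF-C", "EF-N", "EF-P", "EF-Prod"):
        blocks[g] = [i for i, grp in DEFAULT_INDICATOR_GROUPS.items() if grp == g]
    return blocks


def simulate_function_panel(
    n_plots_per_group: int = 5,
    true_paths: pd.DataFrame | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    groups: dict[str, float] | None = None,
    loading: float = 0.9,
) -> tuple[FunctionMatrix, SynthTruth]:
    """Plot × indicator panel generated from a linear latent path structure.

    Latent block scores follow the structural equations given by
    ``true_paths`` (entry [target, source]); residual variances are chosen
    so every latent has unit variance, which makes the entries directly
    comparable to standardized PLS path coefficients. Indicators are
    ``loading``·latent + ``noise_sd``·noise mapped onto plausible
    measurement scales; min–max standardization downstream removes the
    affine part.
    """
    groups = dict(groups or DEFAULT_GROUPS)
    pm = default_true_paths() if true_paths is None else true_paths
    order = list(pm.index)
    # acyclicity over the declared order: only earlier blocks may feed later ones
    upper = np.triu(pm.loc[order, order].to_numpy(), k=0)
    if np.any(upper != 0):
        raise UsageError("true_paths must be acyclic over the declared block order")
    if (pm.abs() > 1).any().any():
        raise UsageError("|true path coefficients| must be <= 1")
    rng = substream(seed, "simulate_function_panel")
    n_groups = len(groups)
    n = n_plots_per_group * n_groups
    plot_ids = [f"{g}_p{r+1}" for g in groups for r in range(n_plots_per_group)]
    plot_groups = pd.Series(
        [g for g in groups for _ in range(n_plots_per_group)], index=plot_ids, name="group"
    )
    alt_raw = np.array([groups[g] for g in plot_groups], dtype=float)
    z = pd.DataFrame(index=plot_ids, columns=order, dtype=float)
    z["altitude"] = (alt_raw - alt_raw.mean()) / alt_raw.std(ddof=0)
    # analytic latent covariance, advanced block by block
    cov = pd.DataFrame(0.0, index=order, columns=order)
    cov.loc["altitude", "altitude"] = 1.0
    for b in order[1:]:
        beta = pm.loc[b, order]
        preds = beta[beta != 0].index.tolist()
        if not preds:
            e = rng.normal(size=n)
            z[b] = (e - e.mean()) / e.std(ddof=0)
            cov.loc[b, b] = 1.0
            continue
        bvec = beta.loc[preds].to_numpy()
        sigma_pp = cov.loc[preds, preds].to_numpy()
        explained = float(bvec @ sigma_pp @ bvec)
        if explained >= 0.95:
            raise UsageError(
                f"block {b!r}: structural part explains {explained:.2f} of unit "
                "variance; reduce path coefficients"
            )
        resid_sd = np.sqrt(1.0 - explained)
        z[b] = z[preds].to_numpy() @ bvec + resid_sd * rng.normal(size=n)
        cross = sigma_pp @ bvec
        for p_, c_ in zip(preds, cross):
            cov.loc[b, p_] = cov.loc[p_, b] = c_
        # covariance with non-predecessor earlier blocks via their cov with preds
        for other in order[: order.index(b)]:
            if other in preds:
                continue
            val = float(cov.loc[other, preds].to_numpy() @ bvec)
            cov.loc[b, other] = cov.loc[other, b] = val
        cov.loc[b, b] = 1.0
    # --- indicators on measurement scales ---
    scales = {
        "soil_TC": (25.0, 6.0), "stem_TC": (440.0, 30.0), "leaf_TC": (460.0, 25.0),
        "sucrase": (18.0, 4.0),
        "soil_TN": (2.1, 0.5), "stem_TN": (12.0, 2.5), "leaf_TN": (28.0, 4.0),
        "urease": (0.9, 0.2),
        "soil_TP": (0.65, 0.12), "stem_TP": (1.4, 0.3), "leaf_TP": (2.1, 0.4),
        "alkaline_phosphatase": (1.1, 0.25), "acid_phosphatase": (2.4, 0.5),
        "plant_height": (75.0, 15.0), "stem_biomass": (9.0, 2.0),
        "leaf_biomass": (6.5, 1.5), "crown_width": (48.0, 9.0),
    }
    values = {}
    for ind, grp in DEFAULT_INDICATOR_GROUPS.items():
        mu, sd = scales[ind]
        core = loading * z[grp] + noise_sd * rng.normal(size=n)
        values[ind] = mu + sd * core
    fm = FunctionMatrix(pd.DataFrame(values, index=plot_ids),
                        dict(DEFAULT_INDICATOR_GROUPS), plot_groups)
    manifest = pd.DataFrame(index=plot_ids)
    manifest["altitude_m"] = z["altitude"]
    for b in ("pH", "EF-C", "EF-N", "EF-P", "EF-Prod", "EMF"):
        manifest[f"{b}_m"] = z[b] + noise_sd * rng.normal(size=n)
    for b in ("bacteria", "fungi"):
        manifest[f"{b}_m"] = z[b] + noise_sd * rng.normal(size=n)
        for ax in (1, 2):
            manifest[f"{b}_ax{ax}"] = loading * z[b] + noise_sd * rng.normal(size=n)
    manifest = manifest.join(fm.values)
    manifest["pH"] = 7.3 + 0.25 * manifest["pH_m"]
    truth = SynthTruth(true_paths=pm, latents=z, manifest_panel=manifest)
    return fm, truth


# ---------------------------------------------------------------------------
# full study bundle
# ---------------------------------------------------------------------------

DEFAULT_BACTERIAL_REGIMES = {
    "HB1": "drift", "HB2": "drift", "HB3": "drift", "HB4": "heterogeneous_selection",
}
DEFAULT_FUNGAL_REGIMES = {
    "HB1": "dispersal_limitation", "HB2": "dispersal_limitation",
    "HB3": "drift", "HB4": "homogenizing_dispersal",
}


@dataclass
class StudyBundle:
    """Everything the full pipeline consumes, with planted ground truth."""

    tables: dict[str, OtuTable]  # community name → OtuTable
    trees: dict[str, skbio.TreeNode]
    function_matrix: FunctionMatrix
    truth: dict[str, SynthTruth] = field(default_factory=dict)

    @property
    def enzymes(self) -> pd.DataFrame:
        v = self.function_matrix.values
        return pd.DataFrame(
            {
                "CEs": v["sucrase"],
                "NEs": v["urease"],
                "PEs": v["alkaline_phosphatase"] + v["acid_phosphatase"],
            }
        )

    @property
    def soil_chemistry(self) -> pd.DataFrame:
        v = self.function_matrix.values
        out = pd.DataFrame(
            {"TC": v["soil_TC"], "TN": v["soil_TN"], "TP": v["soil_TP"]}
        )
        truth = self.truth.get("panel")
        if truth is not None and truth.manifest_panel is not None:
            out["pH"] = truth.manifest_panel["pH"]
        return out


def make_study_bundle(
    seed: int = 0,
    n_taxa: int = 300,
    reps: int = 5,
    depth: int = 10_000,
    groups: dict[str, float] | None = None,
    bacterial_regimes: dict[str, str] | None = None,
    fungal_regimes: dict[str, str] | None = None,
    communities: tuple[str, ...] = ("bacteria", "fungi"),
) -> StudyBundle:
    """Simulate the whole study: two communities over 4 altitude groups ×
    ``reps`` plots, a shared function panel, enzymes and soil chemistry."""
    groups = dict(groups or DEFAULT_GROUPS)
    regimes_by_comm = {
        "bacteria": dict(bacterial_regimes or DEFAULT_BACTERIAL_REGIMES),
        "fungi": dict(fungal_regimes or DEFAULT_FUNGAL_REGIMES),
    }
    tables: dict[str, OtuTable] = {}
    trees: dict[str, skbio.TreeNode] = {}
    truth: dict[str, SynthTruth] = {}
    for ci, comm in enumerate(communities):
        regimes = regimes_by_comm[comm]
        tree = simulate_tree(n_taxa, seed=seed * 7919 + ci)
        counts_parts, meta_parts = [], []
        optima = None
        envs = {}
        for gi, (g, alt) in enumerate(groups.items()):
            tab, tr = simulate_communities(
                tree,
                regimes[g],
                n_samples=reps,
                depth=depth,
                seed=seed * 104729 + ci * 97 + gi,
                sample_prefix=f"{comm[:1].upper()}{g}_r",
                group=g,
            )
            md = tab.metadata.copy()
            md["altitude_m"] = alt
            counts_parts.append(tab.counts)
            meta_parts.append(md)
            optima = tr.optima
            envs[g] = tr.env_values[g]
        counts = pd.concat(counts_parts, axis=1)
        metadata = pd.concat(meta_parts)
        taxonomy = _synthetic_taxonomy(
            tree, list(counts.index),
            kingdom="Bacteria" if comm == "bacteria" else "Fungi",
        )
        tables[comm] = OtuTable(counts, taxonomy, metadata)
        trees[comm] = tree
        truth[comm] = SynthTruth(regimes=regimes, optima=optima, env_values=envs)
    fm, panel_truth = simulate_function_panel(
        n_plots_per_group=reps, seed=seed, groups=groups
    )
    truth["panel"] = panel_truth
    return StudyBundle(tables, trees, fm, truth)


def write_bundle(bundle: StudyBundle, out_dir) -> dict[str, str]:
    """Write the full input bundle as plain text plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for comm, tab in bundle.tables.items():
        for kind, p in write_otu_table(tab, out, prefix=f"{comm}_").items():
            paths[f"{comm}_{kind}"] = str(p)
        tree_path = out / f"{comm}_tree.nwk"
        write_newick(bundle.trees[comm], tree_path)
        paths[f"{comm}_tree"] = str(tree_path)
    for kind, p in write_function_matrix(bundle.function_matrix, out).items():
        paths[f"function_{kind}"] = str(p)
    bundle.enzymes.to_csv(out / "enzymes.csv")
    paths["enzymes"] = str(out / "enzymes.csv")
    bundle.soil_chemistry.to_csv(out / "soil_chemistry.csv")
    paths["soil_chemistry"] = str(out / "soil_chemistry.csv")
    truth_doc = {}
    for key, tr in bundle.truth.items():
        truth_doc[key] = {
            "regimes": tr.regimes,
            "true_paths": None
            if tr.true_paths is None
            else {
                f"{s}->{t}": float(tr.true_paths.loc[t, s])
                for t in tr.true_paths.index
                for s in tr.true_paths.columns
                if tr.true_paths.loc[t, s] != 0
            },
        }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=2)
    paths["truth"] = str(out / "truth.json")
    return paths
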