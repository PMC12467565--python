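"""End-to-end orchestration of the study workflow.

``run_study`` sequences the stages — relative abundance, alpha diversity,
ordination + ANOSIM, co-occurrence networks, assembly null models,
stoichiometry, multifunctionality with ANOVA letters, PLS path model and
RDA — on real or synthetic inputs and collects every result surface as a
machine-readable table. A stage whose inputs are absent (e.g. no phylogeny
for a community) is marked skipped instead of failing the run.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from . import assembly as asm
from . import community as comm
from . import inference, multifun, network
from .plspm import plspm as fit_plspm
from .config import RunConfig, spawn_seed
from .exceptions import AltifunError, UsageError
from .io import FunctionMatrix, OtuTable, write_network

__all__ = ["StudyInputs", "StudyReport", "run_study"]

SCHEMA_VERSION = 1


@dataclass
class StudyInputs:
    tables: dict[str, OtuTable]
    trees: dict[str, skbio.TreeNode] = field(default_factory=dict)
    function_matrix: FunctionMatrix | None = None
    enzymes: pd.DataFrame | None = None
    soil_chemistry: pd.DataFrame | None = None


@dataclass
class StudyReport:
    config: RunConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, dict] = field(default_factory=dict)
    networks: dict[str, network.CoNetwork] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION

    def to_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            df.to_csv(out / f"{name}.csv")
        for name, net in sorted(self.networks.items()):
            write_network(net, out / f"{name}.graphml", format="graphml")
        meta = {
            "schema_version": self.schema_version,
            "config": self.config.__dict__,
            "skipped": sorted(self.skipped),
            "scalars": self.scalars,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True, default=float)


def run_study(inputs: StudyInputs, config: RunConfig | None = None) -> StudyReport:
    """Run every stage in dependency order; see module docstring."""
    cfg = config or RunConfig()
    if not inputs.tables:
        raise UsageError("no community tables supplied")
    rep = StudyReport(config=cfg)
    for name, tab in inputs.tables.items():
        _community_stages(rep, name, tab, cfg)
        tree = inputs.trees.get(name)
        if tree is None:
            rep.skipped.append(f"{name}:assembly (no tree)")
        else:
            _assembly_stage(rep, name, tab, tree, cfg)
    if inputs.function_matrix is None:
        rep.skipped.append("multifunctionality (no function matrix)")
    else:
        _function_stages(rep, inputs, cfg)
    return rep


def _community_stages(rep: StudyReport, name: str, tab: OtuTable, cfg: RunConfig) -> None:
    ab = comm.aggregate_relative_abundance(tab, rank="phylum")
    rep.tables[f"{name}_phylum_abundance"] = ab.proportions
    rep.tables[f"{name}_phylum_group_means"] = ab.group_means()
    alpha = comm.alpha_diversity(tab)
    rep.tables[f"{name}_alpha_diversity"] = alpha
    letters = {}
    for metric in ("chao1", "shannon"):
        try:
            res = inference.anova_lsd(alpha[metric], tab.groups)
            letters[metric] = res.letters
        except AltifunError:
            rep.skipped.append(f"{name}:alpha_anova_{metric}")
    if letters:
        rep.tables[f"{name}_alpha_letters"] = pd.DataFrame(letters)
    dm = comm.bray_curtis(tab)
    rep.tables[f"{name}_bray_curtis"] = dm
    ord_ = comm.pcoa(dm, n_axes=2)
    rep.tables[f"{name}_pcoa"] = ord_.coordinates
    rep.scalars[f"{name}_pcoa_proportion_explained"] = {
        f"PCo{i+1}": float(p) for i, p in enumerate(ord_.proportion_explained)
    }
    rep.scalars[f"{name}_anosim"] = comm.anosim(
        dm, tab.groups, n_permutations=cfg.n_permutations,
        seed=spawn_seed(cfg.seed, f"anosim-{name}"),
    )
    try:
        net = network.build_conetwork(
            tab, rank="genus", r_cut=cfg.r_cut, p_cut=cfg.p_cut,
            min_prevalence=cfg.min_prevalence,
        )
        topo = network.topology(net, seed=spawn_seed(cfg.seed, f"topology-{name}"))
        rep.networks[f"{name}_network"] = net
        rep.tables[f"{name}_topology"] = topo.as_series().to_frame(name).T
    except AltifunError as exc:
        rep.skipped.append(f"{name}:network ({exc})")


def _assembly_stage(rep: StudyReport, name: str, tab: OtuTable,
                    tree: skbio.TreeNode, cfg: RunConfig) -> None:
    groups = tab.groups
    pairs = [
        (a, b)
        for _, members in groups.groupby(groups)
        for i, a in enumerate(list(members.index))
        for b in list(members.index)[i + 1:]
    ]
    bnti = asm.beta_nti(
        tab, tree, n_nulls=cfg.n_nulls,
        seed=spawn_seed(cfg.seed, f"bnti-{name}"), pairs=pairs,
    )
    rc = asm.raup_crick_bray(
        tab, n_nulls=cfg.n_nulls,
        seed=spawn_seed(cfg.seed, f"rc-{name}"), pairs=pairs,
    )
    result = asm.partition_processes(
        bnti, rc, groups, bnti_cut=cfg.bnti_cut, rc_cut=cfg.rc_cut
    )
    rep.tables[f"{name}_beta_nti"] = bnti
    rep.tables[f"{name}_raup_crick"] = rc
    rep.tables[f"{name}_assembly_fractions"] = result.fractions
    rep.scalars[f"{name}_assembly_dominant"] = result.dominant.to_dict()


def _function_stages(rep: StudyReport, inputs: StudyInputs, cfg: RunConfig) -> None:
    fm = inputs.function_matrix
    emf = multifun.emf_result(fm)
    table = emf.ef.copy()
    table["EMF"] = emf.emf
    table["group"] = fm.plot_groups.loc[table.index]
    rep.tables["ef_emf"] = table
    rep.tables["ef_emf_correlations"] = emf.correlations
    letters = {}
    for col in [c for c in table.columns if c != "group"]:
        try:
            res = inference.anova_lsd(table[col], fm.plot_groups)
            letters[col] = res.letters
        except AltifunError:
            rep.skipped.append(f"anova:{col}")
    if letters:
        rep.tables["ef_emf_letters"] = pd.DataFrame(letters)
    if inputs.soil_chemistry is not None and {"TC", "TN", "TP"} <= set(
        inputs.soil_chemistry.columns
    ):
        rep.tables["element_ratios"] = multifun.element_ratios(inputs.soil_chemistry)
    else:
        rep.skipped.append("element_ratios (no soil chemistry)")
    if inputs.enzymes is not None:
        stoich = multifun.enzyme_vector(inputs.enzymes, convention=cfg.va_convention)
        st = stoich.ratios.copy()
        st["VL"] = stoich.vector_length
        st = st.join(stoich.vector_angle)
        st["limitation"] = stoich.limitation
        rep.tables["enzyme_stoichiometry"] = st
    else:
        rep.skipped.append("enzyme_stoichiometry (no enzyme activities)")
    _ordination_models(rep, inputs, emf, cfg)


def _ordination_models(rep: StudyReport, inputs: StudyInputs,
                       emf: multifun.EmfResult, cfg: RunConfig) -> None:
    """RDA of phylum composition on function indices and the PLS path model."""
    fm = inputs.function_matrix
    plots = list(fm.values.index)
    # EF-Prod is kept out: EMF already carries it, and including all four
    # groups plus their exact mean would make X singular
    nutrient_efs = [g for g in ("EF-C", "EF-N", "EF-P") if g in emf.ef.columns]
    explanatory = emf.ef[nutrient_efs].copy()
    explanatory["EMF"] = emf.emf
    if inputs.soil_chemistry is not None and "pH" in inputs.soil_chemistry.columns:
        explanatory["pH"] = inputs.soil_chemistry.loc[plots, "pH"]
    axes: dict[str, pd.DataFrame] = {}
    for name, tab in inputs.tables.items():
        if len(tab.sample_ids) != len(plots):
            rep.skipped.append(f"rda:{name} (plots/samples mismatch)")
            continue
        ab = comm.aggregate_relative_abundance(tab, rank="phylum")
        rel = ab.proportions.T  # samples × phyla, aligned by position to plots
        rel.index = plots
        try:
            res = inference.rda(inference.hellinger(rel), explanatory)
        except AltifunError as exc:
            rep.skipped.append(f"rda:{name} ({exc})")
            continue
        rep.scalars[f"{name}_rda"] = {
            "proportion_explained": res.proportion_explained,
            "axis_proportions": [float(p) for p in res.axis_proportions[:2]],
        }
        rep.tables[f"{name}_rda_biplot"] = res.biplot_scores
        dm = comm.bray_curtis(tab)
        coords = comm.pcoa(dm, n_axes=2).coordinates
        coords.index = plots
        axes[name] = coords
    _plspm_stage(rep, inputs, emf, axes, cfg)


def _plspm_stage(rep: StudyReport, inputs: StudyInputs, emf: multifun.EmfResult,
                 axes: dict[str, pd.DataFrame], cfg: RunConfig) -> None:
    fm = inputs.function_matrix
    plots = list(fm.values.index)
    if inputs.soil_chemistry is None or "pH" not in getattr(
        inputs.soil_chemistry, "columns", []
    ):
        rep.skipped.append("plspm (no pH)")
        return
    data = pd.DataFrame(index=plots)
    meta = fm.plot_groups.loc[plots]
    alt = (
        inputs.tables[next(iter(inputs.tables))]
        .metadata.groupby("group")["altitude_m"]
        .first()
    )
    if alt.isna().any():
        rep.skipped.append("plspm (no altitude metadata)")
        return
    data["altitude"] = alt.loc[meta].to_numpy()
    data["pH"] = inputs.soil_chemistry.loc[plots, "pH"].to_numpy()
    blocks: dict[str, list[str]] = {"altitude": ["altitude"], "pH": ["pH"]}
    order = ["altitude", "pH"]
    for name, coords in axes.items():
        cols = [f"{name}_ax1", f"{name}_ax2"]
        data[cols[0]] = coords.iloc[:, 0]
        data[cols[1]] = coords.iloc[:, 1] if coords.shape[1] > 1 else coords.iloc[:, 0]
        blocks[name] = cols
        order.append(name)
    for g in ("EF-C", "EF-N", "EF-P"):
        if g in emf.ef.columns:
            data[g] = emf.ef[g]
            blocks[g] = [g]
            order.append(g)
    data["EMF"] = emf.emf
    blocks["EMF"] = ["EMF"]
    order.append("EMF")
    pm = pd.DataFrame(0, index=order, columns=order)
    for t in order[1:]:
        for s in order[: order.index(t)]:
            if s in ("EF-C", "EF-N", "EF-P") and t != "EMF":
                continue  # nutrient functions feed EMF, not each other
            pm.loc[t, s] = 1
    try:
        model = fit_plspm(
            data, blocks, pm, n_bootstrap=cfg.n_bootstrap,
            seed=spawn_seed(cfg.seed, "plspm"),
        )
    except AltifunError as exc:
        rep.skipped.append(f"plspm ({exc})")
        return
    rep.tables["plspm_paths"] = model.path_table.set_index(["source", "target"])
    rep.scalars["plspm"] = {
        "gof": model.gof,
        "r_squared": {k: float(v) for k, v in model.r_squared.items()},
    }
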