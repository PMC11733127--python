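"""Synthetic culturomics experiments with known ground truth.

Emulates the statistical structure of a donor x media-modification
cultivation campaign read out by shotgun sequencing:

* donor-dominated baseline composition (shared log-normal core plus a
  donor-specific log-normal perturbation),
* modification-specific growth effects with phylogenetic signal
  (Brownian motion on a Yule tree, plus i.i.d. noise),
* clade-level kills emulating antibiotic-like modifications,
* a planted low-abundance target taxon boosted in a known
  "supporting set" of modifications (ground truth for design
  recovery), and
* multinomial sequencing-depth noise producing sparse detection.

Every stochastic operation takes an explicit seed; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import DataValueError, UsageError
from .tables_io import (
    BASE_MODIFICATION,
    RANKS,
    AbundanceTable,
    write_abundance_table,
    write_metadata,
    write_newick,
    write_taxonomy,
)

# Default experiment dimensions: a desk-scale analog of a 6-donor x
# 50-modification campaign (full size available via parameters).
DEFAULT_N_TAXA = 150
DEFAULT_N_DONORS = 6
DEFAULT_N_MODIFICATIONS = 20
DEFAULT_DEPTH = 50_000
DEFAULT_DELTA = 4.0
DEFAULT_N_SUPPORTING = 5

# Baseline composition: shared log-normal core (sigma=1.5) plus a
# donor-specific log-normal perturbation (sigma=0.8) so donor identity
# dominates composition while modifications still shift it.
SIGMA_CORE = 1.5
SIGMA_DONOR = 0.8

# Modification effects: Brownian motion on the tree (per unit branch
# length) plus i.i.d. noise per taxon; kills hit whole clades.
DEFAULT_SIGMA_PHYLO = 1.0
DEFAULT_SIGMA_IID = 0.4
DEFAULT_P_KILL = 0.3

# Default taxonomy depth cuts, as fractions of tree height
# (phylum, class, order, family, genus); chosen so a 150-leaf tree
# yields realistic rank counts (~6 phyla, ~120 genera).
DEFAULT_DEPTH_CUT_FRACTIONS = (0.07, 0.16, 0.28, 0.44, 0.62)

_BRANCH_SCALE = 0.1  # mean of exponential branch lengths


@dataclass
class CommunityModel:
    """Generative parameters for one simulated cultivation campaign."""

    tree: TreeNode
    donor_baselines: pd.DataFrame  # donors x taxa, > 0
    log_effects: pd.DataFrame  # modifications x taxa, "Base" row all 0
    kill_mask: pd.DataFrame  # modifications x taxa, bool

    def __post_init__(self) -> None:
        taxa = [t.name for t in self.tree.tips()]
        for frame in (self.donor_baselines, self.log_effects, self.kill_mask):
            if sorted(frame.columns) != sorted(taxa):
                raise DataValueError("model matrices must cover exactly the tree leaves")
        if (self.donor_baselines.to_numpy() <= 0).any():
            raise DataValueError("donor baselines must be positive")
        if BASE_MODIFICATION not in self.log_effects.index:
            raise DataValueError("log_effects must contain the 'Base' row")
        if not np.allclose(self.log_effects.loc[BASE_MODIFICATION].to_numpy(), 0.0):
            raise DataValueError("'Base' log-effects row must be identically zero")
        if self.kill_mask.loc[BASE_MODIFICATION].any():
            raise DataValueError("'Base' kill-mask row must be all false")

    @property
    def taxa(self) -> list[str]:
        return list(self.log_effects.columns)

    @property
    def donor_ids(self) -> list[str]:
        return list(self.donor_baselines.index)

    @property
    def modification_ids(self) -> list[str]:
        return list(self.log_effects.index)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass(frozen=True)
class GroundTruth:
    """Planted enrichment target: what a design run should recover."""

    target_feature: str
    supporting_set: frozenset[str]
    delta: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_feature": self.target_feature,
                "supporting_set": sorted(self.supporting_set),
                "delta": self.delta,
                "seed": self.seed,
            },
            indent=2,
        )


@dataclass(frozen=True)
class FunctionCatalog:
    """Mapping between taxa and the KO gene families they carry."""

    features_to_kos: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for feature, kos in self.features_to_kos.items():
            for ko in kos:
                if not (len(ko) == 6 and ko[0] == "K" and ko[1:].isdigit()):
                    raise DataValueError(f"malformed KO id {ko!r} for {feature!r}")

    @property
    def ko_ids(self) -> list[str]:
        return sorted({ko for kos in self.features_to_kos.values() for ko in kos})

    def carriers(self, ko: str) -> frozenset[str]:
        return frozenset(
            f for f, kos in self.features_to_kos.items() if ko in kos
        )


# ---------------------------------------------------------------------------
# tree + taxonomy
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Rooted Yule (pure-birth) tree with exponential branch lengths.

    Topology is grown by repeatedly bifurcating a uniformly chosen
    current leaf; each edge then gets an i.i.d. Exponential(mean 0.1)
    length.  Leaves are named ``mOTU_0001`` ... in postorder.
    """
    if n_taxa < 2:
        raise UsageError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None)
    leaves = [root]
    while len(leaves) < n_taxa:
        idx = int(rng.integers(len(leaves)))
        parent = leaves.pop(idx)
        children = [TreeNode(), TreeNode()]
        parent.extend(children)
        leaves.extend(children)
    counter = 0
    for node in root.postorder(include_self=True):
        if node.is_tip():
            counter += 1
            node.name = f"mOTU_{counter:04d}"
        if node is not root:
            node.length = float(rng.exponential(_BRANCH_SCALE))
    root.length = 0.0
    return root


def _node_depths(tree: TreeNode) -> dict[int, float]:
    depths: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depths[id(node)] = depths[id(node.parent)] + (node.length or 0.0)
    return depths


def tree_height(tree: TreeNode) -> float:
    depths = _node_depths(tree)
    return max(depths[id(t)] for t in tree.tips())


def taxonomy_from_tree(
    tree: TreeNode, depth_cuts: Sequence[float]
) -> pd.DataFrame:
    """Derive a nested six-rank taxonomy by cutting the tree at depths.

    ``depth_cuts`` are five strictly increasing depths assigned to
    phylum..genus; the clade below the edge crossing each cut becomes
    the rank label.  Species is the leaf itself.  Because cuts
    increase, labels nest (each genus lies within one family, etc.).
    """
    cuts = list(depth_cuts)
    if len(cuts) != 5:
        raise UsageError("exactly 5 depth cuts required (phylum..genus)")
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise UsageError("depth cuts must be strictly increasing")
    height = tree_height(tree)
    if cuts[0] <= 0 or cuts[-1] >= height:
        raise UsageError(f"depth cuts must lie within (0, tree height={height:.4g})")

    depths = _node_depths(tree)
    # clade labels per (rank, node) assigned in preorder for determinism
    label_maps: list[dict[int, str]] = [dict() for _ in cuts]
    counters = [0] * len(cuts)
    prefixes = ("p", "c", "o", "f", "g")

    rows = {}
    for leaf in tree.tips():
        path = list(leaf.ancestors())[::-1] + [leaf]  # root .. leaf
        lineage: dict[str, str] = {}
        for k, cut in enumerate(cuts):
            crossing = None
            for node in path[1:]:  # skip root (depth 0)
                if depths[id(node)] >= cut:
                    crossing = node
                    break
            if crossing is None:  # leaf shallower than cut
                crossing = leaf
            key = id(crossing)
            if key not in label_maps[k]:
                counters[k] += 1
                label_maps[k][key] = f"{prefixes[k]}__{counters[k]:03d}"
            lineage[RANKS[k]] = label_maps[k][key]
        lineage["species"] = leaf.name
        rows[leaf.name] = lineage
    taxonomy = pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)]
    taxonomy.index.name = "feature_id"
    return taxonomy


def default_depth_cuts(tree: TreeNode) -> list[float]:
    height = tree_height(tree)
    return [f * height for f in DEFAULT_DEPTH_CUT_FRACTIONS]


# ---------------------------------------------------------------------------
# modification effects
# ---------------------------------------------------------------------------

def _leaf_edge_incidence(tree: TreeNode) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Leaves, leaf x edge 0/1 incidence, and edge lengths (non-root nodes)."""
    edges = [n for n in tree.preorder(include_self=False)]
    index = {id(n): i for i, n in enumerate(edges)}
    lengths = np.array([n.length or 0.0 for n in edges])
    leaves = [t.name for t in tree.tips()]
    incidence = np.zeros((len(leaves), len(edges)))
    for li, leaf in enumerate(tree.tips()):
        node = leaf
        while node.parent is not None:
            incidence[li, index[id(node)]] = 1.0
            node = node.parent
    return leaves, incidence, lengths


def simulate_effects(
    tree: TreeNode,
    modification_ids: Sequence[str],
    sigma_phylo: float,
    sigma_iid: float,
    p_kill: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-modification log growth multipliers with phylogenetic signal.

    For each non-Base modification the taxon effects are a Brownian
    draw on the tree — each edge contributes N(0, sigma_phylo^2 * L)
    shared by all descendant leaves, so a leaf pair's covariance is
    sigma_phylo^2 times their shared root-path length — plus
    N(0, sigma_iid^2) i.i.d. noise.  With probability ``p_kill`` a
    uniformly chosen internal (non-root) clade is killed outright.
    """
    if sigma_phylo < 0 or sigma_iid < 0:
        raise UsageError("sigmas must be non-negative")
    if not 0 <= p_kill <= 1:
        raise UsageError("p_kill must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    leaves, incidence, lengths = _leaf_edge_incidence(tree)
    internal = [
        n for n in tree.preorder(include_self=False) if not n.is_tip()
    ]
    leaf_sets = {
        id(n): [t.name for t in n.tips()] for n in internal
    }

    effects = pd.DataFrame(
        0.0, index=list(modification_ids), columns=leaves
    )
    kills = pd.DataFrame(
        False, index=list(modification_ids), columns=leaves
    )
    for mod in modification_ids:
        if mod == BASE_MODIFICATION:
            continue
        edge_draw = rng.normal(0.0, sigma_phylo * np.sqrt(lengths))
        leaf_eff = incidence @ edge_draw
        leaf_eff += rng.normal(0.0, sigma_iid, size=len(leaves))
        effects.loc[mod] = leaf_eff
        if internal and rng.random() < p_kill:
            clade = internal[int(rng.integers(len(internal)))]
            kills.loc[mod, leaf_sets[id(clade)]] = True
    return effects, kills


def plant_target(
    model: CommunityModel,
    target: str,
    supporting_set: Sequence[str],
    delta: float,
    seed: int = 0,
) -> tuple[CommunityModel, GroundTruth]:
    """Boost ``target``'s log-effect by ``delta`` in the supporting set.

    The target is also excused from kills in supporting modifications
    (a supporting medium sustains the target's growth by definition).
    """
    support = frozenset(supporting_set)
    if not support:
        raise UsageError("supporting set must be non-empty")
    if BASE_MODIFICATION in support:
        raise UsageError("supporting set may not contain 'Base'")
    if target not in model.log_effects.columns:
        raise UsageError(f"unknown target feature {target!r}")
    unknown = support - set(model.modification_ids)
    if unknown:
        raise UsageError(f"unknown modification(s): {sorted(unknown)}")
    effects = model.log_effects.copy()
    kills = model.kill_mask.copy()
    for mod in support:
        effects.loc[mod, target] += delta
        kills.loc[mod, target] = False
    planted = CommunityModel(
        tree=model.tree,
        donor_baselines=model.donor_baselines,
        log_effects=effects,
        kill_mask=kills,
    )
    truth = GroundTruth(
        target_feature=target, supporting_set=support, delta=delta, seed=seed
    )
    return planted, truth


# ---------------------------------------------------------------------------
# baselines + counts
# ---------------------------------------------------------------------------

def simulate_baselines(
    taxa: Sequence[str],
    donor_ids: Sequence[str],
    seed: int,
    sigma_core: float = SIGMA_CORE,
    sigma_donor: float = SIGMA_DONOR,
) -> pd.DataFrame:
    """Donor x taxa positive baseline weights (log-normal core x perturbation)."""
    rng = np.random.default_rng(seed)
    core = np.exp(rng.normal(0.0, sigma_core, size=len(taxa)))
    rows = {
        d: core * np.exp(rng.normal(0.0, sigma_donor, size=len(taxa)))
        for d in donor_ids
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = list(taxa)
    frame.index.name = "donor_id"
    return frame


def expected_fractions(model: CommunityModel) -> pd.DataFrame:
    """Noise-free expected composition per (donor, modification) sample.

    Rows are indexed ``donor|modification``; useful for closed-form
    checks of planted effects before sequencing noise is applied.
    """
    rows = {}
    for donor in model.donor_ids:
        base = model.donor_baselines.loc[donor].to_numpy()
        for mod in model.modification_ids:
            w = base * np.exp(model.log_effects.loc[mod].to_numpy())
            w = np.where(model.kill_mask.loc[mod].to_numpy(), 0.0, w)
            total = w.sum()
            rows[f"{donor}|{mod}"] = w / total if total > 0 else w
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = model.taxa
    return frame


def simulate_counts(
    model: CommunityModel, depth: int, seed: int
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Multinomial read counts for every (donor, modification) plate.

    Each culture sample draws ``depth`` reads from the closed product
    of baseline x growth multiplier (killed taxa weighted 0); one
    stool sample per donor is drawn from the closed baselines alone.
    Returns the counts table and its metadata frame.
    """
    if depth < 1:
        raise UsageError("sequencing depth must be >= 1")
    rng = np.random.default_rng(seed)
    taxa = model.taxa
    rows: dict[str, np.ndarray] = {}
    meta: dict[str, dict[str, str]] = {}
    for donor in model.donor_ids:
        base = model.donor_baselines.loc[donor].to_numpy()
        stool_id = f"{donor}.stool"
        rows[stool_id] = rng.multinomial(depth, base / base.sum())
        meta[stool_id] = {
            "donor_id": donor, "modification_id": "", "sample_type": "stool",
        }
        for mod in model.modification_ids:
            w = base * np.exp(model.log_effects.loc[mod].to_numpy())
            w = np.where(model.kill_mask.loc[mod].to_numpy(), 0.0, w)
            sid = f"{donor}.{mod}"
            total = w.sum()
            if total == 0:
                warnings.warn(
                    f"sample {sid} has all-zero weights; emitting zero row",
                    stacklevel=2,
                )
                rows[sid] = np.zeros(len(taxa), dtype=np.int64)
            else:
                rows[sid] = rng.multinomial(depth, w / total)
            meta[sid] = {
                "donor_id": donor,
                "modification_id": mod,
                "sample_type": "culture",
            }
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.columns = taxa
    counts.index.name = "sample_id"
    metadata = pd.DataFrame.from_dict(meta, orient="index")
    metadata.index.name = "sample_id"
    return AbundanceTable(counts, mode="counts"), metadata


# ---------------------------------------------------------------------------
# functions (KO catalog)
# ---------------------------------------------------------------------------

def assign_functions(
    feature_ids: Sequence[str],
    n_ko: int,
    seed: int,
    carriers: Mapping[str, Sequence[str]] | None = None,
) -> FunctionCatalog:
    """Random (or caller-specified) KO -> carrier-taxa assignment.

    When ``carriers`` is given it maps KO ids to their carrier
    features; otherwise each of ``n_ko`` KOs is carried by a random
    subset of taxa (1 + Poisson(3) carriers).
    """
    features = list(feature_ids)
    mapping: dict[str, set[str]] = {f: set() for f in features}
    if carriers is not None:
        for ko, carrier_list in carriers.items():
            for f in carrier_list:
                if f not in mapping:
                    raise UsageError(f"unknown carrier feature {f!r} for {ko}")
                mapping[f].add(ko)
    else:
        rng = np.random.default_rng(seed)
        for k in range(1, n_ko + 1):
            ko = f"K{k:05d}"
            n_carriers = min(len(features), 1 + int(rng.poisson(3)))
            chosen = rng.choice(len(features), size=n_carriers, replace=False)
            for idx in chosen:
                mapping[features[int(idx)]].add(ko)
    return FunctionCatalog(
        {f: frozenset(kos) for f, kos in mapping.items()}
    )


def function_table(table: AbundanceTable, catalog: FunctionCatalog) -> AbundanceTable:
    """Samples x KO abundance: unnormalized sum of carrier fractions."""
    if table.mode != "fraction":
        raise UsageError("function_table requires a closed (fraction) table")
    kos = catalog.ko_ids
    values = np.zeros((len(table.sample_ids), len(kos)))
    col_index = {f: i for i, f in enumerate(table.feature_ids)}
    data = table.values()
    for j, ko in enumerate(kos):
        carrier_cols = [
            col_index[f] for f in catalog.carriers(ko) if f in col_index
        ]
        if carrier_cols:
            values[:, j] = data[:, carrier_cols].sum(axis=1)
    frame = pd.DataFrame(values, index=table.data.index, columns=kos)
    return AbundanceTable(frame, mode="functional")


# ---------------------------------------------------------------------------
# whole-experiment convenience + bundle IO
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExperiment:
    """One fully simulated campaign: model, tables, metadata, truth."""

    model: CommunityModel
    truth: GroundTruth
    counts: AbundanceTable
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    catalog: FunctionCatalog
    depth: int
    seed: int


def simulate_experiment(
    seed: int,
    n_taxa: int = DEFAULT_N_TAXA,
    n_donors: int = DEFAULT_N_DONORS,
    n_modifications: int = DEFAULT_N_MODIFICATIONS,
    depth: int = DEFAULT_DEPTH,
    delta: float = DEFAULT_DELTA,
    n_supporting: int = DEFAULT_N_SUPPORTING,
    sigma_phylo: float = DEFAULT_SIGMA_PHYLO,
    sigma_iid: float = DEFAULT_SIGMA_IID,
    p_kill: float = DEFAULT_P_KILL,
    n_ko: int = 100,
) -> SyntheticExperiment:
    """End-to-end simulation with a planted low-abundance target.

    The target is chosen as a taxon from the lower quartile of the
    shared baseline core (low-abundance, mirroring the hard-to-culture
    species that motivate targeted enrichment), boosted by ``delta``
    log units in ``n_supporting`` randomly chosen modifications.
    """
    if n_supporting > n_modifications:
        raise UsageError("n_supporting cannot exceed n_modifications")
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=6)]
    tree = simulate_tree(n_taxa, seed=sub[0])
    taxa = [t.name for t in tree.tips()]
    donor_ids = [f"D{i+1}" for i in range(n_donors)]
    mods = [BASE_MODIFICATION] + [f"M{i+1:02d}" for i in range(n_modifications)]

    baselines = simulate_baselines(taxa, donor_ids, seed=sub[1])
    effects, kills = simulate_effects(
        tree, mods, sigma_phylo, sigma_iid, p_kill, seed=sub[2]
    )
    model = CommunityModel(
        tree=tree, donor_baselines=baselines, log_effects=effects, kill_mask=kills
    )

    # low-abundance target: lower quartile of mean baseline weight
    mean_base = baselines.mean(axis=0)
    q25 = mean_base.quantile(0.25)
    candidates = sorted(mean_base.index[mean_base <= q25])
    target_rng = np.random.default_rng(sub[3])
    target = candidates[int(target_rng.integers(len(candidates)))]
    support = target_rng.choice(
        [m for m in mods if m != BASE_MODIFICATION],
        size=n_supporting,
        replace=False,
    )
    model, truth = plant_target(model, target, list(support), delta, seed=seed)

    counts, metadata = simulate_counts(model, depth=depth, seed=sub[4])
    taxonomy = taxonomy_from_tree(tree, default_depth_cuts(tree))
    catalog = assign_functions(taxa, n_ko=n_ko, seed=sub[5])
    return SyntheticExperiment(
        model=model,
        truth=truth,
        counts=counts,
        metadata=metadata,
        taxonomy=taxonomy,
        catalog=catalog,
        depth=depth,
        seed=seed,
    )


def write_bundle(experiment: SyntheticExperiment, outdir: str | Path) -> list[Path]:
    """Write the five-file input bundle plus catalog and ground truth."""
    from .tables_io import close_composition

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _record(p: Path) -> Path:
        paths.append(p)
        return p

    write_abundance_table(
        experiment.counts, _record(out / "motu_counts.tsv")
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fractions = close_composition(experiment.counts)
    ko_table = function_table(fractions, experiment.catalog)
    write_abundance_table(ko_table, _record(out / "ko_abundance.tsv"))
    write_metadata(experiment.metadata, _record(out / "metadata.tsv"))
    write_taxonomy(experiment.taxonomy, _record(out / "taxonomy.tsv"))
    write_newick(experiment.model.tree, _record(out / "tree.nwk"))
    catalog_frame = pd.DataFrame(
        {
            "feature_id": list(experiment.catalog.features_to_kos),
            "ko_ids": [
                ";".join(sorted(kos))
                for kos in experiment.catalog.features_to_kos.values()
            ],
        }
    ).set_index("feature_id")
    catalog_frame.to_csv(_record(out / "ko_catalog.tsv"), sep="\t")
    (_record(out / "ground_truth.json")).write_text(experiment.truth.to_json())
    return paths
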