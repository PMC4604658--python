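"""Synthetic dual-marker communities with known truth.

Generates everything the analysis consumes — a pair of marker phylogenies
sharing topology up to a controlled number of SPR edits, Jukes–Cantor
sequences evolved along each tree at marker-specific rates (the functional
marker faster than the ribosomal one), a soils-by-factors environmental
table over a pH 3.5–8.5 gradient, and per-soil read counts drawn from a
Gaussian niche response to pH whose optima evolve by Brownian motion on the
tree. Each generator is seeded independently (config seed + fixed offset),
so any stage can be regenerated on its own and identical configs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .core_io import (
    CANONICAL_FACTORS,
    EnvTable,
    Phylogeny,
    SequenceRecord,
    ValidationError,
    parse_newick,
    write_newick,
)

PH_RANGE = (3.5, 8.5)

# per-operation RNG offsets (kept stable so stages regenerate independently)
_OFF_TREE, _OFF_SPR, _OFF_SEQ16, _OFF_SEQAMO, _OFF_ENV, _OFF_ABUND = (
    11, 23, 37, 41, 53, 67)


@dataclass(frozen=True)
class FactorSpec:
    """Marginal range and target Spearman correlation with pH for one
    synthetic environmental factor."""

    low: float
    high: float
    rho: float = 0.0  # target Spearman correlation with pH

    def __post_init__(self) -> None:
        if abs(self.rho) > 1:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")


#: Default study design: ranges loosely matching UK mineral-to-organic soils,
#: organic matter / water / C:N declining with pH, Zn the only metal tracking
#: pH. Non-pH correlations are deliberately moderate so pH stays the dominant
#: gradient.
DEFAULT_FACTOR_SPEC: dict[str, FactorSpec] = {
    "organic_matter_pct": FactorSpec(2, 95, -0.8),
    "carbon_pct": FactorSpec(1, 50, -0.6),
    "bulk_density": FactorSpec(0.2, 1.6, 0.6),
    "water_content": FactorSpec(5, 90, -0.7),
    "nitrogen_pct": FactorSpec(0.05, 2.5, -0.5),
    "nitrogen_stock": FactorSpec(2, 25, -0.3),
    "mineralisable_n_stock": FactorSpec(5, 80, -0.2),
    "c_n_ratio": FactorSpec(8, 30, -0.6),
    "phosphorus": FactorSpec(5, 60, 0.1),
    "total_mineralisable_n": FactorSpec(5, 120, -0.2),
    "nitrate_pct": FactorSpec(0, 90, 0.6),
    "air_temperature": FactorSpec(6, 11, 0.2),
    "rain": FactorSpec(50, 250, -0.4),
    "sun": FactorSpec(3, 5, 0.2),
    "Cd": FactorSpec(0.1, 1.0, 0.0),
    "Cr": FactorSpec(10, 100, 0.0),
    "Cu": FactorSpec(5, 50, 0.0),
    "Ni": FactorSpec(5, 50, 0.0),
    "Pb": FactorSpec(10, 200, 0.0),
    "Zn": FactorSpec(20, 200, 0.4),
    "Al": FactorSpec(1e3, 5e4, 0.0),
    "Ti": FactorSpec(100, 2000, 0.0),
    "Mn": FactorSpec(50, 2000, 0.0),
    "As": FactorSpec(2, 20, 0.0),
    "Se": FactorSpec(0.2, 2.0, 0.0),
    "Mo": FactorSpec(0.5, 5.0, 0.0),
    "Hg": FactorSpec(0.02, 0.3, 0.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of a synthetic dual-marker survey.

    Defaults emulate the real design this pipeline targets: 46 soils over a
    pH 3.5–8.5 gradient, ~592 bp amplicons, on the order of 10^4 reads per
    soil, and a faster-evolving functional marker.
    """

    n_taxa: int = 32
    n_soils: int = 46
    seq_length: int = 592
    bm_sigma2: float = 0.8       # pH^2 per unit branch length
    niche_width: float = 0.5     # Gaussian niche sd, pH units
    depth: int = 10_000          # reads per soil per marker
    spr_moves: int = 0           # topological incongruence between markers
    rate_16S: float = 0.015      # expected substitutions/site/branch unit
    rate_amoA: float = 0.06
    effect_factors: dict = field(default_factory=dict)  # extra factor -> FactorSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_soils < 3:
            raise ValueError("n_soils must be >= 3")
        if self.niche_width <= 0:
            raise ValueError("niche_width must be > 0")
        if self.bm_sigma2 < 0:
            raise ValueError("bm_sigma2 must be >= 0")
        if self.spr_moves < 0:
            raise ValueError("spr_moves must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study."""

    tree_16S: Phylogeny
    tree_amoA: Phylogeny
    true_optima: dict[str, float]
    true_links: dict[str, str]   # amoA tip -> 16S tip
    env: EnvTable
    is_aoa: dict[str, bool]


@dataclass
class SyntheticStudy:
    """A full ready-to-analyse synthetic data set."""

    config: SimulationConfig
    records_16S: list[SequenceRecord]
    records_amoA: list[SequenceRecord]
    counts: pd.DataFrame          # soils x taxa read counts (shared niche truth)
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _yule_topology(n_taxa: int, rng: np.random.Generator) -> Phylogeny:
    """Yule (random-splits) topology with iid unit-mean exponential branch
    lengths; supports set to 1.0."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    tree.seed_node.support = None
    left, right = dendropy.Node(), dendropy.Node()
    tree.seed_node.add_child(left)
    tree.seed_node.add_child(right)
    tips = [left, right]
    while len(tips) < n_taxa:
        node = tips.pop(rng.integers(len(tips)))
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        tips.extend([a, b])
    leaves = list(tree.leaf_node_iter())
    # label tips in random order: iteration order tracks topology, and
    # labels must carry no topological information
    order = rng.permutation(len(leaves))
    for i, k in enumerate(order, start=1):
        leaves[k].taxon = taxa.new_taxon(label=f"t{i:03d}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            edge.length = None
        else:
            edge.length = float(rng.exponential(1.0))
    for nd in tree.preorder_node_iter():
        nd.support = None if nd.is_leaf() or nd is tree.seed_node else 1.0
    return Phylogeny(tree)


def _apply_spr(phy: Phylogeny, rng: np.random.Generator) -> None:
    """One random subtree-prune-regraft edit in place.

    The regraft edge is constrained to differ from the pruned edge, its
    parent edge and its sibling edge, so the topology always changes.
    """
    tree = phy.tree
    candidates = [
        nd for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and nd.parent_node.parent_node is not None
    ]
    rng.shuffle(candidates)
    for prune_node in candidates:
        parent = prune_node.parent_node
        sibling = [c for c in parent.child_nodes() if c is not prune_node][0]
        in_subtree = set(prune_node.preorder_iter())
        forbidden = in_subtree | {parent, sibling}
        grand_ = parent.parent_node
        if grand_ is not None and grand_.parent_node is None:
            # unrooted, the edge above `parent` and the root's other child
            # edge are the same edge: regrafting there is a no-op
            forbidden |= set(grand_.child_nodes())
        targets = [
            nd for nd in tree.preorder_node_iter()
            if nd.parent_node is not None and nd not in forbidden
        ]
        if not targets:
            continue
        target = targets[rng.integers(len(targets))]
        # detach
        grand = parent.parent_node
        parent.remove_child(prune_node)
        grand.remove_child(parent)
        for child in parent.child_nodes():
            parent.remove_child(child)
            child.edge.length = (child.edge.length or 0.0) + (
                parent.edge.length or 0.0)
            grand.add_child(child)
        # regraft onto the edge above `target`
        tparent = target.parent_node
        new = dendropy.Node()
        new.support = 1.0
        half = (target.edge.length or 0.0) / 2.0
        tparent.remove_child(target)
        tparent.add_child(new)
        new.edge.length = half
        new.add_child(target)
        target.edge.length = half
        new.add_child(prune_node)
        return
    raise ValidationError("no valid SPR move on this tree")


def simulate_tree_pair(
    n_taxa: int, spr_moves: int = 0, seed: int = 0,
) -> tuple[Phylogeny, Phylogeny, dict[str, str]]:
    """Simulate two marker phylogenies sharing a Yule topology up to
    ``spr_moves`` random SPR edits; returns (tree_16S, tree_amoA, links)
    with ``links`` the tip-to-tip identity map."""
    if spr_moves > 0 and n_taxa < 4:
        raise ValueError("need n_taxa >= 4 to apply SPR moves")
    rng = np.random.default_rng(seed + _OFF_TREE)
    first = _yule_topology(n_taxa, rng)
    second = parse_newick(write_newick(first))
    spr_rng = np.random.default_rng(seed + _OFF_SPR)
    for _ in range(spr_moves):
        _apply_spr(second, spr_rng)
    links = {label: label for label in first.tip_labels}
    return first, second, links


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def evolve_sequences(
    tree: Phylogeny, seq_length: int, rate: float, seed: int = 0,
    marker: str = "16S", sample_id: str = "sim",
) -> list[SequenceRecord]:
    """Evolve one sequence per tip under Jukes–Cantor along the tree.

    The root sequence is uniform over {A,C,G,T}; on a branch of length ``b``
    each site substitutes with probability (3/4)(1 − e^(−4·rate·b/3)), to a
    uniformly chosen different base. ``rate`` is in expected substitutions
    per site per unit branch length.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(
        seed + (_OFF_SEQ16 if marker == "16S" else _OFF_SEQAMO))
    root_seq = rng.integers(0, 4, size=seq_length)
    states: dict[int, np.ndarray] = {id(tree.tree.seed_node): root_seq}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        parent_seq = states[id(nd.parent_node)]
        b = nd.edge.length or 0.0
        p_sub = 0.75 * (1.0 - np.exp(-4.0 * rate * b / 3.0))
        seq = parent_seq.copy()
        hit = rng.random(seq_length) < p_sub
        if hit.any():
            # jump to one of the three other bases, uniformly
            seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        states[id(nd)] = seq
    records = []
    for leaf in tree.tree.leaf_node_iter():
        residues = "".join(_BASES[states[id(leaf)]])
        records.append(SequenceRecord(
            id=leaf.taxon.label, marker=marker, residues=residues,
            sample_id=sample_id, count=1))
    return records


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def simulate_env_factors(
    n_soils: int, seed: int = 0,
    factor_spec: dict[str, FactorSpec] | None = None,
) -> EnvTable:
    """Simulate the soils-by-factors table.

    pH is uniform on [3.5, 8.5]. Each factor is generated through a Gaussian
    copula on the pH ranks with Pearson correlation 2·sin(π·ρ_s/6), which
    targets the requested Spearman ρ_s; the marginal is a monotone map onto
    the factor's range, so ρ_s = ±1 is achieved exactly. Vegetation is
    assigned from pH and organic-matter bands (moorland/forest at the acid,
    organic end through grassland to agricultural at the alkaline end).
    """
    spec = dict(DEFAULT_FACTOR_SPEC if factor_spec is None else factor_spec)
    rng = np.random.default_rng(seed + _OFF_ENV)
    from scipy.stats import norm

    ph = rng.uniform(*PH_RANGE, size=n_soils)
    z_ph = norm.ppf((ph - PH_RANGE[0]) / (PH_RANGE[1] - PH_RANGE[0]))
    cols: dict[str, np.ndarray] = {"pH": ph}
    for name, fs in spec.items():
        rho_p = 2.0 * np.sin(np.pi * fs.rho / 6.0)
        if abs(fs.rho) == 1.0:
            z = np.sign(fs.rho) * z_ph
        else:
            eps = rng.standard_normal(n_soils)
            z = rho_p * z_ph + np.sqrt(max(0.0, 1.0 - rho_p ** 2)) * eps
        cols[name] = fs.low + (fs.high - fs.low) * norm.cdf(z)
    index = pd.Index([f"S{i:03d}" for i in range(1, n_soils + 1)],
                     name="soil_id")
    df = pd.DataFrame(cols, index=index)
    om = df["organic_matter_pct"] if "organic_matter_pct" in df else None
    veg = []
    for i in range(n_soils):
        p = ph[i]
        rich = om is not None and om.iloc[i] > 40
        if p < 4.5:
            veg.append("moorland" if rich else "forest")
        elif p < 5.8:
            veg.append("forest" if rich else "grassland")
        elif p < 6.8:
            veg.append("grassland")
        else:
            veg.append("agricultural")
    df["vegetation"] = veg
    ordered = [c for c in CANONICAL_FACTORS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return EnvTable(df[ordered + extra])


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

def simulate_bm_optima(
    tree: Phylogeny, bm_sigma2: float, seed: int = 0,
    root_state: float | None = None,
) -> dict[str, float]:
    """Brownian-motion pH optima along the tree, root at the gradient
    midpoint unless given."""
    rng = np.random.default_rng(seed + _OFF_ABUND)
    root = float(np.mean(PH_RANGE)) if root_state is None else root_state
    states = {id(tree.tree.seed_node): root}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        b = nd.edge.length or 0.0
        states[id(nd)] = states[id(nd.parent_node)] + rng.normal(
            0.0, np.sqrt(bm_sigma2 * b))
    return {leaf.taxon.label: states[id(leaf)]
            for leaf in tree.tree.leaf_node_iter()}


def simulate_abundances(
    tree: Phylogeny, env: EnvTable, bm_sigma2: float, niche_width: float,
    depth: int, seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Niche-driven read counts: expected relative abundance of taxon *i* in
    soil *s* is ∝ exp(−(pH_s − opt_i)² / (2·w²)); counts are multinomial at
    ``depth`` reads per soil."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if niche_width <= 0:
        raise ValueError("niche_width must be > 0")
    optima = simulate_bm_optima(tree, bm_sigma2, seed)
    tips = list(optima)
    opt = np.array([optima[t] for t in tips])
    rng = np.random.default_rng(seed + _OFF_ABUND + 1)
    rows = []
    ph = env.factor("pH").to_numpy(dtype=float)
    for s in range(len(env.soil_ids)):
        weights = np.exp(-((ph[s] - opt) ** 2) / (2.0 * niche_width ** 2))
        total = weights.sum()
        if total <= 0 or not np.isfinite(total):
            probs = np.full(len(tips), 1.0 / len(tips))
        else:
            probs = weights / total
        rows.append(rng.multinomial(depth, probs))
    counts = pd.DataFrame(rows, index=pd.Index(env.soil_ids, name="soil_id"),
                          columns=tips)
    return counts, optima


# ---------------------------------------------------------------------------
# whole-study assembly
# ---------------------------------------------------------------------------

def _records_from_counts(
    tip_seqs: dict[str, str], counts: pd.DataFrame, marker: str,
) -> list[SequenceRecord]:
    records = []
    for soil in counts.index:
        for tip in counts.columns:
            c = int(counts.at[soil, tip])
            if c > 0:
                records.append(SequenceRecord(
                    id=f"{tip}.{soil}", marker=marker,
                    residues=tip_seqs[tip], sample_id=str(soil), count=c))
    return records


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run the full generator: tree pair, sequences for both markers,
    environment, and niche-driven per-soil counts shared by the markers."""
    t16, tamo, links = simulate_tree_pair(
        config.n_taxa, config.spr_moves, config.seed)
    seqs16 = {r.id: r.residues for r in evolve_sequences(
        t16, config.seq_length, config.rate_16S, config.seed, marker="16S")}
    seqsamo = {r.id: r.residues for r in evolve_sequences(
        tamo, config.seq_length, config.rate_amoA, config.seed, marker="amoA")}
    spec = dict(DEFAULT_FACTOR_SPEC)
    spec.update(config.effect_factors)
    env = simulate_env_factors(config.n_soils, config.seed, spec)
    counts, optima = simulate_abundances(
        t16, env, config.bm_sigma2, config.niche_width, config.depth,
        config.seed)
    # non-AOA lineage := the smaller clade under the root of the 16S tree
    root_children = t16.tree.seed_node.child_nodes()
    clades = [set(l.taxon.label for l in ch.leaf_iter())
              for ch in root_children]
    non_aoa = min(clades, key=lambda s: (len(s), sorted(s)))
    is_aoa = {t: (t not in non_aoa) for t in t16.tip_labels}
    truth = SyntheticTruth(
        tree_16S=t16, tree_amoA=tamo, true_optima=optima,
        true_links=links, env=env, is_aoa=is_aoa)
    return SyntheticStudy(
        config=config,
        records_16S=_records_from_counts(seqs16, counts, "16S"),
        records_amoA=_records_from_counts(
            counts=counts.rename(columns=links), tip_seqs=seqsamo,
            marker="amoA"),
        counts=counts,
        truth=truth)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Emit the study in the pipeline's input formats plus a truth TSV
    (tip, true pH optimum, cross-marker link, AOA flag)."""
    from pathlib import Path

    from .core_io import write_env_table, write_fasta, write_newick_file

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(study.records_16S, out / "reads_16S.fasta")
    write_fasta(study.records_amoA, out / "reads_amoA.fasta")
    write_env_table(study.truth.env, out / "env.tsv")
    write_newick_file(study.truth.tree_16S, out / "true_tree_16S.nwk")
    write_newick_file(study.truth.tree_amoA, out / "true_tree_amoA.nwk")
    rows = []
    for tip in study.truth.tree_16S.tip_labels:
        rows.append({
            "tip": tip,
            "true_ph_optimum": study.truth.true_optima[tip],
            "link_amoA": {v: k for k, v in study.truth.true_links.items()}.get(
                tip, tip),
            "is_aoa": study.truth.is_aoa[tip],
        })
    pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)
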