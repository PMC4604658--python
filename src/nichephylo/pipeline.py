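"""End-to-end orchestration: simulate/load -> cluster -> coherence ->
trees -> clade delineation -> preferences -> ancestral states -> congruence.

A single config drives the whole run; every stage writes deterministic
TSV/Newick outputs into the run directory, a manifest records the config
and seeds, and a plain-text log gets one line per stage with wall time and
output digests. Any stage failure aborts the run with the stage named and
a FAILED marker left next to the partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancestral import reconstruct_habitat_traits, tip_trait_values
from .clade_analysis import (
    annotate_read_fractions,
    clade_abundance_matrix,
    delineate_clusters,
    preference_table,
)
from .clustering import (
    DEFAULT_MIN_READS_PER_SOIL,
    DEFAULT_THRESHOLDS,
    multiscale_cluster,
    pairwise_identity,
    passthrough_recombinant_filter,
    relative_abundance_matrix,
)
from .community_stats import coherence_table, spearman_matrix
from .congruence import (
    ClusterAnnotation,
    build_correspondence,
    congruence_report,
    parafit_global,
)
from .core_io import (
    EnvTable,
    read_env_table,
    read_fasta,
    write_abundance_matrix,
    write_newick_file,
)
from .phylo_inference import DistanceMatrix, bootstrap_supports, patristic_matrix
from .synthetic_data import SimulationConfig, simulate_study, write_study

ASR_TRAITS = ("pH", "water_content", "organic_matter_pct", "nitrate_pct")


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    outdir: str
    simulation: SimulationConfig | None = None
    fasta_16s: str | None = None
    fasta_amoa: str | None = None
    env_table: str | None = None
    aoa_tips: str | None = None          # TSV: tip, is_aoa
    thresholds: tuple = DEFAULT_THRESHOLDS
    min_reads_per_soil: int = DEFAULT_MIN_READS_PER_SOIL
    nperm: int = 999
    alpha: float = 0.05
    n_boot: int = 100
    run_congruence: bool = True
    coherence_factors: list[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None:
            missing = [k for k in ("fasta_16s", "fasta_amoa", "env_table")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(
                    "config needs either a simulation block or input paths; "
                    f"missing: {missing}")
        if self.nperm < 99:
            raise ValueError("nperm must be >= 99")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.thresholds:
            raise ValueError("empty threshold ladder")


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    sim = raw.pop("simulation", None)
    cfg = PipelineConfig(
        **{k: tuple(v) if k == "thresholds" else v for k, v in raw.items()},
        simulation=SimulationConfig(**sim) if sim else None)
    cfg.validate()
    return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


class _Runner:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.log = open(outdir / "pipeline.log", "w", encoding="utf-8")

    def stage(self, name):
        runner = self

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc is None:
                    digests = ",".join(
                        f"{p.name}:{_digest(p)}"
                        for p in sorted(runner.outdir.glob("*"))
                        if p.is_file() and p.name != "pipeline.log")
                    runner.log.write(
                        f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{name}\t"
                        f"ok\t{dt:.2f}s\t{digests}\n")
                    runner.log.flush()
                else:
                    runner.log.write(
                        f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{name}\t"
                        f"FAILED\t{dt:.2f}s\t{exc}\n")
                    runner.log.flush()
                    (runner.outdir / "FAILED").write_text(
                        f"stage: {name}\nerror: {exc}\n")
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the run directory."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    runner = _Runner(out)

    manifest = {
        "version": __version__,
        "config": {k: (dataclasses.asdict(v)
                       if dataclasses.is_dataclass(v) else v)
                   for k, v in dataclasses.asdict(config).items()},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))

    # ---- stage 1: inputs -------------------------------------------------
    with runner.stage("inputs"):
        if config.simulation is not None:
            study = simulate_study(config.simulation)
            write_study(study, out / "inputs")
            rec16 = study.records_16S
            recamo = study.records_amoA
            env = study.truth.env
            is_aoa = study.truth.is_aoa
            true_links = study.truth.true_links
        else:
            rec16 = read_fasta(config.fasta_16s)
            recamo = read_fasta(config.fasta_amoa)
            env = read_env_table(config.env_table)
            is_aoa = None
            true_links = None
            if config.aoa_tips:
                df = pd.read_csv(config.aoa_tips, sep="\t")
                is_aoa = dict(zip(df.iloc[:, 0].astype(str),
                                  df.iloc[:, 1].astype(bool)))
        rec16 = passthrough_recombinant_filter(rec16)
        recamo = passthrough_recombinant_filter(recamo)

    # ---- stage 2: multi-scale clustering ---------------------------------
    with runner.stage("clustering"):
        datasets = {"16S": rec16, "amoA": recamo}
        if is_aoa is not None:
            datasets["16S_AOA"] = [
                r for r in rec16 if is_aoa.get(r.id.split(".")[0], True)]
        abundance: dict[str, dict[float, object]] = {}
        for name, recs in datasets.items():
            clusters = multiscale_cluster(recs, config.thresholds)
            abundance[name] = {}
            for t, cs in clusters.items():
                mat = relative_abundance_matrix(
                    cs, recs, config.min_reads_per_soil)
                abundance[name][t] = mat
                write_abundance_matrix(
                    mat, out / f"abundance_{name}_{int(round(t*100))}.tsv")
                pd.Series(cs.assignments).rename("cluster").to_csv(
                    out / f"assignments_{name}_{int(round(t*100))}.tsv",
                    sep="\t")

    # ---- stage 3: coherence table + factor correlations -------------------
    with runner.stage("coherence"):
        table = coherence_table(
            abundance, env, factors=config.coherence_factors,
            nperm=config.nperm, alpha=config.alpha, seed=config.seed)
        flat = table.to_frame()
        flat.columns = [f"{d}@{int(round(t*100))}" for d, t in flat.columns]
        flat.to_csv(out / "coherence_table.tsv", sep="\t")
        sig = table.significant.copy()
        sig.columns = [f"{d}@{int(round(t*100))}" for d, t in sig.columns]
        sig.to_csv(out / "coherence_significant.tsv", sep="\t")
        spearman_matrix(env).to_csv(out / "spearman_factors.tsv", sep="\t")

    # ---- stage 4: trees ---------------------------------------------------
    with runner.stage("trees"):
        tip_seqs: dict[str, dict[str, str]] = {}
        trees = {}
        for name, recs in (("16S", rec16), ("amoA", recamo)):
            seqs: dict[str, str] = {}
            for r in recs:
                seqs.setdefault(r.id.split(".")[0], r.residues)
            tip_seqs[name] = seqs
            from .core_io import SequenceRecord
            marker = recs[0].marker
            uniq = [SequenceRecord(id=t, marker=marker, residues=s,
                                   sample_id="all", count=1)
                    for t, s in seqs.items()]
            tree = bootstrap_supports(uniq, n_boot=config.n_boot,
                                      seed=config.seed)
            trees[name] = tree
            write_newick_file(tree, out / f"tree_{name}.nwk")

    # ---- stage 5: clade delineation + preferences -------------------------
    with runner.stage("delineation"):
        clades = {}
        prefs = {}
        clade_mats = {}
        for name, recs in (("16S", rec16), ("amoA", recamo)):
            seqs = tip_seqs[name]
            ident = lambda a, b, _s=seqs: pairwise_identity(_s[a], _s[b])
            cls = delineate_clusters(trees[name], ident)
            annotate_read_fractions(cls, recs)
            clades[name] = cls
            mat = clade_abundance_matrix(cls, recs)
            clade_mats[name] = mat
            ptab = preference_table(cls, mat, env)
            prefs[name] = ptab
            ptab.to_csv(out / f"preferences_{name}.tsv", sep="\t",
                        index=False)
            rows = [{"cluster": c.id,
                     "members": ";".join(sorted(c.member_tips)),
                     "support": c.root_support,
                     "min_identity": c.min_pairwise_identity,
                     "read_fraction": c.total_read_fraction,
                     "unplaced": c.unplaced}
                    for c in cls]
            pd.DataFrame(rows).to_csv(out / f"clades_{name}.tsv", sep="\t",
                                      index=False)

    # ---- stage 6: ancestral state reconstruction --------------------------
    with runner.stage("ancestral"):
        traits = [t for t in ASR_TRAITS if t in env.data.columns]
        tip_traits = tip_trait_values(rec16, env, traits)
        results = reconstruct_habitat_traits(trees["16S"], tip_traits, traits)
        rows = []
        for trait, res in results.items():
            for node, state in res.node_states.items():
                rows.append({"trait": trait, "node": node, "state": state,
                             "variance": res.node_variances[node]})
        pd.DataFrame(rows).to_csv(out / "asr_states.tsv", sep="\t",
                                  index=False)
        summary = pd.DataFrame(
            [{"trait": t, "root_state": r.root_state, "root_se": r.root_se,
              "sigma2": r.sigma2_hat} for t, r in results.items()])
        summary.to_csv(out / "asr_summary.tsv", sep="\t", index=False)

    # ---- stage 7: congruence ----------------------------------------------
    if config.run_congruence:
        with runner.stage("congruence"):
            ann = {}
            for name in ("amoA", "16S"):
                ptab = prefs[name].set_index("cluster")
                refs = {}
                if true_links is not None:
                    links = (true_links if name == "amoA"
                             else {v: v for v in true_links.values()})
                    for c in clades[name]:
                        refs[c.id] = frozenset(
                            links.get(t, t) for t in c.member_tips)
                ann[name] = {
                    c.id: ClusterAnnotation(
                        id=c.id,
                        read_fraction=c.total_read_fraction,
                        mean_ph=float(ptab.loc[c.id, "mean_pH"])
                        if c.id in ptab.index else float("nan"),
                        references=refs.get(c.id, frozenset()))
                    for c in clades[name]}
            A = build_correspondence(
                list(ann["amoA"].values()), list(ann["16S"].values()))
            d16 = cluster_distance_matrix(trees["16S"], clades["16S"])
            damo = cluster_distance_matrix(trees["amoA"], clades["amoA"])
            result = parafit_global(
                d16.reorder(list(A.data.columns)),
                damo.reorder(list(A.data.index)),
                A, nperm=config.nperm, seed=config.seed)
            report = congruence_report(A, result, ann["amoA"], ann["16S"])
            report.to_csv(out / "congruence_report.tsv", sep="\t",
                          index=False)

    runner.log.close()
    return out


def cluster_distance_matrix(tree, clusters) -> DistanceMatrix:
    """Cluster-level distances: mean patristic distance between the two
    clusters' member tips (zero diagonal)."""
    tipmat = patristic_matrix(tree)
    idx = {l: i for i, l in enumerate(tipmat.labels)}
    n = len(clusters)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = [idx[t] for t in clusters[i].member_tips]
            b = [idx[t] for t in clusters[j].member_tips]
            d[i, j] = d[j, i] = tipmat.values[np.ix_(a, b)].mean()
    return DistanceMatrix([c.id for c in clusters], d)
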