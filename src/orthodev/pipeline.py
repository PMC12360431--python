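"""Pipeline orchestration: staged execution with a run manifest.

Stages (simulate -> quantify -> de -> cluster -> homology -> paralogs ->
network -> enrich -> report) each read their inputs from the output
directory of earlier stages and append a machine-readable manifest entry
(parameters plus SHA-256 checksums of every file written).  All randomness
derives from the single root seed via named substreams, so a rerun with the
same config and seed reproduces every output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, diffexpr, enrichment, expression, homology, networks, paralogs
from .containers import ARCHETYPES, COMPARISONS, ExpressionMatrix, STAGES
from .diffexpr import DEThresholds
from .report import cluster_share_percent, percentage
from .syndata import SynthConfig, generate, load_dataset, write_dataset

STAGE_ORDER = (
    "simulate",
    "quantify",
    "de",
    "cluster",
    "homology",
    "paralogs",
    "network",
    "enrich",
    "report",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters; the seed is mandatory."""

    outdir: Path
    seed: int
    syn: dict = field(default_factory=dict)  # SynthConfig overrides
    de_lfc: float = 1.0
    de_alpha: float = 0.05
    de_lfc_inclusive: bool = True
    de_alpha_inclusive: bool = False
    k: int = 6
    kmeans_max_iter: int = 1000
    kmeans_restarts: int = 10
    network_mode: str = "percentile"  # or "absolute"
    network_lower_rank: float = 0.05
    network_upper_rank: float = 0.95
    network_abs_threshold: float = 0.8
    baits: list[str] = field(default_factory=list)
    enrich_alpha: float = 0.05
    pcc_threshold: float = 0.9

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.network_mode not in ("percentile", "absolute"):
            raise ValueError(f"unknown network mode {self.network_mode!r}")
        for name in ("de_alpha", "enrich_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @property
    def thresholds(self) -> DEThresholds:
        return DEThresholds(
            lfc=self.de_lfc,
            alpha=self.de_alpha,
            lfc_inclusive=self.de_lfc_inclusive,
            alpha_inclusive=self.de_alpha_inclusive,
        )

    def synth_config(self) -> SynthConfig:
        return SynthConfig(seed=self.seed, **self.syn)

    def substream_seed(self, name: str) -> int:
        key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if outdir is not None:
            raw["outdir"] = outdir
        if seed is not None:
            raw["seed"] = seed
        if "seed" not in raw:
            raise ValueError("config must provide a seed")
        if "outdir" not in raw:
            raise ValueError("config must provide an outdir")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(config: PipelineConfig) -> Path:
    return config.outdir / "manifest.json"


def _append_manifest(config: PipelineConfig, stage: str, params: dict, files: list[Path]) -> None:
    path = _manifest_path(config)
    manifest = {}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest[stage] = {
        "params": params,
        "seed": config.seed,
        "outputs": {
            str(f.relative_to(config.outdir)): _sha256(f) for f in sorted(files)
        },
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(path: Path, prior_stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing {path.name}; run stage '{prior_stage}' first"
        )
    return path


# ---------------------------------------------------------------- stages


def stage_simulate(config: PipelineConfig) -> None:
    syn = config.synth_config()
    bundle = generate(syn)
    outdir = config.outdir / "syn"
    write_dataset(bundle, outdir)
    _append_manifest(
        config, "simulate", {"syn": syn.to_dict()}, list(outdir.iterdir())
    )


def _load_bundle(config: PipelineConfig):
    _require(config.outdir / "syn" / "config.yaml", "simulate")
    return load_dataset(config.outdir / "syn")


def stage_quantify(config: PipelineConfig) -> None:
    bundle = _load_bundle(config)
    outdir = config.outdir / "expr"
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for sp in bundle.config.species:
        cm = bundle.counts[sp]
        lengths = bundle.truth.genes.loc[
            bundle.truth.genes["species"] == sp, "length"
        ]
        tpm = expression.compute_tpm(cm, lengths)
        factors = expression.size_factors(cm)
        vst = expression.vst_transform(cm, factors)
        tpm.to_tsv(outdir / f"tpm_{sp}.tsv")
        vst.to_tsv(outdir / f"vst_{sp}.tsv")
        factors.to_csv(outdir / f"size_factors_{sp}.tsv", sep="\t")
        coding = bundle.truth.genes.loc[bundle.truth.genes["species"] == sp, "coding"]
        qrows = []
        for stage in STAGES:
            qt = expression.quartile_table(tpm, coding, stage)
            for cls in qt.counts.index:
                row = {"stage": stage, "class": cls}
                row.update(qt.counts.loc[cls].to_dict())
                row["chi2"] = qt.chi2[cls]
                row["df"] = qt.df
                row["p"] = qt.p[cls]
                qrows.append(row)
        pd.DataFrame(qrows).to_csv(outdir / f"quartiles_{sp}.tsv", sep="\t", index=False)
        tr = bundle.truth.transcripts
        t2g = tr[tr["gene"].isin(cm.genes)].set_index("transcript")["gene"]
        expression.isoform_census(t2g).to_csv(outdir / f"isoforms_{sp}.tsv", sep="\t")
        files += [
            outdir / f"tpm_{sp}.tsv",
            outdir / f"vst_{sp}.tsv",
            outdir / f"size_factors_{sp}.tsv",
            outdir / f"quartiles_{sp}.tsv",
            outdir / f"isoforms_{sp}.tsv",
        ]
    _append_manifest(config, "quantify", {}, files)


def stage_de(config: PipelineConfig) -> None:
    bundle = _load_bundle(config)
    outdir = config.outdir / "de"
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for sp in bundle.config.species:
        cm = bundle.counts[sp]
        factors = expression.size_factors(cm)
        disp = diffexpr.estimate_dispersion(cm, factors)
        for comparison in COMPARISONS:
            res = diffexpr.de_test(
                cm, comparison, factors, disp, thresholds=config.thresholds
            )
            path = outdir / f"de_{sp}_{comparison}.tsv"
            res.to_csv(path, sep="\t")
            files.append(path)
    _append_manifest(
        config,
        "de",
        {"thresholds": dataclasses.asdict(config.thresholds)},
        files,
    )


def load_de_results(config: PipelineConfig, species: str) -> dict[str, pd.DataFrame]:
    out = {}
    for comparison in COMPARISONS:
        path = _require(
            config.outdir / "de" / f"de_{species}_{comparison}.tsv", "de"
        )
        out[comparison] = pd.read_csv(path, sep="\t", index_col="gene")
    return out


def load_vst(config: PipelineConfig, species: str) -> ExpressionMatrix:
    path = _require(config.outdir / "expr" / f"vst_{species}.tsv", "quantify")
    return ExpressionMatrix.from_tsv(path, kind="VST")


def stage_cluster(config: PipelineConfig) -> None:
    bundle = _load_bundle(config)
    outdir = config.outdir / "cluster"
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for sp in bundle.config.species:
        results = load_de_results(config, sp)
        degs = diffexpr.deg_sets(results)
        vst = load_vst(config, sp)
        genes = sorted(degs.union & set(vst.genes))
        matrix, flagged = clustering.standardize_genes(vst, genes)
        matrix = matrix.drop(index=flagged)
        assignment = clustering.kmeans_cluster(
            matrix,
            k=config.k,
            max_iter=config.kmeans_max_iter,
            n_restarts=config.kmeans_restarts,
            seed=config.substream_seed(f"kmeans:{sp}"),
            design=vst.design,
        )
        clustering.assign_archetypes(assignment)
        table = pd.DataFrame(
            {
                "cluster": assignment.labels,
                "archetype": assignment.archetype_labels(),
            }
        )
        table.index.name = "gene"
        path = outdir / f"clusters_{sp}.tsv"
        table.to_csv(path, sep="\t")
        assignment.centroids.to_csv(outdir / f"centroids_{sp}.tsv", sep="\t")
        pd.Series(flagged, name="gene").to_csv(
            outdir / f"zero_variance_{sp}.tsv", sep="\t", index=False
        )
        files += [path, outdir / f"centroids_{sp}.tsv", outdir / f"zero_variance_{sp}.tsv"]
    _append_manifest(
        config, "cluster", {"k": config.k, "restarts": config.kmeans_restarts}, files
    )


def load_archetype_labels(config: PipelineConfig, species: str) -> pd.Series:
    path = _require(config.outdir / "cluster" / f"clusters_{species}.tsv", "cluster")
    table = pd.read_csv(path, sep="\t", index_col="gene")
    return table["archetype"]


def stage_homology(config: PipelineConfig) -> None:
    bundle = _load_bundle(config)
    hs = bundle.homology
    sp_a, sp_b = bundle.config.species
    outdir = config.outdir / "homology"
    outdir.mkdir(parents=True, exist_ok=True)
    res_a = load_de_results(config, sp_a)
    res_b = load_de_results(config, sp_b)
    degs_a = diffexpr.deg_sets(res_a)
    degs_b = diffexpr.deg_sets(res_b)
    labels_a = load_archetype_labels(config, sp_a)
    labels_b = load_archetype_labels(config, sp_b)
    pairs = hs.one2one_pairs()

    summary = homology.relationship_summary(hs)
    partition = homology.shared_de_partition(pairs, degs_a.union, degs_b.union)
    partition_counts = {cell: int(len(df)) for cell, df in partition.items()}
    synchrony = {}
    for comparison in COMPARISONS:
        st = homology.synchrony_stats(
            pairs, res_a[comparison], res_b[comparison], comparison
        )
        synchrony[comparison] = {
            "same_by_stage": st.same_by_stage,
            "n_asynchronous": st.n_asynchronous,
            "percent_same": st.percent_same,
        }
    stage_mat = homology.stage_overlap_matrix(res_a, res_b, partition["both"])
    overlap = homology.cluster_overlap(
        partition["both"], labels_a, labels_b, n_de_pairs=partition_counts["both"]
    )
    core = homology.gastrula_core(partition["both"], res_a, res_b)
    kcore = homology.g_cluster_core(partition["both"], labels_a, labels_b)

    stage_mat.to_csv(outdir / "stage_overlap.tsv", sep="\t")
    overlap.matrix.to_csv(outdir / "cluster_overlap.tsv", sep="\t")
    core.to_csv(outdir / "gastrula_core.tsv", sep="\t", index=False)
    kcore.to_csv(outdir / "g_cluster_core.tsv", sep="\t", index=False)
    info = {
        "relationship_summary": summary,
        "partition": partition_counts,
        "synchrony": synchrony,
        "cluster_overlap": {
            "trace": overlap.trace,
            "percent_same": overlap.percent_same,
            "n_pairs": overlap.n_pairs,
            "n_unassigned": overlap.n_unassigned,
        },
        "gastrula_core_size": int(len(core)),
        "g_cluster_core_size": int(len(kcore)),
    }
    (outdir / "summary.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    _append_manifest(
        config,
        "homology",
        {},
        [
            outdir / "stage_overlap.tsv",
            outdir / "cluster_overlap.tsv",
            outdir / "gastrula_core.tsv",
            outdir / "g_cluster_core.tsv",
            outdir / "summary.json",
        ],
    )


def stage_paralogs(config: PipelineConfig) -> None:
    bundle = _load_bundle(config)
    outdir = config.outdir / "paralogs"
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    info = {}
    for sp in bundle.config.species:
        pairs = bundle.homology.paralog_pairs.get(sp, [])
        results = load_de_results(config, sp)
        labels = load_archetype_labels(config, sp)
        vst = load_vst(config, sp)
        pk = paralogs.classify_pk(pairs, labels)
        pcc, frac_high = paralogs.pair_pcc(pairs, vst, threshold=config.pcc_threshold)
        pk["pcc"] = pcc
        sp_info = {
            "pk_counts": paralogs.class_counts(pk, "pk_class"),
            "pk1_same_fraction": paralogs.pattern_similarity(pk),
            "fraction_pcc_high": frac_high,
            "p_counts": {},
            "p1_same_fraction": {},
        }
        for comparison in COMPARISONS:
            cp = paralogs.classify_p(pairs, results[comparison], comparison)
            path = outdir / f"paralogs_{sp}_{comparison}.tsv"
            cp.to_csv(path, sep="\t", index=False)
            files.append(path)
            sp_info["p_counts"][comparison] = paralogs.class_counts(cp, "p_class")
            sp_info["p1_same_fraction"][comparison] = paralogs.pattern_similarity(cp)
        path = outdir / f"paralogs_{sp}_clusters.tsv"
        pk.to_csv(path, sep="\t", index=False)
        files.append(path)
        info[sp] = sp_info
    (outdir / "summary.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    files.append(outdir / "summary.json")
    _append_manifest(config, "paralogs", {"pcc_threshold": config.pcc_threshold}, files)


def default_baits(config: PipelineConfig, bundle) -> list[str]:
    """First (by group id) one-to-one both-DE pair: one bait per species."""
    sp_a, sp_b = bundle.config.species
    degs_a = diffexpr.deg_sets(load_de_results(config, sp_a)).union
    degs_b = diffexpr.deg_sets(load_de_results(config, sp_b)).union
    pairs = bundle.homology.one2one_pairs()
    both = pairs[pairs["gene_a"].isin(degs_a) & pairs["gene_b"].isin(degs_b)]
    if len(both) == 0:
        raise PipelineError("no one-to-one both-DE pair available as default baits")
    row = both.sort_values("group").iloc[0]
    return [row["gene_a"], row["gene_b"]]


def stage_network(config: PipelineConfig) -> None:
    bundle = _load_bundle(config)
    outdir = config.outdir / "network"
    outdir.mkdir(parents=True, exist_ok=True)
    baits = config.baits or default_baits(config, bundle)
    nets = []
    files = []
    for bait in baits:
        sp = bait.split("|", 1)[0]
        vst = load_vst(config, sp)
        profile = networks.pcc_profile(bait, vst)
        if config.network_mode == "percentile":
            cutoffs = networks.percentile_cutoffs(
                profile.drop(index=bait, errors="ignore"),
                config.network_lower_rank,
                config.network_upper_rank,
            )
        else:
            cutoffs = networks.absolute_cutoffs(config.network_abs_threshold)
        net = networks.build_network(bait, vst, cutoffs)
        networks.annotate_families(net, bundle.homology)
        edges = net.edges.copy()
        edges["family"] = edges["partner"].map(net.families)
        safe = bait.replace("|", "_")
        path = outdir / f"edges_{safe}.tsv"
        edges.to_csv(path, sep="\t", index=False)
        files.append(path)
        nets.append(net)
    comparisons = {}
    for i in range(len(nets)):
        for j in range(i + 1, len(nets)):
            cmp_ = networks.compare_networks(nets[i], nets[j], bundle.homology)
            key = f"{nets[i].bait}~{nets[j].bait}"
            comparisons[key] = {
                "shared_families": int(len(cmp_.shared)),
                "concordant": cmp_.n_concordant,
                "discordant": cmp_.n_discordant,
                "unique_a": len(cmp_.unique_a),
                "unique_b": len(cmp_.unique_b),
                "same_species": cmp_.same_species,
            }
    (outdir / "comparison.json").write_text(
        json.dumps(comparisons, indent=2, sort_keys=True)
    )
    files.append(outdir / "comparison.json")
    _append_manifest(
        config,
        "network",
        {"mode": config.network_mode, "baits": baits},
        files,
    )


def stage_enrich(config: PipelineConfig) -> None:
    bundle = _load_bundle(config)
    outdir = config.outdir / "enrich"
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    target = bundle.config.enriched_archetype
    for sp in bundle.config.species:
        labels = load_archetype_labels(config, sp)
        go = bundle.truth.go
        sp_go = go[go["gene"].str.startswith(f"{sp}|")]
        population = set(sp_go["gene"])
        query = set(labels.index[labels == target]) & population
        result = enrichment.enrich(query, sp_go, population, alpha=config.enrich_alpha)
        path = outdir / f"enrich_{sp}_{target}.tsv"
        result.to_csv(path, sep="\t", index=False)
        files.append(path)
    _append_manifest(
        config, "enrich", {"alpha": config.enrich_alpha, "archetype": target}, files
    )


def stage_report(config: PipelineConfig) -> dict:
    """Assemble the paper-style summary tables from stage outputs."""
    bundle = _load_bundle(config)
    outdir = config.outdir / "report"
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"species": list(bundle.config.species)}
    coding = bundle.truth.genes["coding"]
    for sp in bundle.config.species:
        results = load_de_results(config, sp)
        degs = diffexpr.deg_sets(results)
        labels = load_archetype_labels(config, sp)
        cluster_sizes = labels.value_counts().to_dict()
        n_deg = degs.total
        sp_sum = {
            "deg_total": n_deg,
            "deg_per_comparison": {
                c: int(len(s)) for c, s in degs.per_comparison.items()
            },
            "deg_up_per_stage": {
                f"{c}:{st}": int(len(s)) for (c, st), s in degs.up.items()
            },
            "noncoding_deg_percent": percentage(
                sum(1 for g in degs.union if not bool(coding.get(g, True))), n_deg, 1
            )
            if n_deg
            else 0.0,
            "cluster_sizes": {a: int(cluster_sizes.get(a, 0)) for a in ARCHETYPES},
            "cluster_share_percent": {
                a: cluster_share_percent(int(cluster_sizes.get(a, 0)), n_deg)
                for a in ARCHETYPES
            }
            if n_deg
            else {},
        }
        summary[sp] = sp_sum
    hom_path = _require(config.outdir / "homology" / "summary.json", "homology")
    summary["homology"] = json.loads(hom_path.read_text())
    par_path = _require(config.outdir / "paralogs" / "summary.json", "paralogs")
    summary["paralogs"] = json.loads(par_path.read_text())
    net_path = _require(config.outdir / "network" / "comparison.json", "network")
    summary["networks"] = json.loads(net_path.read_text())
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _append_manifest(config, "report", {}, [outdir / "summary.json"])
    return summary


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "de": stage_de,
    "cluster": stage_cluster,
    "homology": stage_homology,
    "paralogs": stage_paralogs,
    "network": stage_network,
    "enrich": stage_enrich,
    "report": stage_report,
}


def run_stage(name: str, config: PipelineConfig):
    if name not in STAGE_FUNCS:
        raise PipelineError(f"unknown stage {name!r}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    return STAGE_FUNCS[name](config)


def run_all(config: PipelineConfig) -> dict:
    for name in STAGE_ORDER:
        result = run_stage(name, config)
    return result  # the report summary


def manifest_checksums(config: PipelineConfig) -> dict[str, str]:
    """Flat relpath -> sha256 map over all stages (for determinism checks)."""
    manifest = json.loads(_manifest_path(config).read_text())
    out: dict[str, str] = {}
    for stage in manifest.values():
        out.update(stage["outputs"])
    return out
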