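"""Synthetic two-species developmental transcriptome generator.

Emulates the statistical structure of a two-coral-species gastrulation
RNA-seq comparison: orthogroups over two species with realistic
relationship-class proportions, six stage-archetype expression patterns
plus flat genes, negative-binomial counts at three replicates per stage,
planted conserved/divergent archetype fractions for ortholog and in-paralog
pairs, coding/noncoding labels, flat GO annotations with one term biased
toward a chosen archetype, and transcript-level isoform ids.

Every random draw flows from the config seed through named substreams, so
fixed seeds give bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ARCHETYPE_UP, FLAT, CountMatrix, make_design
from .homology import RELATIONSHIP_CLASSES, HomologySet, parse_groups, write_groups


@dataclass
class SynthConfig:
    """Generator parameters; defaults describe the emulated study design."""

    seed: int
    n_orthogroups: int = 3000
    relationship_mix: dict[str, float] = field(
        default_factory=lambda: {
            "one2one": 0.86,
            "one2many_A": 0.10,
            "one2many_B": 0.02,
            "many2many": 0.02,
        }
    )
    n_paralog_pairs_per_species: tuple[int, int] = (1500, 500)
    archetype_probs: dict[str, float] = field(
        default_factory=lambda: {
            "C1": 0.1, "C2": 0.1, "C3": 0.1, "C4": 0.1, "C5": 0.1, "C6": 0.1,
            FLAT: 0.4,
        }
    )
    conserved_fraction_orthologs: float = 0.15
    conserved_fraction_paralogs: tuple[float, float] = (0.50, 0.85)
    base_mean_log_mu: float = 4.0
    base_mean_log_sigma: float = 1.0
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    noncoding_fraction: float = 0.10
    n_go_terms: int = 50
    go_terms_per_gene: int = 3
    enriched_term_archetype_bias: float = 4.0
    enriched_archetype: str = "C3"
    species: tuple[str, str] = ("adi", "ate")
    multi_isoform_fraction: float = 0.15

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        mix_sum = sum(self.relationship_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"relationship_mix sums to {mix_sum}, not 1")
        if set(self.relationship_mix) != set(RELATIONSHIP_CLASSES):
            raise ValueError("relationship_mix must cover exactly the four classes")
        prob_sum = sum(self.archetype_probs.values())
        if abs(prob_sum - 1.0) > 1e-9:
            raise ValueError(f"archetype_probs sums to {prob_sum}, not 1")
        for name in ("conserved_fraction_orthologs", "noncoding_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for v in self.conserved_fraction_paralogs:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"conserved_fraction_paralogs value {v} outside [0, 1]")
        if any(p < 0 for p in self.relationship_mix.values()) or any(
            p < 0 for p in self.archetype_probs.values()
        ):
            raise ValueError("proportions must be non-negative")
        if self.n_orthogroups < 0 or self.n_replicates < 1:
            raise ValueError("counts must be non-negative (replicates >= 1)")
        if self.nb_dispersion <= 0 or self.effect_log2fc < 0:
            raise ValueError("nb_dispersion must be > 0 and effect_log2fc >= 0")
        if self.enriched_term_archetype_bias < 1:
            raise ValueError("enriched_term_archetype_bias must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = list(self.species)
        d["n_paralog_pairs_per_species"] = list(self.n_paralog_pairs_per_species)
        d["conserved_fraction_paralogs"] = list(self.conserved_fraction_paralogs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in (
            "species",
            "n_paralog_pairs_per_species",
            "conserved_fraction_paralogs",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


_STREAM_HOMOLOGY = 0
_STREAM_TRUTH = 1
_STREAM_COUNTS_A = 2
_STREAM_COUNTS_B = 3
_STREAM_ANNOTATION = 4


def sample_homology(config: SynthConfig) -> HomologySet:
    """Draw orthogroups realizing the relationship mix, plus paralog pairs.

    Gene ids follow the ``species|name`` convention of OrthoMCL groups
    files; in-paralog pairs are standalone within-species gene pairs listed
    separately (as a pair file, not inside the groups).
    """
    rng = _rng(config, _STREAM_HOMOLOGY)
    sp_a, sp_b = config.species
    classes = list(config.relationship_mix)
    probs = np.array([config.relationship_mix[c] for c in classes])
    draw = rng.choice(len(classes), size=config.n_orthogroups, p=probs)
    groups: dict[str, dict[str, list[str]]] = {}
    counter = {sp_a: 0, sp_b: 0}

    def new_gene(sp: str) -> str:
        counter[sp] += 1
        return f"{sp}|g{counter[sp]:05d}"

    def many(sp: str) -> list[str]:
        size = 2 + int(rng.random() < 0.3)
        return [new_gene(sp) for _ in range(size)]

    for i, ci in enumerate(draw):
        cls = classes[ci]
        gid = f"OG{i + 1:05d}"
        if cls == "one2one":
            members = {sp_a: [new_gene(sp_a)], sp_b: [new_gene(sp_b)]}
        elif cls == "one2many_A":
            members = {sp_a: many(sp_a), sp_b: [new_gene(sp_b)]}
        elif cls == "one2many_B":
            members = {sp_a: [new_gene(sp_a)], sp_b: many(sp_b)}
        else:
            members = {sp_a: many(sp_a), sp_b: many(sp_b)}
        groups[gid] = members

    paralog_pairs: dict[str, list[tuple[str, str]]] = {}
    for sp, n_pairs in zip(config.species, config.n_paralog_pairs_per_species):
        pairs = []
        for j in range(n_pairs):
            counter[sp] += 1
            g1 = f"{sp}|p{j + 1:04d}a"
            g2 = f"{sp}|p{j + 1:04d}b"
            pairs.append((g1, g2))
        paralog_pairs[sp] = pairs
    return HomologySet(species=config.species, groups=groups, paralog_pairs=paralog_pairs)


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests."""

    genes: pd.DataFrame  # index gene: species, orthogroup, archetype, coding, length
    ortholog_pairs: pd.DataFrame  # gene_a, gene_b, group, conserved
    paralog_pairs: pd.DataFrame  # species, gene1, gene2, conserved
    go: pd.DataFrame  # gene, term
    transcripts: pd.DataFrame  # transcript, gene

    def validate(self) -> None:
        if self.genes.index.duplicated().any():
            raise ValueError("a gene appears more than once in the truth table")
        for _, row in self.ortholog_pairs[self.ortholog_pairs["conserved"]].iterrows():
            a = self.genes.loc[row["gene_a"], "archetype"]
            b = self.genes.loc[row["gene_b"], "archetype"]
            if a != b:
                raise ValueError("conserved pair with differing archetypes")


def _draw_archetype(rng: np.random.Generator, probs: dict[str, float]) -> str:
    labels = list(probs)
    return labels[rng.choice(len(labels), p=np.array(list(probs.values())))]


def _draw_nonflat(rng: np.random.Generator, probs: dict[str, float]) -> str:
    labels = [a for a in probs if a != FLAT]
    p = np.array([probs[a] for a in labels])
    return labels[rng.choice(len(labels), p=p / p.sum())]


def _draw_different(rng: np.random.Generator, probs: dict[str, float], avoid: str) -> str:
    labels = [a for a in probs if a != FLAT and a != avoid]
    p = np.array([probs[a] for a in labels])
    return labels[rng.choice(len(labels), p=p / p.sum())]


def build_truth(config: SynthConfig, hs: HomologySet) -> TruthTable:
    """Plant archetypes, conservation flags, labels and annotations.

    Within a pair, flatness is coupled (both flat or both non-flat) and
    non-conserved non-flat pairs receive explicitly different archetypes,
    so the planted conserved fraction is exact among non-flat pairs.
    """
    rng = _rng(config, _STREAM_TRUTH)
    sp_a, sp_b = config.species
    probs = config.archetype_probs
    p_flat = probs.get(FLAT, 0.0)
    archetype: dict[str, str] = {}
    ortho_rows = []

    def plant_pair(g1: str, g2: str, f_conserved: float) -> bool:
        if rng.random() < p_flat:
            archetype[g1] = FLAT
            archetype[g2] = FLAT
            return True  # vacuously conserved (both flat)
        a = _draw_nonflat(rng, probs)
        archetype[g1] = a
        if rng.random() < f_conserved:
            archetype[g2] = a
            return True
        archetype[g2] = _draw_different(rng, probs, avoid=a)
        return False

    for gid in sorted(hs.groups):
        members = hs.groups[gid]
        cls = hs.relationship(gid)
        if cls == "one2one":
            ga, gb = members[sp_a][0], members[sp_b][0]
            conserved = plant_pair(ga, gb, config.conserved_fraction_orthologs)
            ortho_rows.append(
                {"gene_a": ga, "gene_b": gb, "group": gid, "conserved": conserved}
            )
        else:
            for sp in (sp_a, sp_b):
                for g in members.get(sp, []):
                    archetype[g] = _draw_archetype(rng, probs)

    para_rows = []
    for sp, frac in zip(config.species, config.conserved_fraction_paralogs):
        for g1, g2 in hs.paralog_pairs.get(sp, []):
            conserved = plant_pair(g1, g2, frac)
            para_rows.append(
                {"species": sp, "gene1": g1, "gene2": g2, "conserved": conserved}
            )

    all_genes = sorted(archetype)
    species_of = {g: g.split("|", 1)[0] for g in all_genes}
    g2grp = hs.gene_to_group()
    ann_rng = _rng(config, _STREAM_ANNOTATION)
    coding = ann_rng.random(len(all_genes)) >= config.noncoding_fraction
    lengths = np.exp(
        ann_rng.uniform(np.log(500.0), np.log(5000.0), size=len(all_genes))
    ).round().astype(int)
    genes = pd.DataFrame(
        {
            "species": [species_of[g] for g in all_genes],
            "orthogroup": [g2grp.get(g, "") for g in all_genes],
            "archetype": [archetype[g] for g in all_genes],
            "coding": coding,
            "length": lengths,
        },
        index=pd.Index(all_genes, name="gene"),
    )

    # flat GO annotation with one term biased toward the chosen archetype
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    go_rows = []
    for g in all_genes:
        weights = np.ones(config.n_go_terms)
        if archetype[g] == config.enriched_archetype:
            weights[0] = config.enriched_term_archetype_bias
        weights /= weights.sum()
        chosen = ann_rng.choice(
            config.n_go_terms,
            size=min(config.go_terms_per_gene, config.n_go_terms),
            replace=False,
            p=weights,
        )
        for t in chosen:
            go_rows.append({"gene": g, "term": terms[t]})

    # isoforms: most genes one transcript, a planted fraction get >= 2
    t_rows = []
    for g in all_genes:
        k = 1
        if ann_rng.random() < config.multi_isoform_fraction:
            k = 2 + ann_rng.geometric(0.7) - 1
        for j in range(1, k + 1):
            t_rows.append({"transcript": f"{g}.{j}", "gene": g})

    truth = TruthTable(
        genes=genes,
        ortholog_pairs=pd.DataFrame(
            ortho_rows, columns=["gene_a", "gene_b", "group", "conserved"]
        ),
        paralog_pairs=pd.DataFrame(
            para_rows, columns=["species", "gene1", "gene2", "conserved"]
        ),
        go=pd.DataFrame(go_rows, columns=["gene", "term"]),
        transcripts=pd.DataFrame(t_rows, columns=["transcript", "gene"]),
    )
    truth.validate()
    return truth


def planted_log2fc(archetype_label: str, earlier: str, later: str, effect: float) -> float:
    """True log2 fold change (later over earlier) implied by an archetype."""
    if archetype_label == FLAT:
        return 0.0
    up = ARCHETYPE_UP[archetype_label]
    return effect * ((later in up) - (earlier in up))


def simulate_counts(
    truth: TruthTable, config: SynthConfig, species: str
) -> CountMatrix:
    """Negative-binomial counts for one species.

    Gene g in sample s draws NB with mean
    ``mu_g * 2^(effect * up_g(stage_s)) * sf_s`` and shared dispersion;
    size factors sf_s are log-uniform in [0.7, 1.4].
    """
    stream = _STREAM_COUNTS_A if species == config.species[0] else _STREAM_COUNTS_B
    rng = _rng(config, stream)
    genes = truth.genes.index[truth.genes["species"] == species]
    if len(genes) == 0:
        design = make_design(species, n_replicates=config.n_replicates)
        return CountMatrix(
            counts=pd.DataFrame(
                np.zeros((0, len(design)), dtype=np.int64),
                index=pd.Index([], name="gene"),
                columns=design.index,
            ),
            design=design,
        )
    design = make_design(species, n_replicates=config.n_replicates)
    mu = np.exp(
        rng.normal(config.base_mean_log_mu, config.base_mean_log_sigma, size=len(genes))
    )
    sf = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=len(design)))
    arch = truth.genes.loc[genes, "archetype"].to_numpy()
    up = np.zeros((len(genes), len(design)))
    for j, sample in enumerate(design.index):
        stage = design.loc[sample, "stage"]
        up[:, j] = [
            1.0 if (a != FLAT and stage in ARCHETYPE_UP[a]) else 0.0 for a in arch
        ]
    mean = mu[:, None] * np.power(2.0, config.effect_log2fc * up) * sf[None, :]
    r = 1.0 / config.nb_dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    return CountMatrix(
        counts=pd.DataFrame(
            counts.astype(np.int64), index=pd.Index(genes, name="gene"), columns=design.index
        ),
        design=design,
    )


@dataclass
class SynDataBundle:
    config: SynthConfig
    homology: HomologySet
    truth: TruthTable
    counts: dict[str, CountMatrix]


def generate(config: SynthConfig) -> SynDataBundle:
    """Full dataset: homology, truth, and per-species count matrices."""
    hs = sample_homology(config)
    truth = build_truth(config, hs)
    counts = {sp: simulate_counts(truth, config, sp) for sp in config.species}
    return SynDataBundle(config=config, homology=hs, truth=truth, counts=counts)


def write_dataset(bundle: SynDataBundle, outdir) -> None:
    """Emit the dataset as plain-text TSV/groups/YAML files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    for sp in cfg.species:
        bundle.counts[sp].to_tsv(outdir / f"counts_{sp}.tsv")
        genes = bundle.truth.genes
        sub = genes[genes["species"] == sp]
        sub[["length", "coding"]].to_csv(outdir / f"genes_{sp}.tsv", sep="\t")
        go = bundle.truth.go
        go[go["gene"].isin(sub.index)].to_csv(
            outdir / f"go_{sp}.tsv", sep="\t", index=False
        )
        pairs = pd.DataFrame(
            bundle.homology.paralog_pairs.get(sp, []), columns=["gene1", "gene2"]
        )
        pairs.to_csv(outdir / f"paralog_pairs_{sp}.tsv", sep="\t", index=False)
        tr = bundle.truth.transcripts
        tr[tr["gene"].isin(sub.index)].to_csv(
            outdir / f"transcripts_{sp}.tsv", sep="\t", index=False
        )
    write_groups(bundle.homology, outdir / "groups.txt")
    bundle.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    bundle.truth.ortholog_pairs.to_csv(
        outdir / "truth_ortholog_pairs.tsv", sep="\t", index=False
    )
    bundle.truth.paralog_pairs.to_csv(
        outdir / "truth_paralog_pairs.tsv", sep="\t", index=False
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_dataset(outdir) -> SynDataBundle:
    """Re-read a written dataset into the in-memory containers."""
    outdir = Path(outdir)
    with open(outdir / "config.yaml") as fh:
        cfg = SynthConfig.from_dict(yaml.safe_load(fh))
    hs = parse_groups(outdir / "groups.txt", species=cfg.species)
    for sp in cfg.species:
        pairs = pd.read_csv(outdir / f"paralog_pairs_{sp}.tsv", sep="\t")
        hs.paralog_pairs[sp] = [tuple(r) for r in pairs.to_numpy()]
    genes = pd.read_csv(outdir / "truth_genes.tsv", sep="\t", index_col="gene")
    if len(genes):
        genes["orthogroup"] = genes["orthogroup"].fillna("")
    go = pd.concat(
        [pd.read_csv(outdir / f"go_{sp}.tsv", sep="\t") for sp in cfg.species],
        ignore_index=True,
    )
    transcripts = pd.concat(
        [pd.read_csv(outdir / f"transcripts_{sp}.tsv", sep="\t") for sp in cfg.species],
        ignore_index=True,
    )
    truth = TruthTable(
        genes=genes,
        ortholog_pairs=pd.read_csv(outdir / "truth_ortholog_pairs.tsv", sep="\t"),
        paralog_pairs=pd.read_csv(outdir / "truth_paralog_pairs.tsv", sep="\t"),
        go=go,
        transcripts=transcripts,
    )
    counts = {
        sp: CountMatrix.from_tsv(outdir / f"counts_{sp}.tsv") for sp in cfg.species
    }
    return SynDataBundle(config=cfg, homology=hs, truth=truth, counts=counts)
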