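"""Parameter-recovery and calibration evaluation against planted truth.

These routines run the analysis modules on a generated dataset and compare
the results with the generator's ground truth: differential-expression
sensitivity and empirical FDR against planted fold changes, clustering
agreement (adjusted Rand index) against planted archetypes, recovery of the
planted ortholog/paralog conservation fractions, and null-data calibration
of the DE test and the quartile chi-square.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import clustering, diffexpr, expression, paralogs
from .containers import COMPARISONS, FLAT, ExpressionMatrix, make_design
from .diffexpr import DEThresholds
from .syndata import SynDataBundle, SynthConfig, generate, planted_log2fc


def run_de(bundle: SynDataBundle, thresholds: DEThresholds = DEThresholds()):
    """Size factors, dispersion and both stage comparisons per species."""
    results: dict[str, dict[str, pd.DataFrame]] = {}
    for sp in bundle.config.species:
        cm = bundle.counts[sp]
        factors = expression.size_factors(cm)
        disp = diffexpr.estimate_dispersion(cm, factors)
        results[sp] = {
            comparison: diffexpr.de_test(cm, comparison, factors, disp, thresholds)
            for comparison in COMPARISONS
        }
    return results


def de_recovery(bundle: SynDataBundle, results=None) -> dict:
    """Sensitivity and empirical FDR of DEG calls against planted truth."""
    if results is None:
        results = run_de(bundle)
    effect = bundle.config.effect_log2fc
    arch = bundle.truth.genes["archetype"]
    n_true = n_found = n_called = n_false = 0
    for sp in bundle.config.species:
        for comparison, res in results[sp].items():
            earlier, later = COMPARISONS[comparison]
            truth_lfc = np.array(
                [planted_log2fc(arch[g], earlier, later, effect) for g in res.index]
            )
            called = res["is_deg"].to_numpy()
            is_true = truth_lfc != 0
            n_true += int(is_true.sum())
            n_found += int((called & is_true).sum())
            n_called += int(called.sum())
            n_false += int((called & ~is_true).sum())
    return {
        "sensitivity": n_found / n_true if n_true else float("nan"),
        "fdr": n_false / n_called if n_called else 0.0,
        "n_true": n_true,
        "n_called": n_called,
    }


def cluster_species(bundle: SynDataBundle, species: str, seed: int, results=None):
    """DEG-union clustering with archetype labels, as the pipeline runs it."""
    if results is None:
        results = run_de(bundle)
    cm = bundle.counts[species]
    factors = expression.size_factors(cm)
    vst = expression.vst_transform(cm, factors)
    degs = diffexpr.deg_sets(results[species])
    genes = sorted(degs.union & set(vst.genes))
    matrix, flagged = clustering.standardize_genes(vst, genes)
    matrix = matrix.drop(index=flagged)
    assignment = clustering.kmeans_cluster(matrix, seed=seed, design=vst.design)
    clustering.assign_archetypes(assignment)
    return assignment.archetype_labels()


def clustering_recovery(bundle: SynDataBundle, seed: int, results=None) -> dict:
    """Per-species ARI of recovered archetypes against planted (non-flat) ones."""
    if results is None:
        results = run_de(bundle)
    arch = bundle.truth.genes["archetype"]
    out: dict = {"labels": {}}
    aris = []
    for i, sp in enumerate(bundle.config.species):
        labels = cluster_species(bundle, sp, seed + i, results)
        out["labels"][sp] = labels
        truthy = arch.reindex(labels.index)
        mask = truthy != FLAT
        ari = adjusted_rand_score(truthy[mask], labels[mask])
        out[f"ari_{sp}"] = float(ari)
        aris.append(ari)
    out["ari_min"] = float(min(aris))
    return out


def conserved_fraction_recovery(
    bundle: SynDataBundle, labels_a: pd.Series, labels_b: pd.Series
) -> dict:
    """Same-archetype fraction among clustered non-flat one-to-one pairs."""
    arch = bundle.truth.genes["archetype"]
    op = bundle.truth.ortholog_pairs
    nonflat = op[
        (arch[op["gene_a"]].values != FLAT) & (arch[op["gene_b"]].values != FLAT)
    ]
    both = nonflat[
        nonflat["gene_a"].isin(labels_a.index) & nonflat["gene_b"].isin(labels_b.index)
    ]
    same = (
        labels_a[both["gene_a"]].values == labels_b[both["gene_b"]].values
    ).mean()
    return {
        "recovered": float(same),
        "planted": bundle.config.conserved_fraction_orthologs,
        "n_pairs": int(len(both)),
    }


def paralog_conservation_recovery(
    bundle: SynDataBundle, labels: dict[str, pd.Series]
) -> dict:
    """Pk1 same-archetype fraction per species vs the planted fraction."""
    out = {}
    for sp, planted in zip(
        bundle.config.species, bundle.config.conserved_fraction_paralogs
    ):
        pk = paralogs.classify_pk(bundle.homology.paralog_pairs[sp], labels[sp])
        out[sp] = {
            "recovered": paralogs.pattern_similarity(pk),
            "planted": planted,
            "n_pk1": int((pk["pk_class"] == "Pk1").sum()),
        }
    return out


def null_de_calibration(seed: int, n_orthogroups: int = 900) -> dict:
    """Fraction of genes at padj < 0.05 on effect-free synthetic data."""
    config = SynthConfig(
        seed=seed,
        n_orthogroups=n_orthogroups,
        n_paralog_pairs_per_species=(0, 0),
        effect_log2fc=0.0,
    )
    bundle = generate(config)
    sp = config.species[0]
    cm = bundle.counts[sp]
    factors = expression.size_factors(cm)
    disp = diffexpr.estimate_dispersion(cm, factors)
    rates = []
    n_genes = len(cm.genes)
    for comparison in COMPARISONS:
        res = diffexpr.de_test(cm, comparison, factors, disp)
        rates.append(float((res["padj"] < 0.05).mean()))
    return {"rate": max(rates), "rates": rates, "n_genes": n_genes}


def quartile_null_calibration(
    seed: int, n_iter: int = 1000, n_transcripts: int = 150
) -> dict:
    """Chi-square rejection rate when both classes share one abundance law."""
    rng = np.random.default_rng(seed)
    design = make_design("sp", stages=("PC",), n_replicates=3)
    genes = [f"sp|t{i:04d}" for i in range(n_transcripts)]
    n_reject = n_tests = 0
    for _ in range(n_iter):
        mu = rng.lognormal(2.0, 1.0, n_transcripts)
        vals = mu[:, None] * rng.lognormal(0.0, 0.2, (n_transcripts, 3))
        vals = vals / vals.sum(axis=0) * 1e6
        tpm = ExpressionMatrix(
            values=pd.DataFrame(vals, index=genes, columns=design.index),
            design=design,
            kind="TPM",
        )
        coding = pd.Series(rng.random(n_transcripts) < 0.5, index=genes)
        qt = expression.quartile_table(tpm, coding, "PC")
        for cls in qt.p.index:
            n_tests += 1
            n_reject += int(qt.p[cls] < 0.05)
    return {"rate": n_reject / n_tests, "n_tests": n_tests}
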