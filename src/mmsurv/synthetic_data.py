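"""Synthetic cohorts with the statistical structure the screen assumes.

The generator emulates an exome-sequenced high-grade serous ovarian
carcinoma cohort: ~50 somatic mutations per tumor (Poisson), TP53
mutated in ~70% of samples, GO-like gene sets of 50-500 genes with
overlap, ages around 60 years, and right-censored survival times from
an exponential proportional-hazards model whose log-hazard is linear
in the *capped* per-term burden of any planted terms plus a small age
effect.  Planting the effect on the capped burden — exactly the
quantity the screen tests — makes recovery a sharp test of the
pipeline rather than of model misspecification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from mmsurv.io_formats import ClinicalTable, GOAnnotation, GODag, MutationTable
from mmsurv.mms import DEFAULT_EXCLUDED_GENES

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort", "simulate_expression", "write_cohort"]

# variant-class mix of validated somatic calls in the emulated cohort
_VARIANT_PROBS = {
    "missense": 0.6809,
    "silent": 0.2139,
    "nonsense": 0.0426,
    "splice_site": 0.0220,
    "other": 0.0406,
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level generator settings.

    Defaults mirror the emulated study conditions: 320 samples, ~50
    mutations each over a universe of 18920 annotated genes, 70% TP53
    prevalence, 100 terms of 50-500 genes.  At these rates the mean
    capped burden per term is ~0.4 — mostly 0 or 1, occasionally 2 —
    which is the dose regime the cap is designed for.
    ``baseline_hazard`` of ln(2)/44 per month puts the baseline median
    overall survival at 44 months; ``censoring_rate`` 0.01/month
    yields roughly 40% censoring.  ``planted_effects`` maps term ids
    to a per-dose log hazard ratio applied to the capped burden.
    """

    n_samples: int = 320
    n_genes: int = 18920
    n_terms: int = 100
    term_size_range: tuple[int, int] = (50, 500)
    mean_mutations_per_sample: float = 50.0
    tp53_prevalence: float = 0.70
    planted_effects: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = float(np.log(2) / 44.0)
    censoring_rate: float = 0.01
    age_mean: float = 60.0
    age_sd: float = 10.0
    beta_age: float = 0.02
    burden_cap: int = 2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("term_size_range must satisfy 1 <= lo <= hi <= n_genes")
        if not 0 <= self.tp53_prevalence <= 1:
            raise ValueError("tp53_prevalence must lie in [0, 1]")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValueError("hazard rates must be positive")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to make it."""

    mutations: MutationTable
    clinical: ClinicalTable
    annotation: GOAnnotation
    dag: GODag
    truth: dict
    config: SimConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical.sample_ids)


def _term_ids(n: int) -> list[str]:
    # synthetic accession space: looks like GO ids, cannot collide with
    # real ones because the 99xxxxx block is unassigned
    return [f"GO:99{i:05d}" for i in range(n)]


def simulate_cohort(config: SimConfig = SimConfig()) -> SyntheticCohort:
    """Draw one cohort; bit-identical for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.term_size_range

    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    term_ids = _term_ids(config.n_terms)
    # log-uniform sizes: GO term sizes are right-skewed within the band
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_terms)).astype(int)
    sizes = np.clip(sizes, lo, hi)
    term_to_genes = {
        t: set(rng.choice(genes, size=s, replace=False)) for t, s in zip(term_ids, sizes)
    }
    for t in config.planted_effects:
        if t not in term_to_genes:
            raise ValueError(f"planted term {t!r} is not among the generated terms")
    annotation = GOAnnotation(
        term_to_genes=term_to_genes,
        term_names={t: f"synthetic term {i}" for i, t in enumerate(term_ids)},
    )

    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    n_mut = rng.poisson(config.mean_mutations_per_sample, size=config.n_samples)
    classes = list(_VARIANT_PROBS)
    probs = np.array(list(_VARIANT_PROBS.values()))
    rec_samples, rec_genes = [], []
    for s, m in zip(sample_ids, n_mut):
        rec_samples.extend([s] * int(m))
        rec_genes.extend(rng.choice(genes, size=int(m), replace=True))
    tp53 = rng.random(config.n_samples) < config.tp53_prevalence
    for s, has in zip(sample_ids, tp53):
        if has:
            rec_samples.append(s)
            rec_genes.append("TP53")
    n_rec = len(rec_samples)
    records = pd.DataFrame(
        {
            "sample_id": rec_samples,
            "gene_symbol": rec_genes,
            "variant_class": rng.choice(classes, size=n_rec, p=probs),
            "validated": np.ones(n_rec, dtype=bool),
        }
    )
    mutations = MutationTable(records)

    # capped burdens of the planted terms, computed exactly as the
    # screen computes them (TP53 excluded, cap applied)
    burden = {}
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    for t, beta in config.planted_effects.items():
        members = term_to_genes[t] - set(DEFAULT_EXCLUDED_GENES)
        in_term = records["gene_symbol"].isin(members)
        raw = np.zeros(config.n_samples)
        np.add.at(raw, records.loc[in_term, "sample_id"].map(sample_index).to_numpy(), 1)
        burden[t] = np.minimum(raw, config.burden_cap)

    age = np.empty(config.n_samples)
    for i in range(config.n_samples):
        a = rng.normal(config.age_mean, config.age_sd)
        while a < 18:
            a = rng.normal(config.age_mean, config.age_sd)
        age[i] = a

    log_hr = config.beta_age * (age - config.age_mean)
    for t, beta in config.planted_effects.items():
        log_hr = log_hr + beta * burden[t]
    hazard = config.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / config.censoring_rate, size=config.n_samples)
    os_months = np.minimum(t_event, t_cens)
    os_event = t_event <= t_cens

    # progression precedes death: a faster exponential with the same
    # linear predictor, censored by the same follow-up process
    t_prog = rng.exponential(1.0 / (2.0 * hazard))
    pfs_months = np.minimum(t_prog, t_cens)
    pfs_event = t_prog <= t_cens

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "os_months": os_months,
                "os_event": os_event,
                "age": age,
                "pfs_months": pfs_months,
                "pfs_event": pfs_event,
            }
        )
    )

    graph = nx.MultiDiGraph()
    root = "GO:9900000-root"
    graph.add_node(root, name="synthetic root", namespace="synthetic")
    for t in term_ids:
        graph.add_node(t, name=annotation.name(t), namespace="synthetic")
        graph.add_edge(t, root, key="is_a")
    dag = GODag(graph=graph)

    truth = {
        "planted_effects": dict(config.planted_effects),
        "true_hazard": hazard,
        "true_event_time": t_event,
        "planted_burden": burden,
        "tp53": tp53.astype(int),
    }
    return SyntheticCohort(
        mutations=mutations,
        clinical=clinical,
        annotation=annotation,
        dag=dag,
        truth=truth,
        config=config,
    )


def simulate_expression(
    cohort: SyntheticCohort, n_predictive_genes: int = 0, effect_size: float = 0.0
) -> pd.DataFrame:
    """Genes x samples expression matrix tied to the cohort.

    Baseline expression is standard normal per gene; the first
    ``n_predictive_genes`` genes get their mean shifted by
    ``effect_size`` times the standardized log true event time, which
    induces a survival association of the sign of ``effect_size``.
    """
    config = cohort.config
    if n_predictive_genes > config.n_genes:
        raise ValueError("n_predictive_genes exceeds n_genes")
    rng = np.random.default_rng(config.seed + 1_000_003)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    samples = cohort.sample_ids
    X = rng.normal(size=(config.n_genes, len(samples)))
    if n_predictive_genes and effect_size:
        logt = np.log(cohort.truth["true_event_time"])
        z = (logt - logt.mean()) / logt.std()
        X[:n_predictive_genes] += effect_size * z
    return pd.DataFrame(X, index=genes, columns=samples)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the cohort as the plain-text files the readers consume.

    Produces a MAF-style TSV, a clinical TSV, a two-column gene2go
    TSV, a minimal OBO file and a JSON sidecar of the planted truth;
    returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    maf = outdir / "mutations.maf.tsv"
    rec = cohort.mutations.records
    pd.DataFrame(
        {
            "Hugo_Symbol": rec["gene_symbol"],
            "Tumor_Sample_Barcode": rec["sample_id"],
            "Variant_Classification": rec["variant_class"],
            "Validation_Status": np.where(rec["validated"], "Valid", "Unknown"),
        }
    ).to_csv(maf, sep="\t", index=False)
    paths["mutations"] = str(maf)

    clin = outdir / "clinical.tsv"
    rows = cohort.clinical.rows.copy()
    rows["os_event"] = np.where(rows["os_event"], "DECEASED", "LIVING")
    rows["pfs_event"] = np.where(rows["pfs_event"].astype(bool), "DECEASED", "LIVING")
    rows.to_csv(clin, sep="\t", index=False)
    paths["clinical"] = str(clin)

    g2g = outdir / "gene2go.tsv"
    with open(g2g, "w") as fh:
        for t in sorted(cohort.annotation.term_to_genes):
            for g in sorted(cohort.annotation.term_to_genes[t]):
                fh.write(f"{g}\t{t}\n")
    paths["gene2go"] = str(g2g)

    obo = outdir / "ontology.obo"
    with open(obo, "w") as fh:
        fh.write("format-version: 1.2\n")
        for node, data in cohort.dag.graph.nodes(data=True):
            fh.write(f"\n[Term]\nid: {node}\nname: {data.get('name', node)}\n")
            fh.write(f"namespace: {data.get('namespace', 'synthetic')}\n")
            for _, parent, rel in cohort.dag.graph.out_edges(node, keys=True):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
    paths["ontology"] = str(obo)

    truth = outdir / "truth.json"
    with open(truth, "w") as fh:
        json.dump(
            {
                "planted_effects": cohort.truth["planted_effects"],
                "seed": cohort.config.seed,
                "n_samples": cohort.config.n_samples,
                "tp53": [int(v) for v in cohort.truth["tp53"]],
            },
            fh,
            indent=1,
        )
    paths["truth"] = str(truth)
    return paths
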