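"""Reproducible cohort-level experiments.

Two kinds of quantities live here.  The marginal summary recomputes,
through the analysis functions, every derived count and percentage of
the reference cohort fixture (shared fractions, driver-event fractions,
clonality proportions, gene prevalences, the clonality chi-square).
The recovery experiments measure how well the full pipeline recovers
generator ground truth: subtype concordance on a mixed cohort, Cox
hazard-ratio estimation on replicated cohorts, the clustering
optimizer against exhaustive enumeration, and normalized-VAF clonality
calibration for truncal mutations.
"""

from __future__ import annotations

import numpy as np

from .clonality import (
    best_partition,
    brute_force_partition,
    normalize_vafs,
    partition_mutations,
)
from .datasets import synthetic_reference_cohort
from .drivers import classify_driver_events, load_driver_genes
from .pipeline import analyze_synthetic_cohort
from .simulate import SimulationConfig, simulate_cohort
from .stats import group_compare, survival_analysis
from .subtypes import stromal_gene_status


def _pct(numer: int, denom: int) -> float:
    return round(100.0 * numer / denom, 1)


def reference_summary() -> dict[str, dict[str, float]]:
    """Recompute every derived count/percentage from the reference fixture.

    Returns ``{name: {"value": v, "n": denominator}}`` with percentages
    rounded to one decimal, the precision such figures are quoted at.
    """
    cohort = synthetic_reference_cohort()
    genes = load_driver_genes()

    n_stroma_muts = n_neo_muts = 0
    n_mutant_stroma = 0
    n_shared = n_sspec = n_nspec = 0
    shared_drivers = sspec_drivers = nspec_drivers = 0
    shared_stroma_clonal = shared_both_clonal = nspec_clonal = 0
    stroma_gene_patients: dict[str, int] = {"KRAS": 0, "TP53": 0, "CDKN2A": 0}
    neo_gene_patients: dict[str, int] = {"KRAS": 0, "TP53": 0}
    gene_clonal = {
        ("KRAS", "stroma"): [0, 0],
        ("TP53", "stroma"): [0, 0],
        ("KRAS", "neoplasm"): [0, 0],
        ("TP53", "neoplasm"): [0, 0],
    }

    for comps in cohort.values():
        stroma, neoplasm = comps["stroma"], comps["neoplasm"]
        n_stroma_muts += len(stroma)
        n_neo_muts += len(neoplasm)
        n_mutant_stroma += len(stroma) > 0

        part = partition_mutations(stroma, neoplasm)
        n_shared += len(part.shared)
        n_sspec += len(part.stroma_specific)
        n_nspec += len(part.neoplasm_specific)

        s_norm = {m.key: m for m in normalize_vafs(stroma)} if stroma.mutations else {}
        n_norm = {m.key: m for m in normalize_vafs(neoplasm)}
        neo_driver = {c.key: c for c in classify_driver_events(neoplasm, genes)}
        s_driver = {c.key: c for c in classify_driver_events(stroma, genes)}

        for k in part.shared:
            if neo_driver[k].is_driver_event:
                shared_drivers += 1
            if s_norm[k].clonal:
                shared_stroma_clonal += 1
                if n_norm[k].clonal:
                    shared_both_clonal += 1
        for k in part.stroma_specific:
            if s_driver[k].is_driver_event:
                sspec_drivers += 1
        for k in part.neoplasm_specific:
            if neo_driver[k].is_driver_event:
                nspec_drivers += 1
            if n_norm[k].clonal:
                nspec_clonal += 1

        s_flags = stromal_gene_status(stroma, ("KRAS", "TP53", "CDKN2A"))
        for g in stroma_gene_patients:
            stroma_gene_patients[g] += s_flags[g]
        n_genes = {m.gene for m in neoplasm.mutations}
        for g in neo_gene_patients:
            neo_gene_patients[g] += g in n_genes

        for m in stroma.mutations:
            if (m.gene, "stroma") in gene_clonal:
                acc = gene_clonal[(m.gene, "stroma")]
                acc[0] += 1
                acc[1] += s_norm[m.key].clonal
        for m in neoplasm.mutations:
            if (m.gene, "neoplasm") in gene_clonal:
                acc = gene_clonal[(m.gene, "neoplasm")]
                acc[0] += 1
                acc[1] += n_norm[m.key].clonal

    chi2, chi2_p = group_compare(
        np.array(
            [
                [shared_stroma_clonal, n_shared - shared_stroma_clonal],
                [nspec_clonal, n_nspec - nspec_clonal],
            ],
            dtype=float,
        ),
        test="chi_square",
    )

    out = {
        "n_stromal_mutations": {"value": n_stroma_muts, "n": 39},
        "n_neoplastic_mutations": {"value": n_neo_muts, "n": 50},
        "n_shared_mutations": {"value": n_shared, "n": n_stroma_muts},
        "n_stroma_specific": {"value": n_sspec, "n": n_stroma_muts},
        "n_neoplasm_specific": {"value": n_nspec, "n": n_neo_muts},
        "pct_stromal_mutations_shared": {
            "value": _pct(n_shared, n_stroma_muts),
            "n": n_stroma_muts,
        },
        "pct_patients_mutant_stroma": {"value": _pct(n_mutant_stroma, 50), "n": 50},
        "pct_shared_driver_events": {
            "value": _pct(shared_drivers, n_shared),
            "n": n_shared,
        },
        "pct_stroma_specific_driver_events": {
            "value": _pct(sspec_drivers, n_sspec),
            "n": n_sspec,
        },
        "pct_neoplasm_specific_driver_events": {
            "value": _pct(nspec_drivers, n_nspec),
            "n": n_nspec,
        },
        "pct_shared_clonal_in_stroma": {
            "value": _pct(shared_stroma_clonal, n_shared),
            "n": n_shared,
        },
        "pct_shared_clonal_in_both": {
            "value": _pct(shared_both_clonal, n_shared),
            "n": n_shared,
        },
        "pct_neoplasm_specific_clonal": {
            "value": _pct(nspec_clonal, n_nspec),
            "n": n_nspec,
        },
        "pct_stroma_kras": {"value": _pct(stroma_gene_patients["KRAS"], 39), "n": 39},
        "pct_stroma_tp53": {"value": _pct(stroma_gene_patients["TP53"], 39), "n": 39},
        "pct_stroma_cdkn2a": {
            "value": _pct(stroma_gene_patients["CDKN2A"], 39),
            "n": 39,
        },
        "pct_neoplasm_kras": {"value": _pct(neo_gene_patients["KRAS"], 50), "n": 50},
        "pct_neoplasm_tp53": {"value": _pct(neo_gene_patients["TP53"], 50), "n": 50},
        "clonality_chi2_p": {"value": chi2_p, "n": n_shared + n_nspec},
    }
    for (gene, comp), (total, clonal) in gene_clonal.items():
        out[f"pct_{gene.lower()}_clonal_{comp}"] = {
            "value": _pct(clonal, total),
            "n": total,
        }
    return out


def subtype_recovery(
    n_patients: int = 500, seed: int = 1
) -> dict[str, float]:
    """Fraction of synthetic patients whose pipeline subtype equals truth.

    Balanced subtype mix at the generator's default sequencing depth.
    Patients the pipeline cannot subtype count as misses.
    """
    config = SimulationConfig(
        n_patients=n_patients, subtype_mix=(0.25, 0.25, 0.25, 0.25), seed=seed
    )
    cohort = simulate_cohort(config)
    analyses = analyze_synthetic_cohort(cohort, seed=seed + 1)
    truth = {t.patient_id: t.subtype for t in cohort.truths}
    hits = sum(
        1 for pid, a in analyses.items() if a.subtype.subtype == truth[pid]
    )
    return {"recovery_pct": round(100.0 * hits / n_patients, 2), "n": n_patients}


def hr_recovery(
    n_replicates: int = 100,
    n_patients: int = 200,
    true_hr: float = 3.0,
    seed: int = 1,
) -> dict[str, float]:
    """Cox hazard-ratio recovery over replicated synthetic cohorts.

    Each replicate draws a fresh cohort with the given true
    neoplasm-like hazard ratio and fits the univariate Cox model;
    reports the mean estimate and 95%-CI coverage of the truth.
    """
    hrs = []
    covered = 0
    for rep in range(n_replicates):
        rep_seed = (seed * 1_000_003 + rep) % (2**31 - 1)
        cohort = simulate_cohort(
            SimulationConfig(
                n_patients=n_patients,
                neoplasm_like_hazard_ratio=true_hr,
                seed=rep_seed,
            )
        )
        flags = {t.patient_id: t.neoplasm_like for t in cohort.truths}
        res = survival_analysis(cohort.clinical, flags)
        hrs.append(res.hazard_ratio)
        covered += res.hr_ci[0] <= true_hr <= res.hr_ci[1]
    return {
        "mean_hr": round(float(np.mean(hrs)), 3),
        "coverage_pct": round(100.0 * covered / n_replicates, 1),
        "n": n_patients,
        "n_replicates": n_replicates,
    }


def clustering_oracle(n_instances: int = 200, seed: int = 1) -> dict[str, float]:
    """Clustering optimizer vs exhaustive enumeration on small instances.

    Random instances with <=8 mutations from <=3 true clusters; reports
    the share of instances where the optimizer's classification
    likelihood reaches the enumeration optimum (tolerance 1e-6) and the
    worst observed gap.
    """
    rng = np.random.default_rng(seed)
    max_gap = 0.0
    matched = 0
    for trial in range(n_instances):
        n = int(rng.integers(2, 9))
        k_true = int(rng.integers(1, 4))
        ccfs = rng.uniform(0.05, 1.0, size=k_true)
        ccf = ccfs[rng.integers(k_true, size=n)]
        depth = rng.integers(200, 1500, size=n).astype(float)
        alt = rng.binomial(depth.astype(int), ccf * 0.5).astype(float)
        factor = np.full(n, 0.5)
        _, em_ll = best_partition(alt, depth, factor, max_labels=3, seed=trial)
        _, opt_ll = brute_force_partition(alt, depth, factor, max_labels=3)
        gap = opt_ll - em_ll
        max_gap = max(max_gap, gap)
        matched += gap <= 1e-6
    return {
        "match_pct": round(100.0 * matched / n_instances, 1),
        "max_gap": float(max_gap),
        "n": n_instances,
    }


def truncal_clonality_calibration(
    n_patients: int = 150, seed: int = 1
) -> dict[str, float]:
    """How often simulated truncal mutations are called clonal.

    Runs the somatic filter on each generated neoplastic specimen and
    applies the normalized-VAF rule; the denominator is every simulated
    truncal mutation (undetected ones count against calibration).
    """
    cohort = simulate_cohort(SimulationConfig(n_patients=n_patients, seed=seed))
    analyses = analyze_synthetic_cohort(cohort, seed=seed + 1)
    truth = {t.patient_id: t for t in cohort.truths}
    total = clonal = 0
    for pid, analysis in analyses.items():
        truncal_keys = {m.key for m in truth[pid].clones[0].mutations}
        if not truncal_keys:
            continue
        norms = {m.key: m for m in normalize_vafs(analysis.neoplasm)}
        total += len(truncal_keys)
        clonal += sum(1 for k in truncal_keys if k in norms and norms[k].clonal)
    return {
        "clonal_pct": round(100.0 * clonal / total, 2),
        "n": total,
    }
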