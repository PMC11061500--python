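"""End-to-end orchestration of the filtering, inference and cpDNA stages.

These functions tie the stage modules together the way the command-line
interface exposes them: the filter cascade with a per-step retention report,
the replicate ABC-RF analysis of an observed dataset, a calibration run on
pseudo-observed datasets, and the chloroplast direction workflow.  Every
result bundle embeds provenance (configuration hash, master seed, statistic
registry version, software version) sufficient to reproduce it bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__, abcrf, cpdna as cpdna_mod, genotypes, sumstats
from .abcrf import ReplicateSummary, build_reference_table, classify, estimate_parameters, fit_model_choice
from .scenarios import PriorSpec, draw_parameters, generations_to_years, scenario_lineages, _SCENARIO_TIMES
from .synthetic_data import StudyDesign, make_pod

__all__ = [
    "FilterParams",
    "run_filter_cascade",
    "run_inference",
    "run_calibration",
    "run_cpdna",
    "provenance",
]


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def provenance(config: dict, seed: int) -> dict:
    """Reproducibility stamp embedded in every output artifact."""
    return {
        "config_hash": _config_hash(config),
        "master_seed": int(seed),
        "stat_registry": sumstats.STAT_REGISTRY_VERSION,
        "software_version": __version__,
    }


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the full filtering cascade, in application order."""

    min_reproducibility: float = 1.0
    min_locus_call_rate: float = 1.0
    min_individual_call_rate: float = 1.0
    thin_seed: int = 0
    polymorphism_groups: tuple[str, ...] = ()
    polymorphism_mode: str = "strict"
    min_maf: float = 0.05


def run_filter_cascade(
    ds: genotypes.SnpDataset, params: FilterParams
) -> tuple[genotypes.SnpDataset, pd.DataFrame]:
    """Apply the filter steps in cascade order with a retention report.

    Order: locus reproducibility and call rate, individual call rate,
    monomorphic removal, one-SNP-per-clone thinning, within-group
    polymorphism (if groups are named), pooled MAF.  Call rates are
    recomputed on the surviving matrix at each step.  Only the thinning
    step consumes randomness.
    """
    steps: list[tuple[str, genotypes.SnpDataset]] = [("input", ds)]
    ds = genotypes.filter_loci(ds, params.min_reproducibility, 0.0)
    steps.append(("reproducibility", ds))
    ds = genotypes.filter_loci(ds, 0.0, params.min_locus_call_rate)
    steps.append(("locus_call_rate", ds))
    ds = genotypes.filter_individuals(ds, params.min_individual_call_rate)
    steps.append(("individual_call_rate", ds))
    ds = genotypes.remove_monomorphic(ds)
    steps.append(("monomorphic", ds))
    ds = genotypes.thin_secondary_snps(ds, params.thin_seed)
    steps.append(("thin_secondary", ds))
    if params.polymorphism_groups:
        ds = genotypes.filter_group_polymorphism(
            ds, list(params.polymorphism_groups), params.polymorphism_mode
        )
        steps.append((f"group_polymorphism_{params.polymorphism_mode}", ds))
    ds = genotypes.filter_maf(ds, params.min_maf)
    steps.append(("maf", ds))
    report = pd.DataFrame(
        {
            "step": [name for name, _ in steps],
            "loci": [d.n_loci for _, d in steps],
            "individuals": [d.n_individuals for _, d in steps],
        }
    )
    return ds, report


def run_inference(
    observed: genotypes.SnpDataset,
    design: StudyDesign,
    prior: PriorSpec,
    scenario_ids=(1, 2, 3, 4, 5, 6),
    n_per_scenario: int = 2_000,
    n_trees: int = 500,
    n_replicates: int = 10,
    seed: int = 0,
    add_lda: bool = True,
    estimate: bool = True,
) -> dict:
    """Replicate ABC-RF scenario choice + parameter estimation on a dataset.

    Builds ``n_replicates`` independent reference tables matching the study
    design, classifies the observed summary vector on each, summarizes vote
    fractions and posterior probabilities, and (optionally) estimates the
    winning scenario's parameters with a quantile regression forest on a
    fresh table, reporting times both in generations and calendar years.
    """
    observed_stats = sumstats.compute_summaries(observed)
    summary: ReplicateSummary = abcrf.replicate_analysis(
        observed_stats, scenario_ids, prior, design.sample_config,
        design.n_loci, design.min_maf, n_per_scenario, n_trees,
        n_replicates, seed, add_lda=add_lda,
    )
    config = {
        "design": design.name, "sample_sizes": design.sample_sizes,
        "n_loci": design.n_loci, "min_maf": design.min_maf,
        "prior": prior.to_dict(), "n_per_scenario": n_per_scenario,
        "n_trees": n_trees, "n_replicates": n_replicates, "add_lda": add_lda,
        "scenario_ids": list(scenario_ids),
    }
    result = {
        "selected_scenario": summary.selected,
        "votes_mean": summary.votes_mean,
        "votes_sd": summary.votes_sd,
        "posterior_prob_mean": summary.posterior_mean,
        "posterior_prob_sd": summary.posterior_sd,
        "prior_error_rate_mean": summary.prior_error_mean,
        "provenance": provenance(config, seed),
    }
    if estimate:
        est_seed = np.random.SeedSequence([int(seed), 10_001]).generate_state(1)[0] % (2**31)
        table = build_reference_table(
            scenario_ids, prior, design.sample_config, design.n_loci,
            design.min_maf, n_per_scenario, seed=int(est_seed),
        )
        sid = summary.selected
        t_hyb, t_div = _SCENARIO_TIMES[sid]
        params = sorted({t_hyb, t_div, "t5"}) + ["r1"] + [
            f"N_{lin}" for lin in scenario_lineages(sid)
        ]
        posteriors = estimate_parameters(
            table, sid, observed_stats, params, n_trees=n_trees, seed=int(est_seed)
        )
        g = prior.generation_time_years
        est = {}
        for p in posteriors:
            entry = {"median": p.median, "q05": p.q05, "q95": p.q95}
            if p.name.startswith("t"):
                entry["median_years"] = p.median * g
                entry["q05_years"] = p.q05 * g
                entry["q95_years"] = p.q95 * g
            est[p.name] = entry
        result["parameter_estimates"] = est
    return result


def run_calibration(
    design: StudyDesign,
    prior: PriorSpec,
    scenario_ids=(1, 2, 3, 4, 5, 6),
    n_pods_per_scenario: int = 5,
    n_per_scenario: int = 500,
    n_trees: int = 300,
    seed: int = 0,
    add_lda: bool = True,
    estimate_params: tuple[str, ...] = ("r1",),
) -> dict:
    """Score scenario recovery and parameter recovery on pseudo-observed data.

    One reference table (shared by all pseudo-observed datasets) is built and
    a classifier trained on it; per scenario, ``n_pods_per_scenario`` PODs
    are drawn from the prior, classified, and — for the requested parameters,
    when defined under the true scenario — estimated, recording bias and
    whether the 90% interval covers the truth.  Returns the confusion matrix
    (true scenario x selected scenario), vote distributions, and the
    parameter-recovery table.
    """
    table = build_reference_table(
        scenario_ids, prior, design.sample_config, design.n_loci,
        design.min_maf, n_per_scenario, seed=int(seed),
    )
    fit = fit_model_choice(table, n_trees=n_trees, add_lda=add_lda, seed=int(seed))
    ids = sorted(int(s) for s in scenario_ids)
    confusion = pd.DataFrame(0, index=ids, columns=ids)
    vote_rows, recovery_rows = [], []
    for sid in ids:
        for k in range(n_pods_per_scenario):
            rng = np.random.default_rng([int(seed), 777, sid, k])
            theta = draw_parameters(prior, sid, rng)
            pod, truth = make_pod(sid, design, rng, theta=theta, prior=prior)
            stats = sumstats.compute_summaries(pod)
            res = classify(fit, stats)
            confusion.loc[sid, res.selected] += 1
            vote_rows.append({"true_scenario": sid, "pod": k, **{
                f"votes_{s}": res.votes[s] for s in ids}})
            for pname in estimate_params:
                true_val = truth["params"].get(pname)
                if true_val is None or np.isnan(true_val):
                    continue
                post = estimate_parameters(
                    table, sid, stats, [pname], n_trees=n_trees, seed=int(seed) + k
                )[0]
                recovery_rows.append({
                    "true_scenario": sid, "pod": k, "parameter": pname,
                    "truth": true_val, "median": post.median,
                    "bias": post.median - true_val,
                    "covered_90": bool(post.q05 <= true_val <= post.q95),
                })
    config = {
        "design": design.name, "n_pods_per_scenario": n_pods_per_scenario,
        "n_per_scenario": n_per_scenario, "n_trees": n_trees,
        "prior": prior.to_dict(), "scenario_ids": ids,
    }
    return {
        "confusion": confusion,
        "votes": pd.DataFrame(vote_rows),
        "recovery": pd.DataFrame(recovery_rows),
        "prior_error_rate": fit.prior_error_rate,
        "provenance": provenance(config, seed),
    }


def run_cpdna(
    aln: cpdna_mod.HaplotypeAlignment,
    class_a_ids,
    class_b_ids,
    query_ids=None,
    locality: dict[str, str] | None = None,
    min_sites: int = 2,
    label_a: str = "A",
    label_b: str = "B",
) -> dict:
    """Diagnostic discovery plus maternal classification of query sequences."""
    diag = cpdna_mod.find_diagnostics(aln, class_a_ids, class_b_ids, label_a, label_b)
    if query_ids is None:
        query_ids = [i for i in aln.ids if i not in set(class_a_ids) | set(class_b_ids)]
    labels, audit = {}, {}
    for sid in query_ids:
        label, agreement = cpdna_mod.classify_maternal(aln.sequences[sid], diag, min_sites)
        labels[sid] = label
        audit[sid] = agreement
    table = cpdna_mod.summarize_directions(labels, locality) if labels else pd.DataFrame()
    return {"diagnostics": diag, "labels": labels, "audit": audit, "directions": table}
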