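"""Random-forest approximate Bayesian computation (ABC-RF).

Model choice trains a classification random forest on a reference table of
simulations (scenario label, drawn parameters, summary statistics),
optionally augmented with linear-discriminant projection axes fitted on the
table.  The observed dataset is assigned the scenario with the plurality of
per-tree votes; the posterior probability of that choice is estimated by a
second, regression forest trained on the out-of-bag misclassification
indicator (posterior = 1 - predicted error at the observed point), and the
prior error rate is the overall out-of-bag misclassification.  Parameters
are estimated with quantile regression forests: the posterior distribution
of a parameter is the training responses weighted by how often they share a
leaf with the observed point, from which weighted median and 5%/95%
quantiles are reported.  Replicate analyses repeat the whole procedure on
independently simulated reference tables and report means and standard
deviations of vote fractions and posterior probabilities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from . import __version__
from .coalsim import SampleConfig, SimulationCapError, simulate_snp_dataset
from .scenarios import PriorSpec, build_scenario, draw_parameters
from .sumstats import STAT_REGISTRY_VERSION, compute_summaries

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceTable",
    "ModelChoiceFit",
    "ModelChoiceResult",
    "ParamPosterior",
    "ReplicateSummary",
    "build_reference_table",
    "fit_model_choice",
    "classify",
    "estimate_parameters",
    "replicate_analysis",
]

#: order of parameter columns in reference tables (union over scenarios)
PARAM_COLUMNS = [
    "t1", "t2", "t3", "t4", "t5", "r1",
    "N_PAM_N", "N_PAM_S", "N_HYB_N", "N_HYB_S", "N_HIM",
    "N_PAM_anc", "N_HYB_anc", "N_ANC",
]

RECOMMENDED_SIMS = (2_000, 20_000)


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summaries) rows plus provenance."""

    table: pd.DataFrame
    stat_cols: list[str]
    param_cols: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def scenario_ids(self) -> list[int]:
        return sorted(self.table["scenario_id"].unique().tolist())

    def stats_matrix(self) -> np.ndarray:
        return self.table[self.stat_cols].to_numpy(dtype=float)

    def save(self, csv_path, sidecar_path=None) -> None:
        """Persist as CSV with a JSON provenance sidecar."""
        self.table.to_csv(csv_path, index=False)
        sidecar_path = sidecar_path or str(csv_path) + ".json"
        meta = {
            "stat_cols": self.stat_cols,
            "param_cols": self.param_cols,
            "provenance": self.provenance,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, csv_path, sidecar_path=None) -> "ReferenceTable":
        sidecar_path = sidecar_path or str(csv_path) + ".json"
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(pd.read_csv(csv_path), meta["stat_cols"], meta["param_cols"],
                   meta.get("provenance", {}))


def build_reference_table(
    scenario_ids,
    prior: PriorSpec,
    config: SampleConfig,
    n_loci: int,
    min_maf: float,
    n_per_scenario: int,
    seed: int,
    max_attempts: int = 10_000,
    groups=None,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` reference rows per scenario.

    Each row draws a parameter vector from the prior, simulates a SNP
    dataset matching the observed design (sample sizes, locus count, MAF
    threshold), and computes the summary vector.  Rows are reproducible
    individually: row ``i`` of scenario ``s`` uses the generator seeded with
    ``(seed, s, i)``.  Draws whose simulation exhausts the rejection cap are
    resampled (counted in provenance).
    """
    scenario_ids = list(scenario_ids)
    if not RECOMMENDED_SIMS[0] <= n_per_scenario <= RECOMMENDED_SIMS[1]:
        logger.warning(
            "n_per_scenario=%d outside the recommended range %s",
            n_per_scenario, RECOMMENDED_SIMS,
        )
    rows = []
    resampled = 0
    stat_cols: list[str] | None = None
    for sid in scenario_ids:
        for i in range(n_per_scenario):
            rng = np.random.default_rng([int(seed), int(sid), i])
            while True:
                theta = draw_parameters(prior, sid, rng)
                scn = build_scenario(sid, theta, prior)
                try:
                    ds = simulate_snp_dataset(scn, config, n_loci, min_maf, rng, max_attempts)
                except SimulationCapError:
                    resampled += 1
                    continue
                break
            stats = compute_summaries(ds, groups)
            if stat_cols is None:
                stat_cols = list(stats.index)
            row = {"scenario_id": sid}
            row.update({c: np.nan for c in PARAM_COLUMNS})
            row.update(theta.as_flat_dict())
            row.update(stats.to_dict())
            rows.append(row)
    table = pd.DataFrame(rows, columns=["scenario_id"] + PARAM_COLUMNS + stat_cols)
    provenance = {
        "seed": int(seed),
        "n_per_scenario": int(n_per_scenario),
        "scenario_ids": scenario_ids,
        "n_loci": int(n_loci),
        "min_maf": float(min_maf),
        "sample_sizes": dict(config.sizes),
        "prior": prior.to_dict(),
        "resampled_draws": resampled,
        "stat_registry": STAT_REGISTRY_VERSION,
        "software_version": __version__,
    }
    return ReferenceTable(table, stat_cols, PARAM_COLUMNS, provenance)


# ---------------------------------------------------------------------------
# Model choice
# ---------------------------------------------------------------------------


@dataclass
class ModelChoiceFit:
    """Trained scenario classifier with its feature pipeline and OOB record."""

    forest: RandomForestClassifier
    lda: LinearDiscriminantAnalysis | None
    stat_cols: list[str]
    col_means: np.ndarray
    table: ReferenceTable
    oob_predicted: np.ndarray  # predicted scenario per row (-1 if never OOB)
    prior_error_rate: float
    seed: int
    _error_regressor: RandomForestRegressor | None = field(default=None, repr=False)

    def error_regressor(self) -> RandomForestRegressor:
        """Regression forest of the OOB misclassification indicator (cached)."""
        if self._error_regressor is None:
            y = self.table.table["scenario_id"].to_numpy(dtype=int)
            has_oob = self.oob_predicted >= 0
            xt = self.features(self.table.stats_matrix())
            err = (self.oob_predicted[has_oob] != y[has_oob]).astype(float)
            reg = RandomForestRegressor(
                n_estimators=self.forest.n_estimators, random_state=self.seed + 1, n_jobs=1
            )
            reg.fit(xt[has_oob], err)
            self._error_regressor = reg
        return self._error_regressor

    def features(self, stats: np.ndarray) -> np.ndarray:
        x = np.array(stats, dtype=float, copy=True)
        nan = np.isnan(x)
        if nan.any():
            x[nan] = np.broadcast_to(self.col_means, x.shape)[nan]
        if self.lda is not None:
            x = np.hstack([x, self.lda.transform(x)])
        return x


@dataclass
class ModelChoiceResult:
    """Vote fractions, selected scenario and confidence measures."""

    votes: dict[int, float]
    selected: int
    posterior_prob: float
    prior_error_rate: float

    def __post_init__(self) -> None:
        total = sum(self.votes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"vote fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.votes.values()):
            raise ValueError("vote fractions must be non-negative")

    def subset_vote_share(self, subset) -> float:
        """Combined vote mass of an arbitrary scenario subset."""
        return float(sum(self.votes.get(int(s), 0.0) for s in subset))


def fit_model_choice(
    table: ReferenceTable, n_trees: int = 500, add_lda: bool = True, seed: int = 0
) -> ModelChoiceFit:
    """Train the scenario-choice random forest on a reference table.

    With ``add_lda`` (default), K-1 linear-discriminant axes fitted on the
    table are appended to the summary features.  Out-of-bag predictions are
    retained for the prior error rate and the posterior-probability model.
    """
    y = table.table["scenario_id"].to_numpy(dtype=int)
    x = table.stats_matrix()
    col_means = np.nanmean(x, axis=0)
    nan = np.isnan(x)
    if nan.any():
        x[nan] = np.broadcast_to(col_means, x.shape)[nan]
    lda = None
    if add_lda and len(np.unique(y)) > 1:
        lda = LinearDiscriminantAnalysis(n_components=len(np.unique(y)) - 1)
        lda.fit(x, y)
        x = np.hstack([x, lda.transform(x)])
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=int(seed), n_jobs=1
    )
    forest.fit(x, y)
    oob = forest.oob_decision_function_
    has_oob = ~np.isnan(oob).all(axis=1)
    oob_pred = np.full(y.size, -1, dtype=int)
    oob_pred[has_oob] = forest.classes_[np.argmax(oob[has_oob], axis=1)]
    prior_error = float((oob_pred[has_oob] != y[has_oob]).mean()) if has_oob.any() else np.nan
    return ModelChoiceFit(forest, lda, list(table.stat_cols), col_means, table,
                          oob_pred, prior_error, int(seed))


def classify(fit: ModelChoiceFit, observed: pd.Series) -> ModelChoiceResult:
    """Classify an observed summary vector: votes, winner, posterior probability.

    The observed vector's statistic names must match the reference table's
    exactly (hard error otherwise).  Vote fractions are per-tree plurality
    votes; the posterior probability follows the out-of-bag error-regression
    scheme of the ABC-RF literature.
    """
    if list(observed.index) != fit.stat_cols:
        raise ValueError(
            "observed summary-statistic header does not match the reference table "
            f"({len(observed.index)} vs {len(fit.stat_cols)} names)"
        )
    x = fit.features(observed.to_numpy(dtype=float)[None, :])
    tree_preds = np.array(
        [fit.forest.classes_[int(est.predict(x)[0])] for est in fit.forest.estimators_]
    )
    classes = fit.forest.classes_
    votes = {int(c): float((tree_preds == c).mean()) for c in classes}
    selected = int(classes[np.argmax([votes[int(c)] for c in classes])])
    posterior = float(np.clip(1.0 - fit.error_regressor().predict(x)[0], 0.0, 1.0))
    return ModelChoiceResult(votes, selected, posterior, fit.prior_error_rate)


# ---------------------------------------------------------------------------
# Parameter estimation (quantile regression forest)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamPosterior:
    """Weighted posterior quantiles of one parameter."""

    name: str
    median: float
    q05: float
    q95: float

    def __post_init__(self) -> None:
        if not self.q05 <= self.median <= self.q95:
            raise ValueError(f"quantiles out of order for {self.name}")


def _weighted_quantiles(y: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(y)
    y, w = y[order], w[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return np.interp(qs, cw, y)


def estimate_parameters(
    table: ReferenceTable,
    scenario_id: int,
    observed: pd.Series,
    params: list[str],
    n_trees: int = 500,
    seed: int = 0,
    min_samples_leaf: int = 5,
) -> list[ParamPosterior]:
    """Quantile-regression-forest posteriors for the selected scenario.

    The table is restricted to the scenario's rows; for each parameter a
    random-forest regression of the parameter on the summary statistics is
    fitted, the posterior is the training responses weighted by leaf
    co-occurrence with the observed point, and the weighted median and
    5%/95% quantiles are reported.
    """
    sub = table.table[table.table["scenario_id"] == scenario_id]
    if sub.empty:
        raise ValueError(f"no rows for scenario {scenario_id} in the reference table")
    if list(observed.index) != list(table.stat_cols):
        raise ValueError("observed summary-statistic header does not match the table")
    x = sub[table.stat_cols].to_numpy(dtype=float)
    col_means = np.nanmean(x, axis=0)
    nan = np.isnan(x)
    if nan.any():
        x[nan] = np.broadcast_to(col_means, x.shape)[nan]
    xo = observed.to_numpy(dtype=float)[None, :].copy()
    nan = np.isnan(xo)
    if nan.any():
        xo[nan] = np.broadcast_to(col_means, xo.shape)[nan]

    out = []
    for k, name in enumerate(params):
        y = sub[name].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"parameter {name!r} is not defined under scenario {scenario_id}")
        reg = RandomForestRegressor(
            n_estimators=n_trees, random_state=int(seed) + k, n_jobs=1,
            min_samples_leaf=min_samples_leaf,
        )
        reg.fit(x, y)
        leaves = reg.apply(x)  # (n, T)
        leaf_obs = reg.apply(xo)[0]  # (T,)
        w = np.zeros(y.size)
        for t in range(leaves.shape[1]):
            same = leaves[:, t] == leaf_obs[t]
            n_same = same.sum()
            if n_same:
                w[same] += 1.0 / n_same
        q05, med, q95 = _weighted_quantiles(y, w, (0.05, 0.5, 0.95))
        out.append(ParamPosterior(name, float(med), float(q05), float(q95)))
    return out


# ---------------------------------------------------------------------------
# Replicate analyses
# ---------------------------------------------------------------------------


@dataclass
class ReplicateSummary:
    """Vote-fraction and posterior-probability spread over replicate analyses."""

    votes_mean: dict[int, float]
    votes_sd: dict[int, float]
    posterior_mean: float
    posterior_sd: float
    prior_error_mean: float
    selected: int
    per_replicate: list[ModelChoiceResult] = field(repr=False, default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate)

    def subset_vote_share(self, subset) -> tuple[float, float]:
        """Mean and SD of the combined vote mass of a scenario subset."""
        shares = np.array([r.subset_vote_share(subset) for r in self.per_replicate])
        sd = float(shares.std(ddof=1)) if shares.size > 1 else float("nan")
        return float(shares.mean()), sd


def replicate_analysis(
    observed: pd.Series,
    scenario_ids,
    prior: PriorSpec,
    config: SampleConfig,
    n_loci: int,
    min_maf: float,
    n_per_scenario: int,
    n_trees: int,
    n_replicates: int,
    seed: int,
    add_lda: bool = True,
    groups=None,
) -> ReplicateSummary:
    """Repeat table building + model choice on independent reference tables.

    Replicate ``r`` uses master seed ``(seed, r)`` for its table and forest,
    so replicates are independent yet the whole analysis is reproducible
    from one seed.  With a single replicate the SD fields are NaN (warning).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if n_replicates == 1:
        logger.warning("single replicate: standard deviations will be NaN")
    results = []
    for r in range(n_replicates):
        rep_seed = np.random.SeedSequence([int(seed), r]).generate_state(1)[0] % (2**31)
        table = build_reference_table(
            scenario_ids, prior, config, n_loci, min_maf, n_per_scenario,
            seed=int(rep_seed), groups=groups,
        )
        fit = fit_model_choice(table, n_trees=n_trees, add_lda=add_lda, seed=int(rep_seed))
        results.append(classify(fit, observed))
    ids = sorted(int(s) for s in scenario_ids)
    votes = np.array([[res.votes[s] for s in ids] for res in results])
    post = np.array([res.posterior_prob for res in results])
    prior_err = np.array([res.prior_error_rate for res in results])
    sd = votes.std(axis=0, ddof=1) if n_replicates > 1 else np.full(len(ids), np.nan)
    mean_votes = votes.mean(axis=0)
    return ReplicateSummary(
        votes_mean=dict(zip(ids, mean_votes.tolist())),
        votes_sd=dict(zip(ids, sd.tolist())),
        posterior_mean=float(post.mean()),
        posterior_sd=float(post.std(ddof=1)) if n_replicates > 1 else float("nan"),
        prior_error_mean=float(np.nanmean(prior_err)),
        selected=int(ids[int(np.argmax(mean_votes))]),
        per_replicate=results,
    )
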