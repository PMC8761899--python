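"""Inter-environment and inter-population prediction schemes.

Two scenarios are implemented, both training on line values averaged over
a pair of environments and validating in the held-out environment:

* intra-population — repeated stratified k-fold cross-validation over the
  pooled panel: train on 90% of lines (with population proportions
  preserved per fold), predict the held-out 10% in the third environment,
  and score the Pearson predictive ability r_ab separately within each
  population to avoid bias from population mean differences.
* inter-population — train on all lines of a single population, validate
  within each other population in the remaining environment.

Aggregation order is fixed and explicit: folds -> repetitions -> sets of
training environments -> populations -> grand mean. Undefined correlations
(constant predictions or too-small cells) are recorded as missing and
excluded from means, never zero-filled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rilgs.gsmodels import GSModel
from rilgs.matrix import GenotypeMatrix

MIN_VALIDATION_LINES = 3


@dataclass
class CVScheme:
    """Settings of one cross-validation experiment."""

    scenario: str = "intra_population"
    k_folds: int = 10
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("intra_population", "inter_population"):
            raise ValueError(f"unknown scenario: {self.scenario}")
        if self.k_folds < 2:
            raise ValueError("need >= 2 folds")


@dataclass
class CVResult:
    """Per-cell predictive abilities plus the aggregation tree."""

    scenario: str
    records: pd.DataFrame  # columns depend on scenario; r_ab may be NaN
    aggregation_order: tuple = (
        "fold",
        "rep",
        "env_set",
        "population",
    )

    def grand_mean(self) -> float:
        return float(self.aggregate("population")["r_ab"].mean())

    def aggregate(self, level: str) -> pd.DataFrame:
        """Mean r_ab at the requested level, averaging in the stated order."""
        df = self.records
        if self.scenario == "intra_population":
            by_rep = (
                df.groupby(["population", "env_set", "rep"], as_index=False)["r_ab"]
                .mean()
            )
            by_env = by_rep.groupby(["population", "env_set"], as_index=False)[
                "r_ab"
            ].mean()
            by_pop = by_env.groupby("population", as_index=False)["r_ab"].mean()
        else:
            by_env = df.groupby(
                ["train_population", "population", "env_set"], as_index=False
            )["r_ab"].mean()
            by_val = by_env.groupby(
                ["train_population", "population"], as_index=False
            )["r_ab"].mean()
            if level == "train_population":
                return by_val.groupby("train_population", as_index=False)[
                    "r_ab"
                ].mean()
            by_pop = by_val.groupby("population", as_index=False)["r_ab"].mean()
        if level == "rep" and self.scenario == "intra_population":
            return by_rep
        if level == "env_set":
            return by_env
        if level == "population":
            return by_pop
        raise ValueError(f"unknown aggregation level: {level}")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def predictive_ability(observed, predicted) -> float:
    """Pearson correlation of observed vs predicted; NaN when degenerate."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) < MIN_VALIDATION_LINES:
        return np.nan
    # tolerance guards against constant vectors whose numerical std is ~1e-16
    tol_o = 1e-10 * max(1.0, float(np.abs(obs).max()))
    tol_p = 1e-10 * max(1.0, float(np.abs(pred).max()))
    if np.std(obs) <= tol_o or np.std(pred) <= tol_p:
        return np.nan
    return float(np.corrcoef(obs, pred)[0, 1])


def make_training_targets(blups: pd.DataFrame, env_pair: tuple[str, str]) -> pd.Series:
    """Per-line mean of environment-wise values over two training environments.

    Lines missing in either environment are excluded (the drop is visible
    from the returned index).
    """
    e1, e2 = env_pair
    for env in env_pair:
        if env not in blups.columns:
            raise ValueError(f"environment {env!r} missing from line values")
    pair = blups[[e1, e2]].dropna()
    return pair.mean(axis=1)


def stratified_folds(
    populations: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition line indices into k folds preserving population proportions.

    Within each population the (shuffled) lines are dealt round-robin to
    folds, so per-fold population counts differ from proportionality by at
    most one line.
    """
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for pop in pd.unique(populations):
        idx = np.flatnonzero(populations == pop)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[(pos + offset) % k].append(int(i))
        offset += len(idx) % k  # rotate the short folds across populations
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _env_sets(envs: list[str]) -> list[tuple[tuple[str, str], str]]:
    """All (training pair, validation environment) splits of the environments."""
    out = []
    for val in envs:
        train = tuple(e for e in envs if e != val)
        for pair in itertools.combinations(train, 2):
            out.append((pair, val))
    return out


def _resolve_model(model):
    if isinstance(model, GSModel):
        return GSModel(model.name, **model.kwargs)
    if isinstance(model, str):
        return GSModel(model)
    if hasattr(model, "fit") and hasattr(model, "predict"):
        return model  # any duck-typed fit/predict object
    raise ValueError("model must be a GSModel, a model name, or have fit/predict")


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def intra_population_cv(
    geno: GenotypeMatrix,
    blups: pd.DataFrame,
    model="rrblup",
    scheme: CVScheme | None = None,
) -> CVResult:
    """Pooled-panel stratified CV, scored within population.

    ``blups`` is a line x environment table of genotype values (typically
    per-environment BLUPs). For each choice of two training environments,
    each repetition re-draws stratified folds; the model trains on the
    two-environment mean of the training lines and predicts the held-out
    lines' values in the validation environment.
    """
    scheme = scheme or CVScheme()
    envs = sorted(blups.columns)
    if len(envs) < 3:
        raise ValueError("need >= 3 environments (two for training, one held out)")
    lines = blups.index.to_numpy()
    order = pd.Index(geno.line_ids).get_indexer(lines)
    if (order < 0).any():
        raise ValueError("lines in phenotype table missing from genotype matrix")
    X = geno.values[order]
    pops = geno.populations[order]
    rng = np.random.default_rng(scheme.seed)
    rows = []
    for pair, val_env in _env_sets(envs):
        targets = make_training_targets(blups, pair)
        y = targets.reindex(lines).to_numpy()
        y_val = blups[val_env].reindex(lines).to_numpy()
        usable = ~np.isnan(y) & ~np.isnan(y_val)
        for rep in range(scheme.repetitions):
            folds = stratified_folds(pops, scheme.k_folds, rng)
            for f, hold in enumerate(folds):
                hold = hold[usable[hold]]
                train = np.setdiff1d(np.flatnonzero(usable), hold)
                m = _resolve_model(model).fit(X[train], y[train])
                pred = m.predict(X[hold])
                for pop in pd.unique(pops):
                    sel = pops[hold] == pop
                    r = predictive_ability(y_val[hold][sel], pred[sel])
                    rows.append(
                        {
                            "env_set": "+".join(pair),
                            "val_env": val_env,
                            "rep": rep,
                            "fold": f,
                            "population": pop,
                            "n": int(sel.sum()),
                            "r_ab": r,
                        }
                    )
    return CVResult("intra_population", pd.DataFrame(rows))


def inter_population_cv(
    geno: GenotypeMatrix,
    blups: pd.DataFrame,
    model="rrblup",
    scheme: CVScheme | None = None,
) -> CVResult:
    """Train on one whole population, validate within each other population."""
    scheme = scheme or CVScheme(scenario="inter_population")
    envs = sorted(blups.columns)
    if len(envs) < 3:
        raise ValueError("need >= 3 environments (two for training, one held out)")
    lines = blups.index.to_numpy()
    order = pd.Index(geno.line_ids).get_indexer(lines)
    if (order < 0).any():
        raise ValueError("lines in phenotype table missing from genotype matrix")
    X = geno.values[order]
    pops = geno.populations[order]
    pop_names = list(pd.unique(pops))
    if len(pop_names) < 2:
        raise ValueError("inter-population prediction needs >= 2 populations")
    rows = []
    for train_pop in pop_names:
        tr_idx = np.flatnonzero(pops == train_pop)
        for pair, val_env in _env_sets(envs):
            targets = make_training_targets(blups, pair)
            y = targets.reindex(lines).to_numpy()
            y_val = blups[val_env].reindex(lines).to_numpy()
            tr = tr_idx[~np.isnan(y[tr_idx])]
            m = _resolve_model(model).fit(X[tr], y[tr])
            for val_pop in pop_names:
                if val_pop == train_pop:
                    continue
                va = np.flatnonzero((pops == val_pop) & ~np.isnan(y_val))
                pred = m.predict(X[va])
                r = predictive_ability(y_val[va], pred)
                rows.append(
                    {
                        "train_population": train_pop,
                        "env_set": "+".join(pair),
                        "val_env": val_env,
                        "population": val_pop,
                        "n": len(va),
                        "r_ab": r,
                    }
                )
    return CVResult("inter_population", pd.DataFrame(rows))


def check_inter_population_args(train_pop: str, val_pop: str) -> None:
    """Guard against scoring a model on its own training population."""
    if train_pop == val_pop:
        raise ValueError("training and validation population must differ")
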