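"""End-to-end orchestration: simulate -> QC -> variance components/BLUP ->
cross-validation -> GWAS -> selection-efficiency scenarios.

A single master seed fans out deterministically to per-stage seeds, and a
manifest in the output directory records the configuration, stage seeds
and artifact names so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rilgs import crossval, gain, gwas, markers, simulate, varcomp
from rilgs.gsmodels import MODEL_NAMES

log = logging.getLogger(__name__)

KNOWN_MODELS = tuple(m.lower() for m in MODEL_NAMES)


@dataclass
class RunConfig:
    """Validated settings of a full pipeline run."""

    out_dir: str = "rilgs_run"
    seed: int = 0
    traits: tuple = ("yield", "protein", "protein_yield")
    # simulation
    population_sizes: tuple = (102, 100, 104)
    n_env: int = 3
    n_blocks: int = 3
    generations: int = 6
    n_chromosomes: int = 7
    markers_per_chromosome: int = 150
    marker_missing_rate: float = 0.05
    sample_missing_rate: float = 0.02
    # filtering
    mpm: float = 0.2
    mps: float = 0.25
    maf_min: float = 0.05
    impute_method: str = "knn"
    # genomic prediction
    model: str = "rrblup"
    cv_folds: int = 10
    cv_reps: int = 10
    # GWAS
    n_pcs: int = 10
    alpha: float = 0.05
    fdr_q: float = 0.05
    # gain scenarios
    p_P: float = 0.10
    t_P_values: tuple = (1.0, 2.0)

    def __post_init__(self) -> None:
        if self.model.lower() not in KNOWN_MODELS:
            raise ValueError(f"unknown model name: {self.model}")
        if not 0 <= self.mpm <= 1 or not 0 <= self.mps <= 1:
            raise ValueError("mpm and mps must lie in [0, 1]")
        if self.impute_method not in ("knn", "mode"):
            raise ValueError(f"unknown imputation method: {self.impute_method}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        coerced = {}
        for k, v in raw.items():
            coerced[k] = tuple(v) if isinstance(v, list) else v
        return cls(**coerced)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()},
                fh,
                sort_keys=True,
            )


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the in-memory report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds = _stage_seeds(config.seed)
    manifest = {"seed": config.seed, "stage_seeds": seeds, "artifacts": {}}
    bundle: dict = {"config": config}

    # --- stage 1: simulate --------------------------------------------------
    sim_cfg = simulate.SimConfig(
        population_sizes=tuple(config.population_sizes),
        generations=config.generations,
        n_blocks=config.n_blocks,
        n_env=config.n_env,
        marker_missing_rate=config.marker_missing_rate,
        sample_missing_rate=config.sample_missing_rate,
        seed=seeds[0],
    )
    gmap = simulate.default_map(
        n_chromosomes=config.n_chromosomes,
        markers_per_chromosome=config.markers_per_chromosome,
        seed=seeds[0],
    )
    G, plots, truth = simulate.simulate_panel(sim_cfg, genome_map=gmap, seed=seeds[0])
    markers.write_vcf(G, out / "genotypes.vcf")
    simulate.write_phenotypes(plots, out / "phenotypes.csv")
    bundle["truth"] = truth

    # --- stage 2: filtering + imputation ------------------------------------
    Gf, report = markers.filter_pipeline(
        G, mpm=config.mpm, mps=config.mps, maf_min=config.maf_min
    )
    Gi = markers.impute(Gf, method=config.impute_method)
    Gi.to_tsv(out / "matrix.tsv")
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    kept = set(Gi.line_ids)
    plots = plots[plots["line"].isin(kept)].reset_index(drop=True)
    bundle["geno"] = Gi
    bundle["filter_report"] = report

    # --- stage 3: variance components + BLUPs -------------------------------
    comp_rows, blups = [], {}
    for trait in config.traits:
        vc = varcomp.anova_multi_env(plots, trait)
        vcp = varcomp.anova_multi_env(plots, trait, include_population=True)
        h2 = varcomp.heritability_multi_env(
            vc.s_g2, vc.s_ge2, vc.s_e2, vc.e, vc.n
        ).h2
        comp_rows.append(
            {
                "trait": trait, "mean": vc.m, "s_g2": vc.s_g2, "s_ge2": vc.s_ge2,
                "ratio_g_ge": vc.ratio_g_ge, "s_e2": vc.s_e2,
                "s_r2": vcp.s_r2, "s_gr2": vcp.s_gr2, "s_re2": vcp.s_re2,
                "s_gre2": vcp.s_gre2,
                "cv_g_pct": varcomp.cv_g(vc.s_g2, vc.m), "h2_multi_env": h2,
            }
        )
        blups[trait] = varcomp.blups_per_environment(plots, trait)
    components = pd.DataFrame(comp_rows)
    components.to_csv(out / "components.tsv", sep="\t", index=False)
    bundle["components"] = components
    bundle["blups"] = blups

    # --- stage 4: cross-validation ------------------------------------------
    scheme = crossval.CVScheme(
        k_folds=config.cv_folds, repetitions=config.cv_reps, seed=seeds[3]
    )
    cv_rows = []
    cv_results = {}
    for trait in config.traits:
        intra = crossval.intra_population_cv(
            bundle["geno"], blups[trait], model=config.model, scheme=scheme
        )
        inter = crossval.inter_population_cv(
            bundle["geno"], blups[trait], model=config.model,
            scheme=crossval.CVScheme(scenario="inter_population", seed=seeds[3]),
        )
        cv_results[trait] = {"intra": intra, "inter": inter}
        cv_rows.append(
            {
                "trait": trait,
                "intra_r_ab": intra.grand_mean(),
                "inter_r_ab": inter.grand_mean(),
            }
        )
    cv_summary = pd.DataFrame(cv_rows)
    cv_summary.to_csv(out / "cv.tsv", sep="\t", index=False)
    bundle["cv"] = cv_results
    bundle["cv_summary"] = cv_summary

    # --- stage 5: GWAS -------------------------------------------------------
    gwas_tables = {}
    for trait in ("yield", "protein"):
        if trait not in config.traits:
            continue
        y = blups[trait].mean(axis=1).reindex(bundle["geno"].line_ids).to_numpy()
        res = gwas.gwas_scan(
            bundle["geno"], y, n_pcs=config.n_pcs,
            alpha=config.alpha, fdr_q=config.fdr_q,
        )
        res.table.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
        gwas_tables[trait] = res
    bundle["gwas"] = gwas_tables

    # --- stage 6: selection efficiency ---------------------------------------
    trait = "protein_yield" if "protein_yield" in config.traits else config.traits[0]
    vc = varcomp.anova_multi_env(plots, trait)
    h2_sel = varcomp.heritability_multi_env(vc.s_g2, vc.s_ge2, vc.s_e2, e=2, n=3).h2
    scen_rows = []
    for scenario_name, key in (("intra", "intra_r_ab"), ("inter", "inter_r_ab")):
        r_ab = float(cv_summary.loc[cv_summary["trait"] == trait, key].iloc[0])
        for t_P in config.t_P_values:
            sc = gain.GainScenario(r_ab=r_ab, h2=h2_sel, p_P=config.p_P, t_P=t_P)
            d = sc.to_dict()
            d["scenario"] = scenario_name
            scen_rows.append(d)
    scenarios = pd.DataFrame(scen_rows)
    scenarios.to_json(out / "scenario.json", orient="records", indent=2)
    bundle["gain"] = scenarios

    for art in ("genotypes.vcf", "phenotypes.csv", "matrix.tsv", "components.tsv",
                "cv.tsv", "scenario.json"):
        manifest["artifacts"][art] = _sha(out / art)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def report_tables(bundle: dict) -> dict[str, pd.DataFrame]:
    """Publication-style summary tables assembled from the run's own numbers."""
    tables = {}
    if "components" in bundle:
        comp = bundle["components"]
        tables["variance_components"] = comp[
            ["trait", "s_g2", "s_ge2", "ratio_g_ge", "s_r2", "s_gr2", "s_re2", "s_gre2"]
        ]
    if "cv" in bundle:
        rows = []
        for trait, res in bundle["cv"].items():
            intra = res["intra"]
            by_val = intra.records.groupby("val_env")["r_ab"].mean()
            inter = res["inter"].aggregate("train_population").set_index(
                "train_population"
            )["r_ab"]
            row = {"trait": trait}
            row.update({f"val:{k}": v for k, v in by_val.items()})
            row["val:mean"] = intra.grand_mean()
            row.update({f"train:{k}": v for k, v in inter.items()})
            row["train:mean"] = res["inter"].grand_mean()
            rows.append(row)
        tables["predictive_ability"] = pd.DataFrame(rows)
    if "gain" in bundle:
        g = bundle["gain"]
        piv = g.pivot_table(
            index="scenario", columns="t_P", values="efficiency_ratio"
        )
        piv.columns = [f"ratio_tP={c:g}" for c in piv.columns]
        tables["efficiency"] = piv.reset_index()
    return tables
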