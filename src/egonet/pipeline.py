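"""End-to-end orchestration: ingest -> constraint -> score -> fits -> outputs.

`run_analysis` reproduces the full dyad-level analysis on any compatible
dataset (read from files or generated in place): Burt constraints and
pooled structural-hole tertiles, the tetrachoric-PCA peer health behavior
score, covariate recodes, and one cluster-robust logistic fit per outcome,
with Table-style odds-ratio CSVs, predicted probabilities at covariate
means, fit diagnostics, and a machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import network_model as nm
from . import regression as reg
from .peer_score import code_indicators, first_pc_score, tetrachoric_matrix
from .structural_holes import ConstraintResult, ego_constraints, proportional_strengths
from .synthetic_data import SimConfig, generate_population

log = logging.getLogger("egonet")

BASE_TERMS = [
    "age", "male", "college", "married", "working", "current_smoker", "alcohol",
    "income_middle", "income_high", "income_missing", "peer_score",
    "muni_Mitaka", "muni_Kashiwa", "muni_Tokorozawa",
    "sh_low", "sh_high",
]

__all__ = [
    "AnalysisConfig",
    "build_design",
    "fit_outcome",
    "run_analysis",
    "descriptive_table",
    "overall_participation_rate",
    "compute_constraints",
    "compute_peer_scores",
]


@dataclass
class AnalysisConfig:
    """Run configuration (file-based or simulated input)."""

    outdir: str = "egonet_out"
    outcomes: tuple = nm.OUTCOMES
    recode_variant: str = "main"
    peer_smoking_adjust: bool = False
    cluster_small_sample: bool = True
    # file inputs
    ego_path: str | None = None
    peers_path: str | None = None
    networks_path: str | None = None
    schema: dict | None = None
    # or simulate in place
    simulate: SimConfig | None = None
    seed: int | None = None

    def validate(self) -> "AnalysisConfig":
        if not set(self.outcomes) <= set(nm.OUTCOMES):
            raise ValueError(f"outcomes must be a subset of {nm.OUTCOMES}")
        file_mode = self.ego_path is not None
        if file_mode == (self.simulate is not None):
            raise ValueError("exactly one of file inputs or a simulate block is required")
        if self.simulate is not None and self.seed is None:
            raise ValueError("simulated runs require a seed")
        return self


def compute_constraints(triples) -> dict:
    """Dyadic constraints per ego, keyed by ego_id."""
    out = {}
    for ego, _, net in triples:
        P = proportional_strengths(net.adjacency)
        out[ego.ego_id] = ConstraintResult(ego_id=ego.ego_id, constraint=ego_constraints(P, 0))
    return out


def compute_peer_scores(triples):
    """Tetrachoric-PCA peer health behavior scores over the pooled peers."""
    flat = [p for _, peers, _ in triples for p in peers]
    X, sums = code_indicators(flat)
    R, smoothed = tetrachoric_matrix(X)
    pc = first_pc_score(R, X)
    scores = {}
    i = 0
    for ego, peers, _ in triples:
        for p in peers:
            scores[(ego.ego_id, p.peer_index)] = float(pc.scores[i])
            i += 1
    return scores, {"loadings": pc.loadings, "eigenvalues": pc.eigenvalues,
                    "correlation": R, "smoothed": smoothed, "behavior_sum": sums}


def build_design(table: pd.DataFrame, outcome: str, peer_smoking_adjust: bool = False):
    """Design matrix (with intercept) for one outcome's dyad-level fit.

    The middle structural-hole category, the low income tertile and the
    first municipality are the reference levels; the ego-smoking covariate
    is dropped from the non-smoking model.
    """
    terms = [t for t in BASE_TERMS if not (outcome == "nonsmoking" and t == "current_smoker")]
    if peer_smoking_adjust:
        terms = terms + ["peer_current_smoker"]
    tab = table.copy()
    tab["sh_low"] = (tab["sh_category"] == "low").astype(int)
    tab["sh_high"] = (tab["sh_category"] == "high").astype(int)
    X = np.column_stack([np.ones(len(tab))] + [tab[t].to_numpy(dtype=float) for t in terms])
    names = ["intercept"] + terms
    y = tab["outcome"].to_numpy(dtype=int)
    clusters = tab["ego_id"].to_numpy()
    return X, y, clusters, names


def fit_outcome(table: pd.DataFrame, outcome: str, peer_smoking_adjust: bool = False,
                cluster_small_sample: bool = True) -> dict:
    """Fit one outcome: cluster-robust OR table, Figure-style predicted
    probabilities, and diagnostics."""
    X, y, clusters, names = build_design(table, outcome, peer_smoking_adjust)
    fit = reg.fit_logistic(X, y, names=names)
    rob = reg.cluster_robust_covariance(fit, X, y, clusters, small_sample=cluster_small_sample)
    ors = reg.odds_ratio_table(fit, rob.vcov_cluster)
    focal = {
        "low": {"sh_low": 1, "sh_high": 0},
        "middle": {"sh_low": 0, "sh_high": 0},
        "high": {"sh_low": 0, "sh_high": 1},
    }
    probs = reg.predicted_probabilities(fit, rob.vcov_cluster, X, focal)
    chi2, df, p_hl = reg.hosmer_lemeshow(y, fit.predict(X))
    mcf, nag = reg.pseudo_r2(fit)
    vifs = reg.vif(X[:, 1:], names=names[1:])
    return {
        "outcome": outcome,
        "fit": fit,
        "robust": rob,
        "or_table": ors,
        "predicted": probs,
        "diagnostics": {
            "hosmer_lemeshow": {"chi2": chi2, "df": df, "p": p_hl},
            "mcfadden_r2": mcf,
            "nagelkerke_r2": nag,
            "vif": dict(zip(vifs["term"], vifs["vif"])),
            "n": fit.n,
            "n_clusters": rob.n_clusters,
            "converged": fit.converged,
        },
    }


def descriptive_table(dyad_table: pd.DataFrame) -> dict:
    """Table-1-style descriptives for egos (one row each) and pooled dyads."""
    egos = dyad_table.drop_duplicates("ego_id")
    c = dyad_table["constraint"].to_numpy()
    q1, med, q3 = np.percentile(c, [25, 50, 75])
    counts = dyad_table["sh_category"].value_counts().to_dict()
    return {
        "n_egos": int(len(egos)),
        "n_dyads": int(len(dyad_table)),
        "age_mean": float(egos["age"].mean()),
        "age_sd": float(egos["age"].std()),
        "pct_male": float(egos["male"].mean() * 100),
        "pct_college": float(egos["college"].mean() * 100),
        "pct_married": float(egos["married"].mean() * 100),
        "pct_working": float(egos["working"].mean() * 100),
        "pct_current_smoker": float(egos["current_smoker"].mean() * 100),
        "pct_alcohol": float(egos["alcohol"].mean() * 100),
        "income_category_pct": {
            k: float(v * 100)
            for k, v in egos["income_category"].value_counts(normalize=True).items()
        },
        "constraint_median": float(med),
        "constraint_iqr": float(q3 - q1),
        "constraint_skewness": float(stats.skew(c)),
        "sh_category_counts": {k: int(counts.get(k, 0)) for k in ("low", "middle", "high")},
        "peer_score_mean": float(dyad_table["peer_score"].mean()),
        "peer_score_sd": float(dyad_table["peer_score"].std()),
    }


def overall_participation_rate(contact_rate: float, cooperation_rate: float) -> dict:
    """Overall participation = contact rate x cooperation rate."""
    for r in (contact_rate, cooperation_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    p = contact_rate * cooperation_rate
    return {"proportion": p, "percent": round(100 * p, 1)}


def recovery_study(n_reps: int, n_egos: int, seed: int, or_high: float = 1.35,
                   or_low: float = 1.0, outcome: str = "exercise") -> pd.DataFrame:
    """Parameter-recovery experiment on category-homogeneous populations.

    Each replicate generates a fresh population with equal thirds of star /
    paired / complete egos and the given structural-hole odds ratios, runs
    the full constraint -> tertile -> dyad pipeline, and fits the dyad-level
    logistic model (intercept + sh dummies, middle as reference) with
    ego-clustered robust standard errors.  Returns one row per replicate
    with the estimated OR(high vs middle), its 95% CI, and whether the CI
    covers the generating value.
    """
    from .synthetic_data import generate_population, recovery_config

    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rows = []
    for rep in range(n_reps):
        cfg = recovery_config(n_egos=n_egos, or_high=or_high, or_low=or_low)
        pop = generate_population(cfg, int(seeds[rep]))
        tab = pop.dyad_table(outcome)
        X, y, clusters, names = build_design(tab, outcome)
        keep = [0, names.index("sh_low"), names.index("sh_high")]
        Xs = X[:, keep]
        fit = reg.fit_logistic(Xs, y, names=["intercept", "sh_low", "sh_high"])
        rob = reg.cluster_robust_covariance(fit, Xs, y, clusters)
        ors = reg.odds_ratio_table(fit, rob.vcov_cluster).set_index("term")
        hi = ors.loc["sh_high"]
        rows.append({
            "replicate": rep,
            "or_high": hi["or"],
            "ci_low": hi["ci_low"],
            "ci_high": hi["ci_high"],
            "covered": bool(hi["ci_low"] <= or_high <= hi["ci_high"]),
        })
    return pd.DataFrame(rows)


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline and write the output bundle.

    Returns a dict with the in-memory results; files go to config.outdir
    (odds-ratio and predicted-probability CSVs per outcome, diagnostics
    JSON, descriptives JSON, and a run manifest).  Content files carry no
    timestamps, so identical config + seed reproduce byte-identical output.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        log.info("generating synthetic population (n_egos=%d, seed=%s)",
                 config.simulate.n_egos, config.seed)
        pop = generate_population(config.simulate, config.seed)
        triples, excluded = pop.triples, []
    else:
        log.info("reading study files")
        triples, flagged = nm.read_ego_networks(
            config.ego_path, config.peers_path, config.networks_path, config.schema
        )
        triples, missing_ids = nm.complete_case_filter(triples)
        excluded = [{"ego_id": str(e), "reason": r} for e, r in flagged] + [
            {"ego_id": str(e), "reason": "missing outcome/covariate data"} for e in missing_ids
        ]

    constraints = compute_constraints(triples)
    scores, score_report = compute_peer_scores(triples)

    results, manifest_fits = {}, {}
    for outcome in config.outcomes:
        table = nm.to_dyad_table(triples, constraints, scores, outcome, config.recode_variant)
        res = fit_outcome(table, outcome, config.peer_smoking_adjust, config.cluster_small_sample)
        res["table"] = table
        results[outcome] = res
        res["or_table"].to_csv(outdir / f"or_{outcome}.csv", index=False, float_format="%.6g")
        res["predicted"].to_csv(outdir / f"predicted_{outcome}.csv", index=False, float_format="%.6g")
        manifest_fits[outcome] = res["diagnostics"]
        log.info("fitted %s: n=%d dyads, %d egos", outcome, res["fit"].n,
                 res["robust"].n_clusters)

    first = results[config.outcomes[0]]["table"]
    desc = descriptive_table(first)
    (outdir / "descriptives.json").write_text(json.dumps(desc, indent=1, sort_keys=True))
    (outdir / "diagnostics.json").write_text(json.dumps(manifest_fits, indent=1, sort_keys=True))
    manifest = {
        "n_egos": desc["n_egos"],
        "n_dyads": desc["n_dyads"],
        "excluded": excluded,
        "n_excluded": len(excluded),
        "outcomes": list(config.outcomes),
        "recode_variant": config.recode_variant,
        "peer_smoking_adjust": config.peer_smoking_adjust,
        "seed": config.seed,
        "peer_score_loadings": np.asarray(score_report["loadings"]).round(8).tolist(),
        "peer_score_eigenvalues": np.asarray(score_report["eigenvalues"]).round(8).tolist(),
        "tetrachoric_smoothed": bool(score_report["smoothed"]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"results": results, "descriptives": desc, "manifest": manifest,
            "score_report": score_report}
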