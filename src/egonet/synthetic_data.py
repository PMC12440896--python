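"""Synthetic survey-style study populations with known ground truth.

The real survey data are access-restricted, so every pipeline stage is
exercised on generated populations that emulate the study design: egos
with the published covariate margins, four named peers each, peer-peer tie
blocks spanning star -> complete configurations, four correlated binary
peer health behaviors thresholded from a latent multivariate normal, and
ego-level binary outcomes drawn from a logistic model on structural-hole
category shares plus covariates.

Network density classes
-----------------------
star      peer-peer block empty; every dyad has C_ij = 1/16
paired    peers 1-2 and 3-4 tied; every dyad has C_ij = 9/64
partial   i.i.d. Bernoulli(p_ego) peer-peer block, p_ego drawn per ego
complete  all peers tied; every dyad has C_ij = 49/256

Class counts follow the configured mixture exactly (largest-remainder
rounding, order shuffled), so with an equal three-way star/paired/complete
mixture the pooled structural-hole tertiles coincide with the density
classes — the basis of the parameter-recovery fixtures.

Outcomes are generated at the ego level and replicated across the ego's
four dyad rows, reproducing the within-ego outcome dependence that
motivates ego-clustered standard errors.  Covariate contributions to the
linear predictor are centered at their sample means, so the configured
prevalence is the marginal prevalence at covariate means and the slopes
keep their configured values exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import covariates as cov
from .network_model import (
    MUNICIPALITIES,
    NETWORK_SIZE,
    EgoNetwork,
    EgoRecord,
    PeerRecord,
    to_dyad_table,
    validate_network,
    write_ego_networks,
)
from .peer_score import code_indicators, first_pc_score, tetrachoric_matrix
from .structural_holes import ConstraintResult, ego_constraints, proportional_strengths, tertile_categorize

NETWORK_CLASSES = ("star", "paired", "partial", "complete")
# true structural-hole category of every dyad of a homogeneous ego
CLASS_TRUE_CATEGORY = {"star": "high", "paired": "middle", "complete": "low"}

_ln = np.log


def _table2_betas():
    """Default outcome coefficients (log odds ratios) per outcome."""
    shared_muni = ("muni_Mitaka", "muni_Kashiwa", "muni_Tokorozawa")
    ex = {
        "age": _ln(1.03), "male": _ln(1.59), "college": _ln(1.20),
        "married": _ln(1.01), "working": _ln(0.77), "current_smoker": _ln(0.64),
        "alcohol": _ln(1.21), "income_middle": _ln(0.99), "income_high": _ln(1.49),
        "income_missing": _ln(1.36), "peer_score": _ln(1.42),
        "muni_Mitaka": _ln(1.12), "muni_Kashiwa": _ln(1.26), "muni_Tokorozawa": _ln(0.99),
        "sh_low": _ln(0.97), "sh_high": _ln(1.35),
    }
    de = {
        "age": _ln(1.00), "male": _ln(0.60), "college": _ln(1.41),
        "married": _ln(1.00), "working": _ln(0.72), "current_smoker": _ln(0.77),
        "alcohol": _ln(1.08), "income_middle": _ln(1.17), "income_high": _ln(1.47),
        "income_missing": _ln(1.05), "peer_score": _ln(1.07),
        "muni_Mitaka": _ln(1.01), "muni_Kashiwa": _ln(1.11), "muni_Tokorozawa": _ln(0.89),
        "sh_low": _ln(1.06), "sh_high": _ln(1.20),
    }
    ns = {
        "age": _ln(1.00), "male": _ln(0.29), "college": _ln(2.35),
        "married": _ln(0.99), "working": _ln(0.46),
        "alcohol": _ln(0.65), "income_middle": _ln(1.58), "income_high": _ln(1.79),
        "income_missing": _ln(1.25), "peer_score": _ln(2.13),
        "muni_Mitaka": _ln(1.48), "muni_Kashiwa": _ln(1.76), "muni_Tokorozawa": _ln(1.18),
        "sh_low": _ln(0.81), "sh_high": _ln(0.88),
    }
    del shared_muni
    return {"exercise": ex, "dental": de, "nonsmoking": ns}


@dataclass
class SimConfig:
    """Study-condition parameters of the generator (defaults = published margins)."""

    n_egos: int = 1705
    # network density classes; probabilities over NETWORK_CLASSES
    network_mix: dict = field(
        default_factory=lambda: {"star": 0.25, "paired": 0.10, "partial": 0.40, "complete": 0.25}
    )
    partial_p_range: tuple = (0.2, 0.8)
    # ego covariate margins
    p_male: float = 0.42
    p_college: float = 0.74
    p_married: float = 0.74
    p_working: float = 0.87
    age_mean: float = 45.7
    age_sd: float = 6.9
    municipality_probs: tuple = (0.19, 0.21, 0.30, 0.30)
    # raw category distributions whose recodes hit the published margins:
    # exercise >=1-2/wk -> 0.38, alcohol >=3-4/wk -> 0.37
    exercise_freq_probs: tuple = (0.05, 0.05, 0.12, 0.16, 0.22, 0.40)
    alcohol_freq_probs: tuple = (0.15, 0.10, 0.12, 0.15, 0.20, 0.20, 0.08)
    p_former_given_nonsmoker: float = 0.287  # former vs never split
    # income (JPY/year): lognormal household income, OECD-modified scale
    income_log_mean: float = np.log(5.0e6)
    income_log_sd: float = 0.55
    p_income_missing: float = 0.13  # neither household nor individual income
    p_individual_only: float = 0.05
    # peer attributes and behaviors
    peer_male: float = 0.58
    peer_age_within: float = 0.58
    peer_edu_probs: tuple = (0.23, 0.60, 0.17)  # <=HS, >=college, NA
    peer_work_probs: tuple = (0.86, 0.12, 0.02)  # yes, no, NA
    # latent healthy prevalences before missingness; coded-1 margins are
    # prevalence*(1-missing) ~ (0.19, 0.74, 0.20, 0.78)
    peer_healthy_prev: tuple = (0.32, 0.78, 0.22, 0.79)
    peer_missing_rates: tuple = (0.40, 0.05, 0.09, 0.01)
    peer_latent_R: np.ndarray = field(
        default_factory=lambda: np.full((4, 4), 0.2) + 0.8 * np.eye(4)
    )
    # outcome models: marginal prevalence at covariate means + log-OR betas
    outcome_prevalence: dict = field(
        default_factory=lambda: {"exercise": 0.38, "dental": 0.51, "nonsmoking": 0.87}
    )
    outcome_betas: dict = field(default_factory=_table2_betas)

    def validate(self) -> "SimConfig":
        if self.n_egos < 1:
            raise ValueError("n_egos must be positive")
        mix = self.network_mix
        if not mix or any(k not in NETWORK_CLASSES for k in mix):
            raise ValueError(f"network_mix keys must be among {NETWORK_CLASSES}")
        if any(p < 0 for p in mix.values()) or not np.isclose(sum(mix.values()), 1.0):
            raise ValueError("network_mix probabilities must be non-negative and sum to 1")
        R = np.asarray(self.peer_latent_R, dtype=float)
        if R.shape != (4, 4) or not np.allclose(R, R.T) or np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("peer_latent_R must be a symmetric PSD 4x4 correlation matrix")
        for p in (self.p_male, self.p_college, self.p_married, self.p_working,
                  self.p_income_missing, *self.peer_healthy_prev, *self.peer_missing_rates):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        return self


def recovery_config(n_egos: int = 2000, or_high: float = 1.35, or_low: float = 1.0,
                    prevalence: float = 0.4) -> SimConfig:
    """Config for parameter-recovery runs: category-homogeneous networks.

    Equal thirds of star / paired / complete egos make the pooled
    structural-hole tertiles coincide exactly with the density classes, so
    the dyad-level coefficient on each category dummy has the configured
    log odds ratio as its exact generating counterpart.  All covariate
    effects are switched off.
    """
    betas = {name: {"sh_high": np.log(or_high), "sh_low": np.log(or_low)}
             for name in ("exercise", "dental", "nonsmoking")}
    return SimConfig(
        n_egos=n_egos,
        network_mix={"star": 1 / 3, "paired": 1 / 3, "complete": 1 / 3},
        outcome_betas=betas,
        outcome_prevalence={"exercise": prevalence, "dental": prevalence, "nonsmoking": prevalence},
    )


@dataclass
class SimPopulation:
    """Generated study with observables and ground-truth labels kept apart."""

    config: SimConfig
    seed: int
    triples: list  # (EgoRecord, [PeerRecord x4], EgoNetwork)
    constraints: dict  # ego_id -> ConstraintResult
    scores: dict  # (ego_id, peer_index) -> peer health behavior score
    ego_frame: pd.DataFrame  # model-ready ego covariates + sh shares + outcomes
    truth: dict  # network class per ego, true betas, latent R, true categories

    def dyad_table(self, outcome: str, variant: str = "main") -> pd.DataFrame:
        return to_dyad_table(self.triples, self.constraints, self.scores, outcome, variant)

    def write(self, outdir) -> dict:
        """Emit the study files plus a ground-truth JSON; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "egos": outdir / "egos.csv",
            "peers": outdir / "peers.csv",
            "networks": outdir / "networks.json",
            "truth": outdir / "truth.json",
        }
        write_ego_networks(self.triples, paths["egos"], paths["peers"], paths["networks"])
        truth = {
            "seed": self.seed,
            "network_class": self.truth["network_class"],
            "true_sh_category": self.truth["true_sh_category"],
            "outcome_betas": {
                k: {t: float(v) for t, v in d.items()} for k, d in self.truth["outcome_betas"].items()
            },
            "latent_R": np.asarray(self.config.peer_latent_R).tolist(),
        }
        paths["truth"].write_text(json.dumps(truth, indent=0, sort_keys=True))
        return paths


# ---------------------------------------------------------------------------
# component generators


def _mixture_counts(mix: dict, n: int) -> list:
    """Largest-remainder allocation of n egos to density classes."""
    classes = [c for c in NETWORK_CLASSES if mix.get(c, 0) > 0]
    quotas = np.array([mix[c] * n for c in classes])
    counts = np.floor(quotas).astype(int)
    rem = n - counts.sum()
    frac = quotas - counts
    # ties broken toward the denser class so cumulative counts in density
    # order always reach the pooled tertile boundaries
    order = sorted(range(len(classes)), key=lambda i: (-frac[i], -i))
    for i in range(rem):
        counts[order[i % len(classes)]] += 1
    out = []
    for c, k in zip(classes, counts):
        out.extend([c] * int(k))
    return out


def generate_peer_networks(config: SimConfig, rng: np.random.Generator):
    """Draw one validated EgoNetwork per ego plus its density class label."""
    config.validate()
    n = config.n_egos
    classes = _mixture_counts(config.network_mix, n)
    rng.shuffle(classes)
    nets = []
    for i, cls in enumerate(classes):
        a = np.zeros((5, 5), dtype=int)
        a[0, 1:] = a[1:, 0] = 1
        if cls == "complete":
            a[1:, 1:] = 1 - np.eye(4, dtype=int)
        elif cls == "paired":
            a[1, 2] = a[2, 1] = 1
            a[3, 4] = a[4, 3] = 1
        elif cls == "partial":
            p = rng.uniform(*config.partial_p_range)
            blk = (rng.random((4, 4)) < p).astype(int)
            blk = np.triu(blk, 1)
            blk = blk + blk.T
            a[1:, 1:] = blk
        nets.append(validate_network(EgoNetwork(ego_id=f"ego{i:05d}", adjacency=a)))
    return nets, classes


def generate_peer_behaviors(config: SimConfig, n_peers: int, rng: np.random.Generator):
    """Latent-normal draw of the four binary healthy indicators.

    Returns ``(healthy, missing)`` boolean arrays of shape (n_peers, 4);
    healthy is the latent truth, missing the DK/NA mask applied before the
    missing->0 coding downstream.
    """
    R = np.asarray(config.peer_latent_R, dtype=float)
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("peer_latent_R must be positive semidefinite")
    L = np.linalg.cholesky(R + 1e-12 * np.eye(4))
    Z = rng.standard_normal((n_peers, 4)) @ L.T
    thresholds = norm.ppf(config.peer_healthy_prev)
    healthy = Z <= thresholds  # P(healthy) = prevalence
    missing = rng.random((n_peers, 4)) < np.asarray(config.peer_missing_rates)
    return healthy, missing


def _conditional_category(rng, probs, labels, positive_idx, y):
    """Sample a raw category consistent with a generated binary outcome."""
    probs = np.asarray(probs, dtype=float)
    mask = np.zeros(len(labels), dtype=bool)
    mask[positive_idx] = True
    sel = mask if y == 1 else ~mask
    p = probs * sel
    p = p / p.sum()
    return labels[rng.choice(len(labels), p=p)]


def generate_outcomes(config: SimConfig, ego_frame: pd.DataFrame, outcome: str,
                      rng: np.random.Generator) -> np.ndarray:
    """Ego-level Bernoulli outcomes from the configured logistic model.

    The linear predictor is ``logit(prevalence) + sum_k beta_k (x_k -
    mean(x_k))`` with the structural-hole terms entering as the ego's
    share of dyads in the high / low category; centering pins the
    configured prevalence at covariate means without touching the slopes.
    """
    betas = config.outcome_betas[outcome]
    lp = np.zeros(len(ego_frame))
    for term, b in betas.items():
        if term not in ego_frame.columns:
            raise KeyError(f"outcome term {term!r} not available for generation")
        x = ego_frame[term].to_numpy(dtype=float)
        lp = lp + b * (x - x.mean())
    p0 = config.outcome_prevalence[outcome]
    lp = lp + np.log(p0 / (1 - p0))
    return (rng.random(len(ego_frame)) < expit(lp)).astype(int)


def generate_population(config: SimConfig, seed: int) -> SimPopulation:
    """Compose networks, covariates, peers, scores and outcomes into a study."""
    config.validate()
    root = np.random.SeedSequence(seed)
    # counter-derived substreams per component keep the draw order of one
    # component independent of the others
    s_net, s_cov, s_peer, s_out = [np.random.default_rng(s) for s in root.spawn(4)]
    n = config.n_egos

    nets, classes = generate_peer_networks(config, s_net)
    ego_ids = [net.ego_id for net in nets]

    # --- constraints through the real pipeline path
    constraints = {}
    for net in nets:
        P = proportional_strengths(net.adjacency)
        constraints[net.ego_id] = ConstraintResult(ego_id=net.ego_id, constraint=ego_constraints(P, 0))
    sh_all = np.concatenate([constraints[e].sh_index for e in ego_ids])
    cat = tertile_categorize(sh_all)
    labels = cat.labels.reshape(n, NETWORK_SIZE)
    prop_high = (labels == "high").mean(axis=1)
    prop_low = (labels == "low").mean(axis=1)

    # --- ego covariates
    male = (s_cov.random(n) < config.p_male).astype(int)
    college = (s_cov.random(n) < config.p_college).astype(int)
    married = (s_cov.random(n) < config.p_married).astype(int)
    working = (s_cov.random(n) < config.p_working).astype(int)
    age = np.round(s_cov.normal(config.age_mean, config.age_sd, n), 1)
    muni = s_cov.choice(len(MUNICIPALITIES), size=n, p=config.municipality_probs)
    alcohol_freq = [
        cov.ALCOHOL_LEVELS[s_cov.choice(len(cov.ALCOHOL_LEVELS), p=config.alcohol_freq_probs)]
        for _ in range(n)
    ]
    # household composition + income with a dedicated missing mechanism
    adults = 1 + married + (s_cov.random(n) < 0.15).astype(int)
    children = np.minimum(s_cov.poisson(0.9, n), 4)
    hh_income = np.exp(s_cov.normal(config.income_log_mean, config.income_log_sd, n))
    ind_income = np.exp(s_cov.normal(config.income_log_mean - 0.35, config.income_log_sd, n))
    u = s_cov.random(n)
    miss_all = u < config.p_income_missing
    ind_only = (u >= config.p_income_missing) & (u < config.p_income_missing + config.p_individual_only)

    # --- peers: attributes, behaviors, and the pipeline-computed score
    n_peers = n * NETWORK_SIZE
    healthy, missing = generate_peer_behaviors(config, n_peers, s_peer)
    peer_male = s_peer.random(n_peers) < config.peer_male
    peer_within = s_peer.random(n_peers) < config.peer_age_within
    peer_edu = s_peer.choice(3, size=n_peers, p=config.peer_edu_probs)
    peer_work = s_peer.choice(3, size=n_peers, p=config.peer_work_probs)

    edu_lab = ("≤high-school", "≥college", "NA")
    work_lab = ("yes", "no", "NA")
    beh_labels = (
        ("frequent", "rare"),
        ("non-smoker", "current"),
        ("does-not", "drinks"),
        ("underweight/normal", "overweight/obese"),
    )
    beh_fields = ("exercise", "smoking", "alcohol", "body_size")
    peer_records = []
    for i in range(n):
        four = []
        for j in range(NETWORK_SIZE):
            r = i * NETWORK_SIZE + j
            kw = {
                "peer_index": j + 1,
                "age_band": "within ±5y" if peer_within[r] else "outside ±5y",
                "sex": "male" if peer_male[r] else "female",
                "education": edu_lab[peer_edu[r]],
                "working": work_lab[peer_work[r]],
            }
            for c, fld in enumerate(beh_fields):
                if missing[r, c]:
                    kw[fld] = "NA"
                else:
                    kw[fld] = beh_labels[c][0] if healthy[r, c] else beh_labels[c][1]
            four.append(PeerRecord(**kw))
        peer_records.append(four)

    flat_peers = [p for four in peer_records for p in four]
    X, _ = code_indicators(flat_peers)
    R, _ = tetrachoric_matrix(X)
    pc = first_pc_score(R, X)
    scores = {}
    for i, e in enumerate(ego_ids):
        for j in range(NETWORK_SIZE):
            scores[(e, j + 1)] = float(pc.scores[i * NETWORK_SIZE + j])
    ego_peer_score = pc.scores.reshape(n, NETWORK_SIZE).mean(axis=1)

    # --- ego-level model frame for outcome generation
    frame = pd.DataFrame(
        {
            "ego_id": ego_ids,
            "age": age,
            "male": male,
            "college": college,
            "married": married,
            "working": working,
            "alcohol": [cov.recode_alcohol(a) for a in alcohol_freq],
            "peer_score": ego_peer_score,
            "sh_high": prop_high,
            "sh_low": prop_low,
        }
    )
    for m in MUNICIPALITIES[1:]:
        frame[f"muni_{m}"] = (np.array([MUNICIPALITIES[k] for k in muni]) == m).astype(int)
    eq_vals = np.where(miss_all, np.nan, np.where(ind_only, ind_income, hh_income /
                       (1 + 0.5 * (adults - 1) + 0.3 * children)))
    inc_cat = cov.income_categories([None if np.isnan(v) else v for v in eq_vals])
    for lab in ("middle", "high", "missing"):
        frame[f"income_{lab}"] = (inc_cat == lab).astype(int)

    # --- outcomes: non-smoking first (it feeds the smoking covariate)
    y_ns = generate_outcomes(config, frame, "nonsmoking", s_out)
    frame["current_smoker"] = 1 - y_ns
    y_ex = generate_outcomes(config, frame, "exercise", s_out)
    y_de = generate_outcomes(config, frame, "dental", s_out)
    frame["nonsmoking"] = y_ns
    frame["exercise"] = y_ex
    frame["dental"] = y_de

    # --- raw ego records consistent with the generated outcomes
    ex_labels = np.array(cov.EXERCISE_LEVELS, dtype=object)
    triples = []
    for i, e in enumerate(ego_ids):
        if y_ns[i] == 1:
            smoking = "former" if s_out.random() < config.p_former_given_nonsmoker else "never"
        else:
            smoking = "current"
        exercise_frequency = _conditional_category(
            s_out, config.exercise_freq_probs, ex_labels, range(4), y_ex[i]
        )
        rec = EgoRecord(
            ego_id=e,
            age=float(age[i]),
            sex="male" if male[i] else "female",
            education=int(college[i]),
            marital=int(married[i]),
            working=int(working[i]),
            smoking_status=smoking,
            alcohol_frequency=alcohol_freq[i],
            exercise_frequency=str(exercise_frequency),
            dental_care=int(y_de[i]),
            municipality=MUNICIPALITIES[muni[i]],
            household_income=None if (miss_all[i] or ind_only[i]) else float(hh_income[i]),
            individual_income=float(ind_income[i]) if ind_only[i] else None,
            household_adults=int(adults[i]),
            household_children=int(children[i]),
        )
        triples.append((rec, peer_records[i], nets[i]))

    truth = {
        "network_class": dict(zip([str(e) for e in ego_ids], classes)),
        "true_sh_category": {
            str(e): CLASS_TRUE_CATEGORY.get(c) for e, c in zip(ego_ids, classes)
        },
        "outcome_betas": config.outcome_betas,
        "pipeline_sh_labels": labels,
    }
    return SimPopulation(
        config=config,
        seed=seed,
        triples=triples,
        constraints=constraints,
        scores=scores,
        ego_frame=frame,
        truth=truth,
    )
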