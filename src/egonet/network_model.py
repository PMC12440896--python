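"""Data model and I/O for name-generator egocentric networks.

Each respondent (ego) names exactly four peers; ties among {ego, peer 1..4}
are recorded in a 5x5 binary adjacency with the ego at node 0.  Because the
name generator itself establishes the ego-peer tie, row 0 / column 0 must
be all ones for nominated peers; a zero there is a data error, not a
missing tie.  Egos naming fewer than four peers are flagged for exclusion
(the constraint index varies with network size, so the analysis sample is
restricted to uniform size-4 networks).

On-disk formats are plain text: one UTF-8 CSV for egos, one for peers
(four rows per ego), and either a JSON sidecar mapping ego_id to its 5x5
matrix or 25 wide-format 0/1 columns ``adj_r_c`` appended to the ego CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from .structural_holes import ConstraintResult, tertile_categorize

NETWORK_SIZE = 4
MUNICIPALITIES = ("Adachi", "Mitaka", "Kashiwa", "Tokorozawa")
OUTCOMES = ("exercise", "dental", "nonsmoking")

PEER_CATEGORY_DOMAINS = {
    "age_band": ("within ±5y", "outside ±5y", "NA"),
    "sex": ("male", "female", "NA"),
    "education": ("≤high-school", "≥college", "NA"),
    "working": ("yes", "no", "NA"),
    "exercise": ("frequent", "rare", "NA"),
    "smoking": ("current", "non-smoker", "NA"),
    "alcohol": ("drinks", "does-not", "NA"),
    "body_size": ("underweight/normal", "overweight/obese", "NA"),
}

__all__ = [
    "NETWORK_SIZE",
    "MUNICIPALITIES",
    "OUTCOMES",
    "PeerRecord",
    "EgoRecord",
    "EgoNetwork",
    "NetworkParseError",
    "validate_network",
    "read_ego_networks",
    "write_ego_networks",
    "complete_case_filter",
    "to_dyad_table",
]


class NetworkParseError(ValueError):
    """Structured parse/validation failure naming the offending ego."""

    def __init__(self, ego_id, message):
        self.ego_id = ego_id
        super().__init__(f"ego {ego_id!r}: {message}")


@dataclass(frozen=True)
class PeerRecord:
    """One named peer, as reported by the ego (DK/NA allowed everywhere)."""

    peer_index: int
    age_band: str = "NA"
    sex: str = "NA"
    education: str = "NA"
    working: str = "NA"
    exercise: str = "NA"
    smoking: str = "NA"
    alcohol: str = "NA"
    body_size: str = "NA"

    def __post_init__(self):
        if not 1 <= self.peer_index <= NETWORK_SIZE:
            raise ValueError(f"peer_index must be 1..{NETWORK_SIZE}")
        for name, domain in PEER_CATEGORY_DOMAINS.items():
            val = getattr(self, name)
            if val not in domain:
                raise ValueError(f"peer field {name}={val!r} outside domain {domain}")


@dataclass(frozen=True)
class EgoRecord:
    """One respondent with raw (pre-recode) covariate values."""

    ego_id: object
    age: float
    sex: str  # male / female
    education: int  # 1 = college graduation or higher
    marital: int  # 1 = married
    working: int  # 1 = working
    smoking_status: str  # current / former / never
    alcohol_frequency: str  # cov.ALCOHOL_LEVELS
    exercise_frequency: str  # cov.EXERCISE_LEVELS
    dental_care: int  # 1 = used preventive dental care in past year
    municipality: str
    household_income: float | None = None
    individual_income: float | None = None
    household_adults: int = 1
    household_children: int = 0

    def __post_init__(self):
        if not np.isfinite(self.age):
            raise ValueError("age must be finite")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.municipality not in MUNICIPALITIES:
            raise ValueError(f"unknown municipality {self.municipality!r}")
        if self.smoking_status not in cov.SMOKING_LEVELS:
            raise ValueError(f"unknown smoking status {self.smoking_status!r}")
        if self.alcohol_frequency not in cov.ALCOHOL_LEVELS:
            raise ValueError(f"unknown alcohol frequency {self.alcohol_frequency!r}")
        if self.exercise_frequency not in cov.EXERCISE_LEVELS:
            raise ValueError(f"unknown exercise frequency {self.exercise_frequency!r}")


@dataclass(frozen=True)
class EgoNetwork:
    """5x5 binary adjacency over {ego, peer1..peer4}, ego at node 0."""

    ego_id: object
    adjacency: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "adjacency", np.asarray(self.adjacency))


def validate_network(net: EgoNetwork) -> EgoNetwork:
    """Validate and canonicalize a 5x5 ego network adjacency.

    Checks the 0/1 domain, zero diagonal, symmetry, and that the ego is
    tied to every nominated peer (row 0 all ones off-diagonal).
    """
    a = np.asarray(net.adjacency)
    if a.shape != (NETWORK_SIZE + 1, NETWORK_SIZE + 1):
        raise NetworkParseError(net.ego_id, f"adjacency must be 5x5, got {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise NetworkParseError(net.ego_id, "adjacency entries must be 0 or 1")
    if np.any(np.diag(a) != 0):
        raise NetworkParseError(net.ego_id, "adjacency diagonal must be zero")
    if not np.array_equal(a, a.T):
        raise NetworkParseError(net.ego_id, "adjacency is asymmetric")
    if np.any(a[0, 1:] != 1):
        raise NetworkParseError(net.ego_id, "ego must be tied to every nominated peer")
    return EgoNetwork(ego_id=net.ego_id, adjacency=a.astype(int))


# ---------------------------------------------------------------------------
# I/O


def _ego_from_row(row: dict) -> EgoRecord:
    def _opt(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return float(v)

    return EgoRecord(
        ego_id=row["ego_id"],
        age=float(row["age"]),
        sex=row["sex"],
        education=int(row["education"]),
        marital=int(row["marital"]),
        working=int(row["working"]),
        smoking_status=row["smoking_status"],
        alcohol_frequency=row["alcohol_frequency"],
        exercise_frequency=row["exercise_frequency"],
        dental_care=int(row["dental_care"]),
        municipality=row["municipality"],
        household_income=_opt(row.get("household_income")),
        individual_income=_opt(row.get("individual_income")),
        household_adults=int(row.get("household_adults", 1) or 1),
        household_children=int(row.get("household_children", 0) or 0),
    )


def read_ego_networks(ego_path, peers_path, networks_path, schema=None):
    """Read and validate the three study files.

    Returns ``(triples, excluded)`` where each triple is
    ``(EgoRecord, [PeerRecord x4], EgoNetwork)`` and `excluded` lists
    ``(ego_id, reason)`` for egos naming fewer than four peers.  `schema`
    optionally maps canonical column names to file column names, e.g.
    ``{"ego": {"age": "q1_age"}}``.
    """
    schema = schema or {}
    # keep "NA" as a literal category token; blank cells mean missing
    egos = pd.read_csv(ego_path, dtype={"ego_id": str}, keep_default_na=False)
    peers = pd.read_csv(peers_path, dtype={"ego_id": str}, keep_default_na=False)
    if schema.get("ego"):
        egos = egos.rename(columns={v: k for k, v in schema["ego"].items()})
    if schema.get("peer"):
        peers = peers.rename(columns={v: k for k, v in schema["peer"].items()})
    for required in ("ego_id", "age", "sex"):
        if required not in egos.columns:
            raise KeyError(f"ego file missing required column {required!r}")
    if "ego_id" not in peers.columns or "peer_index" not in peers.columns:
        raise KeyError("peer file missing required column 'ego_id'/'peer_index'")

    networks_path = Path(networks_path)
    raw_nets = json.loads(networks_path.read_text())

    peer_fields = [f.name for f in dc_fields(PeerRecord)]
    triples, excluded = [], []
    for row in egos.to_dict("records"):
        ego = _ego_from_row(row)
        sub = peers[peers["ego_id"] == ego.ego_id].sort_values("peer_index")
        if len(sub) < NETWORK_SIZE:
            excluded.append((ego.ego_id, f"named {len(sub)} peers (<{NETWORK_SIZE})"))
            continue
        if len(sub) > NETWORK_SIZE:
            raise NetworkParseError(ego.ego_id, f"{len(sub)} peer rows (> {NETWORK_SIZE})")
        precs = [
            PeerRecord(**{k: r[k] for k in peer_fields}) for r in sub.to_dict("records")
        ]
        if sorted(p.peer_index for p in precs) != list(range(1, NETWORK_SIZE + 1)):
            raise NetworkParseError(ego.ego_id, "peer_index values must be 1..4 unique")
        if str(ego.ego_id) not in raw_nets:
            raise NetworkParseError(ego.ego_id, "no adjacency matrix in networks file")
        mat = np.asarray(raw_nets[str(ego.ego_id)])
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise NetworkParseError(ego.ego_id, f"adjacency not square: {mat.shape}")
        net = validate_network(EgoNetwork(ego_id=ego.ego_id, adjacency=mat))
        triples.append((ego, precs, net))
    return triples, excluded


def write_ego_networks(triples, ego_path, peers_path, networks_path) -> None:
    """Write triples back to the three study files (round-trip safe)."""
    ego_rows, peer_rows, nets = [], [], {}
    for ego, precs, net in triples:
        d = {f.name: getattr(ego, f.name) for f in dc_fields(EgoRecord)}
        ego_rows.append(d)
        for p in precs:
            pr = {"ego_id": ego.ego_id}
            pr.update({f.name: getattr(p, f.name) for f in dc_fields(PeerRecord)})
            peer_rows.append(pr)
        nets[str(ego.ego_id)] = net.adjacency.astype(int).tolist()
    pd.DataFrame(ego_rows).to_csv(ego_path, index=False)
    pd.DataFrame(peer_rows).to_csv(peers_path, index=False)
    Path(networks_path).write_text(json.dumps(nets, indent=0, sort_keys=True))


def complete_case_filter(triples, outcome_name: str = None):
    """Drop egos with missing outcome or covariate data (income excepted).

    The file model stores raw categories as strings, so missingness shows
    up as NaN floats from pandas; income fields are allowed to be missing
    because the analysis carries a dedicated "missing" income category.
    Returns ``(kept, excluded_ids)``.
    """
    kept, excluded = [], []
    check = [
        "age", "sex", "education", "marital", "working",
        "smoking_status", "alcohol_frequency", "exercise_frequency",
        "dental_care", "municipality",
    ]
    for triple in triples:
        ego = triple[0]
        bad = False
        for name in check:
            v = getattr(ego, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                bad = True
        if bad:
            excluded.append(ego.ego_id)
        else:
            kept.append(triple)
    return kept, excluded


# ---------------------------------------------------------------------------
# Dyad table assembly


def _outcome_value(ego: EgoRecord, outcome_name: str, variant: str) -> int:
    if outcome_name == "exercise":
        return cov.recode_exercise(ego.exercise_frequency, variant)
    if outcome_name == "dental":
        return int(ego.dental_care)
    if outcome_name == "nonsmoking":
        return cov.recode_smoking(ego.smoking_status)
    raise ValueError(f"unknown outcome {outcome_name!r}")


def to_dyad_table(
    triples,
    constraints: dict,
    scores: dict,
    outcome_name: str,
    variant: str = "main",
) -> pd.DataFrame:
    """Assemble the ego-peer tie (dyad) analysis table.

    `constraints` maps ego_id -> ConstraintResult, `scores` maps
    ``(ego_id, peer_index)`` -> peer health behavior score.  Structural-
    hole categories come from pooled tertiles of 1/C over all dyads in
    the table; equivalent-income categories from pooled tertiles of the
    observed incomes.  One row per dyad, 4 per ego, sorted by
    (ego_id, peer_index); the outcome is ego-level and repeats within ego.
    """
    if outcome_name not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    triples = sorted(triples, key=lambda t: str(t[0].ego_id))
    rows = []
    incomes = []
    for ego, precs, net in triples:
        if ego.ego_id not in constraints:
            raise KeyError(f"missing constraint result for ego {ego.ego_id!r}")
        cres: ConstraintResult = constraints[ego.ego_id]
        eq = cov.equivalent_income(
            ego.household_income, ego.household_adults,
            ego.household_children, ego.individual_income,
        )
        incomes.append(eq.value)
        y = _outcome_value(ego, outcome_name, variant)
        muni = {f"muni_{m}": int(ego.municipality == m) for m in MUNICIPALITIES[1:]}
        for p in precs:
            key = (ego.ego_id, p.peer_index)
            if key not in scores:
                raise KeyError(f"missing peer score for dyad {key!r}")
            rows.append(
                {
                    "ego_id": ego.ego_id,
                    "peer_index": p.peer_index,
                    "constraint": float(cres.constraint[p.peer_index - 1]),
                    "sh_index": float(cres.sh_index[p.peer_index - 1]),
                    "outcome": y,
                    "age": ego.age,
                    "male": int(ego.sex == "male"),
                    "college": int(ego.education),
                    "married": int(ego.marital),
                    "working": int(ego.working),
                    "current_smoker": int(ego.smoking_status == "current"),
                    "alcohol": cov.recode_alcohol(ego.alcohol_frequency),
                    **muni,
                    "peer_score": float(scores[key]),
                    "peer_current_smoker": int(p.smoking == "current"),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no dyads to assemble")
    cat = tertile_categorize(table["sh_index"].to_numpy())
    table["sh_category"] = cat.labels
    inc_cat = cov.income_categories(incomes)
    per_ego = dict(zip((str(t[0].ego_id) for t in triples), inc_cat))
    table["income_category"] = [per_ego[str(e)] for e in table["ego_id"]]
    for lab in ("middle", "high", "missing"):
        table[f"income_{lab}"] = (table["income_category"] == lab).astype(int)
    table = table.sort_values(["ego_id", "peer_index"], kind="stable").reset_index(drop=True)
    return table
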