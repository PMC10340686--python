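"""Ground-truth generators: constrained random DAGs, linear-Gaussian SEM
sampling, a clinical-cohort emulator, and categorical encoding.

The cohort emulator reproduces the marginal structure of a surgical NSCLC
cohort — demographics, CT-derived body-composition volumes/densities/masses,
pathological stage codes, a binary recurrence outcome and a continuous
recurrence-free-survival outcome — from a known ground-truth structural
equation model, so structure and effect recovery are directly testable.
Outcome variables are sinks in every generated graph, making each cohort a
valid target for the grouped search.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .effects import SemSpec
from .graphs import Dag
from .scoring import Dataset
from .search import RoleAssignment, VariableSpec

__all__ = [
    "CohortSpec",
    "random_constrained_dag",
    "random_sem_spec",
    "sample_linear_sem",
    "simulate_cohort",
    "encode_variables",
    "DEFAULT_CODEBOOK",
]

logger = logging.getLogger(__name__)

# Integer codings for the standard non-numeric clinical columns.
DEFAULT_CODEBOOK: dict[str, dict[str, int]] = {
    "race": {"white": 1, "african american": 2, "black": 2, "other": 3, "asian": 3},
    "smoking": {"current": 1, "prior": 1, "current and prior": 1, "never": 2},
    "histology": {"adenocarcinoma": 1, "squamous": 2, "squamous cell carcinoma": 2,
                  "other": 3},
}

# Logistic latent noise has SD pi/sqrt(3); used both for the nominal noise
# scale of the binary outcome node and for the probit-style mean correction.
_LOGISTIC_SD = math.pi / math.sqrt(3.0)


def _load_default_config() -> dict:
    with resources.files("gges.data").joinpath("cohort_default.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class CohortSpec:
    """Parameters of the synthetic clinical cohort.

    ``config`` holds the full variable menu: categorical marginals, the linear
    structural equations of every continuous variable, and the outcome forms.
    The default is loaded from the packaged ``cohort_default.yaml``.
    """

    n: int = 363
    seed: int = 0
    config: dict = field(default_factory=_load_default_config)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        for name, spec in self.config["categorical"].items():
            probs = spec["probs"]
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"category probabilities of {name!r} sum to {sum(probs)}")
            if len(probs) != len(spec["values"]):
                raise ValueError(f"values/probs length mismatch for {name!r}")
        for name, eq in self.config["continuous"].items():
            if eq["noise_sd"] <= 0:
                raise ValueError(f"non-positive noise SD for {name!r}")

    @classmethod
    def from_yaml(cls, path, n: int | None = None, seed: int | None = None) -> "CohortSpec":
        with open(path) as fh:
            config = yaml.safe_load(fh)
        return cls(
            n=n if n is not None else config.get("n", 363),
            seed=seed if seed is not None else config.get("seed", 0),
            config=config,
        )


def random_constrained_dag(
    n_causal: int,
    n_outcome: int,
    edge_prob: float = 0.5,
    seed: int = 0,
    n_edges: int | None = None,
) -> Dag:
    """Random DAG with outcome nodes as sinks.

    Causal nodes get a random topological order with Bernoulli(edge_prob)
    edges along it; each causal→outcome edge is included with the same
    probability.  With ``n_edges`` set, exactly that many admissible edges
    are drawn uniformly without replacement instead.  Deterministic per seed.
    """
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    causal = [f"c{i}" for i in range(n_causal)]
    outcome = [f"o{i}" for i in range(n_outcome)]
    order = list(rng.permutation(n_causal))
    admissible = [
        (causal[order[i]], causal[order[j]])
        for i in range(n_causal) for j in range(i + 1, n_causal)
    ] + [(c, o) for c in causal for o in outcome]
    if n_edges is not None:
        if n_edges > len(admissible):
            raise ValueError(
                f"cannot place {n_edges} edges; only {len(admissible)} admissible")
        picks = rng.choice(len(admissible), size=n_edges, replace=False)
        edges = [admissible[i] for i in sorted(picks)]
    else:
        mask = rng.random(len(admissible)) < edge_prob
        edges = [e for e, keep in zip(admissible, mask) if keep]
    return Dag(causal + outcome, edges)


def random_sem_spec(
    dag: Dag,
    seed: int,
    weight_range: tuple[float, float] = (0.8, 1.5),
    signed: bool = True,
    noise_sd: float = 1.0,
) -> SemSpec:
    """Random edge weights with |β| drawn uniformly from ``weight_range``."""
    rng = np.random.default_rng(seed)
    lo, hi = weight_range
    weights = {}
    for e in dag.sorted_edges():
        b = rng.uniform(lo, hi)
        if signed and rng.random() < 0.5:
            b = -b
        weights[e] = float(b)
    return SemSpec(dag, weights, {n: noise_sd for n in dag.nodes})


def sample_linear_sem(
    spec: SemSpec,
    n: int,
    seed: int,
    roles: RoleAssignment | None = None,
) -> Dataset:
    """Sample ``n`` rows from a linear-Gaussian SEM, in topological order.

    Each node is its intercept plus the weighted sum of its parents plus
    independent Gaussian noise.  Deterministic per seed.  ``roles`` supplies
    variable metadata; by default every variable is marked causal.
    """
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    nodes = spec.dag.nodes
    columns: dict[str, np.ndarray] = {}
    for node in spec.dag.topological_order():
        col = np.full(n, spec.intercept_of(node))
        for parent in spec.dag.parents(node):
            col = col + spec.weights[(parent, node)] * columns[parent]
        col = col + rng.normal(0.0, spec.noise_sd[node], size=n)
        columns[node] = col
    values = np.column_stack([columns[v] for v in nodes])
    specs = roles.specs if roles is not None else [VariableSpec(v) for v in nodes]
    if [s.name for s in specs] != list(nodes):
        raise ValueError("role assignment order must match the SEM's node order")
    return Dataset(values, specs)


def _categorical_sd(values, probs) -> float:
    v = np.asarray(values, dtype=float)
    p = np.asarray(probs, dtype=float)
    mean = float(v @ p)
    return float(math.sqrt(max((v - mean) ** 2 @ p, 1e-12)))


def simulate_cohort(spec: CohortSpec | None = None) -> tuple[Dataset, SemSpec]:
    """Generate a synthetic cohort table plus its exact generating model.

    Categorical demographics and stage codes are sampled from their marginal
    distributions; continuous body-composition variables follow the linear
    equations of the cohort config; binary recurrence follows a logistic form
    over stage and body composition (intercept corrected analytically so the
    population mean hits its target); recurrence-free survival is linear plus
    noise, truncated below at zero.

    The returned :class:`SemSpec` records the ground-truth graph and the
    linear-predictor weights of every node.  For the two outcome nodes the
    generating form is not linear-Gaussian (logistic link; truncation), so
    their weights are latent-scale coefficients rather than exact total
    effects; structure-recovery checks use the graph, and effect-recovery
    checks use pure linear SEMs instead.
    """
    spec = spec if spec is not None else CohortSpec()
    cfg = spec.config
    rng = np.random.default_rng(spec.seed)
    columns: dict[str, np.ndarray] = {}
    edges: dict[tuple[str, str], float] = {}
    noise_sd: dict[str, float] = {}
    intercepts: dict[str, float] = {}
    kinds: dict[str, str] = {}

    for name, cat in cfg["categorical"].items():
        columns[name] = rng.choice(cat["values"], size=spec.n, p=cat["probs"]).astype(float)
        noise_sd[name] = _categorical_sd(cat["values"], cat["probs"])
        intercepts[name] = float(np.asarray(cat["values"], float) @ np.asarray(cat["probs"]))
        kinds[name] = "coded-categorical"

    for name, eq in cfg["continuous"].items():
        col = np.full(spec.n, float(eq["intercept"]))
        for parent, beta in eq["parents"].items():
            col = col + float(beta) * columns[parent]
            edges[(parent, name)] = float(beta)
        col = col + rng.normal(0.0, float(eq["noise_sd"]), size=spec.n)
        columns[name] = col
        noise_sd[name] = float(eq["noise_sd"])
        intercepts[name] = float(eq["intercept"])
        kinds[name] = "continuous"

    rec = cfg["recurrence"]
    eta = np.zeros(spec.n)
    for parent, beta in rec["parents"].items():
        eta = eta + float(beta) * columns[parent]
        edges[(parent, rec["name"])] = float(beta)
    eta_c = eta - eta.mean()
    # probit-approximation correction: keeps E[outcome] at target_mean despite
    # the variance of the linear predictor
    alpha = logit(rec["target_mean"]) * math.sqrt(1.0 + eta_c.var() / 2.896)
    columns[rec["name"]] = (rng.random(spec.n) < expit(alpha + eta_c)).astype(float)
    noise_sd[rec["name"]] = _LOGISTIC_SD
    intercepts[rec["name"]] = float(alpha)
    kinds[rec["name"]] = "coded-categorical"

    surv = cfg["survival"]
    col = np.zeros(spec.n)
    for parent, beta in surv["parents"].items():
        col = col + float(beta) * columns[parent]
        edges[(parent, surv["name"])] = float(beta)
    intercept = float(surv["target_mean"]) - col.mean()
    col = intercept + col + rng.normal(0.0, float(surv["noise_sd"]), size=spec.n)
    columns[surv["name"]] = np.maximum(col, 0.0)
    noise_sd[surv["name"]] = float(surv["noise_sd"])
    intercepts[surv["name"]] = intercept
    kinds[surv["name"]] = "continuous"

    names = list(columns)
    outcome_names = {rec["name"], surv["name"]}
    var_specs = [
        VariableSpec(v, "outcome" if v in outcome_names else "causal", kinds[v])
        for v in names
    ]
    dag = Dag(names, edges)
    assert all(dag.children(o) == () for o in outcome_names)
    sem = SemSpec(dag, edges, noise_sd, intercepts)
    return Dataset(np.column_stack([columns[v] for v in names]), var_specs), sem


def cohort_roles(d: Dataset) -> RoleAssignment:
    """Role assignment carried by a simulated cohort's variable metadata."""
    return RoleAssignment(d.variables)


class EncodingError(ValueError):
    """A string value has no integer code in the codebook."""


def encode_variables(
    raw: pd.DataFrame,
    codebook: Mapping[str, Mapping[str, int]] | None = None,
    roles: RoleAssignment | None = None,
) -> Dataset:
    """Integer-code string columns and return a complete-case numeric dataset.

    Non-numeric columns are mapped through the codebook (matched
    case-insensitively); numeric columns pass through unchanged.  Rows with
    missing values are dropped with a logged count.
    """
    codebook = codebook if codebook is not None else DEFAULT_CODEBOOK
    frame = raw.copy()
    coded_cols = set()
    for col in frame.columns:
        if pd.api.types.is_numeric_dtype(frame[col]):
            continue
        if col not in codebook:
            raise EncodingError(f"non-numeric column {col!r} absent from the codebook")
        mapping = {str(k).strip().lower(): v for k, v in codebook[col].items()}
        coded_cols.add(col)

        def code(value, col=col, mapping=mapping):
            if pd.isna(value):
                return np.nan
            key = str(value).strip().lower()
            if key not in mapping:
                raise EncodingError(f"column {col!r}: unmapped value {value!r}")
            return float(mapping[key])

        frame[col] = frame[col].map(code)
    n_before = len(frame)
    frame = frame.dropna()
    dropped = n_before - len(frame)
    if dropped:
        logger.info("ENCODE dropped %d incomplete rows of %d", dropped, n_before)
    if roles is None:
        specs = [
            VariableSpec(c, "causal",
                         "coded-categorical" if c in coded_cols else "continuous")
            for c in frame.columns
        ]
    else:
        specs = roles.specs
    return Dataset(frame.to_numpy(dtype=float), specs)
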