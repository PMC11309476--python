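"""Phylogenetic path analysis by the d-separation (d-sep) method.

Each candidate causal model (a DAG over genome size GS, minimum cell volume
CV, doubling time DT, temperature TEMP and GC content GC) implies a basis
set of conditional-independence claims: for every non-adjacent pair (x, y),
x is independent of y given the union of their parents. Each claim is
tested by a PGLS regression (with ML Pagel's lambda) of the downstream
variable on the other plus the conditioning set; the claim p-values combine
into Fisher's C = -2 sum(ln p), chi-square with 2k df under the model.
Models are ranked by CICc = C + 2 q n / (n - q - 1) and averaged with
exp(-delta/2) weights ("full" averaging zero-fills coefficients of absent
paths).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .comparative import LambdaGLS, pgls_fit
from .phylo import Phylogeny, phylo_covariance

__all__ = [
    "CausalModel",
    "DSepClaim",
    "PathModelResult",
    "AveragedModel",
    "VARIABLES",
    "model_registry",
    "parse_dag_spec",
    "basis_set",
    "test_claim",
    "fisher_c",
    "cicc",
    "rank_models",
    "fit_paths",
    "average_models",
    "run_path_analysis",
]

#: the five path-analysis variables, in canonical (tie-breaking) order
VARIABLES = ("GS", "CV", "DT", "TEMP", "GC")

#: default mapping from transformed trait-table columns to path variables
TRAIT_COLUMN_MAP = {
    "genome_size_log10": "GS",
    "min_cell_vol_log10": "CV",
    "doubling_time_log10": "DT",
    "growth_temperature_c": "TEMP",
    "gc_percent": "GC",
}


def path_variables_frame(traits: pd.DataFrame) -> pd.DataFrame:
    """Select and rename a transformed trait table to the GS/CV/DT/TEMP/GC
    variables used by the model registry."""
    cols = {c: v for c, v in TRAIT_COLUMN_MAP.items() if c in traits.columns}
    missing = set(TRAIT_COLUMN_MAP.values()) - set(cols.values()) - set(traits.columns)
    if missing:
        raise ValueError(f"trait table lacks path variables: {sorted(missing)}")
    out = traits.rename(columns=cols)
    return out[list(VARIABLES)]


@dataclass(frozen=True)
class CausalModel:
    """A named DAG over the path-analysis variables (isolated vertices kept)."""

    name: str
    edges: tuple[tuple[str, str], ...]
    vertices: tuple[str, ...] = VARIABLES

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"{self.name}: self-loop on {u}")
            if u not in self.vertices or v not in self.vertices:
                raise ValueError(f"{self.name}: unknown vertex in edge {u}->{v}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"{self.name}: cyclic model ({cycle})")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class DSepClaim:
    """Conditional-independence claim x _||_ y | conditioning_set.

    ``child`` is the member of {x, y} regressed on the other in the test
    (the vertex that is not an ancestor of the other).
    """

    x: str
    y: str
    conditioning_set: tuple[str, ...]
    child: str

    @property
    def other(self) -> str:
        return self.y if self.child == self.x else self.x


def parse_dag_spec(text: str, vertices: tuple[str, ...] = VARIABLES) -> list[CausalModel]:
    """Parse a plain-text DAG spec: ``[name]`` blocks of ``X -> Y`` lines."""
    models: list[CausalModel] = []
    name: str | None = None
    edges: list[tuple[str, str]] = []

    def flush():
        if name is not None:
            models.append(CausalModel(name=name, edges=tuple(edges), vertices=vertices))

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            name = line[1:-1].strip()
            edges = []
            continue
        if "->" not in line:
            raise ValueError(f"line {lineno}: expected 'X -> Y', got {raw!r}")
        u, v = (part.strip() for part in line.split("->", 1))
        if name is None:
            raise ValueError(f"line {lineno}: edge before any [model] header")
        edges.append((u, v))
    flush()
    return models


def model_registry(spec_file: "str | Path | None" = None) -> list[CausalModel]:
    """The candidate-model set: the built-in 14 models or a user DAG file."""
    if spec_file is None:
        text = resources.files("nucleotype.data").joinpath("default_models.dag").read_text()
    else:
        text = Path(spec_file).read_text()
    return parse_dag_spec(text)


def _topo_index(g: nx.DiGraph, vertices: tuple[str, ...]) -> dict[str, int]:
    order = list(nx.lexicographical_topological_sort(g, key=vertices.index))
    return {v: i for i, v in enumerate(order)}


def basis_set(model: CausalModel) -> list[DSepClaim]:
    """The d-separation basis set of a DAG.

    One claim per non-adjacent pair (x, y): x _||_ y given
    parents(x) | parents(y). The designated response ("child") is the vertex
    that is not an ancestor of the other; if neither is an ancestor of the
    other the tie is broken by topological order (the later vertex responds).
    """
    g = model.graph()
    topo = _topo_index(g, model.vertices)
    ancestors = {v: nx.ancestors(g, v) for v in g.nodes}
    claims: list[DSepClaim] = []
    verts = sorted(g.nodes, key=topo.get)
    for i, x in enumerate(verts):
        for y in verts[i + 1 :]:
            if g.has_edge(x, y) or g.has_edge(y, x):
                continue
            if x in ancestors[y]:
                child = y
            elif y in ancestors[x]:
                child = x
            else:
                child = y if topo[y] > topo[x] else x
            cond = tuple(sorted(
                (set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y},
                key=topo.get,
            ))
            claims.append(DSepClaim(x=x, y=y, conditioning_set=cond, child=child))
    return claims


def test_claim(
    tree: Phylogeny,
    data: pd.DataFrame,
    claim: DSepClaim,
    engine: LambdaGLS | None = None,
) -> float:
    """p-value of one d-sep claim via PGLS with ML lambda.

    Regresses ``claim.child`` on the other variable plus the conditioning
    set and returns the two-sided p-value of the other variable's slope.
    """
    predictors = [claim.other] + list(claim.conditioning_set)
    fit = pgls_fit(tree, data, claim.child, predictors, lam="ML", engine=engine)
    return float(fit.pvalues[claim.other])


def fisher_c(p_values) -> tuple[float, int, float]:
    """Fisher's C = -2 sum(ln p); returns (C, df, p) with df = 2k.

    An empty claim list (saturated model) gives C = 0, p = 1.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return 0.0, 0, 1.0
    if np.any(ps <= 0):
        raise ValueError(
            "claim p-value of 0 makes Fisher's C infinite; floor it explicitly "
            "(e.g. at machine epsilon) before combining"
        )
    if np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    c = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * ps.size
    return c, df, float(stats.chi2.sf(c, df))


def cicc(c: float, q: int, n: int) -> float:
    """CICc = C + 2 q n / (n - q - 1); q = edges + vertices of the model."""
    if n <= q + 1:
        raise ValueError(f"sample size n={n} must exceed q+1={q + 1}")
    return float(c + 2.0 * q * n / (n - q - 1))


@dataclass
class PathModelResult:
    model: CausalModel
    claims: list[DSepClaim]
    p_values: list[float]
    C: float
    df: int
    p_model: float
    q: int
    n: int
    CICc: float
    delta_CICc: float = float("nan")
    weight: float = float("nan")


def evaluate_model(
    model: CausalModel,
    tree: Phylogeny,
    data: pd.DataFrame,
    engine: LambdaGLS | None = None,
) -> PathModelResult:
    """Test every basis claim of one model and assemble its C/CICc result."""
    claims = basis_set(model)
    ps = [test_claim(tree, data, cl, engine=engine) for cl in claims]
    c, df, p_model = fisher_c(ps)
    q = model.n_edges + model.n_vertices
    n = len(data)
    return PathModelResult(
        model=model, claims=claims, p_values=ps,
        C=c, df=df, p_model=p_model, q=q, n=n, CICc=cicc(c, q, n),
    )


def rank_models(results: list[PathModelResult]) -> list[PathModelResult]:
    """Attach delta-CICc and Akaike-style weights; sort ascending by CICc."""
    if not results:
        raise ValueError("no model results to rank")
    best = min(r.CICc for r in results)
    deltas = np.array([r.CICc - best for r in results])
    raw = np.exp(-deltas / 2.0)
    weights = raw / raw.sum()
    for r, d, w in zip(results, deltas, weights):
        r.delta_CICc = float(d)
        r.weight = float(w)
    return sorted(results, key=lambda r: r.CICc)


def fit_paths(
    model: CausalModel,
    tree: Phylogeny,
    data: pd.DataFrame,
    engine: LambdaGLS | None = None,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Standardized path coefficients: edge -> (beta, SE).

    Every variable is z-scored, then each vertex with parents is regressed
    on its parents by PGLS (ML lambda); the edge coefficient is that
    parent's slope.
    """
    g = model.graph()
    used = sorted({v for e in model.edges for v in e})
    z = data[used].copy()
    z = (z - z.mean()) / z.std(ddof=1)
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for v in g.nodes:
        parents = sorted(g.predecessors(v), key=model.vertices.index)
        if not parents:
            continue
        fit = pgls_fit(tree, z, v, parents, lam="ML", engine=engine)
        for p in parents:
            out[(p, v)] = (float(fit.params[p]), float(fit.bse[p]))
    return out


@dataclass
class AveragedModel:
    coefficients: dict[tuple[str, str], float]
    standard_errors: dict[tuple[str, str], float]
    weights: dict[str, float]
    mode: str = "full"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"from": e[0], "to": e[1], "coef": c,
             "se": self.standard_errors[e]}
            for e, c in sorted(self.coefficients.items())
        ]
        return pd.DataFrame(rows)


def average_models(
    results: list[PathModelResult],
    fits: dict[str, dict[tuple[str, str], tuple[float, float]]],
    mode: str = "full",
) -> AveragedModel:
    """Weight-average standardized path coefficients across models.

    ``full`` averaging treats an edge absent from a model as beta = 0 (SE 0);
    ``conditional`` renormalizes the weights over the models containing the
    edge. SEs use the unconditional-variance formula: weighted within-model
    variance plus the weighted squared deviation of each model's coefficient
    from the average.
    """
    if mode not in ("full", "conditional"):
        raise ValueError("mode must be 'full' or 'conditional'")
    if not results:
        raise ValueError("empty model set")
    ranked = rank_models(list(results))
    weights = {r.model.name: r.weight for r in ranked}
    all_edges = sorted({e for f in fits.values() for e in f})
    coefs: dict[tuple[str, str], float] = {}
    ses: dict[tuple[str, str], float] = {}
    for edge in all_edges:
        if mode == "full":
            terms = [
                (weights[name], *fits[name].get(edge, (0.0, 0.0)))
                for name in weights
            ]
        else:
            have = [name for name in weights if edge in fits.get(name, {})]
            wsum = sum(weights[name] for name in have)
            terms = [
                (weights[name] / wsum, *fits[name][edge]) for name in have
            ]
        avg = sum(w * b for w, b, _ in terms)
        var = sum(w * (se**2 + (b - avg) ** 2) for w, b, se in terms)
        coefs[edge] = avg
        ses[edge] = math.sqrt(var)
    return AveragedModel(coefficients=coefs, standard_errors=ses,
                         weights=weights, mode=mode)


def run_path_analysis(
    tree: Phylogeny,
    data: pd.DataFrame,
    models: list[CausalModel] | None = None,
    average: str = "full",
):
    """Full workflow: test, rank and average a candidate model set.

    Returns (ranked results, AveragedModel). The data frame must contain
    the model variables as columns, indexed by species.
    """
    if models is None:
        models = model_registry()
    used = sorted({v for m in models for e in m.edges for v in e})
    from .comparative import _align

    covmat, frame = _align(tree, data, used)
    engine = LambdaGLS(covmat)
    results = [evaluate_model(m, tree, frame, engine=engine) for m in models]
    ranked = rank_models(results)
    fits = {m.name: fit_paths(m, tree, frame, engine=engine) for m in models}
    return ranked, average_models(ranked, fits, mode=average)


def results_table(ranked: list[PathModelResult]) -> pd.DataFrame:
    """Per-model summary table (C, df, p, q, CICc, delta, weight)."""
    return pd.DataFrame(
        [
            {"model": r.model.name, "C": r.C, "df": r.df, "p": r.p_model,
             "q": r.q, "n": r.n, "CICc": r.CICc,
             "delta_CICc": r.delta_CICc, "weight": r.weight}
            for r in ranked
        ]
    )
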