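"""d-separation phylogenetic path analysis.

Each candidate causal DAG implies a basis set of conditional-independence
claims (one per non-adjacent vertex pair, conditioning on the union of both
vertices' parents).  Every claim is tested by a phylogenetic regression —
OU-PGLS for continuous responses, Firth-penalised phylogenetic logistic
regression for binary ones — and the claim p-values combine into Fisher's
C statistic, which is chi-square distributed with 2k df when the DAG is
compatible with the data.  Models are ranked by the small-sample
information criterion CICc = C + 2 q n/(n - 1 - q) with q the number of
directed edges; models within 2 CICc of the best are retained and their
standardized path coefficients averaged with Akaike-style weights
(full averaging: a model lacking an edge contributes zero).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phyloreg import OUCorrelation, pgls_fit, phylo_logistic_fit
from .trees import Phylogeny

__all__ = [
    "CausalDAG",
    "DSepClaim",
    "PathModelFit",
    "basis_set",
    "test_claim",
    "fisher_c",
    "cicc",
    "fit_dag",
    "rank_and_weight",
    "average_paths",
    "builtin_hypotheses",
]

RETENTION_DELTA = 2.0  # models within this CICc of the best are retained


@dataclass(frozen=True)
class CausalDAG:
    """A named directed acyclic graph over observed variables."""

    name: str
    vertices: tuple
    edges: tuple  # of (cause, effect) pairs

    def __post_init__(self):
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("duplicate vertices")
        vs = set(self.vertices)
        for u, v in self.edges:
            if u not in vs or v not in vs:
                raise ValueError(f"edge ({u},{v}) references unknown vertex")
        self.topological_order()  # raises on cycles

    def parents(self, v) -> list:
        return [u for u, w in self.edges if w == v]

    def adjacent(self, a, b) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges

    def topological_order(self) -> list:
        """Kahn's algorithm with deterministic (insertion-order) tie-breaks."""
        indeg = {v: 0 for v in self.vertices}
        for _, w in self.edges:
            indeg[w] += 1
        order, ready = [], [v for v in self.vertices if indeg[v] == 0]
        while ready:
            v = ready.pop(0)
            order.append(v)
            for u, w in self.edges:
                if u == v:
                    indeg[w] -= 1
                    if indeg[w] == 0:
                        ready.append(w)
        if len(order) != len(self.vertices):
            raise ValueError(f"graph {self.name!r} has a cycle")
        return order

    @property
    def q(self) -> int:
        """Parameter count for CICc: the number of directed edges."""
        return len(self.edges)

    def to_dict(self) -> dict:
        return {"name": self.name, "vertices": list(self.vertices),
                "edges": [list(e) for e in self.edges]}

    @classmethod
    def from_dict(cls, d: dict) -> "CausalDAG":
        return cls(d["name"], tuple(d["vertices"]),
                   tuple(tuple(e) for e in d["edges"]))


@dataclass(frozen=True)
class DSepClaim:
    """X independent of Y given Z; Y (the response) is the later vertex in
    the DAG's causal order."""

    x: str
    y: str
    z: tuple


def basis_set(dag: CausalDAG) -> list[DSepClaim]:
    """The d-separation basis: one claim per non-adjacent pair, conditioning
    on the union of both vertices' parents.

    Ordering is canonical — pairs sorted by (topological position of the
    response, then lexicographic) — so the basis is independent of vertex
    insertion order.
    """
    topo = dag.topological_order()
    pos = {v: i for i, v in enumerate(topo)}
    claims = []
    for i, a in enumerate(dag.vertices):
        for b in dag.vertices[i + 1:]:
            if dag.adjacent(a, b):
                continue
            x, y = (a, b) if pos[a] < pos[b] else (b, a)
            z = tuple(sorted((set(dag.parents(a)) | set(dag.parents(b)))
                             - {a, b}))
            claims.append(DSepClaim(x, y, z))
    claims.sort(key=lambda c: (pos[c.y], c.x, c.y))
    return claims


def _is_binary(col: pd.Series) -> bool:
    vals = set(pd.unique(col.dropna()))
    return vals <= {0, 1, 0.0, 1.0}


def _standardize(col: pd.Series) -> pd.Series:
    """z-score continuous variables; leave binary 0/1 codes untouched."""
    if _is_binary(col):
        return col.astype(float)
    return (col - col.mean()) / col.std(ddof=1)


def test_claim(
    claim: DSepClaim,
    data: pd.DataFrame,
    tree: Phylogeny,
    logistic_alpha: float | None = None,
) -> float:
    """p-value of X's coefficient in the regression Y ~ X + Z.

    The response is the claim's later-in-causal-order vertex; a binary
    response is fitted with phylogenetic logistic regression, a continuous
    one with OU-PGLS (ML alpha).
    """
    for v in (claim.x, claim.y, *claim.z):
        if v not in data.columns:
            raise KeyError(f"variable {v!r} missing from data")
    X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    X[claim.x] = _standardize(data[claim.x]).values
    for z in claim.z:
        X[z] = _standardize(data[z]).values
    yraw = data[claim.y]
    if _is_binary(yraw):
        fit = phylo_logistic_fit(yraw.astype(float).values, X, tree,
                                 alpha=logistic_alpha)
        return float(fit.pvalues[claim.x])
    fit = pgls_fit(_standardize(yraw).values, X, tree, OUCorrelation())
    return float(fit.pvalues[claim.x])


def fisher_c(p_values) -> tuple[float, int, float]:
    """Fisher's C = -2 sum(ln p); df = 2k; chi-square upper-tail p."""
    ps = np.asarray(list(p_values), dtype=float)
    if np.any(ps > 1) or np.any(ps < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        import warnings

        warnings.warn("p-value of 0 clamped to the smallest positive float")
        ps = np.clip(ps, np.finfo(float).tiny, None)
    C = float(-2.0 * np.sum(np.log(ps))) if len(ps) else 0.0
    df = 2 * len(ps)
    p = float(stats.chi2.sf(C, df)) if df else 1.0
    return C, df, p


def cicc(C: float, q: int, n: int) -> float:
    """CICc = C + 2 q n / (n - 1 - q); requires n > q + 1."""
    if n <= q + 1:
        raise ValueError(f"need n > q + 1 (n={n}, q={q})")
    return float(C + 2.0 * q * n / (n - 1.0 - q))


@dataclass
class PathModelFit:
    dag: CausalDAG
    claim_pvalues: dict
    C: float
    df: int
    C_pvalue: float
    q: int
    n: int
    CICc: float
    delta_CICc: float = np.nan
    weight: float = np.nan
    retained: bool = False
    path_coefficients: dict = field(default_factory=dict)  # edge -> std coef

    def to_dict(self) -> dict:
        return {
            "model": self.dag.name,
            "claims": {f"{c.x} _||_ {c.y} | {','.join(c.z) or '{}'}": p
                       for c, p in self.claim_pvalues.items()},
            "C": self.C,
            "df": self.df,
            "C_pvalue": self.C_pvalue,
            "q": self.q,
            "n": self.n,
            "CICc": self.CICc,
            "delta_CICc": self.delta_CICc,
            "weight": self.weight,
            "retained": self.retained,
            "path_coefficients": {f"{u}->{v}": c for (u, v), c
                                  in self.path_coefficients.items()},
        }


def _edge_coefficients(dag: CausalDAG, data: pd.DataFrame, tree: Phylogeny,
                       logistic_alpha: float | None = None) -> dict:
    """Standardized path coefficient per edge: each vertex with parents is
    regressed on all its parents."""
    coefs: dict = {}
    for v in dag.vertices:
        parents = dag.parents(v)
        if not parents:
            continue
        X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
        for p in parents:
            X[p] = _standardize(data[p]).values
        yraw = data[v]
        if _is_binary(yraw):
            fit = phylo_logistic_fit(yraw.astype(float).values, X, tree,
                                     alpha=logistic_alpha)
        else:
            fit = pgls_fit(_standardize(yraw).values, X, tree, OUCorrelation())
        for p in parents:
            coefs[(p, v)] = float(fit.params[p])
    return coefs


def fit_dag(
    dag: CausalDAG,
    data: pd.DataFrame,
    tree: Phylogeny,
    compute_paths: bool = True,
    logistic_alpha: float | None = None,
) -> PathModelFit:
    """Test a DAG's basis set and compute its C, CICc and (optionally) its
    standardized path coefficients."""
    claims = basis_set(dag)
    pvals = {c: test_claim(c, data, tree, logistic_alpha) for c in claims}
    C, df, p = fisher_c(pvals.values())
    n = len(data)
    fit = PathModelFit(
        dag=dag, claim_pvalues=pvals, C=C, df=df, C_pvalue=p,
        q=dag.q, n=n, CICc=cicc(C, dag.q, n),
    )
    if compute_paths:
        fit.path_coefficients = _edge_coefficients(dag, data, tree,
                                                   logistic_alpha)
    return fit


def rank_and_weight(fits: list[PathModelFit],
                    retention_delta: float = RETENTION_DELTA
                    ) -> list[PathModelFit]:
    """Annotate fits with delta-CICc, normalized exp(-delta/2) weights and a
    retained flag (delta <= retention threshold); sorted best first."""
    if not fits:
        raise ValueError("no fits to rank")
    best = min(f.CICc for f in fits)
    raw = []
    for f in fits:
        f.delta_CICc = f.CICc - best
        raw.append(np.exp(-f.delta_CICc / 2.0))
    total = float(np.sum(raw))
    for f, r in zip(fits, raw):
        f.weight = float(r / total)
        f.retained = f.delta_CICc <= retention_delta
    return sorted(fits, key=lambda f: f.CICc)


def average_paths(retained_fits: list[PathModelFit],
                  method: str = "full") -> dict:
    """Weight-averaged standardized coefficients over the retained models.

    ``full`` averaging lets a model lacking an edge contribute zero to that
    edge; weights are renormalized over the retained set.
    """
    if method != "full":
        raise ValueError("only avg_method='full' is implemented")
    if not retained_fits:
        raise ValueError("empty retained set")
    wsum = sum(f.weight for f in retained_fits)
    edges = sorted({e for f in retained_fits for e in f.path_coefficients})
    return {
        e: sum(f.weight * f.path_coefficients.get(e, 0.0)
               for f in retained_fits) / wsum
        for e in edges
    }


_SDS, _TEMP, _LEN = "sds", "ambient_temperature", "breeding_length"


def builtin_hypotheses(set_name: str = "ABCD",
                       life_history_models: list[dict] | None = None
                       ) -> list[CausalDAG]:
    """Candidate causal hypotheses.

    ``ABCD``: the four 3-variable chains over sex-determination system,
    breeding-season ambient temperature and breeding-season length —
    A: sds -> temp -> length; B: sds -> length -> temp;
    C: temp -> sds -> length; D: temp -> length -> sds.

    ``life_history``: a user-configurable set over those variables plus a
    life-history index; pass explicit edge-list dicts (see
    :meth:`CausalDAG.from_dict`) since no canonical topology set exists.
    """
    if set_name == "ABCD":
        v = (_SDS, _TEMP, _LEN)
        return [
            CausalDAG("A", v, ((_SDS, _TEMP), (_TEMP, _LEN))),
            CausalDAG("B", v, ((_SDS, _LEN), (_LEN, _TEMP))),
            CausalDAG("C", v, ((_TEMP, _SDS), (_SDS, _LEN))),
            CausalDAG("D", v, ((_TEMP, _LEN), (_LEN, _SDS))),
        ]
    if set_name == "life_history":
        if not life_history_models:
            raise ValueError(
                "the life-history hypothesis topologies are study-specific: "
                "supply life_history_models as a list of "
                "{'name', 'vertices', 'edges'} dicts"
            )
        return [CausalDAG.from_dict(d) for d in life_history_models]
    raise ValueError(f"unknown hypothesis set {set_name!r}")
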