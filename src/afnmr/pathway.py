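"""Metabolite-set over-representation analysis (ORA) and pathway impact.

Given a query set of metabolites (e.g. the promoted biomarkers) and a
pathway library, each pathway is scored with a one-tailed hypergeometric
test (over-representation only), adjusted for multiple testing with
Holm (step-down, family-wise) and Benjamini-Hochberg (step-up, FDR)
procedures, both supporting a family size larger than the number of
tested pathways (untested family members are treated as p = 1).

Pathway impact is topological: the sum of relative betweenness
centralities of the hit compounds in the pathway's compound graph,
divided by the total centrality of the graph.

A small self-contained pathway library over the 27-metabolite default
library (KEGG-shaped names and memberships, hand-built graphs) is
bundled so the stage runs with no external database.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathwayDB",
    "ORARow",
    "build_default_pathway_db",
    "ora_hypergeometric",
    "adjust_holm",
    "adjust_bh",
    "impact_betweenness",
    "pathway_table",
]

log = logging.getLogger("afnmr.pathway")


@dataclass
class PathwayDB:
    """Pathway library: compound sets, a compound universe, and optional
    per-pathway undirected compound graphs."""

    pathways: dict[str, set[str]]
    universe: set[str]
    graphs: dict[str, nx.Graph] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            extra = members - self.universe
            if extra:
                raise ValueError(f"{name}: compounds {sorted(extra)} not in universe")
            g = self.graphs.get(name)
            if g is not None and not set(g.nodes) <= members:
                raise ValueError(f"{name}: graph nodes not a subset of the pathway")


@dataclass
class ORARow:
    pathway: str
    total: int  # K: pathway size
    expected: float  # n * K / N
    hits: int  # k
    raw_p: float
    log_p: float  # -log10(raw_p)
    holm_p: float = np.nan
    fdr_p: float = np.nan
    impact: float = np.nan
    hit_compounds: tuple[str, ...] = ()


def build_default_pathway_db() -> PathwayDB:
    """Bundled toy pathway library over the default 27 metabolites.

    Fourteen small KEGG-shaped pathways with hand-built compound graphs;
    entirely self-contained (synthetic stand-in for an external pathway
    database, which is out of scope to ship).
    """
    from .synth import build_default_library

    universe = {m.name for m in build_default_library()}
    amino = {
        "alanine", "glycine", "valine", "leucine", "isoleucine", "threonine",
        "glutamate", "glutamine", "histidine", "phenylalanine", "tyrosine",
        "tryptophan",
    }
    p: dict[str, set[str]] = {
        "Aminoacyl-tRNA biosynthesis": set(amino),
        "Alanine, aspartate and glutamate metabolism":
            {"alanine", "glutamate", "glutamine", "pyruvate", "succinate", "citrate"},
        "Glycine, serine and threonine metabolism":
            {"glycine", "threonine", "betaine", "dimethylglycine", "choline", "pyruvate"},
        "Citrate cycle (TCA cycle)":
            {"citrate", "succinate", "pyruvate", "glutamate"},
        "Glycolysis / Gluconeogenesis":
            {"glucose", "pyruvate", "lactate", "acetate"},
        "Pyruvate metabolism":
            {"pyruvate", "lactate", "acetate", "succinate"},
        "Inositol phosphate metabolism": {"myo-inositol", "glucose"},
        "Butanoate metabolism":
            {"3-hydroxybutyrate", "succinate", "pyruvate", "acetate"},
        "Synthesis and degradation of ketone bodies":
            {"acetone", "3-hydroxybutyrate", "acetate"},
        "Valine, leucine and isoleucine degradation":
            {"valine", "leucine", "isoleucine", "3-hydroxybutyrate"},
        "Phenylalanine, tyrosine and tryptophan biosynthesis":
            {"phenylalanine", "tyrosine", "tryptophan"},
        "Nitrogen metabolism": {"glutamine", "glutamate", "glycine", "urea"},
        "Arginine biosynthesis": {"glutamate", "glutamine", "urea"},
        "Galactose metabolism": {"glucose", "myo-inositol"},
    }
    edges = {
        "Aminoacyl-tRNA biosynthesis": [
            ("glutamate", "glutamine"), ("glycine", "threonine"),
            ("valine", "leucine"), ("leucine", "isoleucine"),
            ("phenylalanine", "tyrosine"), ("tyrosine", "tryptophan"),
            ("alanine", "glutamate"), ("histidine", "glutamate"),
        ],
        "Alanine, aspartate and glutamate metabolism": [
            ("alanine", "pyruvate"), ("pyruvate", "citrate"),
            ("citrate", "succinate"), ("glutamate", "glutamine"),
            ("glutamate", "succinate"),
        ],
        "Glycine, serine and threonine metabolism": [
            ("choline", "betaine"), ("betaine", "dimethylglycine"),
            ("dimethylglycine", "glycine"), ("glycine", "pyruvate"),
            ("threonine", "glycine"),
        ],
        "Citrate cycle (TCA cycle)": [
            ("pyruvate", "citrate"), ("citrate", "succinate"),
            ("succinate", "glutamate"),
        ],
        "Glycolysis / Gluconeogenesis": [
            ("glucose", "pyruvate"), ("pyruvate", "lactate"),
            ("pyruvate", "acetate"),
        ],
        "Pyruvate metabolism": [
            ("pyruvate", "lactate"), ("pyruvate", "acetate"),
            ("pyruvate", "succinate"),
        ],
        "Inositol phosphate metabolism": [("glucose", "myo-inositol")],
        "Butanoate metabolism": [
            ("pyruvate", "acetate"), ("acetate", "3-hydroxybutyrate"),
            ("succinate", "pyruvate"),
        ],
        "Synthesis and degradation of ketone bodies": [
            ("acetate", "3-hydroxybutyrate"), ("3-hydroxybutyrate", "acetone"),
        ],
        "Valine, leucine and isoleucine degradation": [
            ("valine", "leucine"), ("leucine", "isoleucine"),
            ("leucine", "3-hydroxybutyrate"),
        ],
        "Phenylalanine, tyrosine and tryptophan biosynthesis": [
            ("phenylalanine", "tyrosine"), ("tyrosine", "tryptophan"),
        ],
        "Nitrogen metabolism": [
            ("glutamine", "glutamate"), ("glutamate", "glycine"),
            ("glutamine", "urea"),
        ],
        "Arginine biosynthesis": [
            ("glutamate", "glutamine"), ("glutamine", "urea"),
        ],
        "Galactose metabolism": [("glucose", "myo-inositol")],
    }
    graphs = {}
    for name, members in p.items():
        g = nx.Graph()
        g.add_nodes_from(sorted(members))
        g.add_edges_from(edges.get(name, []))
        graphs[name] = g
    return PathwayDB(pathways=p, universe=universe, graphs=graphs)


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def ora_hypergeometric(query: set[str], db: PathwayDB) -> list[ORARow]:
    """One-tailed hypergeometric over-representation per pathway.

    raw_p = P(X >= k) for X ~ Hypergeometric(N, K, n) with N the
    universe size, K the pathway size, n the mapped query size and k the
    hit count; expected = n*K/N.  Query compounds outside the universe
    are dropped with a warning.  Rows are sorted by raw_p, with impact
    attached where the pathway has a graph.
    """
    query = set(query)
    outside = query - db.universe
    if outside:
        warnings.warn(f"query compounds not in universe dropped: {sorted(outside)}",
                      stacklevel=2)
        query = query & db.universe
    if not query:
        raise ValueError("no query compounds map to the pathway universe")
    N, n = len(db.universe), len(query)
    rows = []
    for name, members in db.pathways.items():
        K = len(members)
        hit = tuple(sorted(query & members))
        k = len(hit)
        raw_p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        raw_p = min(max(raw_p, np.finfo(float).tiny), 1.0)
        g = db.graphs.get(name)
        rows.append(
            ORARow(
                pathway=name, total=K, expected=n * K / N, hits=k,
                raw_p=raw_p, log_p=float(-np.log10(raw_p)),
                impact=impact_betweenness(set(hit), g) if g is not None else np.nan,
                hit_compounds=hit,
            )
        )
    rows.sort(key=lambda r: (r.raw_p, r.pathway))
    return rows


# ---------------------------------------------------------------------------
# Multiple-testing adjustment with explicit family size
# ---------------------------------------------------------------------------

def _check_p(p: np.ndarray, m: int | None) -> tuple[np.ndarray, int]:
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size {m} smaller than the number of p-values {p.size}")
    return p, int(m)


def adjust_holm(p_values, family_size: int | None = None) -> np.ndarray:
    """Holm step-down adjustment with family size ``family_size``.

    Untested family members are assumed to have p = 1 (they can only sit
    at the end of the step-down order, so only the multiplier changes):
    adj_(r) = max_{s <= r} p_(s) * (m - s + 1), capped at 1, returned in
    the input order.
    """
    p, m = _check_p(p_values, family_size)
    order = np.argsort(p, kind="stable")
    mult = m - np.arange(p.size)
    adj_sorted = np.minimum(np.maximum.accumulate(p[order] * mult), 1.0)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def adjust_bh(p_values, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with family size ``family_size``.

    adj_(r) = min_{s >= r} p_(s) * m / s over the supplied values (the
    assumed-p=1 family members never lower the running minimum), capped
    at 1, returned in the input order.
    """
    p, m = _check_p(p_values, family_size)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    stepped = np.minimum.accumulate((p[order] * m / ranks)[::-1])[::-1]
    adj_sorted = np.minimum(stepped, 1.0)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Topological impact
# ---------------------------------------------------------------------------

def impact_betweenness(query: set[str], pathway_graph: nx.Graph) -> float:
    """Pathway impact: relative betweenness centrality of the hit nodes.

    impact = sum of betweenness centralities over hit nodes / sum over
    all nodes (0 when the graph has no centrality mass).  Query members
    absent from the graph are ignored with a warning.
    """
    if pathway_graph.number_of_nodes() == 0:
        return 0.0
    missing = set(query) - set(pathway_graph.nodes)
    if missing:
        warnings.warn(f"query nodes not in pathway graph ignored: {sorted(missing)}",
                      stacklevel=2)
    bc = nx.betweenness_centrality(pathway_graph, normalized=True)
    denom = sum(bc.values())
    if denom == 0:
        return 0.0
    return float(sum(bc[n] for n in query if n in bc) / denom)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def pathway_table(
    rows: list[ORARow],
    p_threshold: float = 0.05,
    impact_threshold: float = 0.1,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Adjusted, flagged pathway report.

    Attaches Holm and BH columns (family size defaults to the number of
    rows, i.e. the full pathway library that was tested), flags pathways
    with raw p < ``p_threshold`` AND at least two hit compounds as
    enriched, and impact > ``impact_threshold`` as high-impact.
    """
    if not rows:
        return pd.DataFrame(
            columns=["pathway", "total", "expected", "hits", "raw_p", "log_p",
                     "holm_p", "fdr_p", "impact", "enriched", "high_impact"]
        )
    ps = np.array([r.raw_p for r in rows])
    holm = adjust_holm(ps, family_size)
    fdr = adjust_bh(ps, family_size)
    for r, h, f in zip(rows, holm, fdr):
        r.holm_p, r.fdr_p = float(h), float(f)
    df = pd.DataFrame(
        {
            "pathway": [r.pathway for r in rows],
            "total": [r.total for r in rows],
            "expected": [r.expected for r in rows],
            "hits": [r.hits for r in rows],
            "raw_p": [r.raw_p for r in rows],
            "log_p": [r.log_p for r in rows],
            "holm_p": [r.holm_p for r in rows],
            "fdr_p": [r.fdr_p for r in rows],
            "impact": [r.impact for r in rows],
        }
    )
    df["enriched"] = (df["raw_p"] < p_threshold) & (df["hits"] >= 2)
    df["high_impact"] = df["impact"] > impact_threshold
    return df
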