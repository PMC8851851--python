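"""Cellular-location categories and interaction-network neighborhoods.

Annotation is consumed from user-supplied flat tables (e.g. exports from
the Gene Ontology resource and STRING) so the package stays network-free:

* annotation TSV — ``gene_id<TAB>biotype<TAB>locations`` with locations
  semicolon-separated;
* edge TSV — ``gene_a<TAB>gene_b<TAB>score`` with confidence scores in
  [0, 1], undirected.

Classified genes are binned into five mutually exclusive categories:
noncoding RNAs first (biotype overrides any location), then coding genes by
location precedence extracellular > plasma membrane > cytoplasm > nucleus;
genes with no annotated location are ``unclassified``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Union

import networkx as nx
import pandas as pd

from .cascade import LAYERS

BIOTYPES = ("coding", "noncoding")
LOCATIONS = ("extracellular", "plasma_membrane", "cytoplasm", "nucleus")
CATEGORIES = ("noncoding_rna",) + LOCATIONS + ("unclassified",)

#: STRING-style minimum interaction score presets
SCORE_PRESETS = {"medium": 0.400, "high": 0.700, "highest": 0.900}

EdgeList = Union[pd.DataFrame, Iterable[tuple[str, str, float]]]


def assign_location(biotype: str, locations: Iterable[str]) -> str:
    """Bin one gene into a single category (see module docstring)."""
    if biotype not in BIOTYPES:
        raise ValueError(f"unknown biotype {biotype!r}; expected one of {BIOTYPES}")
    locations = set(locations)
    bad = locations - set(LOCATIONS)
    if bad:
        raise ValueError(
            f"unknown location token(s) {sorted(bad)}; expected subset of {LOCATIONS}"
        )
    if biotype == "noncoding":
        return "noncoding_rna"
    for loc in LOCATIONS:  # fixed precedence, extracellular first
        if loc in locations:
            return loc
    return "unclassified"


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the annotation TSV; returns gene-indexed biotype/locations/category."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna({"locations": ""})
    expected = ["gene_id", "biotype", "locations"]
    if list(frame.columns[:3]) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    if frame["gene_id"].duplicated().any():
        dup = frame["gene_id"][frame["gene_id"].duplicated()]
        raise ValueError(f"{path}: duplicate gene id(s) {sorted(set(dup))[:5]}")
    frame = frame.set_index("gene_id")
    locs = frame["locations"].map(
        lambda s: frozenset(t for t in str(s).split(";") if t)
    )
    try:
        category = [assign_location(b, l) for b, l in zip(frame["biotype"], locs)]
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None
    return pd.DataFrame(
        {"biotype": frame["biotype"], "locations": locs, "category": category},
        index=frame.index,
    )


def location_summary(
    classification: pd.DataFrame | pd.Series,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Contingency table of onion layer x location category.

    Genes absent from the annotation table are counted as ``unclassified``;
    row sums therefore equal the layer sizes.
    """
    layers = classification["layer"] if isinstance(classification, pd.DataFrame) \
        else classification
    if layers.empty:
        return pd.DataFrame(columns=list(CATEGORIES))
    if annotations is None:
        category = pd.Series("unclassified", index=layers.index)
    else:
        category = annotations["category"].reindex(layers.index).fillna("unclassified")
    table = pd.crosstab(layers.rename("layer"), category.rename("category"))
    table = table.reindex(columns=list(CATEGORIES), fill_value=0)
    order = [l for l in LAYERS if l in table.index]
    return table.loc[order]


def read_edges(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    expected = ["gene_a", "gene_b", "score"]
    if list(frame.columns[:3]) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    return frame


def _as_graph(edges: EdgeList) -> nx.Graph:
    if isinstance(edges, pd.DataFrame):
        rows = edges[["gene_a", "gene_b", "score"]].itertuples(index=False)
    else:
        rows = edges
    graph = nx.Graph()
    for a, b, score in rows:
        if a == b:
            raise ValueError(f"self-edge on {a!r} is not allowed")
        score = float(score)
        if not 0 <= score <= 1:
            raise ValueError(f"edge ({a!r}, {b!r}) has score {score} outside [0, 1]")
        # undirected; duplicate (a,b)/(b,a) entries keep the highest score
        if graph.has_edge(a, b):
            score = max(score, graph.edges[a, b]["score"])
        graph.add_edge(a, b, score=score)
    return graph


def neighborhood(edges: EdgeList, focus: str, min_score: float = 0.400) -> set[str]:
    """Genes sharing an edge with ``focus`` at confidence >= ``min_score``.

    A focus gene absent from the edge list yields an empty set with a
    warning rather than an error.
    """
    if not 0 <= min_score <= 1:
        raise ValueError(f"min_score must be in [0, 1], got {min_score}")
    graph = _as_graph(edges)
    if focus not in graph:
        warnings.warn(f"focus gene {focus!r} has no edges", UserWarning, stacklevel=2)
        return set()
    return {n for n, data in graph[focus].items() if data["score"] >= min_score}


def neighborhood_by_layer(
    edges: EdgeList,
    focus: str,
    classification: pd.DataFrame | pd.Series,
    min_score: float = 0.400,
) -> pd.Series:
    """Count the focus gene's neighbors per onion layer."""
    layers = classification["layer"] if isinstance(classification, pd.DataFrame) \
        else classification
    neighbors = neighborhood(edges, focus, min_score)
    counts = layers.reindex(sorted(neighbors)).value_counts()
    return counts.reindex(list(LAYERS), fill_value=0).astype(int)
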