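"""Drug-AE network: cluster drugs by refined electrical features, add
positive/negative correlation pole nodes, and quantify pole separability.

Distances are Euclidean on z-scored refined features. The two pole nodes
sit at the class centroids; the distance between them summarizes how well
the refined features separate AE-positive from AE-negative drugs. Layout is
left to the consumer (e.g. a force-directed renderer); only distances and
edge weights are contractual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import DegenerateLabelsError, InvalidArgumentError
from .model import FeatureSelection

log = logging.getLogger(__name__)

POS_POLE, NEG_POLE = "__positive_pole__", "__negative_pole__"


def drug_feature_matrix(
    rows: pd.DataFrame, selection: FeatureSelection
) -> pd.DataFrame:
    """Per-drug mean of the selected features, z-scored per feature.

    ``rows`` must carry a ``drug_id`` column plus the selected feature
    columns. With a single drug, z-scoring is degenerate and skipped (the
    raw mean row is returned and a warning logged).
    """
    if not selection.selected:
        raise InvalidArgumentError("empty feature selection")
    missing = [f for f in selection.selected if f not in rows.columns]
    if missing:
        raise InvalidArgumentError(f"rows missing selected features: {missing}")
    mat = rows.groupby("drug_id")[selection.selected].mean()
    if len(mat) < 2:
        log.warning("single drug: z-scoring skipped")
        return mat
    sd = mat.std(ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return (mat - mat.mean()) / sd


@dataclass
class DrugAENetwork:
    graph: nx.Graph
    ae: str
    pole_separation: float
    nearest_pole_agreement: float

    def edge_list(self) -> pd.DataFrame:
        rows = [
            dict(source=u, target=v, weight=d["weight"], edge_type=d["edge_type"])
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def summary(self) -> dict:
        return {
            "ae": self.ae,
            "n_drugs": sum(
                1 for n, d in self.graph.nodes(data=True) if d.get("node_type") == "drug"
            ),
            "pole_separation": self.pole_separation,
            "nearest_pole_agreement": self.nearest_pole_agreement,
        }


def build_network(
    matrix: pd.DataFrame,
    labels: pd.Series,
    ae: str = "ae",
    edge_quantile: float = 0.9,
    receptor_classes: pd.Series | None = None,
) -> DrugAENetwork:
    """Build the drug-AE network for one adverse effect.

    Pole nodes sit at the positive- and negative-class centroids;
    ``pole_separation`` is the Euclidean distance between them. Drug-drug
    edges keep the most similar pairs (similarity 1/(1+distance) above the
    ``edge_quantile`` quantile); every drug is linked to both poles with its
    similarity as weight.
    """
    labels = labels.reindex(matrix.index)
    if labels.isna().any():
        raise InvalidArgumentError("labels missing for some drugs")
    y = labels.values.astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError(ae)
    X = matrix.values.astype(float)
    pos_centroid = X[y == 1].mean(axis=0)
    neg_centroid = X[y == 0].mean(axis=0)
    pole_separation = float(np.linalg.norm(pos_centroid - neg_centroid))

    d_pos = np.linalg.norm(X - pos_centroid, axis=1)
    d_neg = np.linalg.norm(X - neg_centroid, axis=1)
    agreement = float(np.mean((d_pos < d_neg).astype(int) == y))

    g = nx.Graph()
    for drug, lab in zip(matrix.index, y):
        attrs = {"node_type": "drug", "label": int(lab)}
        if receptor_classes is not None and drug in receptor_classes.index:
            attrs["receptor_class"] = str(receptor_classes[drug])
        g.add_node(drug, **attrs)
    g.add_node(POS_POLE, node_type="pole", label=1)
    g.add_node(NEG_POLE, node_type="pole", label=0)

    if len(matrix) >= 2:
        dmat = squareform(pdist(X))
        sims = 1.0 / (1.0 + dmat)
        iu = np.triu_indices(len(matrix), k=1)
        thresh = float(np.quantile(sims[iu], edge_quantile))
        for a, b in zip(*iu):
            if sims[a, b] >= thresh:
                g.add_edge(
                    matrix.index[a],
                    matrix.index[b],
                    weight=float(sims[a, b]),
                    edge_type="drug-drug",
                )
    for i, drug in enumerate(matrix.index):
        g.add_edge(drug, POS_POLE, weight=float(1.0 / (1.0 + d_pos[i])), edge_type="drug-pole")
        g.add_edge(drug, NEG_POLE, weight=float(1.0 / (1.0 + d_neg[i])), edge_type="drug-pole")

    return DrugAENetwork(
        graph=g,
        ae=ae,
        pole_separation=pole_separation,
        nearest_pole_agreement=agreement,
    )


def class_cluster_score(matrix: pd.DataFrame, receptor_classes: pd.Series) -> float:
    """Fraction of drugs whose nearest neighbour (feature distance) shares
    their receptor class; requires at least two classes."""
    classes = receptor_classes.reindex(matrix.index)
    if classes.isna().any():
        raise InvalidArgumentError("receptor classes unknown for some drugs")
    if classes.nunique() < 2:
        raise InvalidArgumentError("need at least two receptor classes")
    X = matrix.values.astype(float)
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    return float(np.mean(classes.values[nn] == classes.values))


def plot_network(net: DrugAENetwork, path=None, seed: int = 0):
    """Force-directed rendering (layout coordinates are non-contractual)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(net.graph, seed=seed, weight="weight")
    labels = nx.get_node_attributes(net.graph, "label")
    kinds = nx.get_node_attributes(net.graph, "node_type")
    colors = [
        "gold" if kinds[n] == "pole" else ("tab:red" if labels[n] else "tab:blue")
        for n in net.graph.nodes
    ]
    sizes = [400 if kinds[n] == "pole" else 100 for n in net.graph.nodes]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx(net.graph, pos=pos, node_color=colors, node_size=sizes,
                     with_labels=False, ax=ax, edge_color="0.8")
    ax.set_title(f"{net.ae}: pole separation {net.pole_separation:.2f}")
    ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
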