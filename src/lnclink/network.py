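"""Bipartite lncRNA-mRNA network construction and connectivity summaries.

An edge joins a lncRNA to an mRNA when their permutation p falls below a
threshold (strict inequality).  The robustness summary reports, per
threshold, how many lncRNAs retain at least one significant mRNA partner —
the quantity the three-threshold analysis (p < 5e-2, 5e-3, 5e-4) probes.
Because each lncRNA is tested against many candidate mRNAs, near-total
connectivity at a loose threshold is expected even under the null: with M
independent candidates the chance of at least one edge is 1 - (1-alpha)^M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ValidationError

DEFAULT_THRESHOLDS = (5e-2, 5e-3, 5e-4)


@dataclass
class ConnectivitySummary:
    threshold: float
    n_lnc_total: int
    n_lnc_connected: int
    fraction_connected: float
    n_edges: int
    degrees: dict = field(default_factory=dict)
    n_lnc_untestable: int = 0


def _validate_edges(edges: pd.DataFrame) -> None:
    required = {"lnc_id", "mrna_id", "r", "p_perm"}
    missing = required - set(edges.columns)
    if missing:
        raise ValidationError(f"edge table missing column(s) {sorted(missing)}")
    if edges.duplicated(["lnc_id", "mrna_id"]).any():
        raise ValidationError("edge table has duplicate (lnc_id, mrna_id) pairs")


def _tested(edges: pd.DataFrame) -> pd.DataFrame:
    if "skip_reason" in edges.columns:
        skip = edges["skip_reason"].fillna("").astype(str)
        return edges.loc[skip == ""]
    return edges


def build_bipartite_network(edges: pd.DataFrame, p_threshold: float) -> nx.Graph:
    """Bipartite graph of pairs with p_perm < p_threshold (strict).

    Nodes carry ``probe_class`` and the conventional ``bipartite`` attribute
    (0 for lncRNA, 1 for mRNA); edges carry r and p_perm.  All tested
    probes appear as nodes so zero-degree lncRNAs remain visible.
    """
    if not 0 < p_threshold <= 1:
        raise ValidationError("p_threshold must lie in (0, 1]")
    _validate_edges(edges)
    tested = _tested(edges)
    g = nx.Graph()
    for lnc in pd.unique(tested["lnc_id"]):
        g.add_node(lnc, probe_class="lncRNA", bipartite=0)
    for mrna in pd.unique(tested["mrna_id"]):
        g.add_node(mrna, probe_class="mRNA", bipartite=1)
    sig = tested.loc[tested["p_perm"] < p_threshold]
    for row in sig.itertuples(index=False):
        g.add_edge(row.lnc_id, row.mrna_id, r=float(row.r), p_perm=float(row.p_perm))
    return g


def connectivity_summary(
    edges: pd.DataFrame, thresholds=DEFAULT_THRESHOLDS
) -> list[ConnectivitySummary]:
    """Per-threshold count/fraction of lncRNAs with >= 1 significant partner.

    The denominator is every lncRNA with at least one testable pair;
    lncRNAs whose every pair was skipped (constant vectors) were never
    testable and are counted separately in ``n_lnc_untestable``.
    """
    _validate_edges(edges)
    tested = _tested(edges)
    all_lnc = pd.unique(edges["lnc_id"])
    testable = set(pd.unique(tested["lnc_id"]))
    untestable = len(all_lnc) - len(testable)
    out = []
    for thr in thresholds:
        if not 0 < thr <= 1:
            raise ValidationError("thresholds must lie in (0, 1]")
        sig = tested.loc[tested["p_perm"] < thr]
        degrees = sig.groupby("lnc_id").size().to_dict()
        n_connected = len(degrees)
        n_total = len(testable)
        out.append(
            ConnectivitySummary(
                threshold=float(thr),
                n_lnc_total=n_total,
                n_lnc_connected=n_connected,
                fraction_connected=(n_connected / n_total) if n_total else 0.0,
                n_edges=int(len(sig)),
                degrees={l: int(degrees.get(l, 0)) for l in testable},
                n_lnc_untestable=int(untestable),
            )
        )
    return out


def summary_frame(summaries: list[ConnectivitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": [s.threshold for s in summaries],
            "n_lnc_total": [s.n_lnc_total for s in summaries],
            "n_lnc_connected": [s.n_lnc_connected for s in summaries],
            "fraction_connected": [s.fraction_connected for s in summaries],
            "n_edges": [s.n_edges for s in summaries],
            "n_lnc_untestable": [s.n_lnc_untestable for s in summaries],
        }
    )


def export_network(g: nx.Graph, path, format: str = "graphml") -> None:
    """Write the network as GraphML or an edge-list TSV for external tools."""
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        rows = [
            {"lnc_id": u if g.nodes[u]["probe_class"] == "lncRNA" else v,
             "mrna_id": v if g.nodes[u]["probe_class"] == "lncRNA" else u,
             "r": d.get("r", np.nan),
             "p_perm": d.get("p_perm", np.nan)}
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["lnc_id", "mrna_id", "r", "p_perm"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )
    else:
        raise ValidationError(f"unknown export format {format!r}; expected graphml or edge_tsv")


def import_network(path, format: str = "graphml") -> nx.Graph:
    if format != "graphml":
        raise ValidationError("only graphml re-import is supported")
    return nx.read_graphml(path)
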