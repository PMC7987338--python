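"""Simple Ratio Index association networks and node position metrics.

Networks are built per maternal-loss incident for two 6-month windows (pre
and post loss) and two association types (2-m proximity, affiliative
contact).  The Simple Ratio Index of a dyad is the proportion of focal
scans *of either member* during which the pair was recorded associating:

    SRI(A, B) = x_AB / (n_A + n_B)

where n_A, n_B are the members' focal-scan counts in the window and x_AB
counts scans whose focal is A or B with the other member in the relevant
partner set.  Because exactly one individual is focal per scan, joint-focal
scans cannot occur and the denominator is the plain sum.

Node metrics (binary degree, weighted degree, eigenvector centrality) are
normalized to the maximum over all nodes of their network so positions are
comparable across incidents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SRINetwork",
    "compute_sri",
    "build_network",
    "build_paired_networks",
    "node_metrics",
    "metric_change",
    "InadequateDataError",
]


class InadequateDataError(ValueError):
    """An incident without enough focal scans to analyse (dropped upstream)."""


def validate_scans(scans: pd.DataFrame) -> None:
    """Check the focal-scan invariants: focal not its own partner and
    contact partners a subset of proximity partners, row by row."""
    for k, row in enumerate(scans.itertuples(index=False)):
        prox, cont = set(row.proximity_partners), set(row.contact_partners)
        if row.focal in prox or row.focal in cont:
            raise ValueError(f"scan {k}: focal {row.focal} appears in its own partner set")
        if not cont <= prox:
            raise ValueError(
                f"scan {k}: contact partners {sorted(cont - prox)} not within 2 m set"
            )


def _partner_column(assoc_type: str) -> str:
    if assoc_type not in ("proximity", "contact"):
        raise ValueError(f"assoc_type must be 'proximity' or 'contact', got {assoc_type!r}")
    return f"{assoc_type}_partners"


@dataclass
class SRINetwork:
    """Weighted undirected association network for one (incident, period,
    association-type) triple, with per-node focal-scan counts."""

    incident: str
    period: str                  # "pre" or "post"
    assoc_type: str              # "proximity" or "contact"
    nodes: list
    focal_counts: pd.Series      # scans as focal, per node
    adjacency: np.ndarray        # symmetric SRI weights in [0, 1]

    def __post_init__(self):
        A = self.adjacency
        if A.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node list")
        if not np.allclose(A, A.T):
            raise ValueError("SRI adjacency must be symmetric")
        if A.min() < 0 or A.max() > 1:
            raise ValueError("SRI weights must lie in [0, 1]")

    def weight(self, a, b) -> float:
        i, j = self.nodes.index(a), self.nodes.index(b)
        return float(self.adjacency[i, j])

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.nodes)):
            for j in range(i + 1, len(self.nodes)):
                rows.append(dict(incident=self.incident, period=self.period,
                                 assoc_type=self.assoc_type,
                                 id_a=self.nodes[i], id_b=self.nodes[j],
                                 sri=self.adjacency[i, j]))
        return pd.DataFrame(rows)


def _count_arrays(scans: pd.DataFrame, nodes: list, assoc_type: str):
    """Focal counts and pairwise association counts over ``nodes``."""
    index = {n: k for k, n in enumerate(nodes)}
    g = len(nodes)
    focal_counts = np.zeros(g, dtype=int)
    assoc = np.zeros((g, g), dtype=int)
    col = _partner_column(assoc_type)
    for focal, partners in zip(scans["focal"], scans[col]):
        fi = index.get(focal)
        if fi is None:
            continue
        focal_counts[fi] += 1
        for p in partners:
            pi = index.get(p)
            if pi is not None:
                assoc[fi, pi] += 1
    return focal_counts, assoc


def compute_sri(scans: pd.DataFrame, dyad: tuple, assoc_type: str = "proximity") -> float:
    """Simple Ratio Index of one dyad over a scan table.

    Raises on an unsampled dyad (neither member was ever focal).
    """
    a, b = dyad
    focal_counts, assoc = _count_arrays(scans, [a, b], assoc_type)
    denom = focal_counts.sum()
    if denom == 0:
        raise ValueError(f"unsampled dyad {dyad}: no focal scans of either member")
    return float((assoc[0, 1] + assoc[1, 0]) / denom)


def build_network(scans: pd.DataFrame, nodes: Iterable, assoc_type: str,
                  incident: str = "", period: str = "") -> SRINetwork:
    """SRI network over ``nodes`` from the scans falling in one window."""
    nodes = list(nodes)
    focal_counts, assoc = _count_arrays(scans, nodes, assoc_type)
    if np.any(focal_counts == 0):
        missing = [n for n, c in zip(nodes, focal_counts) if c == 0]
        raise ValueError(f"unsampled dyad: nodes {missing} have no focal scans")
    denom = focal_counts[:, None] + focal_counts[None, :]
    A = (assoc + assoc.T) / denom
    np.fill_diagonal(A, 0.0)
    return SRINetwork(incident=incident, period=period, assoc_type=assoc_type,
                      nodes=nodes, focal_counts=pd.Series(focal_counts, index=nodes),
                      adjacency=A)


def build_paired_networks(
    scans: pd.DataFrame,
    incident: Mapping,
    assoc_type: str = "proximity",
    window_days: int = 183,
    min_scans: int = 12,
) -> tuple[SRINetwork, SRINetwork]:
    """Paired pre/post-loss networks over a shared node set.

    Windows are ``window_days`` calendar days ending the day before the
    loss (pre) and starting on the loss date (post).  Nodes are the
    individuals with strictly more than ``min_scans`` focal scans in *both*
    windows, excluding the orphans' mother (her pre-loss relationships are
    analysed separately).  An orphan falling below the scan threshold means
    the incident lacks adequate data and raises
    :class:`InadequateDataError`.
    """
    loss = pd.Timestamp(incident["date"])
    wd = pd.Timedelta(days=window_days)
    dates = pd.to_datetime(scans["date"])
    pre = scans[(dates >= loss - wd) & (dates < loss)]
    post = scans[(dates >= loss) & (dates < loss + wd)]
    if not len(pre):
        raise ValueError("window uncovered: no scans in the pre-loss window")
    if not len(post):
        raise ValueError("window uncovered: no scans in the post-loss window")

    counts_pre = pre["focal"].value_counts()
    counts_post = post["focal"].value_counts()
    eligible = sorted(
        set(counts_pre.index[counts_pre > min_scans])
        & set(counts_post.index[counts_post > min_scans])
    )
    eligible = [n for n in eligible if n != incident["mother_id"]]
    below = [o for o in incident["orphan_ids"] if o not in eligible]
    if below:
        raise InadequateDataError(
            f"incident {incident.get('incident', '?')}: orphans {below} below the "
            f">{min_scans}-scan threshold in one of the windows"
        )
    name = incident.get("incident", "")
    return (
        build_network(pre, eligible, assoc_type, incident=name, period="pre"),
        build_network(post, eligible, assoc_type, incident=name, period="post"),
    )


# ---------------------------------------------------------------------------
# Node metrics
# ---------------------------------------------------------------------------


def _eigenvector_scores(A: np.ndarray) -> np.ndarray:
    """Leading-eigenvector scores of a weighted adjacency, max-normalized.

    Isolated nodes score 0; the remaining (possibly disconnected) subgraph
    uses the leading eigenvector of its adjacency, whose mass sits on the
    dominant component.  Entries are taken in absolute value (the Perron
    vector is non-negative on that component up to sign).
    """
    g = A.shape[0]
    degree = A.sum(axis=1)
    active = degree > 0
    scores = np.zeros(g)
    if active.sum() >= 2:
        sub = A[np.ix_(active, active)]
        w, v = np.linalg.eigh(sub)
        lead = np.abs(v[:, np.argmax(w)])
        scores[active] = lead
    if scores.max() > 0:
        scores = scores / scores.max()
    return scores


def node_metrics(network: SRINetwork) -> pd.DataFrame:
    """Normalized binary degree, weighted degree, and eigenvector centrality.

    Binary degree counts nonzero incident edges and weighted degree sums
    incident SRI weights; both are divided by their maximum over the
    network, so at least one node attains 1 (eigenvector centrality is
    max-normalized by construction).  An all-zero network yields zeros
    with a warning.
    """
    if len(network.nodes) < 2:
        raise ValueError("node metrics need a network with at least 2 nodes")
    A = network.adjacency
    binary = (A > 0).sum(axis=1).astype(float)
    weighted = A.sum(axis=1)
    if weighted.max() == 0:
        warnings.warn("all-zero network: node metrics set to 0", stacklevel=2)
        eigen = np.zeros(len(network.nodes))
    else:
        binary = binary / binary.max()
        weighted = weighted / weighted.max()
        eigen = _eigenvector_scores(A)
    return pd.DataFrame(
        {
            "binary_degree_norm": binary,
            "weighted_degree_norm": weighted,
            "eigenvector": eigen,
        },
        index=pd.Index(network.nodes, name="node"),
    )


METRICS = ("binary_degree_norm", "weighted_degree_norm", "eigenvector")


def metric_change(pre: pd.DataFrame, post: pd.DataFrame,
                  immature_nodes: Iterable) -> pd.DataFrame:
    """Per-node metric changes plus the initial-value deviance covariate.

    ``delta_<m>`` is post minus pre; ``deviance_<m>`` is the node's pre-loss
    value minus the mean pre-loss value over the immature nodes of the same
    network (signed), which controls for unusually high or low starting
    positions.
    """
    if list(pre.index) != list(post.index):
        raise ValueError("pre and post metrics cover different node sets")
    immature = [n for n in immature_nodes if n in pre.index]
    out = pd.DataFrame(index=pre.index)
    for m in METRICS:
        out[f"delta_{m}"] = post[m] - pre[m]
        out[f"deviance_{m}"] = pre[m] - pre.loc[immature, m].mean()
    return out
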