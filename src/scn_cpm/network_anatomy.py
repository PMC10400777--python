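"""Anatomical summaries of identified networks.

Node degree (number of selected edges incident to a region), top-degree
node tables, and counts of selected edges within and between canonical
large-scale networks.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from scn_cpm.atlas_io import RegionAtlas
    from scn_cpm.cpm_engine import SignedEdgeMasks
    from scn_cpm.scn_builder import EdgeIndex

from scn_cpm.atlas_io import UNASSIGNED


def _sign_mask(mask: "SignedEdgeMasks", sign: str) -> np.ndarray:
    if sign == "positive":
        return mask.positive
    if sign == "negative":
        return mask.negative
    raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")


def node_degree(
    mask: "SignedEdgeMasks",
    edge_index: "EdgeIndex",
    atlas: "RegionAtlas",
    sign: str = "positive",
) -> pd.DataFrame:
    """Degree of every region in the selected network of the given sign.

    The sum of degrees equals twice the number of selected edges (handshake
    identity). Rows follow atlas order.
    """
    m = _sign_mask(mask, sign)
    if m.size != edge_index.n_edges:
        raise ValueError("mask length does not match the edge index")
    N = edge_index.n_regions
    if atlas.n_regions != N:
        raise ValueError("atlas region count does not match the edge index")
    deg = np.zeros(N, dtype=int)
    pairs = edge_index.pairs[m]
    np.add.at(deg, pairs[:, 0], 1)
    np.add.at(deg, pairs[:, 1], 1)
    return pd.DataFrame(
        {
            "region_id": atlas.region_ids,
            "region_name": atlas.region_names,
            "degree": deg,
            "sign": sign,
        }
    )


def top_k_nodes(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k highest-degree regions, ties broken by atlas (row) order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    # stable sort keeps atlas order within equal degrees
    return table.sort_values("degree", ascending=False, kind="stable").head(k).reset_index(
        drop=True
    )


def canonical_summary(
    mask: "SignedEdgeMasks",
    edge_index: "EdgeIndex",
    atlas: "RegionAtlas",
    sign: str = "positive",
) -> pd.DataFrame:
    """Selected-edge counts within and between canonical networks.

    Returns a symmetric K x K integer matrix with within-network counts on
    the diagonal; its upper triangle plus diagonal sums to the number of
    selected edges. Regions without a mapping are tallied under an explicit
    ``UNASSIGNED`` bucket so the count is conserved. Networks are ordered
    alphabetically, ``UNASSIGNED`` last.
    """
    m = _sign_mask(mask, sign)
    if m.size != edge_index.n_edges:
        raise ValueError("mask length does not match the edge index")
    if atlas.n_regions != edge_index.n_regions:
        raise ValueError("atlas region count does not match the edge index")

    nets = [atlas.network_of(rid) for rid in atlas.region_ids]
    names = sorted(set(nets) - {UNASSIGNED})
    if UNASSIGNED in nets:
        names.append(UNASSIGNED)
    idx = {name: k for k, name in enumerate(names)}
    K = len(names)

    counts = np.zeros((K, K), dtype=int)
    for a, b in edge_index.pairs[m]:
        ka, kb = idx[nets[a]], idx[nets[b]]
        lo, hi = min(ka, kb), max(ka, kb)
        counts[lo, hi] += 1
    counts = counts + np.triu(counts, k=1).T  # symmetrize off-diagonal
    return pd.DataFrame(counts, index=names, columns=names)
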