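"""Per-sample phylogenetic diversity metrics: Faith's PD, MPD, MNTD.

Faith's PD is root-inclusive by default (the spanning subtree of the sample's
taxa plus the path to the root), matching the common picante default; a flag
gives the root-exclusive variant. MPD defaults to presence-based (unweighted)
with an abundance-weighted mode.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import MissingBranchLengthError
from .tree import Phylogeny, _node_name, normalize_name

__all__ = ["faith_pd", "mpd", "mntd", "diversity_table", "sample_taxa"]


def faith_pd(tree: Phylogeny, taxa, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a taxon set.

    Sum of branch lengths of the minimal subtree spanning the taxa; with
    ``include_root`` (default) the subtree is additionally required to span
    the root, so the stem paths down to the root are counted.
    """
    taxa = set(taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    by_name = {normalize_name(_node_name(l)): l for l in tree.tips}
    missing = [t for t in taxa if normalize_name(t) not in by_name]
    if missing:
        raise ValueError("taxa not found among tree tips: " + ", ".join(sorted(missing)))

    # union of root-ward paths from every sampled tip
    on_path = set()
    for t in taxa:
        node = by_name[normalize_name(t)]
        while node.parent_node is not None and node not in on_path:
            on_path.add(node)
            node = node.parent_node

    if not include_root:
        # drop the stem edges below the MRCA of the sample
        node = by_name[normalize_name(next(iter(taxa)))]
        # the MRCA is the deepest node whose subtree holds every sampled tip
        counts = {}
        for t in taxa:
            node = by_name[normalize_name(t)]
            while node is not None:
                counts[node] = counts.get(node, 0) + 1
                node = node.parent_node
        mrca = max(
            (n for n, c in counts.items() if c == len(taxa)),
            key=lambda n: sum(1 for a in _ancestors(n)),
        )
        drop = set()
        node = mrca
        while node.parent_node is not None:
            drop.add(node)
            node = node.parent_node
        on_path -= drop

    total = 0.0
    for node in on_path:
        if node.edge.length is None:
            raise MissingBranchLengthError(
                f"branch length absent above node {_node_name(node)!r}; "
                "run bladj first"
            )
        total += node.edge.length
    return total


def _ancestors(node):
    while node.parent_node is not None:
        node = node.parent_node
        yield node


def _dm_indices(dm: DistanceMatrix, taxa) -> np.ndarray:
    lookup = {normalize_name(i): k for k, i in enumerate(dm.ids)}
    missing = [t for t in taxa if normalize_name(t) not in lookup]
    if missing:
        raise ValueError(
            "taxa not found in distance matrix: " + ", ".join(sorted(missing))
        )
    return np.array(sorted(lookup[normalize_name(t)] for t in set(taxa)), dtype=int)


def mpd(dm: DistanceMatrix, taxa, weights=None) -> float:
    """Mean pairwise patristic distance among the taxa of one sample.

    Unweighted (default): mean of d(i, j) over unordered pairs i != j.
    With ``weights`` (mapping taxon -> abundance): sum w_i w_j d(i, j) over
    i != j divided by sum w_i w_j. Returns NaN (with a warning) for a
    single-taxon sample.
    """
    idx = _dm_indices(dm, taxa)
    if idx.size < 2:
        warnings.warn("MPD undefined for a single-taxon sample", stacklevel=2)
        return float("nan")
    sub = dm.data[np.ix_(idx, idx)]
    if weights is None:
        n = idx.size
        return float(sub.sum() / (n * (n - 1)))
    wl = {normalize_name(k): float(v) for k, v in dict(weights).items()}
    ids = [dm.ids[i] for i in idx]
    w = np.array([wl[normalize_name(i)] for i in ids])
    ww = np.outer(w, w)
    np.fill_diagonal(ww, 0.0)
    return float((ww * sub).sum() / ww.sum())


def mntd(dm: DistanceMatrix, taxa) -> float:
    """Mean distance from each taxon to its nearest co-occurring taxon."""
    idx = _dm_indices(dm, taxa)
    if idx.size < 2:
        warnings.warn("MNTD undefined for a single-taxon sample", stacklevel=2)
        return float("nan")
    sub = dm.data[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def sample_taxa(communities: pd.DataFrame, sample) -> list[str]:
    """Species with positive abundance in one row of a community matrix."""
    row = communities.loc[sample]
    return list(row.index[row > 0])


def diversity_table(
    tree: Phylogeny,
    communities: pd.DataFrame,
    include_root: bool = True,
) -> pd.DataFrame:
    """Per-sample richness, PD, propPD, MPD and MNTD (Table-3-style layout).

    ``communities``: samples as rows, species as columns, non-negative
    abundances or presence. Every species present must be a tree tip.
    """
    tipset = {normalize_name(n) for n in tree.tip_names}
    used = [
        s for s in communities.columns if (communities[s] > 0).any()
    ]
    unknown = sorted(s for s in used if normalize_name(s) not in tipset)
    if unknown:
        raise ValueError(
            "species in community matrix absent from tree: " + ", ".join(unknown)
        )
    dm = tree.patristic_distances()
    total = tree.total_branch_length()
    rows = []
    for sample in communities.index:
        taxa = sample_taxa(communities, sample)
        if not taxa:
            warnings.warn(f"sample {sample!r} is empty; skipped", stacklevel=2)
            continue
        pd_val = faith_pd(tree, taxa, include_root=include_root)
        if len(taxa) >= 2:
            mpd_val = mpd(dm, taxa)
            mntd_val = mntd(dm, taxa)
        else:
            warnings.warn(
                f"sample {sample!r} has a single taxon; MPD/MNTD undefined",
                stacklevel=2,
            )
            mpd_val = mntd_val = float("nan")
        rows.append(
            {
                "sample": sample,
                "ntaxa": len(taxa),
                "PD": pd_val,
                "tree_branch_length": total,
                "propPD": pd_val / total,
                "MPD": mpd_val,
                "MNTD": mntd_val,
            }
        )
    return pd.DataFrame(rows).set_index("sample")
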