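"""Phylomatic-style supertree grafting and BLADJ branch-length adjustment.

``graft_supertree`` attaches a species list onto a family/genus backbone
using a taxonomy table (species -> genus -> family), creating polytomies at
the attachment points. ``bladj`` then dates the tree: nodes named in an age
table keep their ages, every other internal node is placed by even spacing
between its nearest dated ancestor and a dated descendant, and branch
lengths are recomputed as age differences — yielding an ultrametric tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd

from .errors import AgeConflictError, UngraftableSpeciesError
from .tree import Phylogeny, _node_name, normalize_name

__all__ = [
    "TaxonomyTable",
    "AgeTable",
    "graft_supertree",
    "bladj",
    "total_branch_length",
]


@dataclass
class TaxonomyTable:
    """Species -> genus -> family mapping driving supertree grafting."""

    table: pd.DataFrame  # columns: species, genus, family

    def __post_init__(self):
        df = self.table
        required = {"species", "genus", "family"}
        if not required.issubset(df.columns):
            raise ValueError(f"taxonomy table needs columns {sorted(required)}")
        df = df[["species", "genus", "family"]].astype(str)
        for col in ("species", "genus", "family"):
            if (df[col].str.strip() == "").any():
                raise ValueError(f"taxonomy table has empty {col} entries")
        keys = df["species"].map(normalize_name)
        if keys.duplicated().any():
            dups = df.loc[keys.duplicated(), "species"].tolist()
            raise ValueError(f"duplicate species in taxonomy: {dups}")
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_file(cls, path) -> "TaxonomyTable":
        """Read ``species<TAB>genus<TAB>family`` or phylomatic ``family/genus/species``."""
        lines = [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        rows = []
        header_like = lines and "species" in lines[0].lower()
        for ln in lines[1:] if header_like else lines:
            if "/" in ln and "\t" not in ln:
                family, genus, species = ln.split("/")
            else:
                parts = ln.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"bad taxonomy line: {ln!r}")
                species, genus, family = parts
            rows.append(
                {"species": species.strip(), "genus": genus.strip(), "family": family.strip()}
            )
        return cls(pd.DataFrame(rows))

    def lookup(self, species: str):
        key = normalize_name(species)
        hit = self.table[self.table["species"].map(normalize_name) == key]
        if hit.empty:
            return None
        row = hit.iloc[0]
        return row["genus"], row["family"]

    @property
    def species(self) -> list[str]:
        return self.table["species"].tolist()

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class AgeTable(dict):
    """Node name -> age mapping (Phylocom bladj ``ages`` file)."""

    def __init__(self, mapping):
        cleaned = {}
        for name, age in dict(mapping).items():
            age = float(age)
            if age < 0:
                raise ValueError(f"negative age for node {name!r}")
            key = normalize_name(str(name))
            if key in cleaned:
                raise ValueError(f"duplicate node name in age table: {name!r}")
            cleaned[key] = age
        super().__init__(cleaned)
        self._original = {normalize_name(str(k)): str(k) for k in dict(mapping)}

    @classmethod
    def from_file(cls, path) -> "AgeTable":
        mapping = {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t") if "\t" in ln else ln.split()
            if len(parts) != 2:
                raise ValueError(f"bad ages line: {ln!r}")
            if parts[0].lower() in {"node", "node_name", "name"}:
                continue
            mapping[parts[0]] = float(parts[1])
        return cls(mapping)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for key, age in self.items():
                fh.write(f"{self._original.get(key, key)}\t{age:g}\n")


def graft_supertree(
    backbone: Phylogeny,
    taxonomy: TaxonomyTable,
    species,
    drop_ungraftable: bool = False,
) -> Phylogeny:
    """Attach each species to its genus node, or under its family node.

    Rules: (i) if the backbone has a node named for the species' genus, the
    species becomes a child of that node; (ii) otherwise, if the family node
    exists, a new genus node is created beneath it and the species attached
    there. Species whose family is absent are ungraftable. The result is
    pruned to exactly the requested species, and the backbone's own branch
    lengths are discarded (only bladj ages define lengths).
    """
    species = sorted(set(species), key=normalize_name)
    if not species:
        raise ValueError("empty species set")

    work = backbone.copy()
    tree = work._tree

    def name_index():
        idx = {}
        for node in tree.preorder_node_iter():
            label = _node_name(node)
            if label:
                idx.setdefault(normalize_name(label), node)
        return idx

    index = name_index()
    ungraftable = []
    grafted = []
    for sp in species:
        sp_key = normalize_name(sp)
        if sp_key in index:  # species already on the backbone
            grafted.append(sp)
            continue
        rec = taxonomy.lookup(sp)
        if rec is None:
            ungraftable.append(sp)
            continue
        genus, family = rec
        attach = index.get(normalize_name(genus))
        if attach is None:
            fam_node = index.get(normalize_name(family))
            if fam_node is None:
                ungraftable.append(sp)
                continue
            attach = dendropy.Node()
            attach.label = genus
            fam_node.add_child(attach)
            index[normalize_name(genus)] = attach
        if attach.is_leaf() and attach.taxon is not None:
            # genus was a backbone tip; it becomes internal
            attach.label = attach.taxon.label
            attach.taxon = None
        leaf = dendropy.Node()
        leaf.taxon = tree.taxon_namespace.require_taxon(label=sp)
        attach.add_child(leaf)
        index[sp_key] = leaf
        grafted.append(sp)

    if ungraftable and not drop_ungraftable:
        raise UngraftableSpeciesError(ungraftable)
    if ungraftable:
        warnings.warn(
            "dropping ungraftable species: " + ", ".join(ungraftable),
            stacklevel=2,
        )
    if not grafted:
        raise UngraftableSpeciesError(ungraftable)

    keep = {normalize_name(sp) for sp in grafted}
    while True:
        doomed = [
            leaf
            for leaf in tree.leaf_node_iter()
            if normalize_name(_node_name(leaf) or "") not in keep
            and leaf.parent_node is not None
        ]
        if not doomed:
            break
        for leaf in doomed:
            leaf.parent_node.remove_child(leaf)

    for node in tree.preorder_node_iter():
        node.edge.length = None
    return Phylogeny(tree)


def bladj(tree: Phylogeny, ages: AgeTable | dict) -> Phylogeny:
    """Date a tree from fixed node ages by even interpolation.

    Nodes named in ``ages`` keep their table age; tips not named are fixed
    at age 0. Undated nodes are assigned ages path by path: the dated node A
    with the greatest age that still has undated descendants picks, among
    the dated nodes reachable through undated intermediates only, the
    terminal B with the fewest intervening edges (ties to the oldest B);
    the j-th of the k-1 intermediate nodes on the k-edge path A..B receives
    age(A) - j * (age(A) - age(B)) / k. Assigned ages are then fixed.
    Branch lengths become parent age minus child age; the result is
    ultrametric whenever the table is internally consistent.
    """
    if not isinstance(ages, AgeTable):
        ages = AgeTable(ages)
    out = tree.copy()
    t = out._tree

    fixed: dict = {}
    for node in t.preorder_node_iter():
        label = _node_name(node)
        key = normalize_name(label) if label else None
        if key is not None and key in ages:
            node.age = ages[key]
            fixed[node] = True
        elif node.is_leaf():
            node.age = 0.0
            fixed[node] = True
        else:
            node.age = None
            fixed[node] = False

    root = t.seed_node
    if not fixed[root]:
        raise ValueError(
            "root node must be named in the age table "
            f"(root label: {_node_name(root)!r})"
        )

    # fixed-vs-fixed consistency along ancestry
    for node in t.preorder_node_iter():
        if not fixed[node] or node.parent_node is None:
            continue
        anc = node.parent_node
        while anc is not None and not fixed[anc]:
            anc = anc.parent_node
        if anc is not None and anc.age < node.age - 1e-12:
            raise AgeConflictError(
                f"age table conflict: ancestor {_node_name(anc)!r} "
                f"(age {anc.age:g}) is younger than descendant "
                f"{_node_name(node)!r} (age {node.age:g})"
            )

    # oldest fixed descendant below each node: an interpolated age is never
    # allowed to undercut it, otherwise a short path to a young terminal
    # could contradict an older fixed node on a side branch
    floor = {}
    for node in t.postorder_node_iter():
        best = node.age if fixed[node] else 0.0
        for child in node.child_nodes():
            best = max(best, floor[child])
        floor[node] = best

    def sort_key(node):
        return (-node.age, _node_name(node) or "")

    while True:
        candidates = [
            n
            for n in t.preorder_node_iter()
            if fixed[n] and any(not fixed[c] for c in n.child_nodes())
        ]
        if not candidates:
            break
        anchor = min(candidates, key=sort_key)
        # frontier: dated nodes reachable through undated intermediates only
        best = None  # (n_edges, -ageB, nameB, path)
        stack = [(c, [anchor, c]) for c in anchor.child_nodes() if not fixed[c]]
        while stack:
            node, path = stack.pop()
            for child in node.child_nodes():
                cpath = path + [child]
                if fixed[child]:
                    cand = (
                        len(cpath) - 1,
                        -child.age,
                        _node_name(child) or "",
                        cpath,
                    )
                    if best is None or cand[:3] < best[:3]:
                        best = cand
                else:
                    stack.append((child, cpath))
        k, _, _, path = best
        age_a, age_b = anchor.age, path[-1].age
        for j, node in enumerate(path[1:-1], start=1):
            node.age = max(age_a - j * (age_a - age_b) / k, floor[node])
            fixed[node] = True

    for node in t.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        length = node.parent_node.age - node.age
        if length < -1e-9:
            raise AgeConflictError(
                f"interpolated ages conflict: node {_node_name(node)!r} "
                f"(age {node.age:g}) older than its parent "
                f"{_node_name(node.parent_node)!r} (age {node.parent_node.age:g})"
            )
        node.edge.length = max(length, 0.0)
    return Phylogeny(t, validate=False)


def total_branch_length(tree: Phylogeny) -> float:
    """Sum of branch lengths over the whole tree, excluding any root stem."""
    return tree.total_branch_length()
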