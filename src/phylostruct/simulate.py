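"""Synthetic study-system generator.

Emulates a subalpine-meadow slope gradient: an 88-species pool organized in
families and genera (backbone + taxonomy + node ages for grafting and
dating), five slope levels (N, NE, E, SE, S) of four quadrats each with a
declining richness schedule (51, 41, 34, 29, 23 species), a tunable
phylogenetic assembly process per level (lambda > 0 assembles relatives
together, lambda = 0 reduces exactly to the phylogeny-pool null draw,
lambda < 0 repels relatives), and soil/trait tables whose monotone gradient
and coupling let a constrained ordination recover a dominant first axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .supertree import AgeTable, TaxonomyTable, bladj, graft_supertree
from .tree import Phylogeny, parse_newick

__all__ = [
    "GeneratorConfig",
    "generate_backbone",
    "generate_communities",
    "generate_env_traits",
    "generate_dataset",
    "write_fixtures",
]

SOIL_FACTORS = ("SWC", "STN", "STP", "NP", "SOC", "SAN", "SAP", "pH")
TRAITS = ("SLA", "LDMC", "LWC", "LCC", "LKC", "LPC", "LNC", "SPAD")

# per-trait (sign of soil coupling, output mean, output sd) in field units
_TRAIT_SPEC = {
    "SLA": (+1, 180.0, 40.0),   # cm^2/g
    "LDMC": (-1, 0.35, 0.06),   # fraction
    "LWC": (+1, 65.0, 6.0),     # %
    "LCC": (+1, 430.0, 25.0),   # mg/g
    "LKC": (+1, 15.0, 3.0),     # mg/g
    "LPC": (-1, 1.8, 0.3),      # mg/g
    "LNC": (+1, 22.0, 4.0),     # mg/g
    "SPAD": (-1, 42.0, 5.0),    # unitless
}


@dataclass
class GeneratorConfig:
    """Study-condition knobs; defaults are the emulated field design."""

    pool_size: int = 88
    n_levels: int = 5
    quadrats_per_level: int = 4
    richness_schedule: tuple = (51, 41, 34, 29, 23)
    lambda_schedule: tuple = (2.0, 0.0, -1.0, -1.5, -2.0)
    level_names: tuple = ("N", "NE", "E", "SE", "S")
    n_families: int = 12
    genera_per_family: tuple = (2, 6)
    root_age: float = 140.0
    family_age_range: tuple = (0.25, 0.5)   # fraction of root age
    genus_age_range: tuple = (0.15, 0.45)   # fraction of family age
    clade_age_decay: tuple = (0.5, 0.85)    # per-level fraction of parent age
    coupling: float = 0.9          # trait-vs-soil R^2 target
    env_noise_sd: float = 0.15     # SD of soil noise on the unit gradient
    abundance_meanlog: float = 1.0
    abundance_sdlog: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if len(self.richness_schedule) != self.n_levels:
            raise ValueError("richness schedule length must equal n_levels")
        if len(self.lambda_schedule) != self.n_levels:
            raise ValueError("lambda schedule length must equal n_levels")
        if max(self.richness_schedule) > self.pool_size:
            raise ValueError("richness exceeds pool size")
        if min(self.richness_schedule) < 1:
            raise ValueError("richness schedule must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        entropy = 0 if self.seed is None else self.seed
        return np.random.default_rng(
            np.random.SeedSequence(entropy=entropy, spawn_key=(stream,))
        )


def generate_backbone(config: GeneratorConfig):
    """Family/genus backbone, taxonomy and node ages for the species pool.

    Families are nested into a random binary arrangement of named,
    dated order-level clades (a star of families would make every
    inter-family distance identical and flatten the phylogenetic signal),
    genera sit inside families, and the species pool is spread over the
    genera so every genus holds at least one species. Returns the undated
    backbone Phylogeny, a TaxonomyTable covering the pool, and an AgeTable
    naming the root, every order-level clade, family and genus.
    """
    rng = config.rng(0)
    lo, hi = config.genera_per_family
    genera_counts = rng.integers(lo, hi + 1, size=config.n_families)

    families = [f"Family{f + 1:02d}" for f in range(config.n_families)]
    genera, genus_family = [], {}
    for fam, count in zip(families, genera_counts):
        for g in range(count):
            name = f"Genus{len(genera) + 1:02d}"
            genera.append(name)
            genus_family[name] = fam

    # spread the species pool over genera: each genus gets >= 1 species
    n_genera = len(genera)
    extra = rng.multinomial(
        max(config.pool_size - n_genera, 0), np.full(n_genera, 1.0 / n_genera)
    )
    records = []
    for g_idx, genus in enumerate(genera):
        for s in range(1 + int(extra[g_idx])):
            sp = f"{genus}_sp{s + 1:02d}"
            records.append(
                {"species": sp, "genus": genus, "family": genus_family[genus]}
            )
    records = records[: config.pool_size]
    taxonomy = TaxonomyTable(pd.DataFrame(records))

    ages = {"root": config.root_age}
    for fam in families:
        ages[fam] = config.root_age * rng.uniform(*config.family_age_range)
    for genus in genera:
        ages[genus] = ages[genus_family[genus]] * rng.uniform(*config.genus_age_range)

    # random binary joins of family clades into named order-level nodes;
    # ages assigned root-down with geometric decay so deep divergences are
    # spread over time (a ladder of near-root joins would collapse most
    # inter-family distances onto 2 * root age and flatten the signal)
    subtrees = [(fam, None) for fam in families]  # (newick payload key, children)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        subtrees.append((None, (left, right)))
    n_join = 0

    def assign(node, parent_age):
        nonlocal n_join
        key, children = node
        if children is None:
            return "(" + ",".join(
                g for g in genera if genus_family[g] == key
            ) + ")" + key

        def oldest_family(sub):
            k, ch = sub
            if ch is None:
                return ages[k]
            return max(oldest_family(ch[0]), oldest_family(ch[1]))

        floor = max(oldest_family(children[0]), oldest_family(children[1]))
        if key is None and parent_age is None:
            name, age = "root", config.root_age
        else:
            n_join += 1
            name = f"Clade{n_join:02d}"
            age = max(floor + 0.05 * (parent_age - floor),
                      parent_age * rng.uniform(*config.clade_age_decay))
            age = min(age, floor + 0.97 * (parent_age - floor))
            ages[name] = age
        left_txt = assign(children[0], age)
        right_txt = assign(children[1], age)
        return f"({left_txt},{right_txt}){name}"

    backbone = parse_newick(assign(subtrees[0], None) + ";")
    return backbone, taxonomy, AgeTable(ages)


def _assemble_quadrat(dist, depth, richness, lam, rng) -> np.ndarray:
    """Sequential weighted assembly of one quadrat's species indices."""
    pool = dist.shape[0]
    first = int(rng.integers(pool))
    picked = [first]
    dist_sum = dist[:, first].copy()
    available = np.ones(pool, dtype=bool)
    available[first] = False
    for _ in range(richness - 1):
        mean_d = dist_sum / len(picked)
        weights = np.exp(-lam * mean_d / depth)
        weights[~available] = 0.0
        weights /= weights.sum()
        nxt = int(rng.choice(pool, p=weights))
        picked.append(nxt)
        available[nxt] = False
        dist_sum += dist[:, nxt]
    return np.array(sorted(picked), dtype=int)


def generate_communities(tree: Phylogeny, config: GeneratorConfig) -> pd.DataFrame:
    """Quadrat x species abundance matrix along the slope gradient.

    Each quadrat of level L is assembled at the level's scheduled richness:
    the first species uniformly, each later pick with weight proportional
    to exp(-lambda_L * mean patristic distance to the picks so far / tree
    depth). Included species receive log-normal integer abundances.
    """
    dm = tree.patristic_distances()
    species = list(dm.ids)
    dist = dm.data
    depth = tree.root_age()
    rng = config.rng(1)
    rows, labels = [], []
    for lev in range(config.n_levels):
        richness = config.richness_schedule[lev]
        if richness > len(species):
            raise ValueError("richness exceeds pool size")
        lam = config.lambda_schedule[lev]
        for q in range(config.quadrats_per_level):
            idx = _assemble_quadrat(dist, depth, richness, lam, rng)
            abundance = np.zeros(len(species))
            counts = np.maximum(
                1,
                np.round(
                    rng.lognormal(
                        config.abundance_meanlog,
                        config.abundance_sdlog,
                        size=idx.size,
                    )
                ),
            )
            abundance[idx] = counts
            rows.append(abundance)
            labels.append(f"{config.level_names[lev]}{q + 1}")
    return pd.DataFrame(rows, index=labels, columns=species)


def generate_env_traits(communities: pd.DataFrame, config: GeneratorConfig):
    """Sample-level trait and soil tables with a shared monotone gradient.

    Soil factors decline from the first (north) to the last (south) level
    (pH increases); each leaf trait responds linearly to the realized soil
    gradient with the configured coupling (fraction of unit variance
    explained) plus independent noise, then is mapped into field units.
    """
    rng = config.rng(2)
    samples = list(communities.index)
    level_of = {
        s: next(
            i
            for i, name in enumerate(config.level_names)
            if str(s).rstrip("0123456789") == name
        )
        for s in samples
    }
    g = np.array(
        [1.0 - level_of[s] / max(config.n_levels - 1, 1) for s in samples]
    )  # 1 at N, 0 at S

    noisy = {
        f: g + rng.normal(0.0, config.env_noise_sd, size=len(samples))
        for f in SOIL_FACTORS
    }
    env = pd.DataFrame(
        {
            "SWC": 0.15 + 0.25 * noisy["SWC"],
            "STN": 1.0 + 2.0 * noisy["STN"],
            "STP": 0.4 + 0.6 * noisy["STP"],
            "NP": 2.0 + 1.5 * noisy["NP"],
            "SOC": 20.0 + 30.0 * noisy["SOC"],
            "SAN": 50.0 + 100.0 * noisy["SAN"],
            "SAP": 5.0 + 10.0 * noisy["SAP"],
            "pH": 8.2 - 1.2 * noisy["pH"],
        },
        index=samples,
    )

    # latent soil axis actually realized in the noisy table
    z = env.apply(lambda col: (col - col.mean()) / col.std(ddof=1))
    latent = (z.drop(columns=["pH", "NP"]).mean(axis=1) - z["pH"]).values
    latent = (latent - latent.mean()) / latent.std(ddof=1)

    c = float(np.clip(config.coupling, 0.0, 1.0))
    traits = {}
    for trait in TRAITS:
        sign, mean, sd = _TRAIT_SPEC[trait]
        signal = sign * np.sqrt(c) * latent
        noise = np.sqrt(1.0 - c) * rng.normal(size=len(samples))
        traits[trait] = mean + sd * (signal + noise)
    trait_table = pd.DataFrame(traits, index=samples)
    trait_table["LDMC"] = trait_table["LDMC"].clip(0.05, 0.95)
    trait_table["LWC"] = trait_table["LWC"].clip(1.0, 99.0)
    return trait_table, env


def generate_dataset(config: GeneratorConfig | None = None) -> dict:
    """Run the whole generator: backbone -> graft -> bladj -> communities -> tables."""
    config = config or GeneratorConfig()
    backbone, taxonomy, ages = generate_backbone(config)
    supertree = graft_supertree(backbone, taxonomy, taxonomy.species)
    dated = bladj(supertree, ages)
    communities = generate_communities(dated, config)
    traits, env = generate_env_traits(communities, config)
    return {
        "config": config,
        "backbone": backbone,
        "taxonomy": taxonomy,
        "ages": ages,
        "tree": dated,
        "communities": communities,
        "traits": traits,
        "env": env,
    }


def write_fixtures(outdir, config: GeneratorConfig | None = None) -> dict:
    """Write every generated input as plain-text files plus a manifest."""
    config = config or GeneratorConfig()
    data = generate_dataset(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data["backbone"].write(outdir / "backbone.nwk")
    data["tree"].write(outdir / "supertree_dated.nwk")
    data["taxonomy"].write(outdir / "taxonomy.tsv")
    data["ages"].write(outdir / "ages.tsv")
    data["communities"].to_csv(outdir / "comm.tsv", sep="\t")
    data["traits"].to_csv(outdir / "traits.tsv", sep="\t")
    data["env"].to_csv(outdir / "env.tsv", sep="\t")
    manifest = {
        "seed": config.seed,
        "pool_size": config.pool_size,
        "richness_schedule": list(config.richness_schedule),
        "lambda_schedule": list(config.lambda_schedule),
        "files": [
            "backbone.nwk",
            "supertree_dated.nwk",
            "taxonomy.tsv",
            "ages.tsv",
            "comm.tsv",
            "traits.tsv",
            "env.tsv",
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return data
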