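"""Null-model randomization and standardized effect sizes (NRI / NTI).

The null model is the phylogeny-pool, richness-preserving randomization:
each sample's species identities are replaced by a uniform draw, of the same
richness, from all tips of the phylogeny. Observed MPD (or MNTD) is
standardized against the null distribution with the ecologist's sign flip,

    NRI = -1 * (MPD_obs - mean(MPD_null)) / sd(MPD_null),

so positive values mean phylogenetic clustering and negative values
overdispersion. Significance uses a two-sided rank p-value; communities are
classified clustered / overdispersed / random at a chosen alpha.

The model/results pair is the main entry point::

    model = CommunityStructureModel(tree, comm, metric="mpd")
    res = model.fit(replicates=999, seed=42)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import sample_taxa
from .tree import Phylogeny, normalize_name

__all__ = [
    "NullSpec",
    "null_draw",
    "ses_metric",
    "classify",
    "CommunityStructureModel",
    "CommunityStructureResults",
]

_METRIC_COLUMN = {"mpd": "NRI", "mntd": "NTI"}


@dataclass
class NullSpec:
    """Configuration of the null-model randomization."""

    model: str = "phylogeny_pool"
    replicates: int = 999
    seed: int | None = None

    def __post_init__(self):
        if self.model not in {"phylogeny_pool", "sample_pool"}:
            raise ValueError(f"unknown null model: {self.model!r}")
        if self.replicates < 99:
            raise ValueError("need >= 99 replicates for p-value reporting")


def _draw_indices(pool_size: int, richness: int, n_draws: int, rng) -> np.ndarray:
    """(n_draws, richness) index array; each row a uniform subset w/o replacement."""
    if richness > pool_size:
        raise ValueError(
            f"richness {richness} exceeds pool size {pool_size}"
        )
    keys = rng.random((n_draws, pool_size))
    part = np.argpartition(keys, richness - 1, axis=1)[:, :richness]
    return np.sort(part, axis=1)


def null_draw(pool, richness: int, rng) -> set:
    """One richness-preserving uniform draw from the phylogeny pool."""
    pool = sorted(pool)
    if richness < 2:
        raise ValueError("richness must be >= 2")
    idx = _draw_indices(len(pool), richness, 1, rng)[0]
    return {pool[i] for i in idx}


def _mpd_rows(dist: np.ndarray, idx: np.ndarray) -> np.ndarray:
    r = idx.shape[1]
    sub = dist[idx[:, :, None], idx[:, None, :]]
    return sub.sum(axis=(1, 2)) / (r * (r - 1))


def _mntd_rows(dist: np.ndarray, idx: np.ndarray) -> np.ndarray:
    r = idx.shape[1]
    sub = dist[idx[:, :, None], idx[:, None, :]].copy()
    sub[:, np.arange(r), np.arange(r)] = np.inf
    return sub.min(axis=2).mean(axis=1)


_METRIC_FUNC = {"mpd": _mpd_rows, "mntd": _mntd_rows}


def rank_p_value(null_values: np.ndarray, observed: float) -> float:
    """Two-sided rank p with the +1 correction; never exactly zero."""
    r = int((null_values < observed).sum())
    n = null_values.size
    p = 2.0 * min(r + 1, n - r + 1) / (n + 1)
    return min(p, 1.0)


def classify(nri: float, p: float, alpha: float = 0.05) -> str:
    """clustered if NRI>0 and p<alpha; overdispersed if NRI<0 and p<alpha; else random."""
    if np.isnan(nri):
        return "undefined"
    if p < alpha and nri > 0:
        return "clustered"
    if p < alpha and nri < 0:
        return "overdispersed"
    return "random"


class CommunityStructureModel:
    """Phylogenetic community structure of samples against a null model.

    Parameters
    ----------
    tree : Phylogeny
        Dated phylogeny whose tips define the species pool.
    communities : pandas.DataFrame
        Sample x species abundance/presence matrix.
    metric : {"mpd", "mntd"}
        Observed statistic; MPD is standardized to NRI, MNTD to NTI.
    null_model : {"phylogeny_pool", "sample_pool"}
        Pool used by the randomization: all tree tips (default) or only the
        species observed anywhere in the matrix.
    weighted : bool
        Abundance-weighted observed MPD (null draws stay presence-based).
    """

    def __init__(
        self,
        tree: Phylogeny,
        communities: pd.DataFrame,
        metric: str = "mpd",
        null_model: str = "phylogeny_pool",
        weighted: bool = False,
    ):
        metric = metric.lower()
        if metric not in _METRIC_FUNC:
            raise ValueError(f"metric must be one of {sorted(_METRIC_FUNC)}")
        self.tree = tree
        self.communities = communities
        self.metric = metric
        self.null_model = null_model
        self.weighted = weighted

        dm = tree.patristic_distances()
        self._ids = list(dm.ids)
        self._dist = dm.data
        self._pos = {normalize_name(i): k for k, i in enumerate(self._ids)}

        tipset = set(self._pos)
        used = [s for s in communities.columns if (communities[s] > 0).any()]
        unknown = sorted(s for s in used if normalize_name(s) not in tipset)
        if unknown:
            raise ValueError(
                "species in community matrix absent from tree: "
                + ", ".join(unknown)
            )
        if null_model == "phylogeny_pool":
            self._pool = np.arange(len(self._ids))
        else:
            self._pool = np.array(
                sorted({self._pos[normalize_name(s)] for s in used}), dtype=int
            )

    def fit(
        self,
        replicates: int = 999,
        seed: int | None = None,
        alpha: float = 0.05,
    ) -> "CommunityStructureResults":
        """Run the randomization and return per-sample SES results.

        Each sample gets its own random stream derived from (seed, sample
        index), so adding samples never perturbs the draws of others.
        """
        spec = NullSpec(self.null_model, replicates, seed)
        metric_rows = _METRIC_FUNC[self.metric]
        col = _METRIC_COLUMN[self.metric]
        rows = []
        excluded = []
        for i, sample in enumerate(self.communities.index):
            taxa = sample_taxa(self.communities, sample)
            if len(taxa) < 2:
                excluded.append(sample)
                continue
            idx_obs = np.array(
                sorted(self._pos[normalize_name(t)] for t in taxa), dtype=int
            )[None, :]
            if self.weighted and self.metric == "mpd":
                row = self.communities.loc[sample]
                w = np.array(
                    [row[t] for t in sorted(taxa, key=lambda t: self._pos[normalize_name(t)])],
                    dtype=float,
                )
                sub = self._dist[np.ix_(idx_obs[0], idx_obs[0])]
                ww = np.outer(w, w)
                np.fill_diagonal(ww, 0.0)
                observed = float((ww * sub).sum() / ww.sum())
            else:
                observed = float(metric_rows(self._dist, idx_obs)[0])

            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(i,))
                if seed is not None
                else None
            )
            draws = self._pool[
                _draw_indices(self._pool.size, len(taxa), replicates, rng)
            ]
            nulls = metric_rows(self._dist, draws)
            mu = float(nulls.mean())
            sd = float(nulls.std(ddof=1))
            if sd <= 0.0:
                warnings.warn(
                    f"degenerate null distribution for sample {sample!r}",
                    stacklevel=2,
                )
                ses = float("nan")
                p = float("nan")
            else:
                ses = -1.0 * (observed - mu) / sd
                p = rank_p_value(nulls, observed)
            rows.append(
                {
                    "sample": sample,
                    "ntaxa": len(taxa),
                    "observed": observed,
                    "null_mean": mu,
                    "null_sd": sd,
                    col: ses,
                    "p_value": p,
                    "classification": classify(ses, p, alpha),
                }
            )
        if excluded:
            warnings.warn(
                f"samples excluded (fewer than 2 taxa): {excluded}", stacklevel=2
            )
        table = pd.DataFrame(rows)
        if not table.empty:
            table = table.set_index("sample")
        return CommunityStructureResults(
            model=self, table=table, spec=spec, alpha=alpha, excluded=excluded
        )


@dataclass
class CommunityStructureResults:
    """Per-sample SES table with null-model provenance."""

    model: CommunityStructureModel
    table: pd.DataFrame
    spec: NullSpec
    alpha: float
    excluded: list = field(default_factory=list)

    @property
    def ses_column(self) -> str:
        return _METRIC_COLUMN[self.model.metric]

    @property
    def ses(self) -> pd.Series:
        return self.table[self.ses_column]

    @property
    def classifications(self) -> pd.Series:
        return self.table["classification"]

    def by_level(self, level_of=None) -> pd.DataFrame:
        """Mean +/- SD of the SES per group of samples (e.g. per slope).

        ``level_of`` maps a sample label to its group; the default strips a
        trailing quadrat number ("N3" -> "N").
        """
        if level_of is None:
            def level_of(s):
                return str(s).rstrip("0123456789") or str(s)
        col = self.ses_column
        df = self.table.copy()
        df["level"] = [level_of(s) for s in df.index]
        grouped = df.groupby("level", sort=False)[col]
        out = grouped.agg(["mean", "std", "count"])
        out.columns = [f"{col}_mean", f"{col}_sd", "n_samples"]
        return out

    def summary(self) -> str:
        col = self.ses_column
        lines = [
            f"Community phylogenetic structure ({col}; "
            f"null model: {self.spec.model}, {self.spec.replicates} replicates, "
            f"alpha={self.alpha})",
            "",
            self.table.round(4).to_string(),
        ]
        if self.excluded:
            lines += ["", f"excluded (<2 taxa): {self.excluded}"]
        counts = self.table["classification"].value_counts().to_dict()
        lines += ["", f"classification counts: {counts}"]
        return "\n".join(lines)


def ses_metric(
    tree: Phylogeny,
    communities: pd.DataFrame,
    metric: str = "mpd",
    spec: NullSpec | None = None,
    alpha: float = 0.05,
    weighted: bool = False,
) -> pd.DataFrame:
    """Functional wrapper: fit a CommunityStructureModel, return its table."""
    spec = spec or NullSpec()
    model = CommunityStructureModel(
        tree, communities, metric=metric, null_model=spec.model, weighted=weighted
    )
    return model.fit(replicates=spec.replicates, seed=spec.seed, alpha=alpha).table
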