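"""End-to-end orchestration: graft -> bladj -> diversity -> SES -> ordination.

``run_pipeline`` is a pure function of its inputs and seed: rerunning with
the same configuration writes byte-identical tables. Every stage failure is
re-raised as a :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .diversity import diversity_table
from .errors import PipelineError
from .io import read_community_matrix, read_table, write_table
from .nullmodels import CommunityStructureModel
from .ordination import PCAOrdination, RDAOrdination
from .supertree import AgeTable, TaxonomyTable, bladj, graft_supertree
from .tree import Phylogeny

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """File paths and analysis settings for one pipeline run."""

    backbone: str
    taxonomy: str
    ages: str
    communities: str
    outdir: str
    traits: str | None = None
    env: str | None = None
    metric: str = "mpd"
    null_model: str = "phylogeny_pool"
    replicates: int = 999
    seed: int | None = None
    alpha: float = 0.05
    weighted: bool = False
    include_root_pd: bool = True
    hellinger: bool = True
    pca_axes: int = 4
    rda_axes: int = 4

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def input_paths(self):
        paths = {
            "backbone": self.backbone,
            "taxonomy": self.taxonomy,
            "ages": self.ages,
            "communities": self.communities,
        }
        if self.traits:
            paths["traits"] = self.traits
        if self.env:
            paths["env"] = self.env
        return paths


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis and write its report bundle to ``outdir``.

    Artifacts: supertree_dated.nwk, diversity.tsv, ses_quadrat.tsv,
    ses_by_level.tsv, pca_summary.tsv (+ scores), rda_summary.tsv
    (+ scores, when trait/env tables are given), run_log.txt.
    """
    for name, path in config.input_paths().items():
        if not Path(path).exists():
            raise PipelineError(f"stage 'inputs' failed: missing {name} file {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    backbone = _stage("read_backbone")(Phylogeny.read, config.backbone)
    taxonomy = _stage("read_taxonomy")(TaxonomyTable.from_file, config.taxonomy)
    ages = _stage("read_ages")(AgeTable.from_file, config.ages)
    comm = _stage("read_communities")(read_community_matrix, config.communities)

    species = [s for s in comm.columns if (comm[s] > 0).any()]
    supertree = _stage("graft")(graft_supertree, backbone, taxonomy, species)
    dated = _stage("bladj")(bladj, supertree, ages)
    dated.write(outdir / "supertree_dated.nwk")

    div = _stage("diversity")(
        diversity_table, dated, comm, include_root=config.include_root_pd
    )
    write_table(div.round(6), outdir / "diversity.tsv", index_label="sample")

    def _ses():
        model = CommunityStructureModel(
            dated,
            comm,
            metric=config.metric,
            null_model=config.null_model,
            weighted=config.weighted,
        )
        return model.fit(
            replicates=config.replicates, seed=config.seed, alpha=config.alpha
        )

    ses_res = _stage("ses")(_ses)
    write_table(ses_res.table.round(6), outdir / "ses_quadrat.tsv", index_label="sample")
    write_table(ses_res.by_level().round(6), outdir / "ses_by_level.tsv",
                index_label="level")

    pca_res = _stage("pca")(
        lambda: PCAOrdination(comm, hellinger_transform=config.hellinger).fit(
            config.pca_axes
        )
    )
    write_table(pca_res.summary(), outdir / "pca_summary.tsv", index_label="")
    write_table(pca_res.site_scores.round(6), outdir / "pca_site_scores.tsv",
                index_label="sample")

    results = {"tree": dated, "diversity": div, "ses": ses_res, "pca": pca_res}
    if config.traits and config.env:
        traits = _stage("read_traits")(read_table, config.traits)
        env = _stage("read_env")(read_table, config.env)
        rda_res = _stage("rda")(
            lambda: RDAOrdination(traits, env).fit(config.rda_axes)
        )
        write_table(rda_res.summary(), outdir / "rda_summary.tsv", index_label="")
        write_table(rda_res.site_scores.round(6), outdir / "rda_site_scores.tsv",
                    index_label="sample")
        results["rda"] = rda_res

    log = [
        f"phylostruct {__version__} (python {sys.version.split()[0]})",
        f"inputs: {config.input_paths()}",
        f"seed: {config.seed}",
        f"null model: {config.null_model}, replicates: {config.replicates}, "
        f"alpha: {config.alpha}",
        f"metric: {config.metric}, abundance-weighted: {config.weighted}",
        f"Faith's PD root-inclusive: {config.include_root_pd}",
        f"PCA Hellinger transform: {config.hellinger}",
        f"samples excluded from SES (<2 taxa): {ses_res.excluded}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return results
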