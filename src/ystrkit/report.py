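"""End-to-end report bundle: the full analysis pipeline on one table.

Produces, in an output directory: per-population + pooled diversity
summaries (JSON and TSV), the per-population gene-diversity matrix,
pairwise FST and permutation p-value matrices, raw and Bonferroni
p-values, a two-level AMOVA table over all populations, MDS coordinates
of the (clamped) FST matrix, and a machine-readable run manifest. The
bundle is byte-identical across reruns with the same inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import DistanceModel, amova_two_level, pairwise_fst_matrix
from .data import Dataset
from .diversity import POOLED_SCOPE, gd_matrix, summarize
from .errors import ConfigError, YstrError
from .io import write_matrix_tsv
from .mds import classical_mds

__all__ = ["RunConfig", "run_report"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one report run."""

    outdir: Path
    model: DistanceModel = DistanceModel.identity
    B: int = 10_000
    seed: int | None = None
    mds_dims: int = 2
    combine_dys385: bool = False
    extra: dict = field(default_factory=dict)  # recorded in the manifest

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.seed is None:
            raise ConfigError("seed is required for a report run")


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except YstrError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return wrapped
    return decorator


@_stage("summarize")
def _write_summaries(ds: Dataset, outdir: Path) -> list[dict]:
    summaries = [summarize(pop, ds.panel) for pop in ds.populations]
    summaries.append(summarize(ds))
    rounded = [s.rounded() for s in summaries]
    (outdir / "summary.json").write_text(
        json.dumps(rounded, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )
    rows = [
        {k: r[k] for k in ("scope", "n", "h", "HD", "DC", "HMP")} for r in rounded
    ]
    pd.DataFrame(rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    return rounded


@_stage("gd-matrix")
def _write_gd(ds: Dataset, outdir: Path, combine: bool) -> pd.DataFrame:
    gd = gd_matrix(ds, combine_dys385=combine)
    write_matrix_tsv(gd.round(3), outdir / "gd_matrix.tsv", float_format="%.3f")
    return gd


@_stage("compare")
def _write_fst(ds: Dataset, cfg: RunConfig, outdir: Path):
    fst = pairwise_fst_matrix(ds, model=cfg.model, B=cfg.B, seed=cfg.seed)
    write_matrix_tsv(fst.values, outdir / "fst.tsv")
    write_matrix_tsv(fst.pvalues, outdir / "fst_pvalues.tsv")
    write_matrix_tsv(fst.bonferroni(), outdir / "fst_pvalues_bonferroni.tsv")
    amova = amova_two_level(ds.populations, ds.panel, cfg.model)
    amova.as_table().to_csv(outdir / "amova.tsv", sep="\t", index=False)
    return fst, amova


@_stage("mds")
def _write_mds(fst, cfg: RunConfig, outdir: Path):
    k = len(fst.population_ids)
    m = min(cfg.mds_dims, k - 1)
    emb = classical_mds(fst.clamped(), m=m)
    emb.coordinates.to_csv(outdir / "mds.tsv", sep="\t")
    return emb


def run_report(ds: Dataset, cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest dictionary."""
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("report: %d populations, N=%d, model=%s, B=%d, seed=%d",
             len(ds.populations), ds.N, cfg.model.value, cfg.B, cfg.seed)

    rounded = _write_summaries(ds, outdir)
    _write_gd(ds, outdir, cfg.combine_dys385)
    fst, amova = _write_fst(ds, cfg, outdir)
    emb = _write_mds(fst, cfg, outdir)

    pooled = next(r for r in rounded if r["scope"] == POOLED_SCOPE)
    manifest = {
        "ystrkit_version": __version__,
        "seed": cfg.seed,
        "B": cfg.B,
        "distance_model": cfg.model.value,
        "mds_dims": emb.m,
        "combine_dys385": cfg.combine_dys385,
        "populations": ds.population_ids,
        "N": ds.N,
        "pooled": {k: pooled[k] for k in ("n", "h", "HD", "DC", "HMP")},
        "amova_phi": amova.phi,
        "mds_goodness": emb.goodness,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
        **({"parameters": cfg.extra} if cfg.extra else {}),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest
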