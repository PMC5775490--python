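"""Stage orchestration: config-driven runs with a written manifest.

Stages run in dependency order (simulate -> qc -> structure/pcnm ->
gf/gdm -> offset); each stage reads its inputs from the output directory,
so stages can also be run one at a time across separate invocations.  A
run is fully determined by (config, seed, inputs) and records all three in
``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    EnvRaster,
    GenotypeMatrix,
    LandgenError,
    SampleTable,
    read_genotypes,
    read_raster,
    read_sample_table,
    write_genotypes,
    write_raster,
    write_sample_table,
)
from .synthetic_landscape import SimConfig, make_env_rasters, simulate_genotypes
from .genotype_qc import FilterConfig, filter_genotypes
from .popgen_structure import admixture_em, cv_choose_k, diversity_stats, pairwise_fst, pca
from .spatial_pcnm import pcnm, retain_half
from .gradient_forest import ForestConfig, GfModel, fit_gf, gf_importance_split, gf_transform
from .gdm_model import GdmModel, IsplineBasis, build_site_pairs, fit_gdm, gdm_importance
from .offset_mapping import gdm_offset, gf_offset, rgb_map

logger = logging.getLogger("landgen")

STAGE_ORDER = ["simulate", "qc", "structure", "pcnm", "gf", "gdm", "offset"]


@dataclass
class RunManifest:
    pipeline_version: str
    config: dict
    seed: int
    stages: list[str]
    input_checksums: dict
    started: str
    finished: str = ""

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _need(outdir: Path, fname: str, producer: str):
    p = outdir / fname
    if not p.exists():
        raise LandgenError(
            f"missing artifact {fname!r}; run the {producer!r} stage first"
        )
    return p


def _load_rasters(outdir: Path) -> tuple[dict, EnvRaster]:
    mask = read_raster(_need(outdir, "mask.asc", "simulate"))
    rasters: dict[str, tuple[EnvRaster, EnvRaster]] = {}
    for cur in sorted(outdir.glob("env_*_current.asc")):
        name = cur.name[len("env_") : -len("_current.asc")]
        fut = outdir / f"env_{name}_future.asc"
        rasters[name] = (read_raster(cur), read_raster(fut) if fut.exists() else read_raster(cur))
    if not rasters:
        raise LandgenError("no env_*_current.asc rasters; run the 'simulate' stage first")
    return rasters, mask


def _load_genotypes(outdir: Path, filtered: bool = True) -> GenotypeMatrix:
    fname = "genotypes_filtered.tsv" if filtered else "genotypes.tsv"
    producer = "qc" if filtered else "simulate"
    return read_genotypes(_need(outdir, fname, producer), "dosage012")


def _env_at_samples(
    rasters: dict, table: SampleTable, which: int = 0
) -> pd.DataFrame:
    coords = table.coords(table.df["sample_id"])
    return pd.DataFrame(
        {
            name: [pair[which].value_at(x, y) for x, y in coords]
            for name, pair in rasters.items()
        },
        index=list(table.df["sample_id"]),
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: dict, outdir: Path, seed: int) -> None:
    sim = SimConfig(**{**cfg.get("simulate", {}), "seed": seed})
    rasters, mask = make_env_rasters(sim)
    gm, truth, table = simulate_genotypes(sim, rasters=rasters, mask=mask)
    write_genotypes(gm, outdir / "genotypes.tsv")
    write_sample_table(table, outdir / "samples.csv")
    write_raster(mask, outdir / "mask.asc")
    for name, (cur, fut) in rasters.items():
        write_raster(cur, outdir / f"env_{name}_current.asc")
        write_raster(fut, outdir / f"env_{name}_future.asc")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "F_true": truth.F_true.tolist(),
                "Q_true": truth.Q_true.tolist(),
                "cline_center": truth.cline_center,
                "cline_slope": truth.cline_slope,
                "adaptive_locus_ids": truth.adaptive_locus_ids,
                "neutral_locus_ids": truth.neutral_locus_ids,
            },
            fh,
        )


def _stage_qc(cfg: dict, outdir: Path, seed: int) -> None:
    gm = _load_genotypes(outdir, filtered=False)
    fc = FilterConfig(**cfg.get("qc", {}))
    out, report = filter_genotypes(gm, fc)
    write_genotypes(out, outdir / "genotypes_filtered.tsv")
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(report, fh, indent=1)


def _stage_structure(cfg: dict, outdir: Path, seed: int) -> None:
    gm = _load_genotypes(outdir)
    table = read_sample_table(_need(outdir, "samples.csv", "simulate"))
    sc = cfg.get("structure", {})
    K_range = sc.get("K_range", [1, 2, 3, 4, 5])
    curve = cv_choose_k(
        gm, K_range, folds=sc.get("folds", 5),
        mask_frac=sc.get("mask_frac", 0.1), seed=seed,
        n_restarts=sc.get("n_restarts", 1),
    )
    with open(outdir / "cv_curve.json", "w") as fh:
        json.dump(
            {"curve": curve.table.reset_index().to_dict("records"),
             "argmin_k": curve.argmin_k},
            fh, indent=1,
        )
    fit = admixture_em(gm, curve.argmin_k, seed=seed)
    pd.DataFrame(
        fit.Q, index=fit.sample_ids,
        columns=[f"Q{k + 1}" for k in range(fit.K)],
    ).to_csv(outdir / "admixture_Q.tsv", sep="\t")
    if table.df["group"].nunique() >= 2:
        pairwise_fst(gm, table).to_frame().to_csv(outdir / "fst.tsv", sep="\t")
    diversity_stats(gm, table).table.to_csv(outdir / "diversity.tsv", sep="\t")
    pca(gm).to_frame().to_csv(outdir / "pca_scores.tsv", sep="\t")


def _stage_pcnm(cfg: dict, outdir: Path, seed: int) -> None:
    table = read_sample_table(_need(outdir, "samples.csv", "simulate"))
    basis = pcnm(
        table.coords(table.df["sample_id"]),
        sample_ids=list(table.df["sample_id"]),
    )
    preds = retain_half(basis, rounding=cfg.get("pcnm", {}).get("rounding", "ceil"))
    preds.index.name = "sample_id"
    preds.to_csv(outdir / "pcnm.tsv", sep="\t")


def _stage_gf(cfg: dict, outdir: Path, seed: int) -> None:
    gm = _load_genotypes(outdir)
    table = read_sample_table(_need(outdir, "samples.csv", "simulate"))
    rasters, _mask = _load_rasters(outdir)
    pcnm_tab = pd.read_csv(
        _need(outdir, "pcnm.tsv", "pcnm"), sep="\t", index_col=0
    )
    env = _env_at_samples(rasters, table)
    predictors = env.join(pcnm_tab)
    fc = ForestConfig(**{**cfg.get("gf", {}), "seed": seed})
    model = fit_gf(gm, predictors, fc)
    model.to_json(outdir / "gf_model.json")
    with open(outdir / "gf_importance.json", "w") as fh:
        json.dump(
            {"importance": model.importance,
             "split": gf_importance_split(model)},
            fh, indent=1,
        )


def _stage_gdm(cfg: dict, outdir: Path, seed: int) -> None:
    gm = _load_genotypes(outdir)
    table = read_sample_table(_need(outdir, "samples.csv", "simulate"))
    rasters, _mask = _load_rasters(outdir)
    env = _env_at_samples(rasters, table)
    spt = build_site_pairs(gm, table, env)
    basis = IsplineBasis.from_site_pairs(
        spt, n_splines=cfg.get("gdm", {}).get("n_splines", 3)
    )
    model = fit_gdm(spt, basis, include_geo=cfg.get("gdm", {}).get("include_geo", True))
    model.to_json(outdir / "gdm_model.json")
    with open(outdir / "gdm_importance.json", "w") as fh:
        json.dump(
            {"importance": gdm_importance(model).to_dict(),
             "pct_deviance_explained": model.pct_deviance_explained},
            fh, indent=1,
        )


def _stage_offset(cfg: dict, outdir: Path, seed: int) -> None:
    rasters, mask = _load_rasters(outdir)
    current = {n: pair[0] for n, pair in rasters.items()}
    future = {n: pair[1] for n, pair in rasters.items()}
    drop = tuple(cfg.get("offset", {}).get("drop", ["substrate_age"]))
    gf_path = outdir / "gf_model.json"
    gdm_path = outdir / "gdm_model.json"
    if not gf_path.exists() and not gdm_path.exists():
        raise LandgenError(
            "offset stage needs a fitted model; run the 'gf' or 'gdm' stage first"
        )
    if gf_path.exists():
        gf_model = GfModel.from_json(gf_path)
        og = gf_offset(gf_model, current, future, mask, drop=drop)
        write_raster(og.raster, outdir / "offset_gf.asc")
        tg = gf_transform(
            gf_model,
            {k: v for k, v in current.items() if k not in drop},
            mask, include_pcnm=False,
        )
        rgb = rgb_map(tg)
        for ch, ras in rgb.to_rasters().items():
            write_raster(ras, outdir / f"rgb_{ch}.asc")
        rgb.to_png(outdir / "rgb_preview.png")
    if gdm_path.exists():
        gdm_mod = GdmModel.from_json(gdm_path)
        og = gdm_offset(gdm_mod, current, future, mask, drop=drop)
        write_raster(og.raster, outdir / "offset_gdm.asc")


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "structure": _stage_structure,
    "pcnm": _stage_pcnm,
    "gf": _stage_gf,
    "gdm": _stage_gdm,
    "offset": _stage_offset,
}


def run_pipeline(
    config_path,
    outdir=None,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> Path:
    """Run the configured stages in dependency order; returns the outdir."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = [s for s in cfg.get("stages", []) if s not in STAGE_ORDER]
    if unknown:
        raise LandgenError(f"unknown stages {unknown}; valid: {STAGE_ORDER}")
    run_stages = stages or cfg.get("stages") or STAGE_ORDER
    run_stages = [s for s in STAGE_ORDER if s in run_stages]
    outdir = Path(outdir or cfg.get("outdir", "landgen_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = cfg.get("seed")
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31))
        print(f"landgen: no seed configured; drew seed {seed}")
    manifest = RunManifest(
        pipeline_version=__version__,
        config=cfg,
        seed=int(seed),
        stages=run_stages,
        input_checksums={config_path.name: _sha256(config_path)},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for stage in run_stages:
        logger.info("running stage %s", stage)
        _STAGES[stage](cfg, outdir, int(seed))
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return outdir
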