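"""End-to-end analysis: diversity profiles, Mantel panel, Arrhenius fits.

``run_all`` reads a YAML config naming the OTU table, metadata and
(optionally) the tree, then executes: optional rarefaction -> alpha
diversity per sample and per site -> Faith PD / NRI when a tree is present
-> Bray-Curtis and environmental distances -> BioENV -> a partial-Mantel
panel (each factor tested controlling for the others) -> Boltzmann-
Arrhenius fits with AIC model selection.  Everything is written to the
output directory as TSV tables plus a JSON report whose provenance block
(seed, config hash, versions) suffices to reproduce every number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alpha_diversity import alpha_profile, chao1
from .matrix_stats import (
    bioenv,
    bray_curtis,
    env_distance,
    mantel,
    partial_mantel,
)
from .mte_models import (
    arrhenius_points,
    fit_linear,
    fit_piecewise,
    fit_quadratic,
    select_model,
)
from .phylo_diversity import nri_profile, read_newick
from .tables_io import pool_by_site, read_metadata, read_otu_table, rarefy

__all__ = ["run_all", "RunReport", "PipelineError"]

log = logging.getLogger("thermodiv.pipeline")

_FITTERS = {
    "linear": fit_linear,
    "quadratic": fit_quadratic,
    "piecewise": fit_piecewise,
}

#: Default partial-Mantel panel: each factor controlling for the others,
#: with total N and total C entering as one joint factor.
_DEFAULT_PANEL = [
    {"factor": ["temperature_c"], "controls": ["precipitation_mm", "ph", "total_n", "total_c"]},
    {"factor": ["precipitation_mm"], "controls": ["temperature_c", "ph", "total_n", "total_c"]},
    {"factor": ["ph"], "controls": ["temperature_c", "precipitation_mm", "total_n", "total_c"]},
    {"factor": ["total_n", "total_c"], "controls": ["temperature_c", "precipitation_mm", "ph"]},
]

_DEFAULTS = {
    "tree": None,
    "rarefy_depth": None,
    "seed": 0,
    "n_perm": 999,
    "n_null": 1000,
    "nri": False,
    "richness": "chao1",
    "models": ["linear", "quadratic", "piecewise"],
    "bioenv_variables": [
        "temperature_c",
        "precipitation_mm",
        "ph",
        "moisture_pct",
        "total_c",
        "total_n",
    ],
    "mantel_panel": _DEFAULT_PANEL,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunReport:
    alpha_sample: pd.DataFrame
    alpha_site: pd.DataFrame
    mantel_panel: pd.DataFrame
    bioenv_ranking: pd.DataFrame | None
    mte_fits: pd.DataFrame
    model_selection: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def _load_config(config_path: Path) -> dict:
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    for key in ("table", "metadata"):
        if key not in cfg:
            raise PipelineError(f"config must name {key!r}")
    base = config_path.parent
    for key in ("table", "metadata", "tree"):
        if cfg.get(key):
            cfg[key] = str((base / cfg[key]).resolve())
    return cfg


def _richness_column(profile: pd.DataFrame, which: str) -> pd.Series:
    if which not in profile.columns:
        raise PipelineError(f"unknown richness measure {which!r}")
    return profile[which]


def run_all(config_path, out_dir) -> RunReport:
    """Run the whole analysis described by a YAML config; see module docs."""
    config_path = Path(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger = logging.getLogger("thermodiv")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        cfg = _load_config(config_path)
        cfg_hash = hashlib.sha256(config_path.read_bytes()).hexdigest()
        seed = int(cfg["seed"])

        meta = _stage("read_metadata")(read_metadata)(cfg["metadata"])
        table = _stage("read_table")(read_otu_table)(cfg["table"], metadata=meta)
        tree = None
        if cfg.get("tree"):
            tree = _stage("read_tree")(read_newick)(cfg["tree"])
        else:
            log.info("no tree configured; skipping Faith PD and NRI")

        if cfg["rarefy_depth"]:
            table = _stage("rarefy")(rarefy)(table, int(cfg["rarefy_depth"]), seed)

        alpha_s = _stage("alpha_sample")(alpha_profile)(table, "sample", tree=tree)
        alpha_site = _stage("alpha_site")(alpha_profile)(table, "site", tree=tree)
        if tree is not None and cfg["nri"]:
            nri_s = _stage("nri_sample")(nri_profile)(
                table, tree, "sample", n_null=int(cfg["n_null"]), seed=seed
            )
            alpha_s = alpha_s.join(nri_s["nri"])
            nri_t = _stage("nri_site")(nri_profile)(
                table, tree, "site", n_null=int(cfg["n_null"]), seed=seed
            )
            alpha_site = alpha_site.join(nri_t["nri"])

        comm = _stage("bray_curtis")(bray_curtis)(table)

        bioenv_rank = None
        variables = [v for v in cfg["bioenv_variables"] if v in meta.table.columns]
        if variables:
            bio = _stage("bioenv")(bioenv)(comm, meta, variables)
            bioenv_rank = bio.ranking.copy()
            bioenv_rank["subset"] = bioenv_rank["subset"].map(lambda s: ",".join(s))

        panel_rows = []
        for entry in cfg["mantel_panel"]:
            factor = entry["factor"]
            controls = entry.get("controls", [])
            if any(v not in meta.table.columns for v in factor + controls):
                log.info("skipping panel row %s: variable missing", factor)
                continue
            dfac = env_distance(meta, factor)
            if controls:
                dctrl = [env_distance(meta, [c]) for c in controls]
                res = _stage("partial_mantel")(partial_mantel)(
                    comm, dfac, dctrl,
                    n_perm=int(cfg["n_perm"]), seed=seed, control_names=controls,
                )
            else:
                res = _stage("mantel")(mantel)(
                    comm, dfac, n_perm=int(cfg["n_perm"]), seed=seed
                )
            panel_rows.append(
                {
                    "factor": ",".join(factor),
                    "controls": ",".join(controls),
                    "r_M": res.r,
                    "p": res.p,
                }
            )
        panel = pd.DataFrame(panel_rows)

        site_meta = meta.site_table()
        fit_rows, sel_frames = [], []
        for level, profile in (("sample", alpha_s), ("site", alpha_site)):
            rich = _richness_column(profile, cfg["richness"])
            temps = (
                meta.table.loc[rich.index, "temperature_c"]
                if level == "sample"
                else site_meta.loc[rich.index, "temperature_c"]
            )
            pts = arrhenius_points(rich.to_numpy(), temps.to_numpy(), units=rich.index)
            fits = []
            for name in cfg["models"]:
                try:
                    fit = _stage(f"fit_{name}_{level}")(_FITTERS[name])(pts)
                except PipelineError as exc:
                    log.info("skipping %s fit at %s level: %s", name, level, exc)
                    continue
                fits.append(fit)
                fit_rows.append(
                    {
                        "level": level,
                        "richness": cfg["richness"],
                        "form": fit.form,
                        "e_a": fit.ea,
                        "r2": fit.r2,
                        "aic": fit.aic,
                        "n_obs": fit.n_obs,
                    }
                )
            if len(fits) >= 2:
                sel = select_model(fits)
                frame = sel.table.copy()
                frame.insert(0, "level", level)
                sel_frames.append(frame)
        mte_fits = pd.DataFrame(fit_rows)
        selection = (
            pd.concat(sel_frames, ignore_index=True) if sel_frames else pd.DataFrame()
        )

        provenance = {
            "config_path": str(config_path),
            "config_sha256": cfg_hash,
            "seed": seed,
            "n_perm": int(cfg["n_perm"]),
            "n_null": int(cfg["n_null"]),
            "rarefy_depth": cfg["rarefy_depth"],
            "thermodiv_version": __version__,
            "tree_used": tree is not None,
        }

        alpha_s.to_csv(out / "alpha_sample.tsv", sep="\t")
        alpha_site.to_csv(out / "alpha_site.tsv", sep="\t")
        panel.to_csv(out / "mantel_panel.tsv", sep="\t", index=False)
        if bioenv_rank is not None:
            bioenv_rank.to_csv(out / "bioenv.tsv", sep="\t", index=False)
        mte_fits.to_csv(out / "mte_fits.tsv", sep="\t", index=False)
        selection.to_csv(out / "model_selection.tsv", sep="\t", index=False)

        report = {
            "provenance": provenance,
            "mantel_panel": panel.to_dict(orient="records"),
            "mte_fits": mte_fits.to_dict(orient="records"),
            "bioenv_best": (
                bioenv_rank.iloc[0].to_dict() if bioenv_rank is not None else None
            ),
        }
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
        )
        log.info("report written to %s", out)
        return RunReport(
            alpha_sample=alpha_s,
            alpha_site=alpha_site,
            mantel_panel=panel,
            bioenv_ranking=bioenv_rank,
            mte_fits=mte_fits,
            model_selection=selection,
            provenance=provenance,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
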