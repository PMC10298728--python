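"""File-based pipeline: simulate -> adjust -> grm -> fit -> cv -> report.

Every stage reads its inputs from, and writes its outputs to, a single
artifact directory, so each stage is independently runnable and
inspectable.  A manifest records the package version, the resolved
configuration, all derived seeds and the SHA-256 checksum of every
artifact; reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import PartitionScheme, family_parent_map, random_cv, report, scheme_cv
from .design import (
    adjust,
    adjust_all,
    anova_and_lsd,
    compute_correction_factors,
    generation_contrasts,
    validate_design,
)
from .gblup import GBLUP
from .grm import GRM, build_grm
from .io import DosageMatrix, FieldTrial, impute_missing, read_dosage_csv, write_dosage_csv
from .simulate import StudyDesignConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "PipelineError", "RunConfig", "run_pipeline", "STAGES"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class PipelineError(RuntimeError):
    """Stage failure at run time (CLI exit code 3)."""


_ALLOWED = {
    "": {"seed", "outdir", "log_level", "simulate", "grm", "fit", "cv"},
    "simulate": {
        "n_founders",
        "n_loci",
        "maf_min",
        "n_blocks",
        "test_plots_per_block",
        "s1_family_sizes",
        "f1_family_sizes",
        "f1_crosses",
        "double_reduction_alpha",
    },
    "grm": {"method", "maf_min"},
    "fit": {"method", "traits", "n_burn_in", "n_samples"},
    "cv": {"n_reps", "train_fraction", "traits"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with per-stage parameter blocks."""

    seed: int = 1
    outdir: str = "tetrablup_out"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    grm: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _ALLOWED[""]
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section in ("simulate", "grm", "fit", "cv"):
            block = raw.get(section) or {}
            if not isinstance(block, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            bad = set(block) - _ALLOWED[section]
            if bad:
                raise ConfigError(
                    f"unknown keys in config section {section!r}: {sorted(bad)}"
                )
        return cls(
            seed=int(raw.get("seed", 1)),
            outdir=str(raw.get("outdir", "tetrablup_out")),
            log_level=str(raw.get("log_level", "INFO")),
            simulate=dict(raw.get("simulate") or {}),
            grm=dict(raw.get("grm") or {}),
            fit=dict(raw.get("fit") or {}),
            cv=dict(raw.get("cv") or {}),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_mapping(raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "log_level": self.log_level,
            "simulate": self.simulate,
            "grm": self.grm,
            "fit": self.fit,
            "cv": self.cv,
        }


DEMO_CONFIG = {
    "seed": 7,
    "simulate": {"n_loci": 300, "s1_family_sizes": 40, "f1_family_sizes": 40},
    "cv": {"n_reps": 10},
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _update_manifest(outdir: Path, stage: str, files: list[Path], extra: dict | None = None):
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else
        {"package": "tetrablup", "version": __version__, "stages": {}}
    )
    manifest["stages"][stage] = {
        "files": {f.name: _sha256(f) for f in files},
        **(extra or {}),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(outdir: Path, name: str, producer: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise PipelineError(
            f"missing artifact {name!r} in {outdir}; run the {producer!r} stage first"
        )
    return p


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    names = ["simulate", "fit", "cv"]
    return {n: int(s.generate_state(1)[0] % 2**31) for n, s in zip(names, ss.spawn(3))}


# ----------------------------------------------------------------- stages
def stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    from .simulate import GameteModel

    seeds = _stage_seeds(cfg.seed)
    params = dict(cfg.simulate)
    alpha = params.pop("double_reduction_alpha", 0.0)
    if "f1_crosses" in params:
        params["f1_crosses"] = tuple(tuple(c) for c in params["f1_crosses"])
    if isinstance(params.get("s1_family_sizes"), list):
        params["s1_family_sizes"] = tuple(params["s1_family_sizes"])
    if isinstance(params.get("f1_family_sizes"), list):
        params["f1_family_sizes"] = tuple(params["f1_family_sizes"])
    try:
        study = StudyDesignConfig(seed=seeds["simulate"], **params)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulate config invalid: {exc}") from exc
    dm, trial, pedigree = simulate_study(study, gamete_model=GameteModel(alpha))
    files = []
    write_dosage_csv(dm, outdir / "dosages.csv")
    files.append(outdir / "dosages.csv")
    trial.write_tsv(outdir / "trial.tsv")
    files.append(outdir / "trial.tsv")
    pedigree.to_csv(outdir / "pedigree.csv", index=False)
    files.append(outdir / "pedigree.csv")
    meta = {
        "seed": cfg.seed,
        "stage_seed": seeds["simulate"],
        "double_reduction_alpha": alpha,
        "n_individuals": dm.n_individuals,
        "n_loci": dm.n_loci,
    }
    (outdir / "simulate_meta.json").write_text(json.dumps(meta, indent=2))
    files.append(outdir / "simulate_meta.json")
    _update_manifest(outdir, "simulate", files, {"seed": seeds["simulate"]})
    return files


def stage_adjust(cfg: RunConfig, outdir: Path) -> list[Path]:
    trial = FieldTrial.read_tsv(_require(outdir, "trial.tsv", "simulate"))
    pedigree = pd.read_csv(
        _require(outdir, "pedigree.csv", "simulate"), keep_default_na=False
    )
    adjusted = adjust_all(trial)
    adjusted.index.name = "entry"
    files = [outdir / "adjusted.tsv"]
    adjusted.to_csv(files[0], sep="\t")
    check_rule = validate_design(len(trial.checks), trial.n_blocks)
    stats = {"design_rule": {"passed": bool(check_rule), "message": check_rule.message}}
    for trait in trial.traits:
        an = anova_and_lsd(trial, trait)
        adj = adjust(trial, compute_correction_factors(trial, trait))
        gc = generation_contrasts(adj, pedigree, anova=an)
        stats[trait] = {
            "mse": an.mse,
            "df_error": an.df_error,
            "lsd_0_05": an.lsd_0_05,
            "lsd_cases": an.lsd,
            "group_means": gc.group_means,
            "contrasts": {
                k: {"estimate": c.estimate, "se": c.se, "p": c.p_value}
                for k, c in gc.contrasts.items()
            },
            "proportional_inbreeding_depression": gc.proportional_inbreeding_depression,
            "heterosis": gc.heterosis,
        }
    p = outdir / "anova.json"
    p.write_text(json.dumps(stats, indent=2))
    files.append(p)
    _update_manifest(outdir, "adjust", files)
    return files


def stage_grm(cfg: RunConfig, outdir: Path) -> list[Path]:
    path = _require(outdir, "dosages.csv", "simulate")
    try:
        dm = read_dosage_csv(path)
    except ValueError as exc:
        raise PipelineError(f"grm stage: {exc}") from exc
    dm = impute_missing(dm)
    g = build_grm(
        dm,
        method=cfg.grm.get("method", "full_tetraploid"),
        maf_min=float(cfg.grm.get("maf_min", 0.01)),
    )
    files = [outdir / "grm.csv", outdir / "grm_long.tsv"]
    g.write_csv(files[0])
    g.write_long_tsv(files[1])
    _update_manifest(
        outdir, "grm", files, {"method": g.method, "n_loci_used": g.n_loci_used}
    )
    return files


def _load_fit_inputs(outdir: Path):
    g = GRM.read_csv(_require(outdir, "grm.csv", "grm"))
    adjusted = pd.read_csv(
        _require(outdir, "adjusted.tsv", "adjust"), sep="\t", index_col=0
    )
    common = [i for i in g.ids if i in adjusted.index]
    idx = [g.ids.index(i) for i in common]
    K = g.values[np.ix_(idx, idx)]
    return K, adjusted.loc[common], common


def stage_fit(cfg: RunConfig, outdir: Path) -> list[Path]:
    seeds = _stage_seeds(cfg.seed)
    K, adjusted, ids = _load_fit_inputs(outdir)
    traits = cfg.fit.get("traits") or list(adjusted.columns)
    method = cfg.fit.get("method", "reml")
    out = {}
    for trait in traits:
        if trait not in adjusted.columns:
            raise ConfigError(f"fit: unknown trait {trait!r}")
        model = GBLUP(
            method=method,
            seed=seeds["fit"],
            n_burn_in=int(cfg.fit.get("n_burn_in", 1000)),
            n_samples=int(cfg.fit.get("n_samples", 2000)),
        )
        fit = model.fit(K, adjusted[trait].to_numpy())
        d = fit.to_dict()
        d["ids"] = ids
        out[trait] = d
    p = outdir / "fits.json"
    p.write_text(json.dumps(out, indent=2))
    _update_manifest(outdir, "fit", [p], {"method": method, "seed": seeds["fit"]})
    return [p]


def stage_cv(cfg: RunConfig, outdir: Path) -> list[Path]:
    seeds = _stage_seeds(cfg.seed)
    K, adjusted, ids = _load_fit_inputs(outdir)
    pedigree = pd.read_csv(
        _require(outdir, "pedigree.csv", "simulate"), keep_default_na=False
    )
    ped = pedigree.set_index("id")
    offspring = [i for i in ids if i in ped.index and ped.loc[i, "generation"] != "S0"]
    oidx = [ids.index(i) for i in offspring]
    families = [ped.loc[i, "family"] for i in offspring]
    fam_parents = family_parent_map(pedigree)
    scheme = PartitionScheme(
        n_reps=int(cfg.cv.get("n_reps", 50)),
        train_fraction=float(cfg.cv.get("train_fraction", 0.7)),
        seed=seeds["cv"],
    )
    traits = cfg.cv.get("traits") or list(adjusted.columns)
    Ko = K[np.ix_(oidx, oidx)]
    matrices = []
    overall = {}
    for trait in traits:
        y = adjusted.loc[offspring, trait].to_numpy()
        res = random_cv(y, Ko, scheme, ids=offspring)
        overall[trait] = {"mean": res.mean, "sd": res.sd, "n_reps": scheme.n_reps}
        m = scheme_cv(
            y, Ko, families, fam_parents, trait=trait, scheme=scheme, ids=offspring
        )
        matrices.append(m)
    paths = report(matrices, outdir)
    p = outdir / "random_cv.json"
    p.write_text(json.dumps(overall, indent=2))
    files = [Path(paths["table"]), Path(paths["reps"]), p]
    _update_manifest(outdir, "cv", files, {"seed": seeds["cv"]})
    return files


def stage_report(cfg: RunConfig, outdir: Path) -> list[Path]:
    anova = json.loads(_require(outdir, "anova.json", "adjust").read_text())
    acc = pd.read_csv(_require(outdir, "accuracy.tsv", "cv"), sep="\t", na_values=["NA"])
    summary = {
        "design_rule": anova.pop("design_rule"),
        "traits": {
            t: {
                "group_means": v["group_means"],
                "lsd_0_05": v["lsd_0_05"],
                "contrast_p": {k: c["p"] for k, c in v["contrasts"].items()},
                "proportional_inbreeding_depression": v[
                    "proportional_inbreeding_depression"
                ],
            }
            for t, v in anova.items()
        },
        "accuracy_by_relatedness": {
            str(k): (None if pd.isna(v) else float(v))
            for k, v in acc.groupby("relatedness")["accuracy"].mean().items()
        },
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2))
    lines = ["trait\tS0\tS1\tF1\tLSD_0.05\tp(S0 vs S1)\tp(S0 vs F1)\tp(S1 vs F1)"]
    for t, v in summary["traits"].items():
        gm = v["group_means"]
        cp = v["contrast_p"]
        lines.append(
            f"{t}\t{gm['S0']:.3g}\t{gm['S1']:.3g}\t{gm['F1']:.3g}\t"
            f"{v['lsd_0_05']:.3g}\t{cp['S0_vs_S1']:.2g}\t{cp['S0_vs_F1']:.2g}\t"
            f"{cp['S1_vs_F1']:.2g}"
        )
    table = outdir / "summary_table.tsv"
    table.write_text("\n".join(lines) + "\n")
    _update_manifest(outdir, "report", [p, table])
    return [p, table]


STAGES = {
    "simulate": stage_simulate,
    "adjust": stage_adjust,
    "grm": stage_grm,
    "fit": stage_fit,
    "cv": stage_cv,
    "report": stage_report,
}
_ORDER = ["simulate", "adjust", "grm", "fit", "cv", "report"]


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute every stage in order; returns the artifact directory."""
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    for name in _ORDER:
        logger.info("stage %s", name)
        STAGES[name](cfg, outdir)
    return outdir
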