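"""Pipeline chaining simulate -> estimate-gm -> fit-aci -> fit-temp -> effects -> report.

Each stage reads the CSVs the previous stage wrote, so any stage can also
be pointed at real instrument exports.  A run manifest (seed, package
version, constants hash, output checksums) makes replays verifiable:
rerunning with the same config reproduces every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import calibration as cal
from . import io as wio
from .aci import fit_aci
from .effects import factorial_anova, percent_change, significance_stars, tukey_letters
from .isotope import estimate_gm_table
from .synthetic import (ExperimentConfig, generate_aci_curves, generate_design,
                        generate_gas_exchange, generate_isotope_obs,
                        generate_temperature_campaign, generate_traits,
                        derived_leaf_indices)
from .tempresp import (TempSeries, build_table1, fit_arrhenius, fit_parabola,
                       fit_peaked, fit_q10, fit_quadratic)

log = logging.getLogger("wheatphys")

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths, seed and generator settings for one pipeline run."""

    outdir: str
    seed: int
    n_per_cell: int = 10
    noise_cv_traits: float = 0.10
    noise_cv_gas: float = 0.05
    max_aci_fits: int = 16       # cap per run to keep the stage quick
    campaign_reps: int = 5
    campaign_noise_cv: float = 0.03
    log_level: str = "INFO"

    def experiment(self) -> ExperimentConfig:
        return ExperimentConfig(seed=self.seed, n_per_cell=self.n_per_cell,
                                noise_cv_traits=self.noise_cv_traits,
                                noise_cv_gas=self.noise_cv_gas)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _constants_hash() -> str:
    payload = json.dumps(
        {"cultivars": {k: asdict(v) for k, v in cal.CULTIVARS.items()},
         "effects": cal.EFFECTS, "baselines": cal.SCOUT_BASELINES},
        sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    exp = cfg.experiment()
    design = generate_design(exp)
    paths = {
        "design": out / "design.csv",
        "gas_exchange": out / "gas_exchange.csv",
        "aci": out / "aci_curves.csv",
        "isotope": out / "isotope.csv",
        "traits": out / "traits.csv",
        "campaign": out / "temperature_campaign.csv",
    }
    design.to_csv(paths["design"], index=False)
    wio.write_gas_exchange(generate_gas_exchange(design, exp),
                           paths["gas_exchange"])
    wio.write_aci_curves(generate_aci_curves(design, exp), paths["aci"])
    wio.write_isotope(generate_isotope_obs(design, exp), paths["isotope"])
    wio.write_traits(derived_leaf_indices(generate_traits(design, exp)),
                     paths["traits"])
    generate_temperature_campaign(
        exp, n_rep=cfg.campaign_reps,
        noise_cv=cfg.campaign_noise_cv).to_csv(paths["campaign"], index=False)
    return paths


def stage_estimate_gm(cfg: PipelineConfig, out: Path) -> Path:
    iso_path = out / "isotope.csv"
    if not iso_path.exists():
        raise StageError("estimate-gm: missing isotope file "
                         f"{iso_path} (run simulate first or supply one)")
    df = estimate_gm_table(wio.read_isotope(iso_path))
    res = out / "gm_estimates.csv"
    df.to_csv(res, index=False)
    return res


def stage_fit_aci(cfg: PipelineConfig, out: Path) -> Path:
    curves = wio.read_aci_curves(out / "aci_curves.csv")
    meta = pd.read_csv(out / "aci_curves.csv").drop_duplicates("plant_id")
    meta = meta.set_index("plant_id")
    rows = []
    for pid in list(curves)[: cfg.max_aci_fits]:
        try:
            fit = fit_aci(curves[pid])
            rows.append({"plant_id": pid,
                         "cultivar": meta.loc[pid, "cultivar"],
                         "co2": meta.loc[pid, "co2"], "hs": meta.loc[pid, "hs"],
                         "Vcmax": fit.Vcmax, "Jmax": fit.Jmax, "rss": fit.rss,
                         "se_Vcmax": fit.se_Vcmax, "se_Jmax": fit.se_Jmax,
                         "converged": fit.converged,
                         "fit_method": "joint-least-squares",
                         "fit_axis": fit.fit_axis})
        except Exception as exc:  # keep other curves going
            log.warning("A-Ci fit failed for %s: %s", pid, exc)
    res = out / "aci_fits.csv"
    pd.DataFrame(rows).to_csv(res, index=False)
    return res


def stage_fit_temp(cfg: PipelineConfig, out: Path) -> Path:
    camp = pd.read_csv(out / "temperature_campaign.csv")
    tables = []
    for cvname, grp in camp.groupby("cultivar"):
        def series(par):
            g = grp[grp["parameter"] == par]
            return TempSeries(parameter=par, Tleaf=g["Tleaf"].to_numpy(),
                              value=g["value"].to_numpy(), cultivar=cvname)
        fits = {
            "Vcmax": fit_arrhenius(series("Vcmax")),
            "Jmax": fit_peaked(series("Jmax")),
            "Rd": fit_arrhenius(series("Rd")),
            "Rd_q10": fit_q10(series("Rd")),
            "Asat": fit_parabola(series("Asat")),
            "gm": fit_quadratic(series("gm")),
        }
        tables.append(build_table1(fits, cultivar=cvname))
    res = out / "table1.csv"
    pd.concat(tables, ignore_index=True).to_csv(res, index=False)
    return res


#: (trait, treatment filter, reference filter, label) contrasts reported
#: by the effects stage.
def _default_contrasts(exp: ExperimentConfig):
    a, e = exp.ambient_co2, exp.elevated_co2
    return [
        ("total_dry_mass", "T3",
         dict(cultivar="Yitpi", co2=a, hs="Control"),
         dict(cultivar="Scout", co2=a, hs="Control"),
         "Yitpi vs Scout biomass, aCO2 control, anthesis"),
        ("total_dry_mass", "T3",
         dict(cultivar="Yitpi", co2=e, hs="Control"),
         dict(cultivar="Yitpi", co2=a, hs="Control"),
         "eCO2 biomass stimulation, Yitpi control, anthesis"),
        ("grain_number", "T4",
         dict(cultivar="Scout", co2=e, hs="Control"),
         dict(cultivar="Scout", co2=a, hs="Control"),
         "eCO2 grain number stimulation, Scout control, maturity"),
        ("grain_protein", "T4",
         dict(cultivar="Yitpi", co2=e, hs="Control"),
         dict(cultivar="Yitpi", co2=a, hs="Control"),
         "eCO2 grain protein change, Yitpi control, maturity"),
    ]


def _select(df, timepoint, **cell):
    m = df["timepoint"] == timepoint
    for k, v in cell.items():
        m &= df[k] == v
    return df.loc[m]


def stage_effects(cfg: PipelineConfig, out: Path) -> tuple[Path, Path]:
    traits = wio.read_traits(out / "traits.csv")
    exp = cfg.experiment()
    rows = []
    for trait, tp, cell_t, cell_r, label in _default_contrasts(exp):
        t = _select(traits, tp, **cell_t)[trait].dropna()
        r = _select(traits, tp, **cell_r)[trait].dropna()
        est = percent_change(t, r, B=2000, seed=cfg.seed)
        rows.append({"contrast": label, "trait": trait, "timepoint": tp,
                     "percent": est.percent, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "n_treat": est.n_treat,
                     "n_ref": est.n_ref})
    effects_path = out / "effects.csv"
    pd.DataFrame(rows).to_csv(effects_path, index=False)

    anova_frames = []
    t4 = traits[traits["timepoint"] == "T4"]
    for trait in ("total_dry_mass", "grain_number", "grain_N"):
        tab = factorial_anova(t4, trait).reset_index(names="term")
        tab.insert(0, "trait", trait)
        tab["stars"] = [significance_stars(p) if np.isfinite(p) else ""
                        for p in tab["PR(>F)"]]
        anova_frames.append(tab)
    anova_path = out / "anova.csv"
    pd.concat(anova_frames, ignore_index=True).to_csv(anova_path, index=False)

    # Tukey letters on T4 grain number cell means (cultivar x CO2, control).
    ctl = t4[t4["hs"] == "Control"]
    cells = ctl.groupby(["cultivar", "co2"])["grain_number"]
    means = {f"{c}@{int(co2)}": m for (c, co2), m in cells.mean().items()}
    mse = float((cells.var(ddof=1) * (cells.count() - 1)).sum()
                / (cells.count() - 1).sum())
    nh = len(means) / (1.0 / cells.count()).sum()
    letters = tukey_letters(means, mse, int((cells.count() - 1).sum()), nh)
    cm = cells.mean().reset_index().rename(columns={"grain_number": "mean"})
    cm["letters"] = [letters[f"{c}@{int(co2)}"]
                     for c, co2 in zip(cm["cultivar"], cm["co2"])]
    cm.to_csv(out / "grain_number_letters.csv", index=False)
    return effects_path, anova_path


def stage_report(cfg: PipelineConfig, out: Path) -> Path:
    lines = ["# Synthetic experiment pipeline report", ""]
    for name in ("table1.csv", "effects.csv", "anova.csv"):
        p = out / name
        if p.exists():
            lines.append(f"## {name}\n")
            lines.append(pd.read_csv(p).to_markdown(index=False))
            lines.append("")
    report = out / "report.md"
    report.write_text("\n".join(lines))

    outputs = sorted(p for p in out.glob("*.csv"))
    manifest = {
        "seed": cfg.seed,
        "n_per_cell": cfg.n_per_cell,
        "package_version": __version__,
        "constants_sha256": _constants_hash(),
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return report


_STAGES = ("simulate", "estimate-gm", "fit-aci", "fit-temp", "effects",
           "report")


def run_pipeline(cfg: PipelineConfig,
                 stages: tuple[str, ...] = _STAGES) -> Path:
    """Run the requested stages in dependency order; returns the out dir.

    A stage failure halts the run with the stage name; outputs written by
    earlier stages persist.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    funcs = {
        "simulate": stage_simulate,
        "estimate-gm": stage_estimate_gm,
        "fit-aci": stage_fit_aci,
        "fit-temp": stage_fit_temp,
        "effects": stage_effects,
        "report": stage_report,
    }
    for name in _STAGES:
        if name not in stages:
            continue
        log.info("stage %s", name)
        try:
            funcs[name](cfg, out)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    return out
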