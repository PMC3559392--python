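"""Run configuration and the end-to-end pipeline driver.

``RunConfig`` is a flat, YAML-serializable record of every knob the pipeline
exposes; unspecified fields take the documented defaults.  ``run_all``
executes the stages in method order — energy completion → millimolar
adjustment → FBA → weights → balance — and writes all module outputs plus a
manifest (config echo, stage counts, solver metadata, checksums) into a run
directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import balance as balance_mod
from . import fba as fba_mod
from . import infer as infer_mod
from . import model_io, synthetic, thermo, weights as weights_mod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs carry a FAILED marker."""


@dataclass
class RunConfig:
    # inputs
    model_path: str | None = None
    model_format: str = "tabular"
    formation_table: str | None = None
    reaction_table: str | None = None
    media_path: str | None = None
    out_dir: str = "thermoweight_run"
    # synthetic fallback when no model path is given
    synthetic_spec: dict = field(default_factory=dict)
    # thermodynamics
    temperature: float = 298.0
    gas_constant: float = thermo.R_KCAL
    default_conc: float = 1e-3
    special_conc: dict = field(
        default_factory=lambda: {"h2": 0.000034, "o2": 0.000055}
    )
    excluded_compounds: list = field(default_factory=lambda: ["h2o", "h"])
    energy_unit: str = "kcal/mol"
    # solvers
    sv_cutoff: float = infer_mod.DEFAULT_SV_CUTOFF
    minimize_total_flux: bool = False
    strict_minimal_media: bool = True
    # weights
    bin_edges: list = field(default_factory=lambda: list(weights_mod.DEFAULT_BIN_EDGES))
    zero_tol: float = weights_mod.ZERO_TOL
    extreme_scopes: list = field(default_factory=lambda: ["<-200", ">40"])
    # misc
    strict: bool = False
    seed: int = 0

    def adjustment_config(self) -> thermo.AdjustmentConfig:
        return thermo.AdjustmentConfig(
            R=self.gas_constant,
            T=self.temperature,
            default_conc=self.default_conc,
            special_conc=dict(self.special_conc),
            excluded_compounds=frozenset(self.excluded_compounds),
            energy_unit=self.energy_unit,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Execute the whole pipeline; returns the run directory.

    Any stage error leaves the outputs written so far next to a ``FAILED``
    marker file and re-raises as :class:`PipelineError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}
    try:
        # ---- load or synthesize the model -------------------------------
        if config.model_path:
            model = model_io.load_model(config.model_path, config.model_format)
            if not model.reaction_class:
                model_io.classify_reactions(model)
            tables = thermo.EnergyTables()
            if config.formation_table:
                thermo.load_energy_table(config.formation_table, "formation",
                                         model, config.strict, tables)
            if config.reaction_table:
                thermo.load_energy_table(config.reaction_table, "reaction",
                                         model, config.strict, tables)
        else:
            spec = synthetic.SyntheticSpec(
                **{"seed": config.seed, **config.synthetic_spec}
            )
            result = synthetic.generate(spec)
            model, tables = result.model, result.masked
            manifest["stages"]["synthetic"] = {
                "masked_compounds": len(result.masked_compounds),
                "constraint_rank": result.constraint_rank,
            }
        manifest["stages"]["model"] = model.summary()

        # ---- completion --------------------------------------------------
        tables, problem, report = infer_mod.complete_energies(
            model, tables, sv_cutoff=config.sv_cutoff
        )
        manifest["stages"]["infer"] = {
            "n_unknown_compounds": problem.n_unknown,
            "n_equations": len(problem.usable_rows),
            "rank": problem.rank,
            "residual_norm": problem.residual_norm(),
            "weakly_determined": problem.weakly_determined,
        }
        report.to_csv(out / "consistency_report.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "compound": problem.X_ids,
                "value": problem.X0,
                "weakly_determined": [
                    c in problem.weakly_determined for c in problem.X_ids
                ],
            }
        ).to_csv(out / "inferred_formation_energies.tsv", sep="\t", index=False)

        # ---- millimolar adjustment ---------------------------------------
        cfg = config.adjustment_config()
        thermo.adjust_all(model, tables, cfg)
        thermo.write_energy_tables(tables, model,
                                   out / "completed_reaction_energies.tsv")

        # ---- FBA ---------------------------------------------------------
        problem_fba = fba_mod.FluxProblem(model)
        if config.media_path:
            media_df = pd.read_csv(config.media_path, sep="\t")
            media = {
                r.reaction_id: (float(r.lb), float(r.ub))
                for r in media_df.itertuples(index=False)
            }
            problem_fba = fba_mod.apply_media(
                problem_fba, media, config.strict_minimal_media
            )
        flux = fba_mod.solve_fba(problem_fba, config.minimize_total_flux)
        if flux.solver_status != "optimal":
            raise PipelineError(f"FBA status: {flux.solver_status}")
        v = flux.as_dict(model)
        pd.DataFrame(
            {"reaction_id": model.reaction_ids, "flux": flux.v}
        ).to_csv(out / "fluxes.tsv", sep="\t", index=False)
        manifest["stages"]["fba"] = {
            "objective_value": flux.objective_value, **flux.metadata,
        }

        # ---- weights -----------------------------------------------------
        scope = model.reactions_of_class("internal")
        w = weights_mod.compute_weights(tables.dGm, v, scope, config.zero_tol)
        w.rename_axis("reaction_id").reset_index().to_csv(
            out / "weights.tsv", sep="\t", index=False
        )
        hist = weights_mod.bin_weights(w, tuple(config.bin_edges), config.zero_tol)
        hist.to_csv(out / "weight_histogram.tsv", sep="\t", index=False)
        extremes = weights_mod.extreme_reactions(w, list(config.extreme_scopes))
        scatter, r_coef, p_val = weights_mod.scatter_and_correlation(
            w, pd.Series(v).reindex(w.index)
        )
        scatter.rename_axis("reaction_id").reset_index().to_csv(
            out / "scatter_w_v.tsv", sep="\t", index=False
        )
        weights_mod.export_graph(model, w, out / "weighted_network.graphml")
        manifest["stages"]["weights"] = {
            "histogram": dict(zip(hist["scope"], hist["count"].astype(int))),
            "extremes": extremes,
            "pearson_r": r_coef,
            "pearson_p": p_val,
            "zero_tolerance": config.zero_tol,
        }

        # ---- balance -----------------------------------------------------
        classes = dict(zip(model.reaction_ids, model.reaction_class))
        bal = balance_mod.energy_balance(
            tables.dGm, v, classes, config.energy_unit, flux.metadata
        )
        balance_mod.write_balance(bal, out / "balance.tsv")
        manifest["stages"]["balance"] = {
            "G_env": bal.G_env,
            "G_sys": bal.G_sys,
            "G_phy": bal.G_phy,
            "chemical_fraction_pct": bal.chemical_fraction_pct,
            "physical_fraction_pct": bal.physical_fraction_pct,
            "unit": f"{bal.energy_unit}*gDW^-1*h^-1",
        }
    except Exception as exc:
        (out / "FAILED").write_text(str(exc))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(str(exc)) from exc

    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    manifest["units_note"] = (
        f"energies {config.energy_unit}; fluxes mmol*gDW^-1*h^-1; "
        "weights/balance kcal*gDW^-1*h^-1; classes internal/exchange/biomass, "
        "biomass excluded from balance sums"
    )

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=_default))
    logger.info("pipeline complete: outputs in %s", out)
    return out
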