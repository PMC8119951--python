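"""End-to-end pipeline orchestration over a run directory.

Stages: simulate -> preprocess (probe-level normalization chain, optional) ->
per-group DEG tests -> cross-cohort consistency selection -> combined PCA /
PC1 metrics -> RDFS reduction -> persistence -> external-cohort validation ->
covariate regression.  Every stage writes its artifacts (TSV/JSON) into the
run directory and records its parameters and output hashes in a
machine-readable manifest, so re-running with the same config and seed
reproduces the run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .consistency import overlap_summary, select_consistent_degs
from .containers import ComparisonGroup, ConfigurationError, DataError
from .discriminant import (
    PC1Discriminant,
    combine_groups,
    fit_pc1_model,
    minmax_rescale,
    roc_metrics,
    separation_test,
)
from .preprocess import demographic_match_check, group_deg_test, normalize_chain
from .rdfs import persistence_curve_export, run_search
from .regression import RegressionSpec, compute_vif, fit_gene_regressions, _dummy_design
from .simulate import (
    SimulationConfig,
    SyntheticStudy,
    config_from_dict,
    config_to_dict,
    generate_probe_level,
    generate_study,
    generate_validation_group,
    read_study,
    write_study,
)
from .validation import direction_concordance, impute_missing_genes, project_cohort

STAGES = (
    "simulate",
    "preprocess",
    "degs",
    "select",
    "pc1",
    "rdfs",
    "persist",
    "validate",
    "regress",
)


@dataclass
class PipelineConfig:
    """Schema-validated configuration of a full run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    probe_level: bool = False      # route expression through the probe-level chain
    probes_per_gene: int = 2
    n_control_probes: int = 10
    n_unmapped: int = 10
    alpha: float = 0.05
    min_groups: int = 3
    mode: str = "joint"
    test_variant: str = "student"
    rdfs_runs: int = 10
    rdfs_iterations: int = 50
    test_fraction: float = 0.1
    min_set_size: int = 2
    imputation_mode: str = "label_mean"
    validation_cases: int = 20
    validation_controls: int = 20
    validation_drop_gene: bool = True
    regression_covariates: tuple = ("age", "gender", "group")
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.mode not in ("joint", "independent"):
            raise ConfigurationError(f"unknown selection mode {self.mode!r}")
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError("test_fraction must lie in (0, 1)")
        for name in ("rdfs_runs", "rdfs_iterations", "min_groups", "min_set_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = config_to_dict(self.simulation)
        d["regression_covariates"] = list(self.regression_covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if "regression_covariates" in d:
            d["regression_covariates"] = tuple(d["regression_covariates"])
        return cls(simulation=config_from_dict(sim), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Stage executor bound to one run directory."""

    def __init__(self, rundir: str | Path, config: PipelineConfig):
        config.validate()
        self.rundir = Path(rundir)
        self.rundir.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.manifest_path = self.rundir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"config": config.to_dict(), "stages": {}}
        )

    # -- manifest helpers -------------------------------------------------
    def _record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "params": params,
            "outputs": {str(p.relative_to(self.rundir)): _sha256(p) for p in outputs},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    def _study(self) -> SyntheticStudy:
        sub = "processed" if (self.rundir / "processed" / "config.yaml").exists() else "study"
        return read_study(self.rundir / sub)

    # -- stages -----------------------------------------------------------
    def simulate(self) -> SyntheticStudy:
        study = generate_study(self.config.simulation)
        out = write_study(study, self.rundir / "study")
        self._record(
            "simulate",
            {"seed": self.config.simulation.seed},
            sorted(out.glob("*")),
        )
        return study

    def preprocess(self) -> SyntheticStudy:
        """Probe-level normalization chain; pass-through when disabled."""
        study = read_study(self.rundir / "study")
        if not self.config.probe_level:
            self._record("preprocess", {"probe_level": False}, [])
            return study
        pm = generate_probe_level(
            study,
            probes_per_gene=self.config.probes_per_gene,
            n_control_probes=self.config.n_control_probes,
            n_unmapped=self.config.n_unmapped,
            seed=self.config.seed,
        )
        expr = normalize_chain(pm)
        groups = []
        for g in study.groups:
            groups.append(
                ComparisonGroup(
                    name=g.name,
                    tissue=g.tissue,
                    smoking_status=g.smoking_status,
                    expression=expr.loc[:, g.subjects],
                    labels=g.labels,
                    covariates=g.covariates,
                )
            )
        processed = SyntheticStudy(groups=groups, truth=study.truth, config=study.config)
        out = write_study(processed, self.rundir / "processed")
        self._record(
            "preprocess",
            {"probe_level": True, "probes_per_gene": self.config.probes_per_gene},
            sorted(out.glob("*")),
        )
        return processed

    def degs(self) -> dict:
        study = self._study()
        outdir = self.rundir / "degs"
        outdir.mkdir(exist_ok=True)
        tables, outputs = {}, []
        for g in study.groups:
            t = group_deg_test(g, test_variant=self.config.test_variant)
            path = outdir / f"deg_{g.name}.tsv"
            t.to_csv(path, sep="\t")
            tables[g.name] = t
            outputs.append(path)
            match = demographic_match_check(g)
            mpath = outdir / f"matching_{g.name}.tsv"
            match.to_csv(mpath, sep="\t", index=False)
            outputs.append(mpath)
        self._record("degs", {"test_variant": self.config.test_variant}, outputs)
        return tables

    def _deg_tables(self) -> dict:
        outdir = self.rundir / "degs"
        tables = {}
        for path in sorted(outdir.glob("deg_*.tsv")):
            tables[path.stem.removeprefix("deg_")] = pd.read_csv(path, sep="\t", index_col=0)
        if not tables:
            raise DataError("no DEG tables found; run the degs stage first")
        return tables

    def select(self):
        tables = self._deg_tables()
        cfg = self.config
        selection = select_consistent_degs(
            tables,
            tissue=cfg.simulation.tissue,
            min_groups=cfg.min_groups,
            mode=cfg.mode,
            alpha=cfg.alpha,
        )
        summary = overlap_summary(tables, alpha=cfg.alpha, selection=selection)
        outdir = self.rundir / "selection"
        outdir.mkdir(exist_ok=True)
        ev_path = outdir / "evidence.tsv"
        selection.evidence.to_csv(ev_path, sep="\t")
        genes_path = outdir / "selected_genes.tsv"
        selection.evidence.loc[selection.genes].to_csv(genes_path, sep="\t")
        prov = {
            "alpha": cfg.alpha,
            "mode": cfg.mode,
            "min_groups": cfg.min_groups,
            "n_selected": len(selection.genes),
            "n_up": summary.get("n_up"),
            "n_down": summary.get("n_down"),
            "per_group_significant": summary["per_group"],
            "venn": summary["venn"].to_dict(),
        }
        prov_path = outdir / "provenance.json"
        prov_path.write_text(json.dumps(prov, indent=1, sort_keys=True))
        self._record("select", {"alpha": cfg.alpha, "mode": cfg.mode}, [ev_path, genes_path, prov_path])
        return selection

    def _selected_genes(self) -> list:
        path = self.rundir / "selection" / "selected_genes.tsv"
        if not path.exists():
            raise DataError("no selection found; run the select stage first")
        return list(pd.read_csv(path, sep="\t", index_col=0).index)

    def pc1(self) -> dict:
        study = self._study()
        genes = self._selected_genes()
        combined = combine_groups(study.groups, genes)
        model, scores = fit_pc1_model(combined)
        p_sep, test_name = separation_test(
            model.scores_, combined.labels.to_numpy(), context="standalone"
        )
        metrics = roc_metrics(
            model.orientation_ * model.scores_, combined.labels.to_numpy()
        )
        outdir = self.rundir / "pc1"
        outdir.mkdir(exist_ok=True)
        scores_path = outdir / "scores.tsv"
        scores.to_csv(scores_path, sep="\t")
        model_path = outdir / "model.json"
        model.save(model_path, genes)
        roc_path = outdir / "roc.tsv"
        metrics.roc_table().to_csv(roc_path, sep="\t", index=False)
        summary = {
            "n_genes": len(genes),
            "pc1_variance_ratio": float(model.explained_variance_ratio_[0]),
            "separation_p": p_sep,
            "separation_test": test_name,
            "auc": metrics.auc,
        }
        sum_path = outdir / "summary.json"
        sum_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        self._record("pc1", {"n_genes": len(genes)}, [scores_path, model_path, roc_path, sum_path])
        return summary

    def rdfs(self) -> list:
        study = self._study()
        genes = self._selected_genes()
        combined = combine_groups(study.groups, genes)
        cfg = self.config
        results = run_search(
            combined,
            genes,
            n_runs=cfg.rdfs_runs,
            n_iterations=cfg.rdfs_iterations,
            test_fraction=cfg.test_fraction,
            min_set_size=cfg.min_set_size,
            random_state=cfg.seed,
        )
        outdir = self.rundir / "rdfs"
        outdir.mkdir(exist_ok=True)
        path = outdir / "runs.json"
        path.write_text(json.dumps([r.to_dict() for r in results], indent=1))
        self._record(
            "rdfs",
            {"runs": cfg.rdfs_runs, "iterations": cfg.rdfs_iterations, "seed": cfg.seed},
            [path],
        )
        return results

    def _run_results_raw(self) -> list[dict]:
        path = self.rundir / "rdfs" / "runs.json"
        if not path.exists():
            raise DataError("no RDFS results found; run the rdfs stage first")
        return json.loads(path.read_text())

    def persist(self):
        from .rdfs import PersistenceResult

        raw = self._run_results_raw()
        best_sets = [r["best_genes"] for r in raw]
        current = list(best_sets[0])
        curve = [len(current)]
        for s in best_sets[1:]:
            member = set(s)
            current = [g for g in current if g in member]
            curve.append(len(current))
        pr = PersistenceResult(genes=current, curve=curve)
        outdir = self.rundir / "persist"
        outdir.mkdir(exist_ok=True)
        genes_path = outdir / "persistent_genes.tsv"
        pd.Series(pr.genes, name="gene").to_csv(genes_path, sep="\t", index=False)
        curve_path = outdir / "persistence_curve.tsv"
        persistence_curve_export(pr).to_csv(curve_path, sep="\t", index=False)
        self._record("persist", {"n_runs": len(best_sets)}, [genes_path, curve_path])
        return pr

    def _persistent(self) -> list:
        path = self.rundir / "persist" / "persistent_genes.tsv"
        if not path.exists():
            raise DataError("no persistent set found; run the persist stage first")
        return list(pd.read_csv(path, sep="\t")["gene"])

    def validate_external(self) -> dict:
        study = self._study()
        cfg = self.config
        persistent = self._persistent()
        if len(persistent) < cfg.min_set_size:
            raise DataError("persistent set too small to validate")
        val_group = generate_validation_group(
            cfg.simulation,
            n_cases=cfg.validation_cases,
            n_controls=cfg.validation_controls,
            seed=cfg.seed + 1,
        )
        combined = combine_groups(study.groups, persistent)
        model = PC1Discriminant().fit(
            combined.X.to_numpy(float), combined.labels.to_numpy()
        )
        val_rescaled = minmax_rescale(val_group.expression).T
        available = persistent[1:] if (cfg.validation_drop_gene and len(persistent) > cfg.min_set_size) else persistent
        X_val = val_rescaled.loc[:, available]
        completed, imputed = impute_missing_genes(
            X_val,
            persistent,
            combined,
            labels=val_group.labels,
            mode=cfg.imputation_mode,
        )
        result = project_cohort(
            completed,
            model,
            persistent,
            labels=val_group.labels,
            imputed_genes=imputed,
            imputation_mode=cfg.imputation_mode if imputed else None,
        )
        val_deg = group_deg_test(val_group, test_variant=cfg.test_variant)
        reference = pd.read_csv(
            self.rundir / "selection" / "evidence.tsv", sep="\t", index_col=0
        )["direction"]
        concordance = direction_concordance(val_deg, reference.loc[persistent])
        outdir = self.rundir / "validate"
        outdir.mkdir(exist_ok=True)
        scores_path = outdir / "validation_scores.tsv"
        result.scores.to_csv(scores_path, sep="\t")
        conc_path = outdir / "concordance.tsv"
        concordance.to_csv(conc_path, sep="\t")
        summary = dict(result.to_dict())
        summary["concordant_fraction"] = float(concordance["concordant"].mean())
        sum_path = outdir / "summary.json"
        sum_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        self._record(
            "validate",
            {"imputation_mode": cfg.imputation_mode, "leakage_warning": result.leakage_warning},
            [scores_path, conc_path, sum_path],
        )
        return summary

    def regress(self) -> pd.DataFrame:
        study = self._study()
        persistent = self._persistent()
        expr = pd.concat([g.expression for g in study.groups], axis=1)
        meta = pd.concat(
            [
                g.covariates.assign(group=g.name, label=g.labels)
                for g in study.groups
            ]
        )
        spec = RegressionSpec(
            exposure="fev1_pct_pred",
            covariates=list(self.config.regression_covariates),
        )
        design = _dummy_design(meta, [spec.exposure] + spec.covariates)
        vif = compute_vif(design)
        table = fit_gene_regressions(expr, meta, spec, genes=persistent)
        outdir = self.rundir / "regression"
        outdir.mkdir(exist_ok=True)
        vif_path = outdir / "vif.tsv"
        vif.to_csv(vif_path, sep="\t")
        coef_path = outdir / "coefficients.tsv"
        table.to_csv(coef_path, sep="\t", index=False)
        self._record(
            "regress",
            {"exposure": spec.exposure, "covariates": spec.covariates},
            [vif_path, coef_path],
        )
        return table


def run_pipeline(config: PipelineConfig, rundir: str | Path) -> Path:
    """Execute every stage in order; returns the run directory."""
    run = PipelineRun(rundir, config)
    run.simulate()
    run.preprocess()
    run.degs()
    run.select()
    run.pc1()
    run.rdfs()
    run.persist()
    run.validate_external()
    run.regress()
    return run.rundir
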