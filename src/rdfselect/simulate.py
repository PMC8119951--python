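"""Synthetic multi-cohort case/control expression studies.

Emulates the structure of multi-platform COPD microarray compilations: several
comparison groups per tissue, each with its own additive batch offset per gene,
a set of *planted* genes whose case/control shift has the same sign in every
group, *decoy* genes whose shift flips sign in at least one group, null genes,
Gaussian per-gene noise, and clinical covariates (age, gender, pack-years,
FEV1 % predicted) whose distributions depend on the disease label.

The generator is the ground truth for every downstream stage: the emitted
``truth`` table records each gene's role and per-group shift sign, so recovery
rates (sensitivity of consistency selection, precision of the persistent set)
can be measured exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CASE, CONTROL, ComparisonGroup, ConfigurationError, ProbeMatrix

GENE_ROLES = ("planted", "decoy", "null")


@dataclass
class CovariateModel:
    """Distributional parameters for the clinical covariates.

    Defaults emulate elderly smoker cohorts: cases have markedly lower lung
    function (FEV1 % predicted) and a heavier smoking history.
    """

    fev1_control_mean: float = 95.0   # % predicted
    fev1_case_shift: float = -35.0    # additive shift for cases
    fev1_sd: float = 12.0
    age_mean: float = 64.0            # years
    age_sd: float = 8.0
    prob_male: float = 0.5
    pack_years_mean: float = 45.0
    pack_years_sd: float = 15.0
    pack_years_case_shift: float = 10.0


@dataclass
class SimulationConfig:
    """Configuration of one synthetic study (one tissue).

    ``effect_size`` is the per-gene case/control shift in units of the
    within-group residual SD (``noise_sd``); a ``(lo, hi)`` tuple draws one
    size per effect gene uniformly from the range.
    """

    n_groups: int = 3
    n_genes: int = 500
    n_planted: int = 30
    n_decoy: int = 10
    n_cases_per_group: int = 40
    n_controls_per_group: int = 40
    effect_size: float | tuple[float, float] = 1.0
    batch_sd: float = 0.5     # SD of per-(group, gene) additive offsets, log2 units
    noise_sd: float = 1.0     # residual SD, log2 units
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    tissue: str = "WLT"
    smoking_status: str = "FS"
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_groups", "n_genes", "n_planted", "n_decoy",
                     "n_cases_per_group", "n_controls_per_group"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        if self.n_planted + self.n_decoy > self.n_genes:
            raise ConfigurationError("n_planted + n_decoy exceeds n_genes")
        lo, hi = self._effect_range()
        if lo < 0 or hi < lo:
            raise ConfigurationError(f"effect_size must be >= 0, got {self.effect_size!r}")
        for name in ("batch_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def _effect_range(self) -> tuple[float, float]:
        if isinstance(self.effect_size, (tuple, list)):
            lo, hi = self.effect_size
            return float(lo), float(hi)
        return float(self.effect_size), float(self.effect_size)


@dataclass
class SyntheticStudy:
    """Generated comparison groups plus the per-gene ground truth.

    ``truth`` is indexed by gene with columns ``role`` (planted/decoy/null),
    ``effect`` (shift magnitude in log2 units) and one ``sign_<group>`` column
    per group holding -1/0/+1.
    """

    groups: list[ComparisonGroup]
    truth: pd.DataFrame
    config: SimulationConfig

    @property
    def genes(self) -> pd.Index:
        return self.truth.index

    def genes_with_role(self, role: str) -> list[str]:
        if role not in GENE_ROLES:
            raise ValueError(f"unknown role {role!r}")
        return list(self.truth.index[self.truth["role"] == role])


def _gene_level_truth(config: SimulationConfig, gene_ss: np.random.SeedSequence):
    """Per-gene parameters (baseline, roles, signs, effects) for one study.

    Drawn from the dedicated gene-level stream so that any cohort generated
    for the same config+seed shares the same ground truth.
    """
    rg = np.random.default_rng(gene_ss)
    n_genes = config.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene")
    baseline = rg.normal(config.baseline_mean, config.baseline_sd, n_genes)
    roles = np.array(
        ["planted"] * config.n_planted
        + ["decoy"] * config.n_decoy
        + ["null"] * (n_genes - config.n_planted - config.n_decoy)
    )
    n_effect = config.n_planted + config.n_decoy
    base_sign = rg.choice([-1.0, 1.0], size=n_effect)
    lo, hi = config._effect_range()
    effect_sd_units = rg.uniform(lo, hi, n_effect) if hi > lo else np.full(n_effect, lo)
    effect = np.zeros(n_genes)
    effect[:n_effect] = effect_sd_units * config.noise_sd
    flip_group = rg.integers(0, config.n_groups, size=config.n_decoy)
    base_signs = np.zeros(n_genes)
    base_signs[:n_effect] = base_sign
    return genes, baseline, roles, effect, base_signs, flip_group


def _draw_group(
    config: SimulationConfig,
    rng: np.random.Generator,
    name: str,
    genes: pd.Index,
    baseline: np.ndarray,
    shift: np.ndarray,
    n_cases: int,
    n_controls: int,
) -> ComparisonGroup:
    cm = config.covariates
    n = n_cases + n_controls
    case = np.zeros(n, dtype=bool)
    case[:n_cases] = True
    subjects = pd.Index([f"{name}_S{j:03d}" for j in range(n)], name="subject")
    batch = rng.normal(0.0, config.batch_sd, len(genes))
    x = (
        baseline[:, None]
        + batch[:, None]
        + np.where(case[None, :], shift[:, None], 0.0)
        + rng.normal(0.0, config.noise_sd, (len(genes), n))
    )
    expr = pd.DataFrame(x, index=genes, columns=subjects)
    age = rng.normal(cm.age_mean, cm.age_sd, n)
    gender = np.where(rng.random(n) < cm.prob_male, "male", "female")
    pack_years = rng.normal(cm.pack_years_mean, cm.pack_years_sd, n) + np.where(
        case, cm.pack_years_case_shift, 0.0
    )
    fev1 = rng.normal(cm.fev1_control_mean, cm.fev1_sd, n) + np.where(
        case, cm.fev1_case_shift, 0.0
    )
    covariates = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "pack_years": np.clip(pack_years, 0.0, None),
            "fev1_pct_pred": fev1,
        },
        index=subjects,
    )
    labels = pd.Series(np.where(case, CASE, CONTROL), index=subjects, name="label")
    return ComparisonGroup(
        name=name,
        tissue=config.tissue,
        smoking_status=config.smoking_status,
        expression=expr,
        labels=labels,
        covariates=covariates,
    )


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a multi-group case/control study from ``config``.

    The expression model for gene *i*, group *g*, subject *j* is::

        x = baseline_i + batch_{g,i} + 1[case_j] * sign_{g,i} * effect_i + eps

    with ``eps ~ N(0, noise_sd^2)`` and ``batch_{g,i} ~ N(0, batch_sd^2)``.
    Planted genes keep one sign across all groups; decoy genes flip sign in
    exactly one randomly chosen group; null genes have sign 0.  Identical
    config + seed gives bit-identical output.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    gene_ss, *group_ss = root.spawn(1 + config.n_groups)
    genes, baseline, roles, effect, base_signs, flip_group = _gene_level_truth(
        config, gene_ss
    )
    # per-group, per-gene shift sign: planted constant, decoys flip once, null 0
    signs = np.tile(base_signs, (config.n_groups, 1))
    for d in range(config.n_decoy):
        signs[flip_group[d], config.n_planted + d] *= -1.0

    groups: list[ComparisonGroup] = []
    for g in range(config.n_groups):
        rng = np.random.default_rng(group_ss[g])
        groups.append(
            _draw_group(
                config,
                rng,
                f"{config.tissue}{g + 1}",
                genes,
                baseline,
                signs[g] * effect,
                config.n_cases_per_group,
                config.n_controls_per_group,
            )
        )

    truth = pd.DataFrame({"role": roles, "effect": effect}, index=genes)
    for g, grp in enumerate(groups):
        truth[f"sign_{grp.name}"] = signs[g].astype(int)
    return SyntheticStudy(groups=groups, truth=truth, config=config)


def generate_validation_group(
    config: SimulationConfig,
    n_cases: int = 20,
    n_controls: int = 20,
    seed: int = 1,
    name: str = "VAL1",
) -> ComparisonGroup:
    """Draw an independent cohort from the same gene-level ground truth.

    Shares baseline, effect sizes and planted signs with the study generated
    from ``config`` (decoys carry their unflipped base sign); subjects, batch
    offsets, noise and covariates come from a fresh stream keyed by ``seed``,
    emulating an external validation population.
    """
    config.validate()
    gene_ss = np.random.SeedSequence(config.seed).spawn(1)[0]
    genes, baseline, _, effect, base_signs, _ = _gene_level_truth(config, gene_ss)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 9173, seed)))
    return _draw_group(
        config, rng, name, genes, baseline, base_signs * effect, n_cases, n_controls
    )


def generate_probe_level(
    study: SyntheticStudy,
    probes_per_gene: int = 2,
    n_control_probes: int = 0,
    n_unmapped: int = 0,
    seed: int = 0,
) -> ProbeMatrix:
    """Expand a study's gene-level log2 matrix into probe-level intensities.

    Subjects of all groups are concatenated column-wise.  Probe ``k`` of a
    gene measures ``2 ** (x + a_k)`` with a fixed per-probe affinity offset
    ``a_k`` (``a_0 = 0``); control and unmapped probes carry gene-independent
    lognormal intensities.  The output exercises the probe filters and the
    highest-mean collapse rule.
    """
    if probes_per_gene < 1:
        raise ConfigurationError("probes_per_gene must be >= 1")
    if n_control_probes < 0 or n_unmapped < 0:
        raise ConfigurationError("probe counts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((study.config.seed, seed, 7)))
    expr = pd.concat([g.expression for g in study.groups], axis=1)

    rows, probe_ids, gene_ids, controls = [], [], [], []
    for gene in expr.index:
        x = expr.loc[gene].to_numpy()
        for k in range(probes_per_gene):
            affinity = 0.0 if k == 0 else rng.normal(0.0, 1.0)
            rows.append(np.exp2(x + affinity))
            probe_ids.append(f"{gene}_p{k}")
            gene_ids.append(gene)
            controls.append(False)
    n_samples = expr.shape[1]
    for c in range(n_control_probes):
        rows.append(np.exp2(rng.normal(6.0, 0.5, n_samples)))
        probe_ids.append(f"CTRL_{c:04d}")
        gene_ids.append(None)
        controls.append(True)
    for u in range(n_unmapped):
        rows.append(np.exp2(rng.normal(7.0, 1.0, n_samples)))
        probe_ids.append(f"UNMAPPED_{u:04d}")
        gene_ids.append(None)
        controls.append(False)

    idx = pd.Index(probe_ids, name="probe")
    intensities = pd.DataFrame(np.vstack(rows), index=idx, columns=expr.columns)
    annotation = pd.DataFrame({"gene_id": gene_ids, "is_control": controls}, index=idx)
    return ProbeMatrix(intensities=intensities, annotation=annotation)


# ---------------------------------------------------------------------------
# on-disk representation (TSV matrices + TSV metadata + YAML config)

def write_study(study: SyntheticStudy, directory: str | Path) -> Path:
    """Write a study as TSV matrices, metadata/truth tables and a YAML config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for grp in study.groups:
        grp.expression.to_csv(directory / f"expression_{grp.name}.tsv", sep="\t")
        meta = grp.covariates.copy()
        meta.insert(0, "label", grp.labels)
        meta.insert(0, "group", grp.name)
        meta.insert(2, "tissue", grp.tissue)
        meta.insert(3, "smoking_status", grp.smoking_status)
        meta_rows.append(meta)
    pd.concat(meta_rows).to_csv(directory / "metadata.tsv", sep="\t")
    study.truth.to_csv(directory / "truth.tsv", sep="\t")
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(study.config), fh, sort_keys=True)
    return directory


def read_study(directory: str | Path) -> SyntheticStudy:
    """Read a study written by :func:`write_study`."""
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        config = config_from_dict(yaml.safe_load(fh))
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", index_col=0)
    groups = []
    for name in meta["group"].unique():
        sub = meta[meta["group"] == name]
        expr = pd.read_csv(directory / f"expression_{name}.tsv", sep="\t", index_col=0)
        expr.columns.name = "subject"
        expr.index.name = "gene"
        groups.append(
            ComparisonGroup(
                name=name,
                tissue=str(sub["tissue"].iloc[0]),
                smoking_status=str(sub["smoking_status"].iloc[0]),
                expression=expr,
                labels=sub["label"].rename("label").rename_axis("subject"),
                covariates=sub.drop(columns=["group", "label", "tissue", "smoking_status"])
                .rename_axis("subject"),
            )
        )
    return SyntheticStudy(groups=groups, truth=truth, config=config)


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    if isinstance(d["effect_size"], tuple):
        d["effect_size"] = list(d["effect_size"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    cov = d.pop("covariates", {})
    if isinstance(d.get("effect_size"), list):
        d["effect_size"] = tuple(d["effect_size"])
    return SimulationConfig(covariates=CovariateModel(**cov), **d)
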