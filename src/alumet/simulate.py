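"""Synthetic-data generators with planted ground truth for every stage.

Every generator is a pure function of its parameters and a seed, and
returns the planted truth alongside the data, so each pipeline stage can
be scored without external downloads. Defaults emulate the study
conditions the pipeline targets: blood microarray matrices with
missingness and downregulation concentrated in Alu-inserted genes,
COBRA gel lanes produced by a four-state methylation mixture with
mass-proportional band intensities, and triplicate Ct tables generated
from a true log2 fold change.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import INSERTION_TYPES, AluInsertionTable
from .cobra import (
    FRAGMENT_LENGTHS,
    BandProfile,
    StateMixture,
    add_gel_noise,
    compute_methylation,
    forward_profile,
)
from .expression import ExpressionStudy
from .integration import summaries_frame

__all__ = [
    "DEFAULT_TYPE_FREQUENCIES",
    "DEFAULT_GROUP_MIXTURES",
    "DEFAULT_SUBGROUP_LOG2FC",
    "DEFAULT_COHORT_SIZES",
    "generate_annotation",
    "generate_expression_study",
    "generate_multistudy",
    "generate_cobra_cohort",
    "generate_ct_cohort",
    "generate_methylation_expression_cohort",
    "SCENARIOS",
    "simulate_scenario",
]

#: Per-type insertion frequencies among Alu-inserted genes (intronic
#: dominates; exonic > exonized > promoter).
DEFAULT_TYPE_FREQUENCIES: Dict[str, float] = {
    "exonic": 0.12,
    "exonized": 0.06,
    "intronic": 0.95,
    "promoter": 0.04,
}

#: Fraction of a transcriptome universe carrying at least one Alu insertion
#: (roughly 13.5k of ~22k protein-coding genes).
DEFAULT_ALU_FRACTION = 0.6

#: Group-level methylation-state mixtures (uu, mu=mCuC, um=uCmC, mm) for an
#: LCL cohort: unaffected controls and the three phenotypic subgroups.
DEFAULT_GROUP_MIXTURES: Dict[str, StateMixture] = {
    "control": StateMixture.normalized(0.3383, 0.2176, 0.1871, 0.2570),
    "M": StateMixture.normalized(0.3177, 0.2299, 0.2006, 0.2517),
    "L": StateMixture.normalized(0.3638, 0.2093, 0.1932, 0.2337),
    "S": StateMixture.normalized(0.3464, 0.2043, 0.1788, 0.2706),
}

#: True AluS log2 fold changes per phenotypic subgroup vs matched controls.
DEFAULT_SUBGROUP_LOG2FC: Dict[str, float] = {"M": 0.06, "L": -1.77, "S": 1.88}

#: Cohort sizes: 20 matched controls and 36 cases split into subgroups.
DEFAULT_COHORT_SIZES: Dict[str, int] = {"control": 20, "M": 10, "L": 6, "S": 20}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, StateMixture):
        return list(obj.as_tuple())
    if isinstance(obj, AluInsertionTable):
        return {g: sorted(ts) for g, ts in obj.entries.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def generate_annotation(
    n_genes: int = 1000,
    type_frequencies: Optional[Mapping[str, float]] = None,
    seed=None,
    gene_prefix: str = "G",
) -> AluInsertionTable:
    """Independent per-type Alu membership over ``n_genes`` candidate genes.

    Genes drawing no type are omitted from the table, so with the default
    frequencies nearly every listed gene is intronic and a minority carry
    additional exonic/exonized/promoter insertions.
    """
    freqs = dict(DEFAULT_TYPE_FREQUENCIES if type_frequencies is None else type_frequencies)
    bad = {t: f for t, f in freqs.items() if not 0 <= f <= 1}
    if bad:
        raise ValueError(f"type frequencies must lie in [0, 1]: {bad}")
    rng = _rng(seed)
    genes = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    entries = {}
    draws = {t: rng.random(n_genes) < freqs.get(t, 0.0) for t in INSERTION_TYPES}
    for i, gene in enumerate(genes):
        types = frozenset(t for t in INSERTION_TYPES if draws[t][i])
        if types:
            entries[gene] = types
    return AluInsertionTable(entries)


def _annotation_over_universe(
    genes: Sequence[str], alu_fraction: float, rng: np.random.Generator
) -> AluInsertionTable:
    """Annotation for an expression universe: ``alu_fraction`` of genes are
    Alu-inserted, with conditional per-type frequencies; a gene drawing no
    type defaults to intronic (the overwhelmingly most common type)."""
    n_alu = int(round(alu_fraction * len(genes)))
    alu_genes = rng.choice(len(genes), size=n_alu, replace=False)
    entries = {}
    for i in alu_genes:
        types = frozenset(
            t for t in INSERTION_TYPES if rng.random() < DEFAULT_TYPE_FREQUENCIES[t]
        ) or frozenset({"intronic"})
        entries[genes[i]] = types
    return AluInsertionTable(entries)


def generate_expression_study(
    n_genes: int = 5000,
    n_case: int = 20,
    n_control: int = 20,
    frac_deg: float = 0.05,
    frac_down: float = 0.7,
    alu_down_enrichment: float = 1.0,
    missing_rate: float = 0.1,
    effect_size: float = 3.0,
    alu_fraction: float = DEFAULT_ALU_FRACTION,
    annotation: Optional[AluInsertionTable] = None,
    forced_down: Optional[Set[str]] = None,
    seed=None,
    study_id: str = "SIM1",
) -> Tuple[ExpressionStudy, dict]:
    """Simulate one case-control expression study with planted DEGs.

    Baseline intensities are i.i.d. normal; planted DEGs are shifted by
    ``effect_size`` SD units (down in cases for downregulated genes, up
    for upregulated). Downregulated genes are drawn preferentially from
    Alu-inserted genes with odds multiplier ``alu_down_enrichment``
    (1 = no Alu-DEG association, the enrichment null). Entries go missing
    completely at random at ``missing_rate``.
    """
    rng = _rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    if annotation is None:
        annotation = _annotation_over_universe(genes, alu_fraction, rng)
    alu = annotation.genes
    is_alu = np.array([g in alu for g in genes])

    n_deg = int(round(frac_deg * n_genes))
    n_down = int(round(n_deg * frac_down))
    n_up = n_deg - n_down
    forced = sorted(set(forced_down or ()))
    if len(forced) > n_down:
        raise ValueError("forced_down larger than the planted downregulated set")
    free = np.array([i for i, g in enumerate(genes) if g not in set(forced)])
    weights = np.where(is_alu[free], float(alu_down_enrichment), 1.0)
    down_idx = rng.choice(free, size=n_down - len(forced), replace=False,
                          p=weights / weights.sum())
    down = set(np.array(genes)[down_idx]) | set(forced)
    remaining = [i for i, g in enumerate(genes) if g not in down]
    up_idx = rng.choice(remaining, size=n_up, replace=False)
    up = set(np.array(genes)[up_idx])

    n_samples = n_case + n_control
    values = rng.normal(loc=8.0, scale=1.0, size=(n_genes, n_samples))
    down_mask = np.array([g in down for g in genes])
    up_mask = np.array([g in up for g in genes])
    values[down_mask, :n_case] -= effect_size
    values[up_mask, :n_case] += effect_size
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan

    samples = [f"{study_id}_case{i:03d}" for i in range(n_case)] + [
        f"{study_id}_ctrl{i:03d}" for i in range(n_control)
    ]
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    study = ExpressionStudy(matrix=matrix, groups=groups, study_id=study_id)
    truth = {
        "study_id": study_id,
        "down": down,
        "up": up,
        "alu_genes": alu,
        "annotation": annotation,
        "params": {
            "n_genes": n_genes, "n_case": n_case, "n_control": n_control,
            "frac_deg": frac_deg, "frac_down": frac_down,
            "alu_down_enrichment": alu_down_enrichment,
            "missing_rate": missing_rate, "effect_size": effect_size,
        },
    }
    return study, truth


def generate_multistudy(
    n_studies: int = 4,
    core_size: int = 50,
    alu_down_enrichment: float = 3.0,
    seed=None,
    **study_kwargs,
) -> dict:
    """Simulate several studies sharing one annotation and a planted core
    of Alu-inserted downregulated genes (the reproducibility target).

    Returns a dict with 'studies' (list of ExpressionStudy), 'truths',
    'annotation' and 'core' (the shared gene set, all Alu-inserted and
    planted downregulated in every study).
    """
    rng = _rng(seed)
    n_genes = study_kwargs.pop("n_genes", 5000)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    annotation = _annotation_over_universe(
        genes, study_kwargs.pop("alu_fraction", DEFAULT_ALU_FRACTION), rng
    )
    core = set(rng.choice(sorted(annotation.genes), size=core_size, replace=False))
    studies, truths = [], []
    for k in range(n_studies):
        study, truth = generate_expression_study(
            n_genes=n_genes,
            annotation=annotation,
            forced_down=core,
            alu_down_enrichment=alu_down_enrichment,
            seed=rng,
            study_id=f"SIM{k + 1}",
            **study_kwargs,
        )
        studies.append(study)
        truths.append(truth)
    return {"studies": studies, "truths": truths, "annotation": annotation, "core": core}


def generate_cobra_cohort(
    mixtures_by_group: Optional[Mapping[str, StateMixture]] = None,
    n_per_group: Optional[Mapping[str, int] | int] = None,
    concentration: Optional[float] = 2500.0,
    cv: float = 0.02,
    seed=None,
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate COBRA gel lanes for a grouped cohort.

    Each sample's state mixture is a Dirichlet perturbation of its group
    mixture (``concentration`` scales the Dirichlet; None disables the
    jitter), forward-simulated to band shares and degraded with
    lognormal gel noise of coefficient of variation ``cv``.

    Returns (bands, labels, truth): ``bands`` has columns sample_id,
    b133..b32; ``labels`` maps sample_id to group/subgroup.
    """
    mixtures = dict(DEFAULT_GROUP_MIXTURES if mixtures_by_group is None else mixtures_by_group)
    if n_per_group is None:
        n_per_group = {g: DEFAULT_COHORT_SIZES.get(g, 10) for g in mixtures}
    elif isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in mixtures}
    rng = _rng(seed)
    band_rows, label_rows = [], []
    sample_truth = {}
    for group, mix in mixtures.items():
        for i in range(n_per_group[group]):
            sid = f"{group}{i:02d}"
            if concentration is None:
                p = mix
            else:
                alpha = np.maximum(np.asarray(mix.as_tuple()) * concentration, 1e-9)
                p = StateMixture(*rng.dirichlet(alpha))
            profile = add_gel_noise(forward_profile(p, sample_id=sid), cv=cv, seed=rng)
            band_rows.append([sid] + list(profile.shares))
            label_rows.append(
                {
                    "sample_id": sid,
                    "group": "control" if group == "control" else "case",
                    "subgroup": "none" if group == "control" else group,
                }
            )
            sample_truth[sid] = p
    bands = pd.DataFrame(
        band_rows, columns=["sample_id"] + [f"b{frag}" for frag in FRAGMENT_LENGTHS]
    )
    labels = pd.DataFrame(label_rows)
    truth = {
        "group_mixtures": mixtures,
        "sample_mixtures": sample_truth,
        "params": {"concentration": concentration, "cv": cv,
                   "n_per_group": dict(n_per_group)},
    }
    return bands, labels, truth


def generate_ct_cohort(
    true_log2fc_by_group: Optional[Mapping[str, float]] = None,
    n_per_group: Optional[Mapping[str, int] | int] = None,
    replicate_sd: float = 0.15,
    sample_sd: float = 0.25,
    baseline_dct: float = 5.0,
    ref_ct_mean: float = 18.0,
    ref_ct_sd: float = 0.3,
    n_replicates: int = 3,
    seed=None,
) -> Tuple[pd.DataFrame, dict]:
    """Simulate a triplicate Ct table from true group log2 fold changes.

    Reference Ct is ~ Normal(ref_ct_mean, ref_ct_sd) per sample; each
    sample's true dCt is ``baseline_dct`` minus its group's log2FC
    (controls sit at the baseline) plus Normal(0, sample_sd) biological
    noise; every replicate adds Normal(0, replicate_sd) technical noise.
    """
    if replicate_sd < 0 or sample_sd < 0:
        raise ValueError("noise SDs must be non-negative")
    fcs = dict(DEFAULT_SUBGROUP_LOG2FC if true_log2fc_by_group is None else true_log2fc_by_group)
    groups = ["control"] + [g for g in fcs if g != "control"]
    if n_per_group is None:
        n_per_group = {g: DEFAULT_COHORT_SIZES.get(g, 10) for g in groups}
    elif isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in groups}
    rng = _rng(seed)
    rows = []
    sample_truth = {}
    for group in groups:
        log2fc = 0.0 if group == "control" else float(fcs[group])
        for i in range(n_per_group[group]):
            sid = f"{group}{i:02d}"
            ref_ct = ref_ct_mean + (rng.normal(0.0, ref_ct_sd) if ref_ct_sd > 0 else 0.0)
            dct = baseline_dct - log2fc + (rng.normal(0.0, sample_sd) if sample_sd > 0 else 0.0)
            sample_truth[sid] = dct
            meta = {
                "group": "control" if group == "control" else "case",
                "subgroup": "none" if group in ("control", "ASD") else group,
            }
            for assay, mean_ct in (("target", ref_ct + dct), ("reference", ref_ct)):
                for rep in range(1, n_replicates + 1):
                    noise = rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0
                    rows.append(
                        {"sample_id": sid, "assay": assay, "replicate": rep,
                         "ct": mean_ct + noise, **meta}
                    )
    table = pd.DataFrame(rows)
    truth = {
        "true_log2fc": fcs,
        "sample_dct": sample_truth,
        "params": {"replicate_sd": replicate_sd, "sample_sd": sample_sd,
                   "baseline_dct": baseline_dct, "n_per_group": dict(n_per_group),
                   "n_replicates": n_replicates},
    }
    return table, truth


def generate_methylation_expression_cohort(
    n: int = 20,
    rho: float = 0.5149,
    mixture: Optional[StateMixture] = None,
    concentration: float = 2500.0,
    cv: float = 0.02,
    expression_scale: float = 0.25,
    seed=None,
) -> Tuple[pd.DataFrame, pd.Series, dict]:
    """Simulate matched methylation summaries and relative expression with
    a target Pearson correlation ``rho`` between %uCmC and expression.

    Expression is an affine function of the standardized %uCmC plus
    independent noise, so the population correlation equals ``rho``.
    """
    if not -1 <= rho <= 1:
        raise ValueError("rho must lie in [-1, 1]")
    rng = _rng(seed)
    mix = DEFAULT_GROUP_MIXTURES["M"] if mixture is None else mixture
    bands, _, truth = generate_cobra_cohort(
        {"cohort": mix}, n_per_group=n, concentration=concentration, cv=cv, seed=rng
    )
    summaries = []
    for _, row in bands.iterrows():
        profile = BandProfile.from_intensities(
            row[[f"b{f}" for f in FRAGMENT_LENGTHS]].to_numpy(dtype=float),
            sample_id=row["sample_id"],
        )
        summaries.append(compute_methylation(profile))
    frame = summaries_frame(summaries)
    u = frame["pct_uCmC"].to_numpy(dtype=float)
    z = (u - u.mean()) / u.std(ddof=0)
    eps = rng.normal(size=n)
    y = rho * z + np.sqrt(max(0.0, 1 - rho * rho)) * eps
    expression = pd.Series(np.maximum(1.0 + expression_scale * y, 1e-6), index=frame.index,
                           name="rel_expr")
    truth = {"rho": rho, "mixture": mix, "params": {"n": n, "cv": cv,
             "concentration": concentration, "expression_scale": expression_scale}}
    return frame, expression, truth


# ---------------------------------------------------------------------------
# Scenario presets for the CLI

SCENARIOS = ("multistudy-enrichment", "null", "cobra-subgroups", "qpcr-subgroups", "full")


def _write_expression_files(outdir: Path, bundle: dict, cfg_expr: dict) -> None:
    bundle["annotation"].write(outdir / "annotation.tsv")
    studies = []
    for study in bundle["studies"]:
        matrix_path = outdir / f"{study.study_id}_matrix.tsv"
        samples_path = outdir / f"{study.study_id}_samples.tsv"
        study.matrix.to_csv(matrix_path, sep="\t", na_rep="NA", float_format="%.6g")
        pd.DataFrame(
            {"sample_id": study.matrix.columns, "group": study.groups.to_numpy()}
        ).to_csv(samples_path, sep="\t", index=False)
        studies.append(
            {"id": study.study_id, "matrix": matrix_path.name, "samples": samples_path.name}
        )
    cfg_expr.update(
        {"annotation": "annotation.tsv", "alpha": 0.05, "cutoff": 0.70,
         "min_support": 2, "overlap_type": "all", "overlap_direction": "down",
         "studies": studies}
    )


def simulate_scenario(scenario: str, outdir, seed: int = 0) -> dict:
    """Write every input file for a named scenario plus truth.json and a
    ready-to-run pipeline config.yaml; returns the truth dict."""
    import yaml

    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth: dict = {"scenario": scenario, "seed": seed}
    config: dict = {"seed": seed}

    if scenario in ("multistudy-enrichment", "null", "full"):
        enrich = 1.0 if scenario == "null" else 3.0
        bundle = generate_multistudy(alu_down_enrichment=enrich, seed=rng)
        config["expression"] = {}
        _write_expression_files(outdir, bundle, config["expression"])
        truth["core"] = bundle["core"]
        truth["studies"] = bundle["truths"]

    if scenario in ("cobra-subgroups", "full"):
        bands, labels, cobra_truth = generate_cobra_cohort(seed=rng)
        bands.to_csv(outdir / "bands.csv", index=False, float_format="%.8g")
        labels.to_csv(outdir / "cobra_samples.tsv", sep="\t", index=False)
        truth["cobra"] = cobra_truth
        config["cobra"] = {
            "bands": "bands.csv",
            "samples": "cobra_samples.tsv",
            "comparisons": [
                {"label": "ASD vs control", "case": {"group": "case"},
                 "control": {"group": "control"}},
                *(
                    {"label": f"subgroup {g} vs control", "case": {"subgroup": g},
                     "control": {"group": "control"}}
                    for g in ("M", "L", "S")
                ),
            ],
        }

    if scenario in ("qpcr-subgroups", "full"):
        ct, ct_truth = generate_ct_cohort(seed=rng)
        ct.to_csv(outdir / "ct.csv", index=False, float_format="%.6f")
        truth["qpcr"] = ct_truth
        config["qpcr"] = {
            "ct": "ct.csv",
            "comparisons": [
                {"label": f"subgroup {g} vs control", "case": {"subgroup": g},
                 "control": {"group": "control"}}
                for g in ("M", "L", "S")
            ],
        }

    if scenario == "full":
        config["correlation"] = {"comparison": "subgroup M vs control", "stratum": "M"}

    with open(outdir / "truth.json", "w") as fh:
        json.dump(_jsonable(truth), fh, indent=2, sort_keys=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return truth
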