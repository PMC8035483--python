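"""End-to-end orchestration: cohort -> cleaning -> connectomes -> sparsity
sweep -> group statistics.

Every stochastic step draws its seed from ``master_seed`` through the
deterministic hash in :mod:`connsweep._seeds`, so a run is reproducible from
its config alone.  Subjects failing motion QC are excluded before network
construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import netcon, preproc, stats, sweep, synth
from .atlas import load_atlas_labels

log = logging.getLogger("connsweep")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All knobs of a pipeline run; serializable to/from YAML."""

    out_dir: str = "scratch/run"
    input_dir: str | None = None  # read a written cohort instead of generating
    master_seed: int = 0
    # cohort
    group_sizes: dict = field(default_factory=lambda: {"CI": 36, "NCI": 30, "HC": 48})
    n_regions: int = 90
    n_volumes: int = 240
    tr: float = 2.0
    ar_coeff: float = 0.3
    base_strength: float = 0.28
    attenuations: dict = field(default_factory=lambda: {"HC": 0.0, "NCI": 0.3, "CI": 0.6})
    subject_attenuation_sd: float = 0.15
    score_coupling: float = 0.5
    spike_rate: float = 1.0
    # preprocessing
    discard: int = 10
    band: tuple = (0.01, 0.08)
    fd_threshold: float = 0.5
    # connectivity
    shrinkage: float = 0.8
    # sweep
    candidate_s_min: float = 0.05
    candidate_s_max: float = 0.50
    grid_step: float = 0.01
    n_null: int = 20
    swaps_per_edge: int = 10
    # statistics
    t_variant: str = "pooled"
    # eGFR is deliberately not a default covariate: in an ESRD-vs-control
    # design it separates patients from controls almost perfectly, so
    # adjusting for it absorbs the patient-vs-control contrast itself
    ancova_covariates: list = field(default_factory=lambda: ["age", "sex"])
    correlation_covariates: list = field(default_factory=lambda: ["age", "sex", "education"])
    alpha: float = 0.05
    # io
    write_timeseries: bool = False

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)


@dataclass
class RunReport:
    n_generated: int
    n_qc_failed: int
    qc_failed_subjects: list
    scrubbed_volumes: dict
    selected_range: tuple
    group_auc_summary: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    correlations: pd.DataFrame
    significant_regions: dict


def _sex_indicator(series: pd.Series) -> np.ndarray:
    return (series == "M").to_numpy(dtype=float)


def _covariate_matrix(pheno: pd.DataFrame, names: list) -> np.ndarray:
    cols = []
    for c in names:
        cols.append(_sex_indicator(pheno[c]) if c == "sex" else pheno[c].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(pheno), 0))


def demographic_table(pheno: pd.DataFrame, t_variant: str = "pooled") -> pd.DataFrame:
    """Demographics/cognition tests across the three groups.

    Sex by chi-square, quantitative three-group variables by one-way ANOVA,
    and patient-only eGFR by two-sample t test -- mirroring how mixed
    two/three-group cohort tables are conventionally reported.
    """
    rows = []
    groups = ["CI", "NCI", "HC"]
    counts = np.array([
        [(pheno[(pheno.group == g)].sex == "M").sum(),
         (pheno[(pheno.group == g)].sex == "F").sum()] for g in groups
    ])
    res = stats.chi_square_test(counts)
    rows.append(("sex", "chi_square", res.statistic, res.p))
    for var in ["age", "education", "moca", "tmt_a", "tmt_b", "sdmt"]:
        summ = [
            (int((pheno.group == g).sum()),
             float(pheno.loc[pheno.group == g, var].mean()),
             float(pheno.loc[pheno.group == g, var].std(ddof=1)))
            for g in groups
        ]
        res = stats.one_way_anova_from_summary(summ)
        rows.append((var, "anova", res.statistic, res.p))
    ci = pheno[pheno.group == "CI"]["egfr"]
    nci = pheno[pheno.group == "NCI"]["egfr"]
    res = stats.two_sample_t_from_summary(
        len(ci), ci.mean(), ci.std(ddof=1), len(nci), nci.mean(), nci.std(ddof=1),
        variant=t_variant,
    )
    rows.append(("egfr_CI_vs_NCI", f"t_{t_variant}", res.statistic, res.p))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

    atlas = load_atlas_labels(expected_regions=90) if config.n_regions == 90 else None
    region_labels = list(atlas["abbreviation"]) if atlas is not None else None

    # ------------------------------------------------------------------ synth
    if config.input_dir is None:
        ccfg = synth.CohortConfig(
            group_sizes=dict(config.group_sizes),
            n_regions=config.n_regions,
            n_volumes=config.n_volumes,
            tr=config.tr,
            ar_coeff=config.ar_coeff,
            base_strength=config.base_strength,
            attenuations=dict(config.attenuations),
            subject_attenuation_sd=config.subject_attenuation_sd,
            score_coupling=config.score_coupling,
            spike_rate=config.spike_rate,
            region_labels=region_labels,
        )
        cohort = synth.generate_cohort(ccfg, master_seed=config.master_seed,
                                       out_dir=out / "cohort" if config.write_timeseries else None)
        pheno = cohort.table.to_dataframe()
        series, motions = cohort.timeseries, cohort.motion
        (out / "ground_truth.json").write_text(json.dumps(cohort.ground_truth, indent=1))
    else:
        indir = Path(config.input_dir)
        pheno = pd.read_csv(indir / "cohort.csv")
        series, motions = {}, {}
        for sid in pheno["subject_id"]:
            series[sid] = synth.read_subject_timeseries(indir / f"{sid}_roits.tsv", config.tr)
            motions[sid] = synth.read_subject_motion(indir / f"{sid}_motion.tsv", config.tr)
    log.info("cohort: %d subjects", len(pheno))

    # ---------------------------------------------------------------- preproc
    qc_failed, qc_records, clean = [], {}, {}
    for sid in pheno["subject_id"]:
        qc = preproc.qc_motion(motions[sid])
        if not qc.passed:
            qc_failed.append(sid)
            qc_records[sid] = {"qc_pass": False, "offending": qc.offending_parameter}
            log.warning("subject %s excluded by motion QC (%s)", sid, qc.offending_parameter)
            continue
        ts = preproc.clean_timeseries(
            series[sid], motions[sid], discard=config.discard, band=tuple(config.band),
            fd_threshold=config.fd_threshold,
        )
        clean[sid] = ts
        qc_records[sid] = {
            "qc_pass": True,
            "discarded": config.discard,
            "scrubbed": int((~ts.volume_mask).sum()),
        }
    (out / "qc.json").write_text(json.dumps(qc_records, indent=1))
    pheno = pheno[~pheno["subject_id"].isin(qc_failed)].reset_index(drop=True)
    if pheno.groupby("group").size().min() == 0:
        raise PipelineError("a group is empty after motion QC")

    # ----------------------------------------------------------------- netcon
    conns = {sid: netcon.partial_correlation_matrix(clean[sid], shrinkage=config.shrinkage)
             for sid in pheno["subject_id"]}

    # ------------------------------------------------------------------ sweep
    candidate = sweep.SparsityGrid(config.candidate_s_min, config.candidate_s_max,
                                   config.grid_step)
    sigma_tab = sweep.sigma_over_grid(conns, candidate, n_null=config.n_null,
                                      swaps_per_edge=config.swaps_per_edge,
                                      seed=config.master_seed)
    grid = sweep.determine_sparsity_range(conns, candidate, sigma_table=sigma_tab)
    log.info("selected sparsity range: %.2f-%.2f", grid.s_min, grid.s_max)
    sigma_tab.to_csv(out / "sigma_table.csv", float_format="%.8g")

    curves = sweep.cohort_curves(conns, grid, n_null=config.n_null,
                                 swaps_per_edge=config.swaps_per_edge,
                                 seed=config.master_seed)
    labels = region_labels or clean[next(iter(clean))].region_labels
    auc = sweep.auc_table(curves, region_labels=labels)
    auc.to_csv(out / "metrics_auc.csv", float_format="%.10g")
    sweep.curves_to_long(curves, region_labels=labels).to_csv(
        out / "metrics_curves.csv", index=False, float_format="%.8g")

    # ------------------------------------------------------------------ stats
    pheno = pheno.set_index("subject_id").loc[auc.index]
    pheno.index.name = "subject_id"
    pheno = pheno.reset_index()
    grp = pheno["group"].to_numpy()
    cov = _covariate_matrix(pheno, list(config.ancova_covariates))

    table1 = demographic_table(pheno, t_variant=config.t_variant)
    table1.to_csv(out / "table1_style.csv", index=False, float_format="%.6g")

    rows2 = []
    for m in sweep.GLOBAL_METRIC_NAMES:
        y = auc[m].to_numpy()
        res = stats.ancova_group_test(y, grp, cov)
        means = {g: float(y[grp == g].mean()) for g in ("CI", "NCI", "HC")}
        sds = {g: float(y[grp == g].std(ddof=1)) for g in ("CI", "NCI", "HC")}
        rows2.append({
            "metric": m, "F": res.statistic, "p": res.p,
            **{f"mean_{g}": means[g] for g in means},
            **{f"sd_{g}": sds[g] for g in sds},
            **{f"p_{a}_vs_{b}": v for (a, b), v in res.posthoc.items()},
            "direction": res.effect_direction,
        })
    table2 = pd.DataFrame(rows2)
    table2.to_csv(out / "table2_style.csv", index=False, float_format="%.6g")

    rows3 = []
    for lab in labels:
        for m in sweep.NODAL_METRIC_NAMES:
            y = auc[f"{m}:{lab}"].to_numpy()
            res = stats.ancova_group_test(y, grp, cov)
            rows3.append({
                "region": lab, "metric": m, "F": res.statistic, "p": res.p,
                **{f"p_{a}_vs_{b}": v for (a, b), v in res.posthoc.items()},
                "direction": res.effect_direction,
            })
    table3 = pd.DataFrame(rows3)
    table3.to_csv(out / "table3_style.csv", index=False, float_format="%.6g")
    sig3 = table3[table3.p < config.alpha]
    significant_regions = {
        m: sorted(sig3.loc[sig3.metric == m, "region"].unique().tolist())
        for m in sweep.NODAL_METRIC_NAMES
    }
    sig_regions_any = sorted({r for rs in significant_regions.values() for r in rs})

    # score correlations within the CI group, over significant regions
    ci_mask = pheno["group"] == "CI"
    ci_pheno = pheno[ci_mask]
    ci_auc = auc.loc[ci_pheno["subject_id"]]
    ccov = _covariate_matrix(ci_pheno, list(config.correlation_covariates))
    corr_rows = []
    for lab in sig_regions_any:
        for m in sweep.NODAL_METRIC_NAMES:
            if lab not in significant_regions[m]:
                continue
            for score in ["moca", "tmt_a", "tmt_b", "sdmt"]:
                try:
                    res = stats.partial_correlation_test(
                        ci_auc[f"{m}:{lab}"].to_numpy(),
                        ci_pheno[score].to_numpy(dtype=float),
                        ccov, pair=(f"{m}:{lab}", score),
                    )
                except stats.StatsError:
                    continue
                corr_rows.append({"measure": f"{m}:{lab}", "score": score,
                                  "r": res.r, "p": res.p})
    correlations = pd.DataFrame(corr_rows, columns=["measure", "score", "r", "p"])
    if len(correlations):
        correlations["q"] = stats.bh_fdr(correlations["p"].to_numpy())
    else:
        correlations["q"] = pd.Series(dtype=float)
    correlations.to_csv(out / "correlations.csv", index=False, float_format="%.6g")

    summary = auc[list(sweep.GLOBAL_METRIC_NAMES)].copy()
    summary["group"] = grp
    group_auc_summary = summary.groupby("group").agg(["mean", "std"])

    report = RunReport(
        n_generated=len(qc_records),
        n_qc_failed=len(qc_failed),
        qc_failed_subjects=qc_failed,
        scrubbed_volumes={sid: rec.get("scrubbed", 0) for sid, rec in qc_records.items()},
        selected_range=(grid.s_min, grid.s_max),
        group_auc_summary=group_auc_summary,
        table1=table1,
        table2=table2,
        table3=table3,
        correlations=correlations,
        significant_regions=significant_regions,
    )
    _write_report_json(report, out / "run_report.json")
    return report


def _write_report_json(report: RunReport, path: Path) -> None:
    d = {
        "n_generated": report.n_generated,
        "n_qc_failed": report.n_qc_failed,
        "qc_failed_subjects": report.qc_failed_subjects,
        "selected_range": list(report.selected_range),
        "significant_regions": report.significant_regions,
        "group_sigma_auc_mean": {
            g: float(report.group_auc_summary.loc[g, ("sigma", "mean")])
            for g in report.group_auc_summary.index
        },
    }
    path.write_text(json.dumps(d, indent=1))
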