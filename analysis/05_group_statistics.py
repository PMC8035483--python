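"""Three-group statistics on the AUC metrics.

ANCOVA (covariates: age, sex) with Bonferroni post hoc tests on each global
metric and on each region x nodal-metric AUC; partial correlations (adjusted
for age, sex, education) between the significant regions' nodal AUCs and
cognition scores within the CI group, Benjamini-Hochberg corrected.

Writes results/table2_style.csv, results/table3_style.csv,
results/correlations.csv and results/dmn_recovery.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SCRATCH, parse_args

from connsweep import stats, sweep
from connsweep.pipeline import _covariate_matrix, demographic_table


def main() -> None:
    parse_args(__doc__)
    pheno = pd.read_csv(SCRATCH / "cohort" / "cohort.csv")
    auc = pd.read_csv(SCRATCH / "metrics_auc.csv", index_col=0)
    pheno = pheno.set_index("subject_id").loc[auc.index].reset_index(names="subject_id")
    grp = pheno["group"].to_numpy()
    cov = _covariate_matrix(pheno, ["age", "sex"])

    demographic_table(pheno).to_csv(RESULTS / "table1_style.csv", index=False,
                                    float_format="%.4g")

    rows = []
    for m in sweep.GLOBAL_METRIC_NAMES:
        res = stats.ancova_group_test(auc[m].to_numpy(), grp, cov)
        rows.append({"metric": m, "F": res.statistic, "p": res.p,
                     **{f"p_{a}_vs_{b}": v for (a, b), v in res.posthoc.items()},
                     "direction": res.effect_direction})
    table2 = pd.DataFrame(rows)
    table2.to_csv(RESULTS / "table2_style.csv", index=False, float_format="%.4g")
    print(table2[["metric", "F", "p", "direction"]].round(4))

    nodal_cols = [c for c in auc.columns if ":" in c]
    rows = []
    for col in nodal_cols:
        m, region = col.split(":", 1)
        res = stats.ancova_group_test(auc[col].to_numpy(), grp, cov)
        rows.append({"region": region, "metric": m, "F": res.statistic, "p": res.p,
                     "direction": res.effect_direction})
    table3 = pd.DataFrame(rows)
    table3.to_csv(RESULTS / "table3_style.csv", index=False, float_format="%.4g")
    sig = table3[table3.p < 0.05]
    print(f"{sig.region.nunique()} regions significant in at least one nodal metric")

    gt = json.loads((SCRATCH / "cohort" / "ground_truth.json").read_text())
    dmn = set(gt["dmn_abbreviations"])
    recovered = sorted(dmn & set(sig.region))
    (RESULTS / "dmn_recovery.json").write_text(json.dumps(
        {"seeded": sorted(dmn), "recovered": recovered,
         "recovery_rate": f"{len(recovered)}/{len(dmn)}"}, indent=1))
    print(f"seeded DMN regions recovered: {len(recovered)}/{len(dmn)}: {recovered}")

    ci = pheno[pheno.group == "CI"]
    ci_auc = auc.loc[ci.subject_id]
    ccov = _covariate_matrix(ci, ["age", "sex", "education"])
    rows = []
    for _, r in sig.iterrows():
        col = f"{r.metric}:{r.region}"
        for score in ["moca", "tmt_a", "tmt_b", "sdmt"]:
            try:
                res = stats.partial_correlation_test(
                    ci_auc[col].to_numpy(), ci[score].to_numpy(dtype=float), ccov)
            except stats.StatsError:
                continue
            rows.append({"measure": col, "score": score, "r": res.r, "p": res.p})
    corr = pd.DataFrame(rows)
    if len(corr):
        corr["q"] = stats.bh_fdr(corr["p"].to_numpy())
        corr = corr.sort_values("q")
    corr.to_csv(RESULTS / "correlations.csv", index=False, float_format="%.4g")
    print(corr.head(8).round(3))


if __name__ == "__main__":
    main()
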