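"""Select the sparsity range and summarize metric curves as AUCs.

Applies the selection rule -- the largest contiguous run of grid points on
which the small-world scalar sigma is estimable and exceeds 1.0 for every
subject (candidate grid 0.05-0.50, step 0.01, 20 degree-preserving null
networks per point) -- then computes all global and nodal metrics over the
selected range and integrates each curve to a single AUC scalar.

Writes results/selected_range.json and results/metrics_auc_global.csv;
the full per-region AUC table and the per-subject sigma table go to
scratch/analysis/.
"""

import json
import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import CANDIDATE_GRID, N_NULL, RESULTS, SCRATCH, parse_args

from connsweep import netcon, sweep
from connsweep.preproc import TimeSeriesMatrix


def main() -> None:
    args = parse_args(__doc__)
    warnings.filterwarnings("ignore", category=RuntimeWarning)
    conns = {}
    for path in sorted((SCRATCH / "clean").glob("*_clean.tsv")):
        sid = path.name.replace("_clean.tsv", "")
        df = pd.read_csv(path, sep="\t")
        mask = df.pop("retained").to_numpy(dtype=bool)
        ts = TimeSeriesMatrix(df.to_numpy(dtype=float), 2.0, list(df.columns),
                              volume_mask=mask)
        conns[sid] = netcon.partial_correlation_matrix(ts)

    candidate = sweep.SparsityGrid(*CANDIDATE_GRID)
    tab = sweep.sigma_over_grid(conns, candidate, n_null=N_NULL, seed=args.seed)
    tab.to_csv(SCRATCH / "sigma_table.csv", float_format="%.8g")
    grid = sweep.determine_sparsity_range(conns, candidate, sigma_table=tab)
    print(f"selected sparsity range: {grid.s_min:.2f}-{grid.s_max:.2f} "
          f"({len(grid)} points)")
    (RESULTS / "selected_range.json").write_text(json.dumps(
        {"s_min": grid.s_min, "s_max": grid.s_max, "step": grid.step,
         "n_subjects": len(conns), "n_null": N_NULL}, indent=1))

    curves = sweep.cohort_curves(conns, grid, n_null=N_NULL, seed=args.seed)
    labels = next(iter(conns.values())).region_labels
    auc = sweep.auc_table(curves, region_labels=labels)
    # the full subject x (metric, region) table is bulky; results/ keeps the
    # global metrics, the full table stays with the other intermediates
    auc.to_csv(SCRATCH / "metrics_auc.csv", float_format="%.10g")
    auc[list(sweep.GLOBAL_METRIC_NAMES)].to_csv(
        RESULTS / "metrics_auc_global.csv", float_format="%.10g")
    print(auc[list(sweep.GLOBAL_METRIC_NAMES)].describe().round(4))


if __name__ == "__main__":
    main()
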