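"""Synthetic-cohort generator.

Emulates a three-group resting-state fMRI study of end-stage renal disease:
36 patients with cognitive impairment (CI, MoCA < 26), 30 patients without
(NCI), and 48 healthy controls (HC), each with a 240-volume scan at TR = 2 s
over 90 atlas regions.

The ground truth is a sparse Gaussian graphical model per group: a modular
precision matrix whose implied partial correlations form clustered
within-module structure with sparse between-module shortcuts (a small-world
substrate).  Group differences are injected by attenuating precision entries
incident to seven default-mode-network (DMN) nodes, ordered
HC (none) < NCI < CI, plus per-subject attenuation jitter so that every
subject carries an individual "true DMN nodal strength".  Cognition scores
are linear functions of that latent strength plus noise, so recovery of the
seeded regions and of score-network correlations can be tested against the
recorded ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._seeds import derive_seed
from .preproc import MotionTrace, TimeSeriesMatrix

GROUPS = ("CI", "NCI", "HC")

#: 0-based atlas indices of the seeded DMN regions: SFGmed.L, SFGmed.R,
#: PCG.L, HIP.R, AMYG.R, ANG.L, PCUN.R.
DMN_INDICES = (22, 23, 34, 37, 41, 64, 67)

DMN_ABBREVIATIONS = ("SFGmed.L", "SFGmed.R", "PCG.L", "HIP.R", "AMYG.R", "ANG.L", "PCUN.R")


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ground-truth precision model
# ---------------------------------------------------------------------------

def default_module_partition(n_regions: int = 90, n_modules: int | None = None) -> list[np.ndarray]:
    """Contiguous partition into equal modules (6 x 15 for the 90-region default).

    When ``n_modules`` is not given, the divisor of ``n_regions`` giving
    module sizes closest to 15 is chosen (modules of ~15 regions mimic
    large-scale functional systems).
    """
    if n_modules is None:
        divisors = [d for d in range(2, n_regions // 2 + 1) if n_regions % d == 0]
        if not divisors:
            raise SynthError(f"no valid module count divides {n_regions} regions")
        n_modules = min(divisors, key=lambda d: abs(n_regions / d - 15))
    if n_regions % n_modules:
        raise SynthError("n_regions must be divisible by n_modules")
    size = n_regions // n_modules
    return [np.arange(k * size, (k + 1) * size) for k in range(n_modules)]


def build_group_precision(
    n_regions: int,
    module_partition: list[np.ndarray],
    base_strength: float,
    dmn_indices: tuple[int, ...],
    attenuation: float,
    seed: int,
    diag_margin: float = 0.1,
    secondary_scale: float = 0.8,
    chords_per_module: int = 2,
    between_per_node: float = 1.5,
    between_scale: float = 0.25,
    hub_boost: float = 1.8,
    hub_extra_links: int = 6,
    hub_link_scale: float = 0.5,
) -> np.ndarray:
    """Symmetric positive-definite precision matrix with modular topology.

    Within each module, nodes form a ring with graded weights: strong links
    to the two nearest module neighbours (magnitude ~ ``base_strength``) and
    weaker triangle-closing links two steps away (``secondary_scale`` x
    base), plus a couple of random chords; sparse weaker links join modules.
    Grading matters: diagonal loading spreads each node's precision budget
    over its partners, so concentrating weight on two partners is what makes
    the implied partial correlations of the backbone rise clear of the
    sampling noise of a short scan, as in empirical connectomes where a few
    edges dominate each region's conditional dependence.

    The seeded ``dmn_indices`` are built as hubs, as their anatomical
    counterparts are: their incident weights are scaled by ``hub_boost`` and
    each receives ``hub_extra_links`` additional between-module connector
    links (``hub_link_scale`` x base).  Above-average baseline centrality is
    what lets an attenuation of those nodes register as *decreased* nodal
    centrality across a whole range of binarization thresholds.

    Off-diagonal entries are negative so the implied partial correlations
    -Omega_ij / sqrt(Omega_ii Omega_jj) are positive.  Entries incident to
    ``dmn_indices`` are multiplied by (1 - attenuation).  The diagonal is
    loaded to ``diag_margin`` above each row's absolute off-diagonal sum
    (taken before attenuation, so attenuation scales the implied partial
    correlations of seeded pairs exactly proportionally), which guarantees
    strict diagonal dominance and hence positive-definiteness; the result is
    still verified by Cholesky and any failure raises rather than being
    repaired.
    """
    if not 0 <= attenuation <= 1:
        raise SynthError("attenuation must lie in [0, 1]")
    flat = np.concatenate([np.asarray(m) for m in module_partition])
    if sorted(flat.tolist()) != list(range(n_regions)):
        raise SynthError("module sets must partition the region indices")

    rng = np.random.default_rng(seed)
    w = np.zeros((n_regions, n_regions))

    def put(i: int, j: int, mag: float) -> None:
        w[i, j] = w[j, i] = max(w[i, j], mag)

    for module in module_partition:
        module = np.asarray(module)
        m = len(module)
        for a in range(m):
            put(int(module[a]), int(module[(a + 1) % m]),
                base_strength * rng.uniform(0.9, 1.1))
            put(int(module[a]), int(module[(a + 2) % m]),
                base_strength * secondary_scale * rng.uniform(0.75, 1.25))
        for _ in range(chords_per_module):
            a, b = rng.choice(m, size=2, replace=False)
            put(int(module[a]), int(module[b]),
                base_strength * secondary_scale * rng.uniform(0.75, 1.25))

    # sparse between-module shortcuts
    n_between = int(round(between_per_node * n_regions / 2))
    module_of = np.empty(n_regions, dtype=int)
    for k, module in enumerate(module_partition):
        module_of[np.asarray(module)] = k
    placed = 0
    while placed < n_between:
        i, j = rng.integers(0, n_regions, size=2)
        if i == j or module_of[i] == module_of[j] or w[i, j] > 0:
            continue
        put(int(i), int(j), base_strength * between_scale * rng.uniform(0.75, 1.25))
        placed += 1

    dmn = np.zeros(n_regions, dtype=bool)
    dmn[list(dmn_indices)] = True
    incident = dmn[:, None] | dmn[None, :]
    # hub structure at the seeded nodes, independent of attenuation
    w = np.where(incident, w * hub_boost, w)
    for i in np.flatnonzero(dmn):
        added = 0
        while added < hub_extra_links:
            j = int(rng.integers(0, n_regions))
            if j == i or module_of[j] == module_of[i] or w[i, j] > 0:
                continue
            put(i, j, base_strength * hub_link_scale * rng.uniform(0.75, 1.25))
            added += 1
    # diagonal is loaded from the *unattenuated* row sums: dominance still
    # holds (attenuation only shrinks off-diagonals), and the implied partial
    # correlations of DMN-incident pairs scale exactly by (1 - attenuation)
    # instead of being partially cancelled by a lighter diagonal
    diag = diag_margin + np.abs(w).sum(axis=1)
    w = np.where(incident, w * (1.0 - attenuation), w)

    omega = -w
    np.fill_diagonal(omega, diag)
    omega = (omega + omega.T) / 2.0
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - construction forbids it
        raise SynthError("constructed precision matrix is not positive definite") from exc
    return omega


def implied_partial_correlation(precision: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix implied by a precision matrix (zero diagonal)."""
    d = np.sqrt(np.diag(precision))
    p = -precision / np.outer(d, d)
    np.fill_diagonal(p, 0.0)
    return p


@dataclass
class GroundTruthModel:
    """Per-group precision matrices plus the seeded-region bookkeeping."""

    n_regions: int
    region_labels: list[str]
    dmn_indices: tuple[int, ...]
    precision_by_group: dict[str, np.ndarray]
    attenuation_by_group: dict[str, float]

    def __post_init__(self) -> None:
        atts = self.attenuation_by_group
        if not (atts["HC"] <= atts["NCI"] < atts["CI"] < 1):
            raise SynthError("attenuation must satisfy HC <= NCI < CI < 1")
        for g, om in self.precision_by_group.items():
            if not np.array_equal(om, om.T):
                raise SynthError(f"precision for {g} is not exactly symmetric")
            np.linalg.cholesky(om)  # raises if not positive definite


def build_ground_truth(
    n_regions: int = 90,
    region_labels: list[str] | None = None,
    dmn_indices: tuple[int, ...] | None = None,
    base_strength: float = 0.28,
    attenuations: dict[str, float] | None = None,
    seed: int = 0,
    n_modules: int | None = None,
) -> GroundTruthModel:
    """Build the three group models from one shared wiring seed.

    The same seed (hence identical wiring and weight jitter) is used for all
    groups, so groups differ *only* through the DMN attenuation factor.
    """
    if attenuations is None:
        attenuations = {"HC": 0.0, "NCI": 0.3, "CI": 0.6}
    if region_labels is None:
        region_labels = [f"R{i:03d}" for i in range(n_regions)]
    if dmn_indices is None:
        # the packaged atlas indices at 90 regions; otherwise 7 seeded nodes
        # spread evenly so every module partition is touched
        if n_regions == 90:
            dmn_indices = DMN_INDICES
        else:
            dmn_indices = tuple(np.linspace(0, n_regions - 1, 7).astype(int).tolist())
    partition = default_module_partition(n_regions, n_modules)
    wiring_seed = derive_seed(seed, "wiring")
    prec = {
        g: build_group_precision(
            n_regions, partition, base_strength, dmn_indices, attenuations[g], wiring_seed
        )
        for g in GROUPS
    }
    return GroundTruthModel(n_regions, list(region_labels), tuple(dmn_indices), prec, dict(attenuations))


# ---------------------------------------------------------------------------
# Time-series simulation
# ---------------------------------------------------------------------------

def simulate_subject_timeseries(
    precision: np.ndarray,
    n_volumes: int,
    tr: float,
    ar_coeff: float,
    seed: int,
    region_labels: list[str] | None = None,
) -> TimeSeriesMatrix:
    """Sample a T x N series from the Gaussian graphical model.

    Innovations are multivariate normal with covariance inv(precision);
    temporal smoothness is an AR(1) with coefficient ``ar_coeff`` scaled so
    the stationary spatial covariance equals inv(precision) exactly.
    """
    if n_volumes < 2:
        raise SynthError("need at least 2 volumes")
    if not 0 <= ar_coeff < 1:
        raise SynthError("ar_coeff must lie in [0, 1)")
    n = precision.shape[0]
    try:
        chol_prec = np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:
        raise SynthError("precision matrix is singular or not positive definite") from exc
    # solve L^T X = Z gives samples with covariance inv(precision)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_volumes, n))
    innov = np.linalg.solve(chol_prec.T, z.T).T
    x = np.empty_like(innov)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - ar_coeff**2)
    for t in range(1, n_volumes):
        x[t] = ar_coeff * x[t - 1] + scale * innov[t]
    labels = region_labels if region_labels is not None else [f"R{i:03d}" for i in range(n)]
    return TimeSeriesMatrix(x, tr, list(labels))


def simulate_motion(
    n_volumes: int,
    tr: float,
    seed: int,
    n_spikes: int,
    discard: int = 10,
    walk_sd: float = 0.01,
    spike_step: float = 0.6,
) -> MotionTrace:
    """Small bounded head-motion trace with planted displacement spikes.

    Baseline is a clipped random walk well under the 1.0 mm / 1.0 degree
    exclusion rule.  Each spike is a step change of ``spike_step`` mm in the
    x-translation that toggles on/off, so exactly one volume per spike
    exceeds a 0.5 mm framewise-displacement threshold.  Spikes are placed
    after the discard window with >= 5 volumes separation.
    """
    rng = np.random.default_rng(seed)
    m = np.cumsum(rng.normal(0.0, walk_sd, size=(n_volumes, 6)), axis=0)
    m = np.clip(m, -0.3, 0.3)
    if n_spikes > 0:
        candidates = np.arange(discard + 5, n_volumes - 2)
        chosen: list[int] = []
        order = rng.permutation(candidates)
        for t in order:
            if all(abs(t - c) >= 5 for c in chosen):
                chosen.append(int(t))
            if len(chosen) == n_spikes:
                break
        level = 0.0
        steps = np.zeros(n_volumes)
        for t in sorted(chosen):
            level = spike_step if level == 0.0 else 0.0
            steps[t:] = level
        m[:, 0] = m[:, 0] + steps
    return MotionTrace(m, tr)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    egfr: float
    moca: int
    tmt_a: float
    tmt_b: float
    sdmt: int
    seed: int

    def __post_init__(self) -> None:
        if self.group in ("CI", "NCI"):
            if (self.group == "CI") != (self.moca < 26):
                raise SynthError("group label inconsistent with MoCA < 26 rule")
        if min(self.tmt_a, self.tmt_b) <= 0:
            raise SynthError("durations must be positive")


@dataclass
class CohortTable:
    subjects: list[SubjectRecord]
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise SynthError("subject ids must be unique")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([asdict(s) for s in self.subjects])


@dataclass
class CohortConfig:
    """Study conditions for the default synthetic cohort."""

    group_sizes: dict[str, int] = field(default_factory=lambda: {"CI": 36, "NCI": 30, "HC": 48})
    n_regions: int = 90
    n_volumes: int = 240
    tr: float = 2.0
    ar_coeff: float = 0.3
    base_strength: float = 0.28
    attenuations: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "NCI": 0.3, "CI": 0.6}
    )
    subject_attenuation_sd: float = 0.15
    score_coupling: float = 0.5
    spike_rate: float = 1.0  # Poisson mean of planted motion spikes per subject
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if min(self.group_sizes.values()) < 3:
            raise SynthError("each group needs at least 3 subjects")


#: Table of score distributions per group: mean, sd.  MoCA is kept
#: uncoupled from the network ground truth; timed tests couple negatively
#: (slower with weaker DMN), SDMT positively.
SCORE_PARAMS = {
    "moca": {"CI": (21.00, 4.57), "NCI": (27.27, 0.91), "HC": (27.54, 1.11)},
    "tmt_a": {"CI": (51.69, 16.56), "NCI": (43.23, 13.27), "HC": (38.19, 9.32)},
    "tmt_b": {"CI": (71.42, 16.50), "NCI": (63.17, 12.64), "HC": (58.19, 9.83)},
    "sdmt": {"CI": (37.03, 11.24), "NCI": (44.50, 10.28), "HC": (48.21, 10.15)},
}


@dataclass
class Cohort:
    """A fully sampled synthetic cohort with its generative ground truth."""

    table: CohortTable
    timeseries: dict[str, TimeSeriesMatrix]
    motion: dict[str, MotionTrace]
    ground_truth: dict
    model: GroundTruthModel
    config: CohortConfig


def generate_cohort(config: CohortConfig | None = None, master_seed: int = 0,
                    out_dir: str | Path | None = None) -> Cohort:
    """Sample a complete cohort: phenotypes, time series, and motion traces.

    Per-subject seeds are derived from ``(master_seed, subject_id)`` so a
    subject's data is reproducible regardless of cohort ordering.  Cognition
    scores are linear in each subject's standardized true DMN nodal strength
    (coupling ``config.score_coupling``) plus independent noise, which
    targets within-CI score-network correlations around |r| = 0.4-0.5.
    """
    if config is None:
        config = CohortConfig()
    model = build_ground_truth(
        n_regions=config.n_regions,
        region_labels=config.region_labels,
        base_strength=config.base_strength,
        attenuations=config.attenuations,
        seed=master_seed,
    )
    partition = default_module_partition(config.n_regions)
    wiring_seed = derive_seed(master_seed, "wiring")
    prec_kwargs = dict(
        n_regions=config.n_regions,
        module_partition=partition,
        base_strength=config.base_strength,
        dmn_indices=model.dmn_indices,
        seed=wiring_seed,
    )

    subjects: list[dict] = []
    for group in GROUPS:
        for k in range(config.group_sizes[group]):
            sid = f"{group}{k + 1:03d}"
            subjects.append({"subject_id": sid, "group": group})

    timeseries: dict[str, TimeSeriesMatrix] = {}
    motion: dict[str, MotionTrace] = {}
    gt_subjects: dict[str, dict] = {}
    latent: dict[str, float] = {}
    nodal_strength: dict[str, dict[str, float]] = {}

    seeded_names = (
        DMN_ABBREVIATIONS if tuple(model.dmn_indices) == DMN_INDICES
        else tuple(model.region_labels[i] for i in model.dmn_indices)
    )
    for sub in subjects:
        sid = sub["subject_id"]
        group = sub["group"]
        sseed = derive_seed(master_seed, sid)
        rng = np.random.default_rng(sseed)
        att = float(np.clip(
            config.attenuations[group] + rng.normal(0.0, config.subject_attenuation_sd),
            0.0, 0.9,
        ))
        prec = build_group_precision(attenuation=att, **prec_kwargs)
        pc = implied_partial_correlation(prec)
        strengths = {
            name: float(np.abs(pc[idx]).sum())
            for name, idx in zip(seeded_names, model.dmn_indices)
        }
        latent[sid] = float(np.mean(list(strengths.values())))
        nodal_strength[sid] = strengths

        ts = simulate_subject_timeseries(
            prec, config.n_volumes, config.tr, config.ar_coeff,
            derive_seed(master_seed, sid, "ts"), region_labels=model.region_labels,
        )
        n_spikes = int(np.random.default_rng(derive_seed(master_seed, sid, "spikes"))
                       .poisson(config.spike_rate))
        mot = simulate_motion(config.n_volumes, config.tr,
                              derive_seed(master_seed, sid, "motion"), n_spikes)
        timeseries[sid] = ts
        motion[sid] = mot
        sub.update(seed=sseed, attenuation=att, n_spikes=n_spikes)
        gt_subjects[sid] = {
            "seed": sseed,
            "attenuation": att,
            "planted_spike_count": n_spikes,
            "dmn_strength": latent[sid],
            "dmn_nodal_strength": strengths,
        }

    # standardize the latent strength within group, then couple scores to it
    records: list[SubjectRecord] = []
    c = config.score_coupling
    for group in GROUPS:
        members = [s for s in subjects if s["group"] == group]
        vals = np.array([latent[s["subject_id"]] for s in members])
        z = (vals - vals.mean()) / vals.std() if vals.std() > 0 else np.zeros(len(vals))
        for s, zi in zip(members, z):
            sid = s["subject_id"]
            rng = np.random.default_rng(derive_seed(master_seed, sid, "pheno"))
            age = float(np.clip(rng.normal(31.5, 7.5), 18, 45))
            sex = "M" if rng.random() < 0.64 else "F"
            edu = float(np.clip(rng.normal(11.3, 2.7), 6, 20))
            if group == "HC":
                egfr = float(np.clip(rng.normal(105, 12), 60, 150))
            else:
                egfr = float(np.clip(rng.normal(8, 3), 2, 15))

            def score(name: str, coupled: float) -> float:
                mu, sd = SCORE_PARAMS[name][group]
                eps = rng.normal()
                return mu + sd * (coupled * zi + np.sqrt(1 - coupled**2) * eps)

            moca_raw = score("moca", 0.0)
            if group == "CI":
                moca = int(np.clip(round(moca_raw), 5, 25))
            else:
                moca = int(np.clip(round(moca_raw), 26, 30))
            tmt_a = float(np.clip(score("tmt_a", -c), 10, 300))
            tmt_b = float(np.clip(score("tmt_b", -c), 15, 400))
            sdmt = int(np.clip(round(score("sdmt", c)), 5, 110))
            records.append(SubjectRecord(sid, group, age, sex, edu, egfr,
                                         moca, tmt_a, tmt_b, sdmt, s["seed"]))

    table = CohortTable(records, dict(config.group_sizes))
    ground_truth = {
        "master_seed": master_seed,
        "attenuation_by_group": config.attenuations,
        "score_coupling": config.score_coupling,
        "base_strength": config.base_strength,
        "dmn_indices": list(model.dmn_indices),
        "dmn_abbreviations": list(seeded_names),
        "subjects": gt_subjects,
    }
    cohort = Cohort(table, timeseries, motion, ground_truth, model, config)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write per-subject TSVs, motion TSVs, cohort.csv, and ground_truth.json."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, ts in cohort.timeseries.items():
        pd.DataFrame(ts.values, columns=ts.region_labels).to_csv(
            out / f"{sid}_roits.tsv", sep="\t", index=False, float_format="%.6g"
        )
        pd.DataFrame(
            cohort.motion[sid].values, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
        ).to_csv(out / f"{sid}_motion.tsv", sep="\t", index=False, float_format="%.6g")
    cohort.table.to_dataframe().to_csv(out / "cohort.csv", index=False, float_format="%.6g")
    (out / "ground_truth.json").write_text(json.dumps(cohort.ground_truth, indent=1))


def read_subject_timeseries(path: str | Path, tr: float) -> TimeSeriesMatrix:
    """Read a `<id>_roits.tsv` written by :func:`write_cohort`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return TimeSeriesMatrix(df.to_numpy(dtype=float), tr, list(df.columns))


def read_subject_motion(path: str | Path, tr: float) -> MotionTrace:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return MotionTrace(df.to_numpy(dtype=float), tr)
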