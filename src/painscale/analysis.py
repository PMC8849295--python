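"""Group-level analyses on scored trial tables.

Group comparisons use assumption-light resampling instead of repeated
measures ANOVA: a paired sign-flip permutation test on subject-level
means for timepoint contrasts (exact enumeration for small cohorts), a
label-shuffle two-sample permutation test for sire contrasts, and Holm
adjustment for multiplicity within a report table.  Uncertainty on group
means comes from a cluster bootstrap that resamples subjects, not trials.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import __version__
from .errors import FeatureUnavailableError, InputError, PairingError, SchemaError, StageError
from .pain_scale import fit_scale, score_trials, vfh_threshold
from .synthetic_data import default_config, generate_cohort
from .trial_model import save_model

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------


def group_summary(
    scored: pd.DataFrame,
    keys=("stimulus", "timepoint"),
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group mean PC1 score with cluster-bootstrap 95% CI.

    The bootstrap resamples subjects (with replacement) and averages
    subject means, respecting within-subject clustering.
    """
    if scored.empty:
        raise InputError("scored table is empty")
    keys = list(keys)
    for k in keys:
        if k not in scored.columns:
            raise SchemaError(f"grouping key {k!r} not in table")
    for col in ("pc1_score", "pain_probability", "pain_call", "subject_id"):
        if col not in scored.columns:
            raise SchemaError(f"column {col!r} required (score the table first)")

    rng = np.random.default_rng(seed)
    rows = []
    for gvals, g in scored.groupby(keys, sort=True, dropna=False):
        if not isinstance(gvals, tuple):
            gvals = (gvals,)
        subj_means = g.groupby("subject_id")["pc1_score"].mean()
        mean = float(subj_means.mean())
        if len(subj_means) == 1:
            lo = hi = float(subj_means.iloc[0])
        else:
            arr = subj_means.to_numpy()
            idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
            boots = arr[idx].mean(axis=1)
            lo, hi = (float(q) for q in np.quantile(boots, [0.025, 0.975]))
            lo, hi = min(lo, mean), max(hi, mean)
        rows.append(
            dict(zip(keys, gvals))
            | {
                "n": int(len(g)),
                "n_subjects": int(len(subj_means)),
                "mean_pc1": mean,
                "ci_low": lo,
                "ci_high": hi,
                "mean_pain_probability": float(g["pain_probability"].mean()),
                "fraction_pain_call": float(g["pain_call"].mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

EXACT_ENUMERATION_LIMIT = 4096  # enumerate all sign patterns when 2**n <= this


@dataclass
class PairedTestResult:
    observed_mean_difference: float
    p_value: float
    n_subjects: int
    exact: bool


def paired_permutation_test(
    baseline_scores,
    post_scores,
    baseline_subjects,
    post_subjects,
    n_perm: int = 9999,
    seed: int = 0,
) -> PairedTestResult:
    """Two-sided sign-flip permutation test on subject-level paired means.

    Trials are aggregated to one mean per subject per condition; the
    statistic is the mean of (post − baseline) subject differences, its
    null distribution generated by flipping the sign of each subject's
    difference.  All ``2**n`` sign patterns are enumerated when
    ``2**n <= 4096``; otherwise ``n_perm`` random flips are drawn and the
    identity pattern is included.
    """
    base = pd.Series(np.asarray(baseline_scores, dtype=float),
                     index=np.asarray(baseline_subjects)).groupby(level=0).mean()
    post = pd.Series(np.asarray(post_scores, dtype=float),
                     index=np.asarray(post_subjects)).groupby(level=0).mean()
    only_base = sorted(set(base.index) - set(post.index))
    only_post = sorted(set(post.index) - set(base.index))
    if only_base or only_post:
        raise PairingError(
            f"unmatched subjects: baseline-only {only_base}, post-only {only_post}"
        )
    subjects = sorted(base.index)
    d = (post[subjects] - base[subjects]).to_numpy()
    n = d.size
    if n == 0:
        raise InputError("no paired subjects")
    obs = float(d.mean())

    if 2**n <= EXACT_ENUMERATION_LIMIT:
        # all sign patterns via the bits of 0..2^n-1
        m = 2**n
        bits = ((np.arange(m)[:, None] >> np.arange(n)[None, :]) & 1).astype(float)
        signs = 1.0 - 2.0 * bits
        null = (signs * d).mean(axis=1)
        p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
        return PairedTestResult(obs, p, n, exact=True)

    if n_perm < 999:
        raise InputError("n_perm must be at least 999")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = (signs * d).mean(axis=1)
    count = int(np.sum(np.abs(null) >= abs(obs) - 1e-12)) + 1  # include identity
    p = count / (n_perm + 1)
    return PairedTestResult(obs, float(p), n, exact=False)


def two_sample_permutation_test(a, b, n_perm: int = 9999, seed: int = 0) -> tuple[float, float]:
    """Label-shuffle permutation test of a mean difference (two-sided).

    Used for sire-group contrasts on subject-level quantities.  Returns
    ``(observed difference a − b, p value)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be nonempty")
    res = stats.permutation_test(
        (a, b),
        lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
        permutation_type="independent",
        alternative="two-sided",
        n_resamples=n_perm,
        rng=np.random.default_rng(seed),
        vectorized=True,
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# orientation heatmap
# ---------------------------------------------------------------------------


def orientation_heatmap(table: pd.DataFrame, stimulus_order) -> pd.Series:
    """Percent of rats lifting the paw before orienting, per stimulus.

    Aggregated per rat first (each rat contributes one proportion per
    stimulus), then averaged across rats, matching a "percentage of
    rats" reading; stimuli are reported in the given intensity order.
    """
    if "lift_before_orient" not in table.columns:
        raise SchemaError("column 'lift_before_orient' required")
    avail = table[table["lift_before_orient"].notna()]
    if avail.empty:
        raise FeatureUnavailableError("lift_before_orient is missing for every trial")
    keys = []
    for stim in stimulus_order:
        if isinstance(stim, tuple):
            name, force = stim
            sub = avail[(avail["stimulus"] == name) & (avail["force_grams"] == force)]
            key = f"{name}@{force:g}"
        else:
            sub = avail[avail["stimulus"] == stim]
            key = str(stim)
        per_rat = sub.groupby("subject_id")["lift_before_orient"].mean()
        keys.append((key, 100.0 * float(per_rat.mean()) if len(per_rat) else np.nan))
    return pd.Series(dict(keys), name="percent_lift_before_orient")[[k for k, _ in keys]]


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_experiment(
    out_dir: str | Path,
    scenario: str | None = None,
    trials_path: str | Path | None = None,
    seed: int = 0,
    n_perm: int = 9999,
) -> Path:
    """Simulate (optional) → fit → score → summaries → tests → report.

    Writes ``cohort.csv`` (if simulated), ``model.json``, ``scored.csv``,
    ``summary.csv``, ``tests.csv`` and ``report.md`` with provenance
    (seed, version, config hash) into ``out_dir``.  Any stage failure
    raises :class:`StageError` naming the stage; partial outputs are kept.
    """
    from .trial_model import read_trials, write_trials

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = {"scenario": scenario, "trials_path": str(trials_path) if trials_path else None,
            "seed": seed, "n_perm": n_perm}

    if scenario is not None:
        try:
            config = default_config(scenario, seed=seed)
            trials, truth = generate_cohort(config)
            write_trials(trials, out / "cohort.csv")
            (out / "cohort.truth.json").write_text(json.dumps(truth, indent=2))
        except Exception as exc:  # noqa: BLE001
            raise StageError("simulate", str(exc)) from exc
    elif trials_path is not None:
        try:
            trials = read_trials(trials_path)
        except Exception as exc:  # noqa: BLE001
            raise StageError("read_trials", str(exc)) from exc
    else:
        raise StageError("configure", "either a scenario or a trials file is required")

    try:
        baseline = trials[(trials["timepoint"] == "baseline")]
        model = fit_scale(baseline, seed=seed)
        save_model(model, out / "model.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError("fit", str(exc)) from exc

    try:
        scored = score_trials(model, trials)
        scored.to_csv(out / "scored.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("score", str(exc)) from exc

    try:
        keys = ["sire", "stimulus", "force_grams", "timepoint"]
        summary = group_summary(scored, keys, seed=seed)
        summary.to_csv(out / "summary.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("summary", str(exc)) from exc

    try:
        tests = _timepoint_tests(scored, n_perm=n_perm, seed=seed)
        tests.to_csv(out / "tests.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("tests", str(exc)) from exc

    try:
        _write_report(out, spec, scored, summary, tests)
    except Exception as exc:  # noqa: BLE001
        raise StageError("report", str(exc)) from exc
    return out


def _timepoint_tests(scored: pd.DataFrame, n_perm: int, seed: int) -> pd.DataFrame:
    """Paired baseline-vs-post tests per sire × stimulus, Holm-adjusted."""
    rows = []
    post_tps = [tp for tp in ("post15min", "post60min") if (scored["timepoint"] == tp).any()]
    for sire, sg in scored.groupby("sire"):
        for stim, g in sg.groupby("stimulus"):
            base = g[g["timepoint"] == "baseline"]
            for tp in post_tps:
                post = g[g["timepoint"] == tp]
                if base.empty or post.empty:
                    continue
                res = paired_permutation_test(
                    base["pc1_score"], post["pc1_score"],
                    base["subject_id"], post["subject_id"],
                    n_perm=n_perm, seed=seed,
                )
                rows.append(
                    {
                        "sire": sire, "stimulus": stim, "contrast": f"{tp} - baseline",
                        "mean_difference": res.observed_mean_difference,
                        "p_value": res.p_value, "n_subjects": res.n_subjects,
                        "exact": res.exact,
                    }
                )
    tests = pd.DataFrame(rows)
    if not tests.empty:
        tests["p_holm"] = multipletests(tests["p_value"], method="holm")[1]
    return tests


def _write_report(out: Path, spec: dict, scored: pd.DataFrame, summary: pd.DataFrame, tests: pd.DataFrame):
    lines = [
        "# painscale experiment report",
        "",
        f"- package version: {__version__}",
        f"- seed: {spec['seed']}",
        f"- scenario: {spec['scenario']}",
        f"- config hash: {_config_hash(spec)}",
        f"- trials scored: {len(scored)}",
        "",
        "## Group summary (mean PC1, cluster-bootstrap 95% CI)",
        "",
        summary.to_markdown(index=False),
        "",
    ]
    if not tests.empty:
        lines += [
            "## Timepoint contrasts (paired sign-flip permutation, Holm-adjusted)",
            "",
            tests.to_markdown(index=False),
            "",
        ]
    if {"VFH"} <= set(scored["stimulus"].unique()) and "pain_probability" in scored.columns:
        vfh = scored[scored["stimulus"] == "VFH"]
        by_force = vfh.groupby("force_grams")["pain_probability"].mean().mul(100.0)
        lines += [
            "## Mean pain-like probability per von Frey force (%)",
            "",
            by_force.to_frame("mean_pain_probability_pct").to_markdown(),
            "",
        ]
    (out / "report.md").write_text("\n".join(lines))


@dataclass
class MultigenerationalReplicate:
    """One simulated multigenerational experiment, analyzed both ways."""

    pain_scale_p: float          # morphine-sired HP baseline vs post15min, paired
    saline_pain_scale_p: float   # same contrast in saline-sired controls
    vfh_sire_p: float            # sire contrast on VFH threshold change
    pain_mean_difference: float


def multigenerational_replicate(seed: int, n_subjects: int = 12) -> MultigenerationalReplicate:
    """Simulate one multigenerational cohort and analyze it both ways.

    The pain-scale route fits the scale on the cohort's own baseline
    trials, scores everything, and runs the paired sign-flip test on the
    morphine-sired HP 15-min contrast.  The traditional route assigns
    each subject a morphine-insensitive mechanical sensitivity, simulates
    ascending von Frey series at baseline and 15 min, and compares
    threshold changes between sire groups with a label-shuffle test.
    """
    from .synthetic_data import generate_vfh_response_series

    config = default_config("multigenerational", seed=seed, n_subjects=n_subjects)
    trials, _ = generate_cohort(config)
    baseline = trials[trials["timepoint"] == "baseline"]
    model = fit_scale(baseline, seed=seed)
    scored = score_trials(model, trials)

    def paired_p(sire):
        g = scored[(scored["stimulus"] == "HP") & (scored["sire"] == sire)]
        b = g[g["timepoint"] == "baseline"]
        p = g[g["timepoint"] == "post15min"]
        return paired_permutation_test(
            b["pc1_score"], p["pc1_score"], b["subject_id"], p["subject_id"], seed=seed
        )

    res_m = paired_p("morphine_sired")
    res_s = paired_p("saline_sired")

    deltas = {}
    for i_s, sire in enumerate(("saline_sired", "morphine_sired")):
        ds = []
        for subj in range(n_subjects):
            rng = np.random.default_rng([seed, i_s, subj])
            sens = float(rng.lognormal(np.log(8.0), 0.3))  # grams; unchanged by morphine
            th_b = vfh_threshold(generate_vfh_response_series(sens, seed=seed * 1000 + i_s * 100 + 2 * subj))
            th_p = vfh_threshold(generate_vfh_response_series(sens, seed=seed * 1000 + i_s * 100 + 2 * subj + 1))
            ds.append((th_p if th_p is not None else 300.0) - (th_b if th_b is not None else 300.0))
        deltas[sire] = ds
    _, vfh_p = two_sample_permutation_test(
        deltas["morphine_sired"], deltas["saline_sired"], n_perm=999, seed=seed
    )
    return MultigenerationalReplicate(
        pain_scale_p=res_m.p_value,
        saline_pain_scale_p=res_s.p_value,
        vfh_sire_p=vfh_p,
        pain_mean_difference=res_m.observed_mean_difference,
    )


def vfh_threshold_table(series_by_subject: dict) -> pd.DataFrame:
    """Traditional thresholds for a mapping subject -> force response map."""
    rows = []
    for subj, series in series_by_subject.items():
        th = vfh_threshold(series)
        rows.append({"subject_id": subj, "threshold_g": np.nan if th is None else th})
    return pd.DataFrame(rows)
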