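"""End-to-end experiment pipelines over the synthetic generator.

These drivers simulate one subject at a time (patterns, epochs, behavior),
preprocess, reduce to per-subject similarity timecourses or amplitude
tables, and then run the group-level statistics, so a full-scale
experiment (25 subjects x 240 trials x 62 channels x 1,750 samples) never
holds more than one subject's raw data in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import erp, rsa
from .design import CONGRUENT, DesignTable, INCONGRUENT_MATCH, INCONGRUENT_MISMATCH
from .erp import FRONTOCENTRAL, ROIS, TestResult
from .preprocess import baseline_correct, filter_epochs, reject_artifacts
from .simulate import (
    EpochSet,
    SimParams,
    default_design,
    generate_item_patterns,
    simulate_behavior,
    simulate_epochs,
)

__all__ = [
    "RsaExperimentResult",
    "ErpExperimentResult",
    "simulate_subject",
    "run_rsa_experiment",
    "run_erp_experiment",
]

#: Analysis windows in ms relative to noun onset.
PRENOUN_WINDOW = (-2000.0, 0.0)
POSTNOUN_WINDOW = (0.0, 1000.0)
CLASSIFIER_INTERVAL = (-2000.0, -1000.0)


@dataclass
class RsaExperimentResult:
    """Group-level output of one simulated RSA experiment."""

    times: np.ndarray  # ms, analysis window
    r_animate: np.ndarray  # (subjects, time)
    r_inanimate: np.ndarray
    t_series: np.ndarray
    df: int
    clusters: list[rsa.ClusterResult]
    rejection_rate: float

    def significant_clusters(self) -> list[rsa.ClusterResult]:
        return [c for c in self.clusters if c.significant]


@dataclass
class ErpExperimentResult:
    """Group-level amplitude and behavioral statistics of one experiment."""

    amplitudes: pd.DataFrame  # subject x (classifier type, congruency, roi)
    anova: dict[str, TestResult]
    congruency_by_roi: pd.DataFrame  # incongruent-vs-congruent per ROI
    mismatch_by_roi: pd.DataFrame  # mismatch-vs-match per classifier type x ROI
    prenoun_vs_zero: dict[str, TestResult]
    prenoun_condition_diff: TestResult
    rt: TestResult
    rt_difference_ms: float
    rt_means: dict[str, float]


def simulate_subject(
    design: DesignTable,
    params: SimParams,
    rng: np.random.Generator,
    dtype=np.float32,
) -> EpochSet:
    """One subject's epochs with subject-specific item patterns."""
    patterns = generate_item_patterns(design, params, rng)
    solo = replace(params, n_subjects=1)
    return simulate_epochs(design, patterns, solo, rng, dtype=dtype)


def _subject_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_rsa_experiment(
    params: SimParams | None = None,
    design: DesignTable | None = None,
    seed: int = 0,
    analysis: str = "prenoun",
    baseline: tuple[float, float] | None = (-2500.0, -2000.0),
    filter_band: tuple[float, float] | None = None,
    reject_uv: float | None = 70.0,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    fisher_z: bool = False,
    dtype=np.float32,
) -> RsaExperimentResult:
    """Simulate a full experiment and run the time-resolved RSA.

    ``analysis="prenoun"`` computes classifier-locked similarity from
    classifier onset to noun onset (item = classifier, all surviving
    trials); ``"postnoun"`` computes noun-locked similarity over the noun
    display (item = each classifier's congruent-noun set).  Epochs are
    baseline-corrected on the pre-classifier interval, optionally
    band-pass filtered, and amplitude/accuracy rejected; the condition
    contrast is assessed with the sign-flip max-cluster permutation test.
    """
    params = params or SimParams()
    design = design if design is not None else default_design(rng_seed=seed)
    if analysis == "prenoun":
        window, item_key = PRENOUN_WINDOW, "classifier"
    elif analysis == "postnoun":
        window, item_key = POSTNOUN_WINDOW, "noun_set"
    else:
        raise ValueError(f"unknown analysis {analysis!r}")

    rngs = _subject_rngs(seed, params.n_subjects + 1)
    behavior = simulate_behavior(design, params, rngs[-1])

    animate_ids = design.classifier_ids("animate")
    inanimate_ids = design.classifier_ids("inanimate")
    r_a, r_i = [], []
    dropped = kept_total = 0
    times_win = None
    for s in range(params.n_subjects):
        epochs = simulate_subject(design, params, rngs[s], dtype=dtype)
        if filter_band is not None:
            epochs = filter_epochs(epochs, *filter_band)
        if baseline is not None:
            epochs = baseline_correct(epochs, baseline)
        if reject_uv is not None:
            beh_s = behavior[behavior["subject"] == s].assign(subject=0)
            epochs, log = reject_artifacts(epochs, beh_s, reject_uv)
            dropped += int((~log.table["kept"]).sum())
            kept_total += len(log.table)
        erps = rsa.item_erps(epochs, item_key=item_key)[0]
        idx = epochs.time_indices(window)
        if times_win is None:
            times_win = epochs.times[idx]
        by_id = {e.item_id: e for e in erps}
        for ids, store in ((animate_ids, r_a), (inanimate_ids, r_i)):
            items = [
                rsa.ItemERP(i, by_id[i].data[:, idx]) for i in ids
            ]
            tc = rsa.similarity_timecourse(items, fisher_z=fisher_z)
            store.append(tc.r_mean)

    r_a = np.vstack(r_a)
    r_i = np.vstack(r_i)
    t_series, df = rsa.condition_contrast_timecourse(r_a, r_i)
    clusters = rsa.permutation_cluster_test(
        r_a - r_i,
        n_permutations=n_permutations,
        seed=seed,
        cluster_alpha=cluster_alpha,
        times=times_win,
    )
    return RsaExperimentResult(
        times=times_win,
        r_animate=r_a,
        r_inanimate=r_i,
        t_series=t_series,
        df=df,
        clusters=clusters,
        rejection_rate=(dropped / kept_total) if kept_total else 0.0,
    )


def run_erp_experiment(
    params: SimParams | None = None,
    design: DesignTable | None = None,
    seed: int = 0,
    n400_window: tuple[float, float] = (300.0, 500.0),
    pred_window: tuple[float, float] = (-200.0, 0.0),
    pred_baseline: tuple[float, float] = (-300.0, -200.0),
    reject_uv: float | None = 70.0,
    fdr_q: float = 0.05,
    dtype=np.float32,
) -> ErpExperimentResult:
    """Simulate a full experiment and run the amplitude statistics.

    Computes (a) N400 mean amplitudes 300-500 ms per classifier type x
    congruency x ROI with the 2 x 3 x 9 within-subject ANOVA, the
    incongruent-vs-congruent contrast per ROI, and the mismatch-vs-match
    contrast per classifier type and ROI (both FDR-corrected across
    ROIs); (b) the pre-noun mean amplitude over ``pred_window`` at the
    nine fronto-central electrodes after re-baselining on
    ``pred_baseline``, tested against zero per condition; and (c) the
    behavioral latency contrast.
    """
    params = params or SimParams()
    design = design if design is not None else default_design(rng_seed=seed)
    rngs = _subject_rngs(seed, params.n_subjects + 1)
    behavior = simulate_behavior(design, params, rngs[-1])

    amp_rows = []
    pre_rows = []
    for s in range(params.n_subjects):
        epochs = simulate_subject(design, params, rngs[s], dtype=dtype)
        epochs = baseline_correct(epochs, (params.epoch_span[0],
                                           params.epoch_span[0] + 500.0))
        if reject_uv is not None:
            beh_s = behavior[behavior["subject"] == s].assign(subject=0)
            epochs, _ = reject_artifacts(epochs, beh_s, reject_uv)
        for roi, electrodes in ROIS.items():
            tab = erp.mean_amplitude(epochs, n400_window, electrodes)
            tab["roi"] = roi
            tab["subject"] = s
            amp_rows.append(tab)
        pre = baseline_correct(epochs, pred_baseline)
        tab = erp.mean_amplitude(
            pre, pred_window, FRONTOCENTRAL, group_by=("animacy_constraint",)
        )
        tab["subject"] = s
        pre_rows.append(tab)

    amplitudes = pd.concat(amp_rows, ignore_index=True).rename(
        columns={"animacy_constraint": "classifier_type"}
    )
    prenoun = pd.concat(pre_rows, ignore_index=True)

    anova = erp.rm_anova(
        amplitudes, factors=["classifier_type", "congruency", "roi"]
    )

    cell = amplitudes.pivot_table(
        index="subject", columns=["classifier_type", "congruency", "roi"],
        values="mean_uv",
    )

    def _contrast(rows_a, rows_b) -> TestResult:
        return erp.t_test(rows_a, rows_b, mode="paired")

    cong_rows = []
    for roi in ROIS:
        inc = np.mean(
            [
                cell[(ct, cg, roi)]
                for ct in ("animate", "inanimate")
                for cg in (INCONGRUENT_MATCH, INCONGRUENT_MISMATCH)
            ],
            axis=0,
        )
        con = np.mean(
            [cell[(ct, CONGRUENT, roi)] for ct in ("animate", "inanimate")],
            axis=0,
        )
        res = _contrast(inc, con)
        cong_rows.append((roi, res.statistic, res.df, res.p_value))
    congruency_by_roi = pd.DataFrame(
        cong_rows, columns=["roi", "t", "df", "p"]
    )
    congruency_by_roi["significant"], congruency_by_roi["p_fdr"] = erp.fdr_bh(
        congruency_by_roi["p"], fdr_q
    )

    mm_rows = []
    for ct in ("animate", "inanimate"):
        block = []
        for roi in ROIS:
            res = _contrast(
                cell[(ct, INCONGRUENT_MISMATCH, roi)],
                cell[(ct, INCONGRUENT_MATCH, roi)],
            )
            block.append((ct, roi, res.statistic, res.df, res.p_value))
        sub = pd.DataFrame(
            block, columns=["classifier_type", "roi", "t", "df", "p"]
        )
        sub["significant"], sub["p_fdr"] = erp.fdr_bh(sub["p"], fdr_q)
        mm_rows.append(sub)
    mismatch_by_roi = pd.concat(mm_rows, ignore_index=True)

    pre_cell = prenoun.pivot_table(
        index="subject", columns="animacy_constraint", values="mean_uv"
    )
    prenoun_vs_zero = {
        ct: erp.t_test(pre_cell[ct], mode="one_sample_vs_zero")
        for ct in pre_cell.columns
    }
    prenoun_condition_diff = erp.t_test(
        pre_cell["animate"], pre_cell["inanimate"], mode="paired"
    )

    rt_res, rt_diff, rt_means = erp.rt_contrast(behavior)
    return ErpExperimentResult(
        amplitudes=amplitudes,
        anova=anova,
        congruency_by_roi=congruency_by_roi,
        mismatch_by_roi=mismatch_by_roi,
        prenoun_vs_zero=prenoun_vs_zero,
        prenoun_condition_diff=prenoun_condition_diff,
        rt=rt_res,
        rt_difference_ms=rt_diff,
        rt_means=rt_means,
    )
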