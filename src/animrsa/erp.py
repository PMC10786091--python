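"""Amplitude-domain ERP statistics.

Covers the two amplitude analyses of a classifier-noun prediction study:
the pre-noun "prediction potential" (mean amplitude over the last 200 ms
before noun onset at nine fronto-central electrodes, tested against zero)
and the post-noun N400 (mean amplitude 300-500 ms at nine scalp ROIs,
entered into a 2 x 3 x 9 within-subject ANOVA of classifier type x
congruency x ROI), plus the behavioral latency contrast.

Window convention throughout: half-open ``[start, end)`` ms, inclusive of
the sample at ``start``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .design import CONGRUENT, INCONGRUENT_MATCH, INCONGRUENT_MISMATCH
from .exceptions import ParameterError
from .simulate import EpochSet

__all__ = [
    "FRONTOCENTRAL",
    "ROIS",
    "TestResult",
    "mean_amplitude",
    "t_test",
    "rm_anova",
    "fdr_bh",
    "rt_contrast",
]

#: Fronto-central electrodes where the prediction potential is measured.
FRONTOCENTRAL = ["FC1", "FCZ", "FC2", "C1", "CZ", "C2", "CP1", "CPZ", "CP2"]

#: The nine scalp regions of interest for the N400 distribution analysis.
ROIS: dict[str, list[str]] = {
    "left_anterior": ["F3", "F5", "FC3"],
    "middle_anterior": ["FZ"],
    "right_anterior": ["F4", "F6", "FC4"],
    "left_middle": ["C3", "C5"],
    "middle_middle": ["CZ"],
    "right_middle": ["C4", "C6"],
    "left_posterior": ["P3", "P5"],
    "middle_posterior": ["PZ"],
    "right_posterior": ["P4", "P6"],
}


@dataclass(frozen=True)
class TestResult:
    """A single test statistic with df, p and direction.

    ``degenerate`` marks zero-variance inputs whose p-value is not
    meaningful (treated as non-significant downstream).
    """

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    direction: int = 0  # sign of the effect (-1, 0, +1)
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < 0.05


def mean_amplitude(
    epochs: EpochSet,
    window_ms: tuple[float, float],
    electrodes: Sequence[str],
    group_by: Sequence[str] = ("animacy_constraint", "congruency"),
) -> pd.DataFrame:
    """Mean amplitude per subject x condition cell.

    Averages over the samples in ``[start, end)`` ms, the listed
    electrodes, and the surviving trials of each cell defined by the
    ``group_by`` columns of the design table.  Returns a long-format frame
    with columns ``subject``, ``*group_by``, ``mean_uv`` and ``n_trials``.
    """
    tidx = epochs.time_indices(window_ms)
    if tidx.size == 0:
        raise ParameterError(f"window {window_ms} contains no samples")
    cidx = epochs.ch_index(electrodes)
    per_trial = epochs.data[:, :, cidx][..., tidx].mean(axis=(2, 3))  # (S, T)

    cells = epochs.design.trials[list(group_by)]
    rows = []
    for s in range(epochs.n_subjects):
        kept = epochs.kept(s)
        df = cells.assign(val=per_trial[s])[kept]
        agg = df.groupby(list(group_by), observed=True)["val"].agg(["mean", "size"])
        for key, (m, n) in agg.iterrows():
            key = (key,) if not isinstance(key, tuple) else key
            rows.append((s, *key, m, int(n)))
    return pd.DataFrame(
        rows, columns=["subject", *group_by, "mean_uv", "n_trials"]
    )


def t_test(
    values_a: Sequence[float],
    values_b: Sequence[float] | None = None,
    mode: str = "one_sample_vs_zero",
) -> TestResult:
    """Student t-test: one-sample against zero, or paired.

    Zero-variance input yields a degenerate result (t = 0, p = 1 when the
    mean is also zero, otherwise an infinite statistic with p = 0).
    """
    a = np.asarray(values_a, dtype=float)
    if mode == "paired":
        if values_b is None:
            raise ParameterError("paired mode needs two samples")
        b = np.asarray(values_b, dtype=float)
        if a.shape != b.shape:
            raise ParameterError("paired samples must have equal length")
        d = a - b
    elif mode == "one_sample_vs_zero":
        if values_b is not None:
            raise ParameterError("one-sample mode takes a single sample")
        d = a
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    n = d.size
    if n < 2:
        raise ParameterError("need at least two observations")
    df = n - 1
    sd = d.std(ddof=1)
    m = d.mean()
    if sd == 0.0:
        if m == 0.0:
            return TestResult(0.0, df, 1.0, 0, degenerate=True)
        return TestResult(float(np.sign(m)) * np.inf, df, 0.0,
                          int(np.sign(m)), degenerate=True)
    t = m / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), df, float(p), int(np.sign(t)))


def rm_anova(
    table: pd.DataFrame,
    factors: Sequence[str],
    depvar: str = "mean_uv",
    subject: str = "subject",
) -> dict[str, TestResult]:
    """Repeated-measures ANOVA over fully-crossed within-subject factors.

    Thin wrapper over a standard within-subject sums-of-squares
    decomposition (statsmodels ``AnovaRM``); no sphericity correction is
    applied.  Returns one :class:`TestResult` per main effect and
    interaction, keyed like ``"classifier_type:congruency"``.
    """
    counts = table.groupby([subject, *factors], observed=True).size()
    n_cells = table[subject].nunique() * int(
        np.prod([table[f].nunique() for f in factors])
    )
    if len(counts) != n_cells or counts.max() != counts.min():
        raise ParameterError("design must be complete and balanced")
    try:
        fit = AnovaRM(
            data=table, depvar=depvar, subject=subject, within=list(factors),
            aggregate_func="mean",
        ).fit()
    except ValueError as e:
        raise ParameterError(str(e)) from None
    out: dict[str, TestResult] = {}
    for effect, row in fit.anova_table.iterrows():
        f = float(row["F Value"])
        out[effect.replace(":", ":")] = TestResult(
            statistic=f,
            df=(float(row["Num DF"]), float(row["Den DF"])),
            p_value=float(row["Pr > F"]),
            direction=0,
        )
    return out


def fdr_bh(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up selection and adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, p_adj


def rt_contrast(
    behavior: pd.DataFrame, mode: str = "paired"
) -> tuple[TestResult, float, dict[str, float]]:
    """Latency contrast: animacy-match minus animacy-mismatch (ms).

    Responses exist only for incongruent phrases; a positive difference
    means judgments were faster when the noun additionally violated the
    classifier's animacy constraint.  ``mode="paired"`` compares
    per-subject condition means; ``"independent"`` pools trials.
    """
    inc = behavior[behavior["congruency"] != CONGRUENT]
    means = inc.groupby("congruency", observed=True)["rt_ms"].mean()
    for lev in (INCONGRUENT_MATCH, INCONGRUENT_MISMATCH):
        if lev not in means.index:
            raise ParameterError(f"condition {lev!r} missing from behavior table")
    diff = float(means[INCONGRUENT_MATCH] - means[INCONGRUENT_MISMATCH])
    if mode == "paired":
        cell = inc.groupby(["subject", "congruency"], observed=True)["rt_ms"].mean()
        a = cell.xs(INCONGRUENT_MATCH, level="congruency")
        b = cell.xs(INCONGRUENT_MISMATCH, level="congruency")
        common = a.index.intersection(b.index)
        res = t_test(a[common], b[common], mode="paired")
    elif mode == "independent":
        a = inc.loc[inc["congruency"] == INCONGRUENT_MATCH, "rt_ms"]
        b = inc.loc[inc["congruency"] == INCONGRUENT_MISMATCH, "rt_ms"]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        res = TestResult(float(t), float(len(a) + len(b) - 2), float(p),
                         int(np.sign(t)))
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return res, diff, {k: float(v) for k, v in means.items()}
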