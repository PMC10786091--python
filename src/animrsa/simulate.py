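"""Synthetic epoched EEG and behavioral latencies with known ground truth.

The generator emulates a classifier-noun reading experiment: 25 subjects,
62 channels, 500 Hz, 3,500 ms epochs spanning a 500 ms pre-stimulus
baseline, a 1,000 ms classifier display, a 1,000 ms blank interval and a
1,000 ms noun display, with t = 0 at noun onset.

Per-trial signal model (all terms in μV)::

    x(c, t) = pred_amplitude * w_pred(t) * pattern_noun(c)
            - pred_shift     * w_pred(t) * topo(c)
            - n400_weight    * n400_amplitude * w_n400(t) * topo(c)
            + noun_amplitude * w_noun(t) * pattern_noun(c)
            + classifier_amplitude * w_clf(t) * pattern_classifier(c)
            + noise(c, t)

where the ``w`` are Hann envelopes over their windows, ``topo`` is a fixed
centro-parietal topography peaking at Cz, and ``pattern_noun`` carries the
ground-truth similarity structure: nouns of animacy group *g* share a
common spatial component with weight ``sqrt(rho_g)``, so the expected
pairwise pattern correlation within the group is ``rho_g``.  The N400 is a
negative deflection graded by congruency; by default the extra
animacy-mismatch negativity exists only under animate-constraining
classifiers, matching the asymmetry the analysis is meant to recover.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .design import (
    CONGRUENT,
    INCONGRUENT_MATCH,
    INCONGRUENT_MISMATCH,
    DesignTable,
    assign_blocks,
    build_design,
    default_lexicon,
)
from .exceptions import ParameterError

__all__ = [
    "CHANNELS_62",
    "SimParams",
    "EpochSet",
    "default_design",
    "scalp_topography",
    "generate_item_patterns",
    "simulate_epochs",
    "simulate_behavior",
]

# 62-channel 10-10 montage (Neuroscan-style labels).
CHANNELS_62 = [
    "FP1", "FPZ", "FP2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "O1", "OZ", "O2",
]
assert len(CHANNELS_62) == 62

_ROW_WEIGHT = {
    "FP": 0.10, "AF": 0.20, "F": 0.45, "FT": 0.40, "FC": 0.75, "T": 0.40,
    "C": 1.00, "TP": 0.50, "CP": 0.90, "P": 0.65, "PO": 0.35, "O": 0.15,
}
_LAT_WEIGHT = {0: 1.0, 1: 0.9, 2: 0.9, 3: 0.7, 4: 0.7, 5: 0.45, 6: 0.45,
               7: 0.25, 8: 0.25}


def scalp_topography(ch_names: Sequence[str]) -> np.ndarray:
    """Smooth centro-parietal weighting peaking at Cz (value 1).

    Used both for the N400 deflection and for the deterministic pre-noun
    negative shift; weights fall off towards anterior, posterior and
    lateral sites.
    """
    out = np.empty(len(ch_names))
    for i, name in enumerate(ch_names):
        m = re.fullmatch(r"([A-Z]+?)(Z|\d+)", name.upper())
        if not m:
            raise ParameterError(f"cannot parse channel label {name!r}")
        row, lat = m.group(1), m.group(2)
        out[i] = _ROW_WEIGHT[row] * (_LAT_WEIGHT[0] if lat == "Z"
                                     else _LAT_WEIGHT[int(lat)])
    return out


def _default_n400_weights() -> dict[tuple[str, str], float]:
    # The extra animacy-mismatch negativity is present only under
    # animate-constraining classifiers (match weight == mismatch weight on
    # the inanimate side reproduces the reported null).
    return {
        ("animate", CONGRUENT): 0.0,
        ("animate", INCONGRUENT_MATCH): 1.0,
        ("animate", INCONGRUENT_MISMATCH): 2.0,
        ("inanimate", CONGRUENT): 0.0,
        ("inanimate", INCONGRUENT_MATCH): 1.0,
        ("inanimate", INCONGRUENT_MISMATCH): 1.0,
    }


@dataclass(frozen=True)
class SimParams:
    """Ground-truth parameters of the synthetic experiment.

    Windows are in ms relative to noun onset (t = 0); amplitudes in μV.
    ``rho_animate``/``rho_inanimate`` are the within-group expected pairwise
    pattern correlations carried by the noun patterns during the
    pre-activation and noun windows.
    """

    n_subjects: int = 25
    n_channels: int = 62
    fs: float = 500.0
    epoch_span: tuple[float, float] = (-2500.0, 1000.0)
    rho_animate: float = 0.5
    rho_inanimate: float = 0.1
    pred_window: tuple[float, float] = (-240.0, 0.0)
    pred_amplitude: float = 5.0
    pred_shift: float = 2.0
    noun_window: tuple[float, float] = (0.0, 1000.0)
    noun_amplitude: float = 2.0
    classifier_window: tuple[float, float] = (-2000.0, -1000.0)
    classifier_amplitude: float = 0.0
    n400_window: tuple[float, float] = (300.0, 500.0)
    n400_amplitude: float = 3.0
    n400_weights: Mapping[tuple[str, str], float] = field(
        default_factory=_default_n400_weights
    )
    noise_sd: float = 14.0
    ar_coef: float = 0.0
    rt_base: float = 674.0
    rt_mismatch_advantage: float = 22.0
    rt_sd: float = 195.0
    p_correct: float = 0.953
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        for name in ("rho_animate", "rho_inanimate"):
            rho = getattr(self, name)
            if not (0.0 <= rho < 1.0):
                raise ParameterError(f"{name} must lie in [0, 1)")
        lo, hi = self.epoch_span
        for wname in ("pred_window", "noun_window", "classifier_window",
                      "n400_window"):
            a, b = getattr(self, wname)
            if not (lo <= a < b <= hi):
                raise ParameterError(f"{wname} {a, b} outside epoch span")
        if self.noise_sd < 0 or self.rt_sd < 0:
            raise ParameterError("noise_sd and rt_sd must be non-negative")
        if not (0.0 < self.p_correct <= 1.0):
            raise ParameterError("p_correct must lie in (0, 1]")
        if not (-1.0 < self.ar_coef < 1.0):
            raise ParameterError("ar_coef must lie in (-1, 1)")

    def times(self) -> np.ndarray:
        """Uniform time axis in ms, t = 0 at noun onset."""
        dt = 1000.0 / self.fs
        n = int(round((self.epoch_span[1] - self.epoch_span[0]) / dt))
        return self.epoch_span[0] + dt * np.arange(n)

    def channel_names(self) -> list[str]:
        if self.n_channels == len(CHANNELS_62):
            return list(CHANNELS_62)
        if self.n_channels < len(CHANNELS_62):
            # keep the analysis electrodes (fronto-central strip and the
            # nine scalp ROIs) first so reduced-channel simulations still
            # cover the measurement sites
            first = [
                "CZ", "FCZ", "CPZ", "C1", "C2", "FC1", "FC2", "CP1", "CP2",
                "FZ", "PZ", "C3", "C4", "C5", "C6", "F3", "F4", "F5", "F6",
                "FC3", "FC4", "P3", "P4", "P5", "P6",
            ]
            priority = first + [c for c in CHANNELS_62 if c not in first]
            return priority[: self.n_channels]
        return list(CHANNELS_62) + [
            f"X{i}" for i in range(1, self.n_channels - len(CHANNELS_62) + 1)
        ]


@dataclass
class EpochSet:
    """Epoched multichannel EEG: subjects x trials x channels x time (μV)."""

    data: np.ndarray
    times: np.ndarray
    fs: float
    ch_names: list[str]
    design: DesignTable
    keep_mask: np.ndarray | None = None  # (n_subjects, n_trials) bool

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ParameterError("data must be 4-D (subjects, trials, channels, time)")
        n_s, n_t, n_c, n_time = self.data.shape
        if n_time != len(self.times):
            raise ParameterError("time axis length mismatch")
        if n_c != len(self.ch_names):
            raise ParameterError("channel label count mismatch")
        if n_t != len(self.design.trials):
            raise ParameterError("trial dimension does not match design")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1000.0 / self.fs)):
            raise ParameterError("times must increase uniformly at 1000/fs ms")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def ch_index(self, names: Sequence[str]) -> np.ndarray:
        """Channel indices for labels (case-insensitive, so Cz == CZ)."""
        lut = {c.upper(): i for i, c in enumerate(self.ch_names)}
        try:
            return np.array([lut[n.upper()] for n in names])
        except KeyError as e:
            raise ParameterError(f"unknown electrode {e.args[0]!r}") from None

    def time_indices(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Sample indices with window convention [start, end) ms."""
        a, b = window_ms
        idx = np.nonzero((self.times >= a - 1e-9) & (self.times < b - 1e-9))[0]
        return idx

    def kept(self, subject: int) -> np.ndarray:
        if self.keep_mask is None:
            return np.ones(self.data.shape[1], dtype=bool)
        return self.keep_mask[subject]

    def copy_with(self, data: np.ndarray | None = None,
                  keep_mask: np.ndarray | None = None) -> "EpochSet":
        return EpochSet(
            data=self.data if data is None else data,
            times=self.times,
            fs=self.fs,
            ch_names=list(self.ch_names),
            design=self.design,
            keep_mask=self.keep_mask if keep_mask is None else keep_mask,
        )

    def save(self, path: str | Path) -> None:
        """Persist to HDF5 with a JSON metadata sidecar (``<path>.json``)."""
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            if self.keep_mask is not None:
                f.create_dataset("keep_mask", data=self.keep_mask)
            f.attrs["fs"] = self.fs
            f.attrs["ch_names"] = json.dumps(self.ch_names)
            for name in ("trials", "classifiers", "nouns"):
                f.attrs[f"design_{name}"] = getattr(self.design, name).to_csv(
                    sep="\t", index=False
                )
        sidecar = {
            "fs": self.fs,
            "n_subjects": int(self.data.shape[0]),
            "n_trials": int(self.data.shape[1]),
            "ch_names": self.ch_names,
            "t_start_ms": float(self.times[0]),
            "t_stop_ms": float(self.times[-1]),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        import io

        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times"][()]
            keep = f["keep_mask"][()] if "keep_mask" in f else None
            fs = float(f.attrs["fs"])
            ch_names = json.loads(f.attrs["ch_names"])
            frames = {
                name: pd.read_csv(
                    io.StringIO(f.attrs[f"design_{name}"]), sep="\t"
                )
                for name in ("trials", "classifiers", "nouns")
            }
        design = DesignTable(frames["trials"], frames["classifiers"], frames["nouns"])
        return cls(data, times, fs, ch_names, design, keep)


def default_design(rng_seed: int = 0, n_blocks: int = 3) -> DesignTable:
    """The canonical 12-classifier x 120-noun design with blocks assigned."""
    classifiers, nouns = default_lexicon(rng_seed=rng_seed)
    design = build_design(classifiers, nouns, rng_seed=rng_seed)
    return assign_blocks(design, n_blocks, rng_seed=rng_seed)


def hann_envelope(times: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    """Hann (sin^2) envelope supported on [start, end] ms, zero elsewhere."""
    a, b = window_ms
    env = np.zeros_like(times, dtype=float)
    inside = (times >= a) & (times <= b)
    env[inside] = np.sin(np.pi * (times[inside] - a) / (b - a)) ** 2
    return env


def generate_item_patterns(
    design: DesignTable, params: SimParams, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Spatial patterns per item with group-structured noun similarity.

    For a noun of animacy group *g* the pattern is
    ``sqrt(rho_g) * shared_g + sqrt(1 - rho_g) * unique``, with shared and
    unique components i.i.d. standard normal across channels; the expected
    pairwise correlation of two noun patterns within the group is
    ``rho_g``.  Classifier patterns are mutually independent (no shared
    group component) so any classifier-locked similarity difference is a
    false positive by construction.
    """
    n_c = params.n_channels
    shared = {
        "animate": rng.standard_normal(n_c),
        "inanimate": rng.standard_normal(n_c),
    }
    rho = {"animate": params.rho_animate, "inanimate": params.rho_inanimate}
    patterns: dict[str, np.ndarray] = {}
    for _, row in design.nouns.iterrows():
        g = row["animacy"]
        patterns[row["id"]] = np.sqrt(rho[g]) * shared[g] + np.sqrt(
            1.0 - rho[g]
        ) * rng.standard_normal(n_c)
    for cid in design.classifiers["id"]:
        patterns[cid] = rng.standard_normal(n_c)
    return patterns


def _add_trial_signals(
    out: np.ndarray,
    design: DesignTable,
    params: SimParams,
    times: np.ndarray,
    patterns: Mapping[str, np.ndarray],
) -> None:
    """Add the deterministic signal into ``out`` (trials, ch, time) in place.

    Each component touches only its envelope's support, so assembly cost is
    proportional to the component windows, not the epoch length.
    """
    topo = scalp_topography(params.channel_names())
    trials = design.trials
    noun_pat = np.stack([patterns[n] for n in trials["noun_id"]])  # (T, C)

    def add(env: np.ndarray, spatial: np.ndarray) -> None:
        sl = np.nonzero(env > 0)[0]
        if sl.size == 0:
            return
        lo, hi = sl[0], sl[-1] + 1
        spatial = spatial.astype(out.dtype, copy=False)
        env = env[lo:hi].astype(out.dtype, copy=False)
        out[:, :, lo:hi] += spatial[:, :, None] * env[None, None, :]

    add(
        hann_envelope(times, params.pred_window),
        params.pred_amplitude * noun_pat - params.pred_shift * topo[None, :],
    )
    w = np.array(
        [
            params.n400_weights[(ac, cg)]
            for ac, cg in zip(trials["animacy_constraint"], trials["congruency"])
        ]
    )
    add(
        hann_envelope(times, params.n400_window),
        -(w * params.n400_amplitude)[:, None] * topo[None, :],
    )
    if params.noun_amplitude:
        add(hann_envelope(times, params.noun_window),
            params.noun_amplitude * noun_pat)
    if params.classifier_amplitude:
        clf_pat = np.stack([patterns[c] for c in trials["classifier_id"]])
        add(hann_envelope(times, params.classifier_window),
            params.classifier_amplitude * clf_pat)


def simulate_epochs(
    design: DesignTable,
    patterns: Mapping[str, np.ndarray] | Sequence[Mapping[str, np.ndarray]],
    params: SimParams,
    rng: np.random.Generator,
    dtype: np.dtype | type = np.float64,
) -> EpochSet:
    """Simulate epoched EEG for all subjects.

    ``patterns`` is either a single item->pattern mapping applied to every
    subject, or a sequence of ``n_subjects`` mappings (subject-specific
    representational geometry, the pipeline default).  Noise is i.i.d.
    Gaussian per channel and sample with sd ``noise_sd``; with
    ``ar_coef != 0`` it is an AR(1) process along time with the same
    marginal sd.  Deterministic given ``rng``'s state.
    """
    times = params.times()
    if isinstance(patterns, Mapping):
        pattern_sets: Sequence[Mapping[str, np.ndarray]] = [
            patterns
        ] * params.n_subjects
    else:
        pattern_sets = list(patterns)
        if len(pattern_sets) != params.n_subjects:
            raise ParameterError(
                "need one pattern mapping per subject (or a single mapping)"
            )

    n_s, n_t = params.n_subjects, len(design.trials)
    shape = (n_s, n_t, params.n_channels, len(times))
    data = np.empty(shape, dtype=dtype)
    for s in range(n_s):
        if params.noise_sd:
            noise = rng.standard_normal(shape[1:], dtype=np.float32)
            if params.ar_coef:
                a = params.ar_coef
                from scipy.signal import lfilter

                noise = lfilter([np.sqrt(1 - a * a)], [1.0, -a], noise, axis=-1)
            if params.noise_sd != 1.0:
                noise *= np.float32(params.noise_sd)
            data[s] = noise
        else:
            data[s] = 0.0
        _add_trial_signals(data[s], design, params, times, pattern_sets[s])
    return EpochSet(
        data=data,
        times=times,
        fs=params.fs,
        ch_names=params.channel_names(),
        design=design,
        keep_mask=None,
    )


def simulate_behavior(
    design: DesignTable, params: SimParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-trial response latencies and correctness for incongruent trials.

    The task is a plausibility judgment, so responses exist only for
    incongruent phrases.  Latency model:
    ``RT = rt_base - rt_mismatch_advantage * 1[animacy_mismatch] + N(0, rt_sd)``,
    floored at 100 ms; correctness is Bernoulli(``p_correct``).
    """
    rows = design.trials[design.trials["congruency"] != CONGRUENT]
    out = []
    for s in range(params.n_subjects):
        rt = (
            params.rt_base
            - params.rt_mismatch_advantage
            * (rows["congruency"] == INCONGRUENT_MISMATCH).to_numpy()
            + params.rt_sd * rng.standard_normal(len(rows))
        )
        rt = np.maximum(rt, 100.0)
        correct = rng.random(len(rows)) < params.p_correct
        out.append(
            pd.DataFrame(
                {
                    "subject": s,
                    "trial_index": rows["trial_index"].to_numpy(),
                    "congruency": rows["congruency"].to_numpy(),
                    "rt_ms": rt,
                    "correct": correct,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
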