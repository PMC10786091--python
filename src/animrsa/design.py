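"""Experimental design for classifier-noun animacy-prediction studies.

Mandarin numeral classifiers constrain semantic features of the noun they
modify; in particular a classifier licenses either animate nouns
(human/animal subgroups) or inanimate nouns (natural-object/artifact
subgroups).  The canonical design crosses 12 classifiers (3 per subgroup)
with 10 congruent nouns each, and re-pairs every noun once to create
incongruent phrases:

* ``congruent`` — noun from the classifier's own subgroup (120 trials);
* ``incongruent_animacy_match`` — noun from the *other* subgroup of the same
  animacy class, e.g. a human classifier with an animal noun (60 trials);
* ``incongruent_animacy_mismatch`` — noun from the opposite animacy class,
  e.g. a human classifier with a natural-object noun (60 trials).

Every noun is used exactly twice (once congruent, once incongruent) and all
240 classifier-noun pairs are distinct.  Trials are presented in three
blocks of 80 with 40 congruent and 40 incongruent trials each.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError

__all__ = [
    "ANIMACY_OF_SUBGROUP",
    "SUBGROUPS",
    "CONGRUENT",
    "INCONGRUENT_MATCH",
    "INCONGRUENT_MISMATCH",
    "LexItem",
    "DesignTable",
    "congruency_of",
    "build_design",
    "assign_blocks",
    "enumerate_within_pairs",
    "default_lexicon",
    "write_design",
    "read_design",
]

SUBGROUPS = ("human", "animal", "natural_object", "artifact")

ANIMACY_OF_SUBGROUP = {
    "human": "animate",
    "animal": "animate",
    "natural_object": "inanimate",
    "artifact": "inanimate",
}

#: Re-pairing partner within the same animacy class (human <-> animal,
#: natural_object <-> artifact): produces incongruent, animacy-matched trials.
MATCH_PARTNER = {
    "human": "animal",
    "animal": "human",
    "natural_object": "artifact",
    "artifact": "natural_object",
}

#: Re-pairing partner across animacy classes (human <-> natural_object,
#: animal <-> artifact): produces incongruent, animacy-mismatched trials.
MISMATCH_PARTNER = {
    "human": "natural_object",
    "natural_object": "human",
    "animal": "artifact",
    "artifact": "animal",
}

CONGRUENT = "congruent"
INCONGRUENT_MATCH = "incongruent_animacy_match"
INCONGRUENT_MISMATCH = "incongruent_animacy_mismatch"
CONGRUENCY_LEVELS = (CONGRUENT, INCONGRUENT_MATCH, INCONGRUENT_MISMATCH)

TRIAL_COLUMNS = [
    "classifier_id",
    "noun_id",
    "animacy_constraint",
    "subgroup",
    "noun_subgroup",
    "congruency",
    "block",
    "trial_index",
]


@dataclass(frozen=True)
class LexItem:
    """A lexical item (classifier or noun) with its norming properties.

    ``stroke_count`` is the visual-complexity proxy (number of strokes of
    the written character); ``log_frequency`` is corpus log frequency.
    """

    id: str
    role: str  # "classifier" | "noun"
    subgroup: str
    stroke_count: int = 8
    log_frequency: float = 1.5

    def __post_init__(self) -> None:
        if self.role not in ("classifier", "noun"):
            raise DesignError(f"unknown role {self.role!r}")
        if self.subgroup not in SUBGROUPS:
            raise DesignError(f"unknown subgroup {self.subgroup!r}")
        if self.stroke_count < 1:
            raise DesignError("stroke_count must be >= 1")

    @property
    def animacy(self) -> str:
        return ANIMACY_OF_SUBGROUP[self.subgroup]


def congruency_of(classifier_subgroup: str, noun_subgroup: str) -> str:
    """Congruency label implied by the (classifier, noun) subgroup pairing."""
    for sg in (classifier_subgroup, noun_subgroup):
        if sg not in SUBGROUPS:
            raise DesignError(f"unknown subgroup {sg!r}")
    if classifier_subgroup == noun_subgroup:
        return CONGRUENT
    if ANIMACY_OF_SUBGROUP[classifier_subgroup] == ANIMACY_OF_SUBGROUP[noun_subgroup]:
        return INCONGRUENT_MATCH
    return INCONGRUENT_MISMATCH


@dataclass
class DesignTable:
    """All trial specifications plus the classifier and noun item tables.

    ``trials`` has one row per trial with columns :data:`TRIAL_COLUMNS`;
    ``block`` is 0 until :func:`assign_blocks` has run, 1..n_blocks after.
    """

    trials: pd.DataFrame
    classifiers: pd.DataFrame
    nouns: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def classifier_ids(self, animacy: str | None = None) -> list[str]:
        tab = self.classifiers
        if animacy is not None:
            tab = tab[tab["animacy"] == animacy]
        return list(tab["id"])

    def congruency_counts(self) -> dict[str, int]:
        return self.trials["congruency"].value_counts().to_dict()

    def copy(self) -> "DesignTable":
        return DesignTable(
            self.trials.copy(), self.classifiers.copy(), self.nouns.copy()
        )


def _items_frame(items: Sequence[LexItem]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [it.id for it in items],
            "subgroup": [it.subgroup for it in items],
            "animacy": [it.animacy for it in items],
            "stroke_count": [it.stroke_count for it in items],
            "log_frequency": [it.log_frequency for it in items],
        }
    )


def build_design(
    classifiers: Sequence[LexItem],
    nouns: Mapping[str, Sequence[LexItem]],
    rng_seed: int = 0,
) -> DesignTable:
    """Build the full trial table from classifiers and their congruent nouns.

    Parameters
    ----------
    classifiers
        The classifier items.  Equal numbers of animate- and
        inanimate-constraining classifiers are required; either all four
        subgroups are populated with equal counts, or exactly two subgroups
        of opposite animacy (a minimal scaled design).
    nouns
        Mapping ``classifier_id -> its congruent nouns`` (each noun's
        subgroup must equal its classifier's).  All classifiers must be
        given the same number of nouns; in the four-subgroup scheme that
        number must be even so the incongruent half splits into
        animacy-matched and animacy-mismatched re-pairings.
    rng_seed
        Seed for the random re-pairing (a uniform assignment under the
        constraint that each noun is reused exactly once).

    Returns
    -------
    DesignTable
        ``2 * n_nouns_total`` trials; every (classifier, noun) pair
        distinct; blocks unassigned (0).
    """
    rng = np.random.default_rng(rng_seed)

    by_subgroup: dict[str, list[LexItem]] = {}
    for c in classifiers:
        if c.role != "classifier":
            raise DesignError(f"item {c.id!r} is not a classifier")
        by_subgroup.setdefault(c.subgroup, []).append(c)
    n_animate = sum(1 for c in classifiers if c.animacy == "animate")
    n_inanimate = len(classifiers) - n_animate
    if n_animate != n_inanimate or n_animate == 0:
        raise DesignError(
            f"need equal nonzero numbers of animate and inanimate "
            f"classifiers, got {n_animate}/{n_inanimate}"
        )

    counts = {len(nouns.get(c.id, ())) for c in classifiers}
    if len(counts) != 1 or 0 in counts:
        raise DesignError("every classifier needs the same nonzero noun count")
    k = counts.pop()

    noun_items: list[LexItem] = []
    pools: dict[str, list[LexItem]] = {sg: [] for sg in SUBGROUPS}
    seen: set[str] = set()
    for c in classifiers:
        for n in nouns[c.id]:
            if n.role != "noun":
                raise DesignError(f"item {n.id!r} is not a noun")
            if n.subgroup != c.subgroup:
                raise DesignError(
                    f"congruent noun {n.id!r} ({n.subgroup}) does not match "
                    f"classifier {c.id!r} ({c.subgroup})"
                )
            if n.id in seen:
                raise DesignError(f"duplicate noun id {n.id!r}")
            seen.add(n.id)
            noun_items.append(n)
            pools[n.subgroup].append(n)

    populated = [sg for sg in SUBGROUPS if by_subgroup.get(sg)]
    rows: list[tuple[str, str, str]] = []  # (classifier_id, noun_id, congruency)
    for c in classifiers:
        for n in nouns[c.id]:
            rows.append((c.id, n.id, CONGRUENT))

    if len(populated) == 4:
        sizes = {len(by_subgroup[sg]) for sg in SUBGROUPS}
        if len(sizes) != 1:
            raise DesignError("four-subgroup designs need equal classifier counts")
        if k % 2:
            raise DesignError(
                "nouns per classifier must be even to split incongruent "
                "re-pairings into match and mismatch halves"
            )
        # Pool of subgroup X serves the match-partner's classifiers with one
        # half and the mismatch-partner's classifiers with the other half.
        for sg in SUBGROUPS:
            pool = list(pools[sg])
            order = rng.permutation(len(pool))
            shuffled = [pool[i] for i in order]
            half = len(shuffled) // 2
            rows += _deal(by_subgroup[MATCH_PARTNER[sg]], shuffled[:half], k // 2)
            rows += _deal(by_subgroup[MISMATCH_PARTNER[sg]], shuffled[half:], k // 2)
    elif len(populated) == 2:
        a, b = populated
        if ANIMACY_OF_SUBGROUP[a] == ANIMACY_OF_SUBGROUP[b]:
            raise DesignError(
                "two-subgroup designs need subgroups of opposite animacy"
            )
        if len(by_subgroup[a]) != len(by_subgroup[b]):
            raise DesignError("two-subgroup designs need equal classifier counts")
        for src, dst in ((a, b), (b, a)):
            pool = list(pools[src])
            order = rng.permutation(len(pool))
            shuffled = [pool[i] for i in order]
            rows += _deal(by_subgroup[dst], shuffled, k)
    else:
        raise DesignError(
            "re-pairing scheme infeasible: populate all four subgroups or "
            "exactly two of opposite animacy"
        )

    noun_sub = {n.id: n.subgroup for n in noun_items}
    clf_sub = {c.id: c.subgroup for c in classifiers}
    trials = pd.DataFrame(
        {
            "classifier_id": [r[0] for r in rows],
            "noun_id": [r[1] for r in rows],
        }
    )
    trials["subgroup"] = trials["classifier_id"].map(clf_sub)
    trials["animacy_constraint"] = trials["subgroup"].map(ANIMACY_OF_SUBGROUP)
    trials["noun_subgroup"] = trials["noun_id"].map(noun_sub)
    trials["congruency"] = [
        congruency_of(clf_sub[c], noun_sub[n]) for c, n, _ in rows
    ]
    # label from the subgroup pairing must agree with the assignment scheme
    assert list(trials["congruency"][: len(noun_items)]) == [CONGRUENT] * len(
        noun_items
    )
    trials["block"] = 0
    trials["trial_index"] = np.arange(len(trials))
    trials = trials[TRIAL_COLUMNS]

    return DesignTable(
        trials=trials,
        classifiers=_items_frame(classifiers),
        nouns=_items_frame(noun_items),
    )


def _deal(
    classifiers: Sequence[LexItem], pool: Sequence[LexItem], per: int
) -> list[tuple[str, str, str]]:
    if len(pool) != per * len(classifiers):
        raise DesignError(
            f"re-pairing infeasible: pool of {len(pool)} nouns cannot supply "
            f"{per} each to {len(classifiers)} classifiers"
        )
    out = []
    it = iter(pool)
    for c in classifiers:
        for _ in range(per):
            n = next(it)
            out.append((c.id, n.id, congruency_of(c.subgroup, n.subgroup)))
    return out


def assign_blocks(
    design: DesignTable, n_blocks: int, rng_seed: int = 0
) -> DesignTable:
    """Split trials into blocks balanced for congruency and randomize order.

    Each block receives equal numbers of congruent and incongruent trials
    (and, when counts divide evenly, equal numbers of each of the three
    congruency conditions).  The order within each block is randomized under
    ``rng_seed``; the same seed reproduces the assignment exactly.
    """
    n = design.n_trials
    if n_blocks < 1 or n % n_blocks:
        raise DesignError(f"{n} trials cannot be split into {n_blocks} blocks")
    rng = np.random.default_rng(rng_seed)
    trials = design.trials

    counts = trials["congruency"].value_counts()
    if all(c % n_blocks == 0 for c in counts):
        strata = [trials.index[trials["congruency"] == lev] for lev in counts.index]
    else:
        is_con = trials["congruency"] == CONGRUENT
        n_con, n_inc = int(is_con.sum()), int((~is_con).sum())
        if n_con % n_blocks or n_inc % n_blocks:
            raise DesignError(
                "congruent/incongruent counts are not divisible across blocks"
            )
        strata = [trials.index[is_con], trials.index[~is_con]]

    blocks: list[list[int]] = [[] for _ in range(n_blocks)]
    for idx in strata:
        order = rng.permutation(len(idx))
        chunk = len(idx) // n_blocks
        for b in range(n_blocks):
            blocks[b].extend(idx[order[b * chunk : (b + 1) * chunk]])

    pieces = []
    for b, members in enumerate(blocks):
        members = [members[i] for i in rng.permutation(len(members))]
        piece = trials.loc[members].copy()
        piece["block"] = b + 1
        pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    out["trial_index"] = np.arange(len(out))
    return DesignTable(out[TRIAL_COLUMNS], design.classifiers.copy(), design.nouns.copy())


def enumerate_within_pairs(item_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All C(n, 2) unordered pairs of distinct ids, in input order.

    For the six classifiers of one animacy class this yields the
    6*5/2 = 15 pairs entering the within-condition similarity average.
    """
    ids = list(item_ids)
    if len(ids) < 2:
        raise DesignError("need at least two items to form pairs")
    if len(set(ids)) != len(ids):
        raise DesignError("item ids must be distinct")
    return list(itertools.combinations(ids, 2))


def default_lexicon(
    n_per_subgroup: int = 3,
    nouns_per_classifier: int = 10,
    rng_seed: int = 0,
) -> tuple[list[LexItem], dict[str, list[LexItem]]]:
    """Synthetic classifiers and congruent nouns with matched norms.

    Stroke counts and log frequencies are drawn from the same distributions
    in every subgroup (uniform 4..14 strokes; normal log frequency,
    mean 1.5, sd 0.4), so the groups are matched in expectation on visual
    complexity and frequency, as the stimulus norming requires.
    """
    rng = np.random.default_rng(rng_seed)

    def props() -> dict:
        return {
            "stroke_count": int(rng.integers(4, 15)),
            "log_frequency": float(rng.normal(1.5, 0.4)),
        }

    classifiers: list[LexItem] = []
    nouns: dict[str, list[LexItem]] = {}
    for sg in SUBGROUPS:
        for i in range(n_per_subgroup):
            cid = f"clf_{sg}_{i + 1}"
            classifiers.append(LexItem(cid, "classifier", sg, **props()))
            nouns[cid] = [
                LexItem(f"noun_{sg}_{i + 1}_{j + 1:02d}", "noun", sg, **props())
                for j in range(nouns_per_classifier)
            ]
    return classifiers, nouns


def write_design(design: DesignTable, directory: str | Path) -> None:
    """Serialize a design as TSV files (trials, classifiers, nouns)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    design.trials.to_csv(d / "trials.tsv", sep="\t", index=False)
    design.classifiers.to_csv(d / "classifiers.tsv", sep="\t", index=False)
    design.nouns.to_csv(d / "nouns.tsv", sep="\t", index=False)


def read_design(directory: str | Path) -> DesignTable:
    d = Path(directory)
    return DesignTable(
        trials=pd.read_csv(d / "trials.tsv", sep="\t"),
        classifiers=pd.read_csv(d / "classifiers.tsv", sep="\t"),
        nouns=pd.read_csv(d / "nouns.tsv", sep="\t"),
    )
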