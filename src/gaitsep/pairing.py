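"""Verification-pair construction and subject-disjoint splits.

Verification asks whether two walking frames come from the same person.
Two frame feature vectors a, b are combined into the order-independent
representation

    pair(a, b) = ( |a - b| , |a (.) b| )

(elementwise difference magnitude and elementwise product; on nonnegative
DFT magnitudes the bar on the product changes nothing).  Same-subject pairs
cross acquisition days so the model must bridge day-to-day variability;
different-subject pairs combine frames only from subjects inside the same
(train or test) fold, keeping the folds subject-disjoint.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .spectral import feature_columns

LABELS = ("same", "different")

#: default cap per (label, fold) — exhaustive pairing is combinatorial
DEFAULT_PAIR_CAP = 5000


@dataclasses.dataclass(frozen=True)
class SubjectSplit:
    """Disjoint, exhaustive partition of a cohort into train/test subjects."""

    train_subjects: tuple
    test_subjects: tuple
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise ValueError("train and test subjects overlap")
        if not self.train_subjects or not self.test_subjects:
            raise ValueError("both folds need at least one subject")


@dataclasses.dataclass
class PairFeature:
    """One labelled frame pair in the combined representation."""

    vector: np.ndarray
    label: str
    subject_a: int
    subject_b: int
    split: str = "train"

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.label == "same" and self.subject_a != self.subject_b:
            raise ValueError("a same-subject pair must share its subject id")
        if self.vector.size % 2:
            raise ValueError("pair vector length must be 2*d")


def make_pair(a, b) -> np.ndarray:
    """Combined vector (|a-b|, |a*b|) of two equal-dimension feature vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return np.concatenate([np.abs(a - b), np.abs(a * b)])


def split_subjects(subject_ids: Sequence, n_train: int, seed: int = 0) -> SubjectSplit:
    """Random subject-disjoint split, deterministic under ``seed``."""
    ids = sorted(set(subject_ids))
    if not 1 <= n_train < len(ids):
        raise ValueError(
            f"n_train={n_train} out of range for {len(ids)} subjects"
        )
    perm = np.random.default_rng(seed).permutation(len(ids))
    chosen = {ids[i] for i in perm[:n_train]}
    return SubjectSplit(
        train_subjects=tuple(sorted(chosen)),
        test_subjects=tuple(sorted(set(ids) - chosen)),
        seed=seed,
    )


def _grid_blocks_same(table, subjects, cross_day):
    """Index blocks for same-subject pairs; each block is (idx_a, idx_b)."""
    blocks = []
    subj = table["subject_id"].to_numpy()
    day = table["day"].to_numpy()
    for s in subjects:
        mine = np.flatnonzero(subj == s)
        if cross_day:
            days = np.unique(day[mine])
            if days.size < 2:
                raise ValueError(
                    f"subject {s} lacks frames on two days for cross-day pairing"
                )
            a = mine[day[mine] == days[0]]
            b = mine[day[mine] == days[1]]
            blocks.append((a, b))
        else:
            if mine.size < 2:
                raise ValueError(f"subject {s} has fewer than two frames")
            i, j = np.triu_indices(mine.size, k=1)
            blocks.append((mine[i], mine[j], "paired"))
    return blocks


def _grid_blocks_different(table, subjects):
    subj = table["subject_id"].to_numpy()
    groups = {s: np.flatnonzero(subj == s) for s in subjects}
    blocks = []
    for i, s1 in enumerate(subjects):
        for s2 in subjects[i + 1 :]:
            if groups[s1].size and groups[s2].size:
                blocks.append((groups[s1], groups[s2]))
    return blocks


def sample_pairs(
    features: pd.DataFrame,
    label: str,
    n_pairs: int | None = None,
    subjects: Sequence | None = None,
    cross_day: bool | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sample labelled frame pairs from a feature table.

    Returns ``(X, meta)``: the (n, 2d) pair matrix and a provenance frame
    with columns label/subject_a/subject_b/index_a/index_b.  With
    ``n_pairs=None`` every admissible pair is returned; otherwise exactly
    ``min(n_pairs, available)`` distinct pairs are drawn without
    replacement, deterministically under ``seed``.  ``cross_day`` defaults
    to True for same-subject pairs (the verification protocol) and is
    ignored for different-subject pairs.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    if subjects is None:
        subjects = sorted(features["subject_id"].unique())
    else:
        subjects = sorted(subjects)
        present = set(features["subject_id"].unique())
        absent = [s for s in subjects if s not in present]
        if absent:
            raise ValueError(f"subjects {absent} have no frames in the table")

    if label == "same":
        blocks = _grid_blocks_same(features, subjects, cross_day is not False)
    else:
        if len(subjects) < 2:
            raise ValueError("different-subject pairs need at least 2 subjects")
        blocks = _grid_blocks_different(features, subjects)

    # decode flat pair index -> (row a, row b) across blocks
    sizes = []
    for block in blocks:
        if len(block) == 3:  # pre-paired index arrays
            sizes.append(block[0].size)
        else:
            sizes.append(block[0].size * block[1].size)
    total = int(np.sum(sizes)) if sizes else 0
    if total == 0:
        raise ValueError(f"no admissible {label!r} pairs under these constraints")
    if n_pairs is None or n_pairs >= total:
        chosen = np.arange(total)
    else:
        if n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        chosen = np.sort(
            np.random.default_rng(seed).choice(total, size=n_pairs, replace=False)
        )

    offsets = np.concatenate([[0], np.cumsum(sizes)])
    idx_a = np.empty(chosen.size, dtype=int)
    idx_b = np.empty(chosen.size, dtype=int)
    which = np.searchsorted(offsets, chosen, side="right") - 1
    for bi, block in enumerate(blocks):
        sel = which == bi
        if not np.any(sel):
            continue
        local = chosen[sel] - offsets[bi]
        if len(block) == 3:
            idx_a[sel] = block[0][local]
            idx_b[sel] = block[1][local]
        else:
            a, b = block[0], block[1]
            idx_a[sel] = a[local // b.size]
            idx_b[sel] = b[local % b.size]

    fcols = feature_columns(features)
    values = features[fcols].to_numpy(dtype=float)
    va, vb = values[idx_a], values[idx_b]
    pairs = np.hstack([np.abs(va - vb), np.abs(va * vb)])
    subj = features["subject_id"].to_numpy()
    day = features["day"].to_numpy()
    meta = pd.DataFrame(
        {
            "label": label,
            "subject_a": subj[idx_a],
            "subject_b": subj[idx_b],
            "day_a": day[idx_a],
            "day_b": day[idx_b],
            "index_a": idx_a,
            "index_b": idx_b,
        }
    )
    return pairs, meta


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(int(seed)).generate_state(n)
    return [int(s % (2**31 - 1)) for s in state]


def verification_pairs(
    features: pd.DataFrame,
    split: SubjectSplit,
    n_per_class: int = DEFAULT_PAIR_CAP,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Balanced same/different pairs for both folds of a subject split.

    Same-subject pairs cross days; different-subject pairs stay inside the
    fold's subjects, so neither fold's pairs ever touch the other fold.
    Returns ``(X, labels, folds, meta)`` with per-fold class balance
    ``min(n_per_class, available same, available different)``.
    """
    seeds = _child_seeds(seed, 4)
    parts_x, parts_y, parts_f, parts_m = [], [], [], []
    for fi, (fold, subs) in enumerate(
        (("train", split.train_subjects), ("test", split.test_subjects))
    ):
        xs, ms = sample_pairs(
            features, "same", n_per_class, subjects=subs, seed=seeds[2 * fi]
        )
        xd, md = sample_pairs(
            features, "different", n_per_class, subjects=subs, seed=seeds[2 * fi + 1]
        )
        n = min(len(xs), len(xd))
        for x, m, lab in ((xs[:n], ms.iloc[:n], "same"), (xd[:n], md.iloc[:n], "different")):
            parts_x.append(x)
            parts_y.append(np.full(n, lab, dtype=object))
            parts_f.append(np.full(n, fold, dtype=object))
            m = m.copy()
            m["fold"] = fold
            parts_m.append(m)
    return (
        np.vstack(parts_x),
        np.concatenate(parts_y),
        np.concatenate(parts_f),
        pd.concat(parts_m, ignore_index=True),
    )
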