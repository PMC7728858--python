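"""Variance-based profile selection and the three train/validation splits.

Selection follows a modified Kennard-Stone idea: score every profile by its
Euclidean distance to the mean profile of the whole collection and keep the
distance-extreme profiles (both tails), i.e. the ones carrying the most
explained variance plus the most typical ones.  Two modes are exposed:

* ``quantile`` — keep profiles whose distance lies at or below the q-quantile
  or at or above the (1-q)-quantile of the distance distribution;
* ``target_count`` — keep exactly ``n_target`` profiles, taken alternately
  from the largest- and smallest-distance ends (the pipeline default, since a
  fixed modelling-set size is usually what is wanted).

Splitting is stratified by DILI class.  The train side gets
round-half-up(total x fraction) profiles, apportioned to classes by largest
remainder of the per-class quotas class_size x fraction (ties favour the
positive class).  This single rule reproduces, e.g., 6000 profiles at
3568/2432 -> train 2854/1946 and validation 714/486; 4864 balanced profiles
-> 3891 train / 973 validation; 640 drugs at 427/213 -> 342/170 vs 85/43.

Splits are functions of (ids, labels, seed) only — never of expression values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SelectionError, StratificationError
from .profiles import ProfileSet

STRATEGIES = ("profile-stratified", "drug-stratified", "balanced")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of variance-based selection: kept ids and per-profile distances."""

    selected_profile_ids: tuple[str, ...]
    distances: pd.Series = field(repr=False)  # index: profile_id
    thresholds: tuple[float, ...]
    mode: str

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected_profile_ids)
        return pd.DataFrame(
            {
                "profile_id": self.distances.index,
                "distance": self.distances.to_numpy(),
                "selected": [int(p in sel) for p in self.distances.index],
            }
        )


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/validation profile-id sets with their strategy tag."""

    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    strategy: str
    seed: int

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if set(self.train_ids) & set(self.validation_ids):
            raise ValueError("train and validation ids overlap")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "profile_id": list(self.train_ids) + list(self.validation_ids),
                "assignment": ["train"] * len(self.train_ids)
                + ["validation"] * len(self.validation_ids),
            }
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def train_class_counts(class_sizes: dict[int, int], train_fraction: float) -> dict[int, int]:
    """Per-class train-side counts: round-half-up total, largest-remainder
    apportionment of the per-class quotas, ties to the positive class."""
    total = sum(class_sizes.values())
    n_train = _round_half_up(total * train_fraction)
    quotas = {lab: n * train_fraction for lab, n in class_sizes.items()}
    counts = {lab: min(math.floor(q), class_sizes[lab]) for lab, q in quotas.items()}
    remaining = n_train - sum(counts.values())
    # ties broken toward the positive class (larger label first)
    order = sorted(quotas, key=lambda lab: (quotas[lab] - math.floor(quotas[lab]), lab),
                   reverse=True)
    i = 0
    while remaining > 0:
        lab = order[i % len(order)]
        if counts[lab] < class_sizes[lab]:
            counts[lab] += 1
            remaining -= 1
        i += 1
    return counts


# ----------------------------------------------------------------------
# Variance-based (modified Kennard-Stone) selection
# ----------------------------------------------------------------------

def profile_distances(profiles: ProfileSet) -> pd.Series:
    """Euclidean distance of every profile to the mean profile."""
    mean_profile = profiles.values.mean(axis=1, keepdims=True)
    d = np.linalg.norm(profiles.values - mean_profile, axis=0)
    return pd.Series(d, index=pd.Index(profiles.profile_ids, name="profile_id"))


def variance_select(profiles: ProfileSet, mode: str = "target_count",
                    q: float | None = None,
                    n_target: int | None = None) -> SelectionResult:
    """Select distance-extreme profiles (see module docstring for modes)."""
    if profiles.n_profiles < 2:
        raise SelectionError("need at least 2 profiles to select from")
    dist = profile_distances(profiles)

    if mode == "quantile":
        if q is None or not 0 < q <= 0.5:
            raise SelectionError("quantile mode needs q in (0, 0.5]")
        lo = float(dist.quantile(q))
        hi = float(dist.quantile(1.0 - q))
        keep = dist.index[(dist.to_numpy() <= lo) | (dist.to_numpy() >= hi)]
        selected = tuple(sorted(keep))
        return SelectionResult(selected, dist, (lo, hi), mode)

    if mode == "target_count":
        if n_target is None or n_target < 1:
            raise SelectionError("target_count mode needs a positive n_target")
        if n_target > profiles.n_profiles:
            raise SelectionError(
                f"n_target={n_target} exceeds {profiles.n_profiles} profiles"
            )
        # ties broken by lexical profile_id on both ends
        high = sorted(dist.index, key=lambda p: (-dist[p], p))
        low = sorted(dist.index, key=lambda p: (dist[p], p))
        chosen: list[str] = []
        taken: set[str] = set()
        hi_i = lo_i = 0
        take_high = True
        while len(chosen) < n_target:
            src, idx = (high, hi_i) if take_high else (low, lo_i)
            while src[idx] in taken:
                idx += 1
            chosen.append(src[idx])
            taken.add(src[idx])
            if take_high:
                hi_i = idx + 1
            else:
                lo_i = idx + 1
            take_high = not take_high
        thresholds = (float(dist[chosen[-1]]),)
        return SelectionResult(tuple(chosen), dist, thresholds, mode)

    raise SelectionError(f"unknown selection mode {mode!r}")


# ----------------------------------------------------------------------
# Splitting strategies
# ----------------------------------------------------------------------

def _split_ids_by_class(ids: np.ndarray, labels: np.ndarray, train_fraction: float,
                        rng: np.random.Generator) -> tuple[list[str], list[str]]:
    class_sizes = {1: int((labels == 1).sum()), 0: int((labels == 0).sum())}
    if class_sizes[0] == 0 or class_sizes[1] == 0:
        raise StratificationError("both classes must be present to stratify")
    if min(class_sizes.values()) < 2:
        raise StratificationError("each class needs at least 2 members")
    counts = train_class_counts(class_sizes, train_fraction)
    train: list[str] = []
    valid: list[str] = []
    for lab in (1, 0):
        members = np.sort(ids[labels == lab])  # sorted for seed-stable permutation
        perm = rng.permutation(len(members))
        chosen = set(members[perm[: counts[lab]]])
        train.extend(m for m in members if m in chosen)
        valid.extend(m for m in members if m not in chosen)
    return train, valid


def stratified_split_profiles(profiles: ProfileSet, train_fraction: float = 0.8,
                              seed: int = 0) -> SplitPlan:
    """Random stratified split at profile level, same P/N ratio on both sides."""
    if not 0 < train_fraction < 1:
        raise StratificationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.asarray(profiles.profile_ids, dtype=str)
    train, valid = _split_ids_by_class(ids, profiles.labels, train_fraction, rng)
    return SplitPlan(tuple(train), tuple(valid), "profile-stratified", seed)


def stratified_split_drugs(profiles: ProfileSet, train_fraction: float = 0.8,
                           seed: int = 0) -> SplitPlan:
    """Stratified split at drug level: all of a drug's profiles go to one side,
    so no drug is shared between train and validation."""
    if not 0 < train_fraction < 1:
        raise StratificationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    drug_tab = profiles.drug_label_table()
    drug_ids = drug_tab["drug_id"].to_numpy(dtype=str)
    drug_labels = drug_tab["label"].to_numpy(dtype=int)
    train_drugs, valid_drugs = _split_ids_by_class(
        drug_ids, drug_labels, train_fraction, rng
    )
    train_set, valid_set = set(train_drugs), set(valid_drugs)
    train = [p for p, d in zip(profiles.profile_ids, profiles.drug_ids) if d in train_set]
    valid = [p for p, d in zip(profiles.profile_ids, profiles.drug_ids) if d in valid_set]
    return SplitPlan(tuple(train), tuple(valid), "drug-stratified", seed)


def balanced_downsample(profiles: ProfileSet, seed: int = 0) -> ProfileSet:
    """Randomly subsample the majority class (without replacement) down to the
    minority class size; the minority class is untouched."""
    y = profiles.labels
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise StratificationError("both classes must be present to balance")
    if n_pos == n_neg:
        return profiles.subset(profiles.profile_ids)
    rng = np.random.default_rng(seed)
    major = 1 if n_pos > n_neg else 0
    n_minor = min(n_pos, n_neg)
    ids = np.asarray(profiles.profile_ids, dtype=str)
    major_ids = np.sort(ids[y == major])
    kept_major = set(rng.choice(major_ids, size=n_minor, replace=False))
    keep = [p for p, lab in zip(profiles.profile_ids, y)
            if lab != major or p in kept_major]
    return profiles.subset(keep)


def drug_overlap(plan: SplitPlan, profiles: ProfileSet) -> set[str]:
    """Drugs appearing on both sides of a split (empty for a leak-free plan)."""
    by_drug = dict(zip(profiles.profile_ids, profiles.drug_ids))
    train_drugs = {by_drug[p] for p in plan.train_ids}
    valid_drugs = {by_drug[p] for p in plan.validation_ids}
    return train_drugs & valid_drugs
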