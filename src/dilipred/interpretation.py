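"""Model interpretation: gene signatures of correct predictions and
therapeutic-class (ATC) stratified performance.

A profile's signature is its top-k most up-regulated and top-k most
down-regulated genes by signed moderated Z-score (the profile values are
already a differential statistic, so no re-baselining is applied).  Only
profiles whose predicted label matches the truth contribute.  Pooling the
up and down sets of all contributing profiles and counting each gene's
occurrences yields the high-frequency gene list handed to downstream
enrichment services.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SignatureError
from .metrics import (compute_metrics, confusion, roc_auc, sensitivity,
                      specificity)
from .profiles import ProfileSet

#: WHO first-level therapeutic categories.
ATC_FIRST_LEVEL = tuple("ABCDGHJLMNPRSV")


@dataclass(frozen=True)
class ProfileSignature:
    """Up/down gene sets of one correctly predicted profile."""

    profile_id: str
    up: tuple[str, ...]
    down: tuple[str, ...]
    z_by_gene: dict[str, float] = field(repr=False, hash=False, default_factory=dict)


@dataclass(frozen=True)
class SignatureSummary:
    """Gene-frequency tally across signatures and the top-n ranked list."""

    frequencies: pd.DataFrame = field(repr=False)  # gene_id, count, up/down counts
    top_genes: tuple[str, ...]


def extract_signatures(validation: ProfileSet, predictions, k: int = 100
                       ) -> list[ProfileSignature]:
    """Top-k up/down signatures of every correctly predicted profile.

    Up = k largest signed Z-scores, down = k smallest; ties broken by gene id
    lexical order.  Raises :class:`SignatureError` when 2k exceeds the panel.
    """
    pred = np.asarray(predictions, dtype=int)
    if len(pred) != validation.n_profiles:
        raise ValueError("predictions not aligned with validation profiles")
    if 2 * k > validation.n_genes:
        raise SignatureError(
            f"2k={2 * k} exceeds the {validation.n_genes}-gene panel"
        )
    truth = validation.labels
    genes = np.asarray(validation.gene_ids)
    lex = np.argsort(genes, kind="mergesort")  # secondary key: gene id
    signatures = []
    for j, pid in enumerate(validation.profile_ids):
        if pred[j] != truth[j]:
            continue  # incorrect prediction contributes nothing
        z = validation.values[:, j]
        z_lex = z[lex]
        order_desc = lex[np.argsort(-z_lex, kind="mergesort")]
        order_asc = lex[np.argsort(z_lex, kind="mergesort")]
        up = tuple(genes[order_desc[:k]])
        down = tuple(genes[order_asc[:k]])
        zmap = {g: float(z[i]) for i, g in zip(order_desc[:k], up)}
        zmap.update({g: float(z[i]) for i, g in zip(order_asc[:k], down)})
        signatures.append(ProfileSignature(pid, up, down, zmap))
    return signatures


def high_frequency_genes(signatures: list[ProfileSignature], top_n: int = 200
                         ) -> SignatureSummary:
    """Rank genes by occurrence count across all up/down sets (pooled).

    Ties: larger mean |Z| across contributing profiles, then lexical gene id.
    Direction-resolved counts are reported alongside for transparency.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    up_counts: Counter = Counter()
    down_counts: Counter = Counter()
    abs_z: defaultdict[str, list] = defaultdict(list)
    for sig in signatures:
        up_counts.update(sig.up)
        down_counts.update(sig.down)
        for g in set(sig.up) | set(sig.down):
            abs_z[g].append(abs(sig.z_by_gene[g]))
    genes = sorted(set(up_counts) | set(down_counts))
    freq = pd.DataFrame(
        {
            "gene_id": genes,
            "count": [up_counts[g] + down_counts[g] for g in genes],
            "up_count": [up_counts[g] for g in genes],
            "down_count": [down_counts[g] for g in genes],
            "mean_abs_z": [float(np.mean(abs_z[g])) for g in genes],
        }
    )
    freq = freq.sort_values(
        by=["count", "mean_abs_z", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    top = tuple(freq["gene_id"].head(top_n))
    return SignatureSummary(frequencies=freq, top_genes=top)


def read_atc_table(path) -> pd.DataFrame:
    """Two-column tab-delimited drug_id -> first-level ATC class table."""
    tab = pd.read_csv(path, sep="\t")
    return validate_atc_table(tab)


def validate_atc_table(tab: pd.DataFrame) -> pd.DataFrame:
    if not {"drug_id", "atc_first_level"}.issubset(tab.columns):
        raise ValueError("ATC table needs columns drug_id and atc_first_level")
    tab = tab.astype({"drug_id": str, "atc_first_level": str})
    bad = set(tab["atc_first_level"]) - set(ATC_FIRST_LEVEL)
    if bad:
        raise ValueError(f"unknown ATC first-level classes: {sorted(bad)}")
    return tab[["drug_id", "atc_first_level"]].drop_duplicates()


def atc_stratified_metrics(validation: ProfileSet, predictions,
                           atc: pd.DataFrame, scores=None
                           ) -> tuple[pd.DataFrame, dict]:
    """Per-therapeutic-class performance of the validation predictions.

    A drug mapping to several classes contributes its profiles to each.
    Classes with a single label report the computable metrics and NaN for the
    rest; AUC needs ``scores`` and both labels.  Returns (table, report) where
    report counts unmapped drugs/profiles.
    """
    atc = validate_atc_table(atc)
    pred = np.asarray(predictions, dtype=int)
    truth = validation.labels
    scr = None if scores is None else np.asarray(scores, dtype=float)
    classes_by_drug: defaultdict[str, list] = defaultdict(list)
    for d, c in zip(atc["drug_id"], atc["atc_first_level"]):
        classes_by_drug[d].append(c)

    members: defaultdict[str, list] = defaultdict(list)
    unmapped_drugs = set()
    for j, drug in enumerate(validation.drug_ids):
        if drug in classes_by_drug:
            for c in classes_by_drug[drug]:
                members[c].append(j)
        else:
            unmapped_drugs.add(drug)

    rows = []
    for c in sorted(members):
        idx = np.asarray(members[c])
        y, p = truth[idx], pred[idx]
        cc = confusion(y, p)
        both = len(np.unique(y)) == 2
        row = {"atc_class": c, "n_profiles": len(idx),
               "n_positive": int((y == 1).sum()), "n_negative": int((y == 0).sum())}
        if both:
            auc = roc_auc(y, scr[idx]) if scr is not None else float("nan")
            rep = compute_metrics(cc, auc=auc)
            row.update(rep.as_dict())
        else:  # degenerate stratum: only the defined metrics
            row.update({m: float("nan") for m in
                        ("auc", "mcc", "cohens_kappa", "f1", "v_score")})
            row["accuracy"] = (cc.tp + cc.tn) / cc.total
            row["sensitivity"] = sensitivity(cc) if (y == 1).any() else float("nan")
            row["specificity"] = specificity(cc) if (y == 0).any() else float("nan")
            row["balanced_accuracy"] = float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    n_unmapped_profiles = int(sum(d in unmapped_drugs for d in validation.drug_ids))
    report = {"n_unmapped_drugs": len(unmapped_drugs),
              "n_unmapped_profiles": n_unmapped_profiles,
              "unmapped_drugs": tuple(sorted(unmapped_drugs))}
    return table, report
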