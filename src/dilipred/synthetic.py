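"""Synthetic L1000-like profile generator with a planted, drug-level DILI signal.

The generator emulates Level-5 style data: one replicate-collapsed moderated
Z-score profile per drug/dose/cell-line combination over a fixed landmark-gene
panel.  The clinical label lives at the drug level (a drug is DILI-positive or
-negative); the transcriptomic signal is planted as follows:

* a fixed subset of ``n_signal_genes`` genes carries signal;
* each DILI-positive drug draws, once, a direction in {-1, +1} per signal gene
  (its "signature"), so the direction of regulation is drug-specific and
  recoverable by downstream signature extraction;
* a positive drug's profile shifts each signal gene by
  ``effect_size * dose_weight(dose) * direction``, where the dose weight is a
  logistic function of log-dose scaled to [0.5, 1] (monotone, bounded);
* every profile of every drug additionally receives a scalar offset per
  (drug, cell line) pair with standard deviation ``cell_line_sd``, applied to
  all genes, which makes profiles of the same drug correlated the way repeated
  assays of one compound across cell lines are;
* iid N(0, noise_sd) background noise on every entry, noise_sd = 1 matching
  the Z-score scale.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import InvalidDesignError
from .profiles import ProfileSet

#: Number of landmark genes in the assay the generator emulates.
N_LANDMARK_GENES = 978

#: Drug panel emulated by default: 1279 drugs, 768 positive / 511 negative.
DEFAULT_N_DRUGS = 1279
DEFAULT_POSITIVE_FRACTION = 768 / 1279


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study design."""

    n_genes: int = N_LANDMARK_GENES
    n_drugs: int = DEFAULT_N_DRUGS
    positive_fraction: float = DEFAULT_POSITIVE_FRACTION
    profiles_per_drug: int = 6
    n_signal_genes: int = 50
    effect_size: float = 2.0
    cell_line_sd: float = 0.5
    noise_sd: float = 1.0
    dose_levels: tuple[float, ...] = (0.1, 1.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_levels", tuple(float(d) for d in self.dose_levels))
        if self.n_genes < 1:
            raise InvalidDesignError("n_genes must be positive")
        if self.n_drugs < 2:
            raise InvalidDesignError("need at least 2 drugs (one per class)")
        if not 0.0 < self.positive_fraction < 1.0:
            raise InvalidDesignError("positive_fraction must lie in (0, 1)")
        if self.profiles_per_drug < 1:
            raise InvalidDesignError("profiles_per_drug must be positive")
        if not 0 <= self.n_signal_genes <= self.n_genes:
            raise InvalidDesignError("n_signal_genes must be in [0, n_genes]")
        if self.effect_size < 0:
            raise InvalidDesignError("effect_size must be >= 0")
        if self.cell_line_sd < 0:
            raise InvalidDesignError("cell_line_sd must be >= 0")
        if self.noise_sd <= 0:
            raise InvalidDesignError("noise_sd must be > 0")
        if any(d <= 0 for d in self.dose_levels) or not self.dose_levels:
            raise InvalidDesignError("dose_levels must be positive reals")
        if self.n_positive == 0 or self.n_positive == self.n_drugs:
            raise InvalidDesignError(
                f"design has an empty class: {self.n_positive} positives of {self.n_drugs}"
            )

    @property
    def n_positive(self) -> int:
        return _round_half_up(self.n_drugs * self.positive_fraction)

    @property
    def n_negative(self) -> int:
        return self.n_drugs - self.n_positive

    @property
    def n_cell_lines(self) -> int:
        return max(1, math.ceil(self.profiles_per_drug / len(self.dose_levels)))


@dataclass(frozen=True)
class DrugCatalog:
    """Drug panel: drug ids with DILI labels plus the planted ground truth."""

    drugs: pd.DataFrame = field(repr=False)          # columns: drug_id, dili_label
    signal_genes: np.ndarray = field(repr=False)     # indices into the gene panel
    directions: pd.DataFrame = field(repr=False)     # positive drug_id x signal gene, +-1

    @property
    def drug_ids(self) -> list[str]:
        return self.drugs["drug_id"].tolist()

    @property
    def n_positive(self) -> int:
        return int((self.drugs["dili_label"] == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.drugs["dili_label"] == 0).sum())


def dose_weight(dose, dose_levels) -> np.ndarray:
    """Monotone dose-response weight: logistic in log-dose, scaled to [0.5, 1].

    Centred at the median log dose of the design, so the middle dose of a
    symmetric series gets weight 0.75.
    """
    log_d = np.log(np.asarray(dose, dtype=float))
    centre = float(np.median(np.log(np.asarray(dose_levels, dtype=float))))
    return 0.5 + 0.5 * expit(log_d - centre)


def generate_drug_catalog(config: SyntheticConfig) -> DrugCatalog:
    """Draw the drug panel: labels at the configured prevalence and one
    fixed +-1 signature per positive drug over the signal genes."""
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_drugs)))
    drug_ids = [f"D{i:0{width}d}" for i in range(1, config.n_drugs + 1)]
    labels = np.zeros(config.n_drugs, dtype=int)
    positive_idx = rng.choice(config.n_drugs, size=config.n_positive, replace=False)
    labels[positive_idx] = 1
    drugs = pd.DataFrame({"drug_id": drug_ids, "dili_label": labels})

    signal_genes = np.sort(
        rng.choice(config.n_genes, size=config.n_signal_genes, replace=False)
    )
    pos_ids = drugs.loc[drugs["dili_label"] == 1, "drug_id"].tolist()
    directions = pd.DataFrame(
        rng.choice([-1, 1], size=(len(pos_ids), config.n_signal_genes)),
        index=pd.Index(pos_ids, name="drug_id"),
        columns=[int(g) for g in signal_genes],
    )
    return DrugCatalog(drugs=drugs, signal_genes=signal_genes, directions=directions)


def expected_signal_shift(config: SyntheticConfig, dose: float) -> float:
    """Closed-form magnitude of the planted per-gene shift at one dose:
    effect_size * dose_weight(dose).  Direction is per (drug, gene)."""
    return float(config.effect_size * dose_weight(dose, config.dose_levels))


def simulate_profiles(catalog: DrugCatalog, config: SyntheticConfig) -> ProfileSet:
    """Simulate the genes x profiles Z-score matrix plus per-profile metadata.

    The profile design enumerates (cell line, dose) combinations per drug and
    keeps the first ``profiles_per_drug`` of them.
    """
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from the catalog
    gene_width = len(str(config.n_genes))
    gene_ids = [f"G{i:0{gene_width}d}" for i in range(1, config.n_genes + 1)]
    cell_lines = [f"CL{i + 1}" for i in range(config.n_cell_lines)]
    combos = list(itertools.product(cell_lines, config.dose_levels))
    if len(combos) < config.profiles_per_drug:  # cycle if doses*cells < requested
        reps = math.ceil(config.profiles_per_drug / len(combos))
        combos = (combos * reps)
    combos = combos[: config.profiles_per_drug]

    n_profiles = config.n_drugs * config.profiles_per_drug
    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_profiles))

    meta_rows = []
    profile_ids = []
    label_by_drug = dict(zip(catalog.drugs["drug_id"], catalog.drugs["dili_label"]))
    weights = {d: expected_signal_shift(config, d) / max(config.effect_size, 1e-300)
               for d in config.dose_levels}  # dose weight alone

    col = 0
    for drug_id in catalog.drug_ids:
        label = int(label_by_drug[drug_id])
        # one scalar offset per (drug, cell line), shared by all its genes
        cl_offsets = {cl: rng.normal(0.0, config.cell_line_sd) for cl in cell_lines}
        if label == 1 and config.n_signal_genes > 0:
            direction = catalog.directions.loc[drug_id].to_numpy(dtype=float)
        else:
            direction = None
        for k, (cell_line, dose) in enumerate(combos):
            pid = f"{drug_id}:{cell_line}:{dose:g}:{k}"
            profile_ids.append(pid)
            values[:, col] += cl_offsets[cell_line]
            if direction is not None:
                values[catalog.signal_genes, col] += (
                    config.effect_size * weights[dose] * direction
                )
            meta_rows.append(
                {
                    "profile_id": pid,
                    "drug_id": drug_id,
                    "dose": dose,
                    "duration": 24.0,
                    "cell_line": cell_line,
                    "dili_label": label,
                }
            )
            col += 1

    metadata = pd.DataFrame(meta_rows).set_index("profile_id")
    return ProfileSet(values=values, gene_ids=gene_ids,
                      profile_ids=profile_ids, metadata=metadata)


def generate_profile_set(config: SyntheticConfig) -> ProfileSet:
    """Catalog + simulation in one call."""
    return simulate_profiles(generate_drug_catalog(config), config)


def write_synthetic_run(config: SyntheticConfig, out_dir) -> dict[str, str]:
    """Generate and persist a full synthetic run: wide matrix, metadata,
    drug-level label table, and a manifest recording config and seed."""
    from . import io as dio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = generate_drug_catalog(config)
    profiles = simulate_profiles(catalog, config)
    paths = {
        "matrix": str(out / "matrix.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "labels": str(out / "labels.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    dio.write_profile_set(profiles, paths["matrix"], paths["metadata"])
    catalog.drugs.rename(columns={"dili_label": "label"}).to_csv(
        paths["labels"], sep="\t", index=False
    )
    manifest = {"config": asdict(config), "seed": config.seed}
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
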