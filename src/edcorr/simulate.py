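"""Synthetic reaction worlds for testing the full pipeline.

The generator emulates the statistical structure the pipeline assumes
about decomposed benchmark data without mimicking real hartree-scale
component magnitudes: per-class linear relations between descriptors
and reference energies with weights near 1 and small intercepts,
class-separable feature distributions, heterogeneous energy scales
spanning roughly three orders of magnitude (noncovalent interaction
energies below a kcal/mol up to ionisation-type reaction energies of
hundreds of kcal/mol), and additive Gaussian noise standing in for the
reference method's own uncertainty plus decomposition error.

Reference energies are kept away from zero (|ref| >= 0.1 kcal/mol, by
resampling) so that percentage errors stay well defined; the evaluation
code still guards against near-zero references for external data.

All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from edcorr.features import COMPONENT_COLUMNS, FEATURE_COLUMNS, SUPERSETS

#: Typical |reaction energy| per class, kcal/mol.  Intermolecular
#: noncovalent interactions are the weakest (rare-gas dimers sit well
#: below 1 kcal/mol); SMALL-molecule thermochemistry includes
#: ionisation-type processes of hundreds of kcal/mol.
DEFAULT_ENERGY_SCALES = {
    "INTER": 1.0,
    "INTRA": 5.0,
    "BARRIER": 25.0,
    "LARGE": 100.0,
    "SMALL": 500.0,
}

#: Floor below which reference energies are resampled.
REF_ENERGY_FLOOR = 0.1

# Fixed unit-sum direction of the class mean in descriptor space; each
# class leans on different components so the classes are separable.
# INTER and LARGE describe association processes, so their reaction
# energies are negative on average.
_CLASS_DIRECTIONS = {
    "INTER": -np.array([0.10, 0.05, 0.10, 0.35, 0.05, 0.15, 0.20]),
    "INTRA": np.array([0.05, 0.30, 0.10, 0.05, 0.30, 0.10, 0.10]),
    "BARRIER": np.array([0.40, 0.05, 0.25, 0.10, 0.05, 0.10, 0.05]),
    "LARGE": -np.array([0.05, 0.10, 0.40, 0.05, 0.15, 0.20, 0.05]),
    "SMALL": np.array([0.20, 0.20, 0.05, 0.15, 0.25, 0.05, 0.10]),
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic world.

    Defaults are the standard study conditions used throughout the test
    suite: 300 reactions per class, 0.5 kcal/mol reference noise, true
    weights drawn uniformly in [0.8, 1.2] and intercepts in [-2, 2]
    kcal/mol (drawn once from the seed unless given explicitly).
    """

    n_per_class: int = 300
    noise_sd: float = 0.5
    seed: int = 0
    true_weights: dict[str, np.ndarray] | None = None
    true_intercepts: dict[str, float] | None = None
    energy_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENERGY_SCALES)
    )
    class_feature_spread: float = 0.15  # relative to the class energy scale
    supersets: tuple[str, ...] = SUPERSETS

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.true_weights is not None:
            for cls, w in self.true_weights.items():
                if np.asarray(w).shape != (6,):
                    raise ValueError(f"true_weights[{cls!r}] must have length 6")


def _draw_truth(config: SynthConfig, rng: np.random.Generator):
    weights = {}
    intercepts = {}
    for cls in config.supersets:
        if config.true_weights is not None and cls in config.true_weights:
            weights[cls] = np.asarray(config.true_weights[cls], dtype=float)
        else:
            weights[cls] = rng.uniform(0.8, 1.2, size=6)
        if config.true_intercepts is not None and cls in config.true_intercepts:
            intercepts[cls] = float(config.true_intercepts[cls])
        else:
            intercepts[cls] = float(rng.uniform(-2.0, 2.0))
    return weights, intercepts


def generate_dataset(config: SynthConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a labelled feature table plus its ground truth.

    Per class: descriptor rows are drawn around a class-specific mean
    direction scaled to the class energy magnitude, and the reference is
    the true per-class linear map of the six weighted descriptors plus
    the unweighted dispersion delta, the class intercept, and Gaussian
    noise.  Rows whose reference magnitude falls below 0.1 kcal/mol are
    resampled so percentage errors stay defined.

    Returns ``(table, truth)`` where ``truth`` records the per-class
    weights and intercepts and the config echo.
    """
    for cls in config.supersets:
        if config.energy_scale[cls] < REF_ENERGY_FLOOR:
            raise ValueError(
                f"energy scale for {cls} ({config.energy_scale[cls]}) is below the "
                f"reference-energy floor {REF_ENERGY_FLOOR}; resampling cannot succeed"
            )
    rng = np.random.default_rng(config.seed)
    weights, intercepts = _draw_truth(config, rng)

    rows = []
    for cls in config.supersets:
        scale = config.energy_scale[cls]
        mean = _CLASS_DIRECTIONS[cls] * scale
        spread = config.class_feature_spread * scale
        n_done = 0
        while n_done < config.n_per_class:
            feats = rng.normal(mean, spread)
            noise = rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
            ref = float(feats[:6] @ weights[cls] + feats[6] + intercepts[cls] + noise)
            if abs(ref) < REF_ENERGY_FLOOR:
                continue
            row = {"reaction_id": f"{cls}_{n_done:04d}"}
            row.update(dict(zip(FEATURE_COLUMNS, feats)))
            row["superset"] = cls
            row["ref_energy"] = ref
            rows.append(row)
            n_done += 1

    table = pd.DataFrame(rows, columns=["reaction_id", *FEATURE_COLUMNS, "superset", "ref_energy"])
    truth = {
        "true_weights": {c: [float(x) for x in weights[c]] for c in config.supersets},
        "true_intercepts": {c: intercepts[c] for c in config.supersets},
        "noise_sd": config.noise_sd,
        "n_per_class": config.n_per_class,
        "energy_scale": {c: config.energy_scale[c] for c in config.supersets},
        "seed": config.seed,
    }
    return table, truth


def generate_species_form(
    table: pd.DataFrame, seed: int = 0, share_reactants: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Factor a feature table into species/reactions CSV form.

    Each reaction becomes A + B -> C: two synthetic reactant species
    with random component energies and a product whose components are
    chosen so the stoichiometric difference reproduces the feature row
    exactly.  With ``share_reactants`` the first reactant is shared per
    class, yielding fewer species rows.

    Returns ``(species, terms, meta)`` frames matching the CSV schemas
    of the feature-assembly module (all energies kcal/mol).
    """
    rng = np.random.default_rng(seed)
    species_rows = []
    term_rows = []
    meta_rows = []
    shared: dict[str, tuple[str, np.ndarray]] = {}

    def new_species(sid, comps):
        species_rows.append({"species_id": sid, **dict(zip(COMPONENT_COLUMNS, comps))})

    for _, row in table.iterrows():
        rid = row["reaction_id"]
        deltas = row[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        cls = row["superset"] if pd.notna(row["superset"]) else "NA"
        if share_reactants and cls in shared:
            a_id, a_comps = shared[cls]
        else:
            a_id = f"{cls}_shared_A" if share_reactants else f"{rid}_A"
            a_comps = rng.normal(0.0, 10.0, size=7)
            new_species(a_id, a_comps)
            if share_reactants:
                shared[cls] = (a_id, a_comps)
        b_id = f"{rid}_B"
        b_comps = rng.normal(0.0, 10.0, size=7)
        new_species(b_id, b_comps)
        c_id = f"{rid}_C"
        new_species(c_id, a_comps + b_comps + deltas)  # C - A - B == deltas exactly

        term_rows += [
            {"reaction_id": rid, "species_id": a_id, "coeff": -1.0},
            {"reaction_id": rid, "species_id": b_id, "coeff": -1.0},
            {"reaction_id": rid, "species_id": c_id, "coeff": 1.0},
        ]
        meta_rows.append(
            {
                "reaction_id": rid,
                "superset": row["superset"],
                "dataset": "synthetic",
                "ref_energy": row["ref_energy"],
            }
        )

    species = pd.DataFrame(species_rows, columns=["species_id", *COMPONENT_COLUMNS])
    terms = pd.DataFrame(term_rows, columns=["reaction_id", "species_id", "coeff"])
    meta = pd.DataFrame(meta_rows, columns=["reaction_id", "superset", "dataset", "ref_energy"])
    return species, terms, meta
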