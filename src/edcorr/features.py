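"""Reaction-level descriptors from per-species decomposed energies.

A species table holds, for every chemical species, the seven components
of its total electronic energy: kinetic (``te``), nuclear repulsion
(``vnn``), electron-nuclear attraction (``ven``), exchange (``ex``),
electronic Coulomb (``ej``), correlation (``ec``) and the dispersion
correction (``edisp``).  A reaction is a signed stoichiometric
combination of species (products positive, reactants negative); its
descriptor row is the stoichiometric difference of each component,
expressed in kcal/mol.  By construction the seven deltas sum to the
uncorrected DFT reaction energy.

Barrier heights need no special handling: a transition state is simply
a "product" species, so a barrier is an ordinary reaction row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: CODATA-derived conversion from hartree to kcal/mol.
HARTREE_TO_KCAL = 627.5094740631

#: The five reaction-class labels used by the model library.
SUPERSETS = ("BARRIER", "INTER", "INTRA", "LARGE", "SMALL")

#: Per-species energy components, in fixed order.
COMPONENT_COLUMNS = ("te", "vnn", "ven", "ex", "ej", "ec", "edisp")

#: Reaction-level descriptor columns, in fixed order (matches COMPONENT_COLUMNS).
FEATURE_COLUMNS = ("d_te", "d_vnn", "d_ven", "d_ex", "d_ej", "d_ec", "d_disp")

#: The six columns that carry trainable weights (dispersion is unweighted).
WEIGHTED_COLUMNS = FEATURE_COLUMNS[:6]

_UNITS = ("hartree", "kcal/mol")


class SpeciesTableError(ValueError):
    """Raised when a species table fails parsing or validation."""


class ReactionError(ValueError):
    """Raised when a reaction definition cannot be resolved."""


def load_species_table(path, unit: str | None = None) -> pd.DataFrame:
    """Read a per-species component-energy CSV into kcal/mol.

    Parameters
    ----------
    path
        CSV with header columns ``species_id, te, vnn, ven, ex, ej, ec,
        edisp`` plus optional ``unit`` (per-row) and ``total`` columns.
    unit
        Declared unit of the whole file, ``"hartree"`` or ``"kcal/mol"``.
        Overridden by a per-row ``unit`` column if present; defaults to
        kcal/mol.

    Returns
    -------
    pandas.DataFrame
        Indexed by ``species_id``, component columns in kcal/mol.

    Raises
    ------
    SpeciesTableError
        On missing columns, non-numeric cells, duplicate ids, or a
        ``total`` column inconsistent with the component sum beyond
        1e-6 in the stated unit.
    """
    raw = pd.read_csv(path, dtype={"species_id": str}, float_precision="round_trip")
    missing = [c for c in ("species_id", *COMPONENT_COLUMNS) if c not in raw.columns]
    if missing:
        raise SpeciesTableError(f"species table missing column(s): {', '.join(missing)}")

    dupes = raw["species_id"][raw["species_id"].duplicated()].unique()
    if len(dupes):
        raise SpeciesTableError(f"duplicate species_id: {', '.join(map(str, dupes))}")

    for col in COMPONENT_COLUMNS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[vals.isna()]
        if len(bad):
            row = int(bad[0])
            raise SpeciesTableError(
                f"non-numeric value in column '{col}' at row {row} "
                f"(species_id={raw.loc[row, 'species_id']!r})"
            )
        if not np.isfinite(vals).all():
            raise SpeciesTableError(f"non-finite value in column '{col}'")
        raw[col] = vals.astype(float)

    if "unit" in raw.columns:
        units = raw["unit"].astype(str)
    else:
        units = pd.Series([unit or "kcal/mol"] * len(raw), index=raw.index)
    unknown = sorted(set(units) - set(_UNITS))
    if unknown:
        raise SpeciesTableError(f"unknown unit(s): {', '.join(unknown)}; expected one of {_UNITS}")

    if "total" in raw.columns:
        totals = pd.to_numeric(raw["total"], errors="coerce")
        comp_sum = raw[list(COMPONENT_COLUMNS)].sum(axis=1)
        off = (comp_sum - totals).abs() > 1e-6
        if off.any():
            row = int(raw.index[off][0])
            raise SpeciesTableError(
                f"total column inconsistent with component sum at row {row} "
                f"(species_id={raw.loc[row, 'species_id']!r}, "
                f"|sum-total|={abs(comp_sum[row] - totals[row]):.3e})"
            )

    factor = np.where(units == "hartree", HARTREE_TO_KCAL, 1.0)
    out = raw.set_index("species_id")[list(COMPONENT_COLUMNS)].astype(float)
    out = out.mul(factor, axis=0)
    return out


def load_reactions(terms_path, meta_path=None) -> list[dict]:
    """Read reaction definitions from a long-format stoichiometry CSV.

    ``terms_path`` has columns ``reaction_id, species_id, coeff`` (one row
    per term; products positive, reactants negative).  The optional
    ``meta_path`` CSV carries ``reaction_id, superset, dataset,
    ref_energy`` (reference energies in kcal/mol; blank for pure
    prediction).

    Returns a list of reaction dicts with keys ``reaction_id``,
    ``terms`` (list of ``(species_id, coeff)``), ``superset``,
    ``dataset`` and ``ref_energy``.
    """
    terms = pd.read_csv(
        terms_path, dtype={"reaction_id": str, "species_id": str}, float_precision="round_trip"
    )
    for col in ("reaction_id", "species_id", "coeff"):
        if col not in terms.columns:
            raise ReactionError(f"reactions table missing column '{col}'")
    terms["coeff"] = pd.to_numeric(terms["coeff"], errors="raise").astype(float)
    if (terms["coeff"] == 0).any():
        bad = terms.loc[terms["coeff"] == 0, "reaction_id"].iloc[0]
        raise ReactionError(f"zero stoichiometric coefficient in reaction {bad!r}")

    meta: dict[str, dict] = {}
    if meta_path is not None:
        mraw = pd.read_csv(meta_path, dtype={"reaction_id": str}, float_precision="round_trip")
        for _, row in mraw.iterrows():
            sset = row.get("superset")
            sset = None if pd.isna(sset) else str(sset)
            if sset is not None and sset not in SUPERSETS:
                raise ReactionError(
                    f"reaction {row['reaction_id']!r}: unknown superset {sset!r}; "
                    f"expected one of {SUPERSETS}"
                )
            ref = row.get("ref_energy")
            meta[str(row["reaction_id"])] = {
                "superset": sset,
                "dataset": None if pd.isna(row.get("dataset")) else str(row["dataset"]),
                "ref_energy": None if pd.isna(ref) else float(ref),
            }

    reactions = []
    for rid, grp in terms.groupby("reaction_id", sort=False):
        m = meta.get(str(rid), {})
        reactions.append(
            {
                "reaction_id": str(rid),
                "terms": list(zip(grp["species_id"], grp["coeff"])),
                "superset": m.get("superset"),
                "dataset": m.get("dataset"),
                "ref_energy": m.get("ref_energy"),
            }
        )
    return reactions


def delta_components(reaction: dict, species: pd.DataFrame) -> dict:
    """Assemble one descriptor row: stoichiometric component differences.

    Each delta is ``sum_products(coeff * component) -
    sum_reactants(|coeff| * component)``, i.e. the plain signed sum over
    terms.  All values in kcal/mol (the species frame is already
    converted on load).
    """
    if not reaction["terms"]:
        raise ReactionError(f"reaction {reaction['reaction_id']!r} has no terms")
    deltas = np.zeros(len(COMPONENT_COLUMNS))
    for sid, coeff in reaction["terms"]:
        if coeff == 0:
            raise ReactionError(
                f"reaction {reaction['reaction_id']!r}: zero coefficient for {sid!r}"
            )
        if sid not in species.index:
            raise ReactionError(
                f"reaction {reaction['reaction_id']!r}: unresolved species_id {sid!r}"
            )
        deltas += coeff * species.loc[sid, list(COMPONENT_COLUMNS)].to_numpy(dtype=float)
    row = {"reaction_id": reaction["reaction_id"]}
    row.update(dict(zip(FEATURE_COLUMNS, deltas)))
    row["superset"] = reaction.get("superset")
    row["ref_energy"] = reaction.get("ref_energy")
    return row


def build_feature_table(reactions: list[dict], species: pd.DataFrame) -> pd.DataFrame:
    """Batch :func:`delta_components`: one row per reaction, order kept."""
    rows = [delta_components(r, species) for r in reactions]
    cols = ["reaction_id", *FEATURE_COLUMNS, "superset", "ref_energy"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into the six weighted columns and dispersion.

    Returns ``(X, d_disp)`` with ``X`` of shape (n, 6).
    """
    X = table[list(WEIGHTED_COLUMNS)].to_numpy(dtype=float)
    d_disp = table["d_disp"].to_numpy(dtype=float)
    return X, d_disp


def dft_reaction_energy(table: pd.DataFrame) -> np.ndarray:
    """Uncorrected DFT reaction energy: the sum of the seven delta columns."""
    return table[list(FEATURE_COLUMNS)].to_numpy(dtype=float).sum(axis=1)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the feature CSV (full float precision, round-trip safe)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV written by :func:`write_feature_table`."""
    tbl = pd.read_csv(path, dtype={"reaction_id": str}, float_precision="round_trip")
    missing = [c for c in ("reaction_id", *FEATURE_COLUMNS) if c not in tbl.columns]
    if missing:
        raise SpeciesTableError(f"feature table missing column(s): {', '.join(missing)}")
    if "superset" in tbl.columns:
        tbl["superset"] = tbl["superset"].where(tbl["superset"].notna(), None)
    return tbl
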