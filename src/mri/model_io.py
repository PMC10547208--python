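"""Readers and writers for the formats the tool touches.

SBML models are read and written through COBRApy; expression and phenotype
tables are UTF-8 TSV files parsed with pandas.  The in-memory model is a
plain matrix-level container (:class:`StoichiometricModel`) so that the
downstream MILP assembly never depends on a modelling framework.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "StoichiometricModel",
    "ExpressionProfile",
    "PhenotypeTable",
    "read_sbml_model",
    "write_sbml_model",
    "read_expression_table",
    "write_expression_table",
    "read_gene_mapping",
    "read_phenotype_table",
    "save_result_json",
]

#: Column names accepted in phenotype tables, with units.
PHENOTYPE_QUANTITIES = (
    "growth_rate",      # 1/h
    "growth_yield",     # gDCW/mmol substrate
    "oxygen_uptake",    # mmol/gDCW/h
    "substrate_uptake", # mmol/gDCW/h
)


@dataclass
class StoichiometricModel:
    """A genome-scale metabolic model at the matrix level.

    ``S`` is the m x n stoichiometric matrix (rows = metabolites, columns =
    reactions).  Flux bounds are in mmol/gDCW/h.  ``gene_rules`` holds the
    Boolean gene-protein-reaction text per reaction (AND = enzyme complex,
    OR = isozymes); ``genes`` lists every gene identifier appearing in a
    rule.  ``exchange_flags`` marks reactions whose column has at most one
    nonzero coefficient, i.e. pseudo-reactions across the system boundary.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    objective_coeffs: np.ndarray
    rhs: np.ndarray
    gene_rules: list[str]
    genes: list[str]
    exchange_flags: np.ndarray
    biomass_reaction: str | None = None

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"reaction {reaction_id!r} not in model") from None

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        m, n = self.S.shape
        if m != self.n_metabolites or n != self.n_reactions:
            raise ValueError(
                f"S is {m}x{n} but model lists {self.n_metabolites} "
                f"metabolites and {self.n_reactions} reactions"
            )
        if np.any(self.lower_bound > self.upper_bound):
            bad = np.flatnonzero(self.lower_bound > self.upper_bound)
            raise ValueError(
                f"lower bound exceeds upper bound for reactions "
                f"{[self.reaction_ids[i] for i in bad[:5]]}"
            )
        rule_genes = set()
        for rule in self.gene_rules:
            rule_genes.update(genes_in_rule(rule))
        missing = rule_genes - set(self.genes)
        if missing:
            raise ValueError(f"genes in rules but not in gene list: {sorted(missing)}")
        expected = compute_exchange_flags(self.S)
        if not np.array_equal(np.asarray(self.exchange_flags, bool), expected):
            raise ValueError("exchange_flags inconsistent with S columns")

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bound=self.lower_bound.copy(),
            upper_bound=self.upper_bound.copy(),
            objective_coeffs=self.objective_coeffs.copy(),
            rhs=self.rhs.copy(),
            gene_rules=list(self.gene_rules),
            genes=list(self.genes),
            exchange_flags=self.exchange_flags.copy(),
            biomass_reaction=self.biomass_reaction,
        )


@dataclass
class ExpressionProfile:
    """Per-strain gene expression levels, on the scale the platform provides.

    Values are consumed as given (the motivating case is log-scale
    microarray intensity); the expression-to-flux constant C absorbs the
    scale.  Gene identifiers are unique and values finite and nonnegative.
    """

    strain_label: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, value in self.values.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"profile {self.strain_label!r}: gene {gene!r} has "
                    f"invalid expression value {value!r}"
                )

    def __contains__(self, gene: str) -> bool:
        return gene in self.values

    def __getitem__(self, gene: str) -> float:
        return self.values[gene]

    @property
    def genes(self) -> set[str]:
        return set(self.values)

    def renamed(self, mapping: Mapping[str, str]) -> "ExpressionProfile":
        """Return a copy with gene identifiers translated through ``mapping``.

        Used to bridge platform gene symbols (e.g. cyoC) to model locus
        tags.  Unmapped genes keep their identifier; a collision after
        mapping is an error.
        """
        out: dict[str, float] = {}
        for gene, value in self.values.items():
            new = mapping.get(gene, gene)
            if new in out:
                raise ValueError(f"gene mapping collides on {new!r}")
            out[new] = value
        return ExpressionProfile(self.strain_label, out)


@dataclass
class PhenotypeTable:
    """Measured growth phenotypes per strain; any cell may be absent."""

    data: pd.DataFrame  # strains as rows, PHENOTYPE_QUANTITIES as columns

    def __post_init__(self) -> None:
        present = self.data.to_numpy(dtype=float)
        if np.any(np.isinf(present)):
            raise ValueError("phenotype table contains non-finite values")
        for col in ("growth_rate", "growth_yield"):
            if col in self.data.columns and (self.data[col].dropna() < 0).any():
                raise ValueError(f"{col} must be >= 0")

    @property
    def strains(self) -> list[str]:
        return list(self.data.index)

    def get(self, strain: str, quantity: str) -> float | None:
        if quantity not in PHENOTYPE_QUANTITIES:
            raise KeyError(
                f"unknown quantity {quantity!r}; accepted: {PHENOTYPE_QUANTITIES}"
            )
        if strain not in self.data.index or quantity not in self.data.columns:
            return None
        value = self.data.at[strain, quantity]
        return None if pd.isna(value) else float(value)


def compute_exchange_flags(S: sp.spmatrix) -> np.ndarray:
    """A reaction is an exchange iff its column has at most one nonzero."""
    counts = np.asarray((S != 0).sum(axis=0)).ravel()
    return counts <= 1


def genes_in_rule(rule: str) -> set[str]:
    """Gene identifiers appearing in a Boolean gene-association string."""
    if not rule or not rule.strip():
        return set()
    from cobra.core.gene import GPR

    return set(GPR.from_string(rule).genes)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def read_sbml_model(path: str | Path) -> StoichiometricModel:
    """Read an SBML model (Level 3 fbc, or Level 2 with annotations).

    Gene rules are preserved verbatim as Boolean text; exchange reactions
    are flagged from the stoichiometry, not from identifiers.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cobra_model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra wraps libsbml errors
        raise ValueError(f"cannot parse SBML file {path}: {exc}") from exc
    return from_cobra(cobra_model)


def from_cobra(cobra_model) -> StoichiometricModel:
    """Convert a ``cobra.Model`` into the matrix-level container."""
    met_ids = [m.id for m in cobra_model.metabolites]
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_ids = [r.id for r in cobra_model.reactions]
    n, m = len(rxn_ids), len(met_ids)

    rows, cols, vals = [], [], []
    lb = np.zeros(n)
    ub = np.zeros(n)
    obj = np.zeros(n)
    rules: list[str] = []
    biomass = None
    for j, rxn in enumerate(cobra_model.reactions):
        if rxn.lower_bound is None or rxn.upper_bound is None:
            raise ValueError(f"reaction {rxn.id} has no flux bounds")
        lb[j], ub[j] = float(rxn.lower_bound), float(rxn.upper_bound)
        coeff = rxn.objective_coefficient
        obj[j] = float(coeff) if coeff else 0.0
        if obj[j] != 0.0 and biomass is None:
            biomass = rxn.id
        rules.append(rxn.gene_reaction_rule or "")
        for met, stoich in rxn.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            vals.append(float(stoich))

    S = sp.csc_matrix((vals, (rows, cols)), shape=(m, n))
    model = StoichiometricModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lower_bound=lb,
        upper_bound=ub,
        objective_coeffs=obj,
        rhs=np.zeros(m),
        gene_rules=rules,
        genes=sorted(g.id for g in cobra_model.genes),
        exchange_flags=compute_exchange_flags(S),
        biomass_reaction=biomass,
    )
    model.validate()
    return model


def to_cobra(model: StoichiometricModel):
    """Build a ``cobra.Model`` from the matrix-level container."""
    import cobra

    cm = cobra.Model("mri_model")
    mets = [cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids]
    cm.add_metabolites(mets)
    S = model.S.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bound[j])
        rxn.upper_bound = float(model.upper_bound[j])
        reactions.append(rxn)
    cm.add_reactions(reactions)
    for j, rxn in enumerate(reactions):
        col = S.getcol(j)
        rxn.add_metabolites(
            {mets[i]: float(v) for i, v in zip(col.indices, col.data)}
        )
        rule = model.gene_rules[j]
        if rule:
            rxn.gene_reaction_rule = rule
    if model.biomass_reaction is not None:
        cm.objective = model.biomass_reaction
    return cm


def write_sbml_model(model: StoichiometricModel, path: str | Path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(Path(path)))


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> list[ExpressionProfile]:
    """Read a TSV of expression levels: gene rows, one column per strain.

    The first column holds gene identifiers (whitespace-trimmed, matched
    case-sensitively downstream); the header row holds strain labels.
    Duplicated genes and non-numeric cells are hard errors — silent
    aggregation could mask data faults.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: no strain columns")
    df.index = df.index.astype(str).str.strip()
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated gene identifiers {dupes}")
    profiles = []
    for strain in df.columns:
        values: dict[str, float] = {}
        for gene, cell in df[strain].items():
            try:
                values[gene] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at gene {gene!r}, "
                    f"strain column {strain!r}"
                ) from None
        profiles.append(ExpressionProfile(str(strain).strip(), values))
    return profiles


def write_expression_table(
    profiles: list[ExpressionProfile], path: str | Path
) -> None:
    genes = sorted(set().union(*(p.genes for p in profiles)))
    df = pd.DataFrame(
        {p.strain_label: [p.values.get(g, np.nan) for g in genes] for p in profiles},
        index=pd.Index(genes, name="gene"),
    )
    df.to_csv(Path(path), sep="\t")


def read_gene_mapping(path: str | Path) -> dict[str, str]:
    """Two-column TSV translating platform gene symbols to model genes."""
    df = pd.read_csv(Path(path), sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mapping file needs two columns")
    return dict(zip(df[0].str.strip(), df[1].str.strip()))


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read a TSV of measured phenotypes: strain rows, quantity columns.

    Missing cells stay absent (NaN), never zero.  Unknown column names are
    rejected with the accepted list.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.empty:
        raise ValueError(f"{path}: no strains")
    unknown = [c for c in df.columns if c not in PHENOTYPE_QUANTITIES]
    if unknown:
        raise ValueError(
            f"{path}: unknown columns {unknown}; accepted names: "
            f"{list(PHENOTYPE_QUANTITIES)}"
        )
    df.index = df.index.astype(str)
    return PhenotypeTable(df.astype(float))


def save_result_json(result, path: str | Path, **extra) -> None:
    """Serialize an adaptation-score result (or any mapping) to JSON."""
    if hasattr(result, "to_dict"):
        payload = result.to_dict()
    else:
        payload = dict(result)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
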