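"""Key-gene identification and downstream reprogramming analyses.

The selection procedure applies two factors: a gene must (1) convert all
of its expression into flux in the wild-type strain under the unlimited
condition (usage slack alpha_j = 0), and (2) show a large absolute
expression difference between wild-type and the mean of the evolved
strains.  Genes passing both are candidate origins of the metabolic
reprogramming; their conditional adaptation scores across strains, and the
correlation of those scores with measured growth phenotypes, quantify how
strongly each candidate separates wild-type from evolved metabolism.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .milp import (
    AdaptationResult,
    MediumSpec,
    apply_medium,
    build_mri_problem,
    conditional_adaptation_score,
    full_usage_gene_set,
    solve_adaptation_score,
)
from .model_io import ExpressionProfile, PhenotypeTable, StoichiometricModel
from .transform import convert_model

logger = logging.getLogger(__name__)

__all__ = [
    "KeyGeneTable",
    "CorrelationReport",
    "AnalysisConfig",
    "identify_key_genes",
    "pearson_correlation",
    "compare_usage_sets",
    "adaptation_score_ratio",
    "run_full_analysis",
]


@dataclass
class KeyGeneTable:
    """Ranked wild-type fully-used genes with expression differences.

    ``table`` has one row per gene (index) with columns:
    ``delta_expression`` (|E_WT - mean E_evolved|, expression units),
    ``rank`` (1 = largest delta), ``selected`` (top_k and delta above the
    threshold), and ``wt_extreme`` (wild-type level is the minimum or
    maximum across all strains — the differentiation diagnostic).
    """

    table: pd.DataFrame
    top_k: int

    @property
    def selected_genes(self) -> list[str]:
        sel = self.table[self.table["selected"]]
        return list(sel.index)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(Path(path), sep="\t", index_label="gene")


@dataclass
class CorrelationReport:
    """Pearson correlation between scores and one phenotype quantity."""

    quantity: str
    pairs: list[tuple[float, float]]
    pearson_r: float
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("pearson_r outside [-1, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value outside (0, 1]")


def identify_key_genes(
    wt_fully_used: AdaptationResult | set[str],
    wt_profile: ExpressionProfile,
    evolved_profiles: list[ExpressionProfile],
    top_k: int = 2,
    min_delta: float = 0.0,
) -> KeyGeneTable:
    """Rank wild-type fully-used genes by WT-vs-evolved expression change.

    ``wt_fully_used`` may be a witness result (its ``fully_used_genes``)
    or an explicit gene set, e.g. the solver-independent
    optimality-preserving set from :func:`full_usage_gene_set`.  Genes
    missing from any evolved profile are excluded with a warning.  Rows are
    sorted by descending delta, ties broken by gene identifier; the top_k
    rows with delta strictly above ``min_delta`` are flagged selected.
    """
    if not evolved_profiles:
        raise ValueError("need at least one evolved profile")
    if isinstance(wt_fully_used, AdaptationResult):
        gene_set = set(wt_fully_used.fully_used_genes)
    else:
        gene_set = set(wt_fully_used)

    rows = []
    for gene in sorted(gene_set):
        if gene not in wt_profile:
            logger.warning("gene %s not in wild-type profile; excluded", gene)
            continue
        missing = [p.strain_label for p in evolved_profiles if gene not in p]
        if missing:
            logger.warning(
                "gene %s missing from evolved profiles %s; excluded",
                gene, missing,
            )
            continue
        e_wt = float(wt_profile[gene])
        e_ev = [float(p[gene]) for p in evolved_profiles]
        delta = abs(e_wt - float(np.mean(e_ev)))
        all_levels = [e_wt, *e_ev]
        wt_extreme = e_wt == min(all_levels) or e_wt == max(all_levels)
        rows.append((gene, delta, wt_extreme))

    df = pd.DataFrame(
        rows, columns=["gene", "delta_expression", "wt_extreme"]
    ).set_index("gene")
    # descending delta, lexicographic gene id on ties
    df = df.sort_values(
        by=["delta_expression"], ascending=False, kind="mergesort"
    )
    order = sorted(
        df.index, key=lambda g: (-df.at[g, "delta_expression"], g)
    )
    df = df.loc[order]
    df["rank"] = np.arange(1, len(df) + 1)
    df["selected"] = (df["rank"] <= top_k) & (df["delta_expression"] > min_delta)
    return KeyGeneTable(table=df, top_k=top_k)


def pearson_correlation(
    x, y, quantity: str = ""
) -> CorrelationReport:
    """Sample Pearson r with a two-sided t-distribution p-value (n-2 df)."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: a constant vector has no correlation")
    r, p = stats.pearsonr(x, y)
    return CorrelationReport(
        quantity=quantity,
        pairs=list(zip(x.tolist(), y.tolist())),
        pearson_r=float(r),
        p_value=float(p),
    )


def compare_usage_sets(
    usage_sets: dict[str, set[str]]
) -> dict[frozenset[str], int]:
    """Venn-region counts over 2-4 per-strain fully-used gene sets.

    Keys are the nonempty strain combinations (frozensets of labels);
    values count genes present in exactly those strains.  Region counts
    sum to the size of the union.
    """
    if not 2 <= len(usage_sets) <= 4:
        raise ValueError(
            "compare_usage_sets handles 2-4 strains; report a pairwise "
            "matrix for more"
        )
    labels = list(usage_sets)
    regions: dict[frozenset[str], int] = {}
    for k in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, k):
            inside = frozenset(combo)
            genes = set.intersection(*(usage_sets[s] for s in inside))
            for other in labels:
                if other not in inside:
                    genes -= usage_sets[other]
            regions[inside] = len(genes)
    return regions


def adaptation_score_ratio(
    numerator: AdaptationResult, denominator: AdaptationResult
) -> float:
    """Ratio of two conditional scores (e.g. carbon uptake vs a key gene).

    A lower ratio in an evolved strain means its expression pattern favors
    the denominator's target relatively more than the wild-type's does.
    """
    if denominator.score <= 0:
        raise ValueError("denominator adaptation score must be > 0")
    return numerator.score / denominator.score


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Knobs of the full pipeline.

    ``C`` is the expression-to-flux constant (mmol/gDCW/h per expression
    unit).  ``use_witness_only`` makes the wild-type filter use the single
    solver witness instead of the solver-independent optimality-preserving
    set.  ``ratio_numerator`` optionally names a reaction (typically the
    carbon-uptake exchange) whose conditional score is divided by each key
    gene's conditional score per strain.
    """

    medium: MediumSpec
    C: float
    top_k: int = 2
    min_delta: float = 0.0
    use_witness_only: bool = False
    ratio_numerator: str | None = None
    venn_strains: list[str] | None = None
    tol: float = 1e-6
    dnf_cap: int = 32
    time_limit: float | None = None  # seconds per MILP solve

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config file: medium exchange list, C, tolerances, caps.

        Expected keys: ``unlimited_exchanges`` (list), ``carbon_source``,
        ``C``; optional: ``top_k``, ``min_delta``, ``use_witness_only``,
        ``ratio_numerator``, ``venn_strains``, ``tol``, ``dnf_cap``,
        ``time_limit``.
        """
        raw = json.loads(Path(path).read_text())
        try:
            medium = MediumSpec(
                unlimited_exchanges=frozenset(raw.pop("unlimited_exchanges")),
                carbon_source=raw.pop("carbon_source"),
            )
            C = float(raw.pop("C"))
        except KeyError as exc:
            raise ValueError(f"config {path}: missing required key {exc}") from exc
        known = {f.name for f in cls.__dataclass_fields__.values()} - {
            "medium", "C",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(medium=medium, C=C, **raw)


def run_full_analysis(
    model: StoichiometricModel,
    profiles: list[ExpressionProfile],
    phenotypes: PhenotypeTable | None,
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Unlimited scores -> key genes -> conditional panels -> correlations.

    The first profile is taken as wild-type.  Returns a JSON-serializable
    bundle; with ``out_dir`` the bundle and per-table TSVs are written.
    Stages that cannot run (e.g. no phenotypes) are flagged, not fatal.
    """
    if not profiles:
        raise ValueError("no expression profiles given")
    wt_profile, evolved = profiles[0], list(profiles[1:])
    converted = convert_model(model, cap=config.dnf_cap)
    bounded = apply_medium(converted, config.medium)

    bundle: dict = {
        "C": config.C,
        "wild_type": wt_profile.strain_label,
        "strains": [p.strain_label for p in profiles],
        "status": {},
    }

    problems = {
        p.strain_label: build_mri_problem(
            bounded, p, config.C, tol=config.tol, time_limit=config.time_limit
        )
        for p in profiles
    }
    unlimited = {
        label: solve_adaptation_score(problem)
        for label, problem in problems.items()
    }
    bundle["unlimited_scores"] = {
        label: {"P": r.P, "score": r.score} for label, r in unlimited.items()
    }
    bundle["status"]["unlimited"] = "ok"

    wt_label = wt_profile.strain_label
    if config.use_witness_only:
        wt_set = set(unlimited[wt_label].fully_used_genes)
    else:
        wt_set = full_usage_gene_set(problems[wt_label], unlimited[wt_label])
    bundle["wild_type_fully_used"] = sorted(wt_set)

    if evolved:
        key_table = identify_key_genes(
            wt_set, wt_profile, evolved, top_k=config.top_k,
            min_delta=config.min_delta,
        )
        bundle["key_genes"] = {
            "selected": key_table.selected_genes,
            "table": key_table.table.reset_index().to_dict(orient="records"),
        }
        bundle["status"]["key_genes"] = "ok"
        key_genes = key_table.selected_genes
    else:
        key_table = None
        key_genes = []
        bundle["status"]["key_genes"] = "not computed: no evolved profiles"

    conditional: dict[str, dict[str, AdaptationResult]] = {}
    for gene in key_genes:
        conditional[gene] = {
            label: conditional_adaptation_score(problem, gene)
            for label, problem in problems.items()
        }
    bundle["conditional_scores"] = {
        gene: {label: r.score for label, r in panel.items()}
        for gene, panel in conditional.items()
    }
    bundle["status"]["conditional"] = "ok" if key_genes else "not computed"

    # correlations of each key gene's conditional panel with each phenotype
    correlations: dict[str, dict[str, dict]] = {}
    if phenotypes is not None and key_genes:
        for gene, panel in conditional.items():
            correlations[gene] = {}
            for quantity in ("growth_rate", "growth_yield", "oxygen_uptake"):
                pairs = [
                    (panel[label].score, phenotypes.get(label, quantity))
                    for label in panel
                ]
                pairs = [(s, m) for s, m in pairs if m is not None]
                if len(pairs) < 3:
                    correlations[gene][quantity] = {
                        "status": "not computed: fewer than 3 measured strains"
                    }
                    continue
                try:
                    rep = pearson_correlation(
                        [s for s, _ in pairs], [m for _, m in pairs], quantity
                    )
                except ValueError as exc:
                    correlations[gene][quantity] = {"status": f"error: {exc}"}
                    continue
                correlations[gene][quantity] = {
                    "pearson_r": rep.pearson_r,
                    "p_value": rep.p_value,
                    "n": len(pairs),
                }
        bundle["status"]["correlations"] = "ok"
    else:
        bundle["status"]["correlations"] = "not computed: no phenotypes"
    bundle["correlations"] = correlations

    # usage-set comparison across up to 4 strains under the first key gene
    if key_genes:
        gene = key_genes[0]
        labels = config.venn_strains or [p.strain_label for p in profiles[:4]]
        sets = {
            label: set(conditional[gene][label].fully_used_genes)
            for label in labels
            if label in conditional[gene]
        }
        if 2 <= len(sets) <= 4:
            regions = compare_usage_sets(sets)
            bundle["usage_set_regions"] = {
                "&".join(sorted(k)): v for k, v in regions.items()
            }
            bundle["status"]["usage_sets"] = "ok"
        else:
            bundle["status"]["usage_sets"] = "not computed: need 2-4 strains"
    else:
        bundle["status"]["usage_sets"] = "not computed"

    # score ratios, e.g. carbon-source uptake over key-gene score
    if config.ratio_numerator and key_genes:
        ratios: dict[str, dict[str, float]] = {}
        for gene in key_genes:
            ratios[gene] = {}
            for label, problem in problems.items():
                num = conditional_adaptation_score(
                    problem, config.ratio_numerator
                )
                ratios[gene][label] = adaptation_score_ratio(
                    num, conditional[gene][label]
                )
        bundle["score_ratios"] = {
            "numerator": config.ratio_numerator,
            "values": ratios,
        }
        bundle["status"]["ratios"] = "ok"
    else:
        bundle["status"]["ratios"] = "not computed"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "bundle.json").write_text(json.dumps(bundle, indent=2))
        if key_table is not None:
            key_table.to_tsv(out / "keygenes.tsv")
        if conditional:
            panel = pd.DataFrame(
                {
                    gene: {lab: r.score for lab, r in p.items()}
                    for gene, p in conditional.items()
                }
            )
            panel.to_csv(out / "conditional_scores.tsv", sep="\t",
                         index_label="strain")
    return bundle
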