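import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import linprog

import mri
from mri.model_io import StoichiometricModel, compute_exchange_flags
from mri.transform import (
    build_gene_map,
    convert_model,
    expand_gpr_without_or,
    gpr_to_dnf,
    split_reversible,
)


def _small_model(reactions, metabolites):
    met_index = {m: i for i, m in enumerate(metabolites)}
    S = np.zeros((len(metabolites), len(reactions)))
    ids, lbs, ubs, rules = [], [], [], []
    genes = set()
    for j, (rid, stoich, lb, ub, rule) in enumerate(reactions):
        ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        rules.append(rule)
        for met, coeff in stoich.items():
            S[met_index[met], j] = coeff
        from mri.model_io import genes_in_rule

        genes |= genes_in_rule(rule)
    Ssp = sp.csc_matrix(S)
    return StoichiometricModel(
        metabolite_ids=list(metabolites),
        reaction_ids=ids,
        S=Ssp,
        lower_bound=np.array(lbs, float),
        upper_bound=np.array(ubs, float),
        objective_coeffs=np.zeros(len(reactions)),
        rhs=np.zeros(len(metabolites)),
        gene_rules=rules,
        genes=sorted(genes),
        exchange_flags=compute_exchange_flags(Ssp),
    )


class TestSplitReversible:
    def test_irreversible_reaction_passes_through(self):
        model = _small_model(
            [("EX_A", {"A": -1}, -1000, 0, ""),
             ("R1", {"A": -1, "B": 1}, 0, 1000, "g1"),
             ("EX_B", {"B": -1}, 0, 1000, "")],
            ["A", "B"],
        )
        irr = split_reversible(model)
        assert "R1" in irr.base.reaction_ids
        assert irr.reversible_groups == []

    def test_reversible_split_negates_column(self, toy1):
        irr = split_reversible(toy1)
        ids = irr.base.reaction_ids
        assert "R3_f" in ids and "R3_b" in ids
        S = irr.base.S.toarray()
        f, b = ids.index("R3_f"), ids.index("R3_b")
        np.testing.assert_allclose(S[:, f], -S[:, b])
        assert irr.base.lower_bound.min() >= 0
        assert irr.base.upper_bound[f] == 1000
        assert irr.base.upper_bound[b] == 1000
        assert len(irr.reversible_groups) == 1

    def test_backward_only_reaction_is_flipped(self):
        model = _small_model(
            [("EX_A", {"A": -1}, -1000, 0, ""),
             ("EX_B", {"B": -1}, 0, 1000, ""),
             ("R1", {"B": -1, "A": 1}, -1000, 0, "g1")],
            ["A", "B"],
        )
        irr = split_reversible(model)
        j = irr.base.reaction_ids.index("R1")
        # flipped: now consumes A, produces B, bounds [0, 1000]
        S = irr.base.S.toarray()
        assert S[0, j] == -1 and S[1, j] == 1
        assert irr.base.lower_bound[j] == 0
        assert irr.base.upper_bound[j] == 1000
        assert irr.origin[j].direction == "b"

    def test_inconsistent_bounds_raise(self, toy1):
        bad = toy1.copy()
        bad.lower_bound[1], bad.upper_bound[1] = 5.0, -5.0
        with pytest.raises(ValueError, match="inconsistent"):
            split_reversible(bad)

    def test_idempotent(self, toy1):
        once = split_reversible(toy1)
        twice = split_reversible(once.base)
        assert twice.base.reaction_ids == once.base.reaction_ids
        assert (twice.base.S != once.base.S).nnz == 0
        assert twice.reversible_groups == []  # nothing left to split


class TestGPRExpansion:
    @pytest.mark.parametrize(
        "rule,expected",
        [
            ("g1", [{"g1"}]),
            ("g1 or g2", [{"g1"}, {"g2"}]),
            ("(g1 and g2) or g3", [{"g1", "g2"}, {"g3"}]),
            ("g1 and g2", [{"g1", "g2"}]),
            ("(g1 or g2) and g3", [{"g1", "g3"}, {"g2", "g3"}]),
            ("", []),
        ],
    )
    def test_dnf(self, rule, expected):
        assert gpr_to_dnf(rule) == [frozenset(s) for s in expected]

    def test_dnf_cap_aborts(self):
        # (a1 or b1) and (a2 or b2) ... expands to 2^k disjuncts
        rule = " and ".join(f"(a{i} or b{i})" for i in range(6))
        with pytest.raises(ValueError, match="cap"):
            gpr_to_dnf(rule, cap=32)

    def test_unparseable_rule_quoted(self):
        with pytest.raises(ValueError, match="g1 and and"):
            gpr_to_dnf("g1 and and")

    def test_isozyme_copies_share_column(self):
        model = _small_model(
            [("EX_A", {"A": -1}, -1000, 0, ""),
             ("R", {"A": -1, "B": 1}, 0, 1000, "g1 or g2"),
             ("EX_B", {"B": -1}, 0, 1000, "")],
            ["A", "B"],
        )
        irr = expand_gpr_without_or(split_reversible(model))
        ids = irr.base.reaction_ids
        assert "R#1" in ids and "R#2" in ids
        S = irr.base.S.toarray()
        np.testing.assert_array_equal(
            S[:, ids.index("R#1")], S[:, ids.index("R#2")]
        )
        assert irr.base.gene_rules[ids.index("R#1")] == "g1"
        assert irr.base.gene_rules[ids.index("R#2")] == "g2"

    def test_complex_disjunct_kept_whole(self):
        model = _small_model(
            [("EX_A", {"A": -1}, -1000, 0, ""),
             ("R", {"A": -1, "B": 1}, 0, 1000, "(g1 and g2) or g3"),
             ("EX_B", {"B": -1}, 0, 1000, "")],
            ["A", "B"],
        )
        irr = expand_gpr_without_or(split_reversible(model))
        rules = {
            irr.base.gene_rules[irr.base.reaction_ids.index(rid)]
            for rid in ("R#1", "R#2")
        }
        assert rules == {"g1 and g2", "g3"}

    def test_reversible_isozyme_pairs_all_cross_directions(self):
        """Every forward copy opposes every backward copy of its source."""
        model = _small_model(
            [("EX_A", {"A": -1}, -1000, 0, ""),
             ("R", {"A": -1, "B": 1}, -1000, 1000, "g1 or g2"),
             ("EX_B", {"B": -1}, 0, 1000, "")],
            ["A", "B"],
        )
        irr = expand_gpr_without_or(split_reversible(model))
        (grp,) = irr.reversible_groups
        assert len(grp.forward) == 2 and len(grp.backward) == 2
        for fi, backs in irr.opposite_pairs:
            assert backs == frozenset(grp.backward)

    def test_expansion_idempotent(self, toy1):
        once = expand_gpr_without_or(split_reversible(toy1))
        twice = expand_gpr_without_or(once)
        assert twice.base.reaction_ids == once.base.reaction_ids
        assert twice.base.gene_rules == once.base.gene_rules


class TestGeneMap:
    def test_toy1_gene_map(self, toy1):
        irr = convert_model(toy1)
        ids = irr.base.reaction_ids
        assert set(irr.gene_map["g3"]) == {ids.index("R3_f"), ids.index("R3_b")}
        assert irr.gene_map["g1"] == [ids.index("R1")]

    def test_measured_but_unmapped_gene_dropped(self, toy1):
        irr = convert_model(toy1)
        profile = mri.ExpressionProfile(
            "WT", {"g1": 1, "g2": 1, "g3": 1, "alien": 9}
        )
        from mri.transform import mapped_measured_genes

        genes = mapped_measured_genes(irr, profile)
        assert genes == ["g1", "g2", "g3"]  # P = model-gene overlap

    def test_isozyme_copies_map_to_own_gene(self):
        model = _small_model(
            [("EX_A", {"A": -1}, -1000, 0, ""),
             ("R", {"A": -1, "B": 1}, 0, 1000, "g1 or g2"),
             ("EX_B", {"B": -1}, 0, 1000, "")],
            ["A", "B"],
        )
        irr = convert_model(model)
        ids = irr.base.reaction_ids
        assert irr.gene_map["g1"] == [ids.index("R#1")]
        assert irr.gene_map["g2"] == [ids.index("R#2")]


class TestFluxSpaceEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_lp_optimum_preserved_by_conversion(self, seed):
        """Any LP optimum is identical on the original and converted model."""
        model, _, _ = mri.random_toy_model(seed)
        rng = np.random.default_rng(seed + 1000)
        c = rng.normal(size=model.n_reactions)

        res_orig = linprog(
            -c,
            A_eq=model.S,
            b_eq=model.rhs,
            bounds=np.column_stack([model.lower_bound, model.upper_bound]),
            method="highs",
        )
        irr = convert_model(model)
        # converted objective: source coefficient, negated on backward copies
        c_conv = np.array(
            [
                c[model.reaction_ids.index(o.source_id)]
                * (1 if o.direction == "f" else -1)
                for o in irr.origin
            ]
        )
        res_conv = linprog(
            -c_conv,
            A_eq=irr.base.S,
            b_eq=irr.base.rhs,
            bounds=np.column_stack(
                [irr.base.lower_bound, irr.base.upper_bound]
            ),
            method="highs",
        )
        assert res_orig.status == 0 and res_conv.status == 0
        assert res_conv.fun == pytest.approx(res_orig.fun, abs=1e-6)

    def test_pair_count_matches_reversible_sources(self):
        for seed in range(10):
            model, _, _ = mri.random_toy_model(seed)
            n_rev = int(np.sum((model.lower_bound < 0) & (model.upper_bound > 0)))
            irr = convert_model(model)
            assert len(irr.reversible_groups) == n_rev
            # one pair per (forward copy, backward set)
            assert len(irr.opposite_pairs) == sum(
                len(g.forward) for g in irr.reversible_groups
            )
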