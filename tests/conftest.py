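import logging

import pytest

import mri

# the expression-capacity warning for C=0 runs is expected noise in tests
logging.getLogger("mri.milp").setLevel(logging.ERROR)


def check_witness(problem, result, tol=1e-6):
    """Assert every structural invariant of an accepted MILP solution."""
    assert 0 <= result.score <= result.P
    flux = result.witness_flux
    for gene in problem.genes:
        cap = problem.expression_cap(gene)
        used = sum(
            flux[problem.model.base.reaction_ids[i]]
            for i in problem.model.gene_map[gene]
        )
        alpha = result.alpha_values[gene]
        assert abs(used + alpha - cap) <= 10 * tol
        assert -tol <= alpha <= cap + 10 * tol
    for gene in result.fully_used_genes:
        assert result.alpha_values[gene] <= 10 * tol
    ids = problem.model.base.reaction_ids
    for grp in problem.model.reversible_groups:
        fwd = sum(flux[ids[i]] for i in grp.forward)
        bwd = sum(flux[ids[i]] for i in grp.backward)
        assert min(fwd, bwd) <= 10 * tol


@pytest.fixture(scope="session")
def toy1():
    return mri.toy1_model()


@pytest.fixture(scope="session")
def toy1_wt():
    wt, _ = mri.toy1_profiles()
    return wt


@pytest.fixture(scope="session")
def toy1_ev():
    _, ev = mri.toy1_profiles()
    return ev


@pytest.fixture(scope="session")
def medium():
    return mri.toy1_medium()


@pytest.fixture(scope="session")
def toy1_converted(toy1, medium):
    return mri.apply_medium(mri.convert_model(toy1), medium)


@pytest.fixture(scope="session")
def toy1_problem(toy1_converted, toy1_wt):
    return mri.build_mri_problem(toy1_converted, toy1_wt, C=1.0)


@pytest.fixture(scope="session")
def toy1_result(toy1_problem):
    return mri.solve_adaptation_score(toy1_problem)
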