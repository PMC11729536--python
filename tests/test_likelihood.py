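import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from stormsurv import cjs
from stormsurv import synthdata as syn
from stormsurv.encounters import MArray, build_marray, histories_to_matrix

from oracles import classic_cjs_nll, latent_fate_nll


def random_dataset(n_occ, seed, p_seen=0.8, p_unseen=0.45):
    config = syn.SimConfig(
        n_occasions=n_occ, releases_per_occasion=40,
        phi=0.85, p_seen=p_seen, p_unseen=p_unseen, seed=seed,
    )
    hists, _ = syn.simulate_histories(config)
    return histories_to_matrix(hists), build_marray(hists)


def test_binomial_kernel_two_occasions():
    ma = MArray(2, np.array([10, 0]), np.array([[0, 5], [0, 0]]))
    theta = np.array([logit(0.5), logit(1 - 1e-12), logit(1 - 1e-12)])
    nll = cjs.negloglik(ma, cjs.ModelStructure.parse("phi(.) p(./.)"), theta)
    assert 2 * nll == pytest.approx(-2 * (5 * np.log(0.5) + 5 * np.log(0.5)), abs=1e-6)


@pytest.mark.parametrize("n_occ", [3, 4, 5])
@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_marray_likelihood_equals_latent_fate_enumeration(n_occ, seed):
    """The split-history m-array multinomial must equal the individual-history
    likelihood summed exhaustively over latent death times."""
    X, ma = random_dataset(n_occ, seed)
    T = n_occ - 1
    rng = np.random.default_rng(seed + 100)
    phi = rng.uniform(0.5, 0.95, T)
    ps = rng.uniform(0.5, 0.95, T)
    pu = rng.uniform(0.2, 0.7, T)
    structure = cjs.ModelStructure.parse("phi(t) p(t/t)")
    theta = np.concatenate([logit(phi), logit(ps), logit(pu)])
    ours = cjs.negloglik(ma, structure, theta)
    oracle = latent_fate_nll(X, phi, ps, pu)
    assert ours == pytest.approx(oracle, rel=1e-10)


@pytest.mark.parametrize("seed", [10, 11])
def test_equal_detection_groups_reduce_to_classic_cjs(seed):
    X, ma = random_dataset(5, seed, p_seen=0.6, p_unseen=0.6)
    T = 4
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.5, 0.95, T)
    p = rng.uniform(0.3, 0.9, T)
    theta = np.concatenate([logit(phi), logit(p), logit(p)])
    ours = cjs.negloglik(ma, cjs.ModelStructure.parse("phi(t) p(t/t)"), theta)
    oracle = classic_cjs_nll(ma.releases, ma.next_recapture, phi, p)
    assert ours == pytest.approx(oracle, rel=1e-10)


def test_structural_zero_cell_with_count_is_infinite():
    ma = MArray(3, np.array([10, 5, 0]), np.array([[0, 4, 2], [0, 0, 3], [0, 0, 0]]))
    # a seen-group logit of +40 saturates p_seen to exactly 1, making the
    # skip-a-year cell m_13 = 2 structurally impossible
    theta = np.array([logit(0.8), 40.0, logit(0.5)])
    val = cjs.negloglik(ma, cjs.ModelStructure.parse("phi(.) p(./.)"), theta)
    assert np.isinf(val)


def test_analytic_gradient_matches_finite_differences(sim_dataset):
    ma = sim_dataset["marray"]
    for label in ("phi(t) p(./t)", "phi(t) p(t+m)", "phi(.) p(t/.)"):
        structure = cjs.ModelStructure.parse(label)
        design = cjs.build_design(structure, ma.n_occasions)
        rng = np.random.default_rng(7)
        theta = rng.normal(scale=0.4, size=design.k)
        g = cjs.negloglik_grad(ma, structure, theta, design=design)
        eps = 1e-6
        for j in range(design.k):
            e = np.zeros(design.k)
            e[j] = eps
            fd = (
                cjs.negloglik(ma, structure, theta + e, design=design)
                - cjs.negloglik(ma, structure, theta - e, design=design)
            ) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_formula_gradient_matches_finite_differences(sim_dataset):
    ma = sim_dataset["marray"]
    T = ma.n_occasions - 1
    cov = pd.DataFrame({"PC1": np.linspace(-1, 1, T), "sSST": np.cos(np.arange(T))})
    structure = cjs.ModelStructure.parse("phi(PC1 * sSST) p(./t)")
    design = cjs.build_design(structure, ma.n_occasions, cov)
    theta = np.linspace(-0.4, 0.4, design.k)
    g = cjs.negloglik_grad(ma, structure, theta, design=design)
    eps = 1e-6
    for j in range(design.k):
        e = np.zeros(design.k)
        e[j] = eps
        fd = (
            cjs.negloglik(ma, structure, theta + e, design=design)
            - cjs.negloglik(ma, structure, theta - e, design=design)
        ) / (2 * eps)
        assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_interaction_with_zero_coefficient_equals_additive(sim_dataset):
    ma = sim_dataset["marray"]
    T = ma.n_occasions - 1
    cov = pd.DataFrame({"a": np.sin(np.arange(T)), "b": np.linspace(-1, 1, T)})
    add = cjs.ModelStructure.parse("phi(a + b) p(./.)")
    inter = cjs.ModelStructure.parse("phi(a * b) p(./.)")
    theta_add = np.array([1.8, -0.3, 0.2, 1.0, 0.1])
    theta_int = np.insert(theta_add, 3, 0.0)  # interaction slope fixed at zero
    assert cjs.negloglik(ma, inter, theta_int, cov) == pytest.approx(
        cjs.negloglik(ma, add, theta_add, cov), rel=1e-12
    )


def test_nesting_monotonicity(sim_dataset):
    ma = sim_dataset["marray"]
    T = ma.n_occasions - 1
    cov = pd.DataFrame({"PC1": np.sin(np.arange(T))})
    f0 = cjs.fit(ma, "phi(.) p(./.)", compute_vcov=False)
    f1 = cjs.fit(ma, "phi(PC1) p(./.)", covariates=cov, compute_vcov=False)
    assert f1.minus2lnl <= f0.minus2lnl + 1e-6


def test_perfect_detection_closed_form():
    """With p fixed at 1 the likelihood reduces to independent binomials whose
    MLE is the per-interval ratio m_{i,i+1} / R_i."""
    config = syn.SimConfig(
        n_occasions=5, releases_per_occasion=200,
        phi=0.8, p_seen=1.0, p_unseen=1.0, seed=9,
    )
    hists, _ = syn.simulate_histories(config)
    ma = build_marray(hists)
    structure = cjs.ModelStructure.parse("phi(t) p(./.)")
    m = np.array([ma.next_recapture[i, i + 1] for i in range(4)], float)
    R = ma.releases[:4].astype(float)
    ratio = m / R

    def nll_at(phi_vec):
        theta = np.concatenate([logit(phi_vec), [40.0, 0.0]])  # p_seen = 1
        return cjs.negloglik(ma, structure, theta)

    binom = -np.sum(m * np.log(ratio) + (R - m) * np.log(1 - ratio))
    assert nll_at(ratio) == pytest.approx(binom, rel=1e-10)
    for j in range(4):  # ratio is the minimiser in every coordinate
        for eps in (-0.02, 0.02):
            bumped = ratio.copy()
            bumped[j] += eps
            assert nll_at(bumped) > nll_at(ratio)
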