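"""Histogram building, the L1 objective, LP estimation, bootstrap, KS."""
import numpy as np
import pytest

from ardsrec import (AnalysisConfig, Cohort, CohortConfig, Severity,
                     SEVERITY_ORDER, build_hist2d, estimate_fraction,
                     generate_cohort, ks_compare, mixture_objective)
from ardsrec.errors import (BinningMismatchError, InvalidInputError,
                            SmallStratumError, UnidentifiableError)
from ardsrec.mixture import bootstrap_fractions
from ardsrec.pipeline import split_subgroups
from ardsrec.types import Density2D, Subgroup


def _hist(values, edges_pbw=(0, 1, 2), edges_vt=(0, 1)):
    values = np.asarray(values, dtype=float).reshape(
        len(edges_pbw) - 1, len(edges_vt) - 1)
    return Density2D(axis_pbw=np.asarray(edges_pbw, float),
                     axis_vt=np.asarray(edges_vt, float),
                     values=values, kind="histogram")


def _random_hist(rng, shape=(4, 6)):
    v = rng.random(shape)
    return Density2D(axis_pbw=np.arange(shape[0] + 1, dtype=float),
                     axis_vt=np.arange(shape[1] + 1, dtype=float),
                     values=v / v.sum(), kind="histogram")


# --------------------------------------------------------------------------
# histograms

def test_hist_single_cell_mass():
    h = build_hist2d([(60.0, 6.1)] * 4)
    assert h.values.max() == pytest.approx(1.0)
    assert h.values.sum() == pytest.approx(1.0, abs=1e-12)


def test_hist_normalization_and_uniform_expectation():
    rng = np.random.default_rng(0)
    cfg = AnalysisConfig()
    e1, e2 = cfg.hist_pbw_edges(), cfg.hist_vt_edges()
    pts = np.column_stack([rng.uniform(e1[0], e1[-1], 10_000),
                           rng.uniform(e2[0], e2[-1], 10_000)])
    h = build_hist2d(pts, cfg)
    assert h.values.sum() == pytest.approx(1.0, abs=1e-12)
    n_cells = h.values.size
    p = 1.0 / n_cells
    sd = np.sqrt(p * (1 - p) / 10_000)
    assert np.all(np.abs(h.values - p) < 3.5 * sd)


def test_hist_clips_out_of_range_points():
    with pytest.warns(RuntimeWarning):
        h = build_hist2d([(120.0, 20.0), (60.0, 6.0)])
    assert h.values.sum() == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------------------------------
# objective

def test_objective_exact_match_is_zero():
    h = _hist([0.6, 0.4])
    assert mixture_objective(1.0, h, h, _hist([0.5, 0.5])) == pytest.approx(0.0)


def test_objective_two_bin_hand_case():
    h_ards = _hist([0.6, 0.4])
    h_doc = _hist([1.0, 0.0])
    h_ctrl = _hist([0.0, 1.0])
    assert mixture_objective(0.6, h_ards, h_doc, h_ctrl) == pytest.approx(0.0)
    assert mixture_objective(0.0, h_ards, h_doc, h_ctrl) == pytest.approx(1.2)


def test_objective_domain_and_binning_errors():
    h = _hist([0.6, 0.4])
    with pytest.raises(InvalidInputError):
        mixture_objective(1.5, h, h, h)
    other = _hist([0.5, 0.3, 0.2], edges_pbw=(0, 1, 2, 3))
    with pytest.raises(BinningMismatchError):
        mixture_objective(0.5, h, h, other)


def test_objective_is_convex_in_f():
    rng = np.random.default_rng(1)
    h_a, h_d, h_c = (_random_hist(rng) for _ in range(3))
    fs = np.linspace(0, 1, 1001)
    deltas = np.array([mixture_objective(f, h_a, h_d, h_c) for f in fs])
    second_diff = deltas[2:] - 2 * deltas[1:-1] + deltas[:-2]
    assert np.all(second_diff >= -1e-10)


# --------------------------------------------------------------------------
# estimation

def test_exact_convex_combination_identified():
    rng = np.random.default_rng(2)
    h_doc, h_ctrl = _random_hist(rng), _random_hist(rng)
    mix = 0.3 * h_doc.values + 0.7 * h_ctrl.values
    h_ards = Density2D(axis_pbw=h_doc.axis_pbw, axis_vt=h_doc.axis_vt,
                       values=mix, kind="histogram")
    fit = estimate_fraction(h_ards, h_doc, h_ctrl)
    assert fit.f_hat == pytest.approx(0.3, abs=1e-9)
    assert fit.delta == pytest.approx(0.0, abs=1e-12)


def test_endpoint_cases():
    rng = np.random.default_rng(3)
    h_doc, h_ctrl = _random_hist(rng), _random_hist(rng)
    assert estimate_fraction(h_ctrl, h_doc, h_ctrl).f_hat == pytest.approx(0.0)
    assert estimate_fraction(h_doc, h_doc, h_ctrl).f_hat == pytest.approx(1.0)


def test_identical_references_unidentifiable():
    rng = np.random.default_rng(4)
    h = _random_hist(rng)
    with pytest.raises(UnidentifiableError):
        estimate_fraction(h, h, h)


@pytest.mark.parametrize("method", ["exact", "linprog"])
def test_estimate_matches_grid_oracle(method):
    """LP/breakpoint optimum matches a 0.001-step brute-force scan."""
    rng = np.random.default_rng(5)
    fs = np.linspace(0, 1, 1001)
    for _ in range(30):
        h_a, h_d, h_c = (_random_hist(rng) for _ in range(3))
        fit = estimate_fraction(h_a, h_d, h_c, method=method)
        deltas = np.array([mixture_objective(f, h_a, h_d, h_c) for f in fs])
        assert fit.delta <= deltas.min() + 1e-3
        assert mixture_objective(fit.f_hat, h_a, h_d, h_c) == \
            pytest.approx(fit.delta, abs=1e-9)


def test_exact_and_linprog_agree():
    rng = np.random.default_rng(6)
    for _ in range(20):
        h_a, h_d, h_c = (_random_hist(rng) for _ in range(3))
        a = estimate_fraction(h_a, h_d, h_c, method="exact")
        b = estimate_fraction(h_a, h_d, h_c, method="linprog")
        assert a.delta == pytest.approx(b.delta, abs=1e-9)
        assert a.f_hat == pytest.approx(b.f_hat, abs=1e-6)


def test_flat_segment_reported_as_midpoint():
    """A hand-built case whose objective is flat on f in [0.2, 0.5]:
    the estimator must report the midpoint 0.35 and flag non-uniqueness."""
    edges = (0, 1, 2, 3, 4)
    h_ctrl = _hist([0.25, 0.25, 0.25, 0.25], edges_pbw=edges)
    h_doc = _hist([0.45, 0.05, 0.35, 0.15], edges_pbw=edges)    # d = ctrl + (0.2,-0.2,0.1,-0.1)
    h_ards = _hist([0.35, 0.21, 0.26, 0.18], edges_pbw=edges)   # c = (0.1,-0.04,0.01,-0.07)
    fit = estimate_fraction(h_ards, h_doc, h_ctrl)
    assert fit.non_unique
    assert fit.f_hat == pytest.approx(0.35, abs=1e-9)
    assert fit.delta == pytest.approx(0.12, abs=1e-12)
    assert mixture_objective(0.2, h_ards, h_doc, h_ctrl) == pytest.approx(0.12)
    assert mixture_objective(0.5, h_ards, h_doc, h_ctrl) == pytest.approx(0.12)


def test_bin_permutation_invariance():
    rng = np.random.default_rng(7)
    h_a, h_d, h_c = (_random_hist(rng) for _ in range(3))
    base = estimate_fraction(h_a, h_d, h_c)
    perm = rng.permutation(h_a.values.size)

    def permuted(h):
        v = h.values.ravel()[perm].reshape(h.values.shape)
        return Density2D(axis_pbw=h.axis_pbw, axis_vt=h.axis_vt,
                         values=v, kind="histogram")

    out = estimate_fraction(permuted(h_a), permuted(h_d), permuted(h_c))
    assert out.f_hat == pytest.approx(base.f_hat, abs=1e-12)
    assert out.delta == pytest.approx(base.delta, abs=1e-12)


def test_monotone_contamination_raises_fraction():
    """Swapping control-like synthetic patients for documented-like ones
    increases the estimated recognised fraction."""
    cfg = AnalysisConfig()
    recs = generate_cohort(CohortConfig(n_ards=10, n_control=2000, seed=21))
    groups = split_subgroups(recs)
    ctrl = [(r.pbw_kg, r.vt_std) for r in groups[Subgroup.CONTROL_NONDOC]]
    # documented-like behaviour: 6 mL/kg for everyone
    doc_like = [(p, 6.0) for p, _ in ctrl]
    h_doc = build_hist2d(doc_like[:1000], cfg)
    h_ctrl = build_hist2d(ctrl[:1000], cfg)
    prev = -1.0
    pool_ctrl = ctrl[1000:]
    pool_doc = doc_like[1000:]
    n = len(pool_ctrl)
    for q in np.arange(0.1, 0.95, 0.1):
        k = int(q * n)
        sample = pool_doc[:k] + pool_ctrl[k:]
        f = estimate_fraction(build_hist2d(sample, cfg), h_doc, h_ctrl).f_hat
        assert f >= prev - 0.02
        prev = f
    assert prev > 0.8


def test_bootstrap_single_iteration_collapses_ci(subgroups):
    doc = subgroups[Subgroup.POOLED_DOC]
    ctrl = subgroups[Subgroup.CONTROL_NONDOC]
    ards = subgroups[Subgroup.ARDS_NONDOC]
    fit = bootstrap_fractions(ards, doc, ctrl, n_boot=1, seed=3)
    assert fit.ci99[0] == pytest.approx(fit.ci99[1])
    assert fit.mean == pytest.approx(fit.bootstrap_fractions[0])


def test_bootstrap_small_stratum_refused(subgroups):
    with pytest.raises(SmallStratumError):
        bootstrap_fractions(subgroups[Subgroup.ARDS_NONDOC][:4],
                            subgroups[Subgroup.POOLED_DOC],
                            subgroups[Subgroup.CONTROL_NONDOC], n_boot=10)


def test_bootstrap_deterministic(subgroups):
    args = (subgroups[Subgroup.ARDS_NONDOC][:100],
            subgroups[Subgroup.POOLED_DOC],
            subgroups[Subgroup.CONTROL_NONDOC])
    a = bootstrap_fractions(*args, n_boot=50, seed=11)
    b = bootstrap_fractions(*args, n_boot=50, seed=11)
    assert np.array_equal(a.bootstrap_fractions, b.bootstrap_fractions)


def test_bootstrap_ci_narrows_with_stratum_size():
    cfg_small = CohortConfig(n_ards=120, n_control=400, seed=5)
    cfg_big = CohortConfig(n_ards=480, n_control=400, seed=5)
    widths = []
    for cfg in (cfg_small, cfg_big):
        groups = split_subgroups(generate_cohort(cfg))
        ards = groups[Subgroup.ARDS_NONDOC]
        fit = bootstrap_fractions(ards, groups[Subgroup.POOLED_DOC],
                                  groups[Subgroup.CONTROL_NONDOC],
                                  n_boot=300, seed=17)
        widths.append(fit.ci99[1] - fit.ci99[0])
    assert widths[1] < widths[0]


# --------------------------------------------------------------------------
# KS comparison

def test_ks_identical_and_disjoint():
    a = list(np.linspace(0, 1, 50))
    d, p, sig = ks_compare(a, a)
    assert d == pytest.approx(0.0) and p == pytest.approx(1.0) and not sig
    d, p, sig = ks_compare(a, [x + 2.0 for x in a])
    assert d == pytest.approx(1.0) and sig


def test_ks_rejects_tiny_input():
    with pytest.raises(InvalidInputError):
        ks_compare([0.5], [0.1, 0.2])


def test_ks_power_at_the_observed_gap_scale():
    """Two 1000-draw bootstrap-like samples whose means differ by 0.12
    are separated at the corrected threshold in >= 95% of replicates."""
    rng = np.random.default_rng(19)
    hits = 0
    n_rep = 40
    for _ in range(n_rep):
        a = rng.normal(0.22, 0.05, 1000)
        b = rng.normal(0.34, 0.05, 1000)
        _, _, sig = ks_compare(a, b)
        hits += sig
    assert hits >= int(0.95 * n_rep)
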