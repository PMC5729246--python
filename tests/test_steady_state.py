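"""Steady-state model behaviour: Hill blocks, cascade composition, burden
fixed point, ODE oracle agreement and logic classification."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txcascade.circuits import monitor_culture
from txcascade.params import BurdenParams, HillParams, default_parameters
from txcascade.steady_state import (
    Condition,
    bm_steady_state,
    cascade_outputs,
    classify_logic_behaviour,
    hill_rate,
    nbm_steady_state,
    ode_reference_steady_state,
)

X1 = HillParams(delta=0.14, alpha=14.63, K=4.16, eta=1.42, orientation="inducible")


@pytest.mark.parametrize(
    "hill, level, expected",
    [
        (X1, X1.K, 0.14 + 14.63 / 2),  # half of the range at I = K
        (X1, 0.0, 0.14),  # inducible off-state limit is the basal rate
        (
            HillParams(delta=0.2, alpha=3.0, K=5.0, eta=2.0, orientation="repressible"),
            0.0,
            3.2,  # repressible unrepressed limit is delta + alpha
        ),
    ],
)
def test_hill_rate_examples(hill, level, expected):
    assert hill_rate(hill, level) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [-1.0, np.nan, np.inf])
def test_hill_rate_rejects_invalid_input(bad):
    with pytest.raises(ValueError):
        hill_rate(X1, bad)


@given(
    level=st.floats(0.0, 1e6),
    eta=st.floats(0.31, 9.9),
    k=st.floats(1e-2, 1e4),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_hill_rate_bounded_and_monotone_by_orientation(level, eta, k):
    """Rates stay within [delta, delta+alpha]; orientation sets the slope sign."""
    for orientation, sign in (("inducible", 1), ("repressible", -1)):
        h = HillParams(delta=0.1, alpha=2.0, K=k, eta=eta, orientation=orientation)
        lo, hi = hill_rate(h, level), hill_rate(h, level + 1.0)
        assert 0.1 - 1e-12 <= lo <= 2.1 + 1e-12
        assert sign * (hi - lo) >= -1e-12


def test_single_block_output_approaches_rate_at_low_growth(reg, nbm_params):
    """With mu -> 0 the maturation factor a/(mu+a) -> 1, so output -> S."""
    topo = reg["X_1_r"]
    cond = Condition(hsl=100.0, mu=1e-9)
    s = hill_rate(nbm_params.hill["X_1"], 100.0)
    res = nbm_steady_state(topo, cond, nbm_params)
    assert res.s_cell_norm_rfp == pytest.approx(s, rel=1e-6)


def test_saturating_single_block_matches_closed_form_and_ode(reg, nbm_params):
    topo = reg["X_1_r"]
    cond = Condition(hsl=1e7, mu=0.01)
    res = nbm_steady_state(topo, cond, nbm_params)
    closed = 0.0167 * (0.14 + 14.63) / (0.01 + 0.0167)
    assert res.s_cell_norm_rfp == pytest.approx(closed, rel=1e-4)
    ode = ode_reference_steady_state(topo, cond, nbm_params, model="NBM")
    assert ode.s_cell_norm_rfp == pytest.approx(res.s_cell_norm_rfp, rel=1e-3)


def test_nbm_cascade_monotone_with_repressor_parity(reg, nbm_params, growth_table):
    """Composed cascades rise or fall with HSL according to the parity of
    sign-inverting (repressible) elements, on a dense grid."""
    hsl = np.concatenate([[0.0], np.geomspace(1e-3, 1e5, 60)])
    for cid, topo in reg.items():
        if topo.input_device == "none":
            continue
        out = cascade_outputs(topo, hsl, np.full_like(hsl, 0.014), nbm_params, "NBM")
        diffs = np.diff(out["RFP"]) * topo.expected_direction
        assert np.all(diffs >= -1e-12), f"{cid} violates monotonicity parity"


def test_bm_with_zero_burden_equals_nbm(reg, nbm_params):
    params = copy.deepcopy(nbm_params)
    params.burden = BurdenParams(s_m=1.75)  # every load term zero
    hsl = np.concatenate([[0.0], np.geomspace(0.1, 1e4, 8)])
    mu = np.full_like(hsl, 0.012)
    for cid in ("X_1_r", "X_rep_TLr", "X_1_TLrg", "X_2_Twr"):
        topo = reg[cid]
        a = cascade_outputs(topo, hsl, mu, params, "NBM")
        b = cascade_outputs(topo, hsl, mu, params, "BM")
        assert np.max(np.abs(a["RFP"] - b["RFP"]) / np.abs(a["RFP"])) <= 1e-10


def test_luxr_load_alone_halves_monitor_output(bm_params):
    """With the heaviest lumped LuxR term (Sigma = 1) and no other load the
    shared-capacity denominator is 2: a 50% output reduction."""
    topo = monitor_culture()
    from dataclasses import replace

    topo = replace(topo, sigma_class="lac")
    cond = Condition(hsl=0.0, mu=1e-9)
    loaded = bm_steady_state(topo, cond, bm_params)
    free = bm_steady_state(topo, cond, bm_params.updated({"Sigma.lac": 0.0}))
    assert loaded.d_hat == pytest.approx(2.0, abs=1e-9)
    assert loaded.s_cell_norm_gfp / free.s_cell_norm_gfp == pytest.approx(0.5, rel=1e-9)


def test_bm_fixed_point_self_consistency(reg, bm_params):
    """Recomputing D_hat from the returned maximum rates reproduces it."""
    topo = reg["X_1_TLrg"]
    res = bm_steady_state(topo, Condition(hsl=50.0, mu=0.012), bm_params, tol=1e-11)
    b = bm_params.burden
    loads = [b.J_tet, b.J_lac, b.J_RFP]
    d_recomputed = 1.0 + b.sigma["lambda"] + sum(J * s for J, s in zip(loads, res.s_max))
    assert d_recomputed == pytest.approx(res.d_hat, rel=1e-9)
    assert res.d_hat >= 1.0
    for s, s_max in zip(res.s, res.s_max):
        assert s == pytest.approx(s_max / res.d_hat, rel=1e-12)


def test_output_non_increasing_in_resource_usage(reg, bm_params):
    """Raising any J or Sigma never increases circuit output; D_hat >= 1."""
    topo = reg["X_2_Trg"]
    cond = Condition(hsl=30.0, mu=0.012)
    last = {"J_tet": None, "J_RFP": None, "Sigma.lac": None}
    for key in last:
        outs = []
        for scale in (0.0, 0.5, 1.0, 2.0, 5.0):
            base = bm_params.to_flat()[key]
            res = bm_steady_state(topo, cond, bm_params.updated({key: base * scale}))
            assert res.d_hat >= 1.0
            outs.append(res.s_cell_norm_rfp)
        assert np.all(np.diff(outs) <= 1e-12), f"output increased with {key}"


def test_repressor_level_inverse_in_removal_rate(reg, nbm_params):
    """P = S / (mu + gamma): doubling the removal rate exactly halves the level."""
    topo = reg["X_2_Tr"]
    gamma = nbm_params.constants.gamma_tet
    mu1 = 0.01
    mu2 = 2 * (mu1 + gamma) - gamma  # so that mu2 + gamma = 2 (mu1 + gamma)
    p1 = nbm_steady_state(topo, Condition(20.0, mu1), nbm_params).protein[0]
    p2 = nbm_steady_state(topo, Condition(20.0, mu2), nbm_params).protein[0]
    assert p2 == pytest.approx(p1 / 2, rel=1e-12)


def test_algebraic_steady_state_matches_ode_oracle_randomized(reg, bm_params):
    """Fixed-point / explicit algebra vs time integration on >= 100 randomized
    topologies, parameters and conditions, within 0.1%."""
    rng = np.random.default_rng(7)
    ids = [cid for cid, t in reg.items() if t.input_device != "none"]
    checked = 0
    while checked < 100:
        cid = ids[rng.integers(len(ids))]
        topo = reg[cid]
        scale = {
            k: v * float(np.exp(rng.normal(0.0, 0.25)))
            for k, v in bm_params.to_flat().items()
            if not k.endswith(".eta")
        }
        params = bm_params.updated(scale)
        cond = Condition(
            hsl=float(rng.choice([0.0, 10 ** rng.uniform(-1, 4)])),
            mu=float(rng.uniform(0.008, 0.025)),
        )
        model = "BM" if rng.random() < 0.6 else "NBM"
        if model == "BM":
            alg = bm_steady_state(topo, cond, params)
        else:
            alg = nbm_steady_state(topo, cond, params)
        ode = ode_reference_steady_state(topo, cond, params, model=model, t_end=30000.0)
        assert ode.s_cell_norm_rfp == pytest.approx(alg.s_cell_norm_rfp, rel=1e-3)
        if alg.s_cell_norm_gfp is not None:
            assert ode.s_cell_norm_gfp == pytest.approx(alg.s_cell_norm_gfp, rel=1e-3)
        checked += 1


def test_ode_oracle_zero_synthesis_gives_zero_levels(reg, nbm_params):
    params = nbm_params.updated(
        {"X_1.delta": 1e-300, "X_1.alpha": 1e-300}
    )
    res = ode_reference_steady_state(reg["X_1_r"], Condition(0.0, 0.01), params, model="NBM")
    assert res.s_cell_norm_rfp == pytest.approx(0.0, abs=1e-12)


class TestLogicClassification:
    def test_direction_labels(self):
        up = classify_logic_behaviour([1.0, 1.1, 0.9], [10.0, 9.5, 10.2])
        assert up.label == "OFF-to-ON"
        down = classify_logic_behaviour([10.0], [1.0])
        assert down.label == "ON-to-OFF"

    def test_equal_medians_flat_with_warning(self):
        with pytest.warns(UserWarning):
            flat = classify_logic_behaviour([2.0, 2.0], [2.0, 2.0])
        assert flat.label == "flat"

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            classify_logic_behaviour([], [1.0])

    def test_mismatch_flag_against_parity_expectation(self, reg):
        topo = reg["X_1_TLr"]  # two inversions: expected OFF-to-ON
        cls = classify_logic_behaviour([5.0], [1.0], expected_direction=topo.expected_direction)
        assert cls.expected == "OFF-to-ON"
        assert cls.mismatch is True


def test_burden_inverts_three_block_cascade_logic(reg, nbm_params, bm_params):
    """At the packaged parameters the X_1 -> tet -> lac cascade rises with HSL
    under the no-burden model but falls under the burden model (tetR load
    inflates the shared denominator at high induction)."""
    topo = reg["X_1_TLr"]
    mu = 0.012
    nbm_lo = nbm_steady_state(topo, Condition(0.0, mu), nbm_params).s_cell_norm_rfp
    nbm_hi = nbm_steady_state(topo, Condition(1e4, mu), nbm_params).s_cell_norm_rfp
    bm_lo = bm_steady_state(topo, Condition(0.0, mu), bm_params).s_cell_norm_rfp
    bm_hi = bm_steady_state(topo, Condition(1e4, mu), bm_params).s_cell_norm_rfp
    assert nbm_hi > nbm_lo
    assert bm_hi < bm_lo
    cls = classify_logic_behaviour([bm_lo], [bm_hi], expected_direction=topo.expected_direction)
    assert cls.label == "ON-to-OFF" and cls.mismatch is True
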