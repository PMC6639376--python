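import numpy as np
import pandas as pd
import pytest

import oracles
from corm.info_theory import (
    JointHistogram,
    ResponseTable,
    blahut_arimoto,
    build_joint_histogram,
    capacity_ensemble_sweep,
    channel_capacity,
    dose_response,
    marginal_entropy,
    mutual_information,
    quadrant_capacities,
    response_entropy,
)
from corm.synthetic_data import sample_inputs


def _bsc_table(n, seed, p=0.1):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    y = np.abs(x - (rng.random(n) < p).astype(float))
    return ResponseTable(pd.DataFrame({"AA0": x, "AG0": x, "Y": y}), f"bsc{seed}")


def _identity_table(n=500):
    x = np.linspace(0.01, 16.0, n)
    return ResponseTable(pd.DataFrame({"AA0": x, "AG0": x, "Y": x}), "identity")


# ---------------------------------------------------------------------------
# Mutual information


def test_mi_identity_channel():
    counts = np.eye(4) * 25
    assert mutual_information(counts) == pytest.approx(2.0)


def test_mi_independent_channel():
    counts = np.outer([10, 30], [20, 20])
    assert mutual_information(counts) == pytest.approx(0.0, abs=1e-12)


def test_mi_against_brute_force_oracle():
    counts = [[3, 1], [1, 3]]
    assert mutual_information(np.array(counts, dtype=float)) == pytest.approx(
        oracles.mutual_information_brute_force(counts)
    )


def test_mi_bounded_by_marginal_entropies():
    rng = np.random.default_rng(0)
    for _ in range(25):
        counts = rng.integers(0, 20, size=(4, 6)).astype(float)
        if counts.sum() == 0:
            continue
        mi = mutual_information(counts)
        hx = marginal_entropy(counts.sum(axis=1))
        hy = marginal_entropy(counts.sum(axis=0))
        assert -1e-12 <= mi <= min(hx, hy) + 1e-9


def test_joint_histogram_marginals_consistent():
    rng = np.random.default_rng(1)
    x, y = rng.random(300), rng.random(300)
    hist = build_joint_histogram(x, y, 5, 8)
    assert hist.n == 300
    assert hist.counts.sum(axis=1).sum() == 300


# ---------------------------------------------------------------------------
# Response entropy


def test_response_entropy_constant_is_zero():
    assert response_entropy(np.full(100, 3.7)) == 0.0


def test_response_entropy_distinct_uniform():
    values = np.arange(500, dtype=float)
    assert response_entropy(values, 500) == pytest.approx(np.log2(500))


def test_response_entropy_coarsening_non_increasing():
    rng = np.random.default_rng(2)
    values = rng.random(400)
    fine = np.linspace(0, 1, 17)
    coarse = fine[::2]  # merged adjacent bins
    assert response_entropy(values, coarse) <= response_entropy(values, fine) + 1e-12


# ---------------------------------------------------------------------------
# Blahut-Arimoto


def test_ba_identity_conditional():
    cap, _ = blahut_arimoto(np.eye(8))
    assert cap == pytest.approx(3.0, abs=1e-6)


def test_ba_bsc_closed_form():
    cap, _ = blahut_arimoto(np.array([[0.9, 0.1], [0.1, 0.9]]))
    assert cap == pytest.approx(oracles.bsc_capacity_closed_form(0.1), abs=1e-6)


def test_ba_monotone_objective():
    rng = np.random.default_rng(3)
    q = rng.random((6, 5))
    q /= q.sum(axis=1, keepdims=True)
    cap, _, trace = blahut_arimoto(q, return_trace=True)
    assert np.all(np.diff(trace) >= -1e-12)
    assert cap >= 0


# ---------------------------------------------------------------------------
# Dose response


@pytest.fixture(scope="module")
def nominal_table(network, nominal):
    inputs = sample_inputs("independent", n=60, seed=9)
    return dose_response(network, nominal, inputs.pairs)


def test_dose_response_ag_zero_rows(network, nominal):
    pairs = np.array([[4.0, 0.0], [8.0, 0.0], [16.0, 0.0]])
    table = dose_response(network, nominal, pairs)
    assert np.allclose(table.frame["PGG"], 0.0, atol=1e-12)


def test_dose_response_determinism(network, nominal):
    pairs = np.array([[4.0, 2.0], [4.0, 2.0]])
    table = dose_response(network, nominal, pairs)
    row0, row1 = table.frame.iloc[0], table.frame.iloc[1]
    assert (row0 == row1).all()


def test_dose_response_monotone_pg_in_aa(network, nominal):
    pairs = np.column_stack([np.linspace(0.5, 16, 12), np.full(12, 4.0)])
    table = dose_response(network, nominal, pairs)
    assert (np.diff(table.frame["PG"].to_numpy()) > -1e-9).all()


def test_dose_response_warns_outside_range(network, nominal, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="corm.info_theory"):
        dose_response(network, nominal, np.array([[20.0, 1.0]]))
    assert any("outside" in rec.message for rec in caplog.records)


def test_dose_response_has_ten_response_columns(nominal_table):
    assert len(nominal_table.response_columns) == 10
    assert set(nominal_table.response_columns) >= {"PG", "PGG"}


# ---------------------------------------------------------------------------
# Channel capacity


def test_capacity_identity_channel_approaches_log2_n():
    est = channel_capacity(
        _identity_table(500), "AA", "Y", n_x=500, n_y_values=(500,), bias_correction=False
    )
    assert est.value == pytest.approx(np.log2(500), abs=1e-6)


def test_capacity_constant_response_flagged():
    frame = pd.DataFrame({"AA0": np.linspace(0, 16, 100), "AG0": np.zeros(100), "Y": np.ones(100)})
    est = channel_capacity(ResponseTable(frame, "const"), "AA", "Y")
    assert est.value == 0.0
    assert "degenerate_response" in est.flags


def test_capacity_bsc_matches_closed_form():
    est = channel_capacity(
        _bsc_table(20000, 123), "AA", "Y", n_x=2, n_y_values=(2,), n_replicates=5, seed=1
    )
    assert est.value == pytest.approx(oracles.bsc_capacity_closed_form(0.1), abs=0.02)


def test_capacity_at_least_plugin_mi(nominal_table):
    for response in ("PG", "PGG"):
        est = channel_capacity(nominal_table, "AA", response, n_replicates=2)
        assert est.raw_value >= est.plugin_mi - 1e-9
        assert 0.0 <= est.value <= np.log2(nominal_table.n)


def test_capacity_estimator_consistency_on_bsc():
    """Raw estimator bias shrinks roughly linearly with sample size."""
    true = oracles.bsc_capacity_closed_form(0.1)

    def mean_gap(n):
        gaps = [
            abs(
                channel_capacity(
                    _bsc_table(n, 100 + s), "AA", "Y", n_x=2, n_y_values=(2,),
                    bias_correction=False,
                ).raw_value
                - true
            )
            for s in range(8)
        ]
        return float(np.mean(gaps))

    assert mean_gap(1200) < 0.65 * mean_gap(300)


def test_capacity_requires_enough_rows():
    with pytest.raises(ValueError):
        channel_capacity(_identity_table(20), "AA", "Y")


def test_capacity_unknown_input_spec(nominal_table):
    with pytest.raises(ValueError):
        channel_capacity(nominal_table, "substrate", "PG")


def test_capacity_unknown_response(nominal_table):
    with pytest.raises(KeyError):
        channel_capacity(nominal_table, "AA", "nope")


# ---------------------------------------------------------------------------
# Quadrants


def test_quadrant_row_counts():
    sample = sample_inputs("independent", n=2000, seed=11)
    aa, ag = sample.pairs[:, 0], sample.pairs[:, 1]
    for aa_low in (True, False):
        for ag_low in (True, False):
            mask = ((aa < 8) == aa_low) & ((ag < 8) == ag_low)
            assert 400 <= mask.sum() <= 600


def test_quadrant_identity_channel():
    # AA0 = AG0 = Y, so only the low/low and high/high quadrants are populated;
    # each behaves as a noiseless identity channel over its m rows.
    table = _identity_table(2000)
    quads = quadrant_capacities(
        table, "Y", input_spec="AA", n_x=2000, n_y_values=(2000,), bias_correction=False
    )
    populated = {k: v for k, v in quads.items() if not v.flags}
    assert set(populated) == {("low", "low"), ("high", "high")}
    for est in populated.values():
        assert est.value == pytest.approx(np.log2(est.n), abs=1e-6)


def test_quadrant_few_rows_flagged():
    rng = np.random.default_rng(8)
    frame = pd.DataFrame(
        {"AA0": rng.uniform(0, 16, 120), "AG0": rng.uniform(0, 16, 120)}
    )
    frame["Y"] = frame["AA0"]
    quads = quadrant_capacities(ResponseTable(frame, "few"), "Y")
    assert all("unreliable_few_rows" in est.flags for est in quads.values())


# ---------------------------------------------------------------------------
# Ensemble sweep


def test_sweep_single_set_yields_ten_rows(network, nominal):
    table = capacity_ensemble_sweep(
        network, [nominal], "correlated_1", n_samples=60, seed=4, n_replicates=2
    )
    assert len(table) == 10
    assert set(table["response"]) == set(network.complex_ids) | {"PG", "PGG"}
    assert (table["mode"] == "correlated_1").all()


def test_sweep_determinism(network, nominal):
    kwargs = dict(n_samples=60, seed=4, n_replicates=2, responses=["PG"])
    a = capacity_ensemble_sweep(network, [nominal], "independent", **kwargs)
    b = capacity_ensemble_sweep(network, [nominal], "independent", **kwargs)
    pd.testing.assert_frame_equal(a, b)


def test_sweep_empty_ensemble_rejected(network):
    with pytest.raises(ValueError):
        capacity_ensemble_sweep(network, [], "independent")
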