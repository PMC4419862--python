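"""M scores, omega scores, scanning, cluster calling, permutation null."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm, spearmanr

from middascan import (
    DegenerateStatisticsError,
    InputError,
    SimulationConfig,
    call_clusters,
    enumerate_cccs,
    enumerate_virtual_clusters,
    m_scores,
    omega_scores,
    permutation_null,
    scan,
    simulate,
)
from middascan.middas_core import MScoreTrack
from tests.conftest import make_order


def brute_force_m(z, order, ncl):
    """Independent oracle: explicit per-window sums."""
    ids = order.gene_ids()
    pos = {g: k for k, g in enumerate(ids)}
    return np.array(
        [sum(z[pos[g]] for g in vc.gene_ids) for vc in enumerate_virtual_clusters(order, ncl)]
    )


def brute_force_omega(M, d):
    mu, sd = M.mean(), M.std()
    out = np.empty(len(M))
    for i, m in enumerate(M):
        zm = (m - mu) / sd
        p = max(2 * norm.sf(abs(zm)), 1e-300)
        out[i] = -(zm**d) * math.log(p)
    return out


def test_m_scores_trivial_cases(order10):
    z = np.arange(10, dtype=float)
    track = m_scores(z, order10, 3)
    assert track.M[0] == pytest.approx(0 + 1 + 2)
    track1 = m_scores(z, order10, 1)
    np.testing.assert_allclose(track1.M, z)


def test_m_scores_match_brute_force_multi_contig():
    rng = np.random.default_rng(7)
    from middascan import GeneOrder, GeneRecord

    recs = [
        GeneRecord(f"c{c}g{i:03d}", f"c{c}", i * 100 + 1, i * 100 + 50)
        for c, n in enumerate((23, 15, 12))
        for i in range(n)
    ]
    order = GeneOrder(recs)
    z = rng.normal(size=50)
    for ncl in (1, 4, 7):
        track = m_scores(z, order, ncl)
        np.testing.assert_allclose(track.M, brute_force_m(z, order, ncl), atol=1e-9)
        assert track.mean == pytest.approx(track.M.mean())
        assert track.sd == pytest.approx(track.M.std())


def test_m_scores_need_two_windows():
    order = make_order(3)
    with pytest.raises(DegenerateStatisticsError):
        m_scores(np.array([1.0, 2.0, 3.0]), order, 3)  # single window


def test_omega_hand_values():
    """Z_M = 2, d = 3: P = 2*Phi(-2) = 0.04550, omega = -8*ln(P) ~ 24.72."""
    M = np.array([2.0, -2.0, 0.0])
    track = MScoreTrack(
        ncl=3,
        contig=np.array(["c1"] * 3, dtype=object),
        start_index=np.arange(1, 4),
        M=M,
        mean=0.0,
        sd=1.0,
    )
    omega = omega_scores(track, d=3)
    expected = -(2.0**3) * math.log(2 * norm.sf(2.0))
    assert expected == pytest.approx(24.72, abs=0.01)
    assert omega.omega[0] == pytest.approx(expected)
    assert omega.omega[1] == pytest.approx(-expected)  # odd symmetry
    assert omega.omega[2] == 0.0  # center of the distribution


@pytest.mark.parametrize("d", [0, 2, -1, 4])
def test_even_or_nonpositive_d_rejected(d):
    track = MScoreTrack(
        ncl=1,
        contig=np.array(["c1", "c1"], dtype=object),
        start_index=np.arange(1, 3),
        M=np.array([1.0, -1.0]),
        mean=0.0,
        sd=1.0,
    )
    with pytest.raises(InputError):
        omega_scores(track, d=d)


@pytest.mark.parametrize("d", [1, 3, 5])
@pytest.mark.parametrize("tail", ["parametric", "empirical"])
def test_omega_sign_matches_z(d, tail):
    rng = np.random.default_rng(11)
    order = make_order(80)
    z = rng.normal(size=80)
    track = m_scores(z, order, 4)
    omega = omega_scores(track, d=d, tail=tail)
    # omega is exactly 0 where P = 1 (the empirical tail assigns P = 1
    # to the least extreme window); elsewhere the signs must agree
    nz = omega.omega != 0
    assert np.all(np.sign(omega.omega[nz]) == np.sign(omega.z_m[nz]))
    assert np.all(np.abs(omega.omega[~nz]) == 0)


@pytest.mark.parametrize("d", [1, 3])
def test_abs_omega_strictly_monotone_in_abs_z(d):
    """|omega| grows strictly with |Z_M| under the normal-tail P."""
    zs = np.linspace(0.1, 8.0, 120)
    p = np.maximum(2 * norm.sf(zs), 1e-300)
    omega = -(zs**d) * np.log(p)
    assert np.all(np.diff(omega) > 0)


def test_scan_track_count_and_determinism(default_sim):
    order, matrix, _ = default_sim
    pairs = enumerate_cccs(matrix.conditions)
    assert len(pairs) == 6  # C(4,2)
    t1 = scan(matrix, order, pairs, [9, 10, 11])
    t2 = scan(matrix, order, pairs, [9, 10, 11])
    assert len(t1) == 18
    for key in t1:
        np.testing.assert_array_equal(t1[key].omega, t2[key].omega)


def test_scan_oracle_equivalence_small():
    """Full-path M and omega equal an independent brute-force
    reimplementation on a random 200-gene genome."""
    config = SimulationConfig(
        n_genes=200,
        n_contigs=2,
        clusters=(),
        conditions=(("prod", 2), ("non", 2)),
        seed=5,
    )
    order, matrix, _ = simulate(config)
    pairs = enumerate_cccs(matrix.conditions)
    tracks = scan(matrix, order, pairs, [3, 6], pseudocount=1.0)
    from middascan.expression_stats import compute_m_values, zscore
    from middascan.middas_core import standardize_profile

    for pair in pairs:
        profile = compute_m_values(matrix, pair, pseudocount=1.0)
        z = standardize_profile(profile)
        for ncl in (3, 6):
            got = tracks[(pair.label, ncl)]
            M = brute_force_m(z, order, ncl)
            np.testing.assert_allclose(got.M, M, atol=1e-9)
            np.testing.assert_allclose(got.omega, brute_force_omega(M, 3), atol=1e-9)


def test_ncl1_d1_ranking_matches_abs_z():
    rng = np.random.default_rng(3)
    order = make_order(150)
    z = rng.normal(size=150)
    z = (z - z.mean()) / z.std()
    omega = omega_scores(m_scores(z, order, 1), d=1)
    rho = spearmanr(np.abs(omega.omega), np.abs(omega.z_m)).statistic
    assert rho == pytest.approx(1.0)


def test_empirical_tail_probabilities_are_frequencies():
    order = make_order(40)
    z = np.random.default_rng(9).normal(size=40)
    omega = omega_scores(m_scores(z, order, 2), tail="empirical")
    n = omega.n_windows
    # each P is the exact share of windows at least as extreme
    for i in range(n):
        assert omega.p[i] == pytest.approx(
            np.mean(np.abs(omega.z_m) >= abs(omega.z_m[i]))
        )


def _toy_track(omegas, ncl, ccc="a/b"):
    n = len(omegas)
    return type(
        "T",
        (),
        {
            "ncl": ncl,
            "contig": np.array(["c1"] * n, dtype=object),
            "start_index": np.arange(1, n + 1),
            "M": np.array(omegas, dtype=float),
            "z_m": np.sign(np.array(omegas, dtype=float)),
            "p": np.full(n, 0.5),
            "omega": np.array(omegas, dtype=float),
            "d": 3,
            "ccc": ccc,
        },
    )()


def test_call_clusters_merging_rule(order10):
    """Two overlapping significant windows: one call, gene set from the
    peak window, extras listed as extension candidates."""
    omegas = [0.0, 100.0, 80.0, 0.0, 0.0, 0.0, 50.0, 0.0]
    track = _toy_track(omegas, ncl=3)
    calls = call_clusters([track], order10, threshold=40.0)
    assert len(calls) == 2
    first = calls[0]
    assert first.gene_ids == ("g0001", "g0002", "g0003")  # window at start 2
    assert first.extension_candidates == ("g0004",)  # extra gene of window 3
    assert first.peak_omega == pytest.approx(100.0)
    second = calls[1]
    assert second.gene_ids == ("g0006", "g0007", "g0008")
    assert second.extension_candidates == ()


def test_call_clusters_modes_and_errors(order10):
    track = _toy_track([0.0, -90.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0], ncl=3)
    assert call_clusters([track], order10, threshold=50.0, mode="positive") == []
    calls = call_clusters([track], order10, threshold=50.0, mode="absolute")
    assert len(calls) == 1 and calls[0].sign == -1
    with pytest.raises(InputError):
        call_clusters([track], order10, threshold=0.0)


def test_cross_ncl_merge_keeps_strongest_call(order10):
    small = _toy_track([0.0, 120.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0], ncl=3)
    big = _toy_track([0.0, 70.0, 0.0, 0.0, 0.0, 0.0], ncl=5)
    calls = call_clusters([small, big], order10, threshold=50.0)
    assert len(calls) == 1
    assert calls[0].peak_ncl == 3
    assert calls[0].peak_omega == pytest.approx(120.0)
    # genes of the absorbed ncl=5 window survive as extension candidates
    assert set(calls[0].extension_candidates) == {"g0004", "g0005"}


def test_different_cccs_never_merge(order10):
    t1 = _toy_track([0.0, 120.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0], ncl=3, ccc="a/b")
    t2 = _toy_track([0.0, 120.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0], ncl=3, ccc="a/c")
    calls = call_clusters([t1, t2], order10, threshold=50.0)
    assert len(calls) == 2
    assert {c.ccc for c in calls} == {"a/b", "a/c"}


def test_permutation_null_is_seeded_and_below_signal():
    config = SimulationConfig(n_genes=400, seed=3)
    order, matrix, truth = simulate(config)
    pair = enumerate_cccs(matrix.conditions)[0]  # prod/veg1
    q1 = permutation_null(matrix, order, pair, ncl=10, n_perm=30, seed=42)
    q2 = permutation_null(matrix, order, pair, ncl=10, n_perm=30, seed=42)
    assert q1 == q2
    tracks = scan(matrix, order, [pair], [10])
    observed = np.abs(tracks[(pair.label, 10)].omega).max()
    assert observed > q1[0.95]


def test_permutation_null_propagates_degenerate_sigma():
    import pandas as pd

    from middascan import ExpressionMatrix

    order = make_order(20)
    values = pd.DataFrame(
        {
            "p1": np.full(20, 4.0),
            "p2": np.full(20, 4.0),
            "n1": np.full(20, 2.0),
            "n2": np.full(20, 2.0),
        },
        index=pd.Index(order.gene_ids(), name="gene_id"),
    )
    sheet = pd.DataFrame(
        {
            "sample_id": ["p1", "p2", "n1", "n2"],
            "condition": ["prod", "prod", "non", "non"],
            "replicate": ["1", "2", "1", "2"],
        }
    )
    matrix = ExpressionMatrix(values, sheet)
    from middascan import ConditionPair

    with pytest.raises(DegenerateStatisticsError):
        permutation_null(matrix, order, ConditionPair("prod", "non"), ncl=3, n_perm=10, seed=1)


def test_null_window_mean_near_zero():
    """Background windows average near zero: |mean M| < 3 se."""
    config = SimulationConfig(n_genes=1000, clusters=(), seed=8)
    order, matrix, _ = simulate(config)
    pair = enumerate_cccs(matrix.conditions)[0]
    tracks = scan(matrix, order, [pair], [5])
    M = tracks[(pair.label, 5)].M
    se = M.std() / math.sqrt(len(M))
    assert abs(M.mean()) < 3 * se
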