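"""Poisson exact intervals, sensitivity grids and Monte Carlo propagation."""

import math
from decimal import Decimal

import pytest

from norscba import (
    MonteCarloSpec,
    break_even_mortality,
    deaths_averted_grid,
    monte_carlo_mortality,
    poisson_exact_ci,
    two_way_sensitivity,
)
from norscba.currency import D

VOL = D("1320304.68")


# --- exact Poisson interval vs a brute-force tail-sum inversion oracle -----

def _poisson_cdf(k, mu):
    term, total = math.exp(-mu), math.exp(-mu)
    for i in range(1, k + 1):
        term *= mu / i
        total += term
    return total


def _bisect(fn, lo, hi, tol=1e-12):
    for _ in range(200):
        mid = (lo + hi) / 2
        if fn(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2


def oracle_ci(k, n, level=0.95):
    """Invert Poisson tail sums directly (no chi-square shortcut)."""
    alpha = 1 - level
    if k == 0:
        low = 0.0
    else:
        low = _bisect(lambda mu: alpha / 2 - (1 - _poisson_cdf(k - 1, mu)),
                      0, 10 * k + 50) / n
    high = _bisect(lambda mu: _poisson_cdf(k, mu) - alpha / 2,
                   0, 10 * k + 50) / n
    return low, high


@pytest.mark.parametrize("k", range(11))
@pytest.mark.parametrize("n", [23, 100])
def test_exact_interval_matches_tail_sum_oracle(k, n):
    got = poisson_exact_ci(k, n)
    want = oracle_ci(k, n)
    assert got[0] == pytest.approx(want[0], abs=1e-6)
    assert got[1] == pytest.approx(want[1], abs=1e-6)


def test_zero_count_interval():
    low, high = poisson_exact_ci(0, 23)
    assert low == 0.0
    assert high == pytest.approx(-math.log(0.025) / 23, abs=1e-9)


@pytest.mark.parametrize("k", range(1, 6))
def test_interval_covers_the_point_estimate(k):
    low, high = poisson_exact_ci(k, 100)
    assert low < k / 100 < high


def test_interval_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        poisson_exact_ci(0, 0)
    with pytest.raises(ValueError):
        poisson_exact_ci(-1, 10)
    with pytest.raises(ValueError):
        poisson_exact_ci(0, 10, level=1.0)


# --- scaling grid: deaths averted across service size and Pi ---------------

# Published grid: rows N = 10,000 .. 1,000; columns Pi = 0% .. 0.7%.
SCALING_GRID = {
    10000: [4500, 4490, 4480, 4470, 4460, 4450, 4440, 4430],
    9000: [4050, 4041, 4032, 4023, 4014, 4005, 3996, 3987],
    8000: [3600, 3592, 3584, 3576, 3568, 3560, 3552, 3544],
    7000: [3150, 3143, 3136, 3129, 3122, 3115, 3108, 3101],
    6000: [2700, 2694, 2688, 2682, 2676, 2670, 2664, 2658],
    5000: [2250, 2245, 2240, 2235, 2230, 2225, 2220, 2215],
    4000: [1800, 1796, 1792, 1788, 1784, 1780, 1776, 1772],
    3000: [1350, 1347, 1344, 1341, 1338, 1335, 1332, 1329],
    2000: [900, 898, 896, 894, 892, 890, 888, 886],
    1000: [450, 449, 448, 447, 446, 445, 444, 443],
}
PI_GRID = [D(p) / 1000 for p in range(8)]


def test_scaling_grid_reproduces_all_published_cells():
    grid = deaths_averted_grid(list(SCALING_GRID), PI_GRID, "0.45")
    for i, (n, row) in enumerate(SCALING_GRID.items()):
        assert list(grid.cells[i]) == row, f"N={n}"


def test_scaling_grid_zero_when_pi_equals_pn():
    grid = deaths_averted_grid([1000, 5000], ["0.45"], "0.45")
    assert all(cell == 0 for row in grid.cells for cell in row)


# --- two-way grid: operating-budget scale x unwitnessed mortality ----------

MULTIPLIERS = [D(m) / 100 for m in range(200, 20, -20)]
PN_VALUES = [D(x) for x in
             "0.08 0.10 0.20 0.30 0.40 0.45 0.50 0.60 0.70 0.80".split()]


@pytest.fixture(scope="module")
def two_way():
    return two_way_sensitivity(23, VOL, "1368375.00", "221726.18",
                               MULTIPLIERS, PN_VALUES)


@pytest.mark.parametrize("mult, pn, net, ratio", [
    ("2.00", "0.08", "-529115.57", "0.82"),
    ("1.00", "0.45", "12075052.26", "8.59"),
    ("1.00", "0.08", "839259.43", "1.53"),
    ("1.00", "0.80", "22703504.93", "15.28"),
    ("1.00", "0.10", "1446599.58", "1.91"),
])
def test_two_way_grid_reproduces_published_cells(two_way, mult, pn, net, ratio):
    cell = two_way.cell(D(mult), D(pn))
    assert cell == (Decimal(net), Decimal(ratio))


def test_two_way_grid_monotone_in_both_axes(two_way):
    nets = [[cell[0] for cell in row] for row in two_way.cells]
    for row in nets:  # increasing in pn across columns
        assert all(a < b for a, b in zip(row, row[1:]))
    for col in zip(*nets):  # rows ordered by decreasing multiplier
        assert all(a < b for a, b in zip(col, col[1:]))


def test_two_way_breakeven_cell_has_unit_ratio():
    total = D("1590101.18")
    pn = break_even_mortality(total, 23, VOL)
    grid = two_way_sensitivity(23, VOL, "1368375.00", "221726.18", ["1"], [pn])
    net, ratio = grid.cells[0][0]
    assert abs(net) <= D("0.01")
    assert ratio == D("1.00")


# --- Monte Carlo over the unwitnessed-overdose mortality -------------------

def test_fixed_scenario_reproduces_point_estimate():
    mc = monte_carlo_mortality(MonteCarloSpec("fixed", low=0.45, n_draws=1000,
                                              seed=7), 66, VOL)
    assert mc.mean_deaths_averted == pytest.approx(29.7)
    assert round(mc.mean_deaths_averted) == 30
    assert mc.mean_pn == pytest.approx(0.45)


def test_uniform_mean_matches_analytic_value():
    spec = MonteCarloSpec("uniform", 0.08, 0.80, n_draws=100_000, seed=11)
    mc = monte_carlo_mortality(spec, 23, VOL)
    se = (0.80 - 0.08) / math.sqrt(12) / math.sqrt(spec.n_draws)
    assert abs(mc.mean_pn - 0.44) < 3 * se


def test_degenerate_uniform_is_constant():
    mc = monte_carlo_mortality(MonteCarloSpec("uniform", 0.3, 0.3,
                                              n_draws=100, seed=0), 10, VOL)
    assert mc.pn_interval == (pytest.approx(0.3), pytest.approx(0.3))


def test_monte_carlo_seed_reproducibility():
    spec = MonteCarloSpec("uniform", 0.08, 0.80, n_draws=20_000, seed=42)
    a = monte_carlo_mortality(spec, 23, VOL)
    b = monte_carlo_mortality(spec, 23, VOL)
    assert a == b
    means = [monte_carlo_mortality(
        MonteCarloSpec("uniform", 0.08, 0.80, n_draws=20_000, seed=s),
        23, VOL).mean_pn for s in range(5)]
    se = (0.80 - 0.08) / math.sqrt(12) / math.sqrt(20_000)
    assert all(abs(m - 0.44) < 3 * se for m in means)


def test_spec_validation():
    with pytest.raises(ValueError):
        MonteCarloSpec("uniform", 0.8, 0.1)
    with pytest.raises(ValueError):
        MonteCarloSpec("gamma")
    with pytest.raises(ValueError):
        MonteCarloSpec(n_draws=0)


# --- break-even mortality ---------------------------------------------------

def test_break_even_mortality():
    pn = break_even_mortality("1590101.18", 23, VOL)
    assert float(pn) == pytest.approx(0.05236, abs=1e-5)
    assert pn > D("0.05")
    assert break_even_mortality(0, 23, VOL) == 0
    with pytest.raises(ValueError):
        break_even_mortality(100, 0, VOL)
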