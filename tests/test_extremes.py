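import math

import mpmath
import numpy as np
import pytest

from mutload import (
    extreme_multiplier,
    fittest_likely,
    format_table1,
    idealized_max,
    idealized_z_score,
    load_metrics,
    make_parameters,
    table1_grid,
)
from mutload.parameters import ParameterError

# Published reference grid: fittest-likely fitness exp(5*sqrt(nus)) by
# (s, f), with the idealized exp(2nu) bottom row.  The f=0.10 idealized
# cell is the computed e^3.2 = 24.53; the source table prints 24.45,
# which does not match the stated formula (documented discrepancy).
REFERENCE_GRID = {
    1e-4: [1.03, 1.05, 1.07, 1.11, 1.15, 1.22],
    1e-3: [1.09, 1.15, 1.22, 1.37, 1.56, 1.88],
    1e-2: [1.33, 1.56, 1.88, 2.72, 4.11, 7.39],
    "All sites AA": [1.90, 4.95, 24.53, 3.0e3, 8.9e6, 7.9e13],
}
F_VALUES = (0.02, 0.05, 0.10, 0.25, 0.50, 1.0)


class TestFittestLikely:
    def test_running_example(self, params_f005):
        ext = fittest_likely(params_f005, c=5.0)
        assert ext.w_max_likely == pytest.approx(1.56, abs=0.005)
        assert ext.m_or_k == pytest.approx(4 * params_f005.nu / params_f005.s)
        assert ext.r == pytest.approx(5 * math.sqrt(ext.m_or_k))

    def test_quarter_genome(self, params_f025):
        # nus = 0.04, exp(5*0.2) = e
        assert fittest_likely(params_f025).w_max_likely == pytest.approx(
            math.e, rel=1e-12
        )

    def test_exact_form_close_to_asymptotic(self):
        # The exponential form drops terms of relative size ~ r*s (from
        # log(1-s/2) vs -s/2), so agreement tightens as s shrinks.  At the
        # canonical working point (f=0.05, s=0.01) the forms agree to 1%;
        # the gap only widens appreciably for s=0.01 with f >= 0.25.
        for f in F_VALUES:
            for s in (1e-4, 1e-3):
                ext = fittest_likely(make_parameters(f=f, s=s))
                assert ext.w_max_likely_exact == pytest.approx(
                    ext.w_max_likely, rel=1e-2
                )
        ext = fittest_likely(make_parameters(f=0.05, s=1e-2))
        assert ext.w_max_likely_exact == pytest.approx(ext.w_max_likely, rel=1e-2)
        # large-nus corner: the asymptote overestimates by several percent
        ext = fittest_likely(make_parameters(f=1.0, s=1e-2))
        assert ext.w_max_likely_exact == pytest.approx(ext.w_max_likely, rel=0.10)
        assert ext.w_max_likely_exact < ext.w_max_likely

    def test_additive_recessive_asymptotics_identical(self, params_f005):
        add = fittest_likely(params_f005).w_max_likely
        rec = fittest_likely(params_f005.with_(scheme="recessive")).w_max_likely
        assert rec == pytest.approx(add, rel=1e-15)

    def test_no_load_limit(self):
        ext = fittest_likely(make_parameters(u=0.0))
        assert ext.w_max_likely == 1.0
        assert ext.w_max_likely_exact == 1.0

    def test_ideal_dominates_likely(self):
        for f in (0.05, 0.25, 1.0):
            for s in (1e-4, 1e-2):
                ext = fittest_likely(make_parameters(f=f, s=s))
                assert ext.w_max_ideal >= ext.w_max_likely >= 1.0

    @pytest.mark.parametrize("field", ["f", "u", "s"])
    def test_monotone_increasing(self, field):
        p = make_parameters(f=0.1, s=1e-3)
        lo = fittest_likely(p).w_max_likely
        hi = fittest_likely(p.with_(**{field: getattr(p, field) * 2})).w_max_likely
        assert hi > lo
        assert fittest_likely(p, c=6.0).w_max_likely > lo


class TestIdealizedMax:
    def test_additive_headline(self, params_f005):
        im = idealized_max(params_f005)
        assert im.exact == pytest.approx(4.95, abs=0.005)
        assert im.asymptotic == pytest.approx(math.exp(1.6), rel=1e-6)

    def test_recessive_headline(self, params_f005_recessive):
        im = idealized_max(params_f005_recessive)
        assert im.exact == pytest.approx(math.exp(0.8), rel=1e-3)
        assert im.exact == pytest.approx(2.23, abs=0.005)

    def test_haploid_convention_comparison(self):
        # smaller genome estimate used in the fertility-limit comparison
        p = make_parameters(f=0.10, g=6.114e9)
        assert round(idealized_max(p).asymptotic) == 21
        assert round(idealized_max(p.with_(f=0.20)).asymptotic) == 452


class TestZScore:
    def test_additive(self, params_f005):
        assert idealized_z_score(params_f005) == pytest.approx(44, abs=0.5)

    def test_recessive(self, params_f005_recessive):
        assert idealized_z_score(params_f005_recessive) == pytest.approx(14, abs=0.5)

    def test_undefined_without_mutation(self):
        with pytest.raises(ParameterError):
            idealized_z_score(make_parameters(u=0.0))


class TestLoadMetrics:
    def test_crow_load_vs_ideal(self, params_f005):
        m = load_metrics(params_f005, which="ideal")
        assert m.L_crow == pytest.approx(1 - 1 / 4.95, abs=1e-3)
        assert m.ratio == pytest.approx(1 / (1 - m.L_crow))

    def test_crow_load_vs_likely(self, params_f005):
        m = load_metrics(params_f005, which="likely")
        assert m.L_crow == pytest.approx(1 - 1 / 1.56, abs=0.005)

    def test_haldane_load(self, params_f005):
        m = load_metrics(params_f005)
        assert m.L_haldane == pytest.approx(1 - math.exp(-1.6), rel=1e-9)

    def test_no_mutation(self):
        m = load_metrics(make_parameters(u=0.0))
        assert m.L_crow == 0.0 and m.L_haldane == 0.0 and m.ratio == 1.0


class TestTable1:
    def test_reproduces_reference_values(self):
        grid = table1_grid()
        for s, expected_row in REFERENCE_GRID.items():
            row = grid.loc[s]
            for f, expected in zip(F_VALUES, expected_row):
                rel = 0.01 if expected > 100 else 0.005 / expected
                assert row[f] == pytest.approx(expected, rel=rel), (s, f)

    def test_monotone_left_to_right_and_top_to_bottom(self):
        grid = table1_grid()
        values = grid.to_numpy()
        assert (np.diff(values, axis=1) > 0).all()
        assert (np.diff(values, axis=0) > 0).all()

    def test_formatting(self):
        formatted = format_table1(table1_grid())
        assert formatted.loc[1e-3].tolist() == [
            "1.09", "1.15", "1.22", "1.37", "1.56", "1.88",
        ]
        assert formatted.loc["All sites AA", 0.25] == "3.0e3"

    def test_single_cell(self):
        grid = table1_grid(f_values=[1.0], s_values=[0.01])
        assert grid.loc[0.01, 1.0] == pytest.approx(7.39, abs=0.005)

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            table1_grid(f_values=[], s_values=[0.01])


class TestExtremeMultiplier:
    def test_paper_constant(self):
        assert extreme_multiplier(1e9) == 5.0

    def test_median_at_n_two(self):
        assert extreme_multiplier(2, mode="quantile") == pytest.approx(0.0, abs=1e-12)

    def test_quantile_against_high_precision_oracle(self):
        # independent evaluation: Phi^-1(1 - 1e-9) via mpmath erfinv at 50 dp
        with mpmath.workdps(50):
            expected = float(mpmath.sqrt(2) * mpmath.erfinv(1 - mpmath.mpf(2) / 10**9))
        assert extreme_multiplier(1e9, mode="quantile") == pytest.approx(
            expected, rel=1e-9
        )

    def test_tiny_population_rejected(self):
        with pytest.raises(ParameterError):
            extreme_multiplier(1)
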