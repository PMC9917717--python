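"""Condition contrasts, Storey q-values, representative-band selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hypercoh import pipeline, simulate
from hypercoh.errors import ParameterError
from hypercoh.groupstats import (condition_contrast, glm_candidates,
                                 select_representative, storey_fdr)


def storey_bruteforce(p, lam=0.5):
    """Direct transcription of the pFDR estimator: pi0 from the tail beyond
    lambda, then the step-up minimum of pi0*m*p/rank over the sorted family.
    Deliberately loop-based and independent of the vectorized implementation."""
    m = len(p)
    pi0 = sum(1 for v in p if v > lam) / (m * (1.0 - lam))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pi0 * m * p[i] / rank)
        q[i] = min(running, 1.0)
    return pi0, q


class TestConditionContrast:
    def test_identical_conditions_are_exact_null(self):
        vals = np.random.default_rng(0).random((5, 4))
        res = condition_contrast(vals, vals.copy())
        assert np.allclose(res.t, 0.0) and np.allclose(res.p, 1.0)

    def test_matches_scipy_paired_t(self, rng):
        coop = rng.random((5, 3)) + 0.1
        ind = rng.random((5, 3))
        res = condition_contrast(coop, ind, paired=True)
        for c in range(3):
            ref = stats.ttest_rel(coop[:, c], ind[:, c])
            assert res.t[c] == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p[c] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_unpaired_matches_scipy(self, rng):
        coop = rng.random((6, 2))
        ind = rng.random((6, 2))
        res = condition_contrast(coop, ind, paired=False)
        ref = stats.ttest_ind(coop[:, 0], ind[:, 0])
        assert res.t[0] == pytest.approx(ref.statistic, rel=1e-10)

    def test_missing_dyads_dropped_per_cell(self, rng):
        coop = rng.random((5, 2))
        ind = rng.random((5, 2))
        coop[0, 0] = np.nan
        ind[1, 0] = np.nan
        res = condition_contrast(coop, ind)
        assert res.n_dyads[0] == 3 and res.n_dyads[1] == 5
        ref = stats.ttest_rel(coop[2:, 0], ind[2:, 0])
        assert res.t[0] == pytest.approx(ref.statistic, rel=1e-10)

    def test_too_few_dyads_flagged_untested(self, rng):
        coop = rng.random((2, 1))
        ind = rng.random((2, 1))
        res = condition_contrast(coop, ind)
        assert not res.tested[0] and np.isnan(res.t[0])


class TestStoreyFdr:
    def test_all_ones_saturated_null(self):
        res = storey_fdr(np.ones(100))
        assert res.pi0 == 1.0
        assert np.allclose(res.q, 1.0)

    def test_matches_bruteforce_on_random_inputs(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            p = rng.random(300)
            res = storey_fdr(p)
            pi0_bf, q_bf = storey_bruteforce(p.tolist())
            assert res.pi0 == pytest.approx(pi0_bf, abs=1e-14)
            assert np.abs(res.q - np.array(q_bf)).max() < 1e-12

    def test_spiked_family_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([np.full(10, 0.001), rng.random(990)])
        res = storey_fdr(p)
        _, q_bf = storey_bruteforce(p.tolist())
        assert np.abs(res.q[:10] - np.array(q_bf)[:10]).max() < 1e-12
        assert (res.q[:10] < 0.2).all()

    def test_uniform_null_yields_no_discoveries(self):
        p = np.random.default_rng(0).random(10_000)
        assert (storey_fdr(p).q < 0.05).sum() == 0

    def test_q_monotone_in_p(self, rng):
        p = rng.random(500)
        q = storey_fdr(p).q
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_permutation_equivariance(self, rng):
        p = rng.random(200)
        perm = rng.permutation(200)
        q = storey_fdr(p).q
        q_perm = storey_fdr(p[perm]).q
        assert np.allclose(q_perm, q[perm], atol=1e-15)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ParameterError):
            storey_fdr(np.array([]))
        with pytest.raises(ParameterError):
            storey_fdr(np.array([0.5, 1.2]))


def _cells(p_by_band, freq=None):
    rows = []
    for (ch_a, ch_b), pvals in p_by_band.items():
        for band, p in enumerate(pvals):
            rows.append({"ch_a": ch_a, "ch_b": ch_b, "band_index": band,
                         "freq_hz": (freq or [0.05] * len(pvals))[band],
                         "n_dyads": 10, "t": 2.0, "p": p, "tested": True,
                         "direction": "COOP>IND", "q": p})
    return pd.DataFrame(rows)


class TestRepresentativeSelection:
    def test_smallest_p_selected(self):
        cells = _cells({(1, 2): [0.5, 0.01, 0.3]})
        rep = select_representative(cells)
        assert len(rep) == 1 and rep.iloc[0]["band_index"] == 1

    def test_tie_broken_toward_lower_band(self):
        cells = _cells({(1, 2): [0.01, 0.01]})
        rep = select_representative(cells)
        assert rep.iloc[0]["band_index"] == 0

    def test_untested_pairs_excluded(self):
        cells = _cells({(1, 2): [0.5], (2, 3): [0.1]})
        cells.loc[cells["ch_a"] == 2, "tested"] = False
        rep = select_representative(cells)
        assert set(zip(rep["ch_a"], rep["ch_b"])) == {(1, 2)}


class TestGlmCandidates:
    def test_empty_when_nothing_below_threshold(self):
        cells = _cells({(1, 2): [0.5, 0.01]})
        assert glm_candidates(cells, p_threshold=1e-3).empty

    def test_frequency_window_enforced(self):
        cells = _cells({(1, 2): [1e-6, 1e-6]}, freq=[0.05, 0.2])
        out = glm_candidates(cells)
        assert len(out) == 1 and out.iloc[0]["freq_hz"] == 0.05

    def test_direction_enforced(self):
        cells = _cells({(1, 2): [1e-6]})
        cells["direction"] = "COOP<IND"
        assert glm_candidates(cells).empty

    def test_one_representative_per_pair(self):
        cells = _cells({(1, 2): [1e-6, 1e-5], (1, 3): [1e-4]})
        out = glm_candidates(cells)
        assert len(out) == 2
        sel = out[(out["ch_a"] == 1) & (out["ch_b"] == 2)]
        assert sel.iloc[0]["band_index"] == 0


class TestSimulationPower:
    def test_coupled_cell_is_family_minimum(self):
        """Coupling present only in the cooperative condition drives that
        cell's p to the family minimum (within the injected band's octave)."""
        hits = 0
        n_runs = 6
        for seed in range(n_runs):
            params = simulate.SimParams(
                n_channels=2, duration=300.0,
                coupling_pairs=(simulate.CouplingPair(1, 2, 0.09, 2.0),),
                event_spec=simulate.EventSpec(lock_mode="always"), seed=seed)
            recs = simulate.simulate_experiment(8, params, couple_in="COOP")
            res = pipeline.analyze_recordings(recs)
            bbs = res.bbs_cells[res.bbs_cells["tested"]]
            best = bbs.loc[bbs["p"].idxmin()]
            k = res.grid.nearest_band(0.09)
            if (best["ch_a"], best["ch_b"]) == (1, 2) and abs(best["band_index"] - k) <= 2:
                hits += 1
        assert hits >= n_runs - 1
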